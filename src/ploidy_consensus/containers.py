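"""Core in-memory containers shared by every pipeline stage.

Expression matrices live in a :class:`pandas.DataFrame` (genes x samples),
interaction networks in a :class:`networkx.Graph`; the dataclasses here add
the domain metadata (group labels, platform kind, species) and enforce the
invariants the downstream statistics rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError

DIPLOID = "diploid"
POLYPLOID = "polyploid"
GROUP_LABELS = (DIPLOID, POLYPLOID)

PLATFORM_COUNTS = "counts"
PLATFORM_INTENSITY = "intensity"
PLATFORM_KINDS = (PLATFORM_COUNTS, PLATFORM_INTENSITY)


@dataclass
class ExpressionDataset:
    """One cohort: genes x samples matrix plus ploidy group labels.

    Parameters
    ----------
    name
        Cohort label used in reports and file names.
    matrix
        Genes x samples values; index = gene ids, columns = sample ids.
        Raw counts for ``platform='counts'``, (log-)intensities otherwise.
    sample_groups
        Mapping sample id -> group label in ``{'diploid', 'polyploid'}``.
    platform
        ``'counts'`` or ``'intensity'``; decides the normalization path.
    species
        Free-text species label (e.g. ``'human'``, ``'mouse'``); gene ids of
        non-target species are resolvable only through an ortholog map.
    """

    name: str
    matrix: pd.DataFrame
    sample_groups: dict[str, str]
    platform: str
    species: str = "human"

    def __post_init__(self) -> None:
        idx = self.matrix.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(
                f"dataset {self.name!r}: duplicate gene id(s): {dupes[:5]}"
            )
        if self.platform not in PLATFORM_KINDS:
            raise ValidationError(
                f"dataset {self.name!r}: platform must be one of {PLATFORM_KINDS}, "
                f"got {self.platform!r}"
            )
        missing = [s for s in self.matrix.columns if s not in self.sample_groups]
        if missing:
            raise ValidationError(
                f"dataset {self.name!r}: samples missing a group label: {missing}"
            )
        bad_labels = {
            g for g in self.sample_groups.values() if g not in GROUP_LABELS
        }
        if bad_labels:
            raise ValidationError(
                f"dataset {self.name!r}: unknown group label(s) {sorted(bad_labels)}; "
                f"expected one of {GROUP_LABELS}"
            )
        values = self.matrix.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError(
                f"dataset {self.name!r}: matrix contains non-finite values"
            )
        if self.platform == PLATFORM_COUNTS and (values < 0).any():
            raise ValidationError(
                f"dataset {self.name!r}: counts platform with negative values"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    def group_columns(self, group: str) -> list[str]:
        """Sample ids (in matrix column order) belonging to ``group``."""
        return [s for s in self.matrix.columns if self.sample_groups[s] == group]


@dataclass
class SignatureCollection:
    """Named gene sets with optional per-set description (GMT semantics)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"signature {name!r} has no members")
            self.sets[name] = frozenset(members)
        self.descriptions = {
            name: self.descriptions.get(name, "") for name in self.sets
        }

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignatureCollection):
            return NotImplemented
        return self.sets == other.sets and self.descriptions == other.descriptions


@dataclass
class OrthologMap:
    """Unique (species-A gene, species-B gene) pairs.

    ``one_to_one()`` restricts to pairs where both partners occur exactly
    once, which is what the expression-mapping step consumes.
    """

    pairs: list[tuple[str, str]]
    species_a: str = "human"
    species_b: str = "mouse"

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValidationError("ortholog map contains duplicate pairs")

    def one_to_one(self) -> dict[str, str]:
        """Mapping species-B id -> species-A id, 1:1 pairs only."""
        from collections import Counter

        count_a = Counter(a for a, _ in self.pairs)
        count_b = Counter(b for _, b in self.pairs)
        return {
            b: a
            for a, b in self.pairs
            if count_a[a] == 1 and count_b[b] == 1
        }


def validate_network(graph: nx.Graph) -> nx.Graph:
    """Check the simple-undirected-graph invariants (no self-loops)."""
    if graph.is_directed() or graph.is_multigraph():
        raise ValidationError("interaction network must be a simple undirected graph")
    loops = list(nx.nodes_with_selfloops(graph))
    if loops:
        raise ValidationError(f"interaction network has self-loops at {loops[:5]}")
    return graph
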