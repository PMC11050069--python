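"""Sign-consistent consensus calls across independent cohorts.

A gene is a consensus gene only if it was testable in every cohort (the
shared universe is the intersection of tested gene sets) and was called a
significant DEG in the same direction in every single cohort. Cohorts are
independent experiments, so consistency across all of them multiplies the
individual false-positive probabilities and the intersection acts as a
stringent meta-analysis without combining p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .diffexp import DIRECTION_DOWN, DIRECTION_NONE, DIRECTION_UP
from .errors import ValidationError


@dataclass
class ConsensusSet:
    """Genes consistently up (or down) across all cohorts."""

    up: frozenset[str]
    down: frozenset[str]
    n_cohorts: int
    matrix: pd.DataFrame  # genes x cohorts, entries in {up, down, none}

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValidationError("consensus up and down sets overlap")


def build_direction_matrix(
    per_cohort_results: list[pd.DataFrame],
    cohort_names: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the genes x cohorts direction matrix.

    Every result table must already be in the shared gene namespace (mouse
    cohorts mapped through :func:`~ploidy_consensus.io_formats.apply_orthologs`
    beforehand). Rows exist only for genes tested in every cohort; a gene
    missing from any one cohort cannot be consistently regulated in all
    comparisons and is excluded.
    """
    if not per_cohort_results:
        raise ValidationError("no cohort results supplied")
    if cohort_names is None:
        cohort_names = [f"cohort_{i + 1}" for i in range(len(per_cohort_results))]
    if len(cohort_names) != len(per_cohort_results):
        raise ValidationError("cohort_names length mismatch")
    universes = [set(res["gene_id"]) for res in per_cohort_results]
    universe = set.intersection(*universes)
    if not universe:
        raise ValidationError(
            "no gene is testable in all cohorts; check ortholog coverage and "
            "that all cohorts share the target-species gene namespace"
        )
    genes = sorted(universe)
    columns = {}
    for name, res in zip(cohort_names, per_cohort_results):
        directions = res.set_index("gene_id")["direction"]
        columns[name] = directions.reindex(genes).fillna(DIRECTION_NONE)
    return pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))


def call_consensus(matrix: pd.DataFrame) -> ConsensusSet:
    """Extract the all-up and all-down rows of a direction matrix."""
    if matrix.shape[1] == 0:
        raise ValidationError("direction matrix has no cohorts")
    up = frozenset(matrix.index[(matrix == DIRECTION_UP).all(axis=1)])
    down = frozenset(matrix.index[(matrix == DIRECTION_DOWN).all(axis=1)])
    return ConsensusSet(
        up=up, down=down, n_cohorts=matrix.shape[1], matrix=matrix
    )


def consensus_from_results(
    per_cohort_results: list[pd.DataFrame],
    cohort_names: list[str] | None = None,
) -> ConsensusSet:
    """Convenience wrapper: direction matrix + consensus call in one step."""
    return call_consensus(build_direction_matrix(per_cohort_results, cohort_names))
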