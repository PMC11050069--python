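"""Readers and writers for the plain-text formats the pipeline exchanges.

All tables are tab-separated UTF-8 with a header row and no quoting.
Expression matrices carry the gene identifier in a first column named
``gene_id``; gene identifiers are case-sensitive and preserved verbatim.
Signature collections use the GMT convention (one set per line:
name, description, then members). All readers validate and raise
:class:`~ploidy_consensus.errors.FormatError` on malformed input.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import (
    ExpressionDataset,
    OrthologMap,
    SignatureCollection,
    validate_network,
)
from .errors import FormatError

logger = logging.getLogger(__name__)

GENE_COLUMN = "gene_id"


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    metadata_path: str | Path,
    platform: str,
    species: str = "human",
    name: str | None = None,
) -> ExpressionDataset:
    """Read an expression TSV plus its sample-metadata TSV.

    The expression file has columns ``gene_id, <sample>, <sample>, ...``;
    the metadata file has columns ``sample, group`` with group in
    ``{diploid, polyploid}``. Sample order follows the expression header.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={0: str})
    if table.columns[0] != GENE_COLUMN:
        raise FormatError(
            f"{path}: first column must be {GENE_COLUMN!r}, got {table.columns[0]!r}"
        )
    dupes = table[GENE_COLUMN][table[GENE_COLUMN].duplicated()].unique().tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate gene id(s): {dupes[:5]}")
    matrix = table.set_index(GENE_COLUMN)
    try:
        matrix = matrix.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in meta.columns:
            raise FormatError(f"{metadata_path}: missing column {col!r}")
    groups = dict(zip(meta["sample"], meta["group"]))
    unlabelled = [s for s in matrix.columns if s not in groups]
    if unlabelled:
        raise FormatError(
            f"{path}: sample(s) absent from metadata: {unlabelled}"
        )
    try:
        return ExpressionDataset(
            name=name or path.stem,
            matrix=matrix,
            sample_groups={s: groups[s] for s in matrix.columns},
            platform=platform,
            species=species,
        )
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    out = dataset.matrix.copy()
    out.index.name = GENE_COLUMN
    out.to_csv(path, sep="\t")


def write_sample_metadata(dataset: ExpressionDataset, path: str | Path) -> None:
    meta = pd.DataFrame(
        {
            "sample": list(dataset.matrix.columns),
            "group": [dataset.sample_groups[s] for s in dataset.matrix.columns],
        }
    )
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT signature collections
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> SignatureCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: signature {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate signature {name!r}")
            sets[name] = frozenset(members)
            descriptions[name] = description
    return SignatureCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: SignatureCollection, path: str | Path) -> None:
    """Emit GMT with members sorted for byte-stable output."""
    with open(path, "w", encoding="utf-8") as handle:
        for name in sorted(collection.sets):
            members = sorted(collection.sets[name])
            desc = collection.descriptions.get(name, "")
            handle.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# interaction networks
# ---------------------------------------------------------------------------

def read_edge_list(
    path: str | Path, min_score: float | None = None
) -> nx.Graph:
    """Read an undirected edge list TSV into a simple graph.

    Columns: ``gene_a, gene_b`` with an optional third ``score`` column.
    When ``min_score`` is given only edges with score strictly greater
    than the threshold are kept (the STRING-style ``score > cutoff``
    convention). Duplicate rows collapse to one edge; self-loop rows are
    dropped with a warning.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if table.shape[1] < 2:
        raise FormatError(f"{path}: edge list needs at least two columns")
    has_score = table.shape[1] >= 3
    graph = nx.Graph()
    n_loops = 0
    for row in table.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        if a == b:
            n_loops += 1
            continue
        if has_score:
            score = float(row[2])
            if min_score is not None and not score > min_score:
                continue
            graph.add_edge(a, b, score=score)
        else:
            graph.add_edge(a, b)
    if n_loops:
        logger.warning("%s: dropped %d self-loop row(s)", path, n_loops)
    return validate_network(graph)


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    rows = sorted((min(a, b), max(a, b)) for a, b in graph.edges())
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("gene_a\tgene_b\n")
        for a, b in rows:
            handle.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# ortholog maps and plain gene lists
# ---------------------------------------------------------------------------

def read_orthologs(
    path: str | Path, species_a: str = "human", species_b: str = "mouse"
) -> OrthologMap:
    """Read a two-column TSV of (species-A gene, species-B gene) pairs."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise FormatError(f"{path}: ortholog table needs two columns")
    pairs = list(dict.fromkeys(zip(table.iloc[:, 0], table.iloc[:, 1])))
    return OrthologMap(pairs=pairs, species_a=species_a, species_b=species_b)


def write_orthologs(ortholog_map: OrthologMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"{ortholog_map.species_a}\t{ortholog_map.species_b}\n")
        for a, b in ortholog_map.pairs:
            handle.write(f"{a}\t{b}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line (a leading ``gene_id`` header line is allowed)."""
    with open(path, encoding="utf-8") as handle:
        genes = [line.strip() for line in handle if line.strip()]
    if genes and genes[0] == GENE_COLUMN:
        genes = genes[1:]
    if len(set(genes)) != len(genes):
        raise FormatError(f"{path}: duplicate entries in gene list")
    return genes


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(GENE_COLUMN + "\n")
        for gene in sorted(genes):
            handle.write(str(gene) + "\n")


# ---------------------------------------------------------------------------
# ortholog translation of expression datasets
# ---------------------------------------------------------------------------

def apply_orthologs(
    dataset: ExpressionDataset,
    ortholog_map: OrthologMap,
    target_species: str | None = None,
) -> ExpressionDataset:
    """Translate gene ids into the target-species namespace.

    Only genes with a strict 1:1 ortholog pair are kept; genes mapping to
    several targets (or sharing a target with another source gene) are
    dropped, so the translated ids are unique by construction and the
    cross-cohort intersection stays well defined.
    """
    target_species = target_species or ortholog_map.species_a
    if dataset.species == target_species:
        return dataset
    if target_species == ortholog_map.species_a:
        translation = ortholog_map.one_to_one()
    elif target_species == ortholog_map.species_b:
        translation = {a: b for b, a in ortholog_map.one_to_one().items()}
    else:
        raise FormatError(
            f"target species {target_species!r} not in ortholog map "
            f"({ortholog_map.species_a!r}, {ortholog_map.species_b!r})"
        )
    keep = [g for g in dataset.matrix.index if g in translation]
    if not keep:
        logger.warning(
            "dataset %s: no gene has a 1:1 ortholog; result is empty", dataset.name
        )
    matrix = dataset.matrix.loc[keep].rename(index=translation)
    return ExpressionDataset(
        name=dataset.name,
        matrix=matrix,
        sample_groups=dict(dataset.sample_groups),
        platform=dataset.platform,
        species=target_species,
    )
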