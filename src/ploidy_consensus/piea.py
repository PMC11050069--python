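"""Protein-interaction enrichment analysis (PIEA): master-regulator calls.

Each sufficiently connected gene is treated like a gene signature whose
members are its one-step interactome neighbors. If that neighborhood is
over-represented in a DEG set (hypergeometric upper tail over a shared
background universe, BH-corrected across all tested genes), the focal gene
is a candidate master regulator — a hub whose interactome moves with
ploidy. Master-regulator status additionally requires the hub itself to be
a member of the consensus set, i.e. to show the consistent ploidy-dependent
expression it is supposed to drive.

Only genes with strictly more than ``min_degree`` interactants (default 5)
are tested; smaller neighborhoods carry too little signal for the
hypergeometric test to be meaningful.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .consensus import ConsensusSet
from .diffexp import benjamini_hochberg
from .enrichment import hypergeom_upper_tail
from .errors import ValidationError

PIEA_COLUMNS = ["gene_id", "K_nb", "k_nb", "n_set", "N_bg", "p", "fdr"]


def neighborhood(network: nx.Graph, gene: str) -> set[str]:
    """One-step neighbors of ``gene``, excluding the gene itself."""
    if gene not in network:
        return set()
    return set(network.neighbors(gene)) - {gene}


def piea_scan(
    network: nx.Graph,
    deg_set: set[str],
    background: set[str],
    min_degree: int = 5,
) -> pd.DataFrame:
    """Score every hub gene's neighborhood against ``deg_set``.

    Neighborhoods and the DEG set are both restricted to ``background``
    before counting, so the test's sampling universe is coherent; network
    nodes outside the background are ignored entirely. Candidates are
    genes with more than ``min_degree`` in-background interactants
    (strict). Returns a table sorted by p ascending with BH FDR across all
    candidates.
    """
    deg_set = set(deg_set)
    background = set(background)
    offenders = deg_set - background
    if offenders:
        raise ValidationError(
            f"DEG set genes outside the background: {sorted(offenders)[:10]}"
        )
    N_bg = len(background)
    n_set = len(deg_set)
    rows = []
    for gene in sorted(background & set(network.nodes)):
        nbhd = neighborhood(network, gene) & background
        K_nb = len(nbhd)
        if K_nb <= min_degree:
            continue
        k_nb = len(nbhd & deg_set)
        p = hypergeom_upper_tail(N_bg, K_nb, n_set, k_nb)
        rows.append(
            {
                "gene_id": gene,
                "K_nb": K_nb,
                "k_nb": k_nb,
                "n_set": n_set,
                "N_bg": N_bg,
                "p": p,
            }
        )
    table = pd.DataFrame(rows, columns=[c for c in PIEA_COLUMNS if c != "fdr"])
    if len(table):
        table["fdr"] = benjamini_hochberg(table["p"].to_numpy())
    else:
        table["fdr"] = pd.Series(dtype=float)
    return table[PIEA_COLUMNS].sort_values(
        ["p", "gene_id"], kind="stable"
    ).reset_index(drop=True)


def select_master_regulators(
    up_records: pd.DataFrame,
    down_records: pd.DataFrame,
    consensus: ConsensusSet,
    fdr_cut: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Call up/down master regulators from two directional PIEA scans.

    A gene is an up regulator when its neighborhood is enriched in the
    consensus-up set at ``fdr < fdr_cut`` AND the gene itself belongs to
    the consensus-up set (it must show the consistent expression change);
    symmetric for down. The outputs are disjoint because the consensus
    sets are.
    """
    def _select(records: pd.DataFrame, members: frozenset[str]) -> list[str]:
        if not len(records) or not members:
            return []
        hits = records[(records["fdr"] < fdr_cut)]
        return sorted(g for g in hits["gene_id"] if g in members)

    return _select(up_records, consensus.up), _select(down_records, consensus.down)
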