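"""Gene-signature over-representation with O/E ratio and BH FDR.

For a query gene set of size n drawn against a background universe of size
N, a signature occupying K background genes and overlapping the query in k
genes is scored with the upper tail of the hypergeometric distribution,
P(X >= k), the expected overlap e = n*K/N, and the observed/expected ratio
O/E = k/e. Signatures are reported when FDR < 0.01 and O/E > 1.5 (both
strict), the conventional reporting thresholds for this kind of screen;
the unfiltered table is always available for inspection.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SignatureCollection
from .diffexp import benjamini_hochberg
from .errors import DomainError, ValidationError

REPORT_COLUMNS = ["signature", "gene_number", "oe_ratio", "fdr", "member_genes"]

FULL_COLUMNS = [
    "signature",
    "k",
    "K",
    "n",
    "N",
    "expected",
    "oe_ratio",
    "p",
    "fdr",
    "member_genes",
]


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` background size, ``K`` marked genes in the background, ``n``
    query size, ``k`` observed overlap. Computed through the survival
    function of :class:`scipy.stats.hypergeom`, which works in log-space
    and stays accurate for N well above 1e5.
    """
    for label, value in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(value) != value or value < 0:
            raise DomainError(f"{label} must be a non-negative integer, got {value}")
    if K > N or n > N:
        raise DomainError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise DomainError(f"k={k} exceeds min(K, n)={min(K, n)}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: set[str],
    collection: SignatureCollection,
    background: set[str],
    fdr_cut: float = 0.01,
    oe_cut: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every signature against ``query`` over ``background``.

    Returns ``(full_table, filtered_table)``; both are sorted by FDR then
    p. The filtered table keeps rows with ``fdr < fdr_cut`` and
    ``oe_ratio > oe_cut`` (both strict). Signature members outside the
    background are ignored when sizing K, so O/E is always well defined;
    signatures with no background member are not tested.
    """
    query = set(query)
    background = set(background)
    offenders = query - background
    if offenders:
        raise ValidationError(
            f"query genes outside the background: {sorted(offenders)[:10]}"
        )
    if not background:
        raise ValidationError("empty background universe")
    N = len(background)
    n = len(query)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & background
        K = len(members)
        if K == 0:
            continue
        overlap = members & query
        k = len(overlap)
        expected = n * K / N
        oe = k / expected if expected > 0 else np.nan
        p = hypergeom_upper_tail(N, K, n, k)
        rows.append(
            {
                "signature": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "expected": expected,
                "oe_ratio": oe,
                "p": p,
                "member_genes": ",".join(sorted(overlap)),
            }
        )
    full = pd.DataFrame(rows, columns=[c for c in FULL_COLUMNS if c != "fdr"])
    if len(full):
        full["fdr"] = benjamini_hochberg(full["p"].to_numpy())
    else:
        full["fdr"] = pd.Series(dtype=float)
    full = full[FULL_COLUMNS].sort_values(
        ["fdr", "p", "signature"], kind="stable"
    ).reset_index(drop=True)
    filtered = full[(full["fdr"] < fdr_cut) & (full["oe_ratio"] > oe_cut)]
    return full, filtered.reset_index(drop=True)


def write_report(records: pd.DataFrame, path: str | Path) -> None:
    """Write the signature / gene-number / O/E / FDR report table.

    O/E is rendered to 2 decimals and FDR in scientific notation, the
    conventional presentation for these screens.
    """
    out = pd.DataFrame(
        {
            "signature": records.get("signature", pd.Series(dtype=str)),
            "gene_number": records.get("k", pd.Series(dtype=int)),
            "oe_ratio": [
                f"{v:.2f}" for v in records.get("oe_ratio", pd.Series(dtype=float))
            ],
            "fdr": [f"{v:.2e}" for v in records.get("fdr", pd.Series(dtype=float))],
            "member_genes": records.get("member_genes", pd.Series(dtype=str)),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    table = pd.read_csv(path, sep="\t", dtype={"signature": str})
    if list(table.columns) != REPORT_COLUMNS:
        raise ValidationError(
            f"{path}: expected columns {REPORT_COLUMNS}, got {list(table.columns)}"
        )
    table["oe_ratio"] = table["oe_ratio"].astype(float)
    table["fdr"] = table["fdr"].astype(float)
    return table
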