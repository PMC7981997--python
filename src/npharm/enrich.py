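"""Gene-set over-representation analysis with BH-FDR control.

Over-representation of a query gene list in annotation terms (GO
BP/CC/MF, KEGG pathways) is tested with the hypergeometric upper tail
P(X >= k) — or its conservative EASE variant P(X >= k-1), which
discounts one overlapping gene.  P-values are adjusted per category with
the Benjamini-Hochberg step-up procedure and gated at FDR < 0.01 by
default.  The rich factor k/K (overlap over term size) is reported for
bubble-chart export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CATEGORIES = ("BP", "CC", "MF", "KEGG")


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    name: str
    category: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"term {self.term_id!r} has no members")


def read_gmt(path: str | Path, category: str) -> list[AnnotationTerm]:
    """Parse a GMT file (term <TAB> description <TAB> genes...)."""
    terms = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        term_id, name, *genes = parts
        members = frozenset(g.strip().upper() for g in genes if g.strip())
        terms.append(AnnotationTerm(term_id, name, category, members))
    return terms


def write_gmt(terms: Iterable[AnnotationTerm], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.name, *sorted(t.members)]) + "\n")


def _check_hypergeom_args(N: int, K: int, n: int, k: int) -> None:
    if not 0 <= K <= N:
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"require 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: annotated genes in the universe, n: query size,
    k: observed overlap.
    """
    _check_hypergeom_args(N, K, n, k)
    # sf(k-1) = P(X >= k); scipy evaluates the tail stably in log space
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ease_p(N: int, K: int, n: int, k: int) -> float:
    """EASE score: the hypergeometric tail with one overlap gene removed.

    Equals 1 for k <= 1; always >= the plain upper tail.
    """
    _check_hypergeom_args(N, K, n, k)
    return hypergeom_upper_tail(N, K, n, max(k - 1, 0))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return np.clip(adjusted, np.finfo(float).tiny, 1.0)


def enrich(
    query: Iterable[str],
    terms: Sequence[AnnotationTerm],
    universe: Iterable[str] | None = None,
    method: str = "hypergeometric",
    fdr_gate: float = 0.01,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each annotation term.

    The universe defaults to the union of all term members.  Query genes
    outside the universe are dropped with a warning; term memberships are
    intersected with the universe and empty terms skipped.  BH adjustment
    is applied within each category separately.  Rows are sorted by FDR
    ascending, then rich factor descending, then term id.
    """
    if method not in ("hypergeometric", "ease"):
        raise ValueError(f"unknown method {method!r}")
    tail = hypergeom_upper_tail if method == "hypergeometric" else ease_p

    if universe is None:
        universe_set: set[str] = set()
        for t in terms:
            universe_set |= t.members
    else:
        universe_set = {str(g).strip().upper() for g in universe}
    if not universe_set:
        raise ValueError("empty universe")

    query_set = {str(g).strip().upper() for g in query}
    if not query_set:
        raise ValueError("empty query gene set")
    outside = query_set - universe_set
    if outside:
        logger.warning(
            "%d query gene(s) outside the universe dropped", len(outside)
        )
        query_set &= universe_set
    if not query_set:
        raise ValueError("no query genes remain inside the universe")

    N, n = len(universe_set), len(query_set)
    rows = []
    for t in terms:
        members = t.members & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & query_set)
        rows.append(
            {
                "term_id": t.term_id,
                "name": t.name,
                "category": t.category,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "rich_factor": k / K,
                "p_value": tail(N, K, n, k),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "term_id", "name", "category", "k", "K", "n", "N",
            "rich_factor", "p_value",
        ],
    )
    if table.empty:
        table["fdr"] = []
        table["significant"] = []
        return table
    table["fdr"] = 1.0
    for cat, idx in table.groupby("category").groups.items():
        table.loc[idx, "fdr"] = bh_fdr(table.loc[idx, "p_value"].to_numpy())
    table["significant"] = table["fdr"] < fdr_gate
    table = table.sort_values(
        ["fdr", "rich_factor", "term_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return table


def bubble_table(result: pd.DataFrame, top: int = 25) -> pd.DataFrame:
    """Bubble-chart export: the top significant terms with rich factor,
    overlap count and FDR."""
    sig = result.loc[result["significant"]]
    return sig.head(top)[["term_id", "name", "category", "rich_factor", "k", "fdr"]]


def write_enrichment(result: pd.DataFrame, path: str | Path) -> None:
    result.to_csv(path, sep="\t", index=False)
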