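"""Compound-target filtering, disease-gene selection and Venn intersections.

The stages implemented here reduce a raw compound->target prediction table
and two disease-gene sources to the final candidate target set:

1. keep predictions with probability >= ``p_min`` (default 0.1),
2. drop candidate compounds left without any passing target,
3. keep disease genes with relevance score >= ``score_min`` (default 10),
4. keep the top and bottom expression deciles (tumor vs normal fold
   change) of an expression matrix,
5. intersect the resulting gene sets.

Gene symbols are normalized (uppercased, whitespace-stripped) on ingest;
no alias mapping is attempted.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

TUMOR = "tumor"
NORMAL = "normal"


def normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


def normalize_symbols(symbols: Iterable[str]) -> set[str]:
    """Uppercase and strip a collection of gene symbols (idempotent)."""
    return {normalize_symbol(s) for s in symbols}


def filter_predictions(
    preds: pd.DataFrame, p_min: float = 0.1
) -> dict[str, set[str]]:
    """Per-compound target sets from a prediction table.

    Every compound appearing in the table gets an entry; compounds whose
    rows all fall below ``p_min`` map to an empty set.  Duplicate
    (compound, gene) rows collapse to one target.

    Raises
    ------
    ValueError
        If any probability lies outside [0, 1]; the offending row index
        is reported.
    """
    probs = pd.to_numeric(preds["probability"], errors="coerce")
    bad = preds.index[~probs.between(0.0, 1.0)]
    if len(bad):
        raise ValueError(
            f"probability outside [0, 1] at row index {bad[0]} "
            f"(and {len(bad) - 1} more)" if len(bad) > 1
            else f"probability outside [0, 1] at row index {bad[0]}"
        )
    mapping: dict[str, set[str]] = {
        str(c): set() for c in preds["compound_id"].unique()
    }
    passing = preds.loc[probs >= p_min]
    for compound, gene in zip(passing["compound_id"], passing["gene"]):
        mapping[str(compound)].add(normalize_symbol(gene))
    return mapping


def target_union(mapping: Mapping[str, set[str]]) -> set[str]:
    """Union of all per-compound target sets."""
    out: set[str] = set()
    for genes in mapping.values():
        out |= genes
    return out


def drop_targetless_compounds(
    selected: Iterable[str], mapping: Mapping[str, set[str]]
) -> list[str]:
    """Retain, in order, the selected compounds with a non-empty target set."""
    return [c for c in selected if mapping.get(c)]


def filter_disease_genes(
    records: pd.DataFrame, score_min: float = 10.0
) -> set[str]:
    """Disease genes whose relevance score is at least ``score_min``."""
    scores = pd.to_numeric(records["relevance_score"], errors="coerce")
    if (scores < 0).any():
        idx = records.index[scores < 0][0]
        raise ValueError(f"negative relevance score at row index {idx}")
    keep = records.loc[scores >= score_min, "gene"]
    return normalize_symbols(keep)


def select_top_decile_de(
    expr: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    fraction: float = 0.10,
    pseudocount: float = 1.0,
    method: str = "log2fc",
) -> tuple[set[str], set[str]]:
    """Top and bottom expression fractions by tumor-vs-normal effect.

    ``expr`` is genes x samples with non-negative values; ``labels`` maps
    each sample (column) to "tumor" or "normal".  The per-gene effect is
    log2((mean tumor + pseudocount) / (mean normal + pseudocount)), or a
    Welch t statistic when ``method="welch"``.  The over set is the top
    ``ceil(fraction * G)`` genes by effect, the under set the bottom; ties
    are broken lexicographically by gene symbol, and the two sets are
    always disjoint.
    """
    if not (0 < fraction <= 0.5):
        raise ValueError(f"fraction must lie in (0, 0.5], got {fraction}")
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    tumor_cols = [c for c in expr.columns if labels.get(c) == TUMOR]
    normal_cols = [c for c in expr.columns if labels.get(c) == NORMAL]
    if not tumor_cols or not normal_cols:
        raise ValueError("need at least one tumor and one normal sample")

    values = expr.to_numpy(dtype=float)
    t_idx = [expr.columns.get_loc(c) for c in tumor_cols]
    n_idx = [expr.columns.get_loc(c) for c in normal_cols]
    if method == "log2fc":
        effect = np.log2(
            (values[:, t_idx].mean(axis=1) + pseudocount)
            / (values[:, n_idx].mean(axis=1) + pseudocount)
        )
    elif method == "welch":
        effect, _ = stats.ttest_ind(
            values[:, t_idx], values[:, n_idx], axis=1, equal_var=False
        )
        effect = np.nan_to_num(effect)
    else:
        raise ValueError(f"unknown ranking method {method!r}")

    genes = [normalize_symbol(g) for g in expr.index]
    n_genes = len(genes)
    m = math.ceil(fraction * n_genes)
    if 2 * m > n_genes:
        raise ValueError(
            f"fraction {fraction} selects 2x{m} genes from only {n_genes}"
        )
    order = sorted(range(n_genes), key=lambda i: (-effect[i], genes[i]))
    over = {genes[i] for i in order[:m]}
    under = {genes[i] for i in order[-m:]}
    return over, under


class VennResult(NamedTuple):
    """Sorted intersection plus the Venn summary counts."""

    genes: tuple[str, ...]
    size_a: int
    size_b: int
    size_intersection: int

    def summary(self) -> dict:
        return {
            "a": self.size_a,
            "b": self.size_b,
            "intersection": self.size_intersection,
        }


def intersect(a: Iterable[str], b: Iterable[str]) -> VennResult:
    """Sorted set intersection with a Venn summary."""
    sa, sb = set(a), set(b)
    common = tuple(sorted(sa & sb))
    return VennResult(common, len(sa), len(sb), len(common))
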