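"""Seeded generators for every pipeline input, with planted ground truth.

Each generator emulates one of the database exports the pipeline
consumes — compound descriptors, compound->target predictions,
disease-gene relevance scores, a tumor/normal expression matrix, a scored
PPI edge table and GMT annotations — with structure planted so that the
corresponding pipeline stage has a known right answer.

The default parameters reproduce the funnel shape of a typical herbal
network-pharmacology study: 97 compounds of which 56 pass the
drug-likeness gate and 53 retain targets; 729 predicted targets, 1893
disease genes, 272 in their intersection and 136 surviving differential-
expression validation; PPI modules wired to fixed (nodes, edges) shapes.

A single integer seed drives everything; per-table substreams are derived
deterministically (spawn keys), so adding a generator never perturbs the
tables of another, and re-running with the same seed reproduces
byte-identical tables.
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from npharm.enrich import AnnotationTerm, write_gmt

# substream spawn keys, one per table
_COMPOUNDS, _PREDICTIONS, _DISEASE, _EXPRESSION, _PPI, _ANNOT, _SPLIT = range(1, 8)

#: Default planted PPI module shapes (nodes, edges): seven modules whose
#: density x size scores are 9.667, 5, 4, 3.2, 3, 3 and 2.857.
DEFAULT_MODULES = ((13, 58), (5, 10), (5, 8), (6, 8), (3, 3), (3, 3), (8, 10))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _shuffled(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    return df.iloc[rng.permutation(len(df))].reset_index(drop=True)


# ---------------------------------------------------------------------------
# compounds


def _passing_descriptors(rng: np.random.Generator) -> dict:
    """Descriptors sampled inside the intersection of all five rule boxes."""
    anion = rng.random() < 0.15
    return {
        "mw": round(rng.uniform(250, 450), 1),
        "mlogp": round(rng.uniform(0.5, 3.5), 2),
        "wlogp": round(rng.uniform(0.5, 4.5), 2),
        "xlogp": round(rng.uniform(0.2, 4.5), 2),
        "hbd": int(rng.integers(0, 5)),
        "hba": int(rng.integers(2, 9)),
        "tpsa": round(rng.uniform(30, 74), 1),
        "rotatable_bonds": int(rng.integers(0, 10)),
        "molar_refractivity": round(rng.uniform(50, 120), 1),
        "heavy_atoms": int(rng.integers(22, 61)),
        "rings": int(rng.integers(1, 7)),
        "carbons": int(rng.integers(15, 31)),
        "heteroatoms": int(rng.integers(2, 9)),
        "ionization_class": "anion" if anion else "neutral",
    }


def _failing_descriptors(rng: np.random.Generator) -> dict:
    """Descriptors violating every rule system, with bioavailability 0.17."""
    return {
        "mw": round(rng.uniform(620, 900), 1),
        "mlogp": round(rng.uniform(6, 9), 2),
        "wlogp": round(rng.uniform(6.5, 9), 2),
        "xlogp": round(rng.uniform(6, 9), 2),
        "hbd": int(rng.integers(7, 11)),
        "hba": int(rng.integers(12, 17)),
        "tpsa": round(rng.uniform(160, 260), 1),
        "rotatable_bonds": int(rng.integers(16, 26)),
        "molar_refractivity": round(rng.uniform(140, 200), 1),
        "heavy_atoms": int(rng.integers(75, 120)),
        "rings": int(rng.integers(8, 13)),
        "carbons": int(rng.integers(35, 60)),
        "heteroatoms": int(rng.integers(12, 20)),
        "ionization_class": "neutral",
    }


def gen_compounds(
    n: int = 97, n_pass: int = 56, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Descriptor table with exactly ``n_pass`` rows passing the candidate gate.

    Passing rows are sampled inside the box where all five rule systems
    hold and the bioavailability score is 0.55 or 0.85; failing rows
    violate all five systems and carry score 0.17.
    """
    if not 0 <= n_pass <= n:
        raise ValueError(f"need 0 <= n_pass <= n, got n_pass={n_pass}, n={n}")
    rng = _rng(seed, _COMPOUNDS)
    flags = rng.permutation(np.r_[np.ones(n_pass, bool), np.zeros(n - n_pass, bool)])
    rows = []
    for i, ok in enumerate(flags, start=1):
        cid = f"GEB-C{i:03d}"
        desc = _passing_descriptors(rng) if ok else _failing_descriptors(rng)
        rows.append({"compound_id": cid, "name": cid.lower(), **desc})
    table = pd.DataFrame(rows)
    manifest = {
        "n": n,
        "n_pass": n_pass,
        "pass_ids": [r["compound_id"] for r, ok in zip(rows, flags) if ok],
        "fail_ids": [r["compound_id"] for r, ok in zip(rows, flags) if not ok],
    }
    return table, manifest


# ---------------------------------------------------------------------------
# predictions


def gen_predictions(
    compound_ids: Sequence[str],
    universe_size: int = 729,
    n_targetless: int = 3,
    edge_total: int = 3747,
    seed: int = 0,
    p_min: float = 0.1,
) -> tuple[pd.DataFrame, dict]:
    """Compound->target prediction table with a planted passing structure.

    Exactly ``n_targetless`` compounds receive only sub-threshold
    probabilities (they survive the chemistry gate but drop out of the
    funnel); the remaining compounds share exactly ``edge_total`` passing
    (compound, gene) pairs whose gene union has ``universe_size`` members.
    Duplicate and sub-threshold rows are mixed in to exercise
    deduplication and the probability filter.
    """
    compound_ids = list(compound_ids)
    if n_targetless > len(compound_ids):
        raise ValueError("more targetless compounds than compounds")
    rng = _rng(seed, _PREDICTIONS)
    n_active = len(compound_ids) - n_targetless
    capacity = n_active * universe_size
    if not (max(universe_size, n_active) <= edge_total <= capacity):
        raise ValueError(
            f"edge_total={edge_total} infeasible for {n_active} active "
            f"compounds x {universe_size} genes"
        )
    targetless = sorted(
        rng.choice(compound_ids, size=n_targetless, replace=False).tolist()
    )
    active = [c for c in compound_ids if c not in targetless]
    genes = [f"G{i:04d}" for i in range(1, universe_size + 1)]

    pairs: set[tuple[str, str]] = set()
    for c in active:  # every active compound keeps >= 1 target
        pairs.add((c, genes[rng.integers(universe_size)]))
    covered = {g for _, g in pairs}
    for g in genes:  # every gene appears in the passing union
        if g not in covered:
            pairs.add((active[rng.integers(n_active)], g))
    while len(pairs) < edge_total:
        pairs.add((active[rng.integers(n_active)], genes[rng.integers(universe_size)]))

    ordered = sorted(pairs)
    rows = [
        {"compound_id": c, "gene": g, "probability": round(0.1 + 0.9 * rng.random(), 4)}
        for c, g in ordered
    ]
    # duplicates of ~1% of passing pairs, with a different passing probability
    n_dup = max(1, edge_total // 100)
    for i in rng.choice(len(ordered), size=n_dup, replace=False):
        c, g = ordered[i]
        rows.append(
            {"compound_id": c, "gene": g, "probability": round(0.1 + 0.9 * rng.random(), 4)}
        )
    # sub-threshold noise: targetless compounds only score below p_min
    for c in targetless:
        for _ in range(3):
            rows.append(
                {
                    "compound_id": c,
                    "gene": genes[rng.integers(universe_size)],
                    "probability": round(rng.uniform(0.005, p_min - 0.001), 4),
                }
            )
    for c in rng.choice(active, size=min(10, n_active), replace=False):
        rows.append(
            {
                "compound_id": c,
                "gene": genes[rng.integers(universe_size)],
                "probability": round(rng.uniform(0.005, p_min - 0.001), 4),
            }
        )
    table = _shuffled(pd.DataFrame(rows), rng)
    manifest = {
        "universe_size": universe_size,
        "edge_total": edge_total,
        "genes": genes,
        "targetless": targetless,
        "active": active,
    }
    return table, manifest


# ---------------------------------------------------------------------------
# disease genes


def gen_disease_table(
    target_genes: Iterable[str],
    n_pass: int = 1893,
    overlap_with_targets: int = 272,
    seed: int = 0,
    score_min: float = 10.0,
) -> tuple[pd.DataFrame, dict]:
    """Disease-gene relevance table with a planted passing overlap.

    Exactly ``overlap_with_targets`` genes shared with ``target_genes``
    score at or above ``score_min``; the rest of the ``n_pass`` passing
    genes are disease-only symbols.  Sub-threshold rows (including some
    target genes) are added so the score filter has work to do.
    """
    target_genes = sorted(set(target_genes))
    if overlap_with_targets > min(n_pass, len(target_genes)):
        raise ValueError("overlap larger than a parent set")
    rng = _rng(seed, _DISEASE)
    overlap = sorted(
        rng.choice(target_genes, size=overlap_with_targets, replace=False).tolist()
    )
    fresh = [f"CRC{i:04d}" for i in range(1, n_pass - overlap_with_targets + 1)]
    passing = overlap + fresh
    scores = np.round(score_min + 90 * rng.random(len(passing)), 2)
    if len(scores):
        scores[0] = score_min  # keep one gene exactly at the inclusive boundary
    rows = [
        {"gene": g, "relevance_score": float(s)} for g, s in zip(passing, scores)
    ]
    # sub-threshold: unrelated genes plus target genes outside the overlap
    remaining = [g for g in target_genes if g not in set(overlap)]
    n_low_targets = min(150, len(remaining))
    low_targets = (
        sorted(rng.choice(remaining, size=n_low_targets, replace=False).tolist())
        if n_low_targets
        else []
    )
    for g in low_targets:
        rows.append({"gene": g, "relevance_score": float(round(rng.uniform(0.5, 9.9), 2))})
    for i in range(1, 251):
        rows.append(
            {
                "gene": f"LOW{i:04d}",
                "relevance_score": float(round(rng.uniform(0.5, 9.9), 2)),
            }
        )
    table = _shuffled(pd.DataFrame(rows), rng)
    manifest = {
        "n_pass": n_pass,
        "overlap_genes": overlap,
        "disease_only": fresh,
    }
    return table, manifest


# ---------------------------------------------------------------------------
# expression


def gen_expression(
    G: int = 2000,
    n_tumor: int = 30,
    n_normal: int = 10,
    planted_over: int | Sequence[str] = 30,
    planted_under: int | Sequence[str] = 30,
    log2fc: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Genes x samples expression matrix with planted differential genes.

    Baseline log2 expression is uniform on [4, 10] per gene; each sample
    adds Gaussian log2 noise of scale ``noise_sd``; planted genes are
    shifted by +/-``log2fc`` in tumor samples only.  ``planted_over`` and
    ``planted_under`` may be counts (genes drawn at random) or explicit
    symbol lists.
    """
    rng = _rng(seed, _EXPRESSION)
    if genes is None:
        genes = [f"EXP{i:05d}" for i in range(1, G + 1)]
    else:
        genes = list(genes)
        G = len(genes)

    def _pick(wanted, taken: set[str]) -> list[str]:
        if isinstance(wanted, (int, np.integer)):
            pool = [g for g in genes if g not in taken]
            return sorted(rng.choice(pool, size=int(wanted), replace=False).tolist())
        missing = set(wanted) - set(genes)
        if missing:
            raise ValueError(f"planted genes absent from panel: {sorted(missing)}")
        return sorted(wanted)

    over = _pick(planted_over, set())
    under = _pick(planted_under, set(over))
    if set(over) & set(under):
        raise ValueError("planted over and under sets overlap")

    samples = [f"T{i:03d}" for i in range(1, n_tumor + 1)] + [
        f"N{i:03d}" for i in range(1, n_normal + 1)
    ]
    labels = pd.Series(
        ["tumor"] * n_tumor + ["normal"] * n_normal, index=samples, name="label"
    )
    base = rng.uniform(4, 10, size=G)
    shift = np.zeros(G)
    idx = {g: i for i, g in enumerate(genes)}
    shift[[idx[g] for g in over]] = log2fc
    shift[[idx[g] for g in under]] = -log2fc
    log2_vals = np.empty((G, len(samples)))
    for j, s in enumerate(samples):
        col = base + (shift if labels[s] == "tumor" else 0.0)
        if noise_sd > 0:
            col = col + rng.normal(0.0, noise_sd, size=G)
        log2_vals[:, j] = col
    expr = pd.DataFrame(
        np.round(np.exp2(log2_vals), 4), index=pd.Index(genes, name="gene"),
        columns=samples,
    )
    manifest = {"over": over, "under": under, "log2fc": log2fc, "noise_sd": noise_sd}
    return expr, labels, manifest


# ---------------------------------------------------------------------------
# PPI


def _wire_module(
    nodes: Sequence[str], e: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Connect ``nodes`` with exactly ``e`` edges, guaranteeing a 2-core.

    A spanning cycle is laid first (so every vertex has degree >= 2), then
    random non-edges are added until the count is reached.
    """
    n = len(nodes)
    if not (n <= e <= n * (n - 1) // 2):
        raise ValueError(f"edge count {e} infeasible for a {n}-node cycle-plus module")
    edges = {tuple(sorted((nodes[i], nodes[(i + 1) % n]))) for i in range(n)}
    candidates = [
        tuple(sorted(p)) for p in itertools.combinations(nodes, 2)
        if tuple(sorted(p)) not in edges
    ]
    extra = e - len(edges)
    if extra:
        picked = rng.choice(len(candidates), size=extra, replace=False)
        edges.update(candidates[i] for i in picked)
    return sorted(edges)


def gen_ppi(
    genes: Sequence[str],
    modules: Sequence[tuple[int, int]] = DEFAULT_MODULES,
    background_p: float = 0.02,
    seed: int = 0,
    module_confidence: tuple[float, float] = (0.85, 0.99),
    background_confidence: tuple[float, float] = (0.4, 0.95),
) -> tuple[pd.DataFrame, dict]:
    """Scored PPI edge table with planted dense modules.

    Each (n, e) module is wired exactly to its shape with confidences
    strictly above 0.7; background edges are Erdős–Rényi over the
    non-intra-module pairs with confidences straddling 0.7, so the
    high-confidence filter has both kinds to discard.
    """
    genes = sorted(set(genes))
    need = sum(n for n, _ in modules)
    if need > len(genes):
        raise ValueError(f"modules need {need} nodes, only {len(genes)} genes")
    rng = _rng(seed, _PPI)
    perm = rng.permutation(genes).tolist()
    rows = []
    member_lists: list[list[str]] = []
    intra_pairs: set[tuple[str, str]] = set()
    offset = 0
    for n, e in modules:
        members = perm[offset: offset + n]
        offset += n
        member_lists.append(sorted(members))
        for a, b in _wire_module(members, e, rng):
            rows.append(
                {
                    "protein_a": a,
                    "protein_b": b,
                    "confidence": round(rng.uniform(*module_confidence), 3),
                }
            )
        intra_pairs.update(
            tuple(sorted(p)) for p in itertools.combinations(members, 2)
        )
    if background_p > 0:
        for pair in itertools.combinations(genes, 2):
            pair = tuple(sorted(pair))
            if pair in intra_pairs:
                continue
            if rng.random() < background_p:
                rows.append(
                    {
                        "protein_a": pair[0],
                        "protein_b": pair[1],
                        "confidence": round(rng.uniform(*background_confidence), 3),
                    }
                )
    table = _shuffled(pd.DataFrame(rows), rng)
    manifest = {
        "modules": [
            {"nodes": n, "edges": e, "members": m}
            for (n, e), m in zip(modules, member_lists)
        ],
        "background_p": background_p,
    }
    return table, manifest


# ---------------------------------------------------------------------------
# annotations


def gen_annotations(
    universe: Iterable[str],
    query: Iterable[str],
    planted_size: int = 40,
    planted_overlap: int = 30,
    n_decoys: int = 100,
    size_range: tuple[int, int] = (10, 80),
    category: str = "KEGG",
    seed: int = 0,
) -> tuple[list[AnnotationTerm], dict]:
    """GMT-style annotation terms with one planted enriched term.

    The planted term draws ``planted_overlap`` members from the query and
    the rest from outside it; decoy terms sample the universe uniformly.
    """
    universe = sorted(set(universe))
    query = sorted(set(query))
    if planted_overlap > min(planted_size, len(query)):
        raise ValueError("planted overlap exceeds term or query size")
    outside = [g for g in universe if g not in set(query)]
    if planted_size - planted_overlap > len(outside):
        raise ValueError("not enough non-query genes for the planted term")
    # decoy substreams differ per category so multi-category bundles vary
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_ANNOT, sum(map(ord, category))))
    )
    planted_members = sorted(
        rng.choice(query, size=planted_overlap, replace=False).tolist()
        + rng.choice(outside, size=planted_size - planted_overlap, replace=False).tolist()
    )
    planted_id = f"{category}:PLANTED"
    terms = [
        AnnotationTerm(
            planted_id, f"planted {category} term", category, frozenset(planted_members)
        )
    ]
    for i in range(1, n_decoys + 1):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = frozenset(rng.choice(universe, size=size, replace=False).tolist())
        terms.append(
            AnnotationTerm(f"{category}:{i:04d}", f"decoy {category} {i}", category, members)
        )
    manifest = {"planted_term": planted_id, "planted_overlap": planted_overlap}
    return terms, manifest


# ---------------------------------------------------------------------------
# full bundle


def generate_all(seed: int = 0, outdir: str | Path | None = None) -> dict:
    """All six input tables with the default planted funnel.

    Returns a dict with keys ``compounds``, ``predictions``, ``disease``,
    ``expression``, ``labels``, ``ppi``, ``annotations`` (category ->
    term list) and ``manifest``.  With ``outdir`` set, the tables are
    also written as TSV/GMT plus a ``manifest.json``.
    """
    compounds, m_comp = gen_compounds(n=97, n_pass=56, seed=seed)
    selected = m_comp["pass_ids"]
    predictions, m_pred = gen_predictions(
        selected, universe_size=729, n_targetless=3, edge_total=3747, seed=seed
    )
    disease, m_dis = gen_disease_table(
        m_pred["genes"], n_pass=1893, overlap_with_targets=272, seed=seed
    )
    overlap = m_dis["overlap_genes"]
    # 136 of the 272 intersection genes are planted as differential; the
    # expression panel excludes the other 136, so the second Venn cut is
    # exact by construction
    rng = _rng(seed, _SPLIT)
    shuffled = rng.permutation(overlap).tolist()
    planted_over, planted_under = shuffled[:68], shuffled[68:136]
    panel = sorted(planted_over + planted_under) + [
        f"EXP{i:05d}" for i in range(1, 2000 - 136 + 1)
    ]
    expression, labels, m_expr = gen_expression(
        genes=panel,
        n_tumor=30,
        n_normal=10,
        planted_over=planted_over,
        planted_under=planted_under,
        log2fc=2.0,
        noise_sd=0.5,
        seed=seed,
    )
    final_targets = sorted(planted_over + planted_under)
    ppi, m_ppi = gen_ppi(final_targets, modules=DEFAULT_MODULES, seed=seed)
    universe = sorted(set(m_pred["genes"]) | set(overlap) | set(m_dis["disease_only"]))
    annotations: dict[str, list[AnnotationTerm]] = {}
    m_annot = {}
    for category in ("BP", "CC", "MF", "KEGG"):
        terms, m = gen_annotations(
            universe, final_targets, n_decoys=60, category=category, seed=seed
        )
        annotations[category] = terms
        m_annot[category] = m
    manifest = {
        "seed": seed,
        "compounds": {k: v for k, v in m_comp.items() if k != "fail_ids"},
        "predictions": {k: v for k, v in m_pred.items() if k != "genes"},
        "target_universe_size": len(m_pred["genes"]),
        "disease": {"n_pass": m_dis["n_pass"], "overlap_n": len(overlap)},
        "expression": {
            "over": m_expr["over"],
            "under": m_expr["under"],
            "log2fc": m_expr["log2fc"],
            "noise_sd": m_expr["noise_sd"],
        },
        "final_targets": final_targets,
        "ppi": m_ppi,
        "annotations": m_annot,
    }
    bundle = {
        "compounds": compounds,
        "predictions": predictions,
        "disease": disease,
        "expression": expression,
        "labels": labels,
        "ppi": ppi,
        "annotations": annotations,
        "manifest": manifest,
    }
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["compounds"].to_csv(outdir / "compounds.tsv", sep="\t", index=False)
    bundle["predictions"].to_csv(outdir / "predictions.tsv", sep="\t", index=False)
    bundle["disease"].to_csv(outdir / "disease_genes.tsv", sep="\t", index=False)
    bundle["expression"].to_csv(outdir / "expression.tsv", sep="\t")
    bundle["labels"].rename_axis("sample").to_frame().to_csv(
        outdir / "sample_labels.tsv", sep="\t"
    )
    bundle["ppi"].to_csv(outdir / "ppi_edges.tsv", sep="\t", index=False)
    for category, terms in bundle["annotations"].items():
        write_gmt(terms, outdir / f"annotations_{category}.gmt")
    (outdir / "manifest.json").write_text(
        json.dumps(bundle["manifest"], sort_keys=True, indent=2) + "\n"
    )
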