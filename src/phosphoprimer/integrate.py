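"""Transcript/protein integration and gene-set overlap statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

QUADRANT_CLASSES = (
    "both_up",
    "both_down",
    "protein_only_up",
    "protein_only_down",
    "rna_only_up",
    "rna_only_down",
    "neither",
    "discordant",
)


def _check_layer(results: pd.DataFrame, name: str) -> None:
    if results.index.has_duplicates:
        dupes = results.index[results.index.duplicated()][:3]
        raise ValueError(f"duplicated gene(s) in {name} layer: {list(dupes)}")
    for col in ("log2FC", "call"):
        if col not in results.columns:
            raise ValueError(f"{name} results lack a {col!r} column")


def correlate_layers(
    rna_results: pd.DataFrame, protein_results: pd.DataFrame
) -> tuple[float, int]:
    """Pearson correlation of transcript vs protein log2 fold changes.

    Computed over genes significant in either layer (call != unchanged),
    after dropping genes missing a fold change in either layer — the
    construction used for published transcript-protein scatter plots.
    Returns ``(r, n)``.
    """
    _check_layer(rna_results, "rna")
    _check_layer(protein_results, "protein")
    common = rna_results.index.intersection(protein_results.index)
    r_sub = rna_results.loc[common]
    p_sub = protein_results.loc[common]
    significant = (r_sub["call"] != "unchanged") | (p_sub["call"] != "unchanged")
    x = r_sub.loc[significant, "log2FC"]
    y = p_sub.loc[significant, "log2FC"]
    keep = x.notna() & y.notna()
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"only {len(x)} genes available; need >= 3")
    r = float(stats.pearsonr(x, y).statistic)
    return r, int(len(x))


def classify_quadrants(
    rna_results: pd.DataFrame, protein_results: pd.DataFrame
) -> pd.DataFrame:
    """Classify each gene by the direction of its per-layer calls.

    Genes present in both layers are labeled both_up/both_down (significant
    and concordant at both levels), protein_only_up/down, rna_only_up/down,
    neither, or discordant (significant at both levels with opposite
    signs).  Per-class counts are attached as ``attrs['counts']``.
    """
    _check_layer(rna_results, "rna")
    _check_layer(protein_results, "protein")
    common = rna_results.index.intersection(protein_results.index)
    rna = rna_results.loc[common]
    prot = protein_results.loc[common]

    def classify(rc: str, pc: str) -> str:
        if rc == "unchanged" and pc == "unchanged":
            return "neither"
        if rc == "unchanged":
            return "protein_only_up" if pc == "enhanced" else "protein_only_down"
        if pc == "unchanged":
            return "rna_only_up" if rc == "enhanced" else "rna_only_down"
        if rc == pc:
            return "both_up" if rc == "enhanced" else "both_down"
        return "discordant"

    classes = [
        classify(rc, pc) for rc, pc in zip(rna["call"], prot["call"])
    ]
    out = pd.DataFrame(
        {
            "log2FC_rna": rna["log2FC"],
            "log2FC_protein": prot["log2FC"],
            "quadrant": classes,
        },
        index=common,
    )
    counts = {c: int((out["quadrant"] == c).sum()) for c in QUADRANT_CLASSES}
    out.attrs["counts"] = counts
    return out


@dataclass(frozen=True)
class OverlapTest:
    """Hypergeometric overlap between two gene sets in a finite universe."""

    set_a_size: int
    set_b_size: int
    universe_size: int
    intersection_size: int
    p_value: float
    jaccard: float


def gene_set_overlap(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> OverlapTest:
    """Exact upper-tail hypergeometric test for an observed intersection.

    p = P(X >= k) where X counts elements of B landing in A when B's
    elements are drawn without replacement from the universe.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe:
        raise ValueError("set_a is not contained in the universe")
    if not set_b <= universe:
        raise ValueError("set_b is not contained in the universe")
    m, a, b = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    p = float(stats.hypergeom.sf(k - 1, m, a, b))
    union = len(set_a | set_b)
    jaccard = k / union if union else float("nan")
    return OverlapTest(a, b, m, k, min(p, 1.0), jaccard)
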