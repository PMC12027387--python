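"""Phospho-occupancy normalization against parent-protein abundance.

"Occupancy-level" regulation is the site-level change after removing the
parent protein's abundance change — a ratio of ratios, computed on the log2
scale as ``log2FC_occupancy = log2FC_phospho - log2FC_protein``.  True
stoichiometry estimation (which needs the unmodified counterpart peptides)
is deliberately out of scope.

Occupancy q-values are recomputed by rerunning the moderated test on
protein-normalized intensities (site intensity minus parent-protein
intensity per sample) when the underlying matrices are supplied; otherwise
only the normalized fold changes are thresholded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import Contrast, call_features, permutation_fdr
from .io_tables import FeatureMatrix, parse_site_feature_key

IDENTITY_TOL = 1e-9


def _site_index_frame(results: pd.DataFrame) -> pd.DataFrame:
    parsed = [parse_site_feature_key(k) for k in results.index]
    return pd.DataFrame(
        parsed, columns=["protein_id", "position", "residue", "multiplicity"],
        index=results.index,
    )


def compute_occupancy(
    phospho_results: pd.DataFrame,
    protein_results: pd.DataFrame,
    phospho_matrix: FeatureMatrix | None = None,
    protein_matrix: FeatureMatrix | None = None,
    contrast: Contrast | None = None,
    fold_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    n_permutations: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Normalize site-level changes to parent-protein changes.

    ``phospho_results`` is a called site-level result table indexed by site
    feature keys; ``protein_results`` a called protein-level table indexed
    by protein id.  Sites whose parent protein was not quantified are kept
    and flagged, with occupancy columns left absent.  When both intensity
    matrices and a contrast are given, occupancy statistics (t, p, q) are
    recomputed on protein-normalized intensities; otherwise occupancy calls
    threshold the normalized fold change, reusing the phospho q-value.
    """
    if protein_results.index.has_duplicates:
        dupes = protein_results.index[protein_results.index.duplicated()][:3]
        raise ValueError(f"duplicate parent-protein entries: {list(dupes)}")
    sites = _site_index_frame(phospho_results)
    out = sites.copy()
    out["log2FC_phospho"] = phospho_results["log2FC"]
    out["q_phospho"] = phospho_results.get("q_value")
    out["call_phospho"] = phospho_results.get("call")

    parent = sites["protein_id"]
    quantified = parent.isin(protein_results.index)
    prot_lfc = pd.Series(np.nan, index=out.index)
    prot_lfc[quantified] = protein_results["log2FC"].reindex(
        parent[quantified]
    ).to_numpy()
    out["log2FC_protein"] = prot_lfc
    out["protein_quantified"] = quantified
    out["log2FC_occupancy"] = out["log2FC_phospho"] - out["log2FC_protein"]

    # subtraction identity, asserted pipeline-wide
    ok = out["protein_quantified"]
    resid = (
        out.loc[ok, "log2FC_occupancy"]
        + out.loc[ok, "log2FC_protein"]
        - out.loc[ok, "log2FC_phospho"]
    )
    assert (resid.abs() < IDENTITY_TOL).all()

    recompute = (
        phospho_matrix is not None
        and protein_matrix is not None
        and contrast is not None
    )
    if recompute:
        keep = out.index[ok]
        pv = phospho_matrix.values.loc[keep]
        parents = sites.loc[keep, "protein_id"]
        norm = pv.to_numpy() - protein_matrix.values.reindex(
            parents
        ).to_numpy()
        norm_matrix = FeatureMatrix(
            pd.DataFrame(norm, index=keep, columns=phospho_matrix.sample_ids),
            layer="phospho",
            sample_metadata=phospho_matrix.sample_metadata.copy(),
        )
        occ = call_features(
            permutation_fdr(norm_matrix, contrast, n_permutations, seed=seed),
            fold_threshold,
            fdr_threshold,
        )
        out["q_occupancy"] = occ["q_value"].reindex(out.index)
        out["call_occupancy"] = occ["call"].reindex(out.index)
    else:
        cut = np.log2(fold_threshold)
        lfc, q = out["log2FC_occupancy"], out["q_phospho"]
        call = np.where(
            (lfc <= -cut) & (q < fdr_threshold),
            "reduced",
            np.where((lfc >= cut) & (q < fdr_threshold), "enhanced", "unchanged"),
        )
        out["q_occupancy"] = q.where(ok)
        out["call_occupancy"] = pd.Series(call, index=out.index).where(ok)
    out.loc[~ok, "call_occupancy"] = None
    return out


@dataclass(frozen=True)
class OverlapSummary:
    """Set arithmetic between two call sets in one direction."""

    size_a: int
    size_b: int
    intersection: int
    fraction_a_in_b: float


def _call_set(calls, direction: str) -> set:
    if isinstance(calls, pd.DataFrame):
        calls = calls["call"]
    if isinstance(calls, pd.Series):
        return set(calls.index[calls == direction])
    return set(calls)


def level_overlap(phospho_calls, occupancy_calls, direction: str) -> OverlapSummary:
    """Overlap between e.g. phosphorylation-level and occupancy-level calls.

    Inputs are call Series/DataFrames over the same record universe (the
    named direction is selected from each), or pre-built id sets.  The
    fraction reported is |A∩B| / |A|, to three decimals.
    """
    if direction not in ("reduced", "enhanced"):
        raise ValueError("direction must be 'reduced' or 'enhanced'")
    a = _call_set(phospho_calls, direction)
    b = _call_set(occupancy_calls, direction)
    inter = len(a & b)
    frac = round(inter / len(a), 3) if a else float("nan")
    return OverlapSummary(len(a), len(b), inter, frac)
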