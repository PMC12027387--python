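"""End-to-end orchestration of the analysis chain on one study.

Tying the modules together in the order a real dataset travels:
site table -> normalize/impute -> differential calls (phospho level) ->
occupancy normalization against the proteome -> consensus scan and priming
classification -> transcript/protein integration and regulon overlaps.
Used by the command-line interface, the examples and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .differential import (
    Contrast,
    differential_analysis,
    impute_missing,
    median_normalize,
)
from .integrate import OverlapTest, classify_quadrants, correlate_layers, gene_set_overlap
from .io_tables import FeatureMatrix, ProteinSequenceRecord, site_feature_matrix
from .motif import (
    MultiplicityStats,
    map_sites_to_matches,
    multiplicity_statistics,
    protein_summary,
    scan_consensus,
)
from .occupancy import OverlapSummary, compute_occupancy, level_overlap
from .simulate import SyntheticStudy

# Layer-specific fold thresholds: 2-fold for phosphopeptides, 1.5-fold for
# transcripts and proteins; FDR 0.05 everywhere.
PHOSPHO_FOLD = 2.0
EXPRESSION_FOLD = 1.5
FDR = 0.05


def site_calls_table(phospho_results: pd.DataFrame) -> pd.DataFrame:
    """Expand site feature keys into per-record call rows for the scanner."""
    from .io_tables import parse_site_feature_key

    parsed = [parse_site_feature_key(k) for k in phospho_results.index]
    out = pd.DataFrame(
        parsed,
        columns=["protein_id", "position", "residue", "multiplicity"],
        index=phospho_results.index,
    )
    out["log2FC"] = phospho_results["log2FC"]
    out["q_value"] = phospho_results.get("q_value")
    out["call"] = phospho_results.get("call")
    return out


@dataclass
class PipelineResult:
    """All result tables of one end-to-end run."""

    contrast: Contrast
    phospho_results: pd.DataFrame
    protein_results: pd.DataFrame
    transcript_results: pd.DataFrame
    occupancy: pd.DataFrame
    occupancy_overlap: OverlapSummary
    priming_calls: pd.DataFrame
    priming_proteins: pd.DataFrame
    multiplicity: MultiplicityStats
    correlation_r: float
    correlation_n: int
    quadrants: pd.DataFrame
    regulon_overlap: OverlapTest | None = None
    extras: dict = field(default_factory=dict)


def run_pipeline(
    sequences: list[ProteinSequenceRecord],
    sites: pd.DataFrame,
    transcript: FeatureMatrix,
    protein: FeatureMatrix,
    contrast: Contrast = Contrast(),
    n_permutations: int = 200,
    seed: int = 0,
    gcn5_regulon: set[str] | None = None,
    evidence_level: str = "phospho",
) -> PipelineResult:
    """Run the full chain on one dataset (real or synthetic).

    ``evidence_level`` selects whether the consensus scanner uses
    phosphorylation-level or occupancy-level calls as differential
    evidence; the default keeps the non-normalized phosphoproteome, the
    appropriate choice when protein-level changes are rare among
    phosphoproteins.
    """
    if evidence_level not in ("phospho", "occupancy"):
        raise ValueError("evidence_level must be 'phospho' or 'occupancy'")

    def preprocess(matrix: FeatureMatrix) -> FeatureMatrix:
        m = median_normalize(matrix)
        if m.values.isna().any().any():
            m = impute_missing(m, seed=seed)
        return m

    phospho_matrix = preprocess(site_feature_matrix(sites))
    protein_matrix = preprocess(protein)
    transcript_matrix = preprocess(transcript)
    phospho_results = differential_analysis(
        phospho_matrix, contrast, PHOSPHO_FOLD, FDR, n_permutations,
        seed=seed, normalize=False, impute=False,
    )
    protein_results = differential_analysis(
        protein_matrix, contrast, EXPRESSION_FOLD, FDR, n_permutations,
        seed=seed, normalize=False, impute=False,
    )
    transcript_results = differential_analysis(
        transcript_matrix, contrast, EXPRESSION_FOLD, FDR, n_permutations,
        seed=seed, normalize=False, impute=False,
    )

    occupancy = compute_occupancy(
        phospho_results,
        protein_results,
        phospho_matrix=phospho_matrix,
        protein_matrix=protein_matrix,
        contrast=contrast,
        fold_threshold=PHOSPHO_FOLD,
        fdr_threshold=FDR,
        n_permutations=n_permutations,
        seed=seed,
    )
    occ_overlap = level_overlap(
        set(occupancy.index[occupancy["call_phospho"] == "reduced"]),
        set(occupancy.index[occupancy["call_occupancy"] == "reduced"]),
        "reduced",
    )

    matches = [m for rec in sequences for m in scan_consensus(rec)]
    evidence = site_calls_table(phospho_results)
    if evidence_level == "occupancy":
        evidence = evidence.assign(call=occupancy["call_occupancy"].fillna("unchanged"))
    lengths = {r.protein_id: len(r) for r in sequences}
    priming = map_sites_to_matches(matches, evidence, sequence_lengths=lengths)
    proteins = protein_summary(priming)
    mstats = multiplicity_statistics(priming)

    r, n = correlate_layers(transcript_results, protein_results)
    quadrants = classify_quadrants(transcript_results, protein_results)

    regulon_overlap = None
    if gcn5_regulon is not None:
        mck1_activated = set(
            transcript_results.index[transcript_results["call"] == "reduced"]
        )
        universe = set(transcript_results.index)
        regulon_overlap = gene_set_overlap(
            mck1_activated, gcn5_regulon & universe, universe
        )

    return PipelineResult(
        contrast=contrast,
        phospho_results=phospho_results,
        protein_results=protein_results,
        transcript_results=transcript_results,
        occupancy=occupancy,
        occupancy_overlap=occ_overlap,
        priming_calls=priming,
        priming_proteins=proteins,
        multiplicity=mstats,
        correlation_r=r,
        correlation_n=n,
        quadrants=quadrants,
        regulon_overlap=regulon_overlap,
    )


def run_study(
    study: SyntheticStudy,
    contrast: Contrast = Contrast(),
    n_permutations: int = 200,
    seed: int = 0,
    evidence_level: str = "phospho",
) -> PipelineResult:
    """Run the pipeline on a synthetic study, wiring in its regulon truth."""
    return run_pipeline(
        study.sequences,
        study.sites,
        study.transcript,
        study.protein,
        contrast=contrast,
        n_permutations=n_permutations,
        seed=seed,
        gcn5_regulon=study.truth.regulon("gcn5"),
        evidence_level=evidence_level,
    )
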