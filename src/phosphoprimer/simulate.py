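"""Synthetic multi-omic study generator with planted kinase-substrate truth.

The generator emulates the structure of a two-genotype (wild type vs a Gsk-3
kinase deletion) by two-growth-phase (exponential vs post-diauxic shift)
quantitative study: a TMT-style phosphosite intensity table with multiplicity
classes, a protein-group intensity matrix and a transcript count matrix, all
with per-group replicates, plus the ground truth needed to score recovery.

Planted biology
---------------
* Substrate proteins carry (S/T)XXX(S/T) consensus pairs.  In mutant samples
  the first-position site loses phosphorylation (``effect_size_first_site``
  log2 units) and the +4 "priming" site gains a monophosphorylated
  (multiplicity 1) record (``effect_size_plus4_site`` log2 units), mirroring
  the loss of kinase activity downstream of an intact priming kinase.
* With probability ``fraction_primed_multiplicity_ge2`` the first-position
  phosphorylation is observable only on dual/multi-phosphopeptides
  (multiplicity >= 2), in which case the doubly phosphorylated species also
  reports at the +4 position.
* A configurable fraction of substrates additionally change in parent-protein
  abundance, so occupancy normalization has something to remove.
* Regulon genes carry correlated transcript/protein effects (reduced in the
  mutant at the post-diauxic phase), and a second regulon label set supports
  gene-set overlap statistics.

Site and protein effects at the phospho layer apply to mutant samples in both
phases; transcript/protein regulon effects apply in the post-diauxic phase
only, matching a starvation-induced expression program.

One RNG stream is split off the master seed per generator stage, so e.g.
changing phospho parameters never perturbs the generated sequences.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_tables import FeatureMatrix, ProteinSequenceRecord, parse_sample_names

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# Uniform background with S and T upweighted to 8% each, so that spurious
# (non-planted) consensus matches occur and specificity is measurable.
_ST_FREQ = 0.08
_OTHER_FREQ = (1.0 - 2 * _ST_FREQ) / 18
RESIDUE_FREQUENCIES = {
    aa: (_ST_FREQ if aa in "ST" else _OTHER_FREQ) for aa in AMINO_ACIDS
}

_MULTIPLICITY_PROBS = {1: 0.55, 2: 0.30, 3: 0.15}  # background site classes


class GeneratorConfigError(ValueError):
    """A generator configuration field is invalid; the message names it."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic study.

    Effect sizes are log2 units; ``cv_intensity`` is the coefficient of
    variation of the multiplicative intensity noise; proportions lie in
    [0, 1].  ``genotypes[0]`` is the reference (wild type), ``genotypes[1]``
    the perturbed genotype carrying all planted effects.
    """

    n_proteins: int = 400
    n_substrates: int = 40
    mean_protein_length: int = 450
    n_pairs_per_substrate: int = 3
    background_sites_mean: float = 3.0
    replicates_per_group: int = 3
    genotypes: tuple[str, str] = ("WT", "mck1del")
    phases: tuple[str, ...] = ("EXP", "PDS")
    effect_size_first_site: float = 2.0
    effect_size_plus4_site: float = 1.0
    fraction_primed_multiplicity_ge2: float = 0.75
    cv_intensity: float = 0.2
    missingness_rate: float = 0.1
    protein_effect_overlap: float = 0.1
    protein_overlap_effect: float = -1.0
    mck1_regulon_size: int | None = None  # default: 10% of non-substrate genes
    gcn5_regulon_size: int | None = None  # default: 8% of non-substrate genes
    regulon_overlap_fraction: float = 0.5
    de_effect_mean: float = 1.0
    de_effect_sd: float = 1.0
    transcript_protein_correlation: float = 0.4
    base_log2_intensity: float = 23.0
    base_log2_counts: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        pool = max(0, self.n_proteins - self.n_substrates)
        if self.mck1_regulon_size is None:
            object.__setattr__(self, "mck1_regulon_size", round(0.10 * pool))
        if self.gcn5_regulon_size is None:
            object.__setattr__(self, "gcn5_regulon_size", round(0.08 * pool))
        if self.n_proteins < 1:
            raise GeneratorConfigError("n_proteins must be >= 1")
        if not 0 <= self.n_substrates <= self.n_proteins:
            raise GeneratorConfigError(
                "n_substrates must lie in [0, n_proteins]"
            )
        if self.replicates_per_group < 2:
            raise GeneratorConfigError("replicates_per_group must be >= 2")
        if self.n_pairs_per_substrate < 1:
            raise GeneratorConfigError("n_pairs_per_substrate must be >= 1")
        if self.mean_protein_length < 60:
            raise GeneratorConfigError("mean_protein_length must be >= 60")
        for name in (
            "fraction_primed_multiplicity_ge2",
            "missingness_rate",
            "protein_effect_overlap",
            "regulon_overlap_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GeneratorConfigError(f"{name} must lie in [0, 1]")
        if self.cv_intensity < 0:
            raise GeneratorConfigError("cv_intensity must be >= 0")
        if not -1.0 <= self.transcript_protein_correlation <= 1.0:
            raise GeneratorConfigError(
                "transcript_protein_correlation must lie in [-1, 1]"
            )
        if self.mck1_regulon_size + self.n_substrates > self.n_proteins:
            raise GeneratorConfigError(
                "mck1_regulon_size leaves no room next to n_substrates"
            )
        if len(self.genotypes) != 2:
            raise GeneratorConfigError("genotypes must name exactly two strains")

    @property
    def groups(self) -> list[tuple[str, str]]:
        return [(g, p) for g in self.genotypes for p in self.phases]

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{g}_{p}_{r + 1}"
            for (g, p) in self.groups
            for r in range(self.replicates_per_group)
        ]

    @property
    def noise_sd_log2(self) -> float:
        """Log2-scale noise s.d. implied by a log-normal CV."""
        if self.cv_intensity == 0:
            return 0.0
        return float(np.sqrt(np.log1p(self.cv_intensity**2)) / np.log(2))

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()


@dataclass(frozen=True)
class PlantedSite:
    """One planted consensus pair on a substrate protein."""

    protein_id: str
    first_pos: int
    plus4_pos: int
    effect_first: float
    effect_plus4: float
    primed_only_multi: bool  # first-site record emitted only at multiplicity >= 2

    def __post_init__(self) -> None:
        if self.plus4_pos - self.first_pos != 4:
            raise ValueError("planted pair must be spaced exactly 4 residues")


@dataclass
class TruthLabels:
    """Ground truth planted by the generator, for recovery scoring."""

    substrate_sites: list[PlantedSite]
    regulon_membership: dict[str, str]  # gene -> mck1 | gcn5 | both | neither
    transcript_lfc: dict[str, float]  # planted log2(mutant/WT), PDS phase
    protein_lfc: dict[str, float]
    config_fingerprint: str = ""

    @property
    def substrate_proteins(self) -> set[str]:
        return {s.protein_id for s in self.substrate_sites}

    def regulon(self, label: str) -> set[str]:
        """Genes belonging to a regulon ('mck1' includes 'both', etc.)."""
        return {
            g
            for g, m in self.regulon_membership.items()
            if m == label or (m == "both" and label in ("mck1", "gcn5"))
        }


def _check_truth(config: GeneratorConfig, truth: TruthLabels) -> None:
    if truth.config_fingerprint != config.fingerprint():
        raise ValueError(
            "truth labels were generated under a different configuration"
        )


def _rng_children(config: GeneratorConfig) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(config.seed)
    names = ("effects", "sequences", "phospho", "expression")
    return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(4))}


def _protein_ids(config: GeneratorConfig) -> list[str]:
    width = max(4, len(str(config.n_proteins)))
    return [f"P{i + 1:0{width}d}" for i in range(config.n_proteins)]


# ---------------------------------------------------------------------------
# Sequences + truth
# ---------------------------------------------------------------------------

def generate_sequences(
    config: GeneratorConfig,
) -> tuple[list[ProteinSequenceRecord], TruthLabels]:
    """Generate protein sequences and the complete planted ground truth.

    The first ``n_substrates`` proteins are substrates, each carrying
    ``n_pairs_per_substrate`` non-overlapping planted consensus pairs.
    Regulon membership and all planted effect sizes (site-level, parent
    protein and transcript/protein regulon effects) are drawn here from a
    dedicated effects stream, so downstream generators add measurement noise
    only.
    """
    rngs = _rng_children(config)
    rng_seq, rng_eff = rngs["sequences"], rngs["effects"]
    ids = _protein_ids(config)
    residues = np.array(list(AMINO_ACIDS))
    probs = np.array([RESIDUE_FREQUENCIES[a] for a in AMINO_ACIDS])

    records: list[ProteinSequenceRecord] = []
    planted: list[PlantedSite] = []
    for i, pid in enumerate(ids):
        length = max(60, int(rng_seq.poisson(config.mean_protein_length)))
        seq = rng_seq.choice(residues, size=length, p=probs)
        if i < config.n_substrates:
            # non-overlapping windows: slots spaced 9 residues apart
            n_slots = (length - 10) // 9
            k = config.n_pairs_per_substrate
            if n_slots < k:
                raise GeneratorConfigError(
                    "mean_protein_length too short for n_pairs_per_substrate"
                )
            slots = rng_seq.choice(n_slots, size=k, replace=False)
            for slot in sorted(slots):
                first0 = 5 + int(slot) * 9  # 0-based index of the first S/T
                seq[first0] = rng_seq.choice(["S", "T"])
                seq[first0 + 4] = rng_seq.choice(["S", "T"])
                primed = bool(
                    rng_eff.random() < config.fraction_primed_multiplicity_ge2
                )
                planted.append(
                    PlantedSite(
                        protein_id=pid,
                        first_pos=first0 + 1,
                        plus4_pos=first0 + 5,
                        effect_first=-config.effect_size_first_site,
                        effect_plus4=config.effect_size_plus4_site,
                        primed_only_multi=primed,
                    )
                )
        records.append(ProteinSequenceRecord(pid, "".join(seq)))

    # Regulon structure over the non-substrate genes.
    pool = ids[config.n_substrates:]
    n_mck1 = config.mck1_regulon_size
    n_both = int(round(config.regulon_overlap_fraction * n_mck1))
    n_gcn5_only = max(0, config.gcn5_regulon_size - n_both)
    chosen = list(rng_eff.choice(pool, size=min(len(pool), n_mck1 + n_gcn5_only),
                                 replace=False))
    membership = {g: "neither" for g in ids}
    mck1_genes = chosen[:n_mck1]
    for g in mck1_genes[:n_both]:
        membership[g] = "both"
    for g in mck1_genes[n_both:]:
        membership[g] = "mck1"
    for g in chosen[n_mck1:]:
        membership[g] = "gcn5"

    # Correlated transcript/protein effects for the kinase-activated regulon:
    # reduced in the mutant (the kinase is required for their induction).
    rho = config.transcript_protein_correlation
    transcript_lfc = {g: 0.0 for g in ids}
    protein_lfc = {g: 0.0 for g in ids}
    for g in mck1_genes:
        z1, z2 = rng_eff.standard_normal(2)
        zt = z1
        zp = rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * z2
        transcript_lfc[g] = -config.de_effect_mean + config.de_effect_sd * zt
        protein_lfc[g] = -config.de_effect_mean + config.de_effect_sd * zp

    # A fraction of substrates also change in parent-protein abundance.
    n_overlap = int(round(config.protein_effect_overlap * config.n_substrates))
    overlap_ids = list(
        rng_eff.choice(ids[: config.n_substrates], size=n_overlap, replace=False)
    ) if n_overlap else []
    for pid in overlap_ids:
        protein_lfc[pid] = config.protein_overlap_effect

    truth = TruthLabels(
        substrate_sites=planted,
        regulon_membership=membership,
        transcript_lfc=transcript_lfc,
        protein_lfc=protein_lfc,
        config_fingerprint=config.fingerprint(),
    )
    return records, truth


# ---------------------------------------------------------------------------
# Phosphosite table
# ---------------------------------------------------------------------------

def _censor(
    values: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Left-censoring mask: missingness probability is a logistic function of
    intensity (low-abundance records drop out first), calibrated so the
    overall missing fraction equals ``rate``."""
    if rate <= 0:
        return np.zeros(values.shape, dtype=bool)
    from scipy.optimize import brentq

    flat = values.ravel()
    sd = float(np.std(flat)) or 1.0
    scale = 0.5 * sd

    def mean_prob(x0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp((flat - x0) / scale)))) - rate

    lo, hi = flat.min() - 10 * sd, flat.max() + 10 * sd
    x0 = brentq(mean_prob, lo, hi, xtol=1e-9)
    probs = 1.0 / (1.0 + np.exp((values - x0) / scale))
    return rng.random(values.shape) < probs


def generate_phospho_table(
    config: GeneratorConfig, truth: TruthLabels
) -> pd.DataFrame:
    """Generate the site-level phosphopeptide quantification table.

    One row per (protein, position, residue, multiplicity) with per-sample
    log2-scale intensities.  Planted consensus pairs follow the priming
    model described in the module docstring; background sites carry no
    genotype effect beyond inherited parent-protein changes.
    """
    _check_truth(config, truth)
    rngs = _rng_children(config)
    rng = rngs["phospho"]
    records, _ = generate_sequences(config)
    seq_by_id = {r.protein_id: r.sequence for r in records}
    samples = config.sample_ids
    meta = parse_sample_names(samples)
    mutant = config.genotypes[1]
    pds = config.phases[-1]

    planted_positions: dict[str, set[int]] = {}
    for s in truth.substrate_sites:
        planted_positions.setdefault(s.protein_id, set()).update(
            (s.first_pos, s.plus4_pos)
        )

    rows: list[dict] = []

    def emit(pid: str, pos: int, mult: int, site_effect: float,
             loc_prob: float, base: float) -> None:
        seq = seq_by_id[pid]
        row: dict = {
            "protein_id": pid,
            "position": pos,
            "residue": seq[pos - 1],
            "multiplicity": mult,
            "localization_prob": round(loc_prob, 4),
        }
        sd = config.noise_sd_log2
        for sid in samples:
            g, ph = meta.loc[sid, "genotype"], meta.loc[sid, "phase"]
            x = base
            if g == mutant:
                x += site_effect
                if ph == pds:
                    x += truth.protein_lfc.get(pid, 0.0)
            if sd > 0:
                x += rng.normal(0.0, sd)
            row[sid] = x
        rows.append(row)

    mult_classes = np.array(sorted(_MULTIPLICITY_PROBS))
    mult_p = np.array([_MULTIPLICITY_PROBS[m] for m in mult_classes])

    for pid, seq in seq_by_id.items():
        sty = [i + 1 for i, aa in enumerate(seq) if aa in "STY"]
        taken = planted_positions.get(pid, set())
        avail = [p for p in sty if p not in taken]
        n_bg = min(len(avail), int(rng.poisson(config.background_sites_mean)))
        if n_bg:
            for pos in rng.choice(avail, size=n_bg, replace=False):
                emit(
                    pid,
                    int(pos),
                    int(rng.choice(mult_classes, p=mult_p)),
                    0.0,
                    float(rng.beta(9, 1)),
                    float(rng.normal(config.base_log2_intensity, 2.0)),
                )

    for site in truth.substrate_sites:
        base_first = float(rng.normal(config.base_log2_intensity, 1.5))
        base_plus4 = float(rng.normal(config.base_log2_intensity, 1.5))
        first_mult = 2 if site.primed_only_multi else 1
        loc = lambda: float(1.0 - 0.05 * rng.random())
        emit(site.protein_id, site.first_pos, first_mult,
             site.effect_first, loc(), base_first)
        if site.primed_only_multi:
            # the doubly phosphorylated species also reports at the +4 site
            emit(site.protein_id, site.plus4_pos, 2,
                 site.effect_first, loc(), base_first - 0.5)
        # priming gain: a monophosphorylated record at the +4 site
        emit(site.protein_id, site.plus4_pos, 1,
             site.effect_plus4, loc(), base_plus4)

    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["protein_id", "position", "multiplicity"], kind="stable"
    ).reset_index(drop=True)
    if config.missingness_rate > 0 and len(table):
        vals = table[samples].to_numpy(dtype=float)
        mask = _censor(vals, config.missingness_rate, rng)
        vals[mask] = np.nan
        table[samples] = vals
    return table


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def generate_expression_tables(
    config: GeneratorConfig, truth: TruthLabels
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Generate transcript (log2 counts) and protein (log2 intensity)
    matrices over the same gene universe as the proteins, with the planted
    regulon effects from ``truth`` applied to mutant post-diauxic samples."""
    _check_truth(config, truth)
    rng = _rng_children(config)["expression"]
    ids = _protein_ids(config)
    samples = config.sample_ids
    meta = parse_sample_names(samples)
    mutant = config.genotypes[1]
    pds = config.phases[-1]
    sd = config.noise_sd_log2
    is_effect_sample = np.array(
        [(meta.loc[s, "genotype"] == mutant and meta.loc[s, "phase"] == pds)
         for s in samples]
    )

    def layer(base_level: float, lfc: dict[str, float]) -> np.ndarray:
        base = rng.normal(base_level, 2.0, size=len(ids))
        effects = np.array([lfc.get(g, 0.0) for g in ids])
        x = base[:, None] + np.where(is_effect_sample[None, :], effects[:, None], 0.0)
        if sd > 0:
            x = x + rng.normal(0.0, sd, size=x.shape)
        return x

    tx = layer(config.base_log2_counts, truth.transcript_lfc)
    px = layer(config.base_log2_intensity, truth.protein_lfc)
    if config.missingness_rate > 0:
        mask = _censor(px, config.missingness_rate, rng)
        px = np.where(mask, np.nan, px)

    transcript = FeatureMatrix(
        pd.DataFrame(tx, index=pd.Index(ids, name="feature_id"), columns=samples),
        layer="transcript",
    )
    protein = FeatureMatrix(
        pd.DataFrame(px, index=pd.Index(ids, name="feature_id"), columns=samples),
        layer="protein",
    )
    return transcript, protein


# ---------------------------------------------------------------------------
# Whole-study convenience wrapper
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """All generated artifacts of one synthetic study."""

    config: GeneratorConfig
    sequences: list[ProteinSequenceRecord]
    truth: TruthLabels
    sites: pd.DataFrame
    transcript: FeatureMatrix
    protein: FeatureMatrix


def simulate_study(config: GeneratorConfig | None = None, **overrides) -> SyntheticStudy:
    """Run all three generators under one configuration."""
    if config is None:
        config = GeneratorConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    sequences, truth = generate_sequences(config)
    sites = generate_phospho_table(config, truth)
    transcript, protein = generate_expression_tables(config, truth)
    return SyntheticStudy(config, sequences, truth, sites, transcript, protein)
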