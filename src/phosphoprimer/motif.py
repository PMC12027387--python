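"""Gsk-3 consensus scanning and priming-site classification.

Gsk-3 family kinases phosphorylate the first S/T of an (S/T)XXX(S/T)
consensus, typically after a separate "priming" kinase has phosphorylated
the +4 (C-terminal) S/T.  In a kinase-deletion experiment this predicts a
characteristic signature per consensus pair: reduced phosphorylation at the
first position (often observable only on dual/multi-phosphopeptides,
multiplicity >= 2, because the primed species carries both groups) together
with enhanced monophosphorylation (multiplicity 1) at the +4 position,
where the primed intermediate accumulates.

All (i, i+4) S/T index pairs are reported, including overlapping ones — a
position may be the +4 site of one match and the first site of another, as
in real cascades of 4-spaced serines.  Tyrosine phosphosites are ingested
but never match the consensus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import ProteinSequenceRecord

CLASS_PRIMED_PAIR = "primed_pair"
CLASS_FIRST_ONLY = "first_reduced_only"
CLASS_PLUS4_ONLY = "plus4_only"
CLASS_NONE = "none"


@dataclass(frozen=True)
class ConsensusMatch:
    """One (S/T)XXX(S/T) occurrence; positions are 1-based."""

    protein_id: str
    first_pos: int
    plus4_pos: int
    window_sequence: str

    def __post_init__(self) -> None:
        if self.plus4_pos - self.first_pos != 4:
            raise ValueError("consensus positions must be spaced exactly 4")
        if len(self.window_sequence) != 5:
            raise ValueError("window must cover 5 residues")


def scan_consensus(record: ProteinSequenceRecord) -> list[ConsensusMatch]:
    """All (i, i+4) pairs with S/T at both positions, sorted by first_pos."""
    seq = record.sequence
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_st = (arr == ord("S")) | (arr == ord("T"))
    if len(arr) < 5:
        return []
    firsts = np.nonzero(is_st[:-4] & is_st[4:])[0]
    return [
        ConsensusMatch(record.protein_id, int(i) + 1, int(i) + 5, seq[i : i + 5])
        for i in firsts
    ]


def _site_calls_by_position(
    site_results: pd.DataFrame,
) -> dict[tuple[str, int], list[tuple[int, str]]]:
    """(protein, position) -> [(multiplicity, call), ...]."""
    needed = {"protein_id", "position", "multiplicity", "call"}
    missing = needed - set(site_results.columns)
    if missing:
        raise ValueError(f"site result table missing columns {sorted(missing)}")
    index: dict[tuple[str, int], list[tuple[int, str]]] = {}
    for row in site_results.itertuples():
        index.setdefault((row.protein_id, int(row.position)), []).append(
            (int(row.multiplicity), row.call)
        )
    return index


def map_sites_to_matches(
    matches: list[ConsensusMatch],
    site_results: pd.DataFrame,
    sequence_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Annotate consensus matches with differential phospho evidence.

    ``site_results`` carries one row per quantified site record with
    columns ``protein_id, position, multiplicity, call`` (calls at either
    the phosphorylation or the occupancy level — the caller chooses which
    table to pass).  Each match collects reduced evidence at its first
    position and enhanced evidence at its +4 position and is classified as
    ``primed_pair`` (both), ``first_reduced_only``, ``plus4_only`` or
    ``none``.  ``first_only_in_multi`` flags matches whose reduced
    first-site evidence is confined to multiplicity >= 2 records.
    """
    if sequence_lengths is not None:
        for row in site_results.itertuples():
            length = sequence_lengths.get(row.protein_id)
            if length is not None and row.position > length:
                raise ValueError(
                    f"site {row.protein_id}:{row.position} exceeds sequence "
                    f"length {length}"
                )
    by_pos = _site_calls_by_position(site_results)
    rows = []
    for m in matches:
        first_records = by_pos.get((m.protein_id, m.first_pos), [])
        plus4_records = by_pos.get((m.protein_id, m.plus4_pos), [])
        red = sorted(mult for mult, call in first_records if call == "reduced")
        enh = sorted(mult for mult, call in plus4_records if call == "enhanced")
        if red and enh:
            cls = CLASS_PRIMED_PAIR
        elif red:
            cls = CLASS_FIRST_ONLY
        elif enh:
            cls = CLASS_PLUS4_ONLY
        else:
            cls = CLASS_NONE
        rows.append(
            {
                "protein_id": m.protein_id,
                "first_pos": m.first_pos,
                "plus4_pos": m.plus4_pos,
                "window_sequence": m.window_sequence,
                "classification": cls,
                "first_reduced_multiplicities": tuple(red),
                "plus4_enhanced_multiplicities": tuple(enh),
                "first_only_in_multi": bool(red) and min(red) >= 2,
            }
        )
    columns = [
        "protein_id", "first_pos", "plus4_pos", "window_sequence",
        "classification", "first_reduced_multiplicities",
        "plus4_enhanced_multiplicities", "first_only_in_multi",
    ]
    return pd.DataFrame(rows, columns=columns)


def protein_summary(priming_calls: pd.DataFrame) -> pd.DataFrame:
    """Per-protein flags: any consensus match with reduced first-site
    evidence, and (among those) any full primed pair."""
    def summarize(grp: pd.DataFrame) -> pd.Series:
        has_first = grp["classification"].isin(
            [CLASS_PRIMED_PAIR, CLASS_FIRST_ONLY]
        ).any()
        return pd.Series(
            {
                "any_first_reduced": bool(has_first),
                "any_primed_pair": bool(
                    (grp["classification"] == CLASS_PRIMED_PAIR).any()
                ),
            }
        )

    if priming_calls.empty:
        return pd.DataFrame(columns=["any_first_reduced", "any_primed_pair"])
    return priming_calls.groupby("protein_id").apply(
        summarize, include_groups=False
    )


@dataclass(frozen=True)
class MultiplicityStats:
    """Multiplicity composition of the priming evidence.

    ``frac_first_only_multi``: among distinct first positions with reduced
    evidence, the fraction seen only on multiplicity >= 2 records.
    ``frac_plus4_mono``: among enhanced +4 evidence records, the fraction
    at multiplicity 1.  ``defined`` is False when there is no evidence at
    all (the fractions are then NaN rather than propagating silently).
    """

    frac_first_only_multi: float
    n_first_multi: int
    n_first_total: int
    frac_plus4_mono: float
    n_plus4_mono: int
    n_plus4_total: int
    defined: bool


def multiplicity_statistics(priming_calls: pd.DataFrame) -> MultiplicityStats:
    """Summarize evidence multiplicities over a priming-call table."""
    first_seen: dict[tuple[str, int], list[int]] = {}
    plus4_records: list[int] = []
    for row in priming_calls.itertuples():
        if row.first_reduced_multiplicities:
            first_seen.setdefault(
                (row.protein_id, row.first_pos), []
            ).extend(row.first_reduced_multiplicities)
        plus4_records.extend(row.plus4_enhanced_multiplicities)
    n_first_total = len(first_seen)
    n_first_multi = sum(1 for mults in first_seen.values() if min(mults) >= 2)
    n_plus4_total = len(plus4_records)
    n_plus4_mono = sum(1 for m in plus4_records if m == 1)
    defined = n_first_total > 0 or n_plus4_total > 0
    return MultiplicityStats(
        frac_first_only_multi=(
            n_first_multi / n_first_total if n_first_total else float("nan")
        ),
        n_first_multi=n_first_multi,
        n_first_total=n_first_total,
        frac_plus4_mono=(
            n_plus4_mono / n_plus4_total if n_plus4_total else float("nan")
        ),
        n_plus4_mono=n_plus4_mono,
        n_plus4_total=n_plus4_total,
        defined=defined,
    )


def _has_first_site_match(
    sequence: str, phospho_positions: set[int]
) -> bool:
    """Does any (i, i+4) S/T pair start at a phosphosite position?"""
    for pos in phospho_positions:
        i = pos - 1
        if i + 4 < len(sequence) and sequence[i] in "ST" and sequence[i + 4] in "ST":
            return True
    return False


def consensus_enrichment(
    substrate_proteins: set[str],
    background_proteins: set[str],
    sequences: dict[str, str] | list[ProteinSequenceRecord],
    phospho_positions: dict[str, set[int]],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Enrichment of first-site-phosphorylated consensus matches.

    The statistic is the fraction of substrate proteins carrying at least
    one consensus match whose first position is a phosphosite (from
    ``phospho_positions``, e.g. the reduced-call positions) minus the same
    fraction among background proteins.  The empirical p-value shuffles
    residues within each protein (preserving composition, keeping
    phosphosite positions fixed) and counts null statistics at least as
    large: p = (1 + #null >= observed) / (n_shuffles + 1).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if isinstance(sequences, list):
        sequences = {r.protein_id: r.sequence for r in sequences}

    def statistic(seqs: dict[str, str]) -> float:
        def frac(ids: set[str]) -> float:
            if not ids:
                return 0.0
            hits = sum(
                _has_first_site_match(seqs[p], phospho_positions.get(p, set()))
                for p in ids
            )
            return hits / len(ids)

        return frac(substrate_proteins) - frac(background_proteins)

    observed = statistic(sequences)
    rng = np.random.default_rng(seed)
    involved = substrate_proteins | background_proteins
    arrays = {p: np.array(list(sequences[p])) for p in involved}
    n_ge = 0
    for _ in range(n_shuffles):
        shuffled = {
            p: "".join(rng.permutation(a)) for p, a in arrays.items()
        }
        if statistic(shuffled) >= observed:
            n_ge += 1
    p = (1 + n_ge) / (n_shuffles + 1)
    return observed, p
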