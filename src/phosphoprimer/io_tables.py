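"""Readers, writers and in-memory containers for the pipeline's tabular data.

Conventions
-----------
* Residue coordinates are 1-based throughout (``S113`` is the 113th residue).
* Per-sample intensity columns are named ``<genotype>_<phase>_<replicate>``
  (e.g. ``WT_PDS_2``); sample metadata is recovered by parsing the name.
* Absent intensities are empty TSV fields and ``NaN`` in memory — distinct
  from a measured zero; absence is what triggers imputation downstream.

The module also packages transcriptions of two published result tables
(gene-level transcript/protein fold changes of kinase-activated genes, and
consensus-bearing phosphoproteins with their site/multiplicity strings) as
plain-TSV fixtures for worked-example tests.  These fixtures are manual
transcriptions of printed tables, not machine-readable originals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

SITE_META_COLUMNS = [
    "protein_id",
    "position",
    "residue",
    "multiplicity",
    "localization_prob",
]


class TableFormatError(ValueError):
    """A tabular input violates the documented schema."""


@dataclass(frozen=True)
class ProteinSequenceRecord:
    """A protein sequence with 1-based residue coordinates."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.protein_id!r}")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.protein_id!r}: non-standard residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_at(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"position {position} outside 1..{len(self.sequence)} "
                f"of {self.protein_id}"
            )
        return self.sequence[position - 1]


_SAMPLE_NAME_RE = re.compile(r"^(?P<genotype>[^_]+)_(?P<phase>[^_]+)_(?P<rep>\d+)$")


def parse_sample_names(sample_ids: Sequence[str]) -> pd.DataFrame:
    """Decode ``genotype_phase_replicate`` column names into a metadata frame."""
    rows = []
    for name in sample_ids:
        m = _SAMPLE_NAME_RE.match(name)
        if m is None:
            raise TableFormatError(
                f"sample column {name!r} does not follow genotype_phase_rep"
            )
        rows.append(
            {
                "sample_id": name,
                "genotype": m["genotype"],
                "phase": m["phase"],
                "replicate": int(m["rep"]),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class FeatureMatrix:
    """Features x samples intensity/count matrix with sample metadata.

    ``values`` holds one row per feature and one column per sample; ``NaN``
    marks an absent measurement.  ``layer`` names the molecular layer
    (``transcript``, ``protein`` or ``phospho``).
    """

    values: pd.DataFrame
    layer: str
    sample_metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()][:3]
            raise TableFormatError(
                f"duplicate feature ids in {self.layer} layer: {list(dupes)}"
            )
        if self.sample_metadata is None:
            self.sample_metadata = parse_sample_names(list(self.values.columns))
        if list(self.sample_metadata.index) != list(self.values.columns):
            raise TableFormatError("sample metadata does not match value columns")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy(), self.layer, self.sample_metadata.copy()
        )

    def samples_for(self, genotype: str | None = None, phase: str | None = None) -> list[str]:
        meta = self.sample_metadata
        keep = pd.Series(True, index=meta.index)
        if genotype is not None:
            keep &= meta["genotype"] == genotype
        if phase is not None:
            keep &= meta["phase"] == phase
        return list(meta.index[keep])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinSequenceRecord]:
    """Read protein sequences, preserving order and enforcing unique ids."""
    records: list[ProteinSequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise TableFormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinSequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise TableFormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinSequenceRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Phosphosite tables
# ---------------------------------------------------------------------------

def read_site_table(
    path: str | Path, min_localization: float = 0.75
) -> tuple[pd.DataFrame, int]:
    """Read a site-level phosphopeptide quantification TSV.

    One row per (protein, position, multiplicity).  Rows whose localization
    probability falls below ``min_localization`` are excluded, mirroring the
    standard class-I site filter.  Returns ``(table, n_excluded)``.
    """
    if not 0.0 <= min_localization <= 1.0:
        raise ValueError("min_localization must lie in [0, 1]")
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = [c for c in SITE_META_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"site table missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in SITE_META_COLUMNS]
    parse_sample_names(sample_cols)  # raises on unknown sample column
    if not df["multiplicity"].isin([1, 2, 3]).all():
        bad = sorted(set(df["multiplicity"]) - {1, 2, 3})
        raise TableFormatError(f"multiplicity values outside {{1,2,3}}: {bad}")
    if ((df["localization_prob"] < 0) | (df["localization_prob"] > 1)).any():
        raise TableFormatError("localization_prob outside [0, 1]")
    if not df["residue"].isin(list("STY")).all():
        raise TableFormatError("phosphosite residue must be S, T or Y")
    keep = df["localization_prob"] >= min_localization
    n_excluded = int((~keep).sum())
    out = df.loc[keep].reset_index(drop=True)
    out[sample_cols] = out[sample_cols].astype(float)
    return out, n_excluded


def write_site_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a site table; NaN intensities become empty fields."""
    table.to_csv(path, sep="\t", index=False, na_rep="")


def site_feature_key(
    protein_id: str, position: int, residue: str, multiplicity: int
) -> str:
    """Stable feature id for one site x multiplicity record."""
    return f"{protein_id}|{residue}{position}|m{multiplicity}"


_SITE_KEY_RE = re.compile(r"^(?P<pid>.+)\|(?P<res>[STY])(?P<pos>\d+)\|m(?P<mult>[123])$")


def parse_site_feature_key(key: str) -> tuple[str, int, str, int]:
    m = _SITE_KEY_RE.match(key)
    if m is None:
        raise ValueError(f"not a site feature key: {key!r}")
    return m["pid"], int(m["pos"]), m["res"], int(m["mult"])


def site_feature_matrix(table: pd.DataFrame) -> FeatureMatrix:
    """Reshape a site table into a phospho-layer :class:`FeatureMatrix`."""
    sample_cols = [c for c in table.columns if c not in SITE_META_COLUMNS]
    keys = [
        site_feature_key(r.protein_id, int(r.position), r.residue, int(r.multiplicity))
        for r in table.itertuples()
    ]
    values = table[sample_cols].copy()
    values.index = pd.Index(keys, name="feature_id")
    return FeatureMatrix(values, layer="phospho")


# ---------------------------------------------------------------------------
# Feature matrices (transcript / protein)
# ---------------------------------------------------------------------------

def read_feature_matrix(path: str | Path, layer: str) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return FeatureMatrix(df.astype(float), layer=layer)


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# Site-string parsing ("S1325(2); S1328(2); S1329(2)")
# ---------------------------------------------------------------------------

_SITE_TOKEN_RE = re.compile(r"^(?P<res>[STY])(?P<pos>\d+)\((?P<mult>\d)\)$")


def parse_site_string(text: str) -> list[tuple[str, int, int]]:
    """Parse a printed phosphosite list into (residue, position, multiplicity).

    The notation is the one used in published site tables: semicolon-separated
    ``S1325(2)`` tokens, where the digit in parentheses is the phospho
    multiplicity class of the quantified peptide species.  The same position
    may recur with different multiplicities.
    """
    if text is None or not text.strip():
        return []
    out: list[tuple[str, int, int]] = []
    for raw in text.split(";"):
        token = raw.strip()
        if not token:
            raise TableFormatError(f"empty site token in {text!r}")
        m = _SITE_TOKEN_RE.match(token)
        if m is None:
            raise TableFormatError(f"malformed site token {token!r}")
        mult = int(m["mult"])
        if mult not in (1, 2, 3):
            raise TableFormatError(f"multiplicity {mult} outside 1..3 in {token!r}")
        out.append((m["res"], int(m["pos"]), mult))
    return out


# ---------------------------------------------------------------------------
# Packaged table fixtures
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {"table1": "table1.tsv", "table2": "table2.tsv"}


@dataclass(frozen=True)
class PaperTableFixture:
    """A transcription of a printed results table, loaded losslessly."""

    table_id: str
    rows: pd.DataFrame


def load_fixture(table_id: str) -> PaperTableFixture:
    """Load a packaged results-table transcription.

    ``table1``: kinase-activated genes with transcript and protein log2 fold
    changes and a flag for genes bound/activated by the Cat8/Adr1
    transcription factors.  ``table2``: consensus-bearing phosphoproteins by
    functional category with reduced (log2FC < -1) and enhanced (log2FC > 1)
    phosphosite strings, each site annotated with its multiplicity.
    """
    if table_id not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {table_id!r}; expected one of "
                       f"{sorted(_FIXTURE_FILES)}")
    ref = resources.files("phosphoprimer.data") / _FIXTURE_FILES[table_id]
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", keep_default_na=False)
    if table_id == "table1":
        df["cat8_adr1_target"] = df["cat8_adr1_target"].astype(bool)
        df["log2fc_rna"] = df["log2fc_rna"].astype(float)
        df["log2fc_protein"] = df["log2fc_protein"].astype(float)
    else:
        df["in_signaling"] = df["in_signaling"].astype(bool)
        df["in_polii"] = df["in_polii"].astype(bool)
        for col in ("reduced_sites", "enhanced_sites"):
            df[col].map(parse_site_string)  # validates the transcription
    return PaperTableFixture(table_id, df)


def load_gene_set(path: str | Path) -> list[str]:
    """Read a gene-set file, one symbol per line, '#' comments allowed."""
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        name = line.split("#", 1)[0].strip()
        if name:
            genes.append(name)
    if len(set(genes)) != len(genes):
        raise TableFormatError(f"duplicate gene symbols in {path}")
    return genes
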