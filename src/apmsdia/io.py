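"""Readers, writers and validation for the pipeline's file formats.

The raw input is a long-format fragment-intensity table (one row per
protein/peptide/fragment/sample) together with a sample-design table that
maps each MS injection to its experimental background (tagged bait vs
untagged control), stimulation condition, time point, biological replicate
and SILAC channel. Missing intensities are encoded as *empty cells*, never
as zero: the downstream imputation rule must be able to distinguish
"not detected" from "observed low".

All identifiers are opaque strings; no accession parsing is attempted so
that both simulator output and real spectral-extraction exports work.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FRAGMENT_COLUMNS = ["protein_id", "peptide_id", "fragment_id", "sample_id", "intensity"]
DESIGN_COLUMNS = ["sample_id", "background", "condition", "time_min", "replicate", "silac_channel"]

BACKGROUNDS = frozenset({"tagged_bait", "untagged_control"})
SILAC_CHANNELS = frozenset({"none", "light", "heavy"})

#: residues accepted in input sequences: the 20 standard amino acids plus
#: selenocysteine (U) and unknown (X)
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" + "UX")


class FormatError(ValueError):
    """A file does not conform to the documented table layout."""


class ValidationError(ValueError):
    """A file parses but violates a data-model invariant."""


# ---------------------------------------------------------------------------
# fragment table


def read_fragment_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format fragment-intensity TSV.

    Columns: protein_id, peptide_id, fragment_id, sample_id, intensity.
    An empty intensity cell means "not detected" and becomes NaN.
    Row order is preserved; duplicate (protein, peptide, fragment, sample)
    keys and negative intensities are rejected.
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[""]
    )
    for col in FRAGMENT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"fragment table {path}: missing required column {col!r}")
    df = df[FRAGMENT_COLUMNS].copy()
    try:
        df["intensity"] = pd.to_numeric(df["intensity"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"fragment table {path}: non-numeric intensity ({exc})") from None
    df["intensity"] = df["intensity"].astype(float)
    validate_fragment_table(df)
    return df


def validate_fragment_table(df: pd.DataFrame) -> None:
    key = ["protein_id", "peptide_id", "fragment_id", "sample_id"]
    for col in key:
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0]) + 1
            raise ValidationError(f"fragment table: empty {col} at data row {row}")
    neg = df["intensity"] < 0
    if neg.any():
        row = int(df.index[neg][0]) + 1
        raise ValidationError(f"fragment table: negative intensity at data row {row}")
    dup = df.duplicated(subset=key)
    if dup.any():
        row = int(df.index[dup][0]) + 1
        raise ValidationError(
            f"fragment table: duplicate (protein, peptide, fragment, sample) key at data row {row}"
        )


def write_fragment_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a fragment table; NaN intensities become empty cells."""
    df[FRAGMENT_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="", lineterminator="\n")


# ---------------------------------------------------------------------------
# sample design


def read_design(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-sample design TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    for col in DESIGN_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"design table {path}: missing required column {col!r}")
    df = df[DESIGN_COLUMNS].copy()
    df["time_min"] = pd.to_numeric(df["time_min"], errors="raise").astype(float)
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    validate_design(df)
    return df


def validate_design(df: pd.DataFrame) -> None:
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"design: duplicate sample_id {dup!r}")
    bad_bg = set(df["background"]) - BACKGROUNDS
    if bad_bg:
        raise ValidationError(
            f"design: unknown background value(s) {sorted(bad_bg)}; expected one of {sorted(BACKGROUNDS)}"
        )
    bad_ch = set(df["silac_channel"]) - SILAC_CHANNELS
    if bad_ch:
        raise ValidationError(
            f"design: unknown silac_channel value(s) {sorted(bad_ch)}; expected one of {sorted(SILAC_CHANNELS)}"
        )
    if (df["time_min"] < 0).any():
        raise ValidationError("design: time_min must be >= 0")
    if (df["replicate"] < 1).any():
        raise ValidationError("design: replicate must be >= 1")


def write_design(df: pd.DataFrame, path: str | Path) -> None:
    out = df[DESIGN_COLUMNS].copy()
    out["time_min"] = out["time_min"].map(lambda t: format(float(t), "g"))
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def check_samples_in_design(table: pd.DataFrame, design: pd.DataFrame) -> None:
    """Every fragment row's sample must resolve to exactly one design row."""
    unknown = set(table["sample_id"].unique()) - set(design["sample_id"])
    if unknown:
        raise ValidationError(f"samples absent from design: {sorted(unknown)[:5]}")


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load protein sequences; the header's first whitespace token is the id."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        seq = str(rec.seq).upper()
        if pid in seqs:
            raise ValidationError(f"FASTA: duplicate protein id {pid!r}")
        if not seq:
            raise ValidationError(f"FASTA: empty sequence for {pid!r}")
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise ValidationError(f"FASTA: invalid residue(s) {sorted(bad)} in {pid!r}")
        seqs[pid] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=pid, description="") for pid, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# contaminants


@dataclasses.dataclass(frozen=True)
class ContaminantList:
    """Affinity-purification contaminant blacklist.

    ``exact`` entries match whole identifiers; ``prefixes`` match identifier
    prefixes (used for whole families such as keratins, myosins, tubulins).
    Matching is case-insensitive.
    """

    exact: frozenset[str] = frozenset()
    prefixes: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.exact) + len(self.prefixes)

    def matches(self, protein_id: str) -> bool:
        pid = protein_id.lower()
        return pid in self.exact or any(pid.startswith(p) for p in self.prefixes)

    @classmethod
    def from_identifiers(cls, ids: Iterable[str]) -> "ContaminantList":
        exact, prefixes = set(), []
        for raw in ids:
            token = raw.strip()
            if not token or token.startswith("#"):
                continue
            if token.endswith("*"):
                prefixes.append(token[:-1].lower())
            else:
                exact.add(token.lower())
        return cls(exact=frozenset(exact), prefixes=tuple(sorted(set(prefixes))))

    @classmethod
    def from_file(cls, path: str | Path) -> "ContaminantList":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        lst = cls.from_identifiers(lines)
        if len(lst) == 0:
            raise ValidationError(f"contaminant list {path} is empty")
        return lst


# ---------------------------------------------------------------------------
# results


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write output tables as byte-stable TSV files.

    Tables carrying (q_value, protein_id) columns are sorted by ascending
    q then protein id so repeated runs produce byte-identical files.
    Returns a name -> path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        table = df.copy()
        if "q_value" in table.columns and "protein_id" in table.columns:
            table = table.sort_values(
                ["q_value", "protein_id"], kind="mergesort"
            ).reset_index(drop=True)
        path = out / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, na_rep="", lineterminator="\n")
        paths[name] = path
    return paths


def matrix_to_frame(matrix: pd.DataFrame) -> pd.DataFrame:
    """Flatten a quant matrix (analyte index x sample columns) for writing."""
    return matrix.reset_index()
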