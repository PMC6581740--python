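"""Interaction stoichiometry via iBAQ with in-silico tryptic digestion.

iBAQ (intensity-based absolute quantification) divides a protein's summed
intensity by its number of theoretically observable tryptic peptides,
giving a quantity proportional to molar abundance. The stoichiometry of a
bait-prey interaction is then the prey's iBAQ divided by the bait's iBAQ
in the same condition: the fraction of bait molecules occupied by that
prey. Digestion is fully tryptic (cleave after K or R except before P) with
no missed cleavages and a 6-30 residue observable window by default; the
convention is configurable and recorded with the results.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from pyteomics import parser as pyt_parser

from .io import ValidationError

#: cleave C-terminal to K or R unless the next residue is proline
TRYPSIN_RULE = r"[KR](?!P)"


@dataclasses.dataclass(frozen=True)
class DigestParams:
    """In-silico digestion settings (original iBAQ convention)."""

    protease: str = "trypsin"
    min_len: int = 6
    max_len: int = 30
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.protease != "trypsin":
            raise ValueError(f"unsupported protease {self.protease!r}")
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("require 1 <= min_len <= max_len")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


def digest(sequence: str, params: DigestParams = DigestParams()) -> set[str]:
    """Unique tryptic peptides of a sequence within the observable length window."""
    peptides = pyt_parser.cleave(
        sequence.upper(), TRYPSIN_RULE, missed_cleavages=params.missed_cleavages
    )
    return {p for p in peptides if params.min_len <= len(p) <= params.max_len}


def theoretical_peptide_count(sequence: str, params: DigestParams = DigestParams()) -> int:
    """Number of theoretically observable tryptic peptides (iBAQ denominator)."""
    return len(digest(sequence, params))


def compute_ibaq(
    protein_matrix: pd.DataFrame,
    sequences: Mapping[str, str],
    params: DigestParams = DigestParams(),
    samples: Iterable[str] | None = None,
    proteins: Iterable[str] | None = None,
) -> pd.DataFrame:
    """iBAQ per protein: mean raw quantity over selected samples / peptide count.

    The matrix must be imputed (raw scale). Proteins whose digestion
    yields zero observable peptides get NaN iBAQ and are flagged; a
    missing sequence raises, listing the offending proteins.
    """
    if proteins is None:
        proteins = list(protein_matrix.index)
    else:
        proteins = list(proteins)
        absent = [p for p in proteins if p not in protein_matrix.index]
        if absent:
            raise ValidationError(f"proteins absent from matrix: {absent}")
    no_seq = [p for p in proteins if p not in sequences]
    if no_seq:
        raise ValidationError(f"no sequence for protein(s): {no_seq}")
    cols = list(samples) if samples is not None else list(protein_matrix.columns)
    missing_cols = [c for c in cols if c not in protein_matrix.columns]
    if missing_cols:
        raise ValidationError(f"samples absent from matrix: {missing_cols}")
    quantity = protein_matrix.loc[proteins, cols].mean(axis=1)
    counts = pd.Series(
        {p: theoretical_peptide_count(sequences[p], params) for p in proteins}
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ibaq = quantity / counts.replace(0, np.nan)
    return pd.DataFrame(
        {
            "protein_id": proteins,
            "mean_quantity": quantity.to_numpy(),
            "peptide_count": counts.to_numpy(),
            "ibaq": ibaq.to_numpy(),
            "undigestable": (counts == 0).to_numpy(),
        }
    ).reset_index(drop=True)


def stoichiometry(ibaq_table: pd.DataFrame, bait_id: str, condition: str = "") -> pd.DataFrame:
    """Prey iBAQ relative to bait iBAQ, as fraction and percentage.

    The bait's own row is exactly 1 (100%). Invariant to any global
    rescaling of intensities.
    """
    table = ibaq_table.set_index("protein_id")
    if bait_id not in table.index:
        raise ValidationError(f"bait {bait_id!r} absent from iBAQ table")
    bait_ibaq = table.loc[bait_id, "ibaq"]
    if not np.isfinite(bait_ibaq) or bait_ibaq <= 0:
        raise ValidationError(f"bait {bait_id!r} has non-positive or undefined iBAQ")
    frac = table["ibaq"] / bait_ibaq
    out = pd.DataFrame(
        {
            "protein_id": table.index,
            "ibaq": table["ibaq"].to_numpy(),
            "stoichiometry_fraction": frac.to_numpy(),
            "stoichiometry_pct": 100.0 * frac.to_numpy(),
        }
    ).reset_index(drop=True)
    out["condition"] = condition
    return out
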