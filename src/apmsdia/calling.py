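"""Two-step interactor calling, contaminant removal, and report tables.

Step 1 (specific interactors): a protein is enriched in a condition when
its median log2 fold change against the matched untagged control exceeds
log2(fc_threshold) with BH-adjusted FDR below ``enrichment_fdr``; it is a
*specific* interactor when enriched in at least ``min_conditions``
independent conditions and not matched by the contaminant blacklist.
Presets follow the study: 3-fold for primary mouse T cells, 6-fold for
Jurkat cells, FDR < 0.01, at least two conditions.

Step 2 (dynamic interactors): among specific interactors, those whose
bait-normalized quantity changes at least ``dynamic_fc_threshold``-fold in
either direction (FDR < ``dynamic_fdr``) between a stimulated and the
unstimulated condition.

Removed contaminants are reported, never silently dropped; the bait and
tag entries are excluded from calling but kept in the report tables.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import ContaminantList, ValidationError

#: proteins the study removed for presence in the AP-MS contaminant
#: repository, plus family prefix rules for keratins, myosins and tubulins
DEFAULT_CONTAMINANTS = ContaminantList.from_identifiers(
    [
        "EEF1A1",
        "GAPDH",
        "HSP90AB1",
        "HSPA5",
        "HSPA8",
        "KRT33B",
        "TUBA1A",
        "TUBA1B",
        "TUBB",
        "TUBA4A",
        "TUBB4B",
        "KRT*",
        "MYH*",
        "MYL*",
        "TUB*",
    ]
)

FC_PRESETS = {"mouse": 3.0, "jurkat": 6.0}


@dataclasses.dataclass(frozen=True)
class CallingParams:
    """Thresholds for the two orthogonal filters."""

    enrichment_fc_threshold: float = 3.0
    enrichment_fdr: float = 0.01
    min_conditions: int = 2
    dynamic_fc_threshold: float = 2.0
    dynamic_fdr: float = 0.05

    def __post_init__(self) -> None:
        if self.enrichment_fc_threshold <= 1 or self.dynamic_fc_threshold <= 0:
            raise ValueError("fold-change thresholds must exceed 1 (enrichment) / 0 (dynamic)")
        if not (0 < self.enrichment_fdr < 1) or not (0 < self.dynamic_fdr < 1):
            raise ValueError("FDR thresholds must lie in (0, 1)")
        if self.min_conditions < 1:
            raise ValueError("min_conditions must be >= 1")

    @classmethod
    def preset(cls, name: str, **overrides) -> "CallingParams":
        return cls(enrichment_fc_threshold=FC_PRESETS[name], **overrides)


def call_specific(
    stats_per_condition: Mapping[str, pd.DataFrame],
    params: CallingParams = CallingParams(),
    contaminants: ContaminantList = DEFAULT_CONTAMINANTS,
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Apply the enrichment filter across conditions and the contaminant filter.

    ``stats_per_condition`` maps a condition label to a protein-stats
    table (protein_id, median_log2_fc, q_value, ...) from a bait-versus-
    control contrast on un-normalized quantities. The enrichment gate is
    one-sided (bait above control). Returns one row per tested protein.
    """
    if not stats_per_condition:
        raise ValidationError("call_specific requires at least one condition contrast")
    exclude = set(exclude)
    log2_thr = math.log2(params.enrichment_fc_threshold)

    per_protein: dict[str, dict] = {}
    for label, stats in stats_per_condition.items():
        for row in stats.itertuples(index=False):
            rec = per_protein.setdefault(
                row.protein_id, {"enriched": [], "best_q": math.inf}
            )
            rec["best_q"] = min(rec["best_q"], float(row.q_value))
            if row.median_log2_fc > log2_thr and row.q_value < params.enrichment_fdr:
                rec["enriched"].append(label)

    rows = []
    for pid in sorted(per_protein):
        rec = per_protein[pid]
        n_enriched = len(rec["enriched"])
        passes = n_enriched >= params.min_conditions
        is_contam = contaminants.matches(pid)
        excluded = pid in exclude
        rows.append(
            {
                "protein_id": pid,
                "enriched_conditions": ";".join(sorted(rec["enriched"])),
                "n_enriched": n_enriched,
                "is_specific": passes and not is_contam and not excluded,
                "is_dynamic": False,
                "removed_as_contaminant": passes and is_contam,
                "excluded": excluded,
                "best_q": rec["best_q"],
            }
        )
    return pd.DataFrame(rows)


def call_dynamic(
    stats_per_contrast: Mapping[str, pd.DataFrame],
    specific_calls: pd.DataFrame,
    params: CallingParams = CallingParams(),
) -> pd.DataFrame:
    """Flag specific interactors as dynamic from bait-normalized contrasts.

    A specific interactor is dynamic when, in at least one stimulated-
    versus-unstimulated contrast of bait-normalized quantities, its
    |median log2 fold change| is at least log2(dynamic_fc_threshold) with
    q below ``dynamic_fdr``. Two-sided: recruitment and loss both count.
    """
    if "is_specific" not in specific_calls.columns or not specific_calls["is_specific"].any():
        raise ValidationError("dynamic filter requires non-empty specific calls")
    log2_thr = math.log2(params.dynamic_fc_threshold)
    dynamic: set[str] = set()
    specific = set(specific_calls.loc[specific_calls["is_specific"], "protein_id"])
    for stats in stats_per_contrast.values():
        hits = stats.loc[
            (stats["median_log2_fc"].abs() >= log2_thr)
            & (stats["q_value"] < params.dynamic_fdr),
            "protein_id",
        ]
        dynamic.update(set(hits) & specific)
    out = specific_calls.copy()
    out["is_dynamic"] = out["protein_id"].isin(dynamic) & out["is_specific"]
    return out


def volcano_table(stats: pd.DataFrame) -> pd.DataFrame:
    """Projection of protein stats onto volcano-plot coordinates."""
    out = stats[["protein_id", "median_log2_fc", "q_value"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_q"] = -np.log10(out["q_value"].to_numpy(dtype=float))
    out = out.drop(columns="q_value")
    return out.sort_values("protein_id", kind="mergesort").reset_index(drop=True)


def heatmap_table(
    protein_matrix: pd.DataFrame,
    interactors: Iterable[str],
    design: pd.DataFrame,
    background: str = "tagged_bait",
) -> pd.DataFrame:
    """Per-time mean intensities of interactors, row-normalized to each row's maximum.

    Uses the tagged-bait samples; each row's values end up in [0, 1] with
    the maximum exactly 1.
    """
    interactors = list(interactors)
    if not interactors:
        raise ValidationError("heatmap_table requires at least one interactor")
    absent = [p for p in interactors if p not in protein_matrix.index]
    if absent:
        raise ValidationError(f"proteins absent from matrix: {absent}")
    sel = design.loc[design["background"] == background]
    times = sorted(sel["time_min"].unique())
    means = pd.DataFrame(index=pd.Index(interactors, name="protein_id"))
    for t in times:
        cols = [c for c in sel.loc[sel["time_min"] == t, "sample_id"] if c in protein_matrix.columns]
        means[f"t{t:g}"] = protein_matrix.loc[interactors, cols].mean(axis=1)
    row_max = means.max(axis=1)
    zero = ~(row_max > 0)
    if zero.any():
        raise ValidationError(f"all-zero intensity row for protein {row_max.index[zero][0]!r}")
    return means.div(row_max, axis=0).reset_index()


def phospho_site_profile(
    peptide_matrix: pd.DataFrame,
    protein_matrix: pd.DataFrame,
    phospho_peptide_id: str,
    unmodified_peptide_id: str,
    bait_id: str,
    imputed_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Bait-normalized per-sample profiles of a phosphosite's two forms.

    Each form's peptide quantity is divided by the bait protein quantity
    in the same sample; imputation flags are propagated when the peptide
    imputation mask is supplied. Returns a tidy frame (sample_id, form,
    peptide_id, normalized_intensity, was_imputed).
    """
    if bait_id not in protein_matrix.index:
        raise ValidationError(f"bait {bait_id!r} absent from protein matrix")
    bait = protein_matrix.loc[bait_id]
    pep_index = peptide_matrix.index.get_level_values("peptide_id")
    frames = []
    for form, pep_id in (("phospho", phospho_peptide_id), ("unmodified", unmodified_peptide_id)):
        hit = pep_index == pep_id
        if not hit.any():
            raise ValidationError(f"unknown peptide id {pep_id!r}")
        row = peptide_matrix.loc[hit].iloc[0]
        normalized = row / bait.reindex(row.index)
        flags = (
            imputed_mask.loc[hit].iloc[0].reindex(row.index)
            if imputed_mask is not None
            else pd.Series(False, index=row.index)
        )
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": row.index,
                    "form": form,
                    "peptide_id": pep_id,
                    "normalized_intensity": normalized.to_numpy(),
                    "was_imputed": flags.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
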