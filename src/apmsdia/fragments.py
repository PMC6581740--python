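"""Fragment reliability filtering, roll-up, imputation and bait normalization.

Mirrors the fragment-level preprocessing of a SWATH/DIA AP-MS analysis:

1. a detection filter keeps a fragment's rows within a condition group
   (background x condition x time) only if it was observed at least
   ``min_detect`` times in that group;
2. a reliability filter drops fragments whose log2 profile disagrees with
   the across-fragment median profile of their peptide (a minimal Pearson
   correlation and a standard-deviation-factor rule, in the spirit of
   mapDIA's fragment selection);
3. roll-up sums retained fragment intensities to peptide quantities and
   peptide quantities to protein quantities;
4. missing analyte values are imputed with a low quantile (default 0.01)
   of that analyte's observed values across all samples;
5. quantities can be normalized per sample to the bait's quantity for the
   dynamic-interactor analysis.

Filters only remove rows — they never alter intensities.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import ValidationError, check_samples_in_design
from .simulate import PHOSPHO_TOKEN

FRAG_KEY = ["protein_id", "peptide_id", "fragment_id"]
GROUP_COLS = ["background", "condition", "time_min"]

#: absolute tolerance (log2 units) below which profile deviations are
#: treated as zero, so numerically identical profiles are never split
DEVIATION_EPS = 1e-9


@dataclasses.dataclass(frozen=True)
class FilterParams:
    """Fragment-filter and imputation settings (defaults follow the study)."""

    min_detect: int = 2
    sd_factor: float = 2.0
    min_correlation: float = 0.25
    impute_quantile: float = 0.01

    def __post_init__(self) -> None:
        if self.min_detect < 1:
            raise ValueError("min_detect must be >= 1")
        if self.sd_factor <= 0:
            raise ValueError("sd_factor must be positive")
        if not (-1.0 <= self.min_correlation <= 1.0):
            raise ValueError("min_correlation must lie in [-1, 1]")
        if not (0.0 < self.impute_quantile < 1.0):
            raise ValueError("impute_quantile must lie in (0, 1)")


def detection_filter(
    table: pd.DataFrame, design: pd.DataFrame, min_detect: int = 2
) -> pd.DataFrame:
    """Keep a fragment's rows per condition group only if observed >= min_detect times.

    Groups are (background, condition, time_min); each group of the same
    fragment is judged independently. SILAC channels within a group count
    toward the same group (the paper filters per condition, not per channel).
    """
    if table.empty:
        return table.copy()
    check_samples_in_design(table, design)
    merged = table.merge(design[["sample_id"] + GROUP_COLS], on="sample_id", how="left")
    detected = merged["intensity"].notna()
    counts = (
        detected.groupby(
            [merged[c] for c in FRAG_KEY] + [merged[c] for c in GROUP_COLS]
        ).transform("sum")
    )
    keep = counts >= min_detect
    return table.loc[keep.to_numpy()].copy()


def _log2_pivot(table: pd.DataFrame) -> pd.DataFrame:
    wide = table.set_index(FRAG_KEY + ["sample_id"])["intensity"].unstack("sample_id")
    with np.errstate(divide="ignore"):
        return np.log2(wide)


def _masked_corr_with_reference(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of x with ref over shared observed entries.

    Returns NaN where fewer than 3 shared samples or zero variance —
    callers treat NaN as "cannot judge, keep".
    """
    mask = ~np.isnan(x) & ~np.isnan(ref)
    n = mask.sum(axis=1)
    xs = np.where(mask, x, 0.0)
    rs = np.where(mask, ref, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = xs.sum(axis=1) / n
        mr = rs.sum(axis=1) / n
        dx = np.where(mask, x - mx[:, None], 0.0)
        dr = np.where(mask, ref - mr[:, None], 0.0)
        cov = (dx * dr).sum(axis=1)
        vx = (dx**2).sum(axis=1)
        vr = (dr**2).sum(axis=1)
        r = cov / np.sqrt(vx * vr)
    r[n < 3] = np.nan
    return r


def reliability_filter(
    table: pd.DataFrame, sd_factor: float = 2.0, min_correlation: float = 0.25
) -> pd.DataFrame:
    """Drop fragments that disagree with their peptide's consensus profile.

    Fragments of one peptide report the same analyte at different
    response factors, so their log2 profiles differ by a constant offset;
    each fragment's profile is therefore centered on its own observed
    mean, and the reference profile is the across-fragment median of the
    centered profiles per sample — both rules compare profile *shape*,
    not abundance. Rule 1 removes fragments whose Pearson correlation
    with the reference (over shared observed samples) is below
    ``min_correlation``. Rule 2, applied to the survivors with a
    recomputed reference, removes fragments whose mean absolute log2
    deviation from the reference exceeds ``sd_factor`` times the standard
    deviation of all residuals within the peptide. Peptides with fewer
    than two fragments pass unchanged, as do fragments whose correlation
    is undefined (fewer than three shared samples or zero variance).

    Rule 2 scores *offset-corrected* residuals (each fragment's residual
    profile centered on its own mean over observed samples): a constant
    offset — whether a response factor or the shift induced by missing
    observations in a high-contrast profile — is not evidence of an
    unreliable fragment; only sample-to-sample disagreement is.
    """
    if table.empty:
        return table.copy()

    wide = _log2_pivot(table)
    wide = wide.sub(wide.mean(axis=1), axis=0)
    ref = wide.groupby(level=[0, 1]).median()
    ref_rows = ref.reindex(wide.index.droplevel(2).set_names(ref.index.names)).to_numpy()
    sizes = wide.groupby(level=[0, 1]).size()
    sizes_rows = sizes.reindex(wide.index.droplevel(2)).to_numpy()

    r = _masked_corr_with_reference(wide.to_numpy(), ref_rows)
    keep1 = (sizes_rows < 2) | np.isnan(r) | (r >= min_correlation)
    kept_index = wide.index[keep1]

    # rule 2 on survivors, reference recomputed
    wide2 = wide.loc[kept_index]
    ref2 = wide2.groupby(level=[0, 1]).median()
    ref2_rows = ref2.reindex(wide2.index.droplevel(2).set_names(ref2.index.names)).to_numpy()
    sizes2 = wide2.groupby(level=[0, 1]).size()
    sizes2_rows = sizes2.reindex(wide2.index.droplevel(2)).to_numpy()

    resid = wide2.to_numpy() - ref2_rows
    with np.errstate(invalid="ignore"):
        resid = resid - np.nanmean(resid, axis=1, keepdims=True)
    dev = np.nanmean(np.abs(resid), axis=1)
    # per-peptide spread: std of all residuals of that peptide
    resid_frame = pd.DataFrame(resid, index=wide2.index)
    spread = resid_frame.stack(future_stack=True).groupby(level=[0, 1]).std(ddof=0)
    spread_rows = spread.reindex(wide2.index.droplevel(2)).to_numpy()

    with np.errstate(invalid="ignore"):
        keep2 = (sizes2_rows < 2) | np.isnan(dev) | np.isnan(spread_rows) | (
            dev <= sd_factor * spread_rows + DEVIATION_EPS
        )
    final_index = wide2.index[keep2]

    key = pd.MultiIndex.from_frame(table[FRAG_KEY])
    return table.loc[key.isin(final_index)].copy()


def rollup(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum retained fragments to peptide and protein quantity matrices.

    Returns (peptide_matrix, protein_matrix): wide frames indexed by
    (protein_id, peptide_id) and protein_id, columns = samples. A quantity
    is missing only when every constituent observation is missing.
    """
    if table.empty:
        empty_pep = pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=["protein_id", "peptide_id"])
        )
        return empty_pep, pd.DataFrame(index=pd.Index([], name="protein_id"))

    pep = (
        table.groupby(["protein_id", "peptide_id", "sample_id"])["intensity"]
        .sum(min_count=1)
        .unstack("sample_id")
    )
    prot = pep.groupby(level=0).sum(min_count=1)
    pep.columns.name = None
    prot.columns.name = None
    return pep, prot


@dataclasses.dataclass
class ImputationResult:
    matrix: pd.DataFrame
    imputed_mask: pd.DataFrame
    dropped: list


def impute_missing(matrix: pd.DataFrame, impute_quantile: float = 0.01) -> ImputationResult:
    """Replace each analyte's missing values with a low quantile of its observed values.

    The quantile uses linear interpolation between order statistics
    (numpy's default). Rows with no observed value cannot be imputed; they
    are dropped and reported in ``dropped``. Idempotent.
    """
    if not (0.0 < impute_quantile < 1.0):
        raise ValueError("impute_quantile must lie in (0, 1)")
    values = matrix.to_numpy(dtype=float)
    observed = ~np.isnan(values)
    n_obs = observed.sum(axis=1)
    keep = n_obs > 0
    dropped = list(matrix.index[~keep])
    values = values[keep]
    with np.errstate(invalid="ignore"):
        fill = np.nanquantile(values, impute_quantile, axis=1)
    mask = np.isnan(values)
    out = np.where(mask, fill[:, None], values)
    kept_index = matrix.index[keep]
    return ImputationResult(
        matrix=pd.DataFrame(out, index=kept_index, columns=matrix.columns),
        imputed_mask=pd.DataFrame(mask, index=kept_index, columns=matrix.columns),
        dropped=dropped,
    )


def normalize_to_bait(
    matrix: pd.DataFrame, bait_id: str, bait_values: pd.Series | None = None
) -> pd.DataFrame:
    """Divide every entry by the bait's quantity in the same sample.

    ``bait_values`` supplies the bait's protein-level quantities when the
    matrix itself is not indexed by protein (e.g. a peptide matrix).
    Raises if the bait is missing or non-positive in any sample, naming it.
    """
    if bait_values is None:
        if bait_id not in matrix.index:
            raise ValidationError(f"bait {bait_id!r} not present in matrix")
        bait_values = matrix.loc[bait_id]
        if isinstance(bait_values, pd.DataFrame):  # peptide-level multiindex
            raise ValidationError(
                f"matrix row for {bait_id!r} is not unique; pass bait_values explicitly"
            )
    bait_values = bait_values.reindex(matrix.columns)
    bad = bait_values.isna() | (bait_values <= 0)
    if bad.any():
        sample = bait_values.index[bad][0]
        raise ValidationError(f"bait {bait_id!r} missing or non-positive in sample {sample!r}")
    return matrix.div(bait_values, axis=1)


def route_phosphopeptides(table: pd.DataFrame, token: str = PHOSPHO_TOKEN) -> pd.DataFrame:
    """Give modified peptides their own protein identifier for testing.

    Peptides whose id carries the modification token are reassigned to the
    synthetic protein id ``<protein>@<peptide_id>`` so that a regulated
    phosphopeptide is tested on its own rather than being averaged into
    (and masked by) its parent protein.
    """
    out = table.copy()
    is_mod = out["peptide_id"].str.contains(token, regex=False)
    out.loc[is_mod, "protein_id"] = (
        out.loc[is_mod, "protein_id"] + "@" + out.loc[is_mod, "peptide_id"]
    )
    return out
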