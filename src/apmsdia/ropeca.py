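"""Paired peptide-level tests aggregated to proteins via the median order statistic.

The protein-level inference follows the reproducibility-optimized
strategy: a paired t-test is computed for every peptide over replicate
pairs of log2 quantities, the protein fold change is the median of its
peptide fold changes, and the protein p-value is the beta-distribution
probability of its median peptide p-value — under the null, the k-th
smallest of n uniform p-values follows Beta(k, n - k + 1), so evaluating
that CDF at the observed median is itself a valid p-value. Protein
p-values are then corrected per contrast with Benjamini-Hochberg.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

#: p-value assigned to a zero-variance peptide with a non-zero mean
#: difference (imputation can create constant rows; a finite floor keeps
#: the beta aggregation defined)
P_FLOOR = 1e-15


class DesignError(ValidationError):
    """Requested groups cannot be paired by replicate."""


def select_group(design: pd.DataFrame, group: Mapping[str, object]) -> pd.DataFrame:
    """Design rows matching a {column: value} selector, sorted by replicate."""
    mask = np.ones(len(design), dtype=bool)
    for col, value in group.items():
        if col not in design.columns:
            raise DesignError(f"unknown design column {col!r}")
        mask &= design[col].to_numpy() == value
    rows = design.loc[mask].sort_values("replicate")
    if rows.empty:
        raise DesignError(f"no samples match group {dict(group)!r}")
    if rows["replicate"].duplicated().any():
        raise DesignError(f"group {dict(group)!r} has duplicate replicate indices")
    return rows


def paired_columns(
    design: pd.DataFrame, group_a: Mapping[str, object], group_b: Mapping[str, object]
) -> tuple[list[str], list[str]]:
    """Sample ids of two groups aligned by replicate index."""
    a = select_group(design, group_a)
    b = select_group(design, group_b)
    if list(a["replicate"]) != list(b["replicate"]):
        raise DesignError(
            f"replicate indices differ between groups: {list(a['replicate'])} vs {list(b['replicate'])}"
        )
    if len(a) < 2:
        raise DesignError("paired test requires at least two replicate pairs")
    return list(a["sample_id"]), list(b["sample_id"])


def peptide_paired_test(
    peptide_matrix: pd.DataFrame,
    design: pd.DataFrame,
    group_a: Mapping[str, object],
    group_b: Mapping[str, object],
) -> pd.DataFrame:
    """Per-peptide paired t-test of log2 quantities, group A versus group B.

    The matrix must be imputed (complete); rows are (protein_id,
    peptide_id). Returns protein_id, peptide_id, log2_fc, t_stat, p_value,
    n_pairs. Zero-variance differences receive p=P_FLOOR when the mean
    difference is non-zero and p=1 when it is zero.
    """
    cols_a, cols_b = paired_columns(design, group_a, group_b)
    missing = [c for c in cols_a + cols_b if c not in peptide_matrix.columns]
    if missing:
        raise DesignError(f"samples absent from matrix: {missing}")
    a = np.log2(peptide_matrix[cols_a].to_numpy(dtype=float))
    b = np.log2(peptide_matrix[cols_b].to_numpy(dtype=float))
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("peptide matrix must be imputed before testing")
    d = a - b
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_sd = sd == 0
    p = np.where(zero_sd & (mean != 0), P_FLOOR, p)
    p = np.where(zero_sd & (mean == 0), 1.0, p)
    with np.errstate(invalid="ignore"):
        t = np.where(zero_sd, np.where(mean != 0, np.inf * np.sign(mean), 0.0), t)
    index = peptide_matrix.index
    return pd.DataFrame(
        {
            "protein_id": index.get_level_values(0),
            "peptide_id": index.get_level_values(1),
            "log2_fc": mean,
            "t_stat": t,
            "p_value": p,
            "n_pairs": n,
        }
    ).reset_index(drop=True)


def beta_median_pvalue(peptide_pvalues) -> float:
    """Protein p-value from the null law of the median order statistic.

    For n peptide p-values, let k = floor(n/2) + 1 (the upper median) and
    m the k-th smallest p-value; returns the Beta(k, n - k + 1) CDF at m,
    the probability that the k-th order statistic of n uniforms is <= m.
    """
    p = np.asarray(list(peptide_pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("beta_median_pvalue requires a non-empty p-value list")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    k = n // 2 + 1
    m = np.sort(p)[k - 1]
    return float(stats.beta.cdf(m, k, n - k + 1))


def protein_aggregate(peptide_stats: pd.DataFrame) -> pd.DataFrame:
    """Aggregate peptide statistics to proteins.

    median_log2_fc is the conventional median of the peptide fold changes
    (mean of the two central values for even counts); the p-value is the
    beta-median aggregation of the peptide p-values.
    """
    def one(group: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "median_log2_fc": float(np.median(group["log2_fc"])),
                "n_peptides": int(len(group)),
                "p_value": beta_median_pvalue(group["p_value"]),
            }
        )

    out = (
        peptide_stats.groupby("protein_id", sort=True)
        .apply(one, include_groups=False)
        .reset_index()
    )
    out["n_peptides"] = out["n_peptides"].astype(int)
    return out


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def protein_differential(
    peptide_matrix: pd.DataFrame,
    design: pd.DataFrame,
    group_a: Mapping[str, object],
    group_b: Mapping[str, object],
) -> pd.DataFrame:
    """Peptide paired tests, protein aggregation and BH adjustment in one step."""
    pep = peptide_paired_test(peptide_matrix, design, group_a, group_b)
    prot = protein_aggregate(pep)
    prot["q_value"] = adjust_bh(prot["p_value"])
    return prot
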