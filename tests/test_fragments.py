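"""Fragment filters, roll-up, imputation and bait normalization."""

import numpy as np
import pandas as pd
import pytest

from apmsdia import fragments as frag
from apmsdia.io import ValidationError


def _design(n_reps=3, times=(0.0,), backgrounds=("tagged_bait", "untagged_control")):
    rows = []
    for bg, tag in zip(backgrounds, ("bait", "ctrl")):
        for t in times:
            for r in range(1, n_reps + 1):
                rows.append((f"{tag}_t{t:g}_r{r}", bg, "pv", float(t), r, "none"))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "background", "condition", "time_min", "replicate", "silac_channel"],
    )


def _table(rows):
    return pd.DataFrame(
        rows, columns=["protein_id", "peptide_id", "fragment_id", "sample_id", "intensity"]
    )


# ---------------------------------------------------------------------------
# detection filter


def test_detection_filter_matches_hand_enumeration():
    design = _design(n_reps=3, times=(0.0, 2.0))
    rows = []
    # 10 fragments with a known detection pattern in the (tagged, t=0) group;
    # all are fully observed in the other three groups
    for i in range(10):
        n_obs = i % 4  # 0..3 observations in the probed group
        for r in range(1, 4):
            value = 100.0 + i if r <= n_obs else np.nan
            rows.append(("P1", "pep1", f"f{i}", f"bait_t0_r{r}", value))
        for sample in design.loc[design["sample_id"].str.startswith("bait_t0") == False, "sample_id"]:
            rows.append(("P1", "pep1", f"f{i}", sample, 50.0))
    table = _table(rows)
    out = frag.detection_filter(table, design, min_detect=2)

    # brute-force oracle: count observations per fragment per group
    merged = table.merge(design, on="sample_id")
    expected_keep = []
    for (pid, pep, fid, bg, cond, t), group in merged.groupby(
        ["protein_id", "peptide_id", "fragment_id", "background", "condition", "time_min"]
    ):
        if group["intensity"].notna().sum() >= 2:
            expected_keep.extend(group.index.tolist())
    # compare retained (fragment, sample) sets
    key = ["protein_id", "peptide_id", "fragment_id", "sample_id"]
    got = set(map(tuple, out[key].to_numpy()))
    want = set(map(tuple, merged.loc[sorted(expected_keep), key].to_numpy()))
    assert got == want
    # fragments observed <2x in the probed group lose exactly that group
    probed = out["sample_id"].str.startswith("bait_t0")
    kept_frags = set(out.loc[probed, "fragment_id"])
    assert kept_frags == {f"f{i}" for i in range(10) if i % 4 >= 2}


def test_detection_filter_single_observation_removed():
    design = _design(n_reps=3, backgrounds=("tagged_bait",))
    table = _table([("P1", "pep1", "f1", "bait_t0_r1", 10.0),
                    ("P1", "pep1", "f1", "bait_t0_r2", np.nan),
                    ("P1", "pep1", "f1", "bait_t0_r3", np.nan)])
    assert frag.detection_filter(table, design, min_detect=2).empty


def test_detection_filter_min_detect_one_drops_only_undetected_groups():
    design = _design(n_reps=2, backgrounds=("tagged_bait",), times=(0.0, 2.0))
    table = _table([
        ("P1", "pep1", "f1", "bait_t0_r1", 1.0),
        ("P1", "pep1", "f1", "bait_t0_r2", np.nan),
        ("P1", "pep1", "f1", "bait_t2_r1", np.nan),
        ("P1", "pep1", "f1", "bait_t2_r2", np.nan),
    ])
    out = frag.detection_filter(table, design, min_detect=1)
    assert out["sample_id"].tolist() == ["bait_t0_r1", "bait_t0_r2"]


def test_detection_filter_unknown_sample_errors():
    design = _design(n_reps=1, backgrounds=("tagged_bait",))
    table = _table([("P1", "pep1", "f1", "mystery", 1.0)])
    with pytest.raises(ValidationError, match="mystery"):
        frag.detection_filter(table, design)


# ---------------------------------------------------------------------------
# reliability filter


def _proportional_table(n_frags=3, scales=(1.0, 2.0, 4.0)):
    profile = np.array([100.0, 400.0, 200.0, 800.0, 50.0, 300.0])
    rows = []
    for i in range(n_frags):
        for s, value in enumerate(profile * scales[i]):
            rows.append(("P1", "pep1", f"f{i}", f"s{s}", value))
    return _table(rows)


def test_exact_scalar_multiples_all_retained():
    table = _proportional_table()
    out = frag.reliability_filter(table)
    pd.testing.assert_frame_equal(out.reset_index(drop=True), table)


def test_anticorrelated_fragment_removed():
    table = _proportional_table(n_frags=2, scales=(1.0, 1.0))
    profile = np.array([100.0, 400.0, 200.0, 800.0, 50.0, 300.0])
    inverted = profile[::-1]
    extra = _table(
        [("P1", "pep1", "bad", f"s{s}", v) for s, v in enumerate(inverted)]
        + [("P1", "pep1", "f9", f"s{s}", v * 3) for s, v in enumerate(profile)]
    )
    out = frag.reliability_filter(pd.concat([table, extra], ignore_index=True))
    assert "bad" not in set(out["fragment_id"])
    assert set(out["fragment_id"]) == {"f0", "f1", "f9"}


def test_singleton_peptides_pass_unchanged():
    table = _table([("P1", "lonely", "f1", f"s{s}", v)
                    for s, v in enumerate([5.0, 1.0, 50.0, 2.0])])
    out = frag.reliability_filter(table)
    pd.testing.assert_frame_equal(out.reset_index(drop=True), table)


def _oracle_reliability(table, sd_factor=2.0, min_correlation=0.25):
    """Independent per-peptide loop implementation of both rules."""
    wide = table.set_index(["protein_id", "peptide_id", "fragment_id", "sample_id"])[
        "intensity"
    ].unstack("sample_id")
    logw = np.log2(wide)
    logw = logw.sub(logw.mean(axis=1), axis=0)

    def corr(x, y):
        mask = x.notna() & y.notna()
        if mask.sum() < 3:
            return np.nan
        xv, yv = x[mask], y[mask]
        if xv.std(ddof=0) == 0 or yv.std(ddof=0) == 0:
            return np.nan
        return np.corrcoef(xv, yv)[0, 1]

    keep = []
    for (pid, pep), sub in logw.groupby(level=[0, 1]):
        if len(sub) < 2:
            keep.extend(sub.index)
            continue
        ref = sub.median(axis=0)
        survivors = []
        for idx, row in sub.iterrows():
            r = corr(row, ref)
            if np.isnan(r) or r >= min_correlation:
                survivors.append(idx)
        sub2 = sub.loc[survivors]
        if len(sub2) < 2:
            keep.extend(sub2.index)
            continue
        ref2 = sub2.median(axis=0)
        resid = (sub2 - ref2).sub((sub2 - ref2).mean(axis=1), axis=0)
        spread = resid.stack().std(ddof=0)
        for idx, row in resid.iterrows():
            dev = row.abs().mean()
            if np.isnan(dev) or np.isnan(spread) or dev <= sd_factor * spread + frag.DEVIATION_EPS:
                keep.append(idx)
    kept = set(keep)
    key = pd.MultiIndex.from_frame(table[["protein_id", "peptide_id", "fragment_id"]])
    return table.loc[key.isin(kept)]


def test_reliability_filter_matches_loop_oracle_on_noisy_fixture():
    rng = np.random.default_rng(17)
    rows = []
    profile = {}
    for p in range(12):
        base = rng.lognormal(8, 1, size=8)  # 8 samples
        profile[p] = base
        n_frag = rng.integers(2, 5)
        for f in range(n_frag):
            scale = rng.lognormal(0, 1)
            noise = rng.lognormal(0, 0.4, size=8)
            values = base * scale * noise
            # sprinkle missingness and one deliberate shape outlier
            for s in range(8):
                v = values[s]
                if rng.random() < 0.1:
                    v = np.nan
                rows.append((f"P{p}", f"pep{p}", f"f{f}", f"s{s}", v))
        # an interfered fragment tracking a different profile
        if p % 3 == 0:
            other = rng.lognormal(8, 1, size=8)
            for s in range(8):
                rows.append((f"P{p}", f"pep{p}", "interf", f"s{s}", other[s]))
    table = _table(rows)
    out = frag.reliability_filter(table)
    oracle = _oracle_reliability(table)
    key = ["protein_id", "peptide_id", "fragment_id", "sample_id"]
    assert set(map(tuple, out[key].dropna(subset=["sample_id"]).to_numpy()[:, :4])) == set(
        map(tuple, oracle[key].to_numpy()[:, :4])
    )


def test_filters_only_remove_rows_never_alter_intensities(spike_experiment):
    table = spike_experiment.fragments
    design = spike_experiment.design
    det = frag.detection_filter(table, design, 2)
    rel = frag.reliability_filter(det)
    merged = rel.merge(
        table, on=["protein_id", "peptide_id", "fragment_id", "sample_id"],
        how="left", suffixes=("", "_orig"),
    )
    assert len(rel) <= len(det) <= len(table)
    same = (merged["intensity"] == merged["intensity_orig"]) | (
        merged["intensity"].isna() & merged["intensity_orig"].isna()
    )
    assert same.all()


# ---------------------------------------------------------------------------
# roll-up


def test_rollup_simple_sums():
    table = _table([
        ("P1", "pepA", "f1", "s1", 100.0),
        ("P1", "pepA", "f2", "s1", 50.0),
        ("P1", "pepB", "f1", "s1", 10.0),
        ("P2", "pepC", "f1", "s1", 7.0),
    ])
    pep, prot = frag.rollup(table)
    assert pep.loc[("P1", "pepA"), "s1"] == 150.0
    assert prot.loc["P1", "s1"] == 160.0
    assert prot.loc["P2", "s1"] == 7.0


def test_rollup_missing_only_when_all_constituents_missing():
    table = _table([
        ("P1", "pepA", "f1", "s1", np.nan),
        ("P1", "pepA", "f2", "s1", np.nan),
        ("P1", "pepA", "f1", "s2", np.nan),
        ("P1", "pepA", "f2", "s2", 5.0),
    ])
    pep, prot = frag.rollup(table)
    assert np.isnan(pep.loc[("P1", "pepA"), "s1"])
    assert pep.loc[("P1", "pepA"), "s2"] == 5.0
    assert np.isnan(prot.loc["P1", "s1"])


def test_rollup_conserves_total_intensity_per_sample(spike_experiment):
    table = frag.detection_filter(
        spike_experiment.fragments, spike_experiment.design, 2
    )
    _, prot = frag.rollup(table)
    by_sample = table.groupby("sample_id")["intensity"].sum(min_count=1)
    np.testing.assert_allclose(
        prot.sum(axis=0).reindex(by_sample.index).to_numpy(),
        by_sample.to_numpy(),
        rtol=1e-9,
    )


def test_rollup_matches_groupby_oracle(small_experiment):
    table = small_experiment.fragments
    pep, _ = frag.rollup(table)
    # dictionary-accumulation oracle
    acc: dict = {}
    for row in table.itertuples(index=False):
        key = (row.protein_id, row.peptide_id, row.sample_id)
        if not np.isnan(row.intensity):
            acc[key] = acc.get(key, 0.0) + row.intensity
    for (pid, pep_id, sample), value in acc.items():
        assert pep.loc[(pid, pep_id), sample] == pytest.approx(value, rel=1e-12)


# ---------------------------------------------------------------------------
# imputation


def test_impute_complete_row_unchanged():
    m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["r"], columns=list("abc"))
    out = frag.impute_missing(m)
    pd.testing.assert_frame_equal(out.matrix, m)
    assert not out.imputed_mask.to_numpy().any()


def test_impute_uses_linear_interpolation_quantile():
    # observed values (10, 20, 30): the 0.01 quantile under the type-7
    # convention sits at fractional position 0.02 between 10 and 20
    m = pd.DataFrame([[10.0, 20.0, 30.0, np.nan]], index=["r"], columns=list("abcd"))
    out = frag.impute_missing(m, 0.01)
    assert out.matrix.loc["r", "d"] == pytest.approx(10.2, abs=1e-12)


def test_impute_idempotent_and_reports_dropped():
    m = pd.DataFrame(
        [[10.0, np.nan, 30.0], [np.nan, np.nan, np.nan]],
        index=["keep", "drop"], columns=list("abc"),
    )
    once = frag.impute_missing(m, 0.01)
    twice = frag.impute_missing(once.matrix, 0.01)
    pd.testing.assert_frame_equal(once.matrix, twice.matrix)
    assert once.dropped == ["drop"]


def test_imputed_value_stays_in_low_tail_of_observed_values():
    """Under the type-7 quantile a small q lands between the smallest and
    second-smallest observed value, close to the minimum."""
    rng = np.random.default_rng(2)
    m = pd.DataFrame(rng.lognormal(5, 1, size=(40, 6)))
    m[m < np.quantile(m.to_numpy(), 0.3)] = np.nan
    m = m.dropna(how="all")
    out = frag.impute_missing(m, 0.01)
    values = np.sort(m.to_numpy(), axis=1)  # NaN sorts last
    lo, second = values[:, 0], values[:, 1]
    filled = out.matrix.to_numpy()[out.imputed_mask.to_numpy()]
    row_of = np.nonzero(out.imputed_mask.to_numpy())[0]
    assert np.all(filled >= lo[row_of] - 1e-12)
    upper = np.where(np.isnan(second), lo, second)
    assert np.all(filled <= upper[row_of] + 1e-12)


def test_impute_quantile_out_of_range_rejected():
    m = pd.DataFrame([[1.0]], columns=["a"])
    with pytest.raises(ValueError):
        frag.impute_missing(m, 1.5)


# ---------------------------------------------------------------------------
# bait normalization


def test_normalize_to_bait_examples():
    m = pd.DataFrame(
        {"s1": [100.0, 50.0], "s2": [200.0, 100.0]}, index=["BAIT", "prey"]
    )
    out = frag.normalize_to_bait(m, "BAIT")
    assert (out.loc["BAIT"] == 1.0).all()
    assert (out.loc["prey"] == 0.5).all()
    # element-wise division oracle
    np.testing.assert_allclose(out.to_numpy(), m.to_numpy() / m.loc["BAIT"].to_numpy())


def test_normalize_to_bait_errors_name_sample():
    m = pd.DataFrame({"s1": [100.0, 50.0], "s2": [0.0, 100.0]}, index=["BAIT", "prey"])
    with pytest.raises(ValidationError, match="s2"):
        frag.normalize_to_bait(m, "BAIT")
    with pytest.raises(ValidationError, match="not present"):
        frag.normalize_to_bait(m.drop(index="BAIT"), "BAIT")


def test_route_phosphopeptides():
    table = _table([
        ("P1", "PEPTIDEK", "f1", "s1", 1.0),
        ("P1", "PEPTIDEK(ph)", "f1", "s1", 2.0),
    ])
    out = frag.route_phosphopeptides(table)
    assert out["protein_id"].tolist() == ["P1", "P1@PEPTIDEK(ph)"]
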