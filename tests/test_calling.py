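"""Two-step interactor calling, contaminant handling and report tables."""

import math

import numpy as np
import pandas as pd
import pytest

from apmsdia import calling
from apmsdia.io import ContaminantList, ValidationError


def _stats(rows):
    return pd.DataFrame(rows, columns=["protein_id", "median_log2_fc", "n_peptides", "p_value", "q_value"])


def test_enriched_in_one_condition_is_not_specific():
    strong = ("P1", 3.0, 4, 1e-6, 1e-5)
    weak = ("P1", 0.1, 4, 0.5, 0.9)
    stats = {"c1": _stats([strong]), "c2": _stats([weak]), "c3": _stats([weak]), "c4": _stats([weak])}
    calls = calling.call_specific(stats, calling.CallingParams(min_conditions=2))
    assert not calls.loc[0, "is_specific"]
    assert calls.loc[0, "n_enriched"] == 1


def test_keratin_prefix_contaminant_removed_but_reported():
    row = ("KRT99", 5.0, 3, 1e-8, 1e-7)
    stats = {"c1": _stats([row]), "c2": _stats([row])}
    calls = calling.call_specific(stats, calling.CallingParams())
    assert calls.loc[0, "removed_as_contaminant"]
    assert not calls.loc[0, "is_specific"]


def test_study_crapome_identifiers_match_default_list():
    for pid in ("EEF1A1", "GAPDH", "HSP90AB1", "HSPA5", "HSPA8", "KRT33B",
                "TUBA1A", "TUBA1B", "TUBB", "TUBA4A", "TUBB4B", "MYH9", "MYL6"):
        assert calling.DEFAULT_CONTAMINANTS.matches(pid)
    for pid in ("PTPN11", "GRB2", "PDCD1"):
        assert not calling.DEFAULT_CONTAMINANTS.matches(pid)


def test_call_specific_matches_rule_enumeration_oracle():
    rng = np.random.default_rng(31)
    params = calling.CallingParams(enrichment_fc_threshold=3.0, enrichment_fdr=0.01, min_conditions=2)
    conditions = ["t0", "t2", "t5"]
    proteins = [f"P{i:02d}" for i in range(27)] + ["KRT01", "TUBB2", "MYH14"]
    stats = {}
    for c in conditions:
        stats[c] = _stats(
            [
                (
                    pid,
                    rng.normal(1.5, 1.2),
                    3,
                    0.0,
                    10 ** rng.uniform(-6, 0),
                )
                for pid in proteins
            ]
        )
    calls = calling.call_specific(stats, params).set_index("protein_id")
    thr = math.log2(3.0)
    for pid in proteins:
        enriched = [
            c for c in conditions
            if stats[c].set_index("protein_id").loc[pid, "median_log2_fc"] > thr
            and stats[c].set_index("protein_id").loc[pid, "q_value"] < 0.01
        ]
        contam = pid.startswith(("KRT", "TUB", "MYH"))
        assert calls.loc[pid, "n_enriched"] == len(enriched)
        assert calls.loc[pid, "is_specific"] == (len(enriched) >= 2 and not contam)


def test_empty_contrast_map_rejected():
    with pytest.raises(ValidationError):
        calling.call_specific({}, calling.CallingParams())


def test_dynamic_gate_examples():
    specific = pd.DataFrame(
        {
            "protein_id": ["P1", "P2"],
            "enriched_conditions": ["a;b", "a;b"],
            "n_enriched": [2, 2],
            "is_specific": [True, True],
            "is_dynamic": [False, False],
            "removed_as_contaminant": [False, False],
            "excluded": [False, False],
            "best_q": [1e-6, 1e-6],
        }
    )
    # P1: 1.5-fold change (below the 2-fold gate) at q=0.001 -> not dynamic;
    # P2: 4-fold at q=0.01 -> dynamic
    contrast = _stats([
        ("P1", math.log2(1.5), 3, 1e-4, 0.001),
        ("P2", math.log2(4.0), 3, 1e-3, 0.01),
    ])
    out = calling.call_dynamic({"t2_vs_t0": contrast}, specific, calling.CallingParams())
    got = out.set_index("protein_id")["is_dynamic"]
    assert not got["P1"] and got["P2"]


def test_dynamic_is_two_sided():
    specific = pd.DataFrame(
        {
            "protein_id": ["P1"], "enriched_conditions": ["a;b"], "n_enriched": [2],
            "is_specific": [True], "is_dynamic": [False],
            "removed_as_contaminant": [False], "excluded": [False], "best_q": [1e-6],
        }
    )
    losing = _stats([("P1", -2.0, 3, 1e-4, 0.001)])
    out = calling.call_dynamic({"c": losing}, specific, calling.CallingParams())
    assert out.loc[0, "is_dynamic"]


def test_dynamic_requires_specific_calls():
    none_specific = pd.DataFrame({"protein_id": ["P1"], "is_specific": [False]})
    with pytest.raises(ValidationError):
        calling.call_dynamic({"c": _stats([])}, none_specific, calling.CallingParams())


def test_dynamic_subset_of_specific_and_thresholds_monotone(spike_result):
    calls = spike_result.tables["calls"]
    assert set(calls.loc[calls["is_dynamic"], "protein_id"]) <= set(
        calls.loc[calls["is_specific"], "protein_id"]
    )
    stats = {
        label.replace("stats_specific_", ""): table
        for label, table in spike_result.tables.items()
        if label.startswith("stats_specific_")
    }
    base = calling.CallingParams()
    n_base = calling.call_specific(stats, base)["is_specific"].sum()
    for tighter in (
        calling.CallingParams(enrichment_fc_threshold=6.0),
        calling.CallingParams(enrichment_fdr=0.001),
        calling.CallingParams(min_conditions=4),
    ):
        assert calling.call_specific(stats, tighter)["is_specific"].sum() <= n_base


def test_contaminant_removal_order_independent(spike_result):
    stats = {
        label.replace("stats_specific_", ""): table
        for label, table in spike_result.tables.items()
        if label.startswith("stats_specific_")
    }
    params = calling.CallingParams()
    after = calling.call_specific(stats, params, calling.DEFAULT_CONTAMINANTS)
    # filter first: drop contaminant rows from stats, then call with an empty list
    filtered = {
        label: table.loc[~table["protein_id"].map(calling.DEFAULT_CONTAMINANTS.matches)]
        for label, table in stats.items()
    }
    before = calling.call_specific(filtered, params, ContaminantList())
    assert set(after.loc[after["is_specific"], "protein_id"]) == set(
        before.loc[before["is_specific"], "protein_id"]
    )


# ---------------------------------------------------------------------------
# report tables


def test_volcano_projection():
    stats = _stats([("P1", 2.0, 3, 0.001, 0.01)])
    out = calling.volcano_table(stats)
    assert out.loc[0, "neg_log10_q"] == pytest.approx(2.0, abs=1e-12)
    assert calling.volcano_table(_stats([])).empty


def test_heatmap_row_normalization():
    design = pd.DataFrame(
        {
            "sample_id": [f"bait_t{t:g}_r{r}" for t in (0, 2, 5, 15) for r in (1, 2)],
            "background": "tagged_bait",
            "condition": "pv",
            "time_min": [t for t in (0.0, 2.0, 5.0, 15.0) for _ in (1, 2)],
            "replicate": [r for _ in range(4) for r in (1, 2)],
            "silac_channel": "none",
        }
    )
    values = {f"bait_t{t:g}_r{r}": v for t, v in zip((0, 2, 5, 15), (2.0, 4.0, 8.0, 4.0)) for r in (1, 2)}
    matrix = pd.DataFrame([values, {k: 3.0 for k in values}], index=["P1", "const"])
    out = calling.heatmap_table(matrix, ["P1", "const"], design).set_index("protein_id")
    np.testing.assert_allclose(out.loc["P1"], [0.25, 0.5, 1.0, 0.5])
    np.testing.assert_allclose(out.loc["const"], [1.0, 1.0, 1.0, 1.0])
    # independent mean-then-divide oracle
    means = [np.mean([values[f"bait_t{t:g}_r{r}"] for r in (1, 2)]) for t in (0, 2, 5, 15)]
    np.testing.assert_allclose(out.loc["P1"].to_numpy(), np.array(means) / max(means))


def test_heatmap_zero_row_errors():
    design = pd.DataFrame(
        {
            "sample_id": ["bait_t0_r1"], "background": "tagged_bait", "condition": "pv",
            "time_min": [0.0], "replicate": [1], "silac_channel": "none",
        }
    )
    matrix = pd.DataFrame({"bait_t0_r1": [0.0]}, index=["dead"])
    with pytest.raises(ValidationError, match="dead"):
        calling.heatmap_table(matrix, ["dead"], design)


def test_phospho_profile_is_bait_normalized_division(small_experiment):
    from apmsdia import fragments as frag

    exp = small_experiment
    routed = frag.route_phosphopeptides(exp.fragments)
    pep, _ = frag.rollup(routed)
    _, prot = frag.rollup(exp.fragments)
    imp_pep = frag.impute_missing(pep)
    imp_prot = frag.impute_missing(prot)
    pep_ids = imp_pep.matrix.index.get_level_values("peptide_id")
    phospho = next(p for p in pep_ids if p.endswith("(ph)"))
    unmod = phospho[: -len("(ph)")]
    out = calling.phospho_site_profile(
        imp_pep.matrix, imp_prot.matrix, phospho, unmod, "BAIT", imp_pep.imputed_mask
    )
    bait = imp_prot.matrix.loc["BAIT"]
    for form, pid in (("phospho", phospho), ("unmodified", unmod)):
        sub = out.query("form == @form").set_index("sample_id")
        row = imp_pep.matrix.xs(pid, level="peptide_id").iloc[0]
        np.testing.assert_allclose(
            sub["normalized_intensity"].to_numpy(),
            (row / bait).reindex(sub.index).to_numpy(),
        )
    with pytest.raises(ValidationError, match="unknown peptide"):
        calling.phospho_site_profile(imp_pep.matrix, imp_prot.matrix, "nope", unmod, "BAIT")


def test_phospho_profile_rises_after_stimulation(small_experiment):
    from apmsdia import fragments as frag

    exp = small_experiment
    routed = frag.route_phosphopeptides(exp.fragments)
    pep, _ = frag.rollup(routed)
    _, prot = frag.rollup(exp.fragments)
    imp_pep = frag.impute_missing(pep)
    imp_prot = frag.impute_missing(prot)
    pep_ids = imp_pep.matrix.index.get_level_values("peptide_id")
    phospho = next(p for p in pep_ids if p.endswith("(ph)"))
    unmod = phospho[: -len("(ph)")]
    out = calling.phospho_site_profile(
        imp_pep.matrix, imp_prot.matrix, phospho, unmod, "BAIT"
    )
    ph = out.query("form == 'phospho'").set_index("sample_id")["normalized_intensity"]
    t0 = ph[[s for s in ph.index if s.startswith("bait_t0_")]].mean()
    t2 = ph[[s for s in ph.index if s.startswith("bait_t2_")]].mean()
    assert t2 > 5 * t0
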