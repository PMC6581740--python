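"""End-to-end orchestration: filters -> statistics -> calls -> stoichiometry -> SILAC.

One configuration object (or YAML document) drives the whole analysis,
either on simulated data with ground truth or on user-supplied
long-format tables. Contrasts are derived from the sample design: every
(condition, time) with both backgrounds yields a bait-versus-control
enrichment contrast; within tagged samples, every stimulated time point
is contrasted against the matched unstimulated (t=0) baseline on
bait-normalized quantities. Reruns with an identical configuration
produce byte-identical outputs.

SILAC designs (light/heavy channels) follow the origin-analysis branch:
fragment filtering, roll-up, and per-protein light/heavy ratio and origin
classification; the enrichment/dynamic calling stages apply to
label-free designs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import calling as _calling
from . import fragments as frag
from . import io as apio
from . import ropeca
from . import silac as _silac
from .stoichiometry import DigestParams, compute_ibaq
from .stoichiometry import stoichiometry as stoichiometry_table
from .simulate import PHOSPHO_TOKEN, SimConfig, simulate_experiment


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one full analysis run.

    Exactly one of ``sim`` (synthetic mode) or the three input paths
    (real-data mode) must be supplied.
    """

    sim: SimConfig | None = None
    fragments_path: str | None = None
    design_path: str | None = None
    fasta_path: str | None = None
    contaminants_path: str | None = None
    filter_params: frag.FilterParams = frag.FilterParams()
    calling_params: _calling.CallingParams = _calling.CallingParams()
    digest_params: DigestParams = DigestParams()
    bait_id: str | None = None
    exclude_ids: tuple[str, ...] = ()
    stoich_time_min: float = 2.0
    phospho_token: str = PHOSPHO_TOKEN
    silac_floor_quantile: float = 0.01
    silac_exclusive_threshold: float = 0.95
    out_dir: str | None = None

    def __post_init__(self) -> None:
        synthetic = self.sim is not None
        real = self.fragments_path is not None or self.design_path is not None
        if synthetic == real:
            raise ValueError("supply exactly one of sim config or input paths")
        if real and (self.fragments_path is None or self.design_path is None):
            raise ValueError("real-data mode requires fragments_path and design_path")
        if real and self.bait_id is None:
            raise ValueError("real-data mode requires bait_id")

    @property
    def resolved_bait_id(self) -> str:
        return self.bait_id if self.bait_id is not None else self.sim.bait_id


@dataclasses.dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    summary: dict[str, Any]
    paths: dict[str, Path] | None = None


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def _specific_contrasts(design: pd.DataFrame) -> list[tuple[str, dict, dict]]:
    """Bait-versus-control contrasts: one per (condition, time) with both backgrounds."""
    out = []
    groups = design.groupby(["condition", "time_min"])["background"].agg(set)
    for (cond, t), bgs in groups.items():
        if {"tagged_bait", "untagged_control"} <= bgs:
            label = f"{cond}_t{t:g}"
            sel_a = {"background": "tagged_bait", "condition": cond, "time_min": t}
            sel_b = {"background": "untagged_control", "condition": cond, "time_min": t}
            out.append((label, sel_a, sel_b))
    return out


def _dynamic_contrasts(design: pd.DataFrame) -> list[tuple[str, dict, dict]]:
    """Stimulated-versus-unstimulated contrasts within tagged samples."""
    out = []
    tagged = design.loc[design["background"] == "tagged_bait"]
    for cond, sub in tagged.groupby("condition"):
        times = sorted(sub["time_min"].unique())
        if 0.0 not in times:
            continue
        baseline = {"background": "tagged_bait", "condition": cond, "time_min": 0.0}
        for t in times:
            if t > 0:
                label = f"{cond}_t{t:g}_vs_t0"
                sel = {"background": "tagged_bait", "condition": cond, "time_min": t}
                out.append((label, sel, baseline))
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and return (and optionally write) all tables."""
    tables: dict[str, pd.DataFrame] = {}
    summary: dict[str, Any] = {}
    bait_id = config.resolved_bait_id

    # ---- stage: inputs
    if config.sim is not None:
        exp = _stage("simulate")(simulate_experiment)(config.sim)
        fragments, design, truth, sequences = exp
        tables["truth"] = truth
        summary["mode"] = "synthetic"
        summary["seed"] = config.sim.seed
    else:
        fragments = _stage("read_fragments")(apio.read_fragment_table)(config.fragments_path)
        design = _stage("read_design")(apio.read_design)(config.design_path)
        sequences = (
            _stage("read_fasta")(apio.read_fasta)(config.fasta_path)
            if config.fasta_path
            else None
        )
        truth = None
        summary["mode"] = "real"
    contaminants = (
        _stage("read_contaminants")(apio.ContaminantList.from_file)(config.contaminants_path)
        if config.contaminants_path
        else _calling.DEFAULT_CONTAMINANTS
    )
    summary["n_fragment_rows_input"] = int(len(fragments))
    summary["n_fragments_input"] = int(
        fragments[frag.FRAG_KEY].drop_duplicates().shape[0]
    )

    # ---- stage: fragment filters
    fp = config.filter_params
    detected = _stage("detection_filter")(frag.detection_filter)(
        fragments, design, fp.min_detect
    )
    summary["n_fragment_rows_after_detection"] = int(len(detected))
    reliable = _stage("reliability_filter")(frag.reliability_filter)(
        detected, fp.sd_factor, fp.min_correlation
    )
    summary["n_fragment_rows_after_reliability"] = int(len(reliable))
    summary["n_fragments_retained"] = int(
        reliable[frag.FRAG_KEY].drop_duplicates().shape[0]
    )

    # ---- stage: roll-up and imputation (phospho-routed for statistics,
    # un-routed for bait normalization, stoichiometry and heatmaps)
    routed = _stage("phospho_routing")(frag.route_phosphopeptides)(
        reliable, config.phospho_token
    )
    pep_r, _prot_r = _stage("rollup")(frag.rollup)(routed)
    _pep_u, prot_u = _stage("rollup")(frag.rollup)(reliable)
    imp_pep_r = _stage("imputation")(frag.impute_missing)(pep_r, fp.impute_quantile)
    imp_prot_u = _stage("imputation")(frag.impute_missing)(prot_u, fp.impute_quantile)
    summary["n_proteins_quantified"] = int(imp_prot_u.matrix.shape[0])
    summary["n_peptides_quantified"] = int(imp_pep_r.matrix.shape[0])
    summary["n_analytes_dropped_all_missing"] = len(imp_pep_r.dropped) + len(
        imp_prot_u.dropped
    )
    summary["n_values_imputed"] = int(imp_pep_r.imputed_mask.to_numpy().sum())
    tables["protein_matrix"] = apio.matrix_to_frame(imp_prot_u.matrix)
    tables["peptide_matrix"] = apio.matrix_to_frame(imp_pep_r.matrix)

    silac_mode = set(design["silac_channel"].unique()) >= {"light", "heavy"}
    if silac_mode:
        _run_silac_branch(config, design, imp_prot_u, prot_u, tables, summary)
        return _finalize(config, tables, summary)

    # ---- stage: enrichment statistics (bait vs control, per condition)
    contrasts = _specific_contrasts(design)
    if not contrasts:
        raise PipelineError("stage 'statistics' failed: no bait-vs-control contrast in design")
    stats_specific: dict[str, pd.DataFrame] = {}
    for label, sel_a, sel_b in contrasts:
        stats = _stage("statistics")(ropeca.protein_differential)(
            imp_pep_r.matrix, design, sel_a, sel_b
        )
        stats_specific[label] = stats
        tables[f"stats_specific_{label}"] = stats
        tables[f"volcano_{label}"] = _calling.volcano_table(stats)
    summary["n_proteins_tested"] = int(
        pd.concat(stats_specific.values())["protein_id"].nunique()
    )

    # ---- stage: specific calls
    tested_ids = set(pd.concat(stats_specific.values())["protein_id"])
    exclude = {bait_id} | {p for p in tested_ids if p.startswith(f"{bait_id}@")}
    exclude |= set(config.exclude_ids)
    calls = _stage("call_specific")(_calling.call_specific)(
        stats_specific, config.calling_params, contaminants, exclude
    )
    summary["n_enriched_any_condition"] = int((calls["n_enriched"] >= 1).sum())
    summary["n_specific"] = int(calls["is_specific"].sum())
    summary["n_removed_as_contaminant"] = int(calls["removed_as_contaminant"].sum())

    # ---- stage: dynamic calls on bait-normalized quantities
    dyn_contrasts = _dynamic_contrasts(design)
    if dyn_contrasts and calls["is_specific"].any():
        tagged_cols = [
            s for s in design.loc[design["background"] == "tagged_bait", "sample_id"]
            if s in imp_pep_r.matrix.columns
        ]
        bait_values = imp_prot_u.matrix.loc[bait_id, tagged_cols]
        norm_pep = _stage("bait_normalization")(frag.normalize_to_bait)(
            imp_pep_r.matrix[tagged_cols], bait_id, bait_values
        )
        stats_dynamic: dict[str, pd.DataFrame] = {}
        for label, sel_a, sel_b in dyn_contrasts:
            stats = _stage("statistics")(ropeca.protein_differential)(
                norm_pep, design, sel_a, sel_b
            )
            stats_dynamic[label] = stats
            tables[f"stats_dynamic_{label}"] = stats
        calls = _stage("call_dynamic")(_calling.call_dynamic)(
            stats_dynamic, calls, config.calling_params
        )
    summary["n_dynamic"] = int(calls["is_dynamic"].sum())
    tables["calls"] = calls

    # ---- stage: heatmap of specific interactors
    specific_ids = sorted(
        set(calls.loc[calls["is_specific"], "protein_id"]) & set(imp_prot_u.matrix.index)
    )
    if specific_ids:
        tables["heatmap"] = _stage("heatmap")(_calling.heatmap_table)(
            imp_prot_u.matrix, specific_ids, design
        )

    # ---- stage: stoichiometry at the configured time point
    if sequences is not None:
        stoich_samples = list(
            design.loc[
                (design["background"] == "tagged_bait")
                & (design["time_min"] == config.stoich_time_min),
                "sample_id",
            ]
        )
        stoich_samples = [s for s in stoich_samples if s in imp_prot_u.matrix.columns]
        if stoich_samples and bait_id in imp_prot_u.matrix.index:
            scored = [p for p in imp_prot_u.matrix.index if p in sequences]
            summary["n_skipped_no_sequence"] = int(
                imp_prot_u.matrix.shape[0] - len(scored)
            )
            ibaq = _stage("ibaq")(compute_ibaq)(
                imp_prot_u.matrix,
                sequences,
                config.digest_params,
                stoich_samples,
                scored,
            )
            label = f"t{config.stoich_time_min:g}"
            tables["stoichiometry"] = _stage("stoichiometry")(stoichiometry_table)(
                ibaq, bait_id, label
            )

    # ---- stage: phospho-site profile (when both forms were quantified)
    pep_ids = imp_pep_r.matrix.index.get_level_values("peptide_id")
    phospho_ids = [p for p in pep_ids if config.phospho_token in p]
    for ph in phospho_ids:
        unmod = ph.replace(config.phospho_token, "")
        if unmod in set(pep_ids):
            profile = _stage("phospho_profile")(_calling.phospho_site_profile)(
                imp_pep_r.matrix, imp_prot_u.matrix, ph, unmod, bait_id,
                imp_pep_r.imputed_mask,
            )
            tables[f"phospho_profile_{unmod}"] = profile

    return _finalize(config, tables, summary)


def _run_silac_branch(config, design, imp_prot_u, prot_u, tables, summary) -> None:
    tagged = design.loc[design["background"] == "tagged_bait"]
    light_ids = tagged.loc[tagged["silac_channel"] == "light"].sort_values(
        ["condition", "time_min", "replicate"]
    )
    heavy_ids = tagged.loc[tagged["silac_channel"] == "heavy"].sort_values(
        ["condition", "time_min", "replicate"]
    )
    light_cols = [s for s in light_ids["sample_id"] if s in prot_u.columns]
    heavy_cols = [s for s in heavy_ids["sample_id"] if s in prot_u.columns]
    n = min(len(light_cols), len(heavy_cols))
    # un-imputed matrices: the floor rule needs to see true missingness
    light = prot_u.reindex(columns=light_cols[:n])
    heavy = prot_u.reindex(columns=heavy_cols[:n])
    ratios, floor = _stage("silac_ratios")(_silac.silac_ratios)(
        light, heavy, config.silac_floor_quantile
    )
    classified = _stage("silac_classify")(_silac.classify_origin)(
        ratios, config.silac_exclusive_threshold
    )
    tables["silac"] = classified
    summary["silac_floor"] = floor
    summary["n_silac_proteins"] = int(len(classified))
    summary["n_origin_light"] = int((classified["origin"] == _silac.ORIGIN_LIGHT).sum())
    summary["n_origin_heavy"] = int((classified["origin"] == _silac.ORIGIN_HEAVY).sum())
    summary["n_origin_mixed"] = int((classified["origin"] == _silac.ORIGIN_MIXED).sum())


def _config_to_jsonable(config: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Mapping):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return convert(config)


def _finalize(config: PipelineConfig, tables, summary) -> PipelineResult:
    paths = None
    if config.out_dir is not None:
        paths = apio.write_results(tables, config.out_dir)
        log = {
            "config": _config_to_jsonable(config),
            "summary": summary,
        }
        log_path = Path(config.out_dir) / "run_log.json"
        log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        paths["run_log"] = log_path
    return PipelineResult(tables=tables, summary=summary, paths=paths)


# ---------------------------------------------------------------------------
# YAML configuration


def load_pipeline_config(path: str | Path, out_dir: str | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML document.

    Top-level keys: ``sim`` (simulator parameters) or ``inputs``
    (fragments/design/fasta/contaminants paths), plus optional
    ``filter_params``, ``calling_params``, ``digest_params`` and scalar
    settings mirroring PipelineConfig fields.
    """
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    kwargs: dict[str, Any] = {}
    if "sim" in doc:
        sim_doc = dict(doc["sim"])
        for key in ("time_points", "occupancy_fractions", "enrichment_folds",
                    "peptides_per_protein", "fragments_per_peptide",
                    "background_intensity_range"):
            if key in sim_doc and sim_doc[key] is not None:
                sim_doc[key] = tuple(sim_doc[key])
        kwargs["sim"] = SimConfig(**sim_doc)
    if "inputs" in doc:
        inputs = doc["inputs"]
        kwargs["fragments_path"] = inputs.get("fragments")
        kwargs["design_path"] = inputs.get("design")
        kwargs["fasta_path"] = inputs.get("fasta")
        kwargs["contaminants_path"] = inputs.get("contaminants")
    if "filter_params" in doc:
        kwargs["filter_params"] = frag.FilterParams(**doc["filter_params"])
    if "calling_params" in doc:
        kwargs["calling_params"] = _calling.CallingParams(**doc["calling_params"])
    if "digest_params" in doc:
        kwargs["digest_params"] = DigestParams(**doc["digest_params"])
    for key in ("bait_id", "stoich_time_min", "phospho_token",
                "silac_floor_quantile", "silac_exclusive_threshold"):
        if key in doc:
            kwargs[key] = doc[key]
    if "exclude_ids" in doc:
        kwargs["exclude_ids"] = tuple(doc["exclude_ids"])
    if out_dir is not None:
        kwargs["out_dir"] = out_dir
    elif "out_dir" in doc:
        kwargs["out_dir"] = doc["out_dir"]
    return PipelineConfig(**kwargs)
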