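"""Synthetic AP-MS / DIA experiment generator with known ground truth.

The generator emulates the statistical structure a fragment-level
interactome analysis assumes, so every downstream stage can be tested
without the deposited raw data:

* tagged-bait versus untagged-control purifications, each with biological
  replicates over a stimulation time course;
* a bait protein present only in tagged purifications;
* true interactors whose specific signal follows
  ``bait_abundance x occupancy x kinetic_profile(t)``, scaled by the ratio
  of prey to bait theoretical tryptic-peptide counts so that iBAQ
  normalization downstream recovers the programmed occupancy exactly in
  expectation;
* a non-specific carry-over level for each interactor (peak specific
  signal divided by its programmed enrichment fold) present in *both*
  backgrounds — without it a protein undetected in controls would lose its
  contrast to the per-analyte imputation rule. In tagged samples the
  carry-over is displaced as specific binding rises
  (``spec*kin + nonspec*(1-kin)``), so at peak recruitment the tagged
  signal equals the specific level exactly (keeping iBAQ occupancy
  recovery unbiased) and the peak bait/control ratio equals the
  programmed enrichment fold exactly;
* sticky contaminants (keratin/myosin/tubulin-like ids) enriched in bait
  pull-downs, so that only the contaminant blacklist removes them;
* background proteins with equal expected intensity in both backgrounds;
* fragment intensities generated as protein abundance x peptide weight x
  fragment weight (weights drawn once per analyte, fixed across samples),
  multiplied by lognormal biological replicate noise shared by all
  fragments of a peptide and a smaller independent per-fragment technical
  noise — reproducing the within-peptide fragment-profile correlation
  structure the reliability filter assumes;
* independent missingness per fragment observation, with an optional
  left-censoring mode, and optional heavy/light SILAC channels.

Generation is a pure function of the configuration (including its seed).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from . import io as apio

#: token marking a phosphorylated peptide form in peptide_id
PHOSPHO_TOKEN = "(ph)"

#: residues used for synthetic tryptic peptides: no K/R (cleavage sites),
#: no P (would suppress cleavage), so every generated peptide is counted
#: exactly once by an in-silico tryptic digestion with the KP rule
_AA_POOL = "ACDEFGHILMNQSTVWY"

_CONTAMINANT_PREFIXES = ("KRT", "TUB", "MYH")


class ConfigError(ValueError):
    """Invalid simulator configuration."""


class Experiment(NamedTuple):
    fragments: pd.DataFrame
    design: pd.DataFrame
    truth: pd.DataFrame
    sequences: dict[str, str]


def _kinetic_shape(t: float) -> float:
    """Smooth recruit-and-release shape peaking at 2 min, in [0, 1]."""
    if t <= 0:
        return 0.0
    return (t / 2.0) * math.exp(1.0 - t / 2.0)


def default_kinetic_profile(time_points) -> dict[float, float]:
    """Transient recruitment profile (PD-1-like, peak at 2 min), floored at 0.05."""
    prof = {float(t): max(0.05, round(_kinetic_shape(float(t)), 4)) for t in time_points}
    peak = max(prof.values())
    return {t: round(v / peak, 4) for t, v in prof.items()}


def constitutive_profile(time_points) -> dict[float, float]:
    return {float(t): 1.0 for t in time_points}


def default_phospho_profile(time_points) -> dict[float, float]:
    """Fraction of bait molecules phosphorylated on the reporter site."""
    return {
        float(t): round(0.02 + 0.88 * _kinetic_shape(float(t)), 4) for t in time_points
    }


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic AP-MS experiment.

    Defaults mirror the design of the primary-T-cell time-course screens:
    two backgrounds (tagged bait / untagged control), a 0/0.5/2/5/15-min
    pervanadate time course, three biological replicates, lognormal
    biological noise with CV 0.2 and 10% random missingness.
    """

    n_background_proteins: int = 500
    n_true_interactors: int = 20
    n_contaminants: int = 10
    n_replicates: int = 3
    time_points: tuple[float, ...] = (0.0, 0.5, 2.0, 5.0, 15.0)
    condition: str = "pervanadate"
    bait_id: str = "BAIT"
    bait_abundance: float = 1e6
    #: fraction of bait molecules bound at peak, one per interactor;
    #: default log-spaced over [0.01, 0.5]
    occupancy_fractions: tuple[float, ...] | None = None
    #: programmed bait/control enrichment fold, one per interactor
    enrichment_folds: tuple[float, ...] | None = None
    #: fraction of interactors given a time-varying recruitment profile
    #: (the rest are constitutive); ignored if kinetic_profiles is given
    kinetic_fraction: float = 0.5
    kinetic_profiles: tuple[Mapping[float, float], ...] | None = None
    contaminant_enrichment_fold: float = 8.0
    background_intensity_range: tuple[float, float] = (1e3, 1e5)
    peptides_per_protein: tuple[int, int] = (3, 8)
    fragments_per_peptide: tuple[int, int] = (3, 6)
    cv_biological: float = 0.2
    #: independent per-fragment measurement noise on top of the shared
    #: peptide-level biological noise
    cv_technical: float = 0.05
    missing_rate: float = 0.1
    #: if set, observations below this intensity go missing with a
    #: probability that increases linearly as intensity falls to zero
    censor_threshold: float | None = None
    #: simulate phosphorylated + unmodified forms of the bait's first peptide
    simulate_phospho: bool = False
    silac: bool = False
    #: protein -> fraction of its molecules from the light-labeled cell;
    #: default (SILAC mode): bait and background light, interactors cycle
    #: through (1.0, 0.5, 0.0)
    light_fractions: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_background_proteins, self.n_true_interactors, self.n_contaminants) < 0:
            raise ConfigError("protein counts must be non-negative")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.cv_biological < 0 or self.cv_technical < 0:
            raise ConfigError("noise CVs must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.bait_abundance <= 0:
            raise ConfigError("bait_abundance must be positive")
        for name in ("occupancy_fractions", "enrichment_folds", "kinetic_profiles"):
            value = getattr(self, name)
            if value is not None and len(value) != self.n_true_interactors:
                raise ConfigError(
                    f"{name} must have one entry per interactor "
                    f"({len(value)} given, {self.n_true_interactors} interactors)"
                )
        if self.occupancy_fractions is not None:
            if any(not (0 < f <= 1) for f in self.occupancy_fractions):
                raise ConfigError("occupancy fractions must lie in (0, 1]")
        if self.enrichment_folds is not None:
            if any(f <= 1 for f in self.enrichment_folds):
                raise ConfigError("enrichment folds must exceed 1")
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise ConfigError("peptides_per_protein range invalid")
        lo, hi = self.fragments_per_peptide
        if not (1 <= lo <= hi):
            raise ConfigError("fragments_per_peptide range invalid")

    # resolved per-interactor parameter vectors -----------------------------

    def resolved_occupancies(self) -> np.ndarray:
        if self.occupancy_fractions is not None:
            return np.asarray(self.occupancy_fractions, dtype=float)
        if self.n_true_interactors == 0:
            return np.empty(0)
        return np.geomspace(0.01, 0.5, self.n_true_interactors)

    def resolved_enrichment_folds(self) -> np.ndarray:
        if self.enrichment_folds is not None:
            return np.asarray(self.enrichment_folds, dtype=float)
        return np.full(self.n_true_interactors, 16.0)

    def resolved_kinetics(self) -> list[dict[float, float]]:
        if self.kinetic_profiles is not None:
            profiles = []
            for prof in self.kinetic_profiles:
                prof = {float(t): float(v) for t, v in prof.items()}
                missing = set(map(float, self.time_points)) - set(prof)
                if missing:
                    raise ConfigError(f"kinetic profile lacks time point(s) {sorted(missing)}")
                if any(not (0 <= v <= 1) for v in prof.values()):
                    raise ConfigError("kinetic profile values must lie in [0, 1]")
                profiles.append(prof)
            return profiles
        n_kin = int(round(self.kinetic_fraction * self.n_true_interactors))
        kin = default_kinetic_profile(self.time_points)
        const = constitutive_profile(self.time_points)
        # kinetic interactors first, constitutive afterwards
        return [dict(kin) for _ in range(n_kin)] + [
            dict(const) for _ in range(self.n_true_interactors - n_kin)
        ]


def format_profile(profile: Mapping[float, float]) -> str:
    return "|".join(f"{t:g}:{v:g}" for t, v in sorted(profile.items()))


def parse_profile(text: str) -> dict[float, float]:
    out: dict[float, float] = {}
    for token in str(text).split("|"):
        t, v = token.split(":")
        out[float(t)] = float(v)
    return out


def _make_sequence(rng: np.random.Generator, n_peptides: int) -> tuple[str, list[str]]:
    """A synthetic sequence with exactly ``n_peptides`` tryptic peptides.

    Each peptide is nine residues from an alphabet without K/R/P followed
    by K, so a fully tryptic digestion (cleave after K/R unless before P,
    length range 6-30) yields exactly the generated peptides.
    """
    peptides: list[str] = []
    seen: set[str] = set()
    while len(peptides) < n_peptides:
        pep = "".join(rng.choice(list(_AA_POOL), size=9)) + "K"
        if pep not in seen:  # uniqueness keeps the theoretical count exact
            seen.add(pep)
            peptides.append(pep)
    return "".join(peptides), peptides


def _build_design(config: SimConfig) -> pd.DataFrame:
    rows = []
    for background, tag in (("tagged_bait", "bait"), ("untagged_control", "ctrl")):
        for t in config.time_points:
            for rep in range(1, config.n_replicates + 1):
                base = f"{tag}_t{float(t):g}_r{rep}"
                if config.silac:
                    for suffix, channel in (("_L", "light"), ("_H", "heavy")):
                        rows.append((base + suffix, background, config.condition, float(t), rep, channel))
                else:
                    rows.append((base, background, config.condition, float(t), rep, "none"))
    return pd.DataFrame(rows, columns=apio.DESIGN_COLUMNS)


def simulate_experiment(config: SimConfig) -> Experiment:
    """Generate a fragment table, design, ground truth and sequence set.

    Deterministic for a fixed configuration: two calls with the same
    config (seed included) return identical tables.
    """
    rng = np.random.default_rng(config.seed)

    occupancies = config.resolved_occupancies()
    folds = config.resolved_enrichment_folds()
    kinetics = config.resolved_kinetics()

    # ---- protein roster (bait, interactors, contaminants, background)
    protein_ids = [config.bait_id]
    roles = ["bait"]
    for i in range(config.n_true_interactors):
        protein_ids.append(f"INT{i + 1:02d}")
        roles.append("interactor")
    for i in range(config.n_contaminants):
        prefix = _CONTAMINANT_PREFIXES[i % len(_CONTAMINANT_PREFIXES)]
        protein_ids.append(f"{prefix}{i + 1:03d}")
        roles.append("contaminant")
    for i in range(config.n_background_proteins):
        protein_ids.append(f"BG{i + 1:04d}")
        roles.append("background")
    n_prot = len(protein_ids)

    # ---- sequences with controlled tryptic-peptide counts
    lo, hi = config.peptides_per_protein
    n_pep = rng.integers(lo, hi + 1, size=n_prot)
    sequences: dict[str, str] = {}
    peptides_of: list[list[str]] = []
    for pid, k in zip(protein_ids, n_pep):
        seq, peps = _make_sequence(rng, int(k))
        sequences[pid] = seq
        peptides_of.append(peps)

    # ---- per-protein expected abundance in each design sample
    design = _build_design(config)
    n_samples = len(design)
    tagged = (design["background"] == "tagged_bait").to_numpy()
    times = design["time_min"].to_numpy()

    lo_bg, hi_bg = config.background_intensity_range
    base_levels = np.zeros(n_prot)
    abund = np.zeros((n_prot, n_samples))
    interactor_idx = 0
    n_pep_bait = int(n_pep[0])
    for p in range(n_prot):
        role = roles[p]
        if role == "bait":
            abund[p, tagged] = config.bait_abundance
        elif role == "interactor":
            occ = occupancies[interactor_idx]
            fold = folds[interactor_idx]
            kin = kinetics[interactor_idx]
            spec_peak = config.bait_abundance * occ * n_pep[p] / n_pep_bait
            nonspec = spec_peak / fold
            base_levels[p] = nonspec
            kin_t = np.array([kin[float(t)] for t in times])
            tagged_level = spec_peak * kin_t + nonspec * (1.0 - kin_t)
            abund[p, :] = np.where(tagged, tagged_level, nonspec)
            interactor_idx += 1
        elif role == "contaminant":
            level = np.exp(rng.uniform(np.log(lo_bg), np.log(hi_bg)))
            base_levels[p] = level
            abund[p, :] = np.where(tagged, level * config.contaminant_enrichment_fold, level)
        else:  # background
            level = np.exp(rng.uniform(np.log(lo_bg), np.log(hi_bg)))
            base_levels[p] = level
            abund[p, :] = level

    # ---- SILAC channel split
    light_frac = np.ones(n_prot)
    if config.silac:
        if config.light_fractions is None:
            cycle = (1.0, 0.5, 0.0)
            k = 0
            for p in range(n_prot):
                if roles[p] == "interactor":
                    light_frac[p] = cycle[k % len(cycle)]
                    k += 1
        else:
            for p, pid in enumerate(protein_ids):
                if pid in config.light_fractions:
                    frac = float(config.light_fractions[pid])
                    if not (0 <= frac <= 1):
                        raise ConfigError(f"light fraction for {pid} outside [0, 1]")
                    light_frac[p] = frac
        chan = design["silac_channel"].to_numpy()
        chan_factor = np.where(chan == "light", light_frac[:, None], (1.0 - light_frac)[:, None])
        abund = abund * chan_factor

    # ---- peptide layer: weights sum to 1 within each protein
    pep_protein_idx: list[int] = []
    pep_ids: list[str] = []
    pep_weights: list[float] = []
    for p in range(n_prot):
        k = int(n_pep[p])
        w = rng.lognormal(0.0, 0.5, size=k)
        w = w / w.sum()
        for j in range(k):
            pep_protein_idx.append(p)
            pep_ids.append(peptides_of[p][j])
            pep_weights.append(w[j])
    pep_protein_idx = np.asarray(pep_protein_idx)
    pep_weights_arr = np.asarray(pep_weights)

    pep_abund = abund[pep_protein_idx, :] * pep_weights_arr[:, None]

    # phospho forms of the bait's first peptide: the unmodified row is
    # down-weighted by the phosphorylated fraction and a phospho row added,
    # so the two forms always sum to the parent peptide's signal
    if config.simulate_phospho:
        phi_prof = default_phospho_profile(config.time_points)
        phi = np.array([phi_prof[float(t)] for t in times])
        bait_rows = np.flatnonzero(pep_protein_idx == 0)
        site = int(bait_rows[0])
        phospho_row = pep_abund[site, :] * phi
        pep_abund[site, :] = pep_abund[site, :] * (1.0 - phi)
        pep_protein_idx = np.append(pep_protein_idx, 0)
        pep_ids.append(pep_ids[site] + PHOSPHO_TOKEN)
        pep_abund = np.vstack([pep_abund, phospho_row])

    n_peptides_total = len(pep_ids)

    # ---- fragment layer: weights sum to 1 within each peptide
    lo_f, hi_f = config.fragments_per_peptide
    n_frag = rng.integers(lo_f, hi_f + 1, size=n_peptides_total)
    frag_pep_idx = np.repeat(np.arange(n_peptides_total), n_frag)
    frag_ids = np.concatenate([[f"y{j + 1}" for j in range(k)] for k in n_frag])
    frag_w = rng.lognormal(0.0, 0.5, size=len(frag_pep_idx))
    # normalize within peptide
    sums = np.zeros(n_peptides_total)
    np.add.at(sums, frag_pep_idx, frag_w)
    frag_w = frag_w / sums[frag_pep_idx]

    expected = pep_abund[frag_pep_idx, :] * frag_w[:, None]

    # ---- noise (unit-mean lognormal): biological at the peptide level,
    # shared by that peptide's fragments; technical per fragment
    def _lognoise(cv: float, shape: tuple[int, ...]) -> np.ndarray:
        if cv <= 0:
            return np.ones(shape)
        sigma = math.sqrt(math.log1p(cv**2))
        return rng.lognormal(-sigma**2 / 2.0, sigma, size=shape)

    bio = _lognoise(config.cv_biological, (n_peptides_total, n_samples))
    tech = _lognoise(config.cv_technical, expected.shape)
    intensity = expected * bio[frag_pep_idx, :] * tech

    p_miss = np.full(expected.shape, config.missing_rate)
    if config.censor_threshold is not None:
        thr = float(config.censor_threshold)
        frac_below = np.clip(1.0 - intensity / thr, 0.0, 1.0)
        p_miss = p_miss + (1.0 - p_miss) * frac_below
    missing = rng.random(expected.shape) < p_miss

    # ---- long-format table: a row exists wherever the analyte is present
    present = expected > 0
    frag_i, samp_i = np.nonzero(present)
    values = intensity[frag_i, samp_i]
    values = np.where(missing[frag_i, samp_i], np.nan, values)
    protein_arr = np.asarray(protein_ids, dtype=object)
    pep_arr = np.asarray(pep_ids, dtype=object)
    fragments = pd.DataFrame(
        {
            "protein_id": protein_arr[pep_protein_idx[frag_pep_idx[frag_i]]],
            "peptide_id": pep_arr[frag_pep_idx[frag_i]],
            "fragment_id": frag_ids[frag_i],
            "sample_id": design["sample_id"].to_numpy()[samp_i],
            "intensity": values,
        }
    )

    # ---- ground truth
    occ_col = np.full(n_prot, np.nan)
    fold_col = np.full(n_prot, np.nan)
    kin_col = [""] * n_prot
    is_kin = np.zeros(n_prot, dtype=bool)
    interactor_idx = 0
    for p in range(n_prot):
        if roles[p] == "interactor":
            occ_col[p] = occupancies[interactor_idx]
            fold_col[p] = folds[interactor_idx]
            prof = kinetics[interactor_idx]
            kin_col[p] = format_profile(prof)
            is_kin[p] = len(set(prof.values())) > 1
            interactor_idx += 1
        elif roles[p] == "contaminant":
            fold_col[p] = config.contaminant_enrichment_fold
    truth = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "role": roles,
            "is_true_interactor": [r == "interactor" for r in roles],
            "is_contaminant": [r == "contaminant" for r in roles],
            "is_kinetic": is_kin,
            "occupancy_fraction": occ_col,
            "enrichment_fold": fold_col,
            "kinetic_profile": kin_col,
            "peptide_count": n_pep.astype(int),
            "light_fraction": light_frac,
            "base_level": base_levels,
        }
    )
    return Experiment(fragments, design, truth, sequences)


def simulate_silac_experiment(config: SimConfig) -> Experiment:
    """Generate a SILAC (heavy/light) experiment; requires ``config.silac``."""
    if not config.silac:
        raise ConfigError("simulate_silac_experiment requires a config with silac=True")
    return simulate_experiment(config)


def expected_log2_enrichment(truth: pd.DataFrame, time_min: float) -> pd.Series:
    """Programmed log2(bait/control) per protein at one time point.

    Background proteins have 0; the bait (absent from controls) has NaN.
    """
    out = pd.Series(0.0, index=truth["protein_id"].to_numpy())
    for _, row in truth.iterrows():
        pid = row["protein_id"]
        if row["role"] == "bait":
            out[pid] = np.nan
        elif row["role"] == "interactor":
            kin = parse_profile(row["kinetic_profile"])[float(time_min)]
            fold = row["enrichment_fold"]
            out[pid] = math.log2(1.0 + (fold - 1.0) * kin)
        elif row["role"] == "contaminant":
            out[pid] = math.log2(row["enrichment_fold"])
    return out


def write_experiment(exp: Experiment, out_dir: str | Path) -> dict[str, Path]:
    """Write fragments.tsv, design.tsv, truth.tsv and proteins.fasta."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fragments": out / "fragments.tsv",
        "design": out / "design.tsv",
        "truth": out / "truth.tsv",
        "fasta": out / "proteins.fasta",
    }
    apio.write_fragment_table(exp.fragments, paths["fragments"])
    apio.write_design(exp.design, paths["design"])
    exp.truth.to_csv(paths["truth"], sep="\t", index=False, na_rep="", lineterminator="\n")
    apio.write_fasta(exp.sequences, paths["fasta"])
    return paths
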