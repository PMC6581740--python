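# apmsdia

Quantitative interactome analysis for affinity-purification mass
spectrometry (AP-MS) measured by data-independent acquisition (DIA/SWATH),
from long-format fragment intensities to high-confidence bait interactors,
interaction stoichiometries and SILAC origin calls — with a ground-truth
simulator so every stage is benchmarkable without raw instrument data.

It is aimed at proteomics analysts who have fragment-level DIA
quantities for tagged-bait and untagged-control purifications (the
classic coinhibitory-receptor signalosome design: a Twin-Strep-tagged
receptor pulled down over a stimulation time course, against matched
untagged controls) and want a tested, reproducible implementation of the
downstream statistics.

## What it computes

**Fragment processing.** Fragments must be observed at least twice per
condition (background × condition × time). A reliability filter then
compares each fragment's centered log2 profile with its peptide's
across-fragment median profile and drops fragments with Pearson
correlation < 0.25 or with a mean absolute shape deviation above 2× the
peptide's residual spread (the "minimal correlation" and "standard
deviation factor" settings of mapDIA-style fragment selection). Retained
fragments are summed to peptide and protein quantities; missing analyte
values are imputed with the 0.01 quantile of that analyte's observed
values.

**Interactor statistics (reproducibility-optimized).** For each peptide,
a paired t-test over replicate pairs r of log2 quantities:

    d_r = log2(x_bait,r) − log2(x_ctrl,r),   t = mean(d) / (sd(d)/√n)

Protein-level significance uses the median order statistic: with n
peptide p-values and k = ⌊n/2⌋ + 1, the protein p-value is the
Beta(k, n−k+1) CDF at the k-th smallest peptide p — the null law of the
median of n uniforms. Protein fold change is the median peptide log2
fold change; Benjamini–Hochberg controls the FDR per contrast.

**Two orthogonal filters.** A protein is a *specific* interactor when it
is > 3-fold (primary T-cell preset; 6-fold for Jurkat) more abundant in
bait than control purifications at FDR < 0.01 in at least two
independent conditions, and is not on the contaminant blacklist
(recurrent AP-MS background plus all keratins/myosins/tubulins). A
specific interactor is *dynamic* when its bait-normalized quantity
changes ≥ 2-fold (FDR < 0.05, either direction) between stimulated and
unstimulated conditions.

**Stoichiometry.** iBAQ = protein quantity ÷ number of theoretical
tryptic peptides (fully tryptic, cleave after K/R except before P,
length 6–30). The interaction stoichiometry of a prey is its iBAQ
divided by the bait's iBAQ in the same condition — the fraction of bait
molecules it occupies.

**SILAC origin.** In mixed-cell experiments where the partner cell is
heavy-labeled, per-protein light/heavy ratios (undetected channels
floored at the 1% quantile of detected values) classify each interactor
as T-cell exclusive, APC exclusive, or mixed.

## Worked example

The benchmark screen spikes 20 true interactors (half with transient
recruitment peaking 2 min after stimulation) among 500 background
proteins and 10 sticky contaminants:

```sh
python analysis/01_simulate.py          # write benchmark datasets
python analysis/04_call_interactors.py  # full pipeline vs ground truth
python analysis/05_stoichiometry.py     # iBAQ occupancy recovery
```

prints

```
specific calls: 20 (true interactors: 20)
  true positives 20, false positives 0, missed 0
contaminants removed by blacklist: 10
dynamic calls: 10; kinetic interactors recovered 10/10

INT01: programmed 13.0% -> recovered 14.18% (9.1% relative error)
INT02: programmed 1.4% -> recovered 1.35% (3.5% relative error)
INT03: programmed 69.0% -> recovered 69.90% (1.3% relative error)
20-seed mean recovered: 12.98% / 1.395% / 69.1%  (mean relative bias -0.14%)
```

i.e. the two-step filter recovers the programmed interactome exactly
(all 20 interactors specific, the 10 contaminants removed by the
blacklist rather than mis-called, the 10 kinetic interactors flagged
dynamic), and bait-normalized iBAQ recovers programmed occupancies of
13%, 1.4% and 69% to within a few percent.

The same stages are available programmatically:

```python
from apmsdia import SimConfig, PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(sim=SimConfig(seed=7), out_dir="out"))
print(res.summary["n_specific"], res.summary["n_dynamic"])
```

and as a CLI (`apmsdia simulate|process|test|call|stoich|silac|run`) for
real exports: a long-format fragment TSV (`protein_id, peptide_id,
fragment_id, sample_id, intensity`; empty cell = not detected), a sample
design TSV, and a FASTA of protein sequences.

## Layout

- `src/apmsdia/` — the library: `io`, `simulate`, `fragments`, `ropeca`
  (peptide→protein statistics), `calling`, `stoichiometry`, `silac`,
  `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and end-to-end statistical tests.
- `docs/methods.md` — models, assumptions, parameter choices and
  limitations.
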