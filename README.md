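# apms

Quantitative AP-MS interactomics and EPSC event analysis.

`apms` is a tested, reusable implementation of the analysis stack used
to dissect membrane-protein complexes by affinity purification coupled
to mass spectrometry (AP-MS) — motivated by the AMPA-type glutamate
receptor proteome, where serial purifications and quantitative
specificity calling identify receptor sub-populations such as the
FRRS1l/CPT1c-containing assemblies of the endoplasmic reticulum — plus
the electrophysiological event analysis (EPSC amplitude, kinetics,
paired-pulse ratio, AMPA/NMDA ratio) used to measure the functional
consequences of perturbing those assemblies. It is aimed at proteomics
and synaptic-physiology labs that want these estimators as plain,
scriptable Python functions with synthetic ground-truth data for every
stage.

## What it computes

Starting from peptide-level peak volumes PV(p, d) (a peptide's m/z
intensity integrated over chromatographic time in AP dataset d):

- **Protein profiles** — each peptide's PVs are normalized to their own
  maximum over datasets (cancelling the peptide response factor),
  peptides are ranked by mean pairwise Pearson correlation, and the
  per-dataset median over the best-correlating half (at least 3) gives
  the protein's relative abundance profile.
- **Molecular abundance** — profiles are scaled by a single
  least-squares factor onto QconCAT standard-peptide calibration
  anchors; proteins without standards use the spectral estimator
  (summed isoform-specific PVs per MS-accessible residue). Abundances
  are normalized to each dataset's primary target; for anti-GluA1-4
  APs the co-purified AMPAR amount is Σ(GluA1-4)/4.
- **Specificity** — per-protein enrichment ratios rPV against IgG,
  target-depletion and knockout controls, thresholded at
  exp(median + 3·1.4826·MAD) of the background log-rPV mode; a protein
  is a bona fide interactor when it passes with ≥ 2 independent
  antibodies and every depletion/knockout control.
- **Two-step partitioning** — for serial, target-depleting AP pairs,
  the fraction captured by the first step is F = rPV/(rPV + 1), with
  1 − F in the second step (conserved exactly).
- **Group comparisons** — abundance ratios (e.g. knockout/wild-type)
  with two-sided t-tests, and cross-dataset Pearson correlation of a
  focal protein against subunits and subunit-set sums.
- **EPSC events** — peak within 2 ms of the presynaptic AP, latency at
  5% of peak (accepted in 0.2–2 ms), 20–80% rise time, mono-exponential
  decay τ over 40 ms, acceptance filters (amplitude > 20 pA, clean
  decay ≥ 40 ms, rise 0.4–2.0 ms), paired-pulse and AMPA/NMDA ratios,
  amplitude histograms, Mann-Whitney U tests.

Every stage has a synthetic-data generator with known ground truth
(`apms.synthdata`), so recovery is testable without any external data.
See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

Simulate a two-antibody AP bundle, run the pipeline, and inspect the
target-normalized abundances:

```sh
apms simulate --preset apms --seed 0 --out bundle/
apms run --pv-table bundle/pv_table.tsv --calibration bundle/calibration.tsv \
         --meta bundle/dataset_meta.tsv --out run/
```

```python
>>> import pandas as pd
>>> norm = pd.read_csv("run/normalized_abundance.tsv", sep="\t", index_col=0)
>>> norm.round(3).head(4)
            AP_1   AP_2
protein_id
TARGET       1.0  1.000
PRY01        0.5  0.605
PRY02        0.5  0.497
PRY03        0.5  0.497
```

The bait (`TARGET`) is exactly 1 in each AP by construction of the
normalization. The simulated preys were generated at half the bait's
abundance: in `AP_1`, where every protein has a calibration anchor,
the fit pins the normalized value at exactly 0.5, while in the
uncalibrated `AP_2` the recovered values scatter around 0.5 with the
simulation's 20% measurement CV.

The same library functions reproduce printed-statistics arithmetic
directly:

```python
>>> from apms import report
>>> report.proportions_from_counts({"er": 815, "pm": 33}).rounded_percent
(96.1, 3.9)
>>> report.percent_reduction(report.GroupMeans(1.12, (0.57, 0.65)), 5).rounded
45.0
```

— i.e. 815 of 848 immunogold particles correspond to 96.1% ER
localization, and AMPA/NMDA ratios of 0.57 and 0.65 against a control
of 1.12 pool to a 45% reduction.

## Command-line interface

`apms` exposes subcommands `simulate`, `run`, `quant`, `twostep`,
`ephys` and `report`; every command with randomness takes `--seed`.
All inputs and outputs are tab-separated text (traces as two-column
CSV), with ground truth and report metadata as JSON.
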