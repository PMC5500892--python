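# Methods

## Scope

`apms` implements the quantitative analysis stack behind
affinity-purification mass-spectrometry (AP-MS) interactomics of
membrane-protein complexes — here modelled on the AMPA-receptor
proteome, with FRRS1l/CPT1c-containing receptor assemblies as the
motivating system — together with the event-level analysis of
excitatory postsynaptic currents (EPSCs) used to assess the functional
consequences of perturbing such assemblies. The pipeline starts at
peptide-level feature tables (peak volumes); raw-spectra processing,
peptide identification and retention-time alignment are upstream and
out of scope.

## Label-free quantification from peak volumes

The elementary datum is the peak volume PV(p, d): peptide p's m/z
signal intensity integrated over chromatographic time in AP dataset d.
The estimator assumes PV(p, d) = A(i, d) · R(p) · ε, where A is the
molecular abundance of p's protein i, R an unknown peptide response
factor (ionization/digestion efficiency, roughly log-normal over
peptides), and ε multiplicative measurement noise. Because R is
time-invariant, dividing each peptide's PVs by that peptide's maximum
over all datasets cancels R exactly; the resulting relative peptide
profiles of one protein are, up to noise, replicates of the same latent
relative abundance profile.

Peptides are then ranked by their mean pairwise Pearson correlation
across datasets (pairwise-complete, requiring ≥ 3 shared observations
per pair; pairs below that contribute r = 0 so that undefined
correlations cannot dominate the ranking). Peptides with mean r below a
cutoff (default 0) are treated as outliers or false assignments and
removed; of the n remaining, the k = max(k_min, ⌈fraction·n⌉)
best-correlating are kept (k = n when n ≤ k_min; defaults k_min = 3,
fraction = 0.5, no upper cap — an optional `k_cap` exists for users who
want the historical "2–7" behaviour). Ties are broken lexicographically
by sequence so selection is deterministic. The protein profile is the
per-dataset median over the selected profiles; the median plus the
correlation ranking makes the estimate robust to a single grossly
distorted peptide (exactly reproduced by the noiseless-outlier test).

Calibration against concatenated-standard peptides (QconCAT) is a
single non-negative least-squares scale factor per protein,
s = Σ p·c / Σ p², fitted globally over all datasets with anchors.
Fitting one global factor rather than per-dataset factors is a design
choice: per-dataset factors would absorb exactly the biological signal
the profile carries. For proteins without standards, the spectral
estimator `abundance_spec` (summed isoform-specific PVs divided by the
number of MS-accessible isoform-specific amino acids) provides a
comparable scale; only its rank order is trusted in tests.

Abundances are normalized per dataset to the primary target protein(s);
for anti-GluA1-4 purifications the reference equals the co-purified
AMPAR amount, defined as (GluA1 + GluA2 + GluA3 + GluA4)/4. Control
datasets (IgG, depletion, knockout) have no meaningfully captured
target and pass through unnormalized; they serve only as rPV
denominators.

## Specificity analysis

Enrichment of a protein between two dataset groups is rPV: per
first-group replicate, its abundance divided by the mean abundance over
the second group; replicate ratios are combined as mean ± s.e.m.
(n − 1 denominator). Proteins undetected in a control are given a
detection-floor abundance of half the smallest observed value in that
dataset (flagged as imputed) so that finite ratios exist, mirroring how
specific interactors absent from IgG controls still receive ratios.

The specificity threshold is estimated from the distribution of all
detected proteins' rPVs in a comparison: on log(rPV), threshold =
exp(median + c · 1.4826 · MAD) with c = 3 by default. Median/MAD track
the dominant background mode and are insensitive to the minority of
truly enriched proteins; at least 20 finite rPVs are required,
otherwise the estimator refuses and asks for a manual threshold. The
histogram procedure behind published thresholds is not fully specified
anywhere we could follow; this robust mode-plus-spread rule is our
declared reading, with the multiplier configurable.

A protein is called a bona fide interactor when it exceeds the
threshold versus IgG with at least two independent antibodies *and* in
every available comparison against a depletion or knockout control.
On pure-background simulations this consensus yields no calls in ≥ 95%
of seeds.

## Two-step (serial) purifications

Serial APs deplete the first target exhaustively, then purify the
flow-through with a second antibody. The fraction of a protein
co-assembled with the first target is F = rPV/(rPV + 1) where rPV is
the first-to-second abundance ratio; the second step holds 1 − F by
construction, so the partition conserves unity exactly. F is computed
per first-AP replicate against the averaged second APs and reported as
mean ± s.e.m. (mean of per-replicate F values, matching the
per-replicate-rPV phrasing of the source workflow). A protein absent
from the second AP is fully captured (F = 1) and flagged as a boundary
case.

## Group comparisons and correlation

Wild-type versus knockout (or control- versus knockdown-shRNA)
comparisons use per-protein abundance ratios mean(A)/mean(B) on
target-normalized abundances with a two-sided Student's t-test
(equal-variance, ≥ 2 replicates per group); significance stars at
p < 0.01 (**) and p < 0.001 (***). No multiple-testing correction is
applied — the analysis reports per-protein ratios the way the source
workflow does, and the test suite treats the p-values as descriptive.
Cross-dataset correlation reports Pearson r between a focal protein's
abundance vector and individual subunits as well as per-dataset sums
over named subunit sets (e.g. the auxiliary core subunits), ranked.

## EPSC analysis

Traces are inward-negative current recordings (default 20 kHz);
amplitudes are reported as positive magnitudes. Per event:

- baseline: mean of the 5 ms preceding the reference point (the
  stimulus AP for evoked events). The window length is our choice — the
  source conventions do not state one — and is short enough to avoid
  prior events that pass the 40-ms cleanliness rule.
- peak: extremum of the baseline-subtracted current within 2 ms after
  the presynaptic AP. Events peaking later are under-estimated by
  design; for spontaneous events, where no AP pins the peak, a 5-ms
  window is used instead.
- onset/latency: first crossing of 5% of peak amplitude; evoked
  latencies must lie in [0.2, 2] ms.
- rise time: first 20% and 80% crossings before the peak, linearly
  interpolated. For a saturating-exponential rise this equals
  ln 4 · τ_rise, which the tests verify to within one sampling
  interval.
- decay: mono-exponential A·e^(−t/τ) least-squares fit from the peak
  over a 40-ms window (the segment guaranteed clean by the acceptance
  rule), initialized from a log-linear regression.

Events enter summaries only when amplitude > 20 pA, no later event
onset falls within 40 ms, and the rise time lies in [0.4, 2.0] ms; each
violated rule is recorded as a rejection reason, and the tests check
each rule is individually necessary.

Spontaneous-event detection (the pre-filter the published rules do not
specify) is a declared stand-in: the smoothed trace's derivative is
thresholded at 3 robust standard deviations — the fast rising phase
produces a large positive slope while the slow decay cannot retrigger —
and each candidate must be confirmed by a ≥ 3σ amplitude deflection
within 2 ms. Paired-pulse analysis subtracts the first event's fitted
decay before measuring the second amplitude, so 50-Hz pairs are not
contaminated by residual decay; PPR = 100·amp2/amp1. AMPA/NMDA ratios
divide the AMPA component (total minus the NMDA component remaining
after AMPAR block) by the NMDA amplitude.

Group significance for electrophysiology uses the two-sided
Mann-Whitney U test: exact null distribution for combined n ≤ 20
without ties, tie-corrected normal approximation otherwise; two
all-identical groups return p = 1 by convention.

## Descriptive report statistics

Category percentages from integer counts, pooled percent-of-control
(100·mean(treatment means)/control) and percent reduction
(its complement) use half-away-from-zero rounding applied *after*
pooling; pooling across treatment conditions is an unweighted mean of
group means, not of raw events. Whether published pooled figures
average conditions or describe them separately is ambiguous; the
pooled-mean reading is implemented and is the one under which the
worked examples round to the printed 96.1%, 45% and 60% figures.

## Synthetic data: what it emulates and what it does not

The AP-MS generator draws PV(p, d) = A(i, d)·R(p)·ε(p, d) with
log-normal R (σ default 0.5) and unit-mean log-normal ε of configurable
CV (default 0.2); optional "outlier" peptides receive an extra
independent per-dataset log-normal distortion (magnitude 10), and an
optional logistic-in-log-PV dropout emulates detection limits (off by
default). Replicate-to-replicate PV variance figures are not published
for this workflow; the CVs used in the recovery experiments (0.1–0.2)
were chosen once as typical for label-free MS intensities. Zero latent
abundance is reported as missing ("not detected"). The generator does
not emulate chromatographic drift, co-eluting interference, shared
peptides between paralogs, or intensity-dependent variance — so
passing recovery tests demonstrate correctness of the estimators under
the stated noise model, not robustness to every artefact of real
LC-MS data.

EPSC traces are sums of difference-of-exponential events
(1 − e^(−t/τr))·e^(−t/τd), scaled to peak amplitude, on Gaussian
baseline noise — chosen so the decay is mono-exponential and the rise
time has a closed form, giving exact oracles. Defaults: amplitude
100 pA (CV 0.3), τ_rise 0.4 ms, τ_decay 11.3 ms (a typical control
decay constant for the studied synapse), latency 0.5 ms, noise s.d.
2 pA, 20 kHz sampling. τ_rise and latency are set so that default
events satisfy the acceptance rules and peak within the evoked 2-ms
window; real synapses show wider kinetic diversity. Event rates above
25 Hz necessarily violate the 40-ms clean-decay rule and are logged as
a warning.

## Numerical conventions

- Tables: TSV, UTF-8, '.' decimal, empty string = missing (distinct
  from 0); floats serialized at six significant digits, below
  measurement precision, so read∘write is the identity.
- All generators take an explicit integer seed
  (`numpy.random.default_rng`); pipeline outputs are a pure function of
  (inputs, config, seed).
- Degenerate inputs: all-missing peptides are dropped with a warning;
  an all-zero abundance model, a zero-total count table and an empty
  comparison group are errors; an all-identical rPV distribution
  yields its common value as a (warned) degenerate threshold.
- Problem sizes in the recovery experiments (e.g. 10 proteins × 8
  datasets × 6 peptides, 100 seeds; 205 proteins for specificity,
  50 seeds) were chosen as the smallest configurations at which the
  Monte-Carlo bands are stable from seed to seed.

## Known limitations

- No protein inference from shared peptides beyond the
  isoform-specific flag; no SAINT/CompPASS-style probabilistic
  interaction scoring (the explicit threshold rules are the point).
- The correlation-based outlier filter and the rPV histogram threshold
  are declared approximations of procedures whose full details are not
  restated in the sources available to us.
- The spontaneous-event detector is a simple slope-threshold device;
  deconvolution- or template-based detectors would recover more
  overlapping events.
- QconCAT calibration assumes anchors share the profile's scale up to
  one factor; systematic per-dataset calibration drift is not modelled.
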