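"""Synthetic AP-MS peak-volume matrices and EPSC traces with known truth.

The AP-MS generator draws, for every peptide p of protein i in dataset d,

    PV(p, d) = A(i, d) * R(p) * eps(p, d) [* O(p, d)]

where A is the latent molecular abundance, R a log-normal per-peptide
response factor (ionization efficiency), eps multiplicative log-normal
measurement noise of a given CV (unit mean), and O an optional
per-dataset distortion applied to "outlier" peptides that breaks their
correlation with siblings. Abundances of zero are reported as missing
("not detected"), and an optional logistic-in-log-PV dropout emulates
the detection limit. Every generator is a pure function of its seed;
in the noiseless limit all outputs reduce to closed forms.

EPSC traces are sums of difference-of-exponential events,
A * (1 - exp(-t/tau_rise)) * exp(-t/tau_decay) scaled to peak amplitude,
on Gaussian baseline noise, so the decay phase is mono-exponential and
the 20-80% rise time has the closed form ln(4) * tau_rise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import DatasetMeta, PeptideRecord, PVMatrix, ValidationError

logger = logging.getLogger("apms")

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative measurement-noise model for simulated PVs.

    sigma_response is the log-sd of the per-peptide response factor;
    cv the coefficient of variation of the unit-mean log-normal
    measurement noise; outlier peptides (probability outlier_prob)
    receive an extra independent per-dataset log-normal distortion of
    log-sd ln(outlier_magnitude). Dropout, when enabled, is logistic in
    log10(PV) with probability 1/2 at dropout_midpoint_pv, so
    low-abundance peptides drop out preferentially.
    """

    sigma_response: float = 0.5
    cv: float = 0.2
    outlier_prob: float = 0.0
    outlier_magnitude: float = 10.0
    dropout_midpoint_pv: float | None = None
    dropout_steepness: float = 2.0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValidationError("cv must be >= 0")
        if self.sigma_response < 0:
            raise ValidationError("sigma_response must be >= 0")
        if not 0 <= self.outlier_prob <= 1:
            raise ValidationError("outlier_prob must be in [0, 1]")
        if self.outlier_magnitude <= 1:
            raise ValidationError("outlier_magnitude must be > 1")
        if self.dropout_midpoint_pv is not None and self.dropout_midpoint_pv <= 0:
            raise ValidationError("dropout_midpoint_pv must be > 0")

    def dropout_probability(self, pv: np.ndarray) -> np.ndarray:
        if self.dropout_midpoint_pv is None:
            return np.zeros_like(pv, dtype=float)
        x = np.log10(np.maximum(pv, 1e-300)) - math.log10(self.dropout_midpoint_pv)
        return 1.0 / (1.0 + np.exp(self.dropout_steepness * x))


NOISELESS = NoiseModel(sigma_response=0.0, cv=0.0)


@dataclass(frozen=True)
class ComplexModel:
    """Latent truth of an AP-MS experiment: protein abundances per dataset.

    ``true_abundance`` is proteins x datasets (arbitrary units, >= 0);
    zero means the protein is not captured in that dataset. Optional
    dataset metadata describes targets and controls.
    """

    true_abundance: pd.DataFrame
    datasets: tuple[DatasetMeta, ...] | None = None

    def __post_init__(self) -> None:
        arr = self.true_abundance.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("true abundances must be finite")
        if (arr < 0).any():
            raise ValidationError("true abundances must be >= 0")
        if self.datasets is not None:
            ids = [d.dataset_id for d in self.datasets]
            if ids != list(self.true_abundance.columns):
                raise ValidationError("dataset metadata must match columns")


@dataclass
class ApmsTruth:
    """Ground-truth record stored beside a simulated PV matrix."""

    true_abundance: pd.DataFrame
    responses: pd.Series  # per peptide
    outlier_peptides: tuple[str, ...]
    protein_of: pd.Series

    def relative_profiles(self) -> pd.DataFrame:
        """True relative abundance: each protein scaled to its maximum."""
        ab = self.true_abundance
        return ab.div(ab.max(axis=1), axis=0)


# ---------------------------------------------------------------------------
# AP-MS generators
# ---------------------------------------------------------------------------

def _random_sequences(rng: np.random.Generator, n: int, length: int = 10) -> list[str]:
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        s = "".join(rng.choice(_AA, size=length))
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    return seqs


def _noise_factors(
    rng: np.random.Generator, cv: float, shape: tuple[int, ...]
) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(sigma * rng.standard_normal(shape) - 0.5 * sigma * sigma)


def simulate_apms(
    model: ComplexModel,
    noise: NoiseModel,
    n_peptides_per_protein: int,
    seed: int,
) -> tuple[PVMatrix, ApmsTruth]:
    """Draw a peptide-level PV matrix from a latent abundance model."""
    if n_peptides_per_protein < 1:
        raise ValidationError("n_peptides_per_protein must be >= 1")
    ab = model.true_abundance
    if not (ab.to_numpy() > 0).any():
        raise ValidationError("degenerate model: all abundances are zero")
    rng = np.random.default_rng(seed)

    proteins = list(ab.index)
    n_pep = n_peptides_per_protein * len(proteins)
    seqs = _random_sequences(rng, n_pep)
    protein_of = pd.Series(
        np.repeat(proteins, n_peptides_per_protein), index=seqs, name="protein_id"
    )
    responses = pd.Series(
        np.exp(noise.sigma_response * rng.standard_normal(n_pep)),
        index=seqs,
        name="response",
    )
    outlier_mask = rng.random(n_pep) < noise.outlier_prob

    a = ab.to_numpy(dtype=float)
    a_pep = np.repeat(a, n_peptides_per_protein, axis=0)
    pv = a_pep * responses.to_numpy()[:, None]
    pv *= _noise_factors(rng, noise.cv, pv.shape)
    if outlier_mask.any():
        sigma_out = math.log(noise.outlier_magnitude)
        distort = np.exp(sigma_out * rng.standard_normal(pv.shape))
        pv[outlier_mask] *= distort[outlier_mask]

    values = pd.DataFrame(pv, index=seqs, columns=ab.columns)
    values = values.mask(values == 0)  # not captured -> not detected
    p_drop = noise.dropout_probability(values.to_numpy())
    drop = (rng.random(values.shape) < p_drop) & values.notna().to_numpy()
    values = values.mask(drop)

    peptides = [PeptideRecord(protein_of[s], s) for s in seqs]
    datasets = list(model.datasets) if model.datasets is not None else None
    truth = ApmsTruth(
        true_abundance=ab,
        responses=responses,
        outlier_peptides=tuple(np.array(seqs)[outlier_mask]),
        protein_of=protein_of,
    )
    return PVMatrix(peptides, values, datasets), truth


def simulate_twostep(
    totals: Mapping[str, float] | pd.Series,
    fraction_first_true: Mapping[str, float],
    noise: NoiseModel,
    n_replicates: int = 3,
    n_peptides_per_protein: int = 4,
    seed: int = 0,
) -> tuple[PVMatrix, ApmsTruth, list[str], list[str]]:
    """Simulate serial AP pairs where step 1 exhaustively depletes the target.

    Each protein's total abundance is split F : (1 - F) between the first
    and second AP of every replicate pair, so expected(first + second)
    equals the total exactly. F = 1 leaves the protein undetected in the
    second AP. Returns the matrix, the truth, and the first/second
    dataset ids.
    """
    totals = pd.Series(totals, dtype=float)
    f = pd.Series(dict(fraction_first_true), dtype=float).reindex(totals.index)
    if f.isna().any():
        raise ValidationError("fraction_first_true must cover every protein")
    if ((f < 0) | (f > 1)).any():
        raise ValidationError("true fractions must lie in [0, 1]")
    first_ids = [f"first_{r + 1}" for r in range(n_replicates)]
    second_ids = [f"second_{r + 1}" for r in range(n_replicates)]
    ab = pd.DataFrame(
        {
            **{d: totals * f for d in first_ids},
            **{d: totals * (1.0 - f) for d in second_ids},
        }
    )
    model = ComplexModel(ab)
    pv, truth = simulate_apms(model, noise, n_peptides_per_protein, seed)
    return pv, truth, first_ids, second_ids


# ---------------------------------------------------------------------------
# preset AP-MS scenarios
# ---------------------------------------------------------------------------

def specificity_model(
    n_preys: int = 5,
    n_background: int = 200,
    target_abundance: float = 100.0,
    prey_abundance: float = 50.0,
    background_abundance: float = 20.0,
) -> tuple[ComplexModel, dict[str, list[str]]]:
    """Two antibody APs plus IgG and target-depletion controls.

    True preys are captured only in the target APs; background proteins
    bind non-specifically at equal amounts everywhere. Returns the model
    and the comparison groups (dataset ids keyed by role).
    """
    preys = [f"PRY{i + 1:02d}" for i in range(n_preys)]
    background = [f"BKG{i + 1:03d}" for i in range(n_background)]
    cols = ["AP_ab1", "AP_ab2", "IgG", "depletion"]
    rows: dict[str, list[float]] = {"TARGET": [target_abundance, target_abundance, 0.0, 0.0]}
    for p in preys:
        rows[p] = [prey_abundance, prey_abundance, 0.0, 0.0]
    for b in background:
        rows[b] = [background_abundance] * 4
    ab = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    groups = {
        "ab1": ["AP_ab1"],
        "ab2": ["AP_ab2"],
        "igg": ["IgG"],
        "depletion": ["depletion"],
        "true_preys": preys,
        "background": background,
    }
    return ComplexModel(ab), groups


def knockout_model(
    n_wt: int = 4,
    n_ko: int = 4,
    knocked_protein: str = "FRRS1l",
    reduction: float = 0.9,
    baseline_abundance: float = 20.0,
    n_stable: int = 10,
) -> tuple[ComplexModel, dict[str, list[str]]]:
    """Anti-GluA1-4 APs from wild-type vs knockout tissue.

    GluA1-4 are the (target) reference at equal amounts in both
    genotypes; one protein is reduced by ``reduction`` in the knockout;
    stable constituents span a range of abundances.
    """
    wt = [f"WT_{r + 1}" for r in range(n_wt)]
    ko = [f"KO_{r + 1}" for r in range(n_ko)]
    cols = wt + ko
    rows: dict[str, list[float]] = {}
    for g in ("GluA1", "GluA2", "GluA3", "GluA4"):
        rows[g] = [100.0] * len(cols)
    rows[knocked_protein] = [baseline_abundance] * n_wt + [
        baseline_abundance * (1.0 - reduction)
    ] * n_ko
    for i in range(n_stable):
        level = 5.0 * (i + 1)
        rows[f"STAB{i + 1:02d}"] = [level] * len(cols)
    ab = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    meta = tuple(
        DatasetMeta(
            dataset_id=c,
            target_protein_ids=frozenset(("GluA1", "GluA2", "GluA3", "GluA4")),
            antibody_id="anti-GluA1-4",
            replicate_group="WT" if c in wt else "KO",
        )
        for c in cols
    )
    return ComplexModel(ab, meta), {"wt": wt, "ko": ko}


def random_abundance_model(
    n_proteins: int,
    n_datasets: int,
    seed: int,
    log10_range: float = 2.0,
) -> ComplexModel:
    """Independent log-uniform abundances spanning ``log10_range`` decades."""
    rng = np.random.default_rng(seed)
    ab = 10.0 ** (log10_range * rng.random((n_proteins, n_datasets)) + 1.0)
    frame = pd.DataFrame(
        ab,
        index=[f"PROT{i + 1:03d}" for i in range(n_proteins)],
        columns=[f"AP_{j + 1}" for j in range(n_datasets)],
    )
    return ComplexModel(frame)


# ---------------------------------------------------------------------------
# EPSC traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EPSCSimParams:
    """Parameters of the synthetic EPSC generator (defaults mimic control
    recordings: tau_decay 11.3 ms, 20 kHz sampling, inward events)."""

    amplitude_mean_pA: float = 100.0
    amplitude_cv: float = 0.3
    tau_rise_ms: float = 0.4
    tau_decay_ms: float = 11.3
    rate_hz: float = 2.0
    noise_sd_pA: float = 2.0
    sampling_khz: float = 20.0
    latency_ms: float = 0.5

    def __post_init__(self) -> None:
        if self.tau_rise_ms <= 0 or self.tau_decay_ms <= 0:
            raise ValidationError("time constants must be > 0")
        if self.sampling_khz < 10:
            raise ValidationError("sampling rate must be >= 10 kHz")
        if self.rate_hz < 0 or self.noise_sd_pA < 0 or self.amplitude_cv < 0:
            raise ValidationError("rate, noise sd and amplitude CV must be >= 0")


@dataclass(frozen=True)
class TrueEvent:
    onset_ms: float
    amplitude_pA: float
    tau_rise_ms: float
    tau_decay_ms: float

    @property
    def peak_time_ms(self) -> float:
        tr, td = self.tau_rise_ms, self.tau_decay_ms
        return self.onset_ms + tr * math.log1p(td / tr)


def epsc_waveform(
    t_ms: np.ndarray, amplitude: float, tau_rise_ms: float, tau_decay_ms: float
) -> np.ndarray:
    """Positive-magnitude event shape scaled to peak exactly at ``amplitude``."""
    tr, td = tau_rise_ms, tau_decay_ms
    tp = tr * math.log1p(td / tr)
    g = (1.0 - math.exp(-tp / tr)) * math.exp(-tp / td)
    t = np.maximum(np.asarray(t_ms, dtype=float), 0.0)
    shape = (1.0 - np.exp(-t / tr)) * np.exp(-t / td)
    shape[np.asarray(t_ms) < 0] = 0.0
    return amplitude * shape / g


def simulate_epsc_train(
    params: EPSCSimParams,
    duration_s: float,
    seed: int,
    ap_times_ms: Sequence[float] | None = None,
    amplitudes_pA: Sequence[float] | None = None,
):
    """Synthetic current trace (inward events negative) plus its true events.

    Spontaneous mode (no ``ap_times_ms``): event onsets are Poisson at
    ``rate_hz`` and amplitudes log-normal around the mean. Evoked mode:
    one event per presynaptic AP marker, onset at AP + latency, with
    optional fixed ``amplitudes_pA``. Event rates above 25 Hz make
    overlap-free (>= 40 ms) decays impossible and are logged as a
    warning.
    """
    from .ephys import Trace  # local import to avoid a cycle

    if duration_s <= 0:
        raise ValidationError("duration must be > 0")
    rng = np.random.default_rng(seed)
    dt_ms = 1.0 / params.sampling_khz
    n = int(round(duration_s * 1000.0 / dt_ms))
    t = np.arange(n) * dt_ms
    current = params.noise_sd_pA * rng.standard_normal(n)

    if ap_times_ms is None:
        if params.rate_hz > 25.0:
            logger.warning(
                "event rate %.1f Hz > 25 Hz: inter-event intervals below the "
                "40 ms clean-decay requirement are certain",
                params.rate_hz,
            )
        n_events = rng.poisson(params.rate_hz * duration_s)
        onsets = np.sort(rng.uniform(0.0, duration_s * 1000.0, size=n_events))
        ap_times: tuple[float, ...] = ()
    else:
        onsets = np.asarray(ap_times_ms, dtype=float) + params.latency_ms
        ap_times = tuple(float(x) for x in ap_times_ms)

    if amplitudes_pA is not None:
        amps = np.asarray(amplitudes_pA, dtype=float)
        if amps.size != onsets.size:
            raise ValidationError("amplitudes_pA must match the number of events")
    else:
        amps = params.amplitude_mean_pA * _noise_factors(
            rng, params.amplitude_cv, (onsets.size,)
        )

    events: list[TrueEvent] = []
    support_ms = 30.0 * params.tau_decay_ms  # amplitude < 1e-13 beyond this
    for onset, amp in zip(onsets, amps):
        lo = max(int(onset / dt_ms), 0)
        hi = min(int((onset + support_ms) / dt_ms) + 1, n)
        if lo >= n:
            continue
        current[lo:hi] -= epsc_waveform(
            t[lo:hi] - onset, amp, params.tau_rise_ms, params.tau_decay_ms
        )
        events.append(
            TrueEvent(float(onset), float(amp), params.tau_rise_ms, params.tau_decay_ms)
        )
    return Trace(dt_ms, current, ap_times), events
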