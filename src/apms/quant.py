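"""Label-free protein quantification from peptide peak volumes.

The estimator follows the calibrated peak-volume workflow used for
membrane-protein interactomes:

1. each peptide's PVs are divided by that peptide's maximum over all AP
   datasets, yielding a relative peptide profile in [0, 1] that is
   invariant to the peptide's (unknown) response factor;
2. peptides of a protein are ranked by their mean pairwise Pearson
   correlation across datasets, gross outliers (mean r below a cutoff)
   are removed, and the best-correlating subset is kept;
3. the per-dataset median over the selected peptide profiles is the
   protein's relative abundance profile;
4. a single non-negative least-squares scale factor maps the relative
   profile onto calibration anchors from concatenated standard peptides
   (QconCAT), giving molecular abundance on an absolute-like scale.

For proteins lacking calibration standards the spectral estimator
``abundance_spec`` (summed isoform-specific PVs per MS-accessible amino
acid) provides a comparable per-protein abundance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import DatasetMeta, PVMatrix, ValidationError

logger = logging.getLogger("apms")

GLUA_IDS = ("GluA1", "GluA2", "GluA3", "GluA4")


# ---------------------------------------------------------------------------
# peptide profiles
# ---------------------------------------------------------------------------

def normalize_peptide_profiles(pv: PVMatrix) -> pd.DataFrame:
    """Divide each peptide row by its own maximum over all datasets.

    Missing stays missing. Peptides never observed (all missing, or with
    maximum 0) carry no relative information and are dropped with a
    warning. The result is scale-invariant per peptide: multiplying one
    peptide's PVs by any c > 0 leaves its profile unchanged.
    """
    vals = pv.values
    maxes = vals.max(axis=1)
    dead = maxes.isna() | (maxes <= 0)
    if dead.any():
        logger.warning(
            "dropping %d peptide(s) with no observed PV", int(dead.sum())
        )
    kept = vals.loc[~dead]
    return kept.div(maxes.loc[~dead], axis=0)


def _mean_pairwise_r(arr: np.ndarray, min_shared: int) -> tuple[np.ndarray, bool]:
    """Mean pairwise Pearson r per row over pairwise-complete columns.

    Pairs with fewer than ``min_shared`` shared observations (or with an
    undefined correlation) contribute r = 0. Returns the per-row means
    and a flag telling whether *any* pair had enough shared data.
    """
    n = arr.shape[0]
    mask = ~np.isnan(arr)
    rsum = np.zeros(n)
    any_shared = False
    for i in range(n):
        for j in range(i + 1, n):
            shared = mask[i] & mask[j]
            r = 0.0
            if shared.sum() >= min_shared:
                any_shared = True
                x = arr[i, shared]
                y = arr[j, shared]
                sx = x.std()
                sy = y.std()
                if sx > 0 and sy > 0:
                    r = float(np.corrcoef(x, y)[0, 1])
                    if math.isnan(r):
                        r = 0.0
            rsum[i] += r
            rsum[j] += r
    return rsum / max(n - 1, 1), any_shared


def _selection_size(n: int, k_min: int, k_cap: int | None, fraction: float) -> int:
    if n <= k_min:
        return n
    k = max(k_min, math.ceil(fraction * n))
    if k_cap is not None:
        k = min(k, k_cap)
    return min(k, n)


@dataclass(frozen=True)
class PeptideSelection:
    """Outcome of ranking one protein's peptides by mutual correlation."""

    selected: tuple[str, ...]
    mean_r: Mapping[str, float]
    excluded_outliers: tuple[str, ...]
    low_confidence: bool


def rank_and_select_peptides(
    profiles: pd.DataFrame,
    *,
    k_min: int = 3,
    k_cap: int | None = None,
    fraction: float = 0.5,
    min_shared: int = 3,
    outlier_r_cutoff: float = 0.0,
) -> PeptideSelection:
    """Rank one protein's peptide profiles and keep the best-correlating k.

    Peptides whose mean pairwise r falls below ``outlier_r_cutoff`` are
    excluded first (outlier / false-assignment filter); the remaining
    peptides are ranked by mean pairwise r, ties broken lexicographically
    by sequence, and ``k = max(k_min, ceil(fraction * n))`` are kept
    (all of them when n <= k_min). If no peptide pair shares at least
    ``min_shared`` datasets the ranking is uninformative: all peptides
    are used and the result is flagged low-confidence.
    """
    n = len(profiles)
    if n == 0:
        raise ValidationError("no peptide profiles given")
    seqs = list(profiles.index)
    if n == 1:
        return PeptideSelection((seqs[0],), {seqs[0]: math.nan}, (), True)

    mean_r, any_shared = _mean_pairwise_r(
        profiles.to_numpy(dtype=float), min_shared
    )
    r_by_seq = dict(zip(seqs, mean_r.tolist()))
    if not any_shared:
        return PeptideSelection(tuple(sorted(seqs)), r_by_seq, (), True)

    outliers = tuple(s for s in seqs if r_by_seq[s] < outlier_r_cutoff)
    candidates = [s for s in seqs if r_by_seq[s] >= outlier_r_cutoff]
    low_confidence = False
    if not candidates:  # everything looked like an outlier; keep all
        candidates = list(seqs)
        outliers = ()
        low_confidence = True

    k = _selection_size(len(candidates), k_min, k_cap, fraction)
    ranked = sorted(candidates, key=lambda s: (-r_by_seq[s], s))
    return PeptideSelection(tuple(ranked[:k]), r_by_seq, outliers, low_confidence)


def protein_profile(selected_profiles: pd.DataFrame) -> pd.Series:
    """Per-dataset median over the selected peptide profiles.

    Missing values are ignored per dataset; a dataset where every
    selected peptide is missing stays missing.
    """
    if len(selected_profiles) == 0:
        raise ValidationError("peptides_used must be non-empty")
    return selected_profiles.median(axis=0, skipna=True)


@dataclass
class QuantResult:
    """Protein-level relative profiles plus per-protein selection metadata."""

    profiles: pd.DataFrame  # proteins x datasets
    selections: dict[str, PeptideSelection]

    @property
    def meta(self) -> pd.DataFrame:
        rows = []
        for pid, sel in self.selections.items():
            rows.append(
                {
                    "protein_id": pid,
                    "n_peptides_used": len(sel.selected),
                    "peptides_used": ";".join(sel.selected),
                    "n_outliers_excluded": len(sel.excluded_outliers),
                    "low_confidence": sel.low_confidence,
                }
            )
        return pd.DataFrame(rows).set_index("protein_id")


def protein_profiles(
    pv: PVMatrix,
    *,
    k_min: int = 3,
    k_cap: int | None = None,
    fraction: float = 0.5,
    min_shared: int = 3,
    outlier_r_cutoff: float = 0.0,
) -> QuantResult:
    """Relative abundance profile for every protein in the matrix.

    Only isoform-specific peptides are used; proteins without any are
    excluded with a log message.
    """
    specific = pv.specific_only()
    dropped = set(pv.protein_ids) - set(specific.protein_ids)
    if dropped:
        logger.warning(
            "excluding %d protein(s) without isoform-specific peptides: %s",
            len(dropped),
            sorted(dropped),
        )
    prof = normalize_peptide_profiles(specific)
    protein_of = specific.protein_of.loc[prof.index]

    profiles: dict[str, pd.Series] = {}
    selections: dict[str, PeptideSelection] = {}
    for pid in specific.protein_ids:
        seqs = protein_of.index[protein_of == pid]
        if len(seqs) == 0:
            logger.warning("protein %s lost all peptides after filtering", pid)
            continue
        sub = prof.loc[seqs]
        sel = rank_and_select_peptides(
            sub,
            k_min=k_min,
            k_cap=k_cap,
            fraction=fraction,
            min_shared=min_shared,
            outlier_r_cutoff=outlier_r_cutoff,
        )
        profiles[pid] = protein_profile(sub.loc[list(sel.selected)])
        selections[pid] = sel
    frame = pd.DataFrame(profiles).T
    frame.index.name = "protein_id"
    return QuantResult(frame, selections)


# ---------------------------------------------------------------------------
# calibration and absolute-like scales
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    abundance: pd.Series
    scale: float
    calibrated: bool


def calibrate_qconcat(
    profile: pd.Series, calibration: pd.Series
) -> CalibrationResult:
    """Scale a relative profile to best fit its calibration anchors.

    The single factor s minimizes sum((s * profile - calibration)^2) over
    the datasets where both are available: s = sum(p*c) / sum(p^2). With
    no overlap the protein stays uncalibrated and is flagged.
    """
    common = [
        d
        for d in calibration.index
        if d in profile.index and not math.isnan(profile[d])
    ]
    if not common:
        logger.warning("no calibration overlap; protein left uncalibrated")
        return CalibrationResult(profile * math.nan, math.nan, False)
    p = profile[common].to_numpy(dtype=float)
    c = calibration[common].to_numpy(dtype=float)
    denom = float(np.sum(p * p))
    scale = float(np.sum(p * c)) / denom if denom > 0 else 0.0
    scale = max(scale, 0.0)
    return CalibrationResult(profile * scale, scale, True)


def calibrate_all(
    profiles: pd.DataFrame, calibration: "CalibrationTable"
) -> tuple[pd.DataFrame, pd.Series]:
    """Calibrate every profile that has anchors; returns (abundance, flag)."""
    rows = {}
    flags = {}
    for pid, profile in profiles.iterrows():
        cal = calibration.for_protein(pid)
        if len(cal) == 0:
            rows[pid] = profile * math.nan
            flags[pid] = False
            continue
        res = calibrate_qconcat(profile, cal)
        rows[pid] = res.abundance
        flags[pid] = res.calibrated
    ab = pd.DataFrame(rows).T.reindex(profiles.index)
    ab.index.name = "protein_id"
    return ab, pd.Series(flags, name="calibrated").reindex(profiles.index)


def abundance_spec(
    pv: PVMatrix, accessible_aa: Mapping[str, int]
) -> pd.DataFrame:
    """Spectral abundance: summed isoform-specific PVs per accessible residue.

    For each protein and dataset the assigned isoform-specific PVs are
    summed and divided by the number of MS-accessible isoform-specific
    amino acids; used for proteins without calibration standards.
    """
    specific = pv.specific_only()
    protein_of = specific.protein_of
    out: dict[str, pd.Series] = {}
    for pid in specific.protein_ids:
        if pid not in accessible_aa:
            logger.warning("no accessible_aa for protein %s; excluded", pid)
            continue
        aa = accessible_aa[pid]
        if aa <= 0:
            raise ValidationError(f"accessible_aa for {pid} must be > 0")
        seqs = protein_of.index[protein_of == pid]
        sub = specific.values.loc[seqs]
        total = sub.sum(axis=0, min_count=1)  # all-missing dataset -> NaN
        out[pid] = total / aa
    frame = pd.DataFrame(out).T
    frame.index.name = "protein_id"
    return frame


def ampar_amount(
    abundance: pd.DataFrame, glua_ids: Sequence[str] = GLUA_IDS
) -> pd.Series:
    """Amount of co-purified AMPARs: sum of GluA1-4 abundances / 4."""
    present = [g for g in glua_ids if g in abundance.index]
    if not present:
        return pd.Series(math.nan, index=abundance.columns, name="ampar_amount")
    amt = abundance.loc[present].sum(axis=0, min_count=1) / len(glua_ids)
    amt.name = "ampar_amount"
    return amt


def normalize_to_target(
    abundance: pd.DataFrame,
    datasets: Sequence[DatasetMeta],
    glua_ids: Sequence[str] = GLUA_IDS,
) -> tuple[pd.DataFrame, pd.Series]:
    """Normalize each AP dataset to the abundance of its primary target(s).

    Multi-target datasets (e.g. anti-GluA1-4 mixtures) use the mean over
    their targets, so the target level of an anti-GluA1-4 AP equals the
    co-purified AMPAR amount sum(GluA1-4)/4. Datasets whose target is
    missing or zero are excluded with a log message; control datasets
    without a captured target (IgG etc.) pass through unnormalized.

    Returns the normalized table and the per-dataset AMPAR amount.
    """
    by_id = {m.dataset_id: m for m in datasets}
    missing = [d for d in abundance.columns if d not in by_id]
    if missing:
        raise ValidationError(f"no metadata for datasets: {missing}")
    norm = {}
    for did in abundance.columns:
        meta = by_id[did]
        col = abundance[did]
        if meta.control_kind != "none":
            norm[did] = col
            continue
        targets = [t for t in sorted(meta.target_protein_ids) if t in col.index]
        if not targets:
            logger.warning("dataset %s: no quantified target; excluded", did)
            continue
        ref = col[targets].mean(skipna=True)
        if not math.isfinite(ref) or ref <= 0:
            logger.warning("dataset %s: target abundance missing/zero; excluded", did)
            continue
        norm[did] = col / ref
    out = pd.DataFrame(norm)
    out.index.name = "protein_id"
    return out, ampar_amount(abundance, glua_ids)
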