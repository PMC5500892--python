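"""Ratio-based specificity analysis, two-step AP partitioning and group tests.

A protein's enrichment between two groups of AP datasets is expressed as
rPV, the ratio of its (target-normalized) abundance in each first-group
replicate over the mean abundance across the second group. Specificity
thresholds are estimated from the background mode of the log-rPV
distribution of all detected proteins; a protein is called a specific
interactor when it exceeds the threshold against IgG with at least two
independent antibodies and against every available depletion/knockout
control.

For serial (two-step) APs the fraction of a protein captured by the
first, target-depleting purification is F = rPV / (rPV + 1), with
1 - F left for the second step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import ValidationError

logger = logging.getLogger("apms")

MAD_TO_SIGMA = 1.4826  # consistency factor for a normal distribution


# ---------------------------------------------------------------------------
# rPV and thresholds
# ---------------------------------------------------------------------------

def impute_undetected(
    abundance: pd.DataFrame,
    columns: Sequence[str],
    factor: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace missing abundances by a per-dataset detection floor.

    The floor is ``factor`` times the smallest positive abundance
    observed in that dataset; columns with nothing observed are left
    untouched. Returns the imputed table and a boolean mask of imputed
    cells.
    """
    sub = abundance[list(columns)].copy()
    imputed = sub.isna()
    for c in sub.columns:
        col = sub[c]
        observed = col[col > 0]
        if observed.empty:
            imputed[c] = False
            continue
        sub[c] = col.fillna(factor * observed.min())
    return sub, imputed


def compute_rpv(
    abundance: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    imputation_factor: float = 0.5,
) -> pd.DataFrame:
    """Per-protein rPV between two dataset groups (mean of per-replicate ratios).

    For each replicate dataset in ``group_a`` the ratio against the mean
    abundance over ``group_b`` is formed; the reported rPV is the mean of
    these ratios with its s.e.m. (n-1 denominator). Proteins undetected
    in every dataset of both groups are excluded; remaining missing
    values are imputed at the per-dataset detection floor.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if not group_a or not group_b:
        raise ValidationError("both comparison groups must be non-empty")
    both = group_a + group_b
    detected = abundance[both].notna().any(axis=1)
    if (~detected).any():
        logger.info(
            "rPV: excluding %d protein(s) absent from both groups",
            int((~detected).sum()),
        )
    ab = abundance.loc[detected]
    imp, mask = impute_undetected(ab, both, imputation_factor)
    b_mean = imp[group_b].mean(axis=1)
    ratios = imp[group_a].div(b_mean, axis=0)
    n = ratios.notna().sum(axis=1)
    rpv = ratios.mean(axis=1)
    sem = ratios.std(axis=1, ddof=1) / np.sqrt(n.where(n > 0))
    out = pd.DataFrame(
        {
            "rpv": rpv,
            "sem": sem,
            "n_replicates": n,
            "n_imputed": mask.sum(axis=1),
        }
    )
    out.index.name = "protein_id"
    return out


def estimate_threshold(
    rpvs: Sequence[float] | np.ndarray | pd.Series,
    multiplier: float = 3.0,
    min_proteins: int = 20,
) -> float:
    """Specificity threshold from the background mode of an rPV distribution.

    Robust location/scale on log(rPV): threshold = exp(median +
    multiplier * 1.4826 * MAD). The median/MAD pair tracks the
    (dominant) background mode and is insensitive to the minority of
    truly enriched proteins in the upper tail.
    """
    arr = np.asarray(rpvs, dtype=float)
    arr = arr[np.isfinite(arr) & (arr > 0)]
    if arr.size < min_proteins:
        raise ValidationError(
            f"need at least {min_proteins} finite rPVs to estimate a "
            f"threshold (got {arr.size}); supply a manual threshold"
        )
    logs = np.log(arr)
    med = float(np.median(logs))
    mad = float(np.median(np.abs(logs - med)))
    if mad == 0.0:
        logger.warning("degenerate rPV distribution (zero spread)")
    return float(np.exp(med + multiplier * MAD_TO_SIGMA * mad))


# ---------------------------------------------------------------------------
# specificity consensus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Comparison:
    """One rPV comparison of target APs against one control."""

    name: str
    antibody_id: str
    control_kind: str  # igg | depletion | knockout
    rpv: pd.DataFrame  # output of compute_rpv
    threshold: float

    def passes(self) -> pd.Series:
        return (self.rpv["rpv"] / self.threshold) > 1.0


def call_specific(
    comparisons: Sequence[Comparison],
    n_antibody_min: int = 2,
    required_control_kinds: Sequence[str] = ("depletion", "knockout"),
) -> pd.DataFrame:
    """Consensus specificity call across antibodies and control kinds.

    A protein is a bona fide interactor when (i) it exceeds the
    threshold versus IgG with at least ``n_antibody_min`` independent
    antibodies and (ii) it exceeds the threshold in every provided
    comparison against a depletion/knockout control. A protein absent
    from a comparison fails that comparison.
    """
    if not comparisons:
        raise ValidationError("at least one comparison required")
    all_proteins = sorted(set().union(*(c.rpv.index for c in comparisons)))
    flags = pd.DataFrame(index=pd.Index(all_proteins, name="protein_id"))
    for c in comparisons:
        flags[c.name] = c.passes().reindex(all_proteins).fillna(False)

    igg = [c for c in comparisons if c.control_kind == "igg"]
    required = [c for c in comparisons if c.control_kind in required_control_kinds]

    n_ab = pd.Series(0, index=flags.index)
    for pid in flags.index:
        n_ab[pid] = len(
            {c.antibody_id for c in igg if bool(flags.loc[pid, c.name])}
        )
    flags["n_antibodies_passed"] = n_ab
    ok_required = (
        flags[[c.name for c in required]].all(axis=1)
        if required
        else pd.Series(True, index=flags.index)
    )
    flags["is_specific"] = (n_ab >= n_antibody_min) & ok_required
    return flags


# ---------------------------------------------------------------------------
# two-step (serial) AP partitioning
# ---------------------------------------------------------------------------

def fraction_first(rpv):
    """Fraction captured in the first of two serial APs: F = rPV/(rPV+1).

    A bijection (0, inf) -> (0, 1); F(1/x) = 1 - F(x). Accepts scalars
    or arrays; rPV = inf maps to F = 1 (protein fully captured first).
    """
    arr = np.asarray(rpv, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValidationError("rPV must be >= 0")
    with np.errstate(invalid="ignore"):
        out = np.where(np.isinf(arr), 1.0, arr / (arr + 1.0))
    if np.isscalar(rpv) or arr.ndim == 0:
        return float(out)
    return out


def twostep_partition(
    abundance: pd.DataFrame,
    first_ids: Sequence[str],
    second_ids: Sequence[str],
) -> pd.DataFrame:
    """Fraction F of each protein captured by the first serial AP.

    Per first-AP replicate, rPV = abundance / mean(second-AP abundances);
    F = rPV/(rPV+1) per replicate, reported as mean ± s.e.m. Proteins
    detected in neither AP are excluded. A protein entirely missing from
    the second (respectively first) APs is fully captured: F = 1
    (respectively 0), flagged as imputed at the boundary.
    """
    first_ids = list(first_ids)
    second_ids = list(second_ids)
    if not first_ids or not second_ids:
        raise ValidationError("need first and second AP datasets")
    detected = abundance[first_ids + second_ids].notna().any(axis=1)
    ab = abundance.loc[detected]

    rows = []
    for pid, row in ab.iterrows():
        firsts = row[first_ids].dropna()
        second_mean = row[second_ids].mean(skipna=True)
        boundary = False
        if firsts.empty:
            f_vals = np.array([0.0])
            boundary = True
        elif not math.isfinite(second_mean) or second_mean == 0:
            f_vals = np.array([1.0])
            boundary = True
        else:
            f_vals = fraction_first(firsts.to_numpy() / second_mean)
            f_vals = np.atleast_1d(f_vals)
        f = float(np.mean(f_vals))
        sem = (
            float(np.std(f_vals, ddof=1) / math.sqrt(len(f_vals)))
            if len(f_vals) > 1
            else math.nan
        )
        rows.append(
            {
                "protein_id": pid,
                "fraction_first": f,
                "sem": sem,
                "fraction_second": 1.0 - f,
                "n_replicates": len(f_vals),
                "boundary_imputed": boundary,
            }
        )
    out = pd.DataFrame(rows).set_index("protein_id")
    return out


# ---------------------------------------------------------------------------
# group comparisons and correlation
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    if not math.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return ""


def compare_groups(
    abundance: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Per-protein abundance ratio mean(A)/mean(B) with a two-sided t-test.

    Needs >= 2 replicates per group for a p-value; with fewer the ratio
    is still reported and p is unavailable. A zero group-B mean yields an
    infinite ratio which is flagged and excluded from testing.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    rows = []
    for pid, row in abundance.iterrows():
        a = row[group_a].dropna().to_numpy(dtype=float)
        b = row[group_b].dropna().to_numpy(dtype=float)
        if a.size == 0 and b.size == 0:
            continue
        mean_a = float(np.mean(a)) if a.size else math.nan
        mean_b = float(np.mean(b)) if b.size else math.nan
        infinite = bool(mean_b == 0 and mean_a != 0)
        ratio = math.inf if infinite else (
            mean_a / mean_b if mean_b not in (0.0,) else math.nan
        )
        p = math.nan
        if a.size >= 2 and b.size >= 2 and not infinite:
            if np.ptp(a) == 0 and np.ptp(b) == 0 and mean_a == mean_b:
                p = 1.0  # identical constant groups
            else:
                p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        rows.append(
            {
                "protein_id": pid,
                "ratio": ratio,
                "p_value": p,
                "stars": significance_stars(p),
                "n_a": a.size,
                "n_b": b.size,
                "ratio_infinite": infinite,
            }
        )
    return pd.DataFrame(rows).set_index("protein_id")


def cross_dataset_correlation(
    abundance: pd.DataFrame,
    focal_protein: str,
    subunit_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Pearson r of a focal protein against subunits and subunit-set sums.

    Computes r across AP datasets between the focal protein's abundance
    vector and (a) each individual protein appearing in any set and
    (b) the per-dataset sum over each named set. Results are ranked by
    r; zero-variance vectors give an undefined r and are flagged.
    """
    if abundance.shape[1] < 4:
        raise ValidationError("need at least 4 datasets for correlation analysis")
    if focal_protein not in abundance.index:
        raise ValidationError(f"focal protein {focal_protein!r} not quantified")
    focal = abundance.loc[focal_protein]

    vectors: dict[str, tuple[str, pd.Series]] = {}
    members = sorted({m for ms in subunit_sets.values() for m in ms})
    for m in members:
        if m not in abundance.index:
            raise ValidationError(f"subunit {m!r} not quantified")
        vectors[m] = ("protein", abundance.loc[m])
    for name, ms in subunit_sets.items():
        vectors[f"sum({name})"] = (
            "sum",
            abundance.loc[list(ms)].sum(axis=0, min_count=1),
        )

    rows = []
    for label, (kind, vec) in vectors.items():
        shared = focal.notna() & vec.notna()
        x = focal[shared].to_numpy(dtype=float)
        y = vec[shared].to_numpy(dtype=float)
        undefined = x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0
        r = math.nan if undefined else float(np.corrcoef(x, y)[0, 1])
        rows.append(
            {
                "label": label,
                "kind": kind,
                "r": r,
                "n_datasets": int(shared.sum()),
                "undefined": undefined,
            }
        )
    out = pd.DataFrame(rows).set_index("label")
    return out.sort_values("r", ascending=False, na_position="last")
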