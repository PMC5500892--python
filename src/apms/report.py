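"""Descriptive summary computations and the aggregate report bundle.

Covers the small arithmetic behind printed quantitative claims —
category proportions from immunogold particle counts, pooled
percent-of-control and percent-reduction from group means — plus the
Mann-Whitney U test used for electrophysiological group comparisons,
and the collection of all stage outputs into one report bundle.

Rounding is half-away-from-zero, applied after pooling, which is the
order under which e.g. counts of 815/848 print as 96.1% and a pooled
45.5% reduction prints as 45% at a 5% step.
"""

from __future__ import annotations

import json
import math
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import ValidationError


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (1.5 -> 2, -1.5 -> -2)."""
    f = 10.0**decimals
    return math.copysign(math.floor(abs(x) * f + 0.5) / f, x)


def round_to_step(x: float, step: float) -> float:
    """Round to the nearest multiple of ``step``, half away from zero."""
    if step <= 0:
        raise ValidationError("rounding step must be > 0")
    return round_half_away(x / step) * step


# ---------------------------------------------------------------------------
# counts and group means
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Proportions:
    labels: tuple[str, ...]
    exact_percent: tuple[float, ...]
    rounded_percent: tuple[float, ...]
    total: int


def proportions_from_counts(
    counts: Mapping[str, int], decimals: int = 1
) -> Proportions:
    """Percentages per category from integer counts.

    Exact values always sum to 100%; rounded values (half away from
    zero, ``decimals`` places) are reported alongside.
    """
    labels = tuple(counts)
    values = [int(counts[k]) for k in labels]
    if any(v < 0 for v in values):
        raise ValidationError("counts must be >= 0")
    total = sum(values)
    if total == 0:
        raise ValidationError("total count must be > 0")
    exact = tuple(100.0 * v / total for v in values)
    rounded = tuple(round_half_away(p, decimals) for p in exact)
    return Proportions(labels, exact, rounded, total)


@dataclass(frozen=True)
class GroupMeans:
    """A control mean plus one or more treatment means, same units."""

    control_mean: float
    treatment_means: tuple[float, ...]
    units: str = ""

    def __post_init__(self) -> None:
        if self.control_mean <= 0:
            raise ValidationError("control mean must be > 0 for ratios")
        if not self.treatment_means:
            raise ValidationError("need at least one treatment mean")


@dataclass(frozen=True)
class PercentResult:
    exact: float
    rounded: float


def percent_remaining(
    means: GroupMeans, rounding_step: float | None = None
) -> PercentResult:
    """Pooled percent-of-control: 100 * mean(treatments) / control.

    Treatment means are pooled as an unweighted mean of group means
    before the single division; rounding (to the nearest
    ``rounding_step``) happens last.
    """
    pooled = float(np.mean(means.treatment_means))
    exact = 100.0 * pooled / means.control_mean
    rounded = round_to_step(exact, rounding_step) if rounding_step else exact
    return PercentResult(exact, rounded)


def percent_reduction(
    means: GroupMeans, rounding_step: float | None = None
) -> PercentResult:
    """Pooled percent reduction: 100 * (1 - mean(treatments)/control).

    Complements :func:`percent_remaining` exactly before rounding.
    """
    remaining = percent_remaining(means).exact
    exact = 100.0 - remaining
    rounded = round_to_step(exact, rounding_step) if rounding_step else exact
    return PercentResult(exact, rounded)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # "exact" | "asymptotic"


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test (U reported for the first group).

    Uses the exact null distribution for combined n <= 20 without ties
    and the tie-corrected normal approximation otherwise. Two groups of
    entirely identical values carry no ordering information and return
    p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        return MannWhitneyResult(a.size * b.size / 2.0, 1.0, "asymptotic")
    if a.size + b.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), method)


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

#: stage-output files collected into the bundle, keyed by section name.
REPORT_SECTIONS = {
    "abundance": "normalized_abundance.tsv",
    "specificity": "specificity_calls.tsv",
    "twostep": "twostep_fractions.tsv",
    "comparisons": "comparisons.tsv",
    "ephys": "ephys_summary.tsv",
}


def build_report(run_dir: str | Path, out_dir: str | Path) -> dict:
    """Collect stage outputs into report.json (+ heatmap.tsv when present).

    Sections whose table is missing are listed as absent; the report is
    still produced. The abundance section doubles as the heat-map
    matrix (proteins x APs of target-normalized abundance).
    """
    run_dir = Path(run_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"sections": {}, "absent": []}
    for name, filename in REPORT_SECTIONS.items():
        path = run_dir / filename
        if not path.exists():
            report["absent"].append(name)
            continue
        df = pd.read_csv(path, sep="\t", index_col=0)
        report["sections"][name] = {
            "file": filename,
            "n_rows": int(df.shape[0]),
            "columns": list(df.columns),
        }
        if name == "abundance":
            shutil.copyfile(path, out_dir / "heatmap.tsv")
    report["absent"] = sorted(report["absent"])
    with (out_dir / "report.json").open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
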