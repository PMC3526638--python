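"""Verification-phase immunoassay scoring.

Tissue-microarray (TMA) immunohistochemistry sections are scored by two
independent raters: the percentage P of positively stained cells (0-100%)
and the staining intensity I (0 none, 1 weak, 2 moderate, 3 strong).  The
percentage collapses into a P score of 0-9 over ten bins (0-5, 5-15, ...,
85-100) and the quick score is the product Q = P x I, bounded by 0 and 27.
Paired tumor / adjacent-normal sections are compared with a nonparametric
signed-rank test.

Western-blot densitometry (integrated optical density, IOD) from several
membranes is made comparable by dividing each lane by the IOD of a pooled
calibration sample run on the same membrane, which cancels per-membrane
multiplicative batch factors exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TMASection",
    "PairedTestResult",
    "WBResult",
    "percent_to_pscore",
    "quick_score",
    "score_table",
    "paired_compare",
    "wb_normalize",
]

#: right-open bin edges for the percentage -> P score mapping; the top bin
#: is closed at 100.
_P_EDGES = np.array([5.0, 15.0, 25.0, 35.0, 45.0, 55.0, 65.0, 75.0, 85.0])


def percent_to_pscore(percent):
    """Collapse a positive-cell percentage into the 0-9 P score.

    Bins: [0,5) -> 0, [5,15) -> 1, [15,25) -> 2, ..., [75,85) -> 8,
    [85,100] -> 9.  Accepts scalars or arrays; raises on values outside
    [0, 100].
    """
    arr = np.asarray(percent, dtype=float)
    if np.any(arr < 0) or np.any(arr > 100):
        raise ValueError("percentage must lie in [0, 100]")
    score = np.digitize(arr, _P_EDGES)
    return int(score) if np.isscalar(percent) or arr.ndim == 0 else score


@dataclass
class TMASection:
    """One scored TMA section with per-rater percentage/intensity calls."""

    case_id: str
    tissue: str  # "tumor" | "adjacent_normal"
    percent_by_rater: tuple[float, ...]
    intensity_by_rater: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.percent_by_rater or not self.intensity_by_rater:
            raise ValueError("at least one rater evaluation is required")
        if any(not 0 <= p <= 100 for p in self.percent_by_rater):
            raise ValueError("percentage must lie in [0, 100]")
        if any(i not in (0, 1, 2, 3) for i in self.intensity_by_rater):
            raise ValueError("intensity must be one of {0, 1, 2, 3}")

    @property
    def p_score(self) -> int:
        return percent_to_pscore(float(np.mean(self.percent_by_rater)))

    @property
    def q_score(self) -> float:
        return quick_score(self.percent_by_rater, self.intensity_by_rater)


def quick_score(
    percent_by_rater,
    intensity_by_rater,
    method: str = "average_raw",
) -> float:
    """Quick score Q = P x I for one section.

    ``method="average_raw"`` (default) averages the raw percentages and
    intensities over raters first, then bins the averaged percentage and
    multiplies by the averaged intensity — the least information is lost
    before the product.  ``method="average_q"`` computes one Q per rater
    and averages those.  Averaged intensity may be fractional, so Q may be
    non-integer; the 0-27 bound always holds.
    """
    pct = np.asarray(percent_by_rater, dtype=float)
    inten = np.asarray(intensity_by_rater, dtype=float)
    if pct.size == 0 or inten.size == 0:
        raise ValueError("at least one rater evaluation is required")
    if method == "average_raw":
        return float(percent_to_pscore(float(pct.mean())) * inten.mean())
    if method == "average_q":
        qs = [percent_to_pscore(float(p)) * i for p, i in zip(pct, inten)]
        return float(np.mean(qs))
    raise ValueError("method must be 'average_raw' or 'average_q'")


def score_table(sections: pd.DataFrame, method: str = "average_raw") -> pd.DataFrame:
    """Per-case quick scores from a long rater table.

    Expects columns ``case_id, tissue, rater, percent, intensity``; returns
    one row per (case, tissue) with the averaged percentage/intensity, the
    P score and Q.
    """
    required = {"case_id", "tissue", "rater", "percent", "intensity"}
    if missing := required - set(sections.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for (case, tissue), sub in sections.groupby(["case_id", "tissue"], sort=False):
        q = quick_score(sub["percent"].to_numpy(), sub["intensity"].to_numpy(), method)
        rows.append(
            {
                "case_id": case,
                "tissue": tissue,
                "mean_percent": sub["percent"].mean(),
                "mean_intensity": sub["intensity"].mean(),
                "p_score": percent_to_pscore(float(sub["percent"].mean())),
                "q_score": q,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    n_pairs: int
    median_difference: float
    test: str
    alternative: str


def paired_compare(
    q_scores: pd.DataFrame,
    test: str = "wilcoxon",
    alternative: str = "greater",
    tumor_label: str = "tumor",
    normal_label: str = "adjacent_normal",
) -> PairedTestResult:
    """Paired tumor-vs-normal comparison of quick scores.

    ``q_scores`` is the output of :func:`score_table` (or any frame with
    ``case_id, tissue, q_score``).  Cases missing either section are
    dropped.  Differences are tumor minus normal; the default test is the
    Wilcoxon signed-rank with a one-sided "tumor higher" alternative; a
    paired t test is available via ``test="ttest"``.  All-zero differences
    give p = 1 by contract.
    """
    wide = q_scores.pivot_table(index="case_id", columns="tissue", values="q_score")
    wide = wide.dropna(subset=[tumor_label, normal_label])
    if len(wide) < 5:
        raise ValueError("need at least 5 complete tumor/normal pairs")
    diff = (wide[tumor_label] - wide[normal_label]).to_numpy(dtype=float)
    if not np.any(diff):
        return PairedTestResult(0.0, 1.0, len(diff), 0.0, test, alternative)
    if test == "wilcoxon":
        stat, p = sps.wilcoxon(diff, alternative=alternative)
    elif test == "ttest":
        stat, p = sps.ttest_rel(
            wide[tumor_label], wide[normal_label], alternative=alternative
        )
    else:
        raise ValueError("test must be 'wilcoxon' or 'ttest'")
    return PairedTestResult(
        float(stat), float(p), len(diff), float(np.median(diff)), test, alternative
    )


@dataclass
class WBResult:
    normalized: pd.DataFrame
    t_statistic: float
    p_value: float
    contrast: tuple[tuple[str, ...], tuple[str, ...]]


def wb_normalize(
    measurements: pd.DataFrame,
    contrast: tuple | None = None,
) -> WBResult:
    """Calibration-lane normalization of western-blot IOD values.

    ``measurements`` needs columns ``sample_id, group, membrane_id, iod,
    is_calibration``.  Every membrane must carry exactly one calibration
    lane (the pooled sample run on each blot); each sample's IOD is divided
    by its membrane's calibration IOD, making values comparable across
    membranes.  A two-sample t test then compares the two sides of
    ``contrast`` (each a group label or tuple of labels); with exactly two
    group levels the contrast is inferred.
    """
    required = {"sample_id", "group", "membrane_id", "iod", "is_calibration"}
    if missing := required - set(measurements.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (measurements["iod"] <= 0).any():
        raise ValueError("IOD values must be positive")
    cal = measurements[measurements["is_calibration"].astype(bool)]
    per_membrane = cal.groupby("membrane_id")["iod"].agg(list)
    all_membranes = measurements["membrane_id"].unique()
    for mem in all_membranes:
        lanes = per_membrane.get(mem, [])
        if len(lanes) != 1:
            raise ValueError(
                f"membrane {mem!r} must have exactly one calibration lane, found {len(lanes)}"
            )
    cal_iod = per_membrane.map(lambda v: v[0])
    samples = measurements[~measurements["is_calibration"].astype(bool)].copy()
    samples["normalized"] = samples["iod"] / samples["membrane_id"].map(cal_iod).to_numpy()

    labels = samples["group"].unique()
    if contrast is None:
        if len(labels) != 2:
            raise ValueError("contrast must be given when there are not exactly 2 groups")
        contrast = ((labels[0],), (labels[1],))
    side_a = tuple(np.atleast_1d(contrast[0]))
    side_b = tuple(np.atleast_1d(contrast[1]))
    a = samples.loc[samples["group"].isin(side_a), "normalized"]
    b = samples.loc[samples["group"].isin(side_b), "normalized"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each contrast side needs at least 2 samples")
    stat, p = sps.ttest_ind(a, b)
    return WBResult(
        normalized=samples,
        t_statistic=float(stat),
        p_value=float(p),
        contrast=(side_a, side_b),
    )
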