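"""Targeted verification by stable-isotope-dilution MRM.

For each monitored peptide transition, the light (endogenous, 12C) peak
area is divided by the heavy (spiked 13C standard) peak area.  Assay
linearity is characterized on a base-3 dilution series: ordinary least
squares of log3(observed ratio) on log3(nominal ratio), with the Pearson R
of that fit as the linearity measure and the dilution point whose observed
ratio is closest to 1 as the anchor assigning the endogenous amount.

Detection and quantification limits follow the usual targeted-assay rules:

* LOQ — lowest dilution point whose replicate CV is below 20% and whose
  restriction of the calibration fit (that point and above) keeps
  Pearson R > 0.99;
* LOD — concentration at which the interpolated signal-to-noise ratio
  equals 3.

Observed cohort ratios are converted to absolute serum concentrations by
inverting the fitted log3 line, multiplying by the heavy spike to get fmol
on column, and scaling by the serum-equivalent volume on column and the
protein molar mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lfq import PanelModel, ROCResult, logistic_panel, roc_auc

__all__ = [
    "CalibrationCurve",
    "ConcentrationRecord",
    "CohortReport",
    "MOLAR_MASS_G_PER_MOL",
    "compute_ratios",
    "fit_calibration",
    "determine_loq",
    "determine_lod",
    "interassay_cv",
    "select_best_transition",
    "absolute_concentration",
    "cohort_stats",
]

_LOG3 = np.log(3.0)

#: full-length molar masses (g/mol) of the two quantified serum glycoproteins.
MOLAR_MASS_G_PER_MOL = {"A1BG": 54254.0, "LRG1": 38178.0}

#: serum-equivalent volume digested onto the column (microliters).
DEFAULT_SERUM_VOLUME_UL = 0.1


def _log3(x):
    return np.log(x) / _LOG3


# ---------------------------------------------------------------------------
# containers


@dataclass
class CalibrationCurve:
    """Fitted log3-log3 dilution curve for one transition."""

    peptide: str
    transition_id: str
    points: pd.DataFrame  # nominal_light_fmol, nominal_ratio, mean_ratio, replicate_cv, n_replicates
    slope: float
    intercept: float
    pearson_r: float
    anchor_index: int
    spike_heavy_fmol: float
    loq_fmol: float | None = None
    lod_fmol: float | None = None
    mean_heavy_area: float = float("nan")


@dataclass
class ConcentrationRecord:
    """Absolute quantification of one protein in one serum sample."""

    sample_id: str
    protein: str
    group: str
    ratio: float
    fmol_on_column: float
    serum_conc_ug_per_ml: float
    extrapolated: bool = False


@dataclass
class CohortReport:
    per_protein: pd.DataFrame
    roc: dict[str, ROCResult]
    panel: PanelModel
    panel_roc: ROCResult
    demographics: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# ratios


def compute_ratios(measurements: pd.DataFrame) -> pd.DataFrame:
    """Light/heavy peak-area ratios per (sample, peptide, transition).

    ``measurements`` is the long table with columns ``peptide,
    transition_id, label, area`` plus any identifying columns (sample_id,
    replicate_id, point_index ...).  Rows with ``qc_pass == False`` are
    excluded before pairing.  A light area of zero yields ratio 0 with a
    ``below_lod`` flag; a missing or zero heavy partner is an error.
    """
    df = measurements.copy()
    if "qc_pass" in df.columns:
        df = df[df["qc_pass"].astype(bool)]
    required = {"peptide", "transition_id", "label", "area"}
    if missing := required - set(df.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    if not set(df["label"].unique()) <= {"light", "heavy"}:
        raise ValueError("label must be 'light' or 'heavy'")
    id_cols = [c for c in df.columns if c not in ("label", "area")]
    wide = df.pivot_table(
        index=id_cols, columns="label", values="area", aggfunc="first"
    ).reset_index()
    if "heavy" not in wide.columns or wide["heavy"].isna().any():
        raise ValueError("every (sample, peptide, transition) needs a heavy partner")
    if "light" not in wide.columns or wide["light"].isna().any():
        raise ValueError("every (sample, peptide, transition) needs a light partner")
    if (wide["heavy"] <= 0).any():
        raise ValueError("heavy peak areas must be positive")
    wide["ratio"] = wide["light"] / wide["heavy"]
    wide["below_lod"] = wide["light"] == 0
    return wide


# ---------------------------------------------------------------------------
# calibration


def fit_calibration(series: pd.DataFrame, peptide: str = "", transition_id: str = "") -> CalibrationCurve:
    """Least-squares fit of the base-3 dilution curve.

    ``series`` carries one row per replicate with columns
    ``nominal_light_fmol, spike_heavy_fmol, light_area, heavy_area`` (or a
    precomputed ``ratio`` column).  Replicates of each dilution point are
    averaged; the fit is OLS of log3(mean observed ratio) on log3(nominal
    ratio), with per-point replicate CV retained for LOQ determination.
    The anchor point — observed ratio closest to 1 — marks where the
    endogenous amount equals the heavy spike.
    """
    df = series.copy()
    if "ratio" not in df.columns:
        for col in ("light_area", "heavy_area"):
            if col not in df.columns:
                raise ValueError("series needs light_area/heavy_area or a ratio column")
        df["ratio"] = df["light_area"] / df["heavy_area"]
    if "nominal_light_fmol" not in df.columns:
        raise ValueError("series needs a nominal_light_fmol column")
    spike = float(df["spike_heavy_fmol"].iloc[0]) if "spike_heavy_fmol" in df.columns else float("nan")
    df["nominal_ratio"] = df["nominal_light_fmol"] / spike if np.isfinite(spike) else df["nominal_light_fmol"]

    def _cv(v):
        v = np.asarray(v, dtype=float)
        return float(v.std(ddof=1) / v.mean()) if v.size > 1 else 0.0

    pts = (
        df.groupby("nominal_light_fmol", sort=True)
        .agg(
            nominal_ratio=("nominal_ratio", "first"),
            mean_ratio=("ratio", "mean"),
            replicate_cv=("ratio", _cv),
            n_replicates=("ratio", "size"),
        )
        .reset_index()
    )
    if len(pts) < 3:
        raise ValueError("need at least 3 dilution points")
    x = _log3(pts["nominal_ratio"].to_numpy())
    y = _log3(pts["mean_ratio"].to_numpy())
    fit = sps.linregress(x, y)
    anchor = int(np.argmin(np.abs(pts["mean_ratio"].to_numpy() - 1.0)))
    heavy_mean = float(df["heavy_area"].mean()) if "heavy_area" in df.columns else float("nan")
    return CalibrationCurve(
        peptide=peptide,
        transition_id=transition_id,
        points=pts,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        anchor_index=anchor,
        spike_heavy_fmol=spike,
        mean_heavy_area=heavy_mean,
    )


def determine_loq(
    curve: CalibrationCurve,
    max_cv: float = 0.20,
    min_r: float = 0.99,
) -> float | None:
    """Lowest quantifiable concentration under the linearity + precision rules.

    Scanning dilution points from the lowest concentration upward, the LOQ
    is the first point whose replicate CV is below ``max_cv`` and for which
    the Pearson R of the fit restricted to that point and above exceeds
    ``min_r`` (at least 3 points are required to assess linearity).
    Returns ``None`` — not quantifiable — when no point satisfies both;
    otherwise the LOQ in fmol, also stored on ``curve.loq_fmol``.
    """
    pts = curve.points.sort_values("nominal_light_fmol").reset_index(drop=True)
    x = _log3(pts["nominal_ratio"].to_numpy())
    y = _log3(pts["mean_ratio"].to_numpy())
    cv = pts["replicate_cv"].to_numpy()
    n = len(pts)
    for i in range(n):
        if cv[i] >= max_cv:
            continue
        if n - i < 3:
            continue
        r = sps.pearsonr(x[i:], y[i:]).statistic
        if r > min_r:
            loq = float(pts["nominal_light_fmol"].iloc[i])
            curve.loq_fmol = loq
            return loq
    curve.loq_fmol = None
    return None


def determine_lod(
    concentration_fmol,
    snr,
    target_snr: float = 3.0,
    curve: CalibrationCurve | None = None,
) -> float:
    """Concentration at which the interpolated signal-to-noise equals 3.

    ``snr`` must be monotone increasing with concentration; interpolation
    is linear in log-log space (S/N proportional to concentration between
    measured points).  Raises when the S/N never reaches the target.
    """
    conc = np.asarray(concentration_fmol, dtype=float)
    s = np.asarray(snr, dtype=float)
    if np.any(s <= 0) or np.any(conc <= 0):
        raise ValueError("concentrations and S/N must be positive")
    order = np.argsort(conc)
    conc, s = conc[order], s[order]
    if np.any(np.diff(s) < 0):
        raise ValueError("S/N must be monotone non-decreasing in concentration")
    if s.max() < target_snr:
        raise ValueError(f"S/N never reaches {target_snr}")
    exact = np.flatnonzero(s == target_snr)
    if exact.size:
        lod = float(conc[exact[0]])
    elif s.min() > target_snr:
        # below the measured range: extrapolate S/N proportional to concentration
        lod = float(conc[0] * target_snr / s[0])
    else:
        lod = float(np.exp(np.interp(np.log(target_snr), np.log(s), np.log(conc))))
    if curve is not None:
        curve.lod_fmol = lod
    return lod


def interassay_cv(replicates) -> float:
    """Coefficient of variation, percent: 100 * sd / mean (sd with ddof=1)."""
    v = np.asarray(replicates, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicates")
    mean = v.mean()
    if mean == 0:
        raise ValueError("mean of replicates is zero")
    return float(100.0 * v.std(ddof=1) / mean)


def select_best_transition(curves: list[CalibrationCurve]) -> str:
    """Transition with the best linearity response.

    Highest Pearson R wins; ties break by lower LOQ (non-quantifiable
    counts as infinite), then by higher mean heavy peak area.
    """
    if not curves:
        raise ValueError("no calibration curves supplied")

    def key(c: CalibrationCurve):
        loq = c.loq_fmol if c.loq_fmol is not None else float("inf")
        heavy = c.mean_heavy_area if np.isfinite(c.mean_heavy_area) else 0.0
        return (-c.pearson_r, loq, -heavy)

    return min(curves, key=key).transition_id


# ---------------------------------------------------------------------------
# absolute quantification


def absolute_concentration(
    ratio: float,
    curve: CalibrationCurve,
    spike_fmol: float | None = None,
    serum_volume_ul: float = DEFAULT_SERUM_VOLUME_UL,
    molar_mass_g_per_mol: float | None = None,
    sample_id: str = "",
    protein: str = "",
    group: str = "",
) -> ConcentrationRecord:
    """Convert an observed light/heavy ratio to an absolute serum level.

    The fitted log3 line is inverted to a nominal ratio, multiplied by the
    heavy spike for fmol on column, then divided by the serum-equivalent
    volume on column and scaled by the protein molar mass to ug/mL.
    Ratios outside the calibrated observed range are flagged as
    extrapolated (still converted).
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    spike = curve.spike_heavy_fmol if spike_fmol is None else spike_fmol
    if not np.isfinite(spike) or spike <= 0:
        raise ValueError("a positive heavy spike amount is required")
    if molar_mass_g_per_mol is None:
        if protein not in MOLAR_MASS_G_PER_MOL:
            raise ValueError("molar_mass_g_per_mol required for unknown protein")
        molar_mass_g_per_mol = MOLAR_MASS_G_PER_MOL[protein]
    y = _log3(ratio)
    nominal = 3.0 ** ((y - curve.intercept) / curve.slope)
    fmol = nominal * spike
    y_obs = _log3(curve.points["mean_ratio"].to_numpy())
    extrapolated = bool(y < y_obs.min() or y > y_obs.max())
    # fmol * M [g/mol] = 1e-9 * M ug; per (vol_ul * 1e-3) mL of serum
    conc = fmol * molar_mass_g_per_mol * 1e-6 / serum_volume_ul
    return ConcentrationRecord(
        sample_id=sample_id,
        protein=protein,
        group=group,
        ratio=float(ratio),
        fmol_on_column=float(fmol),
        serum_conc_ug_per_ml=float(conc),
        extrapolated=extrapolated,
    )


# ---------------------------------------------------------------------------
# cohort statistics


def records_to_frame(records: list[ConcentrationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "protein": [r.protein for r in records],
            "group": [r.group for r in records],
            "ratio": [r.ratio for r in records],
            "fmol_on_column": [r.fmol_on_column for r in records],
            "serum_conc_ug_per_ml": [r.serum_conc_ug_per_ml for r in records],
            "extrapolated": [r.extrapolated for r in records],
        }
    )


def cohort_stats(
    concentrations: pd.DataFrame,
    demographics: pd.DataFrame | None = None,
    control_label: str = "N",
    value_col: str = "serum_conc_ug_per_ml",
) -> CohortReport:
    """Cancer/control statistics over measured serum concentrations.

    ``concentrations`` is long (``sample_id, protein, group`` plus the
    value column).  Per protein: a two-sample t test cancer vs control and
    a ROC analysis; jointly: a logistic-regression panel over all proteins
    scored by its in-sample predicted probabilities.  Optional
    ``demographics`` (indexed by or containing ``sample_id``): binary
    columns are tested by two-sample t test on each protein's
    concentration, numeric columns (e.g. age) by Pearson correlation.
    """
    wide = concentrations.pivot_table(
        index="sample_id", columns="protein", values=value_col
    )
    groups = concentrations.drop_duplicates("sample_id").set_index("sample_id")["group"]
    groups = groups.loc[wide.index]
    is_cancer = (groups != control_label).astype(int).to_numpy()
    if len(np.unique(is_cancer)) < 2:
        raise ValueError("both cancer and control samples are required")

    per_protein = []
    roc: dict[str, ROCResult] = {}
    for prot in wide.columns:
        v = wide[prot]
        a = v[is_cancer == 1]
        b = v[is_cancer == 0]
        t, p = sps.ttest_ind(a, b)
        r = roc_auc(v.to_numpy(), is_cancer)
        roc[str(prot)] = r
        per_protein.append(
            {
                "protein": prot,
                "mean_cancer": a.mean(),
                "mean_control": b.mean(),
                "fold_cancer_vs_control": a.mean() / b.mean(),
                "t_statistic": t,
                "p_value": p,
                "auc": r.auc,
                "auc_ci_low": r.ci_low,
                "auc_ci_high": r.ci_high,
            }
        )
    panel, panel_roc = logistic_panel(wide, is_cancer)

    demo_rows = None
    if demographics is not None:
        demo = demographics.copy()
        if "sample_id" in demo.columns:
            demo = demo.set_index("sample_id")
        demo = demo.loc[wide.index]
        rows = []
        for col in demo.columns:
            series = demo[col]
            for prot in wide.columns:
                v = wide[prot].to_numpy(dtype=float)
                levels = pd.unique(series.dropna())
                if len(levels) == 2:
                    a = v[(series == levels[0]).to_numpy()]
                    b = v[(series == levels[1]).to_numpy()]
                    stat, p = sps.ttest_ind(a, b)
                    rows.append(
                        {"variable": col, "protein": prot, "kind": "ttest",
                         "statistic": stat, "p_value": p}
                    )
                elif pd.api.types.is_numeric_dtype(series):
                    res = sps.pearsonr(series.to_numpy(dtype=float), v)
                    rows.append(
                        {"variable": col, "protein": prot, "kind": "pearson",
                         "statistic": res.statistic, "p_value": res.pvalue}
                    )
                else:
                    raise ValueError(
                        f"demographic {col!r} is neither binary nor numeric"
                    )
        demo_rows = pd.DataFrame(rows)

    return CohortReport(
        per_protein=pd.DataFrame(per_protein),
        roc=roc,
        panel=panel,
        panel_roc=panel_roc,
        demographics=demo_rows,
    )
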