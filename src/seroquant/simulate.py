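"""Synthetic cohort generators with ground truth for every pipeline stage.

The generators emulate the statistical structure of a serum biomarker
study: a discovery cohort of 18 sera (5 normal, 8 adenocarcinoma, 5
squamous) profiled by spectral counting over ~650 proteins spanning six
orders of magnitude of abundance; target/decoy PSM score mixtures per
charge state; base-3 stable-isotope dilution series with replicate noise;
and paired tumor / adjacent-normal TMA scores with a tumor shift.  Each
generator returns the simulated measurements together with the hidden
truth used by parameter-recovery and error-rate tests.

All randomness flows through an explicit ``seed`` field; a fixed seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lfq import CountMatrix
from .psm import PSMRecord

__all__ = [
    "CountSimConfig",
    "PSMSimConfig",
    "MRMSimConfig",
    "TMASimConfig",
    "MRMSimData",
    "generate_count_matrix",
    "generate_psm_table",
    "generate_mrm_dataset",
    "generate_tma_cohort",
]


# ---------------------------------------------------------------------------
# spectral-count matrices


@dataclass(frozen=True)
class CountSimConfig:
    """Study-scale defaults: 647 proteins, 5/8/5 cohort, ~35k PSMs/sample.

    ``frac_differential`` defaults to 101/647 — the fraction of proteins
    truly shifted between cancer and normal cohorts.  Base abundances are
    log-uniform over ``abundance_range_orders`` decades; counts are
    negative-binomial (gamma-Poisson) with the given dispersion, since
    spectral counts are overdispersed relative to Poisson.
    """

    n_proteins: int = 647
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"N": 5, "AD": 8, "SCC": 5}
    )
    abundance_range_orders: float = 6.0
    frac_differential: float = 101 / 647
    log2_fold: float = 1.0
    depth_per_sample: float = 35_000.0
    dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or any(v <= 0 for v in self.n_per_group.values()):
            raise ValueError("dimensions must be positive")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ValueError("frac_differential must lie in [0, 1]")
        if self.log2_fold < 0:
            raise ValueError("log2_fold must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.depth_per_sample <= 0:
            raise ValueError("depth_per_sample must be positive")


def generate_count_matrix(cfg: CountSimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a protein-by-sample spectral-count matrix plus truth table.

    Differential proteins (a fixed, rounded count) have their expected
    counts multiplied by ``2**(+-log2_fold)`` in the cancer cohorts (half
    up-, half down-regulated).  The truth table carries ``truth_``-prefixed
    columns: the differential flag (effective only when ``log2_fold > 0``),
    the signed log2 fold and the base relative abundance.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    proteins = [f"PROT_{i:04d}" for i in range(n)]
    samples, labels = [], []
    for g, k in cfg.n_per_group.items():
        samples += [f"{g}{j + 1}" for j in range(k)]
        labels += [g] * k

    base = 10.0 ** rng.uniform(0.0, cfg.abundance_range_orders, n)
    rel = base / base.sum()

    n_diff = int(round(cfg.frac_differential * n))
    diff_idx = rng.choice(n, size=n_diff, replace=False)
    signs = rng.choice([1.0, -1.0], size=n_diff)
    log2_fold = np.zeros(n)
    log2_fold[diff_idx] = signs * cfg.log2_fold

    depth = cfg.depth_per_sample * rng.lognormal(0.0, 0.1, size=len(samples))
    is_cancer = np.array([lab != "N" for lab in labels])
    mu = rel[:, None] * depth[None, :]
    mu = mu * np.where(is_cancer[None, :], 2.0 ** log2_fold[:, None], 1.0)

    shape = 1.0 / cfg.dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam)

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=proteins, columns=samples),
        groups=pd.Series(labels, index=samples, name="group"),
    )
    flagged = np.zeros(n, dtype=bool)
    if cfg.log2_fold > 0:
        flagged[diff_idx] = True
    truth = pd.DataFrame(
        {
            "protein_id": proteins,
            "truth_differential": flagged,
            "truth_log2_fold": np.where(flagged, log2_fold, 0.0),
            "truth_base_abundance": rel,
        }
    ).set_index("protein_id")
    return matrix, truth


# ---------------------------------------------------------------------------
# PSM tables


@dataclass(frozen=True)
class PSMSimConfig:
    """Target/decoy Xcorr and deltaCn mixtures per charge state.

    Decoy scores and incorrect-target scores are drawn from the same
    distributions — the equal-chance assumption underlying target-decoy
    FDR estimation.  That assumption is also a statement about counts: an
    unmatchable spectrum hits the forward and reverse halves of a composite
    database with equal probability, so ``n_decoys`` defaults (``None``) to
    the expected number of incorrect targets,
    ``round((1 - frac_correct) * n_targets)`` — the regime in which the
    decoy estimate is unbiased.  Gaussian locations place the
    accepted-score landscape where high-confidence SEQUEST identifications
    live (2+ below 3+).
    """

    n_targets: int = 10_000
    n_decoys: int | None = None
    frac_correct: float = 0.6
    score_params: dict[str, dict[int, tuple[float, float]]] = field(
        default_factory=lambda: {
            "correct": {2: (3.4, 0.5), 3: (4.2, 0.7)},
            "incorrect": {2: (1.6, 0.45), 3: (2.0, 0.55)},
        }
    )
    deltacn_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"correct": (0.28, 0.09), "incorrect": (0.06, 0.04)}
    )
    n_proteins: int = 300
    n_database: int = 50_000
    charge_probs: tuple[float, float] = (0.6, 0.4)  # P(2+), P(3+)
    decoy_prefix: str = "REV_"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_correct <= 1.0:
            raise ValueError("frac_correct must lie in [0, 1]")
        if self.n_targets < 0 or (self.n_decoys is not None and self.n_decoys < 0):
            raise ValueError("counts must be non-negative")


def generate_psm_table(cfg: PSMSimConfig) -> tuple[list[PSMRecord], np.ndarray]:
    """Simulate a PSM table; returns records plus hidden correctness labels.

    Exactly ``round(frac_correct * n_targets)`` targets are correct (high
    score population, accessions from the ``n_proteins`` truly present
    proteins); the rest, and all decoys, draw from the incorrect
    populations and hit random accessions across the full ``n_database``
    search space — mirroring a composite forward/reverse database, where a
    false match rarely lands on a protein that is really in the sample.
    Decoys carry reversed-database accessions and are never correct.
    """
    rng = np.random.default_rng(cfg.seed)
    n_t = cfg.n_targets
    n_d = (
        cfg.n_decoys
        if cfg.n_decoys is not None
        else int(round((1.0 - cfg.frac_correct) * n_t))
    )
    n_correct = int(round(cfg.frac_correct * n_t))
    correct = np.zeros(n_t + n_d, dtype=bool)
    correct[rng.permutation(n_t)[:n_correct]] = True  # targets only

    def draw_scores(pop: str, charges: np.ndarray) -> np.ndarray:
        out = np.empty(charges.size)
        for c, (loc, scale) in cfg.score_params[pop].items():
            m = charges == c
            out[m] = rng.normal(loc, scale, m.sum())
        return np.clip(out, 0.0, None)

    def draw_dcn(pop: str, size: int) -> np.ndarray:
        loc, scale = cfg.deltacn_params[pop]
        return np.clip(rng.normal(loc, scale, size), 0.0, 1.0)

    charges = rng.choice([2, 3], size=n_t + n_d, p=cfg.charge_probs)
    xcorr = np.empty(n_t + n_d)
    dcn = np.empty(n_t + n_d)
    incorrect = ~correct
    xcorr[correct] = draw_scores("correct", charges[correct])
    xcorr[incorrect] = draw_scores("incorrect", charges[incorrect])
    dcn[correct] = draw_dcn("correct", int(correct.sum()))
    dcn[incorrect] = draw_dcn("incorrect", int(incorrect.sum()))

    prot_of = rng.integers(0, cfg.n_proteins, size=n_t + n_d)
    db_of = rng.integers(0, cfg.n_database, size=n_t + n_d)
    pep_of = rng.integers(0, 5, size=n_t + n_d)

    records: list[PSMRecord] = []
    for i in range(n_t + n_d):
        is_decoy = i >= n_t
        if is_decoy:
            acc = f"{cfg.decoy_prefix}P{db_of[i]:05d}"
            pep = f"DECPEP_{i:06d}"
        elif correct[i]:
            acc = f"P{prot_of[i]:05d}"
            pep = f"PEP_{prot_of[i]:05d}_{pep_of[i]}"
        else:
            acc = f"P{db_of[i]:05d}"
            pep = f"RNDPEP_{i:06d}"
        records.append(
            PSMRecord(
                spectrum_id=f"scan_{i:06d}",
                peptide=pep,
                accessions=(acc,),
                charge=int(charges[i]),
                xcorr=float(xcorr[i]),
                delta_cn=float(dcn[i]),
                is_decoy=is_decoy,
            )
        )
    return records, correct


# ---------------------------------------------------------------------------
# MRM datasets


@dataclass(frozen=True)
class MRMSimConfig:
    """Base-3 dilution series plus a cancer/control cohort for one peptide.

    The dilution series anchors the light amount at the heavy spike in the
    middle of the series, spanning ``dilution_base**(n_dilution_points-1)``
    overall.  Noise is multiplicative lognormal, independent between light
    and heavy channels, at the given replicate CV; the lowest
    ``n_noisy_points`` points get CV inflated to ``noisy_cv`` so a true
    LOQ knee exists.  Cohort light/heavy ratios reflect ``group_fold`` in
    cancer samples on top of lognormal biological spread.
    """

    true_conc_fmol: float = 50.0
    spike_heavy_fmol: float = 50.0
    dilution_base: int = 3
    n_dilution_points: int = 8
    replicate_cv: float = 0.05
    n_replicates: int = 5
    cohort_sizes: dict[str, int] = field(
        default_factory=lambda: {"NSCLC": 70, "N": 30}
    )
    group_fold: float = 2.0
    biological_cv: float = 0.35
    n_noisy_points: int = 0
    noisy_cv: float = 0.4
    control_group: str = "N"
    peptide: str = "HQFLLTGDTQGR"
    transition_id: str = "y8"
    heavy_area_scale: float = 1e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_conc_fmol <= 0 or self.spike_heavy_fmol <= 0:
            raise ValueError("amounts must be positive")
        if self.replicate_cv < 0 or self.biological_cv < 0 or self.noisy_cv < 0:
            raise ValueError("CVs must be non-negative")
        if self.dilution_base < 2 or self.n_dilution_points < 2:
            raise ValueError("dilution series needs base >= 2 and >= 2 points")


@dataclass
class MRMSimData:
    dilution: pd.DataFrame
    cohort: pd.DataFrame
    truth: dict


def _mult_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal factors with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-sigma**2 / 2.0, sigma, size)


def generate_mrm_dataset(cfg: MRMSimConfig) -> MRMSimData:
    """Simulate dilution-series and cohort MRM measurements.

    The dilution table has one row per replicate per point (columns
    ``point_index, nominal_light_fmol, spike_heavy_fmol, replicate_id,
    light_area, heavy_area``); the cohort table is the long transition
    format (``sample_id, group, peptide, transition_id, label, area,
    qc_pass``).  Truth records the planted concentration, fold and — when
    noisy low points are configured — the LOQ knee concentration.
    """
    rng = np.random.default_rng(cfg.seed)
    npts, base = cfg.n_dilution_points, float(cfg.dilution_base)
    anchor = npts // 2
    nominal = cfg.spike_heavy_fmol * base ** (np.arange(npts) - anchor)

    point_cv = np.full(npts, cfg.replicate_cv)
    point_cv[: cfg.n_noisy_points] = cfg.noisy_cv

    rows = []
    for i in range(npts):
        noise_l = _mult_noise(rng, point_cv[i], cfg.n_replicates)
        noise_h = _mult_noise(rng, cfg.replicate_cv, cfg.n_replicates)
        heavy = cfg.heavy_area_scale * noise_h
        light = cfg.heavy_area_scale * (nominal[i] / cfg.spike_heavy_fmol) * noise_l
        for r in range(cfg.n_replicates):
            rows.append(
                {
                    "point_index": i,
                    "nominal_light_fmol": nominal[i],
                    "spike_heavy_fmol": cfg.spike_heavy_fmol,
                    "replicate_id": r,
                    "light_area": light[r],
                    "heavy_area": heavy[r],
                }
            )
    dilution = pd.DataFrame(rows)

    crows = []
    true_ratio = cfg.true_conc_fmol / cfg.spike_heavy_fmol
    for grp, size in cfg.cohort_sizes.items():
        fold = 1.0 if grp == cfg.control_group else cfg.group_fold
        bio = _mult_noise(rng, cfg.biological_cv, size)
        heavy = cfg.heavy_area_scale * _mult_noise(rng, cfg.replicate_cv, size)
        light = heavy * true_ratio * fold * bio * _mult_noise(rng, cfg.replicate_cv, size)
        for j in range(size):
            sid = f"{grp}_{j + 1:03d}"
            for label, area in (("light", light[j]), ("heavy", heavy[j])):
                crows.append(
                    {
                        "sample_id": sid,
                        "group": grp,
                        "peptide": cfg.peptide,
                        "transition_id": cfg.transition_id,
                        "label": label,
                        "area": area,
                        "qc_pass": True,
                    }
                )
    cohort = pd.DataFrame(crows)

    truth = {
        "true_conc_fmol": cfg.true_conc_fmol,
        "group_fold": cfg.group_fold,
        "nominal_light_fmol": nominal,
        "loq_knee_fmol": float(nominal[cfg.n_noisy_points]) if cfg.n_noisy_points else float(nominal[0]),
    }
    return MRMSimData(dilution=dilution, cohort=cohort, truth=truth)


# ---------------------------------------------------------------------------
# TMA cohorts


@dataclass(frozen=True)
class TMASimConfig:
    """Paired tumor / adjacent-normal sections scored by two pathologists.

    Defaults emulate the verification cohort: 89 valid pairs, tumor
    sections mostly strongly and extensively stained, normal sections
    weakly so.  Percentages are truncated Gaussians on [0, 100];
    intensities are categorical over {0, 1, 2, 3}.
    """

    n_pairs: int = 89
    tumor_percent_mean: float = 70.0
    tumor_percent_sd: float = 20.0
    normal_percent_mean: float = 25.0
    normal_percent_sd: float = 15.0
    intensity_probs: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "tumor": (0.05, 0.15, 0.40, 0.40),
            "adjacent_normal": (0.35, 0.40, 0.18, 0.07),
        }
    )
    n_pathologists: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs <= 0 or self.n_pathologists <= 0:
            raise ValueError("dimensions must be positive")
        for tissue, probs in self.intensity_probs.items():
            p = np.asarray(probs, dtype=float)
            if p.size != 4 or (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"invalid intensity probabilities for {tissue!r}")


def generate_tma_cohort(cfg: TMASimConfig) -> pd.DataFrame:
    """Simulate the long rater table: case_id, tissue, rater, percent, intensity."""
    rng = np.random.default_rng(cfg.seed)
    params = {
        "tumor": (cfg.tumor_percent_mean, cfg.tumor_percent_sd),
        "adjacent_normal": (cfg.normal_percent_mean, cfg.normal_percent_sd),
    }
    rows = []
    for i in range(cfg.n_pairs):
        case = f"case_{i + 1:03d}"
        for tissue in ("tumor", "adjacent_normal"):
            mean, sd = params[tissue]
            probs = np.asarray(cfg.intensity_probs[tissue], dtype=float)
            for rater in range(cfg.n_pathologists):
                pct = float(np.clip(rng.normal(mean, sd), 0.0, 100.0))
                inten = int(rng.choice(4, p=probs))
                rows.append(
                    {
                        "case_id": case,
                        "tissue": tissue,
                        "rater": f"rater_{rater + 1}",
                        "percent": pct,
                        "intensity": inten,
                    }
                )
    return pd.DataFrame(rows)
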