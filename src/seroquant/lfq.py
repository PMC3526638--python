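"""Discovery-phase label-free quantification by spectral counting.

Relative protein abundance between serum cohorts is measured by the number
of peptide-spectrum matches (PSMs) assigned to each protein group per
sample.  The module provides:

* the relative enrichment factor ``Re = (n_f/n) / (N_f/N)`` — a protein's
  within-sample share of PSMs relative to its share over the whole cohort;
* permutation-based ANOVA-F and two-sample t tests on any protein-by-sample
  value matrix, with joint label permutation across proteins;
* significance filtering at a raw p-value threshold (no multiplicity
  correction — the screening rule is deliberately liberal, candidates go to
  orthogonal verification);
* ``log2(count + 1)`` transformation followed by quantile normalization;
* hierarchical clustering and PCA (biplot-style: sample scores plus
  protein loadings) of normalized matrices;
* ROC analysis with a DeLong-type asymptotic confidence interval and a
  logistic-regression biomarker panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "CountMatrix",
    "EnrichmentTable",
    "PanelModel",
    "ROCResult",
    "ClusterResult",
    "PCAResult",
    "enrichment_factor",
    "permutation_test",
    "filter_significant",
    "normalize_log_quantile",
    "hierarchical_cluster",
    "pca_biplot",
    "roc_auc",
    "logistic_panel",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountMatrix:
    """Protein-by-sample spectral counts with cohort labels.

    Parameters
    ----------
    counts
        Integer DataFrame, proteins as rows, samples as columns.
    groups
        Series mapping each sample (column) to a cohort label
        (e.g. ``"N"``, ``"AD"``, ``"SCC"``).
    """

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("spectral counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.groups = self.groups.loc[list(self.counts.columns)]

    @property
    def proteins(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def group_labels(self) -> np.ndarray:
        return self.groups.to_numpy()

    def to_tsv(self, counts_path, groups_path) -> None:
        out = self.counts.copy()
        out.index.name = "protein_id"
        out.to_csv(counts_path, sep="\t")
        g = self.groups.rename("group").to_frame()
        g.index.name = "sample_id"
        g.to_csv(groups_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, groups_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="protein_id")
        groups = pd.read_csv(groups_path, sep="\t", index_col="sample_id")["group"]
        return cls(counts=counts, groups=groups)


@dataclass
class EnrichmentTable:
    """Per-protein enrichment factors and test results."""

    re: pd.DataFrame
    p_anova: pd.Series | None = None
    p_ttest: pd.DataFrame | None = None
    significant: pd.Series | None = None


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass
class PanelModel:
    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    predicted_prob: np.ndarray
    separation_flag: bool = False


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: pd.Series
    samples: list[str]


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # proteins x components
    explained_variance_ratio: np.ndarray
    column_means: pd.Series = field(default=None)


# ---------------------------------------------------------------------------
# enrichment factor


def enrichment_factor(m: CountMatrix) -> EnrichmentTable:
    """Relative enrichment factor ``Re = (n_f/n) / (N_f/N)`` per protein/sample.

    ``n_f`` is the protein's PSM count in one sample, ``n`` the sample's
    total count, ``N_f`` the protein's total over all samples and ``N`` the
    grand total.  Proteins never observed (``N_f = 0``) are dropped; a zero
    cell gives ``Re = 0``.  For every sample the identity
    ``sum_f (N_f/N) * Re[f, s] = 1`` holds whenever the column total is
    non-zero.
    """
    counts = m.counts.astype(float)
    grand = counts.to_numpy().sum()
    if grand == 0:
        raise ValueError("all-zero count matrix")
    col_tot = counts.sum(axis=0)
    if (col_tot == 0).any():
        bad = list(col_tot.index[col_tot == 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    row_tot = counts.sum(axis=1)
    keep = row_tot > 0
    counts = counts.loc[keep]
    row_tot = row_tot.loc[keep]
    share_in_sample = counts.div(col_tot, axis=1)
    global_share = row_tot / grand
    re = share_in_sample.div(global_share, axis=0)
    return EnrichmentTable(re=re)


# ---------------------------------------------------------------------------
# permutation tests


def _group_indices(labels: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(labels == g) for g in pd.unique(labels)]


def _f_stat(x: np.ndarray, gidx: list[np.ndarray]) -> np.ndarray:
    """One-way ANOVA F per row, vectorized over rows."""
    k = len(gidx)
    n = x.shape[1]
    grand = x.mean(axis=1)
    ssb = np.zeros(x.shape[0])
    ssw = np.zeros(x.shape[0])
    for idx in gidx:
        sub = x[:, idx]
        mu = sub.mean(axis=1)
        ssb += idx.size * (mu - grand) ** 2
        ssw += ((sub - mu[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ssb / (k - 1)) / (ssw / (n - k))


def _t_stat(x: np.ndarray, gidx: list[np.ndarray]) -> np.ndarray:
    """Pooled-variance two-sample t per row, vectorized over rows."""
    a, b = x[:, gidx[0]], x[:, gidx[1]]
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(sp2 * (1 / na + 1 / nb))


def permutation_test(
    values,
    groups,
    n_perm: int = 10_000,
    statistic: str = "F",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Permutation p-values per protein row.

    Sample labels are permuted jointly across all rows ``n_perm`` times and
    ``p = (1 + #{|stat_perm| >= |stat_obs|}) / (n_perm + 1)`` — never
    exactly zero.  ``statistic`` is ``"F"`` (one-way ANOVA over all label
    levels) or ``"t"`` (pooled two-sample t; requires exactly two levels).
    Constant rows get ``p = 1``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(values, dtype=float)
    index = values.index if isinstance(values, pd.DataFrame) else pd.RangeIndex(x.shape[0])
    labels = np.asarray(groups)
    if labels.shape[0] != x.shape[1]:
        raise ValueError("groups length must match number of samples")
    gidx = _group_indices(labels)
    if statistic == "t" and len(gidx) != 2:
        raise ValueError("statistic 't' requires exactly two group levels")
    if any(idx.size < 2 for idx in gidx):
        raise ValueError("every compared group needs at least 2 samples")
    stat_fn = _f_stat if statistic == "F" else _t_stat

    obs = np.abs(stat_fn(x, gidx))
    obs = np.where(np.isnan(obs), np.inf, obs)  # 0/0 rows handled via `constant`

    if rng is None:
        rng = np.random.default_rng(seed)
    n_samples = x.shape[1]
    exceed = np.zeros(x.shape[0], dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n_samples)
        stat = np.abs(stat_fn(x[:, perm], gidx))
        stat = np.where(np.isnan(stat), 0.0, stat)
        exceed += stat >= obs
    p = (1 + exceed) / (n_perm + 1)
    p[np.ptp(x, axis=1) == 0] = 1.0
    return pd.Series(p, index=index, name=f"p_{statistic.lower()}")


def filter_significant(
    p_anova: pd.Series,
    p_ttest: pd.DataFrame | None = None,
    alpha: float = 0.01,
    rule: str = "or",
) -> pd.DataFrame:
    """Flag proteins with raw ``p < alpha``.

    ``rule="or"`` (default) flags a protein when the ANOVA p or any pairwise
    t-test p is below ``alpha``; ``rule="and"`` requires all of them.  No
    multiple-testing correction is applied — flagged proteins are screening
    candidates, not confirmatory calls.  The returned frame records which
    test(s) fired.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if rule not in ("or", "and"):
        raise ValueError("rule must be 'or' or 'and'")
    hits = pd.DataFrame({"anova": p_anova < alpha})
    if p_ttest is not None:
        for col in p_ttest.columns:
            hits[str(col)] = p_ttest[col] < alpha
    sig = hits.any(axis=1) if rule == "or" else hits.all(axis=1)
    fired = hits.apply(lambda r: ",".join(c for c in hits.columns if r[c]), axis=1)
    return pd.DataFrame({"significant": sig, "fired_by": fired})


# ---------------------------------------------------------------------------
# normalization


def normalize_log_quantile(m) -> pd.DataFrame:
    """``log2(count + 1)`` then quantile normalization across samples.

    Every column is forced onto the common reference distribution of
    per-rank row means; tied values receive the mean of the reference
    values spanned by their (average) rank.
    """
    counts = m.counts if isinstance(m, CountMatrix) else pd.DataFrame(m)
    logx = np.log2(counts.to_numpy(dtype=float) + 1.0)
    ref = np.sort(logx, axis=0).mean(axis=1)
    out = np.empty_like(logx)
    for j in range(logx.shape[1]):
        ranks = sps.rankdata(logx[:, j], method="average")  # 1-based, .5 on ties
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (ref[lo] + ref[hi])
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# clustering / PCA


def hierarchical_cluster(
    x: pd.DataFrame,
    k: int = 2,
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of samples (columns) of a normalized matrix.

    Returns the scipy linkage matrix plus flat cluster labels from cutting
    the dendrogram at ``k`` clusters.
    """
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if x.shape[1] < k:
        raise ValueError("fewer samples than requested clusters")
    data = x.to_numpy(dtype=float).T
    z = sch.linkage(data, method=method, metric=metric)
    labels = sch.fcluster(z, t=k, criterion="maxclust")
    return ClusterResult(linkage=z, labels=pd.Series(labels, index=x.columns), samples=list(x.columns))


def pca_biplot(x: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Centered PCA of samples with protein loadings (biplot arrows).

    Rows of ``x`` are proteins, columns are samples.  Sample scores are the
    projections on the principal components; loadings are the right
    singular vectors per protein.  Component sign convention: the
    largest-magnitude loading of each component is made positive.
    """
    if x.shape[1] < 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 samples and 2 proteins")
    data = x.to_numpy(dtype=float).T  # samples x proteins
    means = data.mean(axis=0)
    centered = data - means
    if not centered.any():
        raise ValueError("zero-variance data")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if n_components is None:
        n_components = min(centered.shape)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # deterministic signs: largest |loading| per component positive
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    scores = u * s
    evr = s**2 / (centered**2).sum()
    comps = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=x.columns, columns=comps),
        loadings=pd.DataFrame(vt.T, index=x.index, columns=comps),
        explained_variance_ratio=evr,
        column_means=pd.Series(means, index=x.index),
    )


# ---------------------------------------------------------------------------
# ROC / logistic panel


def _auc_rank(score: np.ndarray, label: np.ndarray) -> float:
    """Mann-Whitney AUC; ties count one half."""
    pos = score[label == 1]
    neg = score[label == 0]
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    n1, n0 = pos.size, neg.size
    return (ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def _delong_se(score: np.ndarray, label: np.ndarray) -> float:
    """DeLong asymptotic standard error of the AUC estimate."""
    pos = score[label == 1]
    neg = score[label == 0]
    # placement values: per positive, fraction of negatives it beats (ties .5)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / neg.size for p in pos])
    v01 = np.array([(np.sum(pos > n) + 0.5 * np.sum(pos == n)) / pos.size for n in neg])
    s10 = v10.var(ddof=1) if pos.size > 1 else 0.0
    s01 = v01.var(ddof=1) if neg.size > 1 else 0.0
    return float(np.sqrt(s10 / pos.size + s01 / neg.size))


def roc_auc(score, label, conf_level: float = 0.95) -> ROCResult:
    """ROC curve and AUC with a DeLong-type asymptotic confidence interval.

    AUC is the rank (Mann-Whitney) statistic with ties counted one half —
    invariant to any strictly increasing transform of the score.
    """
    score = np.asarray(score, dtype=float)
    label = np.asarray(label).astype(int)
    if set(np.unique(label)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(label)) < 2:
        raise ValueError("both classes must be present")
    auc = _auc_rank(score, label)
    se = _delong_se(score, label)
    zq = sps.norm.ppf(0.5 + conf_level / 2)
    fpr, tpr, _ = _sk_roc_curve(label, score)
    return ROCResult(
        auc=float(auc),
        ci_low=float(max(0.0, auc - zq * se)),
        ci_high=float(min(1.0, auc + zq * se)),
        fpr=fpr,
        tpr=tpr,
    )


def logistic_panel(features, label, max_iter: int = 2000) -> tuple[PanelModel, ROCResult]:
    """Maximum-likelihood logistic fit of a biomarker panel.

    All features enter as one block (no selection).  In-sample predicted
    probabilities are scored by :func:`roc_auc` — the panel's discriminative
    power.  Perfect separation is reported via ``separation_flag`` (the
    diverging linear predictor still orders the samples, so the AUC is
    computable).
    """
    X = pd.DataFrame(features)
    y = np.asarray(label).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if (X.nunique() <= 1).all():
        raise ValueError("all features are constant")
    model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lbfgs may report non-convergence under separation
        model.fit(X.to_numpy(dtype=float), y)
    z = model.decision_function(X.to_numpy(dtype=float))
    # strict separation: every case scores above every control, so the MLE diverges
    separation = bool(z[y == 1].min() > z[y == 0].max())
    prob = np.clip(model.predict_proba(X.to_numpy(dtype=float))[:, 1], 1e-12, 1 - 1e-12)
    panel = PanelModel(
        feature_names=list(map(str, X.columns)),
        coefficients=model.coef_.ravel().copy(),
        intercept=float(model.intercept_[0]),
        predicted_prob=prob,
        separation_flag=separation,
    )
    return panel, roc_auc(prob, y)
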