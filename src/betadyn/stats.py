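"""Single-trial brain-behaviour statistics.

Implements the study-level statistical machinery: z-score outlier cleaning,
per-timepoint OLS of reaction times on a beta measure, shuffled-correspondence
null slopes, cluster-based permutation tests over time or frequency with
sign-flip nulls and a max-cluster-statistic correction, Cohen's d over
cluster-averaged differences, median splits and paired contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

__all__ = [
    "RegressionTimecourse",
    "Cluster",
    "ClusterTestResult",
    "zscore_clean",
    "regress_timecourse",
    "shuffled_null",
    "cluster_permutation_test",
    "cohens_d_cluster",
    "median_split",
    "paired_contrast",
]


@dataclass
class RegressionTimecourse:
    slopes: np.ndarray  # per time point, z-units RT per z-unit feature
    intercepts: np.ndarray
    r_squared: np.ndarray
    max_r_squared: float
    n_retained: np.ndarray  # trials retained per time point


@dataclass
class Cluster:
    indices: np.ndarray  # contiguous index set over the clustering axis
    stat: float  # sum of pointwise paired t-values
    p: float  # Monte-Carlo p (+1 corrected)
    d: float  # Cohen's d of the cluster-averaged differences


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    t_values: np.ndarray
    threshold: float
    n_perm: int

    @property
    def min_p(self) -> float:
        """Smallest cluster p; 1.0 when no cluster formed."""
        return min((c.p for c in self.clusters), default=1.0)


def _z(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate input: zero variance")
    return (v - v.mean()) / sd


def zscore_clean(feature: np.ndarray, rts: np.ndarray,
                 z_limit: float = 3.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score both variables and drop trials with |z| > 3 on either.

    Returns (clean feature z, clean RT z, retained-trial boolean mask); the
    retained pairs are *not* re-z-scored.
    """
    feature = np.asarray(feature, dtype=float)
    rts = np.asarray(rts, dtype=float)
    if len(feature) < 3:
        raise ValueError("need at least 3 trials")
    zf, zr = _z(feature), _z(rts)
    keep = (np.abs(zf) <= z_limit) & (np.abs(zr) <= z_limit)
    return zf[keep], zr[keep], keep


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R^2 of y = a*x + b by least squares."""
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    if sxx == 0:
        return np.nan, np.nan, np.nan
    a = ((x - xm) * (y - ym)).sum() / sxx
    b = ym - a * xm
    resid = y - (a * x + b)
    syy = ((y - ym) ** 2).sum()
    r2 = np.nan if syy == 0 else 1.0 - (resid**2).sum() / syy
    return a, b, r2


def _zscore_columns(feature_tc: np.ndarray,
                    z_limit: float) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise z-scores and the per-column outlier-retention mask."""
    mu = feature_tc.mean(axis=0)
    sd = feature_tc.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        zf = (feature_tc - mu) / sd
    bad = sd == 0
    zf[:, bad] = np.nan
    mf = np.where(bad[None, :], False, np.abs(zf) <= z_limit)
    zf = np.where(mf, zf, 0.0)
    return zf, mf


def _masked_regression(zf: np.ndarray, mf: np.ndarray, zr_rows: np.ndarray,
                       mr_rows: np.ndarray):
    """OLS of y on x per (shuffle, time point) over the jointly retained trials.

    The z-scored feature ``zf`` (trials x times, zeroed outside its retention
    mask ``mf``) is paired with one or more z-scored RT rows ``zr_rows``
    (shuffles x trials, masked by ``mr_rows``). Because the joint retention
    mask factorizes into the feature mask times the RT mask, all OLS sums
    reduce to matrix products; pairs are not re-z-scored, so OLS re-centres
    within the retained set. Returns (slopes, intercepts, r2, n) each of
    shape (shuffles, times); entries with < 3 retained trials or zero
    retained variance are NaN.
    """
    F1 = mf.astype(float)
    Fx = zf * F1
    Fxx = zf * Fx
    R1 = mr_rows.astype(float)
    Ry = np.where(mr_rows, zr_rows, 0.0)
    Ryy = zr_rows * Ry
    n = R1 @ F1
    Sx, Sxx = R1 @ Fx, R1 @ Fxx
    Sy, Sxy = Ry @ F1, Ry @ Fx
    Syy = Ryy @ F1
    denx = n * Sxx - Sx**2
    deny = n * Syy - Sy**2
    num = n * Sxy - Sx * Sy
    ok = (n >= 3) & (denx > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(ok, num / denx, np.nan)
        intercept = np.where(ok, (Sy - slope * Sx) / n, np.nan)
        r2 = np.where(ok & (deny > 0), num**2 / (denx * deny), np.nan)
    return slope, intercept, r2, n


def regress_timecourse(feature_tc: np.ndarray,
                       rts: np.ndarray) -> RegressionTimecourse:
    """Per-timepoint OLS of reaction time on a single-trial feature.

    ``feature_tc`` is trials x times. At each time point both variables are
    z-scored, |z| > 3 trials removed, and RT regressed on the feature; on
    z-scored pairs the slope equals the Pearson correlation.
    """
    feature_tc = np.asarray(feature_tc, dtype=float)
    rts = np.asarray(rts, dtype=float)
    zf, mf = _zscore_columns(feature_tc, 3.0)
    zr, mr = _zscore_columns(rts[:, None], 3.0)
    slope, intercept, r2, n = _masked_regression(zf, mf, zr.T, mr.T)
    max_r2 = np.nan if np.all(np.isnan(r2)) else float(np.nanmax(r2))
    return RegressionTimecourse(slope[0], intercept[0], r2[0], max_r2,
                                n[0].astype(int))


def shuffled_null(feature_tc: np.ndarray, rts: np.ndarray,
                  n_shuffles: int = 100, seed: int = 0) -> np.ndarray:
    """Mean slope timecourse after shuffling the feature-RT correspondence.

    Each shuffle permutes the RT assignment across trials and recomputes the
    slope timecourse (including the |z| > 3 cleaning, which travels with the
    permuted RTs); the mean over shuffles is the per-participant null.
    """
    rng = np.random.default_rng(seed)
    feature_tc = np.asarray(feature_tc, dtype=float)
    rts = np.asarray(rts, dtype=float)
    zf, mf = _zscore_columns(feature_tc, 3.0)
    zr, mr = _zscore_columns(rts[:, None], 3.0)
    perms = np.stack([rng.permutation(len(rts)) for _ in range(n_shuffles)])
    slope, _, _, _ = _masked_regression(zf, mf, zr[perms, 0], mr[perms, 0])
    return slope.mean(axis=0)


def _find_clusters(t: np.ndarray, thresh: float) -> list[tuple[np.ndarray, float]]:
    """Contiguous same-sign supra-threshold runs and their summed t."""
    out = []
    supra = np.where(np.abs(t) > thresh, np.sign(t), 0.0)
    edges = np.flatnonzero(np.diff(np.r_[0, (supra != 0).astype(int), 0]))
    for start, stop in zip(edges[::2], edges[1::2]):
        signs = supra[start:stop]
        # split a run at sign changes
        cuts = np.flatnonzero(np.diff(signs)) + 1
        for a, b in zip(np.r_[0, cuts], np.r_[cuts, stop - start]):
            idx = np.arange(start + a, start + b)
            out.append((idx, float(t[idx].sum())))
    return out


def _paired_t(diff: np.ndarray) -> np.ndarray:
    """Pointwise paired t across subjects (axis 0); zero where SD is zero."""
    n = diff.shape[0]
    mu = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mu / (sd / np.sqrt(n))
    return np.where(sd == 0, 0.0, t)


def cluster_permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    n_perm: int = 1000,
    alpha_cluster: float = 0.05,
    seed: int = 0,
) -> ClusterTestResult:
    """Cluster-based permutation test for paired conditions along one axis.

    ``cond_a`` and ``cond_b`` are subjects x bins (time points or frequency
    bins). Pointwise paired t-values are thresholded at the two-tailed t
    critical value for ``alpha_cluster``; contiguous same-sign runs form
    clusters whose statistic is the summed t. The null distribution is the
    max |cluster statistic| over ``n_perm`` random per-subject sign flips of
    the paired differences; Monte-Carlo p-values carry the +1 correction.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("conditions must be subjects x bins with equal shape")
    n_subj = a.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    diff = a - b
    thresh = float(spstats.t.ppf(1 - alpha_cluster / 2, df=n_subj - 1))
    t_obs = _paired_t(diff)
    obs = _find_clusters(t_obs, thresh)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        t_p = _paired_t(diff * signs[p][:, None])
        cl = _find_clusters(t_p, thresh)
        if cl:
            null_max[p] = max(abs(s) for _, s in cl)

    clusters = []
    for idx, stat in obs:
        pval = (1 + np.sum(null_max >= abs(stat))) / (n_perm + 1)
        clusters.append(Cluster(indices=idx, stat=stat, p=float(pval),
                                d=cohens_d_cluster(diff, idx)))
    return ClusterTestResult(clusters=clusters, t_values=t_obs,
                             threshold=thresh, n_perm=n_perm)


def cohens_d_cluster(diffs: np.ndarray, cluster_idx: np.ndarray) -> float:
    """Cohen's d of the per-subject differences averaged within a cluster."""
    cluster_idx = np.asarray(cluster_idx)
    if cluster_idx.size == 0:
        raise ValueError("cluster must be nonempty")
    per_subj = np.asarray(diffs, dtype=float)[:, cluster_idx].mean(axis=1)
    sd = per_subj.std(ddof=1)
    if sd == 0:
        if np.allclose(per_subj, 0):
            return 0.0
        warnings.warn("zero between-subject SD; d undefined", RuntimeWarning)
        return np.nan
    return float(per_subj.mean() / sd)


def median_split(rts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trial indices of the fast (< median) and slow (>= median) halves."""
    rts = np.asarray(rts, dtype=float)
    if len(rts) < 2:
        raise ValueError("need at least 2 trials")
    med = np.median(rts)
    fast = np.flatnonzero(rts < med)
    slow = np.flatnonzero(rts >= med)
    if fast.size == 0:
        warnings.warn("all reaction times identical; fast half is empty",
                      RuntimeWarning)
    return fast, slow


def paired_contrast(a: np.ndarray, b: np.ndarray,
                    method: str = "t") -> tuple[float, float, float]:
    """Two-tailed paired contrast on per-subject means.

    ``method='t'`` runs a paired t test, ``method='wilcoxon'`` the signed-rank
    test with normal approximation. Returns (statistic, p, Cohen's d) where d
    is mean difference / SD of differences. Zero-variance differences leave
    the statistic undefined (NaN) with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need paired 1-d samples with >= 3 subjects")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return 0.0, 1.0, 0.0
        warnings.warn("zero variance of differences; statistic undefined",
                      RuntimeWarning)
        return np.nan, np.nan, np.nan
    d = float(diff.mean() / sd)
    if method == "t":
        res = spstats.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue), d
    if method == "wilcoxon":
        res = spstats.wilcoxon(a, b, method="approx", correction=False)
        z = float(res.zstatistic)
        return z, float(res.pvalue), d
    raise ValueError("method must be 't' or 'wilcoxon'")
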