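"""Richness, beta-diversity and distance-based permutation tests.

All three permutation tests operate on a dissimilarity matrix and follow
the add-one convention p = (1 + exceedances) / (1 + permutations), with
ties counted as exceedances, so a permutation p-value is never zero.

* :func:`raup_crick` - probabilistic beta-diversity: for each sample
  pair, the probability that two null assemblages (each sample rebuilt by
  drawing its observed richness from the OTU pool with selection
  probability proportional to OTU occupancy) share *more* OTUs than
  observed, plus half the tie probability.  Values near 0 mean the pair
  shares more OTUs than expected by chance; near 1, fewer.
* :func:`permanova` - Anderson's distance-based pseudo-F via the Gower
  centred inner-product matrix; the default treats depth as a single
  numeric predictor (model df = 1).
* :func:`permdisp` - homogeneity of multivariate dispersions: distance
  to group centroid in principal-coordinate space with the standard
  negative-eigenvalue correction, then a one-way F with label permutation.
* :func:`mantel_correlogram` - Mantel r between community dissimilarity
  and membership of each geographic distance class, with progressive
  Holm correction across classes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CommunityMatrix

__all__ = [
    "DistanceMatrix",
    "PermTestResult",
    "richness_per_sample",
    "depth_trend_test",
    "raup_crick",
    "permanova",
    "permdisp",
    "mantel_correlogram",
]

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities over named samples."""

    data: np.ndarray
    ids: list[str]
    metric_name: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.ids = [str(i) for i in self.ids]
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


@dataclass
class PermTestResult:
    """Outcome of a (permutation) test: statistic, p and bookkeeping."""

    statistic: float
    p_value: float
    n_permutations: int
    permutation_seed: int | None = None
    extra: dict = field(default_factory=dict)


def richness_per_sample(matrix: CommunityMatrix) -> pd.Series:
    """Number of OTUs with at least one read, per sample."""
    return (matrix.counts > 0).sum(axis=1).rename("richness")


def depth_trend_test(
    richness: pd.Series | dict,
    depth_of_sample: pd.Series | dict,
) -> PermTestResult:
    """Ordinary least-squares trend of per-depth mean richness on depth.

    Richness is first averaged within each depth value, then regressed on
    depth as a single numeric predictor.  Returns the regression F with
    (1, n_depths - 2) degrees of freedom; with 10 depth classes this is
    the (1, 8)-df test.
    """
    richness = pd.Series(richness, dtype=float)
    depth = pd.Series(depth_of_sample, dtype=float).reindex(richness.index)
    if depth.isna().any():
        raise ValueError("every sample needs a depth value")
    per_depth = richness.groupby(depth).mean()
    k = len(per_depth)
    if k < 3:
        raise ValueError(f"need >= 3 depth classes, got {k}")
    x = per_depth.index.to_numpy(dtype=float)
    y = per_depth.to_numpy(dtype=float)
    df_resid = k - 2
    sxx = ((x - x.mean()) ** 2).sum()
    if sxx == 0:
        raise ValueError("depth values are constant")
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    ss_reg = slope**2 * sxx
    ss_res = ((y - intercept - slope * x) ** 2).sum()
    if ss_res <= 1e-12 * max(ss_reg, 1.0):
        f_stat = math.inf if ss_reg > 0 else 0.0
        p = 0.0 if ss_reg > 0 else 1.0
    else:
        f_stat = ss_reg / (ss_res / df_resid)
        p = float(stats.f.sf(f_stat, 1, df_resid))
    return PermTestResult(
        statistic=float(f_stat),
        p_value=p,
        n_permutations=0,
        extra={"df": (1, df_resid), "slope": float(slope), "intercept": float(intercept)},
    )


# ---------------------------------------------------------------------------
# Raup-Crick beta-diversity
# ---------------------------------------------------------------------------

def raup_crick(
    matrix: CommunityMatrix,
    n_null: int = 999,
    seed: int = 0,
    signed: bool = False,
) -> DistanceMatrix:
    """Raup-Crick dissimilarity by null-assemblage randomisation.

    Each null replicate rebuilds every sample by drawing its observed
    richness from the OTU pool without replacement, with selection
    probabilities proportional to each OTU's occupancy frequency across
    samples.  For a pair the dissimilarity is the fraction of replicates
    whose null shared-OTU count exceeds the observed count, plus half the
    tie fraction, so 0 = far more shared than chance, 1 = far less.  With
    ``signed=True`` the value is rescaled to [-1, 1] as 2p - 1.

    A sample with zero richness is assigned the uninformative value 0.5
    against every other sample (logged).
    """
    presence = (matrix.counts.to_numpy() > 0)
    n, J = presence.shape
    if n == 0 or J == 0:
        raise ValueError("empty community matrix")
    richness = presence.sum(axis=1)
    occupancy = presence.sum(axis=0).astype(float)
    weights = occupancy.copy()
    # OTUs never observed cannot enter a null assemblage
    weights[weights == 0] = 0.0
    if weights.sum() == 0:
        raise ValueError("all OTUs absent everywhere")

    obs_shared = (presence.astype(np.float32) @ presence.astype(np.float32).T)
    rng = np.random.default_rng(seed)
    greater = np.zeros((n, n), dtype=np.int64)
    ties = np.zeros((n, n), dtype=np.int64)
    col = np.arange(J)
    pos = weights > 0
    inv_w = np.zeros(J)
    inv_w[pos] = 1.0 / weights[pos]
    for _ in range(n_null):
        # weighted sampling without replacement (exponential sort keys),
        # vectorised across samples
        keys = np.full((n, J), np.inf)
        keys[:, pos] = rng.standard_exponential((n, pos.sum())) * inv_w[pos]
        order = np.argsort(keys, axis=1)
        mask = col[None, :] < richness[:, None]
        null = np.zeros((n, J), dtype=np.float32)
        np.put_along_axis(null, order, mask.astype(np.float32), axis=1)
        shared = null @ null.T
        greater += shared > obs_shared
        ties += shared == obs_shared
    dissim = (greater + 0.5 * ties) / n_null
    np.fill_diagonal(dissim, 0.0)
    empty = richness == 0
    if empty.any():
        logger.warning("%d sample(s) with zero richness set to dissimilarity 0.5", empty.sum())
        dissim[empty, :] = 0.5
        dissim[:, empty] = 0.5
        np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0
    if signed:
        off = ~np.eye(n, dtype=bool)
        dissim[off] = 2.0 * dissim[off] - 1.0
    return DistanceMatrix(dissim, matrix.sample_ids, metric_name="raup-crick")


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _design_matrix(predictor: np.ndarray, coding: str) -> np.ndarray:
    if coding == "numeric":
        x = predictor.astype(float)
        return np.column_stack([np.ones_like(x), x])
    # categorical: intercept + dummies for all but one level
    levels = pd.unique(predictor)
    cols = [np.ones(len(predictor))]
    for lv in levels[1:]:
        cols.append((predictor == lv).astype(float))
    return np.column_stack(cols)


def _pseudo_f(g: np.ndarray, x: np.ndarray) -> tuple[float, int, int]:
    n = g.shape[0]
    q, _ = np.linalg.qr(x)
    m = x.shape[1] - 1  # model df (intercept excluded)
    tr_total = float(np.trace(g))
    # tr(HG) with H = QQ^T; the intercept column contributes nothing to a
    # centred G but is kept for generality
    tr_model = float(np.einsum("ij,jk,ik->", q.T, g, q.T))
    ss_model = tr_model  # centred G: intercept part is ~0
    ss_resid = tr_total - ss_model
    df_resid = n - m - 1
    f = (ss_model / m) / (ss_resid / df_resid)
    return f, m, df_resid


def permanova(
    dist: DistanceMatrix,
    predictor,
    n_perm: int = 10000,
    seed: int = 0,
    coding: str | None = None,
) -> PermTestResult:
    """Distance-based permutational ANOVA (pseudo-F, label permutation).

    ``predictor`` is one value per sample, aligned with ``dist.ids``.
    Numeric predictors are fitted as a single regression slope (model
    df = 1); categorical ones as group dummies.  ``coding`` forces
    ``"numeric"`` or ``"categorical"``; by default numeric dtypes are
    treated as numeric.
    """
    pred = np.asarray(pd.Series(predictor).reindex(dist.ids).to_numpy()
                      if isinstance(predictor, (pd.Series, dict)) else predictor)
    if len(pred) != dist.n:
        raise ValueError("predictor length does not match distance matrix")
    if len(pd.unique(pred)) < 2:
        raise ValueError("predictor is constant")
    if coding is None:
        coding = "numeric" if np.issubdtype(np.asarray(pred).dtype, np.number) else "categorical"
    g = _gower_center(dist.data)
    x = _design_matrix(pred, coding)
    f_obs, df_model, df_resid = _pseudo_f(g, x)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(dist.n)
        f_perm, _, _ = _pseudo_f(g, _design_matrix(pred[perm], coding))
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermTestResult(
        statistic=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        permutation_seed=seed,
        extra={"df": (df_model, df_resid), "coding": coding},
    )


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------

def _pcoa_dispersion_distances(dist: DistanceMatrix, labels: np.ndarray) -> np.ndarray:
    """Per-sample distance to its group centroid in PCoA space.

    Axes with negative eigenvalues are kept as imaginary components whose
    squared contributions are subtracted; squared distances are clamped
    at zero before the square root (standard practice for non-Euclidean
    dissimilarities such as Raup-Crick).
    """
    g = _gower_center(dist.data)
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    keep = np.abs(eigval) > 1e-10
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    coords = eigvec * np.sqrt(np.abs(eigval))[None, :]
    positive = eigval > 0
    z = np.empty(dist.n)
    for lv in pd.unique(labels):
        idx = np.where(labels == lv)[0]
        centroid = coords[idx].mean(axis=0)
        delta2 = (coords[idx] - centroid) ** 2
        d2 = delta2[:, positive].sum(axis=1) - delta2[:, ~positive].sum(axis=1)
        z[idx] = np.sqrt(np.clip(d2, 0.0, None))
    return z


def _anova_f(values: np.ndarray, labels: np.ndarray) -> tuple[float, int, int]:
    levels = pd.unique(labels)
    n = len(values)
    k = len(levels)
    grand = values.mean()
    ss_between = sum(
        len(values[labels == lv]) * (values[labels == lv].mean() - grand) ** 2 for lv in levels
    )
    ss_within = sum(
        ((values[labels == lv] - values[labels == lv].mean()) ** 2).sum() for lv in levels
    )
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        return (math.inf if ss_between > 0 else 0.0), df_b, df_w
    return float((ss_between / df_b) / (ss_within / df_w)), df_b, df_w


def permdisp(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 10000,
    seed: int = 0,
) -> PermTestResult:
    """Permutation test for homogeneity of multivariate dispersions.

    Distances to group centroids are computed once in principal-coordinate
    space; the one-way F on those distances is then recomputed under
    permutations of the group labels.  Groups of size 1 are excluded with
    a warning; ten depth classes give the (9, n-10)-df test.
    """
    labels = np.asarray(pd.Series(groups).reindex(dist.ids).to_numpy()
                        if isinstance(groups, (pd.Series, dict)) else groups)
    if len(labels) != dist.n:
        raise ValueError("group labels do not match distance matrix")
    counts = pd.Series(labels).value_counts()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        logger.warning("excluding size-1 group(s) from dispersion test: %s", singletons)
        keep = ~pd.Series(labels).isin(singletons).to_numpy()
        idx = np.where(keep)[0]
        dist = DistanceMatrix(dist.data[np.ix_(idx, idx)], [dist.ids[i] for i in idx],
                              dist.metric_name)
        labels = labels[keep]
    if len(pd.unique(labels)) < 2:
        raise ValueError("need >= 2 groups with >= 2 members")
    z = _pcoa_dispersion_distances(dist, labels)
    f_obs, df_b, df_w = _anova_f(z, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_perm, _, _ = _anova_f(z, labels[rng.permutation(len(labels))])
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermTestResult(
        statistic=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        permutation_seed=seed,
        extra={"df": (df_b, df_w), "group_dispersions": {
            str(lv): float(z[labels == lv].mean()) for lv in pd.unique(labels)
        }},
    )


# ---------------------------------------------------------------------------
# Mantel correlogram
# ---------------------------------------------------------------------------

def mantel_correlogram(
    dist: DistanceMatrix,
    positions,
    n_classes: int | None = None,
    class_width: float | None = None,
    n_perm: int = 10000,
    seed: int = 0,
) -> list[PermTestResult]:
    """Mantel correlogram along a 1-D spatial axis.

    Geographic distances between samples are binned into equal-width
    classes (Sturges' rule on the number of pairs when ``n_classes`` and
    ``class_width`` are unset).  For each class the Mantel r between the
    community dissimilarity matrix and the class-membership indicator is
    tested by permuting sample order; the returned p-values carry a
    progressive Holm correction across classes in ``extra["p_corrected"]``.
    A negative r in a class means samples at that distance are *more*
    similar than average.  Classes with fewer than 2 pairs are omitted.
    """
    pos = np.asarray(pd.Series(positions).reindex(dist.ids).to_numpy()
                     if isinstance(positions, (pd.Series, dict)) else positions, dtype=float)
    n = dist.n
    if n < 3:
        raise ValueError("need at least 3 samples for a correlogram")
    if len(pos) != n:
        raise ValueError("positions do not match distance matrix")
    geo = np.abs(pos[:, None] - pos[None, :])
    tri = np.triu_indices(n, k=1)
    m = len(tri[0])
    if class_width is not None:
        edges = np.arange(0.0, geo[tri].max() + class_width, class_width)
        if edges[-1] <= geo[tri].max():
            edges = np.append(edges, geo[tri].max() + 1e-9)
    else:
        if n_classes is None:
            n_classes = int(np.ceil(1 + np.log2(m)))  # Sturges on the pair count
        edges = np.linspace(0.0, geo[tri].max() + 1e-9, n_classes + 1)

    rng = np.random.default_rng(seed)
    results: list[PermTestResult] = []
    d = dist.data

    classes = []  # (lo, hi, standardized member vector over pairs, n_pairs)
    for k in range(len(edges) - 1):
        lo, hi = edges[k], edges[k + 1]
        member = ((geo >= lo) & (geo < hi)).astype(float)
        np.fill_diagonal(member, 0.0)
        mv = member[tri]
        n_pairs = int(mv.sum())
        if n_pairs < 2 or mv.std() == 0:
            logger.info("distance class [%g, %g) has %d pair(s); omitted", lo, hi, n_pairs)
            continue
        mv = (mv - mv.mean()) / mv.std()
        classes.append((lo, hi, mv, n_pairs))

    def _std_pairs(mat: np.ndarray) -> np.ndarray:
        v = mat[tri]
        s = v.std()
        return np.zeros_like(v) if s == 0 else (v - v.mean()) / s

    d_std = _std_pairs(d)
    r_obs_all = np.array([float((d_std * mv).mean()) for _, _, mv, _ in classes])
    exceed_all = np.zeros(len(classes), dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        dp = _std_pairs(d[np.ix_(perm, perm)])
        r_perm = np.array([float((dp * mv).mean()) for _, _, mv, _ in classes])
        exceed_all += np.abs(r_perm) >= np.abs(r_obs_all) - 1e-12

    for idx, (lo, hi, _, n_pairs) in enumerate(classes):
        r_obs = float(r_obs_all[idx])
        p = (1 + int(exceed_all[idx])) / (1 + n_perm)
        results.append(
            PermTestResult(
                statistic=r_obs,
                p_value=float(p),
                n_permutations=n_perm,
                permutation_seed=seed,
                extra={"class_index": len(results), "lower": float(lo), "upper": float(hi),
                       "midpoint": float((lo + hi) / 2), "n_pairs": n_pairs},
            )
        )
    # progressive Holm correction: class k is corrected within classes 1..k
    for i, res in enumerate(results):
        ps = [r.p_value for r in results[: i + 1]]
        order = np.argsort(ps)
        holm = np.empty(len(ps))
        running = 0.0
        for rank, j in enumerate(order):
            running = max(running, (len(ps) - rank) * ps[j])
            holm[j] = min(1.0, running)
        res.extra["p_corrected"] = float(holm[i])
    return results
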