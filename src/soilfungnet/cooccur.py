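"""Compositionally aware co-occurrence inference between OTUs.

Sequencing read counts carry only relative information, so naive
correlations between relative abundances are biased (they must sum to a
constraint).  Two estimators that address this are implemented from their
definitions:

* :func:`estimate_sparcc` - log-ratio-variance basis correlations: from
  pairwise variances of log-ratios t_ij = Var(log(x_i / x_j)) the latent
  (basis) variances w_i are solved under a sparsity assumption, giving
  basis correlations r_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)).
  Strongly correlated pairs are iteratively excluded from the averaging
  and the procedure is repeated over Dirichlet resamples of the
  compositions, taking the median.
* :func:`estimate_mb` - neighbourhood selection: after a centred
  log-ratio transform, each OTU is regressed on all others with an L1
  penalty; edges are the selected neighbourhoods (OR rule by default)
  with the regularisation strength chosen by StARS-style stability
  selection over random subsamples.

:func:`threshold_to_graph` turns a correlation estimate into a signed
association network at a fixed absolute-correlation cutoff (0.4 by
default, the conventional choice for these data).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from .io import CommunityMatrix

__all__ = [
    "CorrelationEstimate",
    "AssociationGraph",
    "estimate_sparcc",
    "clr_transform",
    "estimate_mb",
    "threshold_to_graph",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationEstimate:
    """Estimated basis correlations (OTUs x OTUs) and basis variances."""

    rho: pd.DataFrame
    basis_variance: pd.Series
    n_resamples: int
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        r = self.rho.to_numpy()
        if not np.allclose(r, r.T, atol=1e-9):
            raise ValueError("correlation matrix is not symmetric")
        if np.any(np.abs(r) > 1 + 1e-9):
            raise ValueError("correlations exceed [-1, 1]")


@dataclass
class AssociationGraph:
    """Signed, weighted, undirected association network over OTUs."""

    nodes: list[str]
    edges: list[tuple[str, str, float, str]]  # (otu_a, otu_b, weight, sign)
    method: str = "log-ratio-correlation"
    depth_class: str | None = None
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        seen = set()
        canon = []
        for a, b, w, sign in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if sign not in ("+", "-"):
                raise ValueError(f"edge sign must be '+' or '-', got {sign!r}")
            if (sign == "+") != (w > 0):
                raise ValueError(f"edge ({a}, {b}) sign {sign!r} inconsistent with weight {w}")
            key = tuple(sorted((a, b)))
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
            node_set.update(key)
            canon.append((key[0], key[1], float(w), sign))
        self.nodes = sorted(node_set)
        self.edges = sorted(canon, key=lambda e: (e[0], e[1]))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def filter_sign(self, sign: str) -> "AssociationGraph":
        if sign not in ("+", "-"):
            raise ValueError("sign must be '+' or '-'")
        edges = [e for e in self.edges if e[3] == sign]
        nodes = sorted({e[0] for e in edges} | {e[1] for e in edges})
        return AssociationGraph(
            nodes=nodes, edges=edges, method=self.method,
            depth_class=self.depth_class, threshold_used=self.threshold_used,
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(method=self.method)
        g.add_nodes_from(self.nodes)
        for a, b, w, sign in self.edges:
            g.add_edge(a, b, weight=w, sign=sign)
        return g


# ---------------------------------------------------------------------------
# log-ratio-variance basis correlations
# ---------------------------------------------------------------------------

def _solve_basis_variances(t: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Solve the sparsity-assuming linear system for basis variances.

    For OTU i with active partner set J_i:  sum_{j in J_i} t_ij =
    |J_i| w_i + sum_{j in J_i} w_j  (correlation terms dropped under the
    sparsity assumption).
    """
    a = active.astype(float)
    np.fill_diagonal(a, 0.0)
    lhs = np.diag(a.sum(axis=1)) + a
    rhs = (t * a).sum(axis=1)
    omega, *_ = np.linalg.lstsq(lhs, rhs, rcond=None)
    return np.clip(omega, 1e-10, None)


def _basis_correlations(
    t: np.ndarray, n_exclusion_iters: int, exclusion_threshold: float
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    d = t.shape[0]
    active = np.ones((d, d), dtype=bool)
    np.fill_diagonal(active, False)
    excluded: list[tuple[int, int]] = []
    for _ in range(n_exclusion_iters + 1):
        omega = _solve_basis_variances(t, active)
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        rho = (omega[:, None] + omega[None, :] - t) / denom
        np.fill_diagonal(rho, 1.0)
        if len(excluded) >= n_exclusion_iters:
            break
        masked = np.where(active, np.abs(rho), 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        active[i, j] = active[j, i] = False
        excluded.append((min(i, j), max(i, j)))
    return np.clip(rho, -1.0, 1.0), omega, excluded


def estimate_sparcc(
    matrix: CommunityMatrix,
    n_resamples: int = 20,
    n_exclusion_iters: int = 10,
    exclusion_threshold: float = 0.1,
    seed: int = 0,
) -> CorrelationEstimate:
    """Basis correlations from log-ratio variances with Dirichlet resampling.

    Each resample converts counts to compositions by a posterior draw
    from Dirichlet(counts + 1) per sample, computes all pairwise
    log-ratio variances, solves for basis variances under sparsity with
    iterative exclusion of the most correlated pairs, and the final
    estimate is the elementwise median over resamples, clamped to
    [-1, 1].  Input should be an unrarefied, prevalence-filtered,
    single-depth count matrix.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    n, d = counts.shape
    if d < 4:
        raise ValueError(f"need >= 4 OTUs for an identifiable basis-variance system, got {d}")
    constant = counts.std(axis=0) == 0
    if constant.any():
        bad = [matrix.otu_ids[k] for k in np.where(constant)[0]]
        logger.warning("excluding %d zero-variance OTU(s): %s", len(bad), bad[:5])
        keep = [o for o, c in zip(matrix.otu_ids, constant) if not c]
        return estimate_sparcc(
            matrix.subset(otu_ids=keep), n_resamples, n_exclusion_iters,
            exclusion_threshold, seed,
        )
    rng = np.random.default_rng(seed)
    rhos = np.empty((n_resamples, d, d))
    excluded_all: set[tuple[int, int]] = set()
    omega_last = None
    for r in range(n_resamples):
        gamma = rng.standard_gamma(counts + 1.0)
        comp = gamma / gamma.sum(axis=1, keepdims=True)
        logs = np.log(comp)
        cov = np.cov(logs, rowvar=False)
        var = np.diag(cov)
        t = var[:, None] + var[None, :] - 2.0 * cov
        rho, omega_last, excluded = _basis_correlations(
            t, n_exclusion_iters, exclusion_threshold
        )
        excluded_all.update(excluded)
        rhos[r] = rho
    rho_med = np.median(rhos, axis=0)
    rho_med = np.clip((rho_med + rho_med.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho_med, 1.0)
    otus = matrix.otu_ids
    return CorrelationEstimate(
        rho=pd.DataFrame(rho_med, index=otus, columns=otus),
        basis_variance=pd.Series(omega_last, index=otus, name="basis_variance"),
        n_resamples=n_resamples,
        excluded_pairs=sorted((otus[i], otus[j]) for i, j in excluded_all),
        seed=seed,
    )


def clr_transform(matrix: CommunityMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centred log-ratio transform: log(count + pseudocount) minus the
    sample's mean log.  Every output row sums to zero."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logs = np.log(matrix.counts.to_numpy(dtype=float) + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=matrix.sample_ids, columns=matrix.otu_ids)


# ---------------------------------------------------------------------------
# neighbourhood selection with stability selection
# ---------------------------------------------------------------------------

def _neighborhood_coefs(z: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """L1-regularised neighbourhood regressions for every node.

    Returns coefs[a, i, j]: coefficient of predictor j in node i's
    regression at alphas[a] (coefs[a, i, i] = 0).
    """
    n, d = z.shape
    out = np.zeros((len(alphas), d, d))
    idx = np.arange(d)
    for i in range(d):
        x = z[:, idx != i]
        y = z[:, i]
        # lasso_path requires decreasing alphas
        order = np.argsort(alphas)[::-1]
        _, coefs, _ = lasso_path(x, y, alphas=alphas[order])
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        coefs = coefs[:, inv]  # back to caller's alpha order
        out[:, i, idx != i] = coefs.T
    return out


def estimate_mb(
    matrix: CommunityMatrix,
    lambda_grid: np.ndarray | None = None,
    stability_reps: int = 50,
    stability_subsample: float | None = None,
    stars_threshold: float = 0.05,
    rule: str = "OR",
    pseudocount: float = 1.0,
    seed: int = 0,
    depth_class: str | None = None,
) -> AssociationGraph:
    """Sparse conditional-dependence graph via neighbourhood selection.

    CLR-transformed abundances are fitted with per-node lasso regressions
    over a penalty grid; the penalty is chosen by StARS-style stability
    selection (the least regularisation whose average edge instability
    over random subsamples stays below ``stars_threshold``).  Edge signs
    come from the sign of the averaged selected coefficients.

    ``stability_subsample`` is the subsample fraction; the default
    (``None``) follows the stability-selection convention of 0.8 for
    n <= 144 and 10*sqrt(n)/n for larger n, so that subsamples stay
    genuinely perturbing as n grows.
    """
    if rule not in ("OR", "AND"):
        raise ValueError("rule must be 'OR' or 'AND'")
    if lambda_grid is None:
        lambda_grid = np.logspace(-3, 0, 30)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid is empty")
    counts = matrix.counts
    n, d = counts.shape
    if d < 2:
        raise ValueError("need >= 2 OTUs")
    if n < 10:
        raise ValueError(f"need >= 10 samples, got {n}")
    z_full = clr_transform(matrix, pseudocount).to_numpy()
    z_full = z_full - z_full.mean(axis=0, keepdims=True)

    rng = np.random.default_rng(seed)
    if stability_subsample is None:
        stability_subsample = 0.8 if n <= 144 else 10.0 * math.sqrt(n) / n
    b = max(2, min(n - 1, int(round(stability_subsample * n))))
    freq = np.zeros((len(lambda_grid), d, d))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lasso convergence chatter on tiny penalties
        for _ in range(stability_reps):
            rows = rng.choice(n, size=b, replace=False)
            z = z_full[rows] - z_full[rows].mean(axis=0, keepdims=True)
            coefs = _neighborhood_coefs(z, lambda_grid)
            sel = coefs != 0.0
            if rule == "OR":
                adj = sel | sel.transpose(0, 2, 1)
            else:
                adj = sel & sel.transpose(0, 2, 1)
            freq += adj
        theta = freq / stability_reps
        iu = np.triu_indices(d, k=1)
        instability = (2.0 * theta * (1.0 - theta))[:, iu[0], iu[1]].mean(axis=1)

        # StARS: scan from strongest penalty down, monotonise instability,
        # pick the weakest penalty still below the threshold
        order = np.argsort(lambda_grid)[::-1]
        monotone = np.maximum.accumulate(instability[order])
        admissible = order[monotone <= stars_threshold]
        if admissible.size == 0:
            logger.warning("no penalty met the stability threshold; returning empty graph")
            return AssociationGraph(
                nodes=matrix.otu_ids, edges=[], method="neighborhood-selection",
                depth_class=depth_class, threshold_used=None,
            )
        chosen = admissible[-1]  # last admissible while descending = smallest lambda
        alpha = float(lambda_grid[chosen])

        coefs = _neighborhood_coefs(z_full, np.array([alpha]))[0]
    sel = coefs != 0.0
    adj = (sel | sel.T) if rule == "OR" else (sel & sel.T)
    weight = (coefs + coefs.T) / 2.0
    otus = matrix.otu_ids
    edges = []
    for i, j in zip(*np.triu_indices(d, k=1)):
        if adj[i, j]:
            w = float(weight[i, j])
            if w == 0.0:
                # selected but averaged to zero: take the nonzero direction
                w = float(coefs[i, j] if coefs[i, j] != 0 else coefs[j, i])
            edges.append((otus[i], otus[j], w, "+" if w > 0 else "-"))
    return AssociationGraph(
        nodes=otus, edges=edges, method="neighborhood-selection",
        depth_class=depth_class, threshold_used=alpha,
    )


def threshold_to_graph(
    est: CorrelationEstimate,
    cutoff: float = 0.4,
    sign: str = "both",
    depth_class: str | None = None,
) -> AssociationGraph:
    """Signed association network from correlations at an absolute cutoff.

    Edges are pairs with |rho| >= cutoff; ``sign`` restricts to
    ``"positive"``, ``"negative"`` or keeps ``"both"``.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie strictly between 0 and 1")
    if sign not in ("positive", "negative", "both"):
        raise ValueError("sign must be 'positive', 'negative' or 'both'")
    rho = est.rho.to_numpy()
    otus = list(est.rho.columns)
    edges = []
    d = len(otus)
    for i in range(d):
        for j in range(i + 1, d):
            r = float(rho[i, j])
            if abs(r) < cutoff:
                continue
            if sign == "positive" and r <= 0:
                continue
            if sign == "negative" and r >= 0:
                continue
            edges.append((otus[i], otus[j], r, "+" if r > 0 else "-"))
    return AssociationGraph(
        nodes=otus, edges=edges, method="log-ratio-correlation",
        depth_class=depth_class, threshold_used=cutoff,
    )
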