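"""Reference-free methylome deconvolution by regularized NMF.

A bulk beta-value matrix D (features x samples, entries in [0, 1]) is
factorized into latent methylation components T (features x k, entries in
[0, 1]) and mixing proportions A (k x samples, columns on the probability
simplex) by minimizing

    || D - T A ||_F^2  +  lambda * sum_jc T_jc (1 - T_jc)

The penalty pushes component methylomes towards the biologically expected
0/1 poles.  Optimization alternates an exact per-entry box-constrained
quadratic update for T (interior stationary point and both bounds are
evaluated, so each coordinate step is a global scalar minimizer) with
simplex-projected gradient descent on the columns of A (convex quadratic,
step 1/L, monotone).  The objective is therefore non-increasing at every
alternating step; this is asserted at run time.  Multiple random restarts
guard against local minima; the best final objective wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

_MONOTONE_TOL = 1e-9


def _project_simplex_columns(A: np.ndarray) -> np.ndarray:
    """Euclidean projection of each column onto the probability simplex."""
    k, n = A.shape
    u = np.sort(A, axis=0)[::-1]
    css = np.cumsum(u, axis=0) - 1.0
    ind = np.arange(1, k + 1)[:, None]
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[::-1], axis=0) - 1
    theta = css[rho, np.arange(n)] / (rho + 1.0)
    return np.maximum(A - theta, 0.0)


def _objective(D, T, A, lam, W=None) -> float:
    R = D - T @ A
    if W is not None:
        R = R * W
    return float(np.sum(R * R) + lam * np.sum(T * (1.0 - T)))


def _update_A(D, T, A, W=None, n_inner: int = 40, tol: float = 1e-10) -> np.ndarray:
    """Simplex-projected gradient descent on the quadratic A-subproblem.

    All columns are updated jointly: with 0/1 weights each column's
    Hessian T' diag(w) T is dominated by T' T, so the step 1 / (2 L) with
    L the largest eigenvalue of T' T is a valid monotone step for every
    column, masked or not.
    """
    L = max(np.linalg.eigvalsh(T.T @ T)[-1], 1e-12)
    prev = None
    for _ in range(n_inner):
        R = T @ A - D
        if W is not None:
            R = R * W
        A = _project_simplex_columns(A - (T.T @ R) / L)
        cur = float(np.sum(R * R))
        if prev is not None and prev - cur < tol * (1.0 + prev):
            break
        prev = cur
    return A


def _update_T(D, T, A, lam, W=None) -> np.ndarray:
    """Exact coordinate minimization of T over [0, 1], one component at a time.

    For entry (j, c) the objective is the scalar quadratic
    a t^2 + b t + const with a = sum_i w_ji A_ci^2 - lambda.  The interior
    stationary point (when a > 0) and both bounds are candidates; the
    minimizer is selected per entry, so the step never increases the
    objective.
    """
    T = T.copy()
    E = D - T @ A  # residual, kept in sync
    if W is not None:
        Wm = W
    for c in range(T.shape[1]):
        u = A[c, :]
        t_old = T[:, c]
        if W is None:
            s = float(u @ u) * np.ones(T.shape[0])
            b = -2.0 * ((E + np.outer(t_old, u)) @ u) + lam
        else:
            s = Wm @ (u * u)
            b = -2.0 * (((E + np.outer(t_old, u)) * Wm) @ u) + lam
        a = s - lam
        cand = np.empty((T.shape[0], 3))
        with np.errstate(divide="ignore", invalid="ignore"):
            interior = np.where(a > 0, -b / (2.0 * a), 0.0)
        cand[:, 0] = np.clip(interior, 0.0, 1.0)
        cand[:, 1] = 0.0
        cand[:, 2] = 1.0
        vals = a[:, None] * cand**2 + b[:, None] * cand
        t_new = cand[np.arange(T.shape[0]), np.argmin(vals, axis=1)]
        E += np.outer(t_old - t_new, u)
        T[:, c] = t_new
    return T


@dataclass
class DeconvolutionResult:
    """Factorization output: components, proportions and diagnostics."""

    T: np.ndarray
    A: np.ndarray
    k: int
    lam: float
    objective_trace: list[float]
    restarts_used: int
    seed: int
    feature_ids: list | None = None
    sample_ids: list | None = None

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]


def deconvolute(
    D: np.ndarray | pd.DataFrame,
    k: int,
    lam: float = 1.0,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-7,
    mask: np.ndarray | None = None,
) -> DeconvolutionResult:
    """Factorize a bulk methylation matrix into k components.

    ``D`` must be finite with entries in [0, 1] (rows with missing values
    are the caller's responsibility; ``mask`` optionally marks entries to
    include in the fit, for cross-validation).  Restarts draw T from
    Uniform(0, 1) and A columns from Dirichlet(1); each restart runs
    alternating minimization until the relative objective decrease falls
    below ``tol`` or ``max_iter`` iterations; the restart with the best
    final objective is returned.  Deterministic given ``seed``.
    """
    feature_ids = sample_ids = None
    if isinstance(D, pd.DataFrame):
        feature_ids = list(D.index)
        sample_ids = list(D.columns)
        D = D.to_numpy(dtype=float)
    D = np.asarray(D, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("D must be finite (drop or impute missing rows upstream)")
    if D.min() < 0 or D.max() > 1:
        raise ValueError("D entries must lie in [0, 1]")
    m, n = D.shape
    if k < 1 or k > min(m, n):
        raise ValueError(f"k must be in [1, {min(m, n)}]")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    W = None if mask is None else np.asarray(mask, dtype=float)

    root = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x6D6F6D])
    restart_seeds = root.integers(0, 2**31 - 1, size=n_restarts)

    best: DeconvolutionResult | None = None
    for r, rs in enumerate(restart_seeds):
        rng = np.random.default_rng(rs)
        T = rng.uniform(0.0, 1.0, size=(m, k))
        A = rng.dirichlet(np.ones(k), size=n).T
        trace = [_objective(D, T, A, lam, W)]
        for _ in range(max_iter):
            A = _update_A(D, T, A, W)
            obj_a = _objective(D, T, A, lam, W)
            if obj_a > trace[-1] + _MONOTONE_TOL * (1.0 + abs(trace[-1])):
                raise RuntimeError("objective increased in A-step")
            T = _update_T(D, T, A, lam, W)
            obj_t = _objective(D, T, A, lam, W)
            if obj_t > obj_a + _MONOTONE_TOL * (1.0 + abs(obj_a)):
                raise RuntimeError("objective increased in T-step")
            trace.append(obj_t)
            if trace[-2] - trace[-1] < tol * (1.0 + trace[-2]):
                break
        if best is None or trace[-1] < best.objective:
            best = DeconvolutionResult(
                T=T, A=A, k=k, lam=lam, objective_trace=trace,
                restarts_used=r + 1, seed=int(seed),
                feature_ids=feature_ids, sample_ids=sample_ids,
            )
    assert best is not None
    best.restarts_used = n_restarts
    return best


def match_components_to_truth(
    A_est: np.ndarray, A_true: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal component permutation (Hungarian on proportion correlation).

    Returns (permutation applied to the estimated components, permuted
    A_est).  Used to resolve the permutation ambiguity before comparing a
    factorization to simulation truth.
    """
    from scipy.optimize import linear_sum_assignment

    k = A_true.shape[0]
    C = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            C[i, j] = -np.corrcoef(A_true[i], A_est[j])[0, 1]
    _, perm = linear_sum_assignment(np.nan_to_num(C, nan=1.0))
    return perm, A_est[perm]


def select_model(
    D: np.ndarray | pd.DataFrame,
    k_grid: Sequence[int],
    lambda_grid: Sequence[float],
    folds: int = 3,
    seed: int = 0,
    holdout_fraction: float = 0.10,
    n_restarts: int = 2,
    max_iter: int = 60,
) -> tuple[int, float, pd.DataFrame]:
    """Choose (k, lambda) by masked-entry cross-validation.

    Each fold hides a random ``holdout_fraction`` of entries, fits on the
    rest (masked objective) and scores the reconstruction RMSE on the
    hidden entries.  The pair minimizing the mean RMSE wins; ties go to
    the smaller k, then the larger lambda.  Deterministic given ``seed``.
    """
    if len(k_grid) == 0 or len(lambda_grid) == 0:
        raise ValueError("grids must be non-empty")
    if isinstance(D, pd.DataFrame):
        D = D.to_numpy(dtype=float)
    D = np.asarray(D, dtype=float)
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xCF])
    masks = []
    for _ in range(folds):
        hide = rng.random(D.shape) < holdout_fraction
        if not hide.any() or hide.all():
            raise ValueError("degenerate holdout mask")
        masks.append(~hide)

    rows = []
    for k in k_grid:
        for lam in lambda_grid:
            rmses = []
            for f, keep in enumerate(masks):
                res = deconvolute(
                    D, k=k, lam=lam, n_restarts=n_restarts,
                    seed=int(rng.integers(2**31 - 1)), max_iter=max_iter,
                    mask=keep,
                )
                recon = res.T @ res.A
                hidden = ~keep
                rmses.append(
                    float(np.sqrt(np.mean((recon[hidden] - D[hidden]) ** 2)))
                )
            rows.append({"k": k, "lambda": lam, "cv_rmse": float(np.mean(rmses))})
    table = pd.DataFrame(rows)
    # ties -> smaller k, then larger lambda
    order = table.sort_values(
        by=["cv_rmse", "k", "lambda"], ascending=[True, True, False],
        kind="mergesort",
    )
    bestrow = order.iloc[0]
    return int(bestrow["k"]), float(bestrow["lambda"]), table


def match_components(
    T: pd.DataFrame, references: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Correlate each component with each reference methylome.

    ``T`` (features x components) and ``references`` (features x
    reference methylomes) are joined on their shared features (>= 100
    required).  Pearson correlations are tested (two-sided), BH-adjusted
    over all (component, reference) pairs; a call of ``positive`` /
    ``negative`` is made only below ``alpha``, otherwise ``none``.

    Also performs average-linkage hierarchical clustering of components
    and references jointly on 1 - correlation distance; returns
    (match table, linkage matrix, column labels in linkage order).
    """
    shared = T.index.intersection(references.index)
    if len(shared) < 100:
        raise ValueError(f"only {len(shared)} shared features; need >= 100")
    Tm = T.loc[shared]
    Rm = references.loc[shared]

    rows = []
    for lmc in Tm.columns:
        for ref in Rm.columns:
            r, p = stats.pearsonr(Tm[lmc], Rm[ref])
            rows.append({"lmc": lmc, "reference": ref, "correlation": float(r), "p": float(p)})
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    table["call"] = np.where(
        table["p_adj"] > alpha, "none", np.where(table["correlation"] > 0, "positive", "negative")
    )

    joint = pd.concat([Tm, Rm], axis=1)
    corr = np.corrcoef(joint.to_numpy(dtype=float).T)
    dist = 1.0 - corr
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    return table, Z, list(joint.columns)


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{0.0:.6g}"
        left, right = node.get_left(), node.get_right()
        bl_l = node.dist - (left.dist if not left.is_leaf() else 0.0)
        bl_r = node.dist - (right.dist if not right.is_leaf() else 0.0)

        def with_len(child, bl):
            s = rec(child)
            base = s.rsplit(":", 1)[0] if child.is_leaf() else s.rsplit(":", 1)[0]
            return f"{base}:{bl:.6g}"

        return f"({with_len(left, bl_l)},{with_len(right, bl_r)}):0"

    s = rec(tree)
    return s.rsplit(":", 1)[0] + ";"


def compare_proportions_by_group(
    proportions: pd.Series, labels: pd.DataFrame
) -> pd.DataFrame:
    """Wilcoxon rank-sum of one component's proportions across binary labels.

    ``proportions`` is one row of A indexed by sample; ``labels`` holds
    one binary categorical column per clinical variable (same sample
    index).  Labels with fewer than two samples per level, or not exactly
    two levels, are skipped.  Medians per level and BH-adjusted p-values
    across labels are reported.
    """
    rows = []
    for col in labels.columns:
        lab = labels[col].dropna()
        common = proportions.index.intersection(lab.index)
        lab = lab.loc[common]
        levels = sorted(lab.unique(), key=str)
        if len(levels) != 2:
            continue
        x = proportions.loc[lab.index[lab == levels[0]]].to_numpy(dtype=float)
        y = proportions.loc[lab.index[lab == levels[1]]].to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            continue
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append(
            {
                "label": col,
                "level_A": levels[0], "level_B": levels[1],
                "n_A": len(x), "n_B": len(y),
                "median_A": float(np.median(x)), "median_B": float(np.median(y)),
                "statistic": float(stat), "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
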