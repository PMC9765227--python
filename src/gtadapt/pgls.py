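"""Phylogenetic generalized least squares with Pagel lambda/delta/kappa
branch-length transformations estimated by maximum likelihood.

The error covariance of a Brownian trait on a rooted tree is
``C[i, j] = shared root-to-tip path length of tips i and j``.  The three
Pagel transformations act in the standard order: kappa raises each branch
length to a power (kappa -> 0 is the punctuational model), the covariance
is rebuilt, delta raises every covariance entry to a power (depth scaling),
and lambda multiplies the off-diagonal entries (phylogenetic signal).

The model follows the statsmodels idiom: :class:`PGLS` is built from data
and a tree, and ``fit()`` returns a :class:`PGLSResults` carrying the
estimates, their uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

logger = logging.getLogger(__name__)

DELTA_MAX = 3.0
KAPPA_MAX = 3.0
_EPS = 1e-4  # open lower bound for delta and kappa

#: multi-start points (lambda, delta, kappa) for the ML search
DEFAULT_STARTS = ((1.0, 1.0, 1.0), (0.0, 1.0, 1.0), (0.5, 1.0, 1.0))


class SingularCovarianceError(np.linalg.LinAlgError):
    pass


# ---------------------------------------------------------------------------
# Tree -> covariance machinery


@dataclass(frozen=True)
class TreeStructure:
    """Edge decomposition of a (pruned) tree over a fixed tip order.

    ``incidence`` is tips x edges 0/1; edge e contributes ``lengths[e]`` to
    C[i, j] whenever tips i and j both descend from it, so
    ``C = incidence @ diag(lengths**kappa) @ incidence.T``.
    """

    labels: tuple[str, ...]
    incidence: np.ndarray
    lengths: np.ndarray

    def covariance(self, kappa: float = 1.0) -> np.ndarray:
        lens = self.lengths if kappa == 1.0 else self.lengths ** kappa
        return (self.incidence * lens) @ self.incidence.T

    def prune(self, tips: set[str] | list[str]) -> "TreeStructure":
        """Restrict to a tip subset, merging serial edges and dropping the
        new stem (edges above the subset's MRCA), exactly as pruning the
        tree and suppressing unifurcations would."""
        keep = sorted(tips)
        index = {lab: i for i, lab in enumerate(self.labels)}
        missing = [t for t in keep if t not in index]
        if missing:
            raise KeyError(f"tips not in tree: {missing}")
        rows = self.incidence[[index[t] for t in keep]]
        n = len(keep)
        colsum = rows.sum(axis=0)
        active = (colsum > 0) & (colsum < n)  # drop empty edges and the stem
        rows = rows[:, active]
        lengths = self.lengths[active]
        # merge edges subtending the same tip subset (serial after pruning)
        patterns: dict[bytes, int] = {}
        merged_cols = []
        merged_lens = []
        for e in range(rows.shape[1]):
            key = rows[:, e].tobytes()
            if key in patterns:
                merged_lens[patterns[key]] += lengths[e]
            else:
                patterns[key] = len(merged_cols)
                merged_cols.append(rows[:, e])
                merged_lens.append(lengths[e])
        return TreeStructure(
            labels=tuple(keep),
            incidence=np.column_stack(merged_cols) if merged_cols else np.zeros((n, 0)),
            lengths=np.asarray(merged_lens, dtype=float),
        )


def tree_structure(tree: dendropy.Tree) -> TreeStructure:
    """Edge decomposition of a rooted dendropy tree (root stem excluded).

    Tips are ordered by sorted label; branch lengths must be >= 0.
    """
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    index = {lab: i for i, lab in enumerate(leaves)}
    cols = []
    lens = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length
        if length is None:
            raise ValueError("tree has a branch without a length")
        if length < 0:
            raise ValueError("tree has a negative branch length")
        below = np.zeros(len(leaves))
        for lf in node.leaf_iter():
            below[index[lf.taxon.label]] = 1.0
        cols.append(below)
        lens.append(float(length))
    incidence = np.column_stack(cols) if cols else np.zeros((len(leaves), 0))
    return TreeStructure(tuple(leaves), incidence, np.asarray(lens))


@dataclass(frozen=True)
class PhyloCovariance:
    """Brownian covariance over a tip set (sorted label order)."""

    labels: tuple[str, ...]
    matrix: np.ndarray


def covariance_from_tree(
    tree: dendropy.Tree, tips: list[str] | set[str] | None = None
) -> PhyloCovariance:
    """C[i, j] = shared root-to-tip path length, after pruning to ``tips``."""
    structure = tree_structure(tree)
    if tips is not None:
        if len(set(tips)) < 3:
            raise ValueError("need at least 3 tips for a phylogenetic covariance")
        structure = structure.prune(set(tips))
    return PhyloCovariance(structure.labels, structure.covariance())


def pagel_transform_covariance(
    structure: TreeStructure, lam: float, delta: float, kappa: float
) -> np.ndarray:
    """Apply kappa (branches), then delta (covariance entries), then lambda
    (off-diagonal scaling) to the structure's Brownian covariance."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda={lam} outside [0, 1]")
    if not 0.0 < delta <= DELTA_MAX:
        raise ValueError(f"delta={delta} outside (0, {DELTA_MAX}]")
    if not 0.0 < kappa <= KAPPA_MAX:
        raise ValueError(f"kappa={kappa} outside (0, {KAPPA_MAX}]")
    C = structure.covariance(kappa)
    if delta != 1.0:
        C = np.where(C > 0, C, 0.0) ** delta
    if lam != 1.0:
        diag = np.diag(C).copy()
        C = lam * C
        np.fill_diagonal(C, diag)
    return C


def transform_pagel(
    tree: dendropy.Tree,
    lam: float,
    delta: float,
    kappa: float,
    tips: list[str] | set[str] | None = None,
) -> PhyloCovariance:
    structure = tree_structure(tree)
    if tips is not None:
        structure = structure.prune(set(tips))
    return PhyloCovariance(
        structure.labels, pagel_transform_covariance(structure, lam, delta, kappa)
    )


_RIDGE_WARNED = False


def _cholesky_with_ridge(C: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor; on failure add a single small ridge and warn."""
    try:
        return linalg.cholesky(C, lower=True)
    except linalg.LinAlgError:
        ridge = 1e-8 * float(np.mean(np.diag(C)))
        global _RIDGE_WARNED
        if not _RIDGE_WARNED:
            logger.warning("covariance singular; adding ridge %.3g "
                           "(further occurrences logged at DEBUG)", ridge)
            _RIDGE_WARNED = True
        else:
            logger.debug("covariance singular; adding ridge %.3g", ridge)
        try:
            return linalg.cholesky(C + ridge * np.eye(len(C)), lower=True)
        except linalg.LinAlgError as exc:
            dup = _closest_pair(C)
            raise SingularCovarianceError(
                f"covariance is singular even after ridge; tips {dup[0]!r} and "
                f"{dup[1]!r} are phylogenetically indistinguishable"
            ) from exc


def _closest_pair(C: np.ndarray) -> tuple[int, int]:
    d = np.diag(C)
    dist = d[:, None] + d[None, :] - 2 * C
    np.fill_diagonal(dist, np.inf)
    i, j = divmod(int(np.argmin(dist)), len(C))
    return i, j


# ---------------------------------------------------------------------------
# GLS core


@dataclass
class GLSFit:
    slope: float
    intercept: float
    slope_se: float
    sigma2: float
    loglik: float
    slope_p: float
    nobs: int


def _gls_core(x: np.ndarray, y: np.ndarray, L: np.ndarray) -> GLSFit:
    """GLS of y on [1, x] given the lower Cholesky factor of the covariance."""
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    xtx = Xw.T @ Xw
    try:
        xtx_inv = linalg.inv(xtx)
    except linalg.LinAlgError as exc:
        raise ValueError("predictor has no variance") from exc
    beta = xtx_inv @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    # floor the ML variance so an exact linear relation (sigma2 = 0) yields a
    # huge but finite likelihood instead of breaking the optimizer
    sigma2_ml = max(rss / n, 1e-300)
    loglik = -0.5 * (n * (np.log(2 * np.pi * sigma2_ml) + 1.0) + logdet)
    df = n - 2
    sigma2 = rss / df if df > 0 else np.nan
    se = float(np.sqrt(max(sigma2, 0.0) * xtx_inv[1, 1]))
    slope = float(beta[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = slope / se if se > 0 else np.inf * np.sign(slope or 1.0)
    slope_p = float(2.0 * stats.t.sf(abs(tval), df)) if df > 0 else np.nan
    return GLSFit(slope, float(beta[0]), se, float(sigma2), float(loglik),
                  slope_p, n)


def gls_fit(x: np.ndarray, y: np.ndarray, C: np.ndarray | PhyloCovariance) -> GLSFit:
    """One GLS regression of y on x under a fixed covariance.

    With ``C`` the identity this reduces exactly to ordinary least squares
    and the classical t-test on the slope.
    """
    if isinstance(C, PhyloCovariance):
        C = C.matrix
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) != len(C):
        raise ValueError("x, y and C must cover the same tips")
    if len(x) < 3:
        raise ValueError("need at least 3 tips")
    if np.allclose(x, x[0]):
        raise ValueError("predictor has no variance")
    return _gls_core(x, y, _cholesky_with_ridge(np.asarray(C, dtype=float)))


# ---------------------------------------------------------------------------
# The model / results pair


class PGLS:
    """Phylogenetic GLS regression model of one trait on another.

    Parameters
    ----------
    y, x : array-like
        Per-tip response and predictor, aligned with ``labels``.
    tree : dendropy.Tree or TreeStructure
        Rooted phylogeny with branch lengths; it is pruned to ``labels``.
    labels : sequence of str
        Tip labels for the rows of ``y``/``x``.
    """

    def __init__(self, y, x, tree, labels) -> None:
        labels = list(labels)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        if len(labels) < 3:
            raise ValueError("need at least 3 shared tips")
        y = np.asarray(y, dtype=float)
        x = np.asarray(x, dtype=float)
        if not (np.isfinite(y).all() and np.isfinite(x).all()):
            raise ValueError("x and y must be finite")
        if np.allclose(x, x[0]):
            raise ValueError("predictor has no variance")
        structure = tree if isinstance(tree, TreeStructure) else tree_structure(tree)
        structure = structure.prune(set(labels))
        order = {lab: i for i, lab in enumerate(labels)}
        perm = [order[lab] for lab in structure.labels]
        self.structure = structure
        self.endog = y[perm]
        self.exog = x[perm]
        self.labels = structure.labels
        self._kappa_cache: tuple[float, np.ndarray] | None = None

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, ycol: str, xcol: str, tree) -> "PGLS":
        """Build from a DataFrame indexed by tip label; rows with missing
        values in either column are dropped."""
        sub = data[[ycol, xcol]].dropna()
        return cls(sub[ycol].to_numpy(), sub[xcol].to_numpy(), tree, list(sub.index))

    def loglik(self, lam: float, delta: float, kappa: float) -> float:
        """Profile log-likelihood at fixed transformation parameters."""
        # memoize the kappa-transformed Brownian covariance: finite-difference
        # gradients perturb one parameter at a time, so kappa is often reused
        if self._kappa_cache is not None and self._kappa_cache[0] == kappa:
            base = self._kappa_cache[1]
        else:
            base = self.structure.covariance(kappa)
            self._kappa_cache = (kappa, base)
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda={lam} outside [0, 1]")
        if not 0.0 < delta <= DELTA_MAX or not 0.0 < kappa <= KAPPA_MAX:
            raise ValueError("delta/kappa outside their range")
        C = np.where(base > 0, base, 0.0) ** delta if delta != 1.0 else base
        if lam != 1.0:
            diag = np.diag(C).copy()
            C = lam * C
            np.fill_diagonal(C, diag)
        return _gls_core(self.exog, self.endog, _cholesky_with_ridge(C)).loglik

    def fit(self, starts=DEFAULT_STARTS) -> "PGLSResults":
        """Maximize the likelihood jointly over (lambda, delta, kappa).

        Bounded L-BFGS-B from each start; the best of the converged starts
        wins.  If no start converges the best-so-far point is returned with
        ``converged=False`` rather than being dropped.
        """
        bounds = [(0.0, 1.0), (_EPS, DELTA_MAX), (_EPS, KAPPA_MAX)]

        def neg_loglik(theta: np.ndarray) -> float:
            try:
                return -self.loglik(*theta)
            except SingularCovarianceError:
                return 1e12

        best = None
        any_converged = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for start in starts:
                res = optimize.minimize(
                    neg_loglik, np.asarray(start, dtype=float),
                    method="L-BFGS-B", bounds=bounds,
                    options={"ftol": 1e-8, "gtol": 1e-5, "maxiter": 100},
                )
                if best is None or res.fun < best.fun:
                    best = res
                any_converged = any_converged or bool(res.success)
        lam, delta, kappa = (float(v) for v in best.x)
        C = pagel_transform_covariance(self.structure, lam, delta, kappa)
        core = _gls_core(self.exog, self.endog, _cholesky_with_ridge(C))
        return PGLSResults(self, core, lam, delta, kappa, any_converged)

    def fit_fixed(self, lam=1.0, delta=1.0, kappa=1.0) -> "PGLSResults":
        """GLS at fixed transformation parameters (no ML search)."""
        C = pagel_transform_covariance(self.structure, lam, delta, kappa)
        core = _gls_core(self.exog, self.endog, _cholesky_with_ridge(C))
        return PGLSResults(self, core, lam, delta, kappa, True)


class PGLSResults:
    """Estimates, uncertainties and diagnostics of a fitted :class:`PGLS`."""

    def __init__(self, model: PGLS, core: GLSFit, lam, delta, kappa, converged):
        self.model = model
        self.params = pd.Series(
            {"intercept": core.intercept, "slope": core.slope}
        )
        self.bse = pd.Series({"intercept": np.nan, "slope": core.slope_se})
        self.pvalues = pd.Series({"intercept": np.nan, "slope": core.slope_p})
        self.lam = lam
        self.delta = delta
        self.kappa = kappa
        self.sigma2 = core.sigma2
        self.llf = core.loglik
        self.nobs = core.nobs
        self.converged = converged

    @property
    def slope(self) -> float:
        return float(self.params["slope"])

    @property
    def intercept(self) -> float:
        return float(self.params["intercept"])

    @property
    def slope_p(self) -> float:
        return float(self.pvalues["slope"])

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Two-sided confidence interval for the slope."""
        tcrit = stats.t.ppf(1 - alpha / 2, self.nobs - 2)
        half = tcrit * float(self.bse["slope"])
        return self.slope - half, self.slope + half

    def summary(self) -> str:
        lines = [
            "Phylogenetic GLS (Pagel lambda/delta/kappa, ML)",
            f"  n tips:      {self.nobs}",
            f"  slope:       {self.slope:.6g}  (SE {self.bse['slope']:.3g},"
            f" p {self.slope_p:.3g})",
            f"  intercept:   {self.intercept:.6g}",
            f"  lambda:      {self.lam:.4f}",
            f"  delta:       {self.delta:.4f}",
            f"  kappa:       {self.kappa:.4f}",
            f"  sigma2:      {self.sigma2:.6g}",
            f"  loglik:      {self.llf:.4f}",
            f"  converged:   {self.converged}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<PGLSResults slope={self.slope:.4g} p={self.slope_p:.3g}>"


def pgls_ml(x, y, tree, labels, starts=DEFAULT_STARTS) -> PGLSResults:
    """Convenience wrapper: fit a :class:`PGLS` by maximum likelihood."""
    return PGLS(y, x, tree, labels).fit(starts=starts)
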