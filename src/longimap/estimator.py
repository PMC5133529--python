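"""Estimating-equation solver for the multipoint LD mapping model.

The parameter vector delta = (tau, N, C, C*) solves the stacked estimating
equations S(delta) = S1 + S2 = 0, where for each affection class the
contribution of one offspring-visit row is::

    (d mu/d delta)  Cov^-1(Z)  {Z - m * mu}

with Z the row's vector of transmission statistics over markers, mu the
model expectation for one parental side, and m the per-entry count of
resolvable parental sides (2 when both parents are informative, 1 when only
one is).  Missing entries are dropped together with the matching rows and
columns of the working covariance.

Families are the independent sampling units: standard errors come from the
sandwich estimator A^-1 B A^-T with A the delta-derivative of the total
estimating function and B the sum of outer products of per-family
contributions, so siblings, repeated visits and marker correlation all stay
inside the family blocks.

Numerically, each gene fit (a) groups rows by missingness pattern and
caches the corresponding covariance sub-block inverses, which reduces every
S evaluation to two (4 x M)(M) products; (b) seeds a damped Newton
iteration from a profile grid over tau (marker positions plus interior
points, at a reference N), solving the linear (C, C*) sub-problem in closed
form at each grid point and breaking ties toward the leftmost tau; and
(c) treats marker positions as knots of the piecewise-smooth tau surface:
derivatives are one-sided near knots, and roots where the tau-equation
flips sign across a knot (or presses on a box bound) are solved with tau
pinned there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

from .ldmodel import ModelParams, dmu_ddelta, recomb_fraction
from .transmission import ZMatrix

__all__ = [
    "WorkingCov",
    "GeneFit",
    "GeneData",
    "InformativeDataError",
    "estimate_working_cov",
    "estimating_functions",
    "solve_delta",
    "sandwich_variance",
    "wald_test_c",
    "fit_gene",
    "scan_genes",
    "bonferroni_threshold",
]

N_BOUNDS = (1.0, 500.0)
N0_DEFAULT = 20.0   # grid-stage N: geometric midpoint of the N box
_COND_MAX = 1e8


class InformativeDataError(ValueError):
    """No informative transmissions to fit on."""


@dataclass
class WorkingCov:
    """Regularized working covariance of the Z rows for one affection class."""

    cov: np.ndarray          # (M, M) regularized covariance
    inv: np.ndarray          # its inverse
    shrinkage: float         # diagonal-shrinkage intensity used
    n_rows: int
    dropped: List[int] = field(default_factory=list)  # all-missing columns


def estimate_working_cov(zmatrix: ZMatrix, affected: Optional[bool] = None
                         ) -> WorkingCov:
    """Pooled empirical covariance of the Z rows of one class, shrunk toward
    its diagonal until well conditioned.

    Pairwise-complete handling of missing entries; all-missing marker
    columns are dropped (replaced by unit-diagonal placeholders that no
    missingness pattern ever touches) with a warning.  The shrinkage
    intensity is the smallest lambda in {0, 0.05, ...} for which the
    regularized matrix is positive-definite with condition number < 1e8.
    """
    zm = zmatrix if affected is None else zmatrix.rows(affected)
    z = zm.z
    if z.shape[0] < 2:
        raise InformativeDataError(
            "need at least 2 rows in the class to estimate Cov(Z)")
    S = pd.DataFrame(z).cov(min_periods=2).to_numpy()
    M = S.shape[1]
    dropped = [j for j in range(M) if not np.isfinite(S[j, j])]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} all-missing marker column(s) "
                      "from the working covariance")
    # degenerate (constant or unobserved) columns get a neutral unit variance
    var = np.diag(S).copy()
    pos = var[np.isfinite(var) & (var > 0)]
    floor = 0.5 * np.median(pos) if pos.size else 1.0
    bad = ~np.isfinite(var) | (var < floor)
    S[np.isnan(S)] = 0.0
    d_idx = np.arange(M)
    S[d_idx[bad], d_idx[bad]] = np.where(np.isfinite(var[bad]) & (var[bad] > 0),
                                         np.maximum(var[bad], floor), floor)
    for j in dropped:
        S[j, :] = S[:, j] = 0.0
        S[j, j] = 1.0
    S = 0.5 * (S + S.T)

    diag = np.diag(np.diag(S))
    lam_used = 1.0
    for lam in np.arange(0.0, 1.0 + 1e-9, 0.05):
        Sreg = (1 - lam) * S + lam * diag
        w = np.linalg.eigvalsh(Sreg)
        if w[0] > 0 and w[-1] / w[0] < _COND_MAX:
            lam_used = float(lam)
            break
    Sreg = (1 - lam_used) * S + lam_used * diag
    inv = np.linalg.inv(Sreg)
    resid = np.linalg.norm(Sreg @ inv - np.eye(M))
    if resid > 1e-6:
        inv = np.linalg.pinv(Sreg)
    return WorkingCov(Sreg, inv, lam_used, z.shape[0], dropped)


# ---------------------------------------------------------------------------
# Per-gene preprocessed data
# ---------------------------------------------------------------------------

class _ClassStats:
    """Missingness-pattern sufficient statistics for one affection class."""

    def __init__(self, z: np.ndarray, m: np.ndarray, family: np.ndarray,
                 cov: WorkingCov):
        obs = m > 0
        keep = obs.any(axis=1)
        self.z = z[keep]
        self.m = m[keep].astype(float)
        self.family = family[keep]
        obs = obs[keep]
        self.n_rows = self.z.shape[0]
        M = z.shape[1]
        self.cov = cov

        # group rows by missingness pattern; cache sub-block inverses
        if self.n_rows:
            pat, inverse = np.unique(obs, axis=0, return_inverse=True)
        else:
            pat = np.zeros((0, M), bool)
            inverse = np.zeros(0, int)
        self.row_pattern = inverse
        self.pattern_obs = [np.flatnonzero(p) for p in pat]
        self.pattern_winv = [
            np.linalg.inv(cov.cov[np.ix_(o, o)]) for o in self.pattern_obs]

        zf = np.nan_to_num(self.z)
        self.vtilde = np.zeros(M)
        self.K = np.zeros((M, M))
        # GLS merit-function blocks: Q = q0 - 2 coef g'u + coef^2 g'H g
        self.q0 = 0.0
        self.u = np.zeros(M)
        self.H = np.zeros((M, M))
        for pid, (o, W) in enumerate(zip(self.pattern_obs, self.pattern_winv)):
            rows = np.flatnonzero(inverse == pid)
            zo, mo = zf[rows][:, o], self.m[rows][:, o]
            zsum = zo.sum(axis=0)
            msum = mo.sum(axis=0)
            self.vtilde[o] += W @ zsum
            self.K[np.ix_(o, o)] += W * msum[None, :]
            self.q0 += float(np.einsum("ri,ij,rj->", zo, W, zo))
            self.u[o] += W @ (mo * zo).sum(axis=0)
            self.H[np.ix_(o, o)] += W * (mo.T @ mo)

    def row_contribution(self, r: int, mu: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """(observed index, Winv @ residual) for one row at expectation mu."""
        o = self.pattern_obs[self.row_pattern[r]]
        W = self.pattern_winv[self.row_pattern[r]]
        resid = np.nan_to_num(self.z[r])[o] - self.m[r][o] * mu[o]
        return o, W @ resid


@dataclass
class GeneData:
    """Everything solve/sandwich need for one gene x phenotype scheme."""

    positions: np.ndarray
    pi: np.ndarray
    aff: _ClassStats
    unaff: Optional[_ClassStats]
    map_function: str = "haldane"

    @classmethod
    def build(cls, zmatrix: ZMatrix, positions, pi,
              cov_aff: Optional[WorkingCov] = None,
              cov_unaff: Optional[WorkingCov] = None,
              map_function: str = "haldane") -> "GeneData":
        za = zmatrix.rows(True)
        zu = zmatrix.rows(False)
        if za.n_rows == 0 or not (za.m > 0).any():
            raise InformativeDataError("no informative affected trios")
        if cov_aff is None:
            cov_aff = estimate_working_cov(za)
        aff = _ClassStats(za.z, za.m, za.family, cov_aff)
        unaff = None
        if zu.n_rows >= 2 and (zu.m > 0).any():
            if cov_unaff is None:
                cov_unaff = estimate_working_cov(zu)
            unaff = _ClassStats(zu.z, zu.m, zu.family, cov_unaff)
        return cls(np.asarray(positions, float), np.asarray(pi, float),
                   aff, unaff, map_function)

    @property
    def region(self) -> Tuple[float, float]:
        return float(self.positions[0]), float(self.positions[-1])

    def g_vector(self, tau: float, n_gen: float) -> np.ndarray:
        theta = recomb_fraction(self.positions, tau, self.map_function)
        return (1 - 2 * theta) * np.exp(n_gen * np.log1p(-theta)) * self.pi


def _s_vector(delta: ModelParams, data: GeneData) -> np.ndarray:
    """Stacked estimating function S(delta) = S1 + S2 (4-vector)."""
    g = data.g_vector(delta.tau, delta.n_gen)
    S = np.zeros(4)
    for which, cls, coef in ((1, data.aff, delta.c_eff),
                             (2, data.unaff, delta.c_star)):
        if cls is None:
            continue
        D = dmu_ddelta(delta, data.pi, data.positions, which, data.map_function)
        S += D @ (cls.vtilde - coef * (cls.K @ g))
    if not np.all(np.isfinite(S)):
        raise FloatingPointError("non-finite estimating function value")
    return S


def estimating_functions(delta: ModelParams, data, pi=None, cov=None,
                         positions=None, map_function: str = "haldane"
                         ) -> np.ndarray:
    """Evaluate the stacked estimating function S(delta).

    ``data`` may be a prebuilt :class:`GeneData`, or a raw
    :class:`~longimap.transmission.ZMatrix` together with ``pi``,
    ``positions`` and optionally per-class working covariances
    ``cov = (cov_affected, cov_unaffected)``.
    """
    if isinstance(data, GeneData):
        return _s_vector(delta, data)
    cov_aff, cov_unaff = cov if cov is not None else (None, None)
    gd = GeneData.build(data, positions, pi, cov_aff, cov_unaff, map_function)
    return _s_vector(delta, gd)


def _solve_linear_effects(data: GeneData, tau: float, n_gen: float
                          ) -> Tuple[float, float]:
    """Closed-form (C, C*) solving their estimating-equation components at
    fixed (tau, N), clipped to [-1, 1]."""
    g = data.g_vector(tau, n_gen)
    out = []
    for cls in (data.aff, data.unaff):
        if cls is None:
            out.append(0.0)
            continue
        denom = float(g @ (cls.K @ g))
        num = float(g @ cls.vtilde)
        out.append(float(np.clip(num / denom, -1, 1)) if denom > 1e-12 else 0.0)
    return out[0], out[1]


def _gls_objective(data: GeneData, tau: float, n_gen: float
                   ) -> Tuple[float, float, float]:
    """Profile GLS merit function used to rank grid seeds.

    Q(delta) = sum_rows (z - m*mu)' W (z - m*mu), minimized in closed form
    over (C, C*) at fixed (tau, N).  Unlike the raw estimating-function
    norm, Q is comparable across (tau, N) candidates (the norm degenerates
    where the tau/N derivatives vanish, e.g. at small N).
    Returns (Q, C, C*).
    """
    g = data.g_vector(tau, n_gen)
    q = 0.0
    coefs = []
    for cls in (data.aff, data.unaff):
        if cls is None:
            coefs.append(0.0)
            continue
        gu = float(g @ cls.u)
        ghg = float(g @ (cls.H @ g))
        coef = float(np.clip(gu / ghg, -1, 1)) if ghg > 1e-12 else 0.0
        q += cls.q0 - 2 * coef * gu + coef ** 2 * ghg
        coefs.append(coef)
    return q, coefs[0], coefs[1]


def _jacobian(delta: ModelParams, data: GeneData) -> np.ndarray:
    """Numeric Jacobian dS/ddelta, 4x4.

    Central differences, except for the tau column near a marker position:
    the tau-component of S jumps across marker knots (the map-distance
    derivative flips sign there), so straddling a knot would measure the
    jump instead of the slope.  Within two steps of a knot the stencil is
    one-sided, taken on the side with more room.
    """
    x = delta.as_array()
    lo, hi = data.region
    h = np.array([max(1e-6 * max(hi - lo, 1e-3), 1e-9),
                  max(1e-5 * max(x[1], 1.0), 1e-7), 1e-7, 1e-7])
    J = np.zeros((4, 4))

    def s_at(k, step):
        xx = x.copy()
        xx[k] += step
        return _s_vector(ModelParams.from_array(xx), data)

    knots = np.asarray(data.positions)
    near_knot = np.min(np.abs(knots - x[0])) < 2 * h[0]
    for k in range(4):
        if k == 0 and (near_knot or x[0] - 2 * h[0] < lo or x[0] + 2 * h[0] > hi):
            side = 1.0 if (hi - x[0]) >= (x[0] - lo) else -1.0
            if near_knot:
                j = int(np.argmin(np.abs(knots - x[0])))
                side = 1.0 if x[0] >= knots[j] else -1.0
                if x[0] + side * 2 * h[0] > hi or x[0] + side * 2 * h[0] < lo:
                    side = -side
            S0 = _s_vector(delta, data)
            S1 = s_at(0, side * h[0])
            S2 = s_at(0, side * 2 * h[0])
            J[:, 0] = side * (-3 * S0 + 4 * S1 - S2) / (2 * h[0])
        else:
            J[:, k] = (s_at(k, h[k]) - s_at(k, -h[k])) / (2 * h[k])
    return J


def _project(x: np.ndarray, region: Tuple[float, float]) -> np.ndarray:
    y = x.copy()
    y[0] = np.clip(y[0], region[0], region[1])
    y[1] = np.clip(y[1], N_BOUNDS[0], N_BOUNDS[1])
    y[2] = np.clip(y[2], -1.0, 1.0)
    y[3] = np.clip(y[3], -1.0, 1.0)
    return y


@dataclass
class GeneFit:
    """Converged estimates and inference for one gene."""

    gene: str
    params: ModelParams
    se_tau: float = np.nan
    se_n: float = np.nan
    se_c: float = np.nan
    se_c_star: float = np.nan
    ci_tau_95: Tuple[float, float] = (np.nan, np.nan)
    p_value_c: float = np.nan
    n_trios_affected: int = 0
    n_trios_unaffected: int = 0
    n_markers: int = 0
    converged: bool = False
    identifiable: bool = True
    iterations: int = 0
    s_norm: float = np.nan
    shrinkage: Tuple[float, float] = (np.nan, np.nan)
    message: str = ""
    vcov: Optional[np.ndarray] = None

    @property
    def se_c_eff(self) -> float:  # alias
        return self.se_c

    @property
    def significant(self) -> bool:
        return np.isfinite(self.p_value_c) and self.p_value_c < 0.05


def _tau_grid(positions: np.ndarray, interior: int = 10) -> np.ndarray:
    pts = [positions]
    for a, b in zip(positions[:-1], positions[1:]):
        if b > a:
            pts.append(np.linspace(a, b, interior + 2)[1:-1])
    return np.unique(np.concatenate(pts))


def solve_delta(data: GeneData, region: Optional[Tuple[float, float]] = None,
                gene: str = "", max_iter: int = 100, tol: float = 1e-6
                ) -> GeneFit:
    """Solve S(delta) = 0 by profile-grid initialization plus damped Newton.

    The grid scores every candidate tau (marker positions and 10 interior
    points per inter-marker interval, crossed with a short geometric grid
    over N) with the closed-form (C, C*); the best point seeds a damped
    Newton iteration with box constraints (tau in the region, N in [1, 500],
    C and C* in [-1, 1]).
    """
    region = region or data.region
    fit = GeneFit(gene=gene, params=ModelParams(np.mean(region), N0_DEFAULT, 0.0, 0.0),
                  n_trios_affected=data.aff.n_rows,
                  n_trios_unaffected=0 if data.unaff is None else data.unaff.n_rows,
                  n_markers=data.positions.size,
                  shrinkage=(data.aff.cov.shrinkage,
                             np.nan if data.unaff is None else data.unaff.cov.shrinkage))

    if np.max(np.abs(data.aff.vtilde)) < 1e-10:
        fit.params = ModelParams(float(np.mean(region)), N0_DEFAULT, 0.0,
                                 _solve_linear_effects(data, np.mean(region), N0_DEFAULT)[1])
        fit.identifiable = False
        fit.message = "all affected transmission statistics are zero; tau not identifiable"
        return fit

    taus = _tau_grid(np.asarray(data.positions))
    taus = taus[(taus >= region[0]) & (taus <= region[1])]
    n0 = N0_DEFAULT
    scored = []
    for tau in taus:
        c, cs = _solve_linear_effects(data, tau, n0)
        S = _s_vector(ModelParams(tau, n0, c, cs), data)
        scored.append((float(S @ S), tau, c, cs))
    scored.sort(key=lambda r: r[:2])  # ties -> leftmost tau

    # Newton from the best grid seed; on convergence failure, retry from the
    # next-best seeds (optimization fallback only -- the first converged
    # solution is kept)
    x = S = None
    converged, it = False, 0
    for _, tau0, c0, cs0 in scored[:3]:
        x1, S1, conv1, it1 = _newton(data, np.array([tau0, n0, c0, cs0]),
                                     region, max_iter, tol)
        if x is None or (conv1 and not converged):
            x, S, converged, it = x1, S1, conv1, it1
        if converged:
            break

    fit.params = ModelParams.from_array(x)
    fit.converged = converged
    fit.iterations = it
    fit.s_norm = float(np.linalg.norm(S))
    if not converged and not fit.message:
        fit.message = "Newton iteration did not converge"
    return fit


def _profile_q(data: GeneData, tau: float, n_gen: float) -> float:
    return _gls_objective(data, tau, n_gen)[0]


def _newton(data: GeneData, x0: np.ndarray, region, max_iter: int, tol: float):
    """Damped Newton on S(delta) = 0 from one seed.

    If the unconstrained iteration stalls, the root may be a kink solution:
    the tau-component of S flips sign across a marker knot (or presses
    against a region/N bound) without a zero crossing.  In that case tau is
    pinned where the profile GLS objective has a one-sided local minimum
    and the reduced system is solved in the remaining parameters.
    """
    x, S, converged, it = _newton_masked(data, x0, region, max_iter, tol,
                                         np.ones(4, bool))
    if converged:
        return x, S, converged, it

    span = region[1] - region[0]
    eps = max(1e-5 * span, 1e-9)
    pins = np.asarray(data.positions)
    cand = np.concatenate([pins, region])
    t0 = float(cand[np.argmin(np.abs(cand - x[0]))])
    q0 = _profile_q(data, t0, x[1])
    left_ok = t0 - eps < region[0] or _profile_q(data, t0 - eps, x[1]) >= q0
    right_ok = t0 + eps > region[1] or _profile_q(data, t0 + eps, x[1]) >= q0
    active = np.ones(4, bool)
    if left_ok and right_ok:
        active[0] = False
        x = x.copy()
        x[0] = t0
    if x[1] <= N_BOUNDS[0] + tol or x[1] >= N_BOUNDS[1] - tol:
        n0 = N_BOUNDS[0] if x[1] <= N_BOUNDS[0] + tol else N_BOUNDS[1]
        inward = n0 + (1.0 if n0 == N_BOUNDS[0] else -1.0) * 1e-3
        if _profile_q(data, x[0], inward) >= _profile_q(data, x[0], n0):
            active[1] = False
            x = x.copy()
            x[1] = n0
    if active.all():
        return x, S, converged, it
    x2, S2, conv2, it2 = _newton_masked(data, x, region, max_iter, tol, active)
    if conv2:
        return x2, S2, True, it + it2
    return x, S, converged, it


def _newton_masked(data: GeneData, x0: np.ndarray, region, max_iter: int,
                   tol: float, active: np.ndarray):
    """Damped Newton restricted to the ``active`` coordinates of delta."""
    x = _project(x0, region)
    ia = np.flatnonzero(active)
    if active[0]:
        # nudge off a knot so the tau-derivative is two-sided
        knots = np.asarray(data.positions)
        if np.min(np.abs(knots - x[0])) < 1e-9:
            span = region[1] - region[0]
            for eps in (1e-4 * span, -1e-4 * span):
                if region[0] < x[0] + eps < region[1]:
                    x[0] += eps
                    break

    S = _s_vector(ModelParams.from_array(x), data)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        J = _jacobian(ModelParams.from_array(x), data)[np.ix_(ia, ia)]

        def newton_dir(vec):
            try:
                d = np.linalg.solve(J, -vec[ia])
            except np.linalg.LinAlgError:
                d = np.linalg.lstsq(J, -vec[ia], rcond=None)[0]
            full = np.zeros(4)
            full[ia] = d
            return full

        step = newton_dir(S)
        if not np.all(np.isfinite(step)):
            break
        # affine-invariant damping: backtrack on the Newton decrement
        # |J^-1 S| measured with the current iterate's Jacobian
        dec0 = np.linalg.norm(step)
        alpha, accepted = 1.0, False
        while alpha >= 1e-4:
            cand = _project(x + alpha * step, region)
            try:
                Sc = _s_vector(ModelParams.from_array(cand), data)
            except FloatingPointError:
                alpha *= 0.5
                continue
            if np.linalg.norm(newton_dir(Sc)) <= dec0 * (1 - 0.25 * alpha) + 1e-300:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            converged = dec0 < tol
            break
        moved = np.max(np.abs(cand - x))
        x, S = cand, Sc
        if moved < tol:
            converged = True
            break
    return x, S, converged, it


def _family_contributions(delta: ModelParams, data: GeneData) -> Dict[int, np.ndarray]:
    """Per-family estimating-function contributions S_i at delta."""
    out: Dict[int, np.ndarray] = {}
    for which, cls, coef in ((1, data.aff, delta.c_eff),
                             (2, data.unaff, delta.c_star)):
        if cls is None:
            continue
        D = dmu_ddelta(delta, data.pi, data.positions, which, data.map_function)
        g = data.g_vector(delta.tau, delta.n_gen)
        mu = coef * g
        for r in range(cls.n_rows):
            o, wr = cls.row_contribution(r, mu)
            fam = int(cls.family[r])
            out[fam] = out.get(fam, np.zeros(4)) + D[:, o] @ wr
    return out


def sandwich_variance(fit: GeneFit, data: GeneData) -> GeneFit:
    """Robust (sandwich) variance A^-1 B A^-T with families as clusters.

    A is the numeric delta-derivative of the total estimating function at
    the estimate; B sums outer products of per-family contributions
    (repeat visits and siblings stay inside their family's block).  Fills
    the SE fields, the 95% CI for tau and the Wald p-value for C in place.
    """
    delta = fit.params
    A = _jacobian(delta, data)
    contribs = _family_contributions(delta, data)
    B = np.zeros((4, 4))
    for s in contribs.values():
        B += np.outer(s, s)

    active = np.array([True, True, True, data.unaff is not None])
    ia = np.flatnonzero(active)
    Aa, Ba = A[np.ix_(ia, ia)], B[np.ix_(ia, ia)]
    d = np.sqrt(np.maximum(np.abs(np.diag(Aa)), 1e-300))
    Dm = np.diag(1.0 / d)
    As = Dm @ Aa @ Dm
    if not np.all(np.isfinite(As)) or np.linalg.cond(As) > 1e12:
        fit.message = (fit.message + "; " if fit.message else "") + \
            "singular A matrix: standard errors not estimable"
        fit.converged = fit.converged and False
        return fit
    Ainv = Dm @ np.linalg.inv(As) @ Dm
    V = Ainv @ Ba @ Ainv.T
    full = np.full((4, 4), np.nan)
    full[np.ix_(ia, ia)] = V
    fit.vcov = full
    var = np.diag(full)
    ses = np.sqrt(np.where(var >= 0, var, np.nan))
    fit.se_tau, fit.se_n, fit.se_c, fit.se_c_star = ses
    if np.isfinite(fit.se_tau):
        fit.ci_tau_95 = (delta.tau - 1.96 * fit.se_tau,
                         delta.tau + 1.96 * fit.se_tau)
    fit.p_value_c = wald_test_c(fit)
    return fit


def wald_test_c(fit: GeneFit) -> float:
    """Two-sided Wald p-value for the genetic effect C."""
    if not np.isfinite(fit.se_c):
        return np.nan
    if fit.se_c == 0:
        warnings.warn("degenerate fit: se(C) = 0")
        return 0.0 if fit.params.c_eff != 0 else 1.0
    return float(2.0 * _norm.sf(abs(fit.params.c_eff) / fit.se_c))


def bonferroni_threshold(n_genes: int, fwer: float = 0.05) -> float:
    """Family-wise Bonferroni significance threshold over tested genes."""
    if n_genes < 1:
        raise ValueError("need at least one tested gene")
    return fwer / n_genes


def fit_gene(zmatrix: ZMatrix, positions, pi, gene: str = "",
             map_function: str = "haldane",
             region: Optional[Tuple[float, float]] = None) -> GeneFit:
    """Full single-gene fit: working covariances, solve, sandwich, Wald."""
    data = GeneData.build(zmatrix, positions, pi, map_function=map_function)
    fit = solve_delta(data, region=region, gene=gene)
    if fit.identifiable:
        sandwich_variance(fit, data)
    return fit


def scan_genes(trios, panel, status_table, gene_table, scheme: str,
               map_function: str = "haldane", fwer: float = 0.05):
    """Gene-based scan: fit each annotated gene's marker interval.

    Markers are assigned to genes by cM-interval overlap; genes with fewer
    than 2 markers are skipped with a warning.  Returns (fits, threshold)
    with the Bonferroni threshold computed over genes actually fit.
    """
    from .ldmodel import estimate_pi
    from .phenotypes import derive_all
    from .transmission import build_z_matrix

    assignments = derive_all(scheme, status_table)
    fits: List[GeneFit] = []
    for row in gene_table.itertuples(index=False):
        lo, hi = float(row.start_cm), float(row.end_cm)
        idx = np.flatnonzero((panel.positions_cm >= lo) &
                             (panel.positions_cm <= hi))
        if idx.size < 2:
            warnings.warn(f"gene {row.gene}: fewer than 2 markers in "
                          f"[{lo}, {hi}] cM; skipped")
            continue
        sub = panel.subset(idx)
        sub_trios = [_subset_trio(t, idx) for t in trios]
        pi = estimate_pi(sub_trios, sub)
        zmat = build_z_matrix(sub_trios, sub, assignments)
        try:
            fit = fit_gene(zmat, sub.positions_cm, pi, gene=row.gene,
                           map_function=map_function)
        except InformativeDataError as exc:
            fit = GeneFit(gene=row.gene,
                          params=ModelParams((lo + hi) / 2, N0_DEFAULT, 0, 0),
                          n_markers=idx.size, identifiable=False,
                          message=str(exc))
        fits.append(fit)
    tested = [f for f in fits if f.identifiable]
    threshold = bonferroni_threshold(len(tested), fwer) if tested else np.nan
    return fits, threshold


def _subset_trio(t, idx):
    import dataclasses
    return dataclasses.replace(
        t, father_counts=t.father_counts[idx], mother_counts=t.mother_counts[idx],
        child_counts=t.child_counts[idx])
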