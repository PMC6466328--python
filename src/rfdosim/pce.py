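"""Sparse polynomial-chaos surrogate machinery for Gaussian inputs.

A scalar model output (a SAR metric) is approximated as a truncated series
in polynomials orthonormal to the input probability law,

    SAR ~ M(X) = sum_j a_j psi_j(X),

where X is the random pose vector (Z-shift, tilt).  The inputs are treated
as Gaussian, so the basis is the tensor product of probabilists' Hermite
polynomials, orthonormalized under the standard normal weight; the
candidate basis contains all multi-indices of total degree <= p, of size
P = C(K+p, p).

Coefficients are estimated from a Latin-hypercube experimental design by
least-angle regression (LAR): the LAR path fixes the order in which basis
terms become active, each path model is refit by ordinary least squares on
its active set (hybrid LAR-OLS), and the model minimizing the corrected
leave-one-out error is kept.  The relative error 1 - Q^2 = eps_LOO /
var(SAR) drives an adaptive loop over design size N and maximum degree p.

The leave-one-out error is computed exactly via the hat-matrix identity
(residual_i / (1 - h_i), squared and averaged) -- algebraically equal to
refitting N times with one point held out -- and then multiplied by the
standard finite-sample correction factor
T = N/(N-P) * (1 + trace((Phi^T Phi)^-1)).

Truncated-Gaussian inputs are standardized as plain Gaussians for the
polynomial weight (truncation at +-3 sd discards ~0.27% of probability
mass); sampling respects the truncation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "InputDistribution",
    "ExperimentalDesign",
    "ObservationSet",
    "PCSurrogate",
    "hermite_eval",
    "basis_size",
    "multi_indices",
    "tensor_basis_matrix",
    "lhs_design",
    "standardize",
    "destandardize",
    "fit_lar",
    "loo_error",
    "adaptive_fit",
    "evaluate",
    "default_pose_distribution",
]


# ---------------------------------------------------------------------------
# Input distributions and standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InputDistribution:
    """Independent truncated-Gaussian marginals of the random inputs.

    Arrays are aligned per input variable: mean and sd in physical units,
    lower/upper the truncation bounds.
    """

    names: tuple[str, ...]
    mean: tuple[float, ...]
    sd: tuple[float, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.names)
        if not (len(self.mean) == len(self.sd) == len(self.lower) == len(self.upper) == k):
            raise ValueError("all marginal arrays must have equal length")
        for s, lo, hi in zip(self.sd, self.lower, self.upper):
            if s <= 0:
                raise ValueError("sd must be positive")
            if lo >= hi:
                raise ValueError("lower bound must be below upper bound")

    @property
    def k(self) -> int:
        return len(self.names)


def default_pose_distribution() -> InputDistribution:
    """Pose variability defaults: the motion limits sit at +-3 sd.

    Z-shift ~ TruncNormal(0, 10/3 cm) on [-10, 10] cm;
    tilt    ~ TruncNormal(0, 5/3 deg) on [-5, 5] deg.
    """
    return InputDistribution(
        names=("z_shift_m", "tilt_deg"),
        mean=(0.0, 0.0),
        sd=(0.10 / 3.0, 5.0 / 3.0),
        lower=(-0.10, -5.0),
        upper=(0.10, 5.0),
    )


def standardize(x: np.ndarray, dist: InputDistribution) -> np.ndarray:
    """Physical inputs -> standard-normal scale, xi_j = (x_j - mean_j)/sd_j."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    return (x - np.asarray(dist.mean)) / np.asarray(dist.sd)


def destandardize(xi: np.ndarray, dist: InputDistribution) -> np.ndarray:
    """Inverse of :func:`standardize`."""
    xi = np.atleast_2d(np.asarray(xi, dtype=np.float64))
    return xi * np.asarray(dist.sd) + np.asarray(dist.mean)


# ---------------------------------------------------------------------------
# Hermite basis
# ---------------------------------------------------------------------------


def hermite_eval(x: np.ndarray, max_degree: int) -> np.ndarray:
    """Orthonormal probabilists' Hermite polynomials He_n / sqrt(n!).

    Returns an array of shape ``(*x.shape, max_degree + 1)`` with the
    degree-n polynomial in the last axis, evaluated by the stable
    orthonormal three-term recurrence
    ``Ht_{n+1} = (x Ht_n - sqrt(n) Ht_{n-1}) / sqrt(n+1)``.
    """
    if max_degree < 0:
        raise ValueError("degree must be >= 0")
    x = np.asarray(x, dtype=np.float64)
    out = np.empty(x.shape + (max_degree + 1,))
    out[..., 0] = 1.0
    if max_degree >= 1:
        out[..., 1] = x
    for n in range(1, max_degree):
        out[..., n + 1] = (
            x * out[..., n] - math.sqrt(n) * out[..., n - 1]
        ) / math.sqrt(n + 1)
    return out


def basis_size(k: int, p: int) -> int:
    """Number of multi-indices of total degree <= p in k variables: C(k+p, p)."""
    if k < 1 or p < 0:
        raise ValueError("require k >= 1 and p >= 0")
    return math.comb(k + p, p)


def multi_indices(k: int, p: int) -> list[tuple[int, ...]]:
    """All multi-indices with total degree <= p, graded-lexicographic order.

    Within each total degree, indices are ordered with the leading variable
    carrying the highest degree first, e.g. k=2, p=1 -> (0,0), (1,0), (0,1).
    """
    if k < 1 or p < 0:
        raise ValueError("require k >= 1 and p >= 0")

    def compositions(total: int, parts: int) -> Iterable[tuple[int, ...]]:
        if parts == 1:
            yield (total,)
            return
        for first in range(total, -1, -1):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest

    out: list[tuple[int, ...]] = []
    for d in range(p + 1):
        out.extend(compositions(d, k))
    return out


def tensor_basis_matrix(
    xi: np.ndarray, indices: Sequence[tuple[int, ...]]
) -> np.ndarray:
    """Regression matrix Psi[i, j] = prod_m He~_{alpha_j_m}(xi[i, m])."""
    xi = np.atleast_2d(np.asarray(xi, dtype=np.float64))
    k = xi.shape[1]
    max_deg = max((max(a) for a in indices), default=0)
    uni = hermite_eval(xi, max_deg)  # (n, k, max_deg+1)
    n = xi.shape[0]
    psi = np.ones((n, len(indices)))
    for j, alpha in enumerate(indices):
        for m in range(k):
            if alpha[m] > 0:
                psi[:, j] *= uni[:, m, alpha[m]]
    return psi


# ---------------------------------------------------------------------------
# Experimental design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentalDesign:
    """LHS pose samples (physical units) with their distribution and seed."""

    poses: np.ndarray  # (N, K)
    dist: InputDistribution
    seed: int

    @property
    def n(self) -> int:
        return self.poses.shape[0]

    def standardized(self) -> np.ndarray:
        return standardize(self.poses, self.dist)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.poses, columns=list(self.dist.names)).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class ObservationSet:
    """Model outputs aligned with the rows of an experimental design."""

    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(v).all():
            raise ValueError("observations must be finite")
        if (v < 0).any():
            raise ValueError("SAR observations must be >= 0")
        object.__setattr__(self, "values", v)


def _truncnorm(mean: float, sd: float, lower: float, upper: float):
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def lhs_design(
    n: int, dist: InputDistribution, seed: int
) -> ExperimentalDesign:
    """Latin-hypercube sample of the truncated-Gaussian input law.

    Each marginal is divided into ``n`` equal-probability strata; one
    uniform point is drawn inside each stratum and mapped through the
    truncated-normal inverse CDF; strata are independently permuted across
    dimensions.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("design size must be >= 1")
    rng = np.random.default_rng(seed)
    poses = np.empty((n, dist.k))
    for j in range(dist.k):
        strata = rng.permutation(n)
        u = (strata + rng.uniform(size=n)) / n
        tn = _truncnorm(dist.mean[j], dist.sd[j], dist.lower[j], dist.upper[j])
        poses[:, j] = tn.ppf(u)
    # guard against ppf rounding at the extreme strata
    poses = np.clip(poses, np.asarray(dist.lower), np.asarray(dist.upper))
    return ExperimentalDesign(poses=poses, dist=dist, seed=seed)


def sample_distribution(
    n: int, dist: InputDistribution, seed: int | np.random.Generator
) -> np.ndarray:
    """Plain Monte-Carlo draw (n, K) from the truncated-Gaussian input law."""
    rng = np.random.default_rng(seed)
    out = np.empty((n, dist.k))
    for j in range(dist.k):
        tn = _truncnorm(dist.mean[j], dist.sd[j], dist.lower[j], dist.upper[j])
        out[:, j] = tn.ppf(rng.uniform(size=n))
    return out


# ---------------------------------------------------------------------------
# Leave-one-out error
# ---------------------------------------------------------------------------


def loo_error(
    phi: np.ndarray, y: np.ndarray, corrected: bool = True
) -> tuple[float, float]:
    """Leave-one-out mean-square error and Q^2 of an OLS fit ``phi @ a ~ y``.

    Uses the hat-matrix identity: with h_i the leverage of point i and
    r_i the OLS residual, the prediction error at point i of the model
    refit without point i is r_i / (1 - h_i); eps_LOO is the mean of its
    square -- exactly the explicit N-refit estimator.  With
    ``corrected=True`` the finite-sample factor
    ``N/(N-P) * (1 + trace((phi^T phi)^-1))`` multiplies the estimate.

    Returns ``(eps_loo, q2)`` with ``q2 = 1 - eps_loo / var(y)``; for a
    constant response (zero variance) a perfect constant model gives
    ``(0, 1)``.
    """
    phi = np.asarray(phi, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = phi.shape
    if p >= n:
        raise ValueError("active model must have fewer terms than points")
    q, r = np.linalg.qr(phi)
    if np.abs(np.diag(r)).min() < 1e-12 * max(1.0, np.abs(np.diag(r)).max()):
        raise np.linalg.LinAlgError("regression matrix is rank deficient")
    coef = np.linalg.solve(r, q.T @ y)
    resid = y - phi @ coef
    h = np.sum(q**2, axis=1)
    if np.any(h >= 1.0 - 1e-12):
        raise ValueError("interpolating design point (leverage 1)")
    eps = float(np.mean((resid / (1.0 - h)) ** 2))
    if corrected:
        rinv = np.linalg.inv(r)
        trace_inv = float(np.sum(rinv**2))  # trace((phi^T phi)^-1)
        eps *= n / (n - p) * (1.0 + trace_inv)
    var = float(np.var(y))
    if var == 0.0:
        q2 = 1.0 if eps == 0.0 else -np.inf
    else:
        q2 = 1.0 - eps / var
    return eps, q2


# ---------------------------------------------------------------------------
# Least-angle regression
# ---------------------------------------------------------------------------


def _lar_entry_order(x: np.ndarray, y: np.ndarray, max_steps: int) -> list[int]:
    """Order in which columns of ``x`` enter the classic LAR path.

    ``x`` columns must be centred and unit-norm, ``y`` centred.  Ties in
    the entry criterion resolve to the lowest column index.  Stops early
    when the residual correlations vanish.
    """
    n, m = x.shape
    residual = y.copy()
    active: list[int] = []
    inactive = list(range(m))
    tol = 1e-12 * max(1.0, float(np.abs(y).max(initial=0.0)))
    for _ in range(min(max_steps, m, n - 1)):
        c = x.T @ residual
        c_in = c[inactive]
        cmax = float(np.abs(c_in).max(initial=0.0))
        if cmax < tol:
            break
        j = inactive[int(np.argmax(np.abs(c_in)))]  # argmax -> lowest index on tie
        active.append(j)
        inactive.remove(j)
        xa = x[:, active] * np.sign(c[active])
        g = xa.T @ xa
        try:
            w = np.linalg.solve(g, np.ones(len(active)))
        except np.linalg.LinAlgError:
            break
        denom = float(np.sum(w))
        if denom <= 0:
            break
        aa = 1.0 / math.sqrt(denom)
        u = xa @ (aa * w)  # equiangular direction
        if not inactive:
            gamma = cmax / aa
        else:
            a = x[:, inactive].T @ u
            cc = c[inactive]
            with np.errstate(divide="ignore", invalid="ignore"):
                cand = np.concatenate(
                    [(cmax - cc) / (aa - a), (cmax + cc) / (aa + a)]
                )
            cand = cand[np.isfinite(cand) & (cand > tol)]
            gamma = float(cand.min()) if cand.size else cmax / aa
        residual = residual - gamma * u
    return active


# ---------------------------------------------------------------------------
# Surrogate object and fitting
# ---------------------------------------------------------------------------


@dataclass
class PCSurrogate:
    """Fitted sparse polynomial-chaos expansion.

    Attributes
    ----------
    indices
        Active multi-indices (the intercept (0,...,0) is always first).
    coefficients
        OLS-refit coefficients aligned with ``indices``.
    dist
        Input distribution defining the standardizing transform.
    p, n
        Maximum candidate degree and design size used for the fit.
    eps_loo, q2, var_sar
        Corrected leave-one-out error, Q^2 score and observation variance.
    rel_error
        1 - Q^2 = eps_loo / var_sar, the relative surrogate error.
    warning
        True when an adaptive fit failed to reach its threshold and this is
        the best-effort result.
    """

    indices: list[tuple[int, ...]]
    coefficients: np.ndarray
    dist: InputDistribution
    p: int
    n: int
    eps_loo: float
    q2: float
    var_sar: float
    metric: str = ""
    seed: int | None = None
    warning: bool = False

    @property
    def rel_error(self) -> float:
        return 1.0 - self.q2

    @property
    def n_active(self) -> int:
        return len(self.indices)

    def __call__(self, poses: np.ndarray) -> np.ndarray:
        return evaluate(self, poses)

    def to_json(self) -> str:
        return json.dumps(
            {
                "indices": [list(a) for a in self.indices],
                "coefficients": self.coefficients.tolist(),
                "distribution": {
                    "names": list(self.dist.names),
                    "mean": list(self.dist.mean),
                    "sd": list(self.dist.sd),
                    "lower": list(self.dist.lower),
                    "upper": list(self.dist.upper),
                },
                "p": self.p,
                "n": self.n,
                "eps_loo": self.eps_loo,
                "q2": self.q2,
                "var_sar": self.var_sar,
                "metric": self.metric,
                "seed": self.seed,
                "warning": self.warning,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PCSurrogate":
        d = json.loads(text)
        dist = InputDistribution(
            names=tuple(d["distribution"]["names"]),
            mean=tuple(d["distribution"]["mean"]),
            sd=tuple(d["distribution"]["sd"]),
            lower=tuple(d["distribution"]["lower"]),
            upper=tuple(d["distribution"]["upper"]),
        )
        return cls(
            indices=[tuple(a) for a in d["indices"]],
            coefficients=np.asarray(d["coefficients"]),
            dist=dist,
            p=d["p"],
            n=d["n"],
            eps_loo=d["eps_loo"],
            q2=d["q2"],
            var_sar=d["var_sar"],
            metric=d.get("metric", ""),
            seed=d.get("seed"),
            warning=d.get("warning", False),
        )


def evaluate(surrogate: PCSurrogate, poses: np.ndarray) -> np.ndarray:
    """Predict the surrogate at physical poses: sum_j a_j psi_j(xi(x))."""
    poses = np.atleast_2d(np.asarray(poses, dtype=np.float64))
    lo = np.asarray(surrogate.dist.lower)
    hi = np.asarray(surrogate.dist.upper)
    if ((poses < lo) | (poses > hi)).any():
        warnings.warn(
            "evaluating surrogate outside the input truncation bounds",
            stacklevel=2,
        )
    xi = standardize(poses, surrogate.dist)
    psi = tensor_basis_matrix(xi, surrogate.indices)
    return psi @ surrogate.coefficients


def fit_lar(
    design: ExperimentalDesign,
    observations: ObservationSet | np.ndarray,
    p: int,
    metric: str = "",
) -> PCSurrogate:
    """Fit a sparse PC expansion of maximum degree ``p`` by hybrid LAR-OLS.

    The LAR path on the centred, norm-scaled basis matrix fixes the entry
    order of the non-constant terms (the intercept is always active).  Each
    path model is refit by OLS on its active columns; the model with the
    smallest corrected leave-one-out error wins.
    """
    y = (
        observations.values
        if isinstance(observations, ObservationSet)
        else np.asarray(observations, dtype=np.float64).ravel()
    )
    if not np.isfinite(y).all():
        raise ValueError("observations must be finite")
    n = design.n
    if n < 3:
        raise ValueError("need at least 3 design points")
    if len(y) != n:
        raise ValueError("observations must align with the design")

    xi = design.standardized()
    if np.linalg.matrix_rank(np.c_[np.ones(n), xi]) < min(n, xi.shape[1] + 1):
        raise ValueError("degenerate design: rank below number of inputs")
    indices = multi_indices(design.dist.k, p)
    psi = tensor_basis_matrix(xi, indices)

    # LAR runs on centred, unit-norm non-constant columns
    xc = psi[:, 1:] - psi[:, 1:].mean(axis=0)
    norms = np.linalg.norm(xc, axis=0)
    keep = norms > 1e-12
    xs = xc[:, keep] / norms[keep]
    yc = y - y.mean()
    kept_cols = np.flatnonzero(keep) + 1  # map back to psi columns
    order = [int(kept_cols[j]) for j in _lar_entry_order(xs, yc, max_steps=n - 2)]

    var = float(np.var(y))
    best: tuple[float, list[int], np.ndarray] | None = None
    for m in range(len(order) + 1):
        cols = [0] + order[:m]
        if len(cols) >= n:
            break
        phi = psi[:, cols]
        try:
            eps, _ = loo_error(phi, y, corrected=True)
        except (np.linalg.LinAlgError, ValueError):
            continue
        if best is None or eps < best[0]:
            coef, *_ = np.linalg.lstsq(phi, y, rcond=None)
            best = (eps, cols, coef)
    if best is None:
        raise ValueError("no valid model along the LAR path")
    eps, cols, coef = best
    q2 = 1.0 - eps / var if var > 0 else (1.0 if eps == 0 else -np.inf)
    return PCSurrogate(
        indices=[indices[c] for c in cols],
        coefficients=coef,
        dist=design.dist,
        p=p,
        n=n,
        eps_loo=eps,
        q2=q2,
        var_sar=var,
        metric=metric,
        seed=design.seed,
    )


def adaptive_fit(
    design_sampler: Callable[[int], ExperimentalDesign],
    model_runner: Callable[[ExperimentalDesign], np.ndarray],
    p_range: Sequence[int] = (1, 2, 3, 4, 5),
    n_schedule: Sequence[int] = (25, 50, 100),
    threshold: float = 0.01,
    metric: str = "",
) -> PCSurrogate:
    """Adaptive (N, p) refinement of the surrogate.

    Iterates over the design-size schedule and, for each design, over the
    candidate maximum degrees, accepting the first fit whose relative error
    1 - Q^2 falls at or below ``threshold``.  If none qualifies, the fit
    with the smallest relative error is returned with ``warning=True``.
    """
    if not p_range or not n_schedule:
        raise ValueError("p_range and n_schedule must be nonempty")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    best: PCSurrogate | None = None
    for n in n_schedule:
        design = design_sampler(n)
        y = np.asarray(model_runner(design), dtype=np.float64)
        for p in p_range:
            if basis_size(design.dist.k, p) >= n:
                continue
            surrogate = fit_lar(design, y, p, metric=metric)
            if best is None or surrogate.rel_error < best.rel_error:
                best = surrogate
            if surrogate.rel_error <= threshold:
                return surrogate
    if best is None:
        raise ValueError("no (N, p) combination admitted a fit")
    best.warning = True
    warnings.warn(
        f"adaptive fit did not reach 1-Q^2 <= {threshold:g}; "
        f"best relative error {best.rel_error:.3g}",
        stacklevel=2,
    )
    return best
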