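"""Correlated sampling with arbitrary marginals (the NORTA construction).

NORTA ("NORmal To Anything") draws a correlated multivariate normal vector,
pushes each coordinate through the standard-normal CDF to a uniform, and
inverts the desired marginal quantile function.  Monotone marginal
transforms distort Pearson correlation, so for every variable pair the
normal-scale ("intermediate") correlation is calibrated by monotone 1-D
root finding until the *output* correlation matches the requested target.

Calibration evaluates the correlation map with common random numbers drawn
from a fixed internal seed, which makes the adjusted matrix a deterministic
function of the marginals and targets alone; user-level randomness only
enters through the RNG passed to :meth:`NortaGenerator.sample`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, ndtr, ndtri
from statsmodels.stats.correlation_tools import corr_nearest

__all__ = [
    "Marginal",
    "NormalMarginal",
    "LognormalMarginal",
    "LogitNormalMarginal",
    "ScaledBetaMarginal",
    "NegativeBinomialMarginal",
    "NortaGenerator",
    "NortaFeasibilityError",
    "nearest_correlation",
]

# Common-random-number stream used only for calibrating intermediate
# correlations; independent of any user seed.
_CALIBRATION_SEED = 719_571_113
_N_CALIBRATION = 200_000
# Quantile-table resolution for marginals whose exact ppf is expensive.
_TABLE_SIZE = 8192
_RHO_BOUND = 0.9995


class NortaFeasibilityError(ValueError):
    """Raised when a target correlation is unattainable for a marginal pair."""


class Marginal:
    """A univariate marginal defined by its quantile function."""

    def ppf(self, u: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def fast_ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function actually used for calibration *and* sampling.

        Subclasses with an expensive exact ``ppf`` override this with a
        tabulated version; calibration and sampling must share the same
        transform so the calibrated correlations apply exactly.
        """
        return self.ppf(u)

    @property
    def is_degenerate(self) -> bool:
        return False


@dataclass(frozen=True)
class NormalMarginal(Marginal):
    mean: float
    sd: float

    def ppf(self, u):
        return self.mean + self.sd * ndtri(u)


@dataclass(frozen=True)
class LognormalMarginal(Marginal):
    """exp(Normal(mu, sigma)); optionally rounded to integers with a floor.

    Rounding happens inside the quantile transform so that calibration sees
    the discretized variable and correlation targets are met post-rounding.
    """

    mu: float
    sigma: float
    round_to_int: bool = False
    minimum: float | None = None

    def ppf(self, u):
        x = np.exp(self.mu + self.sigma * ndtri(u))
        if self.round_to_int:
            x = np.rint(x)
        if self.minimum is not None:
            x = np.maximum(x, self.minimum)
        return x


@dataclass(frozen=True)
class LogitNormalMarginal(Marginal):
    """expit(Normal(mu, sigma)): a probability-valued marginal on (0, 1)."""

    mu: float
    sigma: float

    def ppf(self, u):
        return expit(self.mu + self.sigma * ndtri(u))


@dataclass(frozen=True)
class ScaledBetaMarginal(Marginal):
    """scale * Beta(a, b), supported on [0, scale]."""

    a: float
    b: float
    scale: float = 1.0

    def ppf(self, u):
        return self.scale * stats.beta.ppf(u, self.a, self.b)

    def fast_ppf(self, u):
        grid_u, grid_x = _beta_table(self)
        return np.interp(np.clip(u, grid_u[0], grid_u[-1]), grid_u, grid_x)


@dataclass(frozen=True)
class NegativeBinomialMarginal(Marginal):
    """Negative binomial with mean/size parametrization.

    ``variance = mean + mean**2 / dispersion``; ``dispersion = inf`` is the
    Poisson limit and ``mean = 0`` a point mass at zero.  The quantile
    function is exact (table of the discrete CDF + searchsorted).
    """

    mean: float
    dispersion: float = math.inf

    def __post_init__(self):
        if self.mean < 0:
            raise ValueError("negative binomial mean must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("negative binomial dispersion must be > 0")

    @property
    def variance(self) -> float:
        if math.isinf(self.dispersion):
            return self.mean
        return self.mean + self.mean**2 / self.dispersion

    @property
    def is_degenerate(self) -> bool:
        return self.mean == 0.0

    def _dist(self):
        if math.isinf(self.dispersion):
            return stats.poisson(self.mean)
        k = self.dispersion
        return stats.nbinom(k, k / (k + self.mean))

    def ppf(self, u):
        return self.fast_ppf(u)

    def fast_ppf(self, u):
        cdf = _discrete_cdf(self)
        idx = np.searchsorted(cdf, u, side="left")
        return np.minimum(idx, len(cdf) - 1).astype(np.float64)


@lru_cache(maxsize=None)
def _beta_table(m: ScaledBetaMarginal):
    u = np.arange(1, _TABLE_SIZE) / _TABLE_SIZE
    return u, m.scale * stats.beta.ppf(u, m.a, m.b)


@lru_cache(maxsize=None)
def _discrete_cdf(m: NegativeBinomialMarginal) -> np.ndarray:
    if m.mean == 0:
        return np.array([1.0])
    dist = m._dist()
    kmax = int(dist.ppf(1.0 - 1e-13)) + 1
    return dist.cdf(np.arange(kmax + 1))


@lru_cache(maxsize=None)
def _calibration_draws() -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(_CALIBRATION_SEED)
    z = rng.standard_normal((2, _N_CALIBRATION))
    return z[0], z[1]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


@lru_cache(maxsize=None)
def intermediate_correlation(m1: Marginal, m2: Marginal, target: float) -> float:
    """Normal-scale correlation whose NORTA output correlation is ``target``.

    Solved by Brent's method on the monotone map rho_z -> cor(F1^{-1}(Phi(Z1)),
    F2^{-1}(Phi(Z2))), evaluated with common random numbers.
    """
    if abs(target) < 1e-12:
        return 0.0
    if m1.is_degenerate or m2.is_degenerate:
        raise NortaFeasibilityError(
            f"pair ({m1}, {m2}): a degenerate marginal cannot carry "
            f"target correlation {target:.3f}"
        )
    z1, z2 = _calibration_draws()
    x1 = m1.fast_ppf(ndtr(z1))

    def output_corr(rho: float) -> float:
        zz = rho * z1 + math.sqrt(max(1.0 - rho * rho, 0.0)) * z2
        return _pearson(x1, m2.fast_ppf(ndtr(zz)))

    hi = output_corr(_RHO_BOUND)
    lo = output_corr(-_RHO_BOUND)
    if target > hi + 0.01 or target < lo - 0.01:
        raise NortaFeasibilityError(
            f"pair ({m1}, {m2}): target correlation {target:.3f} outside "
            f"the attainable range [{lo:.3f}, {hi:.3f}]"
        )
    t = min(max(target, lo), hi)
    if t >= hi:
        return _RHO_BOUND
    if t <= lo:
        return -_RHO_BOUND
    return float(
        optimize.brentq(lambda r: output_corr(r) - t, -_RHO_BOUND, _RHO_BOUND, xtol=1e-4)
    )


def nearest_correlation(matrix: np.ndarray, repair_tol: float = 0.05) -> np.ndarray:
    """Return ``matrix`` if PSD, else the nearest valid correlation matrix.

    Raises if the repair moves any entry by more than ``repair_tol`` —
    a target that far from feasibility is treated as a parameter error.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(matrix), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have a unit diagonal")
    if np.linalg.eigvalsh(matrix).min() >= -1e-10:
        return matrix
    repaired = corr_nearest(matrix, threshold=1e-12, n_fact=200)
    if np.abs(repaired - matrix).max() > repair_tol:
        raise ValueError(
            "target correlation matrix is not positive semi-definite and the "
            f"nearest valid matrix deviates by more than {repair_tol}"
        )
    return np.asarray(repaired)


class NortaGenerator:
    """Sampler for a random vector with given marginals and Pearson targets."""

    def __init__(
        self,
        marginals: Sequence[Marginal],
        target_correlations: np.ndarray,
        repair_tol: float = 0.05,
    ):
        self.marginals = tuple(marginals)
        k = len(self.marginals)
        target = nearest_correlation(np.asarray(target_correlations, float), repair_tol)
        if target.shape != (k, k):
            raise ValueError(
                f"correlation matrix shape {target.shape} does not match "
                f"{k} marginals"
            )
        self.target = target
        self._chol: np.ndarray | None = None

    @property
    def dim(self) -> int:
        return len(self.marginals)

    def intermediate_matrix(self) -> np.ndarray:
        """Pairwise-calibrated normal-scale correlation matrix (PSD-repaired)."""
        k = self.dim
        sigma = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                rho = intermediate_correlation(
                    self.marginals[i], self.marginals[j], float(self.target[i, j])
                )
                sigma[i, j] = sigma[j, i] = rho
        if np.linalg.eigvalsh(sigma).min() < 1e-10:
            sigma = np.asarray(corr_nearest(sigma, threshold=1e-10, n_fact=200))
        return sigma

    def _cholesky(self) -> np.ndarray:
        if self._chol is None:
            sigma = self.intermediate_matrix()
            jitter = 0.0
            for _ in range(10):
                try:
                    self._chol = np.linalg.cholesky(
                        (sigma + jitter * np.eye(self.dim)) / (1.0 + jitter)
                    )
                    break
                except np.linalg.LinAlgError:
                    jitter = max(jitter * 10.0, 1e-12)
            else:  # pragma: no cover - corr_nearest output is PSD
                raise np.linalg.LinAlgError("intermediate matrix not factorizable")
        return self._chol

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw an ``n x k`` matrix with the configured marginals/correlations."""
        if n < 1:
            raise ValueError("n must be >= 1")
        chol = self._cholesky()
        z = rng.standard_normal((n, self.dim)) @ chol.T
        u = ndtr(z)
        out = np.empty((n, self.dim), dtype=np.float64)
        for j, m in enumerate(self.marginals):
            out[:, j] = m.fast_ppf(u[:, j])
        return out
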