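"""Parametric duration laws for gaze timing.

Every dwell time and reaction time in the simulator and in the estimation
pipeline is modelled with one of three positive-duration families that are
standard for human response latencies:

``norm``
    Gaussian with mean ``mu`` (ms) and standard deviation ``rho`` (ms).
    Draws are kept positive by redrawing non-positive values, which slightly
    biases configurations with extreme coefficients of variation.
``lnorm``
    Log-normal with log-mean ``mu`` (log-ms) and log-sd ``rho``.
``exgauss``
    Ex-Gaussian (Gaussian convolved with an exponential): Gaussian component
    ``mu``/``rho`` (ms) and exponential component with mean ``eta`` (ms).
    Its mean is ``mu + eta`` and its SD is ``sqrt(rho**2 + eta**2)``.

Fitting is per participant by maximum likelihood; the family shared across
participants is chosen by the Bayesian information criterion summed over
participants, and the selected family's parameters are then averaged
element-wise across participants (``summarize_parameter``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FAMILIES",
    "MIN_FIT_SIZE",
    "ParameterError",
    "InsufficientDataError",
    "ConsistencyError",
    "DurationDistribution",
    "FitResult",
    "ParameterSummary",
    "sample_duration",
    "dist_moments",
    "bic",
    "fit_family",
    "select_family",
    "summarize_parameter",
]

FAMILIES = ("norm", "lnorm", "exgauss")

#: Minimum number of observations required to fit one participant's data.
MIN_FIT_SIZE = 10

_RHO_FLOOR = 1e-6
_FAMILY_ALIASES = {
    "norm": "norm",
    "normal": "norm",
    "lnorm": "lnorm",
    "lognormal": "lnorm",
    "exgauss": "exgauss",
    "exgaus": "exgauss",
    "exgaussian": "exgauss",
}


class ParameterError(ValueError):
    """Raised for inadmissible distribution parameters."""


class InsufficientDataError(ValueError):
    """Raised when too few observations are available for a fit."""


class ConsistencyError(ValueError):
    """Raised when per-participant fits that must share a family do not."""


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class DurationDistribution:
    """A positive duration law from one of the three supported families.

    Parameters
    ----------
    family : {"norm", "lnorm", "exgauss"}
        Distribution family (case-insensitive aliases accepted).
    mu : float
        Location: mean in ms (norm), log-mean (lnorm), or Gaussian-component
        mean in ms (exgauss).
    rho : float
        Scale: SD in ms (norm/exgauss Gaussian component) or log-sd (lnorm).
        Must be strictly positive.
    eta : float, optional
        Mean of the exponential component in ms; required for (and only
        admissible with) the ex-Gaussian family.
    """

    family: str
    mu: float
    rho: float
    eta: float | None = None

    def __post_init__(self) -> None:
        fam = _FAMILY_ALIASES.get(str(self.family).lower())
        if fam is None:
            raise ParameterError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        object.__setattr__(self, "family", fam)
        if not (self.rho > 0):
            raise ParameterError(f"rho must be > 0, got {self.rho}")
        if fam == "exgauss":
            if self.eta is None or not (self.eta > 0):
                raise ParameterError("exgauss requires eta > 0")
        elif self.eta is not None:
            raise ParameterError(f"eta is only admissible for exgauss, not {fam}")

    @property
    def params(self) -> tuple[float, ...]:
        if self.family == "exgauss":
            return (self.mu, self.rho, float(self.eta))
        return (self.mu, self.rho)

    @property
    def k(self) -> int:
        """Number of free parameters (2 or 3)."""
        return len(self.params)

    def mean(self) -> float:
        if self.family == "norm":
            return float(self.mu)
        if self.family == "lnorm":
            return float(math.exp(self.mu + 0.5 * self.rho**2))
        return float(self.mu + self.eta)

    def sd(self) -> float:
        if self.family == "norm":
            return float(self.rho)
        if self.family == "lnorm":
            return float(math.exp(self.mu + 0.5 * self.rho**2) * math.sqrt(math.expm1(self.rho**2)))
        return float(math.hypot(self.rho, self.eta))

    def moments(self) -> tuple[float, float]:
        """Closed-form (mean, SD) in ms."""
        return self.mean(), self.sd()

    def _draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "norm":
            return rng.normal(self.mu, self.rho, n)
        if self.family == "lnorm":
            return rng.lognormal(self.mu, self.rho, n)
        return rng.normal(self.mu, self.rho, n) + rng.exponential(self.eta, n)

    def sample(self, n: int, seed: int | np.random.Generator | None = None) -> np.ndarray:
        """Draw ``n`` strictly positive durations (ms); non-positive draws are redrawn."""
        if n < 1:
            raise ParameterError(f"n must be >= 1, got {n}")
        rng = _as_rng(seed)
        out = np.empty(n, dtype=float)
        filled = 0
        for _ in range(1000):
            draws = self._draw(n - filled, rng)
            good = draws[draws > 0]
            out[filled : filled + good.size] = good
            filled += good.size
            if filled == n:
                return out
        raise ParameterError(f"could not draw positive durations from {self}")

    def sample_one(self, rng: np.random.Generator) -> float:
        """Single positive draw, for event-driven schedulers."""
        return float(self.sample(1, rng)[0])

    def logpdf(self, x: np.ndarray | float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "norm":
            return stats.norm.logpdf(x, loc=self.mu, scale=self.rho)
        if self.family == "lnorm":
            return stats.lognorm.logpdf(x, s=self.rho, scale=math.exp(self.mu))
        return stats.exponnorm.logpdf(x, self.eta / self.rho, loc=self.mu, scale=self.rho)

    def to_dict(self) -> dict:
        d = {"family": self.family, "mu": float(self.mu), "rho": float(self.rho)}
        if self.eta is not None:
            d["eta"] = float(self.eta)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DurationDistribution":
        return cls(d["family"], float(d["mu"]), float(d["rho"]),
                   float(d["eta"]) if d.get("eta") is not None else None)


def sample_duration(dist: DurationDistribution, n: int,
                    seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` positive durations (ms) from ``dist``; reproducible given ``seed``."""
    return dist.sample(n, seed)


def dist_moments(dist: DurationDistribution) -> tuple[float, float]:
    """Closed-form (mean, SD) of ``dist`` in ms."""
    return dist.moments()


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion: ``k*ln(n) - 2*loglik`` (lower is better)."""
    return k * math.log(n) - 2.0 * loglik


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one family to one participant's durations."""

    family: str
    params: tuple[float, ...]
    loglik: float
    n: int
    bic: float

    @property
    def dist(self) -> DurationDistribution:
        return DurationDistribution(self.family, *self.params)

    def moments(self) -> tuple[float, float]:
        return self.dist.moments()


def _fit_exgauss(x: np.ndarray) -> tuple[float, float, float]:
    # Method-of-moments start (Ratcliff-style skewness split), then bounded
    # quasi-Newton refinement. Fixed initialisation keeps the fit deterministic.
    m = float(x.mean())
    s = float(max(x.std(), _RHO_FLOOR))
    g = float(np.clip(stats.skew(x), 0.01, 2.0))
    eta0 = max(s * (g / 2.0) ** (1.0 / 3.0), 1e-3)
    rho0 = math.sqrt(max(s * s - eta0 * eta0, (0.1 * s) ** 2))
    mu0 = m - eta0

    def nll(theta: np.ndarray) -> float:
        mu, rho, eta = theta
        if rho <= 0 or eta <= 0:
            return 1e12
        lp = stats.exponnorm.logpdf(x, eta / rho, loc=mu, scale=rho)
        if not np.all(np.isfinite(lp)):
            return 1e12
        return float(-lp.sum())

    x0 = np.array([mu0, rho0, eta0])
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B",
        bounds=[(None, None), (_RHO_FLOOR, None), (_RHO_FLOOR, None)],
    )
    theta = res.x if np.isfinite(res.fun) and res.fun <= nll(x0) else x0
    return float(theta[0]), float(max(theta[1], _RHO_FLOOR)), float(max(theta[2], _RHO_FLOOR))


def fit_family(samples: Sequence[float] | np.ndarray, family: str,
               min_n: int = MIN_FIT_SIZE) -> FitResult:
    """Maximum-likelihood fit of ``family`` to positive duration samples (ms).

    norm and lnorm use their closed-form MLEs; exgauss uses a deterministic
    moments-initialised bounded optimisation. Raises
    :class:`InsufficientDataError` below ``min_n`` samples and
    :class:`ParameterError` for non-positive samples with lnorm.
    """
    fam = _FAMILY_ALIASES.get(str(family).lower())
    if fam is None:
        raise ParameterError(f"unknown family {family!r}")
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < min_n:
        raise InsufficientDataError(f"need >= {min_n} samples to fit, got {x.size}")
    if fam == "lnorm" and np.any(x <= 0):
        raise ParameterError("lnorm requires strictly positive samples")

    if fam == "norm":
        params: tuple[float, ...] = (float(x.mean()), float(max(x.std(), _RHO_FLOOR)))
    elif fam == "lnorm":
        lx = np.log(x)
        params = (float(lx.mean()), float(max(lx.std(), _RHO_FLOOR)))
    else:
        params = _fit_exgauss(x)

    dist = DurationDistribution(fam, *params)
    loglik = float(dist.logpdf(x).sum())
    return FitResult(fam, params, loglik, int(x.size), bic(loglik, dist.k, int(x.size)))


def select_family(
    per_participant_samples: Mapping[str, Sequence[float]],
    candidates: Iterable[str] = FAMILIES,
    min_n: int = MIN_FIT_SIZE,
) -> tuple[str, dict[str, FitResult]]:
    """Choose the family minimising total BIC summed over participants.

    Participants with fewer than ``min_n`` observations are dropped from the
    sum symmetrically for all candidate families. Returns the winning family
    and its per-participant fits.
    """
    cands: list[str] = []
    for c in candidates:
        fam = _FAMILY_ALIASES.get(str(c).lower())
        if fam is None:
            raise ParameterError(f"unknown family {c!r}")
        if fam not in cands:
            cands.append(fam)
    if not cands:
        raise ParameterError("no candidate families given")

    eligible = {
        pid: np.asarray(v, dtype=float).ravel()
        for pid, v in per_participant_samples.items()
        if np.asarray(v).size >= min_n
    }
    if not eligible:
        raise InsufficientDataError(
            f"no participant has >= {min_n} observations; cannot select a family")

    best_family: str | None = None
    best_fits: dict[str, FitResult] = {}
    best_total = math.inf
    for fam in cands:
        fits = {pid: fit_family(x, fam, min_n) for pid, x in eligible.items()}
        total = sum(f.bic for f in fits.values())
        if total < best_total:
            best_family, best_fits, best_total = fam, fits, total
    assert best_family is not None
    return best_family, best_fits


@dataclass(frozen=True)
class ParameterSummary:
    """Cross-participant summary of one timing parameter.

    ``mean_params`` is the element-wise average of per-participant fitted
    parameters; ``est_mean``/``est_sd`` are the averages of the per-participant
    closed-form moments (for the ex-Gaussian the two conventions coincide for
    the mean, by linearity; for the log-normal they differ).
    ``raw_mean``/``raw_sd`` are sample moments of the pooled observations.
    """

    parameter_name: str
    family: str
    mean_params: tuple[float, ...]
    est_mean: float
    est_sd: float
    raw_mean: float
    raw_sd: float
    n_participants: int
    n_obs: int


def summarize_parameter(
    name: str,
    fits: Mapping[str, FitResult] | Sequence[FitResult],
    observations: Sequence[float] | np.ndarray | None = None,
) -> ParameterSummary:
    """Average per-participant fits of one timing parameter.

    All fits must share one family (:class:`ConsistencyError` otherwise).
    ``observations`` are the pooled raw values used for the sample-moment
    columns; when omitted those columns are NaN.
    """
    fit_list = list(fits.values()) if isinstance(fits, Mapping) else list(fits)
    if not fit_list:
        raise InsufficientDataError("no fits to summarize")
    families = {f.family for f in fit_list}
    if len(families) > 1:
        raise ConsistencyError(f"mixed families in summary: {sorted(families)}")
    family = fit_list[0].family

    pmat = np.array([f.params for f in fit_list], dtype=float)
    mean_params = tuple(float(v) for v in pmat.mean(axis=0))
    moms = np.array([f.moments() for f in fit_list], dtype=float)
    est_mean, est_sd = (float(v) for v in moms.mean(axis=0))

    if observations is not None:
        obs = np.asarray(observations, dtype=float).ravel()
        raw_mean = float(obs.mean()) if obs.size else math.nan
        raw_sd = float(obs.std(ddof=1)) if obs.size > 1 else 0.0 if obs.size == 1 else math.nan
        n_obs = int(obs.size)
    else:
        raw_mean = raw_sd = math.nan
        n_obs = sum(f.n for f in fit_list)

    return ParameterSummary(
        parameter_name=name,
        family=family,
        mean_params=mean_params,
        est_mean=est_mean,
        est_sd=est_sd,
        raw_mean=raw_mean,
        raw_sd=raw_sd,
        n_participants=len(fit_list),
        n_obs=n_obs,
    )
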