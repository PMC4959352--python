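"""Stationary distribution of the neutral birth–death–influx model and its RSA fit.

The model tracks the abundance ``n`` of one species under per-capita birth
rate ``b``, per-capita death rate ``d`` and a constant influx ``S`` folded
into the birth term, so that births occur at rate ``b*(n + S/b)`` and deaths
at rate ``d*n``.  Ecological neutrality means every species obeys the same
rates, so the stationary law of this single-species chain *is* the relative
species abundance (RSA) distribution of the community.

The stationary law is a Negative Binomial in the two dimensionless ratios
``x = b/d`` (mean-reverting strength, must be < 1 for stationarity) and
``r = S/b`` (the influx-to-birth ratio, the NB shape parameter)::

    P_n = (1 - x)^r / Gamma(r) * x^n / n! * Gamma(n + r)

Observed communities never show the ``n = 0`` class, so the fitted object is
the zero-truncated form scaled to the observed species count ``N_obs``.
Fitting is done on Preston (log2-octave) bin counts by least squares, after
which the total species count ``N`` (zero class included) and the Hubbell
biodiversity number ``theta`` are derived.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .rsa import PrestonHistogram

__all__ = [
    "BirthDeathParams",
    "NeutralFit",
    "ParameterDomainError",
    "PrecisionError",
    "UnderdeterminedFitError",
    "nb_pmf",
    "detailed_balance_pmf",
    "expected_rsa",
    "expected_bin_counts",
    "fit_preston",
    "theta",
]


class ParameterDomainError(ValueError):
    """A model parameter lies outside its admissible domain."""


class PrecisionError(ArithmeticError):
    """A truncation level was insufficient for the requested tolerance."""


class UnderdeterminedFitError(ValueError):
    """Too few informative bins to constrain the two-parameter fit."""


def _check_ratios(ratio_bd: float, ratio_Sb: float) -> None:
    if not (0.0 < ratio_bd < 1.0):
        raise ParameterDomainError(
            f"ratio_bd=b/d must satisfy 0 < b/d < 1, got {ratio_bd!r}"
        )
    if not (ratio_Sb > 0.0):
        raise ParameterDomainError(f"ratio_Sb=S/b must be > 0, got {ratio_Sb!r}")


@dataclasses.dataclass(frozen=True)
class BirthDeathParams:
    """Rates of the birth–death–influx process.

    Parameters
    ----------
    b : float
        Per-capita birth rate (1/time), > 0.
    d : float
        Per-capita death rate (1/time), > 0.  Stationarity requires b < d.
    S : float
        Constant influx (individuals/time), > 0; enters the birth term as
        ``b_n = b*(n + S/b)``.
    """

    b: float
    d: float
    S: float

    def __post_init__(self) -> None:
        for name in ("b", "d", "S"):
            value = getattr(self, name)
            if not (value > 0.0 and math.isfinite(value)):
                raise ParameterDomainError(f"{name} must be positive and finite, got {value!r}")
        if not self.b < self.d:
            raise ParameterDomainError(
                f"stationarity requires b/d < 1, got b/d = {self.b / self.d!r}"
            )

    @property
    def ratio_bd(self) -> float:
        return self.b / self.d

    @property
    def ratio_Sb(self) -> float:
        return self.S / self.b

    @property
    def upsilon(self) -> float:
        """The influx ratio Υ = S/b appearing in the birth rate b_n = b(n+Υ)."""
        return self.S / self.b

    @classmethod
    def from_ratios(cls, ratio_bd: float, ratio_Sb: float, d: float = 1.0) -> "BirthDeathParams":
        """Build rates from the two dimensionless ratios, fixing the time unit via d."""
        _check_ratios(ratio_bd, ratio_Sb)
        b = ratio_bd * d
        return cls(b=b, d=d, S=ratio_Sb * b)

    @property
    def mean_abundance(self) -> float:
        """Fixed point S/(d-b) of the deterministic rate equation."""
        return self.S / (self.d - self.b)


def nb_pmf(n, ratio_bd: float, ratio_Sb: float):
    """Stationary probability of abundance ``n`` (Negative Binomial).

    Computed in log space (log-gamma) and exponentiated at the end, so it is
    usable at ``ratio_bd`` close to 1 and very small ``ratio_Sb``.

    Parameters
    ----------
    n : int or array of int, >= 0
    ratio_bd : float in (0, 1)
    ratio_Sb : float > 0

    Returns
    -------
    float or ndarray : P_n.
    """
    _check_ratios(ratio_bd, ratio_Sb)
    n_arr = np.asarray(n)
    if np.any(n_arr < 0):
        raise ValueError("abundance n must be >= 0")
    x, r = ratio_bd, ratio_Sb
    logp = (
        r * np.log1p(-x)
        - gammaln(r)
        + n_arr * np.log(x)
        - gammaln(n_arr + 1.0)
        + gammaln(n_arr + r)
    )
    out = np.exp(logp)
    return out if out.ndim else float(out)


def detailed_balance_pmf(n_max: int, params: BirthDeathParams) -> np.ndarray:
    """Stationary pmf over 0..n_max from the detailed-balance product.

    Builds ``P_n ∝ Π_{i<n} b_i/d_{i+1}`` with ``b_i = b(i + S/b)`` and
    ``d_i = d*i`` iteratively and normalises by the finite sum.  This is the
    independent route to the stationary law (no Gamma functions) and serves
    as the oracle for :func:`nb_pmf`.

    Raises
    ------
    PrecisionError
        If the truncation at ``n_max`` leaves an estimated tail mass above
        1e-12 of the total.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    x = params.ratio_bd
    r = params.ratio_Sb
    # work in log space: the unnormalised weights can overflow long before
    # the normalised pmf becomes negligible
    logw = np.empty(n_max + 1)
    logw[0] = 0.0
    i = np.arange(n_max, dtype=float)
    logw[1:] = np.cumsum(np.log(x) + np.log(i + r) - np.log(i + 1.0))
    logw -= logw.max()
    w = np.exp(logw)
    total = w.sum()
    pmf = w / total
    # geometric bound on the truncated tail: the ratio P_{n+1}/P_n tends to x
    ratio_at_cut = x * (n_max + r) / (n_max + 1.0)
    rho = max(x, ratio_at_cut)
    if rho >= 1.0:
        raise PrecisionError("cannot bound tail mass: increase n_max")
    tail_bound = pmf[-1] * rho / (1.0 - rho)
    if tail_bound > 1e-12:
        raise PrecisionError(
            f"truncation at n_max={n_max} leaves tail mass bound {tail_bound:.3e} > 1e-12"
        )
    return pmf


def _p0(ratio_bd: float, ratio_Sb: float) -> float:
    return math.exp(ratio_Sb * math.log1p(-ratio_bd))


def _one_minus_p0(ratio_bd: float, ratio_Sb: float) -> float:
    # 1 - (1-x)^r without cancellation when the power is close to 1
    return -math.expm1(ratio_Sb * math.log1p(-ratio_bd))


def expected_rsa(n, ratio_bd: float, ratio_Sb: float, n_obs: float):
    """Expected number of species with abundance ``n`` (zero-truncated RSA).

    ``expected_rsa(n) = n_obs * P_n / (1 - P_0)`` for ``n >= 1``; the zero
    class is removed because unobserved species cannot be counted, and the
    law is rescaled so that the expected counts over ``n >= 1`` sum to the
    observed species total ``n_obs``.
    """
    n_arr = np.asarray(n)
    if np.any(n_arr < 1):
        raise ValueError("the truncated RSA is defined for n >= 1")
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    scale = n_obs / _one_minus_p0(ratio_bd, ratio_Sb)
    out = scale * nb_pmf(n_arr, ratio_bd, ratio_Sb)
    return out if np.ndim(out) else float(out)


def _nbinom(ratio_bd: float, ratio_Sb: float):
    # scipy parametrisation: pmf(k) = C(k+r-1, k) p^r (1-p)^k with p = 1-x
    return stats.nbinom(ratio_Sb, 1.0 - ratio_bd)


def expected_bin_counts(
    ratio_bd: float,
    ratio_Sb: float,
    n_obs: float,
    n_bins: int,
) -> np.ndarray:
    """Expected species count per Preston octave ``[2^k, 2^{k+1})``, k=0..n_bins-1.

    Each bin mass is the difference of the Negative Binomial survival
    function at the bin boundaries (equivalently the difference of the
    cumulative at the bin maximum and minimum), rescaled by the
    zero-truncation factor.  ``n_bins`` octaves are returned; the model mass
    beyond the last octave is *not* folded in.
    """
    _check_ratios(ratio_bd, ratio_Sb)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    dist = _nbinom(ratio_bd, ratio_Sb)
    k = np.arange(n_bins)
    lo = 2**k          # bin covers integers lo .. hi
    hi = 2 ** (k + 1) - 1
    # P(lo <= X <= hi) = sf(lo - 1) - sf(hi); the survival form keeps
    # relative accuracy in deep-tail octaves where cdf differences cancel
    mass = dist.sf(lo - 1) - dist.sf(hi)
    return n_obs / _one_minus_p0(ratio_bd, ratio_Sb) * mass


def predicted_tail_mass(ratio_bd: float, ratio_Sb: float, n_obs: float, n_bins: int) -> float:
    """Expected species count the model puts beyond the last octave (diagnostic)."""
    dist = _nbinom(ratio_bd, ratio_Sb)
    return float(n_obs / _one_minus_p0(ratio_bd, ratio_Sb) * dist.sf(2**n_bins - 1))


def theta(ratio_bd: float, ratio_Sb: float, n_obs: float) -> float:
    """Hubbell biodiversity number of the fitted community.

    ``theta = n_obs / ( [ (1-x)^{-r} - 1 ] * Gamma(r) )`` with ``x = b/d``
    and ``r = S/b``.  Evaluated in log space so that ``Gamma(r)`` for tiny
    ``r`` (the log-series regime) and near-one ``x`` do not overflow.
    """
    _check_ratios(ratio_bd, ratio_Sb)
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    a = -ratio_Sb * math.log1p(-ratio_bd)  # a > 0; (1-x)^{-r} = e^a
    # log(e^a - 1)
    log_em1 = a + math.log1p(-math.exp(-a)) if a > 1e-8 else math.log(math.expm1(a))
    log_theta = math.log(n_obs) - log_em1 - gammaln(ratio_Sb)
    return math.exp(log_theta)


@dataclasses.dataclass
class NeutralFit:
    """Result of fitting the zero-truncated Negative Binomial to a Preston histogram.

    Attributes
    ----------
    ratio_bd, ratio_Sb : fitted b/d and S/b.
    n_obs : observed species count (histogram total), held fixed in the fit.
    n_total : estimated total species count N = n_obs / (1 - P_0) (zero class included).
    theta : Hubbell biodiversity number.
    r_squared : 1 - SS_res/SS_tot on the bin counts (SS_tot about the bin mean).
    converged : whether any optimiser start reported convergence.
    objective : residual sum of squares (lsq mode) or negative log-likelihood (mle).
    mode : "lsq" or "mle".
    observed, expected : per-octave observed and fitted expected species counts.
    tail_mass : expected species count the fit places beyond the last octave.
    """

    ratio_bd: float
    ratio_Sb: float
    n_obs: float
    n_total: float
    theta: float
    r_squared: float
    converged: bool
    objective: float
    mode: str
    observed: np.ndarray
    expected: np.ndarray
    tail_mass: float

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["observed"] = [float(v) for v in self.observed]
        d["expected"] = [float(v) for v in self.expected]
        return d


# starting grid for the multistart search, in natural coordinates
_START_BD = (0.5, 0.9, 0.99, 0.999)
_START_SB = (0.05, 1.0)


def _from_u(u: np.ndarray) -> tuple[float, float]:
    # u = (logit(x), log(r)) keeps both parameters in-domain unconstrained
    x = 1.0 / (1.0 + math.exp(-u[0]))
    r = math.exp(u[1])
    return x, r


def _to_u(x: float, r: float) -> np.ndarray:
    return np.array([math.log(x / (1.0 - x)), math.log(r)])


def fit_preston(hist, mode: str = "lsq") -> NeutralFit:
    """Fit (b/d, S/b) to a Preston histogram with n_obs fixed at the species total.

    ``hist`` is a :class:`~neutralrsa.rsa.PrestonHistogram` or a plain array
    of per-octave species counts (octave k first; fractional counts are
    allowed, e.g. exact model expectations).  ``mode="lsq"`` (default)
    minimises the unweighted sum of squared residuals between observed and
    expected octave counts; ``mode="mle"`` maximises the multinomial
    likelihood of the octave counts (with the beyond-histogram tail as an
    extra, empty category).  Both use a derivative-free Nelder–Mead search
    over (logit(b/d), log(S/b)) from 8 fixed starting points.

    Raises
    ------
    UnderdeterminedFitError
        If fewer than 3 octaves are non-empty.
    """
    if mode not in ("lsq", "mle"):
        raise ValueError(f"mode must be 'lsq' or 'mle', got {mode!r}")
    counts = hist.species_count if isinstance(hist, PrestonHistogram) else hist
    observed = np.asarray(counts, dtype=float)
    n_bins = observed.size
    n_obs = float(observed.sum())
    if np.count_nonzero(observed) < 3:
        warnings.warn("fewer than 3 non-empty octaves: two-parameter fit is underdetermined")
        raise UnderdeterminedFitError(
            f"need >= 3 non-empty octaves, got {np.count_nonzero(observed)}"
        )

    def residuals(u: np.ndarray) -> float:
        x, r = _from_u(u)
        if not (0.0 < x < 1.0) or not (r > 0.0) or not math.isfinite(r):
            return np.inf
        expected = expected_bin_counts(x, r, n_obs, n_bins)
        if mode == "lsq":
            return float(np.sum((observed - expected) ** 2))
        # multinomial NLL over octaves; the beyond-histogram tail is an
        # implicit extra category with zero observations
        probs = expected / n_obs
        with np.errstate(divide="ignore"):
            logp = np.log(np.clip(probs, 1e-300, None))
        return -float(np.sum(observed * logp))

    best = None
    converged = False
    for x0 in _START_BD:
        for r0 in _START_SB:
            res = optimize.minimize(
                residuals,
                _to_u(x0, r0),
                method="Nelder-Mead",
                options={"fatol": 1e-10, "xatol": 1e-8, "maxfev": 10_000},
            )
            if best is None or res.fun < best.fun:
                best = res
            converged = converged or bool(res.success)
    assert best is not None
    x_hat, r_hat = _from_u(best.x)
    expected = expected_bin_counts(x_hat, r_hat, n_obs, n_bins)
    ss_res = float(np.sum((observed - expected) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return NeutralFit(
        ratio_bd=x_hat,
        ratio_Sb=r_hat,
        n_obs=n_obs,
        n_total=n_obs / _one_minus_p0(x_hat, r_hat),
        theta=theta(x_hat, r_hat, n_obs),
        r_squared=r_squared,
        converged=converged,
        objective=float(best.fun),
        mode=mode,
        observed=observed,
        expected=expected,
        tail_mass=predicted_tail_mass(x_hat, r_hat, n_obs, n_bins),
    )
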