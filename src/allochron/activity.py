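"""Circadian activity profiles and the nightly mate-encounter process.

Each adult moth is characterised by a circadian timing trait ``tau`` in
[0, 1] (0 = start of the night, 1 = end of the night).  Its activity
profile over the night is

    A(t; tau) = sqrt( Gamma(a+2) / (Gamma(1+a*tau) * Gamma(1+a*(1-tau))) )
                * t**(a*tau/2) * (1-t)**(a*(1-tau)/2)

so that ``A(t; tau)**2`` is the Beta(1 + a*tau, 1 + a*(1-tau)) density: it
integrates to one over the night, and for a > 0 it is unimodal with its
maximum at t = tau.  The shape parameter ``a`` controls the narrowness of
the profile (a = 0 gives a flat, always-active profile).

The number of encounters between a female i and a male j during one night
is Poisson with mean

    lambda(tau_f, tau_m) = eta * Integral_0^1 A(t; tau_f) A(t; tau_m) dt,

and the time of each encounter is distributed as the normalised product of
the two profiles, which is again a beta density centred on the average
timing of the pair:  Q(t; tau_f, tau_m) = A(t; (tau_f+tau_m)/2)**2.

Because the profiles are normalised, ``eta`` is exactly the expected number
of encounters per night between two individuals with identical timing, so
no timing phenotype enjoys an intrinsic encounter-rate advantage in a
monomorphic population.

The overlap integral has a closed form via log-gamma identities (the
integrand is an unnormalised beta kernel); quadrature is only used as an
independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ActivityParams",
    "activity",
    "encounter_time_density",
    "pair_encounter_mean",
    "pair_encounter_matrix",
    "sample_encounter_count",
    "sample_encounter_time",
]

#: pairs with an expected encounter rate below this are treated as never meeting
LAMBDA_FLOOR = 1e-12


@dataclass(frozen=True)
class ActivityParams:
    """Parameters of the encounter process.

    a
        Narrowness of the activity profile (dimensionless, >= 0); larger
        values concentrate activity around ``tau``.
    eta
        Encounter-rate scale: expected encounters per night between two
        individuals with identical activity profiles (>= 0).
    """

    a: float = 50.0
    eta: float = 25.0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"profile narrowness a must be >= 0, got {self.a}")
        if self.eta < 0:
            raise ValueError(f"encounter rate eta must be >= 0, got {self.eta}")


def _check_unit(name: str, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any((x < 0.0) | (x > 1.0)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return x


def _log_norm(tau: np.ndarray, a: float) -> np.ndarray:
    """log of the normalising constant of the beta density A(t; tau)^2."""
    return gammaln(a + 2.0) - gammaln(1.0 + a * tau) - gammaln(1.0 + a * (1.0 - tau))


def activity(t, tau, a: float):
    """Activity A(t; tau) of an individual with timing ``tau`` at night-time ``t``.

    ``A(t; tau)**2`` is the Beta(1+a*tau, 1+a*(1-tau)) density.  Evaluated in
    log space; endpoints with negative exponents diverge (the density itself
    remains integrable) and are returned as ``inf``.
    """
    t = _check_unit("t", t)
    tau = _check_unit("tau", tau)
    if a < 0:
        raise ValueError("a must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_t = np.where(t > 0.0, np.log(np.where(t > 0.0, t, 1.0)), -np.inf)
        log_1mt = np.where(t < 1.0, np.log(np.where(t < 1.0, 1.0 - t, 1.0)), -np.inf)
        log_a = (
            0.5 * _log_norm(tau, a)
            + 0.5 * a * tau * log_t
            + 0.5 * a * (1.0 - tau) * log_1mt
        )
        # 0 * -inf at an endpoint with zero exponent means the factor is t**0 = 1
        log_a = np.where(np.isnan(log_a), 0.5 * _log_norm(tau, a), log_a)
    out = np.exp(log_a)
    return out if out.ndim else float(out)


def encounter_time_density(t, tau_f, tau_m, a: float):
    """Density Q(t; tau_f, tau_m) of the encounter time of a mixed pair.

    Equal to ``A(t; (tau_f+tau_m)/2)**2`` — a beta density centred on the
    pair's average timing.
    """
    tau_f = _check_unit("tau_f", tau_f)
    tau_m = _check_unit("tau_m", tau_m)
    tau_bar = (tau_f + tau_m) / 2.0
    return activity(t, tau_bar, a) ** 2


def pair_encounter_mean(tau_f, tau_m, params: ActivityParams):
    """Expected number of nightly encounters lambda(tau_f, tau_m).

    Closed form: the product A(t;tau_f)*A(t;tau_m) is an unnormalised beta
    kernel in t with mean exponent (tau_f+tau_m)/2, so the overlap integral
    is a ratio of gamma functions, evaluated stably in log space.  Symmetric
    in its two timing arguments, maximal (= eta) when tau_f == tau_m.
    """
    tau_f = _check_unit("tau_f", tau_f)
    tau_m = _check_unit("tau_m", tau_m)
    a = params.a
    tau_bar = (tau_f + tau_m) / 2.0
    log_overlap = (
        0.5 * _log_norm(tau_f, a)
        + 0.5 * _log_norm(tau_m, a)
        - _log_norm(tau_bar, a)
    )
    out = params.eta * np.exp(log_overlap)
    return out if np.ndim(out) else float(out)


def pair_encounter_matrix(tau_f, tau_m, params: ActivityParams) -> np.ndarray:
    """Encounter-rate matrix lambda[i, j] for females i crossed with males j.

    Rates below ``LAMBDA_FLOOR`` are clipped to zero (such pairs would meet
    less than once per 10^12 nights).
    """
    tau_f = np.atleast_1d(_check_unit("tau_f", tau_f))
    tau_m = np.atleast_1d(_check_unit("tau_m", tau_m))
    a = params.a
    half_norm_f = 0.5 * _log_norm(tau_f, a)
    half_norm_m = 0.5 * _log_norm(tau_m, a)
    tau_bar = (tau_f[:, None] + tau_m[None, :]) / 2.0
    log_overlap = half_norm_f[:, None] + half_norm_m[None, :] - _log_norm(tau_bar, a)
    lam = params.eta * np.exp(log_overlap)
    lam[lam < LAMBDA_FLOOR] = 0.0
    return lam


def sample_encounter_count(lam, rng: np.random.Generator):
    """Poisson number of encounters of a pair (or array of pairs) in one night."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("encounter rate lambda must be >= 0")
    out = rng.poisson(lam)
    return out if np.ndim(lam) else int(out)


def sample_encounter_time(tau_f, tau_m, a: float, rng: np.random.Generator, size=None):
    """Sample encounter time(s) of a pair from Q(t; tau_f, tau_m).

    Q is the Beta(1 + a*tau_bar, 1 + a*(1-tau_bar)) density with
    tau_bar = (tau_f + tau_m)/2.
    """
    tau_f = _check_unit("tau_f", tau_f)
    tau_m = _check_unit("tau_m", tau_m)
    tau_bar = (np.asarray(tau_f, dtype=float) + np.asarray(tau_m, dtype=float)) / 2.0
    return rng.beta(1.0 + a * tau_bar, 1.0 + a * (1.0 - tau_bar), size=size)
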