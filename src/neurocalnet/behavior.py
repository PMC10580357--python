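"""Behavioral pain-threshold estimators.

* :func:`updown_threshold` — Dixon's up-down 50% mechanical withdrawal
  threshold from a von Frey filament staircase.  The estimate has the
  classical form ``10**(Xf + k*delta)`` on the log10-force scale, where
  ``Xf`` is the final applied force, ``delta`` the mean log-spacing of
  the filament set, and ``k`` Dixon's adjustment for the realized
  response pattern.  Rather than hard-coding the printed k-table, ``k``
  is recomputed from Dixon's underlying construction: the maximum-
  likelihood location of a cumulative-normal psychometric with its SD
  fixed at one filament step.  This reproduces the tabulated values
  (e.g. k = -0.5 for a negative->positive ending, +0.5 for the mirror
  pattern) for arbitrary sequence lengths and filament sets, and makes
  the estimator exactly scale-equivariant.
* :func:`logistic_mle_threshold` — an independent logistic-psychometric
  maximum-likelihood estimator on the same sessions, used as a
  cross-validation oracle for the Dixon estimator.
* :func:`latency_summary` — tail-immersion latency mean with a cutoff
  censoring flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit, log_ndtr

__all__ = [
    "UpDownSession",
    "LatencyTrials",
    "updown_threshold",
    "dixon_k",
    "logistic_mle_threshold",
    "latency_summary",
]


@dataclass
class UpDownSession:
    """One von Frey up-down staircase: forces applied, responses observed."""

    forces: list[float]
    responses: list[bool]  # True = paw withdrawal (positive response)
    filament_set: list[float]

    def __post_init__(self) -> None:
        if len(self.forces) != len(self.responses):
            raise ValueError("forces and responses must have equal length")
        if len(self.filament_set) < 2:
            raise ValueError("need at least 2 filaments")
        fs = sorted(self.filament_set)
        if any(a >= b for a, b in zip(fs, fs[1:])):
            raise ValueError("filament_set must be strictly increasing")
        if any(f <= 0 for f in fs):
            raise ValueError("filament forces must be positive")
        self.filament_set = fs
        tol = 1e-9
        for f in self.forces:
            if not any(abs(f - g) <= tol * max(1.0, g) for g in fs):
                raise ValueError(f"applied force {f} g not in filament set")


@dataclass
class LatencyTrials:
    """Tail-immersion latencies at one bath temperature, with cutoff."""

    temperature: float
    latencies: list[float]
    cutoff: float = 15.0

    def __post_init__(self) -> None:
        if self.temperature not in (46.0, 48.0, 52.0):
            raise ValueError("temperature must be 46, 48 or 52 °C")
        if not self.latencies:
            raise ValueError("need at least one trial")
        for lat in self.latencies:
            if not 0 < lat <= self.cutoff:
                raise ValueError(f"latency {lat} s outside (0, cutoff={self.cutoff}]")


def _check_updown_consistency(session: UpDownSession) -> bool:
    """True when the force sequence follows the up-down rule within range."""
    fs = session.filament_set
    for prev_f, prev_r, cur_f in zip(session.forces, session.responses,
                                     session.forces[1:]):
        i = min(range(len(fs)), key=lambda j: abs(fs[j] - prev_f))
        expect = fs[max(i - 1, 0)] if prev_r else fs[min(i + 1, len(fs) - 1)]
        if abs(cur_f - expect) > 1e-9 * max(1.0, expect):
            return False
    return True


def dixon_k(
    forces_log: np.ndarray,
    responses: np.ndarray,
    sigma: float,
    delta: float,
) -> float:
    """Dixon's adjustment k for one realized up-down sequence.

    Computed as ``(mu_hat - x_final) / delta`` where ``mu_hat`` maximizes
    the cumulative-normal psychometric likelihood with SD fixed at
    ``sigma`` (Dixon's tabulation assumes sigma equal to the step size).
    Requires both response types to be present (otherwise the likelihood
    has no interior maximum and the boundary rule applies).
    """
    responses = np.asarray(responses, dtype=bool)
    forces_log = np.asarray(forces_log, dtype=float)

    def nll(mu: float) -> float:
        zs = (forces_log - mu) / sigma
        # log Phi(z) for positives, log Phi(-z) for negatives
        return -float(np.sum(np.where(responses, log_ndtr(zs), log_ndtr(-zs))))

    lo = forces_log.min() - 6 * sigma
    hi = forces_log.max() + 6 * sigma
    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float((res.x - forces_log[-1]) / delta)


def updown_threshold(
    session: UpDownSession,
    psychometric_sd: float | None = None,
) -> float:
    """Dixon up-down 50% withdrawal threshold in grams.

    Boundary conventions: a session with only negative responses (animal
    never withdraws, staircase pinned at the top) returns the maximum
    filament force; only positive responses return the minimum.
    ``psychometric_sd`` (log10 units) defaults to the mean log-step of
    the filament set, Dixon's tabulation assumption.
    """
    responses = np.asarray(session.responses, dtype=bool)
    fs = np.asarray(session.filament_set, dtype=float)
    if not responses.any():
        return float(fs.max())
    if responses.all():
        return float(fs.min())
    if not _check_updown_consistency(session):
        warnings.warn(
            "force sequence inconsistent with the up-down rule; "
            "computing the estimate anyway",
            stacklevel=2,
        )
    log_fs = np.log10(fs)
    delta = float(np.mean(np.diff(log_fs)))
    sigma = psychometric_sd if psychometric_sd is not None else delta
    x = np.log10(np.asarray(session.forces, dtype=float))
    k = dixon_k(x, responses, sigma=sigma, delta=delta)
    return float(10.0 ** (x[-1] + k * delta))


def logistic_mle_threshold(
    session: UpDownSession,
    slope_log10: float | None = None,
) -> float:
    """Brute-force logistic-psychometric MLE of the 50% threshold (grams).

    P(withdrawal | force F) = expit((log10 F - log10 theta) / s) with the
    slope parameter ``s`` fixed (default: the mean log-step of the
    filament set).  Kept deliberately independent of
    :func:`updown_threshold` — different psychometric family, direct
    likelihood maximization — so it can serve as a validation oracle.
    Boundary conventions match the Dixon estimator.
    """
    responses = np.asarray(session.responses, dtype=bool)
    fs = np.asarray(session.filament_set, dtype=float)
    if not responses.any():
        return float(fs.max())
    if responses.all():
        return float(fs.min())
    log_fs = np.log10(fs)
    s = slope_log10 if slope_log10 is not None else float(np.mean(np.diff(log_fs)))
    x = np.log10(np.asarray(session.forces, dtype=float))

    def nll(mu: float) -> float:
        p = expit((x - mu) / s)
        eps = 1e-12
        return -float(
            np.sum(np.where(responses, np.log(p + eps), np.log(1 - p + eps)))
        )

    res = minimize_scalar(
        nll,
        bounds=(log_fs.min() - 6 * s, log_fs.max() + 6 * s),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(10.0 ** res.x)


@dataclass
class LatencySummary:
    mean_latency: float
    censored: bool
    n_trials: int


def latency_summary(trials: LatencyTrials) -> LatencySummary:
    """Arithmetic mean of the (typically three) tail-flick latencies.

    Any trial at the cutoff marks the summary as censored: the true
    latency is only known to be at least the cutoff, so the mean is a
    lower bound there.
    """
    lats = np.asarray(trials.latencies, dtype=float)
    return LatencySummary(
        mean_latency=float(lats.mean()),
        censored=bool(np.any(lats >= trials.cutoff)),
        n_trials=lats.size,
    )
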