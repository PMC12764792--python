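"""Deterministic gametic-recursion baseline for diploid-tetraploid mixtures.

The classical infinite-population recursion with inviable triploids: each
generation diploids contribute x gametes (fraction 1 - p) and unreduced 2x
gametes (fraction p), tetraploids contribute reduced 2x gametes, gametes
unite at random, x + 2x fusions (triploids) die, and tetraploid fertility f
and viability v are expressed relative to the diploid's.  Under equal
fitness the diploid persists only while p < 3 - 2*sqrt(2) = 17.16%; doubling
both tetraploid fertility and viability lowers the exclusion threshold to
9 - 4*sqrt(5) = 5.57% (~6%).

``find_exclusion_threshold`` locates the critical unreduced-gamete rate
either by bisection on this recursion or by scanning the spatial agent-based
model run under the equivalent conditions (the ``felber_config`` preset:
inviable triploids, uniform environment, distance-free mating).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import felber_config
from .engine import run_replicate


class BaselineError(ValueError):
    pass


@dataclass
class RecursionState:
    """Cytotype frequencies plus the gamete and fitness parameters."""

    freq_2x: float = 1.0
    freq_4x: float = 0.0
    unreduced_rate: float = 0.1
    fertility_4x: float = 1.0  # relative to diploid
    viability_4x: float = 1.0

    def __post_init__(self) -> None:
        if not np.isclose(self.freq_2x + self.freq_4x, 1.0):
            raise BaselineError("cytotype frequencies must sum to 1")
        if not 0.0 <= self.unreduced_rate <= 1.0:
            raise BaselineError("unreduced rate must lie in [0, 1]")
        if self.fertility_4x <= 0 or self.viability_4x <= 0:
            raise BaselineError("relative fitness parameters must be positive")


def _step_frequencies(
    d: np.ndarray, p: np.ndarray, f: float, v: float
) -> np.ndarray:
    """One generation of the random-union recursion; returns the new diploid
    frequency (vectorized over arrays of states/rates)."""
    t = 1.0 - d
    w = d + f * t
    px = d * (1.0 - p) / w
    p2 = (d * p + f * t) / w
    w2 = px * px
    w4 = v * p2 * p2
    total = w2 + w4
    return np.where(total > 0, w2 / np.maximum(total, 1e-300), 0.0)


def iterate_recursion(state: RecursionState, generations: int) -> np.ndarray:
    """Frequency trajectory; row g holds (freq_2x, freq_4x) after g steps."""
    if generations < 0:
        raise BaselineError("generations must be >= 0")
    d = state.freq_2x
    traj = np.empty((generations + 1, 2))
    traj[0] = (d, 1.0 - d)
    for g in range(1, generations + 1):
        d = float(
            _step_frequencies(
                np.asarray(d), np.asarray(state.unreduced_rate),
                state.fertility_4x, state.viability_4x,
            )
        )
        traj[g] = (d, 1.0 - d)
    return traj


def _diploid_excluded(
    p: np.ndarray,
    fertility_4x: float,
    viability_4x: float,
    generations: int = 200_000,
    d0: float = 0.999,
    tol: float = 1e-12,
) -> np.ndarray:
    """Vectorized over p: does the recursion drive the diploid to extinction?"""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    d = np.full(p.shape, d0)
    for _ in range(generations):
        d_new = _step_frequencies(d, p, fertility_4x, viability_4x)
        if np.all(np.abs(d_new - d) < tol):
            d = d_new
            break
        d = d_new
    return d < 1e-6


def exclusion_threshold_exact(fertility_4x: float = 1.0, viability_4x: float = 1.0) -> float:
    """Closed-form critical rate: the interior fixed point of the recursion
    exists only while v*(p + f*tau)^2 = (1-p)^2*tau has a positive root."""
    # tau = t/d solves  v*f^2*tau^2 + (2*v*f*p - (1-p)^2)*tau + v*p^2 = 0;
    # the discriminant vanishes at (1-p)^2 = 4*sqrt(v)*f*p ... solved numerically
    # for general (f, v); equal fitness gives 3 - 2*sqrt(2).
    from scipy.optimize import brentq

    f, v = fertility_4x, viability_4x

    def disc(p: float) -> float:
        a = v * f * f
        b = 2.0 * v * f * p - (1.0 - p) ** 2
        c = v * p * p
        if b >= 0:  # no positive root regardless of discriminant
            return -1.0
        return b * b - 4.0 * a * c

    return float(brentq(disc, 1e-9, 0.5, xtol=1e-12))


def find_exclusion_threshold(
    model_variant: str = "deterministic",
    scan: tuple[float, float, float] = (0.10, 0.20, 0.005),
    tolerance: float = 1e-5,
    fertility_4x: float = 1.0,
    viability_4x: float = 1.0,
    replicates: int = 5,
    root_seed: int = 0,
    grid_side: int = 32,
) -> float:
    """Critical unreduced-gamete rate for diploid exclusion.

    ``deterministic``: bisection on the recursion over the scan interval,
    refined to ``tolerance``.  ``abm``: for each scanned rate, run
    ``replicates`` spatial replicates under the recursion-equivalent preset
    and return the smallest rate at which diploids go extinct in the majority
    of them (NaN if none does).
    """
    lo, hi, step = scan
    if not (0.0 <= lo < hi <= 1.0) or step <= 0:
        raise BaselineError(f"bad scan range {scan}")

    if model_variant == "deterministic":
        if _diploid_excluded(lo, fertility_4x, viability_4x)[0]:
            raise BaselineError("scan lower bound already excludes diploids; widen the scan")
        if not _diploid_excluded(hi, fertility_4x, viability_4x)[0]:
            raise BaselineError("scan upper bound keeps a mixed population; widen the scan")
        a, b = lo, hi
        while b - a > tolerance:
            mid = 0.5 * (a + b)
            if _diploid_excluded(mid, fertility_4x, viability_4x)[0]:
                b = mid
            else:
                a = mid
        return 0.5 * (a + b)

    if model_variant == "abm":
        rates = np.arange(lo, hi + 0.5 * step, step)
        for rate in rates:
            cfg = felber_config(unreduced_rate=float(rate), grid_side=grid_side)
            excluded = 0
            for rep in range(replicates):
                seed = int(
                    np.random.SeedSequence([root_seed, int(round(rate * 1e6)), rep])
                    .generate_state(1)[0]
                    & 0x7FFFFFFF
                )
                summary, _ = run_replicate(cfg, seed)
                c2, c3, _c4 = summary.final_census
                if c2 == 0 and c3 == 0 and summary.stop_reason != "extinct":
                    excluded += 1
            if excluded * 2 > replicates:
                return float(rate)
        return float("nan")

    raise BaselineError(f"unknown model variant {model_variant!r}")
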