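"""Plant agents: environmental fitness, fecundity, survival, founding.

Each plant is a hermaphroditic perennial characterised by its ploidy (2x, 3x
or 4x), its age in running cycles, and a five-component Individual
Adaptivity vector (IA) expressed in the same units as the environmental
variables V1..V5.  The environmental component of fitness on a patch is

    E_i = 2 ** ( -|IA_i - V_i * SV| / Limit_i )

per variable, combined (by default) as the geometric mean over the five
variables, so E = 1 exactly when the plant's optimum matches the patch and a
deviation equal to the tolerance limit halves the per-variable component.

E modulates everything demographic: realized fecundity (binomial thinning of
an age-determined cap of 3/6/10 seeds), and the lifespan cap fixed at
establishment (ceil(10 * E) cycles, on top of a flat 10% per-cycle hazard).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .environment import N_LAYERS, EnvironmentGrid, sv_vector

PLOIDIES = (2, 3, 4)

FECUNDITY_CAPS = (3, 6, 10)  # age 1 / age 2 / age >= 3
BASE_LIFESPAN = 10  # cycles at E = 1
DEATH_RATE = 0.1  # flat per-cycle hazard

CombineRule = Literal["geometric", "product", "min"]


class DemographyConfigError(ValueError):
    pass


def _default_limits() -> np.ndarray:
    # Tolerance half-widths for V1..V5 in layer units.  Generous for the
    # near-uniform bioclimatic layers, restrictive for the patchy soil layers
    # (which therefore bound the occupiable area); calibrated together with
    # the synthetic-landscape amplitudes to a ~1000-plant diploid census.
    return np.array([400.0, 1.5, 25.0, 5.0, 3.0])


@dataclass
class ToleranceConfig:
    """Ecological tolerance limits (diploid/triploid baseline) per variable.

    ``limit_multiplier_4x`` rescales every limit for tetraploids: values < 1
    contract and values > 1 broaden the tetraploid niche relative to the
    diploid parents (the swept variable of the tolerance experiments).
    """

    limit: np.ndarray = field(default_factory=_default_limits)
    limit_multiplier_4x: float = 1.0

    def __post_init__(self) -> None:
        self.limit = np.asarray(self.limit, dtype=float)
        if self.limit.shape != (N_LAYERS,):
            raise DemographyConfigError(f"limit must have {N_LAYERS} entries")
        if np.any(self.limit <= 0) or self.limit_multiplier_4x <= 0:
            raise DemographyConfigError("tolerance limits must be strictly positive")

    def limits_for(self, ploidy: int | np.ndarray) -> np.ndarray:
        """Per-variable limits for a ploidy (or array of ploidies)."""
        mult = np.where(np.asarray(ploidy) == 4, self.limit_multiplier_4x, 1.0)
        return self.limit * np.atleast_1d(mult)[..., None] if np.ndim(mult) else self.limit * mult


@dataclass
class Plant:
    """One agent.  ``ia`` holds the five adaptivity values; ``event_id`` tags
    the polyploidization event founding its tetraploid lineage (-1 = none)."""

    id: int
    ploidy: int
    age: int
    ia: np.ndarray
    x: int
    y: int
    event_id: int = -1
    e: float = 1.0
    max_age: int = BASE_LIFESPAN

    def __post_init__(self) -> None:
        if self.ploidy not in PLOIDIES:
            raise DemographyConfigError(f"ploidy must be one of {PLOIDIES}")
        self.ia = np.asarray(self.ia, dtype=float)
        if self.ia.shape != (N_LAYERS,) or not np.all(np.isfinite(self.ia)):
            raise DemographyConfigError("ia must be a finite 5-vector")


# -- fitness ----------------------------------------------------------------


def fitness_component(ia_i: float, v_eff_i: float, limit_i: float) -> float:
    """Single-variable environmental fitness: 2**(-|ia - v|/limit)."""
    if limit_i <= 0:
        raise DemographyConfigError(f"tolerance limit must be > 0, got {limit_i}")
    if not (math.isfinite(ia_i) and math.isfinite(v_eff_i)):
        return 0.0
    return 2.0 ** (-abs(ia_i - v_eff_i) / limit_i)


def combined_fitness(components, rule: CombineRule = "geometric") -> float:
    """Combine the five per-variable components into a single E in [0, 1]."""
    comps = np.asarray(components, dtype=float)
    if np.any((comps < 0) | (comps > 1)):
        raise DemographyConfigError("fitness components must lie in [0, 1]")
    if rule == "geometric":
        return float(np.prod(comps) ** (1.0 / len(comps)))
    if rule == "product":
        return float(np.prod(comps))
    if rule == "min":
        return float(np.min(comps))
    raise DemographyConfigError(f"unknown combination rule {rule!r}")


def environmental_fitness(
    ia: np.ndarray,
    v_eff: np.ndarray,
    limits: np.ndarray,
    rule: CombineRule = "geometric",
) -> np.ndarray:
    """Vectorized E for many plants.

    ``ia`` and ``limits`` are (n, 5), ``v_eff`` is (5, n) (layer-major, as
    returned by :meth:`EnvironmentGrid.values_at`).  NaN environmental values
    (nodata patches) force E = 0.
    """
    dev = np.abs(ia - v_eff.T) / limits
    dev = np.where(np.isfinite(dev), dev, np.inf)
    if rule == "geometric":
        expo = dev.mean(axis=1)
    elif rule == "product":
        expo = dev.sum(axis=1)
    else:  # min component
        expo = dev.max(axis=1)
    with np.errstate(over="ignore"):
        return np.exp2(-expo)


def suitability(ia: np.ndarray, v_eff: np.ndarray, limits: np.ndarray) -> np.ndarray:
    """Hard establishment gate: every per-variable deviation within the limit.

    Equivalent to each per-variable component being >= 0.5.  This is what
    makes the tolerance limit an actual range boundary: seeds cannot
    establish on patches beyond their cytotype's limit of ecological
    tolerance.
    """
    dev = np.abs(ia - v_eff.T) / limits
    dev = np.where(np.isfinite(dev), dev, np.inf)
    return np.all(dev <= 1.0 + 1e-12, axis=1)


# -- fecundity and survival -------------------------------------------------


def age_fecundity_cap(age: int, caps: tuple[int, int, int] = FECUNDITY_CAPS) -> int:
    """Maximum seed number by age: 3 at age 1, 6 at age 2, 10 from age 3 on."""
    if age < 1:
        raise DemographyConfigError(f"reproducing plants have age >= 1, got {age}")
    return caps[min(age, 3) - 1]


def fecundity_caps_vector(ages: np.ndarray, caps: tuple[int, int, int] = FECUNDITY_CAPS) -> np.ndarray:
    return np.asarray(caps)[np.minimum(ages, 3) - 1]


def realized_fecundity(e: float, age: int, rng: np.random.Generator) -> int:
    """Seed count this cycle: Binomial(cap(age), E).

    E = 1 yields the age cap with certainty, E = 0 yields nothing; in between
    each potential seed is realized independently with probability E, which
    keeps offspring counts integral and adds demographic stochasticity.
    """
    return int(rng.binomial(age_fecundity_cap(age), e))


def lifespan_cap(e_at_establishment: float, base: int = BASE_LIFESPAN) -> int:
    """Lifespan cap in cycles, scaled by establishment-time E (>= 1)."""
    return max(1, math.ceil(base * e_at_establishment))


def survival_update(plant: Plant, rng: np.random.Generator, death_rate: float = DEATH_RATE) -> bool:
    """One survival cycle: flat hazard plus the lifespan cap.

    Increments the plant's age on survival; returns True if the plant lives.
    A plant whose incremented age would exceed ``max_age`` dies with
    certainty.
    """
    if rng.random() < death_rate:
        return False
    if plant.age + 1 > plant.max_age:
        return False
    plant.age += 1
    return True


# -- founding ---------------------------------------------------------------


def central_block(grid: EnvironmentGrid, side: int = 20) -> tuple[slice, slice]:
    """Index slices (ys, xs) of the central ``side`` x ``side`` patch block."""
    side_y = min(side, grid.height)
    side_x = min(side, grid.width)
    y0 = (grid.height - side_y) // 2
    x0 = (grid.width - side_x) // 2
    return slice(y0, y0 + side_y), slice(x0, x0 + side_x)


def initialize_population(
    grid: EnvironmentGrid,
    n: int = 30,
    rng: Optional[np.random.Generator] = None,
    block_side: int = 20,
) -> list[Plant]:
    """Place ``n`` diploid founders on distinct central patches.

    Each founder's IA is copied from its own patch's V1..V5, so every founder
    starts at E = 1, with a full lifespan cap.  Founders enter at age 0
    ("cycles completed") and reproduce for the first time at age 1, with the
    age-1 fecundity cap of 3.
    """
    rng = rng or np.random.default_rng()
    ys, xs = central_block(grid, block_side)
    yy, xx = np.meshgrid(np.arange(ys.start, ys.stop), np.arange(xs.start, xs.stop), indexing="ij")
    coords = np.column_stack([xx.ravel(), yy.ravel()])
    finite = np.all(np.isfinite(grid.layers[:, coords[:, 1], coords[:, 0]]), axis=0)
    coords = coords[finite]
    if len(coords) < n:
        raise DemographyConfigError(
            f"central block holds only {len(coords)} usable patches, need {n}"
        )
    chosen = coords[rng.choice(len(coords), size=n, replace=False)] if n else coords[:0]
    plants = []
    for pid, (x, y) in enumerate(chosen):
        ia = grid.layers[:, y, x].copy()
        plants.append(
            Plant(id=pid, ploidy=2, age=0, ia=ia, x=int(x), y=int(y), e=1.0, max_age=BASE_LIFESPAN)
        )
    return plants


def suitable_fraction(
    grid: EnvironmentGrid,
    tolerance: ToleranceConfig,
    ia: np.ndarray | None = None,
    ploidy: int = 2,
) -> float:
    """Fraction of patches within a genotype's tolerance of its optimum.

    With no ``ia`` given, the reference genotype is matched to the central
    patch (the founder area), which is the natural 'maximum possible
    distribution' question for the initial diploid population.
    """
    if ia is None:
        cy, cx = grid.height // 2, grid.width // 2
        ia = grid.layers[:, cy, cx]
    ia = np.asarray(ia, dtype=float)
    lim = tolerance.limit * (tolerance.limit_multiplier_4x if ploidy == 4 else 1.0)
    dev = np.abs(grid.layers - ia[:, None, None]) / lim[:, None, None]
    dev = np.where(np.isfinite(dev), dev, np.inf)
    ok = np.all(dev <= 1.0, axis=0)
    return float(ok.mean())


def suitable_mask(
    grid: EnvironmentGrid, tolerance: ToleranceConfig, ia: np.ndarray, ploidy: int = 2
) -> np.ndarray:
    """Boolean (H, W) mask of patches within tolerance for the given optimum."""
    ia = np.asarray(ia, dtype=float)
    lim = tolerance.limit * (tolerance.limit_multiplier_4x if ploidy == 4 else 1.0)
    dev = np.abs(grid.layers - ia[:, None, None]) / lim[:, None, None]
    dev = np.where(np.isfinite(dev), dev, np.inf)
    return np.all(dev <= 1.0, axis=0)
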