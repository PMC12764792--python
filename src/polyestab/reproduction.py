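"""Gametes, mating pathways, pollen choice, seed ploidy, trait inheritance.

Cytotypes emit gametes in x-dosage classes: diploids make reduced (x) or —
with the swept probability — unreduced (2x) gametes; triploids emit a mix of
reduced x, reduced 2x, unreduced 3x and aneuploid gametes; tetraploids emit
reduced 2x gametes (and optionally unreduced 4x ones).  A sexual seed's
ploidy is the dosage sum of the female and male gamete; any aneuploid gamete
or a sum above 4x is inviable, so the cytotype universe stays {2x, 3x, 4x}.
Seeds that are triploid, or have a triploid parent, carry an extra viability
multiplier (the triploid block as a scalar).

A tetraploid seed formed with at least one unreduced gamete from parents
that are not both tetraploid — or a triploid seed formed through an
unreduced gamete — is a polyploidization event: bilateral when both gametes
are unreduced (2n + 2n), unilateral when exactly one is (2n + n).

Pollen donors are drawn distance-weighted (negative exponential, truncated),
so most seeds are sired from within 1-5 patches and only a trickle from 7-10.
Inheritance follows the infinitesimal model: sexual offspring take midparent
IA values (optionally plus segregation noise, default 0); apomictic
offspring are exact maternal clones, with ploidy carried by an unreduced
female gamete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .demography import Plant

Pathway = Literal["outcross", "self", "apomixis"]
EventType = Literal["bilateral", "unilateral"]

ANEUPLOID = -1  # dosage code for aneuploid gametes


class MatingConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GameteSpec:
    """One gamete class: dosage in multiples of the base number x."""

    dosage: int  # 1, 2, 3, 4 or ANEUPLOID
    klass: Literal["reduced", "unreduced", "aneuploid"]
    parent_ploidy: int

    def __post_init__(self) -> None:
        legal = {
            2: {(1, "reduced"), (2, "unreduced")},
            3: {(1, "reduced"), (2, "reduced"), (3, "unreduced"), (ANEUPLOID, "aneuploid")},
            4: {(2, "reduced"), (4, "unreduced")},
        }
        if (self.dosage, self.klass) not in legal.get(self.parent_ploidy, set()):
            raise MatingConfigError(
                f"illegal gamete {self.klass} {self.dosage}x from a {self.parent_ploidy}x plant"
            )

    @property
    def unreduced(self) -> bool:
        return self.klass == "unreduced"


def _default_triploid_mix() -> dict[str, float]:
    # Partially fertile triploids: mostly unbalanced gametes, a workable
    # minority of euploid x and 2x ones, rare unreduced 3x.
    return {"x": 0.25, "2x": 0.25, "3x": 0.05, "aneuploid": 0.45}


def _zero_rates() -> dict[int, float]:
    return {2: 0.0, 3: 0.0, 4: 0.0}


@dataclass
class MatingConfig:
    """All reproductive-system knobs.

    ``unreduced_rate_2x`` is the headline experimental variable (fraction of
    diploid gametes, female and male alike, that are unreduced); it switches
    on only at ``onset_generation``.  Selfing and apomixis probabilities are
    held per cytotype because the reproductive-mode experiments apply them to
    tetraploid bearers while diploids stay self-sterile outcrossers.
    """

    unreduced_rate_2x: float = 0.006
    unreduced_rate_4x: float = 0.0
    triploid_gamete_mix: dict[str, float] = field(default_factory=_default_triploid_mix)
    selfing_rate: dict[int, float] = field(default_factory=_zero_rates)
    apomixis_rate: dict[int, float] = field(default_factory=_zero_rates)
    triploid_seed_viability: float = 0.1
    onset_generation: int = 200
    pollen_lambda: float = 1.6
    pollen_radius: float = 10.0
    pollen_global: bool = False
    segregation_sd: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        probs = [self.unreduced_rate_2x, self.unreduced_rate_4x, self.triploid_seed_viability]
        probs += list(self.triploid_gamete_mix.values())
        probs += list(self.selfing_rate.values()) + list(self.apomixis_rate.values())
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise MatingConfigError("all rates must lie in [0, 1]")
        if not math.isclose(sum(self.triploid_gamete_mix.values()), 1.0, abs_tol=1e-9):
            raise MatingConfigError("triploid gamete mix must sum to 1")
        for pl in (2, 3, 4):
            if self.selfing_rate.get(pl, 0.0) + self.apomixis_rate.get(pl, 0.0) > 1.0 + 1e-12:
                raise MatingConfigError(f"selfing + apomixis > 1 for ploidy {pl}x")
        if self.pollen_lambda <= 0 or self.pollen_radius < 1:
            raise MatingConfigError("pollen kernel parameters out of range")
        if self.segregation_sd < 0:
            raise MatingConfigError("segregation_sd must be >= 0")

    def selfing_for(self, ploidy: int) -> float:
        return self.selfing_rate.get(ploidy, 0.0)

    def apomixis_for(self, ploidy: int) -> float:
        return self.apomixis_rate.get(ploidy, 0.0)


# -- gamete sampling --------------------------------------------------------


def gamete_class_distribution(
    ploidy: int, cfg: MatingConfig, generation: int | None = None
) -> dict[GameteSpec, float]:
    """Probability distribution over gamete classes for one cytotype.

    Before the onset generation diploid unreduced-gamete production is forced
    to zero (``generation=None`` means 'after onset').
    """
    if ploidy == 2:
        p = cfg.unreduced_rate_2x
        if generation is not None and generation < cfg.onset_generation:
            p = 0.0
        return {
            GameteSpec(1, "reduced", 2): 1.0 - p,
            GameteSpec(2, "unreduced", 2): p,
        }
    if ploidy == 3:
        mix = cfg.triploid_gamete_mix
        return {
            GameteSpec(1, "reduced", 3): mix.get("x", 0.0),
            GameteSpec(2, "reduced", 3): mix.get("2x", 0.0),
            GameteSpec(3, "unreduced", 3): mix.get("3x", 0.0),
            GameteSpec(ANEUPLOID, "aneuploid", 3): mix.get("aneuploid", 0.0),
        }
    if ploidy == 4:
        q = cfg.unreduced_rate_4x
        return {
            GameteSpec(2, "reduced", 4): 1.0 - q,
            GameteSpec(4, "unreduced", 4): q,
        }
    raise MatingConfigError(f"no gamete model for ploidy {ploidy}x")


def sample_gamete(
    ploidy: int, cfg: MatingConfig, rng: np.random.Generator, generation: int | None = None
) -> GameteSpec:
    dist = gamete_class_distribution(ploidy, cfg, generation)
    specs = list(dist)
    probs = np.array([dist[s] for s in specs])
    return specs[rng.choice(len(specs), p=probs)]


def sample_gametes_vector(
    ploidy: np.ndarray, cfg: MatingConfig, rng: np.random.Generator, generation: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized gamete draw: (dosage, unreduced?) arrays, one per parent.

    Aneuploid gametes get dosage ``ANEUPLOID``.
    """
    n = len(ploidy)
    dosage = np.empty(n, dtype=np.int64)
    unreduced = np.zeros(n, dtype=bool)
    u = rng.random(n)

    p2 = cfg.unreduced_rate_2x if generation >= cfg.onset_generation else 0.0
    m2 = ploidy == 2
    unr2 = m2 & (u < p2)
    dosage[m2] = 1
    dosage[unr2] = 2
    unreduced[unr2] = True

    m4 = ploidy == 4
    unr4 = m4 & (u < cfg.unreduced_rate_4x)
    dosage[m4] = 2
    dosage[unr4] = 4
    unreduced[unr4] = True

    m3 = ploidy == 3
    if np.any(m3):
        mix = cfg.triploid_gamete_mix
        edges = np.cumsum([mix.get("x", 0.0), mix.get("2x", 0.0), mix.get("3x", 0.0)])
        u3 = u[m3]
        d3 = np.full(u3.shape, ANEUPLOID, dtype=np.int64)
        d3[u3 < edges[2]] = 3
        d3[u3 < edges[1]] = 2
        d3[u3 < edges[0]] = 1
        dosage[m3] = d3
        unreduced[m3] = d3 == 3
    return dosage, unreduced


# -- pathway choice ---------------------------------------------------------


def choose_pathway(cfg: MatingConfig, rng: np.random.Generator, ploidy: int = 2) -> Pathway:
    """Per-ovule categorical draw among selfing, apomixis and outcrossing."""
    s = cfg.selfing_for(ploidy)
    a = cfg.apomixis_for(ploidy)
    u = rng.random()
    if u < s:
        return "self"
    if u < s + a:
        return "apomixis"
    return "outcross"


# -- pollen donor selection -------------------------------------------------


def pollen_weight(distance: float, cfg: MatingConfig) -> float:
    """Distance weight of a candidate donor: exp(-d/lambda), 0 beyond radius."""
    if distance <= 0 or distance > cfg.pollen_radius:
        return 0.0
    return math.exp(-distance / cfg.pollen_lambda)


def select_pollen_donor(
    mother: Plant, plants: list[Plant], rng: np.random.Generator, cfg: MatingConfig
) -> Optional[Plant]:
    """Sample one living neighbour as pollen donor, or None if isolated.

    Candidates are all plants other than the mother within the truncation
    radius; sampling weight decays exponentially with Euclidean patch
    distance, so nearly all pollen comes from within ~5 patches.  An ovule
    with no candidate aborts (pollen limitation).
    """
    cands = []
    weights = []
    for p in plants:
        if p is mother:
            continue
        if cfg.pollen_global:
            cands.append(p)
            weights.append(1.0)
            continue
        d = math.hypot(p.x - mother.x, p.y - mother.y)
        w = pollen_weight(d, cfg)
        if w > 0:
            cands.append(p)
            weights.append(w)
    if not cands:
        return None
    w = np.asarray(weights)
    return cands[rng.choice(len(cands), p=w / w.sum())]


def pollen_kernel_matrix(cfg: MatingConfig) -> np.ndarray:
    """(2R+1, 2R+1) window of donor weights centred on the mother (weight 0)."""
    r = int(math.ceil(cfg.pollen_radius))
    ax = np.arange(-r, r + 1)
    dist = np.hypot(ax[:, None], ax[None, :])
    with np.errstate(over="ignore"):
        k = np.exp(-dist / cfg.pollen_lambda)
    k[(dist == 0) | (dist > cfg.pollen_radius)] = 0.0
    return k


# -- seed formation and event classification --------------------------------


@dataclass
class Seed:
    """A candidate offspring before dispersal and settlement."""

    ploidy: int
    ia: np.ndarray
    mother_id: int
    event_inherited: int  # maternal lineage tag (-1 = none)
    event_type: Optional[EventType] = None  # set for new polyploidization events
    origin: tuple[int, int] = (0, 0)


def classify_polyploidization(
    female: GameteSpec, male: GameteSpec, offspring_ploidy: int
) -> Optional[EventType]:
    """Bilateral (2n + 2n), unilateral (2n + n), or None (no unreduced gamete)."""
    if female.unreduced and male.unreduced:
        return "bilateral"
    if female.unreduced or male.unreduced:
        return "unilateral"
    return None


def is_new_event(
    female: GameteSpec, male: GameteSpec, offspring_ploidy: int
) -> Optional[EventType]:
    """Event type if this seed founds a new polyploid lineage, else None.

    A new lineage is minted when a 3x or 4x seed forms through an unreduced
    gamete from parents that are both non-tetraploid — a genuinely new
    origin.  Matings that involve an existing tetraploid propagate that
    plant's lineage (the seed inherits its event tag) rather than founding
    a new one, as do crosses with no unreduced gamete.
    """
    etype = classify_polyploidization(female, male, offspring_ploidy)
    if etype is None:
        return None
    if female.parent_ploidy == 4 or male.parent_ploidy == 4:
        return None
    if offspring_ploidy in (3, 4):
        return etype
    return None


def inherit_adaptivity(
    pathway: Pathway,
    mother_ia: np.ndarray,
    father_ia: Optional[np.ndarray],
    rng: np.random.Generator,
    segregation_sd: float = 0.0,
) -> np.ndarray:
    """Offspring IA: midparent for sexual seeds, exact clone for apomixis.

    ``segregation_sd`` adds optional Gaussian noise around the midparent; the
    default of 0 removes drift-like fluctuation from the trait, per the
    infinitesimal-model reading used throughout.
    """
    if pathway == "apomixis":
        return np.array(mother_ia, dtype=float, copy=True)
    if father_ia is None:
        raise MatingConfigError("sexual inheritance requires a father")
    child = 0.5 * (np.asarray(mother_ia, dtype=float) + np.asarray(father_ia, dtype=float))
    if segregation_sd > 0:
        child = child + rng.normal(0.0, segregation_sd, size=child.shape)
    return child


def form_seed(
    mother: Plant,
    pathway: Pathway,
    cfg: MatingConfig,
    rng: np.random.Generator,
    donor: Optional[Plant] = None,
    generation: int | None = None,
) -> Optional[Seed]:
    """Form one seed for an ovule of ``mother``, or None if it fails.

    Sexual pathways combine a female gamete from the mother with a male
    gamete from the donor (the mother herself when selfing); apomictic ovules
    clone the mother through an unreduced female gamete.  Aneuploid gametes
    and dosage sums above 4x abort; triploid seeds and seeds with a triploid
    parent pass a viability lottery.
    """
    if pathway == "apomixis":
        seed = Seed(
            ploidy=mother.ploidy,
            ia=inherit_adaptivity("apomixis", mother.ia, None, rng),
            mother_id=mother.id,
            event_inherited=mother.event_id,
            origin=(mother.x, mother.y),
        )
        if mother.ploidy == 3 and rng.random() >= cfg.triploid_seed_viability:
            return None
        return seed

    if pathway == "self":
        donor = mother
    if donor is None:
        return None  # pollen-limited abort
    female = sample_gamete(mother.ploidy, cfg, rng, generation)
    male = sample_gamete(donor.ploidy, cfg, rng, generation)
    if female.dosage == ANEUPLOID or male.dosage == ANEUPLOID:
        return None
    ploidy = female.dosage + male.dosage
    if ploidy < 2 or ploidy > 4:
        return None
    if (ploidy == 3 or mother.ploidy == 3 or donor.ploidy == 3) and (
        rng.random() >= cfg.triploid_seed_viability
    ):
        return None
    return Seed(
        ploidy=ploidy,
        ia=inherit_adaptivity(pathway, mother.ia, donor.ia, rng, cfg.segregation_sd),
        mother_id=mother.id,
        event_inherited=mother.event_id,
        event_type=is_new_event(female, male, ploidy),
        origin=(mother.x, mother.y),
    )


# -- shifted tetraploid optimum --------------------------------------------


def choose_optimum_patches(
    grid,
    shift_distance: float,
    rng: np.random.Generator,
    n_patches: int = 30,
    ring_halfwidth: float = 2.0,
) -> np.ndarray:
    """Pick the fixed set of shifted-optimum patches for neotetraploids.

    Patches are sampled uniformly from the ring of cells whose Euclidean
    distance to the founder-area centroid is within ``ring_halfwidth`` of the
    requested shift, so the centroid-to-centroid distance matches the
    configured shift.  Returns an (n, 2) array of (x, y) coordinates.
    """
    cy = (grid.height - 1) / 2.0
    cx = (grid.width - 1) / 2.0
    yy, xx = np.mgrid[0 : grid.height, 0 : grid.width]
    dist = np.hypot(xx - cx, yy - cy)
    ring = np.abs(dist - shift_distance) <= ring_halfwidth
    finite = np.all(np.isfinite(grid.layers), axis=0)
    coords = np.column_stack([xx[ring & finite], yy[ring & finite]])
    if len(coords) == 0:
        raise MatingConfigError(
            f"no patches at shift distance {shift_distance} on a "
            f"{grid.width}x{grid.height} grid"
        )
    take = min(n_patches, len(coords))
    return coords[rng.choice(len(coords), size=take, replace=False)]


def assign_shifted_optimum(
    ia: np.ndarray, optimum_patches: np.ndarray, grid, rng: np.random.Generator
) -> np.ndarray:
    """Replace a neotetraploid founder's IA with a random optimum patch's V."""
    if len(optimum_patches) == 0:
        raise MatingConfigError("empty optimum patch set")
    x, y = optimum_patches[rng.integers(len(optimum_patches))]
    return grid.layers[:, y, x].copy()
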