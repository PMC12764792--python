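"""Generation loop, replicate execution, and polyploidization bookkeeping.

One generation executes, in order: (1) a fresh global seasonal factor and
the per-plant environmental fitness E; (2) survival (flat hazard plus the
individual lifespan cap); (3) reproduction — each survivor draws its ovule
count, each ovule picks a pathway (outcross / self / apomixis), a pollen
donor where needed, gametes, and becomes a candidate seed or aborts; (4)
seed dispersal and simultaneous settlement on free suitable patches, best
prospective E winning contested patches; (5) lineage censuses and
establishment detection for pending polyploidization events.

A polyploidization event is logged when a neo-cytotype seed (3x, or 4x from
parents not both 4x, formed through at least one unreduced gamete) actually
establishes; the event is *successful* (SPE) once 50 living tetraploids
carry its lineage tag, *unsuccessful* (UPE) if the run ends first.  A
replicate stops at tetraploid fixation (4x proportion 1), population
extinction, or a fixed horizon after the onset of unreduced-gamete
production.

The population is held in structure-of-arrays form and every step is
vectorized; replicates at the default landscape (~1000 plants) run at a few
milliseconds per generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import demography as demo
from .config import SimulationConfig
from .dispersal import resolve_contention, sample_destinations
from .environment import (
    EnvironmentGrid,
    draw_seasonal_factor,
    generate_synthetic_environment,
    sv_vector,
)
from .reproduction import (
    ANEUPLOID,
    MatingConfig,
    choose_optimum_patches,
    pollen_kernel_matrix,
    sample_gametes_vector,
)

EVENT_TYPES = {1: "bilateral", 2: "unilateral"}
OUTCOMES = {0: "pending", 1: "SPE", 2: "UPE"}


@dataclass
class EventRecord:
    """One logged polyploidization event (founder = establishing neo-cytotype)."""

    event_id: int
    generation_formed: int
    x: int
    y: int
    type: str  # bilateral | unilateral
    founder_ploidy: int
    founder_fitness: float
    outcome: str  # SPE | UPE | pending
    generation_established: Optional[int] = None


@dataclass
class ReplicateSummary:
    """Per-run response variables matching the experiment tables."""

    spe_count: int
    upe_count: int
    bilateral_count: int
    unilateral_count: int
    gpip: Optional[int]
    guf: Optional[int]
    final_4x_proportion: float
    stop_reason: str  # fixation | horizon | extinct
    seed: int
    n_generations: int
    final_census: tuple[int, int, int]  # (2x, 3x, 4x)
    first_spe_location: Optional[tuple[int, int]] = None
    mean_founder_fitness_spe: Optional[float] = None
    mean_founder_fitness_upe: Optional[float] = None


class _EventLog:
    """Columnar event store with cheap per-generation lineage checks."""

    def __init__(self) -> None:
        self.cap = 256
        self.n = 0
        self.type = np.zeros(self.cap, dtype=np.int8)
        self.gen_formed = np.zeros(self.cap, dtype=np.int32)
        self.x = np.zeros(self.cap, dtype=np.int32)
        self.y = np.zeros(self.cap, dtype=np.int32)
        self.founder_e = np.zeros(self.cap, dtype=np.float64)
        self.founder_ploidy = np.zeros(self.cap, dtype=np.int8)
        self.outcome = np.zeros(self.cap, dtype=np.int8)
        self.gen_est = np.full(self.cap, -1, dtype=np.int32)

    def _grow(self, need: int) -> None:
        while self.cap < need:
            self.cap *= 2
        for name in ("type", "gen_formed", "x", "y", "founder_e", "founder_ploidy", "outcome", "gen_est"):
            old = getattr(self, name)
            new = np.zeros(self.cap, dtype=old.dtype)
            if name == "gen_est":
                new[:] = -1
            new[: self.n] = old[: self.n]
            setattr(self, name, new)

    def add(self, etype: np.ndarray, gen: int, x: np.ndarray, y: np.ndarray,
            founder_e: np.ndarray, founder_ploidy: np.ndarray) -> np.ndarray:
        k = len(etype)
        self._grow(self.n + k)
        sl = slice(self.n, self.n + k)
        ids = np.arange(self.n, self.n + k, dtype=np.int64)
        self.type[sl] = etype
        self.gen_formed[sl] = gen
        self.x[sl] = x
        self.y[sl] = y
        self.founder_e[sl] = founder_e
        self.founder_ploidy[sl] = founder_ploidy
        self.n += k
        return ids

    def records(self) -> list[EventRecord]:
        out = []
        for i in range(self.n):
            est = int(self.gen_est[i])
            out.append(
                EventRecord(
                    event_id=i,
                    generation_formed=int(self.gen_formed[i]),
                    x=int(self.x[i]),
                    y=int(self.y[i]),
                    type=EVENT_TYPES[int(self.type[i])],
                    founder_ploidy=int(self.founder_ploidy[i]),
                    founder_fitness=float(self.founder_e[i]),
                    outcome=OUTCOMES[int(self.outcome[i])],
                    generation_established=est if est >= 0 else None,
                )
            )
        return out


class Simulation:
    """State and generation loop of one replicate."""

    def __init__(
        self,
        config: SimulationConfig,
        seed: int,
        grid: Optional[EnvironmentGrid] = None,
        record_census: bool = False,
    ) -> None:
        self.cfg = config
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.grid = grid if grid is not None else generate_synthetic_environment(
            config.env, config.env_seed
        )
        self.generation = 0
        self.events = _EventLog()
        self.record_census = record_census
        self.census_log: list[tuple[int, int, int, int]] = []
        self.sv_log: list[float] = []
        self._kernel = pollen_kernel_matrix(config.mating).ravel()
        cdf = np.cumsum(self._kernel)
        self._kernel_cdf = cdf / cdf[-1]
        self._kr = int(math.ceil(config.mating.pollen_radius))
        self._caps = np.asarray(config.fecundity_caps)
        self._self_lut = np.zeros(5)
        self._apo_lut = np.zeros(5)
        for pl in (2, 3, 4):
            self._self_lut[pl] = config.mating.selfing_for(pl)
            self._apo_lut[pl] = config.mating.apomixis_for(pl)

        if config.shift_distance is not None:
            self.optimum_patches = choose_optimum_patches(
                self.grid, config.shift_distance, self.rng, config.n_optimum_patches
            )
        else:
            self.optimum_patches = None

        self._init_population()

    # -- population arrays --------------------------------------------------

    def _init_population(self) -> None:
        founders = demo.initialize_population(
            self.grid, self.cfg.n_founders, self.rng, self.cfg.founder_block
        )
        n = len(founders)
        self.ploidy = np.fromiter((p.ploidy for p in founders), dtype=np.int8, count=n)
        self.age = np.zeros(n, dtype=np.int16)
        self.x = np.fromiter((p.x for p in founders), dtype=np.int32, count=n)
        self.y = np.fromiter((p.y for p in founders), dtype=np.int32, count=n)
        self.ia = (
            np.stack([p.ia for p in founders]) if n else np.empty((0, 5))
        )
        self.event_id = np.full(n, -1, dtype=np.int64)
        self.max_age = np.full(n, self.cfg.base_lifespan, dtype=np.int16)
        self.e = np.ones(n)

    @property
    def n(self) -> int:
        return len(self.ploidy)

    def census(self) -> tuple[int, int, int]:
        return (
            int(np.sum(self.ploidy == 2)),
            int(np.sum(self.ploidy == 3)),
            int(np.sum(self.ploidy == 4)),
        )

    def _keep(self, mask: np.ndarray) -> None:
        self.ploidy = self.ploidy[mask]
        self.age = self.age[mask]
        self.x = self.x[mask]
        self.y = self.y[mask]
        self.ia = self.ia[mask]
        self.event_id = self.event_id[mask]
        self.max_age = self.max_age[mask]
        self.e = self.e[mask]

    def _append(self, ploidy, age, x, y, ia, event_id, max_age, e) -> None:
        self.ploidy = np.concatenate([self.ploidy, ploidy.astype(np.int8)])
        self.age = np.concatenate([self.age, age.astype(np.int16)])
        self.x = np.concatenate([self.x, x.astype(np.int32)])
        self.y = np.concatenate([self.y, y.astype(np.int32)])
        self.ia = np.concatenate([self.ia, ia])
        self.event_id = np.concatenate([self.event_id, event_id.astype(np.int64)])
        self.max_age = np.concatenate([self.max_age, max_age.astype(np.int16)])
        self.e = np.concatenate([self.e, e])

    # -- per-generation pieces ----------------------------------------------

    def _limits_rows(self, ploidy: np.ndarray) -> np.ndarray:
        mult = np.where(ploidy == 4, self.cfg.tolerance.limit_multiplier_4x, 1.0)
        return self.cfg.tolerance.limit * mult[:, None]

    def _fitness_at(self, ia, ploidy, px, py, svv) -> tuple[np.ndarray, np.ndarray]:
        """(E, suitable) for genotypes evaluated on patches (px, py)."""
        if self.cfg.uniform_e is not None:
            n = len(px)
            return np.full(n, self.cfg.uniform_e), np.ones(n, dtype=bool)
        veff = self.grid.layers[:, py, px] * svv[:, None]
        limits = self._limits_rows(ploidy)
        e = demo.environmental_fitness(ia, veff, limits, self.cfg.fitness_combine)
        suit = demo.suitability(ia, veff, limits)
        return e, suit

    def _select_donors_local(self, occ, mx, my, rng) -> np.ndarray:
        """Distance-weighted donor index per outcross ovule (-1 = aborted).

        ``mx/my`` are the mother coordinates of each outcross ovule.  The
        exponential-kernel draw is done by rejection: propose a displacement
        from the kernel distribution and accept if the target patch is
        occupied — which conditions the kernel on occupied cells, i.e. the
        exact donor distribution.  Ovules still unresolved after a few rounds
        (sparse neighbourhoods) fall back to an explicit weighted draw over
        their mother's window, so the sampled law is exact for everyone.
        """
        r = self._kr
        side = 2 * r + 1
        n_out = len(mx)
        pad = np.full(
            (self.grid.height + 2 * r, self.grid.width + 2 * r), -1, dtype=np.int64
        )
        pad[r : r + self.grid.height, r : r + self.grid.width] = occ

        donor = np.full(n_out, -1, dtype=np.int64)
        unresolved = np.arange(n_out)
        for _ in range(8):
            if len(unresolved) == 0:
                return donor
            u = rng.random(len(unresolved))
            cell = np.searchsorted(self._kernel_cdf, u, side="right")
            tx = mx[unresolved] + cell % side  # padded coords: mother + offset
            ty = my[unresolved] + cell // side
            hit = pad[ty, tx]
            got = hit >= 0
            donor[unresolved[got]] = hit[got]
            unresolved = unresolved[~got]
        if len(unresolved) == 0:
            return donor

        # exact fallback for sparse neighbourhoods
        view = np.lib.stride_tricks.sliding_window_view(pad, (side, side))
        um, inv = np.unique(
            my[unresolved].astype(np.int64) * self.grid.width + mx[unresolved],
            return_inverse=True,
        )
        win = view[um // self.grid.width, um % self.grid.width].reshape(len(um), -1)
        weights = np.where(win >= 0, self._kernel, 0.0)
        cw = np.cumsum(weights, axis=1)
        tot = cw[:, -1]
        draw = tot[inv] * (1.0 - rng.random(len(unresolved)))  # in (0, tot]
        cell = np.sum(cw[inv] < draw[:, None], axis=1)
        cell = np.minimum(cell, win.shape[1] - 1)
        res = win[inv, cell]
        res[tot[inv] <= 0.0] = -1
        donor[unresolved] = res
        return donor

    def _select_donors_global(self, m_out: np.ndarray, rng) -> np.ndarray:
        """Uniform donor among all living plants except the mother."""
        n = self.n
        if n < 2:
            return np.full(len(m_out), -1, dtype=np.int64)
        j = rng.integers(0, n - 1, size=len(m_out))
        return j + (j >= m_out)

    # -- one generation ------------------------------------------------------

    def step(self) -> None:
        cfg = self.cfg
        rng = self.rng
        self.generation += 1
        g = self.generation
        sv = draw_seasonal_factor(rng, cfg.sv_sd)
        if self.record_census:
            self.sv_log.append(sv)
        svv = sv_vector(sv)

        # (2) survival: flat hazard + lifespan cap; age increments on survival
        n = self.n
        if n:
            u = rng.random(n)
            aged = self.age + 1
            alive = (u >= cfg.death_rate) & (aged <= self.max_age)
            self.age = aged
            self._keep(alive)
        if self.n == 0:
            self._post_step(g)
            return

        n = self.n
        occ = np.full((self.grid.height, self.grid.width), -1, dtype=np.int64)
        occ[self.y, self.x] = np.arange(n)

        # (1) refreshed E on the survivors' own patches
        e_self, _ = self._fitness_at(self.ia, self.ploidy, self.x, self.y, svv)
        self.e = e_self

        # (3) ovules
        caps = self._caps[np.minimum(self.age, 3) - 1]
        n_ov = rng.binomial(caps, np.clip(e_self, 0.0, 1.0))
        mothers = np.repeat(np.arange(n), n_ov)
        k = len(mothers)
        if k == 0:
            self._post_step(g)
            return

        m_pl = self.ploidy[mothers].astype(np.int64)
        u = rng.random(k)
        s_rate = self._self_lut[m_pl]
        a_rate = self._apo_lut[m_pl]
        path = np.full(k, 2, dtype=np.int8)  # 0 self, 1 apo, 2 outcross
        path[u < s_rate + a_rate] = 1
        path[u < s_rate] = 0

        # donors for outcross ovules
        donor = mothers.copy()  # selfing: donor = mother
        out = path == 2
        if np.any(out):
            m_out = mothers[out]
            if cfg.mating.pollen_global:
                d = self._select_donors_global(m_out, rng)
            else:
                d = self._select_donors_local(occ, self.x[m_out], self.y[m_out], rng)
            donor[out] = d

        sexual = (path != 1) & (donor >= 0)
        apo = path == 1

        seeds = []  # list of per-field arrays to concatenate

        if np.any(sexual):
            ms = mothers[sexual]
            ds = donor[sexual]
            f_dos, f_unr = sample_gametes_vector(self.ploidy[ms].astype(np.int64), cfg.mating, rng, g)
            m_dos, m_unr = sample_gametes_vector(self.ploidy[ds].astype(np.int64), cfg.mating, rng, g)
            sp = f_dos + m_dos
            ok = (f_dos != ANEUPLOID) & (m_dos != ANEUPLOID) & (sp >= 2) & (sp <= 4)
            tri = ok & ((sp == 3) | (self.ploidy[ms] == 3) | (self.ploidy[ds] == 3))
            lottery = rng.random(len(ms))
            ok &= ~tri | (lottery < cfg.mating.triploid_seed_viability)
            if np.any(ok):
                ms, ds = ms[ok], ds[ok]
                sp = sp[ok]
                f_unr, m_unr = f_unr[ok], m_unr[ok]
                non4 = (self.ploidy[ms] != 4) & (self.ploidy[ds] != 4)
                etype = np.zeros(len(ms), dtype=np.int8)
                any_unr = f_unr | m_unr
                new_lineage = any_unr & (sp >= 3) & non4
                etype[new_lineage & f_unr & m_unr] = 1  # bilateral
                etype[new_lineage & (f_unr ^ m_unr)] = 2  # unilateral
                # lineage tag: maternal, falling back to paternal (a cross of
                # a tagged tetraploid with an untagged plant stays in-lineage)
                inh = np.where(self.event_id[ms] >= 0, self.event_id[ms], self.event_id[ds])
                ia_s = 0.5 * (self.ia[ms] + self.ia[ds])
                if cfg.mating.segregation_sd > 0:
                    ia_s = ia_s + rng.normal(0.0, cfg.mating.segregation_sd, size=ia_s.shape)
                seeds.append(
                    dict(
                        ploidy=sp,
                        ia=ia_s,
                        ox=self.x[ms],
                        oy=self.y[ms],
                        inherit=inh,
                        etype=etype,
                    )
                )

        if np.any(apo):
            ma = mothers[apo]
            tri = self.ploidy[ma] == 3
            ok = ~tri | (rng.random(len(ma)) < cfg.mating.triploid_seed_viability)
            ma = ma[ok]
            if len(ma):
                seeds.append(
                    dict(
                        ploidy=self.ploidy[ma].astype(np.int64),
                        ia=self.ia[ma].copy(),
                        ox=self.x[ma],
                        oy=self.y[ma],
                        inherit=self.event_id[ma],
                        etype=np.zeros(len(ma), dtype=np.int8),
                    )
                )

        if not seeds:
            self._post_step(g)
            return

        sp = np.concatenate([s["ploidy"] for s in seeds])
        s_ia = np.concatenate([s["ia"] for s in seeds])
        ox = np.concatenate([s["ox"] for s in seeds])
        oy = np.concatenate([s["oy"] for s in seeds])
        inherit = np.concatenate([s["inherit"] for s in seeds])
        etype = np.concatenate([s["etype"] for s in seeds])

        # shifted tetraploid optimum: neotetraploid founders adopt the V of a
        # randomly chosen optimum patch before settlement is evaluated
        if self.optimum_patches is not None:
            shift = (sp == 4) & (etype > 0)
            cnt = int(shift.sum())
            if cnt:
                pick = self.optimum_patches[rng.integers(len(self.optimum_patches), size=cnt)]
                s_ia[shift] = self.grid.layers[:, pick[:, 1], pick[:, 0]].T

        # (4) dispersal + settlement
        dx, dy, inside = sample_destinations(
            ox, oy, cfg.dispersal, rng, self.grid.width, self.grid.height
        )
        if not np.any(inside):
            self._post_step(g)
            return
        dx, dy = dx[inside], dy[inside]
        sp, s_ia, inherit, etype = sp[inside], s_ia[inside], inherit[inside], etype[inside]
        e_p, suit = self._fitness_at(s_ia, sp, dx, dy, svv)
        free = occ[dy, dx] < 0
        cand = free & suit
        if not np.any(cand):
            self._post_step(g)
            return
        dx, dy = dx[cand], dy[cand]
        sp, s_ia, inherit, etype = sp[cand], s_ia[cand], inherit[cand], etype[cand]
        e_p = e_p[cand]
        pid = dy.astype(np.int64) * self.grid.width + dx
        win = resolve_contention(pid, e_p, rng)

        dx, dy = dx[win], dy[win]
        sp, s_ia, inherit, etype = sp[win], s_ia[win], inherit[win], etype[win]
        e_p = e_p[win]

        # event minting for establishing neo-cytotypes
        ev_ids = inherit.copy()
        is_event = etype > 0
        if np.any(is_event):
            new_ids = self.events.add(
                etype[is_event], g, dx[is_event], dy[is_event], e_p[is_event], sp[is_event]
            )
            ev_ids[is_event] = new_ids

        max_age = np.minimum(
            np.ceil(cfg.base_lifespan * np.clip(e_p, 1e-9, 1.0)), cfg.base_lifespan
        ).astype(np.int16)
        self._append(
            ploidy=sp,
            age=np.zeros(len(sp)),
            x=dx,
            y=dy,
            ia=s_ia,
            event_id=ev_ids,
            max_age=np.maximum(max_age, 1),
            e=e_p,
        )
        self._post_step(g)

    def _post_step(self, g: int) -> None:
        self.detect_establishment(g)
        if self.record_census:
            c2, c3, c4 = self.census()
            self.census_log.append((g, c2, c3, c4))

    # -- establishment -------------------------------------------------------

    def detect_establishment(self, generation: Optional[int] = None) -> np.ndarray:
        """Flip pending events whose living 4x lineage meets the threshold to SPE.

        Returns the ids of newly established events.  An event never reverts.
        """
        g = generation if generation is not None else self.generation
        ev = self.events
        if ev.n == 0:
            return np.empty(0, dtype=np.int64)
        tagged = self.event_id[(self.ploidy == 4) & (self.event_id >= 0)]
        counts = np.bincount(tagged, minlength=ev.n)
        pending = ev.outcome[: ev.n] == 0
        newly = pending & (counts >= self.cfg.establishment_threshold)
        ids = np.nonzero(newly)[0]
        ev.outcome[ids] = 1
        ev.gen_est[ids] = g
        return ids

    # -- full replicate ------------------------------------------------------

    def run(self) -> ReplicateSummary:
        cfg = self.cfg
        stop_reason = "horizon"
        while self.generation < cfg.max_generation:
            self.step()
            c2, c3, c4 = self.census()
            total = c2 + c3 + c4
            if total == 0:
                stop_reason = "extinct"
                break
            if c4 == total:
                stop_reason = "fixation"
                break
        return self._summarize(stop_reason)

    def _summarize(self, stop_reason: str) -> ReplicateSummary:
        ev = self.events
        pending = ev.outcome[: ev.n] == 0
        ev.outcome[: ev.n][pending] = 2  # finalize to UPE
        spe = int(np.sum(ev.outcome[: ev.n] == 1))
        upe = int(np.sum(ev.outcome[: ev.n] == 2))
        bilateral = int(np.sum(ev.type[: ev.n] == 1))
        unilateral = int(np.sum(ev.type[: ev.n] == 2))
        c2, c3, c4 = self.census()
        total = c2 + c3 + c4
        prop4 = c4 / total if total else 0.0

        gpip = None
        first_loc = None
        spe_mask = ev.outcome[: ev.n] == 1
        if spe_mask.any():
            est = ev.gen_est[: ev.n].astype(np.int64)
            formed = ev.gen_formed[: ev.n].astype(np.int64)
            cand = np.nonzero(spe_mask)[0]
            order = np.lexsort((formed[cand], est[cand]))
            first = cand[order[0]]
            gpip = int(est[first] - formed[first])
            first_loc = (int(ev.x[first]), int(ev.y[first]))

        guf = None
        if stop_reason == "fixation":
            guf = int(self.generation - self.cfg.onset_generation)

        fe = ev.founder_e[: ev.n]
        mean_spe = float(fe[spe_mask].mean()) if spe_mask.any() else None
        upe_mask = ev.outcome[: ev.n] == 2
        mean_upe = float(fe[upe_mask].mean()) if upe_mask.any() else None

        return ReplicateSummary(
            spe_count=spe,
            upe_count=upe,
            bilateral_count=bilateral,
            unilateral_count=unilateral,
            gpip=gpip,
            guf=guf,
            final_4x_proportion=float(prop4),
            stop_reason=stop_reason,
            seed=self.seed,
            n_generations=self.generation,
            final_census=(c2, c3, c4),
            first_spe_location=first_loc,
            mean_founder_fitness_spe=mean_spe,
            mean_founder_fitness_upe=mean_upe,
        )


def step_generation(sim: Simulation) -> Simulation:
    """Advance a simulation by one generation (module-level convenience)."""
    sim.step()
    return sim


def detect_establishment(sim: Simulation, threshold: Optional[int] = None) -> np.ndarray:
    """Establishment check against a possibly overridden lineage threshold."""
    if threshold is not None:
        sim.cfg.establishment_threshold = threshold
    return sim.detect_establishment()


def run_replicate(
    config: SimulationConfig,
    seed: int,
    grid: Optional[EnvironmentGrid] = None,
    record_census: bool = False,
) -> tuple[ReplicateSummary, list[EventRecord]]:
    """Run one full replicate; identical (config, seed) gives identical output."""
    sim = Simulation(config, seed, grid=grid, record_census=record_census)
    summary = sim.run()
    return summary, sim.events.records()


def events_dataframe(events: list[EventRecord]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in events])
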