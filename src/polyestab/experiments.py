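"""Parameter sweeps over the five experiment families and their statistics.

Families (treatment variable applied on top of a shared baseline of 0.6%
unreduced diploid gametes, outcrossing, self-sterile plants):

* ``unreduced``        — diploid unreduced-gamete rate (0.6 ... 20%)
* ``selfing``          — tetraploid selfing rate
* ``apomixis``         — tetraploid apomixis rate
* ``mixed``            — tetraploid mixed mating: apomixis at the treatment
                         level, selfing for the remainder (no outcrossing)
* ``tolerance``        — tetraploid tolerance-limit multiplier, self-sterile
* ``shifted_optimum``  — distance (patches) of the tetraploid optimum shift

Each level is replicated with independently seeded runs; outputs are tidy
long tables of per-replicate response variables (SPE, UPE, bilateral,
unilateral, final 4x proportion, GPIP, GuF).  Treatment means are compared
by one-way ANOVA plus Tukey HSD at alpha = 0.01 and labelled with a compact
letter display, and first-SPE founder locations can be accumulated into
per-patch density maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig
from .demography import suitable_mask
from .engine import run_replicate
from .environment import EnvironmentGrid, generate_synthetic_environment

FAMILIES = ("unreduced", "selfing", "apomixis", "mixed", "tolerance", "shifted_optimum")
_FAMILY_CODES = {name: i for i, name in enumerate(FAMILIES)}

DEFAULT_LEVELS: dict[str, tuple[float, ...]] = {
    "unreduced": (0.006, 0.02, 0.05, 0.10, 0.20),
    "selfing": (0.10, 0.25, 0.50, 0.75, 1.00),
    "apomixis": (0.10, 0.25, 0.50, 0.75, 1.00),
    "mixed": (0.10, 0.25, 0.50, 0.75, 1.00),
    "tolerance": (0.5, 0.75, 1.0, 1.5, 2.0),
    "shifted_optimum": (5.0, 10.0, 20.0, 30.0, 40.0),
}

RESPONSES = ("spe", "upe", "bilateral", "unilateral", "final_4x")


class ExperimentError(ValueError):
    pass


@dataclass
class ExperimentDesign:
    """One family sweep: levels x replicates on a shared base configuration."""

    family: str
    levels: Sequence[float] = ()
    replicates: int = 1000
    base_config: SimulationConfig = field(default_factory=SimulationConfig)
    root_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ExperimentError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if not self.levels:
            self.levels = DEFAULT_LEVELS[self.family]
        if self.replicates < 1:
            raise ExperimentError("replicates must be >= 1")
        for level in self.levels:
            config_for_level(self.family, level, self.base_config)  # validates


def replicate_seed(root_seed: int, family: str, level: float, replicate: int) -> int:
    """Reproducibly independent seed for replicate r of one treatment level."""
    ss = np.random.SeedSequence(
        [int(root_seed), _FAMILY_CODES[family], int(round(level * 1e6)), int(replicate)]
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def config_for_level(family: str, level: float, base: SimulationConfig) -> SimulationConfig:
    """Apply one treatment level to a copy of the base configuration."""
    cfg = base.copy()
    if family == "unreduced":
        if not 0.0 <= level <= 1.0:
            raise ExperimentError(f"unreduced-gamete rate {level} outside [0, 1]")
        cfg.mating.unreduced_rate_2x = level
    elif family == "selfing":
        if not 0.0 <= level <= 1.0:
            raise ExperimentError(f"selfing rate {level} outside [0, 1]")
        cfg.mating.selfing_rate[4] = level
    elif family == "apomixis":
        if not 0.0 <= level <= 1.0:
            raise ExperimentError(f"apomixis rate {level} outside [0, 1]")
        cfg.mating.apomixis_rate[4] = level
    elif family == "mixed":
        # apomixis and selfing combined: the treatment level sets the apomictic
        # ovule fraction and selfing covers the remainder, so tetraploid
        # bearers never depend on outcross pollen.
        if not 0.0 <= level <= 1.0:
            raise ExperimentError(f"mixed-mating level {level} outside [0, 1]")
        cfg.mating.apomixis_rate[4] = level
        cfg.mating.selfing_rate[4] = 1.0 - level
    elif family == "tolerance":
        if level <= 0:
            raise ExperimentError(f"tolerance multiplier must be > 0, got {level}")
        cfg.tolerance.limit_multiplier_4x = level
        cfg.mating.selfing_rate = {2: 0.0, 3: 0.0, 4: 0.0}  # all plants self-sterile
        cfg.mating.apomixis_rate = {2: 0.0, 3: 0.0, 4: 0.0}
    elif family == "shifted_optimum":
        # Tetraploid bearers get selfing assurance here: with a shifted
        # optimum a lone neotetraploid establishes away from other 4x plants
        # and could never found a lineage as an obligate outcrosser; the low
        # GPIP and diploid-tetraploid coexistence this family is meant to
        # exhibit require it.
        if level < 0:
            raise ExperimentError(f"shift distance must be >= 0, got {level}")
        cfg.shift_distance = float(level)
        cfg.mating.selfing_rate = {2: 0.0, 3: 0.0, 4: 1.0}
        cfg.mating.apomixis_rate = {2: 0.0, 3: 0.0, 4: 0.0}
    else:
        raise ExperimentError(f"unknown family {family!r}")
    cfg.mating.validate()
    return cfg


def run_experiment(
    design: ExperimentDesign,
    grid: Optional[EnvironmentGrid] = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the sweep; one row per (family, level, replicate).

    The environmental landscape is generated once (it is a fixed input shared
    by all replicates, like the raster stack it stands in for); stochasticity
    between replicates comes entirely from their derived seeds.
    """
    if grid is None:
        grid = generate_synthetic_environment(design.base_config.env, design.base_config.env_seed)
    rows = []
    for level in design.levels:
        cfg = config_for_level(design.family, level, design.base_config)
        for rep in range(design.replicates):
            seed = replicate_seed(design.root_seed, design.family, level, rep)
            summary, _events = run_replicate(cfg, seed, grid=grid)
            loc = summary.first_spe_location
            rows.append(
                {
                    "family": design.family,
                    "level": level,
                    "replicate": rep,
                    "seed": seed,
                    "spe": summary.spe_count,
                    "upe": summary.upe_count,
                    "bilateral": summary.bilateral_count,
                    "unilateral": summary.unilateral_count,
                    "final_4x": summary.final_4x_proportion,
                    "gpip": summary.gpip,
                    "guf": summary.guf,
                    "stop_reason": summary.stop_reason,
                    "n_generations": summary.n_generations,
                    "first_spe_x": loc[0] if loc else np.nan,
                    "first_spe_y": loc[1] if loc else np.nan,
                    "founder_e_spe": summary.mean_founder_fitness_spe,
                    "founder_e_upe": summary.mean_founder_fitness_upe,
                }
            )
            if progress:
                print(f"{design.family} level={level} rep={rep}: spe={rows[-1]['spe']}")
    return pd.DataFrame(rows)


# -- summaries ---------------------------------------------------------------


def summarize_treatments(table: pd.DataFrame) -> pd.DataFrame:
    """Per-level mean and sd of every response variable (Table-style rows).

    GPIP and GuF are averaged over the replicates where they are defined and
    reported as NaN ('na') when no replicate defines them.
    """
    if table.empty:
        raise ExperimentError("empty replicate table")
    out = []
    for level, sub in table.groupby("level", sort=True):
        if len(sub) < 2:
            raise ExperimentError(f"need >= 2 replicates per level (level {level})")
        row: dict[str, float] = {"level": level, "n": len(sub)}
        for resp in RESPONSES:
            row[f"{resp}_mean"] = sub[resp].mean()
            row[f"{resp}_sd"] = sub[resp].std(ddof=1)
        for resp in ("gpip", "guf"):
            vals = sub[resp].dropna()
            row[f"{resp}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{resp}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        out.append(row)
    return pd.DataFrame(out)


def anova_f(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value across treatment groups."""
    return tuple(map(float, stats.f_oneway(*groups)))


def _tukey_nonsignificant(table: pd.DataFrame, response: str, alpha: float) -> tuple[list, np.ndarray, np.ndarray]:
    """Sorted levels (descending mean), their means, and the pairwise
    non-significance matrix from a Tukey HSD test."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    levels = sorted(table["level"].unique(), key=lambda lv: -table.loc[table["level"] == lv, response].mean())
    means = np.array([table.loc[table["level"] == lv, response].mean() for lv in levels])
    k = len(levels)
    nonsig = np.ones((k, k), dtype=bool)

    values = table[response].to_numpy(dtype=float)
    if np.ptp(values) == 0:  # all observations identical: nothing separates
        return levels, means, nonsig

    res = pairwise_tukeyhsd(values, table["level"].to_numpy(), alpha=alpha)
    g_index = {g: i for i, g in enumerate(res.groupsunique)}
    pos = {lv: levels.index(lv) for lv in levels}
    pair_iter = zip(combinations(sorted(g_index, key=g_index.get), 2), res.reject)
    for (g1, g2), reject in pair_iter:
        i, j = pos[g1], pos[g2]
        nonsig[i, j] = nonsig[j, i] = not bool(reject)
    return levels, means, nonsig


def compare_treatments(
    table: pd.DataFrame, response: str, alpha: float = 0.01
) -> dict[float, str]:
    """Compact letter display over treatment levels for one response.

    Levels sharing a letter are not significantly different under all-pairs
    Tukey HSD at ``alpha``; letters are assigned deterministically by sweeping
    the levels in order of descending mean and merging maximal runs of
    mutually non-significant groups.
    """
    if table["level"].nunique() < 2:
        raise ExperimentError("need >= 2 levels to compare")
    levels, _means, nonsig = _tukey_nonsignificant(table, response, alpha)
    k = len(levels)

    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and all(
            nonsig[a][b] for a in range(i, j + 2) for b in range(a + 1, j + 2)
        ):
            j += 1
        intervals.append((i, j))
    # keep only maximal intervals
    maximal = [
        iv
        for iv in intervals
        if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in intervals)
    ]
    maximal = sorted(set(maximal))
    letters: dict[float, str] = {lv: "" for lv in levels}
    for letter_idx, (lo, hi) in enumerate(maximal):
        letter = chr(ord("a") + letter_idx % 26)
        for idx in range(lo, hi + 1):
            letters[levels[idx]] += letter
    return letters


def treatment_report(
    table: pd.DataFrame, responses: Sequence[str] = RESPONSES, alpha: float = 0.01
) -> pd.DataFrame:
    """Summary table with mean ± sd and Tukey letter group per response."""
    summary = summarize_treatments(table)
    for resp in responses:
        letters = compare_treatments(table, resp, alpha=alpha)
        summary[f"{resp}_letters"] = summary["level"].map(letters)
    return summary


# -- density maps and efficiency --------------------------------------------


def spe_density_map(
    locations: Sequence[tuple[float, float]] | pd.DataFrame,
    dims: tuple[int, int],
) -> np.ndarray:
    """Accumulate first-SPE founder locations into an (H, W) count grid.

    ``locations`` may be an iterable of (x, y) pairs or a replicate table
    with ``first_spe_x`` / ``first_spe_y`` columns (NaN rows ignored).  Total
    mass equals the number of located events.
    """
    height, width = dims
    grid = np.zeros((height, width), dtype=np.int64)
    if isinstance(locations, pd.DataFrame):
        sub = locations.dropna(subset=["first_spe_x", "first_spe_y"])
        xs = sub["first_spe_x"].to_numpy(dtype=int)
        ys = sub["first_spe_y"].to_numpy(dtype=int)
    else:
        pts = list(locations)
        xs = np.array([int(p[0]) for p in pts], dtype=int)
        ys = np.array([int(p[1]) for p in pts], dtype=int)
    np.add.at(grid, (ys, xs), 1)
    return grid


def diploid_range_boundary(config: SimulationConfig, grid: Optional[EnvironmentGrid] = None) -> np.ndarray:
    """(H, W) mask of the maximum possible diploid distribution.

    A patch belongs to the range if it lies within diploid tolerance of at
    least one founder-area genotype (the optima of the central founder block)
    — the region the density-map figures outline in black.
    """
    if grid is None:
        grid = generate_synthetic_environment(config.env, config.env_seed)
    from .demography import central_block

    ys, xs = central_block(grid, config.founder_block)
    optima = grid.layers[:, ys, xs].reshape(grid.layers.shape[0], -1)
    ok = np.zeros((grid.height, grid.width), dtype=bool)
    for j in range(optima.shape[1]):
        ok |= suitable_mask(grid, config.tolerance, optima[:, j], ploidy=2)
    return ok


def establishment_efficiency(summary: pd.DataFrame) -> pd.Series:
    """Per-level efficiency of successful events: mean 4x proportion / mean SPE.

    NaN where the level produced no SPE at all (ratio undefined).
    """
    eff = summary["final_4x_mean"] / summary["spe_mean"]
    eff[summary["spe_mean"] <= 0] = np.nan
    return pd.Series(eff.values, index=summary["level"].values, name="efficiency")
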