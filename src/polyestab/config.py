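"""Run configuration: one object bundling every tunable of a replicate.

Configurations are plain dataclasses with YAML round-tripping, so a run is
fully described by a small text file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .demography import BASE_LIFESPAN, DEATH_RATE, FECUNDITY_CAPS, ToleranceConfig
from .dispersal import DispersalConfig
from .environment import DEFAULT_ENV_SEED, LayerSpec, SyntheticEnvSpec
from .reproduction import MatingConfig


@dataclass
class SimulationConfig:
    """Everything needed to run one replicate (except the RNG seed)."""

    env: SyntheticEnvSpec = field(default_factory=SyntheticEnvSpec)
    env_seed: int = DEFAULT_ENV_SEED
    tolerance: ToleranceConfig = field(default_factory=ToleranceConfig)
    mating: MatingConfig = field(default_factory=MatingConfig)
    dispersal: DispersalConfig = field(default_factory=DispersalConfig)

    n_founders: int = 30
    founder_block: int = 20  # side of the central block founders start in
    death_rate: float = DEATH_RATE
    base_lifespan: int = BASE_LIFESPAN
    fecundity_caps: tuple[int, int, int] = FECUNDITY_CAPS
    sv_sd: float = 1e-3
    horizon_after_onset: int = 1000
    establishment_threshold: int = 50
    fitness_combine: str = "geometric"

    #: clamp E everywhere to this value (homogeneous-environment mode);
    #: fecundity still scales with age.
    uniform_e: Optional[float] = None

    #: shifted-optimum experiment: Euclidean distance (patches) between the
    #: founder-area centroid and the tetraploid optimum patches; None = shared
    #: optimum.
    shift_distance: Optional[float] = None
    n_optimum_patches: int = 30

    @property
    def onset_generation(self) -> int:
        return self.mating.onset_generation

    @property
    def max_generation(self) -> int:
        return self.mating.onset_generation + self.horizon_after_onset

    def copy(self) -> "SimulationConfig":
        cfg = dataclasses.replace(self)
        cfg.tolerance = dataclasses.replace(self.tolerance, limit=self.tolerance.limit.copy())
        cfg.mating = dataclasses.replace(
            self.mating,
            triploid_gamete_mix=dict(self.mating.triploid_gamete_mix),
            selfing_rate=dict(self.mating.selfing_rate),
            apomixis_rate=dict(self.mating.apomixis_rate),
        )
        cfg.dispersal = dataclasses.replace(self.dispersal)
        return cfg

    # -- YAML ---------------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tolerance"]["limit"] = [float(v) for v in self.tolerance.limit]
        d["env"]["layers"] = [dataclasses.asdict(ls) for ls in self.env.layers]
        d["fecundity_caps"] = list(self.fecundity_caps)
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "env" in d:
            env = dict(d["env"])
            env["layers"] = tuple(LayerSpec(**ls) for ls in env.get("layers", []))
            d["env"] = SyntheticEnvSpec(**env)
        if "tolerance" in d:
            tol = dict(d["tolerance"])
            tol["limit"] = np.asarray(tol["limit"], dtype=float)
            d["tolerance"] = ToleranceConfig(**tol)
        if "mating" in d:
            mat = dict(d["mating"])
            for key in ("selfing_rate", "apomixis_rate"):
                if key in mat:
                    mat[key] = {int(k): float(v) for k, v in mat[key].items()}
            d["mating"] = MatingConfig(**mat)
        if "dispersal" in d:
            d["dispersal"] = DispersalConfig(**d["dispersal"])
        if "fecundity_caps" in d:
            d["fecundity_caps"] = tuple(d["fecundity_caps"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def felber_config(
    unreduced_rate: float = 0.15,
    grid_side: int = 32,
    onset_generation: int = 50,
    horizon_after_onset: int = 500,
) -> SimulationConfig:
    """Preset replicating the classical gametic-recursion comparison.

    Uniform environment (every plant at E = 1), inviable triploids, equal
    cytotype fitness, and distance-free ('global') pollen donor choice; the
    ~1000-patch workspace keeps the census on the order of the comparison's
    quasi-equilibrium population.  Only unreduced-gamete dynamics and patch
    competition remain.
    """
    cfg = SimulationConfig()
    flat = tuple(
        LayerSpec(mean=ls.mean, amplitude=0.0, correlation_length=ls.correlation_length)
        for ls in cfg.env.layers
    )
    cfg.env = SyntheticEnvSpec(width=grid_side, height=grid_side, layers=flat)
    cfg.mating = MatingConfig(
        unreduced_rate_2x=unreduced_rate,
        triploid_seed_viability=0.0,
        onset_generation=onset_generation,
        pollen_global=True,
    )
    cfg.horizon_after_onset = horizon_after_onset
    return cfg
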