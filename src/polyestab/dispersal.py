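"""Seed dispersal kernel and settlement of seeds on free patches.

The total effective dispersal kernel is collapsed into a single negative
exponential: a seed's landing distance is exponentially distributed (mean
``lambda_seed`` patches, truncated at ``max_radius``) in a uniformly random
direction, so most seeds land in the immediate neighbourhood of the mother.
Edges are absorbing — a displaced point outside the workspace is a lost
seed.

Settlement is simultaneous within a generation: seeds landing on occupied or
unsuitable patches are discarded, and when several seeds contend for one
free suitable patch the one with the highest prospective environmental
fitness E wins (ties broken uniformly at random).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DispersalConfigError(ValueError):
    pass


@dataclass
class DispersalConfig:
    """Negative-exponential seed kernel parameters (distances in patches)."""

    lambda_seed: float = 1.5
    max_radius: float = 20.0

    def __post_init__(self) -> None:
        if self.lambda_seed <= 0:
            raise DispersalConfigError("lambda_seed must be > 0")
        if self.max_radius < 1:
            raise DispersalConfigError("max_radius must be >= 1")


def sample_distances(
    n: int, cfg: DispersalConfig, rng: np.random.Generator
) -> np.ndarray:
    """Truncated-exponential landing distances (inverse-CDF sampling)."""
    u = rng.random(n)
    tail = 1.0 - np.exp(-cfg.max_radius / cfg.lambda_seed)
    return -cfg.lambda_seed * np.log1p(-u * tail)


def sample_destinations(
    origin_x: np.ndarray,
    origin_y: np.ndarray,
    cfg: DispersalConfig,
    rng: np.random.Generator,
    width: int,
    height: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized landing patches for many seeds.

    Returns (dest_x, dest_y, inside) where ``inside`` marks seeds landing on
    the grid; destinations of lost seeds are undefined.
    """
    n = len(origin_x)
    r = sample_distances(n, cfg, rng)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    dx = np.rint(origin_x + r * np.cos(theta)).astype(np.int64)
    dy = np.rint(origin_y + r * np.sin(theta)).astype(np.int64)
    inside = (dx >= 0) & (dx < width) & (dy >= 0) & (dy < height)
    return dx, dy, inside


def sample_seed_destination(
    origin: tuple[int, int],
    cfg: DispersalConfig,
    rng: np.random.Generator,
    width: int,
    height: int,
) -> tuple[int, int] | None:
    """Landing patch of one seed, or None if it leaves the workspace."""
    dx, dy, inside = sample_destinations(
        np.array([origin[0]]), np.array([origin[1]]), cfg, rng, width, height
    )
    if not inside[0]:
        return None
    return int(dx[0]), int(dy[0])


def resolve_contention(
    patch_id: np.ndarray, prospective_e: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Indices of winning seeds, one per contested patch.

    Among the candidate seeds (all on free, suitable patches) the seed with
    the maximal prospective E wins its patch; exact ties are broken uniformly
    at random.
    """
    n = len(patch_id)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    order = np.lexsort((rng.random(n), -prospective_e, patch_id))
    sorted_pid = patch_id[order]
    first = np.ones(n, dtype=bool)
    first[1:] = sorted_pid[1:] != sorted_pid[:-1]
    return order[first]


def settle_seeds(
    candidates: list[tuple[object, tuple[int, int], float]],
    occupied: np.ndarray,
    suitable: list[bool],
    rng: np.random.Generator,
) -> list[tuple[object, tuple[int, int]]]:
    """Object-level settlement used for small-scale work and tests.

    ``candidates`` is a list of (seed, (x, y), prospective_e); ``occupied``
    is a boolean (H, W) mask of already-held patches; ``suitable`` flags each
    candidate's patch suitability for that seed's cytotype.  Returns the
    (seed, patch) placements; at most one per patch.
    """
    if not candidates:
        return []
    width = occupied.shape[1]
    keep = [
        i
        for i, (seed, (x, y), _e) in enumerate(candidates)
        if suitable[i] and not occupied[y, x]
    ]
    if not keep:
        return []
    pid = np.array([candidates[i][1][1] * width + candidates[i][1][0] for i in keep])
    e = np.array([candidates[i][2] for i in keep])
    winners = resolve_contention(pid, e, rng)
    return [(candidates[keep[w]][0], candidates[keep[w]][1]) for w in winners]
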