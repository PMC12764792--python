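"""Five-layer environmental lattice on which all plants live.

The workspace is a rectangular grid of 0.25 m^2 patches, each holding at most
one plant.  Every patch carries five scalar environmental variables: three
"bioclimatic" layers (V1-V3, e.g. solar radiation, isothermality, annual
precipitation) that are nearly uniform at the micro-scale of the workspace,
and two "soil" layers (V4-V5, e.g. available water capacity and organic
carbon) whose spatial patchiness is what actually restricts where a genotype
can live.

Layers can be loaded from single-band rasters (plain TIFF) or per-layer CSV
dumps, or generated synthetically as smoothed Gaussian random fields that
emulate that structure: near-uniform bioclimatic layers with a long
correlation length, patchy soil layers with a short one.

A global seasonal factor SV ~ Normal(1, 1e-3), drawn once per generation,
multiplies V1-V3 (and only those) to create mild intergenerational
environmental variation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

N_LAYERS = 5
BIOCLIM = (0, 1, 2)  # layer indices scaled by the seasonal factor
SOIL = (3, 4)

PATCH_AREA_M2 = 0.25

#: Environment seed used for the packaged default landscape.  The landscape is
#: a fixed model input (one landscape shared by all replicates of a study);
#: run-to-run randomness lives in the demographic RNG instead.
DEFAULT_ENV_SEED = 0


class EnvironmentConfigError(ValueError):
    """Raised for invalid environment specifications or unreadable layers."""


@dataclass(frozen=True)
class LayerSpec:
    """Synthetic-field recipe for one environmental layer.

    mean
        Central value of the layer, in the variable's own units.
    amplitude
        Standard deviation of the smoothed random field around the mean.
    correlation_length
        Spatial autocorrelation scale in patches (Gaussian smoothing sigma).
    basin_amplitude / basin_radius
        Optional systematic drift away from the central values: the layer
        rises by ``basin_amplitude * (r / basin_radius)**2`` at distance r
        from the grid center.  Soil layers use it so the terrain resembling
        the founding area is one bounded central region inside an otherwise
        unsuitable landscape — the role the soil rasters play on the real
        cropped landscape — instead of a scatter of look-alike blobs.
    """

    mean: float
    amplitude: float
    correlation_length: float
    basin_amplitude: float = 0.0
    basin_radius: float = 50.0

    def validate(self) -> None:
        if self.amplitude < 0 or self.basin_amplitude < 0:
            raise EnvironmentConfigError(f"amplitudes must be >= 0 in {self}")
        if self.correlation_length <= 0 or self.basin_radius <= 0:
            raise EnvironmentConfigError(
                f"correlation/basin lengths must be > 0 in {self}"
            )


def _default_layers() -> tuple[LayerSpec, ...]:
    # V1-V3 near-uniform bioclimatic fields (radiation kJ/m2/day, isothermality %,
    # annual precipitation mm); V4-V5 patchy soil fields (water capacity v%,
    # organic carbon g/kg).  Amplitudes were calibrated once so that, together
    # with the default tolerance limits, the diploid quasi-equilibrium census
    # on the default landscape is on the order of 1000 plants.
    return (
        LayerSpec(mean=15000.0, amplitude=40.0, correlation_length=60.0),
        LayerSpec(mean=55.0, amplitude=0.12, correlation_length=60.0),
        LayerSpec(mean=950.0, amplitude=2.0, correlation_length=60.0),
        LayerSpec(mean=22.0, amplitude=5.0, correlation_length=12.0,
                  basin_amplitude=40.0, basin_radius=50.0),
        LayerSpec(mean=9.0, amplitude=3.0, correlation_length=12.0,
                  basin_amplitude=24.0, basin_radius=50.0),
    )


@dataclass(frozen=True)
class SyntheticEnvSpec:
    """Recipe for a synthetic five-layer landscape."""

    width: int = 100
    height: int = 100
    layers: tuple[LayerSpec, ...] = field(default_factory=_default_layers)

    def validate(self) -> None:
        if self.width < 1 or self.height < 1:
            raise EnvironmentConfigError("grid dimensions must be positive")
        if len(self.layers) != N_LAYERS:
            raise EnvironmentConfigError(f"exactly {N_LAYERS} layers required")
        for spec in self.layers:
            spec.validate()


@dataclass
class EnvironmentGrid:
    """The patch lattice: five co-registered scalar fields.

    ``layers`` has shape (5, height, width); patch coordinates are 0-based
    integers with the origin at the lower-left, ``layers[i, y, x]`` giving
    V_{i+1} on patch (x, y).  Distances are Euclidean between patch centers.
    Non-finite values (raster nodata) mark patches unsuitable for everyone.
    """

    layers: np.ndarray
    patch_area: float = PATCH_AREA_M2

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3 or self.layers.shape[0] != N_LAYERS:
            raise EnvironmentConfigError(
                f"layers must have shape (5, H, W), got {self.layers.shape}"
            )

    @property
    def height(self) -> int:
        return self.layers.shape[1]

    @property
    def width(self) -> int:
        return self.layers.shape[2]

    @property
    def n_patches(self) -> int:
        return self.height * self.width

    def values_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Stack of V1..V5 at the given patch coordinates, shape (5, n)."""
        return self.layers[:, y, x]

    # -- plain-text round trip -------------------------------------------------

    def to_csv_dir(self, directory: str | os.PathLike) -> None:
        """Dump each layer as ``layer_<i>.csv`` (row-major, row 0 = y 0)."""
        os.makedirs(directory, exist_ok=True)
        for i in range(N_LAYERS):
            np.savetxt(
                os.path.join(directory, f"layer_{i + 1}.csv"),
                self.layers[i],
                delimiter=",",
            )

    @classmethod
    def from_csv_dir(cls, directory: str | os.PathLike) -> "EnvironmentGrid":
        layers = [
            np.loadtxt(os.path.join(directory, f"layer_{i + 1}.csv"), delimiter=",", ndmin=2)
            for i in range(N_LAYERS)
        ]
        shapes = {a.shape for a in layers}
        if len(shapes) != 1:
            raise EnvironmentConfigError(f"layer CSVs disagree on dimensions: {shapes}")
        return cls(layers=np.stack(layers))


def _gaussian_random_field(
    shape: tuple[int, int], correlation_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Smoothed white noise, renormalized to zero mean and unit variance."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=correlation_length, mode="reflect")
    sd = smooth.std()
    if sd == 0:  # pathological: huge sigma on a tiny grid
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def generate_synthetic_environment(
    spec: SyntheticEnvSpec | None = None, seed: int = DEFAULT_ENV_SEED
) -> EnvironmentGrid:
    """Build a synthetic landscape from smoothed Gaussian random fields.

    Identical (spec, seed) pairs produce bit-identical grids.  With all
    amplitudes zero the landscape is perfectly uniform.
    """
    spec = spec or SyntheticEnvSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    shape = (spec.height, spec.width)
    layers = np.empty((N_LAYERS,) + shape)
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    r = np.hypot(xx - (spec.width - 1) / 2.0, yy - (spec.height - 1) / 2.0)
    for i, lspec in enumerate(spec.layers):
        value = np.full(shape, lspec.mean)
        if lspec.amplitude > 0:
            value += lspec.amplitude * _gaussian_random_field(
                shape, lspec.correlation_length, rng
            )
        if lspec.basin_amplitude > 0:
            value += lspec.basin_amplitude * (r / lspec.basin_radius) ** 2
        layers[i] = value
    return EnvironmentGrid(layers=layers)


def uniform_environment(width: int, height: int, means: np.ndarray | None = None) -> EnvironmentGrid:
    """Perfectly homogeneous landscape (every patch identical)."""
    if means is None:
        means = np.array([ls.mean for ls in _default_layers()])
    means = np.asarray(means, dtype=float)
    layers = np.broadcast_to(means[:, None, None], (N_LAYERS, height, width)).copy()
    return EnvironmentGrid(layers=layers)


# -- raster loading ---------------------------------------------------------


def _read_single_band(path: str) -> np.ndarray:
    if not os.path.exists(path):
        raise EnvironmentConfigError(f"raster not found: {path}")
    if path.endswith((".csv", ".txt")):
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    else:
        import tifffile

        arr = np.asarray(tifffile.imread(path), dtype=float)
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise EnvironmentConfigError(
            f"{path}: expected a single band, got array of shape {arr.shape}"
        )
    return np.asarray(arr, dtype=float)


def _bilinear_resample(arr: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Node-based bilinear resampling to exactly ``target`` = (height, width).

    Corner cells are preserved and, on integer disaggregation, the original
    nodes reappear unchanged.
    """
    th, tw = target
    src_h, src_w = arr.shape
    ys = np.linspace(0.0, src_h - 1.0, th) if th > 1 else np.array([(src_h - 1) / 2.0])
    xs = np.linspace(0.0, src_w - 1.0, tw) if tw > 1 else np.array([(src_w - 1) / 2.0])
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return ndimage.map_coordinates(arr, [yy, xx], order=1, mode="nearest")


def load_raster_environment(
    paths: list[str],
    window: tuple[int, int, int, int] | None = None,
    target: tuple[int, int] = (100, 100),
    nodata: float | None = None,
) -> EnvironmentGrid:
    """Load five single-band rasters, crop, and bilinearly resample.

    Parameters
    ----------
    paths
        Five raster files (single-band TIFF or CSV), in V1..V5 order.
    window
        Pixel-coordinate crop window ``(row0, row1, col0, col1)`` applied to
        every raster before resampling (half-open; ``None`` = full extent).
    target
        Output grid dimensions ``(height, width)``.
    nodata
        Optional sentinel value mapped to NaN (patches unsuitable for any
        genotype) before interpolation.
    """
    if len(paths) != N_LAYERS:
        raise EnvironmentConfigError(f"exactly {N_LAYERS} raster paths required")
    layers = []
    for path in paths:
        arr = _read_single_band(path)
        if nodata is not None:
            arr = np.where(arr == nodata, np.nan, arr)
        if window is not None:
            r0, r1, c0, c1 = window
            if not (0 <= r0 < r1 <= arr.shape[0] and 0 <= c0 < c1 <= arr.shape[1]):
                raise EnvironmentConfigError(
                    f"{path}: window {window} outside raster extent {arr.shape}"
                )
            arr = arr[r0:r1, c0:c1]
        out = _bilinear_resample(arr, target)
        if nodata is None and not np.all(np.isfinite(out)):
            raise EnvironmentConfigError(f"{path}: resampling produced non-finite values")
        layers.append(out)
    return EnvironmentGrid(layers=np.stack(layers))


# -- seasonal factor --------------------------------------------------------

SV_SD_DEFAULT = 1e-3


def draw_seasonal_factor(rng: np.random.Generator, sd: float = SV_SD_DEFAULT) -> float:
    """One global Gaussian multiplier, mean 1, applied to V1-V3 this generation."""
    return float(1.0 + sd * rng.standard_normal())


def sv_vector(sv: float) -> np.ndarray:
    """Per-layer multipliers: sv for the bioclimatic layers, 1 for soil."""
    vec = np.ones(N_LAYERS)
    vec[list(BIOCLIM)] = sv
    return vec


def effective_variable(
    grid: EnvironmentGrid, patch: tuple[int, int], i: int, sv: float
) -> float:
    """V_i at a patch with the seasonal factor applied (i is 1-based)."""
    if not 1 <= i <= N_LAYERS:
        raise EnvironmentConfigError(f"layer index must be in 1..{N_LAYERS}, got {i}")
    x, y = patch
    value = float(grid.layers[i - 1, y, x])
    return value * sv if (i - 1) in BIOCLIM else value
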