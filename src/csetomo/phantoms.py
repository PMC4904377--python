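"""Simulated specimens and measurement noise.

Two phantoms drive the simulation studies:

* a **membrane phantom** — a 256 × 100 × 256 volume with values in [0, 1]:
  random ellipsoidal shells (membrane-bound compartments) and filled
  ellipsoids (dense bodies) of random size, eccentricity, orientation and
  contrast, superimposed additively on a non-zero background, imitating
  heavy-metal-stained cellular preparations;
* a **nanoparticle phantom** — a 2-D slice of high-contrast, piecewise
  constant discs and crescents on an empty background, imitating
  cross-sections of inorganic nanoparticle assemblies.

Projections are acquired independently for each x–z slice with the geometry
module's projector.  Noise is count-based: in *nanoparticle* mode the
sinogram is scaled so its mean equals the Poisson rate parameter (expected
counts at the mean projection value), sampled, rescaled, and then corrupted
with zero-mean Gaussian noise whose σ is a fraction of the projection mean;
in *membrane* mode only Poisson noise is applied, with the count scale
calibrated so the average noise level is a target fraction of the
projection mean after background subtraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .exceptions import DegenerateInputError, InvalidParameterError
from .geometry import AngleSet, Sinogram, Slice2D, Volume3D, radon_operator

__all__ = [
    "MembranePhantomSpec",
    "NoiseSpec",
    "make_membrane_phantom",
    "make_nanoparticle_phantom",
    "project_volume",
    "add_poisson_gaussian_noise",
    "calibrate_membrane_noise",
    "projected_background_level",
]

_MAX_RETRIES = 200


@dataclass(frozen=True)
class MembranePhantomSpec:
    """Parameters of the membrane phantom generator.

    Defaults reproduce the simulation conditions used throughout the
    package: a (256, 100, 256) volume on a 0.15 background with 40 shells
    and 60 filled bodies, semi-axes of 4–60 voxels, shell walls 1–3 voxels
    thick and additive contrasts 0.2–0.85 (clipped to [0, 1]).
    """

    dims: Tuple[int, int, int] = (256, 100, 256)
    background: float = 0.15
    n_shells: int = 40
    n_filled: int = 60
    semiaxis_range: Tuple[float, float] = (4.0, 60.0)
    shell_thickness_range: Tuple[float, float] = (1.0, 3.0)
    contrast_range: Tuple[float, float] = (0.2, 0.85)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dims) < 2:
            raise InvalidParameterError("phantom dims must all be >= 2")
        if not (0 < self.background < 1):
            raise InvalidParameterError("background must lie in (0, 1)")
        for name, r in (
            ("semiaxis_range", self.semiaxis_range),
            ("shell_thickness_range", self.shell_thickness_range),
            ("contrast_range", self.contrast_range),
        ):
            if not (0 < r[0] < r[1]):
                raise InvalidParameterError(f"{name} must be a non-degenerate positive range")
        if self.n_shells < 0 or self.n_filled < 0:
            raise InvalidParameterError("structure counts must be non-negative")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise parameters.

    ``poisson_rate`` — expected counts at the mean projection value
    (nanoparticle mode); ``gaussian_frac`` — Gaussian σ as a fraction of the
    projection mean (nanoparticle mode); ``target_frac`` — membrane-mode
    average noise level as a fraction of the background-subtracted
    projection mean; ``background_level`` — projection-domain background
    used in that calibration (callers typically pass the projected phantom
    background).
    """

    poisson_rate: float = 5500.0
    gaussian_frac: float = 0.10
    target_frac: float = 0.10
    background_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.poisson_rate > 0):
            raise InvalidParameterError("poisson_rate must be positive")
        for name, v in (("gaussian_frac", self.gaussian_frac), ("target_frac", self.target_frac)):
            if not (0 <= v < 1):
                raise InvalidParameterError(f"{name} must lie in [0, 1)")


# ---------------------------------------------------------------------------
# Phantom generators
# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3-D rotation matrix (via a normalized quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _sample_ellipsoid(
    rng: np.random.Generator,
    dims: Tuple[int, int, int],
    semiaxis_range: Tuple[float, float],
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (center, semi-axes, rotation) for one structure.

    Along axes where the bounding sphere fits, the center is constrained so
    the structure lies fully inside; along thinner axes (e.g. the 100-voxel
    tilt axis for large compartments) the structure may span the volume and
    is clipped, as membranous bodies are clipped by a real section.
    Structures too large to overlap the volume meaningfully are resampled a
    bounded number of times, then rejected.
    """
    lo, hi = semiaxis_range
    for _ in range(_MAX_RETRIES):
        axes = rng.uniform(lo, hi, size=3)
        r = float(axes.max())
        if float(axes.min()) > max(dims):
            continue  # cannot fit in any orientation; resample
        center = np.array(
            [rng.uniform(r, d - 1 - r) if d - 1 - 2 * r > 0 else rng.uniform(0, d - 1)
             for d in dims]
        )
        return center, axes, _random_rotation(rng)
    raise InvalidParameterError(
        f"could not place an ellipsoid from semi-axis range {semiaxis_range} "
        f"inside dims {dims} after {_MAX_RETRIES} retries"
    )


def _paint_ellipsoid(
    vol: np.ndarray,
    center: np.ndarray,
    axes: np.ndarray,
    rot: np.ndarray,
    contrast: float,
    thickness: Optional[float],
) -> None:
    """Add ``contrast`` inside a filled ellipsoid (thickness None) or an
    ellipsoidal shell of the given wall thickness."""
    r = float(axes.max())
    lo = np.maximum(np.floor(center - r - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + r + 2).astype(int), np.array(vol.shape))
    grids = np.meshgrid(
        *(np.arange(lo[i], hi[i]) - center[i] for i in range(3)), indexing="ij"
    )
    pts = np.stack([g.ravel() for g in grids])
    local = rot.T @ pts
    r2_out = ((local / axes[:, None]) ** 2).sum(axis=0)
    region = r2_out <= 1.0
    if thickness is not None:
        inner = np.maximum(axes - thickness, 0.5)
        r2_in = ((local / inner[:, None]) ** 2).sum(axis=0)
        region &= r2_in > 1.0
    mask = region.reshape(grids[0].shape)
    vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]][mask] += contrast


def make_membrane_phantom(spec: MembranePhantomSpec = MembranePhantomSpec()) -> Volume3D:
    """Generate the membrane phantom volume; values in [0, 1], minimum equal
    to the (positive) background, reproducible for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    vol = np.full(spec.dims, spec.background, dtype=float)
    for kind in ("shell",) * spec.n_shells + ("filled",) * spec.n_filled:
        center, axes, rot = _sample_ellipsoid(rng, spec.dims, spec.semiaxis_range)
        contrast = rng.uniform(*spec.contrast_range)
        thickness = rng.uniform(*spec.shell_thickness_range) if kind == "shell" else None
        _paint_ellipsoid(vol, center, axes, rot, contrast, thickness)
    np.clip(vol, 0.0, 1.0, out=vol)
    return Volume3D(vol)


def make_nanoparticle_phantom(
    dims: Tuple[int, int] = (256, 256),
    n_discs: int = 8,
    n_crescents: int = 4,
    seed: int = 0,
    radius_range: Tuple[float, float] = (10.0, 36.0),
    contrast_range: Tuple[float, float] = (0.6, 1.0),
) -> Slice2D:
    """High-contrast piecewise-constant nanoparticle cross-section.

    Non-overlapping discs and crescents (a disc with an offset interior disc
    carved back to background) painted on a zero background; each structure
    carries one constant contrast, so the histogram has at most
    1 + (number of structures) distinct values.
    """
    if min(dims) < 2:
        raise InvalidParameterError("dims must be >= 2 in both axes")
    rng = np.random.default_rng(seed)
    img = np.zeros(dims)
    xx, zz = np.meshgrid(np.arange(dims[0]), np.arange(dims[1]), indexing="ij")
    placed: List[Tuple[float, float, float]] = []
    for kind in ("disc",) * n_discs + ("crescent",) * n_crescents:
        for attempt in range(_MAX_RETRIES):
            rad = rng.uniform(*radius_range)
            cx = rng.uniform(rad, dims[0] - 1 - rad)
            cz = rng.uniform(rad, dims[1] - 1 - rad)
            if all((cx - px) ** 2 + (cz - pz) ** 2 > (rad + pr + 1) ** 2 for px, pz, pr in placed):
                break
        else:
            raise InvalidParameterError(
                f"could not place {n_discs} discs + {n_crescents} crescents "
                f"in dims {dims} without overlap"
            )
        contrast = rng.uniform(*contrast_range)
        d2 = (xx - cx) ** 2 + (zz - cz) ** 2
        img[d2 <= rad * rad] = contrast
        if kind == "crescent":
            phi = rng.uniform(0, 2 * np.pi)
            ox = cx + 0.3 * rad * math.cos(phi)
            oz = cz + 0.3 * rad * math.sin(phi)
            d2i = (xx - ox) ** 2 + (zz - oz) ** 2
            img[d2i <= (0.65 * rad) ** 2] = 0.0
        placed.append((cx, cz, rad))
    return Slice2D(img)


# ---------------------------------------------------------------------------
# Projection and noise
# ---------------------------------------------------------------------------


def project_volume(v: Volume3D, a: AngleSet) -> List[Sinogram]:
    """Radon-project each x–z slice of a volume; one sinogram per y index.

    All slices share one geometry, so the projector matrix is applied to the
    whole slice stack in a single sparse product.
    """
    nx, ny, nz = v.shape
    op = radon_operator((nx, nz), a)
    stack = np.moveaxis(v.voxels, 1, 2).reshape(nx * nz, ny)
    Y = op.forward(stack)  # (tau*sigma, ny)
    return [Sinogram(Y[:, j].reshape(op.n_tilts, op.n_bins), a) for j in range(ny)]


def projected_background_level(
    shape: Tuple[int, int], angles: AngleSet, background: float
) -> float:
    """Mean measurement value of a uniform-background slice through the
    package's projector — the projection-domain background level used by the
    membrane noise calibration (per-ray background varies with tilt because
    oblique paths are longer and corner rays leave the detector)."""
    op = radon_operator(shape, angles)
    return float(op.forward(np.full(shape[0] * shape[1], background)).mean())


def calibrate_membrane_noise(
    y: Sinogram,
    target_frac: float,
    background_level: float,
) -> float:
    """Poisson count scale ``s`` such that sampling ``Poisson(s·y)/s`` gives
    an average noise level (mean per-entry standard deviation, mean(√(y/s)))
    equal to ``target_frac`` times the background-subtracted projection mean.

    Closed form: s = (mean(√y) / (target_frac · mean(y − background)))².
    Doubling the target quarters the scale.
    """
    if not (0 < target_frac < 1):
        raise InvalidParameterError("target_frac must lie in (0, 1)")
    data = y.data
    if np.any(data < 0):
        raise InvalidParameterError("count-based noise requires a non-negative sinogram")
    target_mean = float(np.mean(data - background_level))
    if target_mean <= 0:
        raise DegenerateInputError("background-subtracted projection mean must be positive")
    return float((np.mean(np.sqrt(data)) / (target_frac * target_mean)) ** 2)


def add_poisson_gaussian_noise(
    y: Sinogram,
    ns: NoiseSpec = NoiseSpec(),
    mode: str = "nanoparticle",
    rng: Optional[np.random.Generator] = None,
) -> Sinogram:
    """Apply the measurement-noise model to one sinogram (seeded).

    ``nanoparticle``: scale the sinogram so its mean equals ``poisson_rate``
    (expected counts at the mean projection value), draw Poisson counts,
    rescale, then add zero-mean Gaussian noise with σ = ``gaussian_frac`` ×
    projection mean.  ``membrane``: Poisson only, at the count scale from
    :func:`calibrate_membrane_noise`.
    """
    if mode not in ("nanoparticle", "membrane"):
        raise InvalidParameterError(f"unknown noise mode {mode!r}")
    data = y.data
    if np.any(data < 0):
        raise InvalidParameterError("count-based noise requires a non-negative sinogram")
    if rng is None:
        rng = np.random.default_rng(ns.seed)
    mean_y = float(data.mean())
    if mode == "nanoparticle":
        if mean_y == 0:
            return Sinogram(data.copy(), y.angles, y.detector_spacing)
        scale = ns.poisson_rate / mean_y
        noisy = rng.poisson(data * scale).astype(float) / scale
        if ns.gaussian_frac > 0:
            noisy = noisy + rng.normal(0.0, ns.gaussian_frac * mean_y, size=data.shape)
    else:
        s = calibrate_membrane_noise(y, ns.target_frac, ns.background_level)
        noisy = rng.poisson(data * s).astype(float) / s
    return Sinogram(noisy, y.angles, y.detector_spacing)
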