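"""Single-axis parallel-beam acquisition geometry.

Tilt-angle schemes, the discrete Radon forward projector and its exact
algebraic adjoint, and compressed-sensing coherence diagnostics.

Conventions
-----------
A reconstruction slice ``f(x, z)`` is stored as a 2-D array ``pixels[x, z]``
(first index along the detector/x axis, second along the beam/z axis).  The
specimen is tilted about the y axis; at 0° the beam travels along z and the
detector reads out along x.  Positive tilt rotates the specimen
counterclockwise in the x–z plane (x right, z up), so the detector
coordinate of the pixel centred at ``(x, z)`` (both measured from the image
centre) at tilt ``θ`` is ``u = x·cosθ − z·sinθ``.

The detector has ``σ = n_x`` bins of unit (one pixel) width, centred on the
rotation centre.  The forward projector splats each pixel's value linearly
onto the two detector bins bracketing ``u``; summed over a projection row
this reproduces the image mass exactly (for mass projecting inside the
detector), and individual rays approximate line integrals with a unit step
along the beam.  The adjoint is the exact transpose of the same sparse
operator — the classical linearly-interpolating backprojector — so the pair
is usable inside conjugate-gradient solvers.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple, Union

import numpy as np
import scipy.sparse as sp

from .exceptions import InvalidParameterError

__all__ = [
    "Scheme",
    "AngleSet",
    "Sinogram",
    "Slice2D",
    "Volume3D",
    "make_uniform_angles",
    "undersample_angles",
    "make_random_angles",
    "RadonOperator",
    "radon_operator",
    "radon_forward",
    "radon_adjoint",
    "mutual_coherence",
    "sampling_bound",
]


class Scheme(str, Enum):
    """How a set of tilt angles was generated."""

    UNIFORM = "uniform"
    UNDERSAMPLED = "undersampled"
    RANDOM = "random"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AngleSet:
    """Ordered tilt angles (degrees) defining a single-axis geometry.

    Angles are strictly ascending and restricted to [−90°, 90°]; 0° means
    the beam travels along the specimen z axis.
    """

    angles_deg: np.ndarray
    scheme: Scheme = Scheme.UNIFORM
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, dtype=float)
        if a.ndim != 1 or a.size == 0:
            raise InvalidParameterError("AngleSet needs a non-empty 1-D angle list")
        if not np.all(np.isfinite(a)):
            raise InvalidParameterError("tilt angles must be finite")
        if np.any(a < -90.0) or np.any(a > 90.0):
            raise InvalidParameterError("tilt angles must lie within [-90, 90] degrees")
        if a.size > 1 and not np.all(np.diff(a) > 0):
            raise InvalidParameterError("tilt angles must be strictly ascending")
        a.setflags(write=False)
        object.__setattr__(self, "angles_deg", a)

    def __len__(self) -> int:
        return int(self.angles_deg.size)

    @property
    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(self.angles_deg)


@dataclass(frozen=True)
class Slice2D:
    """A 2-D electron-density slice ``pixels[x, z]``."""

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2 or p.shape[0] < 2 or p.shape[1] < 2:
            raise InvalidParameterError("Slice2D requires a 2-D array of at least 2x2")
        if not np.all(np.isfinite(p)):
            raise InvalidParameterError("Slice2D pixels must be finite")
        object.__setattr__(self, "pixels", p)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class Volume3D:
    """A 3-D tomogram/phantom volume ``voxels[x, y, z]`` (y is the tilt axis)."""

    voxels: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 3:
            raise InvalidParameterError("Volume3D requires a 3-D array")
        if not np.all(np.isfinite(v)):
            raise InvalidParameterError("Volume3D voxels must be finite")
        object.__setattr__(self, "voxels", v)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def xz_slice(self, y: int) -> Slice2D:
        """The x–z slice at tilt-axis index ``y``."""
        return Slice2D(self.voxels[:, y, :], self.voxel_size)


@dataclass(frozen=True)
class Sinogram:
    """Per-slice projection data: ``data[tilt, detector_bin]``.

    Houses the measurement vector y of one x–z reconstruction problem; the
    row count equals the number of tilt angles and the column count σ the
    number of detector bins (one per image pixel column).
    """

    data: np.ndarray
    angles: AngleSet
    detector_spacing: float = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise InvalidParameterError("Sinogram data must be 2-D (tilts x bins)")
        if d.shape[0] != len(self.angles):
            raise InvalidParameterError(
                f"sinogram has {d.shape[0]} rows but {len(self.angles)} angles"
            )
        if not np.all(np.isfinite(d)):
            raise InvalidParameterError("sinogram values must be finite")
        object.__setattr__(self, "data", d)

    @property
    def n_tilts(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]


def as_pixels(f: Union[Slice2D, np.ndarray]) -> np.ndarray:
    """Accept either a :class:`Slice2D` or a bare 2-D array."""
    return f.pixels if isinstance(f, Slice2D) else np.asarray(f, dtype=float)


# ---------------------------------------------------------------------------
# Tilt-angle schemes
# ---------------------------------------------------------------------------


def make_uniform_angles(max_tilt_deg: float, increment_deg: float) -> AngleSet:
    """Uniform tilt scheme −max_tilt, −max_tilt+inc, …, +max_tilt (inclusive).

    E.g. ``make_uniform_angles(70, 2)`` gives the 71-angle ±70°/2° series and
    ``make_uniform_angles(78, 2)`` the 79-projection experimental series.
    """
    if not (0 < max_tilt_deg <= 90):
        raise InvalidParameterError("max_tilt_deg must be in (0, 90]")
    if not (0 < increment_deg <= 2 * max_tilt_deg):
        raise InvalidParameterError("increment_deg must be in (0, 2*max_tilt_deg]")
    n = int(round(2 * max_tilt_deg / increment_deg))
    angles = -max_tilt_deg + increment_deg * np.arange(n + 1)
    # guard against accumulation pushing the last angle past +max_tilt
    angles[-1] = min(angles[-1], max_tilt_deg)
    return AngleSet(angles, Scheme.UNIFORM)


def undersample_angles(a: AngleSet, k: int) -> AngleSet:
    """Keep every k-th tilt (indices 0, k, 2k, …; the first angle is always kept)."""
    if int(k) != k or k < 1:
        raise InvalidParameterError("undersampling factor k must be an integer >= 1")
    k = int(k)
    if k == 1:
        return a
    return AngleSet(a.angles_deg[::k].copy(), Scheme.UNDERSAMPLED, a.seed)


def make_random_angles(n: int, max_tilt_deg: float, seed: int) -> AngleSet:
    """``n`` i.i.d. tilt angles uniform on [−max_tilt, +max_tilt], sorted ascending.

    Models the randomized acquisition variant in which projection angles are
    drawn at random from the mechanically feasible range instead of being
    uniformly spaced.  Draws are not deduplicated (ties have probability
    zero); sorting keeps downstream solvers stable.
    """
    if int(n) != n or n < 1:
        raise InvalidParameterError("number of random tilts must be an integer >= 1")
    if not (0 < max_tilt_deg <= 90):
        raise InvalidParameterError("max_tilt_deg must be in (0, 90]")
    rng = np.random.default_rng(seed)
    angles = np.sort(rng.uniform(-max_tilt_deg, max_tilt_deg, size=int(n)))
    return AngleSet(angles, Scheme.RANDOM, seed)


# ---------------------------------------------------------------------------
# Discrete Radon pair
# ---------------------------------------------------------------------------


class RadonOperator:
    """Sparse-matrix discrete Radon transform for one slice geometry.

    The operator matrix ``R`` has shape ``(τ·σ, n_x·n_z)``; ``forward`` maps a
    flattened slice to a flattened sinogram and ``adjoint`` applies the exact
    transpose.  Both accept stacks of columns, which lets the solver batch
    many slices (or trials) through a single sparse matrix product.
    """

    def __init__(self, shape: Tuple[int, int], angles: AngleSet):
        nx, nz = int(shape[0]), int(shape[1])
        if nx < 2 or nz < 2:
            raise InvalidParameterError("slice shape must be at least 2x2")
        self.shape = (nx, nz)
        self.angles = angles
        self.n_bins = nx
        self.n_tilts = len(angles)
        self._matrix = _build_radon_matrix(self.shape, angles.angles_rad)
        self._matrix_t = self._matrix.T.tocsr()

    @property
    def matrix(self) -> sp.csr_matrix:
        return self._matrix

    def matrices_for_dtype(self, dtype) -> Tuple[sp.csr_matrix, sp.csr_matrix]:
        """(R, Rᵀ) as CSR in the requested dtype; float32 copies are cached
        for the solver's large batched runs."""
        if np.dtype(dtype) == np.float32:
            if not hasattr(self, "_matrix32"):
                self._matrix32 = self._matrix.astype(np.float32)
                self._matrix_t32 = self._matrix_t.astype(np.float32)
            return self._matrix32, self._matrix_t32
        return self._matrix, self._matrix_t

    def forward(self, f_flat: np.ndarray) -> np.ndarray:
        """Apply R to flattened pixels (npix,) or a stack (npix, ncols)."""
        return self._matrix @ f_flat

    def adjoint(self, y_flat: np.ndarray) -> np.ndarray:
        """Apply Rᵀ to flattened measurements (τ·σ,) or a stack."""
        return self._matrix_t @ y_flat


def _build_radon_matrix(shape: Tuple[int, int], angles_rad: np.ndarray) -> sp.csr_matrix:
    nx, nz = shape
    sigma = nx
    npix = nx * nz
    x = np.arange(nx) - (nx - 1) / 2.0
    z = np.arange(nz) - (nz - 1) / 2.0
    X = np.repeat(x, nz)  # pixel (i, j) flattens to i*nz + j
    Z = np.tile(z, nx)
    cols_parts = []
    rows_parts = []
    vals_parts = []
    pix = np.arange(npix, dtype=np.int64)
    for a, th in enumerate(angles_rad):
        u = X * math.cos(th) - Z * math.sin(th) + (sigma - 1) / 2.0
        i0 = np.floor(u).astype(np.int64)
        w1 = u - i0
        for idx, wt in ((i0, 1.0 - w1), (i0 + 1, w1)):
            m = (idx >= 0) & (idx < sigma) & (wt > 0)
            rows_parts.append(a * sigma + idx[m])
            cols_parts.append(pix[m])
            vals_parts.append(wt[m])
    mat = sp.coo_matrix(
        (np.concatenate(vals_parts), (np.concatenate(rows_parts), np.concatenate(cols_parts))),
        shape=(len(angles_rad) * sigma, npix),
    )
    return mat.tocsr()


_OPERATOR_CACHE: "OrderedDict[tuple, RadonOperator]" = OrderedDict()
_OPERATOR_CACHE_SIZE = 4


def radon_operator(shape: Tuple[int, int], angles: AngleSet) -> RadonOperator:
    """Build (or fetch from a small LRU cache) the projector for a geometry."""
    key = (int(shape[0]), int(shape[1]), angles.angles_deg.tobytes())
    op = _OPERATOR_CACHE.get(key)
    if op is None:
        op = RadonOperator(shape, angles)
        _OPERATOR_CACHE[key] = op
        while len(_OPERATOR_CACHE) > _OPERATOR_CACHE_SIZE:
            _OPERATOR_CACHE.popitem(last=False)
    else:
        _OPERATOR_CACHE.move_to_end(key)
    return op


def radon_forward(f: Union[Slice2D, np.ndarray], a: AngleSet) -> Sinogram:
    """Project a slice: entry (i, j) approximates the line integral of ``f``
    along detector ray j at tilt angle i (unit step along the beam)."""
    pix = as_pixels(f)
    if len(a) == 0:  # pragma: no cover - AngleSet forbids this already
        raise InvalidParameterError("empty AngleSet")
    op = radon_operator(pix.shape, a)
    data = op.forward(pix.ravel()).reshape(op.n_tilts, op.n_bins)
    return Sinogram(data, a)


def radon_adjoint(s: Sinogram, shape: Optional[Tuple[int, int]] = None) -> Slice2D:
    """Apply the exact transpose Rᵀ of :func:`radon_forward`.

    ``shape`` defaults to a square slice (σ × σ).  Satisfies
    ``<R f, y> == <f, Rᵀ y>`` to floating-point rounding.
    """
    if shape is None:
        shape = (s.n_bins, s.n_bins)
    if shape[0] != s.n_bins:
        raise InvalidParameterError(
            f"target shape {shape} inconsistent with sinogram of {s.n_bins} bins (sigma = n_x)"
        )
    op = radon_operator(shape, s.angles)
    return Slice2D(op.adjoint(s.data.ravel()).reshape(shape))


# ---------------------------------------------------------------------------
# Coherence diagnostics
# ---------------------------------------------------------------------------


def mutual_coherence(
    dictA: np.ndarray,
    dictB: np.ndarray,
    sample_fraction: float = 1.0,
    seed: int = 0,
) -> float:
    """Mutual coherence μ = √N · max |<φ_i, ψ_j>| over (sub-sampled) vector pairs.

    ``dictA`` and ``dictB`` are arrays of shape (n_vectors, N) whose rows are
    unit-Euclidean-norm measurement / representation vectors.  For orthonormal
    bases μ lies in [1, √N]; the Euclidean and Fourier bases attain the
    incoherent extreme μ = 1.  Large dictionaries may be compared on a random
    subsample of each (``sample_fraction`` of the vectors, seeded).
    """
    A = np.atleast_2d(np.asarray(dictA))
    B = np.atleast_2d(np.asarray(dictB))
    if A.shape[1] != B.shape[1]:
        raise InvalidParameterError("dictionaries must share the ambient dimension N")
    if not (0 < sample_fraction <= 1):
        raise InvalidParameterError("sample_fraction must be in (0, 1]")
    for name, D in (("dictA", A), ("dictB", B)):
        norms = np.linalg.norm(D, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise InvalidParameterError(f"{name} rows must have unit Euclidean norm")
    rng = np.random.default_rng(seed)
    if sample_fraction < 1.0:
        na = max(1, int(math.ceil(sample_fraction * A.shape[0])))
        nb = max(1, int(math.ceil(sample_fraction * B.shape[0])))
        A = A[rng.choice(A.shape[0], size=na, replace=False)]
        B = B[rng.choice(B.shape[0], size=nb, replace=False)]
    G = A @ B.conj().T
    return float(math.sqrt(A.shape[1]) * np.max(np.abs(G)))


def sampling_bound(mu: float, k: float, N: float, C: float = 1.0) -> float:
    """Minimum measurement count m = C·μ²·k·log(N) for recovery of a k-sparse
    signal of length N measured with coherence μ (natural logarithm)."""
    if mu <= 0 or k <= 0 or C <= 0:
        raise InvalidParameterError("mu, k and C must be positive")
    if N <= 1:
        raise InvalidParameterError("signal length N must exceed 1")
    return float(C * mu * mu * k * math.log(N))
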