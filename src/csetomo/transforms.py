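"""Sparsity transforms and shrinkage operators.

Three transform domains are used throughout the package: the total-variation
(gradient) domain, the identity domain, and an orthonormal Daubechies-8
wavelet domain.  The gradient/divergence pair and the wavelet pair are exact
adjoints of each other, which the reconstruction solver's conjugate-gradient
normal operator relies on.

All gradient/divergence/wavelet routines accept either a single slice
(2-D array) or a stack of slices (3-D array whose trailing axis indexes
columns); the transform always acts on the leading two axes, so a whole
batch of reconstruction problems moves through one call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Tuple, Union

import numpy as np
import pywt

from .exceptions import DegenerateInputError, InvalidParameterError
from .geometry import Slice2D

__all__ = [
    "GradientField",
    "WaveletCoeffs",
    "grad2d",
    "div2d",
    "tv_norm",
    "wavelet_forward",
    "wavelet_inverse",
    "soft_threshold",
    "vector_shrink",
    "compressibility_ratio",
]

WAVELET = "db8"  # Daubechies, 8 vanishing moments (16-tap orthogonal filter)
_MODE = "periodization"  # keeps the transform square and orthonormal
DEFAULT_LEVELS = 4


@dataclass
class GradientField:
    """Forward-difference gradient (gx, gz) congruent with the source slice.

    The last entry along each differentiated axis is zero (replicate /
    Neumann boundary), so a constant slice has an identically zero field.
    """

    gx: np.ndarray
    gz: np.ndarray

    def __post_init__(self) -> None:
        if self.gx.shape != self.gz.shape:
            raise InvalidParameterError("gx and gz must be congruent")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.gx.shape

    def magnitude(self) -> np.ndarray:
        """Isotropic per-pixel gradient magnitude √(gx² + gz²)."""
        return np.sqrt(self.gx * self.gx + self.gz * self.gz)


def _as_array(f: Union[Slice2D, np.ndarray]) -> np.ndarray:
    a = f.pixels if isinstance(f, Slice2D) else np.asarray(f, dtype=float)
    if a.ndim not in (2, 3):
        raise InvalidParameterError("expected a slice (2-D) or a slice stack (3-D)")
    if not np.all(np.isfinite(a)):
        raise InvalidParameterError("input must be finite")
    return a


def grad2d(f: Union[Slice2D, np.ndarray]) -> GradientField:
    """Forward differences along x (axis 0) and z (axis 1); linear in ``f``."""
    a = _as_array(f)
    gx = np.zeros_like(a)
    gz = np.zeros_like(a)
    gx[:-1] = a[1:] - a[:-1]
    gz[:, :-1] = a[:, 1:] - a[:, :-1]
    return GradientField(gx, gz)


def div2d(g: GradientField) -> np.ndarray:
    """Discrete divergence, the negative adjoint of :func:`grad2d`:
    ``<grad2d(f), g> == -<f, div2d(g)>`` exactly."""
    gx, gz = g.gx, g.gz
    out = np.zeros_like(gx)
    # backward difference of gx along x, with the boundary terms that make
    # the pair an exact adjoint of the zero-extended forward difference
    out[0] += gx[0]
    out[1:-1] += gx[1:-1] - gx[:-2]
    out[-1] += -gx[-2]
    # same along z
    out[:, 0] += gz[:, 0]
    out[:, 1:-1] += gz[:, 1:-1] - gz[:, :-2]
    out[:, -1] += -gz[:, -2]
    return out


def tv_norm(f: Union[Slice2D, np.ndarray], mode: str = "isotropic") -> float:
    """Total variation of a slice.

    ``isotropic``: Σ √(gx² + gz²); ``anisotropic``: Σ (|gx| + |gz|).  Zero
    exactly when ``f`` is constant; positively homogeneous of degree 1.
    """
    g = grad2d(f)
    if mode == "isotropic":
        return float(np.sum(g.magnitude()))
    if mode == "anisotropic":
        return float(np.sum(np.abs(g.gx)) + np.sum(np.abs(g.gz)))
    raise InvalidParameterError(f"unknown TV mode {mode!r}")


# ---------------------------------------------------------------------------
# Orthonormal wavelet pair
# ---------------------------------------------------------------------------


@dataclass
class WaveletCoeffs:
    """Multi-level 2-D wavelet coefficients plus layout metadata.

    ``array`` holds all subbands packed into a single array of the padded
    image shape (one coefficient per padded pixel — the transform is
    orthonormal with periodic extension); ``slices`` is the pywt layout
    needed for exact inversion, ``pad`` the symmetric zero-padding applied
    before decomposition and ``orig_shape`` the pre-padding shape.
    """

    array: np.ndarray
    slices: List
    levels: int
    orig_shape: Tuple[int, int]
    pad: Tuple[Tuple[int, int], Tuple[int, int]]
    wavelet: str = WAVELET


def _padding(n: int, levels: int) -> Tuple[int, int]:
    m = 1 << levels
    total = (-n) % m
    return total // 2, total - total // 2


def wavelet_forward(
    f: Union[Slice2D, np.ndarray],
    levels: int = DEFAULT_LEVELS,
    pad: bool = True,
) -> WaveletCoeffs:
    """Orthonormal multi-level db8 decomposition with periodic extension.

    Dimensions must be divisible by 2**levels; with ``pad=True`` (default)
    the slice is symmetrically zero-padded to the next multiple and the
    padding is cropped again on inversion, otherwise non-divisible input is
    rejected.  Energy is preserved (Parseval) to floating-point rounding.
    """
    a = _as_array(f)
    if levels < 1:
        raise InvalidParameterError("levels must be >= 1")
    nx, nz = a.shape[0], a.shape[1]
    px, pz = _padding(nx, levels), _padding(nz, levels)
    if (px != (0, 0) or pz != (0, 0)) and not pad:
        raise InvalidParameterError(
            f"shape ({nx}, {nz}) not divisible by 2**{levels} and padding is disabled"
        )
    if px != (0, 0) or pz != (0, 0):
        width = [px, pz] + [(0, 0)] * (a.ndim - 2)
        a = np.pad(a, width)
    with warnings.catch_warnings():
        # pywt warns when levels exceed its heuristic maximum for the filter
        # length; with periodization the transform stays exactly orthonormal.
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(a, WAVELET, mode=_MODE, level=levels, axes=(0, 1))
    arr, slices = pywt.coeffs_to_array(coeffs, axes=(0, 1))
    return WaveletCoeffs(arr, slices, levels, (nx, nz), (px, pz))


def wavelet_inverse(c: WaveletCoeffs) -> np.ndarray:
    """Exact inverse (= adjoint, the transform being orthonormal) of
    :func:`wavelet_forward`; round-trips to 1e-10."""
    try:
        coeffs = pywt.array_to_coeffs(c.array, c.slices, output_format="wavedec2")
        rec = pywt.waverec2(coeffs, c.wavelet, mode=_MODE, axes=(0, 1))
    except (ValueError, TypeError, IndexError) as exc:
        raise InvalidParameterError(f"corrupted wavelet coefficient layout: {exc}") from exc
    (bx, ax), (bz, az) = c.pad
    nx, nz = c.orig_shape
    rec = rec[bx : bx + nx, bz : bz + nz]
    if rec.shape[:2] != (nx, nz):
        raise InvalidParameterError("coefficient layout inconsistent with stored shape")
    return rec


# ---------------------------------------------------------------------------
# Shrinkage operators (the split-Bregman proximal steps)
# ---------------------------------------------------------------------------


def soft_threshold(x: Union[float, np.ndarray], t: float) -> Union[float, np.ndarray]:
    """Scalar soft shrinkage sign(x)·max(|x|−t, 0), elementwise."""
    if t < 0:
        raise InvalidParameterError("threshold must be non-negative")
    if np.isscalar(x):
        ax = abs(x) - t
        return float(np.sign(x) * max(ax, 0.0))
    x = np.asarray(x)
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def vector_shrink(g: GradientField, t: float) -> GradientField:
    """Isotropic (vectorial) shrinkage of a gradient field: each per-pixel
    vector (gx, gz) is scaled by max(‖·‖−t, 0)/‖·‖ (zero where ‖·‖ = 0)."""
    if t < 0:
        raise InvalidParameterError("threshold must be non-negative")
    mag = g.magnitude()
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(mag > 0, np.maximum(mag - t, 0.0) / np.where(mag > 0, mag, 1.0), 0.0)
    return GradientField(g.gx * scale, g.gz * scale)


# ---------------------------------------------------------------------------
# Compressibility
# ---------------------------------------------------------------------------

_DOMAINS = ("TV", "identity", "wavelet")


def transform_to_domain(
    f: Union[Slice2D, np.ndarray], domain: str, levels: int = DEFAULT_LEVELS
) -> np.ndarray:
    """Map a slice into one of the sparsity domains used by the metrics:
    per-pixel isotropic gradient magnitude (TV), the slice itself
    (identity), or the packed wavelet coefficient array (wavelet)."""
    if domain == "TV":
        return grad2d(f).magnitude()
    if domain == "identity":
        return _as_array(f)
    if domain == "wavelet":
        return wavelet_forward(f, levels=levels).array
    raise InvalidParameterError(f"unknown domain {domain!r}; expected one of {_DOMAINS}")


def compressibility_ratio(
    f: Union[Slice2D, np.ndarray],
    n_percent: float,
    domain: str = "identity",
    levels: int = DEFAULT_LEVELS,
) -> float:
    """n%-compressibility ratio of a slice in a transform domain.

    The proportion of transform-domain entries whose magnitude exceeds
    n% of the largest-magnitude entry.  Lies in (0, 1]; smaller means more
    compressible.  Invariant under global rescaling of ``f`` (the threshold
    is relative).  An all-zero input has no largest entry and is rejected.
    """
    if not (0 < n_percent < 100):
        raise InvalidParameterError("n_percent must be in (0, 100)")
    t = np.abs(transform_to_domain(f, domain, levels))
    peak = t.max()
    if peak == 0:
        raise DegenerateInputError("compressibility ratio undefined for an all-zero input")
    return float(np.count_nonzero(t > (n_percent / 100.0) * peak) / t.size)
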