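"""Reference reconstructions: weighted (filtered) backprojection and SIRT.

Both baselines reuse the geometry module's matched projector pair, so the
backprojection step of WBP is exactly the adjoint Rᵀ (the classical
pixel-driven, linearly interpolating backprojector) and SIRT iterates the
normalized residual update on the same discrete system the CS-ET solver
sees.  Both are linear in the measured sinogram.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .exceptions import InvalidParameterError
from .geometry import Sinogram, Slice2D, radon_operator

__all__ = ["wbp_reconstruct", "sirt_reconstruct", "ramp_filter_rows"]

_FILTERS = ("ram-lak", "hamming", "none")


def ramp_filter_rows(data: np.ndarray, window: str = "ram-lak") -> np.ndarray:
    """Frequency-domain ramp filtering of each projection row.

    Rows are zero-padded to the next power of two (at least twice the row
    length) to suppress interperiod interference; the filter is the standard
    ramp ``2·|freq|`` (unit response at the Nyquist frequency), optionally
    apodized by a Hamming window.
    """
    tau, sigma = data.shape
    n = max(64, 1 << int(np.ceil(np.log2(2 * sigma))))
    freq = np.fft.rfftfreq(n)
    filt = 2.0 * np.abs(freq)
    if window == "hamming":
        filt *= 0.54 + 0.46 * np.cos(np.pi * freq / freq.max())
    elif window != "ram-lak":
        raise InvalidParameterError(f"unknown filter window {window!r}")
    spec = np.fft.rfft(data, n=n, axis=1) * filt
    return np.fft.irfft(spec, n=n, axis=1)[:, :sigma]


def wbp_reconstruct(
    y: Sinogram,
    shape: Optional[Tuple[int, int]] = None,
    filter: str = "ram-lak",
) -> Slice2D:
    """Weighted backprojection of one sinogram.

    Each projection row is ramp-filtered in the frequency domain and the
    filtered sinogram backprojected with linear interpolation, scaled by
    π/(2·τ).  ``filter='none'`` skips the filtering and yields plain
    (blurred) backprojection.
    """
    if filter not in _FILTERS:
        raise InvalidParameterError(f"filter must be one of {_FILTERS}")
    if y.data.size == 0:
        raise InvalidParameterError("empty sinogram")
    if shape is None:
        shape = (y.n_bins, y.n_bins)
    if shape[0] != y.n_bins:
        raise InvalidParameterError("slice shape inconsistent with detector bin count")
    data = y.data if filter == "none" else ramp_filter_rows(y.data, filter)
    op = radon_operator(shape, y.angles)
    bp = op.adjoint(data.ravel()).reshape(shape)
    return Slice2D(bp * (np.pi / (2.0 * y.n_tilts)))


def sirt_reconstruct(
    y: Sinogram,
    shape: Optional[Tuple[int, int]] = None,
    iters: int = 30,
    relax: float = 1.0,
) -> Slice2D:
    """Simultaneous iterative reconstruction technique.

    Iterates ``f ← f + relax·C·Rᵀ·Rw·(y − R f)`` from f = 0, where ``Rw``
    and ``C`` are the inverse row-sum and column-sum normalizations of the
    projector (zero sums are replaced by zero weights rather than raising).
    Deterministic; linear in ``y`` for a fixed iteration count.
    """
    if iters < 1:
        raise InvalidParameterError("iters must be >= 1")
    if not (0 < relax <= 2):
        raise InvalidParameterError("relaxation factor must be in (0, 2]")
    if shape is None:
        shape = (y.n_bins, y.n_bins)
    if shape[0] != y.n_bins:
        raise InvalidParameterError("slice shape inconsistent with detector bin count")
    op = radon_operator(shape, y.angles)
    ones_img = np.ones(shape[0] * shape[1])
    row_sums = op.forward(ones_img)
    col_sums = op.adjoint(np.ones(op.n_tilts * op.n_bins))
    with np.errstate(divide="ignore"):
        rw = np.where(row_sums > 0, 1.0 / np.where(row_sums > 0, row_sums, 1.0), 0.0)
        c = np.where(col_sums > 0, 1.0 / np.where(col_sums > 0, col_sums, 1.0), 0.0)
    yflat = y.data.ravel()
    f = np.zeros(shape[0] * shape[1])
    for _ in range(iters):
        f = f + relax * c * op.adjoint(rw * (yflat - op.forward(f)))
    return Slice2D(f.reshape(shape))
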