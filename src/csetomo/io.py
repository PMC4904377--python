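"""File formats, run configuration and test-fixture generation.

Volumes and tilt stacks are stored as MRC2014 (the ET community standard;
mode 2 / float32, written and parsed directly from the fixed 1024-byte
header layout) or as TIFF stacks via :mod:`tifffile`.  Tilt angles travel in
a side-car plain-text file, one angle in degrees per line, ascending (the
IMOD ``.rawtlt`` dialect).  Axis convention on disk: the MRC fast axis is x,
rows are y and sections are z for volumes; for tilt stacks each section is
one projection image (rows = y, columns = detector bins).
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import tifffile
import yaml

from .exceptions import ConsistencyError, FormatError, InvalidParameterError
from .geometry import AngleSet, Scheme, Sinogram, Slice2D, Volume3D, make_uniform_angles
from .phantoms import (
    MembranePhantomSpec,
    make_membrane_phantom,
    make_nanoparticle_phantom,
    project_volume,
)

__all__ = [
    "read_volume",
    "write_volume",
    "read_angles",
    "write_angles",
    "read_tilt_series",
    "write_tilt_series",
    "RunConfig",
    "Fixture",
    "make_fixture",
]

_MRC_HEADER_BYTES = 1024
_MRC_MODE_FLOAT32 = 2


def _write_mrc(path: Path, data: np.ndarray, pixel_size: float) -> None:
    """Write a (nz_sections, ny_rows, nx_cols) float32 array as MRC2014."""
    data = np.ascontiguousarray(data, dtype=np.float32)
    nz, ny, nx = data.shape
    header = bytearray(_MRC_HEADER_BYTES)
    struct.pack_into("<10i", header, 0, nx, ny, nz, _MRC_MODE_FLOAT32, 0, 0, 0, nx, ny, nz)
    struct.pack_into(
        "<6f", header, 40,
        nx * pixel_size, ny * pixel_size, nz * pixel_size, 90.0, 90.0, 90.0,
    )
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<2i", header, 88, 0, 0)  # ispg, nsymbt
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    struct.pack_into("<i", header, 220, 0)  # nlabl
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def _read_mrc(path: Path) -> Tuple[np.ndarray, float]:
    """Read an MRC2014 file, returning ((nz, ny, nx) float32 array, pixel size)."""
    raw = Path(path).read_bytes()
    if len(raw) < _MRC_HEADER_BYTES:
        raise FormatError(f"{path}: file shorter than the 1024-byte MRC header")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    if min(nx, ny, nz) <= 0:
        raise FormatError(f"{path}: invalid dimensions ({nx}, {ny}, {nz}) in header")
    if mode != _MRC_MODE_FLOAT32:
        raise FormatError(f"{path}: unsupported MRC mode {mode} (only mode 2 / float32)")
    if raw[208:212] not in (b"MAP ", b"MAP\x00"):
        raise FormatError(f"{path}: missing MAP magic in header field at byte 208")
    (nsymbt,) = struct.unpack_from("<i", raw, 92)
    cella_x = struct.unpack_from("<f", raw, 40)[0]
    pixel = cella_x / nx if cella_x > 0 else 1.0
    offset = _MRC_HEADER_BYTES + max(nsymbt, 0)
    need = offset + 4 * nx * ny * nz
    if len(raw) < need:
        raise FormatError(
            f"{path}: truncated payload ({len(raw)} bytes, header promises {need})"
        )
    data = np.frombuffer(raw, dtype="<f4", count=nx * ny * nz, offset=offset)
    return data.reshape(nz, ny, nx).copy(), float(pixel)


def write_volume(v: Volume3D, path: Union[str, Path]) -> None:
    """Write a volume as MRC2014 (.mrc/.rec/.st) or a TIFF stack (.tif/.tiff);
    the float32 payload round-trips bitwise."""
    path = Path(path)
    sections = v.voxels.transpose(2, 1, 0).astype(np.float32)  # (z, y, x), x fastest
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, sections)
    else:
        _write_mrc(path, sections, v.voxel_size)


def read_volume(path: Union[str, Path]) -> Volume3D:
    """Read an MRC2014 or TIFF-stack volume into (x, y, z) axis order."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        pixel = 1.0
    else:
        arr, pixel = _read_mrc(path)
    return Volume3D(arr.transpose(2, 1, 0).astype(float), pixel)


def write_angles(a: AngleSet, path: Union[str, Path]) -> None:
    """Write a `.rawtlt`-style angle file: one angle in degrees per line."""
    Path(path).write_text("".join(f"{ang:.4f}\n" for ang in a.angles_deg))


def read_angles(path: Union[str, Path], scheme: Scheme = Scheme.UNIFORM) -> AngleSet:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    try:
        vals = np.array([float(ln) for ln in lines])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric tilt angle line: {exc}") from exc
    return AngleSet(vals, scheme)


def write_tilt_series(sinograms: Sequence[Sinogram], path_mrc: Union[str, Path],
                      path_angles: Union[str, Path]) -> None:
    """Write per-y-slice sinograms as an MRC/TIFF projection stack plus a
    side-car angle file.  Section i of the stack is the projection image at
    tilt i: rows are y slices, columns detector bins."""
    if not sinograms:
        raise InvalidParameterError("no sinograms to write")
    a = sinograms[0].angles
    stack = np.stack([s.data for s in sinograms], axis=1)  # (tau, ny, sigma)
    path_mrc = Path(path_mrc)
    if path_mrc.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path_mrc, stack.astype(np.float32))
    else:
        _write_mrc(path_mrc, stack.astype(np.float32), 1.0)
    write_angles(a, path_angles)


def read_tilt_series(
    path_mrc: Union[str, Path], path_angles: Union[str, Path]
) -> Tuple[List[Sinogram], AngleSet]:
    """Read a projection stack + angle file back into per-y-slice sinograms."""
    path_mrc = Path(path_mrc)
    if path_mrc.suffix.lower() in (".tif", ".tiff"):
        stack = np.asarray(tifffile.imread(path_mrc), dtype=float)
    else:
        stack = _read_mrc(path_mrc)[0].astype(float)
    angles = read_angles(path_angles)
    if stack.ndim != 3:
        raise FormatError(f"{path_mrc}: expected a 3-D projection stack")
    if stack.shape[0] != len(angles):
        raise ConsistencyError(
            f"stack has {stack.shape[0]} projections but angle file lists {len(angles)}"
        )
    ny = stack.shape[1]
    return [Sinogram(stack[:, j, :], angles) for j in range(ny)], angles


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONFIG_DEFAULTS: Dict[str, Dict[str, object]] = {
    "phantom": {
        "kind": "membrane",
        "dims": [256, 100, 256],
        "background": 0.15,
        "n_shells": 40,
        "n_filled": 60,
        "n_discs": 8,
        "n_crescents": 4,
    },
    "geometry": {"max_tilt": 70.0, "increment": 2.0, "undersample": 1, "scheme": "uniform"},
    "noise": {
        "mode": "none",
        "poisson_rate": 5500.0,
        "gaussian_frac": 0.10,
        "target_frac": 0.10,
        "background_level": 0.0,
    },
    "weights": {"preset": "", "nu": 1.0, "lambda_tv": 0.0, "lambda_i": 0.0, "lambda_w": 0.0},
    "solver": {
        "method": "cset",
        "outer_iters": 10,
        "inner_iters": 12,
        "cg_iters": 10,
        "cg_tol": 1e-6,
        "tv_mode": "isotropic",
        "wavelet_levels": 4,
        "nonnegativity": False,
        "workers": 1,
        "filter": "ram-lak",
        "sirt_iters": 30,
        "relax": 1.0,
    },
    "evaluation": {"n_percent": 5.0, "domain": "identity", "n_trials": 10},
    "output": {"volume": "", "tilts": "", "angles": "", "metrics": ""},
}


@dataclass
class RunConfig:
    """Structured settings mirroring every CLI flag; round-trips through
    YAML losslessly and rejects unknown keys."""

    seed: int = 0
    sections: Dict[str, Dict[str, object]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {k: dict(v) for k, v in _CONFIG_DEFAULTS.items()}
        for sec, vals in self.sections.items():
            if sec not in merged:
                raise InvalidParameterError(f"unknown config section {sec!r}")
            for key, val in vals.items():
                if key not in merged[sec]:
                    raise InvalidParameterError(f"unknown config key {sec}.{key}")
                merged[sec][key] = val
        self.sections = merged

    def __getitem__(self, section: str) -> Dict[str, object]:
        return self.sections[section]

    def to_yaml(self, path: Union[str, Path]) -> None:
        doc = {"seed": self.seed, **self.sections}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise FormatError(f"{path}: config must be a YAML mapping")
        seed = int(doc.pop("seed", 0))
        return cls(seed=seed, sections=doc)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@dataclass
class Fixture:
    """A small deterministic phantom + tilt series for regression tests."""

    kind: str
    phantom: Union[Volume3D, Slice2D]
    sinograms: List[Sinogram]
    angles: AngleSet
    metrics: Dict[str, float]
    checksum: str


def make_fixture(kind: str, seed: int = 0) -> Fixture:
    """Deterministic tiny fixtures: a 32×8×32 membrane volume or a 32×32
    nanoparticle slice, each with a ±70°/10° tilt series and summary metrics
    (means and a payload checksum) for golden-value regression tests."""
    angles = make_uniform_angles(70, 10)
    if kind == "tiny-membrane":
        spec = MembranePhantomSpec(
            dims=(32, 8, 32),
            n_shells=4,
            n_filled=6,
            semiaxis_range=(2.0, 9.0),
            shell_thickness_range=(1.0, 2.0),
            seed=seed,
        )
        vol = make_membrane_phantom(spec)
        sinos = project_volume(vol, angles)
        payload = vol.voxels
        phantom: Union[Volume3D, Slice2D] = vol
    elif kind == "tiny-nanoparticle":
        sl = make_nanoparticle_phantom((32, 32), 2, 1, seed=seed, radius_range=(3.0, 7.0))
        from .geometry import radon_forward

        sinos = [radon_forward(sl, angles)]
        payload = sl.pixels
        phantom = sl
    else:
        raise InvalidParameterError(f"unknown fixture kind {kind!r}")
    stack = np.stack([s.data for s in sinos])
    checksum = hashlib.sha256(
        payload.astype(np.float32).tobytes() + stack.astype(np.float32).tobytes()
    ).hexdigest()
    metrics = {
        "phantom_mean": float(payload.mean()),
        "phantom_max": float(payload.max()),
        "sino_mean": float(stack.mean()),
        "sino_max": float(stack.max()),
    }
    return Fixture(kind, phantom, sinos, angles, metrics, checksum)
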