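"""Cryo-EM volume I/O and reciprocal-space preprocessing.

Covers the map-side preparation the validator needs: MRC/CCP4 reading and
writing (via gemmi), resolution truncation in reciprocal space (default
2.5 Å), B-factor blurring/sharpening (Fourier amplitudes scaled by
exp(-B s^2 / 4); positive B blurs, negative sharpens), and sampling of a
local-resolution volume near fragment atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

DEFAULT_DMIN = 2.5
DEFAULT_RESMAP_RADIUS = 2.0


class MapFormatError(ValueError):
    """Malformed or unsupported volume file."""


@dataclass
class MapVolume:
    """A density volume on a regular grid filling its unit cell.

    ``grid`` is indexed [ix, iy, iz] in canonical X, Y, Z axis order;
    ``origin`` is the grid start (nxstart, nystart, nzstart) in voxels.
    """

    grid: np.ndarray
    cell: tuple[float, float, float, float, float, float]
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        # float64 internally: B-factor sharpening amplifies high-frequency
        # quantization noise, so single precision would break exact inverses
        self.grid = np.ascontiguousarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise MapFormatError(f"grid must be 3D with dims >= 2, got {self.grid.shape}")
        if not np.all(np.isfinite(self.grid)):
            raise MapFormatError("grid contains non-finite values")
        if min(self.cell[:3]) <= 0:
            raise MapFormatError("cell lengths must be positive")

    @property
    def unit_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.cell)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        a, b, c = self.cell[:3]
        nx, ny, nz = self.grid.shape
        return (a / nx, b / ny, c / nz)

    def voxel_centers(self) -> np.ndarray:
        """Cartesian coordinates (Å) of every voxel center, shape grid.shape + (3,)."""
        frac = self._frac_axes()
        fx, fy, fz = np.meshgrid(*frac, indexing="ij")
        orth = np.array(self.unit_cell.orth.mat.tolist())
        fr = np.stack([fx, fy, fz], axis=-1)
        return fr @ orth.T

    def _frac_axes(self) -> list[np.ndarray]:
        return [
            (np.arange(n) + o) / n
            for n, o in zip(self.grid.shape, self.origin)
        ]

    def position_of(self, index: tuple[int, int, int]) -> np.ndarray:
        orth = np.array(self.unit_cell.orth.mat.tolist())
        frac = np.array([(i + o) / n for i, o, n
                         in zip(index, self.origin, self.grid.shape)])
        return orth @ frac

    def interpolate(self, positions: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of density at Cartesian positions (Å)."""
        g = gemmi.FloatGrid(self.grid.astype(np.float32))
        g.set_unit_cell(self.unit_cell)
        positions = np.atleast_2d(positions)
        shift = np.array([o / n for o, n in zip(self.origin, self.grid.shape)])
        frac_m = np.array(self.unit_cell.frac.mat.tolist())
        out = np.empty(len(positions))
        for i, pos in enumerate(positions):
            fr = frac_m @ pos - shift
            out[i] = g.interpolate_value(gemmi.Fractional(*fr))
        return out


#: Local-resolution volumes share the grid layout; voxel values are Å.
#: Values <= 0 or non-finite mark voxels where resolution is undefined.
LocalResolutionMap = MapVolume


def read_map(path: str | Path) -> MapVolume:
    """Read an MRC/CCP4 volume; axis order is canonicalized to X, Y, Z.

    The permutation is undone directly from the MAPC/MAPR/MAPS header so
    the grid start (NXSTART...) is preserved rather than wrapped away —
    the volume keeps the absolute coordinate frame it was written in.
    """
    path = Path(path)
    if not path.exists():
        raise MapFormatError(f"map file not found: {path}")
    try:
        ccp4 = gemmi.read_ccp4_map(str(path), setup=False)
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read {path}: {exc}") from exc
    grid = np.array(ccp4.grid, copy=True)
    axis_map = [ccp4.header_i32(w) - 1 for w in (17, 18, 19)]  # file dim -> axis
    if sorted(axis_map) != [0, 1, 2]:
        raise MapFormatError(f"{path}: invalid axis order {axis_map}")
    start_file = [int(ccp4.header_i32(w)) for w in (5, 6, 7)]
    # transpose so dimension i of the array is crystal axis i
    order = [axis_map.index(axis) for axis in range(3)]
    grid = np.ascontiguousarray(np.transpose(grid, order))
    origin = tuple(start_file[order[axis]] for axis in range(3))
    cell = ccp4.grid.unit_cell
    return MapVolume(
        grid=grid,
        cell=(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
        origin=origin,
    )


def write_map(volume: MapVolume, path: str | Path) -> None:
    """Write an MRC/CCP4 2014 volume; read_map round-trips values bit-exactly."""
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(volume.grid.astype(np.float32))
    ccp4.grid.unit_cell = volume.unit_cell
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header()
    for word, value in zip((5, 6, 7), volume.origin):
        ccp4.set_header_i32(word, value)
    ccp4.write_ccp4_map(str(path))


def _s2_grid(volume: MapVolume) -> np.ndarray:
    """|s|^2 = 1/d^2 for every rfftn coefficient of the volume's grid.

    Frequency indices are Miller indices of the cell; |s|^2 = h^T (F F^T) h
    with F the fractionalization matrix, valid for any cell geometry.
    """
    nx, ny, nz = volume.grid.shape
    h = np.fft.fftfreq(nx) * nx
    k = np.fft.fftfreq(ny) * ny
    l = np.fft.rfftfreq(nz) * nz
    frac = np.array(volume.unit_cell.frac.mat.tolist())
    gstar = frac @ frac.T
    hh, kk, ll = np.meshgrid(h, k, l, indexing="ij")
    return (gstar[0, 0] * hh * hh + gstar[1, 1] * kk * kk + gstar[2, 2] * ll * ll
            + 2 * (gstar[0, 1] * hh * kk + gstar[0, 2] * hh * ll + gstar[1, 2] * kk * ll))


def truncate_resolution(volume: MapVolume, d_min: float = DEFAULT_DMIN) -> MapVolume:
    """Zero all Fourier coefficients at resolution better than ``d_min`` (Å).

    A no-op on frequencies the grid cannot represent; idempotent on maps
    already band-limited to ``d_min`` or worse.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    coeffs = np.fft.rfftn(volume.grid.astype(np.float64))
    s2 = _s2_grid(volume)
    coeffs[s2 > 1.0 / d_min ** 2] = 0.0
    out = np.fft.irfftn(coeffs, s=volume.grid.shape, axes=(0, 1, 2))
    return replace(volume, grid=out)


def apply_bfactor(volume: MapVolume, b_factor: float) -> MapVolume:
    """Scale Fourier coefficients by exp(-B s^2 / 4).

    Positive B blurs, negative B sharpens, 0 is the identity;
    blur(+B) followed by sharpen(-B) restores a band-limited map.
    """
    if not np.isfinite(b_factor):
        raise ValueError("B-factor must be finite")
    if b_factor == 0:
        return replace(volume, grid=volume.grid.copy())
    coeffs = np.fft.rfftn(volume.grid.astype(np.float64))
    coeffs *= np.exp(-b_factor * _s2_grid(volume) / 4.0)
    out = np.fft.irfftn(coeffs, s=volume.grid.shape, axes=(0, 1, 2))
    return replace(volume, grid=out)


def shell_power(volume: MapVolume, d_min: float) -> tuple[float, float]:
    """Fourier power (sum |F|^2) below and above resolution ``d_min``.

    Diagnostic companion to :func:`truncate_resolution`.
    """
    coeffs = np.fft.rfftn(volume.grid.astype(np.float64))
    s2 = _s2_grid(volume)
    power = np.abs(coeffs) ** 2
    # rfftn stores only half the coefficients; weight the implicit conjugates
    weight = np.full(power.shape, 2.0)
    weight[..., 0] = 1.0
    if volume.grid.shape[2] % 2 == 0:
        weight[..., -1] = 1.0
    inside = s2 > 1.0 / d_min ** 2
    return float((power * weight)[inside].sum()), float((power * weight)[~inside].sum())


def mean_local_resolution(atom_positions: np.ndarray,
                          resmap: LocalResolutionMap,
                          radius: float = DEFAULT_RESMAP_RADIUS) -> float | None:
    """Mean local resolution (Å) over voxels within ``radius`` of any atom.

    Voxel membership is decided by voxel centers; voxels with non-positive
    or non-finite values are treated as undefined.  Returns ``None`` when
    no defined voxel lies in range, in which case the fragment proceeds
    without resolution-based reporting.
    """
    atoms = np.atleast_2d(np.asarray(atom_positions, dtype=np.float64))
    if atoms.size == 0:
        return None
    centers = resmap.voxel_centers().reshape(-1, 3)
    values = resmap.grid.reshape(-1).astype(np.float64)
    lo = atoms.min(axis=0) - radius
    hi = atoms.max(axis=0) + radius
    boxed = np.all((centers >= lo) & (centers <= hi), axis=1)
    if not np.any(boxed):
        return None
    centers, values = centers[boxed], values[boxed]
    tree = cKDTree(atoms)
    dist, _ = tree.query(centers, distance_upper_bound=radius)
    near = np.isfinite(dist)
    defined = near & np.isfinite(values) & (values > 0)
    if not np.any(defined):
        return None
    return float(values[defined].mean())
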