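"""Quasi-static forward SAR model for a voxel phantom in a transmit coil.

A deterministic, desk-scale stand-in for full-wave electromagnetic
simulation.  The transmit coil is abstracted as a finite-length circularly
polarized B1 field directed along the coil Z-axis; by Faraday's law the
induced electric field of a uniform rotating B1 grows linearly with the
perpendicular distance ``d`` from the coil axis,

    E(r) = (omega * B1 / 2) * d(r) * w(z),

where ``w(z)`` is an axial field profile: 1 inside the coil windings
(|z - z_c| <= L/2), a smooth cos^2 taper of length ``L_t`` beyond each end,
and 0 outside.  B1 and E are peak amplitudes, so the local specific
absorption rate in tissue with conductivity ``sigma`` and density ``rho`` is

    SAR = sigma * E^2 / (2 * rho)       [W/kg].

This preserves the physical dependencies the surrogate study needs -- tissue
conductivity and density, Z-shift through the axial profile, and body tilt
through off-axis geometry -- while each evaluation runs in milliseconds.
Absolute SAR values are not comparable to full-wave solver output.

Dosimetric outputs:

* ``wb_sar`` / ``hd_sar`` -- SAR mass-averaged over the whole body / the head,
* ``psar10g`` -- peak SAR averaged over a contiguous 10 g tissue mass, using
  centred cubes grown in odd voxel-side steps with linear fractional
  weighting of the outermost shell so the enclosed mass equals the target
  exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal

import numpy as np

from .phantoms import (
    TissuePropertyTable,
    VoxelPhantom,
    validate_phantom_labels,
)

__all__ = [
    "CoilField",
    "Pose",
    "SARResult",
    "pose_transform",
    "sar_field",
    "wb_sar",
    "hd_sar",
    "psar10g",
    "normalize_sar",
    "compute_sar_result",
]

#: Pipeline-level pose bounds: |z shift| <= 10 cm, |tilt| <= 5 degrees.
Z_SHIFT_LIMIT_M = 0.10
TILT_LIMIT_DEG = 5.0

TiltAxis = Literal["long", "pitch"]


@dataclass(frozen=True)
class CoilField:
    """Abstract transmit-coil field configuration.

    Parameters
    ----------
    frequency
        Larmor frequency in Hz (64 MHz at 1.5 T).
    b1
        Peak amplitude of the rotating B1 field, tesla.
    length
        Axial length of the uniform-field region (the coil windings), m.
    taper_length
        Length of the cos^2 fringe-field taper beyond each coil end, m.
    z_centre
        Coil centre along the coil Z-axis, m.
    table_offset
        Vertical offset of the body's long axis below the coil axis
        (patient table position), m.
    tilt_axis
        "long": tilt is a roll about the body's own long axis (default);
        "pitch": rotation about a transverse axis through the alignment
        plane.
    """

    frequency: float = 64e6
    b1: float = 1e-6
    length: float = 0.04
    taper_length: float = 0.18
    z_centre: float = 0.0
    table_offset: float = 0.05
    tilt_axis: TiltAxis = "long"

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.b1 <= 0 or self.length <= 0:
            raise ValueError("frequency, b1 and length must be positive")
        if self.taper_length < 0:
            raise ValueError("taper length must be >= 0")
        if self.tilt_axis not in ("long", "pitch"):
            raise ValueError("tilt_axis must be 'long' or 'pitch'")

    @property
    def omega(self) -> float:
        return 2.0 * math.pi * self.frequency

    def axial_profile(self, z: np.ndarray) -> np.ndarray:
        """w(z): 1 inside the coil, cos^2 taper over L_t, 0 beyond."""
        dz = np.abs(np.asarray(z, dtype=np.float64) - self.z_centre)
        half = self.length / 2.0
        w = np.zeros_like(dz)
        w[dz <= half] = 1.0
        if self.taper_length > 0:
            in_taper = (dz > half) & (dz <= half + self.taper_length)
            w[in_taper] = np.cos(
                math.pi * (dz[in_taper] - half) / (2.0 * self.taper_length)
            ) ** 2
        return w


@dataclass(frozen=True)
class Pose:
    """Body pose perturbation: Z-axis shift (m) and tilt (degrees)."""

    z_shift: float = 0.0
    tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.z_shift) and math.isfinite(self.tilt_deg)):
            raise ValueError("pose parameters must be finite")

    @property
    def within_limits(self) -> bool:
        return (
            abs(self.z_shift) <= Z_SHIFT_LIMIT_M
            and abs(self.tilt_deg) <= TILT_LIMIT_DEG
        )


@dataclass(frozen=True)
class SARResult:
    """Scalar SAR metrics for one phantom/pose evaluation."""

    wbsar: float
    hdsar: float
    psar10g: float
    psar10g_location: tuple[int, int, int]
    normalization: Literal["raw_B1", "absorbed_power_1W"]
    pose: tuple[float, float] = (0.0, 0.0)

    def to_json(self) -> str:
        d = asdict(self)
        d["units"] = "W/kg"
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SARResult":
        d = json.loads(text)
        d.pop("units", None)
        d["psar10g_location"] = tuple(d["psar10g_location"])
        d["pose"] = tuple(d.get("pose", (0.0, 0.0)))
        return cls(**d)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


# ---------------------------------------------------------------------------
# Pose transform
# ---------------------------------------------------------------------------


def pose_transform(
    phantom: VoxelPhantom,
    pose: Pose,
    table_offset: float = 0.05,
    tilt_axis: TiltAxis = "long",
    z_centre: float = 0.0,
) -> np.ndarray:
    """Coil-frame centre positions (n_voxel, 3: x, y, z) of all voxels.

    Standard placement (zero pose): the body's long axis is parallel to the
    coil Z-axis and offset below it by ``table_offset`` in y; the phantom's
    alignment plane (central heart level) sits at the coil centre.  The
    pose then rolls the body by ``tilt_deg`` about its own long axis
    (or pitches it about the transverse axis through the alignment plane
    when ``tilt_axis == "pitch"``) and shifts it by ``z_shift`` along Z.

    The rigid transform is applied to voxel centres only; labels are never
    interpolated, so tissue masses are exactly preserved.
    """
    centres = phantom.voxel_centres()  # body frame, grid-axis order
    la = phantom.long_axis
    trans_axes = [a for a in range(3) if a != la]
    zb = centres[:, la] - phantom.alignment_z
    # body's own long axis passes through the transverse grid centre
    x = centres[:, trans_axes[0]]
    y = centres[:, trans_axes[1]]
    for coord, axis in ((x, trans_axes[0]), (y, trans_axes[1])):
        mid = phantom.origin[axis] + phantom.shape[axis] * phantom.voxel_size / 2.0
        coord -= mid

    theta = math.radians(pose.tilt_deg)
    c, s = math.cos(theta), math.sin(theta)
    if tilt_axis == "long":
        x, y = x * c - y * s, x * s + y * c
    else:  # pitch about the transverse x-axis through the alignment plane
        y, zb = y * c - zb * s, y * s + zb * c

    out = np.empty_like(centres)
    out[:, 0] = x
    out[:, 1] = y - table_offset
    out[:, 2] = zb + z_centre + pose.z_shift
    return out


# ---------------------------------------------------------------------------
# SAR field
# ---------------------------------------------------------------------------


def _induced_e2(
    phantom: VoxelPhantom, coil: CoilField, pose: Pose
) -> np.ndarray:
    """E^2 grid, exploiting the separability of the rigid pose transform.

    Equivalent to evaluating ``(omega B1 / 2)^2 d^2 w(z)^2`` at the
    :func:`pose_transform` positions, but built from per-axis coordinate
    vectors with broadcasting (the roll mixes only the two transverse
    axes; the pitch mixes one transverse axis with the long axis).
    """
    la = phantom.long_axis
    trans = [a for a in range(3) if a != la]
    h = phantom.voxel_size

    def axis_coords(axis: int) -> np.ndarray:
        return phantom.origin[axis] + (np.arange(phantom.shape[axis]) + 0.5) * h

    x0 = axis_coords(trans[0])
    x0 -= phantom.origin[trans[0]] + phantom.shape[trans[0]] * h / 2.0
    y0 = axis_coords(trans[1])
    y0 -= phantom.origin[trans[1]] + phantom.shape[trans[1]] * h / 2.0
    zb = axis_coords(la) - phantom.alignment_z

    theta = math.radians(pose.tilt_deg)
    c, s = math.cos(theta), math.sin(theta)
    amp2 = (coil.omega * coil.b1 / 2.0) ** 2
    if coil.tilt_axis == "long":
        x_rot = x0[:, None] * c - y0[None, :] * s
        y_rot = x0[:, None] * s + y0[None, :] * c - coil.table_offset
        d2 = x_rot**2 + y_rot**2  # (n_t0, n_t1)
        w = coil.axial_profile(zb + coil.z_centre + pose.z_shift)  # (n_la,)
        e2 = amp2 * d2[:, :, None] * w[None, None, :] ** 2
    else:  # pitch mixes the second transverse axis with the long axis
        y_rot = y0[:, None] * c - zb[None, :] * s - coil.table_offset
        z_rot = y0[:, None] * s + zb[None, :] * c
        w = coil.axial_profile(z_rot + coil.z_centre + pose.z_shift)
        d2w2 = (x0**2)[:, None, None] * (w**2)[None, :, :] + (
            y_rot**2 * w**2
        )[None, :, :]
        e2 = amp2 * d2w2
    # axes currently ordered (t0, t1, la); restore the grid order
    return np.moveaxis(e2, (0, 1, 2), (trans[0], trans[1], la))


def sar_field(
    phantom: VoxelPhantom,
    props: TissuePropertyTable,
    coil: CoilField,
    pose: Pose = Pose(),
) -> np.ndarray:
    """Per-voxel SAR grid (W/kg) for one pose.

    E = (omega*B1/2) * d * w(z) with d the perpendicular distance from the
    coil axis; SAR = sigma E^2 / (2 rho) at tissue voxels, 0 at background.
    """
    validate_phantom_labels(phantom, props)
    max_label = int(phantom.labels.max())
    sigma = props.lookup_arrays("sigma_S_per_m", max_label)[phantom.labels]
    rho = props.lookup_arrays("rho_kg_per_m3", max_label)[phantom.labels]
    tissue = phantom.tissue_mask
    if (rho[tissue] <= 0).any():
        raise ValueError("zero density at a tissue voxel")

    e2 = _induced_e2(phantom, coil, pose)
    sar = np.zeros(phantom.shape, dtype=np.float64)
    sar[tissue] = sigma[tissue] * e2[tissue] / (2.0 * rho[tissue])
    return sar


# ---------------------------------------------------------------------------
# Mass-averaged metrics
# ---------------------------------------------------------------------------


def _voxel_masses(phantom: VoxelPhantom, props: TissuePropertyTable) -> np.ndarray:
    rho = props.lookup_arrays("rho_kg_per_m3", int(phantom.labels.max()))
    return rho[phantom.labels] * phantom.voxel_volume


def _mass_weighted_mean(
    sar: np.ndarray, mass: np.ndarray, mask: np.ndarray
) -> float:
    total = mass[mask].sum()
    if total <= 0:
        raise ValueError("empty averaging mask")
    return float((sar[mask] * mass[mask]).sum() / total)


def wb_sar(
    sar: np.ndarray, phantom: VoxelPhantom, props: TissuePropertyTable
) -> float:
    """Whole-body SAR: mass-weighted mean over all tissue voxels."""
    return _mass_weighted_mean(sar, _voxel_masses(phantom, props), phantom.tissue_mask)


def hd_sar(
    sar: np.ndarray, phantom: VoxelPhantom, props: TissuePropertyTable
) -> float:
    """Head SAR: mass-weighted mean over the head-mask voxels."""
    return _mass_weighted_mean(sar, _voxel_masses(phantom, props), phantom.head_mask)


# ---------------------------------------------------------------------------
# Peak spatial SAR over a 10 g cube
# ---------------------------------------------------------------------------


def _integral_image(vol: np.ndarray) -> np.ndarray:
    """Zero-padded 3-D summed-volume table."""
    return np.pad(
        vol.cumsum(0).cumsum(1).cumsum(2), ((1, 0), (1, 0), (1, 0))
    )


def _cube_sums(integral: np.ndarray, k: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Sums over (2k+1)^3 cubes centred at every interior voxel.

    Returned array has shape ``(n0-2k, n1-2k, n2-2k)``, index (i,j,l)
    corresponding to the cube centred at voxel (i+k, j+k, l+k).
    """
    n0, n1, n2 = shape
    hi0, lo0 = slice(2 * k + 1, n0 + 1), slice(0, n0 - 2 * k)
    hi1, lo1 = slice(2 * k + 1, n1 + 1), slice(0, n1 - 2 * k)
    hi2, lo2 = slice(2 * k + 1, n2 + 1), slice(0, n2 - 2 * k)
    I = integral
    return (
        I[hi0, hi1, hi2]
        - I[lo0, hi1, hi2]
        - I[hi0, lo1, hi2]
        - I[hi0, hi1, lo2]
        + I[lo0, lo1, hi2]
        + I[lo0, hi1, lo2]
        + I[hi0, lo1, lo2]
        - I[lo0, lo1, lo2]
    )


def psar10g(
    sar: np.ndarray,
    phantom: VoxelPhantom,
    props: TissuePropertyTable,
    target_mass: float = 0.010,
) -> tuple[float, tuple[int, int, int]]:
    """Peak SAR averaged over a contiguous ``target_mass`` of tissue.

    For every tissue voxel a cube centred on it is grown in odd
    voxel-side steps (1, 3, 5, ...) until the enclosed tissue mass reaches
    ``target_mass``; the outermost shell contributes fractionally, linearly
    weighted so the enclosed mass equals the target exactly:

        avg = (P_inner + f * (P_outer - P_inner)) / target_mass,
        f   = (target_mass - M_inner) / (M_outer - M_inner).

    Background voxels carry zero mass and zero power.  Voxels whose cube
    would extend past the grid boundary before reaching the target mass are
    invalid and excluded.  Returns the maximum average and its (0-based)
    centre voxel index; ties resolve to the lexicographically smallest
    index (first in C order).
    """
    if target_mass <= 0:
        raise ValueError("target mass must be positive")
    shape = phantom.shape
    mass = _voxel_masses(phantom, props)
    power = sar * mass
    Im = _integral_image(mass)
    Ip = _integral_image(power)

    tissue = phantom.tissue_mask
    val = np.full(shape, np.nan)
    done = ~tissue
    kmax = (min(shape) - 1) // 2

    # no cube smaller than ceil(target/max_cell_mass) cells can reach the
    # target, so the growth loop may start at that size
    max_cell = float(mass.max())
    if max_cell <= 0:
        raise ValueError("no tissue voxel can enclose the target mass")
    min_cells = target_mass / max_cell
    k0 = max(0, math.ceil((min_cells ** (1.0 / 3.0) - 1.0) / 2.0))
    k0 = min(k0, kmax)
    if k0 > 0:
        m_prev = np.full(shape, np.nan)
        p_prev = np.full(shape, np.nan)
        sl = tuple(slice(k0 - 1, n - (k0 - 1)) for n in shape)
        m_prev[sl] = _cube_sums(Im, k0 - 1, shape)
        p_prev[sl] = _cube_sums(Ip, k0 - 1, shape)
    else:
        m_prev = np.zeros(shape)
        p_prev = np.zeros(shape)
    for k in range(k0, kmax + 1):
        interior = np.zeros(shape, dtype=bool)
        interior[k : shape[0] - k, k : shape[1] - k, k : shape[2] - k] = True
        # voxels still pending but whose cube of this size exits the grid
        # can never reach the target: exclude them
        done |= ~interior
        m_k = np.full(shape, np.nan)
        p_k = np.full(shape, np.nan)
        m_k[interior] = _cube_sums(Im, k, shape).ravel()
        p_k[interior] = _cube_sums(Ip, k, shape).ravel()
        with np.errstate(invalid="ignore"):
            new = (m_k >= target_mass) & ~done
        if new.any():
            frac = (target_mass - m_prev[new]) / (m_k[new] - m_prev[new])
            val[new] = (p_prev[new] + frac * (p_k[new] - p_prev[new])) / target_mass
            done[new] = True
        if done.all():
            break
        m_prev, p_prev = m_k, p_k

    if np.isnan(val).all():
        raise ValueError("no tissue voxel can enclose the target mass")
    peak = float(np.nanmax(val))
    loc = np.unravel_index(int(np.nanargmax(val)), shape)
    return peak, (int(loc[0]), int(loc[1]), int(loc[2]))


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_sar(
    sar: np.ndarray,
    phantom: VoxelPhantom,
    props: TissuePropertyTable,
    mode: Literal["raw_B1", "absorbed_power_1W"] = "raw_B1",
) -> np.ndarray:
    """Rescale a SAR grid to a normalization convention.

    ``raw_B1`` is the identity (SAR at the configured B1 amplitude);
    ``absorbed_power_1W`` scales so the total absorbed power
    ``sum_i SAR_i m_i`` equals 1 W, an absorbed-power approximation of
    net-incident-power normalization.
    """
    if mode == "raw_B1":
        return sar
    if mode != "absorbed_power_1W":
        raise ValueError(f"unknown normalization mode {mode!r}")
    total = float((sar * _voxel_masses(phantom, props)).sum())
    if total <= 0:
        raise ValueError("zero total absorbed power; cannot normalize")
    return sar / total


def compute_sar_result(
    phantom: VoxelPhantom,
    props: TissuePropertyTable,
    coil: CoilField,
    pose: Pose = Pose(),
    normalization: Literal["raw_B1", "absorbed_power_1W"] = "raw_B1",
    target_mass: float = 0.010,
) -> SARResult:
    """One forward evaluation: SAR field plus all scalar metrics."""
    sar = sar_field(phantom, props, coil, pose)
    sar = normalize_sar(sar, phantom, props, normalization)
    peak, loc = psar10g(sar, phantom, props, target_mass)
    return SARResult(
        wbsar=wb_sar(sar, phantom, props),
        hdsar=hd_sar(sar, phantom, props),
        psar10g=peak,
        psar10g_location=loc,
        normalization=normalization,
        pose=(pose.z_shift, pose.tilt_deg),
    )
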