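"""CEST Z-spectrum processing: normalisation, B0 correction, MTRasym / APTw.

The processing chain per voxel is:

1. average repeated frames at each saturation offset and divide by the
   unsaturated reference frame S0 -> Z-spectrum ``Z(w) = Ssat(w)/S0``;
2. estimate the per-voxel static-field offset B0 from the phase difference of
   a dual-echo gradient-echo pair;
3. shift the Z-spectrum by the B0 offset (cubic-spline interpolation on the
   measured curve);
4. evaluate the magnetization-transfer-ratio asymmetry at the amide offset,
   ``MTRasym(3.5 ppm) = Z(-3.5) - Z(+3.5)``, reported in percent as the
   APTw value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .offsets import OffsetScheme
from .phantom import WATER_LARMOR_MHZ_3T, wrap_phase

__all__ = [
    "ZSpectrum",
    "B0Map",
    "normalize_and_average",
    "normalize_stack",
    "compute_b0_map",
    "correct_b0",
    "mtr_asym",
    "compute_aptw_map",
]

#: offsets beyond this magnitude belong to the sparse far wing and are not
#: used when interpolating the exchange-sensitive region
DENSE_REGION_PPM = 6.0


@dataclass
class ZSpectrum:
    """One voxel's normalised Z-spectrum on sorted unique offsets."""

    offsets_ppm: np.ndarray
    z: np.ndarray
    s0: float

    def __post_init__(self) -> None:
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.offsets_ppm.shape != self.z.shape:
            raise ValueError("offsets and z must have the same shape")
        if np.any(np.diff(self.offsets_ppm) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if self.s0 <= 0:
            raise ValueError("reference signal s0 must be positive")

    def value_at(self, offset_ppm: float) -> float:
        """Z at a sampled offset (exact match within 1e-9), else NaN."""
        i = np.argmin(np.abs(self.offsets_ppm - offset_ppm))
        if abs(self.offsets_ppm[i] - offset_ppm) > 1e-9:
            return float("nan")
        return float(self.z[i])


@dataclass
class B0Map:
    """Per-voxel static-field offset in ppm with acquisition metadata."""

    b0_ppm: np.ndarray
    te_delta_ms: float
    larmor_mhz: float


def normalize_and_average(frames: np.ndarray, scheme: OffsetScheme) -> ZSpectrum:
    """Turn one voxel's raw frame vector into a normalised Z-spectrum.

    Repeated offsets are arithmetically averaged *before* division by the
    reference frame, so the result is invariant to a common scale factor on
    all frames.

    Raises
    ------
    ValueError
        If the frame count does not match the scheme, or s0 <= 0.
    """
    frames = np.asarray(frames, dtype=float)
    frame_offsets = scheme.frame_offsets()
    if frames.shape != (len(frame_offsets),):
        raise ValueError(
            f"expected {len(frame_offsets)} frames for this scheme, got {frames.shape}"
        )
    s0_vals = [frames[i] for i, w in enumerate(frame_offsets) if w is None]
    if not s0_vals:
        raise ValueError("scheme has no reference frame; cannot normalise")
    s0 = float(np.mean(s0_vals))
    if s0 <= 0:
        raise ValueError("non-positive reference signal; voxel must be masked out")
    sums: dict[float, list[float]] = {}
    for i, w in enumerate(frame_offsets):
        if w is None:
            continue
        sums.setdefault(w, []).append(frames[i])
    offsets = np.array(sorted(sums), dtype=float)
    z = np.array([np.mean(sums[w]) for w in offsets]) / s0
    return ZSpectrum(offsets_ppm=offsets, z=z, s0=s0)


def normalize_stack(stack: np.ndarray, scheme: OffsetScheme):
    """Vectorised :func:`normalize_and_average` over an image stack.

    Parameters
    ----------
    stack:
        Array of shape ``spatial + (n_frames,)``.

    Returns
    -------
    offsets, z, s0, valid:
        ``offsets`` sorted unique offsets; ``z`` of shape
        ``spatial + (n_offsets,)``; ``s0`` map; ``valid`` boolean map marking
        voxels with a positive reference signal (others hold NaN spectra).
    """
    stack = np.asarray(stack, dtype=float)
    frame_offsets = scheme.frame_offsets()
    if stack.shape[-1] != len(frame_offsets):
        raise ValueError("stack frame count does not match the offset scheme")
    ref_idx = [i for i, w in enumerate(frame_offsets) if w is None]
    if not ref_idx:
        raise ValueError("scheme has no reference frame")
    s0 = stack[..., ref_idx].mean(axis=-1)
    valid = s0 > 0
    groups: dict[float, list[int]] = {}
    for i, w in enumerate(frame_offsets):
        if w is not None:
            groups.setdefault(w, []).append(i)
    offsets = np.array(sorted(groups), dtype=float)
    z = np.empty(stack.shape[:-1] + (offsets.size,), dtype=float)
    for k, w in enumerate(offsets):
        z[..., k] = stack[..., groups[w]].mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = z / s0[..., None]
    z[~valid] = np.nan
    return offsets, z, s0, valid


def compute_b0_map(
    phase_early: np.ndarray,
    phase_late: np.ndarray,
    te_delta_ms: float = 4.92,
    larmor_mhz: float = WATER_LARMOR_MHZ_3T,
) -> B0Map:
    """B0 field map from a dual-echo GRE phase pair.

    The phase difference (wrapped into (-pi, pi]) divided by the echo-time
    difference gives the off-resonance frequency, converted to ppm by the
    scanner Larmor frequency:

    ``df[Hz] = wrap(phi_late - phi_early) / (2*pi*dTE)``,
    ``B0[ppm] = df / larmor_mhz``.

    No phase unwrapping is attempted; fields beyond ``1/(2*dTE)`` Hz alias.
    """
    if te_delta_ms <= 0:
        raise ValueError("te_delta_ms must be positive")
    pe = np.asarray(phase_early, dtype=float)
    pl = np.asarray(phase_late, dtype=float)
    if pe.shape != pl.shape:
        raise ValueError("phase images must have the same shape")
    dphi = wrap_phase(pl - pe)
    df_hz = dphi / (2.0 * np.pi * te_delta_ms * 1e-3)
    return B0Map(b0_ppm=df_hz / larmor_mhz, te_delta_ms=te_delta_ms, larmor_mhz=larmor_mhz)


def _dense_spline(zspec: ZSpectrum) -> tuple[CubicSpline, float, float]:
    sel = np.abs(zspec.offsets_ppm) <= DENSE_REGION_PPM
    x = zspec.offsets_ppm[sel]
    y = zspec.z[sel]
    if x.size < 4:
        raise ValueError("too few offsets within the dense region for spline interpolation")
    return CubicSpline(x, y, extrapolate=False), float(x[0]), float(x[-1])


def correct_b0(zspec: ZSpectrum, b0_ppm: float) -> ZSpectrum:
    """Shift a Z-spectrum to undo a per-voxel B0 offset.

    A field offset ``b0`` displaces the recorded spectrum so the feature that
    belongs at nominal offset ``w`` was recorded at ``w + b0``.  The corrected
    value at ``w`` is therefore the measured curve interpolated at ``w + b0``
    (cubic spline on the densely sampled |w| <= 6 ppm region).  Offsets whose
    shifted position falls outside the sampled dense range become NaN —
    extrapolation is never performed.  Offsets in the sparse far wing
    (|w| > 6 ppm) are passed through unchanged; a sub-ppm shift is negligible
    against their tens-of-ppm spacing.
    """
    if b0_ppm == 0.0:
        return ZSpectrum(zspec.offsets_ppm.copy(), zspec.z.copy(), zspec.s0)
    spline, lo, hi = _dense_spline(zspec)
    z_new = zspec.z.copy()
    dense = np.abs(zspec.offsets_ppm) <= DENSE_REGION_PPM
    target = zspec.offsets_ppm[dense] + b0_ppm
    vals = spline(target)  # NaN outside [lo, hi] (extrapolate=False)
    z_new[dense] = vals
    return ZSpectrum(zspec.offsets_ppm.copy(), z_new, zspec.s0)


def mtr_asym(zspec: ZSpectrum, offset_ppm: float = 3.5) -> float:
    """MTRasym at the given offset: ``Z(-w) - Z(+w)``, as a fraction.

    Uses the sampled values when ``+/-w`` are sampled offsets; otherwise both
    sides are spline-interpolated on the dense region.  Returns NaN when
    either side is unavailable.
    """
    z_neg = zspec.value_at(-offset_ppm)
    z_pos = zspec.value_at(+offset_ppm)
    if np.isnan(z_neg) or np.isnan(z_pos):
        spline, lo, hi = _dense_spline(zspec)
        if -offset_ppm < lo or offset_ppm > hi:
            return float("nan")
        z_neg, z_pos = float(spline(-offset_ppm)), float(spline(offset_ppm))
    return z_neg - z_pos


def compute_aptw_map(
    stack: np.ndarray,
    scheme: OffsetScheme,
    b0_map: B0Map | np.ndarray | None = None,
    mask: np.ndarray | None = None,
    offset_ppm: float = 3.5,
) -> np.ndarray:
    """B0-corrected APTw map in percent from a raw CEST frame stack.

    Voxels outside ``mask``, with non-positive reference signal, or whose
    shifted evaluation offsets leave the sampled range, are NaN.  Values are
    clipped to [-100, 100] percent.
    """
    offsets, z, s0, valid = normalize_stack(stack, scheme)
    spatial = stack.shape[:-1]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    b0 = np.zeros(spatial)
    if b0_map is not None:
        b0 = np.broadcast_to(
            b0_map.b0_ppm if isinstance(b0_map, B0Map) else np.asarray(b0_map), spatial
        )
    aptw = np.full(spatial, np.nan)
    for idx in np.ndindex(spatial):
        if not (mask[idx] and valid[idx]):
            continue
        zs = ZSpectrum(offsets, z[idx], float(s0[idx]))
        if b0[idx] != 0.0:
            zs = correct_b0(zs, float(b0[idx]))
        aptw[idx] = 100.0 * mtr_asym(zs, offset_ppm)
    return np.clip(aptw, -100.0, 100.0)
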