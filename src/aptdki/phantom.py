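"""Synthetic CEST / field-map / diffusion phantoms with known ground truth.

Every downstream stage of the pipeline (Z-spectrum normalisation, B0
correction, MTRasym, kurtosis fitting, ROI statistics) is exercised against
stacks generated here, where the true APTw, B0, S0, MD and MK of every voxel
are known.

The saturation physics is deliberately simple: the steady-state Z-spectrum is
modelled as one minus a sum of Lorentzian lines, one per proton pool.  This
replaces a Bloch–McConnell simulation of the pulsed saturation module — the
analysis layer only ever sees Z-spectra, and Lorentzian pools give an exact,
controllable ground-truth MTRasym (the water line is symmetric about 0 ppm,
so the asymmetry at +/-3.5 ppm is governed entirely by the solute pools).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .offsets import OffsetScheme

__all__ = [
    "LorentzianPool",
    "PhantomTruth",
    "GrePhasePair",
    "WATER_LARMOR_MHZ_3T",
    "zspectrum_model",
    "true_mtr_asym",
    "simulate_zspectrum",
    "simulate_cest_stack",
    "simulate_gre_phase_pair",
    "simulate_dwi_stack",
    "build_lesion_scene",
]

#: water Larmor frequency at a nominal 3.0 T (gamma = 42.58 MHz/T)
WATER_LARMOR_MHZ_3T = 127.74


@dataclass(frozen=True)
class LorentzianPool:
    """One saturable proton pool as a Lorentzian line in the Z-spectrum.

    Parameters
    ----------
    center_ppm:
        Chemical shift of the pool relative to water (amide sits at +3.5 ppm).
    amplitude:
        Peak saturation depth at the line centre, dimensionless in [0, 1].
    fwhm_ppm:
        Full width at half maximum of the line, ppm.
    """

    center_ppm: float
    amplitude: float
    fwhm_ppm: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError(f"pool amplitude must be in [0, 1], got {self.amplitude}")
        if self.fwhm_ppm <= 0:
            raise ValueError(f"pool FWHM must be positive, got {self.fwhm_ppm}")

    def __call__(self, offset_ppm):
        """Saturation depth of this pool at the given offset(s)."""
        hw2 = (self.fwhm_ppm / 2.0) ** 2
        x = np.asarray(offset_ppm, dtype=float) - self.center_ppm
        return self.amplitude * hw2 / (hw2 + x * x)


# Pools used by the default phantom: a broad water/background line (symmetric
# about 0 ppm, hence invisible to MTRasym) plus an amide line at +3.5 ppm whose
# amplitude sets the true APTw.
DEFAULT_WATER_POOL = LorentzianPool(center_ppm=0.0, amplitude=0.85, fwhm_ppm=2.6)


def zspectrum_model(pools: list[LorentzianPool], offsets_ppm, b0_shift_ppm: float = 0.0):
    """Noiseless Z(offset) = 1 - sum of Lorentzian lines, shifted by B0.

    A B0 offset of ``b0_shift_ppm`` moves the whole spectrum: the signal
    recorded at nominal offset ``w`` is the true spectrum at ``w - b0``.
    """
    offsets = np.asarray(offsets_ppm, dtype=float)
    z = np.ones_like(offsets)
    for pool in pools:
        z = z - pool(offsets - b0_shift_ppm)
    return z


def true_mtr_asym(pools: list[LorentzianPool], offset_ppm: float = 3.5) -> float:
    """Analytic MTRasym of the pool model at B0 = 0: Z(-w) - Z(+w)."""
    zm = zspectrum_model(pools, [-offset_ppm, offset_ppm])
    return float(zm[0] - zm[1])


def _check_pools(pools: list[LorentzianPool], offsets: np.ndarray, b0: float) -> None:
    if not pools:
        return
    depth = np.zeros_like(offsets, dtype=float)
    for pool in pools:
        depth = depth + pool(offsets - b0)
    if np.any(depth > 1.0 + 1e-12):
        worst = float(offsets[np.argmax(depth)])
        raise ValueError(
            f"pool saturation depths sum to {depth.max():.3f} > 1 at offset "
            f"{worst} ppm; the Z-spectrum would go negative"
        )


def simulate_zspectrum(
    pools: list[LorentzianPool],
    scheme: OffsetScheme,
    b0_shift_ppm: float = 0.0,
    noise_sd: float = 0.0,
    s0: float = 1000.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one voxel's raw frame signals for an offset scheme.

    Returns the per-frame signal vector in acquisition order (reference frame
    first when present), scaled by ``s0``.  Repeated offsets receive
    independent noise draws; noise is additive Gaussian with standard
    deviation ``noise_sd`` expressed as a fraction of ``s0``.

    Raises
    ------
    ValueError
        If the pools' saturation depths sum above 1 at any sampled offset.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if scheme.n_frames == 0:
        raise ValueError("empty offset scheme")
    frame_offsets = scheme.frame_offsets()
    sat = np.array([w for w in frame_offsets if w is not None], dtype=float)
    _check_pools(pools, sat, b0_shift_ppm)

    signals = np.empty(len(frame_offsets), dtype=float)
    for i, w in enumerate(frame_offsets):
        if w is None:  # unsaturated reference
            signals[i] = s0
        else:
            signals[i] = s0 * zspectrum_model(pools, [w], b0_shift_ppm)[0]
    if noise_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        signals = signals + rng.normal(0.0, noise_sd * s0, size=signals.shape)
    return signals


def simulate_cest_stack(
    amide_amplitude: np.ndarray,
    b0_map_ppm: np.ndarray,
    scheme: OffsetScheme,
    water_pool: LorentzianPool = DEFAULT_WATER_POOL,
    amide_center_ppm: float = 3.5,
    amide_fwhm_ppm: float = 1.4,
    noise_sd: float = 0.0,
    s0: float = 1000.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a full CEST frame stack over an image of amide amplitudes.

    Parameters
    ----------
    amide_amplitude:
        Per-voxel peak depth of the amide line; this is (very nearly) the
        per-voxel true APTw as a fraction.
    b0_map_ppm:
        Per-voxel static-field offset; shifts each voxel's spectrum.

    Returns
    -------
    stack, true_aptw_pct:
        ``stack`` has shape ``amide_amplitude.shape + (scheme.n_frames,)``;
        ``true_aptw_pct`` is the analytic MTRasym(3.5 ppm) in percent at
        B0 = 0 (what a perfect B0-corrected analysis should recover).
    """
    amp = np.asarray(amide_amplitude, dtype=float)
    b0 = np.broadcast_to(np.asarray(b0_map_ppm, dtype=float), amp.shape)
    frame_offsets = scheme.frame_offsets()
    stack = np.empty(amp.shape + (len(frame_offsets),), dtype=float)
    truth = np.empty(amp.shape, dtype=float)
    it = np.ndindex(amp.shape)
    for idx in it:
        pools = [water_pool]
        if amp[idx] > 0:
            pools.append(LorentzianPool(amide_center_ppm, float(amp[idx]), amide_fwhm_ppm))
        stack[idx] = simulate_zspectrum(
            pools, scheme, b0_shift_ppm=float(b0[idx]), noise_sd=noise_sd, s0=s0, rng=rng
        )
        truth[idx] = 100.0 * true_mtr_asym(pools)
    return stack, truth


@dataclass
class GrePhasePair:
    """Dual-echo gradient-echo phase images plus wrap bookkeeping."""

    phase_early: np.ndarray  # radians
    phase_late: np.ndarray   # radians
    te_delta_ms: float
    larmor_mhz: float
    #: voxels whose true off-resonance exceeds the unambiguous range
    #: |f| >= 1/(2*dTE); phase unwrapping is out of scope, so these are flagged
    wrapped: np.ndarray = field(default=None)  # type: ignore[assignment]


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase into (-pi, pi]."""
    w = np.mod(np.asarray(phi, dtype=float) + np.pi, 2.0 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


def simulate_gre_phase_pair(
    b0_map_ppm: np.ndarray,
    te_delta_ms: float = 4.92,
    larmor_mhz: float = WATER_LARMOR_MHZ_3T,
    te1_ms: float = 2.46,
    base_phase: np.ndarray | float = 0.0,
) -> GrePhasePair:
    """Dual-echo GRE phase images consistent with a B0 field map.

    The off-resonance frequency ``f = b0_ppm * larmor_mhz`` (Hz) accrues phase
    ``2*pi*f*TE`` at each echo; both echoes share an arbitrary receiver phase
    ``base_phase``, and each recorded phase is wrapped into (-pi, pi].  The
    phase *difference* wraps once |f| reaches ``1/(2*dTE)``; such voxels are
    flagged in ``wrapped`` rather than unwrapped.
    """
    if te_delta_ms <= 0:
        raise ValueError("te_delta_ms must be positive")
    b0 = np.asarray(b0_map_ppm, dtype=float)
    f_hz = b0 * larmor_mhz
    te1 = te1_ms * 1e-3
    te2 = (te1_ms + te_delta_ms) * 1e-3
    phase_early = wrap_phase(base_phase + 2.0 * np.pi * f_hz * te1)
    phase_late = wrap_phase(base_phase + 2.0 * np.pi * f_hz * te2)
    wrap_limit_hz = 1.0 / (2.0 * te_delta_ms * 1e-3)
    wrapped = np.abs(f_hz) >= wrap_limit_hz
    return GrePhasePair(phase_early, phase_late, te_delta_ms, larmor_mhz, wrapped)


@dataclass
class PhantomTruth:
    """Ground-truth maps for a diffusion/CEST phantom scene.

    Units follow the reporting conventions of the pipeline: APTw in percent,
    B0 in ppm, MD in 1e-3 mm^2/s, MK dimensionless.
    """

    aptw_pct: np.ndarray | None = None
    b0_ppm: np.ndarray | None = None
    s0: np.ndarray | None = None
    md_e3: np.ndarray | None = None
    mk: np.ndarray | None = None
    noise_model: str = "none"
    noise_sigma: float = 0.0


def simulate_dwi_stack(
    truth: PhantomTruth,
    b_values,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate a trace-weighted DWI stack from the kurtosis signal model.

    The noiseless signal is ``S(b) = S0 * exp(-b*MD + b^2*MD^2*MK/6)`` with MD
    in mm^2/s (``truth.md_e3`` is converted from its 1e-3 units).  Rician
    noise of standard deviation ``noise_sigma`` (signal units) is applied as
    the magnitude of a complex Gaussian perturbation.

    Returns an array of shape ``truth.s0.shape + (len(b_values),)``.
    """
    b = np.asarray(b_values, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    if 0.0 not in b:
        raise ValueError("b-values must include b = 0")
    s0 = np.asarray(truth.s0, dtype=float)
    md = np.asarray(truth.md_e3, dtype=float) * 1e-3
    mk = np.asarray(truth.mk, dtype=float)
    expo = -np.multiply.outer(md, b) + np.multiply.outer(md**2 * mk, b**2) / 6.0
    signal = s0[..., None] * np.exp(expo)
    if noise_sigma > 0:
        rng = np.random.default_rng() if rng is None else rng
        re = signal + rng.normal(0.0, noise_sigma, signal.shape)
        im = rng.normal(0.0, noise_sigma, signal.shape)
        signal = np.hypot(re, im)
    return signal


def build_lesion_scene(
    shape: tuple[int, int] = (48, 48),
    lesions: list[dict] | None = None,
    background: dict | None = None,
    b0_amplitude_ppm: float = 0.3,
    seed: int | None = None,
) -> tuple[PhantomTruth, dict[str, np.ndarray]]:
    """Lay out circular lesions on a background and return truth maps + masks.

    Each lesion dict gives ``center`` (row, col), ``radius`` (pixels) and the
    tissue parameters ``aptw_pct``, ``md_e3``, ``mk``.  The B0 field is a
    smooth in-plane gradient scaled to ``b0_amplitude_ppm`` — the spatial
    low-order shim error this pipeline's correction step is meant to absorb.

    Returns the truth container and a dict of boolean lesion masks keyed by
    lesion name.
    """
    if background is None:
        background = {"aptw_pct": 1.0, "md_e3": 1.6, "mk": 0.6, "s0": 1000.0}
    if lesions is None:
        lesions = [
            {"name": "lesion1", "center": (16, 16), "radius": 6,
             "aptw_pct": 3.7, "md_e3": 0.989, "mk": 1.065},
            {"name": "lesion2", "center": (32, 32), "radius": 6,
             "aptw_pct": 2.4, "md_e3": 1.193, "mk": 0.909},
        ]
    rows, cols = np.indices(shape)
    aptw = np.full(shape, float(background["aptw_pct"]))
    md = np.full(shape, float(background["md_e3"]))
    mk = np.full(shape, float(background["mk"]))
    s0 = np.full(shape, float(background.get("s0", 1000.0)))
    masks: dict[str, np.ndarray] = {}
    for i, lesion in enumerate(lesions):
        cy, cx = lesion["center"]
        m = (rows - cy) ** 2 + (cols - cx) ** 2 <= lesion["radius"] ** 2
        aptw[m] = lesion["aptw_pct"]
        md[m] = lesion["md_e3"]
        mk[m] = lesion["mk"]
        masks[lesion.get("name", f"lesion{i + 1}")] = m
    # smooth diagonal field gradient, zero at the image centre
    ramp = (rows / (shape[0] - 1) + cols / (shape[1] - 1)) - 1.0
    b0 = b0_amplitude_ppm * ramp
    truth = PhantomTruth(aptw_pct=aptw, b0_ppm=b0, s0=s0, md_e3=md, mk=mk)
    return truth, masks
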