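"""Voxelwise diffusion-kurtosis model fitting over a multi-b-value series.

Signal model (trace-weighted, direction-averaged):

    S(b) = S0 * exp(-b*MD + b^2 * MD^2 * MK / 6)

with MD the mean diffusivity (mm^2/s) and MK the dimensionless mean kurtosis.
Estimation is two-stage: an ordinary least-squares fit of ln S on (1, -b, b^2)
gives a closed-form initialiser (the model is log-polynomial), which a
bound-constrained signal-domain least-squares refinement then polishes.  The
refinement matters under Rician noise, where the log-domain fit is biased by
the noise floor at high b.

Fitted maps are reported in the conventional units: MD in 1e-3 mm^2/s, MK
dimensionless, clipped to physiological bounds (clipping is flagged, never
silent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DEFAULT_B_VALUES",
    "DkiFit",
    "dki_forward",
    "fit_dki_loglinear",
    "fit_dki_nlls",
    "fit_dki_map",
    "MD_BOUNDS_E3",
    "MK_BOUNDS",
]

#: acquisition b-values (s/mm^2) used by the default protocol
DEFAULT_B_VALUES = (0.0, 500.0, 1000.0, 1500.0, 2000.0)

#: physiological clamp for MD in 1e-3 mm^2/s (free water ~3.0 at body temp)
MD_BOUNDS_E3 = (1e-5, 3.5)
#: physiological clamp for MK
MK_BOUNDS = (0.0, 3.0)


@dataclass
class DkiFit:
    """One voxel's kurtosis-model fit.

    ``md`` is stored in 1e-3 mm^2/s (reporting units); ``mk`` is
    dimensionless.  ``clipped`` records whether any parameter hit its bound,
    ``converged`` whether the estimator finished cleanly.
    """

    s0: float
    md: float
    mk: float
    residual: float
    converged: bool = True
    clipped: bool = False
    method: str = "loglinear"


def dki_forward(s0: float, md: float, mk: float, b) -> np.ndarray:
    """Noiseless kurtosis-model signal at b (s/mm^2); ``md`` in mm^2/s."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    return s0 * np.exp(-b * md + b**2 * md**2 * mk / 6.0)


def _clip_params(md_e3: float, mk: float) -> tuple[float, float, bool]:
    md_c = min(max(md_e3, MD_BOUNDS_E3[0]), MD_BOUNDS_E3[1])
    mk_c = min(max(mk, MK_BOUNDS[0]), MK_BOUNDS[1])
    # flag only clips beyond numerical noise
    clipped = abs(md_c - md_e3) > 1e-9 or abs(mk_c - mk) > 1e-9
    return md_c, mk_c, clipped


def fit_dki_loglinear(b_values, signals) -> DkiFit:
    """Closed-form log-domain fit: OLS of ln S on (1, -b, b^2).

    MD is the coefficient of ``-b``; MK is recovered as ``6*c2/MD^2`` from the
    quadratic coefficient.  Estimates are clipped into the physiological box
    with a flag.  Requires strictly positive signals and at least four
    distinct b-values.
    """
    b = np.asarray(b_values, dtype=float)
    s = np.asarray(signals, dtype=float)
    if b.shape != s.shape:
        raise ValueError("b_values and signals must align")
    if np.unique(b).size < 4:
        raise ValueError("need at least 4 distinct b-values for a 3-parameter fit")
    if np.any(s <= 0):
        raise ValueError("non-positive signal; voxel must be masked out")
    X = np.column_stack([np.ones_like(b), -b, b**2])
    coef, *_ = np.linalg.lstsq(X, np.log(s), rcond=None)
    c0, c1, c2 = coef
    s0 = float(np.exp(c0))
    md = float(c1)  # mm^2/s
    if md <= 0:
        md_e3, mk = MD_BOUNDS_E3[0], 0.0
        clipped = True
    else:
        mk = float(6.0 * c2 / md**2)
        md_e3, mk, clipped = _clip_params(md * 1e3, mk)
    pred = dki_forward(s0, md_e3 * 1e-3, mk, b)
    resid = float(np.linalg.norm(s - pred))
    return DkiFit(s0=s0, md=md_e3, mk=mk, residual=resid,
                  converged=True, clipped=clipped, method="loglinear")


def fit_dki_nlls(b_values, signals, init: DkiFit) -> DkiFit:
    """Bound-constrained signal-domain refinement of a log-linear fit.

    Minimises the signal-domain residual with MD and MK confined to the
    physiological box; returns whichever of {init, refined} has the lower
    residual, so the result never degrades the initialiser.  Deterministic
    given its inputs.
    """
    b = np.asarray(b_values, dtype=float)
    s = np.asarray(signals, dtype=float)

    def resid(theta):
        s0, md_e3, mk = theta
        return dki_forward(s0, md_e3 * 1e-3, mk, b) - s

    x0 = np.array([
        max(init.s0, 1e-12),
        min(max(init.md, MD_BOUNDS_E3[0]), MD_BOUNDS_E3[1]),
        min(max(init.mk, MK_BOUNDS[0]), MK_BOUNDS[1]),
    ])
    lower = [0.0, MD_BOUNDS_E3[0], MK_BOUNDS[0]]
    upper = [np.inf, MD_BOUNDS_E3[1], MK_BOUNDS[1]]
    try:
        sol = least_squares(resid, x0, bounds=(lower, upper), method="trf", xtol=1e-12)
    except Exception:
        out = DkiFit(**{**init.__dict__})
        out.converged = False
        return out
    refined_resid = float(np.linalg.norm(sol.fun))
    if not sol.success or refined_resid > init.residual:
        out = DkiFit(**{**init.__dict__})
        out.converged = bool(sol.success)
        return out
    s0, md_e3, mk = (float(v) for v in sol.x)
    at_bound = (
        np.isclose(md_e3, MD_BOUNDS_E3, atol=1e-9).any()
        or np.isclose(mk, MK_BOUNDS, atol=1e-9).any()
    )
    return DkiFit(s0=s0, md=md_e3, mk=mk, residual=refined_resid,
                  converged=True, clipped=bool(at_bound) or init.clipped, method="nlls")


def fit_dki_map(
    stack: np.ndarray,
    mask: np.ndarray,
    b_values=DEFAULT_B_VALUES,
    refine: bool = True,
):
    """Fit the kurtosis model voxelwise inside a mask.

    Parameters
    ----------
    stack:
        DWI array of shape ``spatial + (n_b,)``.
    mask:
        Boolean array over the spatial dimensions; empty masks are rejected.
    refine:
        Run the signal-domain refinement after the log-linear initialiser.

    Returns
    -------
    md, mk, s0, qc:
        Maps in reporting units (MD in 1e-3 mm^2/s); NaN outside the mask and
        at excluded voxels.  ``qc`` codes 0 = clean fit, 1 = clipped or
        non-converged, 2 = excluded (non-positive signal).
    """
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if stack.shape[:-1] != mask.shape:
        raise ValueError("stack and mask shapes disagree")
    if not mask.any():
        raise ValueError("empty mask")
    b = np.asarray(b_values, dtype=float)
    md = np.full(mask.shape, np.nan)
    mk = np.full(mask.shape, np.nan)
    s0 = np.full(mask.shape, np.nan)
    qc = np.zeros(mask.shape, dtype=np.int8)
    for idx in np.ndindex(mask.shape):
        if not mask[idx]:
            continue
        sig = stack[idx]
        if np.any(sig <= 0):
            qc[idx] = 2
            continue
        fit = fit_dki_loglinear(b, sig)
        if refine:
            fit = fit_dki_nlls(b, sig, fit)
        md[idx], mk[idx], s0[idx] = fit.md, fit.mk, fit.s0
        qc[idx] = 1 if (fit.clipped or not fit.converged) else 0
    return md, mk, s0, qc
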