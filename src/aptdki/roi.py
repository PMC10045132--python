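"""Per-lesion ROI statistics and interobserver agreement.

Two readers each delineate one ROI per lesion on the parameter maps; the
per-reader ROI means are averaged for the final per-patient value, and
agreement between readers is quantified with the two-way random-effects,
absolute-agreement, single-measure intraclass correlation ICC(2,1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

__all__ = ["RoiMeasurement", "IccResult", "roi_mean", "average_readers", "icc_two_way"]


@dataclass(frozen=True)
class RoiMeasurement:
    """Mean of one parameter map over one reader's ROI."""

    patient_id: str
    reader_id: str
    parameter: str
    value: float
    n_voxels: int
    n_nan: int = 0


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_lower: float
    ci_upper: float
    band: str  # low | medium | high


def roi_mean(
    param_map: np.ndarray,
    mask: np.ndarray,
    patient_id: str = "",
    reader_id: str = "",
    parameter: str = "",
) -> RoiMeasurement:
    """Arithmetic mean of a map over a boolean ROI mask.

    NaN voxels (e.g. masked out during map computation) are dropped from the
    mean and reported in ``n_nan``; an all-NaN ROI is an error naming the
    patient and parameter so the failure is traceable.
    """
    param_map = np.asarray(param_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if param_map.shape != mask.shape:
        raise ValueError("map and mask shapes disagree")
    if not mask.any():
        raise ValueError("empty ROI mask")
    vals = param_map[mask]
    good = np.isfinite(vals)
    if not good.any():
        raise ValueError(
            f"ROI contains no finite voxels (patient={patient_id!r}, "
            f"parameter={parameter!r})"
        )
    return RoiMeasurement(
        patient_id=patient_id,
        reader_id=reader_id,
        parameter=parameter,
        value=float(vals[good].mean()),
        n_voxels=int(good.sum()),
        n_nan=int((~good).sum()),
    )


def average_readers(measurements: list[RoiMeasurement] | list[float]) -> float:
    """Reader-averaged final value for one patient/parameter.

    Exactly two reader measurements are required.
    """
    if len(measurements) != 2:
        raise ValueError(f"expected exactly 2 reader measurements, got {len(measurements)}")
    vals = [m.value if isinstance(m, RoiMeasurement) else float(m) for m in measurements]
    return float(np.mean(vals))


def _band(icc: float) -> str:
    if icc < 0.40:
        return "low"
    if icc <= 0.75:
        return "medium"
    return "high"


def icc_two_way(reader1, reader2, alpha: float = 0.05) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares (subjects x raters, one
    observation per cell) with the F-distribution confidence interval of
    McGraw & Wong.  Band labels: < 0.40 low, 0.40-0.75 medium, > 0.75 high
    consistency.

    Raises
    ------
    ValueError
        If fewer than 3 paired subjects, mismatched lengths, or zero variance
        everywhere (ICC undefined).
    """
    y1 = np.asarray(reader1, dtype=float)
    y2 = np.asarray(reader2, dtype=float)
    if y1.shape != y2.shape or y1.ndim != 1:
        raise ValueError("reader vectors must be 1-D and paired")
    n = y1.size
    if n < 3:
        raise ValueError("need at least 3 subjects for an ICC")
    data = np.column_stack([y1, y2])
    k = 2
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_rater = n * np.sum((rater_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_rater
    msb = ss_subj / (n - 1)          # between-subject
    msj = ss_rater / (k - 1)         # between-rater
    mse = ss_err / ((n - 1) * (k - 1))
    if msb < 1e-15 and mse < 1e-15 and msj < 1e-15:
        raise ValueError("zero variance everywhere; ICC undefined")
    denom = msb + (k - 1) * mse + k * (msj - mse) / n
    if abs(denom) < 1e-30:
        raise ValueError("degenerate ANOVA decomposition; ICC undefined")
    icc = (msb - mse) / denom

    # McGraw & Wong F-based interval for ICC(A,1)
    if mse <= 0:
        lo, hi = icc, icc  # perfect agreement: interval collapses
    else:
        fc = msj / mse
        a = (k * icc * fc + n * (1 + (k - 1) * icc) - k * icc)
        vn = (k - 1) * (n - 1) * a**2
        vd = (n - 1) * k**2 * icc**2 * fc**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
        f2u = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f2l = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msb - f2u * mse) / (
            f2u * (k * msj + (k * n - k - n) * mse) + n * msb)
        hi = n * (f2l * msb - mse) / (
            k * msj + (k * n - k - n) * mse + n * f2l * msb)
    return IccResult(icc=float(icc), ci_lower=float(lo), ci_upper=float(hi),
                     band=_band(float(icc)))
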