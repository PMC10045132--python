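"""Synthetic patient cohorts with the study's printed group structure.

A cohort table holds one row per patient: the three reader-averaged imaging
markers (APTw %, MK, MD), demographic/clinical covariates, and the binary
nodal outcome.  The generator reproduces a configured group structure
*exactly* for categorical variables (deterministic assignment then in-group
shuffle, so cross-tabs match the configured counts, not just their
expectation) and draws the continuous markers from per-group normal
distributions, optionally correlated through a Gaussian copula.

Default configuration: 17 node-positive vs 44 node-negative patients with the
marker summaries APTw 3.7 +/- 1.1 vs 2.4 +/- 1.0 %, MK 1.065 +/- 0.185 vs
0.909 +/- 0.189, MD 0.989 +/- 0.195 vs 1.193 +/- 0.337 (1e-3 mm^2/s), and the
categorical margins of the source cohort.

Column coding (all risk levels coded 1):

================  =====================================================
column            meaning
================  =====================================================
patient_id        P001 ...
lnm               1 = lymph-node metastasis
aptw              APTw (%), reader-averaged
mk                mean kurtosis (dimensionless)
md                mean diffusivity (1e-3 mm^2/s)
age               years
tumor_size_mm     maximal tumor diameter (mm)
menopause         1 = post-menopausal
histology_ca      1 = adenocarcinoma (0 = squamous carcinoma)
figo_advanced     1 = FIGO stage IIB-IV
grade_high        1 = high histologic grade
depth_deep        1 = invasion >= 2/3 of cervical wall
scc_ag_high       1 = SCC-Ag > 1.5 ng/mL
vascular          1 = vascular invasion
================  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

__all__ = [
    "GroupMarkerStats",
    "CohortConfig",
    "default_cohort_config",
    "generate_cohort",
    "DEFAULT_EXCLUSIONS",
    "screening_flow",
    "apply_patient_flow",
]

CATEGORICAL_COLUMNS = (
    "menopause", "histology_ca", "figo_advanced", "grade_high",
    "depth_deep", "scc_ag_high", "vascular",
)

# per-group counts of the risk level (coded 1), {column: (non-LNM, LNM)}
DEFAULT_CATEGORICAL_COUNTS = {
    "menopause": (21, 10),
    "histology_ca": (8, 1),
    "figo_advanced": (13, 16),
    "grade_high": (16, 13),
    "depth_deep": (18, 16),
    "scc_ag_high": (26, 14),
    "vascular": (11, 6),
}


@dataclass(frozen=True)
class GroupMarkerStats:
    """Mean/SD summaries of the continuous variables for one outcome group."""

    aptw: tuple[float, float]
    mk: tuple[float, float]
    md: tuple[float, float]
    age: tuple[float, float] = (51.0, 12.0)
    age_range: tuple[float, float] = (28.0, 78.0)
    tumor_size_mm: tuple[float, float] = (36.0, 21.0)
    size_range: tuple[float, float] = (13.0, 105.0)


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for a synthetic cohort.

    ``categorical_counts`` maps each binary covariate to the count of its
    risk level (coded 1) per group, ``(n in non-LNM, n in LNM)``.
    ``marker_corr`` optionally correlates (aptw, mk, md) within each group via
    a Gaussian copula; ``None`` draws them independently.
    """

    n_lnm: int = 17
    n_non_lnm: int = 44
    lnm: GroupMarkerStats = field(default_factory=lambda: GroupMarkerStats(
        aptw=(3.7, 1.1), mk=(1.065, 0.185), md=(0.989, 0.195),
        age=(52.0, 12.0), age_range=(29.0, 70.0),
        tumor_size_mm=(44.0, 19.0), size_range=(13.0, 105.0),
    ))
    non_lnm: GroupMarkerStats = field(default_factory=lambda: GroupMarkerStats(
        aptw=(2.4, 1.0), mk=(0.909, 0.189), md=(1.193, 0.337),
        age=(50.0, 12.0), age_range=(28.0, 78.0),
        tumor_size_mm=(31.0, 17.0), size_range=(15.0, 72.0),
    ))
    categorical_counts: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORICAL_COUNTS))
    marker_corr: np.ndarray | None = None

    def validate(self) -> None:
        if self.n_lnm < 1 or self.n_non_lnm < 1:
            raise ValueError("group sizes must be positive")
        for col, (k_non, k_lnm) in self.categorical_counts.items():
            if not (0 <= k_non <= self.n_non_lnm and 0 <= k_lnm <= self.n_lnm):
                raise ValueError(
                    f"infeasible count for {col!r}: ({k_non}, {k_lnm}) with "
                    f"groups ({self.n_non_lnm}, {self.n_lnm})"
                )
        for grp in (self.lnm, self.non_lnm):
            for name in ("aptw", "mk", "md", "age", "tumor_size_mm"):
                if getattr(grp, name)[1] <= 0:
                    raise ValueError(f"SD for {name} must be positive")
        if self.marker_corr is not None:
            c = np.asarray(self.marker_corr, dtype=float)
            if c.shape != (3, 3) or not np.allclose(c, c.T):
                raise ValueError("marker_corr must be a symmetric 3x3 matrix")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ValueError("marker_corr must be positive semi-definite")


def default_cohort_config() -> CohortConfig:
    return CohortConfig()


def _truncated_normal(rng, mean, sd, lo, hi, n):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _draw_markers(rng, stats: GroupMarkerStats, n: int, corr: np.ndarray | None):
    means = np.array([stats.aptw[0], stats.mk[0], stats.md[0]])
    sds = np.array([stats.aptw[1], stats.mk[1], stats.md[1]])
    if corr is None:
        z = rng.standard_normal((n, 3))
    else:
        L = np.linalg.cholesky(np.asarray(corr) + 1e-12 * np.eye(3))
        z = rng.standard_normal((n, 3)) @ L.T
    return means + sds * z


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Generate a reproducible synthetic cohort table.

    Categorical columns hit their configured per-group counts exactly; the
    continuous markers are normal draws with the configured per-group
    moments; age and tumor size are truncated normals respecting the
    configured ranges.  The same seed always yields the identical table.
    """
    config = config or default_cohort_config()
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    frames = []
    for lnm_flag, n, stats in (
        (0, config.n_non_lnm, config.non_lnm),
        (1, config.n_lnm, config.lnm),
    ):
        markers = _draw_markers(rng, stats, n, config.marker_corr)
        df = pd.DataFrame({
            "lnm": lnm_flag,
            "aptw": markers[:, 0],
            "mk": markers[:, 1],
            "md": markers[:, 2],
            "age": _truncated_normal(rng, *stats.age, *stats.age_range, n),
            "tumor_size_mm": _truncated_normal(
                rng, *stats.tumor_size_mm, *stats.size_range, n),
        })
        for col in CATEGORICAL_COLUMNS:
            k = config.categorical_counts[col][lnm_flag]
            vals = np.zeros(n, dtype=int)
            vals[:k] = 1          # deterministic assignment ...
            rng.shuffle(vals)     # ... then in-group shuffle
            df[col] = vals
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "patient_id", [f"P{i + 1:03d}" for i in range(len(out))])
    return out


# ---------------------------------------------------------------------------
# patient-selection flow

#: exclusion reasons applied, in order, to the screened series
DEFAULT_EXCLUSIONS = (
    ("incomplete_histopathology", 21),
    ("non_cervical_cancer", 9),
    ("tumor_under_10mm", 10),
    ("inadequate_image_quality", 4),
)


def screening_flow(
    n_screened: int = 105,
    exclusions=DEFAULT_EXCLUSIONS,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Build the screening ledger: one row per screened patient.

    Each excluded patient carries exactly one exclusion reason (the first that
    applies, mirroring a sequential eligibility check); included patients have
    reason ``"included"``.  Row order is shuffled so the reasons are not
    positional.
    """
    total_excluded = sum(k for _, k in exclusions)
    if total_excluded > n_screened:
        raise ValueError("exclusions exceed the screened series")
    reasons = []
    for name, k in exclusions:
        reasons.extend([name] * k)
    reasons.extend(["included"] * (n_screened - total_excluded))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reasons = np.array(reasons)
    rng.shuffle(reasons)
    return pd.DataFrame({
        "screen_id": [f"S{i + 1:03d}" for i in range(n_screened)],
        "status": reasons,
    })


def apply_patient_flow(ledger: pd.DataFrame) -> pd.DataFrame:
    """Filter the screening ledger down to the included patients."""
    if "status" not in ledger.columns:
        raise ValueError("ledger must carry a 'status' column")
    return ledger[ledger["status"] == "included"].reset_index(drop=True)
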