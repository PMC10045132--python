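"""Point-scale nomogram rendering of a fitted logistic model.

A nomogram re-expresses the linear predictor as per-covariate point scores:
each predictor's contribution beta*x is shifted to start at 0 at its
least-risky end and rescaled so the strongest predictor (largest
|beta| * range) spans exactly 0-100 points.  Total points map back to the
predicted probability through the inverse logit — the mapping is exact, so a
nomogram read-off equals the direct model prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import LogitResult

__all__ = ["NomogramSpec", "nomogram_from_model"]


@dataclass
class NomogramSpec:
    """Per-predictor point scales plus the total-points -> probability axis."""

    predictors: tuple[str, ...]
    coefs: dict
    ranges: dict                    # name -> (lo, hi)
    refs: dict                      # name -> value carrying 0 points
    scale: float                    # beta*x units per 100 points
    intercept_offset: float         # intercept + sum of beta*ref contributions

    def points(self, name: str, value) -> np.ndarray:
        """Points awarded for ``name`` at ``value`` (vectorised)."""
        beta = self.coefs[name]
        contrib = beta * (np.asarray(value, dtype=float) - self.refs[name])
        return 100.0 * np.abs(contrib) / self.scale if beta != 0 else contrib * 0.0

    def total_points(self, records: pd.DataFrame) -> np.ndarray:
        tot = np.zeros(len(records))
        for name in self.predictors:
            tot = tot + self.points(name, records[name].to_numpy(float))
        return tot

    def probability(self, total_points) -> np.ndarray:
        """Predicted outcome probability at a given total-points value."""
        lp = self.intercept_offset + np.asarray(total_points, dtype=float) * self.scale / 100.0
        return 1.0 / (1.0 + np.exp(-lp))

    def axis_tables(self, n: int = 11) -> dict[str, pd.DataFrame]:
        """Value -> points tables per predictor plus the probability axis."""
        out = {}
        for name in self.predictors:
            lo, hi = self.ranges[name]
            vals = np.linspace(lo, hi, n)
            out[name] = pd.DataFrame({"value": vals, "points": self.points(name, vals)})
        max_total = sum(float(self.points(p, self.ranges[p][1]).max() if self.coefs[p] >= 0
                              else self.points(p, self.ranges[p][0]).max())
                        for p in self.predictors)
        tot = np.linspace(0, max_total, n)
        out["probability_axis"] = pd.DataFrame(
            {"total_points": tot, "probability": self.probability(tot)})
        return out

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "coefs": {k: float(v) for k, v in self.coefs.items()},
            "ranges": {k: [float(a), float(b)] for k, (a, b) in self.ranges.items()},
            "refs": {k: float(v) for k, v in self.refs.items()},
            "scale": float(self.scale),
            "intercept_offset": float(self.intercept_offset),
        }


def nomogram_from_model(model: LogitResult, predictor_ranges: dict) -> NomogramSpec:
    """Build the point-scale nomogram for a converged logistic model.

    Parameters
    ----------
    model:
        Fitted logistic model (must have converged).
    predictor_ranges:
        ``{name: (lo, hi)}`` display range per predictor, e.g. the observed
        data range.  Zero-range predictors are excluded with a warning.

    Notes
    -----
    The reference (0-point) end of each axis is the end minimising
    ``beta * x``, so points are always non-negative; 100 points corresponds
    to ``scale`` units of the linear predictor, where ``scale`` is the
    largest ``|beta| * (hi - lo)`` over the retained predictors.
    """
    if not model.converged:
        raise ValueError("model did not converge; refusing to build a nomogram")
    coefs, ranges, refs = {}, {}, {}
    for name in model.predictors:
        if name not in predictor_ranges:
            raise ValueError(f"no display range for predictor {name!r}")
        lo, hi = (float(v) for v in predictor_ranges[name])
        if hi <= lo:
            warnings.warn(f"predictor {name!r} has zero range; excluded from nomogram")
            continue
        beta = float(model.table.loc[name, "coef"])
        coefs[name] = beta
        ranges[name] = (lo, hi)
        refs[name] = lo if beta >= 0 else hi
    if not coefs:
        raise ValueError("no usable predictors for the nomogram")
    scale = max(abs(b) * (ranges[n][1] - ranges[n][0]) for n, b in coefs.items())
    offset = model.intercept + sum(b * refs[n] for n, b in coefs.items())
    return NomogramSpec(
        predictors=tuple(coefs),
        coefs=coefs,
        ranges=ranges,
        refs=refs,
        scale=float(scale),
        intercept_offset=float(offset),
    )
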