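"""qPCR absolute quantification of F. prausnitzii with 16S normalization.

Cq values are inverted through a log-linear standard curve
(Cq = intercept + slope * log10 copies), triplicates are aggregated by
median, each sample's concentration is divided by its 16S deviation
factor (16S concentration over the cohort-median 16S concentration, a
stool-biomass correction), and the result is scaled by the template
dilution factor (100x by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StandardCurve",
    "DEFAULT_CURVES",
    "fit_standard_curve",
    "quantify",
    "quantify_plate",
    "normalize_deviation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StandardCurve:
    """Log-linear calibration Cq = intercept + slope * log10(copies)."""

    target: str
    intercept: float
    slope: float
    supplied_efficiency: float | None = None
    #: fitted dilution range (log10 copies), for extrapolation warnings
    log10_range: tuple[float, float] | None = None
    warn_on_mismatch: bool = True

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError(f"standard-curve slope must be negative, got {self.slope}")
        eff = self.efficiency
        if (
            self.warn_on_mismatch
            and self.supplied_efficiency is not None
            and abs(eff - self.supplied_efficiency) > 0.01
        ):
            logger.warning(
                "curve %s: supplied efficiency %.1f%% differs from "
                "10^(-1/slope)-1 = %.1f%%; storing both, using neither "
                "downstream",
                self.target, 100 * self.supplied_efficiency, 100 * eff,
            )

    @property
    def efficiency(self) -> float:
        """Amplification efficiency 10^(-1/slope) - 1."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def copies_from_cq(self, cq: float) -> float:
        return 10.0 ** ((self.intercept - cq) / (-self.slope))


#: published calibration curves for the two assay targets
DEFAULT_CURVES = {
    "FPRAU": StandardCurve("FPRAU", 37.342, -3.674, supplied_efficiency=0.851,
                           log10_range=(0.0, 7.0), warn_on_mismatch=False),
    "16S": StandardCurve("16S", 38.230, -3.693, supplied_efficiency=0.854,
                         log10_range=(0.0, 7.0), warn_on_mismatch=False),
}


def fit_standard_curve(points, target: str = "curve") -> StandardCurve:
    """Least-squares fit of (log10 copies, Cq) dilution points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (log10_copies, cq) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct dilution levels")
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise ValueError(f"fitted slope {slope:.4g} is non-negative")
    return StandardCurve(target, float(intercept), float(slope),
                         log10_range=(float(x.min()), float(x.max())))


def quantify(cq_replicates, curve: StandardCurve, agg: str = "median") -> float:
    """Invert replicate Cq values through a standard curve -> copies (GC/uL).

    Replicates are aggregated by median (the assay's reporting convention)
    or mean.  Extrapolation beyond the fitted dilution range is allowed
    with a logged warning.
    """
    cq = np.asarray(cq_replicates, dtype=float)
    if cq.size == 0:
        raise ValueError("need at least one Cq replicate")
    stat = float(np.median(cq) if agg == "median" else np.mean(cq))
    copies = curve.copies_from_cq(stat)
    if curve.log10_range is not None:
        lo, hi = curve.log10_range
        log10c = np.log10(copies) if copies > 0 else -np.inf
        if not lo <= log10c <= hi:
            logger.warning(
                "curve %s: Cq %.2f implies log10 copies %.2f outside the "
                "fitted range [%.1f, %.1f]; extrapolating",
                curve.target, stat, log10c, lo, hi,
            )
    return copies


def quantify_plate(plate: pd.DataFrame, curves: dict[str, StandardCurve],
                   agg: str = "median") -> pd.DataFrame:
    """Aggregate a plate export (sample_id, target, replicate, cq) into one
    concentration per (sample, target)."""
    required = {"sample_id", "target", "cq"}
    if not required.issubset(plate.columns):
        raise ValueError(f"plate must have columns {sorted(required)}")
    rows = []
    for (sid, target), sub in plate.groupby(["sample_id", "target"], sort=True):
        if target not in curves:
            raise ValueError(f"no standard curve for target {target!r}")
        rows.append((sid, target, quantify(sub["cq"].to_numpy(), curves[target], agg=agg)))
    out = pd.DataFrame(rows, columns=["sample_id", "target", "concentration"])
    return out.pivot(index="sample_id", columns="target", values="concentration")


def normalize_deviation(fprau: pd.Series, sixteen_s: pd.Series,
                        dilution_factor: float = 100.0) -> pd.DataFrame:
    """16S deviation-factor normalization of F. prausnitzii concentrations.

    deviation_factor_i = 16S_i / median(16S over the batch);
    fprau_adjusted_i = fprau_raw_i / deviation_factor_i;
    fprau_final_i = fprau_adjusted_i * dilution_factor.

    The batch median must be taken over all baseline samples together; a
    single-sample batch gets deviation factor 1 by construction.
    """
    fprau = fprau.astype(float)
    sixteen_s = sixteen_s.reindex(fprau.index).astype(float)
    if (fprau <= 0).any() or (sixteen_s <= 0).any():
        raise ValueError("concentrations must be positive")
    med = float(sixteen_s.median())
    dev = sixteen_s / med
    adjusted = fprau / dev
    return pd.DataFrame(
        {
            "fprau_raw": fprau,
            "sixteen_s": sixteen_s,
            "deviation_factor": dev,
            "fprau_adjusted": adjusted,
            "fprau_final": adjusted * dilution_factor,
        }
    )
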