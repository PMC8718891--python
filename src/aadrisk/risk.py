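"""Two-class kernel-density risk model for antibiotic-associated diarrhea.

Baseline F. prausnitzii concentrations are min-max normalized over the
pooled cohort; each group's probability density is a mixture of equal-
bandwidth Gaussians centered at its subjects' normalized values; the
posterior risk at a concentration x is

    P_AAD(x) = f_AAD(x) / (f_AAD(x) + f_non-AAD(x)),

with equal group priors (each group density is normalized by its own
sample size).  Region risk ratios compare the posterior AAD probability
of the low-concentration region against the high-concentration region,
using region-integrated density masses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm

__all__ = [
    "KdeRiskModel",
    "RiskPrediction",
    "minmax_normalize",
    "silverman_bandwidth",
    "fit_kde_model",
    "predict_p_aad",
    "region_risk_ratio",
    "extreme_separation_check",
]

MODEL_FORMAT_VERSION = 1


def minmax_normalize(values) -> tuple[np.ndarray, float, float]:
    """Map values onto [0, 1] via (v - min)/(max - min); returns the
    anchors so new queries can be transformed consistently."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to normalize")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise ValueError("constant vector: min-max normalization undefined")
    return (v - lo) / (hi - lo), lo, hi


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = x.std(ddof=1) if n > 1 else 0.0
    q25, q75 = np.percentile(x, [25, 75])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("degenerate data: cannot choose a bandwidth")
    return float(0.9 * spread * n ** (-0.2))


@dataclass
class KdeRiskModel:
    """Fitted two-class Gaussian KDE on normalized concentrations."""

    x_aad: np.ndarray  # normalized AAD training values, in [0, 1]
    x_non_aad: np.ndarray
    bandwidth: float
    norm_min: float  # GC/uL anchors of the min-max transform
    norm_max: float
    #: if False, group densities are unnormalized Gaussian sums, which is
    #: equivalent to weighting the posterior by group size
    equal_priors: bool = True

    def __post_init__(self) -> None:
        self.x_aad = np.asarray(self.x_aad, dtype=float)
        self.x_non_aad = np.asarray(self.x_non_aad, dtype=float)
        if self.x_aad.size == 0 or self.x_non_aad.size == 0:
            raise ValueError("both groups must be non-empty")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        for arr, name in ((self.x_aad, "x_aad"), (self.x_non_aad, "x_non_aad")):
            if ((arr < -1e-9) | (arr > 1 + 1e-9)).any():
                raise ValueError(f"{name}: stored samples must lie in [0, 1]")

    def normalize(self, x) -> np.ndarray:
        """Transform raw GC/uL onto the training normalization scale.
        Values outside [0, 1] are allowed (not clipped)."""
        return (np.asarray(x, dtype=float) - self.norm_min) / (
            self.norm_max - self.norm_min
        )

    def _density(self, centers: np.ndarray, xn: np.ndarray) -> np.ndarray:
        d = norm.pdf(xn[..., None], loc=centers, scale=self.bandwidth)
        total = d.sum(axis=-1)
        return total / centers.size if self.equal_priors else total

    def density_aad(self, xn) -> np.ndarray:
        return self._density(self.x_aad, np.asarray(xn, dtype=float))

    def density_non_aad(self, xn) -> np.ndarray:
        return self._density(self.x_non_aad, np.asarray(xn, dtype=float))

    def _mass(self, centers: np.ndarray, lo: float, hi: float) -> float:
        """Integral of the group density over [lo, hi] on the normalized
        scale, in closed form via the Gaussian CDF."""
        m = (norm.cdf(hi, loc=centers, scale=self.bandwidth)
             - norm.cdf(lo, loc=centers, scale=self.bandwidth)).sum()
        return float(m / centers.size) if self.equal_priors else float(m)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "x_aad": self.x_aad.tolist(),
            "x_non_aad": self.x_non_aad.tolist(),
            "bandwidth": self.bandwidth,
            "norm_min": self.norm_min,
            "norm_max": self.norm_max,
            "equal_priors": self.equal_priors,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "KdeRiskModel":
        d = json.loads(Path(path).read_text())
        d.pop("format_version", None)
        return cls(
            np.asarray(d.pop("x_aad")), np.asarray(d.pop("x_non_aad")), **d
        )


@dataclass(frozen=True)
class RiskPrediction:
    x: float  # raw GC/uL
    x_normalized: float
    f_aad: float
    f_non_aad: float
    p_aad: float


def fit_kde_model(conc_aad, conc_non_aad, bandwidth: float | str = "auto",
                  equal_priors: bool = True) -> KdeRiskModel:
    """Fit the risk model on raw baseline concentrations (GC/uL).

    Min-max normalization is computed over the POOLED cohort.  With
    bandwidth="auto", Silverman's rule is applied to the pooled
    normalized values.
    """
    conc_aad = np.asarray(conc_aad, dtype=float)
    conc_non_aad = np.asarray(conc_non_aad, dtype=float)
    if conc_aad.size == 0 or conc_non_aad.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([conc_aad, conc_non_aad])
    normed, lo, hi = minmax_normalize(pooled)
    if bandwidth == "auto":
        h = silverman_bandwidth(normed)
    else:
        h = float(bandwidth)
    return KdeRiskModel(
        normed[: conc_aad.size], normed[conc_aad.size:], h, lo, hi,
        equal_priors=equal_priors,
    )


def predict_p_aad(model: KdeRiskModel, x: float) -> RiskPrediction:
    """Posterior AAD probability at a raw concentration x (GC/uL)."""
    xn = float(model.normalize(x))
    fa = float(model.density_aad(xn))
    fn = float(model.density_non_aad(xn))
    if fa + fn <= np.finfo(float).tiny:
        raise ValueError(
            "both group densities vanish at this point; use a larger bandwidth"
        )
    return RiskPrediction(float(x), xn, fa, fn, fa / (fa + fn))


def region_risk_ratio(model: KdeRiskModel, low_threshold: float,
                      high_threshold: float, mode: str = "region") -> float:
    """P(AAD | x < low) / P(AAD | x > high) with thresholds in GC/uL.

    mode="region" (default) uses region-integrated density masses
    P(AAD|R) = M_aad(R) / (M_aad(R) + M_non(R)); mode="pointwise"
    evaluates the posterior at the two thresholds instead (sensitivity
    analysis).
    """
    if not low_threshold < high_threshold:
        raise ValueError("low_threshold must be below high_threshold")
    if mode == "pointwise":
        return (predict_p_aad(model, low_threshold).p_aad
                / predict_p_aad(model, high_threshold).p_aad)
    if mode != "region":
        raise ValueError(f"unknown mode {mode!r}")
    lo_n = float(model.normalize(low_threshold))
    hi_n = float(model.normalize(high_threshold))
    big = 1e6  # effectively +/- infinity on the normalized scale
    regions = []
    for a, b in ((-big, lo_n), (hi_n, big)):
        ma = model._mass(model.x_aad, a, b)
        mn = model._mass(model.x_non_aad, a, b)
        if ma + mn <= 1e-12:
            raise ValueError(
                "region has negligible probability mass in both groups"
            )
        regions.append(ma / (ma + mn))
    return regions[0] / regions[1]


def extreme_separation_check(ranked, low: float, high: float) -> dict:
    """Summarize group separation at the extremes of a ranked biomarker.

    ``ranked``: iterable of (subject_id, value, is_aad).  Reports how many
    AAD subjects sit below ``low`` and non-AAD above ``high``, and the
    violations (non-AAD below low, AAD above high).
    """
    aad_below = non_below = aad_above = non_above = 0
    violations = []
    for subject, value, is_aad in ranked:
        if value < low:
            if is_aad:
                aad_below += 1
            else:
                non_below += 1
                violations.append((subject, float(value), "non-AAD below low"))
        elif value > high:
            if is_aad:
                aad_above += 1
                violations.append((subject, float(value), "AAD above high"))
            else:
                non_above += 1
    return {
        "aad_below_low": aad_below,
        "non_aad_below_low": non_below,
        "aad_above_high": aad_above,
        "non_aad_above_high": non_above,
        "violations": violations,
    }
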