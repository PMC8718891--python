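"""Cohort-level configuration for the synthetic study generator.

The defaults encode the study conditions of a 30-subject amoxicillin-
clavulanate challenge cohort: 13 subjects who develop antibiotic-associated
diarrhea (AAD) and 17 who do not, sampled on days 0, 1, 2, 3, 7, 14 and 28,
with group-specific baseline Ruminococcaceae levels, treatment-phase
Enterobacteriaceae blooms, and qPCR-measured Faecalibacterium prausnitzii
concentrations rank-correlated with Ruminococcaceae relative abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

__all__ = ["CohortConfig"]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Group-level means (``rumi_mean_*``, ``bloom_*``) are the published
    cohort summaries; concentration parameters control within-group
    spread and are synthetic modelling choices.
    """

    #: number of subjects who develop AAD / who do not
    n_aad: int = 13
    n_non_aad: int = 17
    #: study days with a stool sample (day 0 = baseline, 1-3 = treatment)
    days: tuple[int, ...] = (0, 1, 2, 3, 7, 14, 28)
    seed: int = 0

    #: per-sample 16S read depth ~ Normal(mean, sd) truncated below at 1000
    read_depth_mean: float = 150_087.0
    read_depth_sd: float = 14_526.0
    read_depth_min: int = 1000

    #: baseline Ruminococcaceae relative abundance: Beta with these means
    rumi_mean_aad: float = 0.084
    rumi_mean_non_aad: float = 0.144
    #: Beta concentration (a+b) for the baseline Ruminococcaceae draw
    rumi_concentration: float = 20.0

    #: probability of an Enterobacteriaceae bloom on days 1-3
    bloom_prob_aad: float = 10 / 13
    bloom_prob_non_aad: float = 5 / 17
    #: peak-day Enterobacteriaceae proportion: Beta with these means
    bloom_mag_mean_aad: float = 0.591
    bloom_mag_mean_non_aad: float = 0.210
    bloom_mag_concentration: float = 60.0
    #: Enterobacteriaceae level on non-peak treatment days, as a fraction
    #: of the peak magnitude
    bloom_adjacent_fraction: float = 0.35

    #: mean within-Ruminococcaceae genus split:
    #: Faecalibacterium, Subdoligranulum, Ruminococcus, other
    genus_split_rumi: tuple[float, ...] = (0.671, 0.117, 0.077, 0.135)
    #: Dirichlet concentration of the per-subject genus split
    genus_concentration: float = 10.0

    #: mean split of the non-Ruminococcaceae mass over the family panel:
    #: Bacteroidaceae, Lachnospiraceae, Enterobacteriaceae, Prevotellaceae,
    #: Bifidobacteriaceae, unassigned
    family_split: tuple[float, ...] = (0.30, 0.36, 0.025, 0.115, 0.08, 0.12)
    family_concentration: float = 80.0

    #: target population Spearman correlation between baseline
    #: Ruminococcaceae proportion and F. prausnitzii concentration
    spearman_target: float = 0.85
    #: log10 GC/uL location/scale of the F. prausnitzii concentration
    fp_log10_loc: float = 7.5
    fp_log10_scale: float = 0.5
    #: log10 sd of the per-subject stool-biomass deviation factor
    biomass_log10_sd: float = 0.15
    #: 16S rRNA gene concentration (GC/uL) of the median-biomass reaction
    sixteen_s_ref: float = 10 ** 4.5

    #: qPCR standard curves as (intercept, slope): Cq = a + b*log10(copies)
    curve_fprau: tuple[float, float] = (37.342, -3.674)
    curve_16s: tuple[float, float] = (38.230, -3.693)
    cq_replicate_sd: float = 0.15
    n_replicates: int = 3
    dilution_factor: float = 100.0

    #: entropy-sharpening exponent applied to the non-Enterobacteriaceae
    #: composition on treatment days (larger = bigger diversity drop)
    treatment_sharpening_aad: float = 1.6
    treatment_sharpening_non_aad: float = 1.15
    #: weight on the baseline composition during recovery, keyed by day
    recovery_weights: tuple[tuple[int, float], ...] = ((7, 0.85), (14, 0.93), (28, 0.97))
    #: Dirichlet concentration of day-to-day compositional noise
    day_noise_concentration: float = 2000.0

    #: number of AAD subjects whose diaries meet the early-stop rule
    #: (>=3 watery episodes within one day)
    n_early_stop: int = 4

    def validate(self) -> None:
        if self.n_aad < 1 or self.n_non_aad < 1:
            raise ValueError("n_aad and n_non_aad must each be >= 1")
        if self.read_depth_mean <= 0 or self.read_depth_sd <= 0:
            raise ValueError("read depth mean and sd must be positive")
        for name in ("rumi_mean_aad", "rumi_mean_non_aad", "bloom_prob_aad",
                     "bloom_prob_non_aad", "bloom_mag_mean_aad",
                     "bloom_mag_mean_non_aad"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for name in ("genus_split_rumi", "family_split"):
            split = getattr(self, name)
            if any(p < 0 or p > 1 for p in split):
                raise ValueError(f"{name} entries must lie in [0, 1]")
            if abs(sum(split) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {sum(split)})")
        if not -1.0 < self.spearman_target < 1.0:
            raise ValueError("spearman_target must lie in (-1, 1)")
        if not 0 <= self.n_early_stop <= self.n_aad:
            raise ValueError("n_early_stop must lie in [0, n_aad]")
        if 0 not in self.days:
            raise ValueError("study days must include the baseline day 0")

    @property
    def n_subjects(self) -> int:
        return self.n_aad + self.n_non_aad

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("days", "genus_split_rumi", "family_split", "curve_fprau",
                    "curve_16s"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "recovery_weights" in d and d["recovery_weights"] is not None:
            d["recovery_weights"] = tuple(
                (int(k), float(v)) for k, v in d["recovery_weights"]
            )
        return cls(**d)
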