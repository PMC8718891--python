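"""Monte-Carlo calibration summaries of the synthetic-cohort generator.

Each function regenerates cohorts from the paper-calibrated defaults,
pushes them through the corresponding analysis stage (taxonomic
aggregation, bloom calling, diary labeling, qPCR quantification) and
returns the measured quantity with its Monte-Carlo standard error.
These close the loop between the generator's configured parameters and
what the analysis recovers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CohortConfig
from .group_stats import spearman
from .labeling import label_cohort
from .qpcr import DEFAULT_CURVES, normalize_deviation, quantify_plate
from .simulate import generate_cohort, sample_id
from .tables import aggregate, call_blooms

__all__ = [
    "MonteCarloEstimate",
    "baseline_rumi_means",
    "bloom_statistics",
    "faecalibacterium_share",
    "aad_label_count",
    "pipeline_spearman",
]

_MOD = 2 ** 31 - 1


def _cohort_seed(base: int, i: int) -> int:
    return int((base * 1_000_003 + i) % _MOD)


@dataclass(frozen=True)
class MonteCarloEstimate:
    mean: float
    se: float
    n: int

    @classmethod
    def of(cls, values) -> "MonteCarloEstimate":
        v = np.asarray(values, dtype=float)
        return cls(float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size)), v.size)


def baseline_rumi_means(n_cohorts: int = 200, seed: int = 1,
                        config: CohortConfig | None = None
                        ) -> dict[str, MonteCarloEstimate]:
    """Day-0 Ruminococcaceae relative abundance per group, measured via
    family-rank aggregation and pooled over cohort replicates."""
    cfg = config or CohortConfig()
    vals: dict[str, list[float]] = {"AAD": [], "non-AAD": []}
    for i in range(n_cohorts):
        study = generate_cohort(cfg, seed=_cohort_seed(seed, i))
        fam = aggregate(study.count_table, "family")
        day0 = fam.metadata.index[fam.metadata["day"] == 0]
        grp = fam.metadata.loc[day0, "group"]
        rumi = fam.values.loc["Ruminococcaceae", day0]
        for g in vals:
            vals[g].extend(rumi[grp == g].tolist())
    return {g: MonteCarloEstimate.of(v) for g, v in vals.items()}


def bloom_statistics(n_cohorts: int = 500, seed: int = 3,
                     threshold: float = 0.10,
                     config: CohortConfig | None = None) -> dict:
    """Enterobacteriaceae bloom occurrence per group (days 1-3, default
    threshold) and mean magnitude among bloom-positive AAD subjects."""
    cfg = config or CohortConfig()
    freq: dict[str, list[float]] = {"AAD": [], "non-AAD": []}
    mags: list[float] = []
    for i in range(n_cohorts):
        study = generate_cohort(cfg, seed=_cohort_seed(seed, i))
        fam = aggregate(study.count_table, "family")
        calls = call_blooms(fam, "Enterobacteriaceae", (1, 2, 3), threshold)
        groups = study.truth["group"].reindex(calls.index)
        for g in freq:
            freq[g].extend(calls.loc[groups == g, "bloom"].astype(float).tolist())
        pos = calls[(groups == "AAD") & calls["bloom"]]
        mags.extend(pos["magnitude"].tolist())
    return {
        "frequency": {g: MonteCarloEstimate.of(v) for g, v in freq.items()},
        "magnitude_aad": MonteCarloEstimate.of(mags),
    }


def faecalibacterium_share(n_cohorts: int = 200, seed: int = 5,
                           config: CohortConfig | None = None
                           ) -> MonteCarloEstimate:
    """Faecalibacterium's share of the Ruminococcaceae family across
    baseline samples (genus abundance over family abundance)."""
    cfg = config or CohortConfig()
    shares: list[float] = []
    for i in range(n_cohorts):
        study = generate_cohort(cfg, seed=_cohort_seed(seed, i))
        fam = aggregate(study.count_table, "family")
        gen = aggregate(study.count_table, "genus")
        day0 = fam.metadata.index[fam.metadata["day"] == 0]
        share = (gen.values.loc["Faecalibacterium", day0]
                 / fam.values.loc["Ruminococcaceae", day0])
        shares.extend(share.tolist())
    return MonteCarloEstimate.of(shares)


def aad_label_count(seed: int = 4, config: CohortConfig | None = None) -> int:
    """Number of subjects labeled AAD by the Bristol-diary rule on one
    generated cohort."""
    study = generate_cohort(config or CohortConfig(), seed=seed)
    labels = label_cohort(study.diaries)
    return int(labels["aad"].sum())


def pipeline_spearman(n_subjects: int = 10_000, seed: int = 2) -> tuple[float, int]:
    """Spearman correlation between measured baseline Ruminococcaceae
    relative abundance and the qPCR-derived F. prausnitzii concentration,
    through the full quantification pipeline, on one large baseline-only
    cohort."""
    base = CohortConfig()
    n_aad = n_subjects // 2
    cfg = CohortConfig.from_dict({
        **base.to_dict(),
        "n_aad": n_aad,
        "n_non_aad": n_subjects - n_aad,
        "days": (0,),
        "seed": _cohort_seed(seed, 0),
    })
    study = generate_cohort(cfg)
    conc = quantify_plate(study.qpcr, DEFAULT_CURVES)
    norm = normalize_deviation(conc["FPRAU"], conc["16S"],
                               cfg.dilution_factor)
    fam = aggregate(study.count_table, "family")
    day0 = [sample_id(s, 0) for s in study.truth.index]
    rumi = fam.values.loc["Ruminococcaceae", day0].to_numpy()
    fp = norm["fprau_final"].reindex(day0).to_numpy()
    rho, _ = spearman(rumi, fp)
    return float(rho), n_subjects
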