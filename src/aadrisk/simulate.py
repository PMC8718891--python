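"""Synthetic antibiotic-challenge cohort generator.

Produces complete study datasets — ASV count tables with taxonomy and
sample metadata, stool diaries, and a qPCR plate — whose statistical
structure matches the analysis assumptions: group-specific baseline
Ruminococcaceae levels, Enterobacteriaceae blooms during the 3-day
treatment phase, recovery toward baseline by day 28, and F. prausnitzii
concentrations rank-correlated with baseline Ruminococcaceae relative
abundance through a Gaussian copula.

A latent "truth" table (true group, composition parameters, bloom
indicators, concentrations) travels with every study so that
parameter-recovery tests can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import CohortConfig
from .labeling import DiaryRecord, StoolDiary
from .tables import CountTable

__all__ = ["SyntheticStudy", "generate_cohort", "sample_id"]

# ASV panel: (family, genus, species, n_asvs, phylum, class, order).
# Empty strings become "Unassigned" on aggregation.  The Ruminococcaceae
# genera are listed in the order of CohortConfig.genus_split_rumi.
_RUMI_GENERA = [
    ("Faecalibacterium", "Faecalibacterium prausnitzii", 3),
    ("Subdoligranulum", "", 3),
    ("Ruminococcus", "", 3),
    ("", "", 3),
]
_OTHER_FAMILIES = [
    # (family, [(genus, n_asvs), ...], phylum, class, order)
    ("Bacteroidaceae", [("Bacteroides", 4)],
     "Bacteroidota", "Bacteroidia", "Bacteroidales"),
    ("Lachnospiraceae", [("Blautia", 3), ("Roseburia", 3)],
     "Firmicutes", "Clostridia", "Lachnospirales"),
    ("Enterobacteriaceae", [("Escherichia-Shigella", 2)],
     "Proteobacteria", "Gammaproteobacteria", "Enterobacterales"),
    ("Prevotellaceae", [("Prevotella", 3)],
     "Bacteroidota", "Bacteroidia", "Bacteroidales"),
    ("Bifidobacteriaceae", [("Bifidobacterium", 3)],
     "Actinobacteriota", "Actinobacteria", "Bifidobacteriales"),
    ("", [("", 6)], "", "", ""),
]


def _build_taxa() -> tuple[list[str], pd.Series, dict]:
    """Return (feature_ids, lineages, index map).

    The index map holds, per family-panel slot, the ASV column indices of
    each genus so compositions can be assembled by slicing.
    """
    feature_ids: list[str] = []
    lineages: dict[str, str] = {}
    idx: dict = {"rumi": [], "families": []}
    k = 0

    def add(family, genus, species, n, phylum, cls, order):
        nonlocal k
        cols = []
        for _ in range(n):
            fid = f"ASV{k:03d}"
            lineages[fid] = (
                f"d__Bacteria;p__{phylum};c__{cls};o__{order};"
                f"f__{family};g__{genus};s__{species}"
            )
            feature_ids.append(fid)
            cols.append(k)
            k += 1
        return cols

    for genus, species, n in _RUMI_GENERA:
        idx["rumi"].append(
            add("Ruminococcaceae", genus, species, n,
                "Firmicutes", "Clostridia", "Oscillospirales")
        )
    for family, genera, phylum, cls, order in _OTHER_FAMILIES:
        fam_cols = []
        for genus, n in genera:
            fam_cols.extend(add(family, genus, "", n, phylum, cls, order))
        idx["families"].append(fam_cols)
    idx["entero"] = idx["families"][2]  # Enterobacteriaceae slot
    return feature_ids, pd.Series(lineages, name="lineage"), idx


_FEATURE_IDS, _LINEAGES, _IDX = _build_taxa()
N_FEATURES = len(_FEATURE_IDS)


@dataclass
class SyntheticStudy:
    """One generated study: counts, diaries, qPCR plate and latent truth."""

    config: CohortConfig
    count_table: CountTable
    diaries: list[StoolDiary]
    qpcr: pd.DataFrame  # sample_id, target in {FPRAU, 16S}, replicate, cq
    truth: pd.DataFrame  # indexed by subject_id


def sample_id(subject: str, day: int) -> str:
    return f"{subject}D{day}"


def _baseline_compositions(cfg: CohortConfig, rumi_p: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """ASV-level baseline composition per subject (n_subjects x N_FEATURES)."""
    n = len(rumi_p)
    comp = np.zeros((n, N_FEATURES))
    genus_alpha = cfg.genus_concentration * np.asarray(cfg.genus_split_rumi)
    family_alpha = cfg.family_concentration * np.asarray(cfg.family_split)
    genus_split = rng.dirichlet(genus_alpha, size=n)
    family_split = rng.dirichlet(family_alpha, size=n)
    for i in range(n):
        for g, cols in enumerate(_IDX["rumi"]):
            w = rng.dirichlet(np.ones(len(cols)))
            comp[i, cols] = rumi_p[i] * genus_split[i, g] * w
        rest = 1.0 - rumi_p[i]
        for f, cols in enumerate(_IDX["families"]):
            w = rng.dirichlet(np.ones(len(cols)))
            comp[i, cols] = rest * family_split[i, f] * w
    return comp


def _treatment_composition(base: np.ndarray, entero_level: float,
                           sharpening: float) -> np.ndarray:
    """Perturb one subject's composition for a treatment day.

    The Enterobacteriaceae fraction is set to ``entero_level`` (its
    within-family ASV weights preserved); the remaining mass is sharpened
    (p^gamma, renormalized) to model the antibiotic's diversity drop, then
    rescaled to 1 - entero_level.
    """
    entero = np.asarray(_IDX["entero"])
    out = np.zeros_like(base)
    e_base = base[entero].sum()
    w_entero = base[entero] / e_base if e_base > 0 else np.full(len(entero), 1 / len(entero))
    rest = base.copy()
    rest[entero] = 0.0
    rest = rest ** sharpening
    rest /= rest.sum()
    out[:] = rest * (1.0 - entero_level)
    out[entero] = entero_level * w_entero
    return out


def generate_cohort(config: CohortConfig | None = None, *,
                    seed: int | None = None) -> SyntheticStudy:
    """Generate one complete synthetic study.

    Deterministic given (config, seed); ``seed`` overrides ``config.seed``.
    """
    cfg = config or CohortConfig()
    if seed is not None:
        cfg = CohortConfig.from_dict({**cfg.to_dict(), "seed": int(seed)})
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    rng_comp, rng_counts, rng_diary, rng_qpcr = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    n = cfg.n_subjects
    subjects = [f"P{i + 1:02d}" for i in range(n)]
    is_aad = np.array([True] * cfg.n_aad + [False] * cfg.n_non_aad)

    # --- latent subject variables via a Gaussian copula ----------------
    # Baseline Ruminococcaceae ~ group-specific Beta.  The F. prausnitzii
    # concentration is coupled to it through a Gaussian copula on the
    # POOLED rumi margin (the two-group mixture CDF): the Pearson
    # parameter r = 2 sin(pi * rho_S / 6) makes the population Spearman
    # across the whole cohort equal spearman_target, and subjects with
    # low rumi (the AAD group, on average) get low concentrations.
    r = 2.0 * np.sin(np.pi * cfg.spearman_target / 6.0)
    c = cfg.rumi_concentration
    means = np.where(is_aad, cfg.rumi_mean_aad, cfg.rumi_mean_non_aad)
    z1 = rng_comp.standard_normal(n)
    rumi_p = stats.beta.ppf(stats.norm.cdf(z1), means * c, (1 - means) * c)
    rumi_p = np.clip(rumi_p, 1e-6, 1 - 1e-6)
    w_aad = cfg.n_aad / n
    a1, b1 = cfg.rumi_mean_aad * c, (1 - cfg.rumi_mean_aad) * c
    a2, b2 = cfg.rumi_mean_non_aad * c, (1 - cfg.rumi_mean_non_aad) * c
    u_pooled = (w_aad * stats.beta.cdf(rumi_p, a1, b1)
                + (1 - w_aad) * stats.beta.cdf(rumi_p, a2, b2))
    z_star = stats.norm.ppf(np.clip(u_pooled, 1e-12, 1 - 1e-12))
    z2 = r * z_star + np.sqrt(1.0 - r ** 2) * rng_comp.standard_normal(n)
    fp_conc = 10 ** (cfg.fp_log10_loc + cfg.fp_log10_scale * z2)

    bloom_prob = np.where(is_aad, cfg.bloom_prob_aad, cfg.bloom_prob_non_aad)
    bloom = rng_comp.random(n) < bloom_prob
    mag_mean = np.where(is_aad, cfg.bloom_mag_mean_aad, cfg.bloom_mag_mean_non_aad)
    bc = cfg.bloom_mag_concentration
    bloom_mag = rng_comp.beta(mag_mean * bc, (1 - mag_mean) * bc)
    bloom_mag = np.where(bloom, bloom_mag, np.nan)
    peak_day = np.where(bloom, rng_comp.integers(1, 4, size=n), -1)

    base_comp = _baseline_compositions(cfg, rumi_p, rng_comp)

    # --- per-sample target compositions --------------------------------
    recovery = dict(cfg.recovery_weights)
    sharpen = np.where(is_aad, cfg.treatment_sharpening_aad,
                       cfg.treatment_sharpening_non_aad)
    entero_cols = np.asarray(_IDX["entero"])
    targets: dict[tuple[str, int], np.ndarray] = {}
    day3_like: dict[int, np.ndarray] = {}
    treatment_days = [d for d in cfg.days if 1 <= d <= 3]
    for i, subj in enumerate(subjects):
        last_treatment = base_comp[i]
        for d in sorted(cfg.days):
            if d == 0:
                t = base_comp[i]
            elif 1 <= d <= 3:
                if bloom[i]:
                    if d == peak_day[i]:
                        e = bloom_mag[i]
                    else:
                        e = bloom_mag[i] * cfg.bloom_adjacent_fraction
                    e = max(e, base_comp[i][entero_cols].sum())
                else:
                    e = base_comp[i][entero_cols].sum()
                t = _treatment_composition(base_comp[i], e, sharpen[i])
                last_treatment = t
            else:
                w = recovery.get(d, 1.0)
                t = w * base_comp[i] + (1 - w) * last_treatment
            targets[(subj, d)] = t

    # --- realized compositions, depths, counts --------------------------
    a_lo = (cfg.read_depth_min - cfg.read_depth_mean) / cfg.read_depth_sd
    sample_ids, cols, meta_rows = [], [], []
    kappa = cfg.day_noise_concentration
    for i, subj in enumerate(subjects):
        for d in sorted(cfg.days):
            t = np.maximum(targets[(subj, d)], 1e-10)
            t = t / t.sum()
            p = rng_counts.dirichlet(kappa * t)
            depth = int(round(stats.truncnorm.rvs(
                a_lo, np.inf, loc=cfg.read_depth_mean, scale=cfg.read_depth_sd,
                random_state=rng_counts,
            )))
            counts = rng_counts.multinomial(depth, p / p.sum())
            sid = sample_id(subj, d)
            sample_ids.append(sid)
            cols.append(counts)
            meta_rows.append((sid, subj, d, "AAD" if is_aad[i] else "non-AAD"))

    counts_df = pd.DataFrame(
        np.column_stack(cols) if cols else np.zeros((N_FEATURES, 0), int),
        index=pd.Index(_FEATURE_IDS, name="feature_id"),
        columns=sample_ids,
    )
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "subject_id", "day", "group"]
    ).set_index("sample_id")
    table = CountTable(counts_df, _LINEAGES, metadata)

    # --- diaries --------------------------------------------------------
    early_idx = set(
        rng_diary.choice(np.flatnonzero(is_aad),
                         size=min(cfg.n_early_stop, cfg.n_aad), replace=False)
    ) if cfg.n_aad else set()
    diaries = []
    for i, subj in enumerate(subjects):
        records: list[DiaryRecord] = []
        watery_per_day = {1: 0, 2: 0, 3: 0}
        if is_aad[i]:
            pd_day = int(peak_day[i]) if bloom[i] else int(rng_diary.integers(1, 4))
            if i in early_idx:
                watery_per_day[pd_day] = 3 + int(rng_diary.poisson(0.7))
                for d in (1, 2, 3):
                    if d != pd_day and rng_diary.random() < 0.4:
                        watery_per_day[d] = int(rng_diary.integers(1, 3))
            else:
                extra = int(rng_diary.binomial(3, 0.3))
                watery_per_day[pd_day] = 1
                days_cycle = [d for d in (1, 2, 3)]
                j = 0
                while extra > 0:
                    d = days_cycle[j % 3]
                    if watery_per_day[d] < 2:
                        watery_per_day[d] += 1
                        extra -= 1
                    j += 1
                    if j > 12:
                        break
        for d in sorted(set(cfg.days) | {1, 2, 3}):
            ep = 0
            for _ in range(watery_per_day.get(d, 0)):
                records.append(DiaryRecord(d, ep, int(rng_diary.choice([6, 7]))))
                ep += 1
            for _ in range(1 + int(rng_diary.poisson(0.3))):
                records.append(DiaryRecord(d, ep, int(rng_diary.integers(2, 6))))
                ep += 1
        diaries.append(StoolDiary(subj, records))

    # --- qPCR plate ------------------------------------------------------
    # The plate measures 100x-diluted baseline extracts; a per-subject
    # biomass deviation multiplies both targets and is removed downstream
    # by 16S deviation-factor normalization.
    dev = 10 ** rng_qpcr.normal(0.0, cfg.biomass_log10_sd, size=n)
    fp_reaction = fp_conc * dev / cfg.dilution_factor
    s16_reaction = cfg.sixteen_s_ref * dev
    a_fp, b_fp = cfg.curve_fprau
    a_16, b_16 = cfg.curve_16s
    rows = []
    for i, subj in enumerate(subjects):
        sid = sample_id(subj, 0)
        for rep in range(1, cfg.n_replicates + 1):
            cq_fp = a_fp + b_fp * np.log10(fp_reaction[i]) \
                + rng_qpcr.normal(0.0, cfg.cq_replicate_sd)
            cq_16 = a_16 + b_16 * np.log10(s16_reaction[i]) \
                + rng_qpcr.normal(0.0, cfg.cq_replicate_sd)
            rows.append((sid, "FPRAU", rep, round(cq_fp, 4)))
            rows.append((sid, "16S", rep, round(cq_16, 4)))
    qpcr = pd.DataFrame(rows, columns=["sample_id", "target", "replicate", "cq"])

    truth = pd.DataFrame(
        {
            "group": np.where(is_aad, "AAD", "non-AAD"),
            "rumi_baseline": rumi_p,
            "fp_conc": fp_conc,
            "bloom": bloom,
            "bloom_magnitude": bloom_mag,
            "peak_day": peak_day,
            "biomass_deviation": dev,
        },
        index=pd.Index(subjects, name="subject_id"),
    )
    return SyntheticStudy(cfg, table, diaries, qpcr, truth)
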