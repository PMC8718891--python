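"""ASV count-table operations: validation, rarefaction, taxonomic
aggregation, relative abundance, and Enterobacteriaceae bloom calling.

The in-memory container is a features x samples integer matrix
(:class:`CountTable`) with a 7-rank semicolon-delimited lineage per
feature and per-sample metadata (subject, study day, group).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "CountTable",
    "TaxonProfile",
    "BloomCall",
    "parse_lineage",
    "rarefy",
    "aggregate",
    "call_blooms",
]

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
UNASSIGNED = "Unassigned"


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Split a lineage string into 7 rank labels.

    Accepts both prefixed ("f__Ruminococcaceae") and bare labels; missing
    trailing ranks are padded with empty strings.
    """
    parts = [p.strip() for p in lineage.split(";")]
    parts += [""] * (len(RANKS) - len(parts))
    out = []
    for part, prefix in zip(parts, _PREFIXES):
        if part.startswith(prefix):
            part = part[len(prefix):]
        out.append(part)
    return tuple(out)


@dataclass
class CountTable:
    """Features x samples non-negative integer count matrix.

    ``counts``: DataFrame, index = feature IDs, columns = sample IDs.
    ``lineages``: Series mapping feature ID -> lineage string.
    ``metadata``: DataFrame indexed by sample ID with at least columns
    ``subject_id``, ``day`` and (optionally) ``group``.
    """

    counts: pd.DataFrame
    lineages: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample IDs in count table")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate feature IDs in count table")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = self.counts.index.difference(self.lineages.index)
        if len(missing):
            raise ValueError(f"features without lineage: {list(missing)[:5]}")
        missing = self.counts.columns.difference(self.metadata.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {list(missing)[:5]}")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.sample_sums()
        zero = totals[totals == 0]
        if len(zero):
            raise ValueError(f"all-zero sample(s): {list(zero.index)}")
        return self.counts / totals

    def subset_samples(self, sample_ids) -> "CountTable":
        return CountTable(
            self.counts.loc[:, list(sample_ids)],
            self.lineages,
            self.metadata.loc[list(sample_ids)],
        )


@dataclass
class TaxonProfile:
    """Relative abundances at one taxonomic rank (taxa x samples)."""

    rank: str
    values: pd.DataFrame  # relative abundances, columns sum to 1
    counts: pd.DataFrame  # aggregated integer counts
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        colsums = self.values.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            bad = colsums[np.abs(colsums - 1) > 1e-9]
            raise ValueError(f"profile columns not normalized: {list(bad.index)[:5]}")


@dataclass(frozen=True)
class BloomCall:
    subject_id: str
    bloom: bool
    magnitude: float | None  # max relative abundance over the window
    peak_day: int | None


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped with a logged
    warning (they cannot be subsampled to the requested effort).
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_sums()
    keep = totals.index[totals >= depth]
    dropped = totals.index.difference(keep)
    if len(dropped):
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, list(dropped),
        )
    cols = {}
    mat = table.counts[keep].to_numpy()
    for j, sid in enumerate(keep):
        cols[sid] = rng.multivariate_hypergeometric(mat[:, j], depth)
    out = pd.DataFrame(cols, index=table.counts.index)
    return CountTable(out, table.lineages, table.metadata.loc[keep])


def aggregate(table: CountTable, rank: str) -> TaxonProfile:
    """Sum counts over features sharing a rank label, then normalize.

    Features with an empty label at ``rank`` are pooled into
    ``"Unassigned"``.  Raises if any sample has zero total counts.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    level = RANKS.index(rank)
    labels = [
        parse_lineage(table.lineages.loc[f])[level] or UNASSIGNED
        for f in table.counts.index
    ]
    agg = table.counts.groupby(pd.Index(labels, name=rank)).sum()
    totals = agg.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return TaxonProfile(rank, agg / totals, agg, table.metadata)


def call_blooms(
    profile: TaxonProfile,
    taxon: str,
    days: tuple[int, ...] = (1, 2, 3),
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Call a bloom per subject: max relative abundance of ``taxon`` over
    the subject's samples on ``days`` at or above ``threshold``.

    The 0.10 default is a declared convention separating reported bloom
    magnitudes from typical baseline Enterobacteriaceae levels; it is not
    a literature constant.  Returns a DataFrame indexed by subject_id with
    columns bloom, magnitude, peak_day; subjects with no sample on the
    requested days get bloom=False and NaN magnitude, with a warning.
    """
    if taxon not in profile.values.index:
        raise ValueError(f"taxon {taxon!r} not present at rank {profile.rank!r}")
    meta = profile.metadata
    rows = []
    for subject, sub in meta.groupby("subject_id", sort=True):
        window = sub[sub["day"].isin(days)]
        if window.empty:
            warnings.warn(
                f"subject {subject}: no samples on days {sorted(days)}; "
                "bloom set to False",
                stacklevel=2,
            )
            rows.append((subject, False, np.nan, pd.NA))
            continue
        vals = profile.values.loc[taxon, window.index]
        peak_sample = vals.idxmax()
        magnitude = float(vals.loc[peak_sample])
        rows.append(
            (
                subject,
                magnitude >= threshold,
                magnitude,
                int(window.loc[peak_sample, "day"]),
            )
        )
    out = pd.DataFrame(
        rows, columns=["subject_id", "bloom", "magnitude", "peak_day"]
    ).set_index("subject_id")
    return out
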