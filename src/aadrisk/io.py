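"""Readers and writers for the study's file formats.

Counts: TSV, rows = features, columns = samples, integer cells.
Taxonomy: TSV feature_id -> 7-rank semicolon-delimited lineage.
Metadata: TSV sample_id, subject_id, day, group.
Diary: CSV subject_id, day, episode_index, bristol.
qPCR: CSV sample_id, target, replicate, cq.
Truth: TSV of the generator's latent per-subject values.

Every file written here starts with '#'-prefixed provenance lines (tool
version, seed, config hash); all readers skip them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .config import CohortConfig
from .labeling import DiaryRecord, StoolDiary
from .simulate import SyntheticStudy
from .tables import CountTable

__all__ = [
    "write_study",
    "read_counts",
    "read_diaries",
    "read_qpcr",
    "read_table",
    "config_hash",
]

FILES = {
    "counts": "counts.tsv",
    "taxonomy": "taxonomy.tsv",
    "metadata": "metadata.tsv",
    "diary": "diary.csv",
    "qpcr": "qpcr.csv",
    "truth": "truth.tsv",
}


def config_hash(config: CohortConfig | dict) -> str:
    d = config.to_dict() if isinstance(config, CohortConfig) else dict(config)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(seed, cfg_hash) -> str:
    return (
        f"# aadrisk v{__version__}\n"
        f"# seed={seed}\n"
        f"# config_hash={cfg_hash}\n"
    )


def _write(df: pd.DataFrame, path: Path, sep: str, seed, cfg_hash,
           index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed, cfg_hash))
        df.to_csv(fh, sep=sep, index=index)


def write_study(study: SyntheticStudy, directory: str | Path) -> dict[str, Path]:
    """Write all study files into ``directory``; returns the file map."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    seed = study.config.seed
    h = config_hash(study.config)
    paths = {k: out / v for k, v in FILES.items()}

    table = study.count_table
    _write(table.counts, paths["counts"], "\t", seed, h)
    tax = table.lineages.loc[table.counts.index].rename("lineage")
    tax.index.name = "feature_id"
    _write(tax.to_frame(), paths["taxonomy"], "\t", seed, h)
    _write(table.metadata, paths["metadata"], "\t", seed, h)

    diary_rows = [
        (d.subject_id, r.day, r.episode_index, r.bristol)
        for d in study.diaries for r in d.records
    ]
    diary = pd.DataFrame(
        diary_rows, columns=["subject_id", "day", "episode_index", "bristol"]
    )
    _write(diary, paths["diary"], ",", seed, h, index=False)
    _write(study.qpcr, paths["qpcr"], ",", seed, h, index=False)
    _write(study.truth, paths["truth"], "\t", seed, h)
    return paths


def read_table(path: str | Path, sep: str = "\t", index_col=0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


def read_counts(counts_path, taxonomy_path, metadata_path) -> CountTable:
    """Assemble a CountTable from its three on-disk components."""
    counts = read_table(counts_path).astype(int)
    counts.index = counts.index.astype(str)
    tax = read_table(taxonomy_path)
    lineages = tax["lineage"].astype(str)
    lineages.index = lineages.index.astype(str)
    meta = read_table(metadata_path)
    meta.index = meta.index.astype(str)
    return CountTable(counts, lineages, meta)


def read_diaries(path: str | Path) -> list[StoolDiary]:
    df = pd.read_csv(Path(path), comment="#")
    required = {"subject_id", "day", "episode_index", "bristol"}
    if not required.issubset(df.columns):
        raise ValueError(f"diary file must have columns {sorted(required)}")
    diaries = []
    for subject, sub in df.groupby("subject_id", sort=True):
        records = [
            DiaryRecord(int(r.day), int(r.episode_index), int(r.bristol))
            for r in sub.itertuples()
        ]
        diaries.append(StoolDiary(str(subject), records))
    return diaries


def read_qpcr(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), comment="#")
    required = {"sample_id", "target", "replicate", "cq"}
    if not required.issubset(df.columns):
        raise ValueError(f"qPCR file must have columns {sorted(required)}")
    return df
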