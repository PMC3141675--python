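"""TSV dialects, pipeline configuration, and the run manifest.

All tables are plain tab-separated files with a header row, UTF-8, ``NA``
for missing values:

* map: ``marker_id  chromosome  position_cM``, sorted by chromosome then
  position.
* genotypes: one row per line, first column ``line_id``, one column per
  marker, codes ``A`` (B73 allele), ``B`` (Mo17 allele), ``NA``.
  Heterozygous codes are rejected: DH lines carry fixed alleles.
* expression: one row per probe, first column ``probe_id``, one float
  column per line.
* annotation: ``probe_id  chromosome  position_cM  unique_flag
  position_known``.
* peaks: ``probe_id  marker_id  chrom  cM  D  p  direction  rank``.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import (
    ALLELE_TO_CODE,
    ExpressionMatrix,
    GeneticMap,
    GenotypeMatrix,
)


# ---------------------------------------------------------------------------
# readers / writers


def write_map(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    for col in ("marker_id", "chromosome", "position_cM"):
        if col not in df.columns:
            raise ValueError(f"map file {path}: missing column {col!r}")
    dup = df["marker_id"][df["marker_id"].duplicated()]
    if len(dup):
        row = int(dup.index[0]) + 2  # 1-based incl. header
        raise ValueError(f"map file {path}: duplicate marker_id "
                         f"{dup.iloc[0]!r} at row {row}")
    for chrom, grp in df.groupby("chromosome", sort=False):
        pos = grp["position_cM"].to_numpy()
        bad = np.where(np.diff(pos) <= 0)[0]
        if bad.size:
            row = int(grp.index[bad[0] + 1]) + 2
            raise ValueError(
                f"map file {path}: positions out of order on chromosome "
                f"{chrom!r} at row {row}"
            )
    return GeneticMap.from_frame(df)


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    genotypes.to_frame().to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[], keep_default_na=False)
    if df.columns[0] != "line_id":
        raise ValueError(f"genotype file {path}: first column must be line_id")
    line_ids = df["line_id"].to_numpy(dtype=object)
    dup = pd.Series(line_ids)[pd.Series(line_ids).duplicated()]
    if len(dup):
        raise ValueError(f"genotype file {path}: duplicate line_id "
                         f"{dup.iloc[0]!r} at row {int(dup.index[0]) + 2}")
    marker_ids = df.columns[1:].to_numpy(dtype=object)
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    codes = np.empty(raw.shape, dtype=np.int8)
    for allele, code in ALLELE_TO_CODE.items():
        codes[raw == allele] = code
    known = np.isin(raw, list(ALLELE_TO_CODE))
    if not known.all():
        i, j = np.argwhere(~known)[0]
        raise ValueError(
            f"genotype file {path}: row {i + 2}, marker {marker_ids[j]!r}: "
            f"code {raw[i, j]!r} is not A/B/NA -- DH lines must be fixed "
            "(no heterozygous calls)"
        )
    return GenotypeMatrix(line_ids, marker_ids, codes)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "probe_id":
        raise ValueError(f"expression file {path}: first column must be probe_id")
    probe_ids = df["probe_id"].astype(str).to_numpy(dtype=object)
    dups = pd.Series(probe_ids)[pd.Series(probe_ids).duplicated()]
    if len(dups):
        raise ValueError(f"expression file {path}: duplicate probe_id "
                         f"{dups.iloc[0]!r} at row {int(dups.index[0]) + 2}")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    # background-corrected/normalized data is allowed to dip below zero,
    # but every entry must be a finite number
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"expression file {path}: non-finite intensity at "
                         f"row {i + 2}, column {df.columns[j + 1]!r}")
    return ExpressionMatrix(probe_ids, df.columns[1:].to_numpy(dtype=object), values)


def write_annotation(annot: pd.DataFrame, path) -> None:
    annot.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    required = {"probe_id", "chromosome", "position_cM", "unique_flag",
                "position_known"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path}: missing columns {sorted(missing)}")
    df["probe_id"] = df["probe_id"].astype(str)
    df["unique_flag"] = df["unique_flag"].astype(bool)
    df["position_known"] = df["position_known"].astype(bool)
    df["chromosome"] = df["chromosome"].where(df["chromosome"].notna(), None)
    return df


def write_peaks(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_peaks(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                       dtype={"probe_id": str})


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """End-to-end run configuration; thresholds default to the study's."""

    map_path: str
    genotype_path: str
    expression_paths: list  # one per biological replicate, in order
    annotation_path: str
    outdir: str
    identify_threshold: float = 1e-6
    validate_threshold: float = 1e-5
    window_cM: float = 10.0
    min_group_size: int = 10
    background_fraction: float = 0.2
    cooperative_max_rank: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.identify_threshold <= 0 or self.validate_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.window_cM <= 0:
            raise ValueError("window_cM must be positive")
        if not 0 < self.background_fraction < 1:
            raise ValueError("background_fraction must be in (0, 1)")
        if len(self.expression_paths) < 1:
            raise ValueError("at least one expression replicate required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# run manifest


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    input_checksums: dict
    version: str = __version__
    seed: int = 0
    started: str = ""
    finished: str = ""
    stage_counts: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
            fh.write("\n")

    @classmethod
    def start(cls, config: PipelineConfig) -> "RunManifest":
        checksums = {}
        paths = [config.map_path, config.genotype_path,
                 config.annotation_path, *config.expression_paths]
        for p in paths:
            if Path(p).exists():
                checksums[str(p)] = file_sha256(p)
        return cls(
            config=asdict(config),
            input_checksums=checksums,
            seed=config.seed,
            started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )
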