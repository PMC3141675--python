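"""Core in-memory containers shared across the pipeline.

The pipeline works on four tabular objects: a genetic map (the scan's
coordinate system, in centimorgans), a genotype matrix of fully homozygous
doubled-haploid (DH) lines, per-replicate expression intensity matrices,
and a probe annotation table.  The first three are thin dataclasses wrapping
numpy arrays (fast paths for the scan); annotation and truth tables are
plain pandas DataFrames.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# Genotype codes.  DH lines are homozygous by construction, so a single
# parental code per call suffices.
B73 = 0
MO17 = 1
MISSING = -1

ALLELE_TO_CODE = {"A": B73, "B": MO17, "NA": MISSING}
CODE_TO_ALLELE = {B73: "A", MO17: "B", MISSING: "NA"}


@dataclass
class GeneticMap:
    """Ordered markers with chromosome and genetic position (cM).

    Markers are stored in map order: grouped by chromosome (in order of
    first appearance) and strictly increasing in position within each
    chromosome.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_cM: np.ndarray

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_cM = np.asarray(self.position_cM, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.marker_id)
        if not (len(self.chromosome) == len(self.position_cM) == n):
            raise ValueError("map columns have unequal lengths")
        if n == 0:
            raise ValueError("genetic map is empty")
        ids, counts = np.unique(self.marker_id.astype(str), return_counts=True)
        if (counts > 1).any():
            dup = ids[counts > 1][0]
            raise ValueError(f"duplicate marker_id {dup!r} in genetic map")
        # strictly sorted within chromosome
        for chrom in self.chromosomes:
            pos = self.position_cM[self.chromosome == chrom]
            bad = np.where(np.diff(pos) <= 0)[0]
            if bad.size:
                raise ValueError(
                    f"markers on chromosome {chrom!r} not strictly sorted "
                    f"by position (offending interval index {bad[0]})"
                )

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> list:
        """Chromosomes in order of first appearance."""
        seen: dict = {}
        for c in self.chromosome:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_index(self) -> dict:
        return {c: i for i, c in enumerate(self.chromosomes)}

    def nearest_marker(self, chrom, pos_cM: float) -> int:
        """Index (in map order) of the marker nearest to (chrom, pos_cM)."""
        on = np.where(self.chromosome == chrom)[0]
        if on.size == 0:
            raise ValueError(f"no markers on chromosome {chrom!r}")
        return int(on[np.argmin(np.abs(self.position_cM[on] - pos_cM))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position_cM": self.position_cM,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        return cls(
            df["marker_id"].to_numpy(dtype=object),
            df["chromosome"].astype(str).to_numpy(dtype=object),
            df["position_cM"].to_numpy(dtype=float),
        )


@dataclass
class GenotypeMatrix:
    """Lines x markers genotype calls for fixed biallelic DH lines.

    ``codes`` is int8 with 0 = B73 allele, 1 = Mo17 allele, -1 = missing.
    Heterozygous calls cannot be represented: DH lines carry fixed alleles.
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"genotype codes shape {self.codes.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        bad = ~np.isin(self.codes, (B73, MO17, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.codes[i, j]} at line "
                f"{self.line_ids[i]!r}, marker {self.marker_ids[j]!r}"
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def marker_index(self, marker_id) -> int:
        idx = np.where(self.marker_ids == marker_id)[0]
        if idx.size == 0:
            raise KeyError(f"unknown marker {marker_id!r}")
        return int(idx[0])

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker B73 allele frequency among non-missing calls."""
        ok = self.codes != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(
                ok.sum(axis=0) > 0,
                (self.codes == B73).sum(axis=0) / np.maximum(ok.sum(axis=0), 1),
                np.nan,
            )

    def to_frame(self) -> pd.DataFrame:
        alleles = np.empty(self.codes.shape, dtype=object)
        for code, a in CODE_TO_ALLELE.items():
            alleles[self.codes == code] = a
        df = pd.DataFrame(alleles, columns=self.marker_ids)
        df.insert(0, "line_id", self.line_ids)
        return df

    def reindex_lines(self, line_ids) -> "GenotypeMatrix":
        """Return a copy with rows in the order of ``line_ids``."""
        pos = {l: i for i, l in enumerate(self.line_ids)}
        try:
            order = [pos[l] for l in line_ids]
        except KeyError as e:
            raise KeyError(f"line {e.args[0]!r} absent from genotype matrix")
        return GenotypeMatrix(
            np.asarray(list(line_ids), dtype=object),
            self.marker_ids.copy(),
            self.codes[order],
        )


@dataclass
class ExpressionMatrix:
    """Probes x lines nonnegative intensities for one biological replicate."""

    probe_ids: np.ndarray
    line_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.line_ids)):
            raise ValueError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.line_ids)} lines"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def probe_index(self, probe_id) -> int:
        idx = np.where(self.probe_ids == probe_id)[0]
        if idx.size == 0:
            raise KeyError(f"unknown probe {probe_id!r}")
        return int(idx[0])

    def row(self, probe_id) -> np.ndarray:
        return self.values[self.probe_index(probe_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.line_ids)
        df.insert(0, "probe_id", self.probe_ids)
        return df

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.probe_ids.copy(), self.line_ids.copy(), self.values.copy()
        )
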