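"""Core in-memory containers for the single-chromosome selection scan.

All coordinates are 1-based inclusive (VCF convention) internally; BED
export converts to 0-based half-open at the single serialization point in
:mod:`sweepx.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SNPMap",
    "GenotypeMatrix",
    "HaplotypeMatrix",
    "PopulationMap",
    "SelectionRegion",
    "MISSING",
]

#: Sentinel for a missing genotype in :class:`GenotypeMatrix.values`.
MISSING: int = -1


@dataclass
class SNPMap:
    """Per-SNP marker map for one chromosome.

    Wraps a DataFrame with columns ``snp_id``, ``chrom``, ``pos``,
    ``ref``, ``alt``, ``ancestral`` where ``ancestral`` is one of
    ``{"ref", "alt", "unknown"}``.  Positions must be strictly
    increasing.
    """

    table: pd.DataFrame

    REQUIRED = ("snp_id", "chrom", "pos", "ref", "alt", "ancestral")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"SNPMap missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        pos = self.table["pos"].to_numpy()
        if len(pos) > 1 and not np.all(np.diff(pos) > 0):
            bad = int(np.flatnonzero(np.diff(pos) <= 0)[0])
            raise ValueError(
                "unsorted positions: "
                f"{self.table['snp_id'].iat[bad]}@{pos[bad]} followed by "
                f"{self.table['snp_id'].iat[bad + 1]}@{pos[bad + 1]}"
            )
        if (pos < 1).any():
            raise ValueError("positions must be >= 1 (1-based)")
        same = self.table["ref"] == self.table["alt"]
        if same.any():
            raise ValueError(
                f"ref == alt at {self.table.loc[same, 'snp_id'].tolist()[:5]}"
            )
        bad_anc = ~self.table["ancestral"].isin(["ref", "alt", "unknown"])
        if bad_anc.any():
            raise ValueError("ancestral must be one of ref/alt/unknown")

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def positions(self) -> np.ndarray:
        return self.table["pos"].to_numpy(dtype=np.int64)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    @property
    def chrom(self) -> str:
        return str(self.table["chrom"].iat[0]) if self.n_snps else ""

    def subset(self, keep: np.ndarray) -> "SNPMap":
        """Row subset by boolean mask or integer index array."""
        return SNPMap(self.table.iloc[np.asarray(keep)].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Samples x SNPs alt-allele dosage matrix; entries in {0,1,2,MISSING}."""

    samples: list[str]
    values: np.ndarray  # int8, shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x SNPs)")
        if self.values.shape[0] != len(self.samples):
            raise ValueError(
                f"{len(self.samples)} samples but {self.values.shape[0]} rows"
            )
        ok = np.isin(self.values, [0, 1, 2, MISSING])
        if not ok.all():
            raise ValueError("genotype entries must be in {0,1,2,missing}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of called (non-missing) entries."""
        return self.values != MISSING

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            [self.samples[i] for i in keep], self.values[keep, :]
        )

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(list(self.samples), self.values[:, keep])


@dataclass
class HaplotypeMatrix:
    """Phased, complete haplotypes: 2*n_samples rows x n_snps columns.

    Entries are 0/1 alt-allele indicators as loaded; the EHH/iHS layer
    re-polarizes to ancestral/derived using the SNP map.  Row ``2*i`` and
    ``2*i + 1`` are the two haplotypes of sample ``i``.
    """

    samples: list[str]
    values: np.ndarray  # int8, shape (2*n_samples, n_snps)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape[0] != 2 * len(self.samples):
            raise ValueError(
                f"expected {2 * len(self.samples)} haplotype rows, "
                f"got {self.values.shape[0]}"
            )
        if not np.isin(self.values, [0, 1]).all():
            raise ValueError("haplotypes must be complete 0/1 (phased)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_haplotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def sample_of_haplotype(self, row: int) -> str:
        return self.samples[row // 2]

    def to_genotypes(self) -> GenotypeMatrix:
        g = self.values[0::2, :].astype(np.int8) + self.values[1::2, :]
        return GenotypeMatrix(list(self.samples), g)

    def subset_samples(self, keep: np.ndarray) -> "HaplotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        rows = np.column_stack([2 * keep, 2 * keep + 1]).ravel()
        return HaplotypeMatrix(
            [self.samples[i] for i in keep], self.values[rows, :]
        )

    def subset_snps(self, keep: np.ndarray) -> "HaplotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return HaplotypeMatrix(list(self.samples), self.values[:, keep])


@dataclass
class PopulationMap:
    """Sample -> population label assignment."""

    assignments: dict[str, str]

    @property
    def populations(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p, None)
        return list(seen)

    @property
    def n_total(self) -> int:
        return len(self.assignments)

    def size(self, population: str) -> int:
        return sum(1 for p in self.assignments.values() if p == population)

    def members(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def label_of(self, sample: str) -> str:
        try:
            return self.assignments[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} has no population label")

    def indices_in(self, samples: list[str], population: str) -> np.ndarray:
        """Indices of `samples` belonging to `population`."""
        unknown = [s for s in samples if s not in self.assignments]
        if unknown:
            raise KeyError(f"samples without population label: {unknown[:5]}")
        return np.array(
            [i for i, s in enumerate(samples)
             if self.assignments[s] == population],
            dtype=np.int64,
        )

    def restrict(self, samples: list[str]) -> "PopulationMap":
        return PopulationMap({s: self.label_of(s) for s in samples})


@dataclass
class SelectionRegion:
    """Candidate interval around outlier SNPs.

    ``start_bp``/``end_bp`` are bp bounds on the 1-based coordinate line
    with length ``end - start`` (a SNP at 122.36 Mb padded by 200 kb
    spans 122.16-122.56 Mb, i.e. 0.40 Mb); BED export writes them
    directly as a half-open interval.
    """

    chrom: str
    start_bp: int
    end_bp: int
    peak_snp: str
    peak_value: float
    method: str  # "ihs" | "fst" | "combined"
    label: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError(
                f"degenerate region [{self.start_bp}, {self.end_bp}]"
            )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6
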