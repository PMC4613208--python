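"""Genotype quality control and PCA structure inspection.

Filters mirror the standard chip-data workflow: samples are dropped for
low call rate (< 90%) or duplication (near-identical genotypes); SNPs
are dropped for call rate < 90%, minor allele frequency < 0.05, or
Hardy-Weinberg disequilibrium (exact-test p < 1e-6).  All removal rules
use strict inequality, so a sample called at exactly 90% survives.

HWE is tested within each population and the minimum p across
populations is compared to the threshold: pooling breeds would flag
genuinely differentiated SNPs (Wahlund effect), which are exactly what
the downstream F_ST scan needs to keep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import MISSING, GenotypeMatrix, PopulationMap, SNPMap

__all__ = [
    "QCReport",
    "filter_samples",
    "filter_snps",
    "hwe_exact_p",
    "impute_residual_missing",
    "pca_coordinates",
]


@dataclass
class QCReport:
    """What was removed and why; one primary reason per item.

    SNP reasons follow the rule order call_rate -> maf -> hwe: a SNP
    failing several rules is reported under the first.
    """

    samples_removed: list[tuple[str, str]] = field(default_factory=list)
    snps_removed: list[tuple[str, str]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"item": s, "kind": "sample", "reason": r}
            for s, r in self.samples_removed
        ] + [
            {"item": s, "kind": "snp", "reason": r}
            for s, r in self.snps_removed
        ]
        return pd.DataFrame(rows, columns=["item", "kind", "reason"])


def filter_samples(
    G: GenotypeMatrix,
    min_call_rate: float = 0.90,
    duplicate_ibs: float = 0.99,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples with call rate < ``min_call_rate``, then duplicates.

    Duplicates: any pair with mean identity-by-state >= ``duplicate_ibs``
    over co-called SNPs loses its later member (input order).
    """
    if G.n_samples == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport(
        thresholds={
            "sample_min_call_rate": min_call_rate,
            "duplicate_ibs": duplicate_ibs,
        }
    )
    called = G.called
    call_rate = called.mean(axis=1)
    low = call_rate < min_call_rate
    for i in np.flatnonzero(low):
        report.samples_removed.append((G.samples[i], "low_call_rate"))

    keep_idx = np.flatnonzero(~low)
    # pairwise IBS over co-called SNPs among survivors of the call-rate rule
    dup: set[int] = set()
    for a_pos, i in enumerate(keep_idx):
        if i in dup:
            continue
        for j in keep_idx[a_pos + 1:]:
            if j in dup:
                continue
            both = called[i] & called[j]
            n_both = int(both.sum())
            if n_both == 0:
                continue
            diff = np.abs(
                G.values[i, both].astype(np.int16)
                - G.values[j, both].astype(np.int16)
            )
            ibs = 1.0 - diff.sum() / (2.0 * n_both)
            if ibs >= duplicate_ibs:
                dup.add(int(j))
                report.samples_removed.append((G.samples[j], "duplicate"))
    keep = np.array([i for i in keep_idx if i not in dup], dtype=np.int64)
    if keep.size == 0:
        raise ValueError("no samples survive QC")
    return G.subset_samples(keep), report


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Sums, over all heterozygote counts compatible with the observed
    allele counts, the conditional probabilities no larger than that of
    the observed configuration (Wigginton-style exact test).  Returns a
    p-value in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = n_Aa + 2 * n_aa  # minor-or-not does not matter: symmetric
    # heterozygote count shares parity with the allele count
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    # log P(n_Aa = h | allele counts) up to a shared constant:
    #   n! / (nAA! nAa! naa!) * 2^nAa  with nAA, naa fixed by h
    n_aa_h = (n_a - hets) // 2
    n_AA_h = n - n_aa_h - hets
    logp = (
        hets * np.log(2.0)
        - gammaln(n_AA_h + 1)
        - gammaln(hets + 1)
        - gammaln(n_aa_h + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == n_Aa)[0]]
    p = float(probs[probs <= obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def _genotype_counts(
    values: np.ndarray, rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sub = values[rows, :]
    return (
        (sub == 0).sum(axis=0),
        (sub == 1).sum(axis=0),
        (sub == 2).sum(axis=0),
    )


def filter_snps(
    G: GenotypeMatrix,
    snp_map: SNPMap,
    pops: PopulationMap | None = None,
    min_call_rate: float = 0.90,
    min_maf: float = 0.05,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeMatrix, SNPMap, QCReport]:
    """Drop SNPs failing call rate, MAF or HWE (in that reason order).

    MAF is computed on called genotypes pooled across all samples.  HWE
    is tested per population when ``pops`` is given (min p across
    populations), else pooled.
    """
    if G.n_snps != snp_map.n_snps:
        raise ValueError("genotype matrix and SNP map disagree on SNP count")
    report = QCReport(
        thresholds={
            "snp_min_call_rate": min_call_rate,
            "min_maf": min_maf,
            "hwe_p_min": hwe_p_min,
        }
    )
    called = G.called
    n_called = called.sum(axis=0)
    call_rate = n_called / G.n_samples
    fail_cr = call_rate < min_call_rate

    alt_counts = np.where(called, G.values, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = alt_counts / (2.0 * n_called)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    fail_maf = ~fail_cr & ((maf < min_maf) | ~np.isfinite(maf))

    if pops is not None:
        groups = [
            pops.indices_in(G.samples, p) for p in pops.populations
        ]
    else:
        groups = [np.arange(G.n_samples)]
    min_hwe_p = np.ones(G.n_snps)
    todo = np.flatnonzero(~fail_cr & ~fail_maf)
    for rows in groups:
        if rows.size == 0:
            continue
        c0, c1, c2 = _genotype_counts(G.values, rows)
        for j in todo:
            if c0[j] + c1[j] + c2[j] == 0:
                continue
            p = hwe_exact_p(int(c0[j]), int(c1[j]), int(c2[j]))
            min_hwe_p[j] = min(min_hwe_p[j], p)
    fail_hwe = ~fail_cr & ~fail_maf & (min_hwe_p < hwe_p_min)

    for j in range(G.n_snps):
        sid = snp_map.table["snp_id"].iat[j]
        if fail_cr[j]:
            report.snps_removed.append((sid, "call_rate"))
        elif fail_maf[j]:
            report.snps_removed.append((sid, "maf"))
        elif fail_hwe[j]:
            report.snps_removed.append((sid, "hwe"))
    keep = ~(fail_cr | fail_maf | fail_hwe)
    if not keep.any():
        raise ValueError("no SNPs survive QC")
    return G.subset_snps(keep), snp_map.subset(keep), report


def impute_residual_missing(
    G: GenotypeMatrix, pops: PopulationMap | None = None
) -> GenotypeMatrix:
    """Fill residual missing entries with the within-population modal
    genotype for that SNP (ties -> smaller genotype code).

    This is a deliberately simple major-genotype fill for the handful of
    entries left after QC; it is not phasing-based imputation.
    """
    values = G.values.copy()
    if pops is not None:
        groups = [pops.indices_in(G.samples, p) for p in pops.populations]
    else:
        groups = [np.arange(G.n_samples)]
    for rows in groups:
        if rows.size == 0:
            continue
        sub = values[np.ix_(rows, np.arange(G.n_snps))]
        miss = sub == MISSING
        if not miss.any():
            continue
        counts = np.stack([(sub == g).sum(axis=0) for g in (0, 1, 2)])
        modal = counts.argmax(axis=0).astype(np.int8)  # argmax takes first max
        sub = np.where(miss, modal[None, :], sub)
        values[np.ix_(rows, np.arange(G.n_snps))] = sub
    # SNPs entirely missing within a group fall back to genotype 0
    values[values == MISSING] = 0
    return GenotypeMatrix(list(G.samples), values)


def pca_coordinates(
    G: GenotypeMatrix, n_components: int = 2
) -> pd.DataFrame:
    """Sample coordinates on the leading genotype principal components.

    Columns are centered and scaled by sqrt(2 p (1-p)) with p the pooled
    alt frequency (the usual drift-variance scaling); monomorphic SNPs
    are skipped.  Missing entries are mean-imputed for the projection.
    Component signs are arbitrary.
    """
    if G.n_samples < 2 or G.n_snps < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 SNPs")
    called = G.called
    n_called = called.sum(axis=0)
    alt_counts = np.where(called, G.values, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt_counts / (2.0 * n_called)
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if poly.sum() < n_components:
        raise ValueError(
            f"only {int(poly.sum())} polymorphic SNPs for "
            f"{n_components} components"
        )
    X = G.values[:, poly].astype(float)
    mean = 2.0 * p[poly]
    X[~called[:, poly]] = np.nan
    X = np.where(np.isnan(X), mean[None, :], X)
    X -= mean[None, :]
    X /= np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))[None, :]
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :n_components] * s[:n_components]
    return pd.DataFrame(
        coords,
        index=pd.Index(G.samples, name="sample"),
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
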