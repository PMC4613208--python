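"""Per-SNP F_ST from expected heterozygosities.

F_ST = (H_T - H_S) / H_T, where H_T = 1 - (p^2 + q^2) is the expected
heterozygosity at the pooled allele frequency (p the sample-size
weighted mean of subpopulation frequencies, q = 1 - p) and
H_S = sum_i 2 p_i (1 - p_i) n_i / N is the weighted mean within-
subpopulation expected heterozygosity.  This is the plain H_T/H_S
estimator without small-sample (Nei / Weir-Cockerham) correction.
Monomorphic SNPs (H_T = 0) yield NA; tiny negative rounding artifacts
are clamped to 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    GenotypeMatrix,
    HaplotypeMatrix,
    PopulationMap,
    SNPMap,
)

__all__ = ["allele_frequencies", "fst_per_snp", "fst_scan"]


def allele_frequencies(
    data: GenotypeMatrix | HaplotypeMatrix,
    pops: PopulationMap,
    subset: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population alt-allele frequency and called-allele counts.

    Accepts genotypes (dosages with missing) or phased haplotypes.
    Returns (freqs, counts) DataFrames with one column per population;
    cells with no called alleles are NaN / 0.
    """
    labels = subset if subset is not None else pops.populations
    known = set(pops.populations)
    for lab in labels:
        if lab not in known:
            raise KeyError(f"unknown population label {lab!r}")
    if isinstance(data, HaplotypeMatrix):
        values = data.values
        samples = data.samples
        per_sample_rows = 2
    else:
        values = data.values
        samples = data.samples
        per_sample_rows = 1

    freqs = {}
    counts = {}
    for lab in labels:
        idx = pops.indices_in(samples, lab)
        if per_sample_rows == 2:
            rows = np.column_stack([2 * idx, 2 * idx + 1]).ravel()
            sub = values[rows, :]
            alt = sub.sum(axis=0, dtype=np.int64)
            n_alleles = np.full(values.shape[1], rows.size, dtype=np.int64)
        else:
            sub = values[idx, :]
            called = sub >= 0
            alt = np.where(called, sub, 0).sum(axis=0, dtype=np.int64)
            n_alleles = 2 * called.sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        freqs[lab] = f
        counts[lab] = n_alleles
    return pd.DataFrame(freqs), pd.DataFrame(counts)


def fst_per_snp(
    p_i: np.ndarray,
    n_i: np.ndarray,
    weighted_pool: bool = True,
) -> dict[str, float]:
    """F_ST for one SNP from subpopulation frequencies and sizes.

    ``p_i``: per-population alt frequency (NaN allowed, those
    populations are dropped); ``n_i``: sample sizes (individuals).
    Returns a dict with p (pooled), H_T, H_S and fst (NaN if H_T = 0).
    """
    p_i = np.asarray(p_i, dtype=float)
    n_i = np.asarray(n_i, dtype=float)
    ok = np.isfinite(p_i) & (n_i > 0)
    p_i, n_i = p_i[ok], n_i[ok]
    if p_i.size < 2:
        raise ValueError("F_ST needs >= 2 populations with data")
    n_total = n_i.sum()
    if weighted_pool:
        p = float((p_i * n_i).sum() / n_total)
    else:
        p = float(p_i.mean())
    q = 1.0 - p
    h_t = 1.0 - (p * p + q * q)
    h_exp = 2.0 * p_i * (1.0 - p_i)
    h_s = float((h_exp * n_i).sum() / n_total)
    if h_t == 0.0:
        fst = float("nan")
    else:
        fst = max(0.0, (h_t - h_s) / h_t)
    return {"p": p, "H_T": h_t, "H_S": h_s, "fst": fst}


def fst_scan(
    data: GenotypeMatrix | HaplotypeMatrix,
    snp_map: SNPMap,
    pops: PopulationMap,
    subset: list[str] | None = None,
    weighted_pool: bool = True,
) -> pd.DataFrame:
    """Per-SNP F_ST track for a subset of populations (default: all).

    The standard study design is one joint scan over all populations
    plus every pairwise scan; call once per subset.
    """
    labels = subset if subset is not None else pops.populations
    if len(labels) < 2:
        raise ValueError("F_ST scan needs >= 2 populations")
    freqs, counts = allele_frequencies(data, pops, labels)
    n_snps = snp_map.n_snps
    f_mat = freqs.to_numpy()  # (n_snps, n_pops)
    n_mat = counts.to_numpy() / 2.0  # alleles -> individuals

    out = {
        "p_pool": np.full(n_snps, np.nan),
        "H_T": np.full(n_snps, np.nan),
        "H_S": np.full(n_snps, np.nan),
        "fst": np.full(n_snps, np.nan),
    }
    for j in range(n_snps):
        ok = np.isfinite(f_mat[j]) & (n_mat[j] > 0)
        if ok.sum() < 2:
            continue
        r = fst_per_snp(f_mat[j], n_mat[j], weighted_pool)
        out["p_pool"][j] = r["p"]
        out["H_T"][j] = r["H_T"]
        out["H_S"][j] = r["H_S"]
        out["fst"][j] = r["fst"]

    track = pd.DataFrame(
        {
            "chrom": snp_map.table["chrom"],
            "pos": snp_map.table["pos"],
            "snp_id": snp_map.table["snp_id"],
        }
    )
    for lab in labels:
        track[f"p_{lab}"] = freqs[lab]
    for key, arr in out.items():
        track[key] = arr
    track["scan"] = "-".join(labels)
    return track
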