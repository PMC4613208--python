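"""Outlier calling and candidate-region construction.

iHS outliers are SNPs with |iHS| strictly above 2 (the usual empirical
autosomal cutoff carried over to the X).  F_ST outliers come from the
boxplot rule: with F_U / F_L the upper and lower quartiles and
Q = F_U - F_L the interquartile range, the fences are UL = F_U + 1.5 Q
and LL = F_L - 1.5 Q; values strictly outside are outliers.  Each
outlier SNP spawns a +-200 kb window; overlapping or book-ended windows
merge into candidate regions.  Two combination rules are provided: the
operational union of the per-method threshold regions, and an FDR rule
(region q < 0.1 in both methods, or q < 0.05 in one) using
Benjamini-Hochberg q-values with empirical upper-tail p-values for
F_ST.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import SelectionRegion, SNPMap

__all__ = [
    "BoxplotThresholds",
    "ihs_outliers",
    "boxplot_outliers",
    "bh_fdr",
    "empirical_upper_tail_p",
    "ihs_gaussian_p",
    "build_regions",
    "merge_regions",
    "combine_candidates",
    "summarize_regions",
    "overlap_length_mb",
]


@dataclass
class BoxplotThresholds:
    f_l: float  # lower quartile
    f_u: float  # upper quartile

    @property
    def q(self) -> float:
        """Interquartile range."""
        return self.f_u - self.f_l

    @property
    def ul(self) -> float:
        return self.f_u + 1.5 * self.q

    @property
    def ll(self) -> float:
        return self.f_l - 1.5 * self.q


def ihs_outliers(
    track: pd.DataFrame, threshold: float = 2.0
) -> pd.DataFrame:
    """SNP rows with |iHS| strictly greater than ``threshold``."""
    z = track["ihs"]
    return track[z.abs() > threshold].copy()


def boxplot_outliers(
    values: np.ndarray, quantile_method: str = "linear"
) -> tuple[BoxplotThresholds, np.ndarray]:
    """Boxplot fences and outlier mask for a sample of statistics.

    Quartiles are computed by linear interpolation at ranks
    0.25 (n - 1) and 0.75 (n - 1) on the sorted finite values
    (``quantile_method`` passes through to numpy for alternatives).
    Returns (thresholds, boolean mask over the input, NaN-safe: NaN is
    never an outlier).  Needs at least 4 finite values.
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size < 4:
        raise ValueError(
            f"boxplot thresholds need >= 4 values, got {finite.size}"
        )
    f_l, f_u = np.quantile(finite, [0.25, 0.75], method=quantile_method)
    thr = BoxplotThresholds(float(f_l), float(f_u))
    with np.errstate(invalid="ignore"):
        mask = (values > thr.ul) | (values < thr.ll)
    mask &= np.isfinite(values)
    return thr, mask


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1).

    NaN entries propagate as NaN and do not count toward m.
    """
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    pf = p[finite]
    m = pf.size
    if m == 0:
        return q
    order = np.argsort(pf, kind="stable")
    ranked = pf[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qf = np.empty(m)
    qf[order] = np.minimum(ranked, 1.0)
    q[finite] = qf
    return q


def empirical_upper_tail_p(values: np.ndarray) -> np.ndarray:
    """Empirical upper-tail rank p-values: p_i = (1 + #{v_j >= v_i}) / (1 + n).

    The add-one smoothing keeps every p strictly inside (0, 1): the
    top-ranked value gets 2/(n+1) rather than an impossible 0.
    NaN in, NaN out.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    out = np.full_like(v, np.nan)
    vf = v[finite]
    n = vf.size
    if n == 0:
        return out
    order = np.argsort(vf, kind="stable")
    # count of values >= v_i, ties included
    sorted_v = vf[order]
    ge_counts = n - np.searchsorted(sorted_v, vf, side="left")
    out[finite] = (1.0 + ge_counts) / (1.0 + n)
    return out


def ihs_gaussian_p(track: pd.DataFrame) -> np.ndarray:
    """Two-sided Gaussian p-values of the standardized iHS."""
    from scipy.stats import norm

    return 2.0 * norm.sf(np.abs(track["ihs"].to_numpy(dtype=float)))


def merge_regions(
    regions: list[SelectionRegion],
) -> list[SelectionRegion]:
    """Merge overlapping or book-ended regions; peak = max |value|."""
    if not regions:
        return []
    regs = sorted(regions, key=lambda r: (r.chrom, r.start_bp, r.end_bp))
    merged = [regs[0]]
    for r in regs[1:]:
        last = merged[-1]
        if r.chrom == last.chrom and r.start_bp <= last.end_bp:
            better = abs(r.peak_value) > abs(last.peak_value)
            merged[-1] = SelectionRegion(
                chrom=last.chrom,
                start_bp=last.start_bp,
                end_bp=max(last.end_bp, r.end_bp),
                peak_snp=r.peak_snp if better else last.peak_snp,
                peak_value=r.peak_value if better else last.peak_value,
                method=last.method,
                label=last.label,
                extras={**last.extras, **r.extras},
            )
        else:
            merged.append(r)
    return merged


def build_regions(
    outliers: pd.DataFrame,
    snp_map: SNPMap,
    value_column: str,
    method: str,
    label: str = "",
    half_width_bp: int = 200_000,
    chrom_length: int | None = None,
) -> list[SelectionRegion]:
    """Window each outlier SNP by +-``half_width_bp`` and merge.

    ``outliers`` must carry pos, snp_id and the statistic column named
    by ``value_column``.  Windows are clamped to [1, chrom_length].
    """
    regions = []
    chrom = snp_map.chrom
    for _, row in outliers.sort_values("pos").iterrows():
        pos = int(row["pos"])
        start = max(1, pos - half_width_bp)
        end = pos + half_width_bp
        if chrom_length is not None:
            end = min(end, chrom_length)
        regions.append(
            SelectionRegion(
                chrom=chrom,
                start_bp=start,
                end_bp=end,
                peak_snp=str(row["snp_id"]),
                peak_value=float(row[value_column]),
                method=method,
                label=label,
            )
        )
    return merge_regions(regions)


def _min_q_over(
    region: SelectionRegion, track: pd.DataFrame, q: np.ndarray
) -> float:
    pos = track["pos"].to_numpy()
    inside = (pos >= region.start_bp) & (pos <= region.end_bp)
    vals = q[inside]
    vals = vals[np.isfinite(vals)]
    return float(vals.min()) if vals.size else float("nan")


def combine_candidates(
    ihs_regions: list[SelectionRegion],
    fst_regions: list[SelectionRegion],
    mode: str = "threshold",
    ihs_track: pd.DataFrame | None = None,
    fst_track: pd.DataFrame | None = None,
    label: str = "",
) -> list[SelectionRegion]:
    """Combine per-method regions into candidate selection regions.

    ``threshold``: the union of the |iHS|-threshold regions and the
    F_ST boxplot regions, merged.  ``fdr``: keep a region when its
    minimum member q-value is below 0.1 in BOTH methods' tracks over
    its span, or below 0.05 in at least one; q-values are BH-adjusted
    Gaussian p for iHS and BH-adjusted empirical upper-tail p for F_ST.
    """
    if mode == "threshold":
        pooled = [
            SelectionRegion(
                r.chrom, r.start_bp, r.end_bp, r.peak_snp, r.peak_value,
                "combined", label or r.label, dict(r.extras),
            )
            for r in [*ihs_regions, *fst_regions]
        ]
        return merge_regions(pooled)
    if mode != "fdr":
        raise ValueError(f"unknown combination mode {mode!r}")
    if ihs_track is None or fst_track is None:
        raise ValueError("mode='fdr' needs both score tracks")
    q_ihs = bh_fdr(ihs_gaussian_p(ihs_track))
    q_fst = bh_fdr(
        empirical_upper_tail_p(fst_track["fst"].to_numpy(dtype=float))
    )
    kept = []
    for r in merge_regions([*ihs_regions, *fst_regions]):
        qa = _min_q_over(r, ihs_track, q_ihs)
        qb = _min_q_over(r, fst_track, q_fst)
        both = np.isfinite(qa) and np.isfinite(qb) and qa < 0.1 and qb < 0.1
        one = (np.isfinite(qa) and qa < 0.05) or (
            np.isfinite(qb) and qb < 0.05
        )
        if both or one:
            kept.append(
                SelectionRegion(
                    r.chrom, r.start_bp, r.end_bp, r.peak_snp,
                    r.peak_value, "combined", label or r.label,
                    {**r.extras, "q_ihs": qa, "q_fst": qb},
                )
            )
    return merge_regions(kept)


def summarize_regions(
    regions_by_key: dict[tuple[str, str], list[SelectionRegion]],
    n_outliers_by_key: dict[tuple[str, str], int] | None = None,
) -> pd.DataFrame:
    """Per (method, label) counts and lengths, Mb to two decimals."""
    rows = []
    for (method, label), regs in regions_by_key.items():
        total = sum(r.length_mb for r in regs)
        rows.append(
            {
                "method": method,
                "label": label,
                "n_outlier_snps": (
                    n_outliers_by_key.get((method, label), pd.NA)
                    if n_outliers_by_key
                    else pd.NA
                ),
                "n_regions": len(regs),
                "avg_length_mb": round(total / len(regs), 2) if regs else 0.0,
                "total_length_mb": round(total, 2),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["method", "label", "n_outlier_snps", "n_regions",
                 "avg_length_mb", "total_length_mb"],
    )


def overlap_length_mb(
    regions_a: list[SelectionRegion],
    regions_b: list[SelectionRegion],
) -> float:
    """Total pairwise intersection length between two merged region
    sets, in Mb."""
    total = 0
    for a in regions_a:
        for b in regions_b:
            if a.chrom != b.chrom:
                continue
            lo = max(a.start_bp, b.start_bp)
            hi = min(a.end_bp, b.end_bp)
            if hi > lo:
                total += hi - lo
    return total / 1e6
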