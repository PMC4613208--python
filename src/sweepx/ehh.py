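"""Extended haplotype homozygosity (EHH) and the integrated haplotype
score (iHS) within one population.

EHH at a flanking SNP is the probability that two randomly drawn
haplotypes carrying the same core allele are identical at every SNP
between the core and that flank (both inclusive).  Integrating EHH over
physical distance on both sides of the core gives iHH, computed
separately for carriers of the ancestral (iHH_A) and derived (iHH_D)
allele.  The unstandardized score is ln(iHH_A / iHH_D); under a sweep
the derived haplotype stays long, iHH_D inflates, and the score goes
strongly negative.  Scores are z-standardized within derived-allele
frequency bins, which removes the well-known frequency dependence of
the log-ratio; the companion value P_iHS = -log10 of the two-sided
Gaussian tail probability of the standardized score.

Integration is over bp (chip data carries no genetic map), stops once
EHH decays below a cutoff (default 0.05), and truncates at inter-SNP
gaps larger than 500 kb, flagging the SNP rather than dropping it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .types import HaplotypeMatrix, PopulationMap, SNPMap

__all__ = [
    "EHHCurve",
    "IhsResult",
    "derived_matrix",
    "ehh_side",
    "integrate_ehh",
    "raw_ihs",
    "standardize_ihs",
    "ihs_scan",
]


@dataclass
class EHHCurve:
    """One side of an EHH decay curve around a core SNP.

    ``distances`` are signed bp offsets from the core (the first entry
    is always 0 with EHH 1); ``ehh`` is non-increasing in |distance|.
    """

    core: int
    allele: str  # "ancestral" | "derived"
    distances: np.ndarray
    ehh: np.ndarray
    available: bool = True

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.int64)
        self.ehh = np.asarray(self.ehh, dtype=float)


@dataclass
class IhsResult:
    snp_id: str
    derived_freq: float
    ihh_a: float
    ihh_d: float
    raw: float  # nan when undefined
    ihs: float = math.nan
    p_ihs: float = math.nan
    flags: set[str] = field(default_factory=set)


def derived_matrix(
    H: HaplotypeMatrix, snp_map: SNPMap
) -> tuple[np.ndarray, np.ndarray]:
    """Re-polarize 0/1 alt-indicator haplotypes to 0=ancestral/1=derived.

    Returns (matrix, usable) where ``usable`` marks SNPs with a resolved
    ancestral allele; columns of unresolved SNPs are left as alt
    indicators and must be excluded from core-SNP use by the caller.
    """
    anc = snp_map.table["ancestral"].to_numpy()
    usable = anc != "unknown"
    D = H.values.copy()
    flip = anc == "alt"  # ancestral is alt => derived is ref
    D[:, flip] = 1 - D[:, flip]
    return D, usable


def ehh_side(
    D: np.ndarray,
    positions: np.ndarray,
    core: int,
    allele_value: int,
    side: str,
    flank_end: int | None = None,
    stop_below: float = 0.0,
) -> EHHCurve:
    """EHH curve on one side of the core among carriers of one allele.

    ``D`` is the population's haplotype matrix (rows=haplotypes) in
    ancestral/derived coding; ``allele_value`` selects the carrier set
    at the core.  The curve starts at the core (distance 0, EHH 1) and
    extends one point per flanking SNP up to ``flank_end`` (inclusive
    index; default chromosome end).  With ``stop_below`` > 0 the walk
    ends at the first point whose EHH drops below it (that point is
    still recorded, so downstream integration can apply its cutoff).
    """
    if side not in {"left", "right"}:
        raise ValueError(f"side must be left/right, got {side!r}")
    carriers = np.flatnonzero(D[:, core] == allele_value)
    n_c = carriers.size
    if n_c < 2:
        return EHHCurve(core, "", np.array([0]), np.array([1.0]),
                        available=False)
    pairs_total = n_c * (n_c - 1) // 2
    step = -1 if side == "left" else 1
    if flank_end is None:
        flank_end = 0 if side == "left" else D.shape[1] - 1
    sub = D[carriers, :]
    labels = np.zeros(n_c, dtype=np.int64)
    dists = [0]
    ehh_vals = [1.0]
    s = core
    while s != flank_end:
        s += step
        key = labels * 2 + sub[:, s]
        _, labels = np.unique(key, return_inverse=True)
        counts = np.bincount(labels)
        ehh = float((counts * (counts - 1) // 2).sum() / pairs_total)
        dists.append(int(positions[s] - positions[core]))
        ehh_vals.append(ehh)
        if ehh < stop_below or ehh == 0.0:
            break
    return EHHCurve(core, "", np.array(dists), np.array(ehh_vals))


def integrate_ehh(
    curve: EHHCurve,
    ehh_cutoff: float = 0.05,
    max_gap_bp: int = 500_000,
) -> tuple[float, set[str]]:
    """Trapezoidal integral of one EHH side over physical distance.

    Integration stops at the first point with EHH < ``ehh_cutoff``
    (excluded) and truncates at the last SNP before any inter-SNP gap
    larger than ``max_gap_bp`` (flag ``truncated_by_gap``).  Returns
    (integral in bp*EHH units, flags).
    """
    flags: set[str] = set()
    if not curve.available:
        return 0.0, {"unavailable"}
    d = np.abs(curve.distances.astype(np.int64))
    e = curve.ehh
    if len(d) <= 1:
        return 0.0, {"no_flank"}
    total = 0.0
    for i in range(1, len(d)):
        if e[i] < ehh_cutoff:
            break
        gap = d[i] - d[i - 1]
        if gap > max_gap_bp:
            flags.add("truncated_by_gap")
            break
        total += gap * (e[i] + e[i - 1]) / 2.0
    return total, flags


def raw_ihs(ihh_a: float, ihh_d: float) -> float:
    """ln(iHH_A / iHH_D); NaN when either integral is zero."""
    if ihh_a <= 0.0 or ihh_d <= 0.0:
        return math.nan
    return math.log(ihh_a / ihh_d)


def _bin_index(freq: np.ndarray, bin_width: float) -> np.ndarray:
    """Derived-frequency bin index on [0.05, 0.95]; right edge closed."""
    idx = np.floor((freq - 0.05) / bin_width).astype(int)
    n_bins = max(1, int(round(0.90 / bin_width)))
    return np.clip(idx, 0, n_bins - 1)


def standardize_ihs(
    raws: np.ndarray,
    derived_freq: np.ndarray,
    bin_width: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Z-standardize raw scores within derived-frequency bins.

    Bins are [0.05, 0.05 + w), ..., closing at 0.95; ``bin_width=1.0``
    collapses everything into a single bin (global standardization).
    Bins with fewer than two finite raws, or zero spread, yield NaN with
    a warning.  Returns (ihs, p_ihs) with
    p_ihs = -log10(2 * (1 - Phi(|ihs|))).
    """
    raws = np.asarray(raws, dtype=float)
    freq = np.asarray(derived_freq, dtype=float)
    ihs = np.full_like(raws, np.nan)
    finite = np.isfinite(raws) & np.isfinite(freq)
    bins = _bin_index(freq, bin_width)
    for b in np.unique(bins[finite]):
        sel = finite & (bins == b)
        vals = raws[sel]
        if vals.size < 2:
            warnings.warn(
                f"frequency bin {b}: {vals.size} scores, cannot "
                "standardize; set to NA",
                stacklevel=2,
            )
            continue
        sd = vals.std(ddof=1)
        if sd == 0.0:
            warnings.warn(
                f"frequency bin {b}: zero spread; set to NA", stacklevel=2
            )
            continue
        ihs[sel] = (vals - vals.mean()) / sd
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 2.0 * norm.sf(np.abs(ihs))
        p_ihs = -np.log10(p)
    return ihs, p_ihs


def ihs_scan(
    H: HaplotypeMatrix,
    snp_map: SNPMap,
    pops: PopulationMap | None = None,
    population: str | None = None,
    min_maf: float = 0.05,
    ehh_cutoff: float = 0.05,
    max_gap_bp: int = 500_000,
    bin_width: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP iHS over one population.

    Cores with an unresolved ancestral allele or a derived frequency
    outside [``min_maf``, 1 - ``min_maf``] are reported as NA.  Raises
    if no SNP yields a defined raw score (e.g. a single-sample panel).
    """
    if pops is not None and population is not None:
        idx = pops.indices_in(H.samples, population)
        if idx.size == 0:
            raise ValueError(f"no samples in population {population!r}")
        H = H.subset_samples(idx)
    D, usable = derived_matrix(H, snp_map)
    positions = snp_map.positions
    n_snps = snp_map.n_snps

    results: list[IhsResult] = []
    for j in range(n_snps):
        sid = snp_map.table["snp_id"].iat[j]
        if not usable[j]:
            results.append(
                IhsResult(sid, math.nan, math.nan, math.nan, math.nan,
                          flags={"no_ancestral"})
            )
            continue
        f = float(D[:, j].mean())
        res = IhsResult(sid, f, math.nan, math.nan, math.nan)
        if f < min_maf or f > 1.0 - min_maf:
            res.flags.add("freq_out_of_range")
            results.append(res)
            continue
        ihh = {}
        for allele_value, name in ((0, "a"), (1, "d")):
            total = 0.0
            for side in ("left", "right"):
                curve = ehh_side(
                    D, positions, j, allele_value, side,
                    stop_below=ehh_cutoff,
                )
                part, fl = integrate_ehh(curve, ehh_cutoff, max_gap_bp)
                total += part
                res.flags |= fl - {"no_flank"}
            ihh[name] = total
        res.ihh_a, res.ihh_d = ihh["a"], ihh["d"]
        res.raw = raw_ihs(res.ihh_a, res.ihh_d)
        results.append(res)

    raws = np.array([r.raw for r in results])
    freqs = np.array([r.derived_freq for r in results])
    if not np.isfinite(raws).any():
        raise ValueError("no eligible SNPs for iHS in this population")
    ihs, p_ihs = standardize_ihs(raws, freqs, bin_width)
    for r, z, p in zip(results, ihs, p_ihs):
        r.ihs, r.p_ihs = float(z), float(p)

    return pd.DataFrame(
        {
            "chrom": snp_map.table["chrom"],
            "pos": snp_map.table["pos"],
            "snp_id": [r.snp_id for r in results],
            "derived_freq": freqs,
            "ihh_a": [r.ihh_a for r in results],
            "ihh_d": [r.ihh_d for r in results],
            "raw_ihs": raws,
            "ihs": ihs,
            "p_ihs": p_ihs,
            "flags": [",".join(sorted(r.flags)) for r in results],
        }
    )
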