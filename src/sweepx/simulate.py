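"""Synthetic phased haplotype panels with known ground truth.

The generator emulates a medium-density chip panel on one long
chromosome: a few populations of modest size, ~1,200 SNPs over
~135 Mb, known ancestral alleles, Balding-Nichols differentiation at a
configurable background level plus a handful of strongly differentiated
loci, and an injected hard sweep (one high-frequency derived allele on
a long shared haplotype).

Neutral background: per SNP an ancestral derived-allele frequency
p ~ U(0.05, 0.95); each population draws its own frequency from
Beta(p (1-F)/F, (1-p) (1-F)/F), whose expected F_ST is approximately F.
Haplotypes are recombinant mosaics of per-population founder
haplotypes with Poisson crossovers along the chromosome, so linkage —
and hence EHH — decays with physical distance.  The sweep is injected
by copying one derived-carrier donor haplotype over a window around the
core into randomly chosen haplotypes until the target frequency is
reached, which guarantees the long-shared-haplotype contrast that iHS
detects while leaving the rest of the chromosome untouched.

This is not a coalescent simulator: there is no demographic history,
no recombination-rate variation, and no genotyping-error model beyond
uniform missingness in :func:`degrade`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    GenotypeMatrix,
    HaplotypeMatrix,
    PopulationMap,
    SNPMap,
)

__all__ = [
    "SimulationConfig",
    "SweepTruth",
    "simulate_neutral",
    "inject_sweep",
    "simulate_panel",
    "degrade",
    "write_panel",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Panel geometry and truth parameters.

    Defaults mirror the ovine X-chromosome chip panel the pipeline is
    designed for: three ewe populations of 89/47/12, 1,200 SNPs over
    135.18 Mb (~110 kb spacing), a diffuse background differentiation
    of F = 0.05 with five strongly differentiated loci at F = 0.5, and
    one hard sweep to derived-allele frequency 0.8 over a 1 Mb span in
    the first (largest) population.
    """

    seed: int = 0
    pop_names: tuple[str, ...] = ("GM", "D", "S")
    n_samples: tuple[int, ...] = (89, 47, 12)
    n_snps: int = 1200
    chrom: str = "X"
    chrom_length_bp: int = 135_180_000
    background_f: float = 0.05
    n_differentiated_loci: int = 5
    differentiated_f: float = 0.5
    n_founders: int = 20
    crossover_rate_per_bp: float = 1e-7
    sweep_population: str | None = "GM"  # None disables the sweep
    sweep_target_freq: float = 0.8
    sweep_span_bp: int = 1_000_000
    sweep_core_pos: int | None = None  # None: drawn away from the ends
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if len(self.pop_names) != len(self.n_samples):
            raise ValueError("pop_names and n_samples length mismatch")
        if self.n_snps < 10:
            raise ValueError("n_snps must be >= 10")
        if not (0.0 <= self.background_f < 1.0):
            raise ValueError("background_f must lie in [0, 1)")
        if self.background_f == 0.0 and self.n_differentiated_loci > 0:
            raise ValueError(
                "differentiated loci need background_f > 0 (the neutral "
                "F = 0 panel has no between-population drift model)"
            )


@dataclass
class SweepTruth:
    """Ground truth of a simulated panel."""

    focal_snp: str | None = None
    focal_pos: int | None = None
    sweep_population: str | None = None
    target_freq: float | None = None
    achieved_freq: float | None = None
    differentiated_loci: list[dict] = field(default_factory=list)
    #: generating per-population derived-allele frequencies (in-memory
    #: only; not serialized)
    generating_freqs: dict | None = field(default=None, compare=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            k: v for k, v in self.__dict__.items()
            if k != "generating_freqs"
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SweepTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sample_positions(
    rng: np.random.Generator, n: int, length: int
) -> np.ndarray:
    """n distinct sorted positions in [1, length]."""
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=2 * n))
    while pos.size < n:
        pos = np.unique(
            np.concatenate([pos, rng.integers(1, length + 1, size=n)])
        )
    return np.sort(rng.choice(pos, size=n, replace=False))


def _balding_nichols(
    rng: np.random.Generator, p: np.ndarray, f: float
) -> np.ndarray:
    """Subpopulation frequencies around ancestral p at differentiation f."""
    if f == 0.0:
        return p.copy()
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    return rng.beta(a, b)


def _mosaic_haplotypes(
    rng: np.random.Generator,
    founders: np.ndarray,  # (n_founders, n_snps)
    positions: np.ndarray,
    n_haplotypes: int,
    crossover_rate: float,
    length: int,
) -> np.ndarray:
    out = np.empty((n_haplotypes, founders.shape[1]), dtype=np.int8)
    for h in range(n_haplotypes):
        k = rng.poisson(crossover_rate * length)
        breaks = np.sort(rng.integers(1, length + 1, size=k))
        seg = np.searchsorted(breaks, positions, side="right")
        choice = rng.integers(0, founders.shape[0], size=k + 1)
        out[h] = founders[choice[seg], np.arange(founders.shape[1])]
    return out


def simulate_neutral(
    cfg: SimulationConfig,
) -> tuple[SNPMap, HaplotypeMatrix, PopulationMap, SweepTruth]:
    """Generate the neutral (no-sweep) differentiated panel.

    Returns the marker map (ancestral alleles recorded as truth), the
    phased panel in alt-indicator coding, the population map, and a
    truth record listing the strongly differentiated loci.  Identical
    seed and config give bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    positions = _sample_positions(rng, cfg.n_snps, cfg.chrom_length_bp)

    p_anc = rng.uniform(0.05, 0.95, size=cfg.n_snps)
    n_pops = len(cfg.pop_names)
    pop_freqs = np.stack(
        [_balding_nichols(rng, p_anc, cfg.background_f)
         for _ in range(n_pops)]
    )  # (n_pops, n_snps) derived-allele frequency

    truth = SweepTruth()
    if cfg.n_differentiated_loci > 0:
        # keep strongly differentiated loci clear of the chromosome ends
        margin = cfg.chrom_length_bp // 20
        interior = np.flatnonzero(
            (positions > margin) & (positions < cfg.chrom_length_bp - margin)
        )
        diff_idx = np.sort(
            rng.choice(interior, size=cfg.n_differentiated_loci,
                       replace=False)
        )
        # Chosen loci must be *reliably* differentiated (they are the
        # ground truth a scan is scored against), so instead of another
        # Balding-Nichols draw — whose realized spread has huge variance
        # — the population frequencies are displaced deterministically:
        # p_i = p + c_i * sqrt(F p (1-p)) with contrasts c_i of mean 0
        # and variance 1 under the population-size weights (the
        # weighting the H_T/H_S estimator uses), randomly permuted
        # across populations.  The realized weighted between-population
        # variance then equals the Balding-Nichols value F p (1-p),
        # i.e. per-locus F_ST ~ F up to sampling noise and clipping.
        w = np.asarray(cfg.n_samples, dtype=float)
        w /= w.sum()
        base = np.arange(n_pops, dtype=float)
        for j in diff_idx:
            c = rng.permutation(base)
            c = c - (w * c).sum()
            c /= np.sqrt((w * c * c).sum())
            sd = np.sqrt(cfg.differentiated_f * p_anc[j] * (1 - p_anc[j]))
            pop_freqs[:, j] = np.clip(p_anc[j] + c * sd, 0.01, 0.99)
        truth.differentiated_loci = [
            {"snp_id": f"snp{j:05d}", "pos": int(positions[j]),
             "f": cfg.differentiated_f}
            for j in diff_idx
        ]

    # founders then mosaics, in derived-allele coding
    blocks = []
    assignments: dict[str, str] = {}
    samples: list[str] = []
    for i, (name, n) in enumerate(zip(cfg.pop_names, cfg.n_samples)):
        founders = (
            rng.random((cfg.n_founders, cfg.n_snps)) < pop_freqs[i]
        ).astype(np.int8)
        haps = _mosaic_haplotypes(
            rng, founders, positions, 2 * n,
            cfg.crossover_rate_per_bp, cfg.chrom_length_bp,
        )
        blocks.append(haps)
        for s in range(n):
            sid = f"{name}_{s:03d}"
            samples.append(sid)
            assignments[sid] = name
    derived = np.vstack(blocks)

    # random ref/alt orientation: derived may be either allele
    anc_is_ref = rng.random(cfg.n_snps) < 0.5
    ref = np.empty(cfg.n_snps, dtype="U1")
    alt = np.empty(cfg.n_snps, dtype="U1")
    base_pair = rng.integers(0, 4, size=(cfg.n_snps, 2))
    base_pair[:, 1] = (base_pair[:, 0] + 1 + base_pair[:, 1] % 3) % 4
    ref[:] = _BASES[base_pair[:, 0]]
    alt[:] = _BASES[base_pair[:, 1]]
    # alt-indicator values: where ancestral is ref, derived==alt => keep;
    # where ancestral is alt, derived==ref => flip
    values = np.where(anc_is_ref[None, :], derived, 1 - derived).astype(
        np.int8
    )
    snp_map = SNPMap(
        pd.DataFrame(
            {
                "snp_id": [f"snp{j:05d}" for j in range(cfg.n_snps)],
                "chrom": cfg.chrom,
                "pos": positions,
                "ref": ref,
                "alt": alt,
                "ancestral": np.where(anc_is_ref, "ref", "alt"),
            }
        )
    )
    H = HaplotypeMatrix(samples, values)
    truth.generating_freqs = {
        name: pop_freqs[i].tolist()
        for i, name in enumerate(cfg.pop_names)
    }
    return snp_map, H, PopulationMap(assignments), truth


def inject_sweep(
    H: HaplotypeMatrix,
    snp_map: SNPMap,
    pops: PopulationMap,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    truth: SweepTruth | None = None,
) -> tuple[HaplotypeMatrix, SweepTruth]:
    """Overwrite haplotypes around a core SNP with one donor haplotype.

    Randomly chosen haplotypes of the sweep population are replaced,
    over the sweep span centered on the core, with copies of a donor
    carrying the derived core allele, until the derived frequency
    reaches the target.  Haplotypes outside the window are untouched.
    """
    truth = truth or SweepTruth()
    if cfg.sweep_population is None:
        return H, truth
    if cfg.sweep_population not in pops.populations:
        raise KeyError(f"unknown sweep population {cfg.sweep_population!r}")
    positions = snp_map.positions
    idx_pop = pops.indices_in(H.samples, cfg.sweep_population)
    pop_rows = np.column_stack([2 * idx_pop, 2 * idx_pop + 1]).ravel()
    anc_col = snp_map.table["ancestral"].to_numpy()
    derived_vals = np.where(
        anc_col == "ref", H.values[pop_rows, :], 1 - H.values[pop_rows, :]
    )
    cur_freq = derived_vals.mean(axis=0)
    if cfg.sweep_core_pos is None:
        # a sweep raises the derived frequency, so the core must start
        # below the target; also stay clear of the chromosome ends
        margin = max(cfg.sweep_span_bp, cfg.chrom_length_bp // 20)
        interior = np.flatnonzero(
            (positions > margin)
            & (positions < cfg.chrom_length_bp - margin)
            & (cur_freq < cfg.sweep_target_freq)
        )
        if interior.size == 0:
            raise ValueError("no eligible core SNP for the sweep")
        core = int(rng.choice(interior))
    else:
        core = int(np.argmin(np.abs(positions - cfg.sweep_core_pos)))

    half = cfg.sweep_span_bp // 2
    lo = positions[core] - half
    hi = positions[core] + half
    if lo < 1 or hi > cfg.chrom_length_bp:
        import warnings

        warnings.warn("sweep span clipped at the chromosome end",
                      stacklevel=2)
    window = np.flatnonzero((positions >= lo) & (positions <= hi))

    idx = pops.indices_in(H.samples, cfg.sweep_population)
    rows = np.column_stack([2 * idx, 2 * idx + 1]).ravel()
    values = H.values.copy()

    anc = snp_map.table["ancestral"].iat[core]
    derived_allele = 1 if anc == "ref" else 0  # alt-indicator of derived
    ancestral_allele = 1 - derived_allele
    carriers = rows[values[rows, core] == derived_allele]
    if carriers.size == 0:
        donor = int(rng.choice(rows))
        values[donor, core] = derived_allele
    else:
        donor = int(rng.choice(carriers))

    target_count = int(round(cfg.sweep_target_freq * rows.size))
    current_freq = carriers.size / rows.size
    if target_count < 1 or cfg.sweep_target_freq <= current_freq:
        raise ValueError(
            f"target frequency {cfg.sweep_target_freq} not above current "
            f"derived frequency {current_freq:.3f}"
        )
    # In a hard sweep every derived carrier descends from the haplotype
    # the mutation arose on, so the final carrier set is exactly the
    # donor plus randomly chosen recipients of its window; haplotypes
    # outside that set revert to the ancestral core allele (their flanks
    # are untouched).  This pins the achieved frequency and makes EHH
    # among derived carriers equal 1 across the span.
    others = rows[rows != donor]
    chosen = rng.choice(others, size=target_count - 1, replace=False)
    sweep_set = np.concatenate([[donor], chosen])
    values[np.ix_(sweep_set, window)] = values[donor, window]
    outside = np.setdiff1d(rows, sweep_set)
    values[outside, core] = ancestral_allele

    achieved = float(
        (values[rows, core] == derived_allele).sum() / rows.size
    )
    truth.focal_snp = snp_map.table["snp_id"].iat[core]
    truth.focal_pos = int(positions[core])
    truth.sweep_population = cfg.sweep_population
    truth.target_freq = cfg.sweep_target_freq
    truth.achieved_freq = achieved
    return HaplotypeMatrix(list(H.samples), values), truth


def simulate_panel(
    cfg: SimulationConfig,
) -> tuple[SNPMap, HaplotypeMatrix, PopulationMap, SweepTruth]:
    """Neutral panel plus the configured sweep, in one call."""
    snp_map, H, pops, truth = simulate_neutral(cfg)
    if cfg.sweep_population is not None:
        # independent stream so the background does not shift with
        # sweep settings
        rng = np.random.default_rng([cfg.seed, 1])
        H, truth = inject_sweep(H, snp_map, pops, cfg, rng, truth)
    return snp_map, H, pops, truth


def degrade(
    data: HaplotypeMatrix | GenotypeMatrix,
    missing_rate: float,
    rng: np.random.Generator,
    unphase: bool = True,
) -> GenotypeMatrix:
    """Collapse to genotypes and mask entries missing at random."""
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    G = data.to_genotypes() if isinstance(data, HaplotypeMatrix) else data
    if not unphase and isinstance(data, HaplotypeMatrix):
        raise ValueError("cannot keep phase in a GenotypeMatrix")
    values = G.values.copy()
    if missing_rate > 0.0:
        mask = rng.random(values.shape) < missing_rate
        values[mask] = MISSING
    return GenotypeMatrix(list(G.samples), values)


def write_panel(
    out_dir: str | Path,
    snp_map: SNPMap,
    H: HaplotypeMatrix,
    pops: PopulationMap,
    truth: SweepTruth,
    chrom_length: int | None = None,
) -> dict[str, Path]:
    """Write VCF + population TSV + truth JSON into a directory."""
    from . import io as sio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "panel.vcf",
        "populations": out / "populations.tsv",
        "truth": out / "truth.json",
    }
    sio.write_vcf(paths["vcf"], snp_map, H, chrom_length)
    sio.write_population_table(pops, paths["populations"])
    truth.to_json(paths["truth"])
    return paths
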