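"""End-to-end orchestration: QC -> iHS per population -> F_ST scans ->
outliers -> regions -> combination -> summary -> annotation.

One chromosome per run.  Every stage writes its artifact under the run
directory with fixed names, and a provenance file records the full
configuration so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import annotate as anno
from . import ehh, fst, io as sio, qc, regions as reg
from .types import PopulationMap, SelectionRegion, SNPMap

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Flat, serializable configuration for one pipeline run.

    Defaults equal the per-module defaults; the config round-trips
    through the key=value text format unchanged.
    """

    vcf: str = ""
    populations: str = ""
    genes: str = ""  # optional; empty skips annotation
    ancestral_table: str = ""  # optional snp_id<TAB>base TSV
    out_dir: str = "sweepx_run"
    seed: int = 0
    # QC
    sample_min_call_rate: float = 0.90
    duplicate_ibs: float = 0.99
    snp_min_call_rate: float = 0.90
    min_maf: float = 0.05
    hwe_p_min: float = 1e-6
    # iHS
    ancestral_fallback: str = "major_allele"
    ehh_cutoff: float = 0.05
    max_gap_bp: int = 500_000
    bin_width: float = 0.05
    ihs_threshold: float = 2.0
    # regions
    half_width_bp: int = 200_000
    pad_bp: int = 100_000
    combine_mode: str = "threshold"
    chrom_length_bp: int = 0  # 0: max position

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = raw.lower() in {"1", "true", "yes"}
            elif isinstance(current, int):
                kwargs[key] = int(raw)
            elif isinstance(current, float):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
        return cls(**kwargs)


@dataclass
class PipelineResult:
    out_dir: Path
    snp_map: SNPMap
    pops: PopulationMap
    ihs_tracks: dict[str, pd.DataFrame]
    fst_tracks: dict[str, pd.DataFrame]
    ihs_regions: dict[str, list[SelectionRegion]]
    fst_regions: dict[str, list[SelectionRegion]]
    combined_regions: dict[str, list[SelectionRegion]]
    summary: pd.DataFrame
    overlaps: pd.DataFrame
    gene_report: pd.DataFrame | None = None
    qc_report: qc.QCReport | None = None


def _read_ancestral_table(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run every stage on a phased VCF panel; see module docstring."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---------------------------------------------------------- load
    snp_map, G, H = sio.read_vcf(cfg.vcf, require_phased=True)
    if H is None:
        raise RuntimeError(
            "stage 'load' failed: panel is not fully phased/complete; "
            "phase and impute upstream"
        )
    pops = sio.read_population_table(cfg.populations).restrict(G.samples)

    # ------------------------------------------------------------ QC
    G1, sample_report = qc.filter_samples(
        G, cfg.sample_min_call_rate, cfg.duplicate_ibs
    )
    keep_samples = [G.samples.index(s) for s in G1.samples]
    pops = pops.restrict(G1.samples)
    G2, snp_map2, snp_report = qc.filter_snps(
        G1, snp_map, pops, cfg.snp_min_call_rate, cfg.min_maf,
        cfg.hwe_p_min,
    )
    keep_snps = [snp_map.snp_ids.index(s) for s in snp_map2.snp_ids]
    H = H.subset_samples(np.array(keep_samples)).subset_snps(
        np.array(keep_snps)
    )
    report = qc.QCReport(
        samples_removed=sample_report.samples_removed,
        snps_removed=snp_report.snps_removed,
        thresholds={**sample_report.thresholds, **snp_report.thresholds},
    )
    report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    logger.info(
        "QC: %d samples and %d SNPs removed; %d x %d panel remains",
        len(report.samples_removed), len(report.snps_removed),
        G2.n_samples, G2.n_snps,
    )

    coords = qc.pca_coordinates(G2)
    coords.insert(0, "population",
                  [pops.label_of(s) for s in coords.index])
    coords.to_csv(out / "pca.tsv", sep="\t")

    # ------------------------------------------------ ancestral state
    table = (
        _read_ancestral_table(cfg.ancestral_table)
        if cfg.ancestral_table
        else None
    )
    snp_map2 = sio.set_ancestral(
        snp_map2, table, cfg.ancestral_fallback, G2
    )

    chrom_length = cfg.chrom_length_bp or int(snp_map2.positions.max())

    # ----------------------------------------------------------- iHS
    ihs_tracks: dict[str, pd.DataFrame] = {}
    ihs_regions: dict[str, list[SelectionRegion]] = {}
    n_outliers: dict[tuple[str, str], int] = {}
    for pop_label in pops.populations:
        track = ehh.ihs_scan(
            H, snp_map2, pops, pop_label,
            min_maf=cfg.min_maf, ehh_cutoff=cfg.ehh_cutoff,
            max_gap_bp=cfg.max_gap_bp, bin_width=cfg.bin_width,
        )
        ihs_tracks[pop_label] = track
        sio.write_score_track(track, out / f"ihs_{pop_label}.tsv")
        outl = reg.ihs_outliers(track, cfg.ihs_threshold)
        n_outliers[("ihs", pop_label)] = len(outl)
        ihs_regions[pop_label] = reg.build_regions(
            outl, snp_map2, "ihs", "ihs", pop_label,
            cfg.half_width_bp, chrom_length,
        )

    # ---------------------------------------------------------- F_ST
    fst_tracks: dict[str, pd.DataFrame] = {}
    fst_regions: dict[str, list[SelectionRegion]] = {}
    subsets = [list(pops.populations)] + [
        list(pair) for pair in combinations(pops.populations, 2)
    ]
    for subset in subsets:
        scan_label = "-".join(subset)
        track = fst.fst_scan(H, snp_map2, pops, subset)
        fst_tracks[scan_label] = track
        sio.write_score_track(track, out / f"fst_{scan_label}.tsv")
        vals = track["fst"].to_numpy(dtype=float)
        thr, mask = reg.boxplot_outliers(vals)
        # only the upper tail marks diversifying selection
        upper = mask & (vals > thr.ul)
        outl = track[upper]
        n_outliers[("fst", scan_label)] = len(outl)
        fst_regions[scan_label] = reg.build_regions(
            outl, snp_map2, "fst", "fst", scan_label,
            cfg.half_width_bp, chrom_length,
        )

    # ------------------------------------------------------- combine
    joint_label = "-".join(pops.populations)
    combined: dict[str, list[SelectionRegion]] = {}
    for pop_label in pops.populations:
        combined[pop_label] = reg.combine_candidates(
            ihs_regions[pop_label],
            fst_regions[joint_label],
            mode=cfg.combine_mode,
            ihs_track=ihs_tracks[pop_label],
            fst_track=fst_tracks[joint_label],
            label=pop_label,
        )

    # ------------------------------------------------------- summary
    regions_by_key: dict[tuple[str, str], list[SelectionRegion]] = {}
    for pop_label, regs in ihs_regions.items():
        regions_by_key[("ihs", pop_label)] = regs
    for scan_label, regs in fst_regions.items():
        regions_by_key[("fst", scan_label)] = regs
    for pop_label, regs in combined.items():
        regions_by_key[("combined", pop_label)] = regs
    summary = reg.summarize_regions(regions_by_key, n_outliers)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False, na_rep="NA")

    overlap_rows = []
    for a, b in combinations(pops.populations, 2):
        overlap_rows.append(
            {
                "label_a": a,
                "label_b": b,
                "overlap_mb": round(
                    reg.overlap_length_mb(combined[a], combined[b]), 2
                ),
            }
        )
    overlaps = pd.DataFrame(
        overlap_rows, columns=["label_a", "label_b", "overlap_mb"]
    )
    overlaps.to_csv(out / "overlaps.tsv", sep="\t", index=False)

    all_regions = [r for regs in regions_by_key.values() for r in regs]
    sio.write_regions_bed(all_regions, out / "regions.bed")
    sio.write_regions_tsv(all_regions, out / "regions.tsv")

    # ---------------------------------------------------- annotation
    gene_report = None
    if cfg.genes:
        genes = sio.read_gene_models(cfg.genes)
        candidates = [r for regs in combined.values() for r in regs]
        gene_report = anno.genes_in_regions(candidates, genes, cfg.pad_bp)
        gene_report.to_csv(out / "genes.tsv", sep="\t", index=False)
    else:
        logger.info("no gene-model file configured; annotation skipped")

    # ---------------------------------------------------- provenance
    with open(out / "provenance.json", "w") as fh:
        json.dump(
            {
                "sweepx_version": __version__,
                "config": dataclasses.asdict(cfg),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    cfg.to_file(out / "config.txt")

    return PipelineResult(
        out_dir=out,
        snp_map=snp_map2,
        pops=pops,
        ihs_tracks=ihs_tracks,
        fst_tracks=fst_tracks,
        ihs_regions=ihs_regions,
        fst_regions=fst_regions,
        combined_regions=combined,
        summary=summary,
        overlaps=overlaps,
        gene_report=gene_report,
        qc_report=report,
    )
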