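"""Readers and writers for the formats the scan touches.

VCF (via cyvcf2), PLINK PED/MAP text, population tables, TSV score
tracks, BED region export and a minimal phased-VCF writer for simulated
panels.  Internal coordinates are 1-based; BED output is 0-based
half-open, converted only here.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    GenotypeMatrix,
    HaplotypeMatrix,
    PopulationMap,
    SelectionRegion,
    SNPMap,
)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_ped_map",
    "read_population_table",
    "write_population_table",
    "set_ancestral",
    "write_score_track",
    "read_score_track",
    "write_regions_bed",
    "write_regions_tsv",
    "read_gene_models",
]


# ---------------------------------------------------------------- VCF

def read_vcf(
    path: str | Path, require_phased: bool = False
) -> tuple[SNPMap, GenotypeMatrix, HaplotypeMatrix | None]:
    """Load biallelic SNP records for one chromosome from a VCF.

    Returns the marker map, the dosage matrix and — when every genotype
    is phased and complete — the haplotype matrix (``None`` otherwise).
    The ancestral allele is taken from the ``AA`` INFO tag when present
    and interpretable, else left ``unknown``.

    Raises ``ValueError`` on multiallelic records, non-SNP alleles,
    unsorted positions, more than one chromosome, or (with
    ``require_phased``) any unphased genotype.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    geno_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    all_phased_complete = True

    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {v.CHROM}:{v.POS} ({v.ID or '.'}); "
                "only biallelic SNPs are supported"
            )
        ref, alt = v.REF, v.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            raise ValueError(
                f"non-SNP alleles {ref}/{alt} at {v.CHROM}:{v.POS}"
            )
        aa = v.INFO.get("AA")
        if aa is not None:
            aa = str(aa).upper()
            ancestral = (
                "ref" if aa == ref.upper()
                else "alt" if aa == alt.upper()
                else "unknown"
            )
        else:
            ancestral = "unknown"
        rows.append(
            {
                "snp_id": v.ID or f"{v.CHROM}_{v.POS}",
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": ref,
                "alt": alt,
                "ancestral": ancestral,
            }
        )

        g = np.full(len(samples), MISSING, dtype=np.int8)
        h = np.full(2 * len(samples), -1, dtype=np.int8)
        for i, gt in enumerate(v.genotypes):  # [a0, a1, phased]
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 or a1 < 0:
                all_phased_complete = False
                continue
            g[i] = a0 + a1
            if not phased:
                if require_phased:
                    raise ValueError(
                        f"unphased genotype for sample {samples[i]} at "
                        f"{v.CHROM}:{v.POS} but phased input was required"
                    )
                all_phased_complete = False
                continue
            h[2 * i] = a0
            h[2 * i + 1] = a1
        geno_cols.append(g)
        hap_cols.append(h)

    if not rows:
        raise ValueError(f"no SNP records in {path}")
    table = pd.DataFrame(rows)
    if table["chrom"].nunique() > 1:
        raise ValueError(
            f"multiple chromosomes in {path}: "
            f"{sorted(table['chrom'].unique())}; one chromosome per run"
        )
    snp_map = SNPMap(table)  # raises on unsorted positions
    G = GenotypeMatrix(samples, np.column_stack(geno_cols))
    H = None
    if all_phased_complete:
        H = HaplotypeMatrix(samples, np.column_stack(hap_cols))
    return snp_map, G, H


def write_vcf(
    path: str | Path,
    snp_map: SNPMap,
    H: HaplotypeMatrix,
    chrom_length: int | None = None,
) -> None:
    """Write a phased VCF 4.2 with AA INFO tags from a haplotype panel."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=AA,Number=1,Type=String,'
            'Description="Ancestral allele">\n'
        )
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        if chrom_length is not None:
            fh.write(
                f"##contig=<ID={snp_map.chrom},length={chrom_length}>\n"
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(H.samples)
            + "\n"
        )
        t = snp_map.table
        for j in range(snp_map.n_snps):
            anc = t["ancestral"].iat[j]
            ref, alt = t["ref"].iat[j], t["alt"].iat[j]
            info = "."
            if anc == "ref":
                info = f"AA={ref}"
            elif anc == "alt":
                info = f"AA={alt}"
            gts = "\t".join(
                f"{H.values[2 * i, j]}|{H.values[2 * i + 1, j]}"
                for i in range(H.n_samples)
            )
            fh.write(
                f"{t['chrom'].iat[j]}\t{t['pos'].iat[j]}\t"
                f"{t['snp_id'].iat[j]}\t{ref}\t{alt}\t.\t.\t{info}\tGT\t"
                f"{gts}\n"
            )


# ------------------------------------------------------------ PED/MAP

def read_ped_map(
    ped_path: str | Path, map_path: str | Path
) -> tuple[SNPMap, GenotypeMatrix]:
    """Load PLINK text PED/MAP; alleles recoded to alt-allele dosage.

    The MAP file gives chrom, snp_id, cM, bp.  Alleles are assigned
    ref/alt by order of first appearance per SNP (first allele seen is
    ref); '0 0' is missing.
    """
    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(
                    f"{map_path}:{ln}: expected 4 MAP columns, "
                    f"got {len(parts)}"
                )
            map_rows.append(
                {
                    "snp_id": parts[1],
                    "chrom": parts[0],
                    "pos": int(parts[3]),
                    "ref": "?",
                    "alt": "?",
                    "ancestral": "unknown",
                }
            )
    n_snps = len(map_rows)

    samples: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_snps} columns "
                    f"(6 metadata + 2 alleles x {n_snps} SNPs), "
                    f"got {len(parts)}"
                )
            samples.append(parts[1])
            allele_rows.append(parts[6:])

    values = np.full((len(samples), n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        seen: list[str] = []
        for i, row in enumerate(allele_rows):
            a, b = row[2 * j], row[2 * j + 1]
            if a == "0" or b == "0":
                continue
            for al in (a, b):
                if al not in seen:
                    seen.append(al)
            if len(seen) > 2:
                raise ValueError(
                    f"SNP {map_rows[j]['snp_id']} has >2 alleles: {seen}"
                )
        if seen:
            map_rows[j]["ref"] = seen[0]
            map_rows[j]["alt"] = seen[1] if len(seen) > 1 else "N"
        else:
            map_rows[j]["ref"], map_rows[j]["alt"] = "N", "N2"
        alt = map_rows[j]["alt"]
        for i, row in enumerate(allele_rows):
            a, b = row[2 * j], row[2 * j + 1]
            if a == "0" or b == "0":
                continue
            values[i, j] = (a == alt) + (b == alt)

    table = pd.DataFrame(map_rows)
    order = np.argsort(table["pos"].to_numpy(), kind="stable")
    table = table.iloc[order].reset_index(drop=True)
    values = values[:, order]
    return SNPMap(table), GenotypeMatrix(samples, values)


# ------------------------------------------------- population tables

def read_population_table(path: str | Path) -> PopulationMap:
    """Two-column TSV (sample, population); a header line is optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (sample, population)")
    if df.iloc[0, 0].lower() in {"sample", "sample_id", "id"}:
        df = df.iloc[1:]
    return PopulationMap(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_population_table(pops: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\n")
        for s, p in pops.assignments.items():
            fh.write(f"{s}\t{p}\n")


# ----------------------------------------------------- ancestral state

def set_ancestral(
    snp_map: SNPMap,
    table: dict[str, str] | None = None,
    fallback: str = "major_allele",
    G: GenotypeMatrix | None = None,
) -> SNPMap:
    """Resolve the ancestral allele per SNP.

    ``table`` maps snp_id -> ancestral base; bases must match one of the
    SNP's alleles.  Remaining unknowns are set to the major allele
    across all samples (``fallback='major_allele'``, requires ``G``) or
    left unknown (``fallback='skip'``, excluded from iHS downstream).
    """
    if fallback not in {"major_allele", "skip"}:
        raise ValueError(f"unknown fallback {fallback!r}")
    t = snp_map.table.copy()
    if table:
        bad = []
        for j in range(len(t)):
            sid = t["snp_id"].iat[j]
            base = table.get(sid)
            if base is None:
                continue
            base = base.upper()
            if base == t["ref"].iat[j].upper():
                t.loc[j, "ancestral"] = "ref"
            elif base == t["alt"].iat[j].upper():
                t.loc[j, "ancestral"] = "alt"
            else:
                bad.append(sid)
        if bad:
            raise ValueError(
                f"ancestral base matches neither allele at: {bad[:10]}"
            )
    unknown = t["ancestral"] == "unknown"
    if fallback == "major_allele" and unknown.any():
        if G is None:
            raise ValueError(
                "fallback='major_allele' requires the genotype matrix"
            )
        warnings.warn(
            f"{int(unknown.sum())} SNPs lack ancestral information; "
            "falling back to the major allele",
            stacklevel=2,
        )
        called = G.called
        with np.errstate(invalid="ignore"):
            alt_freq = np.where(
                called.sum(axis=0) > 0,
                np.where(called, G.values, 0).sum(axis=0)
                / (2.0 * np.maximum(called.sum(axis=0), 1)),
                0.5,
            )
        # ties (freq exactly 0.5) resolve to ref, the reference state
        t.loc[unknown & (alt_freq > 0.5), "ancestral"] = "alt"
        t.loc[unknown & (alt_freq <= 0.5), "ancestral"] = "ref"
    return SNPMap(t)


# ------------------------------------------------------- score tracks

def write_score_track(track: pd.DataFrame, path: str | Path) -> None:
    """Write a per-SNP statistic table as TSV with literal NA."""
    track.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_score_track(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


# --------------------------------------------------------------- BED

def write_regions_bed(
    regions: list[SelectionRegion], path: str | Path
) -> None:
    """Write regions as 0-based half-open BED, name=method, score=peak."""
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tmethod\tpeak_value\tlabel\tpeak_snp\n")
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start_bp}\t{r.end_bp}\t{r.method}\t"
                f"{r.peak_value:.6g}\t{r.label}\t{r.peak_snp}\n"
            )


def write_regions_tsv(
    regions: list[SelectionRegion], path: str | Path
) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "start_bp": r.start_bp,
            "end_bp": r.end_bp,
            "length_mb": round(r.length_mb, 6),
            "method": r.method,
            "label": r.label,
            "peak_snp": r.peak_snp,
            "peak_value": r.peak_value,
            **r.extras,
        }
        for r in regions
    ]
    pd.DataFrame(
        rows,
        columns=[
            "chrom", "start_bp", "end_bp", "length_mb",
            "method", "label", "peak_snp", "peak_value",
        ] if not rows else None,
    ).to_csv(path, sep="\t", index=False, na_rep="NA")


# ------------------------------------------------------- gene models

def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Load gene intervals from BED or GFF3 into a DataFrame.

    Returns columns gene_id, gene_name, chrom, start_bp, end_bp, strand
    with 1-based inclusive coordinates.  GFF3: only ``gene``-type
    features are kept; BED: every record is a gene.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3", ".gtf"}:
        return _read_genes_gff3(path)
    return _read_genes_bed(path)


def _read_genes_bed(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            name = parts[3] if len(parts) > 3 else f"gene{ln}"
            rows.append(
                {
                    "gene_id": name,
                    "gene_name": name,
                    "chrom": parts[0],
                    "start_bp": int(parts[1]) + 1,  # BED is 0-based
                    "end_bp": int(parts[2]),
                    "strand": parts[5] if len(parts) > 5 else ".",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "gene_name", "chrom",
                 "start_bp", "end_bp", "strand"],
    )


def _read_genes_gff3(path: Path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.id
        name = feat.attributes.get("Name", [gid])[0]
        rows.append(
            {
                "gene_id": gid,
                "gene_name": name,
                "chrom": feat.seqid,
                "start_bp": feat.start,  # gffutils keeps 1-based inclusive
                "end_bp": feat.end,
                "strand": feat.strand or ".",
            }
        )
    rows.sort(key=lambda r: (r["chrom"], r["start_bp"]))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "gene_name", "chrom",
                 "start_bp", "end_bp", "strand"],
    )
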