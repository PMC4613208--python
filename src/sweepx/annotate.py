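"""Gene annotation of candidate regions.

Each candidate region is extended by 100 kb up- and downstream before
annotation, and every gene whose interval overlaps the extended region
by at least one bp is reported — partial overlap counts, since sweep
signals routinely clip gene boundaries.  Strand is carried through but
ignored for overlap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import SelectionRegion

__all__ = ["extend_region", "genes_in_regions"]


def extend_region(
    region: SelectionRegion,
    pad_bp: int = 100_000,
    chrom_length: int | None = None,
) -> SelectionRegion:
    """Pad a region by ``pad_bp`` on each side, clamped to the
    chromosome."""
    if pad_bp < 0:
        raise ValueError("pad_bp must be >= 0")
    start = max(1, region.start_bp - pad_bp)
    end = region.end_bp + pad_bp
    if chrom_length is not None:
        end = min(end, chrom_length)
    return SelectionRegion(
        region.chrom, start, end, region.peak_snp, region.peak_value,
        region.method, region.label, dict(region.extras),
    )


def genes_in_regions(
    regions: list[SelectionRegion],
    genes: pd.DataFrame,
    pad_bp: int = 0,
) -> pd.DataFrame:
    """Per-region gene report: every gene intersecting the (padded)
    region in >= 1 bp, ordered by gene start within each region.

    ``genes`` is the frame produced by :func:`sweepx.io.read_gene_models`
    (1-based inclusive start_bp/end_bp).  Raises if no gene shares a
    chromosome name with any region (almost always a naming-convention
    clash, e.g. "X" vs "chrX").
    """
    if regions and len(genes) > 0:
        region_chroms = {r.chrom for r in regions}
        if not region_chroms & set(genes["chrom"].astype(str)):
            raise ValueError(
                f"no shared chromosome between regions {sorted(region_chroms)}"
                f" and gene models {sorted(set(genes['chrom']))[:5]}; "
                "check naming conventions"
            )
    trees: dict[str, IntervalTree] = {}
    for i, g in genes.iterrows():
        # half-open key on the 1-based line: [start, end + 1)
        trees.setdefault(str(g["chrom"]), IntervalTree()).addi(
            int(g["start_bp"]), int(g["end_bp"]) + 1, i
        )
    rows = []
    for r in regions:
        ext = extend_region(r, pad_bp) if pad_bp else r
        hits = trees.get(ext.chrom, IntervalTree()).overlap(
            ext.start_bp, ext.end_bp + 1
        )
        for iv in sorted(hits, key=lambda iv: iv.begin):
            g = genes.loc[iv.data]
            overlap = min(ext.end_bp, int(g["end_bp"])) - max(
                ext.start_bp, int(g["start_bp"])
            ) + 1
            rows.append(
                {
                    "chrom": r.chrom,
                    "region_start_bp": r.start_bp,
                    "region_end_bp": r.end_bp,
                    "method": r.method,
                    "label": r.label,
                    "gene_id": g["gene_id"],
                    "gene_name": g["gene_name"],
                    "gene_start_bp": int(g["start_bp"]),
                    "gene_end_bp": int(g["end_bp"]),
                    "strand": g["strand"],
                    "overlap_bp": int(overlap),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "region_start_bp", "region_end_bp", "method", "label",
            "gene_id", "gene_name", "gene_start_bp", "gene_end_bp",
            "strand", "overlap_bp",
        ],
    )
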