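"""Attribute structural variants to gene-region classes.

Each SV is assigned to exactly one of promoter (2 kb upstream of the start
codon), exon, intron, downstream (1 kb past the stop codon) or intergenic,
by largest base-pair overlap with the labeled regions of all genes. Ties are
broken by the fixed priority exon > promoter > intron > downstream.
All intervals here are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .genome import GeneModel

log = logging.getLogger("haploscent")

CLASS_PRIORITY = {"exon": 0, "promoter": 1, "intron": 2, "downstream": 3}


@dataclass
class SVRecord:
    sv_id: str
    chrom: str
    start0: int
    end: int
    type: str  # DEL | INS | INV

    def __post_init__(self):
        if self.type == "INS":
            self.end = self.start0 + 1
        elif self.end <= self.start0:
            raise ValueError(f"SV {self.sv_id}: end must exceed start for {self.type}")


@dataclass
class RegionAttribution:
    sv_id: str
    gene_id: str | None
    region_class: str
    overlap_bp: int


def gene_regions(gene: GeneModel, up_bp: int = 2000, down_bp: int = 1000,
                 chrom_length: int | None = None) -> dict[str, list[tuple[int, int]]]:
    """Strand-aware labeled regions of one gene, 0-based half-open.

    Promoter runs up to the start codon, downstream from the stop codon;
    introns are the gene span minus exons. Intervals are truncated at the
    chromosome ends when ``chrom_length`` is given.
    """
    cds_lo = min(s for s, _ in gene.cds) if gene.cds else gene.start
    cds_hi = max(e for _, e in gene.cds) if gene.cds else gene.end
    if gene.strand == "+":
        promoter = (cds_lo - 1 - up_bp, cds_lo - 1)
        downstream = (cds_hi, cds_hi + down_bp)
    else:
        promoter = (cds_hi, cds_hi + up_bp)
        downstream = (cds_lo - 1 - down_bp, cds_lo - 1)
    exons = [(s - 1, e) for s, e in gene.exons]
    introns = []
    prev = None
    for s0, e0 in sorted(exons):
        if prev is not None and s0 > prev:
            introns.append((prev, s0))
        prev = max(prev or 0, e0)
    out = {
        "promoter": [promoter],
        "exon": exons,
        "intron": introns,
        "downstream": [downstream],
    }
    for cls, ivals in out.items():
        clipped = []
        for s0, e0 in ivals:
            s0 = max(s0, 0)
            if chrom_length is not None:
                e0 = min(e0, chrom_length)
            if e0 > s0:
                clipped.append((s0, e0))
        out[cls] = clipped
    return out


def attribute_svs(svs: list[SVRecord], genes: list[GeneModel],
                  up_bp: int = 2000, down_bp: int = 1000,
                  chrom_lengths: dict[str, int] | None = None,
                  ) -> tuple[list[RegionAttribution], dict]:
    """Assign each SV a single region class and report class distributions.

    Overlap is aggregated per class across genes; the winning class is the
    one with most overlapping bp (priority order on ties). The distribution
    is reported both over genic SVs only and over all SVs, as percentages.
    """
    genes_by_chrom: dict[str, list[tuple[GeneModel, dict]]] = {}
    known_chroms = {g.chrom for g in genes}
    for g in genes:
        cl = chrom_lengths.get(g.chrom) if chrom_lengths else None
        genes_by_chrom.setdefault(g.chrom, []).append(
            (g, gene_regions(g, up_bp, down_bp, chrom_length=cl))
        )

    attributions: list[RegionAttribution] = []
    for sv in svs:
        if sv.chrom not in known_chroms:
            log.warning("SV %s on unknown chromosome %s skipped", sv.sv_id, sv.chrom)
            continue
        per_class: dict[str, int] = {}
        per_class_gene: dict[str, tuple[int, str]] = {}
        for g, regions in genes_by_chrom[sv.chrom]:
            # cheap span filter including the widest flank
            if sv.start0 >= g.end + up_bp or sv.end <= g.start - 1 - up_bp:
                continue
            for cls, ivals in regions.items():
                ov = sum(max(0, min(sv.end, e0) - max(sv.start0, s0)) for s0, e0 in ivals)
                if ov > 0:
                    per_class[cls] = per_class.get(cls, 0) + ov
                    best = per_class_gene.get(cls, (0, ""))
                    if ov > best[0]:
                        per_class_gene[cls] = (ov, g.gene_id)
        if not per_class:
            attributions.append(RegionAttribution(sv.sv_id, None, "intergenic", 0))
            continue
        win = min(per_class, key=lambda c: (-per_class[c], CLASS_PRIORITY[c]))
        attributions.append(
            RegionAttribution(sv.sv_id, per_class_gene[win][1], win, per_class[win])
        )

    genic = [a for a in attributions if a.region_class != "intergenic"]
    dist = {
        "n_total": len(attributions),
        "n_genic": len(genic),
        "counts": _counts(attributions),
        "pct_of_genic": _pcts(genic),
        "pct_of_all": _pcts(attributions),
    }
    return attributions, dist


def _counts(attrs) -> dict[str, int]:
    out: dict[str, int] = {}
    for a in attrs:
        out[a.region_class] = out.get(a.region_class, 0) + 1
    return out


def _pcts(attrs) -> dict[str, float]:
    n = len(attrs)
    if n == 0:
        return {}
    return {cls: round(100.0 * k / n, 2) for cls, k in _counts(attrs).items()}


def read_sv_table(path) -> list[SVRecord]:
    """Read a BED-like SV table (chrom, start0, end, type[, sv_id])."""
    df = pd.read_csv(path, sep="\t")
    if "sv_id" not in df.columns:
        df["sv_id"] = [f"sv{i:04d}" for i in range(len(df))]
    return [SVRecord(str(r.sv_id), str(r.chrom), int(r.start0), int(r.end), str(r.type))
            for r in df.itertuples(index=False)]


def attribution_table(attrs: list[RegionAttribution]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.sv_id, a.gene_id or "", a.region_class, a.overlap_bp) for a in attrs],
        columns=["sv_id", "gene_id", "region_class", "overlap_bp"],
    )
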