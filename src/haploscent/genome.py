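"""Gene models and genome I/O shared across the pipeline.

Coordinate conventions follow the file formats: GFF3 features are 1-based
inclusive, while derived region sets (promoters, SV intervals) use 0-based
half-open intervals, as in BED.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger("haploscent")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """A protein-coding gene on one haplotype.

    ``start``/``end`` and the exon/CDS interval lists are 1-based inclusive
    (GFF3 convention). ``rank`` is the ordinal position of the gene along its
    chromosome, used by the syntenic chaining step.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    rank: int = -1

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def cds_sequence(self, chrom_seq: str) -> str:
        """Spliced CDS on the coding strand."""
        parts = [chrom_seq[s - 1 : e] for s, e in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = revcomp(seq)
        return seq

    def validate(self) -> None:
        if self.cds_length % 3 != 0:
            raise ValueError(f"CDS length of {self.gene_id} not a multiple of 3")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"exon outside gene span in {self.gene_id}")


def translate_cds(cds_seq: str) -> str:
    """Translate a CDS, standard code; trailing stop removed if present."""
    aa = str(Seq(cds_seq).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa


# ---------------------------------------------------------------------------
# FASTA / GFF3 I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _gff_attr(attrs: str) -> dict[str, str]:
    out = {}
    for kv in attrs.strip().split(";"):
        if "=" in kv:
            k, v = kv.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene/mRNA/exon/CDS features into :class:`GeneModel` records.

    Exon and CDS features are attached to their gene via the Parent chain.
    Ranks are assigned per chromosome by gene start.
    """
    genes: dict[str, GeneModel] = {}
    mrna_to_gene: dict[str, str] = {}
    pending: list[tuple[str, str, int, int]] = []  # (type, parent, start, end)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            a = _gff_attr(attrs)
            start, end = int(start), int(end)
            if ftype == "gene":
                gid = a.get("ID", f"gene_{len(genes)}")
                genes[gid] = GeneModel(gid, chrom, strand, start, end)
            elif ftype == "mRNA":
                mrna_to_gene[a.get("ID", "")] = a.get("Parent", "")
            elif ftype in ("exon", "CDS"):
                pending.append((ftype, a.get("Parent", ""), start, end))
    for ftype, parent, start, end in pending:
        gid = mrna_to_gene.get(parent, parent)
        gene = genes.get(gid)
        if gene is None:
            log.warning("feature with unknown parent %s skipped", parent)
            continue
        (gene.exons if ftype == "exon" else gene.cds).append((start, end))
    out = list(genes.values())
    for g in out:
        g.exons = sorted(g.exons)
        g.cds = sorted(g.cds)
    _assign_ranks(out)
    return out


def _assign_ranks(genes: list[GeneModel]) -> None:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: (g.start, g.gene_id))
        for i, g in enumerate(glist):
            g.rank = i


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\thaploscent\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\thaploscent\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\thaploscent\texon\t{s}\t{e}\t.\t{g.strand}\t.\tID={mrna}.e{i};Parent={mrna}\n"
                )
            # phase bookkeeping for CDS rows, in transcription order
            cds = g.cds if g.strand == "+" else list(reversed(g.cds))
            phase, rows = 0, []
            for s, e in cds:
                rows.append((s, e, phase))
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
            for i, (s, e, ph) in enumerate(sorted(rows), 1):
                fh.write(
                    f"{g.chrom}\thaploscent\tCDS\t{s}\t{e}\t.\t{g.strand}\t{ph}\tID={mrna}.c{i};Parent={mrna}\n"
                )
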