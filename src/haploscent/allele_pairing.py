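"""Allele identification between two phased haplotypes.

Protein-level anchors (reciprocal best hits plus every hit above a similarity
floor) are chained into collinear syntenic blocks by dynamic programming, and
every anchor inside a retained block becomes an allele pair. This mirrors the
MCScan family of collinearity tools: minimum 5 anchors per block and a rank
gap of at most 25 genes, with an internal global aligner replacing BLAST.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio.Align import PairwiseAligner

from .genome import GeneModel, translate_cds

log = logging.getLogger("haploscent")

# alignment scoring constants (protein global alignment)
MATCH_SCORE = 2.0
MISMATCH_SCORE = -1.0
GAP_OPEN = -8.0
GAP_EXTEND = -0.5

# k-mer prescreen: candidate partners must share this fraction of 4-mers
PRESCREEN_K = 4
PRESCREEN_MIN_SHARED = 0.10


@dataclass
class Anchor:
    gene_a: str
    gene_b: str
    similarity: float
    reciprocal_best: bool = False
    chrom_a: str = ""
    chrom_b: str = ""
    rank_a: int = -1
    rank_b: int = -1


@dataclass
class SyntenicBlock:
    block_id: int
    chrom_a: str
    chrom_b: str
    anchors: list[Anchor] = field(default_factory=list)
    orientation: str = "same"  # same | inverted

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass
class AllelePair:
    gene_a: str
    gene_b: str
    block_id: int
    similarity: float


def _aligner() -> PairwiseAligner:
    a = PairwiseAligner(mode="global")
    a.match_score = MATCH_SCORE
    a.mismatch_score = MISMATCH_SCORE
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    return a


def alignment_identity(aligner: PairwiseAligner, pa: str, pb: str) -> float:
    """Global-alignment identity over aligned length (gap columns included)."""
    if not pa or not pb:
        return 0.0
    aln = aligner.align(pa, pb)[0]
    counts = aln.counts()
    return counts.identities / aln.length if aln.length else 0.0


def _kmers(seq: str, k: int = PRESCREEN_K) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def find_anchors(genes_a: list[GeneModel], genes_b: list[GeneModel],
                 cds_a: dict[str, str], cds_b: dict[str, str],
                 min_similarity: float = 0.7) -> list[Anchor]:
    """Protein-similarity anchors between the two haplotype gene sets.

    Returns reciprocal best hits plus any hit with similarity >=
    ``min_similarity``. A shared-k-mer prescreen keeps the all-vs-all
    comparison near-linear; genes whose CDS cannot be translated (internal
    stop) are skipped with a log message.
    """
    if not genes_a or not genes_b:
        log.warning("empty gene set; no anchors")
        return []

    def proteins(genes, cds):
        out = {}
        for g in genes:
            seq = cds.get(g.gene_id, "")
            if not seq:
                continue
            aa = translate_cds(seq)
            if "*" in aa:
                log.info("gene %s has internal stop; skipped from anchoring", g.gene_id)
                continue
            out[g.gene_id] = aa
        return out

    prot_a = proteins(genes_a, cds_a)
    prot_b = proteins(genes_b, cds_b)
    gm_a = {g.gene_id: g for g in genes_a}
    gm_b = {g.gene_id: g for g in genes_b}

    index_b: dict[str, set[str]] = {}
    kmers_b = {}
    for gid, aa in prot_b.items():
        ks = _kmers(aa)
        kmers_b[gid] = ks
        for k in ks:
            index_b.setdefault(k, set()).add(gid)

    aligner = _aligner()
    sims: dict[tuple[str, str], float] = {}
    for ga, aa in prot_a.items():
        ks = _kmers(aa)
        hits: dict[str, int] = {}
        for k in ks:
            for gb in index_b.get(k, ()):
                hits[gb] = hits.get(gb, 0) + 1
        for gb, shared in hits.items():
            denom = min(len(ks), len(kmers_b[gb])) or 1
            if shared / denom < PRESCREEN_MIN_SHARED:
                continue
            sims[(ga, gb)] = alignment_identity(aligner, aa, prot_b[gb])

    best_a: dict[str, tuple[float, str]] = {}
    best_b: dict[str, tuple[float, str]] = {}
    for (ga, gb), s in sims.items():
        if (s, gb) > best_a.get(ga, (-1.0, "")):
            # tie -> lexicographically larger partner wins; deterministic
            best_a[ga] = (s, gb)
        if (s, ga) > best_b.get(gb, (-1.0, "")):
            best_b[gb] = (s, ga)

    anchors = []
    for (ga, gb), s in sorted(sims.items()):
        rbh = best_a.get(ga, (None, None))[1] == gb and best_b.get(gb, (None, None))[1] == ga
        if s >= min_similarity or rbh:
            a, b = gm_a[ga], gm_b[gb]
            anchors.append(Anchor(ga, gb, s, rbh, a.chrom, b.chrom, a.rank, b.rank))
    return anchors


def collapse_tandem(anchors: list[Anchor], rank_gap: int = 1) -> list[Anchor]:
    """Collapse tandem-duplicate anchors sharing a gene with rank-adjacent
    partners, keeping the highest-similarity representative."""
    def collapse(side_key, partner_rank):
        grouped: dict[str, list[Anchor]] = {}
        for a in anchors:
            grouped.setdefault(side_key(a), []).append(a)
        keep = []
        for group in grouped.values():
            group.sort(key=partner_rank)
            cluster: list[Anchor] = []
            for a in group + [None]:
                if cluster and (a is None or partner_rank(a) - partner_rank(cluster[-1]) > rank_gap):
                    keep.append(max(cluster, key=lambda x: (x.similarity, x.reciprocal_best)))
                    cluster = []
                if a is not None:
                    cluster.append(a)
        return keep

    anchors = collapse(lambda a: a.gene_a, lambda a: a.rank_b)
    anchors = collapse(lambda a: a.gene_b, lambda a: a.rank_a)
    return sorted(anchors, key=lambda a: (a.chrom_a, a.rank_a, a.chrom_b, a.rank_b))


def chain_syntenic_blocks(anchors: list[Anchor], min_block: int = 5,
                          max_gap: int = 25) -> list[SyntenicBlock]:
    """Chain anchors into maximum-scoring collinear blocks.

    Per chromosome pair and orientation, dynamic programming finds the chain
    with the most anchors whose gene ranks are strictly monotone on both
    sides with rank gaps <= ``max_gap``; the best chain is peeled off and
    chaining repeats until no chain reaches ``min_block`` anchors.
    """
    by_pair: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        by_pair.setdefault((a.chrom_a, a.chrom_b), []).append(a)

    blocks: list[SyntenicBlock] = []
    bid = 0
    for (ca, cb) in sorted(by_pair):
        pool = by_pair[(ca, cb)]
        while True:
            best_chain, best_orient = None, None
            for orient in ("same", "inverted"):
                chain = _best_chain(pool, orient, max_gap)
                if best_chain is None or len(chain) > len(best_chain):
                    best_chain, best_orient = chain, orient
            if not best_chain or len(best_chain) < min_block:
                break
            blocks.append(SyntenicBlock(bid, ca, cb, best_chain, best_orient))
            bid += 1
            used = set(id(a) for a in best_chain)
            pool = [a for a in pool if id(a) not in used]
    return blocks


def _best_chain(pool: list[Anchor], orientation: str, max_gap: int) -> list[Anchor]:
    if not pool:
        return []
    sgn = 1 if orientation == "same" else -1
    items = sorted(pool, key=lambda a: (a.rank_a, sgn * a.rank_b))
    n = len(items)
    score = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            da = items[i].rank_a - items[j].rank_a
            db = sgn * (items[i].rank_b - items[j].rank_b)
            if 0 < da <= max_gap and 0 < db <= max_gap and score[j] + 1 > score[i]:
                score[i] = score[j] + 1
                prev[i] = j
    k = max(range(n), key=lambda i: score[i])
    chain = []
    while k != -1:
        chain.append(items[k])
        k = prev[k]
    return chain[::-1]


def call_alleles(blocks: list[SyntenicBlock],
                 genes_a: list[GeneModel] | None = None) -> list[AllelePair]:
    """Turn block anchors into allele pairs, one pair per gene at most.

    A gene claimed by anchors of two blocks goes to the larger block (ties to
    the lower block id). Output is sorted by hap1 coordinates when gene
    models are supplied, else by gene id.
    """
    order = sorted(blocks, key=lambda b: (-len(b), b.block_id))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs: list[AllelePair] = []
    for b in order:
        for a in b.anchors:
            if a.gene_a in used_a or a.gene_b in used_b:
                continue
            used_a.add(a.gene_a)
            used_b.add(a.gene_b)
            pairs.append(AllelePair(a.gene_a, a.gene_b, b.block_id, a.similarity))
    if genes_a:
        coord = {g.gene_id: (g.chrom, g.start) for g in genes_a}
        pairs.sort(key=lambda p: coord.get(p.gene_a, ("", 0)))
    else:
        pairs.sort(key=lambda p: p.gene_a)
    return pairs


def pair_alleles(genes_a, genes_b, cds_a, cds_b, min_similarity: float = 0.7,
                 min_block: int = 5, max_gap: int = 25) -> tuple[list[AllelePair], list[SyntenicBlock]]:
    """Anchor -> collapse tandems -> chain -> call, in one step."""
    anchors = find_anchors(genes_a, genes_b, cds_a, cds_b, min_similarity)
    anchors = collapse_tandem(anchors)
    blocks = chain_syntenic_blocks(anchors, min_block=min_block, max_gap=max_gap)
    return call_alleles(blocks, genes_a), blocks


def pairs_table(pairs: list[AllelePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.gene_a, p.gene_b, p.block_id, round(p.similarity, 4)) for p in pairs],
        columns=["gene_a", "gene_b", "block_id", "similarity"],
    )


def blocks_table(blocks: list[SyntenicBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.block_id, b.chrom_a, b.chrom_b, len(b), b.orientation) for b in blocks],
        columns=["block_id", "chrom_a", "chrom_b", "n_anchors", "orientation"],
    )
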