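"""Allele-pair divergence: codon-aware alignment, NG86 Ka/Ks, flank rates.

Ka/Ks follows Nei & Gojobori (1986): per-codon synonymous site fractions by
enumerating the nine single-nucleotide changes (changes to stop codons are
excluded from both site counts and pathways), observed differences resolved
by averaging over all minimal mutational pathways with equal weight, and a
Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3) applied to the proportions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from Bio.Align import PairwiseAligner
from Bio.Data.CodonTable import standard_dna_table

from .genome import GeneModel, revcomp, translate_cds

log = logging.getLogger("haploscent")

CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
BASES = "ACGT"


class InternalStopError(ValueError):
    """CDS contains an in-frame stop before the final codon."""


# ---------------------------------------------------------------------------
# Codon-aware alignment
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    codon_pairs: list[tuple[str, str]]
    n_codons_used: int
    n_codons_dropped: int
    nt_matches: int  # matching nucleotides within retained codon columns


def _protein_aligner() -> PairwiseAligner:
    a = PairwiseAligner(mode="global")
    a.match_score = 2.0
    a.mismatch_score = -1.0
    a.open_gap_score = -8.0
    a.extend_gap_score = -0.5
    return a


def _codons(cds: str) -> list[str]:
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def align_codons(cds_a: str, cds_b: str) -> CodonAlignment:
    """Translate, align the proteins globally, back-thread the codons.

    Codon columns containing an alignment gap or a stop codon in either
    sequence are dropped and counted. Raises :class:`InternalStopError` for
    an in-frame stop before the final codon.
    """
    for name, cds in (("a", cds_a), ("b", cds_b)):
        if len(cds) % 3 != 0:
            raise ValueError(f"cds_{name} length not a multiple of 3")
        aa_body = [CODON_TABLE.get(c, "X") if c not in STOP_CODONS else "*"
                   for c in _codons(cds)[:-1]]
        if "*" in aa_body:
            raise InternalStopError(f"internal stop codon in cds_{name}")

    def prep(cds):
        cod = _codons(cds)
        if cod and cod[-1] in STOP_CODONS:
            cod = cod[:-1]
        aa = "".join(CODON_TABLE.get(c, "X") for c in cod)
        return cod, aa

    cod_a, aa_a = prep(cds_a)
    cod_b, aa_b = prep(cds_b)
    if not cod_a or not cod_b:
        return CodonAlignment([], 0, 0, 0)

    aln = _protein_aligner().align(aa_a, aa_b)[0]
    ia, ib = aln.indices  # -1 marks a gap
    used, dropped, matches = [], 0, 0
    for col in range(aln.length):
        i, j = ia[col], ib[col]
        if i < 0 or j < 0:
            dropped += 1
            continue
        ca, cb = cod_a[i], cod_b[j]
        if ca in STOP_CODONS or cb in STOP_CODONS:
            dropped += 1
            continue
        used.append((ca, cb))
        matches += sum(x == y for x, y in zip(ca, cb))
    return CodonAlignment(used, len(used), dropped, matches)


def cds_identity(alignment: CodonAlignment) -> float:
    """Matching nt columns over aligned nt columns; gap columns mismatch."""
    total = 3 * (alignment.n_codons_used + alignment.n_codons_dropped)
    if total == 0:
        return float("nan")
    return alignment.nt_matches / total


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(N, S) site counts of one codon, stop mutations excluded."""
    aa = CODON_TABLE.get(codon)
    if aa is None:
        return (0.0, 0.0)
    n = s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            tot += 1
            if CODON_TABLE[mut] == aa:
                syn += 1
        if tot:
            s += syn / tot
            n += 1 - syn / tot
        else:  # every change creates a stop: count the position as nonsyn
            n += 1.0
    return n, s


_SITES_CACHE: dict[str, tuple[float, float]] = {}
_PATH_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def _pair_differences(ca: str, cb: str) -> tuple[float, float]:
    """(Nd, Sd) for one codon pair, averaged over minimal pathways.

    Pathways through stop codons are excluded; if every ordering passes a
    stop, all orderings are used (the conventional fallback).
    """
    key = (ca, cb)
    if key in _PATH_CACHE:
        return _PATH_CACHE[key]
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        _PATH_CACHE[key] = (0.0, 0.0)
        return 0.0, 0.0
    valid, fallback = [], []
    for order in itertools.permutations(diff):
        cur = ca
        steps, blocked = [], False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        nd = sum(1 for c1, c2 in steps
                 if c1 in STOP_CODONS or c2 in STOP_CODONS
                 or CODON_TABLE[c1] != CODON_TABLE[c2])
        sd = len(steps) - nd
        (fallback if blocked else valid).append((nd, sd))
    paths = valid or fallback
    nd = sum(p[0] for p in paths) / len(paths)
    sd = sum(p[1] for p in paths) / len(paths)
    _PATH_CACHE[key] = (nd, sd)
    return nd, sd


def jukes_cantor(p: float) -> float:
    """JC69 distance; NaN when p >= 3/4 (saturated)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class NG86Result:
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float
    Ks: float
    kaks: float
    flags: list[str] = field(default_factory=list)


def ng86(alignment: CodonAlignment) -> NG86Result:
    """Nei–Gojobori (1986) Ka/Ks on a gap-free codon alignment."""
    if alignment.n_codons_used < 1:
        raise ValueError("NG86 requires at least one aligned codon")
    N = S = Nd = Sd = 0.0
    for ca, cb in alignment.codon_pairs:
        for c in (ca, cb):
            if c not in _SITES_CACHE:
                _SITES_CACHE[c] = _codon_site_counts(c)
        na, sa = _SITES_CACHE[ca]
        nb, sb = _SITES_CACHE[cb]
        N += (na + nb) / 2.0
        S += (sa + sb) / 2.0
        nd, sd = _pair_differences(ca, cb)
        Nd += nd
        Sd += sd
    pN = Nd / N if N > 0 else 0.0
    pS = Sd / S if S > 0 else 0.0
    flags = []
    Ka, Ks = jukes_cantor(pN), jukes_cantor(pS)
    if math.isnan(Ka) or math.isnan(Ks):
        flags.append("saturated")
    if Ks and not math.isnan(Ks) and not math.isnan(Ka):
        kaks = Ka / Ks
    else:
        kaks = float("nan")
        if Ks == 0.0:
            flags.append("ks_zero")
    return NG86Result(N, S, Nd, Sd, pN, pS, Ka, Ks, kaks, flags)


# ---------------------------------------------------------------------------
# Flanking regions
# ---------------------------------------------------------------------------

def _nt_aligner() -> PairwiseAligner:
    a = PairwiseAligner(mode="global")
    a.match_score = 2.0
    a.mismatch_score = -3.0
    a.open_gap_score = -5.0
    a.extend_gap_score = -2.0
    return a


def _extract_flank(gene: GeneModel, chrom_seq: str, which: str,
                   up_bp: int, down_bp: int) -> str:
    cds_lo = min(s for s, _ in gene.cds)
    cds_hi = max(e for _, e in gene.cds)
    L = len(chrom_seq)
    if (which == "up") == (gene.strand == "+"):
        # left of the CDS on the forward strand
        span = up_bp if which == "up" else down_bp
        s0, e0 = max(cds_lo - 1 - span, 0), cds_lo - 1
    else:
        span = up_bp if which == "up" else down_bp
        s0, e0 = cds_hi, min(cds_hi + span, L)
    seq = chrom_seq[s0:e0]
    return seq if gene.strand == "+" else revcomp(seq)


def flank_divergence(hap1_seqs: dict[str, str], hap2_seqs: dict[str, str],
                     gene_a: GeneModel, gene_b: GeneModel,
                     up_bp: int = 2000, down_bp: int = 1000,
                     min_len: int = 100) -> tuple[float, float, dict]:
    """JC-corrected substitution rate in the 2-kb upstream and 1-kb
    downstream flanks of an allele pair; NaN when a flank is shorter than
    ``min_len`` after truncation at chromosome ends."""
    aligner = _nt_aligner()
    rates, lengths = {}, {}
    for which in ("up", "down"):
        fa = _extract_flank(gene_a, hap1_seqs[gene_a.chrom], which, up_bp, down_bp)
        fb = _extract_flank(gene_b, hap2_seqs[gene_b.chrom], which, up_bp, down_bp)
        lengths[which] = (len(fa), len(fb))
        if len(fa) < min_len or len(fb) < min_len:
            rates[which] = float("nan")
            continue
        aln = aligner.align(fa, fb)[0]
        ia, ib = aln.indices
        comp = [(fa[i], fb[j]) for i, j in zip(ia, ib) if i >= 0 and j >= 0]
        if not comp:
            rates[which] = float("nan")
            continue
        p = sum(a != b for a, b in comp) / len(comp)
        rates[which] = jukes_cantor(p)
    return rates["up"], rates["down"], {"lengths": lengths}


# ---------------------------------------------------------------------------
# Per-pair driver + group contrast
# ---------------------------------------------------------------------------

@dataclass
class DivergenceRecord:
    pair_id: str
    gene_a: str
    gene_b: str
    cds_identity: float = float("nan")
    n_codons_used: int = 0
    n_codons_dropped: int = 0
    Nd: float = float("nan")
    Sd: float = float("nan")
    N_sites: float = float("nan")
    S_sites: float = float("nan")
    pN: float = float("nan")
    pS: float = float("nan")
    Ka: float = float("nan")
    Ks: float = float("nan")
    kaks: float = float("nan")
    flank_up_rate: float = float("nan")
    flank_down_rate: float = float("nan")
    flags: list[str] = field(default_factory=list)


def pair_divergence(pair_id: str, gene_a: GeneModel, gene_b: GeneModel,
                    hap1_seqs: dict[str, str], hap2_seqs: dict[str, str],
                    up_bp: int = 2000, down_bp: int = 1000) -> DivergenceRecord:
    rec = DivergenceRecord(pair_id, gene_a.gene_id, gene_b.gene_id)
    cds_a = gene_a.cds_sequence(hap1_seqs[gene_a.chrom])
    cds_b = gene_b.cds_sequence(hap2_seqs[gene_b.chrom])
    try:
        aln = align_codons(cds_a, cds_b)
    except InternalStopError:
        rec.flags.append("internal_stop")
        aln = None
    if aln is not None and aln.n_codons_used:
        rec.cds_identity = cds_identity(aln)
        rec.n_codons_used = aln.n_codons_used
        rec.n_codons_dropped = aln.n_codons_dropped
        r = ng86(aln)
        rec.Nd, rec.Sd, rec.N_sites, rec.S_sites = r.Nd, r.Sd, r.N, r.S
        rec.pN, rec.pS, rec.Ka, rec.Ks, rec.kaks = r.pN, r.pS, r.Ka, r.Ks, r.kaks
        rec.flags.extend(r.flags)
    rec.flank_up_rate, rec.flank_down_rate, _ = flank_divergence(
        hap1_seqs, hap2_seqs, gene_a, gene_b, up_bp, down_bp)
    return rec


def records_table(records: list[DivergenceRecord]):
    import pandas as pd
    rows = []
    for r in records:
        d = dict(vars(r))
        d["flags"] = ",".join(d["flags"])
        rows.append(d)
    return pd.DataFrame(rows)


@dataclass
class SelectionContrast:
    metric: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    t: float
    p: float
    n_excluded: int
    ran: bool
    reason: str = ""


def compare_selection(records1, records2, metric: str = "kaks") -> SelectionContrast:
    """Welch t-test contrasting a divergence metric between two pair groups
    (e.g. consistent vs inconsistent ASE); NaN/undefined values excluded."""
    if metric not in ("kaks", "flank_up_rate", "flank_down_rate", "Ka", "Ks"):
        raise ValueError(f"unsupported metric {metric!r}")
    v1 = np.array([getattr(r, metric) for r in records1], dtype=float)
    v2 = np.array([getattr(r, metric) for r in records2], dtype=float)
    f1, f2 = v1[np.isfinite(v1)], v2[np.isfinite(v2)]
    excl = (len(v1) - len(f1)) + (len(v2) - len(f2))
    if len(f1) < 2 or len(f2) < 2:
        return SelectionContrast(metric, len(f1), len(f2), float("nan"), float("nan"),
                                 float("nan"), float("nan"), excl, False,
                                 "fewer than 2 finite values in a group")
    t, p = stats.ttest_ind(f1, f2, equal_var=False)
    return SelectionContrast(metric, len(f1), len(f2), float(f1.mean()), float(f2.mean()),
                             float(t), float(p), excl, True)
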