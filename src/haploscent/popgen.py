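"""Population-genetic scans: windowed pi, Weir–Cockerham Fst with top-5%
sweep calling, Patterson's D with a block-jackknife Z, and Martin's fd.

The variant panel is a biallelic alt-dosage matrix (samples x sites) with
sample group labels; VCF loading drops non-biallelic sites and masks
genotypes with read depth below 5, matching the study's variant filters.
Derived alleles are polarized against the outgroup major allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("haploscent")

MISSING = -1  # dosage sentinel


@dataclass
class VariantPanel:
    chroms: np.ndarray          # per-site chromosome name
    positions: np.ndarray       # 1-based
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray          # samples x sites, {0,1,2,MISSING}
    samples: list[str]
    groups: dict[str, str]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def group_rows(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.groups[s] == group]
        if not idx:
            raise KeyError(f"no samples in group {group!r}")
        return np.asarray(idx)

    def subset_group(self, group: str) -> "VariantPanel":
        rows = self.group_rows(group)
        return VariantPanel(self.chroms, self.positions, self.ref, self.alt,
                            self.dosage[rows], [self.samples[i] for i in rows],
                            self.groups, self.chrom_lengths)

    def chrom_length(self, chrom: str) -> int:
        if chrom in self.chrom_lengths:
            return self.chrom_lengths[chrom]
        return int(self.positions[self.chroms == chrom].max())


def read_group_table(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))


def load_vcf(path, group_table: dict[str, str] | str, min_dp: int = 5) -> VariantPanel:
    """Load a VCF into a dosage panel with the study's site/genotype filters.

    Non-biallelic sites are dropped; genotypes with DP < ``min_dp`` are set
    missing; sites left with no called genotype are dropped. Every VCF
    sample must appear in the group table.
    """
    from cyvcf2 import VCF

    if not isinstance(group_table, dict):
        group_table = read_group_table(group_table)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in group_table]
    if unknown:
        raise ValueError(f"samples missing from group table: {unknown}")
    chrom_lengths = {}
    for c, l in zip(vcf.seqnames, vcf.seqlens or []):
        chrom_lengths[c] = int(l)

    chroms, pos, ref, alt, dosages = [], [], [], [], []
    n_multi = n_all_missing = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_multi += 1
            continue
        gt = np.asarray(v.gt_types, dtype=np.int8)  # 0,1,2; 3=unknown
        gt = np.where(gt == 3, MISSING, gt)
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            dp = np.asarray(dp).reshape(-1)
            gt = np.where(dp < min_dp, MISSING, gt)
        if (gt == MISSING).all():
            n_all_missing += 1
            continue
        chroms.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        dosages.append(gt)
    log.info("load_vcf: dropped %d non-biallelic and %d all-missing sites",
             n_multi, n_all_missing)
    dosage = (np.vstack(dosages).T if dosages
              else np.zeros((len(samples), 0), dtype=np.int8))
    return VariantPanel(np.asarray(chroms), np.asarray(pos, dtype=np.int64),
                        np.asarray(ref), np.asarray(alt), dosage.astype(np.int8),
                        samples, dict(group_table), chrom_lengths)


# ---------------------------------------------------------------------------
# Window machinery
# ---------------------------------------------------------------------------

@dataclass
class WindowStat:
    chrom: str
    start0: int
    end: int
    n_sites: int
    value: float


def tile_windows(chrom_len: int, window: int, step: int):
    if not (window >= step > 0):
        raise ValueError("require window >= step > 0")
    start = 0
    while start < chrom_len:
        yield start, min(start + window, chrom_len)
        start += step


def windows_table(stats: list[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [(w.chrom, w.start0, w.end, w.n_sites, w.value) for w in stats],
        columns=["chrom", "start0", "end", "n_sites", "value"],
    )


def _per_chrom(panel: VariantPanel):
    for chrom in sorted(set(panel.chroms.tolist())):
        mask = panel.chroms == chrom
        yield chrom, np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def site_pi(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased per-site heterozygosity 2p(1-p)n/(n-1) over called alleles.

    Returns (pi, n_called_alleles); sites with <2 called alleles are NaN.
    """
    called = dosage != MISSING
    n = 2 * called.sum(axis=0)
    ac = np.where(called, dosage, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, ac / n, np.nan)
        pi = 2.0 * p * (1.0 - p) * n / np.maximum(n - 1, 1)
    pi = np.where(n >= 2, pi, np.nan)
    return pi, n


def pi_windows(panel: VariantPanel, window: int = 10_000, step: int = 5_000,
               min_sites: int = 1) -> list[WindowStat]:
    """Sliding-window nucleotide diversity per bp.

    Monomorphic positions contribute zero and the full window length is the
    denominator (all positions assumed callable).
    """
    pi, _ = site_pi(panel.dosage)
    out = []
    for chrom, idx in _per_chrom(panel):
        cpos = panel.positions[idx] - 1  # 0-based
        cpi = pi[idx]
        ok = ~np.isnan(cpi)
        for s0, e0 in tile_windows(panel.chrom_length(chrom), window, step):
            sel = (cpos >= s0) & (cpos < e0) & ok
            n = int(sel.sum())
            val = float(cpi[sel].sum() / (e0 - s0)) if n >= min_sites else float("nan")
            out.append(WindowStat(chrom, s0, e0, n, val))
    return out


def genome_pi(panel: VariantPanel) -> float:
    """Genome-wide average pairwise diversity per bp."""
    pi, _ = site_pi(panel.dosage)
    total_bp = sum(panel.chrom_length(c) for c in set(panel.chroms.tolist()))
    return float(np.nansum(pi) / total_bp)


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst
# ---------------------------------------------------------------------------

def wc_site_components(dosA: np.ndarray, dosB: np.ndarray):
    """Per-site Weir & Cockerham (1984) variance components for two
    populations, vectorized over sites.

    Returns (a, b, c) arrays; sites where either population has fewer than
    one called individual, or n_bar <= 1, are NaN.
    """
    r = 2.0
    out = []
    stats = []
    for dos in (dosA, dosB):
        called = dos != MISSING
        n_i = called.sum(axis=0).astype(float)          # diploid individuals
        ac = np.where(called, dos, 0).sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_i = ac / (2.0 * n_i)
            h_i = np.where(called, dos == 1, False).sum(axis=0) / n_i
        stats.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = stats
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (1.0 / (nbar - 1.0))
                           * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
                                     - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
        c = hbar / 2.0
    bad = (n1 < 1) | (n2 < 1) | (nbar <= 1)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return a, b, c


def fst_wc_windows(panel: VariantPanel, group1: str, group2: str,
                   window: int = 10_000, step: int = 5_000) -> list[WindowStat]:
    """Windowed weighted Fst = sum(a) / sum(a+b+c) over usable sites."""
    rows1, rows2 = panel.group_rows(group1), panel.group_rows(group2)
    a, b, c = wc_site_components(panel.dosage[rows1], panel.dosage[rows2])
    usable = np.isfinite(a)
    out = []
    for chrom, idx in _per_chrom(panel):
        cpos = panel.positions[idx] - 1
        ca, cb, cc, cu = a[idx], b[idx], c[idx], usable[idx]
        for s0, e0 in tile_windows(panel.chrom_length(chrom), window, step):
            sel = (cpos >= s0) & (cpos < e0) & cu
            n = int(sel.sum())
            if n == 0:
                out.append(WindowStat(chrom, s0, e0, 0, float("nan")))
                continue
            denom = float((ca[sel] + cb[sel] + cc[sel]).sum())
            val = float(ca[sel].sum() / denom) if denom > 0 else float("nan")
            out.append(WindowStat(chrom, s0, e0, n, val))
    return out


@dataclass
class SweepRegion:
    chrom: str
    start0: int
    end: int
    max_value: float
    genes: list[str] = field(default_factory=list)


def select_sweeps(stats: list[WindowStat], top_frac: float = 0.05,
                  genes=None, min_windows: int = 20) -> tuple[float, list[SweepRegion]]:
    """Merge windows at or above the (1 - top_frac) quantile into sweep
    regions and list overlapping genes."""
    vals = np.array([w.value for w in stats], dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("all window values missing")
    if finite.size < min_windows:
        raise ValueError(f"need at least {min_windows} non-missing windows")
    thresh = float(np.quantile(finite, 1.0 - top_frac))
    chosen = [w for w in stats if np.isfinite(w.value) and w.value >= thresh]
    chosen.sort(key=lambda w: (w.chrom, w.start0))
    regions: list[SweepRegion] = []
    for w in chosen:
        if regions and regions[-1].chrom == w.chrom and w.start0 <= regions[-1].end:
            regions[-1].end = max(regions[-1].end, w.end)
            regions[-1].max_value = max(regions[-1].max_value, w.value)
        else:
            regions.append(SweepRegion(w.chrom, w.start0, w.end, w.value))
    if genes:
        for reg in regions:
            reg.genes = [g.gene_id for g in genes
                         if g.chrom == reg.chrom and g.start - 1 < reg.end and g.end > reg.start0]
    return thresh, regions


# ---------------------------------------------------------------------------
# Derived-allele polarization + D / fd
# ---------------------------------------------------------------------------

def derived_freqs(panel: VariantPanel, pops: tuple[str, str, str, str],
                  out_poly_tol: float = 0.1):
    """Per-population derived-allele frequencies polarized by the outgroup.

    The ancestral allele is the outgroup major allele; sites where the
    outgroup derived frequency exceeds ``out_poly_tol``, or where any
    population has no called allele, are masked out.
    """
    freqs = []
    for g in pops:
        dos = panel.dosage[panel.group_rows(g)]
        called = dos != MISSING
        n = 2 * called.sum(axis=0)
        ac = np.where(called, dos, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            freqs.append(np.where(n > 0, ac / n, np.nan))
    p1, p2, p3, po = freqs
    ancestral_is_alt = po > 0.5
    d = [np.where(ancestral_is_alt, 1.0 - p, p) for p in (p1, p2, p3, po)]
    ok = ~np.isnan(p1) & ~np.isnan(p2) & ~np.isnan(p3) & ~np.isnan(po)
    ok &= d[3] <= out_poly_tol
    return d, ok


def _abba_baba(d1, d2, d3, d4):
    abba = (1 - d1) * d2 * d3 * (1 - d4)
    baba = d1 * (1 - d2) * d3 * (1 - d4)
    return abba, baba


@dataclass
class DResult:
    D: float
    Z: float
    n_blocks: int
    abba_sum: float
    baba_sum: float
    n_sites: int
    block_bp: int


def d_statistic(panel: VariantPanel, p1: str, p2: str, p3: str, out: str,
                block_bp: int = 1_000_000, min_blocks: int = 20) -> DResult:
    """Patterson's D on (((P1,P2),P3),O) with a delete-one block jackknife.

    Block size shrinks automatically so at least ``min_blocks`` blocks with
    informative sites exist.
    """
    (d1, d2, d3, d4), ok = derived_freqs(panel, (p1, p2, p3, out))
    abba, baba = _abba_baba(d1, d2, d3, d4)
    abba = np.where(ok, abba, 0.0)
    baba = np.where(ok, baba, 0.0)
    tot_abba, tot_baba = float(abba.sum()), float(baba.sum())
    denom = tot_abba + tot_baba
    n_inf = int((ok & ((abba + baba) > 0)).sum())
    if denom <= 0:
        return DResult(float("nan"), float("nan"), 0, tot_abba, tot_baba, n_inf, block_bp)
    D = (tot_abba - tot_baba) / denom

    genome_bp = sum(panel.chrom_length(c) for c in set(panel.chroms.tolist()))
    if genome_bp // block_bp < min_blocks:
        block_bp = max(genome_bp // min_blocks, 1)
    keys = [f"{c}:{(p - 1) // block_bp}"
            for c, p in zip(panel.chroms.tolist(), panel.positions.tolist())]
    df = pd.DataFrame({"key": keys, "abba": abba, "baba": baba})
    bl = df.groupby("key", sort=True).sum()
    bl = bl[(bl["abba"] + bl["baba"]) > 0]
    m = len(bl)
    if m < 2:
        return DResult(D, float("nan"), m, tot_abba, tot_baba, n_inf, block_bp)
    loo_abba = tot_abba - bl["abba"].values
    loo_baba = tot_baba - bl["baba"].values
    theta = (loo_abba - loo_baba) / (loo_abba + loo_baba)
    var = (m - 1) / m * ((theta - theta.mean()) ** 2).sum()
    se = np.sqrt(var)
    Z = float(D / se) if se > 0 else float("nan")
    return DResult(float(D), Z, m, tot_abba, tot_baba, n_inf, block_bp)


def fd_windows(panel: VariantPanel, p1: str, p2: str, p3: str, out: str,
               window: int = 100_000, step: int = 50_000,
               min_sites: int = 10) -> list[WindowStat]:
    """Martin's fd admixture-fraction estimator in sliding windows.

    fd = S(P1,P2,P3,O) / S(P1,PD,PD,O) with the per-site dynamic donor
    PD = argmax(derived freq of P2, P3). Windows with a negative numerator
    (window-level D < 0) or fewer than ``min_sites`` informative sites are
    reported missing.
    """
    (d1, d2, d3, d4), ok = derived_freqs(panel, (p1, p2, p3, out))
    abba, baba = _abba_baba(d1, d2, d3, d4)
    num = np.where(ok, abba - baba, 0.0)
    pD = np.maximum(d2, d3)
    abba_d, baba_d = _abba_baba(d1, pD, pD, d4)
    den = np.where(ok, abba_d - baba_d, 0.0)
    informative = ok & ((abba + baba) > 0)
    out_stats = []
    for chrom, idx in _per_chrom(panel):
        cpos = panel.positions[idx] - 1
        for s0, e0 in tile_windows(panel.chrom_length(chrom), window, step):
            sel = (cpos >= s0) & (cpos < e0)
            n = int((informative[idx] & sel).sum())
            S_num = float(num[idx][sel].sum())
            S_den = float(den[idx][sel].sum())
            if n < min_sites or S_num < 0 or S_den <= 0:
                out_stats.append(WindowStat(chrom, s0, e0, n, float("nan")))
                continue
            out_stats.append(WindowStat(chrom, s0, e0, n, S_num / S_den))
    return out_stats
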