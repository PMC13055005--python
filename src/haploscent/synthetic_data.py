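"""Seeded synthetic data with the structure of a phased diploid rose genome study.

The generator emulates, at desk scale, the data a haplotype-resolved analysis
consumes: a diploid genome pair at ~1.5% heterozygosity carrying SNPs, small
indels and structural variants; allelic expression counts across four flower
stages with planted consistent/inconsistent/noASE classes; a four-population
panel on the tree (((P1,P2),P3),O) with Balding–Nichols drift, a planted
introgressed segment (P3 donor into P2) and a locally divergent locus; and a
2-phenylethanol-like phenotype driven by a causal non-synonymous haplotype.

Every sub-generator draws from its own RNG stream spawned from the master
seed, so outputs are byte-reproducible and insensitive to draw-count changes
in sibling components.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneModel, write_fasta, write_gff3, revcomp, _assign_ranks
from . import sv_attribution

STOP_CODONS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"

ASE_CLASSES = ("consistent", "inconsistent", "noASE")


class CapacityError(RuntimeError):
    """Raised when variant/gene placement fails after bounded retries."""


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with study-scale defaults.

    Defaults describe two 500-kb chromosomes with 300 genes, ~1.5% SNP
    heterozygosity, a 4 stage x 3 replicate expression design, four
    populations of 25 samples, a 200-kb introgressed segment on chr1 and a
    200-kb locally divergent locus on chr2.
    """

    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_genes: int = 300
    snp_rate: float = 0.015
    indel_rate: float = 0.001
    sv_count: int = 40
    sv_min_len: int = 50
    sv_max_len: int = 2_000
    # planted SV gene-region mix; exon SVs are not planted because they would
    # disrupt reading frames the divergence stage depends on
    sv_region_weights: dict = field(
        default_factory=lambda: {
            "promoter": 0.45,
            "intron": 0.30,
            "downstream": 0.20,
            "intergenic": 0.05,
        }
    )
    # expression design
    n_stages: int = 4
    n_reps: int = 3
    ase_class_proportions: tuple = (0.10, 0.30, 0.60)  # consistent/inconsistent/noASE
    ase_log2_effect: float = 2.0
    nb_dispersion: float = 0.05
    mean_depth: float = 200.0  # expected pooled count per pair/haplotype/stage
    # population panel
    pop_sites_per_chrom: int = 10_000
    # branch drift: n1 = root->(P1,P2,P3) ancestor, n2 = ->(P1,P2) ancestor,
    # p1/p2/p3 = terminal branches; the donor P3 is strongly diverged
    pop_drift: dict = field(
        default_factory=lambda: {"n1": 0.1, "n2": 0.05, "p1": 0.05, "p2": 0.05, "p3": 0.5}
    )
    introgression_fraction: float = 0.3
    # 0-based half-open; None means genome-wide admixture
    introgressed_interval: tuple | None = ("chr1", 150_000, 350_000)
    divergent_interval: tuple = ("chr2", 150_000, 350_000)
    divergent_drift: float = 0.5  # P2 branch drift inside divergent_interval
    n_samples_per_pop: int = 25
    # within-population inbreeding (F_IS): clonally propagated accessions are
    # largely homozygous per locus, which is what per-SNP heterozygosity
    # filters of 0.2 presuppose
    pop_inbreeding: float = 0.8
    vcf_dp: int = 30
    # phenotype
    pheno_effect: float = 6.0  # µg/g per favorable-haplotype copy
    pheno_noise_sd: float = 2.0
    pheno_baseline: float | None = None  # default: 1 + 3*noise SD (keeps values positive)
    seed: int = 0

    def validate(self) -> None:
        p = self.ase_class_proportions
        if len(p) != 3 or abs(sum(p) - 1.0) > 1e-9 or any(x < 0 for x in p):
            raise ConfigError("ase_class_proportions must be 3 non-negative fractions summing to 1")
        if self.sv_min_len < 50:
            raise ConfigError("sv_min_len must be >= 50")
        for name in ("snp_rate", "indel_rate", "introgression_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0,1]")
        for k, v in self.pop_drift.items():
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"drift parameter {k} must lie in [0,1)")
        if self.nb_dispersion < 0 or self.mean_depth <= 0:
            raise ConfigError("nb_dispersion must be >=0 and mean_depth > 0")
        if self.n_stages < 2:
            raise ConfigError("expression design needs at least 2 stages")
        if self.introgressed_interval is not None:
            c, s0, e0 = self.introgressed_interval
            if not (0 <= s0 < e0 <= self.chrom_length):
                raise ConfigError("introgressed_interval outside chromosome bounds")

    def rng_streams(self) -> dict[str, np.random.Generator]:
        ss = np.random.SeedSequence(self.seed)
        names = ("genome", "expression", "population", "phenotype")
        return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}

    @property
    def baseline(self) -> float:
        return self.pheno_baseline if self.pheno_baseline is not None else 1.0 + 3.0 * self.pheno_noise_sd


# ---------------------------------------------------------------------------
# Truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class TruthSet:
    """Ground truth for parameter-recovery tests; JSON-serializable."""

    allele_pair_truth: dict = field(default_factory=dict)
    sv_truth: list = field(default_factory=list)
    introgression_truth: dict = field(default_factory=dict)
    divergent_truth: dict = field(default_factory=dict)
    causal_truth: dict = field(default_factory=dict)
    variant_counts: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Diploid genome
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + stop."""
    sense = [c for c in ("".join(t) for t in itertools.product(BASES, repeat=3))
             if c not in STOP_CODONS and c != "ATG"]
    body = rng.choice(len(sense), size=n_codons - 2)
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    return "ATG" + "".join(sense[i] for i in body) + stop


def _place_genes(config: SimulationConfig, rng: np.random.Generator,
                 chrom_names: list[str]) -> list[GeneModel]:
    per_chrom = config.n_genes // config.n_chromosomes
    extras = config.n_genes - per_chrom * config.n_chromosomes
    genes: list[GeneModel] = []
    for ci, chrom in enumerate(chrom_names):
        n = per_chrom + (1 if ci < extras else 0)
        usable = config.chrom_length - 2 * 2_100  # clearance at both ends
        slot = usable // max(n, 1)
        if slot < 900:
            raise CapacityError(
                f"chromosome {chrom} too short for {n} genes with 2 kb/1 kb flank clearance"
            )
        for gi in range(n):
            span_budget = min(slot - 400, 2_400)
            # 1-3 exons; exon lengths multiples of 3
            for _ in range(50):
                n_ex = int(rng.integers(1, 4))
                ex_lens = [int(rng.integers(50, 151)) * 3 for _ in range(n_ex)]
                intr = [int(rng.integers(100, 401)) for _ in range(n_ex - 1)]
                span = sum(ex_lens) + sum(intr)
                if span <= span_budget:
                    break
            else:
                n_ex, ex_lens, intr, span = 1, [150], [], 150
            lo = 2_100 + gi * slot
            start = lo + int(rng.integers(0, max(slot - span - 200, 1) + 1)) + 100
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = start
            for k, L in enumerate(ex_lens):
                exons.append((pos, pos + L - 1))
                pos += L + (intr[k] if k < len(intr) else 0)
            gid = f"HX{ci + 1}G{(gi + 1) * 100:06d}"
            g = GeneModel(gid, chrom, strand, start, exons[-1][1], exons=exons, cds=list(exons))
            genes.append(g)
    return genes


def _write_cds_into(seq: list[str], gene: GeneModel, cds: str) -> None:
    s = cds if gene.strand == "+" else revcomp(cds)
    i = 0
    for a, b in gene.cds:
        seq[a - 1 : b] = list(s[i : i + (b - a + 1)])
        i += b - a + 1


@dataclass
class DiploidSim:
    hap1: dict[str, str]
    hap2: dict[str, str]
    genes1: list[GeneModel]
    genes2: list[GeneModel]
    sv_table: pd.DataFrame  # chrom, start0, end, type, sv_id (hap1 coords)
    truth: TruthSet


def simulate_diploid(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> DiploidSim:
    """Build hap1, then derive hap2 by applying SNPs, indels and SVs.

    Indels and SVs are confined to non-CDS space so that lifted hap2 gene
    models keep intact reading frames; SNPs may fall anywhere but are
    resampled if they would create an in-frame stop codon.
    """
    config.validate()
    if rng is None:
        rng = config.rng_streams()["genome"]
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    L = config.chrom_length

    hap1 = {c: rng.integers(0, 4, size=L) for c in chrom_names}
    hap1 = {c: "".join(BASES[i] for i in arr) for c, arr in hap1.items()}
    genes1 = _place_genes(config, rng, chrom_names)
    seqs = {c: list(hap1[c]) for c in chrom_names}
    for g in genes1:
        cds = _random_cds(rng, g.cds_length // 3)
        _write_cds_into(seqs[g.chrom], g, cds)
    hap1 = {c: "".join(s) for c, s in seqs.items()}
    _assign_ranks(genes1)

    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes1:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    # per-chromosome CDS position map: genomic pos (1-based) -> (gene, cds index)
    cds_map: dict[str, dict[int, tuple[GeneModel, int]]] = {c: {} for c in chrom_names}
    for g in genes1:
        idx = 0
        order = g.cds if g.strand == "+" else list(reversed(g.cds))
        for s, e in order:
            coords = range(s, e + 1) if g.strand == "+" else range(e, s - 1, -1)
            for p in coords:
                cds_map[g.chrom][p] = (g, idx)
                idx += 1

    # labeled gene regions (0-based half-open) for SV planting truth
    region_sets = {
        c: [(g, sv_attribution.gene_regions(g, chrom_length=L)) for g in genes_by_chrom.get(c, [])]
        for c in chrom_names
    }

    truth = TruthSet()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}  # 0-based half-open

    def overlaps_any(c: str, s0: int, e0: int) -> bool:
        return any(s0 < e and s < e0 for s, e in occupied[c])

    def region_hits(c: str, s0: int, e0: int) -> set[str]:
        hit = set()
        for _, regions in region_sets[c]:
            for cls, ivals in regions.items():
                for rs, re_ in ivals:
                    if s0 < re_ and rs < e0:
                        hit.add(cls)
        return hit

    # --- SVs -------------------------------------------------------------
    sv_rows = []
    classes = list(config.sv_region_weights)
    weights = np.array([config.sv_region_weights[c] for c in classes], dtype=float)
    weights = weights / weights.sum() if weights.sum() > 0 else weights
    planted_classes = [classes[i] for i in rng.choice(len(classes), size=config.sv_count, p=weights)]
    for si, target in enumerate(planted_classes):
        placed = False
        for _ in range(400):
            c = chrom_names[int(rng.integers(len(chrom_names)))]
            svtype = ["DEL", "INS", "INV"][int(rng.integers(3))]
            if target == "intergenic":
                s0 = int(rng.integers(0, L - config.sv_max_len))
                cap = config.sv_max_len
            else:
                cands = [iv for _, regions in region_sets[c] for iv in regions.get(target, [])]
                cands = [iv for iv in cands if iv[1] - iv[0] >= config.sv_min_len + 2]
                if not cands:
                    continue
                rs, re_ = cands[int(rng.integers(len(cands)))]
                cap = re_ - rs - 2
                if cap < config.sv_min_len:
                    continue
                s0 = None
            svlen = int(rng.integers(config.sv_min_len, min(cap, config.sv_max_len) + 1))
            if target != "intergenic":
                s0 = rs + 1 + int(rng.integers(0, (re_ - 1) - (rs + 1) - svlen + 1)) if (re_ - 1) - (rs + 1) - svlen >= 0 else None
                if s0 is None:
                    continue
            span = (s0, s0 + 1) if svtype == "INS" else (s0, s0 + svlen)
            if overlaps_any(c, *span):
                continue
            hits = region_hits(c, *span)
            if target == "intergenic" and hits:
                continue
            if target != "intergenic" and hits != {target}:
                continue
            occupied[c].append(span)
            sv_id = f"sv{si:04d}"
            sv_rows.append(dict(chrom=c, start0=span[0], end=span[1], type=svtype,
                                sv_id=sv_id, svlen=svlen))
            truth.sv_truth.append(dict(sv_id=sv_id, chrom=c, start0=span[0], end=span[1],
                                       type=svtype, region_class=target))
            placed = True
            break
        if not placed:
            raise CapacityError(f"could not place SV {si} in region class '{target}'")

    # --- small indels (non-CDS only) -------------------------------------
    forbidden: dict[str, np.ndarray] = {}
    for c in chrom_names:
        mask = np.zeros(L, dtype=bool)
        for g in genes_by_chrom.get(c, []):
            for s, e in g.cds:
                mask[max(s - 3, 0) : min(e + 2, L)] = True
        forbidden[c] = mask
    indel_rows = []
    for c in chrom_names:
        n_ind = rng.binomial(L, config.indel_rate)
        for _ in range(n_ind):
            for _ in range(50):
                p0 = int(rng.integers(0, L - 12))
                ilen = int(rng.integers(1, 11))
                is_del = rng.random() < 0.5
                span = (p0, p0 + ilen) if is_del else (p0, p0 + 1)
                if forbidden[c][span[0] : span[1] + 1].any() or overlaps_any(c, *span):
                    continue
                occupied[c].append(span)
                indel_rows.append(dict(chrom=c, start0=span[0], end=span[1],
                                       type="del" if is_del else "ins", length=ilen))
                break

    # --- SNPs -------------------------------------------------------------
    snp_rows = []
    seqs2 = {c: list(hap1[c]) for c in chrom_names}
    for c in chrom_names:
        n_snp = rng.binomial(L, config.snp_rate)
        blocked = np.zeros(L, dtype=bool)
        for s, e in occupied[c]:
            blocked[s:e] = True
        pos_all = rng.choice(L, size=min(n_snp * 2, L), replace=False)
        taken = 0
        for p0 in pos_all:
            if taken >= n_snp or blocked[p0]:
                continue
            ref = hap1[c][p0]
            alts = [b for b in BASES if b != ref]
            hit = cds_map[c].get(p0 + 1)
            if hit is not None:
                g, idx = hit
                cstart = (idx // 3) * 3
                codon_pos = list(range(cstart, cstart + 3))
                # rebuild the codon on the coding strand
                order = g.cds if g.strand == "+" else list(reversed(g.cds))
                flat = []
                for s_, e_ in order:
                    flat.extend(range(s_, e_ + 1) if g.strand == "+" else range(e_, s_ - 1, -1))
                codon_g = [flat[i] for i in codon_pos]
                ok_alts = []
                for a in alts:
                    codon = ""
                    for gp in codon_g:
                        base = hap1[c][gp - 1] if gp != p0 + 1 else a
                        codon += base if g.strand == "+" else revcomp(base)
                    if codon not in STOP_CODONS:
                        ok_alts.append(a)
                if not ok_alts:
                    continue
                alts = ok_alts
            alt = alts[int(rng.integers(len(alts)))]
            seqs2[c][p0] = alt
            snp_rows.append((c, int(p0), ref, alt))
            taken += 1
    truth.variant_counts = dict(
        snps=len(snp_rows), indels=len(indel_rows), svs=len(sv_rows)
    )

    # --- structural edits + liftover --------------------------------------
    events: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}  # (pos0, delta)
    edits = []
    for r in indel_rows:
        edits.append((r["chrom"], r["start0"], r["end"], r["type"].upper(), r["length"]))
    for r in sv_rows:
        edits.append((r["chrom"], r["start0"], r["end"], r["type"], r["svlen"]))
    for c, s0, e0, etype, elen in sorted(edits, key=lambda t: -t[1]):
        seq = seqs2[c]
        if etype == "DEL":
            del seq[s0:e0]
            events[c].append((e0, -(e0 - s0)))
        elif etype == "INS":
            ins = "".join(BASES[i] for i in rng.integers(0, 4, size=elen))
            seq[s0:s0] = list(ins)
            events[c].append((s0, elen))
        elif etype == "INV":
            seq[s0:e0] = list(revcomp("".join(seq[s0:e0])))
    hap2 = {c: "".join(s) for c, s in seqs2.items()}

    def lift(c: str, pos1: int) -> int:
        off = sum(d for p, d in events[c] if p <= pos1 - 1)
        return pos1 + off

    genes2 = []
    for g in genes1:
        g2 = GeneModel(
            g.gene_id + "_h2", g.chrom, g.strand,
            lift(g.chrom, g.start), lift(g.chrom, g.end),
            exons=[(lift(g.chrom, s), lift(g.chrom, e)) for s, e in g.exons],
            cds=[(lift(g.chrom, s), lift(g.chrom, e)) for s, e in g.cds],
        )
        if g2.cds_length % 3 != 0:
            raise AssertionError(f"liftover broke reading frame of {g.gene_id}")
        genes2.append(g2)
    _assign_ranks(genes2)

    # --- ASE class planting ------------------------------------------------
    cls_idx = rng.choice(3, size=len(genes1), p=np.asarray(config.ase_class_proportions))
    for g, ci in zip(genes1, cls_idx):
        cls = ASE_CLASSES[ci]
        entry = dict(hap2_gene=g.gene_id + "_h2", ase_class=cls, favored=None,
                     stages_affected=[], directions=[])
        if cls == "consistent":
            entry["favored"] = "hap1" if rng.random() < 0.5 else "hap2"
            entry["stages_affected"] = list(range(1, config.n_stages + 1))
        elif cls == "inconsistent":
            k = int(rng.integers(1, config.n_stages))  # strict subset
            stages = sorted(rng.choice(config.n_stages, size=k, replace=False) + 1)
            entry["stages_affected"] = [int(s) for s in stages]
            entry["directions"] = ["hap1" if rng.random() < 0.5 else "hap2" for _ in stages]
        truth.allele_pair_truth[g.gene_id] = entry

    sv_df = pd.DataFrame(sv_rows, columns=["chrom", "start0", "end", "type", "sv_id", "svlen"])
    return DiploidSim(hap1, hap2, genes1, genes2, sv_df, truth)


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

def _nb(rng: np.random.Generator, mu: float, disp: float, size: int) -> np.ndarray:
    if disp <= 1e-12:
        return rng.poisson(mu, size=size)
    n = 1.0 / disp
    p = n / (n + mu)
    return rng.negative_binomial(n, p, size=size)


def plant_ase_classes(n_pairs: int, proportions, rng: np.random.Generator,
                      n_stages: int = 4) -> TruthSet:
    """Standalone ASE truth (no genome) for expression-only simulations."""
    truth = TruthSet()
    cls_idx = rng.choice(3, size=n_pairs, p=np.asarray(proportions))
    for i, ci in enumerate(cls_idx):
        cls = ASE_CLASSES[ci]
        entry = dict(hap2_gene=f"pair{i:05d}_h2", ase_class=cls, favored=None,
                     stages_affected=[], directions=[])
        if cls == "consistent":
            entry["favored"] = "hap1" if rng.random() < 0.5 else "hap2"
            entry["stages_affected"] = list(range(1, n_stages + 1))
        elif cls == "inconsistent":
            k = int(rng.integers(1, n_stages))
            stages = sorted(rng.choice(n_stages, size=k, replace=False) + 1)
            entry["stages_affected"] = [int(s) for s in stages]
            entry["directions"] = ["hap1" if rng.random() < 0.5 else "hap2" for _ in stages]
        truth.allele_pair_truth[f"pair{i:05d}"] = entry
    return truth


def simulate_expression(truth: TruthSet, config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Negative-binomial stage x replicate allelic counts with planted effects.

    ``mean_depth`` is the expected pooled count per pair/haplotype/stage; the
    planted fold-change multiplies the favored haplotype's mean in the
    affected stages.
    """
    if config.n_stages < 2:
        raise ConfigError("expression design needs at least 2 stages")
    if rng is None:
        rng = config.rng_streams()["expression"]
    mu0 = config.mean_depth / config.n_reps
    fold = 2.0 ** config.ase_log2_effect
    rows = []
    for pair_id in sorted(truth.allele_pair_truth):
        entry = truth.allele_pair_truth[pair_id]
        stages_eff = {}
        if entry["ase_class"] == "consistent":
            for s in entry["stages_affected"]:
                stages_eff[s] = entry["favored"]
        elif entry["ase_class"] == "inconsistent":
            for s, d in zip(entry["stages_affected"], entry["directions"]):
                stages_eff[s] = d
        for stage in range(1, config.n_stages + 1):
            fav = stages_eff.get(stage)
            for hap in ("hap1", "hap2"):
                mu = mu0 * (fold if fav == hap else 1.0)
                counts = _nb(rng, mu, config.nb_dispersion, config.n_reps)
                for rep, cnt in enumerate(counts, 1):
                    rows.append((pair_id, hap, stage, rep, int(cnt)))
    return pd.DataFrame(rows, columns=["gene_id", "haplotype", "stage", "replicate", "count"])


# ---------------------------------------------------------------------------
# Population panel
# ---------------------------------------------------------------------------

POPS = ("P1", "P2", "P3", "O")


@dataclass
class PopulationSim:
    chrom_lengths: dict[str, int]
    sites: pd.DataFrame            # chrom, pos (1-based), ref, alt
    dosage: np.ndarray             # samples x sites, alt-allele dosage
    samples: list[str]
    groups: dict[str, str]
    freqs: dict[str, np.ndarray]   # per-population alt frequency per site
    truth: TruthSet

    def to_panel(self):
        from .popgen import VariantPanel
        return VariantPanel(
            chroms=np.asarray(self.sites["chrom"]),
            positions=np.asarray(self.sites["pos"], dtype=np.int64),
            ref=np.asarray(self.sites["ref"]),
            alt=np.asarray(self.sites["alt"]),
            dosage=self.dosage.astype(np.int8),
            samples=list(self.samples),
            groups=dict(self.groups),
            chrom_lengths=dict(self.chrom_lengths),
        )


def _draw_genotypes(rng, p: np.ndarray, n: int, f_is: float) -> np.ndarray:
    """Diploid dosages with within-population inbreeding F_IS."""
    m = len(p)
    hwe = rng.binomial(2, p, size=(n, m))
    hom = 2 * rng.binomial(1, p, size=(n, m))
    take_hom = rng.random((n, m)) < f_is
    return np.where(take_hom, hom, hwe).astype(np.int8)


def _balding_nichols(rng, p: np.ndarray, F: float) -> np.ndarray:
    if F < 1e-9:
        return p.copy()
    p = np.clip(p, 1e-9, 1 - 1e-9)
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return np.clip(rng.beta(a, b), 0.0, 1.0)


def simulate_population(config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        ref_seqs: dict[str, str] | None = None) -> PopulationSim:
    """Four-population genotype panel on the tree (((P1,P2),P3),O).

    Ancestral frequencies are Uniform(0.05, 0.95); each branch applies
    Balding–Nichols drift. Inside the introgressed interval the recipient
    (P2) frequency becomes (1-f)*own + f*donor (P3); inside the divergent
    interval the P2 branch drift is raised to ``divergent_drift``. The
    outgroup is fixed for the ancestral (REF) allele.
    """
    config.validate()
    if rng is None:
        rng = config.rng_streams()["population"]
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    L = config.chrom_length
    if config.introgressed_interval is None:
        ic, is0, ie0 = "*", 0, L
    else:
        ic, is0, ie0 = config.introgressed_interval
        if ic not in chrom_names or ie0 > L:
            raise ConfigError("introgressed_interval outside simulated chromosomes")

    rows = []
    for c in chrom_names:
        pos = np.sort(rng.choice(L, size=config.pop_sites_per_chrom, replace=False)) + 1
        for p in pos:
            if ref_seqs is not None:
                ref = ref_seqs[c][p - 1]
            else:
                ref = BASES[int(rng.integers(4))]
            alt = BASES[(BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
            rows.append((c, int(p), ref, alt))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    m = len(sites)

    p0 = rng.uniform(0.05, 0.95, size=m)
    d = config.pop_drift
    p_n1 = _balding_nichols(rng, p0, d["n1"])     # ancestor of P1,P2,P3
    p_n2 = _balding_nichols(rng, p_n1, d["n2"])   # ancestor of P1,P2
    p1 = _balding_nichols(rng, p_n2, d["p1"])
    # P2: branch drift boosted inside the locally divergent interval
    dc, ds0, de0 = config.divergent_interval
    in_div = (np.asarray(sites["chrom"]) == dc) & (sites["pos"].values - 1 >= ds0) & (sites["pos"].values - 1 < de0)
    p2 = _balding_nichols(rng, p_n2, d["p2"])
    if in_div.any() and config.divergent_drift > d["p2"]:
        p2_div = _balding_nichols(rng, p_n2, config.divergent_drift)
        p2 = np.where(in_div, p2_div, p2)
    p3 = _balding_nichols(rng, p_n1, d["p3"])

    if ic == "*":
        in_intro = np.ones(m, dtype=bool)
    else:
        in_intro = (np.asarray(sites["chrom"]) == ic) & (sites["pos"].values - 1 >= is0) & (sites["pos"].values - 1 < ie0)
    f = config.introgression_fraction
    if f > 0:
        p2 = np.where(in_intro, (1 - f) * p2 + f * p3, p2)

    freqs = {"P1": p1, "P2": p2, "P3": p3, "O": np.zeros(m)}
    n = config.n_samples_per_pop
    samples, groups, blocks = [], {}, []
    for pop in POPS:
        ids = [f"{pop}_{i + 1:02d}" for i in range(n)]
        samples += ids
        groups.update({s: pop for s in ids})
        if pop == "O":
            g = np.zeros((n, m), dtype=np.int8)
        else:
            g = _draw_genotypes(rng, freqs[pop], n, config.pop_inbreeding)
        blocks.append(g)
    dosage = np.vstack(blocks)

    truth = TruthSet(
        introgression_truth=dict(chrom=ic, start0=int(is0), end=int(ie0),
                                 fraction=float(f), donor="P3", recipient="P2"),
        divergent_truth=dict(chrom=dc, start0=int(ds0), end=int(de0),
                             drift=float(config.divergent_drift)),
    )
    return PopulationSim({c: L for c in chrom_names}, sites, dosage, samples, groups, freqs, truth)


def plant_causal_snp(pop: PopulationSim, genes: list[GeneModel],
                     genome: dict[str, str], config: SimulationConfig,
                     rng: np.random.Generator) -> None:
    """Insert one intermediate-frequency non-synonymous SNP into a gene's CDS.

    The favorable allele is ALT; ingroup frequencies are set to 0.5 so both
    homozygous classes are populated, the outgroup stays ancestral.
    """
    from .haplo_assoc import classify_coding_effect

    order = rng.permutation(len(genes))
    for gi in order:
        g = genes[gi]
        flat = []
        cds_order = g.cds if g.strand == "+" else list(reversed(g.cds))
        for s, e in cds_order:
            flat.extend(range(s, e + 1) if g.strand == "+" else range(e, s - 1, -1))
        # skip start/stop codons
        for pos in rng.permutation(flat[3:-3]):
            ref = genome[g.chrom][pos - 1]
            for alt in rng.permutation([b for b in BASES if b != ref]):
                eff = classify_coding_effect(g.chrom, int(pos), ref, alt, g, genome)
                if eff.effect == "nonsynonymous":
                    _insert_site(pop, g.chrom, int(pos), ref, str(alt), config, rng)
                    pop.truth.causal_truth = dict(
                        gene_id=g.gene_id, chrom=g.chrom,
                        positions=[int(pos)], favorable=str(alt), ref=str(ref),
                    )
                    return
    raise CapacityError("no gene admits a non-synonymous causal SNP")


def _insert_site(pop: PopulationSim, chrom: str, pos: int, ref: str, alt: str,
                 config: SimulationConfig, rng: np.random.Generator) -> None:
    sites = pop.sites
    clash = (sites["chrom"] == chrom) & (sites["pos"] == pos)
    if clash.any():
        keep = ~clash.values
        pop.sites = sites[keep].reset_index(drop=True)
        pop.dosage = pop.dosage[:, keep]
        for k in pop.freqs:
            pop.freqs[k] = pop.freqs[k][keep]
        sites = pop.sites
    row = pd.DataFrame([(chrom, pos, ref, alt)], columns=["chrom", "pos", "ref", "alt"])
    new_sites = pd.concat([sites, row], ignore_index=True)
    order = np.lexsort((new_sites["pos"].values, new_sites["chrom"].values))
    n_samp = pop.dosage.shape[0]
    col = np.zeros((n_samp, 1), dtype=np.int8)
    for i, s in enumerate(pop.samples):
        if pop.groups[s] != "O":
            if rng.random() < config.pop_inbreeding:
                col[i, 0] = 2 * rng.binomial(1, 0.5)
            else:
                col[i, 0] = rng.binomial(2, 0.5)
    new_dos = np.hstack([pop.dosage, col])[:, order]
    pop.sites = new_sites.iloc[order].reset_index(drop=True)
    pop.dosage = new_dos
    for k in pop.freqs:
        v = 0.0 if k == "O" else 0.5
        pop.freqs[k] = np.append(pop.freqs[k], v)[order]


def write_vcf(pop: PopulationSim, path: str | Path, dp: int = 30) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, l in pop.chrom_lengths.items():
            fh.write(f"##contig=<ID={c},length={l}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(pop.samples) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in enumerate(pop.sites.itertuples(index=False)):
            cells = [f"{gt_str[int(d)]}:{dp}" for d in pop.dosage[:, j]]
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT:DP\t"
                     + "\t".join(cells) + "\n")


def write_groups(pop: PopulationSim, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for s in pop.samples:
            fh.write(f"{s}\t{pop.groups[s]}\n")


# ---------------------------------------------------------------------------
# Phenotype
# ---------------------------------------------------------------------------

def simulate_phenotype(pop: PopulationSim, config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-sample 2-PE-like content (µg/g) driven by the causal haplotype."""
    if not pop.truth.causal_truth:
        raise ConfigError("population carries no causal SNP; run plant_causal_snp first")
    if rng is None:
        rng = config.rng_streams()["phenotype"]
    ct = pop.truth.causal_truth
    copies = np.zeros(len(pop.samples))
    for chrom, pos in zip([ct["chrom"]] * len(ct["positions"]), ct["positions"]):
        mask = (pop.sites["chrom"] == chrom) & (pop.sites["pos"] == pos)
        j = int(np.flatnonzero(mask.values)[0])
        dos = pop.dosage[:, j].astype(float)
        fav_dos = dos if ct["favorable"] != ct["ref"] else 2 - dos
        copies = fav_dos if copies.sum() == 0 else np.minimum(copies, fav_dos)
    noise = rng.normal(0.0, config.pheno_noise_sd, size=len(pop.samples))
    pe = config.baseline + config.pheno_effect * copies + noise
    return pd.DataFrame({
        "sample": pop.samples,
        "group": [pop.groups[s] for s in pop.samples],
        "pe_ug_per_g": pe,
    })


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    diploid: DiploidSim
    counts: pd.DataFrame
    pop: PopulationSim
    phenotype: pd.DataFrame
    truth: TruthSet


def simulate_all(config: SimulationConfig, outdir: str | Path | None = None) -> SimBundle:
    """Run every sub-generator from one master seed; optionally write files."""
    streams = config.rng_streams()
    dip = simulate_diploid(config, streams["genome"])
    counts = simulate_expression(dip.truth, config, streams["expression"])
    pop = simulate_population(config, streams["population"], ref_seqs=dip.hap1)
    plant_causal_snp(pop, dip.genes1, dip.hap1, config, streams["population"])
    pheno = simulate_phenotype(pop, config, streams["phenotype"])

    truth = dip.truth
    truth.introgression_truth = pop.truth.introgression_truth
    truth.divergent_truth = pop.truth.divergent_truth
    truth.causal_truth = pop.truth.causal_truth

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(dip.hap1, out / "hap1.fa")
        write_fasta(dip.hap2, out / "hap2.fa")
        write_gff3(dip.genes1, out / "hap1.gff3")
        write_gff3(dip.genes2, out / "hap2.gff3")
        dip.sv_table.drop(columns=["svlen"]).to_csv(out / "sv.tsv", sep="\t", index=False)
        counts.to_csv(out / "counts.tsv", sep="\t", index=False)
        write_vcf(pop, out / "population.vcf", dp=config.vcf_dp)
        write_groups(pop, out / "groups.tsv")
        pheno.to_csv(out / "phenotype.tsv", sep="\t", index=False, float_format="%.6f")
        truth.to_json(out / "truth.json")
    return SimBundle(dip, counts, pop, pheno, truth)
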