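"""Candidate-gene haplotype -> 2-phenylethanol association.

Non-synonymous SNPs inside a gene's CDS are filtered on observed
heterozygosity (<= 0.2) and minor-allele frequency (>= 0.05); samples
homozygous at every retained SNP form haplotype classes named by their
concatenated alleles (e.g. "T" vs "A"); the two most frequent homozygous
classes are contrasted on the phenotype with a Welch t-test, and the
higher-mean class is called the favorable haplotype when p < alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel, revcomp
from .divergence import CODON_TABLE, STOP_CODONS
from .popgen import VariantPanel, MISSING

log = logging.getLogger("haploscent")


@dataclass
class CodingEffect:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene_id: str
    codon_index: int  # 0-based; -1 when noncoding
    ref_aa: str
    alt_aa: str
    effect: str  # synonymous | nonsynonymous | stop_gain | noncoding


def classify_coding_effect(chrom: str, pos: int, ref: str, alt: str,
                           gene: GeneModel, genome: dict[str, str]) -> CodingEffect:
    """Strand-aware codon substitution effect of one SNP on one gene."""
    if genome[chrom][pos - 1] != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: VCF says {ref}, genome has "
            f"{genome[chrom][pos - 1]}"
        )
    order = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
    flat: list[int] = []
    for s, e in order:
        flat.extend(range(s, e + 1) if gene.strand == "+" else range(e, s - 1, -1))
    try:
        idx = flat.index(pos)
    except ValueError:
        return CodingEffect(chrom, pos, ref, alt, gene.gene_id, -1, "", "", "noncoding")
    ci = idx // 3
    codon_pos = flat[ci * 3 : ci * 3 + 3]

    def codon_with(base_at_pos: str) -> str:
        out = ""
        for gp in codon_pos:
            b = genome[chrom][gp - 1] if gp != pos else base_at_pos
            out += b if gene.strand == "+" else revcomp(b)
        return out

    c_ref, c_alt = codon_with(ref), codon_with(alt)
    aa_ref = "*" if c_ref in STOP_CODONS else CODON_TABLE.get(c_ref, "X")
    aa_alt = "*" if c_alt in STOP_CODONS else CODON_TABLE.get(c_alt, "X")
    if aa_alt == "*" and aa_ref != "*":
        eff = "stop_gain"
    elif aa_ref == aa_alt:
        eff = "synonymous"
    else:
        eff = "nonsynonymous"
    return CodingEffect(chrom, pos, ref, alt, gene.gene_id, ci, aa_ref, aa_alt, eff)


def nonsyn_snps_for_gene(panel: VariantPanel, gene: GeneModel,
                         genome: dict[str, str]) -> list[int]:
    """Panel column indices of non-synonymous SNPs inside the gene's CDS."""
    lo = min(s for s, _ in gene.cds)
    hi = max(e for _, e in gene.cds)
    idx = np.flatnonzero((panel.chroms == gene.chrom)
                         & (panel.positions >= lo) & (panel.positions <= hi))
    keep = []
    for j in idx:
        eff = classify_coding_effect(gene.chrom, int(panel.positions[j]),
                                     str(panel.ref[j]), str(panel.alt[j]), gene, genome)
        if eff.effect == "nonsynonymous":
            keep.append(int(j))
    return keep


def filter_assoc_snps(panel: VariantPanel, snp_cols: list[int],
                      het_max: float = 0.2, maf_min: float = 0.05,
                      ) -> tuple[list[int], dict]:
    """Drop SNPs with heterozygote fraction > het_max or MAF < maf_min,
    both over non-missing genotypes. Order-independent."""
    kept, reasons = [], {"het": 0, "maf": 0, "no_calls": 0}
    for j in snp_cols:
        dos = panel.dosage[:, j]
        called = dos != MISSING
        n = int(called.sum())
        if n == 0:
            reasons["no_calls"] += 1
            continue
        het = float((dos[called] == 1).mean())
        p = float(dos[called].sum() / (2 * n))
        maf = min(p, 1 - p)
        drop = False
        if het > het_max:
            reasons["het"] += 1
            drop = True
        if maf < maf_min:
            reasons["maf"] += 1
            drop = True
        if not drop:
            kept.append(j)
    return kept, reasons


def build_gene_haplotypes(panel: VariantPanel, snp_cols: list[int]) -> dict[str, str]:
    """sample -> haplotype class from homozygous genotypes.

    Samples homozygous at every retained SNP get the concatenated allele
    string in position order; any heterozygous or missing genotype puts the
    sample in class "het/other".
    """
    if not snp_cols:
        raise ValueError("need at least one retained SNP")
    cols = sorted(snp_cols, key=lambda j: (str(panel.chroms[j]), int(panel.positions[j])))
    out = {}
    for i, s in enumerate(panel.samples):
        alleles = []
        ok = True
        for j in cols:
            d = panel.dosage[i, j]
            if d == 0:
                alleles.append(str(panel.ref[j]))
            elif d == 2:
                alleles.append(str(panel.alt[j]))
            else:
                ok = False
                break
        out[s] = "".join(alleles) if ok else "het/other"
    return out


@dataclass
class AssociationResult:
    gene_id: str
    snp_positions: list[int]
    class_census: dict[str, int]
    tested_classes: tuple[str, str] | None
    mean_phenotype: dict[str, float]
    t: float
    p: float
    favorable: str | None
    testable: bool
    reason: str = ""
    group_frequencies: dict = field(default_factory=dict)


def haplotype_phenotype_test(classes: dict[str, str], phenotype: pd.DataFrame,
                             alpha: float = 0.05, gene_id: str = "",
                             snp_positions: list[int] | None = None,
                             split: str = "median") -> AssociationResult:
    """Welch t-test on phenotype between the two most frequent homozygous
    haplotype classes; the higher-mean class is favorable when p < alpha.

    Haplotype-class frequencies are also reported within high/low phenotype
    groups (split at the median by default).
    """
    pheno = dict(zip(phenotype["sample"].astype(str), phenotype["pe_ug_per_g"].astype(float)))
    census: dict[str, int] = {}
    for s, cls in classes.items():
        census[cls] = census.get(cls, 0) + 1
    hom = sorted(
        [c for c in census if c != "het/other"],
        key=lambda c: (-census[c], c),
    )
    result = AssociationResult(gene_id, snp_positions or [], census, None, {},
                               float("nan"), float("nan"), None, False)
    candidates = [c for c in hom if census[c] >= 2][:2]
    if len(candidates) < 2:
        result.reason = "fewer than 2 homozygous classes with >=2 samples"
        return result
    c1, c2 = candidates
    v1 = np.array([pheno[s] for s, cl in classes.items() if cl == c1 and s in pheno])
    v2 = np.array([pheno[s] for s, cl in classes.items() if cl == c2 and s in pheno])
    if len(v1) < 2 or len(v2) < 2:
        result.reason = "fewer than 2 phenotyped samples in a class"
        return result
    t, p = stats.ttest_ind(v1, v2, equal_var=False)
    result.tested_classes = (c1, c2)
    result.mean_phenotype = {c1: float(v1.mean()), c2: float(v2.mean())}
    result.t, result.p = float(t), float(p)
    result.testable = True
    if p < alpha:
        result.favorable = c1 if v1.mean() >= v2.mean() else c2
    # class frequencies in high/low phenotype groups
    if split == "median" and len(pheno) >= 2:
        cut = float(np.median(list(pheno.values())))
        for name, cond in (("high", lambda v: v > cut), ("low", lambda v: v <= cut)):
            members = [s for s, v in pheno.items() if cond(v) and s in classes]
            if members:
                freqs: dict[str, float] = {}
                for s in members:
                    freqs[classes[s]] = freqs.get(classes[s], 0) + 1
                result.group_frequencies[name] = {
                    k: round(v / len(members), 4) for k, v in freqs.items()
                }
    return result


def associate_genes(panel: VariantPanel, genes: list[GeneModel],
                    genome: dict[str, str], phenotype: pd.DataFrame,
                    het_max: float = 0.2, maf_min: float = 0.05,
                    alpha: float = 0.05,
                    candidate_ids: list[str] | None = None) -> list[AssociationResult]:
    """Run the full haplotype association over candidate genes (default:
    every gene with retained non-synonymous SNPs)."""
    results = []
    for g in genes:
        if candidate_ids is not None and g.gene_id not in candidate_ids:
            continue
        cols = nonsyn_snps_for_gene(panel, g, genome)
        if not cols:
            continue
        kept, _ = filter_assoc_snps(panel, cols, het_max=het_max, maf_min=maf_min)
        if not kept:
            continue
        classes = build_gene_haplotypes(panel, kept)
        res = haplotype_phenotype_test(
            classes, phenotype, alpha=alpha, gene_id=g.gene_id,
            snp_positions=[int(panel.positions[j]) for j in kept])
        results.append(res)
    return results


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append((r.gene_id, ";".join(map(str, r.snp_positions)),
                     r.tested_classes[0] if r.tested_classes else "",
                     r.tested_classes[1] if r.tested_classes else "",
                     r.t, r.p, r.favorable or "", r.testable))
    return pd.DataFrame(rows, columns=["gene_id", "snp_positions", "class1", "class2",
                                       "t", "p", "favorable", "testable"])
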