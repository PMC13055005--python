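# Methods

This document describes the statistical models implemented in `haploscent`,
the design of the synthetic study generator, and the numerical choices
made throughout. Everything quantitative claimed here is either a formula
implemented in the code or a property asserted by the test suite
(`tests/`) and the acceptance script (`scripts/acceptance.py`).

## 1. Synthetic study generator (`synthetic_data`)

The generator produces a complete, internally consistent study from a
single seed: a phased diploid genome, allelic expression counts, a
four-population genotype panel and a quantitative phenotype, together
with a machine-readable truth record used for parameter recovery.

### 1.1 Diploid genome

- Haplotype 1 is simulated de novo: `n_chromosomes` (default 2)
  chromosomes of `chrom_length` (500 kb) with `n_genes` (300) multi-exon
  genes on random strands. Every CDS starts with ATG, ends with a stop
  codon and contains no internal stop on either haplotype.
- Haplotype 2 is derived from haplotype 1 by planting SNPs
  (`snp_rate` = 0.015/bp), small indels and `sv_count` (40) structural
  variants (DEL/INS, 50–5,000 bp). SNPs inside CDS are resampled when
  they would create an in-frame stop; indels and SVs are restricted to
  non-CDS sequence so that all gene models stay translatable on both
  haplotypes. Coordinates on haplotype 2 are maintained through an exact
  liftover of (position, length-delta) events.
- SV placement is class-weighted (promoter 0.45, intron 0.30, downstream
  0.20, intergenic 0.05) and recorded in the truth table. Exonic SVs are
  deliberately not planted (they would disrupt open reading frames); the
  exon attribution class is exercised by hand-built fixtures in
  `tests/test_sv_attribution.py` instead.

### 1.2 Allelic expression

Each gene pair is assigned an ASE class with proportions
(consistent, inconsistent, noASE) = (0.10, 0.30, 0.60). A class
determines the per-stage log2 allelic fold change (default effect 2.0,
i.e. 4-fold): constant and same-direction for "consistent", direction- or
presence-switching across stages for "inconsistent", zero for "noASE".
Counts for 4 stages × 3 replicates are drawn from a negative binomial
with mean set by the target depth (`mean_depth` = 200 per pair) and
dispersion α = 0.05 (variance μ + αμ²), matching common RNA-seq
overdispersion models.

### 1.3 Population panel

Allele frequencies follow a Balding–Nichols drift process down the tree
(((P1,P2),P3),O): an ancestral frequency per site is drawn uniformly,
then each branch transforms the frequency by a Beta draw with drift
parameter c via Beta(p(1−c)/c, (1−p)(1−c)/c). Branch drifts are
asymmetric — internal node n1 = 0.1, n2 = 0.05, terminal P1 = P2 = 0.05,
and P3 = 0.5 — so that the donor population P3 is strongly
differentiated, which is what gives the D and fd statistics their
contrast. The outgroup O is fixed for the ancestral allele, providing
clean polarization.

Introgression from P3 into P2 is modeled as a frequency blend,
p2' = (1−f)·p2 + f·p3 with `introgression_fraction` f (default 0.3),
applied inside `introgressed_interval` (default chr1:150,000–350,000) or
genome-wide when the interval is `None`. A locally divergent region
(default chr2:150,000–350,000) receives extra drift (0.5) on the P2
branch, creating a P1-vs-P2 Fst sweep signal.

Genotypes are drawn per sample with inbreeding F_IS = 0.8 (heavily
selfed/clonal accessions), 25 samples per population and
`pop_sites_per_chrom` = 10,000 sites per 500-kb chromosome.

### 1.4 Phenotype

One gene carries a planted causal non-synonymous SNP at population
frequency 0.5. The phenotype is
baseline + effect·dosage + N(0, σ²) with effect 6.0, σ = 2.0 and
baseline = 1 + 3σ (keeps values positive, as for a concentration trait).
The favorable allele is ALT by construction and recorded in the truth.

### 1.5 Seeding

All streams derive from one master seed through
`numpy.random.SeedSequence.spawn` (separate genome / expression /
population / phenotype streams), so any subset of the simulation is
reproducible and the streams are statistically independent. Derived
seeds stay below 2³¹.

### 1.6 Realism and limits

The generator is calibrated to plausible plant-genome scales
(≈1.5% inter-haplotype SNP heterozygosity, 4-fold ASE effects, strongly
inbred accessions, a diffuse minority-admixture signal) but it is a
caricature: no recombination or linkage within populations (sites are
exchangeable given the frequency field), no gene conversion, uniform
base composition, no sequencing error in the panel, expression effects
constant within a stage, and SVs never hit exons. These simplifications
are what make exact truth-recovery scoring possible.

### 1.7 Calibration as a design choice

Generator defaults were fixed by analytic reasoning plus throwaway
simulations **before** the corresponding tests were written, and were
not adjusted afterwards. In particular: the asymmetric drift with donor
drift 0.5 and F_IS = 0.8 were chosen so that the D statistic has both a
calibrated null (|Z| < 3 under f = 0) and high power under modest gene
flow; the D-power study condition uses genome-wide admixture
(`introgressed_interval=None`) because a block jackknife over a single
localized segment inflates the standard error through block
heterogeneity, whereas fd — a windowed statistic — is the tool used to
localize the planted interval. These are documented as design decisions,
not tuned outcomes.

## 2. Allele pairing (`allele_pairing`)

Protein sequences from the two haplotypes are compared with global
alignment; anchors are reciprocal best hits plus any hit with identity
≥ 0.7. A 4-mer prescreen (shared fraction ≥ 0.10 of the smaller 4-mer
set) avoids the all-vs-all alignment cost. Anchors are grouped by
(chromosome pair, orientation); within each group the longest strictly
monotone chain (in gene rank on both haplotypes, rank gap ≤ `max_gap`
= 25) is extracted by dynamic programming and peeled off greedily until
no chain of ≥ `min_block` = 5 anchors remains — the standard collinear
block model (MCScan-style). Tandem duplicates are collapsed to the best
representative before chaining; when a gene appears in several blocks,
the larger block wins the allele call. The chaining DP is verified
against exhaustive subset enumeration (`tests/oracles.py`).

## 3. Coding divergence (`divergence`)

CDS pairs are aligned at the protein level (Biopython
`PairwiseAligner`) and the alignment is threaded back to codons, so
gaps respect reading frame. Ka/Ks follows Nei–Gojobori (1986):

- Site counting uses the stop-excluded convention. Mutations to stop
  codons contribute to neither the synonymous nor non-synonymous site
  count, so N + S = 3 per codon always holds.
- Multi-substitution codons are averaged over all substitution orders;
  pathways passing through a stop codon are excluded (with an
  all-pathways fallback if every path hits a stop).
- Proportions are corrected with Jukes–Cantor,
  d = −¾·ln(1 − 4p/3); p ≥ 0.75 yields NaN and a "saturated" flag.
  Ks = 0 yields Ka/Ks = NaN with a "ks_zero" flag rather than infinity.

The implementation is checked at 10⁻¹² against an independent
brute-force oracle that enumerates substitution pathways recursively.
Flank divergence uses 2 kb upstream and 1 kb downstream of the CDS
(strand-aware) with the same JC correction.

## 4. Allele-specific expression (`ase`)

For each gene pair and stage, replicate counts are pooled and tested
with an exact binomial test against p₀ = T₁/(T₁+T₂), the ratio of the
stage's *library* totals — this cancels global library-size imbalance,
so a uniform 3:1 depth skew produces no calls. P-values are adjusted by
Benjamini–Hochberg within each stage; a stage is significant only if
FDR < α (0.05) **and** the library-normalized fold change (pseudocount
0.5 on both alleles) is ≥ `min_fc` = 2. Classes: "consistent" = all
stages significant with the same favored haplotype; "noASE" = no stage
significant; otherwise "inconsistent". A gene with an untestable stage
(zero counts) is never called consistent. RPKM = 10⁹·C/(N·L) is
provided for reporting.

## 5. SV attribution (`sv_attribution`)

Per gene, strand-aware functional regions in 0-based half-open
coordinates: promoter = 2 kb upstream of the start codon, downstream =
1 kb past the stop codon, exon/intron from the gene model, clipped to
chromosome bounds. Insertions are treated as 1-bp points. Each SV is
assigned the class with the largest total overlap aggregated across
genes; exact ties resolve exon > promoter > intron > downstream. Class
percentages are reported over both genic-only and all-SV denominators.

## 6. Population genetics (`popgen`)

- **π**: unbiased per-site heterozygosity 2p(1−p)·n/(n−1) over called
  alleles, summed per window and divided by the *full* window length in
  bp (not just variant sites), in 10-kb windows with 5-kb steps.
- **Fst**: Weir & Cockerham (1984) per-site components a, b, c
  (two-population case, including the observed-heterozygosity h̄ terms),
  combined as the weighted ratio Σa / Σ(a+b+c) per window. Sites where a
  population has no called alleles or n̄ ≤ 1 are NaN. Sweeps = windows
  above the top-5% quantile of non-missing windows, merged when
  overlapping; a scan with fewer than 20 non-missing windows is refused.
  Verified at 10⁻¹² against a literal transcription of the published
  equations.
- **D statistic**: Durand's frequency formulation of Patterson's D,
  polarized by the outgroup major allele (sites with outgroup
  polymorphism beyond tolerance 0.1 are dropped). The standard error is
  a delete-one block jackknife; the block size auto-shrinks until at
  least 20 blocks exist, since a Z-score from fewer blocks is
  unreliable.
- **fd** (Martin et al.): same quartet, with a dynamic donor
  P_D = max(p̂₂, p̂₃) per site, in 100-kb windows with 50-kb steps,
  requiring ≥ 10 informative sites per window; windows with a negative
  numerator are NaN, as fd is only interpretable for excess sharing.
- VCF input is parsed with `cyvcf2`; genotypes below `min_dp` = 5 are
  masked, non-biallelic sites and indels are dropped, and a sample
  missing from the group table is a hard error.

## 7. Haplotype association (`haplo_assoc`)

Non-synonymous SNPs per gene are found by strand-aware codon
substitution against the reference CDS. Sites with heterozygosity > 0.2
or MAF < 0.05 (over non-missing calls) are removed — appropriate for
highly inbred panels where residual heterozygotes are likely errors.
Samples homozygous at every retained site form concatenated haplotype
classes; everything else is "het/other" and excluded. The two most
frequent homozygous classes (each with ≥ 2 samples; ties broken
alphabetically for determinism) are compared with Welch's t-test; the
favorable haplotype is the higher-mean class when p < α. Group
frequencies of each class are reported for samples split at the
phenotype median.

## 8. Numerical and software choices

- Exact tests and corrections use `scipy.stats` (`binomtest`,
  `ttest_ind(equal_var=False)`) and `statsmodels` (`fdrcorrection`);
  alignments use Biopython; VCF I/O uses `cyvcf2`; tables are pandas.
- NaN is used consistently for "not estimable" (saturated JC, Ks = 0,
  empty windows, untestable genes) and flags say why; NaN never
  silently becomes 0.
- Window statistics are vectorized with numpy over per-site component
  arrays; no per-site Python loops in the hot paths.
- `report.json` is written with sorted keys and no timestamps, so equal
  seeds give byte-identical reports (asserted in the tests).

## 9. Validation strategy

Independent oracles were written before the implementations they check:
recursive pathway enumeration for NG86, literal Weir–Cockerham
equations for the Fst components, and exhaustive chain enumeration for
the synteny DP. End-to-end behavior is validated by truth recovery on
simulated data (allele-pair recovery, ASE class recovery, SV class
recovery, sweep and introgression localization, causal-gene detection)
in `tests/test_acceptance.py`, with null-calibration counterparts
(no-ASE false-positive rate, D under f = 0, association type-I error)
asserted alongside the power conditions.
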