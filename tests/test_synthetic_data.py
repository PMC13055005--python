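"""Tests of the synthetic study generator: validity, truth bookkeeping and
statistical behavior of each sub-generator."""

import json

import numpy as np
import pandas as pd
import pytest

from haploscent import synthetic_data as sd
from haploscent.genome import read_fasta, read_gff3, translate_cds
from haploscent import popgen as pg

from conftest import mini_sim_config


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def test_validate_rejects_bad_proportions():
    cfg = sd.SimulationConfig(ase_class_proportions=(0.5, 0.5, 0.5))
    with pytest.raises(sd.ConfigError):
        cfg.validate()


def test_validate_rejects_small_sv():
    with pytest.raises(sd.ConfigError):
        sd.SimulationConfig(sv_min_len=10).validate()


def test_validate_rejects_bad_interval():
    cfg = sd.SimulationConfig(introgressed_interval=("chr1", 400_000, 600_000))
    with pytest.raises(sd.ConfigError):
        cfg.validate()


def test_rng_streams_deterministic_and_distinct():
    a = sd.SimulationConfig(seed=9).rng_streams()
    b = sd.SimulationConfig(seed=9).rng_streams()
    assert a["genome"].integers(1 << 30) == b["genome"].integers(1 << 30)
    x = sd.SimulationConfig(seed=9).rng_streams()
    assert (x["genome"].integers(1 << 30, size=8).tolist()
            != x["expression"].integers(1 << 30, size=8).tolist())


# ---------------------------------------------------------------------------
# diploid genome (shared mini bundle)
# ---------------------------------------------------------------------------

def test_genes_have_clean_orfs(mini_bundle):
    dip = mini_bundle.diploid
    for genes, seqs in ((dip.genes1, dip.hap1), (dip.genes2, dip.hap2)):
        for g in genes:
            g.validate()
            aa = translate_cds(g.cds_sequence(seqs[g.chrom]))
            assert "*" not in aa, g.gene_id


def test_hap2_carries_planted_variant_counts(mini_bundle):
    vc = mini_bundle.truth.variant_counts
    assert vc["svs"] == 10
    # ~1.5% SNPs over 150 kb
    assert 1500 < vc["snps"] < 3200
    assert vc["indels"] > 0


def test_sv_truth_classes_only_planted_ones(mini_bundle):
    classes = {t["region_class"] for t in mini_bundle.truth.sv_truth}
    assert classes <= {"promoter", "intron", "downstream", "intergenic"}


def test_truth_pairs_cover_all_genes(mini_bundle):
    dip = mini_bundle.diploid
    truth = mini_bundle.truth.allele_pair_truth
    assert len(truth) == len(dip.genes1)
    assert all(v["hap2_gene"].endswith("_h2") for v in truth.values())


def test_ranks_assigned_both_haplotypes(mini_bundle):
    for genes in (mini_bundle.diploid.genes1, mini_bundle.diploid.genes2):
        ranks = sorted(g.rank for g in genes)
        assert ranks == list(range(len(genes)))


def test_simulate_diploid_deterministic():
    a = sd.simulate_diploid(mini_sim_config(3))
    b = sd.simulate_diploid(mini_sim_config(3))
    assert a.hap1 == b.hap1 and a.hap2 == b.hap2
    assert a.sv_table.equals(b.sv_table)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def test_expression_mean_scale_and_effect(rng):
    cfg = sd.SimulationConfig(mean_depth=300.0, n_reps=3)
    truth = sd.plant_ase_classes(400, (0.5, 0.0, 0.5), rng)
    counts = sd.simulate_expression(truth, cfg, np.random.default_rng(1))
    pooled = counts.groupby(["gene_id", "haplotype", "stage"])["count"].sum().unstack("haplotype")
    consistent = [k for k, v in truth.allele_pair_truth.items()
                  if v["ase_class"] == "consistent"]
    noase = [k for k, v in truth.allele_pair_truth.items()
             if v["ase_class"] == "noASE"]
    flat = pooled.loc[noase].to_numpy().ravel()
    assert flat.mean() == pytest.approx(300.0, rel=0.05)
    # favored haplotype carries ~4x the depth in every stage
    ratios = []
    for k in consistent:
        fav = truth.allele_pair_truth[k]["favored"]
        other = "hap2" if fav == "hap1" else "hap1"
        sub = pooled.loc[k]
        ratios.append((sub[fav] / sub[other]).mean())
    assert np.mean(ratios) == pytest.approx(4.0, rel=0.1)


def test_expression_counts_schema(mini_bundle):
    counts = mini_bundle.counts
    assert list(counts.columns) == ["gene_id", "haplotype", "stage", "replicate", "count"]
    assert set(counts["stage"]) == {1, 2, 3, 4}
    assert set(counts["replicate"]) == {1, 2, 3}
    assert (counts["count"] >= 0).all()


def test_nb_dispersion_inflates_variance(rng):
    mu = 200.0
    poisson = sd._nb(np.random.default_rng(0), mu, 0.0, 40_000)
    nb = sd._nb(np.random.default_rng(0), mu, 0.1, 40_000)
    assert np.var(poisson) == pytest.approx(mu, rel=0.05)
    assert np.var(nb) == pytest.approx(mu + 0.1 * mu * mu, rel=0.08)


def test_plant_ase_classes_proportions(rng):
    truth = sd.plant_ase_classes(6000, (0.1, 0.3, 0.6), rng)
    labels = [v["ase_class"] for v in truth.allele_pair_truth.values()]
    for cls, frac in zip(("consistent", "inconsistent", "noASE"), (0.1, 0.3, 0.6)):
        assert labels.count(cls) / 6000 == pytest.approx(frac, abs=0.03)
    # inconsistent pairs never carry effects in all stages
    for v in truth.allele_pair_truth.values():
        if v["ase_class"] == "inconsistent":
            assert 1 <= len(v["stages_affected"]) < 4


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def test_balding_nichols_moments(rng):
    p = np.full(40_000, 0.3)
    drawn = sd._balding_nichols(rng, p, 0.2)
    assert drawn.mean() == pytest.approx(0.3, abs=0.01)
    assert drawn.var() == pytest.approx(0.2 * 0.3 * 0.7, rel=0.05)
    assert (drawn >= 0).all() and (drawn <= 1).all()


def test_balding_nichols_zero_drift_identity(rng):
    p = rng.uniform(0, 1, 100)
    assert np.array_equal(sd._balding_nichols(rng, p, 0.0), p)


def test_draw_genotypes_inbreeding(rng):
    p = np.full(5000, 0.5)
    full_inbred = sd._draw_genotypes(rng, p, 40, 1.0)
    assert not (full_inbred == 1).any()
    hwe = sd._draw_genotypes(rng, p, 40, 0.0)
    assert np.isclose((hwe == 1).mean(), 0.5, atol=0.03)


def test_population_outgroup_fixed_ancestral(mini_bundle):
    pop = mini_bundle.pop
    out_rows = [i for i, s in enumerate(pop.samples) if pop.groups[s] == "O"]
    assert (pop.dosage[out_rows] == 0).all()


def test_population_shapes_and_freq_bounds(mini_bundle):
    pop = mini_bundle.pop
    m = pop.sites.shape[0]
    assert pop.dosage.shape == (40, m)
    for k in ("P1", "P2", "P3"):
        assert ((pop.freqs[k] >= 0) & (pop.freqs[k] <= 1)).all()


def test_full_introgression_copies_donor(rng):
    cfg = mini_sim_config()
    cfg.introgression_fraction = 1.0
    pop = sd.simulate_population(cfg, rng)
    it = pop.truth.introgression_truth
    mask = ((pop.sites["chrom"] == it["chrom"]).values
            & (pop.sites["pos"].values - 1 >= it["start0"])
            & (pop.sites["pos"].values - 1 < it["end"]))
    assert np.allclose(pop.freqs["P2"][mask], pop.freqs["P3"][mask])
    assert not np.allclose(pop.freqs["P2"][~mask], pop.freqs["P3"][~mask])


def test_genome_wide_interval_none(rng):
    cfg = mini_sim_config()
    cfg.introgressed_interval = None
    cfg.introgression_fraction = 1.0
    pop = sd.simulate_population(cfg, rng)
    assert pop.truth.introgression_truth["chrom"] == "*"
    assert np.allclose(pop.freqs["P2"], pop.freqs["P3"])


def test_vcf_roundtrip(tmp_path, mini_bundle):
    pop = mini_bundle.pop
    sd.write_vcf(pop, tmp_path / "p.vcf", dp=30)
    sd.write_groups(pop, tmp_path / "g.tsv")
    panel = pg.load_vcf(tmp_path / "p.vcf", tmp_path / "g.tsv", min_dp=5)
    assert panel.dosage.shape == pop.dosage.shape
    assert np.array_equal(panel.dosage, pop.dosage)
    assert panel.positions.tolist() == pop.sites["pos"].tolist()


# ---------------------------------------------------------------------------
# causal SNP + phenotype
# ---------------------------------------------------------------------------

def test_causal_snp_is_nonsynonymous(mini_bundle):
    from haploscent.haplo_assoc import classify_coding_effect
    ct = mini_bundle.truth.causal_truth
    dip = mini_bundle.diploid
    gene = next(g for g in dip.genes1 if g.gene_id == ct["gene_id"])
    eff = classify_coding_effect(ct["chrom"], ct["positions"][0], ct["ref"],
                                 ct["favorable"], gene, dip.hap1)
    assert eff.effect == "nonsynonymous"


def test_phenotype_effect_size(mini_bundle):
    pop, pheno = mini_bundle.pop, mini_bundle.phenotype
    ct = mini_bundle.truth.causal_truth
    j = int(np.flatnonzero((pop.sites["chrom"] == ct["chrom"]).values
                           & (pop.sites["pos"] == ct["positions"][0]).values)[0])
    dos = pop.dosage[:, j]
    vals = pheno.set_index("sample").loc[pop.samples, "pe_ug_per_g"].to_numpy()
    hom_fav = vals[dos == 2]
    hom_ref = vals[dos == 0]
    # planted effect: 6 ug/g per favorable copy -> 12 between homozygotes
    assert hom_fav.mean() - hom_ref.mean() == pytest.approx(12.0, abs=2.5)
    assert (vals > 0).all()


def test_phenotype_requires_causal(rng):
    cfg = mini_sim_config()
    pop = sd.simulate_population(cfg, rng)
    with pytest.raises(sd.ConfigError):
        sd.simulate_phenotype(pop, cfg)


# ---------------------------------------------------------------------------
# bundle + files
# ---------------------------------------------------------------------------

def test_simulate_all_writes_files(tmp_path):
    cfg = mini_sim_config(7)
    sd.simulate_all(cfg, tmp_path)
    names = {p.name for p in tmp_path.iterdir()}
    assert {"hap1.fa", "hap2.fa", "hap1.gff3", "hap2.gff3", "sv.tsv",
            "counts.tsv", "population.vcf", "groups.tsv", "phenotype.tsv",
            "truth.json"} <= names
    # round-trips
    seqs = read_fasta(tmp_path / "hap1.fa")
    genes = read_gff3(tmp_path / "hap1.gff3")
    assert len(genes) == cfg.n_genes
    for g in genes[:5]:
        assert "*" not in translate_cds(g.cds_sequence(seqs[g.chrom]))
    truth = sd.TruthSet.from_json(tmp_path / "truth.json")
    assert truth.causal_truth["gene_id"]
    pheno = pd.read_csv(tmp_path / "phenotype.tsv", sep="\t")
    assert {"sample", "group", "pe_ug_per_g"} <= set(pheno.columns)
    json.loads((tmp_path / "truth.json").read_text())  # valid JSON
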