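"""Unit and oracle tests for pi, Fst, D and fd."""

import math

import numpy as np
import pytest

from haploscent import popgen as pg

from oracles import wc_site_oracle


def make_panel(dosage, positions=None, chrom="chr1", chrom_len=100_000,
               groups=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    positions = np.asarray(positions if positions is not None
                           else np.arange(1, m + 1) * 10, dtype=np.int64)
    samples = [f"s{i}" for i in range(n)]
    groups = groups or {s: "G" for s in samples}
    return pg.VariantPanel(
        chroms=np.array([chrom] * m),
        positions=positions,
        ref=np.array(["A"] * m),
        alt=np.array(["T"] * m),
        dosage=dosage,
        samples=samples,
        groups=groups,
        chrom_lengths={chrom: chrom_len},
    )


def four_pop_panel(d1, d2, d3, d4, **kw):
    """Stack per-population dosage matrices into one labeled panel."""
    mats = [np.asarray(x, dtype=np.int8) for x in (d1, d2, d3, d4)]
    dosage = np.vstack(mats)
    groups = {}
    i = 0
    for pop, mat in zip(("P1", "P2", "P3", "O"), mats):
        for _ in range(mat.shape[0]):
            groups[f"s{i}"] = pop
            i += 1
    return make_panel(dosage, groups=groups, **kw)


# ---------------------------------------------------------------------------
# pi
# ---------------------------------------------------------------------------

def test_site_pi_manual():
    # 3 individuals, p = 2/6, n = 6 alleles: pi = 2*(1/3)*(2/3)*6/5
    pi, n = pg.site_pi(np.array([[0], [1], [1]], dtype=np.int8))
    assert n[0] == 6
    assert pi[0] == pytest.approx(2 * (1 / 3) * (2 / 3) * 6 / 5)


def test_site_pi_missing_excluded():
    pi, n = pg.site_pi(np.array([[0], [pg.MISSING], [2]], dtype=np.int8))
    assert n[0] == 4
    assert pi[0] == pytest.approx(2 * 0.5 * 0.5 * 4 / 3)


def test_site_pi_monomorphic_zero():
    pi, _ = pg.site_pi(np.zeros((5, 1), dtype=np.int8))
    assert pi[0] == 0.0


def test_pi_windows_full_window_denominator():
    # one het site among 4 individuals in a 1 kb window
    panel = make_panel(np.array([[1], [1], [0], [0]]), positions=[500],
                       chrom_len=1000)
    w = pg.pi_windows(panel, window=1000, step=1000)
    site = 2 * 0.25 * 0.75 * 8 / 7
    assert len(w) == 1
    assert w[0].value == pytest.approx(site / 1000)


def test_genome_pi_matches_sum():
    rng = np.random.default_rng(0)
    panel = make_panel(rng.integers(0, 3, size=(10, 50)), chrom_len=2000)
    pi, _ = pg.site_pi(panel.dosage)
    assert pg.genome_pi(panel) == pytest.approx(np.nansum(pi) / 2000)


def test_tile_windows():
    assert list(pg.tile_windows(25, 10, 5)) == [(0, 10), (5, 15), (10, 20),
                                                (15, 25), (20, 25)]
    with pytest.raises(ValueError):
        list(pg.tile_windows(25, 5, 10))


# ---------------------------------------------------------------------------
# Weir & Cockerham
# ---------------------------------------------------------------------------

def test_wc_components_match_oracle_random():
    rng = np.random.default_rng(12)
    dosA = rng.integers(0, 3, size=(15, 80)).astype(np.int8)
    dosB = rng.integers(0, 3, size=(12, 80)).astype(np.int8)
    # sprinkle missing genotypes
    dosA[rng.random(dosA.shape) < 0.1] = pg.MISSING
    dosB[rng.random(dosB.shape) < 0.1] = pg.MISSING
    a, b, c = pg.wc_site_components(dosA, dosB)
    for j in range(80):
        want = wc_site_oracle(list(dosA[:, j]), list(dosB[:, j]))
        if want is None:
            assert math.isnan(a[j])
        else:
            assert (a[j], b[j], c[j]) == pytest.approx(want, abs=1e-12)


def test_wc_fixed_difference_is_one():
    dosA = np.zeros((20, 5), dtype=np.int8)
    dosB = np.full((20, 5), 2, dtype=np.int8)
    a, b, c = pg.wc_site_components(dosA, dosB)
    assert np.allclose(a / (a + b + c), 1.0)


def test_wc_no_calls_nan():
    dosA = np.full((5, 1), pg.MISSING, dtype=np.int8)
    dosB = np.zeros((5, 1), dtype=np.int8)
    a, _, _ = pg.wc_site_components(dosA, dosB)
    assert math.isnan(a[0])


def test_fst_windows_weighted_ratio():
    rng = np.random.default_rng(5)
    d1 = rng.integers(0, 3, size=(10, 40)).astype(np.int8)
    d2 = rng.integers(0, 3, size=(10, 40)).astype(np.int8)
    panel = four_pop_panel(d1, d2, d1, d2, chrom_len=500)
    w = pg.fst_wc_windows(panel, "P1", "P2", window=500, step=500)
    a, b, c = pg.wc_site_components(d1, d2)
    assert w[0].value == pytest.approx(np.nansum(a) / np.nansum(a + b + c))


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def wstat(chrom, s0, e0, v):
    return pg.WindowStat(chrom, s0, e0, 10, v)


def test_select_sweeps_threshold_and_merge():
    vals = list(np.linspace(0.0, 0.9, 39)) + [0.95]
    stats = [wstat("c", i * 100, i * 100 + 200, v) for i, v in enumerate(vals)]
    thresh, regions = pg.select_sweeps(stats, top_frac=0.05)
    assert thresh == pytest.approx(np.quantile(vals, 0.95))
    # the two top overlapping windows merge into one region
    assert len(regions) == 1
    assert regions[0].max_value == pytest.approx(0.95)


def test_select_sweeps_needs_enough_windows():
    stats = [wstat("c", 0, 100, 0.5)] * 5
    with pytest.raises(ValueError):
        pg.select_sweeps(stats)


def test_select_sweeps_gene_annotation():
    from conftest import make_gene
    stats = [wstat("chr1", i * 1000, i * 1000 + 1000, 0.1) for i in range(30)]
    stats[3] = wstat("chr1", 3000, 4000, 0.99)
    g = make_gene("hit", "chr1", "+", exons=[(3500, 3800)])
    _, regions = pg.select_sweeps(stats, genes=[g])
    assert regions[0].genes == ["hit"]


# ---------------------------------------------------------------------------
# polarization, D, fd
# ---------------------------------------------------------------------------

def test_derived_freqs_flips_when_outgroup_alt():
    # outgroup fixed ALT -> ancestral allele is ALT, derived freq = 1 - p
    d1 = np.array([[2, 0]] * 4)
    d4 = np.array([[2, 2]] * 4)
    panel = four_pop_panel(d1, d1, d1, d4, chrom_len=100)
    (f1, _, _, fo), ok = pg.derived_freqs(panel, ("P1", "P2", "P3", "O"))
    assert ok.all()
    assert f1[0] == pytest.approx(0.0)  # ALT-fixed becomes ancestral
    assert f1[1] == pytest.approx(1.0)
    assert np.allclose(fo, 0.0)


def test_derived_freqs_polymorphic_outgroup_masked():
    d = np.array([[1, 0]] * 4)       # outgroup het at site 0
    dI = np.array([[0, 1]] * 4)
    panel = four_pop_panel(dI, dI, dI, d, chrom_len=100)
    _, ok = pg.derived_freqs(panel, ("P1", "P2", "P3", "O"))
    assert not ok[0] and ok[1]


def test_d_statistic_hand_example():
    """One pure ABBA site and nothing else -> D = 1."""
    z = np.zeros((4, 3), dtype=np.int8)
    d1 = z.copy()
    d2 = z.copy(); d2[:, 1] = 2
    d3 = z.copy(); d3[:, 1] = 2
    panel = four_pop_panel(d1, d2, d3, z, chrom_len=100)
    res = pg.d_statistic(panel, "P1", "P2", "P3", "O")
    assert res.D == pytest.approx(1.0)
    assert res.abba_sum == pytest.approx(1.0)
    assert res.baba_sum == pytest.approx(0.0)


def test_d_statistic_antisymmetric_in_p1_p2():
    rng = np.random.default_rng(8)
    mats = [rng.integers(0, 3, size=(8, 300)).astype(np.int8) for _ in range(3)]
    panel = four_pop_panel(mats[0], mats[1], mats[2],
                           np.zeros((8, 300), dtype=np.int8), chrom_len=5000)
    d12 = pg.d_statistic(panel, "P1", "P2", "P3", "O")
    d21 = pg.d_statistic(panel, "P2", "P1", "P3", "O")
    assert d12.D == pytest.approx(-d21.D, abs=1e-12)


def test_d_statistic_no_informative_sites():
    z = np.zeros((4, 5), dtype=np.int8)
    panel = four_pop_panel(z, z, z, z, chrom_len=100)
    res = pg.d_statistic(panel, "P1", "P2", "P3", "O")
    assert math.isnan(res.D) and res.n_blocks == 0


def test_fd_equals_one_when_p2_is_donor_copy():
    """P2 identical to P3 -> the dynamic-donor denominator equals the
    numerator in windows with positive D."""
    rng = np.random.default_rng(3)
    d3 = rng.integers(0, 3, size=(10, 120)).astype(np.int8)
    d1 = np.zeros_like(d3)
    panel = four_pop_panel(d1, d3.copy(), d3, np.zeros_like(d3),
                           positions=np.arange(1, 121) * 10, chrom_len=1200)
    w = pg.fd_windows(panel, "P1", "P2", "P3", "O", window=1200, step=1200,
                      min_sites=5)
    assert w[0].value == pytest.approx(1.0)


def test_fd_window_min_sites_nan():
    z = np.zeros((4, 5), dtype=np.int8)
    panel = four_pop_panel(z, z, z, z, chrom_len=100)
    w = pg.fd_windows(panel, "P1", "P2", "P3", "O", window=100, step=100,
                      min_sites=10)
    assert math.isnan(w[0].value)


def test_fd_negative_numerator_nan():
    """A pure BABA window (negative D) is reported missing, not negative."""
    z = np.zeros((4, 12), dtype=np.int8)
    d1 = z.copy(); d1[:, :] = 2
    d3 = z.copy(); d3[:, :] = 2
    panel = four_pop_panel(d1, z.copy(), d3, z.copy(), chrom_len=200)
    w = pg.fd_windows(panel, "P1", "P2", "P3", "O", window=200, step=200,
                      min_sites=5)
    assert math.isnan(w[0].value)


# ---------------------------------------------------------------------------
# VCF loading
# ---------------------------------------------------------------------------

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=5000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
"""


def write_vcf(tmp_path, body):
    p = tmp_path / "t.vcf"
    p.write_text(VCF_HEADER + body)
    g = tmp_path / "groups.tsv"
    g.write_text("sample\tgroup\ns1\tP1\ns2\tP2\n")
    return p, g


def test_load_vcf_basic(tmp_path):
    vcf, grp = write_vcf(tmp_path,
                         "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT:DP\t0/1:30\t1/1:30\n")
    panel = pg.load_vcf(vcf, grp)
    assert panel.dosage.tolist() == [[1], [2]]
    assert panel.chrom_length("chr1") == 5000
    assert panel.group_rows("P2") == [1]


def test_load_vcf_low_dp_masked(tmp_path):
    vcf, grp = write_vcf(tmp_path,
                         "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT:DP\t0/1:2\t1/1:30\n")
    panel = pg.load_vcf(vcf, grp, min_dp=5)
    assert panel.dosage[0, 0] == pg.MISSING
    assert panel.dosage[1, 0] == 2


def test_load_vcf_non_snp_dropped(tmp_path):
    body = ("chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT:DP\t0/1:30\t1/1:30\n"
            "chr1\t200\t.\tAT\tA\t.\tPASS\t.\tGT:DP\t0/1:30\t0/0:30\n"
            "chr1\t300\t.\tA\tT,G\t.\tPASS\t.\tGT:DP\t0/1:30\t0/0:30\n")
    vcf, grp = write_vcf(tmp_path, body)
    panel = pg.load_vcf(vcf, grp)
    assert panel.positions.tolist() == [100]


def test_load_vcf_unknown_sample_errors(tmp_path):
    vcf, _ = write_vcf(tmp_path,
                       "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT:DP\t0/1:30\t1/1:30\n")
    g = tmp_path / "g2.tsv"
    g.write_text("sample\tgroup\ns1\tP1\n")  # s2 unassigned
    with pytest.raises(ValueError):
        pg.load_vcf(vcf, g)


def test_subset_group():
    panel = four_pop_panel(np.zeros((3, 4), dtype=np.int8),
                           np.ones((3, 4), dtype=np.int8),
                           np.zeros((2, 4), dtype=np.int8),
                           np.zeros((2, 4), dtype=np.int8))
    sub = panel.subset_group("P2")
    assert sub.dosage.shape == (3, 4)
    assert (sub.dosage == 1).all()
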