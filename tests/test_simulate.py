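"""Generator tests: genome ground truth, meiosis, phenotypes, bulks, panel."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imlocus import io, linkage, simulate
from imlocus.simulate import BulkModel, ChromPair, GenomeSpec, Locus, PhenotypeModel


# --- genome -----------------------------------------------------------------

def _small_spec(rate, length=20_000):
    return GenomeSpec(
        pairs=[ChromPair("A03", "D03", length)],
        homeosnp_rate=rate,
        gene_cds_start=2_001,
    )


def test_zero_divergence_gives_identical_homeologs():
    g = simulate.simulate_genome(_small_spec(0.0), seed=3)
    assert g.sequences["A03"] == g.sequences["D03"]
    assert len(g.homeosnp_sites) == 0


def test_homeosnp_count_matches_ground_truth_list():
    # 1-Mb pair at rate 1e-3: ~1000 homeoSNPs, and the emitted list is exact
    g = simulate.simulate_genome(
        GenomeSpec(pairs=[ChromPair("A03", "D03", 1_000_000)], homeosnp_rate=1e-3,
                   gene_cds_start=500_001),
        seed=7,
    )
    a, d = g.sequences["A03"], g.sequences["D03"]
    diff_positions = [i + 1 for i, (x, y) in enumerate(zip(a, d)) if x != y]
    assert diff_positions == list(g.homeosnp_sites["pos"])
    assert 800 < len(diff_positions) < 1200  # ~Poisson(1000)
    # every recorded site really differs with the recorded bases
    for row in g.homeosnp_sites.head(50).itertuples():
        assert a[row.pos - 1] == row.a_base and d[row.pos - 1] == row.d_base


def test_genome_is_deterministic_for_fixed_seed():
    g1 = simulate.simulate_genome(_small_spec(0.01), seed=5)
    g2 = simulate.simulate_genome(_small_spec(0.01), seed=5)
    assert g1.sequences == g2.sequences
    assert g1.homeosnp_sites.equals(g2.homeosnp_sites)


def test_causal_deletion_bookkeeping(genome):
    gene = genome.causal_gene
    cv = genome.causal_variant
    ref = genome.sequences[cv.chromosome]
    assert ref[cv.pos - 1 : cv.pos - 1 + cv.length] == cv.deleted
    assert gene.cds_start <= cv.pos <= gene.cds_end  # inside the coding exon
    assert len(genome.mutant_cds()) == len(gene.cds_sequence) - 22
    assert len(gene.cds_sequence) == 3072  # 1023 codons + stop
    assert len(genome.mutant_cds()) == 3050


def test_gene_model_invariants(genome):
    gene = genome.causal_gene
    assert len(gene.cds_sequence) % 3 == 0
    assert gene.cds_sequence.startswith("ATG")
    assert gene.cds_sequence[-3:] in {"TAA", "TAG", "TGA"}
    assert len(gene.protein) == 1023
    assert len(gene.repeat_blocks) == 25


def test_gene_model_rejects_bad_cds():
    with pytest.raises(ValueError, match="ATG"):
        simulate.GeneModel("g", "A01", 1, 6, "+", "TTGTAA", 1, [])
    with pytest.raises(ValueError, match="stop"):
        simulate.GeneModel("g", "A01", 1, 6, "+", "ATGAAA", 1, [])


# --- F2 meiosis -------------------------------------------------------------

def test_complete_linkage_marker_equals_causal():
    loci = [Locus("causal", "A03", 100, 5.0), Locus("M", "A03", 200, 5.0)]
    pop = simulate.simulate_f2(300, loci, seed=2)
    assert (pop.genotypes["M"] == pop.genotypes["causal"]).all()


def test_causal_bb_fraction_within_binomial_bounds():
    pop = simulate.simulate_f2(2837, [Locus("causal", "A03", 1, 0.0)], seed=4)
    n_bb = int((pop.causal_genotypes == "BB").sum())
    # 99% binomial bounds around p = 1/4 at n = 2837
    lo, hi = stats.binom.ppf([0.005, 0.995], 2837, 0.25)
    assert lo <= n_bb <= hi


def test_two_marker_recombination_matches_map_function():
    # 10 cM apart: observed recombinant-gamete fraction ~ Haldane inverse
    loci = [Locus("causal", "A03", 1, 0.0), Locus("M", "A03", 2, 10.0)]
    pop = simulate.simulate_f2(10_000, loci, seed=6)
    est = linkage.estimate_r(pop.genotypes["causal"], pop.genotypes["M"])
    expected = simulate.recombination_fraction(10.0, "haldane")
    se = np.sqrt(expected * (1 - expected) / (2 * 10_000))
    assert abs(est.r_hat - expected) < 3 * se


def test_one_two_one_segregation_chi2():
    ok = 0
    for seed in range(5):
        pop = simulate.simulate_f2(2000, [Locus("causal", "A03", 1, 0.0)], seed=seed)
        counts = pop.causal_genotypes.value_counts()
        obs = [counts.get(c, 0) for c in ("AA", "AB", "BB")]
        chi2, p = stats.chisquare(obs, [500, 1000, 500])
        ok += p > 0.001
    assert ok == 5


def test_negative_cm_interval_rejected():
    # physical order 1 < 2 < 3 bp but genetic order 0, 5, 3 cM: the middle
    # interval is negative however the loci are oriented
    loci = [
        Locus("causal", "A03", 1, 0.0),
        Locus("M1", "A03", 2, 5.0),
        Locus("M2", "A03", 3, 3.0),
    ]
    with pytest.raises(ValueError, match="negative cM"):
        simulate.simulate_f2(5, loci, seed=0)
    with pytest.raises(ValueError, match="n must be >= 1"):
        simulate.simulate_f2(0, loci[:2], seed=0)


def test_f2_determinism_and_individuals_view():
    loci = [Locus("causal", "A03", 1, 0.0), Locus("M", "A03", 2, 3.0)]
    a = simulate.simulate_f2(50, loci, seed=9)
    b = simulate.simulate_f2(50, loci, seed=9)
    assert a.genotypes.equals(b.genotypes)
    ind = next(a.individuals())
    assert ind.causal_genotype in {"AA", "AB", "BB"}
    assert set(ind.genotypes) == {"M"}


# --- phenotypes --------------------------------------------------------------

def test_phenotypes_are_class_separable_and_marginal_zone_populated():
    pop = simulate.simulate_f2(2981, [Locus("causal", "A03", 1, 0.0)], seed=11)
    phen = simulate.assign_phenotypes(pop, seed=12)
    classes = linkage.classify_phenotypes(phen)
    scored = classes != linkage.UNCLASSIFIED
    # the classifier recovers the true class for every scorable plant
    assert (classes[scored] == phen.loc[scored, "true_class"].map(
        {"im": linkage.IM, "wild_type": linkage.WILD_TYPE})).all()
    # ~5% of phenotyped plants fall in the marginal 26-29% lint zone
    lint = phen["lint_pct"].dropna()
    marginal = ((lint > 26) & (lint <= 29)).mean()
    assert 0.02 < marginal < 0.09
    # micronaire is always drawn, including for no-phenotype plants
    assert phen["mic"].notna().all()


def test_no_phenotype_count_matches_published_rate():
    pop = simulate.simulate_f2(2981, [Locus("causal", "A03", 1, 0.0)], seed=13)
    phen = simulate.assign_phenotypes(pop, seed=14)
    n_missing = int(phen["lint_pct"].isna().sum())
    lo, hi = stats.binom.ppf([0.005, 0.995], 2981, 144 / 2981)
    assert lo <= n_missing <= hi  # expected ~144


def test_perfectly_separable_when_no_missing():
    model = PhenotypeModel(no_phenotype_rate=0.0)
    pop = simulate.simulate_f2(500, [Locus("causal", "A03", 1, 0.0)], seed=15)
    phen = simulate.assign_phenotypes(pop, model, seed=16)
    classes = linkage.classify_phenotypes(phen)
    assert (classes != linkage.UNCLASSIFIED).all()
    assert (classes == phen["true_class"].map(
        {"im": linkage.IM, "wild_type": linkage.WILD_TYPE})).all()


def test_phenotype_model_validation():
    with pytest.raises(ValueError):
        PhenotypeModel(wildtype_lint_sd=0.0)
    with pytest.raises(ValueError):
        PhenotypeModel(no_phenotype_rate=1.0)


# --- bulk variants ------------------------------------------------------------

@pytest.fixture(scope="module")
def bulk_run(genome):
    return simulate.simulate_bsa_experiment(genome, seed=21)


def test_bulk_allele_frequencies(bulk_run, genome):
    records, pop, phen = bulk_run
    by_name = {f"{r.chrom}_{r.pos}": r for r in records}
    causal_rec = next(r for r in records if r.is_indel)
    # the causal site: im bulk nearly fixed for the deletion allele,
    # wild-type bulk near 1/3 (1:2 AA:AB among non-im plants)
    ref_d, alt_d = causal_rec.depths["im_bulk"]
    assert alt_d / (ref_d + alt_d) > 0.95
    ref_d, alt_d = causal_rec.depths["wt_bulk"]
    assert 0.15 < alt_d / (ref_d + alt_d) < 0.5
    # an unlinked site: ~0.5 in both bulks
    unlinked = [r for r in records if r.chrom != genome.causal_variant.chromosome]
    fracs = []
    for r in unlinked:
        for bulk in ("im_bulk", "wt_bulk"):
            rd, ad = r.depths[bulk]
            fracs.append(ad / max(rd + ad, 1))
    assert abs(np.mean(fracs) - 0.5) < 0.05


def test_bulk_qual_separates_linked_from_background(bulk_run, genome):
    records, _, _ = bulk_run
    cv = genome.causal_variant
    causal_rec = next(r for r in records if r.is_indel)
    assert causal_rec.qual > 50
    background = [r.qual for r in records if r.chrom != cv.chromosome]
    assert np.mean([q > 50 for q in background]) < 0.05


def test_bulk_vcf_round_trip(bulk_run, tmp_path):
    records, _, _ = bulk_run
    p = tmp_path / "bulks.vcf"
    io.write_vcf(records, p)
    assert io.read_vcf(p) == records


def test_empty_bulk_raises(genome):
    pop = simulate.simulate_f2(10, [Locus("causal", "A03", 1, 0.0)], seed=1)
    phen = simulate.assign_phenotypes(pop, seed=1)
    phen["true_class"] = "wild_type"  # no im plants at all
    with pytest.raises(ValueError, match="bulk"):
        simulate.make_bulk_variants(pop, phen, genome, BulkModel(bulk_size=2), seed=1)


def test_bulk_model_validation():
    with pytest.raises(ValueError):
        BulkModel(bulk_size=0)
    with pytest.raises(ValueError):
        BulkModel(error_rate=0.6)


# --- panel --------------------------------------------------------------------

def test_panel_single_wildtype_haplotype_all_green():
    hap = [simulate.Haplotype(1.0, {"CFBid0001": "wt", "CFB5887": "wt"})]
    gt = simulate.simulate_panel(20, hap, seed=1, cultivated=False)
    assert (gt == "AA").all().all()


def test_panel_triple_im_count_near_30_of_163():
    counts = []
    for seed in range(20):
        gt = simulate.simulate_panel(163, seed=seed)
        triple = ((gt[["CFB5887", "CFB5888", "CFBid0002"]] == "BB").all(axis=1)).sum()
        counts.append(int(triple))
    assert abs(np.mean(counts) - 30) < 3  # expectation 30 under the default haplotypes


def test_cultivated_flag_forces_candidate_wildtype():
    for seed in range(5):
        gt = simulate.simulate_panel(163, seed=seed, cultivated=True)
        assert (gt["CFBid0001"] == "AA").all()


def test_panel_haplotype_frequencies_must_sum_to_one():
    hap = [simulate.Haplotype(0.5, {"m": "wt"})]
    with pytest.raises(ValueError, match="sum"):
        simulate.simulate_panel(10, hap, seed=0)


# --- expression ----------------------------------------------------------------

def test_expression_null_truth_and_shapes():
    counts, lengths, truth = simulate.simulate_expression(n_genes=10, seed=3)
    assert counts.shape == (10, 4)
    assert (truth["true_log2fc"] == 0).all()
    assert (lengths > 0).all()


def test_expression_recovers_planted_fold_change():
    from imlocus import expression

    errs = []
    for seed in range(5):
        # adequate depth: three replicates and low technical dispersion
        counts, lengths, truth = simulate.simulate_expression(
            n_genes=20, n_reps=3, de_spec={0: -2.1}, dispersion=0.01, seed=seed
        )
        rp = expression.rpkm(counts, lengths)
        grp = rp.T.groupby(["a", "a", "a", "b", "b", "b"]).mean().T
        fc = np.log2((grp["b"].iloc[0] + 0.05) / (grp["a"].iloc[0] + 0.05))
        errs.append(abs(fc - (-2.1)))
    assert max(errs) < 0.5


def test_expression_321_fold_gene_is_top_ranked():
    fc321 = float(np.log2(321))
    counts, lengths, truth = simulate.simulate_expression(
        n_genes=38, de_spec={5: fc321}, seed=9
    )
    from imlocus import expression

    rp = expression.rpkm(counts, lengths)
    grp = rp.T.groupby(["a", "a", "b", "b"]).mean().T
    ratio = (grp["b"] + 0.01) / (grp["a"] + 0.01)
    assert ratio.idxmax() == counts.index[5]
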