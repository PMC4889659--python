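"""Subgenome-specific assay design and in-silico PCR validation."""
import numpy as np
import pytest

from imlocus import markers
from imlocus.markers import HomeoSnp, PrimerParams, revcomp


def _toy_template(seed=0, length=200):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


# --- homeoSNP discovery ------------------------------------------------------

def test_identical_homeologs_have_no_homeosnps():
    s = _toy_template(1)
    assert markers.find_homeosnps(s, s) == []


def test_planted_differences_recovered_exactly():
    a = _toy_template(2, 100)
    d = list(a)
    planted = {10: "A", 50: "C", 90: "G"}
    for pos, base in planted.items():
        d[pos - 1] = base if a[pos - 1] != base else ("T" if base != "T" else "A")
    d = "".join(d)
    found = markers.find_homeosnps(a, d)
    assert [h.pos for h in found] == sorted(planted)
    for h in found:
        assert h.a_base == a[h.pos - 1] and h.d_base == d[h.pos - 1]


def test_homeosnps_match_simulator_ground_truth(genome):
    chrom_a, chrom_d = "A03", "D03"
    lo, hi = 10_000, 12_000
    a = genome.sequences[chrom_a][lo:hi]
    d = genome.sequences[chrom_d][lo:hi]
    found = {h.pos + lo for h in markers.find_homeosnps(a, d)}
    truth = {
        int(r.pos)
        for r in genome.homeosnp_sites.itertuples()
        if r.chromosome == chrom_a and lo < r.pos <= hi
    }
    assert found == truth


def test_length_mismatch_without_alignment_rejected():
    with pytest.raises(ValueError, match="equal-length"):
        markers.find_homeosnps("ACGT", "ACGTT")


# --- SNP assay ---------------------------------------------------------------

@pytest.fixture()
def snp_design():
    rng = np.random.default_rng(2)
    template = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 160)])
    snp_pos = 60
    wild = template[snp_pos - 1]
    mutant = {"A": "G", "G": "A", "C": "T", "T": "C"}[wild]
    anchor_pos = 100
    d_template = list(template)
    d_template[anchor_pos - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[template[anchor_pos - 1]]
    homeo = [HomeoSnp("A03", anchor_pos, template[anchor_pos - 1], d_template[anchor_pos - 1])]
    assay = markers.design_snp_assay(template, snp_pos, wild, mutant, homeo, name="CFB5887_like")
    mutant_a = template[: snp_pos - 1] + mutant + template[snp_pos:]
    mutant_d = list(mutant_a)
    mutant_d[anchor_pos - 1] = d_template[anchor_pos - 1]
    return {
        "assay": assay,
        "template": template,
        "snp_pos": snp_pos,
        "anchor_pos": anchor_pos,
        "wild": wild,
        "mutant": mutant,
        "templates": {
            "wild_A": template,
            "mutant_A": mutant_a,
            "wild_D": "".join(d_template),
            "mutant_D": "".join(mutant_d),
        },
    }


def test_snp_assay_primer_rules(snp_design):
    assay, template = snp_design["assay"], snp_design["template"]
    snp_pos, anchor_pos = snp_design["snp_pos"], snp_design["anchor_pos"]
    # forward 3' base is the mutant allele
    assert assay.forward[-1] == snp_design["mutant"]
    # the 3'-to-3' span is the SNP-to-homeoSNP distance (41 in this layout)
    assert assay.span_3prime == anchor_pos - snp_pos + 1 == 41
    # full amplicon includes both primer footprints
    assert assay.product_sizes["mutant_A"] == 41 + len(assay.forward) - 1 + len(assay.reverse) - 1
    # third-from-3' engineered mismatch is the annealing-strand (self-pairing) base
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    assert assay.forward[-3] == comp[template[snp_pos - 3]]
    assert assay.reverse[-3] == template[anchor_pos + 1]
    # reverse primer is the reverse complement of the template footprint
    # except at the engineered position
    footprint = template[anchor_pos - 1 : anchor_pos - 1 + len(assay.reverse)]
    expected = list(revcomp(footprint))
    diffs = [i for i, (a, b) in enumerate(zip(assay.reverse, expected)) if a != b]
    assert diffs == [len(assay.reverse) - 3]
    # forward differs from template only at the allele base and the engineered position
    f_foot = template[snp_pos - len(assay.forward) : snp_pos]
    fdiffs = [i for i, (a, b) in enumerate(zip(assay.forward, f_foot)) if a != b]
    assert fdiffs == [len(assay.forward) - 3, len(assay.forward) - 1]
    assert 18 <= len(assay.forward) <= 25 and 18 <= len(assay.reverse) <= 25


def test_snp_assay_amplifies_only_mutant_a(snp_design):
    pcr = markers.insilico_pcr(snp_design["assay"], snp_design["templates"])
    assert pcr["mutant_A"].amplifies
    assert pcr["mutant_A"].products == [snp_design["assay"].product_sizes["mutant_A"]]
    for other in ("wild_A", "wild_D", "mutant_D"):
        assert not pcr[other].amplifies, other


def test_snp_assay_requires_anchor_in_range():
    template = _toy_template(9, 500)
    with pytest.raises(markers.PrimerDesignError, match="no anchor"):
        markers.design_snp_assay(template, 50, template[49], "A" if template[49] != "A" else "C", [])


def test_nearest_anchor_preferred():
    template = _toy_template(2, 300)
    wild = template[59]
    mutant = {"A": "G", "G": "A", "C": "T", "T": "C"}[wild]
    homeo = [
        HomeoSnp("A03", 150, template[149], "A" if template[149] != "A" else "C"),
        HomeoSnp("A03", 100, template[99], "A" if template[99] != "A" else "C"),
    ]
    assay = markers.design_snp_assay(template, 60, wild, mutant, homeo)
    assert assay.reverse_anchor.pos == 100


# --- indel assay -------------------------------------------------------------

def test_indel_assay_size_difference_22(genome):
    cv = genome.causal_variant
    lo = cv.pos - 400
    template = genome.sequences[cv.chromosome][lo : cv.pos + 400]
    local = [
        HomeoSnp(cv.chromosome, int(r.pos) - lo, r.a_base, r.d_base)
        for r in genome.homeosnp_sites.itertuples()
        if r.chromosome == cv.chromosome and lo < r.pos <= cv.pos + 400
    ]
    assay = markers.design_indel_assay(template, cv.pos - lo, cv.length, local)
    assert assay.product_sizes["wild_A"] - assay.product_sizes["mutant_A"] == 22
    # in-silico PCR: both A alleles amplify with the designed sizes, D fails
    deleted = template[: cv.pos - lo - 1] + template[cv.pos - lo - 1 + cv.length :]
    d_template = genome.sequences["D03"][lo : cv.pos + 400]
    pcr = markers.insilico_pcr(
        assay, {"wild_A": template, "mutant_A": deleted, "wild_D": d_template}
    )
    assert pcr["wild_A"].products == [assay.product_sizes["wild_A"]]
    assert pcr["mutant_A"].products == [assay.product_sizes["mutant_A"]]
    assert not pcr["wild_D"].amplifies


def test_indel_assay_one_bp():
    template = _toy_template(13, 300)
    homeo = [HomeoSnp("A03", 200, template[199], "A" if template[199] != "A" else "C")]
    assay = markers.design_indel_assay(template, 100, 1, homeo)
    assert assay.product_sizes["wild_A"] - assay.product_sizes["mutant_A"] == 1


def test_indel_anchor_inside_indel_is_an_overlap_error():
    template = _toy_template(15, 300)
    homeo = [HomeoSnp("A03", 110, template[109], "A" if template[109] != "A" else "C")]
    with pytest.raises(markers.PrimerDesignError, match="overlaps indel"):
        markers.design_indel_assay(template, 100, 22, homeo)


# --- properties ---------------------------------------------------------------

def test_tm_formula():
    assert markers.primer_tm("ACGT" * 5) == pytest.approx(64.9 + 41 * (10 - 16.4) / 20)


def test_designed_assays_pass_own_insilico_pcr_across_seeds(genome):
    # every design amplifies its intended template class and no other
    comp = {"A": "G", "G": "A", "C": "T", "T": "C"}
    n_ok = 0
    for offset in (5_000, 25_000, 60_000, 120_000, 200_000):
        template = genome.sequences["A01"][offset : offset + 400]
        d_template = genome.sequences["D01"][offset : offset + 400]
        homeo = [
            HomeoSnp("A01", i + 1, a, d)
            for i, (a, d) in enumerate(zip(template, d_template))
            if a != d
        ]
        assay = None
        for snp_pos in (80, 100, 120, 140, 160):
            wild = template[snp_pos - 1]
            mutant = comp[wild]
            try:
                assay = markers.design_snp_assay(template, snp_pos, wild, mutant, homeo)
                break
            except markers.PrimerDesignError:
                continue
        if assay is None:
            continue
        mut_a = template[: snp_pos - 1] + mutant + template[snp_pos:]
        mut_d = d_template[: snp_pos - 1] + mutant + d_template[snp_pos:]
        pcr = markers.insilico_pcr(
            assay,
            {"wild_A": template, "mutant_A": mut_a, "wild_D": d_template, "mutant_D": mut_d},
        )
        assert pcr["mutant_A"].amplifies
        assert not any(pcr[k].amplifies for k in ("wild_A", "wild_D", "mutant_D"))
        n_ok += 1
    assert n_ok >= 3  # most windows must yield a design with the default homeoSNP rate
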