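"""Synthetic allotetraploid cross generator.

Everything the analysis consumes is generated here with the statistical
structure the downstream inference assumes: an A/D homeolog-pair genome with
homeoSNP divergence and ground-truth recording, a single-exon PPR gene
carrying a 22-bp exonic deletion, F2 populations segregating the recessive
locus, lint%/micronaire phenotypes with a marginal zone, bulk variant calls
with a likelihood-ratio QUAL, a diversity-panel genotype matrix, and
negative-binomial expression counts.

The default genome is a scaled-down miniature: five homeolog pairs of 1 Mb
with a genetic length of 100 cM each, so one 100-kb scan window spans 10 cM —
the same genetic width as a 10-Mb window on a real cotton chromosome at
1 cM/Mb.  All sizes and rates are overridable.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterator, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import VariantRecord

__all__ = [
    "GeneModel",
    "CausalDeletion",
    "SimGenome",
    "GenomeSpec",
    "ChromPair",
    "Locus",
    "F2Individual",
    "F2Population",
    "PhenotypeModel",
    "BulkModel",
    "Haplotype",
    "simulate_genome",
    "simulate_f2",
    "assign_phenotypes",
    "make_bulk_variants",
    "simulate_panel",
    "simulate_expression",
    "default_genome_spec",
    "default_bsa_sites",
    "simulate_bsa_experiment",
    "recombination_fraction",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}

# one codon per amino acid for deterministic back-translation; the generator
# then randomizes synonymous choices where it is free to
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}
_SYNONYMS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"], "Q": ["CAA", "CAG"],
    "E": ["GAA", "GAG"], "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "L": ["CTT", "CTC", "CTA", "CTG", "TTA", "TTG"],
    "K": ["AAA", "AAG"], "M": ["ATG"], "F": ["TTT", "TTC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "W": ["TGG"], "Y": ["TAT", "TAC"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GeneModel:
    """A single-exon protein-coding gene with PPR-style annotation.

    ``transit_peptide_aa`` and ``repeat_blocks`` are annotation inputs (the
    pipeline never predicts them): the number of N-terminal residues forming
    the organellar transit peptide, and 1-based inclusive amino-acid spans of
    the PPR repeats on the reference protein.
    """

    id: str
    chromosome: str
    cds_start: int  # 1-based inclusive, genomic
    cds_end: int
    strand: str
    cds_sequence: str
    transit_peptide_aa: int
    repeat_blocks: list[tuple[int, int]]

    def __post_init__(self):
        n = len(self.cds_sequence)
        if n % 3 != 0:
            raise ValueError(f"gene {self.id}: CDS length {n} not a multiple of 3")
        if not self.cds_sequence.startswith("ATG"):
            raise ValueError(f"gene {self.id}: CDS does not begin with ATG")
        if self.cds_sequence[-3:] not in _STOPS:
            raise ValueError(f"gene {self.id}: CDS does not end with a stop codon")
        internal = {self.cds_sequence[i : i + 3] for i in range(0, n - 3, 3)}
        if internal & _STOPS:
            raise ValueError(f"gene {self.id}: internal stop codon in CDS")
        if self.cds_end - self.cds_start + 1 != n:
            raise ValueError(f"gene {self.id}: coordinates do not match CDS length")

    @property
    def protein(self) -> str:
        from Bio.Seq import Seq

        return str(Seq(self.cds_sequence[:-3]).translate())


@dataclasses.dataclass(frozen=True)
class CausalDeletion:
    """The causal lesion: ``deleted`` bases removed starting at ``pos`` (1-based)."""

    chromosome: str
    pos: int
    deleted: str

    def __post_init__(self):
        if len(self.deleted) == 0:
            raise ValueError("deleted string must be non-empty")

    @property
    def length(self) -> int:
        return len(self.deleted)


@dataclasses.dataclass(frozen=True)
class ChromPair:
    a_name: str
    d_name: str
    length: int


@dataclasses.dataclass
class GenomeSpec:
    """Parameters for :func:`simulate_genome`."""

    pairs: list[ChromPair]
    homeosnp_rate: float = 0.01
    cm_per_mb: float = 100.0
    gene_chromosome: str = "A03"
    gene_cds_start: int = 549_001
    gene_id: str = "PPR01"
    deletion_codon: int = 180
    deletion_length: int = 22

    def __post_init__(self):
        if self.homeosnp_rate < 0 or self.homeosnp_rate >= 1:
            raise ValueError("homeosnp_rate must be in [0, 1)")
        if any(p.length <= 0 for p in self.pairs):
            raise ValueError("chromosome lengths must be positive")


@dataclasses.dataclass
class SimGenome:
    """Realized genome: sequences, gene models, causal deletion, ground truth."""

    sequences: dict[str, str]
    pairs: list[ChromPair]
    homeosnp_rate: float
    cm_per_mb: float
    genes: list[GeneModel]
    causal_variant: CausalDeletion
    homeosnp_sites: pd.DataFrame  # columns: chromosome, pos, a_base, d_base

    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def mutant_cds(self, gene_id: str | None = None) -> str:
        """CDS sequence of the causal gene with the deletion applied."""
        gene = self.causal_gene if gene_id is None else next(
            g for g in self.genes if g.id == gene_id
        )
        offset = self.causal_variant.pos - gene.cds_start  # 0-based within CDS
        k = self.causal_variant.length
        return gene.cds_sequence[:offset] + gene.cds_sequence[offset + k :]

    @property
    def causal_gene(self) -> GeneModel:
        for g in self.genes:
            if (
                g.chromosome == self.causal_variant.chromosome
                and g.cds_start <= self.causal_variant.pos <= g.cds_end
            ):
                return g
        raise ValueError("causal deletion is not inside any annotated CDS")

    def causal_cm(self) -> float:
        return self.causal_variant.pos / 1e6 * self.cm_per_mb

    def write_ground_truth(self, path: str | Path) -> None:
        """JSON sidecar sufficient to score every downstream stage."""
        gene = self.causal_gene
        truth = {
            "causal": dataclasses.asdict(self.causal_variant),
            "causal_gene": gene.id,
            "causal_cm": self.causal_cm(),
            "cm_per_mb": self.cm_per_mb,
            "chrom_lengths": self.chrom_lengths(),
            "n_homeosnps": int(len(self.homeosnp_sites)),
            "homeosnps_by_chrom": {
                c: [int(p) for p in grp["pos"]]
                for c, grp in self.homeosnp_sites.groupby("chromosome")
            },
        }
        Path(path).write_text(json.dumps(truth, indent=1))


@dataclasses.dataclass(frozen=True)
class Locus:
    """A mapped position: genomic (chromosome, bp) plus genetic (cM) coordinates."""

    name: str
    chromosome: str
    pos: int
    cm: float


@dataclasses.dataclass(frozen=True)
class F2Individual:
    id: str
    genotypes: Mapping[str, str]  # locus name -> AA/AB/BB (or missing "NA")
    causal_genotype: str


@dataclasses.dataclass
class F2Population:
    """F2 genotypes as a matrix plus locus metadata.

    ``genotypes`` is individuals x loci with codes in {AA, AB, BB}; the causal
    locus appears as the column named by ``causal_name`` (ground truth).
    """

    genotypes: pd.DataFrame
    loci: list[Locus]
    causal_name: str

    @property
    def causal_genotypes(self) -> pd.Series:
        return self.genotypes[self.causal_name]

    def individuals(self) -> Iterator[F2Individual]:
        for ind_id, row in self.genotypes.iterrows():
            yield F2Individual(
                id=str(ind_id),
                genotypes=row.drop(self.causal_name).to_dict(),
                causal_genotype=row[self.causal_name],
            )


@dataclasses.dataclass
class PhenotypeModel:
    """Lint%/micronaire distributions for the two true classes.

    Distributions are truncated so the scored classes are separable (wild-type
    lint stays above 25%, im lint below 29%, and micronaire splits cleanly at
    3.5), matching a study in which every phenotyped plant classified without
    error; the marginal 26-29% lint zone remains populated and is resolved by
    micronaire downstream.
    """

    wildtype_lint_mean: float = 34.0
    wildtype_lint_sd: float = 3.5
    im_lint_mean: float = 19.0
    im_lint_sd: float = 3.5
    mic_wildtype_mean: float = 4.6
    mic_wildtype_sd: float = 0.5
    mic_im_mean: float = 2.9
    mic_im_sd: float = 0.4
    no_phenotype_rate: float = 144 / 2981
    wildtype_lint_bounds: tuple[float, float] = (25.0, 55.0)
    im_lint_bounds: tuple[float, float] = (5.0, 29.0)
    mic_wildtype_bounds: tuple[float, float] = (3.5, 7.0)
    mic_im_bounds: tuple[float, float] = (1.0, 3.5)

    def __post_init__(self):
        for sd in (self.wildtype_lint_sd, self.im_lint_sd, self.mic_wildtype_sd, self.mic_im_sd):
            if sd <= 0:
                raise ValueError("all standard deviations must be > 0")
        if not 0 <= self.no_phenotype_rate < 1:
            raise ValueError("no_phenotype_rate must be in [0, 1)")


@dataclasses.dataclass
class BulkModel:
    """Pooled-sequencing model for the two phenotype bulks."""

    bulk_size: int = 80
    depth_mean: float = 60.0
    error_rate: float = 0.005
    qual_cap: float = 1000.0

    def __post_init__(self):
        if self.bulk_size < 1:
            raise ValueError("bulk_size must be >= 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


@dataclasses.dataclass(frozen=True)
class Haplotype:
    """A diversity-panel haplotype: frequency plus im/wt state per marker."""

    frequency: float
    alleles: Mapping[str, str]  # marker -> "im" | "wt"


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n, dtype=np.uint8)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def make_ppr_protein(
    rng: np.random.Generator,
    length_aa: int = 1023,
    transit_peptide_aa: int = 43,
    n_repeats: int = 25,
    repeat_len: int = 35,
    orf2_start_aa: int = 211,
    code_pairs: Sequence[tuple[str, str]] | None = None,
) -> tuple[str, list[tuple[int, int]]]:
    """Build a PPR-like protein with planted nucleotide-specifying residues.

    Returns the protein string and repeat blocks (1-based aa spans).  Layout:
    repeat 1 stands alone, repeats 2..n are contiguous starting at aa 141, so
    the first two repeats end before the frameshift truncation point and the
    C-terminal ``n_repeats - 3`` repeats lie wholly inside the restored-frame
    suffix beginning at ``orf2_start_aa``.
    """
    if code_pairs is None:
        # cycle canonical two-residue combinations; positions 4 and 34 in-repeat
        cycle = [("T", "N"), ("N", "D"), ("N", "N"), ("N", "S"), ("T", "D"), ("S", "N")]
        code_pairs = [cycle[i % len(cycle)] for i in range(n_repeats)]
    aa_pool = np.array(list("ARNDCQEGHILKMFPSTWYV"))
    prot = rng.choice(aa_pool, size=length_aa)
    prot[0] = "M"
    prot[orf2_start_aa - 1] = "M"  # restored-frame ORF initiator
    blocks: list[tuple[int, int]] = [(100, 100 + repeat_len - 1)]
    for k in range(1, n_repeats):
        start = 141 + repeat_len * (k - 1)
        blocks.append((start, start + repeat_len - 1))
    if blocks[-1][1] > length_aa:
        raise ValueError("protein too short for the requested repeat layout")
    for (start, _end), (r1, r2) in zip(blocks, code_pairs):
        prot[start - 1 + 4 - 1] = r1   # repeat position 4
        prot[start - 1 + 34 - 1] = r2  # repeat position 34
    return "".join(prot), blocks


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(_SYNONYMS[aa][rng.integers(0, len(_SYNONYMS[aa]))] for aa in protein)


def build_ppr_gene(
    spec: GenomeSpec, rng: np.random.Generator
) -> tuple[GeneModel, CausalDeletion]:
    """Construct the causal gene and its 22-bp exonic deletion.

    Codons around the deletion are fixed so that the frameshifted transcript
    terminates shortly after the deletion (the truncated ORF retains the
    transit peptide and the first two repeats) while a downstream in-register
    ATG opens the C-terminal restored-frame ORF.
    """
    protein, blocks = make_ppr_protein(rng)
    tp_aa = 43
    cds = _back_translate(rng, protein)
    dc = spec.deletion_codon  # deletion removes CDS nt [3*(dc-1)+1 .. +deletion_length]
    # After deleting 22 nt starting at codon `dc`, the canonical frame resumes
    # at base 2 of codon dc+7; fixing codons dc+7/dc+8 to CTA/AAC makes the
    # shifted read TAA, stopping translation right there.
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    codons[dc + 6] = "CTA"  # Leu
    codons[dc + 7] = "AAC"  # Asn
    protein = protein[: dc + 6] + "LN" + protein[dc + 8 :]
    cds = "".join(codons) + "TAA"
    gene = GeneModel(
        id=spec.gene_id,
        chromosome=spec.gene_chromosome,
        cds_start=spec.gene_cds_start,
        cds_end=spec.gene_cds_start + len(cds) - 1,
        strand="+",
        cds_sequence=cds,
        transit_peptide_aa=tp_aa,
        repeat_blocks=blocks,
    )
    del_offset = 3 * (dc - 1)  # 0-based within CDS
    deletion = CausalDeletion(
        chromosome=gene.chromosome,
        pos=gene.cds_start + del_offset,
        deleted=cds[del_offset : del_offset + spec.deletion_length],
    )
    return gene, deletion


def default_genome_spec() -> GenomeSpec:
    pairs = [ChromPair(f"A{i:02d}", f"D{i:02d}", 1_000_000) for i in range(1, 6)]
    return GenomeSpec(pairs=pairs)


def simulate_genome(spec: GenomeSpec | None = None, seed: int = 0) -> SimGenome:
    """Generate an allotetraploid genome with recorded homeoSNP ground truth.

    Each A chromosome gets a D homeolog of equal length diverged at
    ``homeosnp_rate`` substitutions per bp; every divergent site is recorded.
    The causal gene CDS is written into its A chromosome, and the deletion
    coordinates refer to that reference.
    """
    if spec is None:
        spec = default_genome_spec()
    a_names = {p.a_name for p in spec.pairs}
    if spec.gene_chromosome not in a_names:
        raise ValueError(
            f"gene chromosome {spec.gene_chromosome!r} is not an A chromosome of this "
            f"genome ({sorted(a_names)})"
        )
    rng = np.random.default_rng(seed)
    gene, deletion = build_ppr_gene(spec, rng)
    genes = [gene]
    starts_seen: set[tuple[str, int, str]] = set()
    for g in genes:
        key = (g.chromosome, g.cds_start, g.strand)
        if key in starts_seen:
            raise ValueError(f"overlapping genes at {key}")
        starts_seen.add(key)

    sequences: dict[str, str] = {}
    homeo_rows: list[pd.DataFrame] = []
    for pair in spec.pairs:
        a_arr = _random_bases(rng, pair.length)
        for g in genes:
            if g.chromosome == pair.a_name:
                if g.cds_end > pair.length:
                    raise ValueError(f"gene {g.id} does not fit on {pair.a_name}")
                cds = g.cds_sequence
                a_arr[g.cds_start - 1 : g.cds_end] = np.frombuffer(
                    cds.encode("ascii"), dtype=np.uint8
                )
        d_arr = a_arr.copy()
        if spec.homeosnp_rate > 0:
            hits = np.nonzero(rng.random(pair.length) < spec.homeosnp_rate)[0]
            if hits.size:
                # substitute with one of the three other bases
                old_idx = np.searchsorted(_BASES, d_arr[hits])
                new_idx = (old_idx + rng.integers(1, 4, size=hits.size)) % 4
                d_arr[hits] = _BASES[new_idx]
                homeo_rows.append(
                    pd.DataFrame(
                        {
                            "chromosome": pair.a_name,
                            "pos": hits + 1,
                            "a_base": [chr(b) for b in a_arr[hits]],
                            "d_base": [chr(b) for b in d_arr[hits]],
                        }
                    )
                )
        sequences[pair.a_name] = _to_str(a_arr)
        sequences[pair.d_name] = _to_str(d_arr)

    homeosnp_sites = (
        pd.concat(homeo_rows, ignore_index=True)
        if homeo_rows
        else pd.DataFrame(columns=["chromosome", "pos", "a_base", "d_base"])
    )
    genome = SimGenome(
        sequences=sequences,
        pairs=spec.pairs,
        homeosnp_rate=spec.homeosnp_rate,
        cm_per_mb=spec.cm_per_mb,
        genes=genes,
        causal_variant=deletion,
        homeosnp_sites=homeosnp_sites,
    )
    # invariant: the recorded deletion matches the reference sequence
    ref = genome.sequences[deletion.chromosome]
    assert ref[deletion.pos - 1 : deletion.pos - 1 + deletion.length] == deletion.deleted
    _ = genome.causal_gene  # raises if the deletion is not inside a CDS exon
    return genome


# ---------------------------------------------------------------------------
# F2 population
# ---------------------------------------------------------------------------

def recombination_fraction(d_cm: float, map_function: str = "haldane") -> float:
    """Invert a map function: cM distance -> recombination fraction."""
    if d_cm < 0:
        raise ValueError("negative map distance")
    m = d_cm / 100.0  # Morgans
    if map_function == "haldane":
        return 0.5 * (1.0 - np.exp(-2.0 * m))
    if map_function == "kosambi":
        return 0.5 * np.tanh(2.0 * m)
    raise ValueError(f"unknown map function {map_function!r}")


_GT_CODES = np.array(["AA", "AB", "BB"])


def simulate_f2(
    n: int,
    loci: Sequence[Locus],
    seed: int = 0,
    map_function: str = "haldane",
    causal_name: str = "causal",
    missing_rate: float = 0.0,
) -> F2Population:
    """Simulate F2 genotypes by forming two independent gametes per plant.

    Within each chromosome, loci are ordered by cM and crossovers between
    adjacent loci occur with probability given by the inverse map function of
    the cM gap (Haldane by default: no interference).  Loci on different
    chromosomes assort independently.  Genotype frequencies converge to 1:2:1
    per locus; B denotes the im-parent allele.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = [l.name for l in loci]
    if len(set(names)) != len(names):
        raise ValueError("locus names must be unique")
    if causal_name not in names:
        raise ValueError(f"no locus named {causal_name!r} (the causal locus)")
    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[Locus]] = {}
    for l in loci:
        by_chrom.setdefault(l.chromosome, []).append(l)
    for chrom in by_chrom:
        group = sorted(by_chrom[chrom], key=lambda l: (l.cm, l.pos))
        pos_order = [l.pos for l in group]
        if len(group) > 2 and not (
            pos_order == sorted(pos_order) or pos_order == sorted(pos_order, reverse=True)
        ):
            raise ValueError(
                f"negative cM interval on {chrom}: genetic and physical orders disagree"
            )
        gaps = np.diff([l.cm for l in group])
        r = np.array([recombination_fraction(g, map_function) for g in gaps])
        L = len(group)
        gametes = np.empty((2 * n, L), dtype=np.int8)
        gametes[:, 0] = rng.random(2 * n) < 0.5
        if L > 1:
            recomb = rng.random((2 * n, L - 1)) < r
            gametes[:, 1:] = recomb
            np.bitwise_xor.accumulate(gametes, axis=1, out=gametes)
        geno = gametes[0::2] + gametes[1::2]  # 0/1/2 copies of B
        for j, l in enumerate(group):
            columns[l.name] = geno[:, j]
    ids = [f"F2_{i + 1:05d}" for i in range(n)]
    data = {name: _GT_CODES[columns[name]] for name in names}
    df = pd.DataFrame(data, index=pd.Index(ids, name="id"))
    if missing_rate > 0:
        mask = rng.random(df.shape) < missing_rate
        mask[:, names.index(causal_name)] = False  # ground truth never missing
        df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))
    return F2Population(genotypes=df, loci=list(loci), causal_name=causal_name)


def _truncnorm(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float], size: int
) -> np.ndarray:
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def assign_phenotypes(
    population: F2Population,
    model: PhenotypeModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw lint% and micronaire per plant from its causal genotype.

    BB plants draw from the im distributions, AA/AB from wild type.  A
    ``no_phenotype_rate`` fraction of plants gets a missing lint% (they set no
    classifiable fiber); micronaire is always drawn.  Returns a frame indexed
    like the population with columns lint_pct, mic, true_class.
    """
    if model is None:
        model = PhenotypeModel()
    rng = np.random.default_rng(seed)
    causal = population.causal_genotypes.to_numpy()
    n = len(causal)
    is_im = causal == "BB"
    lint = np.empty(n)
    mic = np.empty(n)
    n_im = int(is_im.sum())
    lint[is_im] = _truncnorm(rng, model.im_lint_mean, model.im_lint_sd, model.im_lint_bounds, n_im)
    lint[~is_im] = _truncnorm(
        rng, model.wildtype_lint_mean, model.wildtype_lint_sd, model.wildtype_lint_bounds, n - n_im
    )
    mic[is_im] = _truncnorm(rng, model.mic_im_mean, model.mic_im_sd, model.mic_im_bounds, n_im)
    mic[~is_im] = _truncnorm(
        rng, model.mic_wildtype_mean, model.mic_wildtype_sd, model.mic_wildtype_bounds, n - n_im
    )
    no_pheno = rng.random(n) < model.no_phenotype_rate
    lint[no_pheno] = np.nan
    return pd.DataFrame(
        {
            "lint_pct": lint,
            "mic": mic,
            "true_class": np.where(is_im, "im", "wild_type"),
        },
        index=population.genotypes.index,
    )


# ---------------------------------------------------------------------------
# bulk variant calls
# ---------------------------------------------------------------------------

def contrast_qual(
    alt1: np.ndarray, depth1: np.ndarray, alt2: np.ndarray, depth2: np.ndarray, cap: float = 1000.0
) -> np.ndarray:
    """Phred-scaled likelihood-ratio QUAL for a two-bulk frequency contrast.

    The statistic is the binomial deviance for H0 "both bulks share one alt
    frequency" against the two-frequency alternative; QUAL is the Phred
    transform of its chi-square(1) tail probability.  Background sites behave
    like the null (QUAL rarely above ~20), while sites fixed in the im bulk
    but segregating 1:2 in the wild-type bulk give deviances of 40+ and QUAL
    far above the conventional 50 scan threshold.
    """
    alt1, depth1 = np.asarray(alt1, float), np.asarray(depth1, float)
    alt2, depth2 = np.asarray(alt2, float), np.asarray(depth2, float)

    def _ll(a, d, f):
        f = np.clip(f, 1e-12, 1 - 1e-12)
        return a * np.log(f) + (d - a) * np.log1p(-f)

    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(depth1 > 0, alt1 / np.maximum(depth1, 1), 0.0)
        f2 = np.where(depth2 > 0, alt2 / np.maximum(depth2, 1), 0.0)
        fp = (alt1 + alt2) / np.maximum(depth1 + depth2, 1)
        dev = 2.0 * (_ll(alt1, depth1, f1) + _ll(alt2, depth2, f2) - _ll(alt1 + alt2, depth1 + depth2, fp))
    dev = np.maximum(dev, 0.0)
    qual = -10.0 * stats.chi2.logsf(dev, df=1) / np.log(10.0)
    qual = np.where(depth1 + depth2 == 0, 0.0, qual)
    return np.minimum(qual, cap)


def default_bsa_sites(
    genome: SimGenome,
    background_per_mb: float = 10.0,
    introgression_per_mb: float = 500.0,
    introgression_cm: float = 16.0,
    seed: int = 0,
) -> list[Locus]:
    """Place parent-polymorphic sites as a near-isogenic-line cross leaves them.

    The mutant parent is a NIL of the wild-type parent, so real polymorphism
    concentrates in the residual introgressed segment around the causal locus
    (``introgression_cm`` of genetic length at ``introgression_per_mb``
    density); elsewhere only sparse residual background sites remain
    (``background_per_mb``, segregating but mostly unlinked to the trait).
    This density structure — not the bulk contrast alone — is what makes the
    windowed SNP scan peak sharply at the locus.  The causal deletion site is
    appended as the locus named ``"causal"``.
    """
    rng = np.random.default_rng(seed)
    cv = genome.causal_variant
    half_bp = introgression_cm / 2.0 / genome.cm_per_mb * 1e6
    seg_lo, seg_hi = cv.pos - half_bp, cv.pos + half_bp
    sites: list[Locus] = []
    for pair in genome.pairs:
        n_bg = rng.poisson(background_per_mb * pair.length / 1e6)
        pos = list(rng.integers(1, pair.length + 1, size=n_bg))
        if pair.a_name == cv.chromosome:
            lo = max(1, int(seg_lo))
            hi = min(pair.length, int(seg_hi))
            n_seg = rng.poisson(introgression_per_mb * (hi - lo) / 1e6)
            pos += list(rng.integers(lo, hi + 1, size=n_seg))
        for p in sorted(set(int(x) for x in pos)):
            if pair.a_name == cv.chromosome and p == cv.pos:
                continue
            sites.append(
                Locus(
                    name=f"{pair.a_name}_{p}",
                    chromosome=pair.a_name,
                    pos=p,
                    cm=float(p) / 1e6 * genome.cm_per_mb,
                )
            )
    sites.append(Locus(name="causal", chromosome=cv.chromosome, pos=cv.pos, cm=genome.causal_cm()))
    return sites


def make_bulk_variants(
    population: F2Population,
    phenotypes: pd.DataFrame,
    genome: SimGenome,
    bulk_model: BulkModel | None = None,
    seed: int = 0,
) -> list[VariantRecord]:
    """Simulate pooled variant calls for an im bulk and a wild-type bulk.

    ``bulk_size`` plants per true phenotype class are pooled; per site, each
    bulk's read depth is Poisson and the alt-read count binomial around the
    bulk's B-allele frequency perturbed by the per-base error rate.  QUAL is
    the likelihood-ratio contrast score (:func:`contrast_qual`).  The causal
    deletion site is emitted as an indel record (anchor-base convention); all
    other sites are SNPs with ref/alt drawn from the reference genome.
    """
    if bulk_model is None:
        bulk_model = BulkModel()
    rng = np.random.default_rng(seed)
    classes = phenotypes["true_class"].to_numpy()
    im_idx = np.nonzero(classes == "im")[0]
    wt_idx = np.nonzero(classes == "wild_type")[0]
    if len(im_idx) == 0 or len(wt_idx) == 0:
        raise ValueError("empty bulk: need plants of both phenotype classes")
    if len(im_idx) < bulk_model.bulk_size or len(wt_idx) < bulk_model.bulk_size:
        raise ValueError(
            f"bulk_size {bulk_model.bulk_size} exceeds available plants "
            f"(im {len(im_idx)}, wild-type {len(wt_idx)})"
        )
    im_idx = rng.choice(im_idx, size=bulk_model.bulk_size, replace=False)
    wt_idx = rng.choice(wt_idx, size=bulk_model.bulk_size, replace=False)

    loci = sorted(population.loci, key=lambda l: (l.chromosome, l.pos))
    codes = population.genotypes[[l.name for l in loci]].to_numpy()
    b_counts = (codes == "AB").astype(np.int8) + 2 * (codes == "BB").astype(np.int8)
    two_n = 2 * bulk_model.bulk_size
    f_im = b_counts[im_idx].sum(axis=0) / two_n
    f_wt = b_counts[wt_idx].sum(axis=0) / two_n
    e = bulk_model.error_rate
    f_im_err = f_im * (1 - 2 * e) + e
    f_wt_err = f_wt * (1 - 2 * e) + e
    d_im = rng.poisson(bulk_model.depth_mean, size=len(loci))
    d_wt = rng.poisson(bulk_model.depth_mean, size=len(loci))
    a_im = rng.binomial(d_im, f_im_err)
    a_wt = rng.binomial(d_wt, f_wt_err)
    qual = contrast_qual(a_im, d_im, a_wt, d_wt, cap=bulk_model.qual_cap)

    cv = genome.causal_variant
    records: list[VariantRecord] = []
    for j, locus in enumerate(loci):
        seq = genome.sequences.get(locus.chromosome)
        if locus.name == "causal":
            anchor_pos = cv.pos - 1
            anchor = seq[anchor_pos - 1] if seq else "N"
            ref = anchor + cv.deleted
            alt = anchor
            pos = anchor_pos
        else:
            ref = seq[locus.pos - 1] if seq else "A"
            alt_choices = [b for b in "ACGT" if b != ref]
            alt = alt_choices[rng.integers(0, 3)]
            pos = locus.pos
        records.append(
            VariantRecord(
                chrom=locus.chromosome,
                pos=pos,
                ref=ref,
                alt=alt,
                qual=float(np.round(qual[j], 2)),
                depths={
                    "im_bulk": (int(d_im[j] - a_im[j]), int(a_im[j])),
                    "wt_bulk": (int(d_wt[j] - a_wt[j]), int(a_wt[j])),
                },
            )
        )
    return records


def simulate_bsa_experiment(
    genome: SimGenome,
    n_plants: int = 500,
    bulk_model: BulkModel | None = None,
    phenotype_model: PhenotypeModel | None = None,
    background_per_mb: float = 10.0,
    introgression_per_mb: float = 500.0,
    introgression_cm: float = 16.0,
    seed: int = 0,
) -> tuple[list[VariantRecord], F2Population, pd.DataFrame]:
    """End-to-end bulk experiment: sites -> F2 -> phenotypes -> pooled calls.

    One integer seed drives site placement, meiosis, phenotypes, and
    sequencing noise through independent derived streams.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    sites = default_bsa_sites(
        genome,
        background_per_mb=background_per_mb,
        introgression_per_mb=introgression_per_mb,
        introgression_cm=introgression_cm,
        seed=seeds[0],
    )
    pop = simulate_f2(n_plants, sites, seed=seeds[1], causal_name="causal")
    phen = assign_phenotypes(pop, phenotype_model, seed=seeds[2])
    records = make_bulk_variants(pop, phen, genome, bulk_model, seed=seeds[3])
    return records, pop, phen


# ---------------------------------------------------------------------------
# diversity panel
# ---------------------------------------------------------------------------

def default_panel_haplotypes(
    candidate: str = "CFBid0001",
    flanking: Sequence[str] = ("CFB5887", "CFB5888", "CFBid0002"),
) -> list[Haplotype]:
    """Haplotype frequencies mirroring the published 163-accession panel:
    30/163 accessions carry the im-type state at all three flanking markers,
    56/163 at a strict subset, none at the candidate."""
    f1, f2, f3 = flanking
    wt = {candidate: "wt", f1: "wt", f2: "wt", f3: "wt"}
    triple = {candidate: "wt", f1: "im", f2: "im", f3: "im"}
    single_a = {candidate: "wt", f1: "wt", f2: "im", f3: "wt"}
    single_b = {candidate: "wt", f1: "wt", f2: "wt", f3: "im"}
    return [
        Haplotype(30 / 163, triple),
        Haplotype(26 / 163, single_a),
        Haplotype(30 / 163, single_b),
        Haplotype(77 / 163, wt),
    ]


def simulate_panel(
    n_accessions: int = 163,
    haplotypes: Sequence[Haplotype] | None = None,
    seed: int = 0,
    cultivated: bool = True,
    candidate_marker: str = "CFBid0001",
    selfing: float = 1.0,
) -> pd.DataFrame:
    """Draw a diversity-panel genotype matrix (accessions x markers).

    Accessions are i.i.d. haplotype draws; with the default ``selfing=1`` each
    accession is homozygous for a single haplotype (cotton cultivars are
    inbred).  ``selfing < 1`` draws a second independent haplotype with
    probability ``1 - selfing``, producing heterozygous calls.  With the
    ``cultivated`` flag the candidate marker is forced to the TM-1 allele in
    every accession (the causal lesion is absent from cultivated germplasm).
    """
    if haplotypes is None:
        haplotypes = default_panel_haplotypes(candidate=candidate_marker)
    freqs = np.array([h.frequency for h in haplotypes])
    if not np.isclose(freqs.sum(), 1.0):
        raise ValueError(f"haplotype frequencies sum to {freqs.sum():g}, not 1")
    markers = list(haplotypes[0].alleles)
    for h in haplotypes:
        if list(h.alleles) != markers:
            raise ValueError("all haplotypes must define the same markers")
    rng = np.random.default_rng(seed)
    draw1 = rng.choice(len(haplotypes), size=n_accessions, p=freqs)
    draw2 = draw1.copy()
    if selfing < 1.0:
        outcross = rng.random(n_accessions) >= selfing
        draw2[outcross] = rng.choice(len(haplotypes), size=int(outcross.sum()), p=freqs)
    rows = []
    for h1, h2 in zip(draw1, draw2):
        row = {}
        for m in markers:
            a1 = haplotypes[h1].alleles[m]
            a2 = haplotypes[h2].alleles[m]
            n_im = (a1 == "im") + (a2 == "im")
            row[m] = _GT_CODES[n_im]
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index([f"acc{i + 1:03d}" for i in range(n_accessions)], name="accession"))
    if cultivated:
        df[candidate_marker] = "AA"
    return df


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def simulate_expression(
    n_genes: int = 38,
    n_reps: int = 2,
    de_spec: Mapping[int, float] | None = None,
    seed: int = 0,
    lib_size: float = 20e6,
    dispersion: float = 0.05,
    groups: tuple[str, str] = ("TM1", "im"),
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Negative-binomial counts for an interval gene set with planted effects.

    ``de_spec`` maps gene index (0-based) to true log2 fold change
    (group2/group1); unlisted genes have fold change 1.  Per-gene baseline
    abundance is log-normal so that roughly 40% of genes clear a 1-RPKM
    detection filter, as in the mapped interval.  Returns (counts, lengths,
    truth) where truth carries the true log2 fold changes and DE labels.
    """
    if n_reps < 2:
        raise ValueError("need >= 2 replicates per group")
    de_spec = dict(de_spec or {})
    rng = np.random.default_rng(seed)
    genes = [f"gene{i + 1:03d}" for i in range(n_genes)]
    lengths = pd.Series(rng.integers(500, 4000, size=n_genes), index=genes, name="length_bp")
    base_rpkm = np.exp(rng.normal(np.log(0.8), 1.5, size=n_genes))
    # genes carrying a planted effect are drawn from the quantifiable stratum:
    # a fold change is only meaningful at adequate baseline depth
    for idx in de_spec:
        base_rpkm[idx] = max(base_rpkm[idx], 2.0)
    base_mean = base_rpkm * lib_size * lengths.to_numpy() / 1e9
    log2fc = np.zeros(n_genes)
    for idx, fc in de_spec.items():
        log2fc[idx] = fc
    samples = [f"{g}_{r + 1}" for g in groups for r in range(n_reps)]
    counts = np.empty((n_genes, 2 * n_reps), dtype=np.int64)
    size = 1.0 / dispersion
    for j in range(2 * n_reps):
        mean = base_mean * (2.0 ** log2fc if j >= n_reps else 1.0)
        mean = np.maximum(mean, 1e-8)
        counts[:, j] = rng.negative_binomial(size, size / (size + mean))
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    truth = pd.DataFrame(
        {"true_log2fc": log2fc, "is_de": log2fc != 0.0, "base_rpkm": base_rpkm}, index=genes
    )
    return counts_df, lengths, truth
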