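# Methods

This note documents the models behind `imlocus`: what each stage computes,
what the synthetic generator does and does not emulate, and the numerical
and design choices that were genuinely open.

## The genetic model

The immature-fiber trait is treated as a single recessive Mendelian locus.
An F2 plant's genotype at any locus is written by B-allele dosage (B = the
mutant-parent allele): AA, AB, BB.  Plants that are BB at the causal locus
express the mutant phenotype; all analyses downstream (segregation χ²,
two-point likelihoods, discordance counting) follow from that assumption
plus independent gamete formation without crossover interference.

Meiosis is simulated as a Markov chain along each chromosome: each gamete
starts with a fair-coin allele at the first locus and switches between
parental haplotypes across an interval of d cM with probability given by the
inverse map function (Haldane by default, r = (1 − e^(−2d/100))/2; Kosambi
available, r = tanh(2d/100)/2).  Haldane is the simulation default because
it encodes no interference, which matches the likelihood used for
estimation; nothing in the pipeline depends on interference structure.

## Scaled-down study geometry

The simulated genome is five A/D homeolog pairs of 1 Mb with a genetic
length of 100 cM per chromosome.  One 100-kb scan window therefore spans
10 cM — the same genetic width as a 10-Mb window on a real ~100-Mb cotton
chromosome in a region of 1 cM/Mb.  All statistics exercised here (window
counts, recombination fractions, allele-frequency contrasts) depend on
genetic geometry and sample size, not on absolute base-pair scale, so the
miniature preserves the inference while keeping sequences small enough to
enumerate and verify exactly.  `bsa.window_density` keeps 10 Mb as its
default window for real-scale inputs; the study configuration passes 100 kb.

## The synthetic allotetraploid genome

Each A chromosome receives a D homeolog of equal length diverged by
independent substitutions at `homeosnp_rate` (default 0.01/bp, the order of
A/D homeolog divergence in tetraploid cotton); every divergent site is
recorded as ground truth, so homeoSNP discovery can be scored exactly.  The
generator does not model homeolog indels or structural variation, so the
identity coordinate map suffices for alignment; real marker design must
handle alignment gaps that this package only accepts as an externally
supplied coordinate map.

The causal gene is a single-exon PPR gene constructed to mirror the
published lesion structurally: a 1023-aa protein with a 43-aa N-terminal
transit peptide, 25 repeats of 35 aa (24 contiguous), a methionine at
aa 211, and a 22-bp deletion starting at codon 180.  Two codons downstream
of the deletion are fixed (CTA, AAC) so the shifted frame terminates
immediately: the mutant transcript then yields a 179-aa ORF holding the
transit peptide and the first two repeats, and a restored-frame ORF holding
the C-terminal 813 aa with 22 repeats — the qualitative split reported for
the real transcript (whose exact ORF lengths depend on its consensus
sequence, which is not distributed).  Repeat positions 4 and 34 carry
planted nucleotide-specifying residues so the PPR-code stage has a known
answer.

## Phenotype model

Lint percentage and micronaire are drawn from truncated normals:

| quantity | wild type | im | bounds |
|---|---|---|---|
| lint % | N(34, 3.5²) | N(19, 3.5²) | wt > 25, im < 29 |
| micronaire | N(4.6, 0.5²) | N(2.9, 0.4²) | wt > 3.5, im < 3.5 |

About 5% of plants land in the marginal 26–29% lint zone and are resolved
by micronaire, and a `no_phenotype_rate` fraction (default 144/2981) gets a
missing lint value while keeping genotypes — these plants still contribute
to marker–marker distances, as in the fine-mapping design.  The truncation
makes the scored classes error-free, reflecting a study in which every
phenotyped plant classified cleanly (complete linkage over 2837 plants is
only observable without scoring error).  Real lint distributions have tails
the truncation removes; passing tests therefore demonstrate correctness of
the classification and linkage machinery under clean scoring, not
robustness to phenotyping mistakes.

## Bulk variant calls and the QUAL model

The mutant parent is a near-isogenic line, so parent polymorphism is placed
as a dense introgression segment around the causal locus (default 16 cM at
500 sites/Mb) over sparse genome-wide background (10 sites/Mb).  This
density structure is what produces a single striking window peak; a
uniform-density genome would smear the signal over the contrast-decay
length of several windows.

Per site and bulk (80 plants each, drawn from the classified phenotype
groups of a 500-plant F2), read depth is Poisson (default mean 60×) and the
alt count binomial around the bulk allele frequency perturbed by a per-base
error rate (0.005).  QUAL is the Phred-scaled tail probability of the
binomial likelihood-ratio statistic for "both bulks share one alt
frequency": qual = −10·log10 P(χ²₁ > deviance).  Under this calibration
background sites behave like the null (passing 50 with probability ~10⁻⁵)
while sites tightly linked to the locus (im bulk near fixation, wild-type
bulk near 1/3) give deviances of 40+ and QUAL far above 50 — which is what
makes the conventional "quality > 50" scan threshold meaningful.  The
generator emits genotype-driven variant sites only; it does not simulate
reads, base qualities, or alignment artifacts.

## Marker design rules

SNP assays: the forward primer's 3′-terminal base is the mutant allele; the
reverse primer's 3′ terminus pairs with the nearest downstream homeoSNP's
A-subgenome base (ties toward the smaller product); both primers substitute
their third-from-3′ base with the base of the strand they anneal to, a
self-pairing mismatch that is deterministic and always non-Watson-Crick.
Indel assays flank the lesion with the reverse primer homeoSNP-anchored, so
allele products differ by the indel length on a capillary trace.  Melting
temperature uses the simple 64.9 + 41·(GC − 16.4)/N estimate — a soft
constraint; primer length (18–25 nt) is chosen greedily toward the middle
of the 55–62 °C window, and an unattainable window is an error naming the
best candidate.  The pipeline stage retries nearby target positions and
progressively relaxed windows before giving up, as a bench design would.

In-silico PCR declares a primer bound where the 3′-terminal base matches,
at most one mismatch falls in the final five 3′ bases (the engineered
mismatch uses that budget), and the primer body has at most two further
mismatches.  The body condition is essential: a 3′-window-only rule accepts
~1% of random positions and would make specificity verdicts meaningless.

## Two-point likelihoods

For two codominant loci in coupling, gamete probabilities are (1−r)/2 for
parental and r/2 for recombinant types; the 3×3 F2 class distribution is
the convolution of two independent gametes.  For a locus observed only as a
recessive phenotype, the 3×3 table collapses to 3×2 by pooling trait
dosages {0,1}.  r̂ maximizes the multinomial log-likelihood by bounded
scalar search on [0, 0.5] (tolerance 10⁻⁶), snapping exactly to 0 when the
data contain no recombinant classes; the standard error comes from the
numerically differentiated observed Fisher information.  Kosambi is the
display default (the convention of standard linkage software); both
functions are always reported.  Marker ordering minimizes the sum of
adjacent distances — exhaustively up to 8 markers, greedy
nearest-neighbour with 2-opt refinement above that — and is reported in the
canonical orientation with the lexicographically smaller endpoint first.

## Panel summarization

Accessions default to fully inbred single-haplotype draws (cotton cultivars
are highly selfing), with a `selfing < 1` option for heterozygous calls.
Heterozygotes count as "carries the mutant-type allele" for the ≥ 1-marker
group but not for the homozygous-at-all-flanking group; accessions with a
missing flanking call are excluded from the groups and reported separately.
The exclusion verdict requires zero mutant-type alleles at the candidate
while flanking mutant haplotypes are present — absence of evidence about
the flanking haplotype (an empty flanking set) never supports the verdict.

## ORF analysis

ORFs are enumerated on the forward strand in all three frames from each
region's 5′-most ATG to its stop (nested starts optionally reported), with
a default threshold of 101 aa ("longer than 100 aa"); run-off ORFs are
flagged.  Domain content is computed purely by coordinate overlap after
mapping each ORF onto the reference protein by exact prefix match
(canonical-start ORFs), exact suffix match (restored-frame ORFs), or both
(canonical ORFs with internal in-frame deletions keep both ends intact).
Function is called abolished when no single ORF contains the full transit
peptide and at least half of the repeats — the transit peptide is required
because organellar import is all-or-none, and half the repeat tract is a
conservative lower bound for retaining sequence-specific RNA binding.

## PPR code

The shipped code table is a synthetic default built on the combinatorial
two-residue code idea (e.g. TD→G, TN/SN→A, ND→U, NS→C); its probability
values are this package's own, not a transcription of a published matrix.
Because the literature numbers the nucleotide-specifying positions
inconsistently, the table file declares its own convention (positions 4 and
34 of a 35-aa repeat) and the extractor reads it from the file.  Bit scores
are log-odds against a uniform background, log2(p/0.25) — a convention
under which negative scores exist, matching a logo that displays only
positive bits.  The naive repeat scanner is a sliding-window identity scan
against a 35-aa consensus (threshold 0.5); it finds planted or
well-conserved tandem copies and is documented as not equivalent to a
PROSITE profile search, which is why repeat coordinates are normally
annotation inputs.

## Expression screen

RPKM = 10⁹·C/(N·L) with N defaulting to column sums of the analyzed table;
when the table is an interval slice of the transcriptome, the pipeline
passes the generator's true library size instead (default 2×10⁷), since
interval column sums would inflate every value.  TMM factors are computed
on raw count ratios against a reference sample — gene-wise M = log2 ratio
and A = mean log2 abundance over genes nonzero in both, two-sided trims of
30% on M and 5% on A, inverse-asymptotic-variance weights, factors rescaled
to geometric mean 1 — so a library sequenced twice as deep gets twice the
factor and counts divided by factors are directly comparable.  The
differential test is per-gene one-way ANOVA on log2(count/factor + 0.5)
(equivalent to an equal-variance t-test for two groups); genes with zero
variance get p = 1.  Detection is strict (> 1 RPKM in any sample or group
mean), and candidates are flagged by |log2FC| ≥ 1 with p < 0.05.  The
generator plants effects on genes of quantifiable baseline (≥ 2 RPKM): a
fold change on an undetectable gene is not a recoverable quantity.

## Problem sizes and determinism

Default study sizes follow the study design where one exists: bulks of 80,
2981 plants genotyped, 2837 phenotyped (144/2981 missing), 163 panel
accessions, 38 interval genes with 2 replicates per genotype.  The BSA
source population is 500 plants so that 80 classified mutants are reliably
available in every seeded replicate.  Statistical checks use 20–200 seeded
replicates, enough to bound the quantities they assert at their stated
tolerances.  Every generator consumes a single integer seed through
`numpy.random.SeedSequence` spawning, so every output — including the full
pipeline directory — is byte-identical across reruns with the same seed.

## Known limitations

* No read-level simulation: alignment error, mapping bias between
  subgenomes, and base-quality structure are outside the generator.
* Phenotype scoring is error-free by construction (see above).
* Two-point mapping only; no multipoint likelihood or interference model.
* The PPR code table and repeat scanner are structural stand-ins; motif
  predictions are internally consistent but not transferable to real PPR
  proteins without a literature-derived table.
* The panel model draws accessions i.i.d.; population structure and kinship
  are deliberately out of scope for the exclusion argument implemented.
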