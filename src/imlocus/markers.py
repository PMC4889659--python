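"""Subgenome-specific allele-discriminating assay design for an allotetraploid.

In a genome with two co-resident subgenomes, an ordinary PCR assay amplifies
both homeologs and a genuine allele signal drowns in the homeologous one.
The designs here follow the allele-specific-PCR convention for cotton:

* SNP assays — the forward primer ends (3') on the target SNP carrying the
  mutant-allele base; the reverse primer ends on the nearest homeoSNP with the
  A-subgenome base, making the assay blind to the D homeolog.  Both primers
  carry an engineered third-base-from-3' mismatch (the primer base is replaced
  by the base of the strand it anneals to, a guaranteed self-pair) to sharpen
  annealing stringency.
* Indel assays — primers flank the indel so allele products differ by the
  indel length on capillary electrophoresis; one primer is homeoSNP-anchored.

An in-silico PCR checks every design against the four template classes
(allele x subgenome).
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

__all__ = [
    "HomeoSnp",
    "PrimerParams",
    "MarkerAssay",
    "PcrResult",
    "PrimerDesignError",
    "revcomp",
    "primer_tm",
    "find_homeosnps",
    "design_snp_assay",
    "design_indel_assay",
    "insilico_pcr",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PrimerDesignError(ValueError):
    """No assay satisfying the constraints exists; message names the blocker."""


@dataclasses.dataclass(frozen=True)
class HomeoSnp:
    """A fixed A/D-subgenome difference, in A-subgenome coordinates (1-based)."""

    chromosome: str
    pos: int
    a_base: str
    d_base: str

    def __post_init__(self):
        if self.a_base == self.d_base:
            raise ValueError(f"homeoSNP at {self.chromosome}:{self.pos} has equal bases")


@dataclasses.dataclass
class PrimerParams:
    """Primer constraints; length/Tm windows are conventional defaults."""

    min_len: int = 18
    max_len: int = 25
    tm_min: float = 55.0
    tm_max: float = 62.0
    max_product: int = 400
    max_mm: int = 1  # tolerated mismatches in the final five 3' bases (in-silico PCR)


@dataclasses.dataclass
class MarkerAssay:
    """An allele-discriminating PCR assay.

    ``product_sizes`` maps template class to expected amplicon length in bp
    (None = no amplification); ``span_3prime`` is the inter-3'-end distance
    inclusive (the SNP-to-homeoSNP span for SNP assays).
    """

    name: str
    assay_type: str  # "SNP" | "indel"
    forward: str
    reverse: str
    forward_3prime_allele: str | None
    reverse_anchor: HomeoSnp | None
    mismatch_positions: tuple[int, int]
    product_sizes: dict[str, int | None]
    span_3prime: int
    forward_tm: float
    reverse_tm: float
    forward_start: int  # 1-based template position of the forward 5' end
    reverse_end: int  # 1-based template position of the reverse 5' end


@dataclasses.dataclass
class PcrResult:
    template: str
    amplifies: bool
    products: list[int]


def primer_tm(seq: str) -> float:
    """Simple GC/length melting-temperature estimate: 64.9 + 41*(GC - 16.4)/N."""
    gc = sum(1 for b in seq if b in "GC")
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


def find_homeosnps(
    a_seq: str,
    d_seq: str,
    alignment: Sequence[tuple[int, int]] | None = None,
    chromosome: str = "A",
) -> list[HomeoSnp]:
    """Report every site where the homeologs differ, in A coordinates.

    ``alignment`` is an optional pairwise coordinate map of 1-based
    ``(a_pos, d_pos)`` pairs; by default the identity map is used, which
    requires equal-length homeologs (the simulator's ground truth guarantees
    this before indel divergence, which it does not model).
    """
    if alignment is None:
        if len(a_seq) != len(d_seq):
            raise ValueError(
                f"equal-length homeologs required without an alignment "
                f"({len(a_seq)} vs {len(d_seq)})"
            )
        alignment = [(i, i) for i in range(1, len(a_seq) + 1)]
    out: list[HomeoSnp] = []
    for a_pos, d_pos in alignment:
        if not (1 <= a_pos <= len(a_seq) and 1 <= d_pos <= len(d_seq)):
            raise ValueError(f"alignment pair ({a_pos}, {d_pos}) outside sequences")
        a_b, d_b = a_seq[a_pos - 1], d_seq[d_pos - 1]
        if a_b != d_b:
            out.append(HomeoSnp(chromosome=chromosome, pos=a_pos, a_base=a_b, d_base=d_b))
    return out


def _fit_primer(build, params: PrimerParams, what: str) -> tuple[str, float, int]:
    """Choose a primer length within the window hitting the Tm range.

    ``build(L)`` returns the candidate primer of length L (or None if it does
    not fit the template).  Among in-range candidates the one closest to the
    Tm midpoint wins; if none lands in range the error names the best one.
    """
    mid = (params.tm_min + params.tm_max) / 2.0
    best: tuple[float, str, float, int] | None = None
    in_range: tuple[float, str, float, int] | None = None
    for L in range(params.min_len, params.max_len + 1):
        seq = build(L)
        if seq is None:
            continue
        tm = primer_tm(seq)
        cand = (abs(tm - mid), seq, tm, L)
        if params.tm_min <= tm <= params.tm_max and (in_range is None or cand < in_range):
            in_range = cand
        if best is None or cand < best:
            best = cand
    if in_range is not None:
        _, seq, tm, L = in_range
        return seq, tm, L
    if best is None:
        raise PrimerDesignError(f"{what}: no primer length fits the template")
    _, seq, tm, L = best
    raise PrimerDesignError(
        f"{what}: no primer reaches Tm in [{params.tm_min}, {params.tm_max}] "
        f"(best candidate {seq} with Tm {tm:.1f})"
    )


def _complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def _forward_primer(template: str, end_pos: int, params: PrimerParams, allele: str | None, what: str):
    """Forward primer whose 3' end sits at 1-based ``end_pos``.

    The primer equals the template top strand over its footprint, with the 3'
    base set to ``allele`` (if given) and the third base from the 3' end
    replaced by the annealing-strand (bottom) base — a self-pairing mismatch.
    """

    def build(L: int) -> str | None:
        if end_pos - L < 0:
            return None
        seq = list(template[end_pos - L : end_pos])
        if allele is not None:
            seq[-1] = allele
        seq[-3] = _complement(template[end_pos - 3])
        return "".join(seq)

    seq, tm, L = _fit_primer(build, params, what)
    return seq, tm, end_pos - L + 1


def _reverse_primer(template: str, end_pos: int, params: PrimerParams, what: str):
    """Reverse primer whose 3' end pairs with template position ``end_pos``.

    The primer is the reverse complement of the top strand over
    ``[end_pos, end_pos + L - 1]``; the third base from its 3' end is replaced
    by the annealing-strand (top) base at that position.
    """

    def build(L: int) -> str | None:
        if end_pos - 1 + L > len(template):
            return None
        region = template[end_pos - 1 : end_pos - 1 + L]
        seq = list(revcomp(region))
        seq[-3] = template[end_pos + 1]  # top-strand base at end_pos + 2 (1-based)
        return "".join(seq)

    seq, tm, L = _fit_primer(build, params, what)
    return seq, tm, end_pos + L - 1


def design_snp_assay(
    template_a: str,
    snp_pos: int,
    wild_base: str,
    mutant_base: str,
    homeosnps: Sequence[HomeoSnp],
    params: PrimerParams | None = None,
    name: str = "SNP_assay",
) -> MarkerAssay:
    """Design a mutant-allele, A-subgenome-specific SNP assay.

    ``template_a`` is the wild-type A-subgenome reference; homeoSNP positions
    are in the same coordinates.  The reverse primer anchors on the nearest
    eligible homeoSNP downstream of the SNP (ties toward the smaller
    product).  Raises :class:`PrimerDesignError` when no homeoSNP is in range.
    """
    params = params or PrimerParams()
    if not 1 <= snp_pos <= len(template_a):
        raise ValueError("snp_pos outside template")
    if template_a[snp_pos - 1] != wild_base:
        raise ValueError(
            f"template has {template_a[snp_pos - 1]!r} at {snp_pos}, expected wild base {wild_base!r}"
        )
    eligible = sorted(
        (h for h in homeosnps if h.pos > snp_pos and (h.pos - snp_pos + 1) <= params.max_product),
        key=lambda h: h.pos,
    )
    eligible = [h for h in eligible if h.pos + params.min_len - 1 <= len(template_a)]
    if not eligible:
        raise PrimerDesignError(
            f"{name}: no anchor — no homeoSNP within {params.max_product} bp downstream of the SNP"
        )
    anchor = eligible[0]
    fwd, fwd_tm, fwd_start = _forward_primer(
        template_a, snp_pos, params, mutant_base, f"{name} forward"
    )
    rev, rev_tm, rev_end = _reverse_primer(template_a, anchor.pos, params, f"{name} reverse")
    amplicon = rev_end - fwd_start + 1
    span = anchor.pos - snp_pos + 1
    return MarkerAssay(
        name=name,
        assay_type="SNP",
        forward=fwd,
        reverse=rev,
        forward_3prime_allele=mutant_base,
        reverse_anchor=anchor,
        mismatch_positions=(3, 3),
        product_sizes={"mutant_A": amplicon, "wild_A": None, "mutant_D": None, "wild_D": None},
        span_3prime=span,
        forward_tm=fwd_tm,
        reverse_tm=rev_tm,
        forward_start=fwd_start,
        reverse_end=rev_end,
    )


def design_indel_assay(
    template: str,
    indel_pos: int,
    indel_len: int,
    homeosnps: Sequence[HomeoSnp],
    params: PrimerParams | None = None,
    name: str = "indel_assay",
) -> MarkerAssay:
    """Design an indel-flanking assay sized for capillary electrophoresis.

    ``template`` is the long (insertion-bearing / undeleted) A-subgenome
    allele; the deletion removes ``template[indel_pos .. indel_pos+indel_len-1]``.
    The reverse primer anchors on the nearest homeoSNP downstream of the
    indel; the forward primer ends immediately upstream.  Expected product
    sizes differ by ``indel_len`` between alleles.
    """
    params = params or PrimerParams()
    if not (1 <= indel_pos and indel_pos + indel_len - 1 <= len(template)):
        raise ValueError("indel outside template")
    inside = [h for h in homeosnps if indel_pos <= h.pos <= indel_pos + indel_len - 1]
    downstream = sorted(
        (
            h
            for h in homeosnps
            if h.pos >= indel_pos + indel_len
            and (h.pos - indel_pos + 1) <= params.max_product
            and h.pos + params.min_len - 1 <= len(template)
        ),
        key=lambda h: h.pos,
    )
    if not downstream:
        if inside:
            raise PrimerDesignError(f"{name}: primer overlaps indel (only anchor lies inside it)")
        raise PrimerDesignError(
            f"{name}: no anchor — no homeoSNP within {params.max_product} bp downstream of the indel"
        )
    anchor = downstream[0]
    fwd_end = indel_pos - 1
    if fwd_end < params.min_len:
        raise PrimerDesignError(f"{name}: no room for a forward primer upstream of the indel")
    fwd, fwd_tm, fwd_start = _forward_primer(template, fwd_end, params, None, f"{name} forward")
    rev, rev_tm, rev_end = _reverse_primer(template, anchor.pos, params, f"{name} reverse")
    long_product = rev_end - fwd_start + 1
    return MarkerAssay(
        name=name,
        assay_type="indel",
        forward=fwd,
        reverse=rev,
        forward_3prime_allele=None,
        reverse_anchor=anchor,
        mismatch_positions=(3, 3),
        product_sizes={
            "wild_A": long_product,
            "mutant_A": long_product - indel_len,
            "wild_D": None,
            "mutant_D": None,
        },
        span_3prime=anchor.pos - fwd_end + 1,
        forward_tm=fwd_tm,
        reverse_tm=rev_tm,
        forward_start=fwd_start,
        reverse_end=rev_end,
    )


def _mismatches_3prime(primer: str, target: str, n: int = 5) -> int:
    return sum(1 for a, b in zip(primer[-n:], target[-n:]) if a != b)


def insilico_pcr(
    assay: MarkerAssay,
    templates: Mapping[str, str],
    max_mm: int | None = None,
    max_product: int = 2000,
) -> dict[str, PcrResult]:
    """Evaluate an assay against named templates.

    A primer binds where its 3'-terminal base is matched, at most ``max_mm``
    mismatches fall in the final five 3' bases (the engineered third-base
    mismatch consumes the default budget of 1), and the remainder of the
    primer anneals with at most ``max_mm_body`` mismatches — without the body
    condition, a 3'-window-only rule would accept ~1% of random positions and
    the verdict would be meaningless on realistic templates.  A template
    amplifies iff a forward and a reverse site pair with the reverse
    downstream of the forward; the product spans both primers inclusive.
    """
    max_mm_body = 2
    if max_mm is None:
        max_mm = 1
    fwd, rev = assay.forward, assay.reverse
    Lf, Lr = len(fwd), len(rev)

    def _binds(primer: str, target: str) -> bool:
        if target[-1] != primer[-1]:
            return False
        if _mismatches_3prime(primer, target) > max_mm:
            return False
        body_mm = sum(1 for a, b in zip(primer[:-5], target[:-5]) if a != b)
        return body_mm <= max_mm_body

    out: dict[str, PcrResult] = {}
    for name, seq in templates.items():
        fwd_ends: list[int] = []  # 0-based index of forward 3' base
        for i in range(0, len(seq) - Lf + 1):
            if _binds(fwd, seq[i : i + Lf]):
                fwd_ends.append(i + Lf - 1)
        rev_sites: list[tuple[int, int]] = []  # (3'-end index, footprint end index)
        for i in range(0, len(seq) - Lr + 1):
            if _binds(rev, revcomp(seq[i : i + Lr])):
                rev_sites.append((i, i + Lr - 1))
        products: list[int] = []
        for f_end in fwd_ends:
            f_start = f_end - Lf + 1
            for r_3p, r_end in rev_sites:
                if r_3p > f_end and (r_end - f_start + 1) <= max_product:
                    products.append(r_end - f_start + 1)
        products = sorted(set(products))
        out[name] = PcrResult(template=name, amplifies=bool(products), products=products)
    return out
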