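"""Open-reading-frame analysis of frameshifted transcripts.

Applies a deletion to a wild-type CDS, enumerates forward-strand ORFs in all
three frames, and classifies the functional consequence from annotated domain
content: a frameshift abolishes function when no single remaining ORF retains
both the full N-terminal transit peptide (required for organellar import) and
at least half of the RNA-binding repeats.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Sequence

from Bio.Seq import Seq

from .simulate import GeneModel

__all__ = [
    "OrfRecord",
    "ConsequenceReport",
    "apply_variant",
    "find_orfs",
    "classify_consequence",
]

_STOPS = {"TAA", "TAG", "TGA"}
_NT = set("ACGT")


@dataclasses.dataclass(frozen=True)
class OrfRecord:
    """An ATG-initiated reading frame on a transcript (1-based nt coords).

    ``end`` includes the stop codon when one is present (``has_stop``);
    ``aa_length`` excludes the stop.  ``frame`` is ``(start - 1) % 3``.
    """

    start: int
    end: int
    frame: int
    aa_length: int
    protein: str
    starts_at_canonical_atg: bool
    has_stop: bool = True


def apply_variant(cds: str, deletion: tuple[int, int]) -> str:
    """Delete ``length`` bases starting at 1-based ``pos``; frame shifts by length mod 3."""
    pos, length = deletion
    if length < 1:
        raise ValueError("deletion length must be >= 1")
    if pos < 1 or pos + length - 1 > len(cds):
        raise ValueError(
            f"deletion [{pos}, {pos + length - 1}] outside sequence of length {len(cds)}"
        )
    return cds[: pos - 1] + cds[pos - 1 + length :]


def find_orfs(
    seq: str,
    min_aa: int = 101,
    report_nested: bool = False,
    canonical_start: int = 1,
) -> list[OrfRecord]:
    """Enumerate forward-strand ORFs of at least ``min_aa`` residues.

    Every ATG...stop span in all three frames is considered; ORFs sharing a
    stop are reported only from their 5'-most ATG unless ``report_nested``.
    An ATG left open at the sequence end is reported with ``has_stop=False``.
    The default threshold of 101 selects ORFs longer than 100 aa.
    ``canonical_start`` marks the transcript position of the annotated
    initiator ATG for flagging.
    """
    seq = seq.upper()
    bad = set(seq) - _NT
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    out: list[OrfRecord] = []
    for frame in range(3):
        open_starts: list[int] = []  # 0-based codon start indices since last stop
        i = frame
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if codon == "ATG":
                open_starts.append(i)
            if codon in _STOPS and open_starts:
                starts = open_starts if report_nested else open_starts[:1]
                for s in starts:
                    aa = (i - s) // 3
                    if aa >= min_aa:
                        out.append(
                            OrfRecord(
                                start=s + 1,
                                end=i + 3,
                                frame=frame,
                                aa_length=aa,
                                protein=str(Seq(seq[s:i]).translate()),
                                starts_at_canonical_atg=(s + 1 == canonical_start),
                                has_stop=True,
                            )
                        )
                open_starts = []
            if codon in _STOPS:
                open_starts = []
            i += 3
        # run-off ORFs: ATG without a downstream stop before the sequence end
        starts = open_starts if report_nested else open_starts[:1]
        for s in starts:
            aa = (i - s) // 3
            if aa >= min_aa:
                out.append(
                    OrfRecord(
                        start=s + 1,
                        end=s + 3 * aa,
                        frame=frame,
                        aa_length=aa,
                        protein=str(Seq(seq[s : s + 3 * aa]).translate()),
                        starts_at_canonical_atg=(s + 1 == canonical_start),
                        has_stop=False,
                    )
                )
    out.sort(key=lambda o: (o.start, o.end))
    return out


@dataclasses.dataclass
class OrfDomains:
    orf: OrfRecord
    ref_span: tuple[int, int] | None  # aa span on the reference protein
    contains_transit_peptide: bool
    n_repeats_contained: int


@dataclasses.dataclass
class ConsequenceReport:
    allele: str
    orfs: list[OrfDomains]
    n_repeats_total: int
    function_abolished: bool
    verdict: str


def _prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _suffix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(reversed(a), reversed(b)):
        if x != y:
            break
        n += 1
    return n


def classify_consequence(
    orfs: Sequence[OrfRecord],
    gene: GeneModel,
    allele: str = "allele",
) -> ConsequenceReport:
    """Classify the domain content of each ORF against the gene annotation.

    The transit peptide is contained only by an ORF that starts at the
    canonical ATG and spans the full annotated range.  Repeat counting maps
    each ORF onto reference-protein coordinates by exact residue match:
    canonical-start ORFs by longest shared prefix plus longest shared suffix
    (an internal in-frame deletion leaves both ends of the protein intact),
    downstream restored-frame ORFs by longest shared suffix (the frame
    downstream of a second initiator reproduces the reference reading).
    Function is abolished when no single ORF contains both the full transit
    peptide and at least half the repeats.
    """
    if gene.transit_peptide_aa is None or not gene.repeat_blocks:
        raise ValueError("gene annotation must provide transit peptide and repeat blocks")
    ref = gene.protein
    total = len(gene.repeat_blocks)
    need = math.ceil(total / 2)
    domains: list[OrfDomains] = []
    intact = False
    for orf in orfs:
        if orf.starts_at_canonical_atg:
            k_pre = _prefix_len(orf.protein, ref)
            k_suf = 0 if orf.protein == ref else _suffix_len(orf.protein, ref)
            span = (1, k_pre) if k_pre else None
        else:
            k_pre = 0
            k_suf = _suffix_len(orf.protein, ref)
            span = (len(ref) - k_suf + 1, len(ref)) if k_suf else None
        contains_tp = bool(
            orf.starts_at_canonical_atg and k_pre >= gene.transit_peptide_aa
        )
        suffix_lo = len(ref) - k_suf + 1 if k_suf else len(ref) + 1
        n_rep = sum(
            1
            for s, e in gene.repeat_blocks
            if e <= k_pre or s >= suffix_lo
        )
        if contains_tp and n_rep >= need:
            intact = True
        domains.append(
            OrfDomains(
                orf=orf,
                ref_span=span,
                contains_transit_peptide=contains_tp,
                n_repeats_contained=n_rep,
            )
        )
    verdict = (
        "not abolished: an ORF retains the transit peptide and the repeat domain"
        if intact
        else "function abolished: no ORF retains both the transit peptide and the repeat domain"
    )
    return ConsequenceReport(
        allele=allele,
        orfs=domains,
        n_repeats_total=total,
        function_abolished=not intact,
        verdict=verdict,
    )
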