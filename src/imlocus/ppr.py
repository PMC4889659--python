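"""PPR-code RNA-binding motif prediction.

Pentatricopeptide-repeat proteins bind single-stranded RNA one nucleotide per
~35-aa repeat; two repeat-internal residues largely determine the bound base
(the "PPR code").  This module extracts those residues per repeat, maps them
through a residue-pair -> nucleotide-probability code table to a per-position
probability matrix, and converts it to sequence-logo bit scores (log-odds
against a uniform background, so negative scores exist and the positive-only
view mirrors a published-style logo).

The shipped code table (``data/ppr_code.tsv``) is a synthetic default built
on the combinatorial two-residue code idea; it declares its own intra-repeat
residue-position convention in its header, which the extractor reads, since
the literature numbers these positions inconsistently.
"""
from __future__ import annotations

import dataclasses
import warnings
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "RepeatResidues",
    "CodeTable",
    "Pswm",
    "load_code_table",
    "extract_residues",
    "build_pswm",
    "logo_bits",
    "naive_repeat_scan",
    "DEFAULT_PPR_CONSENSUS",
]

RNA_BASES = ("A", "C", "G", "U")
_AA = set("ARNDCQEGHILKMFPSTWYV")

#: a generic 35-aa P-type PPR repeat consensus used by the naive scanner
DEFAULT_PPR_CONSENSUS = "VTYNTLIDGLCKAGKLDEALELFEEMKEKGIKPDV"


@dataclasses.dataclass(frozen=True)
class RepeatResidues:
    """The nucleotide-specifying residue pair of one repeat (N->C order)."""

    index: int
    residues: tuple[str, str]

    def __post_init__(self):
        for r in self.residues:
            if r not in _AA:
                raise ValueError(f"invalid amino-acid letter {r!r} in repeat {self.index}")


@dataclasses.dataclass
class CodeTable:
    """Residue pair -> probability vector over (A, C, G, U).

    ``positions`` is the 1-based intra-repeat location of the two residues as
    declared by the table file itself.
    """

    mapping: dict[tuple[str, str], np.ndarray]
    positions: tuple[int, int]

    def __post_init__(self):
        for pair, vec in self.mapping.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (4,) or (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(f"probabilities for pair {pair} must be >= 0 and sum to 1")
            self.mapping[pair] = vec

    def lookup(self, pair: tuple[str, str]) -> np.ndarray:
        """Probability vector for a pair; unknown pairs map to uniform with a warning."""
        if pair in self.mapping:
            return self.mapping[pair]
        warnings.warn(f"unknown residue pair {pair}; using uniform probabilities", stacklevel=2)
        return np.full(4, 0.25)


def load_code_table(path: str | Path | None = None) -> CodeTable:
    """Load a code-table TSV (columns pair, pA, pC, pG, pU).

    The header comment ``# positions=i,j`` declares the residue convention.
    With no path, the packaged default table is loaded.
    """
    if path is None:
        source = resources.files("imlocus").joinpath("data", "ppr_code.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    positions: tuple[int, int] | None = None
    mapping: dict[tuple[str, str], np.ndarray] = {}
    header_seen = False
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("positions="):
                i, j = body.split("=", 1)[1].split(",")
                positions = (int(i), int(j))
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        pair_s, *probs = line.split("\t")
        if len(pair_s) != 2 or len(probs) != 4:
            raise ValueError(f"malformed code-table row: {line!r}")
        mapping[(pair_s[0], pair_s[1])] = np.array([float(p) for p in probs])
    if positions is None:
        raise ValueError("code table must declare its residue positions (# positions=i,j)")
    return CodeTable(mapping=mapping, positions=positions)


def extract_residues(
    protein: str,
    repeat_blocks: Sequence[tuple[int, int]],
    positions: tuple[int, int],
) -> list[RepeatResidues]:
    """Pull the nucleotide-specifying residue pair from each repeat.

    ``repeat_blocks`` are 1-based inclusive aa spans on the protein in N->C
    order; ``positions`` are 1-based offsets within a repeat (normally taken
    from the code table's declared convention).
    """
    out: list[RepeatResidues] = []
    for k, (start, end) in enumerate(repeat_blocks, start=1):
        if start < 1 or end > len(protein) or start > end:
            raise ValueError(f"repeat {k} span ({start}, {end}) outside protein")
        length = end - start + 1
        if max(positions) > length:
            raise ValueError(
                f"repeat {k} is {length} aa, shorter than residue position {max(positions)}"
            )
        pair = (protein[start - 1 + positions[0] - 1], protein[start - 1 + positions[1] - 1])
        out.append(RepeatResidues(index=k, residues=pair))
    return out


@dataclasses.dataclass
class Pswm:
    """L x 4 per-position nucleotide probability matrix with logo bit scores.

    Column order follows repeat order, which reads 5'->3' along the predicted
    binding site.  ``bits`` is log2(p / background); probabilities of zero
    give -inf bit scores.
    """

    probs: np.ndarray  # shape (L, 4), rows sum to 1
    background: np.ndarray  # shape (4,)
    bases: tuple[str, ...] = RNA_BASES

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be L x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each row must sum to 1")

    @property
    def bits(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background)

    def consensus(self) -> str:
        return "".join(self.bases[i] for i in self.probs.argmax(axis=1))


def build_pswm(
    residue_pairs: Sequence[RepeatResidues],
    code_table: CodeTable,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> Pswm:
    """Map residue pairs through the code table to a probability matrix."""
    if not residue_pairs:
        raise ValueError("need at least one residue pair")
    probs = np.vstack([code_table.lookup(rp.residues) for rp in residue_pairs])
    return Pswm(probs=probs, background=np.asarray(background, dtype=float))


def logo_bits(pswm: Pswm) -> tuple[np.ndarray, np.ndarray]:
    """Full and positive-only bit-score matrices (negatives zeroed).

    The full matrix is the position-specific weight matrix analogue; the
    positive-only view is what a logo showing only positive bit scores draws.
    """
    full = pswm.bits
    positive = np.where(full > 0, full, 0.0)
    positive = np.where(np.isfinite(positive), positive, 0.0)
    return full, positive


def naive_repeat_scan(
    protein: str,
    period: int = 35,
    seed_motif: str | None = None,
    min_identity: float = 0.5,
) -> list[tuple[int, int]]:
    """Sliding-window identity scan for tandem repeat blocks.

    Scores each window of ``period`` residues by fractional identity to the
    consensus and greedily keeps non-overlapping windows at or above
    ``min_identity`` (highest score first, ties to the N-terminal copy).
    This is a deliberately naive stand-in for a profile scan: it finds planted
    or well-conserved tandem copies, not diverged natural repeats, and is NOT
    equivalent to a PROSITE profile search.
    """
    consensus = seed_motif or DEFAULT_PPR_CONSENSUS
    if len(consensus) != period:
        raise ValueError("seed motif length must equal the period")
    if len(protein) < period:
        return []
    scores = []
    for i in range(len(protein) - period + 1):
        window = protein[i : i + period]
        ident = sum(1 for a, b in zip(window, consensus) if a == b) / period
        if ident >= min_identity:
            scores.append((ident, i))
    scores.sort(key=lambda t: (-t[0], t[1]))
    taken: list[tuple[int, int]] = []
    occupied = np.zeros(len(protein), dtype=bool)
    for _ident, i in scores:
        if not occupied[i : i + period].any():
            occupied[i : i + period] = True
            taken.append((i + 1, i + period))  # 1-based inclusive
    taken.sort()
    return taken
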