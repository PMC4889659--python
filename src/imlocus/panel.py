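"""Diversity-panel marker summarization and causal-candidate exclusion.

The logic: a mutation causing an obvious deleterious phenotype should be
absent from cultivated germplasm, while linked neutral polymorphisms may
persist as a shared haplotype.  A candidate marker is therefore "consistent
with causality" when its mutant-type allele never appears in the panel even
though accessions homozygous mutant-type across the flanking markers exist.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import pandas as pd

__all__ = ["PanelSummary", "summarize_panel", "render_matrix"]

_IM_HOM = "BB"
_WT_HOM = "AA"
_HET = "AB"


@dataclasses.dataclass
class PanelSummary:
    """Per-marker state counts plus the flanking-haplotype co-occurrence groups."""

    n_accessions: int
    per_marker: pd.DataFrame  # rows = markers; columns im_hom/het/wt_hom/missing
    candidate_marker: str
    flanking_markers: list[str]
    n_all_flanking_im_hom: int  # homozygous im-type at every flanking marker
    n_some_flanking_im: int  # im allele (het or hom) at >= 1 flanking marker, not above
    n_no_flanking_im: int
    n_flanking_missing: int  # excluded from the three groups for missing calls
    candidate_im_alleles: int
    candidate_im_carriers: int
    consistent_with_causality: bool


def summarize_panel(
    genotypes: pd.DataFrame,
    candidate_marker: str,
    flanking_markers: Sequence[str],
) -> PanelSummary:
    """Summarize a panel genotype matrix around a candidate causal marker.

    ``genotypes`` has accessions as rows and markers as columns with codes in
    {AA, AB, BB} (B = mutant/im-type allele) or missing.  Heterozygous calls
    count as "carries the im-type allele" for the some-flanking group but not
    for the all-flanking homozygous group.  Accessions with a missing call at
    any flanking marker are excluded from the three groups and reported
    separately.
    """
    if len(genotypes) == 0:
        raise ValueError("empty panel")
    flanking = list(flanking_markers)
    for m in [candidate_marker, *flanking]:
        if m not in genotypes.columns:
            raise ValueError(f"marker {m!r} not in genotype table")

    rows = []
    for marker in genotypes.columns:
        col = genotypes[marker]
        rows.append(
            {
                "marker": marker,
                "im_hom": int((col == _IM_HOM).sum()),
                "het": int((col == _HET).sum()),
                "wt_hom": int((col == _WT_HOM).sum()),
                "missing": int(col.isna().sum()),
            }
        )
    per_marker = pd.DataFrame(rows).set_index("marker")

    if flanking:
        fl = genotypes[flanking]
        missing_mask = fl.isna().any(axis=1)
        all_hom = (fl == _IM_HOM).all(axis=1) & ~missing_mask
        some_im = fl.isin([_IM_HOM, _HET]).any(axis=1) & ~all_hom & ~missing_mask
        none_im = ~all_hom & ~some_im & ~missing_mask
        n_all, n_some = int(all_hom.sum()), int(some_im.sum())
        n_none, n_missing = int(none_im.sum()), int(missing_mask.sum())
    else:
        # no flanking markers: the co-occurrence groups are empty by definition
        n_all = n_some = n_missing = 0
        n_none = len(genotypes)

    cand = genotypes[candidate_marker]
    candidate_im_alleles = int(2 * (cand == _IM_HOM).sum() + (cand == _HET).sum())
    candidate_im_carriers = int(cand.isin([_IM_HOM, _HET]).sum())
    consistent = candidate_im_alleles == 0 and (n_all + n_some) > 0
    return PanelSummary(
        n_accessions=len(genotypes),
        per_marker=per_marker,
        candidate_marker=candidate_marker,
        flanking_markers=flanking,
        n_all_flanking_im_hom=n_all,
        n_some_flanking_im=n_some,
        n_no_flanking_im=n_none,
        n_flanking_missing=n_missing,
        candidate_im_alleles=candidate_im_alleles,
        candidate_im_carriers=candidate_im_carriers,
        consistent_with_causality=consistent,
    )


_SYMBOLS = {_IM_HOM: "R", _WT_HOM: "G", _HET: "O"}


def render_matrix(
    genotypes: pd.DataFrame,
    candidate_marker: str | None = None,
    flanking_markers: Sequence[str] | None = None,
) -> str:
    """Deterministic text rendering of the panel (rows = accessions).

    Cell symbols: R = homozygous im-type, G = homozygous TM-1-type,
    O = heterozygous, . = missing.  When the marker roles are given, rows are
    grouped (all-flanking im homozygotes, then partial carriers, then the
    rest), preserving input order within groups; otherwise input order.
    """
    order = list(genotypes.index)
    if candidate_marker is not None and flanking_markers:
        summary_groups = []
        fl = genotypes[list(flanking_markers)]
        missing_mask = fl.isna().any(axis=1)
        all_hom = (fl == _IM_HOM).all(axis=1) & ~missing_mask
        some_im = fl.isin([_IM_HOM, _HET]).any(axis=1) & ~all_hom & ~missing_mask
        for mask in (all_hom, some_im, ~(all_hom | some_im)):
            summary_groups.extend(genotypes.index[mask])
        order = summary_groups
    lines = ["accession\t" + "\t".join(genotypes.columns)]
    for acc in order:
        row = genotypes.loc[acc]
        cells = [_SYMBOLS.get(v, ".") if pd.notna(v) else "." for v in row]
        lines.append(f"{acc}\t" + "\t".join(cells))
    lines.append("# legend: R = im-type homozygote, G = TM-1-type homozygote, O = heterozygote, . = missing")
    return "\n".join(lines)
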