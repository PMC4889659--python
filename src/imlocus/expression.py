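"""Interval expression screen: RPKM, TMM scaling, ANOVA, and the twofold rule.

Reads-per-kilobase-per-million (RPKM) values are reported per sample or
group; between-sample scaling uses a trimmed mean of M-values (TMM) computed
on raw count ratios against a reference sample, so the factors absorb
sequencing depth and counts divided by their factor are directly comparable.
Differential expression is a per-gene one-way ANOVA on log2 TMM-scaled
counts, and candidate genes are flagged by the significant-twofold rule.
"""
from __future__ import annotations

from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "rpkm",
    "tmm_factors",
    "log2fc",
    "detection_filter",
    "differential_test",
    "twofold_rule",
    "load_interval_table",
]


def rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """RPKM = 1e9 * C / (N * L) per gene and sample.

    ``lib_sizes`` defaults to column sums of the analyzed counts table.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = lib_sizes.reindex(counts.columns).astype(float)
    if (lib_sizes <= 0).any():
        bad = lib_sizes.index[lib_sizes <= 0].tolist()
        raise ValueError(f"zero library size for samples {bad}")
    return 1e9 * counts.div(lib_sizes, axis=1).div(lengths.astype(float), axis=0)


def tmm_factors(
    counts: pd.DataFrame,
    reference_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M scaling factors on raw count ratios vs a reference.

    Per sample, gene-wise M = log2(count_sample / count_ref) and
    A = mean log2 abundance are computed over genes nonzero in both; the most
    extreme ``trim_m`` of M and ``trim_a`` of A are dropped two-sided; the
    factor is 2 to the inverse-asymptotic-variance-weighted mean of the
    surviving M values.  Factors are then rescaled to geometric mean 1, so a
    sample sequenced twice as deep gets a factor twice the reference's before
    rescaling.  Divide counts by their factor to put samples on one scale.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    zero_samples = counts.columns[(counts.sum(axis=0) == 0)].tolist()
    if zero_samples:
        raise ValueError(f"all-zero samples: {zero_samples}")
    if reference_sample is None:
        reference_sample = counts.columns[0]
    ref = counts[reference_sample].to_numpy(dtype=float)
    n_ref = ref.sum()
    factors = {}
    for sample in counts.columns:
        obs = counts[sample].to_numpy(dtype=float)
        if sample == reference_sample:
            factors[sample] = 1.0
            continue
        keep = (obs > 0) & (ref > 0)
        o, r = obs[keep], ref[keep]
        m = np.log2(o / r)
        a = 0.5 * np.log2(o * r)
        lo_m, hi_m = np.quantile(m, [trim_m / 2, 1 - trim_m / 2])
        lo_a, hi_a = np.quantile(a, [trim_a / 2, 1 - trim_a / 2])
        mask = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not mask.any():  # trim degeneracy (e.g. all M identical): use all genes
            mask = np.ones_like(m, dtype=bool)
        n_obs = obs.sum()
        w = 1.0 / np.maximum(
            (n_obs - o[mask]) / (n_obs * o[mask]) + (n_ref - r[mask]) / (n_ref * r[mask]),
            1e-12,
        )
        factors[sample] = float(2.0 ** (np.sum(w * m[mask]) / np.sum(w)))
    f = pd.Series(factors).reindex(counts.columns)
    return f / np.exp(np.log(f).mean())  # geometric mean 1


def log2fc(rpkm_a: float, rpkm_b: float, pseudocount: float = 0.0) -> float:
    """log2((b + pc) / (a + pc)) — the b-over-a expression ratio.

    With the default pseudocount of 0, a zero on either side is undefined and
    raises rather than returning a silent infinity.
    """
    if rpkm_a < 0 or rpkm_b < 0:
        raise ValueError("expression values must be >= 0")
    if pseudocount == 0.0 and (rpkm_a == 0.0 or rpkm_b == 0.0):
        raise ValueError("log2 ratio undefined at zero expression without a pseudocount")
    return float(np.log2((rpkm_b + pseudocount) / (rpkm_a + pseudocount)))


def detection_filter(
    rpkm_values: pd.DataFrame,
    threshold: float = 1.0,
    groups: Sequence[str] | None = None,
) -> list[str]:
    """Genes detected strictly above ``threshold`` RPKM in any sample.

    With ``groups`` (one label per column), group means are compared instead
    of individual samples.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    values = rpkm_values
    if groups is not None:
        values = rpkm_values.T.groupby(list(groups)).mean().T
    detected = (values > threshold).any(axis=1)
    return list(values.index[detected])


def differential_test(
    counts: pd.DataFrame,
    groups: Sequence[str],
    factors: pd.Series | None = None,
) -> pd.Series:
    """Per-gene one-way ANOVA on log2(TMM-scaled counts + 0.5).

    With two groups this is equivalent to an equal-variance t-test.  Genes
    with zero variance everywhere (e.g. constant across all samples) get
    p = 1.  Requires >= 2 replicates per group.
    """
    groups = list(groups)
    if len(groups) != counts.shape[1]:
        raise ValueError("need one group label per sample column")
    levels = sorted(set(groups))
    cols_by_level = [[c for c, g in zip(counts.columns, groups) if g == lv] for lv in levels]
    if len(levels) < 2 or any(len(cols) < 2 for cols in cols_by_level):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    if factors is None:
        factors = tmm_factors(counts)
    scaled = np.log2(counts.div(factors.reindex(counts.columns), axis=1) + 0.5)
    arrays = [scaled[cols].to_numpy() for cols in cols_by_level]
    with np.errstate(invalid="ignore", divide="ignore"):
        _f, p = stats.f_oneway(*arrays, axis=1)
    p = np.where(np.isnan(p), 1.0, p)  # degenerate (constant) genes
    return pd.Series(p, index=counts.index, name="p_value").clip(0.0, 1.0)


def twofold_rule(fold_changes: pd.Series, p_values: pd.Series, alpha: float = 0.05) -> list[str]:
    """Flag genes with |log2FC| >= 1 and p < alpha (significant twofold change)."""
    fold_changes, p_values = fold_changes.align(p_values)
    flag = (fold_changes.abs() >= 1.0) & (p_values < alpha)
    return list(fold_changes.index[flag.fillna(False)])


def load_interval_table() -> pd.DataFrame:
    """The published per-gene RPKM table for the ~2-Mb interval around the locus."""
    with resources.files("imlocus").joinpath("data", "interval_expression.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["NA"])
    return df
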