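"""Two-point F2 linkage analysis and phenotype classification.

The immature-fiber trait is scored qualitatively from lint percentage with a
micronaire tie-break in the marginal zone, tested for 3:1 segregation, and
mapped against codominant markers by maximum-likelihood estimation of the
recombination fraction r under F2 expected class frequencies (coupling phase,
no interference).  Map distances come from the Haldane and Kosambi functions;
marker order is recovered by minimizing the sum of adjacent distances.
"""
from __future__ import annotations

import dataclasses
import itertools
import math
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PhenotypeClass",
    "SegTest",
    "TwoPointEstimate",
    "DiscordanceReport",
    "classify_phenotype",
    "classify_phenotypes",
    "segregation_test",
    "estimate_r",
    "map_distance",
    "order_markers",
    "discordance_check",
    "load_population_compositions",
    "population_summary",
]

WILD_TYPE = "wild_type"
IM = "im"
UNCLASSIFIED = "unclassified"
PhenotypeClass = str

#: lint% at or below which a plant is scored immature outright
LINT_IM_MAX = 25.0
#: upper lint% bound of the marginal zone resolved by micronaire
LINT_MARGINAL_MAX = 29.0
#: micronaire below which a marginal plant is scored immature
MIC_IM_MAX = 3.5


def classify_phenotype(lint_pct: float | None, mic: float | None = None) -> PhenotypeClass:
    """Score one plant from lint percentage and (optionally) micronaire.

    Missing lint -> unclassified.  lint <= 25 -> im.  25 < lint <= 29 is the
    marginal zone: im if mic < 3.5, wild type if mic >= 3.5, unclassified if
    micronaire was not measured.  lint > 29 -> wild type.  (Lint between 25
    and 26 falls under the marginal micronaire rule.)
    """
    lint_missing = lint_pct is None or (isinstance(lint_pct, float) and math.isnan(lint_pct))
    mic_missing = mic is None or (isinstance(mic, float) and math.isnan(mic))
    if not lint_missing and lint_pct < 0:
        raise ValueError(f"negative lint percentage {lint_pct}")
    if not mic_missing and mic < 0:
        raise ValueError(f"negative micronaire {mic}")
    if lint_missing:
        return UNCLASSIFIED
    if lint_pct <= LINT_IM_MAX:
        return IM
    if lint_pct <= LINT_MARGINAL_MAX:
        if mic_missing:
            return UNCLASSIFIED
        return IM if mic < MIC_IM_MAX else WILD_TYPE
    return WILD_TYPE


def classify_phenotypes(phenotypes: pd.DataFrame) -> pd.Series:
    """Vector version over a frame with lint_pct and mic columns."""
    return pd.Series(
        [classify_phenotype(l, m) for l, m in zip(phenotypes["lint_pct"], phenotypes["mic"])],
        index=phenotypes.index,
        name="phenotype_class",
    )


@dataclasses.dataclass
class SegTest:
    observed: tuple[int, int]
    expected_ratio: tuple[int, int]
    chi_square: float
    df: int
    p_value: float


def segregation_test(
    n_dominant_class: int, n_recessive_class: int, ratio: tuple[int, int] = (3, 1)
) -> SegTest:
    """Pearson chi-square (df=1) of observed class counts against a ratio."""
    if n_dominant_class < 0 or n_recessive_class < 0:
        raise ValueError("counts must be non-negative")
    n = n_dominant_class + n_recessive_class
    if n == 0:
        raise ValueError("no classified plants")
    total_ratio = sum(ratio)
    expected = [n * ratio[0] / total_ratio, n * ratio[1] / total_ratio]
    chi2, p = stats.chisquare([n_dominant_class, n_recessive_class], expected)
    return SegTest(
        observed=(n_dominant_class, n_recessive_class),
        expected_ratio=ratio,
        chi_square=float(chi2),
        df=1,
        p_value=float(p),
    )


@dataclasses.dataclass
class TwoPointEstimate:
    r_hat: float
    log_likelihood: float
    n_informative: int
    se: float
    distances_cm: dict[str, float]


def _gamete_probs(r: float) -> np.ndarray:
    """P(gamete carries allele i at locus 1 and allele j at locus 2), coupling."""
    return np.array([[(1 - r) / 2, r / 2], [r / 2, (1 - r) / 2]])


def f2_joint_probs(r: float) -> np.ndarray:
    """3x3 F2 genotype-class probabilities, indexed by B-allele dosage."""
    g = _gamete_probs(r)
    p = np.zeros((3, 3))
    for a1, b1, a2, b2 in itertools.product((0, 1), repeat=4):
        p[a1 + a2, b1 + b2] += g[a1, b1] * g[a2, b2]
    return p


_CODE_TO_DOSAGE = {"AA": 0, "AB": 1, "BB": 2}
_TRAIT_TO_RECESSIVE = {IM: 1, "recessive": 1, "BB": 1, WILD_TYPE: 0, "non_recessive": 0}


def _crosstab(genotypes_a: Sequence, genotypes_b: Sequence, model: str) -> np.ndarray:
    a = pd.Series(list(genotypes_a))
    b = pd.Series(list(genotypes_b))
    if len(a) != len(b):
        raise ValueError("genotype vectors differ in length")
    da = a.map(_CODE_TO_DOSAGE)
    if model == "codominant":
        db = b.map(_CODE_TO_DOSAGE)
        shape = (3, 3)
    elif model == "recessive":
        db = b.map(_TRAIT_TO_RECESSIVE)
        shape = (3, 2)
    else:
        raise ValueError(f"unknown model {model!r}")
    keep = da.notna() & db.notna()
    counts = np.zeros(shape)
    np.add.at(counts, (da[keep].astype(int), db[keep].astype(int)), 1)
    return counts


def _loglik(counts: np.ndarray, r: float, model: str) -> float:
    p = f2_joint_probs(r)
    if model == "recessive":
        # trait classes: non-recessive = dosage {0, 1} at the trait locus
        p = np.stack([p[:, 0] + p[:, 1], p[:, 2]], axis=1)
    with np.errstate(divide="ignore"):
        logp = np.log(np.clip(p, 1e-300, None))
    return float((counts * logp).sum())


def estimate_r(
    genotypes_a: Sequence,
    genotypes_b: Sequence,
    model: str = "codominant",
) -> TwoPointEstimate:
    """Maximum-likelihood recombination fraction between two loci.

    ``model="codominant"`` expects AA/AB/BB codes for both loci;
    ``model="recessive"`` expects the second vector to carry trait classes
    ({im, wild_type} or {recessive, non_recessive}) for a locus observed only
    through a recessive phenotype.  Missing entries are dropped pairwise;
    unclassified plants are uninformative and likewise dropped.  r is found by
    bounded scalar search on [0, 0.5] to 1e-6; the standard error comes from
    the observed Fisher information.
    """
    counts = _crosstab(genotypes_a, genotypes_b, model)
    n = int(counts.sum())
    if n < 2:
        raise ValueError(f"need >= 2 informative pairs, got {n}")
    res = optimize.minimize_scalar(
        lambda r: -_loglik(counts, r, model),
        bounds=(1e-9, 0.5 - 1e-9),
        method="bounded",
        options={"xatol": 1e-6},
    )
    r_hat = float(res.x)
    ll = -float(res.fun)
    # snap to the boundary when the data contain no recombinant classes
    if r_hat < 1e-5 and _loglik(counts, 0.0, model) >= ll:
        r_hat, ll = 0.0, _loglik(counts, 0.0, model)
    h = 1e-4
    if h < r_hat < 0.5 - h:
        d2 = (_loglik(counts, r_hat + h, model) - 2 * ll + _loglik(counts, r_hat - h, model)) / h**2
        se = float(1.0 / np.sqrt(-d2)) if d2 < 0 else float("nan")
    else:
        se = float("nan")
    distances = {
        fn: map_distance(r_hat, fn) if r_hat < 0.5 else float("inf")
        for fn in ("haldane", "kosambi")
    }
    return TwoPointEstimate(
        r_hat=r_hat, log_likelihood=ll, n_informative=n, se=se, distances_cm=distances
    )


def map_distance(r: float, function: str = "kosambi") -> float:
    """Recombination fraction -> centiMorgans.

    Haldane: d = -50 ln(1 - 2r).  Kosambi: d = 25 ln((1 + 2r)/(1 - 2r)).
    r >= 0.5 maps to infinity (unlinked).
    """
    if r < 0:
        raise ValueError("r must be >= 0")
    if r == 0:
        return 0.0
    if r >= 0.5:
        return float("inf")
    if function == "haldane":
        return -50.0 * math.log(1.0 - 2.0 * r)
    if function == "kosambi":
        return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    raise ValueError(f"unknown map function {function!r}")


def order_markers(
    r_matrix: pd.DataFrame,
    function: str = "kosambi",
    max_exhaustive: int = 8,
) -> tuple[list[str], list[float]]:
    """Order markers by minimizing the sum of adjacent map distances.

    ``r_matrix`` is a symmetric marker-by-marker recombination-fraction
    frame.  Up to ``max_exhaustive`` markers are ordered exhaustively; above
    that a greedy nearest-neighbour construction refined by 2-opt is used.
    The returned orientation is canonical: the lexicographically smaller
    endpoint comes first.  Also returns cumulative cM positions.
    """
    names = list(r_matrix.index)
    if list(r_matrix.columns) != names:
        raise ValueError("r matrix must have identical row and column labels")
    mat = r_matrix.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, equal_nan=True):
        raise ValueError("r matrix must be symmetric")
    n = len(names)
    if n < 2:
        return names, [0.0] * n
    dist = np.vectorize(lambda r: map_distance(min(r, 0.499), function))(mat)
    np.fill_diagonal(dist, 0.0)

    def score(order: Sequence[int]) -> float:
        return float(sum(dist[a, b] for a, b in zip(order[:-1], order[1:])))

    if n <= max_exhaustive:
        best = min(
            (p for p in itertools.permutations(range(n)) if p[0] < p[-1]),
            key=score,
        )
        best = list(best)
    else:
        candidates = []
        for start in range(n):
            order = [start]
            left = set(range(n)) - {start}
            while left:
                nxt = min(left, key=lambda j: dist[order[-1], j])
                order.append(nxt)
                left.remove(nxt)
            candidates.append(order)
        best = min(candidates, key=score)
        improved = True
        while improved:
            improved = False
            for i in range(1, n - 1):
                for j in range(i + 1, n):
                    cand = best[:i] + best[i:j + 1][::-1] + best[j + 1:]
                    if score(cand) < score(best) - 1e-12:
                        best, improved = cand, True
    if names[best[-1]] < names[best[0]]:
        best = best[::-1]
    cum = [0.0]
    for a, b in zip(best[:-1], best[1:]):
        cum.append(cum[-1] + dist[a, b])
    return [names[i] for i in best], cum


@dataclasses.dataclass
class DiscordanceReport:
    im_not_bb: int
    wild_type_bb: int
    n_compared: int

    @property
    def complete_linkage(self) -> bool:
        return self.im_not_bb == 0 and self.wild_type_bb == 0


def discordance_check(
    marker_genotypes: Sequence, phenotype_classes: Sequence
) -> DiscordanceReport:
    """Count plants whose marker genotype contradicts their phenotype class.

    Complete linkage holds when no im plant lacks the BB marker genotype and
    no wild-type plant carries it.  Unclassified plants and missing genotypes
    are skipped.
    """
    marker = pd.Series(list(marker_genotypes))
    pheno = pd.Series(list(phenotype_classes))
    if len(marker) != len(pheno):
        raise ValueError("vectors differ in length")
    valid = marker.isin(_CODE_TO_DOSAGE) & pheno.isin([IM, WILD_TYPE])
    marker, pheno = marker[valid], pheno[valid]
    im_not_bb = int(((pheno == IM) & (marker != "BB")).sum())
    wild_bb = int(((pheno == WILD_TYPE) & (marker == "BB")).sum())
    return DiscordanceReport(im_not_bb=im_not_bb, wild_type_bb=wild_bb, n_compared=int(valid.sum()))


def load_population_compositions() -> pd.DataFrame:
    """The three published F2 population compositions (wild:im:no-phenotype)."""
    with resources.files("imlocus").joinpath("data", "f2_populations.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def population_summary(compositions: pd.DataFrame | None = None) -> dict[str, int]:
    """Totals across populations: im plants, genotyped plants, phenotyped plants.

    Every plant is genotyped; plants lacking a classifiable phenotype are
    genotyped but not phenotyped.
    """
    df = compositions if compositions is not None else load_population_compositions()
    im = int(df["im"].sum())
    genotyped = int(df[["wild_type", "im", "no_phenotype"]].to_numpy().sum())
    phenotyped = genotyped - int(df["no_phenotype"].sum())
    return {"im": im, "genotyped": genotyped, "phenotyped": phenotyped}
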