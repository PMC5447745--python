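"""Two-point F2 linkage analysis with the Kosambi map function.

Recombination fractions between codominant markers are estimated from
F2 genotype codes (a = homozygous for the sterile-parent allele, b =
homozygous for the fertile-parent allele, h = heterozygous) by
expectation-maximization on recombinant gamete counts under the standard
no-interference two-locus F2 model.  Distances come from the Kosambi
function d = 25 ln((1+2r)/(1-2r)) cM, markers are ordered by greedy
seriation on the pairwise distance matrix, and the trait locus (coded
codominantly via F3 progeny testing of fertile plants) is placed by
treating it as one more marker.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LinkageGroup",
    "TraitPlacement",
    "kosambi_cm",
    "kosambi_r",
    "estimate_r_f2",
    "two_locus_class_probs",
    "two_locus_loglik",
    "lod_score",
    "order_markers",
    "build_linkage_groups",
    "place_trait_locus",
]

#: genotype code -> number of sterile-parent (P) alleles carried
CODE_TO_DOSE = {"a": 2, "h": 1, "b": 0}
MISSING_CODES = {"-", "", "missing", "nan", "na", None}

# F1 gamete haplotypes in coupling phase: (P allele at locus 1?, at locus 2?)
_HAPS = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
_HAP_REC = np.array([0, 1, 1, 0])  # recombinant gametes


@dataclass(frozen=True)
class LinkageGroup:
    """An ordered set of markers with cumulative Kosambi positions."""

    markers: tuple[str, ...]
    positions_cm: tuple[float, ...]
    pairwise_r: pd.DataFrame

    @property
    def length_cm(self) -> float:
        return self.positions_cm[-1] if self.positions_cm else 0.0


@dataclass(frozen=True)
class TraitPlacement:
    """The two markers closest to the trait locus, with r and cM to each."""

    nearest: tuple[tuple[str, float, float], ...]  # (marker, r_hat, cM)
    n_used: int
    n_excluded: int


def kosambi_cm(r: float) -> float:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) centimorgans.

    Strictly increasing and convex on [0, 0.5); ~100 r for small r.
    """
    if not (0 <= r < 0.5):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


def kosambi_r(d_cm: float) -> float:
    """Inverse Kosambi function: r = tanh(d/50) / 2."""
    if d_cm < 0:
        raise ValueError("map distance must be non-negative")
    return 0.5 * math.tanh(d_cm / 50.0)


def _gamete_probs(r: float) -> np.ndarray:
    return np.array([(1 - r) / 2, r / 2, r / 2, (1 - r) / 2])


def two_locus_class_probs(r: float) -> np.ndarray:
    """3x3 matrix of F2 two-locus genotype-class probabilities.

    Entry [i, j] is the probability of carrying i sterile-parent alleles
    at locus 1 and j at locus 2, for an F1 in coupling phase producing
    independent gametes with no interference.
    """
    p = _gamete_probs(r)
    probs = np.zeros((3, 3))
    for g1 in range(4):
        for g2 in range(4):
            i = _HAPS[g1, 0] + _HAPS[g2, 0]
            j = _HAPS[g1, 1] + _HAPS[g2, 1]
            probs[i, j] += p[g1] * p[g2]
    return probs


def two_locus_loglik(counts: np.ndarray, r: float) -> float:
    """Multinomial log-likelihood of a 3x3 genotype-class count table."""
    probs = two_locus_class_probs(r)
    mask = counts > 0
    with np.errstate(divide="ignore"):  # -inf is the correct value at r=0
        return float(np.sum(counts[mask] * np.log(probs[mask])))


def _codes_to_dose(codes) -> np.ndarray:
    out = np.full(len(codes), -1, dtype=int)
    for i, c in enumerate(codes):
        c = c if c is None else str(c).strip().lower()
        if c in CODE_TO_DOSE:
            out[i] = CODE_TO_DOSE[c]
        elif c not in MISSING_CODES and not (isinstance(c, float) and math.isnan(c)):
            raise ValueError(f"unknown genotype code: {codes[i]!r}")
    return out


def _count_table(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    keep = (d1 >= 0) & (d2 >= 0)
    counts = np.zeros((3, 3))
    np.add.at(counts, (d1[keep], d2[keep]), 1.0)
    return counts


def estimate_r_f2(
    genotypes_m1,
    genotypes_m2,
    min_n: int = 20,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> tuple[float, float]:
    """EM estimate of the recombination fraction between two F2 markers.

    Genotype codes a/b/h (missing as ``-``); individuals missing either
    marker are dropped.  The E-step attributes expected recombinant
    gametes to each of the nine genotype classes (only the double
    heterozygote is phase-ambiguous); the M-step sets r to the expected
    recombinant fraction among the 2n gametes.  Iterated until the
    update moves r by less than ``tol``; ties toward smaller r.

    Returns ``(r_hat, log_likelihood)`` with r capped into [0, 0.5).
    """
    d1, d2 = _codes_to_dose(list(genotypes_m1)), _codes_to_dose(list(genotypes_m2))
    if d1.size != d2.size:
        raise ValueError("genotype vectors must have equal length")
    counts = _count_table(d1, d2)
    n = counts.sum()
    if n < min_n:
        raise ValueError(f"need at least {min_n} doubly genotyped individuals, got {int(n)}")

    # per-class expected recombinant gametes, given r
    def expected_rec(r: float) -> np.ndarray:
        p = _gamete_probs(r)
        num = np.zeros((3, 3))
        den = np.zeros((3, 3))
        for g1 in range(4):
            for g2 in range(4):
                i = _HAPS[g1, 0] + _HAPS[g2, 0]
                j = _HAPS[g1, 1] + _HAPS[g2, 1]
                w = p[g1] * p[g2]
                den[i, j] += w
                num[i, j] += w * (_HAP_REC[g1] + _HAP_REC[g2])
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, 0.0)

    r = 0.25
    for _ in range(max_iter):
        r_new = float(np.sum(counts * expected_rec(r)) / (2 * n))
        r_new = min(max(r_new, 0.0), 0.5 - 1e-9)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    return r, two_locus_loglik(counts, r)


def lod_score(genotypes_m1, genotypes_m2, min_n: int = 20) -> float:
    """LOD for linkage: log10 likelihood ratio of r_hat against r = 0.5."""
    d1, d2 = _codes_to_dose(list(genotypes_m1)), _codes_to_dose(list(genotypes_m2))
    counts = _count_table(d1, d2)
    r_hat, ll = estimate_r_f2(genotypes_m1, genotypes_m2, min_n=min_n)
    return (ll - two_locus_loglik(counts, 0.5 - 1e-9)) / math.log(10)


_R_CAP = 0.49995  # distance cap for nominally unlinked pairs


def _distance_matrix(r_matrix: pd.DataFrame) -> np.ndarray:
    r = r_matrix.to_numpy(dtype=float)
    if r.shape[0] != r.shape[1] or not np.allclose(r, r.T, equal_nan=True):
        raise ValueError("pairwise r matrix must be square and symmetric")
    d = np.zeros_like(r)
    for i, j in itertools.combinations(range(r.shape[0]), 2):
        d[i, j] = d[j, i] = kosambi_cm(min(r[i, j], _R_CAP))
    return d


def order_markers(r_matrix: pd.DataFrame) -> LinkageGroup:
    """Greedy seriation of markers from their pairwise r matrix.

    The two mutually most distant markers seed the order; each remaining
    marker (taken in input order) is inserted at the slot minimizing the
    total adjacent Kosambi distance.  Cumulative positions are summed
    adjacent-pair distances from the first marker.
    """
    names = list(r_matrix.index)
    if len(names) == 0:
        raise ValueError("empty marker set")
    if len(names) == 1:
        return LinkageGroup((names[0],), (0.0,), r_matrix)
    d = _distance_matrix(r_matrix)
    i0, j0 = max(
        itertools.combinations(range(len(names)), 2), key=lambda ij: d[ij[0], ij[1]]
    )
    order = [i0, j0]
    for k in range(len(names)):
        if k in order:
            continue
        best_slot, best_cost = 0, math.inf
        for slot in range(len(order) + 1):
            trial = order[:slot] + [k] + order[slot:]
            cost = sum(d[a, b] for a, b in zip(trial, trial[1:]))
            if cost < best_cost - 1e-12:
                best_slot, best_cost = slot, cost
        order.insert(best_slot, k)
    positions = [0.0]
    for a, b in zip(order, order[1:]):
        positions.append(positions[-1] + d[a, b])
    ordered_names = tuple(names[i] for i in order)
    return LinkageGroup(
        markers=ordered_names,
        positions_cm=tuple(positions),
        pairwise_r=r_matrix.loc[list(ordered_names), list(ordered_names)],
    )


def pairwise_r_matrix(genotypes: pd.DataFrame, min_n: int = 20) -> pd.DataFrame:
    """Estimate r for every marker pair of a genotype matrix
    (rows = individuals, columns = markers, codes a/b/h/-)."""
    cols = list(genotypes.columns)
    r = pd.DataFrame(0.0, index=cols, columns=cols)
    for m1, m2 in itertools.combinations(cols, 2):
        r_hat, _ = estimate_r_f2(genotypes[m1], genotypes[m2], min_n=min_n)
        r.loc[m1, m2] = r.loc[m2, m1] = r_hat
    return r


def build_linkage_groups(
    genotypes: pd.DataFrame, lod_min: float = 3.0, min_n: int = 20
) -> list[LinkageGroup]:
    """Split markers into linkage groups at ``lod_min`` and order each.

    Groups are connected components of the graph joining marker pairs
    with LOD >= lod_min; each component is ordered by greedy seriation.
    """
    cols = list(genotypes.columns)
    r = pairwise_r_matrix(genotypes, min_n=min_n)
    adj = {c: set() for c in cols}
    for m1, m2 in itertools.combinations(cols, 2):
        if lod_score(genotypes[m1], genotypes[m2], min_n=min_n) >= lod_min:
            adj[m1].add(m2)
            adj[m2].add(m1)
    groups, seen = [], set()
    for c in cols:
        if c in seen:
            continue
        comp, stack = [], [c]
        while stack:
            m = stack.pop()
            if m in seen:
                continue
            seen.add(m)
            comp.append(m)
            stack.extend(adj[m] - seen)
        comp = [m for m in cols if m in comp]  # deterministic input order
        groups.append(order_markers(r.loc[comp, comp]))
    return groups


def place_trait_locus(
    trait_codes, genotypes: pd.DataFrame, min_n: int = 20
) -> TraitPlacement:
    """Place the trait locus among markers by two-point estimation.

    ``trait_codes`` is the codominant trait genotype per individual
    (sterile plants a; fertile plants b or h resolved by F3 progeny
    testing, ``-`` if unresolved).  Unresolved individuals are excluded
    with a logged count; the two markers with smallest r are reported
    with their Kosambi distances.
    """
    doses = _codes_to_dose(list(trait_codes))
    n_excluded = int(np.sum(doses < 0))
    if n_excluded:
        logger.info("place_trait_locus: %d individuals excluded (unresolved trait genotype)", n_excluded)
    non_missing = doses[doses >= 0]
    if np.unique(non_missing).size < 2:
        raise ValueError("trait genotypes are monomorphic after exclusions; cannot map")
    results = []
    for marker in genotypes.columns:
        r_hat, _ = estimate_r_f2(trait_codes, genotypes[marker], min_n=min_n)
        results.append((str(marker), r_hat, kosambi_cm(min(r_hat, _R_CAP))))
    results.sort(key=lambda t: t[1])
    return TraitPlacement(
        nearest=tuple(results[:2]),
        n_used=int(np.sum(doses >= 0)),
        n_excluded=n_excluded,
    )
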