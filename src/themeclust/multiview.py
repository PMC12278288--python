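"""Cross-theme cluster concordance and late integration.

Each theme is clustered independently (a multiview design); agreement
between views is then measured on the membership sets with the Jaccard
coefficient J(A, B) = |A∩B| / |A∪B|.  The highest-risk clusters are matched
across the three themes and merged by late integration: the union of the
matched sets is decomposed into the 7 exclusive Venn regions, and the
triple intersection is the set of countries consistently assigned to the
worst cluster in every theme.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import AbstractSet, Mapping

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal rounding with ties away from zero, matching how summary
    tables are conventionally printed (0.725 -> 0.73)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def jaccard(set_a: AbstractSet[str], set_b: AbstractSet[str]) -> float:
    """|A∩B| / |A∪B|.  Undefined (error) when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValidationError("Jaccard coefficient is undefined for two empty sets")
    return len(a & b) / len(union)


@dataclass(frozen=True)
class SimilarityMatrix:
    """k_A x k_B Jaccard coefficients between two themes' clusters, on
    risk-ordered labels (row/column i is cluster label i+1)."""

    theme_pair: tuple[str, str]
    values: np.ndarray

    def entry(self, label_a: int, label_b: int) -> float:
        return float(self.values[label_a - 1, label_b - 1])


def similarity_matrix(
    assign_a: Mapping[str, int],
    assign_b: Mapping[str, int],
    theme_pair: tuple[str, str] = ("A", "B"),
) -> SimilarityMatrix:
    """Pairwise cluster Jaccard matrix between two themes' assignments.

    Both assignments must cover the identical country universe; a mismatch
    reports the symmetric difference.
    """
    ua, ub = set(assign_a), set(assign_b)
    if ua != ub:
        raise ValidationError(
            f"assignment universes differ; symmetric difference: {sorted(ua ^ ub)}"
        )
    labels_a = sorted(set(assign_a.values()))
    labels_b = sorted(set(assign_b.values()))
    values = np.zeros((len(labels_a), len(labels_b)))
    for i, la in enumerate(labels_a):
        sa = {c for c, v in assign_a.items() if v == la}
        for j, lb in enumerate(labels_b):
            sb = {c for c, v in assign_b.items() if v == lb}
            values[i, j] = jaccard(sa, sb)
    return SimilarityMatrix(theme_pair=theme_pair, values=values)


def match_high_risk(
    sim_ab: SimilarityMatrix,
    sim_ac: SimilarityMatrix,
    sim_bc: SimilarityMatrix,
) -> tuple[tuple[int, int, int], bool]:
    """Select one cluster per theme maximizing the pairwise Jaccard sum.

    Exhaustive over all k_A*k_B*k_C triples (k=3 -> 27 candidates), which is
    exact and cheap.  Returns the winning (label_A, label_B, label_C) and
    whether it coincides with the worst-risk labels (k, k, k) on
    risk-ordered models; a mismatch is logged, since it means the most
    concordant clusters are not the highest-risk ones.
    """
    ka, kb = sim_ab.values.shape
    kc = sim_ac.values.shape[1]
    if sim_bc.values.shape != (kb, kc):
        raise ValidationError("similarity matrices have inconsistent shapes")
    best, best_score = None, -np.inf
    for i, j, m in itertools.product(range(ka), range(kb), range(kc)):
        score = sim_ab.values[i, j] + sim_ac.values[i, m] + sim_bc.values[j, m]
        if score > best_score + 1e-12:
            best, best_score = (i + 1, j + 1, m + 1), score
    worst = (ka, kb, kc)
    is_worst = best == worst
    if not is_worst:
        logger.warning(
            "max-similarity triple %s differs from worst-risk triple %s", best, worst
        )
    return best, is_worst


@dataclass(frozen=True)
class VennPartition:
    """The 7 exclusive regions induced by three named country sets.

    Region keys: "<X>_only" for each set name, "<X>&<Y>_only" for each pair,
    and "<X>&<Y>&<Z>" for the triple intersection.  Regions are pairwise
    disjoint and their sizes sum to ``union_size``.
    """

    set_names: tuple[str, str, str]
    regions: Mapping[str, frozenset[str]]
    union_size: int

    def percentages(self, ndigits: int = 1) -> dict[str, float]:
        """Region sizes as percent of the union, rounded half-up."""
        if self.union_size == 0:
            return {k: 0.0 for k in self.regions}
        return {
            k: round_half_up(100.0 * len(v) / self.union_size, ndigits)
            for k, v in self.regions.items()
        }


def late_integrate(
    set_a: AbstractSet[str],
    set_b: AbstractSet[str],
    set_c: AbstractSet[str],
    names: tuple[str, str, str] = ("A", "B", "C"),
) -> VennPartition:
    """Decompose three matched worst-cluster sets into exclusive Venn regions."""
    a, b, c = frozenset(set_a), frozenset(set_b), frozenset(set_c)
    na, nb, nc = names
    regions = {
        f"{na}_only": a - b - c,
        f"{nb}_only": b - a - c,
        f"{nc}_only": c - a - b,
        f"{na}&{nb}_only": (a & b) - c,
        f"{na}&{nc}_only": (a & c) - b,
        f"{nb}&{nc}_only": (b & c) - a,
        f"{na}&{nb}&{nc}": a & b & c,
    }
    return VennPartition(set_names=names, regions=regions, union_size=len(a | b | c))
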