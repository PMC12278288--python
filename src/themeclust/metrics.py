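"""Partition-agreement metrics used to score recovery of planted structure."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy.special import comb

from .errors import ValidationError


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two partitions of the same items.

    ARI = (Index - Expected) / (Max - Expected) over the pair-counting
    contingency table; 1 for identical partitions, ~0 for independent ones.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size != b.size:
        raise ValidationError("partitions must label the same items")
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    contingency = np.zeros((ua.size, ub.size), dtype=np.int64)
    np.add.at(contingency, (ia, ib), 1)
    sum_comb = comb(contingency, 2).sum()
    sum_a = comb(contingency.sum(axis=1), 2).sum()
    sum_b = comb(contingency.sum(axis=0), 2).sum()
    n_pairs = comb(a.size, 2)
    if n_pairs == 0:
        return 1.0
    expected = sum_a * sum_b / n_pairs
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def ari_from_mappings(assign_a: Mapping[str, int], assign_b: Mapping[str, int]) -> float:
    """ARI between two country -> label mappings over their shared universe."""
    keys = sorted(set(assign_a) & set(assign_b))
    if not keys:
        raise ValidationError("mappings share no countries")
    return adjusted_rand_index([assign_a[k] for k in keys], [assign_b[k] for k in keys])
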