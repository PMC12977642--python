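"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each result from first principles via a
different route (rational arithmetic, naive recomputation, clause-by-clause
rule evaluation) and never call the code paths they verify.
"""

from __future__ import annotations

import math
from fractions import Fraction
from math import comb


def oracle_regulation(r_disease, detected_disease, detected_reference,
                      unique_peptides, thresholds, level):
    """Clause-by-clause regulation rule, comparing in log space."""
    minimum = {
        "standard": thresholds.up_min_standard,
        "strict": thresholds.up_min_strict,
    }[level]
    if unique_peptides < minimum:
        return "insufficient_evidence"
    if r_disease is None:
        return {
            (True, False): "exclusive_disease",
            (False, True): "exclusive_reference",
            (False, False): "undetected",
        }[(detected_disease, detected_reference)]
    x = math.log2(r_disease)
    if x > math.log2(thresholds.fc_high):
        return "regulated_up"
    if x < math.log2(thresholds.fc_low):
        return "regulated_down"
    return "unregulated"


def oracle_normalisation(r_disease, r_treated, regulation, thresholds):
    if regulation not in ("regulated_up", "regulated_down") or r_treated is None:
        return "not_applicable"
    if thresholds.fc_low <= r_treated <= thresholds.fc_high:
        return "normalised"
    same_direction = (r_disease > 1) == (r_treated > 1)
    closer_to_one = abs(math.log2(r_treated)) < abs(math.log2(r_disease))
    if same_direction and closer_to_one:
        return "trend"
    return "not_normalised"


def oracle_hypergeom_upper(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact upper tail by rational-arithmetic enumeration."""
    total = comb(N, n)
    acc = Fraction(0)
    for kk in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, kk) * comb(N - K, n - kk), total)
    return acc


def oracle_bh(p_values):
    """Step-up BH applied literally to the definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    for rank_pos, idx in enumerate(order):
        candidates = [
            m * p_values[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def oracle_average_linkage(dist, labels):
    """Naive agglomeration recomputing every inter-cluster mean distance
    from the original matrix at every step.

    Same ordering convention as the package (leaves in input order, merged
    clusters appended; ties broken by the lowest (i, j) pair) so trees are
    directly comparable.
    """
    index = {lab: i for i, lab in enumerate(labels)}
    clusters = [[lab] for lab in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        best_pair = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                total = 0.0
                for a in clusters[i]:
                    for b in clusters[j]:
                        total += dist[index[a]][index[b]]
                mean = total / (len(clusters[i]) * len(clusters[j]))
                if best is None or mean < best:
                    best = mean
                    best_pair = (i, j)
        i, j = best_pair
        merges.append(
            (frozenset(clusters[i]), frozenset(clusters[j]), best)
        )
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges
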