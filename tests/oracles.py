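"""Independent brute-force oracles used to validate the implementations.

These deliberately use different algorithms from the package: the SSR
oracle scans periodic runs character by character instead of regex
matching, and the UPGMA oracle recomputes every cluster distance as the
mean of the original leaf-to-leaf distances instead of incremental
size-weighted updates.
"""

from __future__ import annotations

import numpy as np


def is_primitive(motif: str) -> bool:
    n = len(motif)
    return not any(
        n % d == 0 and motif == motif[:d] * (n // d) for d in range(1, n)
    )


def brute_force_ssrs(sequence: str, min_repeats: dict[int, int]):
    """All maximal perfect tandem repeats as (motif, n_repeats, start, end).

    Coordinates 1-based inclusive; a tract is reported at the smallest unit
    length with a primitive motif, leftmost full-unit alignment.
    """
    s = sequence.upper()
    n = len(s)
    valid = [c in "ACGT" for c in s]
    out = set()
    for k, minrep in min_repeats.items():
        a = 0
        while a + 2 * k <= n:
            if not valid[a]:
                a += 1
                continue
            # grow the period-k run starting at a
            j = a + 1
            while j < n and valid[j] and (j < a + k or s[j] == s[j - k]):
                j += 1
            run_len = j - a
            m = run_len // k
            motif = s[a : a + k]
            if m >= minrep and is_primitive(motif):
                out.add((motif, m, a + 1, a + m * k))
            # next candidate run can only start after the first periodicity break
            a = max(a + 1, j - k + 1) if run_len >= k else j
    return out


def naive_upgma(labels: list[str], d0: np.ndarray):
    """O(n^3)-per-merge UPGMA returning (clade set, cophenetic dict).

    Cluster distances are means over all original leaf pairs; ties broken by
    the lexicographically smallest pair of smallest member labels.
    """
    idx = {l: i for i, l in enumerate(labels)}
    clusters: list[frozenset] = [frozenset([l]) for l in labels]
    heights: dict[frozenset, float] = {}
    clades: set[frozenset] = set()
    coph: dict[tuple, float] = {}

    def dist(c1: frozenset, c2: frozenset) -> float:
        return float(
            np.mean([d0[idx[a], idx[b]] for a in c1 for b in c2])
        )

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(clusters[i], clusters[j])
                key = tuple(sorted((min(clusters[i]), min(clusters[j]))))
                cand = (d, key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        d, _, i, j = best
        merged = clusters[i] | clusters[j]
        for a in clusters[i]:
            for b in clusters[j]:
                coph[(a, b)] = coph[(b, a)] = d
        heights[merged] = d / 2.0
        clades.add(merged)
        clusters = [c for t, c in enumerate(clusters) if t not in (i, j)] + [merged]
    return clades, heights, coph


def brute_force_n50(lengths: list[int], frac: float) -> int:
    total = sum(lengths)
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if acc >= frac * total:
            return l
    raise AssertionError("unreachable")
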