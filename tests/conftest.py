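"""Shared fixtures and independent brute-force oracles.

The oracles re-derive subset-intersection statistics and pairwise
compatibility with plain ``set``/``frozenset`` operations, independently of
the package's bitmask enumeration, so the two paths can be compared.
"""

from __future__ import annotations

from itertools import combinations

import pytest

from truncal import AlterationMatrix

# Worked 4-sample fixture used throughout: two left samples (lineage L1),
# two right samples (lineage R1), truncal {T1, T2}, one sample-private P1.
WORKED_SAMPLE_SETS = {
    "s1": {"T1", "T2", "L1", "P1"},
    "s2": {"T1", "T2", "L1"},
    "s3": {"T1", "T2", "R1"},
    "s4": {"T1", "T2", "R1"},
}


@pytest.fixture
def worked_matrix() -> AlterationMatrix:
    return AlterationMatrix.from_sample_sets(WORKED_SAMPLE_SETS)


def brute_force_profile(matrix: AlterationMatrix):
    """Set-based re-derivation of the concordance and clonal-count
    profiles: enumerate every subset with frozensets, no bitmasks."""
    sets = {s: matrix.sample_set(s) for s in matrix.sample_ids}
    samples = matrix.sample_ids
    n = len(samples)
    global_inter = frozenset.intersection(*map(frozenset, sets.values()))
    fractions, match_counts, size_lists = [], [], []
    for i in range(1, n + 1):
        matches = 0
        sizes = []
        for combo in combinations(samples, i):
            inter = frozenset.intersection(*(frozenset(sets[s]) for s in combo))
            if inter == global_inter:
                matches += 1
            sizes.append(len(inter))
        total = len(sizes)
        fractions.append(matches / total)
        match_counts.append(matches)
        size_lists.append(sizes)
    return fractions, match_counts, size_lists, global_inter


def brute_force_conflicts(matrix: AlterationMatrix) -> set[tuple[str, str]]:
    """Three-gamete test by direct pattern enumeration."""
    pairs = set()
    for a, b in combinations(matrix.alteration_ids, 2):
        row_a = matrix.data.loc[a]
        row_b = matrix.data.loc[b]
        patterns = {(int(x), int(y)) for x, y in zip(row_a, row_b)}
        if {(1, 1), (1, 0), (0, 1)} <= patterns:
            pairs.add((a, b))
    return pairs
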