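"""Subset-intersection concordance: the empirical counterpart of the
sampling curve.

Given ``n`` multi-region samples, the best available estimate of the truly
clonal alteration set is the *minimal clonal list* — the intersection of
the alteration sets of all ``n`` samples.  For every subset size
``i = 1..n`` we enumerate the ``C(n, i)`` sample subsets and record which
of them already recover that minimal list.  The per-size fraction of
recovering subsets is the concordance profile; rescaled theory
(:func:`truncal.core_model.normalized_curve`) is fitted to it to infer the
balancing factor ``f``.

Enumeration is exact whenever the total subset count fits a configurable
cap (the motivating cohorts have n <= 13, i.e. at most 8192 subsets);
beyond the cap, sizes whose ``C(n, i)`` exceeds a per-size budget are
estimated by seeded uniform subset sampling, and the profile records which
sizes were sampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import reduce
from itertools import combinations
from math import comb
from operator import and_

import numpy as np
import pandas as pd

from .matrix_io import AlterationMatrix

__all__ = [
    "ConcordanceProfile",
    "ClonalCountProfile",
    "intersection_set",
    "concordance_profile",
    "clonal_count_profile",
    "profile_table",
]

DEFAULT_SUBSET_CAP = 1_000_000


def intersection_set(matrix: AlterationMatrix, subset: set[str]) -> set[str]:
    """Alterations present in every sample of ``subset``.

    Raises on an empty subset or unknown sample ids.
    """
    subset = set(subset)
    if not subset:
        raise ValueError("subset must contain at least one sample")
    unknown = subset - set(matrix.sample_ids)
    if unknown:
        raise KeyError(f"unknown sample id(s): {sorted(unknown)}")
    sub = matrix.data[sorted(subset)]
    mask = sub.all(axis=1)
    return set(sub.index[mask])


def sample_bitmasks(matrix: AlterationMatrix) -> list[int]:
    """Each sample's alteration set packed into an arbitrary-precision int
    (bit r set iff alteration row r is present).  Subset intersection is
    then a chain of ``&`` and recovery a single equality test."""
    a = matrix.values()
    masks = []
    for j in range(matrix.n_samples):
        m = 0
        for r in np.flatnonzero(a[:, j]):
            m |= 1 << int(r)
        masks.append(m)
    return masks


@dataclass
class ConcordanceProfile:
    """Per subset-size recovery statistics of the minimal clonal list.

    ``fractions[i-1]`` is the (estimated) probability that a uniformly
    chosen ``i``-subset of samples recovers the full-cohort intersection.
    ``subset_counts`` holds C(n, i); ``enumerated`` the number of subsets
    actually evaluated per size (== subset_counts when exact).
    """

    n: int
    sizes: list[int]
    subset_counts: list[int]
    matching_counts: list[int]
    enumerated: list[int]
    fractions: list[float]
    exact: list[bool]
    global_intersection: frozenset[str]
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "i": self.sizes,
                "subsets": self.subset_counts,
                "enumerated": self.enumerated,
                "matches": self.matching_counts,
                "fraction": self.fractions,
            }
        )


@dataclass
class ClonalCountProfile:
    """Distribution of putative clonal-list sizes per subset size.

    ``counts[i]`` is the list of ``|intersection(S)|`` over the evaluated
    ``i``-subsets ``S``; min/mean/max summarise it.  The mean shrinks as
    subsets grow: alterations that look clonal in few samples are exposed
    as sub-clonal by more.
    """

    n: int
    sizes: list[int]
    min_: list[int]
    mean: list[float]
    max_: list[int]
    counts: dict[int, list[int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "i": self.sizes,
                "clonal_min": self.min_,
                "clonal_mean": self.mean,
                "clonal_max": self.max_,
            }
        )


def _enumerate(masks: list[int], cap: int, seed: int | None) -> list[dict]:
    """Shared enumeration engine over sample bitmasks.

    Returns one record per subset size with match counts, evaluated subset
    count and the list of intersection sizes.
    """
    n = len(masks)
    global_mask = reduce(and_, masks)
    total = 2**n - 1
    per_size_budget = max(1, cap // n)
    rng = np.random.default_rng(seed)
    records = []
    for i in range(1, n + 1):
        c = comb(n, i)
        exact = total <= cap or c <= per_size_budget
        sizes_list: list[int] = []
        matches = 0
        if exact:
            iterator = combinations(range(n), i)
            enumerated = c
        else:
            enumerated = per_size_budget
            iterator = (
                tuple(rng.choice(n, size=i, replace=False)) for _ in range(enumerated)
            )
        for idx in iterator:
            inter = reduce(and_, (masks[j] for j in idx))
            if inter == global_mask:
                matches += 1
            sizes_list.append(inter.bit_count())
        records.append(
            {
                "i": i,
                "subsets": c,
                "enumerated": enumerated,
                "matches": matches,
                "fraction": matches / enumerated,
                "sizes": sizes_list,
                "exact": exact,
            }
        )
    return records


def _profile_records(
    matrix: AlterationMatrix, cap: int, seed: int | None
) -> tuple[list[dict], frozenset[str]]:
    if matrix.n_samples < 2:
        raise ValueError("profile undefined for a single sample")
    masks = sample_bitmasks(matrix)
    records = _enumerate(masks, cap, seed)
    global_ids = frozenset(intersection_set(matrix, set(matrix.sample_ids)))
    if not global_ids:
        warnings.warn(
            "global intersection is empty: no alteration is shared by all samples",
            stacklevel=3,
        )
    return records, global_ids


def concordance_profile(
    matrix: AlterationMatrix,
    cap: int = DEFAULT_SUBSET_CAP,
    seed: int | None = None,
) -> ConcordanceProfile:
    """Fraction of ``i``-subsets whose intersection equals the minimal
    clonal list, for every ``i = 1..n``.

    "Recovers" means set equality with the full-cohort intersection, the
    strict reading of concordance.  With exact enumeration the fractions
    are provably non-decreasing in ``i`` (a superset of a recovering subset
    recovers too) and reach exactly 1 at ``i = n``.
    """
    records, global_ids = _profile_records(matrix, cap, seed)
    return ConcordanceProfile(
        n=matrix.n_samples,
        sizes=[r["i"] for r in records],
        subset_counts=[r["subsets"] for r in records],
        matching_counts=[r["matches"] for r in records],
        enumerated=[r["enumerated"] for r in records],
        fractions=[r["fraction"] for r in records],
        exact=[r["exact"] for r in records],
        global_intersection=global_ids,
        seed=seed,
    )


def clonal_count_profile(
    matrix: AlterationMatrix,
    cap: int = DEFAULT_SUBSET_CAP,
    seed: int | None = None,
) -> ClonalCountProfile:
    """Per subset-size distribution of putative clonal-list sizes."""
    records, _ = _profile_records(matrix, cap, seed)
    return ClonalCountProfile(
        n=matrix.n_samples,
        sizes=[r["i"] for r in records],
        min_=[min(r["sizes"]) for r in records],
        mean=[float(np.mean(r["sizes"])) for r in records],
        max_=[max(r["sizes"]) for r in records],
        counts={r["i"]: r["sizes"] for r in records},
    )


def profile_table(
    matrix: AlterationMatrix,
    cap: int = DEFAULT_SUBSET_CAP,
    seed: int | None = None,
) -> pd.DataFrame:
    """Combined concordance + clonal-count table (one enumeration pass
    worth of information, serialisable to TSV)."""
    records, _ = _profile_records(matrix, cap, seed)
    return pd.DataFrame(
        {
            "i": [r["i"] for r in records],
            "subsets": [r["subsets"] for r in records],
            "matches": [r["matches"] for r in records],
            "fraction": [r["fraction"] for r in records],
            "clonal_min": [min(r["sizes"]) for r in records],
            "clonal_mean": [float(np.mean(r["sizes"])) for r in records],
            "clonal_max": [max(r["sizes"]) for r in records],
        }
    )
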