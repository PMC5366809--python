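"""Balancing-factor inference: least-squares fit of the rescaled sampling
curve to an empirical concordance profile, plus subset-robustness scans.

The rescaled curve p_f(i)/p_f(n) has a single free parameter, the
balancing factor f of the tumour's first bifurcation.  Because the
objective can be flat or multi-modal near the unbalanced boundary, the fit
is a deterministic dense grid search over f in [f_min, 0.5] followed by a
bounded scalar refinement inside the winning grid cell — no stochastic
optimiser, identical results on every run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import core_model
from .concordance import ConcordanceProfile, _enumerate, sample_bitmasks
from .matrix_io import AlterationMatrix

__all__ = [
    "BalancingFit",
    "RobustnessResult",
    "fit_balancing",
    "overestimation_probability",
    "robustness_scan",
]

F_MAX = 0.5


@dataclass
class BalancingFit:
    """Inferred balancing factor with fit diagnostics.

    ``f_hat`` is reported on the canonical range (0, 0.5];
    ``boundary_flag`` marks estimates pinned at the search boundary
    (highly unbalanced tumours surface as f_hat ~ f_min), where the point
    estimate should be read as a bound rather than a value.
    """

    f_hat: float
    sse: float
    n: int
    fitted_points: list[tuple[int, float, float]]
    boundary_flag: bool
    method: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "f_hat": self.f_hat,
            "sse": self.sse,
            "n": self.n,
            "boundary_flag": self.boundary_flag,
            "fitted_points": [
                {"i": i, "empirical": e, "fitted": t} for i, e, t in self.fitted_points
            ],
            "method": self.method,
        }


def _sse_on_grid(fractions: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Vectorised sum of squared residuals against the rescaled curve."""
    n = fractions.size
    i = np.arange(1, n + 1)
    g = grid[:, None]
    p = 1.0 - g**i - (1.0 - g) ** i
    norm = p / p[:, -1][:, None]
    return ((norm - fractions) ** 2).sum(axis=1)


def fit_balancing(
    profile: ConcordanceProfile,
    grid_step: float = 1e-3,
    f_min: float = 1e-4,
) -> BalancingFit:
    """Least-squares fit of f to a concordance profile.

    Minimises ``sum_i (fraction_i - p_f(i)/p_f(n))^2`` over
    ``f in [f_min, 0.5]``.  All indices ``i = 1..n`` enter the fit: at
    ``i = n`` both sides are identically 1 (zero residual), and at
    ``i = 1`` the theoretical value is 0 while the data may be positive —
    that residual is informative and retained.

    Exact ties on the grid resolve toward larger f (the more balanced, more
    optimistic reading); refinement is accepted only when it strictly
    improves the grid optimum, so exact grid solutions are returned
    bit-identically.
    """
    if profile.n < 2:
        raise ValueError("cannot fit a profile from a single sample")
    fractions = np.asarray(profile.fractions, dtype=float)
    if np.all(fractions >= 1.0):
        warnings.warn(
            "all subsets already recover the minimal clonal list: degenerate "
            "identical-samples profile, f_hat pinned to 0.5 with large residual",
            stacklevel=2,
        )
        fitted = [
            (i, 1.0, core_model.normalized_curve(F_MAX, i, profile.n))
            for i in range(1, profile.n + 1)
        ]
        sse = float(sum((e - t) ** 2 for _, e, t in fitted))
        return BalancingFit(
            f_hat=F_MAX,
            sse=sse,
            n=profile.n,
            fitted_points=fitted,
            boundary_flag=True,
            method={"degenerate": "identical-samples"},
        )
    grid = np.unique(np.append(np.arange(f_min, F_MAX, grid_step), F_MAX))
    sse = _sse_on_grid(fractions, grid)
    # last index attaining the minimum -> ties toward larger f
    j = len(sse) - 1 - int(np.argmin(sse[::-1]))
    f_best, sse_best = float(grid[j]), float(sse[j])
    lo = float(grid[max(0, j - 1)])
    hi = float(grid[min(len(grid) - 1, j + 1)])
    if hi > lo:
        res = minimize_scalar(
            lambda f: float(_sse_on_grid(fractions, np.array([f]))[0]),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-7},
        )
        if res.fun < sse_best:
            f_best, sse_best = float(res.x), float(res.fun)
    boundary = (f_best - f_min) < 1e-6 or (F_MAX - f_best) < 1e-6
    fitted = [
        (i, float(fractions[i - 1]), core_model.normalized_curve(f_best, i, profile.n))
        for i in range(1, profile.n + 1)
    ]
    return BalancingFit(
        f_hat=f_best,
        sse=sse_best,
        n=profile.n,
        fitted_points=fitted,
        boundary_flag=boundary,
        method={"grid_step": grid_step, "f_min": f_min, "refinement": "bounded-scalar"},
    )


def overestimation_probability(f: float, i: int) -> float:
    """Probability that ``i`` samples misclassify some sub-clonal
    alterations as clonal: the samples all fall on one side of the first
    bifurcation, i.e. the remaining uncertainty ``1 - p_f(i)``."""
    return core_model.uncertainty(core_model.canonical_f(f), i)


@dataclass
class RobustnessResult:
    """Distributions of f_hat over sample subsets, per subset size.

    ``estimates[k]`` holds one f_hat per evaluated k-subset of samples,
    each obtained by re-running the full profile + fit pipeline on that
    subset alone — the tabular equivalent of per-size violin plots.
    """

    n: int
    min_size: int
    estimates: dict[int, list[float]]
    exact: dict[int, bool]
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subset_size": k, "f_hat": f}
            for k, fs in sorted(self.estimates.items())
            for f in fs
        ]
        return pd.DataFrame(rows, columns=["subset_size", "f_hat"])

    def summary(self) -> pd.DataFrame:
        rows = []
        for k, fs in sorted(self.estimates.items()):
            q = np.quantile(fs, [0.025, 0.25, 0.5, 0.75, 0.975])
            rows.append(
                {
                    "subset_size": k,
                    "n_fits": len(fs),
                    "q2.5": q[0],
                    "q25": q[1],
                    "median": q[2],
                    "q75": q[3],
                    "q97.5": q[4],
                }
            )
        return pd.DataFrame(rows)


def robustness_scan(
    matrix: AlterationMatrix,
    min_size: int = 4,
    cap: int = 5000,
    seed: int | None = None,
    grid_step: float = 1e-3,
) -> RobustnessResult:
    """Re-infer f on every sample subset of size min_size..n-1.

    Exact enumeration of the ``C(n, k)`` subsets per size while that count
    is at most ``cap``; larger sizes are estimated from ``cap`` seeded
    uniform draws.  Subsetting works directly on sample bitmasks:
    alterations absent from a subset simply never enter an intersection, so
    no matrix rebuild is needed.
    """
    n = matrix.n_samples
    if n <= min_size:
        raise ValueError(
            f"robustness scan needs more than min_size={min_size} samples, got {n}"
        )
    masks = sample_bitmasks(matrix)
    rng = np.random.default_rng(seed)
    estimates: dict[int, list[float]] = {}
    exact: dict[int, bool] = {}
    for k in range(min_size, n):
        c = comb(n, k)
        if c <= cap:
            subsets = combinations(range(n), k)
            exact[k] = True
        else:
            subsets = (
                tuple(rng.choice(n, size=k, replace=False)) for _ in range(cap)
            )
            exact[k] = False
        fits = []
        for idx in subsets:
            sub_masks = [masks[j] for j in idx]
            records = _enumerate(sub_masks, cap=1_000_000, seed=None)
            prof = ConcordanceProfile(
                n=k,
                sizes=[r["i"] for r in records],
                subset_counts=[r["subsets"] for r in records],
                matching_counts=[r["matches"] for r in records],
                enumerated=[r["enumerated"] for r in records],
                fractions=[r["fraction"] for r in records],
                exact=[r["exact"] for r in records],
                global_intersection=frozenset(),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits.append(fit_balancing(prof, grid_step=grid_step).f_hat)
        estimates[k] = fits
    return RobustnessResult(
        n=n, min_size=min_size, estimates=estimates, exact=exact, seed=seed
    )
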