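"""Closed-form sampling theory for the first bifurcation of a tumour phylogeny.

The earliest bifurcation of a tumour's cell phylogeny divides the neoplasm
into two lineages holding fractions ``f`` and ``1 - f`` of all cells (the
*balancing factor* ``f``).  Alterations above that split are truly clonal;
alterations below it are sub-clonal.  A set of ``i`` independent, spatially
separated samples identifies the true clonal set only if it contains at
least one sample from each side, which happens with probability

.. math::

    p_f(i) = 1 - f^i - (1 - f)^i .

Everything in this module is derived from that single curve:

* :func:`prob_both_sides` -- the curve itself,
* :func:`uncertainty` -- the residual risk ``sigma = 1 - p_f(n)`` of having
  missed one entire side with ``n`` samples,
* :func:`information_gain` -- the increment ``p_f(n+1) - p_f(n)`` from one
  extra sample,
* :func:`required_samples` -- the sampling-design planner: the smallest
  ``n`` with ``uncertainty(f, n) <= sigma_target``,
* :func:`normalized_curve` -- the curve rescaled to reach 1 at the full
  cohort size ``n``, which is what an empirical concordance profile is
  fitted against.

All functions are symmetric under ``f <-> 1 - f``; :func:`canonical_f`
maps ``f`` onto the reporting range ``[0, 0.5]``.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "canonical_f",
    "prob_both_sides",
    "uncertainty",
    "information_gain",
    "normalized_curve",
    "required_samples",
    "SamplingPlan",
]

# hard stop for the incremental planner search; reached only for f ~ 1e-9
_MAX_PLAN_SAMPLES = 10_000_000


def _check_f(f: float) -> float:
    f = float(f)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"balancing factor f must lie in [0, 1], got {f}")
    return f


def _check_i(i: int, name: str = "i") -> int:
    if i != int(i) or i < 1:
        raise ValueError(f"sample count {name} must be a positive integer, got {i}")
    return int(i)


def canonical_f(f: float) -> float:
    """Map a balancing factor onto the canonical reporting range [0, 0.5].

    The two sides of the first bifurcation are interchangeable, so ``f``
    and ``1 - f`` describe the same tree; the smaller fraction is reported.
    """
    f = _check_f(f)
    return min(f, 1.0 - f)


def prob_both_sides(f: float, i: int) -> float:
    """Probability that ``i`` independent samples cover both sides of the
    first bifurcation.

    Parameters
    ----------
    f
        Balancing factor: fraction of tumour cells descending from one side
        of the earliest bifurcation, in ``[0, 1]``.
    i
        Number of independent samples (positive integer).

    Returns
    -------
    float
        ``1 - f**i - (1 - f)**i``, clamped to ``[0, 1]``.

    Notes
    -----
    A single sample is always one-sided: ``prob_both_sides(f, 1) == 0`` for
    every ``f``.  For a balanced tree (``f = 0.5``) the closed form reduces
    to ``1 - 2**(1 - i)``.
    """
    f = _check_f(f)
    i = _check_i(i)
    p = 1.0 - f**i - (1.0 - f) ** i
    return min(1.0, max(0.0, p))


def uncertainty(f: float, n: int) -> float:
    """Remaining uncertainty ``sigma = f**n + (1-f)**n = 1 - p_f(n)``.

    This is the probability that ``n`` samples all come from the same side
    of the first bifurcation, so that some sub-clonal alterations are
    misclassified as clonal.
    """
    f = _check_f(f)
    n = _check_i(n, "n")
    s = f**n + (1.0 - f) ** n
    return min(1.0, max(0.0, s))


def information_gain(f: float, n: int) -> float:
    """Expected gain ``p_f(n + 1) - p_f(n)`` from one additional sample.

    Evaluated in the algebraically simplified form
    ``f**n * (1 - f) + (1 - f)**n * f``, which is non-negative by
    construction and avoids cancellation for large ``n``.  For a balanced
    tree it equals ``2**(-n)``: the return on extra sampling decays
    exponentially.
    """
    f = _check_f(f)
    n = _check_i(n, "n")
    g = f**n * (1.0 - f) + (1.0 - f) ** n * f
    return min(1.0, max(0.0, g))


def normalized_curve(f: float, i: int, n: int) -> float:
    """The sampling curve rescaled by its value at the full cohort size.

    Returns ``prob_both_sides(f, i) / prob_both_sides(f, n)``.  This is the
    theoretical counterpart of the empirical concordance profile, which by
    construction reaches 1 when all ``n`` available samples are combined:
    the rescaled curve is 0 at ``i = 1`` and 1 at ``i = n``, monotone
    non-decreasing in between.

    Raises
    ------
    ValueError
        If ``f`` is 0 or 1 (the denominator vanishes: one side of the tree
        is never sampled and the curve is undefined) or ``n == 1``.
    """
    f = _check_f(f)
    i = _check_i(i)
    n = _check_i(n, "n")
    if f in (0.0, 1.0):
        raise ValueError("degenerate balancing: curve undefined for f in {0, 1}")
    if n == 1:
        raise ValueError("normalized curve undefined for a single sample (n = 1)")
    if i > n:
        raise ValueError(f"subset size i={i} exceeds cohort size n={n}")
    return prob_both_sides(f, i) / prob_both_sides(f, n)


@dataclass(frozen=True)
class SamplingPlan:
    """Result of the sampling-design planner.

    Attributes
    ----------
    f : float
        Canonical balancing factor the plan was computed for.
    sigma_target : float
        Requested remaining uncertainty.
    n_required : int
        Smallest number of independent samples with
        ``uncertainty(f, n) <= sigma_target``.
    achieved_sigma : float
        Uncertainty actually reached at ``n_required``.
    """

    f: float
    sigma_target: float
    n_required: int
    achieved_sigma: float


def required_samples(f: float, sigma_target: float) -> SamplingPlan:
    """Smallest sample count whose remaining uncertainty meets a target.

    Incremental search for the minimal ``n >= 1`` with
    ``uncertainty(f, n) <= sigma_target``.  For the balanced case this
    agrees with the closed form ``n = ceil(1 + log2(1 / sigma))``.

    Parameters
    ----------
    f
        Balancing factor; canonicalized to ``min(f, 1 - f)``.
    sigma_target
        Target remaining uncertainty in ``(0, 1)``.  A target ``>= 1`` is
        met trivially by a single sample.

    Raises
    ------
    ValueError
        If ``f`` is 0 (one side is never sampled, so no finite number of
        samples reaches any confidence) or ``sigma_target <= 0``.
    """
    f = canonical_f(f)
    sigma_target = float(sigma_target)
    if sigma_target <= 0.0:
        raise ValueError("sigma_target must be positive")
    if sigma_target >= 1.0:
        return SamplingPlan(f, sigma_target, 1, uncertainty(f, 1))
    if f == 0.0:
        raise ValueError("unreachable confidence: one side is never sampled")
    n = 1
    while uncertainty(f, n) > sigma_target:
        n += 1
        if n > _MAX_PLAN_SAMPLES:  # pragma: no cover - pathological f
            raise ValueError("required sample count exceeds search limit")
    return SamplingPlan(f, sigma_target, n, uncertainty(f, n))
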