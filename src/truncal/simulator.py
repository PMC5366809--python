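"""Synthetic multi-region tumours with known ground truth.

Emulates the structure of multi-region mutation / copy-number cohorts: a
truncal alteration set carried by every sample, a first bifurcation
splitting the samples into two lineages of fractions ``f`` and ``1 - f``
(each with lineage-private alterations), optional deeper recursive splits,
sample-private alterations, and false-negative dropout that injects
homoplasy.  Because the generating tree and the true ``f`` are known,
every downstream stage — conflict filtering, concordance enumeration,
balancing inference, sampling planning — can be validated without any
external cohort.

Two sample-assignment modes are provided because theory and data analysis
make different assumptions: ``bernoulli`` assigns each sample to the left
lineage independently with probability ``f`` (the independent-sampling
assumption behind the closed-form curve), while ``proportional`` fixes the
realized split at ``round(n * f)`` (the fixed cohort a data analysis
actually sees).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .concordance import concordance_profile
from .inference import fit_balancing
from .matrix_io import AlterationMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTumour",
    "simulate_tumour",
    "tumour_to_matrix",
    "recovery_experiment",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic tumour.

    Alteration counts are Poisson means by default (mutation accumulation
    is a counting process); set ``poisson=False`` for exact fixed counts.
    Defaults mirror a typical multi-region exome cohort: 8 samples,
    ~40 alterations visible per sample.

    ``recursion_depth`` 1 reproduces the two-lineage analytic model;
    deeper values recursively split each lineage's samples again (per-node
    balance equal to the root ``true_f``), giving realistic nested trees.
    """

    true_f: float = 0.5
    n_samples: int = 8
    assignment_mode: Literal["proportional", "bernoulli"] = "proportional"
    truncal: float = 20
    lineage: float = 15
    private: float = 5
    poisson: bool = True
    recursion_depth: int = 1
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.true_f <= 0.5:
            raise ValueError("true_f must lie in (0, 0.5]")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.assignment_mode not in ("proportional", "bernoulli"):
            raise ValueError(f"unknown assignment_mode {self.assignment_mode!r}")
        if min(self.truncal, self.lineage, self.private) < 0:
            raise ValueError("alteration counts must be non-negative")
        if self.recursion_depth < 1:
            raise ValueError("recursion_depth must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class SyntheticTumour:
    """A simulated tumour with full ground truth.

    ``clades`` lists every internal-node alteration set as
    ``(samples, alteration ids)`` pairs, including the two root lineages;
    ``left_alterations`` / ``right_alterations`` are the root-level pair.
    The conceptual tree has arbitrarily many cell-level leaves; only the
    sampled regions are materialised.
    """

    true_f: float
    n_samples: int
    sample_ids: list[str]
    assignment: dict[str, str]
    truncal_alterations: frozenset[str]
    left_alterations: frozenset[str]
    right_alterations: frozenset[str]
    per_sample_private: dict[str, frozenset[str]]
    clades: list[tuple[frozenset[str], frozenset[str]]]
    dropout_rate: float
    seed: int
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def sample_alteration_sets(self) -> dict[str, set[str]]:
        """Pre-dropout alteration set of each sample."""
        sets = {s: set(self.truncal_alterations) for s in self.sample_ids}
        for samples, ids in self.clades:
            for s in samples:
                sets[s].update(ids)
        for s, ids in self.per_sample_private.items():
            sets[s].update(ids)
        return sets

    def truth_dict(self) -> dict:
        return {
            "true_f": self.true_f,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "assignment": self.assignment,
            "truncal_alterations": sorted(self.truncal_alterations),
            "left_alterations": sorted(self.left_alterations),
            "right_alterations": sorted(self.right_alterations),
            "dropout_rate": self.dropout_rate,
        }


def _draw_count(rng: np.random.Generator, value: float, poisson: bool) -> int:
    return int(rng.poisson(value)) if poisson else int(round(value))


def simulate_tumour(config: SimulationConfig) -> SyntheticTumour:
    """Generate one tumour under ``config``; fully reproducible from its seed.

    Proportional mode places ``round(n * f)`` samples on the left side and
    raises if that rounds to an empty side; bernoulli mode assigns each
    sample independently (one-sided cohorts are then possible, and are
    exactly the events the closed-form curve accounts for).
    """
    rng = np.random.default_rng(config.seed)
    width = max(2, len(str(config.n_samples)))
    samples = [f"s{j + 1:0{width}d}" for j in range(config.n_samples)]

    if config.assignment_mode == "proportional":
        n_left = int(round(config.n_samples * config.true_f))
        if n_left in (0, config.n_samples):
            raise ValueError(
                f"requested f={config.true_f} unrepresentable with "
                f"{config.n_samples} samples (round(n*f)={n_left})"
            )
        left = set(rng.choice(samples, size=n_left, replace=False).tolist())
    else:
        left = {s for s in samples if rng.random() < config.true_f}
    assignment = {s: ("left" if s in left else "right") for s in samples}

    counter = iter(range(1, 10**9))

    def new_ids(prefix: str, count: int) -> frozenset[str]:
        return frozenset(f"{prefix}{next(counter):04d}" for _ in range(count))

    truncal = new_ids("T", _draw_count(rng, config.truncal, config.poisson))
    clades: list[tuple[frozenset[str], frozenset[str]]] = []

    def split(members: list[str], prefix: str, depth: int) -> None:
        ids = new_ids(prefix, _draw_count(rng, config.lineage, config.poisson))
        clades.append((frozenset(members), ids))
        if depth < config.recursion_depth and len(members) >= 2:
            k = int(round(len(members) * config.true_f))
            k = min(max(k, 1), len(members) - 1)
            sub_left = rng.choice(members, size=k, replace=False).tolist()
            sub_right = [s for s in members if s not in set(sub_left)]
            split(sub_left, prefix + "L", depth + 1)
            split(sub_right, prefix + "R", depth + 1)

    left_members = sorted(left)
    right_members = [s for s in samples if s not in left]
    # one-sided bernoulli cohorts get a single lineage node
    if left_members:
        split(left_members, "L", 1)
    if right_members:
        split(right_members, "R", 1)
    left_ids = next((ids for m, ids in clades if m == frozenset(left_members)), frozenset())
    right_ids = next(
        (ids for m, ids in clades if m == frozenset(right_members)), frozenset()
    )

    private = {
        s: new_ids(f"P_{s}_", _draw_count(rng, config.private, config.poisson))
        for s in samples
    }
    return SyntheticTumour(
        true_f=config.true_f,
        n_samples=config.n_samples,
        sample_ids=samples,
        assignment=assignment,
        truncal_alterations=truncal,
        left_alterations=left_ids,
        right_alterations=right_ids,
        per_sample_private=private,
        clades=clades,
        dropout_rate=config.dropout_rate,
        seed=config.seed,
        config=config,
    )


def tumour_to_matrix(tumour: SyntheticTumour) -> AlterationMatrix:
    """Emit the observed presence/absence matrix.

    Each true presence is independently flipped to absence with probability
    ``dropout_rate`` (false negatives only — the noise mode multi-region
    sequencing actually suffers from).  Alterations dropped from every
    sample disappear from the matrix with the standard warning.  The
    dropout stream is seeded from the tumour's seed, decoupled from the
    structural draws, so matrix emission is deterministic per tumour.
    """
    sets = tumour.sample_alteration_sets()
    order = sorted(set().union(*sets.values()))
    data = pd.DataFrame(
        [[1 if a in sets[s] else 0 for s in tumour.sample_ids] for a in order],
        index=pd.Index(order, name="alteration_id"),
        columns=tumour.sample_ids,
        dtype=np.int8,
    )
    if tumour.dropout_rate > 0.0:
        rng = np.random.default_rng([tumour.seed, 0xD0])
        keep = rng.random(data.shape) >= tumour.dropout_rate
        data = data.where(keep, 0).astype(np.int8)
    return AlterationMatrix(data)


def recovery_experiment(
    f_grid: list[float],
    reps: int,
    base_config: SimulationConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Parameter-recovery study: simulate, profile, fit, score.

    For every ``f_true`` in ``f_grid`` and every replicate: simulate a
    tumour, emit its matrix, build the concordance profile, fit f, and
    record (a) the estimate, (b) whether the cohort covered both root
    lineages, (c) the fraction of 2-subsets recovering the minimal clonal
    list — the quantity that is exactly 1/2 in expectation for a balanced
    tumour under independent sampling.

    Returns one row per ``f_true`` with columns ``f_true``, ``reps``,
    ``mean_f_hat``, ``mean_abs_error``, ``both_sides_rate``,
    ``two_subset_match_rate``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if base_config is None:
        base_config = SimulationConfig()
    master = np.random.default_rng(seed)
    rows = []
    for f_true in f_grid:
        f_hats, abs_errs, both, pair_rates = [], [], [], []
        for _ in range(reps):
            cfg = replace(
                base_config, true_f=f_true, seed=int(master.integers(2**31))
            )
            tumour = simulate_tumour(cfg)
            matrix = tumour_to_matrix(tumour)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                profile = concordance_profile(matrix)
                fit = fit_balancing(profile)
            f_hats.append(fit.f_hat)
            abs_errs.append(abs(fit.f_hat - f_true))
            both.append(len(set(tumour.assignment.values())) == 2)
            pair_rates.append(profile.fractions[1] if matrix.n_samples >= 2 else np.nan)
        rows.append(
            {
                "f_true": f_true,
                "reps": reps,
                "mean_f_hat": float(np.mean(f_hats)),
                "mean_abs_error": float(np.mean(abs_errs)),
                "both_sides_rate": float(np.mean(both)),
                "two_subset_match_rate": float(np.mean(pair_rates)),
            }
        )
    return pd.DataFrame(rows)
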