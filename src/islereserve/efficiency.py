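"""Protected-area efficiency ratios and null-model significance.

Two efficiency measures compare the existing reserve network with a
quasi-optimal solution:

* minimum set — ratio of the optimal cost (protected cells) to the current
  PA cost; 1 means the current PAs are as lean as the best solution found;
* maximum coverage — ratio of the percentage of species targets reached by
  the current PAs to the percentage reached by the optimal solution under
  the same budget; 0 if the PAs reach no target.

Significance is assessed against a null model of simple random resampling:
the same number of protected cells drawn uniformly without replacement from
the island, with each species' protected proportion recorded per replicate.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .raster import StudyArea

__all__ = [
    "NullDistribution",
    "NullComparison",
    "min_set_efficiency",
    "max_coverage_efficiency",
    "pct_targets_reached",
    "null_model_distribution",
    "compare_to_null",
]


def min_set_efficiency(optimal_cost: int, current_cost: int) -> float:
    """optimal_cost / current_cost; 1 when the current PAs match the optimum."""
    if current_cost <= 0:
        raise ValueError("current PA cost must be positive")
    if optimal_cost <= 0:
        raise ValueError("optimal cost must be positive")
    return optimal_cost / current_cost


def max_coverage_efficiency(current_pct_targets: float, optimal_pct_targets: float) -> float:
    """current / optimal percentage of targets reached; 0 if none reached."""
    if optimal_pct_targets <= 0:
        raise ValueError("optimal solution reaches no target; ratio undefined")
    return current_pct_targets / optimal_pct_targets


def pct_targets_reached(rep: dict, targets: dict) -> float:
    """Percentage of species whose representation meets their target.

    A target counts as reached only when representation >= target; no
    partial credit.
    """
    sids = list(targets)
    if not sids:
        raise ValueError("no species targets")
    reached = sum(1 for s in sids if rep[s] >= targets[s] - 1e-9)
    return 100.0 * reached / len(sids)


@dataclasses.dataclass
class NullDistribution:
    """Per-species protected proportions under uniformly random protection.

    ``proportions`` has shape (n_reps, n_species); every replicate protects
    exactly ``n_protected`` island cells.
    """

    species_ids: list
    proportions: np.ndarray
    n_protected: int
    n_reps: int
    seed: int


def null_model_distribution(
    n_protected: int,
    species_layers: dict,
    area: StudyArea,
    n_reps: int = 999,
    seed: int = 0,
) -> NullDistribution:
    """Simple random resampling with no further restrictions.

    Each replicate draws ``n_protected`` cells uniformly without replacement
    from the study area; each species' protected proportion (hypergeometric
    under the null, mean n_protected / n_island) is recorded.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    n_island = area.n_cells
    if not 0 < n_protected <= n_island:
        raise ValueError("n_protected must lie in (0, n_island]")
    island_flat = np.flatnonzero(area.cells.ravel())
    sids = list(species_layers)
    S = np.asarray(
        [species_layers[s].presence.ravel()[island_flat] for s in sids], dtype=float
    )
    sizes = S.sum(axis=1)
    if np.any(sizes == 0):
        raise ValueError("species with empty ranges cannot enter the null model")
    rng = np.random.default_rng(seed)
    # rank a uniform matrix: the n_protected smallest per row form the draw
    u = rng.random((n_reps, n_island))
    sel = np.argpartition(u, n_protected - 1, axis=1)[:, :n_protected]
    picks = np.zeros((n_reps, n_island), dtype=float)
    np.put_along_axis(picks, sel, 1.0, axis=1)
    proportions = (picks @ S.T) / sizes
    return NullDistribution(
        species_ids=sids,
        proportions=proportions,
        n_protected=int(n_protected),
        n_reps=int(n_reps),
        seed=int(seed),
    )


@dataclasses.dataclass
class NullComparison:
    """Per-species verdicts against the null distribution plus tallies."""

    verdicts: dict            # species_id -> "higher" | "equal" | "less"
    counts: dict              # verdict -> count
    percentages: dict         # verdict -> percent of species
    alpha: float


def compare_to_null(observed: dict, null: NullDistribution, alpha: float = 0.05) -> NullComparison:
    """Classify each species' observed protected proportion against its null
    draws: "higher" above the (1 - alpha) quantile, "less" below the alpha
    quantile, "equal" (non-rejection) otherwise.
    """
    if set(observed) != set(null.species_ids):
        raise ValueError("observed and null species sets differ")
    lo = np.quantile(null.proportions, alpha, axis=0)
    hi = np.quantile(null.proportions, 1.0 - alpha, axis=0)
    verdicts = {}
    for j, sid in enumerate(null.species_ids):
        x = observed[sid]
        if x > hi[j]:
            verdicts[sid] = "higher"
        elif x < lo[j]:
            verdicts[sid] = "less"
        else:
            verdicts[sid] = "equal"
    n = len(verdicts)
    counts = {v: sum(1 for x in verdicts.values() if x == v) for v in ("higher", "equal", "less")}
    percentages = {v: 100.0 * c / n for v, c in counts.items()}
    return NullComparison(verdicts=verdicts, counts=counts, percentages=percentages, alpha=alpha)
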