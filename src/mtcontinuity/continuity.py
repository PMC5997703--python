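"""Drift-only test of maternal population continuity.

The null hypothesis is that two serially sampled groups belong to a
single resident population whose differentiation arose by genetic drift
alone.  For every cell of a grid of (ancient Ne, recent Ne) pairs, the
serial coalescent is run under exponential growth between the two sizes
(growth rate ln(N_recent/N_ancient)/Δgenerations), both groups are drawn
from the single simulated population at their real sampling ages, and the
proportion of replicates with simulated ΦST >= the observed ΦST is
recorded.  Continuity is rejected only when that exceedance proportion is
below α in *every* cell — i.e. no plausible drift scenario in the grid
can produce differentiation as large as observed.  Ties (simulated ==
observed) count as exceedances, which is conservative toward
non-rejection.

At the defaults — 11 × 11 size combinations × 1000 replicates — one
comparison costs 121,000 coalescent simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from .coalsim import (
    DemographicModel,
    SamplingSchedule,
    simulate_fst_replicates,
)
from .exceptions import GridIncompleteError, ModelError, PartitionError
from .io_meta import HaplotypeAlignment
from .popgen import DistanceMatrix, pairwise_distances, phi_st

#: Default grid axes: 11 haploid sizes log-spaced over 500–50,000, a range
#: bracketing skyline-plot estimates of female Ne for regional human
#: populations.
DEFAULT_GRID_MIN = 500.0
DEFAULT_GRID_MAX = 50_000.0
DEFAULT_GRID_STEPS = 11


def default_axis(
    lo: float = DEFAULT_GRID_MIN,
    hi: float = DEFAULT_GRID_MAX,
    steps: int = DEFAULT_GRID_STEPS,
) -> np.ndarray:
    return np.geomspace(lo, hi, steps)


def observed_epoch_fst(
    aln: HaplotypeAlignment,
    partition: Sequence[Sequence[str]],
    missing_policy: str = "complete_deletion",
) -> float:
    """Observed ΦST between two epoch samples of the alignment."""
    if len(partition) != 2:
        raise PartitionError("epoch comparison needs exactly two groups")
    if set(partition[0]) == set(partition[1]):
        raise PartitionError("the two epoch groups are identical")
    ids = list(partition[0]) + list(partition[1])
    dist = pairwise_distances(aln.subset(ids), missing_policy)
    return phi_st(dist, partition)


@dataclass
class ContinuityGrid:
    """Exceedance proportions P(sim ΦST >= observed) over the Ne grid."""

    ne_axis_ancient: np.ndarray
    ne_axis_recent: np.ndarray
    n_reps: int
    observed_fst: float
    proportions: np.ndarray  # (n_ancient, n_recent)
    reps_done: np.ndarray  # replicates actually run per cell
    seed: int | None
    comparison_label: str = ""
    early_stopped: bool = False
    early_alpha: float | None = None

    @property
    def n_simulations(self) -> int:
        return int(self.reps_done.sum())

    @property
    def complete(self) -> bool:
        return bool((self.reps_done == self.n_reps).all())

    @property
    def max_proportion(self) -> float:
        done = self.reps_done > 0
        return float(np.nanmax(self.proportions[done])) if done.any() else math.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions,
            index=[f"{x:.0f}" for x in self.ne_axis_ancient],
            columns=[f"{x:.0f}" for x in self.ne_axis_recent],
        )


@dataclass(frozen=True)
class ContinuityVerdict:
    reject: bool
    alpha: float
    max_proportion: float
    comparison_label: str


def run_grid(
    model_template: DemographicModel,
    schedule: SamplingSchedule,
    observed_fst: float,
    ne_axis_ancient: np.ndarray | Sequence[float] | None = None,
    ne_axis_recent: np.ndarray | Sequence[float] | None = None,
    n_reps: int = 1000,
    seed: int | None = None,
    early_stop_alpha: float | None = None,
    comparison_label: str = "",
) -> ContinuityGrid:
    """Evaluate the continuity null over the Ne grid.

    ``model_template`` supplies anchor time, mutation rate, sequence
    length and generation time; each cell substitutes its
    (ancient, recent) size pair, which fixes the growth rate.  Cells use
    independent, reproducible random streams spawned from ``seed``, so
    results do not depend on evaluation order.

    ``early_stop_alpha`` enables an exact shortcut for verdicts: once any
    cell accumulates ceil(α·n_reps) exceedances its proportion can no
    longer fall below α, non-rejection is decided, and the scan stops.
    The default (None) evaluates the full grid.
    """
    if not math.isfinite(observed_fst):
        raise ModelError("observed_fst must be finite")
    axis_a = np.asarray(
        default_axis() if ne_axis_ancient is None else ne_axis_ancient, dtype=float
    )
    axis_r = np.asarray(
        default_axis() if ne_axis_recent is None else ne_axis_recent, dtype=float
    )
    if (axis_a <= 0).any() or (axis_r <= 0).any():
        raise ModelError("grid axes must contain positive effective sizes")
    na, nr = len(axis_a), len(axis_r)
    proportions = np.full((na, nr), np.nan)
    reps_done = np.zeros((na, nr), dtype=np.int64)
    streams = SeedSequence(seed).spawn(na * nr)
    threshold = (
        None if early_stop_alpha is None else math.ceil(early_stop_alpha * n_reps)
    )
    early = False
    for i, ne_a in enumerate(axis_a):
        for j, ne_r in enumerate(axis_r):
            model = DemographicModel(
                n_recent=ne_r,
                n_anchor=ne_a,
                anchor_gen=model_template.anchor_gen,
                mu=model_template.mu,
                seq_len=model_template.seq_len,
                gen_time=model_template.gen_time,
            )
            rng = default_rng(streams[i * nr + j])
            reps = simulate_fst_replicates(
                model,
                schedule,
                n_reps,
                seed=rng,
                observed_fst=observed_fst,
                stop_at_exceedances=threshold,
            )
            done = reps.n_reps
            exceed = int((reps.values >= observed_fst).sum())
            proportions[i, j] = exceed / done
            reps_done[i, j] = done
            if threshold is not None and exceed >= threshold:
                early = True
                break
        if early:
            break
    return ContinuityGrid(
        ne_axis_ancient=axis_a,
        ne_axis_recent=axis_r,
        n_reps=n_reps,
        observed_fst=observed_fst,
        proportions=proportions,
        reps_done=reps_done,
        seed=seed,
        comparison_label=comparison_label,
        early_stopped=early,
        early_alpha=early_stop_alpha,
    )


def verdict(grid: ContinuityGrid, alpha: float = 0.05) -> ContinuityVerdict:
    """Decide the continuity test: reject iff every cell proportion < α."""
    if grid.early_stopped:
        if grid.early_alpha is None or grid.early_alpha < alpha:
            raise GridIncompleteError(
                "grid stopped early at a stricter alpha than requested"
            )
        # some cell provably reached proportion >= early_alpha >= alpha
        return ContinuityVerdict(
            reject=False,
            alpha=alpha,
            max_proportion=grid.max_proportion,
            comparison_label=grid.comparison_label,
        )
    if not grid.complete:
        raise GridIncompleteError("grid is incomplete; rerun without early stop")
    return ContinuityVerdict(
        reject=bool(grid.max_proportion < alpha),
        alpha=alpha,
        max_proportion=grid.max_proportion,
        comparison_label=grid.comparison_label,
    )


def bonferroni_report(
    grids: Mapping[str, ContinuityGrid], alpha: float = 0.05
) -> pd.DataFrame:
    """Optional multiple-testing view across several epoch comparisons.

    Applies a Bonferroni-adjusted per-comparison level α/m; reports both
    the nominal and adjusted decisions.
    """
    m = len(grids)
    rows = []
    for label, grid in grids.items():
        v = verdict(grid, alpha)
        rows.append(
            {
                "comparison": label,
                "max_proportion": v.max_proportion,
                "reject_nominal": v.reject,
                "reject_bonferroni": bool(v.max_proportion < alpha / m),
            }
        )
    return pd.DataFrame(rows).set_index("comparison")
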