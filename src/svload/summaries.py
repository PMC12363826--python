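"""Population statistics, the outcrossing sweep, and retention thresholds.

The sweep experiment runs replicate simulations over a grid of outcrossing
proportions and summarizes each cell by its equilibrium mean load (mean
mutation copies per individual over the post-burn-in tail).  "Retention" is
operationalized as an equilibrium load of at least ``cutoff`` (default 1.0)
copies per individual; the two thresholds reported are the largest grid
proportion at which no replicate retains, and the smallest grid proportion
from which retention is consistent (every replicate, at that proportion and
all larger ones, retains).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import (
    GenerationSummary,
    Population,
    RunResult,
    equilibrium_mean_load,
    run_replicates,
)
from .model_core import SimParams

__all__ = [
    "SweepCell",
    "SweepResult",
    "RetentionThresholds",
    "generation_summary",
    "allele_frequency_spectrum",
    "sweep_outcrossing",
    "retention_threshold",
    "relative_fitness_allele_freq",
    "sweep_frame",
    "write_sweep",
    "write_sweep_summary",
]


def generation_summary(pop: Population, generation: Optional[int] = None) -> GenerationSummary:
    """Summarize a population: size, load moments, segregating variants, fitness.

    An empty population yields an N=0 row with missing means.
    """
    from .engine import _summary

    s = _summary(pop)
    if generation is not None:
        s.generation = generation
    return s


def allele_frequency_spectrum(
    pop: Population, bins: Optional[Sequence[float]] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of per-variant copy frequencies (copies / 2N).

    Returns (counts, bin_edges); counts sum to the number of distinct
    segregating variants.
    """
    if pop.size < 1:
        raise ValueError("allele_frequency_spectrum requires N >= 1")
    if bins is None:
        bins = np.linspace(0.0, 1.0, 21)
    edges = np.asarray(bins, dtype=float)
    if len(pop.hap_mut) == 0:
        return np.zeros(len(edges) - 1, dtype=np.int64), edges
    uids, copies = np.unique(pop.hap_mut, return_counts=True)
    freqs = copies / (2.0 * pop.size)
    counts, edges = np.histogram(freqs, bins=edges)
    return counts, edges


@dataclass
class SweepCell:
    """One replicate at one outcrossing proportion."""

    outcrossing: float
    replicate: int
    seed: int
    equilibrium_mean_load: float  # NaN when missing (extinct before burn-in)
    extinct: bool

    @property
    def missing(self) -> bool:
        return math.isnan(self.equilibrium_mean_load)


@dataclass
class SweepResult:
    """Replicate equilibrium loads over a grid of outcrossing proportions."""

    grid: List[float]
    cells: Dict[float, List[SweepCell]] = field(default_factory=dict)

    def mean_load(self, o: float) -> float:
        vals = [c.equilibrium_mean_load for c in self.cells[o] if not c.missing]
        return float(np.mean(vals)) if vals else float("nan")

    def sd_load(self, o: float) -> float:
        vals = [c.equilibrium_mean_load for c in self.cells[o] if not c.missing]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")


def sweep_outcrossing(
    params: SimParams,
    grid: Sequence[float],
    R: int = 5,
    base_seed: Optional[int] = None,
    burnin_fraction: float = 0.75,
    threads: int = 1,
) -> SweepResult:
    """Run ``R`` replicates at each outcrossing proportion on the grid.

    Replicate seeds are derived deterministically: the replicate j at grid
    index i uses seed base_seed + i*R + j, so results are independent of
    evaluation order.  Extinct replicates keep their extinction flag; their
    equilibrium load is NaN when extinction precedes the burn-in end.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    grid = sorted(float(o) for o in grid)
    if any(not 0.0 <= o <= 1.0 for o in grid):
        raise ValueError("outcrossing grid values must lie in [0, 1]")
    base = params.seed if base_seed is None else base_seed
    result = SweepResult(grid=list(grid))
    for i, o in enumerate(grid):
        cell_params = params.with_(outcrossing=o)
        runs = run_replicates(cell_params, R=R, base_seed=base + i * R, threads=threads)
        result.cells[o] = [
            SweepCell(
                outcrossing=o,
                replicate=r.replicate,
                seed=r.seed,
                equilibrium_mean_load=equilibrium_mean_load(r, burnin_fraction),
                extinct=r.extinct,
            )
            for r in runs
        ]
    return result


@dataclass
class RetentionThresholds:
    """Grid-resolution-limited retention thresholds (None = not observed)."""

    o_no_retention: Optional[float]
    o_consistent_retention: Optional[float]
    cutoff: float = 1.0


def retention_threshold(sweep: SweepResult, cutoff: float = 1.0) -> RetentionThresholds:
    """Locate the no-retention and consistent-retention grid proportions.

    ``o_no_retention``: largest grid proportion at which every replicate's
    equilibrium load is below ``cutoff`` (a missing/extinct-before-burn-in
    replicate counts as not retaining).  ``o_consistent_retention``: smallest
    grid proportion such that at it *and all larger grid values* every
    replicate's load is at or above ``cutoff``.
    """

    def all_below(o: float) -> bool:
        return all(c.missing or c.equilibrium_mean_load < cutoff for c in sweep.cells[o])

    def all_at_or_above(o: float) -> bool:
        return all((not c.missing) and c.equilibrium_mean_load >= cutoff for c in sweep.cells[o])

    below = [o for o in sweep.grid if all_below(o)]
    o_no = max(below) if below else None

    o_consistent = None
    for idx in range(len(sweep.grid) - 1, -1, -1):
        if all_at_or_above(sweep.grid[idx]):
            o_consistent = sweep.grid[idx]
        else:
            break
    return RetentionThresholds(o_no_retention=o_no, o_consistent_retention=o_consistent, cutoff=cutoff)


def relative_fitness_allele_freq(non_gfp_count: int, total_count: int) -> float:
    """Allele frequency of the non-fluorescent allele in a competition assay.

    Computed as sqrt(non_gfp_count / total_count); plates with zero total
    worms are undefined and must be excluded upstream.
    """
    if total_count <= 0:
        raise ValueError("total_count must be > 0 (zero-worm plates are excluded)")
    if not 0 <= non_gfp_count <= total_count:
        raise ValueError("need 0 <= non_gfp_count <= total_count")
    return math.sqrt(non_gfp_count / total_count)


def sweep_frame(sweep: SweepResult) -> pd.DataFrame:
    rows = [
        {
            "outcrossing": c.outcrossing,
            "replicate": c.replicate,
            "seed": c.seed,
            "equilibrium_mean_load": c.equilibrium_mean_load,
            "extinct": int(c.extinct),
        }
        for o in sweep.grid
        for c in sweep.cells[o]
    ]
    return pd.DataFrame(
        rows, columns=["outcrossing", "replicate", "seed", "equilibrium_mean_load", "extinct"]
    )


def write_sweep(sweep: SweepResult, path) -> None:
    sweep_frame(sweep).to_csv(path, sep="\t", index=False, na_rep=".")


def write_sweep_summary(sweep: SweepResult, path, cutoff: float = 1.0) -> None:
    """Per-proportion mean/sd plus the two retention thresholds, as TSV."""
    thr = retention_threshold(sweep, cutoff=cutoff)
    df = pd.DataFrame(
        {
            "outcrossing": sweep.grid,
            "mean_equilibrium_load": [sweep.mean_load(o) for o in sweep.grid],
            "sd_equilibrium_load": [sweep.sd_load(o) for o in sweep.grid],
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        df.to_csv(fh, sep="\t", index=False, na_rep=".")
        fh.write(f"# retention_cutoff\t{thr.cutoff}\n")
        fh.write(f"# o_no_retention\t{'.' if thr.o_no_retention is None else thr.o_no_retention}\n")
        fh.write(
            "# o_consistent_retention\t"
            f"{'.' if thr.o_consistent_retention is None else thr.o_consistent_retention}\n"
        )
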