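"""The generation loop: reproduction, density-regulated viability, recording.

The population model is non-Wright-Fisher with overlapping generations.
Each tick:

1. every adult initiates Poisson(fecundity) offspring; parents are drawn by
   :func:`svload.reproduction.choose_mating` semantics (selfing with
   probability 1 - o under androdioecy; female x male under dioecy);
2. every individual, parents and newborns alike, survives independently
   with probability min(1, w * K / N_total), where w is its fitness and
   N_total the post-reproduction headcount — soft density regulation around
   the carrying capacity K;
3. survivors age by one; the generation counter advances.

Populations are stored columnarly: one flat int32 array of mutation ids
grouped by haplotype (two haplotypes per individual) plus an offset array,
with per-mutation positions/effects in a shared, append-only table.  All
per-tick work is O(total mutation copies) in vectorized numpy, which is what
makes multi-tens-of-thousands-of-generation runs practical on one CPU.
Mutation ids are never position-sorted inside a haplotype (transmission only
needs the crossing parity of each copy); the object-level API re-sorts on
materialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .model_core import (
    FEMALE,
    HERMAPHRODITE,
    MALE,
    Haplotype,
    Individual,
    SVMutation,
    SimParams,
)

__all__ = [
    "Population",
    "GenerationSummary",
    "RunResult",
    "initialize",
    "step",
    "run",
    "run_replicates",
    "equilibrium_mean_load",
    "trajectory_frame",
    "write_trajectory",
    "TRAJECTORY_COLUMNS",
]

_SEX_CODE = {HERMAPHRODITE: 0, FEMALE: 1, MALE: 2}
_CODE_SEX = {v: k for k, v in _SEX_CODE.items()}

TRAJECTORY_COLUMNS = [
    "generation",
    "N",
    "mean_load",
    "var_load",
    "distinct_variants",
    "mean_segregating_effect",
    "mean_fitness",
    "replicate",
    "seed",
]


def _ranges_concat(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Concatenate arange(s, s+c) for each (s, c) pair, vectorized."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    offsets = np.cumsum(counts) - counts
    return (
        np.arange(total, dtype=np.int64)
        - np.repeat(offsets, counts)
        + np.repeat(np.asarray(starts, dtype=np.int64), counts)
    )


class MutationTable:
    """Append-only registry of every mutation ever created in a run.

    The row index is the mutation uid.  The table is shared by all
    generations of one population; dead mutations simply stop being
    referenced.
    """

    def __init__(self, capacity: int = 1024) -> None:
        self.position = np.empty(capacity, dtype=np.int32)
        self.effect = np.empty(capacity, dtype=np.float64)
        self.origin = np.empty(capacity, dtype=np.int32)
        self.n = 0

    def _grow(self, need: int) -> None:
        cap = len(self.position)
        if self.n + need <= cap:
            return
        new_cap = max(cap * 2, self.n + need)
        for name in ("position", "effect", "origin"):
            old = getattr(self, name)
            new = np.empty(new_cap, dtype=old.dtype)
            new[: self.n] = old[: self.n]
            setattr(self, name, new)

    def append(self, positions: np.ndarray, effects: np.ndarray, origin: int) -> np.ndarray:
        m = len(positions)
        self._grow(m)
        sl = slice(self.n, self.n + m)
        self.position[sl] = positions
        self.effect[sl] = effects
        self.origin[sl] = origin
        ids = np.arange(self.n, self.n + m, dtype=np.int32)
        self.n += m
        return ids


@dataclass
class GenerationSummary:
    """Per-generation population state, one row of the trajectory."""

    generation: int
    N: int
    mean_load: Optional[float]
    var_load: Optional[float]
    distinct_variants: int
    mean_segregating_effect: Optional[float]
    mean_fitness: Optional[float]


class Population:
    """Columnar population state; reproducible from (params, seed)."""

    def __init__(self, params: SimParams, seed: Optional[int] = None) -> None:
        self.params = params
        self.seed = params.seed if seed is None else seed
        self.rng = np.random.default_rng(self.seed)
        self.generation = 0
        self.muts = MutationTable()
        K = params.K
        self.hap_indptr = np.zeros(2 * K + 1, dtype=np.int64)
        self.hap_mut = np.empty(0, dtype=np.int32)
        self.age = np.zeros(K, dtype=np.int32)
        if params.dioecious:
            # equal numbers of males and females at initialization
            sex = np.empty(K, dtype=np.int8)
            half = K // 2
            sex[:half] = _SEX_CODE[FEMALE]
            sex[half:] = _SEX_CODE[MALE]
            self.sex = sex
        else:
            self.sex = np.zeros(K, dtype=np.int8)

    # -- basic accessors ---------------------------------------------------

    @property
    def size(self) -> int:
        return len(self.age)

    @property
    def extinct(self) -> bool:
        return self.size == 0

    def hap_counts(self) -> np.ndarray:
        return np.diff(self.hap_indptr)

    def loads(self) -> np.ndarray:
        c = self.hap_counts()
        return c[0::2] + c[1::2]

    def summed_effects(self) -> np.ndarray:
        """Per-individual sum of mutation-copy effects."""
        N = self.size
        if N == 0 or len(self.hap_mut) == 0:
            return np.zeros(N)
        owner = np.repeat(np.arange(N), self.loads())
        return np.bincount(owner, weights=self.muts.effect[self.hap_mut], minlength=N)

    def fitnesses(self) -> np.ndarray:
        p = self.params
        if p.weighted_fitness:
            x = self.summed_effects()
        else:
            x = self.loads().astype(float)
        return np.exp(-(p.a * x + p.b * x * x / 2.0))

    @property
    def rng_state(self) -> dict:
        return self.rng.bit_generator.state

    # -- object bridge -----------------------------------------------------

    def to_individuals(self) -> List[Individual]:
        """Materialize object-level individuals (sorted haplotypes)."""
        out = []
        ip = self.hap_indptr
        for i in range(self.size):
            haps = []
            for h in (2 * i, 2 * i + 1):
                ids = self.hap_mut[ip[h] : ip[h + 1]]
                haps.append(
                    Haplotype.of(
                        SVMutation(
                            uid=int(m),
                            position=int(self.muts.position[m]),
                            effect=float(self.muts.effect[m]),
                            origin_generation=int(self.muts.origin[m]),
                        )
                        for m in ids
                    )
                )
            out.append(
                Individual(
                    hap1=haps[0],
                    hap2=haps[1],
                    sex=_CODE_SEX[int(self.sex[i])],
                    age=int(self.age[i]),
                )
            )
        return out

    @staticmethod
    def from_individuals(
        individuals: Sequence[Individual], params: SimParams, seed: Optional[int] = None
    ) -> "Population":
        pop = Population(params, seed=seed)
        N = len(individuals)
        uid_map: dict = {}
        data: List[int] = []
        counts = np.empty(2 * N, dtype=np.int64)
        for i, ind in enumerate(individuals):
            for h, hap in enumerate((ind.hap1, ind.hap2)):
                counts[2 * i + h] = len(hap)
                for m in hap:
                    if m.uid not in uid_map:
                        uid_map[m.uid] = pop.muts.append(
                            np.array([m.position]),
                            np.array([m.effect]),
                            m.origin_generation,
                        )[0]
                    data.append(uid_map[m.uid])
        pop.hap_indptr = np.concatenate(([0], np.cumsum(counts)))
        pop.hap_mut = np.asarray(data, dtype=np.int32)
        pop.age = np.array([ind.age for ind in individuals], dtype=np.int32)
        pop.sex = np.array([_SEX_CODE[ind.sex] for ind in individuals], dtype=np.int8)
        return pop


def initialize(params: SimParams, seed: Optional[int] = None) -> Population:
    """K mutation-free individuals of age 0, sexes according to the mode."""
    return Population(params, seed=seed)


def _mating_arrays(pop: Population, O_counts: np.ndarray):
    """Vectorized parent choice for all offspring of one tick.

    Returns (parent1, parent2) index arrays, or None if no mating is
    possible this tick (dioecious population missing one sex).
    """
    p = pop.params
    N = pop.size
    rng = pop.rng
    initiator = np.repeat(np.arange(N, dtype=np.int64), O_counts)
    O = len(initiator)
    if p.dioecious:
        females = np.flatnonzero(pop.sex == _SEX_CODE[FEMALE])
        males = np.flatnonzero(pop.sex == _SEX_CODE[MALE])
        if len(females) == 0 or len(males) == 0:
            return None
        is_f = pop.sex[initiator] == _SEX_CODE[FEMALE]
        mothers = np.where(is_f, initiator, females[rng.integers(0, len(females), O)])
        fathers = np.where(is_f, males[rng.integers(0, len(males), O)], initiator)
        return mothers, fathers
    parent1 = initiator
    parent2 = initiator.copy()
    if N >= 2 and p.outcrossing > 0 and O > 0:
        outx = rng.random(O) < p.outcrossing
        k = int(outx.sum())
        if k:
            parent2[outx] = (parent1[outx] + 1 + rng.integers(0, N - 1, k)) % N
    return parent1, parent2


def step(pop: Population) -> Population:
    """Advance the population by one tick, in place; returns the population.

    Extinction (no survivors) leaves an empty population; it is recorded by
    :func:`run`, not raised.
    """
    p = pop.params
    N = pop.size
    rng = pop.rng
    if N == 0:
        pop.generation += 1
        return pop

    counts_h = pop.hap_counts()
    w_adult = pop.fitnesses()

    # ---- reproduction ----------------------------------------------------
    O_counts = rng.poisson(p.fecundity, N)
    parents = _mating_arrays(pop, O_counts)
    if parents is None:
        O = 0
        gam_counts = np.zeros(0, dtype=np.int64)
        gam_indptr = np.zeros(1, dtype=np.int64)
        gam_mut = np.empty(0, dtype=np.int32)
        sex_off = np.empty(0, dtype=np.int8)
        w_off = np.empty(0)
    else:
        parent1, parent2 = parents
        O = len(parent1)
        M = 2 * O  # meioses; gamete g belongs to offspring g // 2
        P = np.empty(M, dtype=np.int64)
        P[0::2] = parent1
        P[1::2] = parent2

        # gather all parental mutation copies involved, grouped by
        # (meiosis, haplotype-of-origin)
        hap_idx = np.empty(2 * M, dtype=np.int64)
        hap_idx[0::2] = 2 * P
        hap_idx[1::2] = 2 * P + 1
        g_counts = counts_h[hap_idx]
        gather = _ranges_concat(pop.hap_indptr[hap_idx], g_counts)
        copy_mut = pop.hap_mut[gather]
        group_of_copy = np.repeat(np.arange(2 * M, dtype=np.int64), g_counts)
        copy_meiosis = group_of_copy >> 1
        copy_side = (group_of_copy & 1).astype(np.int8)
        copy_pos = pop.muts.position[copy_mut]

        # crossovers: parity of breakpoints <= position decides the active
        # haplotype for each copy
        lam = p.r * (p.L - 1)
        ncopies = len(copy_mut)
        if lam > 0:
            cbp = rng.poisson(lam, M)
            maxc = int(cbp.max()) if M else 0
        else:
            cbp = np.zeros(M, dtype=np.int64)
            maxc = 0
        if maxc > 0:
            bp = rng.integers(1, p.L, size=(M, maxc))
            bp[np.arange(maxc)[None, :] >= cbp[:, None]] = p.L  # sentinel
            bp.sort(axis=1)
            if maxc > 1:  # thin duplicate boundaries
                dup = bp[:, 1:] == bp[:, :-1]
                bp[:, 1:][dup] = p.L
            crossings = (bp[copy_meiosis, :] <= copy_pos[:, None]).sum(axis=1)
        else:
            crossings = np.zeros(ncopies, dtype=np.int64)
        start = rng.integers(0, 2, M).astype(np.int64)
        active = (start[copy_meiosis] + crossings) & 1
        keep = copy_side == active

        # losses: each transmitted copy retained with probability 1 - nu
        if p.nu > 0 and ncopies:
            keep &= rng.random(ncopies) >= p.nu

        kept_mut = copy_mut[keep]
        kept_meiosis = copy_meiosis[keep]
        kept_counts = np.bincount(kept_meiosis, minlength=M).astype(np.int64)

        # gains: Poisson(mu) new mutations per gamete
        mu_eff = p.mu_per_gamete
        if mu_eff > 0:
            n_new = rng.poisson(mu_eff, M)
            G = int(n_new.sum())
        else:
            n_new = np.zeros(M, dtype=np.int64)
            G = 0
        if G:
            new_pos = rng.integers(0, p.L, G)
            new_eff = rng.gamma(p.k, p.theta, G)
            new_ids = pop.muts.append(new_pos, new_eff, pop.generation + 1)
        gam_counts = kept_counts + n_new
        gam_indptr = np.concatenate(([0], np.cumsum(gam_counts)))
        gam_mut = np.empty(int(gam_counts.sum()), dtype=np.int32)
        gam_mut[_ranges_concat(gam_indptr[:-1], kept_counts)] = kept_mut
        if G:
            gam_mut[_ranges_concat(gam_indptr[:-1] + kept_counts, n_new)] = new_ids

        # offspring sex and fitness
        if p.dioecious:
            sex_off = np.where(
                rng.integers(0, 2, O) == 0, _SEX_CODE[FEMALE], _SEX_CODE[MALE]
            ).astype(np.int8)
        else:
            sex_off = np.zeros(O, dtype=np.int8)
        load_off = gam_counts[0::2] + gam_counts[1::2]
        if p.weighted_fitness:
            if len(gam_mut):
                owner = np.repeat(np.arange(O, dtype=np.int64), load_off)
                x_off = np.bincount(owner, weights=pop.muts.effect[gam_mut], minlength=O)
            else:
                x_off = np.zeros(O)
        else:
            x_off = load_off.astype(float)
        w_off = np.exp(-(p.a * x_off + p.b * x_off * x_off / 2.0))

    # ---- density-regulated viability ------------------------------------
    N_total = N + O
    w_all = np.concatenate((w_adult, w_off))
    survive = pop.rng.random(N_total) < np.minimum(1.0, w_all * p.K / N_total)
    sel_ad = np.flatnonzero(survive[:N])
    sel_off = np.flatnonzero(survive[N:])

    # ---- rebuild population arrays --------------------------------------
    had = np.empty(2 * len(sel_ad), dtype=np.int64)
    had[0::2] = 2 * sel_ad
    had[1::2] = 2 * sel_ad + 1
    hoff = np.empty(2 * len(sel_off), dtype=np.int64)
    hoff[0::2] = 2 * sel_off
    hoff[1::2] = 2 * sel_off + 1

    ad_counts = counts_h[had]
    off_counts = gam_counts[hoff] if len(hoff) else np.zeros(0, dtype=np.int64)
    new_counts = np.concatenate((ad_counts, off_counts))
    pop.hap_mut = np.concatenate(
        (
            pop.hap_mut[_ranges_concat(pop.hap_indptr[had], ad_counts)],
            gam_mut[_ranges_concat(gam_indptr[hoff], off_counts)] if len(hoff) else np.empty(0, dtype=np.int32),
        )
    )
    pop.hap_indptr = np.concatenate(([0], np.cumsum(new_counts)))
    pop.age = np.concatenate((pop.age[sel_ad] + 1, np.ones(len(sel_off), dtype=np.int32)))
    pop.sex = np.concatenate((pop.sex[sel_ad], sex_off[sel_off]))
    pop.generation += 1
    return pop


def _summary(pop: Population) -> GenerationSummary:
    N = pop.size
    if N == 0:
        return GenerationSummary(pop.generation, 0, None, None, 0, None, None)
    loads = pop.loads()
    seg = pop.hap_mut
    distinct = int(len(np.unique(seg)))
    mean_eff = float(pop.muts.effect[seg].mean()) if len(seg) else None
    return GenerationSummary(
        generation=pop.generation,
        N=N,
        mean_load=float(loads.mean()),
        var_load=float(loads.var()),
        distinct_variants=distinct,
        mean_segregating_effect=mean_eff,
        mean_fitness=float(pop.fitnesses().mean()),
    )


@dataclass
class RunResult:
    """One replicate's trajectory plus its extinction record."""

    params: SimParams
    seed: int
    summaries: List[GenerationSummary] = field(default_factory=list)
    extinct: bool = False
    extinction_generation: Optional[int] = None
    replicate: int = 0

    @property
    def trajectory(self) -> List[GenerationSummary]:
        return self.summaries


def run(params: SimParams, seed: Optional[int] = None, replicate: int = 0) -> RunResult:
    """Simulate one replicate; deterministic given (params, seed).

    A :class:`GenerationSummary` is recorded at generation 0, every
    ``params.record_every`` ticks, and at the final generation.  Extinction
    terminates the run and is reported as data on the result.
    """
    seed = params.seed if seed is None else seed
    pop = initialize(params, seed=seed)
    result = RunResult(params=params, seed=seed, replicate=replicate)
    result.summaries.append(_summary(pop))
    for _ in range(params.generations):
        step(pop)
        if pop.extinct:
            result.extinct = True
            result.extinction_generation = pop.generation
            result.summaries.append(_summary(pop))
            break
        if pop.generation % params.record_every == 0 or pop.generation == params.generations:
            result.summaries.append(_summary(pop))
    return result


def run_replicates(
    params: SimParams, R: Optional[int] = None, base_seed: Optional[int] = None, threads: int = 1
) -> List[RunResult]:
    """R independent replicates with seeds base_seed + 0 .. base_seed + R-1."""
    R = params.replicates if R is None else R
    if R < 1:
        raise ValueError("R must be >= 1")
    base = params.seed if base_seed is None else base_seed
    seeds = [base + i for i in range(R)]
    if threads > 1:
        from joblib import Parallel, delayed

        return Parallel(n_jobs=threads)(
            delayed(run)(params, seed=s, replicate=i) for i, s in enumerate(seeds)
        )
    return [run(params, seed=s, replicate=i) for i, s in enumerate(seeds)]


def equilibrium_mean_load(
    trajectory: Union[RunResult, Sequence[GenerationSummary]],
    burnin_fraction: float = 0.75,
) -> float:
    """Mean of mean_load over the post-burn-in tail of a trajectory.

    Returns NaN if the trajectory ended (extinction) before the burn-in
    fraction of recorded generations, i.e. the estimate is missing.
    """
    if not 0.0 <= burnin_fraction < 1.0:
        raise ValueError("burnin_fraction must lie in [0, 1)")
    if isinstance(trajectory, RunResult):
        summaries = trajectory.summaries
        target_gens = trajectory.params.generations
    else:
        summaries = list(trajectory)
        target_gens = summaries[-1].generation if summaries else 0
    if not summaries:
        raise ValueError("empty trajectory")
    burn_gen = burnin_fraction * target_gens
    tail = [s.mean_load for s in summaries if s.generation >= burn_gen and s.mean_load is not None]
    if not tail:
        return float("nan")
    return float(np.mean(tail))


def tail_stationarity(
    trajectory: Union[RunResult, Sequence[GenerationSummary]],
    burnin_fraction: float = 0.75,
) -> Tuple[float, float]:
    """(slope, stderr) of mean_load per generation over the post-burn-in tail.

    A tail whose slope differs from zero by more than ~2 standard errors
    suggests the trajectory has not equilibrated; callers log this as a
    warning and never auto-extend the run.
    """
    if isinstance(trajectory, RunResult):
        summaries = trajectory.summaries
        target_gens = trajectory.params.generations
    else:
        summaries = list(trajectory)
        target_gens = summaries[-1].generation if summaries else 0
    burn_gen = burnin_fraction * target_gens
    pts = [
        (s.generation, s.mean_load)
        for s in summaries
        if s.generation >= burn_gen and s.mean_load is not None
    ]
    if len(pts) < 3:
        return float("nan"), float("nan")
    x = np.array([g for g, _ in pts], dtype=float)
    y = np.array([m for _, m in pts], dtype=float)
    x = x - x.mean()
    sxx = float((x * x).sum())
    slope = float((x * y).sum() / sxx)
    resid = y - y.mean() - slope * x
    dof = len(pts) - 2
    stderr = float(np.sqrt((resid * resid).sum() / dof / sxx))
    return slope, stderr


def trajectory_frame(result: RunResult) -> pd.DataFrame:
    """Trajectory as a DataFrame with the canonical column layout."""
    rows = [
        {
            "generation": s.generation,
            "N": s.N,
            "mean_load": s.mean_load,
            "var_load": s.var_load,
            "distinct_variants": s.distinct_variants,
            "mean_segregating_effect": s.mean_segregating_effect,
            "mean_fitness": s.mean_fitness,
            "replicate": result.replicate,
            "seed": result.seed,
        }
        for s in result.summaries
    ]
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def write_trajectory(result: RunResult, path) -> None:
    """Write a trajectory as UTF-8 TSV; missing values rendered as '.'."""
    df = trajectory_frame(result)
    df.to_csv(path, sep="\t", index=False, na_rep=".")
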