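"""Domain types, the epistatic fitness function, and the distribution of fitness effects.

The model tracks structural-variant (SV) alleles on a diploid chromosome of
``L`` nucleotides.  Every mutation carries a small deleterious phenotypic
effect drawn from a gamma distribution Gamma(shape=k, scale=theta).  Fitness
declines faster than linearly with the number of mutation copies carried
(synergistic epistasis):

    w(n) = exp(-(a*n + b*n^2 / 2))

where ``n`` counts mutation *copies* in the diploid genome, so a homozygous
variant contributes 2.  An alternative "weighted" mode applies the same curve
to the summed phenotypic effect S = sum(effect_i) over all copies, which lets
large-effect mutations be purged preferentially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Tuple

import numpy as np

__all__ = [
    "HERMAPHRODITE",
    "FEMALE",
    "MALE",
    "SVMutation",
    "Haplotype",
    "Individual",
    "SimParams",
    "sample_effect",
    "fitness_count",
    "fitness_weighted",
    "load",
]

# Sex labels.  Androdioecious populations contain only hermaphrodites;
# dioecious populations contain females and males.
HERMAPHRODITE = "hermaphrodite"
FEMALE = "female"
MALE = "male"


@dataclass(frozen=True)
class SVMutation:
    """One structural-variant allele.

    Parameters
    ----------
    uid
        Opaque identifier, unique within a simulation run.
    position
        0-based nucleotide index on the chromosome, in ``[0, L)``.
    effect
        Dimensionless deleterious phenotypic effect, >= 0.
    origin_generation
        Generation at which the mutation arose.
    """

    uid: int
    position: int
    effect: float
    origin_generation: int = 0

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"position must be >= 0, got {self.position}")
        if self.effect < 0:
            raise ValueError(f"effect must be >= 0, got {self.effect}")
        if self.origin_generation < 0:
            raise ValueError("origin_generation must be >= 0")

    @property
    def sort_key(self) -> Tuple[int, int]:
        return (self.position, self.uid)


@dataclass(frozen=True)
class Haplotype:
    """An ordered collection of SV mutations on one chromosome copy.

    Mutations are kept sorted by (position, uid); construction enforces the
    invariant so downstream code may rely on it.
    """

    mutations: Tuple[SVMutation, ...] = ()

    @staticmethod
    def of(mutations: Iterable[SVMutation]) -> "Haplotype":
        return Haplotype(tuple(sorted(mutations, key=lambda m: m.sort_key)))

    def __post_init__(self) -> None:
        keys = [m.sort_key for m in self.mutations]
        if keys != sorted(keys):
            raise ValueError("Haplotype mutations must be sorted by (position, uid)")

    def __len__(self) -> int:
        return len(self.mutations)

    def __iter__(self) -> Iterator[SVMutation]:
        return iter(self.mutations)

    def positions(self) -> np.ndarray:
        return np.array([m.position for m in self.mutations], dtype=np.int64)


@dataclass
class Individual:
    """A diploid individual: two haplotypes, a sex, and an age in generations."""

    hap1: Haplotype = field(default_factory=Haplotype)
    hap2: Haplotype = field(default_factory=Haplotype)
    sex: str = HERMAPHRODITE
    age: int = 0

    def __post_init__(self) -> None:
        if self.sex not in (HERMAPHRODITE, FEMALE, MALE):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age < 0:
            raise ValueError("age must be >= 0")

    @property
    def load(self) -> int:
        """Diploid mutation-copy count (homozygous variants count twice)."""
        return len(self.hap1) + len(self.hap2)

    def summed_effect(self) -> float:
        return sum(m.effect for m in self.hap1) + sum(m.effect for m in self.hap2)


_ANDRODIOECIOUS = "androdioecious"
_DIOECIOUS = "dioecious"
_COUNT = "count"
_WEIGHTED = "weighted"


@dataclass(frozen=True)
class SimParams:
    """All model constants for one simulation run.

    Defaults are the study conditions: chromosome length L = 10,000 nt,
    gain rate mu = 0.01 per gamete per transmission, loss rate nu = 0.001
    per mutation copy per transmission, recombination r = 1e-4 per adjacent
    site, fitness curvature a = 0.001 and b = 0.0006, gamma DFE with
    shape k = 1 and scale theta = 2, and carrying capacity K = 1000.
    """

    L: int = 10_000
    mu: float = 0.01
    nu: float = 0.001
    r: float = 1e-4
    a: float = 0.001
    b: float = 0.0006
    k: float = 1.0
    theta: float = 2.0
    K: int = 1000
    outcrossing: float = 1.0
    mode: str = _ANDRODIOECIOUS
    fitness_mode: str = _COUNT
    fecundity: float = 2.0
    generations: int = 1000
    replicates: int = 1
    seed: int = 0
    record_every: int = 10
    mu_unit: str = "gamete"  # "gamete" (U = 2*mu per offspring) or "offspring"

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if self.K < 2:
            raise ValueError("K must be >= 2")
        for name in ("mu", "nu", "r", "a", "b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("nu", "r", "outcrossing"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.k <= 0 or self.theta <= 0:
            raise ValueError("gamma DFE requires k > 0 and theta > 0")
        if self.mode not in (_ANDRODIOECIOUS, _DIOECIOUS):
            raise ValueError(f"mode must be androdioecious or dioecious, got {self.mode!r}")
        if self.fitness_mode not in (_COUNT, _WEIGHTED):
            raise ValueError(f"fitness_mode must be count or weighted, got {self.fitness_mode!r}")
        if self.mu_unit not in ("gamete", "offspring"):
            raise ValueError("mu_unit must be 'gamete' or 'offspring'")
        if self.fecundity < 0:
            raise ValueError("fecundity must be >= 0")
        if self.generations < 0 or self.replicates < 1 or self.record_every < 1:
            raise ValueError("generations >= 0, replicates >= 1, record_every >= 1 required")

    @property
    def dioecious(self) -> bool:
        return self.mode == _DIOECIOUS

    @property
    def weighted_fitness(self) -> bool:
        return self.fitness_mode == _WEIGHTED

    @property
    def mu_per_gamete(self) -> float:
        """Gain rate per gamete, whatever unit mu was stated in."""
        return self.mu if self.mu_unit == "gamete" else self.mu / 2.0

    def with_(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


def sample_effect(k: float, theta: float, rng: np.random.Generator, size=None):
    """Draw deleterious phenotypic effect(s) from Gamma(shape=k, scale=theta)."""
    if k <= 0 or theta <= 0:
        raise ValueError("gamma DFE requires k > 0 and theta > 0")
    return rng.gamma(shape=k, scale=theta, size=size)


def fitness_count(n, a: float, b: float):
    """Viability of an individual carrying ``n`` mutation copies.

    w(n) = exp(-(a*n + b*n^2/2)); w(0) = 1, strictly decreasing in n when
    a > 0 or b > 0.  Accepts scalars or arrays.
    """
    n_arr = np.asarray(n)
    if np.any(n_arr < 0):
        raise ValueError("mutation count n must be >= 0")
    if a < 0 or b < 0:
        raise ValueError("fitness parameters a, b must be >= 0")
    w = np.exp(-(a * n_arr + b * n_arr.astype(float) ** 2 / 2.0))
    return float(w) if np.isscalar(n) else w


def fitness_weighted(S, a: float, b: float):
    """Viability as a function of summed phenotypic effect S = sum(effect_i)."""
    S_arr = np.asarray(S, dtype=float)
    if np.any(S_arr < 0):
        raise ValueError("summed effect S must be >= 0")
    if a < 0 or b < 0:
        raise ValueError("fitness parameters a, b must be >= 0")
    w = np.exp(-(a * S_arr + b * S_arr**2 / 2.0))
    return float(w) if np.isscalar(S) else w


def load(ind: Individual) -> int:
    """Diploid SV copy count of an individual (both haplotypes, copies counted)."""
    return ind.load


def individual_fitness(ind: Individual, params: SimParams) -> float:
    """Fitness of one individual under the configured fitness mode."""
    if params.weighted_fitness:
        return fitness_weighted(ind.summed_effect(), params.a, params.b)
    return fitness_count(ind.load, params.a, params.b)
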