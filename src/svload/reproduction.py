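"""Gametogenesis and mating: recombination, mutation gain/loss, parent choice.

This module gives the reference, individual-level semantics of transmission.
A gamete is produced from a parent by

    recombine -> apply_losses -> apply_gains

in that order: crossovers first shuffle the two parental chromosome copies,
then each surviving mutation copy is lost with probability ``nu`` (back
mutation, e.g. by gene conversion), then Poisson(mu) new mutations are added
at uniform positions.  The vectorized generation loop in :mod:`svload.engine`
implements the same process columnarly; tests hold the two to the same
distributional behaviour.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .model_core import (
    FEMALE,
    HERMAPHRODITE,
    MALE,
    Haplotype,
    Individual,
    SVMutation,
    SimParams,
    sample_effect,
)

__all__ = [
    "MatingChoice",
    "MatingFailure",
    "crossover_positions",
    "recombine",
    "apply_losses",
    "apply_gains",
    "make_offspring",
    "choose_mating",
]

# Process-wide uid source for object-level gametogenesis.  The vectorized
# engine allocates its own ids; runs never mix the two sources.
_uid_counter = itertools.count(1)


class MatingFailure(Exception):
    """Raised when a mating cannot be formed (e.g. a sex is missing)."""


@dataclass(frozen=True)
class MatingChoice:
    """A reproduction event: two parent references and a selfing flag."""

    parent1: Individual
    parent2: Individual
    is_selfing: bool

    def __post_init__(self) -> None:
        if self.is_selfing != (self.parent1 is self.parent2):
            raise ValueError("is_selfing must hold exactly when parent1 is parent2")


def crossover_positions(r: float, L: int, rng: np.random.Generator) -> List[int]:
    """Sample sorted, distinct crossover boundaries for one meiosis.

    The breakpoint count is Poisson(r*(L-1)); each breakpoint is an integer
    boundary in (0, L), uniform.  A boundary ``x`` separates positions x-1
    and x.  Duplicate boundaries are thinned.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    if L < 2:
        raise ValueError("L must be >= 2")
    lam = r * (L - 1)
    if lam == 0:
        return []
    count = rng.poisson(lam)
    if count == 0:
        return []
    draws = rng.integers(1, L, size=count)
    return sorted(set(int(x) for x in draws))


def recombine(
    hapA: Haplotype,
    hapB: Haplotype,
    breakpoints: Sequence[int],
    start_choice: int = 0,
) -> Haplotype:
    """Build a gamete haplotype from two parental haplotypes.

    ``start_choice`` selects the leading haplotype (0 -> hapA, 1 -> hapB).
    At each breakpoint the active haplotype alternates; a mutation at
    position p comes from the haplotype active on the segment containing p,
    i.e. the one selected by the parity of breakpoints <= p.
    """
    if start_choice not in (0, 1):
        raise ValueError("start_choice must be 0 or 1")
    bps = list(breakpoints)
    if bps != sorted(bps):
        raise ValueError("breakpoints must be sorted")
    haps = (hapA, hapB)
    out = []
    for side, hap in enumerate(haps):
        for m in hap:
            crossings = _count_leq(bps, m.position)
            if (start_choice + crossings) % 2 == side:
                out.append(m)
    return Haplotype.of(out)


def _count_leq(sorted_vals: Sequence[int], x: int) -> int:
    import bisect

    return bisect.bisect_right(sorted_vals, x)


def apply_losses(hap: Haplotype, nu: float, rng: np.random.Generator) -> Haplotype:
    """Retain each mutation copy independently with probability 1 - nu."""
    if not 0.0 <= nu <= 1.0:
        raise ValueError("nu must lie in [0, 1]")
    if nu == 0.0 or len(hap) == 0:
        return hap
    keep = rng.random(len(hap)) >= nu
    return Haplotype(tuple(m for m, k in zip(hap, keep) if k))


def apply_gains(
    hap: Haplotype,
    mu: float,
    L: int,
    k: float,
    theta: float,
    generation: int,
    rng: np.random.Generator,
    uid_source=None,
) -> Haplotype:
    """Add Poisson(mu) new mutations at uniform positions in [0, L)."""
    if mu < 0:
        raise ValueError("mu must be >= 0")
    n_new = rng.poisson(mu) if mu > 0 else 0
    if n_new == 0:
        return hap
    uids = uid_source if uid_source is not None else _uid_counter
    new = [
        SVMutation(
            uid=next(uids),
            position=int(rng.integers(0, L)),
            effect=float(sample_effect(k, theta, rng)),
            origin_generation=generation,
        )
        for _ in range(n_new)
    ]
    return Haplotype.of(list(hap) + new)


def _gamete(
    parent: Individual, params: SimParams, generation: int, rng: np.random.Generator
) -> Haplotype:
    bps = crossover_positions(params.r, params.L, rng)
    start = int(rng.integers(0, 2))
    g = recombine(parent.hap1, parent.hap2, bps, start)
    g = apply_losses(g, params.nu, rng)
    g = apply_gains(g, params.mu_per_gamete, params.L, params.k, params.theta, generation, rng)
    return g


def make_offspring(
    choice: MatingChoice,
    params: SimParams,
    rng: np.random.Generator,
    generation: int = 0,
) -> Individual:
    """Produce one offspring from a mating choice.

    Selfing uses two independent meioses of the same parent.  Offspring sex
    follows the mating mode: hermaphrodite under androdioecy, 50/50
    female/male under dioecy.  Offspring age is 0.
    """
    hap_a = _gamete(choice.parent1, params, generation, rng)
    hap_b = _gamete(choice.parent2, params, generation, rng)
    if params.dioecious:
        sex = FEMALE if rng.integers(0, 2) == 0 else MALE
    else:
        sex = HERMAPHRODITE
    return Individual(hap1=hap_a, hap2=hap_b, sex=sex, age=0)


def choose_mating(
    individuals: Sequence[Individual],
    o: float,
    mode: str,
    rng: np.random.Generator,
) -> MatingChoice:
    """Pick parents for one reproduction event.

    Androdioecious mode: with probability ``o`` two distinct uniformly chosen
    hermaphrodites outcross; otherwise one hermaphrodite selfs.  Dioecious
    mode: a uniform female is paired with a uniform male (``o`` is ignored).
    """
    if len(individuals) == 0:
        raise MatingFailure("empty population")
    if mode == "dioecious":
        females = [i for i in individuals if i.sex == FEMALE]
        males = [i for i in individuals if i.sex == MALE]
        if not females or not males:
            raise MatingFailure("dioecious mating requires at least one of each sex")
        mother = females[int(rng.integers(0, len(females)))]
        father = males[int(rng.integers(0, len(males)))]
        return MatingChoice(parent1=mother, parent2=father, is_selfing=False)
    n = len(individuals)
    outcross = n >= 2 and rng.random() < o
    i = int(rng.integers(0, n))
    if not outcross:
        p = individuals[i]
        return MatingChoice(parent1=p, parent2=p, is_selfing=True)
    j = (i + 1 + int(rng.integers(0, n - 1))) % n
    return MatingChoice(parent1=individuals[i], parent2=individuals[j], is_selfing=False)
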