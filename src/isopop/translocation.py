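"""Individual-based, age-structured simulation of small-population genetics.

Yearly cycle (survival -> aging -> translocation -> density-regulated
reproduction -> bookkeeping) over an age- and sex-structured population with
polygynous seasonal mating.  Used for two jobs:

* forecasting rare-allele retention and pedigree inbreeding under
  translocation schedules over a 100-year horizon, with the source modelled
  as an infinite gene pool of fixed allele frequencies; and
* executing demographic crash/recovery segments (two mortality events a few
  years apart, then exponential recovery to carrying capacity) at yearly
  resolution inside the generation-based forward simulator, where the two
  crashes are closer together than one generation.

Rare alleles are those at frequency <= ``rare_threshold`` in the source pool;
retention at year y is the fraction of them carried by at least one living
individual.  Pedigree inbreeding is tracked by the kinship recursion
(offspring inbreeding = kinship of its parents; founders and translocated
immigrants are assumed non-inbred and unrelated).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .synthetic import SourceSpec, draw_allele_frequencies, preset


class ReplicateExtinct(RuntimeError):
    """The population lost one sex entirely or fell below two individuals."""


@dataclass(frozen=True)
class LifeHistory:
    """Vital rates and mating system of the simulated species.

    Defaults describe a long-lived polygynous carnivore: reproduction from
    age 4 to 20 with reduced output past the onset of senescence at 16,
    annual adult survival 0.9, females breeding every other year with a mean
    litter of 2.5, balanced birth sex ratio.  Juvenile survival (ages 0-3)
    is set so a closed population at carrying capacity is demographically
    stationary.
    """

    age_first_repro: int = 4
    age_last_repro: int = 20
    age_senescence: int = 16
    senescent_output: float = 0.5
    adult_survival: float = 0.9
    juvenile_survival: float = 0.7
    juvenile_age_max: int = 3
    max_age: int = 30
    litter_mean: float = 2.5
    breeding_interval_years: int = 2
    sex_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.age_first_repro <= self.age_senescence
                <= self.age_last_repro):
            raise ValueError("need 0 < first repro <= senescence <= last repro")
        for s in (self.adult_survival, self.juvenile_survival):
            if not 0.0 < s <= 1.0:
                raise ValueError("survival rates must be in (0, 1]")

    def survival(self, ages: np.ndarray) -> np.ndarray:
        p = np.where(ages <= self.juvenile_age_max,
                     self.juvenile_survival, self.adult_survival)
        return np.where(ages >= self.max_age, 0.0, p)

    def stable_age_probabilities(self) -> np.ndarray:
        """Cumulative-survivorship (l_a) weights over ages 0..max_age."""
        ages = np.arange(self.max_age + 1)
        l = np.ones(self.max_age + 1)
        for a in range(1, self.max_age + 1):
            l[a] = l[a - 1] * self.survival(np.array([a - 1]))[0]
        return l / l.sum()


@dataclass(frozen=True)
class TranslocationSpec:
    """One translocation forecasting scenario."""

    n_start: int = 220
    carrying_capacity: int | None = None  # defaults to n_start
    horizon_years: int = 100
    batch_size: int = 0
    interval_years: int = 5
    rare_threshold: float = 0.05
    replicates: int = 1000
    seed: int = 0
    source: SourceSpec = field(default_factory=lambda: preset("SEON-like"))

    def __post_init__(self) -> None:
        if self.batch_size < 0:
            raise ValueError("batch_size must be >= 0")
        if self.interval_years <= 0:
            raise ValueError("interval_years must be > 0")
        if not 0.0 < self.rare_threshold <= 0.5:
            raise ValueError("rare_threshold must be in (0, 0.5]")

    @property
    def k(self) -> int:
        return self.carrying_capacity or self.n_start


@dataclass
class RetentionResult:
    """Replicate-mean trajectories (and 95% CIs) over the simulated years."""

    years: np.ndarray
    mean_size: np.ndarray
    mean_retention: np.ndarray
    mean_inbreeding: np.ndarray
    ci_size: np.ndarray  # (2, years)
    ci_retention: np.ndarray
    ci_inbreeding: np.ndarray
    n_extinct: int
    spec: TranslocationSpec
    per_replicate_retention: np.ndarray = None  # (reps, years)


class _Population:
    """Mutable state of one replicate."""

    def __init__(self, states, sex_female, ages, life, rng, track_kinship):
        self.states = states  # (n, L, 2) allele-state indices
        self.female = sex_female
        self.ages = ages
        self.life = life
        self.rng = rng
        n = len(ages)
        self.last_breed = rng.integers(0, life.breeding_interval_years + 1, n)
        self.track_kinship = track_kinship
        self.kinship = np.zeros((n, n)) + np.eye(n) * 0.5 if track_kinship else None
        self.inbreeding = np.zeros(n)
        self.guaranteed = np.zeros(n, dtype=bool)
        self.extinct = False

    @property
    def n(self) -> int:
        return len(self.ages)

    def _keep(self, mask: np.ndarray) -> None:
        self.states = self.states[mask]
        self.female = self.female[mask]
        self.ages = self.ages[mask]
        self.last_breed = self.last_breed[mask]
        self.inbreeding = self.inbreeding[mask]
        self.guaranteed = self.guaranteed[mask]
        if self.track_kinship:
            self.kinship = self.kinship[np.ix_(mask, mask)]

    def _check_viability(self) -> None:
        if self.n < 2 or self.female.all() or (~self.female).all():
            self.extinct = True

    def cull(self, fraction: float) -> None:
        """Uniform random mortality (a crash event)."""
        survive = self.rng.random(self.n) >= fraction
        self._keep(survive)
        self._check_viability()

    def natural_survival(self) -> None:
        p = self.life.survival(self.ages)
        self._keep(self.rng.random(self.n) < p)
        self._check_viability()

    def add_immigrants(self, batch: int, source_freqs: np.ndarray) -> None:
        life, rng = self.life, self.rng
        L, k = source_freqs.shape
        states = np.empty((batch, L, 2), dtype=np.int64)
        for j in range(L):
            states[:, j, :] = rng.choice(k, size=(batch, 2), p=source_freqs[j])
        female = np.arange(batch) % 2 == 0
        ages = rng.integers(life.age_first_repro, life.age_senescence, batch)
        self.states = np.concatenate([self.states, states])
        self.female = np.concatenate([self.female, female])
        self.ages = np.concatenate([self.ages, ages])
        self.last_breed = np.concatenate(
            [self.last_breed, np.full(batch, life.breeding_interval_years)]
        )
        self.inbreeding = np.concatenate([self.inbreeding, np.zeros(batch)])
        self.guaranteed = np.concatenate([self.guaranteed, np.ones(batch, bool)])
        if self.track_kinship:
            n_old = self.kinship.shape[0]
            new = np.zeros((n_old + batch, n_old + batch))
            new[:n_old, :n_old] = self.kinship
            new[n_old:, n_old:] = np.eye(batch) * 0.5
            self.kinship = new

    def reproduce(self, recruit_cap: int) -> int:
        """Density-regulated polygynous reproduction; returns recruits added."""
        life, rng = self.life, self.rng
        self.last_breed += 1  # years since last litter, before this season
        repro_age = (self.ages >= life.age_first_repro) & (
            self.ages <= life.age_last_repro
        )
        mothers_ok = self.female & repro_age & (
            (self.last_breed >= life.breeding_interval_years) | self.guaranteed
        )
        fathers_pool = np.flatnonzero(~self.female & repro_age)
        guaranteed_males = np.flatnonzero(~self.female & repro_age & self.guaranteed)
        m_candidates = np.flatnonzero(mothers_ok)
        self.guaranteed[:] = False
        if recruit_cap <= 0 or m_candidates.size == 0 or fathers_pool.size == 0:
            return 0

        litter_mean = np.where(
            self.ages[m_candidates] >= life.age_senescence,
            life.litter_mean * life.senescent_output,
            life.litter_mean,
        )
        litters = rng.poisson(litter_mean)
        whelped = litters > 0
        m_candidates, litters = m_candidates[whelped], litters[whelped]
        if m_candidates.size == 0:
            return 0
        fathers = rng.choice(fathers_pool, size=m_candidates.size)
        # translocated males are guaranteed at least one mating on arrival
        if guaranteed_males.size and fathers.size:
            slots = rng.choice(
                fathers.size,
                size=min(guaranteed_males.size, fathers.size),
                replace=False,
            )
            fathers[slots] = guaranteed_males[: slots.size]
        self.last_breed[m_candidates] = 0

        mother_of = np.repeat(m_candidates, litters)
        father_of = np.repeat(fathers, litters)
        n_cubs = mother_of.size
        if n_cubs > recruit_cap:
            keep = rng.choice(n_cubs, size=recruit_cap, replace=False)
            mother_of, father_of = mother_of[keep], father_of[keep]
        return self._append_offspring(mother_of, father_of)

    def reproduce_independent(self, n_recruits: int) -> int:
        """Recruitment without litter structure or breeding intervals: each
        recruit draws an independent (mother, father) pair uniformly among
        mature individuals.  This is the convention of generation-overlap
        crash simulators and carries much less family-size variance (hence
        weaker drift) than litter-structured breeding."""
        life, rng = self.life, self.rng
        mature = (self.ages >= life.age_first_repro) & (
            self.ages <= life.age_last_repro
        )
        mothers_pool = np.flatnonzero(self.female & mature)
        fathers_pool = np.flatnonzero(~self.female & mature)
        if n_recruits <= 0 or mothers_pool.size == 0 or fathers_pool.size == 0:
            return 0
        mother_of = rng.choice(mothers_pool, size=n_recruits)
        father_of = rng.choice(fathers_pool, size=n_recruits)
        return self._append_offspring(mother_of, father_of)

    def _append_offspring(self, mother_of: np.ndarray, father_of: np.ndarray) -> int:
        life, rng = self.life, self.rng
        n_cubs = mother_of.size
        gm = rng.integers(0, 2, size=(n_cubs, self.states.shape[1]))
        gf = rng.integers(0, 2, size=(n_cubs, self.states.shape[1]))
        cub_states = np.stack(
            [
                np.take_along_axis(self.states[mother_of], gm[:, :, None], 2)[:, :, 0],
                np.take_along_axis(self.states[father_of], gf[:, :, None], 2)[:, :, 0],
            ],
            axis=2,
        )
        cub_female = rng.random(n_cubs) < life.sex_ratio
        if self.track_kinship:
            K = self.kinship
            f_new = K[mother_of, father_of]
            cross = 0.5 * (K[mother_of, :] + K[father_of, :])
            kin_nn = 0.25 * (
                K[np.ix_(mother_of, mother_of)]
                + K[np.ix_(mother_of, father_of)]
                + K[np.ix_(father_of, mother_of)]
                + K[np.ix_(father_of, father_of)]
            )
            np.fill_diagonal(kin_nn, 0.5 * (1.0 + f_new))
            n_old = K.shape[0]
            new = np.empty((n_old + n_cubs, n_old + n_cubs))
            new[:n_old, :n_old] = K
            new[n_old:, :n_old] = cross
            new[:n_old, n_old:] = cross.T
            new[n_old:, n_old:] = kin_nn
            self.kinship = new
            self.inbreeding = np.concatenate([self.inbreeding, f_new])
        else:
            self.inbreeding = np.concatenate([self.inbreeding, np.zeros(n_cubs)])
        self.states = np.concatenate([self.states, cub_states])
        self.female = np.concatenate([self.female, cub_female])
        self.ages = np.concatenate([self.ages, np.zeros(n_cubs, dtype=np.int64)])
        self.last_breed = np.concatenate(
            [self.last_breed, np.zeros(n_cubs, dtype=np.int64)]
        )
        self.guaranteed = np.concatenate([self.guaranteed, np.zeros(n_cubs, bool)])
        return n_cubs


def _found_population(
    n: int,
    source_freqs: np.ndarray,
    life: LifeHistory,
    rng: np.random.Generator,
    track_kinship: bool,
    states: np.ndarray | None = None,
    female: np.ndarray | None = None,
) -> _Population:
    L, k = source_freqs.shape
    if states is None:
        states = np.empty((n, L, 2), dtype=np.int64)
        for j in range(L):
            states[:, j, :] = rng.choice(k, size=(n, 2), p=source_freqs[j])
    if female is None:
        female = np.arange(n) % 2 == 0
    ages = rng.choice(
        life.max_age + 1, size=n, p=life.stable_age_probabilities()
    )
    return _Population(states, female, ages, life, rng, track_kinship)


def _rare_alleles(freqs: np.ndarray, threshold: float) -> list[np.ndarray]:
    """Per locus, the allele-state indices rare in the source (0 < f <= thr)."""
    return [np.flatnonzero((f > 0) & (f <= threshold)) for f in freqs]


def _retention(pop: _Population, rare: list[np.ndarray]) -> float:
    total = sum(len(r) for r in rare)
    if total == 0:
        return 1.0
    if pop.extinct or pop.n == 0:
        return 0.0
    present = 0
    for j, r in enumerate(rare):
        if len(r) == 0:
            continue
        seen = np.unique(pop.states[:, j, :])
        present += np.isin(r, seen).sum()
    return present / total


def simulate_retention(
    spec: TranslocationSpec,
    life: LifeHistory | None = None,
    track_inbreeding: bool = True,
) -> RetentionResult:
    """Forecast population size, rare-allele retention and inbreeding.

    Runs ``spec.replicates`` independent replicates of the yearly cycle over
    ``spec.horizon_years`` years.  Translocated individuals are breeding-age
    adults drawn from the source gene pool and are guaranteed a breeding
    opportunity in their arrival year.  Extinct replicates stay extinct and
    contribute zero retention from the year of extinction on.
    """
    life = life or LifeHistory()
    src = replace(spec.source, seed=spec.seed)
    freqs = draw_allele_frequencies(src)
    rare = _rare_alleles(freqs, spec.rare_threshold)
    years = np.arange(spec.horizon_years + 1)
    n_y = len(years)
    sizes = np.zeros((spec.replicates, n_y))
    rets = np.zeros((spec.replicates, n_y))
    inbr = np.zeros((spec.replicates, n_y))
    n_extinct = 0

    for rep in range(spec.replicates):
        rng = np.random.default_rng((spec.seed, 10_000 + rep))
        pop = _found_population(spec.n_start, freqs, life, rng, track_inbreeding)
        sizes[rep, 0] = pop.n
        rets[rep, 0] = _retention(pop, rare)
        inbr[rep, 0] = pop.inbreeding.mean()
        for year in years[1:]:
            if not pop.extinct:
                pop.natural_survival()
            if not pop.extinct:
                pop.ages += 1
                if (
                    spec.batch_size > 0
                    and year % spec.interval_years == 0
                ):
                    pop.add_immigrants(spec.batch_size, freqs)
                pop.reproduce(recruit_cap=spec.k - pop.n)
            sizes[rep, year] = 0 if pop.extinct else pop.n
            rets[rep, year] = _retention(pop, rare)
            inbr[rep, year] = (
                np.nan if pop.extinct else pop.inbreeding.mean()
            )
        if pop.extinct:
            n_extinct += 1

    def ci(mat: np.ndarray) -> np.ndarray:
        m = np.nanmean(mat, axis=0)
        se = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(mat.shape[0])
        return np.stack([m - 1.96 * se, m + 1.96 * se])

    return RetentionResult(
        years=years,
        mean_size=sizes.mean(axis=0),
        mean_retention=rets.mean(axis=0),
        mean_inbreeding=np.nanmean(inbr, axis=0),
        ci_size=ci(sizes),
        ci_retention=ci(rets),
        ci_inbreeding=ci(inbr),
        n_extinct=n_extinct,
        spec=spec,
        per_replicate_retention=rets,
    )


def crash_recovery(
    states: np.ndarray,
    ma: float,
    mb: float,
    growth_rate: float,
    years: int,
    life: LifeHistory | None = None,
    rng: np.random.Generator | None = None,
    carrying_capacity: int | None = None,
    crash_gap_years: int = 5,
    migrants_per_year: float = 0.0,
    migrant_pool: np.ndarray | None = None,
) -> np.ndarray:
    """Two mortality events followed by capped exponential recovery.

    ``states`` is a diploid gene pool (n, L, 2) of allele-state indices; the
    fractions ``ma`` and ``mb`` die at years 0 and ``crash_gap_years``.
    Afterwards recruitment is capped so the census grows at most by
    ``growth_rate`` per year up to ``carrying_capacity`` (default: the
    starting size).  Optional migration draws Poisson(``migrants_per_year``)
    individuals per year uniformly from ``migrant_pool``.  Returns the
    surviving gene pool; raises ReplicateExtinct if either sex is lost.
    """
    if not (0.0 <= ma < 1.0 and 0.0 <= mb < 1.0):
        raise ValueError("crash mortalities must be in [0, 1)")
    if growth_rate < 0:
        raise ValueError("growth rate must be >= 0")
    life = life or LifeHistory()
    rng = rng or np.random.default_rng()
    k_cap = carrying_capacity or states.shape[0]
    dummy_freqs = np.ones((states.shape[1], 1))  # founders carry real states
    pop = _found_population(
        states.shape[0], dummy_freqs, life, rng, track_kinship=False,
        states=states.copy(),
    )
    scheduled = pop.n  # census the growth schedule aims at this year
    for year in range(years):
        if year == 0 and ma > 0:
            pop.cull(ma)
            scheduled = pop.n
        if year == crash_gap_years and mb > 0:
            pop.cull(mb)
            scheduled = pop.n
        if pop.extinct:
            raise ReplicateExtinct(f"population extinct at year {year}")
        pop.natural_survival()
        if pop.extinct:
            raise ReplicateExtinct(f"population extinct at year {year}")
        pop.ages += 1
        if migrants_per_year > 0 and migrant_pool is not None:
            n_mig = rng.poisson(migrants_per_year)
            if n_mig > 0:
                idx = rng.integers(0, migrant_pool.shape[0], n_mig)
                pop.states = np.concatenate([pop.states, migrant_pool[idx]])
                pop.female = np.concatenate(
                    [pop.female, rng.random(n_mig) < 0.5]
                )
                pop.ages = np.concatenate(
                    [pop.ages, np.full(n_mig, life.age_first_repro)]
                )
                pop.last_breed = np.concatenate(
                    [pop.last_breed,
                     np.full(n_mig, life.breeding_interval_years)]
                )
                pop.inbreeding = np.concatenate(
                    [pop.inbreeding, np.zeros(n_mig)]
                )
                pop.guaranteed = np.concatenate(
                    [pop.guaranteed, np.ones(n_mig, bool)]
                )
        scheduled = min(k_cap, int(np.ceil(scheduled * (1.0 + growth_rate))))
        pop.reproduce_independent(scheduled - pop.n)
    if pop.extinct or pop.n < 2:
        raise ReplicateExtinct("population did not survive the crash segment")
    return pop.states
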