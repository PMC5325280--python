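"""Allelic-data bottleneck tests.

Two complementary signals of a recent demographic crash:

* **Heterozygosity excess** - after a bottleneck, rare alleles vanish faster
  than heterozygosity falls, so observed gene diversity exceeds the
  equilibrium value H_EQ implied by the surviving allele count.  H_EQ is
  obtained by coalescent simulation conditioned on the observed number of
  alleles; the across-locus signal is assessed with a one-tailed Wilcoxon
  signed-rank test, plus the qualitative mode-shift indicator.

* **M-ratio** - the number of distinct alleles k over the span of allelic
  states r shrinks after a bottleneck because drift removes alleles without
  shrinking the size range.  The observed mean M across loci is compared with
  a critical value Mc, the 5th percentile of mean M in equilibrium
  populations simulated under a two-phase mutation model at pre-bottleneck
  theta = 4 Ne mu.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats

from .coalescent import sim_k_het, sim_mean_m
from .genotype import MISSING, GenotypeTable
from .mutation import MutationModel


class SimulationError(RuntimeError):
    """Raised when a null simulation cannot produce usable replicates."""


# -- equilibrium heterozygosity, conditional on allele count -------------------


def _kernel_params(model: MutationModel) -> tuple[float, float, bool]:
    """(p_multi, geom_p, iam) arguments of the coalescent kernel."""
    if model.kind == "KAM":
        # many-state KAM behaves as an infinite-alleles process for the
        # purpose of the equilibrium null; label every mutation fresh
        return 0.0, 1.0, True
    if model.kind == "SMM":
        return 0.0, 1.0, False
    return model.p_multistep, model.geom_p, False


@lru_cache(maxsize=512)
def _tune_theta(
    n_genes: int,
    k_observed: int,
    kind: str,
    p_multistep: float,
    delta_g: float,
    pilot: int = 400,
) -> float:
    """Bisection on log(theta) so simulated allele counts centre on k_observed.

    Deterministic (fixed internal seeds) and cached: the tuned theta depends
    only on the sample size, the target allele count and the mutation model.
    """
    model = MutationModel(kind=kind, p_multistep=p_multistep, delta_g=delta_g)
    p_multi, geom_p, iam = _kernel_params(model)

    def mean_k(log_theta: float, salt: int) -> float:
        ks, _ = sim_k_het(pilot, n_genes, float(np.exp(log_theta)),
                          p_multi, geom_p, iam, 90_001 + salt)
        return float(ks.mean())

    lo, hi = np.log(1e-3), np.log(500.0)
    for it in range(40):
        mid = 0.5 * (lo + hi)
        if mean_k(mid, it) < k_observed:
            lo = mid
        else:
            hi = mid
    return float(np.exp(0.5 * (lo + hi)))


def simulate_heq(
    n_genes: int,
    k_observed: int,
    model: MutationModel,
    reps: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Sample of equilibrium heterozygosities conditional on k_observed alleles.

    theta is tuned adaptively so simulated allele counts concentrate on the
    observed count, then replicates are retained by rejection until ``reps``
    draws with exactly ``k_observed`` alleles are collected.
    """
    if not 2 <= k_observed <= n_genes:
        raise ValueError("need 2 <= k_observed <= n_genes")
    theta = _tune_theta(n_genes, k_observed, model.kind,
                        model.p_multistep, model.delta_g)
    p_multi, geom_p, iam = _kernel_params(model)
    out: list[float] = []
    attempts = 0
    batch = max(4 * reps, 500)
    salt = 1000
    while len(out) < reps:
        ks, hets = sim_k_het(batch, n_genes, theta, p_multi, geom_p, iam,
                             (seed + salt) % 2**31)
        salt += 1
        out.extend(hets[ks == k_observed].tolist())
        attempts += batch
        if attempts >= 400 * reps and len(out) < max(1, attempts // 1000):
            raise SimulationError(
                f"acceptance rate below 0.1% conditioning on k={k_observed} "
                f"(n={n_genes}); adjust the theta search range"
            )
        if attempts >= 2000 * reps:
            raise SimulationError("conditional simulation failed to converge")
    return np.asarray(out[:reps])


# -- heterozygosity-excess test -------------------------------------------------


@dataclass
class BottleneckReport:
    """Per-locus heterozygosity-excess quantities and the across-locus tests."""

    loci: list[str]
    he_observed: np.ndarray
    heq_mean: np.ndarray
    heq_sd: np.ndarray
    standardized: np.ndarray  # (He - mean H_EQ) / sd(H_EQ)
    n_deficiency: int
    n_excess: int
    wilcoxon_p_excess: float
    mode_shift: bool
    model: MutationModel = field(repr=False, default=None)


def _observed_locus_stats(table: GenotypeTable, population: str):
    sub = table.subset(population)
    rows = []
    for j, locus in enumerate(sub.loci):
        calls = sub.calls[:, j, :]
        flat = calls[calls != MISSING]
        if flat.size < 4:
            warnings.warn(f"locus {locus.name!r}: too few gene copies; excluded")
            continue
        vals, counts = np.unique(flat, return_counts=True)
        if vals.size < 2:
            warnings.warn(f"locus {locus.name!r}: monomorphic; excluded")
            continue
        n = flat.size
        p = counts / n
        he = (n / (n - 1)) * (1.0 - np.sum(p**2))
        rows.append((locus, n, vals, counts, he))
    return rows


def mode_shift(table: GenotypeTable, population: str) -> bool:
    """True when the rarest allele-frequency class (0-0.1) is no longer the
    most populated class of the pooled allele-frequency spectrum."""
    counts = np.zeros(10, dtype=int)
    for _, n, vals, cnts, _ in _observed_locus_stats(table, population):
        classes = np.minimum((cnts / n * 10).astype(int), 9)
        for c in classes:
            counts[c] += 1
    if counts.sum() == 0:
        return False
    return int(np.argmax(counts)) != 0


def het_excess_test(
    table: GenotypeTable,
    population: str,
    model: MutationModel,
    reps: int = 10_000,
    seed: int = 0,
) -> BottleneckReport:
    """Heterozygosity-excess bottleneck test for one population.

    Per polymorphic locus the observed unbiased expected heterozygosity is
    compared with the simulated equilibrium distribution conditional on the
    observed allele count; significance of an across-locus excess is the
    one-tailed Wilcoxon signed-rank probability.
    """
    rows = _observed_locus_stats(table, population)
    if len(rows) < 4:
        raise ValueError("need at least 4 polymorphic loci")
    names, he_obs, mu, sd = [], [], [], []
    for idx, (locus, n, vals, counts, he) in enumerate(rows):
        heq = simulate_heq(n, len(vals), model, reps=reps,
                           seed=(seed + 7919 * idx) % 2**31)
        names.append(locus.name)
        he_obs.append(he)
        mu.append(float(heq.mean()))
        sd.append(float(heq.std(ddof=1)))
    he_obs, mu, sd = map(np.asarray, (he_obs, mu, sd))
    standardized = (he_obs - mu) / np.where(sd > 0, sd, np.nan)
    diffs = he_obs - mu
    n_exc = int((diffs > 0).sum())
    n_def = int((diffs < 0).sum())
    p = float(stats.wilcoxon(diffs, alternative="greater").pvalue)
    return BottleneckReport(
        loci=names,
        he_observed=he_obs,
        heq_mean=mu,
        heq_sd=sd,
        standardized=standardized,
        n_deficiency=n_def,
        n_excess=n_exc,
        wilcoxon_p_excess=p,
        mode_shift=mode_shift(table, population),
        model=model,
    )


# -- M-ratio --------------------------------------------------------------------


@dataclass
class MRatioResult:
    loci: list[str]
    k: np.ndarray
    r: np.ndarray
    m_per_locus: np.ndarray
    mean_m: float
    mc: float | None = None
    p_below: float | None = None
    theta: float | None = None
    delta_g: float | None = None
    p_g: float | None = None
    replicates: int | None = None


def m_ratio(table: GenotypeTable, population: str) -> MRatioResult:
    """Observed M = k/r per locus and across-locus mean.

    r counts allelic states inclusively: (max size - min size)/motif + 1, so
    a locus with every intermediate state present has M = 1.  Monomorphic
    loci are included with M = 1 (k = r = 1) and a warning.
    """
    sub = table.subset(population)
    names, ks, rs = [], [], []
    for j, locus in enumerate(sub.loci):
        calls = sub.calls[:, j, :]
        flat = calls[calls != MISSING]
        if flat.size == 0:
            warnings.warn(f"locus {locus.name!r}: no data; excluded")
            continue
        vals = np.unique(flat)
        if vals.size == 1:
            warnings.warn(f"locus {locus.name!r}: monomorphic; M = 1 by convention")
        span = int((vals.max() - vals.min()) // locus.motif_length) + 1
        names.append(locus.name)
        ks.append(vals.size)
        rs.append(span)
    if not names:
        raise ValueError("no genotyped locus")
    ks, rs = np.asarray(ks), np.asarray(rs)
    m = ks / rs
    return MRatioResult(loci=names, k=ks, r=rs, m_per_locus=m, mean_m=float(m.mean()))


def critical_m(
    theta: float,
    n_genes: int,
    n_loci: int,
    delta_g: float = 3.1,
    p_g: float = 0.1,
    reps: int = 10_000,
    seed: int = 0,
    observed_m: float | None = None,
) -> tuple[float, float | None]:
    """Critical M-ratio from an equilibrium two-phase-model null.

    Simulates ``reps`` equilibrium populations (coalescent of ``n_genes``
    copies per locus, mutations at rate theta/2 per lineage-time unit; a
    mutation is a single repeat step with probability 1 - p_g, else a
    multi-step of at least 2 repeat units, 1 + Geometric with mean delta_g).
    Each locus is conditioned on being polymorphic, since monomorphic loci
    never enter an empirical M calculation.  Per replicate the mean M = k/r
    over ``n_loci`` loci is recorded; Mc is the 5th percentile of that null
    distribution.  When ``observed_m`` is given the second return value is
    the fraction of null replicates below it.
    """
    if theta < 1e-4:
        raise ValueError(
            "theta too small: essentially every locus is monomorphic and the "
            "polymorphism-conditioned null cannot be sampled"
        )
    if delta_g <= 2.0:
        raise ValueError("delta_g must exceed 2 repeat units")
    if reps < 1000:
        raise ValueError("reps must be >= 1000")
    means = sim_mean_m(reps, n_loci, n_genes, float(theta), float(p_g),
                       1.0 / (float(delta_g) - 1.0), seed % 2**31)
    mc = float(np.percentile(means, 5.0))
    p = float(np.mean(means <= observed_m)) if observed_m is not None else None
    return mc, p


def m_ratio_test(
    table: GenotypeTable,
    population: str,
    theta: float,
    delta_g: float = 3.1,
    p_g: float = 0.1,
    reps: int = 10_000,
    seed: int = 0,
) -> MRatioResult:
    """Observed M plus its simulated critical value and tail probability."""
    res = m_ratio(table, population)
    n_genes = 0
    sub = table.subset(population)
    counts = [(sub.calls[:, j, :] != MISSING).sum() for j in range(sub.n_loci)]
    n_genes = int(np.median([c for c in counts if c > 0]))
    mc, p = critical_m(theta, n_genes, len(res.loci), delta_g, p_g,
                       reps=reps, seed=seed, observed_m=res.mean_m)
    res.mc, res.p_below = mc, p
    res.theta, res.delta_g, res.p_g, res.replicates = theta, delta_g, p_g, reps
    return res
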