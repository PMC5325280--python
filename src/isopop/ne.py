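"""Effective population size estimators.

Long-term Ne from equilibrium heterozygosity (infinite-alleles and stepwise
mutation closed forms), contemporary Ne from linkage disequilibrium (Burrows
composite r-squared with the random-mating small-sample bias correction and a
jackknife over locus pairs) and from temporal allele-frequency change (the
moment estimator under sampling plan II), plus the per-generation inbreeding
increment 1/(2 Ne).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype import MISSING, GenotypeTable


class EstimateUndefined(ValueError):
    pass


@dataclass
class NeEstimate:
    method: str  # IAM | SMM | LD | temporal_moment
    point: float  # may be inf when there is no drift/LD signal
    ci: tuple[float, float] | None = None
    settings: dict = field(default_factory=dict)


# -- long-term (mutation-drift equilibrium) -------------------------------------


def ne_long_term(he: float, mu: float, model: str = "IAM") -> float:
    """Closed-form long-term Ne from equilibrium expected heterozygosity.

    IAM: Ne = He / (4 mu (1 - He)).  SMM: Ne = [1/(1 - He)^2 - 1] / (8 mu).
    """
    if not 0.0 <= he < 1.0:
        raise EstimateUndefined("He must be in [0, 1)")
    if mu <= 0:
        raise EstimateUndefined("mutation rate must be positive")
    if model == "IAM":
        return he / (4.0 * mu * (1.0 - he))
    if model == "SMM":
        return (1.0 / (1.0 - he) ** 2 - 1.0) / (8.0 * mu)
    raise ValueError(f"unknown long-term model {model!r}")


def delta_f(ne: float) -> float:
    """Per-generation increment of the inbreeding coefficient, 1/(2 Ne)."""
    if ne <= 0:
        raise EstimateUndefined("Ne must be positive")
    return 1.0 / (2.0 * ne) if np.isfinite(ne) else 0.0


# -- linkage disequilibrium method ----------------------------------------------


def _allele_dosages(table: GenotypeTable, maf: float) -> list[np.ndarray]:
    """Per locus, an (n_alleles_kept, n_individuals) dosage matrix (NaN when
    ungenotyped), keeping alleles with frequency in [maf, 1 - maf]."""
    out = []
    n = table.n_individuals
    for j in range(table.n_loci):
        calls = table.calls[:, j, :]
        genotyped = calls[:, 0] != MISSING
        flat = calls[genotyped].ravel()
        if flat.size == 0:
            out.append(np.empty((0, n)))
            continue
        vals, counts = np.unique(flat, return_counts=True)
        freqs = counts / flat.size
        keep = vals[(freqs >= maf) & (freqs <= 1.0 - maf)]
        rows = np.full((len(keep), n), np.nan)
        for r_i, a in enumerate(keep):
            dos = (calls == a).sum(axis=1).astype(float)
            dos[~genotyped] = np.nan
            rows[r_i] = dos
        out.append(rows)
    return out


def _pair_r2(d1: np.ndarray, d2: np.ndarray) -> tuple[float, int] | None:
    """Mean Burrows composite r^2 over allele pairs of one locus pair."""
    vals = []
    for x in d1:
        for y in d2:
            ok = ~np.isnan(x) & ~np.isnan(y)
            s = ok.sum()
            if s < 2:
                continue
            xs, ys = x[ok], y[ok]
            p, q = xs.mean() / 2.0, ys.mean() / 2.0
            varp, varq = p * (1 - p), q * (1 - q)
            if varp <= 0 or varq <= 0:
                continue
            # Burrows composite disequilibrium with the n/(n-1) correction
            delta = (s / (s - 1.0)) * ((xs * ys).mean() / 2.0 - 2.0 * p * q)
            vals.append(delta**2 / (varp * varq))
    if not vals:
        return None
    return float(np.mean(vals)), len(vals)


def _solve_ne_ld(r2_prime: float) -> float:
    """Invert E[r2'] = 1/(3 Ne) + 0.69/Ne^2 (random mating, S >= 30 branch)."""
    if r2_prime <= 0:
        return float("inf")
    return (1.0 / 3.0 + np.sqrt(1.0 / 9.0 + 2.76 * r2_prime)) / (2.0 * r2_prime)


def ne_ld(
    table: GenotypeTable,
    population: str,
    maf: float = 0.05,
    jackknife: bool = True,
) -> NeEstimate:
    """Contemporary Ne from background linkage disequilibrium.

    Burrows' composite r-squared is averaged over allele pairs across all
    locus pairs after screening alleles below the ``maf`` cutoff; the
    no-drift sampling expectation 1/S + 3.19/S^2 is subtracted and the
    random-mating quadratic is inverted for Ne.  The CI is a jackknife over
    locus pairs.  A non-positive corrected r-squared means no detectable
    drift signal and yields an infinite estimate.
    """
    sub = table.subset(population)
    dosages = _allele_dosages(sub, maf)
    poly = [d for d in dosages if d.shape[0] > 0]
    if len(poly) < 2:
        raise EstimateUndefined("need at least 2 polymorphic loci after MAF screen")
    s_mean = float(np.mean([np.isfinite(d).all(axis=0).sum() for d in poly]))

    pair_stats = []
    for i in range(len(poly) - 1):
        for j in range(i + 1, len(poly)):
            res = _pair_r2(poly[i], poly[j])
            if res is not None:
                pair_stats.append(res)
    if not pair_stats:
        raise EstimateUndefined("no usable locus pair")

    def estimate(stats: list[tuple[float, int]]) -> float:
        w = np.array([n for _, n in stats], dtype=float)
        r2 = np.array([v for v, _ in stats])
        r2_mean = float(np.sum(w * r2) / np.sum(w))
        expected = 1.0 / s_mean + 3.19 / s_mean**2
        return _solve_ne_ld(r2_mean - expected)

    point = estimate(pair_stats)
    ci = None
    if jackknife and len(pair_stats) > 2:
        # jackknife over locus pairs on the corrected r2 scale
        loo = [estimate(pair_stats[:i] + pair_stats[i + 1:])
               for i in range(len(pair_stats))]
        finite = np.array([v for v in loo if np.isfinite(v)])
        if finite.size >= 2 and np.isfinite(point):
            n_j = len(loo)
            # jackknife on 1/Ne (approximately normal), back-transformed
            inv = 1.0 / np.where(np.isfinite(loo), loo, np.inf)
            inv_mean = inv.mean()
            se = np.sqrt((n_j - 1) / n_j * np.sum((inv - inv_mean) ** 2))
            lo_inv, hi_inv = 1.0 / point - 1.96 * se, 1.0 / point + 1.96 * se
            upper = 1.0 / lo_inv if lo_inv > 0 else float("inf")
            lower = 1.0 / hi_inv if hi_inv > 0 else float("inf")
            ci = (float(lower), float(upper))
    return NeEstimate(
        method="LD",
        point=point,
        ci=ci,
        settings={"maf": maf, "S": s_mean, "n_locus_pairs": len(pair_stats)},
    )


# -- temporal moment method ------------------------------------------------------


def _temporal_fc(table0: GenotypeTable, table1: GenotypeTable) -> tuple[float, int, float, float]:
    """Mean standardized allele-frequency variance Fc across alleles and loci."""
    if [l.name for l in table0.loci] != [l.name for l in table1.loci]:
        raise EstimateUndefined("temporal samples must share loci")
    fc_vals = []
    s0_list, s1_list = [], []
    for j in range(table0.n_loci):
        c0, c1 = table0.calls[:, j, :], table1.calls[:, j, :]
        f0, f1 = c0[c0 != MISSING], c1[c1 != MISSING]
        if f0.size == 0 or f1.size == 0:
            continue
        alleles = np.union1d(np.unique(f0), np.unique(f1))
        if alleles.size < 2:
            continue
        s0_list.append(f0.size / 2.0)
        s1_list.append(f1.size / 2.0)
        for a in alleles:
            x = (f0 == a).mean()
            y = (f1 == a).mean()
            z = 0.5 * (x + y)
            denom = z - x * y
            if denom > 0:
                fc_vals.append((x - y) ** 2 / denom)
    if not fc_vals:
        raise EstimateUndefined("no shared polymorphic locus between samples")
    return (float(np.mean(fc_vals)), len(fc_vals),
            float(np.mean(s0_list)), float(np.mean(s1_list)))


def ne_temporal_moment(
    table_t0: GenotypeTable,
    table_t1: GenotypeTable,
    t: int = 1,
) -> NeEstimate:
    """Moment-based temporal Ne under sampling plan II.

    Fc = mean over alleles of (x - y)^2 / ((x + y)/2 - x y); the estimator is
    Ne = t / (2 [Fc - 1/(2 S0) - 1/(2 S1)]).  A bracketed term <= 0 (frequency
    change no larger than sampling noise) yields an infinite estimate.
    """
    if t < 1:
        raise EstimateUndefined("t must be >= 1 generation")
    fc, n_alleles, s0, s1 = _temporal_fc(table_t0, table_t1)
    denom = fc - 1.0 / (2.0 * s0) - 1.0 / (2.0 * s1)
    point = t / (2.0 * denom) if denom > 0 else float("inf")
    return NeEstimate(
        method="temporal_moment",
        point=point,
        settings={"Fc": fc, "n_alleles": n_alleles, "S0": s0, "S1": s1, "t": t},
    )
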