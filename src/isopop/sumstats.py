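"""Diversity, differentiation, inbreeding and relatedness statistics.

The eight indices compared between empirical and simulated populations:
rarefied allelic richness, observed/expected heterozygosity, Weir-Cockerham
F_ST, Jost's D, F_IS (Nei and Weir variants) and mean Queller-Goodnight
pairwise relatedness, plus a locus-resampling percentile bootstrap for their
confidence intervals.

All estimators operate on non-missing gene copies only.  Loci with fewer than
two genotyped individuals in a population are excluded (with a warning) from
locus-averaged statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Callable, Sequence

import numpy as np

from .genotype import MISSING, GenotypeTable


class UndefinedStatistic(ValueError):
    """Raised when a statistic has no defined value on the given data."""


# -- helpers -------------------------------------------------------------------


def _locus_counts(table: GenotypeTable, j: int) -> tuple[np.ndarray, np.ndarray, int]:
    """(allele sizes, gene-copy counts, n genotyped individuals) at locus j."""
    calls = table.calls[:, j, :]
    genotyped = calls[:, 0] != MISSING
    flat = calls[genotyped].ravel()
    vals, counts = np.unique(flat, return_counts=True)
    return vals, counts, int(genotyped.sum())


def _usable_loci(table: GenotypeTable, min_individuals: int = 2) -> list[int]:
    keep = []
    for j in range(table.n_loci):
        _, _, n = _locus_counts(table, j)
        if n >= min_individuals:
            keep.append(j)
        else:
            warnings.warn(
                f"locus {table.loci[j].name!r}: fewer than {min_individuals} "
                "genotyped individuals; excluded",
                stacklevel=3,
            )
    if not keep:
        raise UndefinedStatistic("no locus with enough genotyped individuals")
    return keep


def _resample_loci(table: GenotypeTable, idx: Sequence[int]) -> GenotypeTable:
    return GenotypeTable(
        table.individuals,
        table.populations,
        [table.loci[j] for j in idx],
        table.calls[:, list(idx), :],
        validate=False,
    )


# -- diversity -----------------------------------------------------------------


def heterozygosities(
    table: GenotypeTable, population: str
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Observed and unbiased expected heterozygosity.

    Returns per-locus arrays (H_O, H_E) over usable loci and their means.
    H_E carries the small-sample factor 2n/(2n-1).
    """
    sub = table.subset(population)
    loci = _usable_loci(sub)
    ho = np.empty(len(loci))
    he = np.empty(len(loci))
    for out_j, j in enumerate(loci):
        calls = sub.calls[:, j, :]
        genotyped = calls[:, 0] != MISSING
        n = genotyped.sum()
        ho[out_j] = (calls[genotyped, 0] != calls[genotyped, 1]).mean()
        _, counts, _ = _locus_counts(sub, j)
        p = counts / counts.sum()
        he[out_j] = (2 * n / (2 * n - 1)) * (1.0 - np.sum(p**2))
    return ho, he, float(ho.mean()), float(he.mean())


def allelic_richness(
    table: GenotypeTable, population: str, g: int | None = None
) -> tuple[np.ndarray, float]:
    """Rarefied allelic richness Na(g) per locus and its mean.

    Na(g) = sum_a [1 - C(N - N_a, g) / C(N, g)], the expected number of
    distinct alleles in a subsample of g gene copies.  ``g`` defaults to the
    smallest per-locus genotyped gene count within the population; for
    cross-population comparisons pass the common minimum explicitly.
    """
    sub = table.subset(population)
    loci = _usable_loci(sub)
    gene_counts = []
    for j in loci:
        _, counts, _ = _locus_counts(sub, j)
        gene_counts.append(int(counts.sum()))
    if g is None:
        g = min(gene_counts)
    if g < 1 or g > min(gene_counts):
        raise UndefinedStatistic(
            f"rarefaction size g={g} exceeds available gene copies "
            f"(min {min(gene_counts)})"
        )
    na = np.empty(len(loci))
    for out_j, j in enumerate(loci):
        _, counts, _ = _locus_counts(sub, j)
        n_genes = int(counts.sum())
        denom = comb(n_genes, g)
        na[out_j] = sum(1.0 - comb(n_genes - int(c), g) / denom for c in counts)
    return na, float(na.mean())


# -- differentiation -----------------------------------------------------------


def _wc_components(
    table: GenotypeTable, pops: Sequence[str]
) -> tuple[float, float, float]:
    """Summed Weir-Cockerham variance components (a, b, c) over alleles/loci."""
    subs = [table.subset(p) for p in pops]
    r = len(subs)
    A = B = C = 0.0
    any_poly = False
    for j in range(table.n_loci):
        per_pop = []
        for sub in subs:
            calls = sub.calls[:, j, :]
            genotyped = calls[:, 0] != MISSING
            if genotyped.sum() < 1:
                per_pop = []
                break
            per_pop.append(calls[genotyped])
        if not per_pop:
            continue
        alleles = np.unique(np.concatenate([c.ravel() for c in per_pop]))
        if alleles.size < 2:
            continue
        any_poly = True
        n_i = np.array([c.shape[0] for c in per_pop], dtype=float)
        n_bar = n_i.mean()
        n_c = (r * n_bar - np.sum(n_i**2) / (r * n_bar)) / (r - 1) if r > 1 else n_bar
        for a in alleles:
            p_i = np.array([(c == a).mean() for c in per_pop])
            h_i = np.array(
                [((c[:, 0] == a) ^ (c[:, 1] == a)).mean() for c in per_pop]
            )
            p_bar = np.sum(n_i * p_i) / (r * n_bar)
            h_bar = np.sum(n_i * h_i) / (r * n_bar)
            if r > 1:
                s2 = np.sum(n_i * (p_i - p_bar) ** 2) / ((r - 1) * n_bar)
                A += (n_bar / n_c) * (
                    s2
                    - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4)
                    / (n_bar - 1)
                )
                B += (n_bar / (n_bar - 1)) * (
                    p_bar * (1 - p_bar)
                    - s2 * (r - 1) / r
                    - h_bar * (2 * n_bar - 1) / (4 * n_bar)
                )
            else:
                B += (n_bar / (n_bar - 1)) * (
                    p_bar * (1 - p_bar) - h_bar * (2 * n_bar - 1) / (4 * n_bar)
                )
            C += h_bar / 2
    if not any_poly:
        raise UndefinedStatistic("no shared polymorphic locus")
    return A, B, C


def pairwise_fst(table: GenotypeTable, pop_a: str, pop_b: str) -> float:
    """Weir-Cockerham theta, variance components summed across loci."""
    a, b, c = _wc_components(table, [pop_a, pop_b])
    denom = a + b + c
    if denom == 0:
        raise UndefinedStatistic("zero total variance; F_ST undefined")
    return a / denom


def jost_d(table: GenotypeTable, pop_a: str, pop_b: str) -> float:
    """Jost's estimated D for two populations.

    Per locus: D_est = ((Ht_est - Hs_est) / (1 - Hs_est)) * k/(k-1) with
    Nei-Chesser small-sample estimators (harmonic-mean sample size n~),
      Hs_est = (2n~ / (2n~ - 1)) Hs,   Ht_est = Ht + Hs_est / (2 n~ k).
    Across loci D is combined by the harmonic mean of per-locus values
    (arithmetic fallback when a locus value is non-positive).
    """
    subs = [table.subset(p) for p in (pop_a, pop_b)]
    k = 2
    d_loci = []
    for j in range(table.n_loci):
        per_pop = []
        for sub in subs:
            calls = sub.calls[:, j, :]
            genotyped = calls[:, 0] != MISSING
            if genotyped.sum() < 1:
                per_pop = []
                break
            per_pop.append(calls[genotyped])
        if not per_pop:
            continue
        alleles = np.unique(np.concatenate([c.ravel() for c in per_pop]))
        if alleles.size < 2:
            continue
        n_i = np.array([c.shape[0] for c in per_pop], dtype=float)
        n_t = k / np.sum(1.0 / n_i)  # harmonic mean
        p = np.stack([[(c == a).mean() for a in alleles] for c in per_pop])
        hs = 1.0 - np.mean(np.sum(p**2, axis=1))
        ht = 1.0 - np.sum(np.mean(p, axis=0) ** 2)
        hs_est = (2 * n_t / (2 * n_t - 1)) * hs
        ht_est = ht + hs_est / (2 * n_t * k)
        if 1.0 - hs_est <= 0:
            continue
        d_loci.append(((ht_est - hs_est) / (1.0 - hs_est)) * (k / (k - 1)))
    if not d_loci:
        raise UndefinedStatistic("no shared polymorphic locus")
    d = np.asarray(d_loci)
    if np.all(d > 0):
        return float(len(d) / np.sum(1.0 / d))
    return float(d.mean())


# -- inbreeding ----------------------------------------------------------------


def fis(table: GenotypeTable, population: str, method: str = "nei") -> float:
    """Multilocus within-population inbreeding coefficient.

    ``nei``: 1 - mean(H_O)/mean(H_E) with unbiased H_E.  ``weir``: the
    Weir-Cockerham small-sample estimator 1 - sum(c)/sum(b + c) from the
    within-population variance components.
    """
    if method == "nei":
        _, _, ho, he = heterozygosities(table, population)
        if he == 0:
            raise UndefinedStatistic("H_E is zero at all loci; F_IS undefined")
        return 1.0 - ho / he
    if method == "weir":
        _, b, c = _wc_components(table, [population])
        if b + c == 0:
            raise UndefinedStatistic("no heterozygosity; F_IS undefined")
        return 1.0 - c / (b + c)
    raise ValueError(f"unknown F_IS method {method!r}")


# -- relatedness ---------------------------------------------------------------


def relatedness_matrix(
    table: GenotypeTable, population: str, reference: str | None = None
) -> np.ndarray:
    """Symmetrized Queller-Goodnight relatedness for all unordered pairs.

    For the ordered pair (x, y) at one locus the estimator accumulates
    numerator 0.5*(I[a=c]+I[a=d]+I[b=c]+I[b=d]) - p_a - p_b and denominator
    1 + I[a=b] - p_a - p_b (x carrying alleles a,b and y carrying c,d); the
    symmetric estimate is the ratio of the two orderings' pooled sums across
    loci.  Reference allele frequencies are taken from the whole table by
    default (so members of a drifted deme appear related relative to the
    total sample, the convention of the usual relatedness tools); pass
    ``reference`` to use a specific population instead.  Returns a condensed
    vector (same pair ordering as scipy's pdist).
    """
    from .genotype import allele_frequencies

    sub = table.subset(population)
    n = sub.n_individuals
    if n < 2:
        raise UndefinedStatistic("relatedness needs at least two individuals")
    if reference is None:
        pooled = GenotypeTable(
            table.individuals,
            ["all"] * table.n_individuals,
            table.loci,
            table.calls,
            validate=False,
        )
        freqs = allele_frequencies(pooled, "all").freqs
    else:
        freqs = allele_frequencies(table, reference).freqs

    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for j, pj in enumerate(freqs):
        calls = sub.calls[:, j, :]
        genotyped = calls[:, 0] != MISSING
        a, b = calls[:, 0], calls[:, 1]
        # similarity of ordered pair (i, k): fraction of i's alleles matching k's
        sim = 0.5 * (
            (a[:, None] == a[None, :]).astype(float)
            + (a[:, None] == b[None, :])
            + (b[:, None] == a[None, :])
            + (b[:, None] == b[None, :])
        )
        p = np.array([pj.get(int(x), 0.0) + pj.get(int(y), 0.0)
                      for x, y in zip(a, b)])
        hom = (a == b).astype(float)
        ok = np.outer(genotyped, genotyped)
        # pooled over both orderings: numerators 2*sim - p_i - p_k,
        # denominators 2 + hom_i + hom_k - p_i - p_k
        num += np.where(ok, 2.0 * sim - p[:, None] - p[None, :], 0.0)
        den += np.where(ok, 2.0 + hom[:, None] + hom[None, :]
                        - p[:, None] - p[None, :], 0.0)
    iu = np.triu_indices(n, k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den[iu] != 0, num[iu] / den[iu], np.nan)
    return r


def mean_relatedness(
    table: GenotypeTable, population: str, reference: str | None = None
) -> float:
    """Mean pairwise Queller-Goodnight relatedness within a population."""
    r = relatedness_matrix(table, population, reference=reference)
    return float(np.nanmean(r))


# -- bootstrap -----------------------------------------------------------------


@dataclass
class BootstrapCI:
    lower: float
    upper: float
    point: float
    unstable: bool = False


def bootstrap_ci(
    statistic: Callable[[GenotypeTable], float],
    table: GenotypeTable,
    reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> BootstrapCI:
    """Percentile bootstrap CI resampling loci with replacement.

    ``statistic`` maps a GenotypeTable to a float.  If the statistic is
    undefined on more than 10% of resamples the CI is flagged unstable.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    point = statistic(table)
    vals = []
    failures = 0
    for _ in range(reps):
        idx = rng.integers(0, table.n_loci, size=table.n_loci)
        try:
            vals.append(statistic(_resample_loci(table, idx)))
        except (UndefinedStatistic, ZeroDivisionError):
            failures += 1
    if not vals:
        raise UndefinedStatistic("statistic undefined on every bootstrap resample")
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapCI(
        lower=float(lo),
        upper=float(hi),
        point=float(point),
        unstable=failures > 0.1 * reps,
    )


# -- the eight-index panel -----------------------------------------------------

CATEGORY_OF_STATISTIC = {
    "Na": "diversity",
    "Ho": "diversity",
    "He": "diversity",
    "Fst": "differentiation",
    "JostD": "differentiation",
    "Fis_nei": "inbreeding",
    "Fis_weir": "inbreeding",
    "r": "relatedness",
}


def index_panel(
    table: GenotypeTable,
    population: str,
    reference: str | None = None,
    rarefaction_g: int | None = None,
) -> dict[str, float]:
    """The eight comparison indices for one focal population.

    Differentiation indices are computed against ``reference`` when given
    (otherwise omitted).  Returns a name -> value mapping using the keys of
    ``CATEGORY_OF_STATISTIC``.
    """
    _, na = allelic_richness(table, population, g=rarefaction_g)
    _, _, ho, he = heterozygosities(table, population)
    out = {
        "Na": na,
        "Ho": ho,
        "He": he,
        "Fis_nei": fis(table, population, "nei"),
        "Fis_weir": fis(table, population, "weir"),
        "r": mean_relatedness(table, population),
    }
    if reference is not None:
        out["Fst"] = pairwise_fst(table, population, reference)
        out["JostD"] = jost_d(table, population, reference)
    return out
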