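"""Independent brute-force reference implementations.

Deliberately naive (python loops, literal textbook formulas, exhaustive
enumeration) so they share no code with the package's vectorized estimators.
"""

from itertools import combinations

from isopop.genotype import MISSING


def genotypes(table, pop, j):
    """[(a, b), ...] of non-missing genotypes at locus j in population pop."""
    out = []
    for i, p in enumerate(table.populations):
        a, b = int(table.calls[i, j, 0]), int(table.calls[i, j, 1])
        if p == pop and a != MISSING:
            out.append((a, b))
    return out


def freqs(table, pop, j):
    counts = {}
    for a, b in genotypes(table, pop, j):
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    tot = sum(counts.values())
    return {a: c / tot for a, c in counts.items()}, tot


def obs_het(table, pop, j):
    g = genotypes(table, pop, j)
    return sum(1 for a, b in g if a != b) / len(g)


def exp_het_unbiased(table, pop, j):
    f, n_genes = freqs(table, pop, j)
    return (n_genes / (n_genes - 1)) * (1 - sum(p * p for p in f.values()))


def rarefied_na(table, pop, j, g):
    """Expected allele count in subsamples of g gene copies, by exhaustive
    enumeration of all C(N, g) subsets."""
    copies = []
    for a, b in genotypes(table, pop, j):
        copies.extend([a, b])
    subsets = list(combinations(range(len(copies)), g))
    total = 0
    for idx in subsets:
        total += len({copies[i] for i in idx})
    return total / len(subsets)


def wc_fst(table, pop_a, pop_b):
    """Weir-Cockerham theta via literal per-allele variance components."""
    num = den = 0.0
    r = 2
    for j in range(table.n_loci):
        ga, gb = genotypes(table, pop_a, j), genotypes(table, pop_b, j)
        if not ga or not gb:
            continue
        alleles = sorted({x for g in (ga, gb) for pair in g for x in pair})
        if len(alleles) < 2:
            continue
        n1, n2 = len(ga), len(gb)
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
        for al in alleles:
            p1 = sum((a == al) + (b == al) for a, b in ga) / (2 * n1)
            p2 = sum((a == al) + (b == al) for a, b in gb) / (2 * n2)
            h1 = sum((a == al) != (b == al) for a, b in ga) / n1
            h2 = sum((a == al) != (b == al) for a, b in gb) / n2
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            a_ = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
            )
            b_ = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - s2 * (r - 1) / r
                - hbar * (2 * nbar - 1) / (4 * nbar)
            )
            c_ = hbar / 2
            num += a_
            den += a_ + b_ + c_
    return num / den


def jost_d(table, pop_a, pop_b):
    """Per-locus D_est with Nei-Chesser corrections, harmonic mean across loci
    (arithmetic fallback for non-positive locus values)."""
    vals = []
    for j in range(table.n_loci):
        ga, gb = genotypes(table, pop_a, j), genotypes(table, pop_b, j)
        if not ga or not gb:
            continue
        alleles = sorted({x for g in (ga, gb) for pair in g for x in pair})
        if len(alleles) < 2:
            continue
        n1, n2 = len(ga), len(gb)
        nt = 2 / (1 / n1 + 1 / n2)
        p1 = {al: sum((a == al) + (b == al) for a, b in ga) / (2 * n1)
              for al in alleles}
        p2 = {al: sum((a == al) + (b == al) for a, b in gb) / (2 * n2)
              for al in alleles}
        hs = 1 - (sum(v * v for v in p1.values())
                  + sum(v * v for v in p2.values())) / 2
        ht = 1 - sum(((p1[al] + p2[al]) / 2) ** 2 for al in alleles)
        hs_est = (2 * nt / (2 * nt - 1)) * hs
        ht_est = ht + hs_est / (4 * nt)
        if 1 - hs_est <= 0:
            continue
        vals.append((ht_est - hs_est) / (1 - hs_est) * 2)
    if all(v > 0 for v in vals):
        return len(vals) / sum(1 / v for v in vals)
    return sum(vals) / len(vals)


def fis_nei(table, pop):
    hos, hes = [], []
    for j in range(table.n_loci):
        g = genotypes(table, pop, j)
        if len(g) < 2:
            continue
        hos.append(obs_het(table, pop, j))
        hes.append(exp_het_unbiased(table, pop, j))
    return 1 - (sum(hos) / len(hos)) / (sum(hes) / len(hes))


def qg_relatedness_mean(table, pop):
    """Mean symmetrized Queller-Goodnight relatedness, pooled-table reference."""
    ref = {}
    for j in range(table.n_loci):
        counts = {}
        for i in range(table.n_individuals):
            a, b = int(table.calls[i, j, 0]), int(table.calls[i, j, 1])
            if a == MISSING:
                continue
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        tot = sum(counts.values())
        ref[j] = {a: c / tot for a, c in counts.items()}

    members = [i for i, p in enumerate(table.populations) if p == pop]
    vals = []
    for x, y in combinations(members, 2):
        num = den = 0.0
        for j in range(table.n_loci):
            a, b = int(table.calls[x, j, 0]), int(table.calls[x, j, 1])
            c, d = int(table.calls[y, j, 0]), int(table.calls[y, j, 1])
            if MISSING in (a, b, c, d):
                continue
            for (u, v), (w, z) in (((a, b), (c, d)), ((c, d), (a, b))):
                sim = 0.5 * ((u == w) + (u == z) + (v == w) + (v == z))
                num += sim - ref[j].get(u, 0) - ref[j].get(v, 0)
                den += 1 + (u == v) - ref[j].get(u, 0) - ref[j].get(v, 0)
        if den != 0:
            vals.append(num / den)
    return sum(vals) / len(vals)
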