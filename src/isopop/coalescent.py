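"""Single-locus coalescent simulation with microsatellite mutation models.

A compact numba kernel used by the bottleneck tests: it simulates a Kingman
genealogy of ``n`` gene copies, drops mutations on it as a Poisson process of
rate theta/2 per unit of (coalescent-scaled) branch length, and evolves
allele states under either a (generalized) stepwise model - single repeat
step with probability 1 - p_multi, otherwise a multi-step of at least two
repeat units whose size is 1 + Geometric(geom_p) (sign equiprobable) - or an
infinite-alleles labelling where every mutation creates a fresh allele.

``min_k`` optionally rejects replicates until the sampled locus carries at
least that many alleles; the equilibrium M-ratio null conditions on
polymorphic loci (min_k = 2) because monomorphic loci never enter an
empirical M calculation.

Returned per locus: number of distinct alleles k, the span of allelic states
in repeat units r = max - min + 1 (1 for the infinite-alleles mode, where
state spans are meaningless), and the unbiased expected heterozygosity of the
sample.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _coalescent_locus(n_genes, theta, p_multi, geom_p, iam, min_k):  # pragma: no cover
    n = n_genes
    while True:
        # intercoalescent times and total tree length first: most loci carry
        # no mutation at small theta and can skip topology construction
        times = np.empty(n + 1)
        total_len = 0.0
        for i in range(n, 1, -1):
            t = np.random.exponential(2.0 / (i * (i - 1.0)))
            times[i] = t
            total_len += i * t
        n_mut = np.random.poisson(0.5 * theta * total_len)
        if n_mut == 0:
            if min_k >= 2:
                continue
            return 1, 1, 0.0

        n_nodes = 2 * n - 1
        parent = np.full(n_nodes, -1, dtype=np.int64)
        node_time = np.zeros(n_nodes)
        active = np.empty(n, dtype=np.int64)
        for i in range(n):
            active[i] = i
        cur = n
        nxt = n
        t = 0.0
        for i in range(n, 1, -1):
            t += times[i]
            j1 = np.random.randint(cur)
            a = active[j1]
            active[j1] = active[cur - 1]
            cur -= 1
            j2 = np.random.randint(cur)
            b = active[j2]
            parent[a] = nxt
            parent[b] = nxt
            node_time[nxt] = t
            active[j2] = nxt
            nxt += 1

        # cumulative branch lengths over non-root nodes for uniform placement
        cum = np.empty(n_nodes - 1)
        acc = 0.0
        for v in range(n_nodes - 1):
            acc += node_time[parent[v]] - node_time[v]
            cum[v] = acc

        effect = np.zeros(n_nodes, dtype=np.int64)
        label = np.zeros(n_nodes, dtype=np.int64)
        for m in range(n_mut):
            u = np.random.random() * acc
            v = np.searchsorted(cum, u)
            if v >= n_nodes - 1:
                v = n_nodes - 2
            if iam:
                label[v] = m + 1
            else:
                if np.random.random() < p_multi:
                    step = 1 + np.random.geometric(geom_p)
                else:
                    step = 1
                if np.random.random() < 0.5:
                    step = -step
                effect[v] += step

        state = np.zeros(n_nodes, dtype=np.int64)
        for v in range(n_nodes - 2, -1, -1):
            if iam:
                state[v] = label[v] if label[v] > 0 else state[parent[v]]
            else:
                state[v] = state[parent[v]] + effect[v]

        tips = np.sort(state[:n].copy())
        k = 1
        for i in range(1, n):
            if tips[i] != tips[i - 1]:
                k += 1
        if k < min_k:
            continue
        r = 1 if iam else int(tips[n - 1] - tips[0] + 1)

        # unbiased expected heterozygosity from sample allele counts
        sum_p2 = 0.0
        run = 1
        for i in range(1, n):
            if tips[i] == tips[i - 1]:
                run += 1
            else:
                sum_p2 += (run / n) ** 2
                run = 1
        sum_p2 += (run / n) ** 2
        het = (n / (n - 1.0)) * (1.0 - sum_p2)
        return k, r, het


@njit(cache=True)
def sim_mean_m(n_reps, n_loci, n_genes, theta, p_multi, geom_p, seed):  # pragma: no cover
    """Per-replicate mean M = k/r across polymorphic equilibrium loci."""
    np.random.seed(seed)
    out = np.empty(n_reps)
    for rep in range(n_reps):
        tot = 0.0
        for _ in range(n_loci):
            k, r, _ = _coalescent_locus(n_genes, theta, p_multi, geom_p, False, 2)
            tot += k / r
        out[rep] = tot / n_loci
    return out


@njit(cache=True)
def sim_k_het(n_reps, n_genes, theta, p_multi, geom_p, iam, seed):  # pragma: no cover
    """Allele counts and heterozygosities of unconditioned equilibrium loci."""
    np.random.seed(seed)
    ks = np.empty(n_reps, dtype=np.int64)
    hets = np.empty(n_reps)
    for rep in range(n_reps):
        k, _, het = _coalescent_locus(n_genes, theta, p_multi, geom_p, iam, 0)
        ks[rep] = k
        hets[rep] = het
    return ks, hets
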