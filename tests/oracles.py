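"""Independent naive reference implementations used only to cross-check the
package's statistics on small inputs. Deliberately written as plain double
loops over the defining formulas, sharing no code with the package."""

from itertools import permutations

import numpy as np


def brute_amova_one_level(d: np.ndarray, labels: list) -> dict:
    """One-level AMOVA variance components from a distance matrix, by direct
    evaluation of the sum-of-squares definitions."""
    n = len(labels)
    pops = sorted(set(labels))
    ss_total = 0.0
    for i in range(n):
        for j in range(n):
            ss_total += d[i, j] ** 2
    ss_total /= 2.0 * n
    ss_within = 0.0
    for p in pops:
        idx = [i for i in range(n) if labels[i] == p]
        s = 0.0
        for i in idx:
            for j in idx:
                s += d[i, j] ** 2
        ss_within += s / (2.0 * len(idx))
    ss_among = ss_total - ss_within
    df_a = len(pops) - 1
    df_w = n - len(pops)
    sizes = [labels.count(p) for p in pops]
    n_prime = (n - sum(s**2 for s in sizes) / n) / df_a
    sigma_c = ss_within / df_w
    sigma_a = (ss_among / df_a - sigma_c) / n_prime
    return {
        "sigma_a": sigma_a,
        "sigma_c": sigma_c,
        "phi_st": sigma_a / (sigma_a + sigma_c),
    }


def exact_permutation_phist_p(d: np.ndarray, labels: list) -> float:
    """Exact permutation p-value for Phi_ST over all distinct relabelings."""
    obs = brute_amova_one_level(d, labels)["phi_st"]
    seen = set()
    count_ge = 0
    total = 0
    for perm in permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if brute_amova_one_level(d, list(perm))["phi_st"] >= obs - 1e-12:
            count_ge += 1
    return count_ge / total


def brute_wc_theta(pop_genotypes: dict) -> float:
    """Weir & Cockerham (1984) theta by direct transcription of the a/b/c
    component formulas, one allele and one locus at a time.

    ``pop_genotypes`` maps population -> list of (allele, allele) pairs for a
    single locus.
    """
    pops = sorted(pop_genotypes)
    r = len(pops)
    n_i = [len(pop_genotypes[p]) for p in pops]
    nbar = sum(n_i) / r
    nc = (r * nbar - sum(x**2 for x in n_i) / (r * nbar)) / (r - 1)
    alleles = sorted({a for p in pops for g in pop_genotypes[p] for a in g})
    A = B = C = 0.0
    for al in alleles:
        p_i, h_i = [], []
        for p in pops:
            genos = pop_genotypes[p]
            count = sum(g.count(al) for g in genos)
            p_i.append(count / (2 * len(genos)))
            h_i.append(sum(1 for g in genos if (g[0] == al) != (g[1] == al)) / len(genos))
        pbar = sum(n * x for n, x in zip(n_i, p_i)) / (r * nbar)
        s2 = sum(n * (x - pbar) ** 2 for n, x in zip(n_i, p_i)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        A += a
        B += b
        C += c
    return A / (A + B + C)


def brute_pairwise_pi(seqs: list) -> float:
    """Mean pairwise difference count by literal double loop (equal-length,
    gap-free sequences)."""
    n = len(seqs)
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(1 for a, b in zip(seqs[i], seqs[j]) if a != b)
    return total / (n * (n - 1) / 2)
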