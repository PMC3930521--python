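"""Microsatellite summary statistics, HWE/LD tests, null alleles,
Weir-Cockerham F_ST, Jost's D_est and a drift-based power analysis.

Conventions: expected heterozygosity carries the unbiased 2n/(2n-1)
correction; allelic richness is rarefied over genes actually scored;
multilocus F_IS and F_ST are the Weir-Cockerham variance-component ratios
summed over alleles and loci (not means of per-locus values); Jost's D uses
the Nei-Chesser sample-size-corrected H_S/H_T with the harmonic mean across
loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from benguela.io_formats import MISSING_ALLELE, GenotypeMatrix, PopulationMap
from benguela.rng import derive_rng


# ---------------------------------------------------------------------------
# Per-locus diversity
# ---------------------------------------------------------------------------

def _locus_pop_calls(gm: GenotypeMatrix, labels: np.ndarray, pop, locus_idx: int) -> np.ndarray:
    """(k, 2) array of scored diploid calls for one population and locus."""
    rows = (labels == pop) & ~gm.missing_mask()[:, locus_idx]
    return gm.calls[rows, locus_idx, :]


def allelic_richness(allele_counts: np.ndarray, g_genes: int) -> float:
    """Expected allele count in a random subsample of ``g_genes`` genes.

    AR = sum_a [1 - C(N - N_a, g) / C(N, g)] with N genes scored and N_a
    copies of allele a (hurlbert rarefaction).
    """
    counts = np.asarray(allele_counts, dtype=int)
    counts = counts[counts > 0]
    N = int(counts.sum())
    if g_genes > N:
        raise ValueError(f"rarefaction size {g_genes} exceeds scored genes {N}")
    denom = comb(N, g_genes)
    return float(sum(1.0 - comb(N - c, g_genes) / denom for c in counts))


def unbiased_expected_het(allele_counts: np.ndarray) -> float:
    """H_E = 2n/(2n-1) (1 - sum p^2), n diploid individuals (counts are genes)."""
    counts = np.asarray(allele_counts, dtype=float)
    N = counts.sum()  # genes
    if N < 2:
        return 0.0
    p = counts / N
    return float(N / (N - 1) * (1.0 - np.sum(p**2)))


def _wc_locus_components(pop_calls: dict) -> tuple[float, float, float]:
    """Weir-Cockerham (1984) a, b, c summed over alleles for one locus.

    ``pop_calls`` maps population label -> (k, 2) scored calls.
    """
    pops = [p for p, calls in pop_calls.items() if len(calls) > 0]
    r = len(pops)
    if r < 2:
        return 0.0, 0.0, 0.0
    n_i = np.array([len(pop_calls[p]) for p in pops], dtype=float)
    nbar = n_i.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    n_c = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    alleles = sorted({int(a) for p in pops for a in pop_calls[p].ravel()})
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i = np.array(
            [np.mean(pop_calls[p] == allele) for p in pops]
        )  # allele freq per pop
        h_i = np.array(
            [np.mean((pop_calls[p] == allele).sum(axis=1) == 1) for p in pops]
        )  # heterozygote frequency involving this allele
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / n_c) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


@dataclass
class LocusStats:
    """Per-locus per-population diversity table and multilocus averages."""

    table: pd.DataFrame           # multi-index (locus, statistic) x population
    multilocus: pd.DataFrame      # statistic x population
    rarefaction_genes: int


def locus_summary(
    gm: GenotypeMatrix, popmap: PopulationMap, rarefaction_g: int | None = None
) -> LocusStats:
    """n, Na, AR, H_E, H_O and F_IS per locus and population.

    ``rarefaction_g`` is in diploid individuals (2g genes); by default the
    smallest per-locus per-population number of scored individuals is used.
    Monomorphic locus/population cells report H_E = H_O = 0 and NaN F_IS.
    """
    popmap.validate_ids(gm.sample_ids)
    labels = popmap.site_labels(gm.sample_ids)
    pops = [s for s in popmap.sites if (labels == s).sum() > 0]
    scored = ~gm.missing_mask()
    min_scored = min(
        int((scored[labels == p, l]).sum())
        for p in pops
        for l in range(gm.n_loci)
    )
    g = rarefaction_g if rarefaction_g is not None else min_scored
    if g > min_scored:
        raise ValueError(
            f"rarefaction size {g} individuals exceeds the smallest sample ({min_scored})"
        )
    g_genes = 2 * g
    rows = []
    for l, locus in enumerate(gm.locus_names):
        for p in pops:
            calls = _locus_pop_calls(gm, labels, p, l)
            n = len(calls)
            genes = calls.ravel()
            alleles, counts = np.unique(genes, return_counts=True)
            he = unbiased_expected_het(counts)
            ho = float(np.mean(calls[:, 0] != calls[:, 1])) if n else 0.0
            rows.append(
                {
                    "locus": locus,
                    "population": p,
                    "n": n,
                    "Na": len(alleles),
                    "AR": allelic_richness(counts, g_genes) if n else float("nan"),
                    "H_E": he,
                    "H_O": ho,
                    "F_IS": _wc_fis_single(calls) if len(alleles) > 1 else float("nan"),
                }
            )
    table = pd.DataFrame(rows).set_index(["locus", "population"])
    multi_rows = []
    for p in pops:
        sub = table.xs(p, level="population")
        fis = _wc_fis_multilocus(gm, labels, p)
        multi_rows.append(
            {
                "population": p,
                "n": int(sub["n"].max()),
                "Na": float(sub["Na"].mean()),
                "AR": float(sub["AR"].mean()),
                "H_E": float(sub["H_E"].mean()),
                "H_O": float(sub["H_O"].mean()),
                "F_IS": fis,
            }
        )
    return LocusStats(table, pd.DataFrame(multi_rows).set_index("population"), g_genes)


def _wc_fis_single(calls: np.ndarray) -> float:
    genes = calls.ravel()
    _, counts = np.unique(genes, return_counts=True)
    he = unbiased_expected_het(counts)
    ho = float(np.mean(calls[:, 0] != calls[:, 1]))
    if he == 0:
        return float("nan")
    return 1.0 - ho / he


def _wc_fis_multilocus(gm: GenotypeMatrix, labels: np.ndarray, pop) -> float:
    """Multilocus F_IS for one population: ratio of summed (He-Ho)-type
    components, i.e. 1 - sum Ho / sum He over loci (weighted estimator)."""
    num = den = 0.0
    for l in range(gm.n_loci):
        calls = _locus_pop_calls(gm, labels, pop, l)
        if len(calls) == 0:
            continue
        genes = calls.ravel()
        _, counts = np.unique(genes, return_counts=True)
        he = unbiased_expected_het(counts)
        ho = float(np.mean(calls[:, 0] != calls[:, 1]))
        num += ho
        den += he
    if den == 0:
        return float("nan")
    return 1.0 - num / den


# ---------------------------------------------------------------------------
# HWE and linkage tests
# ---------------------------------------------------------------------------

def hwe_test(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    locus: str,
    n_reps: int = 1000,
    seed: int = 0,
    two_sided: bool = False,
) -> pd.Series:
    """Monte-Carlo exact test for Hardy-Weinberg proportions, per population.

    The 2n scored genes are repeatedly shuffled into random diploid
    genotypes; the statistic is the homozygote count (heterozygote-deficiency
    score). One-sided by default (deficit direction, the biologically usual
    alternative for null alleles/inbreeding); ``two_sided`` doubles the
    smaller tail. p-values carry the +1 correction.
    """
    labels = popmap.site_labels(gm.sample_ids)
    l = gm.locus_names.index(locus)
    out = {}
    for pop in popmap.sites:
        calls = _locus_pop_calls(gm, labels, pop, l)
        if len(calls) == 0:
            continue
        distinct = {tuple(sorted(c)) for c in calls.tolist()}
        if len(distinct) < 3:
            out[pop] = 1.0
            continue
        obs = int((calls[:, 0] == calls[:, 1]).sum())
        genes = calls.ravel().copy()
        rng = derive_rng(seed, "hwe", locus, pop)
        ge = le = 0
        for _ in range(n_reps):
            rng.shuffle(genes)
            hom = int((genes[0::2] == genes[1::2]).sum())
            if hom >= obs:
                ge += 1
            if hom <= obs:
                le += 1
        p_def = (1 + ge) / (1 + n_reps)
        p_exc = (1 + le) / (1 + n_reps)
        out[pop] = min(1.0, 2 * min(p_def, p_exc)) if two_sided else p_def
    return pd.Series(out, name=f"hwe_p[{locus}]")


def ld_test(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    locus_pair: tuple[str, str],
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Permutation test of genotypic linkage disequilibrium per population.

    Single-locus genotypes at the second locus are permuted between
    individuals; the statistic is the log-likelihood G of the two-locus
    genotype contingency table.
    """
    la = gm.locus_names.index(locus_pair[0])
    lb = gm.locus_names.index(locus_pair[1])
    labels = popmap.site_labels(gm.sample_ids)
    scored = ~gm.missing_mask()
    out = {}
    for pop in popmap.sites:
        rows = (labels == pop) & scored[:, la] & scored[:, lb]
        if rows.sum() < 5:
            continue
        ga = [tuple(sorted(c)) for c in gm.calls[rows, la, :].tolist()]
        gb = [tuple(sorted(c)) for c in gm.calls[rows, lb, :].tolist()]
        obs = _g_statistic(ga, gb)
        if obs is None:
            out[pop] = 1.0
            continue
        rng = derive_rng(seed, "ld", *locus_pair, pop)
        gb_arr = np.array(gb, dtype=object)
        ge = 0
        for _ in range(n_reps):
            perm = gb_arr[rng.permutation(len(gb_arr))]
            g = _g_statistic(ga, list(perm))
            if g is not None and g >= obs:
                ge += 1
        out[pop] = (1 + ge) / (1 + n_reps)
    return pd.Series(out, name=f"ld_p[{locus_pair[0]}-{locus_pair[1]}]")


def _g_statistic(ga: list, gb: list) -> float | None:
    sa = pd.Series([f"{a}/{b}" for a, b in ga])
    sb = pd.Series([f"{a}/{b}" for a, b in gb])
    tab = pd.crosstab(sa, sb).to_numpy().astype(float)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return None
    total = tab.sum()
    exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / total
    mask = tab > 0
    return float(2.0 * (tab[mask] * np.log(tab[mask] / exp[mask])).sum())


# ---------------------------------------------------------------------------
# Null alleles (single-null-class EM)
# ---------------------------------------------------------------------------

def null_allele_em(
    calls: np.ndarray, max_iter: int = 1000, tol: float = 1e-9
) -> tuple[float, bool]:
    """EM estimate of a single null allele's frequency under HWE.

    Observed apparent homozygotes A/A are a mixture of true A/A and A/null
    heterozygotes. Missing genotypes are ignored (null/null individuals
    typically fail to amplify and are not modelled as a separate class).
    Returns ``(frequency, converged)``.
    """
    calls = np.asarray(calls)
    calls = calls[calls[:, 0] != MISSING_ALLELE]
    n = len(calls)
    if n == 0:
        return 0.0, True
    alleles = sorted({int(a) for a in calls.ravel()})
    if len(alleles) < 2:
        return 0.0, True
    idx = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    hom_counts = np.zeros(k)
    het_counts = np.zeros(k)  # gene copies in observed heterozygotes
    for a, b in calls.tolist():
        if a == b:
            hom_counts[idx[a]] += 1
        else:
            het_counts[idx[a]] += 1
            het_counts[idx[b]] += 1
    p = np.ones(k) / k
    r = 0.05  # null frequency
    converged = False
    for _ in range(max_iter):
        # E-step: expected null-carrier fraction among apparent a/a homozygotes
        denom = p**2 + 2 * p * r
        w_null = np.where(denom > 0, 2 * p * r / denom, 0.0)
        null_genes = (hom_counts * w_null).sum()
        gene_counts = het_counts + hom_counts * (2 - w_null)
        total = gene_counts.sum() + null_genes
        new_p = gene_counts / total
        new_r = null_genes / total
        if abs(new_r - r) < tol and np.abs(new_p - p).max() < tol:
            p, r = new_p, new_r
            converged = True
            break
        p, r = new_p, new_r
    return float(r), converged


# ---------------------------------------------------------------------------
# Differentiation: Weir-Cockerham theta and Jost's D
# ---------------------------------------------------------------------------

@dataclass
class DifferentiationResult:
    statistic: str
    global_value: float
    per_locus: pd.Series
    pairwise: pd.DataFrame | None = None
    pairwise_p: pd.DataFrame | None = None
    global_p: float | None = None
    notes: list = field(default_factory=list)


def _locus_arrays(gm: GenotypeMatrix) -> list[dict]:
    """Per-locus precomputed allele-dosage (n x k, values 0/1/2) and
    heterozygote-carrier (n x k) matrices, for fast repeated theta evaluation
    under label permutation."""
    out = []
    missing = gm.missing_mask()
    for l in range(gm.n_loci):
        scored = ~missing[:, l]
        calls = gm.calls[:, l, :]
        alleles = np.unique(calls[scored])
        k = len(alleles)
        dosage = np.zeros((gm.n, k))
        het = np.zeros((gm.n, k))
        for ai, al in enumerate(alleles):
            hits = (calls == al).sum(axis=1)
            dosage[:, ai] = np.where(scored, hits, 0)
            het[:, ai] = np.where(scored, hits == 1, 0)
        out.append({"scored": scored, "dosage": dosage, "het": het, "k": k})
    return out


def _theta_components_locus(arr: dict, labels: np.ndarray, pops: list) -> tuple[float, float, float] | None:
    """Weir-Cockerham a, b, c summed over alleles for one precomputed locus;
    None when fewer than two populations are scored or the locus is
    monomorphic."""
    scored = arr["scored"]
    n_i = np.array([float((scored & (labels == p)).sum()) for p in pops])
    use = n_i > 0
    if use.sum() < 2 or arr["k"] < 2:
        return None
    pops_used = [p for p, u in zip(pops, use) if u]
    n_i = n_i[use]
    r = len(pops_used)
    onehot = np.stack([(scored & (labels == p)) for p in pops_used]).astype(float)
    p_mat = (onehot @ arr["dosage"]) / (2 * n_i[:, None])     # (r, k)
    h_mat = (onehot @ arr["het"]) / n_i[:, None]              # (r, k)
    nbar = n_i.mean()
    if nbar <= 1:
        return None
    n_c = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i[:, None] * p_mat).sum(axis=0) / (r * nbar)    # (k,)
    s2 = (n_i[:, None] * (p_mat - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h_mat).sum(axis=0) / (r * nbar)
    a = (nbar / n_c) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def _theta_from_arrays(arrays: list[dict], locus_names, labels: np.ndarray, pops: list):
    a_tot = abc_tot = 0.0
    per_locus = {}
    notes = []
    for arr, locus in zip(arrays, locus_names):
        if arr["k"] < 2:
            notes.append(f"locus {locus} monomorphic overall; excluded from theta")
            per_locus[locus] = float("nan")
            continue
        comp = _theta_components_locus(arr, labels, pops)
        if comp is None:
            per_locus[locus] = float("nan")
            continue
        a, b, c = comp
        denom = a + b + c
        per_locus[locus] = a / denom if denom != 0 else float("nan")
        a_tot += a
        abc_tot += denom
    theta = a_tot / abc_tot if abc_tot != 0 else float("nan")
    return theta, pd.Series(per_locus, name="theta"), notes


def _theta_from_gm(gm: GenotypeMatrix, labels: np.ndarray, pops: list) -> tuple[float, pd.Series, list]:
    return _theta_from_arrays(_locus_arrays(gm), gm.locus_names, labels, pops)


def wc_fst(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    n_perm: int = 1000,
    seed: int = 0,
    pairwise: bool = True,
) -> DifferentiationResult:
    """Weir-Cockerham theta (F_ST), global and pairwise, with permutation p.

    The permutation unit is the individual's multilocus genotype (rows are
    shuffled among populations), preserving within-individual linkage.
    """
    popmap.validate_ids(gm.sample_ids)
    labels = popmap.site_labels(gm.sample_ids)
    pops = [s for s in popmap.sites if (labels == s).sum() > 0]
    if len(pops) < 2:
        raise ValueError("theta needs >= 2 populations")
    arrays = _locus_arrays(gm)
    theta, per_locus, notes = _theta_from_arrays(arrays, gm.locus_names, labels, pops)
    global_p = None
    if n_perm > 0:
        from benguela.amova_phist import permutation_p

        rng = derive_rng(seed, "wc_fst_global")
        null = np.empty(n_perm)
        perm = labels.copy()
        for b in range(n_perm):
            rng.shuffle(perm)
            null[b] = _theta_from_arrays(arrays, gm.locus_names, perm, pops)[0]
        global_p = permutation_p(theta, null)
    pw = pw_p = None
    if pairwise:
        from benguela.amova_phist import permutation_p

        pw = pd.DataFrame(np.nan, index=pops, columns=pops)
        pw_p = pd.DataFrame(np.nan, index=pops, columns=pops)
        for i, p1 in enumerate(pops):
            for p2 in pops[i + 1:]:
                rows = (labels == p1) | (labels == p2)
                sub_labels = labels[rows]
                sub_arrays = [
                    {"scored": a["scored"][rows], "dosage": a["dosage"][rows],
                     "het": a["het"][rows], "k": a["k"]}
                    for a in arrays
                ]
                t, _, _ = _theta_from_arrays(sub_arrays, gm.locus_names, sub_labels, [p1, p2])
                pw.loc[p2, p1] = pw.loc[p1, p2] = t
                if n_perm > 0:
                    rng = derive_rng(seed, "wc_fst_pair", p1, p2)
                    null = np.empty(n_perm)
                    perm = sub_labels.copy()
                    for b in range(n_perm):
                        rng.shuffle(perm)
                        null[b] = _theta_from_arrays(
                            sub_arrays, gm.locus_names, perm, [p1, p2]
                        )[0]
                    pw_p.loc[p2, p1] = pw_p.loc[p1, p2] = permutation_p(t, null)
    return DifferentiationResult("wc_theta", theta, per_locus, pw, pw_p, global_p, notes)


def _dest_locus(pop_freqs: list[np.ndarray], pop_n: list[int]) -> float | None:
    """Jost's D for one locus from per-population allele frequency vectors
    (aligned over the same allele list) and per-population diploid sample
    sizes. Returns None when H_S = 1 (locus uninformative for D)."""
    n_pops = len(pop_freqs)
    freqs = np.vstack(pop_freqs)
    hs_plain = 1.0 - np.mean((freqs**2).sum(axis=1))
    ht_plain = 1.0 - ((freqs.mean(axis=0)) ** 2).sum()
    n_harm = n_pops / np.sum(1.0 / np.asarray(pop_n, dtype=float))
    hs_est = (2 * n_harm / (2 * n_harm - 1)) * hs_plain
    ht_est = ht_plain + hs_est / (2 * n_harm * n_pops)
    if 1.0 - hs_est <= 0:
        return None
    return float((ht_est - hs_est) / (1.0 - hs_est) * n_pops / (n_pops - 1))


def jost_dest(gm: GenotypeMatrix, popmap: PopulationMap, pairwise: bool = True) -> DifferentiationResult:
    """Jost's D_est per locus, multilocus (harmonic mean), and pairwise.

    Negative per-locus values are clamped to zero before the harmonic mean
    (so any zero-D locus drives the multilocus harmonic mean to zero); the
    raw per-locus values are retained in ``per_locus``.
    """
    popmap.validate_ids(gm.sample_ids)
    labels = popmap.site_labels(gm.sample_ids)
    pops = [s for s in popmap.sites if (labels == s).sum() > 0]
    if len(pops) < 2:
        raise ValueError("D_est needs >= 2 populations")

    def _multilocus(pop_subset: list) -> tuple[float, pd.Series, list]:
        per_locus = {}
        notes = []
        for l, locus in enumerate(gm.locus_names):
            freqs, ns = [], []
            alleles = sorted(
                {
                    int(a)
                    for p in pop_subset
                    for a in _locus_pop_calls(gm, labels, p, l).ravel()
                }
            )
            if len(alleles) < 2:
                notes.append(f"locus {locus} monomorphic; skipped for D_est")
                per_locus[locus] = float("nan")
                continue
            skip = False
            for p in pop_subset:
                calls = _locus_pop_calls(gm, labels, p, l)
                if len(calls) == 0:
                    skip = True
                    break
                genes = calls.ravel()
                freqs.append(
                    np.array([(genes == a).mean() for a in alleles])
                )
                ns.append(len(calls))
            if skip:
                per_locus[locus] = float("nan")
                continue
            d = _dest_locus(freqs, ns)
            if d is None:
                notes.append(f"locus {locus} has H_S = 1; skipped for D_est")
                per_locus[locus] = float("nan")
            else:
                per_locus[locus] = d
        series = pd.Series(per_locus, name="dest")
        clamped = series.dropna().clip(lower=0.0)
        if len(clamped) == 0:
            return float("nan"), series, notes
        if (clamped == 0).any():
            return 0.0, series, notes
        return float(len(clamped) / np.sum(1.0 / clamped)), series, notes

    global_d, per_locus, notes = _multilocus(pops)
    pw = None
    if pairwise:
        pw = pd.DataFrame(np.nan, index=pops, columns=pops)
        for i, p1 in enumerate(pops):
            for p2 in pops[i + 1:]:
                d, _, _ = _multilocus([p1, p2])
                pw.loc[p2, p1] = pw.loc[p1, p2] = d
    return DifferentiationResult("jost_dest", global_d, per_locus, pw, None, None, notes)


# ---------------------------------------------------------------------------
# Power analysis (drift simulation)
# ---------------------------------------------------------------------------

@dataclass
class PowerResult:
    target_fst: float
    ne: int
    t_generations: int
    replicates: int
    alpha: float
    significant: np.ndarray
    @property
    def power(self) -> float:
        return float(np.mean(self.significant))


def drift_generations(target_fst: float, ne: int) -> int:
    """Generations of pure drift reaching E[F_ST]: t = ceil(ln(1-F)/ln(1-1/(2Ne)))."""
    if not 0 <= target_fst < 1:
        raise ValueError("target F_ST must be in [0, 1)")
    if ne < 2:
        raise ValueError("Ne must be >= 2")
    if target_fst == 0:
        return 0
    return int(np.ceil(np.log(1 - target_fst) / np.log(1 - 1 / (2 * ne))))


def power_simulation(
    base_freqs: list[np.ndarray],
    ne: int,
    target_fst: float,
    sample_sizes: list[int],
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    test: str = "chi2",
) -> PowerResult:
    """Drift-based power analysis for detecting differentiation.

    Per replicate, each population's allele frequencies (one vector per locus
    in ``base_freqs``) drift ``t`` generations by multinomial resampling of
    2Ne genes; samples of the given sizes are drawn; per-locus allele-count
    homogeneity is tested (chi-squared by default, or Fisher-Freeman-Halton
    via chi2 on 2-population 2-allele collapses when ``test='fisher'`` and the
    table is 2x2); per-locus p-values combine over loci by Fisher's method.
    Power is the fraction of replicates significant at ``alpha``.
    """
    t = drift_generations(target_fst, ne)
    n_pops = len(sample_sizes)
    rng = derive_rng(seed, "power", target_fst, ne, reps)
    significant = np.zeros(reps, dtype=bool)
    for rep in range(reps):
        chis = []
        for freqs in base_freqs:
            counts_per_pop = []
            for s in sample_sizes:
                p = np.asarray(freqs, dtype=float)
                for _ in range(t):
                    genes = rng.multinomial(2 * ne, p)
                    p = genes / (2 * ne)
                keep = p.sum()
                if keep == 0:
                    counts_per_pop = []
                    break
                counts_per_pop.append(rng.multinomial(2 * s, p / keep))
            if not counts_per_pop:
                continue  # locus lost in all populations for this replicate
            tab = np.vstack(counts_per_pop)
            tab = tab[:, tab.sum(axis=0) > 0]
            if tab.shape[1] < 2:
                continue
            if test == "fisher" and tab.shape == (2, 2):
                p_locus = stats.fisher_exact(tab)[1]
                chis.append(-2 * np.log(max(p_locus, 1e-300)))
            else:
                _, p_locus, _, _ = stats.chi2_contingency(tab)
                chis.append(-2 * np.log(max(p_locus, 1e-300)))
        if not chis:
            continue
        combined = stats.chi2.sf(np.sum(chis), 2 * len(chis))
        significant[rep] = combined < alpha
    return PowerResult(target_fst, ne, t, reps, alpha, significant)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def sequential_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down rejections, returned in the input order.

    Sort ascending and reject while p_(i) < alpha / (k - i + 1); the first
    non-rejection stops the procedure.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    k = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(k, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] < alpha / (k - rank):
            reject[idx] = True
        else:
            break
    return reject
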