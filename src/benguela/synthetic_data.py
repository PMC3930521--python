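"""Coalescent and drift simulators producing datasets with the statistical
structure the analysis pipeline assumes.

Three scenarios are generated: (i) two populations that split T generations
ago with optional symmetric migration, sequences evolving under a
two-parameter (transition/transversion-biased) finite-sites model; (ii) a
single population with an instantaneous size change (the sudden-expansion
scenario used for mismatch/neutrality calibration); (iii) microsatellite
genotypes drifting from shared base frequencies, with optional stepwise
mutation and an optional null-allele class. Time is measured in generations
throughout; calendar conversions live in :mod:`benguela.demography`.

The genealogy samplers are written directly (competing exponential waiting
times) so the package carries no simulator dependency; an external coalescent
library serves only as a cross-check oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from benguela.io_formats import MISSING_ALLELE, GenotypeMatrix, PopulationMap, SequenceAlignment
from benguela.rng import derive_rng

_BASES = np.array(["A", "C", "G", "T"])
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the simulated study system.

    Defaults emulate the two-population study system the pipeline is built to
    analyse: an ancient vicariant split (~1.6 My at a 2.2-year generation
    time ~ 7e5 generations, deep enough to fix ~30 differences over 583 bp)
    with no migration, a control-region-sized locus with a strong transition
    bias, per-population mutation-scaled diversity theta_site ~ 0.005 (pi of
    a few per thousand), samples spread over six northern and two southern
    sites with the field study's sample sizes, and microsatellite drift at
    the effective sizes of the power analysis (Ne = 500 or 2000).
    """

    # sequence scenario
    ne: tuple[float, float] = (63_000.0, 100_000.0)
    ne_ancestral: float = 63_000.0
    split_generations: float = 700_000.0
    migration_rate: float = 0.0
    sample_sizes: tuple[int, int] = (104, 40)
    sites_per_deme: tuple[tuple[int, ...], ...] | None = (
        (20, 17, 20, 20, 20, 7),
        (20, 20),
    )
    sequence_length: int = 583
    mu_per_site: float = 4.0e-8
    kappa: float = 10.0
    # single-population expansion scenario
    expansion_n_current: float = 157_000.0
    expansion_n_ancestral: float = 26_600.0
    expansion_generations: float = 53_400.0
    expansion_sample_size: int = 104
    # microsatellites
    msat_n_loci: int = 8
    msat_motif: int = 2
    msat_mutation_rate: float = 1.0e-4
    msat_ne: float = 500.0
    msat_region_generations: int = 54
    msat_site_generations: int = 3
    msat_sample_sizes: tuple[int, ...] = (48, 70, 66, 70, 70, 69)
    msat_sites_northern: int = 4
    msat_base_alleles: int = 10
    msat_null_freq: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.migration_rate, self.mu_per_site, self.msat_mutation_rate, self.msat_null_freq):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if min(self.ne) < 2 or self.ne_ancestral < 2:
            raise ValueError("effective sizes must be >= 2")
        if self.split_generations < 0:
            raise ValueError("split time must be non-negative")
        if self.sites_per_deme is not None:
            totals = tuple(sum(s) for s in self.sites_per_deme)
            if len(totals) != 2 or totals != tuple(self.sample_sizes):
                raise ValueError(
                    f"sites_per_deme totals {totals} must equal sample_sizes {self.sample_sizes}"
                )


# ---------------------------------------------------------------------------
# Genealogy simulation (generations scale)
# ---------------------------------------------------------------------------

def _simulate_two_pop_genealogy(cfg: ScenarioConfig, rng: np.random.Generator):
    """Structured-coalescent genealogy for samples from two demes.

    Returns (parent, time) arrays over 2n-1 nodes (leaves first).
    """
    n1, n2 = cfg.sample_sizes
    n = n1 + n2
    parent = np.full(2 * n - 1, -1, dtype=int)
    node_time = np.zeros(2 * n - 1)
    deme = [0] * n1 + [1] * n2
    active = {0: list(range(n1)), 1: list(range(n1, n))}
    sizes = {0: cfg.ne[0], 1: cfg.ne[1]}
    t = 0.0
    next_node = n
    merged = cfg.split_generations == 0
    if merged:
        active = {0: active[0] + active[1]}
        sizes = {0: cfg.ne_ancestral}
    while sum(len(v) for v in active.values()) > 1:
        rates = {}
        for d, lin in active.items():
            k = len(lin)
            if k >= 2:
                rates[("coal", d)] = k * (k - 1) / 2.0 / sizes[d]
        if not merged and cfg.migration_rate > 0:
            for d, lin in active.items():
                if lin:
                    rates[("mig", d)] = len(lin) * cfg.migration_rate
        total = sum(rates.values())
        if total == 0:
            # isolated demes with single lineages: jump to the split
            t = cfg.split_generations
            active = {0: [l for v in active.values() for l in v]}
            sizes = {0: cfg.ne_ancestral}
            merged = True
            continue
        dt = rng.exponential(1.0 / total)
        if not merged and t + dt > cfg.split_generations:
            t = cfg.split_generations
            active = {0: [l for v in active.values() for l in v]}
            sizes = {0: cfg.ne_ancestral}
            merged = True
            continue
        t += dt
        events, weights = zip(*rates.items())
        ev = events[rng.choice(len(events), p=np.array(weights) / total)]
        if ev[0] == "coal":
            d = ev[1]
            i, j = rng.choice(len(active[d]), size=2, replace=False)
            a, b = active[d][i], active[d][j]
            parent[a] = parent[b] = next_node
            node_time[next_node] = t
            active[d] = [x for x in active[d] if x not in (a, b)] + [next_node]
            next_node += 1
        else:
            d = ev[1]
            other = 1 - d
            i = rng.integers(len(active[d]))
            lin = active[d].pop(i)
            active[other].append(lin)
    return parent, node_time, np.array(deme)


def _simulate_expansion_genealogy(
    n: int, n_current: float, n_ancestral: float, t_change: float, rng: np.random.Generator
):
    """Single-population genealogy with an instantaneous size change
    ``t_change`` generations ago (size ``n_current`` since, ``n_ancestral``
    before)."""
    parent = np.full(2 * n - 1, -1, dtype=int)
    node_time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    next_node = n
    while len(active) > 1:
        k = len(active)
        size = n_current if t < t_change else n_ancestral
        rate = k * (k - 1) / 2.0 / size
        dt = rng.exponential(1.0 / rate)
        if t < t_change and t + dt > t_change:
            t = t_change
            continue
        t += dt
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = next_node
        node_time[next_node] = t
        active = [x for x in active if x not in (a, b)] + [next_node]
        next_node += 1
    return parent, node_time


def _mutate_sequences(
    parent: np.ndarray,
    node_time: np.ndarray,
    n_leaves: int,
    L: int,
    mu_site: float,
    kappa: float,
    rng: np.random.Generator,
) -> list[str]:
    """Drop Poisson mutations on branches and evolve sequences root-to-tip
    under the two-parameter model (transition probability kappa/(kappa+2));
    multiple hits are allowed (finite sites)."""
    n_nodes = 2 * n_leaves - 1
    children: dict[int, list[int]] = {}
    for node in range(n_nodes - 1):
        children.setdefault(parent[node], []).append(node)
    root = n_nodes - 1
    seqs: dict[int, np.ndarray] = {root: rng.choice(_BASES, size=L)}
    p_ts = kappa / (kappa + 2.0)
    stack = [root]
    while stack:
        node = stack.pop()
        for child in children.get(node, []):
            seq = seqs[node].copy()
            branch = node_time[node] - node_time[child]
            n_mut = rng.poisson(mu_site * L * branch)
            for _ in range(n_mut):
                site = rng.integers(L)
                base = seq[site]
                if rng.random() < p_ts:
                    seq[site] = _TRANSITION[base]
                else:
                    seq[site] = _TRANSVERSIONS[base][rng.integers(2)]
            seqs[child] = seq
            stack.append(child)
    return ["".join(seqs[i]) for i in range(n_leaves)]


def simulate_two_pop_sequences(cfg: ScenarioConfig) -> tuple[SequenceAlignment, PopulationMap]:
    """Sequences from two demes splitting ``cfg.split_generations`` ago.

    Within each deme the population is panmictic, so samples are assigned to
    sampling sites (codes N1.. / S1.., groups 'northern' / 'southern') in
    contiguous blocks per ``cfg.sites_per_deme``, reproducing the field
    design of several sites per region with no true substructure within a
    region. Same seed and config give byte-identical output.
    """
    rng = derive_rng(cfg.seed, "two_pop_sequences")
    parent, node_time, deme = _simulate_two_pop_genealogy(cfg, rng)
    n = sum(cfg.sample_sizes)
    seqs = _mutate_sequences(
        parent, node_time, n, cfg.sequence_length, cfg.mu_per_site, cfg.kappa, rng
    )
    ids = [f"ind{i:03d}" for i in range(n)]
    aln = SequenceAlignment.from_records(ids, seqs)
    site_sizes = cfg.sites_per_deme or ((cfg.sample_sizes[0],), (cfg.sample_sizes[1],))
    ind_to_site: dict[str, str] = {}
    site_to_group: dict[str, str] = {}
    cursor = 0
    for d, sizes in enumerate(site_sizes):
        prefix, group = ("N", "northern") if d == 0 else ("S", "southern")
        for s_idx, size in enumerate(sizes):
            code = f"{prefix}{s_idx + 1}"
            site_to_group[code] = group
            for _ in range(size):
                ind_to_site[ids[cursor]] = code
                cursor += 1
    popmap = PopulationMap(ind_to_site, site_to_group)
    return aln, popmap


def simulate_expansion_sequences(cfg: ScenarioConfig) -> SequenceAlignment:
    """Single-population sample under the instantaneous-expansion scenario."""
    rng = derive_rng(cfg.seed, "expansion_sequences")
    n = cfg.expansion_sample_size
    parent, node_time = _simulate_expansion_genealogy(
        n, cfg.expansion_n_current, cfg.expansion_n_ancestral, cfg.expansion_generations, rng
    )
    seqs = _mutate_sequences(
        parent, node_time, n, cfg.sequence_length, cfg.mu_per_site, cfg.kappa, rng
    )
    return SequenceAlignment.from_records([f"ind{i:03d}" for i in range(n)], seqs)


# ---------------------------------------------------------------------------
# Mutational-scale pairwise simulators (infinite sites)
# ---------------------------------------------------------------------------

def _pairwise_from_genealogy(parent: np.ndarray, mut_counts: np.ndarray, n: int) -> np.ndarray:
    """(n, n) pairwise difference matrix from per-branch mutation counts."""
    n_nodes = len(parent)
    # leaves below each node; internal node ids always exceed their children's
    below: list[set] = [({leaf} if leaf < n else set()) for leaf in range(n_nodes)]
    for node in range(n_nodes - 1):
        below[parent[node]] |= below[node]
    diff = np.zeros((n, n))
    all_leaves = set(range(n))
    for node in range(n_nodes - 1):
        c = mut_counts[node]
        if c == 0:
            continue
        inside = sorted(below[node])
        outside = sorted(all_leaves - below[node])
        for i in inside:
            diff[i, outside] += c
    diff = diff + diff.T
    return diff


def _coalescent_mutational(n: int, theta_fn, rng: np.random.Generator):
    """Kingman coalescent in mutational time (tau-units): coalescence rate
    k(k-1)/(2 theta(t)), mutation rate 1/2 per lineage per unit time."""
    parent = np.full(2 * n - 1, -1, dtype=int)
    node_time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    next_node = n
    while len(active) > 1:
        k = len(active)
        theta, boundary = theta_fn(t)
        rate = k * (k - 1) / (2.0 * theta)
        dt = rng.exponential(1.0 / rate)
        if boundary is not None and t < boundary < t + dt:
            t = boundary
            continue
        t += dt
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = next_node
        node_time[next_node] = t
        active = [x for x in active if x not in (a, b)] + [next_node]
        next_node += 1
    branch = np.array(
        [node_time[parent[i]] - node_time[i] for i in range(2 * n - 2)] + [0.0]
    )
    mut = rng.poisson(branch / 2.0)
    return parent, mut


def simulate_coalescent_pairwise(n: int, theta: float, rng: np.random.Generator) -> dict:
    """Constant-size neutral coalescent sample (infinite sites) summarised as
    segregating sites, number of distinct haplotypes and mean pairwise
    differences. E[theta_pi] = theta."""
    parent, mut = _coalescent_mutational(n, lambda t: (theta, None), rng)
    diff = _pairwise_from_genealogy(parent, mut, n)
    iu = np.triu_indices(n, 1)
    pairwise = diff[iu]
    # haplotype partition: identical iff zero pairwise difference
    k = _count_distinct(diff)
    return {
        "segregating_sites": int(mut[:-1].sum()),
        "theta_pi": float(pairwise.mean()),
        "k": k,
        "pairwise": pairwise.astype(int),
    }


def simulate_expansion_pairwise(
    n: int, theta0: float, theta1: float, tau: float, rng: np.random.Generator
) -> np.ndarray:
    """Pairwise difference counts for a sample from a population that grew
    from theta0 to theta1 at mutational time tau before the present."""
    theta1 = max(theta1, 1e-6)
    theta0 = max(theta0, 1e-6)

    def theta_fn(t):
        if t < tau:
            return theta1, tau
        return theta0, None

    parent, mut = _coalescent_mutational(n, theta_fn, rng)
    diff = _pairwise_from_genealogy(parent, mut, n)
    iu = np.triu_indices(n, 1)
    return diff[iu].astype(int)


def _count_distinct(diff: np.ndarray) -> int:
    n = diff.shape[0]
    seen = []
    for i in range(n):
        if not any(diff[i, j] == 0 for j in seen):
            seen.append(i)
    return len(seen)


# ---------------------------------------------------------------------------
# Microsatellites
# ---------------------------------------------------------------------------

def _drift_freqs(
    freq: dict[int, float],
    generations: int,
    two_ne: int,
    mutation_rate: float,
    motif: int,
    rng: np.random.Generator,
) -> dict[int, float]:
    """Wright-Fisher drift of one locus's allele-size frequencies, with
    optional stepwise mutation (+- one motif per event)."""
    for _ in range(generations):
        sizes = sorted(freq)
        p = np.array([freq[s] for s in sizes])
        counts = rng.multinomial(two_ne, p)
        if mutation_rate > 0:
            n_mut = rng.binomial(two_ne, mutation_rate)
            for _ in range(n_mut):
                nonzero = [i for i, c in enumerate(counts) if c > 0]
                src = nonzero[rng.integers(len(nonzero))]
                counts[src] -= 1
                step = motif if rng.random() < 0.5 else -motif
                new_size = sizes[src] + step
                if new_size not in sizes:
                    sizes.append(new_size)
                    counts = np.append(counts, 0)
                    order = np.argsort(sizes)
                    sizes = [sizes[i] for i in order]
                    counts = counts[order]
                counts[sizes.index(new_size)] += 1
        freq = {s: c / counts.sum() for s, c in zip(sizes, counts) if c > 0}
    return freq


def simulate_msat_genotypes(cfg: ScenarioConfig) -> tuple[GenotypeMatrix, PopulationMap]:
    """Diploid microsatellite genotypes under two-stage hierarchical drift.

    Allele frequencies start from a common base draw (symmetric Dirichlet
    over ``msat_base_alleles`` allele sizes spaced by the motif length); each
    of the two regions drifts independently for ``msat_region_generations``
    by multinomial resampling of 2Ne genes, then each site drifts a further
    ``msat_site_generations`` from its region's frequencies, giving strong
    between-region but weak within-region differentiation, as in the study
    system. Stepwise mutation (+- one motif) is applied at
    ``msat_mutation_rate`` per gene per generation. Genotypes are sampled in
    Hardy-Weinberg proportions. With ``msat_null_freq`` > 0 a null allele
    segregates: null homozygotes are recorded as missing, null heterozygotes
    as apparent homozygotes.
    """
    rng = derive_rng(cfg.seed, "msat_genotypes")
    n_pops = len(cfg.msat_sample_sizes)
    two_ne = int(round(2 * cfg.msat_ne))
    base_size = 100
    loci_freqs: list[dict[int, float]] = []
    for _ in range(cfg.msat_n_loci):
        sizes = [base_size + i * cfg.msat_motif for i in range(cfg.msat_base_alleles)]
        freqs = rng.dirichlet(np.ones(cfg.msat_base_alleles))
        loci_freqs.append(dict(zip(sizes, freqs)))

    n_north = min(cfg.msat_sites_northern, n_pops)
    region_of_pop = [0 if i < n_north else 1 for i in range(n_pops)]
    region_freqs: list[list[dict[int, float]]] = []
    for _ in range(2):
        region_freqs.append(
            [
                _drift_freqs(dict(base), cfg.msat_region_generations, two_ne,
                             cfg.msat_mutation_rate, cfg.msat_motif, rng)
                for base in loci_freqs
            ]
        )
    pop_locus_freqs: list[list[dict[int, float]]] = []
    for p_idx in range(n_pops):
        reg = region_freqs[region_of_pop[p_idx]]
        pop_locus_freqs.append(
            [
                _drift_freqs(dict(f), cfg.msat_site_generations, two_ne,
                             cfg.msat_mutation_rate, cfg.msat_motif, rng)
                for f in reg
            ]
        )

    ids, rows, ind_to_site = [], [], {}
    site_codes = [f"P{i + 1}" for i in range(n_pops)]
    null = -999  # sentinel allele state during sampling
    for p_idx, n_ind in enumerate(cfg.msat_sample_sizes):
        for i in range(n_ind):
            ind = f"{site_codes[p_idx]}_{i:03d}"
            ids.append(ind)
            ind_to_site[ind] = site_codes[p_idx]
            row = []
            for l in range(cfg.msat_n_loci):
                freq = pop_locus_freqs[p_idx][l]
                sizes = sorted(freq)
                p = np.array([freq[s] for s in sizes])
                if cfg.msat_null_freq > 0:
                    p = np.append(p * (1 - cfg.msat_null_freq), cfg.msat_null_freq)
                    sizes = sizes + [null]
                a, b = rng.choice(sizes, size=2, replace=True, p=p / p.sum())
                if a == null and b == null:
                    row.append((MISSING_ALLELE, MISSING_ALLELE))
                elif a == null:
                    row.append((int(b), int(b)))
                elif b == null:
                    row.append((int(a), int(a)))
                else:
                    row.append((int(a), int(b)))
            rows.append(row)
    gm = GenotypeMatrix(
        tuple(ids),
        tuple(f"loc{l + 1}" for l in range(cfg.msat_n_loci)),
        np.array(rows),
    )
    groups = {c: ("northern" if region_of_pop[i] == 0 else "southern") for i, c in enumerate(site_codes)}
    popmap = PopulationMap(ind_to_site, groups)
    return gm, popmap
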