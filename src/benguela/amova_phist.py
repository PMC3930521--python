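"""Distance-based hierarchical AMOVA and Phi-statistics with permutation tests.

The analysis of molecular variance partitions the sum of squared inter-
individual distances into hierarchical components (among groups, among
populations within groups, within populations) following the
Excoffier-Smouse-Quattro framework. Squared distances enter the sums of
squares (so a K80 matrix is squared element-wise first), negative variance
components are reported as-is rather than truncated, and permutation p-values
use the (1 + exceedances) / (1 + n_perm) estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from benguela.io_formats import PopulationMap, SequenceAlignment
from benguela.mtdna_diversity import DistanceMatrix, distance_matrix
from benguela.rng import derive_rng


@dataclass
class AmovaResult:
    """Variance components, Phi-statistics and permutation p-values."""

    n_levels: int
    df: dict
    ss: dict
    sigma2: dict                    # 'among_groups', 'among_pops_within', 'within_pops'
    percent: dict
    phi_st: float
    phi_ct: float | None = None
    phi_sc: float | None = None
    p_values: dict = field(default_factory=dict)
    n_perm: int = 0
    negative_components: bool = False

    def table(self) -> pd.DataFrame:
        rows = []
        for level in self.df:
            rows.append(
                {
                    "source": level,
                    "df": self.df[level],
                    "SS": self.ss[level],
                    "variance": self.sigma2.get(level, float("nan")),
                    "percent": self.percent.get(level, float("nan")),
                }
            )
        return pd.DataFrame(rows)


def permutation_p(observed: float, null_draws: np.ndarray) -> float:
    """p = (1 + #{null >= observed}) / (1 + n_perm); never exactly zero."""
    null_draws = np.asarray(null_draws, dtype=float)
    if null_draws.size < 1:
        raise ValueError("need at least one null draw")
    return float((1 + (null_draws >= observed).sum()) / (1 + null_draws.size))


def _ssd_within(d2: np.ndarray, masks: list[np.ndarray]) -> float:
    """Sum over units of (sum of squared distances within unit) / unit size."""
    total = 0.0
    for m in masks:
        idx = np.nonzero(m)[0]
        if idx.size:
            sub = d2[np.ix_(idx, idx)]
            total += sub.sum() / (2.0 * idx.size)
    return total


def _masks(labels: np.ndarray, uniq: list) -> list[np.ndarray]:
    return [labels == u for u in uniq]


def _one_level_components(d2: np.ndarray, pop_labels: np.ndarray):
    n = d2.shape[0]
    pops = list(dict.fromkeys(pop_labels))
    P = len(pops)
    sizes = np.array([(pop_labels == p).sum() for p in pops], dtype=float)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ssd_within(d2, _masks(pop_labels, pops))
    ss_among = ss_total - ss_within
    df_among, df_within = P - 1, n - P
    sigma_c = ss_within / df_within if df_within > 0 else 0.0
    n_prime = (n - (sizes**2).sum() / n) / (P - 1)
    sigma_a = (ss_among / df_among - sigma_c) / n_prime if df_among > 0 else 0.0
    return ss_total, ss_among, ss_within, df_among, df_within, sigma_a, sigma_c


def _phi_st_one_level(d2: np.ndarray, pop_labels: np.ndarray) -> float:
    *_, sigma_a, sigma_c = _one_level_components(d2, pop_labels)
    total = sigma_a + sigma_c
    return sigma_a / total if total != 0 else 0.0


def _two_level_components(d2: np.ndarray, pop_labels: np.ndarray, group_labels: np.ndarray):
    n = d2.shape[0]
    pops = list(dict.fromkeys(pop_labels))
    groups = list(dict.fromkeys(group_labels))
    P, G = len(pops), len(groups)
    ss_total = d2.sum() / (2.0 * n)
    ss_within_pops = _ssd_within(d2, _masks(pop_labels, pops))
    ss_within_groups = _ssd_within(d2, _masks(group_labels, groups))
    ss_ap_wg = ss_within_groups - ss_within_pops
    ss_ag = ss_total - ss_within_groups
    df_ag, df_ap, df_wp = G - 1, P - G, n - P

    pop_sizes = {p: float((pop_labels == p).sum()) for p in pops}
    group_sizes = {g: float((group_labels == g).sum()) for g in groups}
    group_of_pop = {}
    for p in pops:
        gl = group_labels[pop_labels == p]
        if len(set(gl)) != 1:
            raise ValueError(f"population {p!r} spans multiple groups")
        group_of_pop[p] = gl[0]

    sigma_c = ss_within_pops / df_wp if df_wp > 0 else 0.0
    # coefficients (Excoffier et al. 1992 unbalanced-design n', n'', n''')
    sum_sq_by_group = {
        g: sum(pop_sizes[p] ** 2 for p in pops if group_of_pop[p] == g) for g in groups
    }
    n1 = (
        (n - sum(sum_sq_by_group[g] / group_sizes[g] for g in groups)) / df_ap
        if df_ap > 0
        else float("nan")
    )
    n2 = (
        (sum(sum_sq_by_group[g] / group_sizes[g] for g in groups)
         - sum(pop_sizes[p] ** 2 for p in pops) / n) / df_ag
    )
    n3 = (n - sum(group_sizes[g] ** 2 for g in groups) / n) / df_ag

    if df_ap > 0:
        sigma_b = (ss_ap_wg / df_ap - sigma_c) / n1
    else:
        sigma_b = 0.0
    sigma_a = (ss_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    return (
        ss_total, ss_ag, ss_ap_wg, ss_within_pops,
        df_ag, df_ap, df_wp, sigma_a, sigma_b, sigma_c,
    )


def _phis_two_level(d2, pop_labels, group_labels):
    *_, sigma_a, sigma_b, sigma_c = _two_level_components(d2, pop_labels, group_labels)
    total = sigma_a + sigma_b + sigma_c
    phi_st = (sigma_a + sigma_b) / total if total != 0 else 0.0
    phi_ct = sigma_a / total if total != 0 else 0.0
    denom = sigma_b + sigma_c
    phi_sc = sigma_b / denom if denom != 0 else 0.0
    return phi_st, phi_ct, phi_sc


def amova(
    dist: DistanceMatrix,
    popmap: PopulationMap,
    grouping: int = 2,
    n_perm: int = 10_000,
    seed: int = 0,
) -> AmovaResult:
    """Hierarchical AMOVA on a distance matrix.

    ``grouping=1`` treats sites as populations with no higher level and
    returns Phi_ST only; ``grouping=2`` nests sites within their groups and
    returns Phi_CT / Phi_SC / Phi_ST, each with the level-appropriate
    permutation test (individuals among populations for Phi_ST; whole
    populations among groups for Phi_CT; individuals among populations within
    groups for Phi_SC).
    """
    ids = list(dist.ids)
    popmap.validate_ids(ids)
    d2 = dist.values**2
    pop_labels = popmap.site_labels(ids)
    pops = list(dict.fromkeys(pop_labels))
    if len(pops) < 2 and grouping == 1:
        # degenerate: everything within one population
        n = len(ids)
        ss_total = d2.sum() / (2.0 * n)
        return AmovaResult(
            n_levels=1,
            df={"within_pops": n - 1},
            ss={"within_pops": ss_total},
            sigma2={"within_pops": ss_total / (n - 1) if n > 1 else 0.0},
            percent={"within_pops": 100.0},
            phi_st=float("nan"),
            n_perm=0,
        )

    if grouping == 1:
        (ss_total, ss_among, ss_within, df_a, df_w, sigma_a, sigma_c) = (
            _one_level_components(d2, pop_labels)
        )
        total_var = sigma_a + sigma_c
        phi_st = sigma_a / total_var if total_var != 0 else 0.0
        result = AmovaResult(
            n_levels=1,
            df={"among_pops": df_a, "within_pops": df_w},
            ss={"among_pops": ss_among, "within_pops": ss_within},
            sigma2={"among_pops": sigma_a, "within_pops": sigma_c},
            percent={
                "among_pops": 100.0 * sigma_a / total_var if total_var else float("nan"),
                "within_pops": 100.0 * sigma_c / total_var if total_var else float("nan"),
            },
            phi_st=phi_st,
            n_perm=n_perm,
            negative_components=bool(sigma_a < 0),
        )
        if n_perm > 0:
            rng = derive_rng(seed, "amova1", *pops)
            null = np.empty(n_perm)
            labels = pop_labels.copy()
            for b in range(n_perm):
                rng.shuffle(labels)
                null[b] = _phi_st_one_level(d2, labels)
            result.p_values["phi_st"] = permutation_p(phi_st, null)
        return result

    group_labels = popmap.group_labels(ids)
    (
        ss_total, ss_ag, ss_ap, ss_wp, df_ag, df_ap, df_wp,
        sigma_a, sigma_b, sigma_c,
    ) = _two_level_components(d2, pop_labels, group_labels)
    total_var = sigma_a + sigma_b + sigma_c
    phi_st, phi_ct, phi_sc = _phis_two_level(d2, pop_labels, group_labels)
    result = AmovaResult(
        n_levels=2,
        df={"among_groups": df_ag, "among_pops_within": df_ap, "within_pops": df_wp},
        ss={"among_groups": ss_ag, "among_pops_within": ss_ap, "within_pops": ss_wp},
        sigma2={
            "among_groups": sigma_a,
            "among_pops_within": sigma_b,
            "within_pops": sigma_c,
        },
        percent={
            "among_groups": 100.0 * sigma_a / total_var if total_var else float("nan"),
            "among_pops_within": 100.0 * sigma_b / total_var if total_var else float("nan"),
            "within_pops": 100.0 * sigma_c / total_var if total_var else float("nan"),
        },
        phi_st=phi_st,
        phi_ct=phi_ct,
        phi_sc=phi_sc,
        n_perm=n_perm,
        negative_components=bool(sigma_a < 0 or sigma_b < 0),
    )
    if n_perm > 0:
        # Phi_ST: permute individuals among populations (across groups)
        rng = derive_rng(seed, "amova2-phist")
        null_st = np.empty(n_perm)
        labels = pop_labels.copy()
        glab_of_pop = {p: group_labels[pop_labels == p][0] for p in pops}
        for b in range(n_perm):
            rng.shuffle(labels)
            glab = np.array([glab_of_pop[p] for p in labels])
            null_st[b] = _phis_two_level(d2, labels, glab)[0]
        result.p_values["phi_st"] = permutation_p(phi_st, null_st)

        # Phi_CT: permute whole populations among groups
        rng = derive_rng(seed, "amova2-phict")
        groups_of_pops = np.array([glab_of_pop[p] for p in pops])
        null_ct = np.empty(n_perm)
        for b in range(n_perm):
            shuffled = groups_of_pops.copy()
            rng.shuffle(shuffled)
            assign = dict(zip(pops, shuffled))
            glab = np.array([assign[p] for p in pop_labels])
            null_ct[b] = _phis_two_level(d2, pop_labels, glab)[1]
        result.p_values["phi_ct"] = permutation_p(phi_ct, null_ct)

        # Phi_SC: permute individuals among populations within their group
        rng = derive_rng(seed, "amova2-phisc")
        null_sc = np.empty(n_perm)
        labels = pop_labels.copy()
        group_index = {g: np.nonzero(group_labels == g)[0] for g in dict.fromkeys(group_labels)}
        for b in range(n_perm):
            perm = labels.copy()
            for idx in group_index.values():
                perm[idx] = rng.permutation(perm[idx])
            null_sc[b] = _phis_two_level(d2, perm, group_labels)[2]
        result.p_values["phi_sc"] = permutation_p(phi_sc, null_sc)
    return result


@dataclass(frozen=True)
class PairwiseMatrix:
    """Lower-triangle pairwise statistic with matching p-values."""

    units: tuple[str, ...]
    statistic: pd.DataFrame
    p_values: pd.DataFrame
    tag: str


def pairwise_phist(
    aln: SequenceAlignment,
    popmap: PopulationMap,
    model: str = "K80",
    n_perm: int = 10_000,
    seed: int = 0,
) -> PairwiseMatrix:
    """Pairwise Phi_ST between sampling sites with permutation p-values.

    Each site pair is analysed as a two-population one-level AMOVA on the
    chosen distance model. Permutation streams are derived from the master
    seed and the (sorted) pair label, so the matrix is reproducible whatever
    the evaluation order.
    """
    popmap.validate_ids(aln.sample_ids)
    full = distance_matrix(aln, model)
    d2_full = full.values**2
    labels = popmap.site_labels(aln.sample_ids)
    sites = [s for s in popmap.sites if (labels == s).sum() > 0]
    if len(sites) < 2:
        raise ValueError("pairwise Phi_ST needs >= 2 populations with samples")
    stat = pd.DataFrame(np.nan, index=sites, columns=sites)
    pval = pd.DataFrame(np.nan, index=sites, columns=sites)
    for i, s1 in enumerate(sites):
        for s2 in sites[i + 1:]:
            idx = np.nonzero((labels == s1) | (labels == s2))[0]
            d2 = d2_full[np.ix_(idx, idx)]
            sub_labels = labels[idx]
            obs = _phi_st_one_level(d2, sub_labels)
            p = np.nan
            if n_perm > 0:
                rng = derive_rng(seed, "pairwise_phist", s1, s2)
                null = np.empty(n_perm)
                perm = sub_labels.copy()
                for b in range(n_perm):
                    rng.shuffle(perm)
                    null[b] = _phi_st_one_level(d2, perm)
                p = permutation_p(obs, null)
            stat.loc[s2, s1] = stat.loc[s1, s2] = obs
            pval.loc[s2, s1] = pval.loc[s1, s2] = p
    return PairwiseMatrix(tuple(sites), stat, pval, tag=f"phi_st[{model}]")
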