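"""Haplotype collapsing, sequence diversity statistics and distance models.

Site handling follows the convention of the standard AMOVA software: columns
containing a gap or an ambiguous base in *any* analysed sequence are excluded
from haplotype collapsing (complete deletion), while pairwise distances drop
only the sites that are non-comparable for the specific pair (pairwise
deletion). Nucleotide diversity is reported per comparable site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from benguela.io_formats import PopulationMap, SequenceAlignment

BASES = ("A", "C", "G", "T")
TRANSITION_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct haplotypes with per-site and per-group counts."""

    haplotypes: tuple[str, ...]          # representative sequences (comparable sites only)
    ids: tuple[str, ...]                 # H1, H2, ... by decreasing frequency
    counts: pd.DataFrame                 # haplotype id x site
    group_counts: pd.DataFrame           # haplotype id x group
    members: dict                        # haplotype id -> tuple of sample ids
    comparable_sites: tuple[int, ...]

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def private_haplotypes(self, level: str = "group") -> dict:
        """Haplotype ids observed in exactly one site (or group)."""
        table = self.group_counts if level == "group" else self.counts
        out: dict[str, list[str]] = {c: [] for c in table.columns}
        arr = table.to_numpy()
        for row, hid in enumerate(table.index):
            nz = np.nonzero(arr[row])[0]
            if len(nz) == 1:
                out[table.columns[nz[0]]].append(hid)
        return out


@dataclass(frozen=True)
class DiversitySummary:
    n: int
    n_haplotypes: int
    n_private: int
    haplotype_diversity: float
    nucleotide_diversity: float


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with its substitution-model tag."""

    ids: tuple[str, ...]
    values: np.ndarray
    model: str
    saturated: np.ndarray | None = None  # boolean mask of pairs beyond K80 validity

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")
        object.__setattr__(self, "values", v)


def comparable_columns(aln: SequenceAlignment) -> np.ndarray:
    """0-based indices of columns with a plain base (ACGT) in every sequence."""
    arr = aln.as_array()
    ok = np.isin(arr, BASES).all(axis=0)
    return np.nonzero(ok)[0]


def collapse_haplotypes(aln: SequenceAlignment, popmap: PopulationMap) -> HaplotypeTable:
    """Collapse sequences into distinct haplotypes over comparable sites.

    Haplotype ids H1, H2, ... are assigned by decreasing total frequency
    (ties broken by sequence string) so the most abundant haplotype is H1.
    """
    popmap.validate_ids(aln.sample_ids)
    cols = comparable_columns(aln)
    arr = aln.as_array()[:, cols]
    keys = ["".join(row) for row in arr]
    order: dict[str, list[int]] = {}
    for i, k in enumerate(keys):
        order.setdefault(k, []).append(i)
    ranked = sorted(order.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    hap_ids = [f"H{i + 1}" for i in range(len(ranked))]
    sites = list(popmap.sites)
    groups = list(popmap.groups)
    counts = pd.DataFrame(0, index=hap_ids, columns=sites)
    gcounts = pd.DataFrame(0, index=hap_ids, columns=groups)
    members = {}
    for hid, (_, rows) in zip(hap_ids, ranked):
        members[hid] = tuple(aln.sample_ids[r] for r in rows)
        for r in rows:
            site = popmap.site_of(aln.sample_ids[r])
            counts.loc[hid, site] += 1
            gcounts.loc[hid, popmap.site_to_group[site]] += 1
    return HaplotypeTable(
        haplotypes=tuple(k for k, _ in ranked),
        ids=tuple(hap_ids),
        counts=counts,
        group_counts=gcounts,
        members=members,
        comparable_sites=tuple(int(c) for c in cols),
    )


def variable_sites(aln: SequenceAlignment) -> tuple[list[int], list[int]]:
    """Variable and parsimony-informative column indices (0-based).

    A column is variable when >= 2 distinct plain bases are observed among the
    sequences with a base at that column; parsimony-informative when >= 2
    states are each carried by >= 2 sequences.
    """
    arr = aln.as_array()
    variable, informative = [], []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        col = col[np.isin(col, BASES)]
        if col.size == 0:
            continue
        states, counts = np.unique(col, return_counts=True)
        if len(states) >= 2:
            variable.append(j)
            if (counts >= 2).sum() >= 2:
                informative.append(j)
    return variable, informative


def fixed_differences(
    aln: SequenceAlignment, popmap: PopulationMap, level: str = "group"
) -> int:
    """Number of sites at which two groups share no observed base state."""
    labels = (
        popmap.group_labels(aln.sample_ids)
        if level == "group"
        else popmap.site_labels(aln.sample_ids)
    )
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"fixed differences need exactly 2 groups, got {uniq}")
    arr = aln.as_array()
    mask1 = labels == uniq[0]
    mask2 = labels == uniq[1]
    if mask1.sum() == 0 or mask2.sum() == 0:
        raise ValueError("a group has zero sequences")
    count = 0
    for j in range(arr.shape[1]):
        c1 = arr[mask1, j]
        c2 = arr[mask2, j]
        s1 = set(c1[np.isin(c1, BASES)])
        s2 = set(c2[np.isin(c2, BASES)])
        if s1 and s2 and not (s1 & s2):
            count += 1
    return count


def haplotype_diversity(counts: np.ndarray | list) -> float:
    """Unbiased gene (haplotype) diversity h = n/(n-1) (1 - sum p_i^2)."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def _pair_diff_and_len(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    ok = np.isin(a, BASES) & np.isin(b, BASES)
    return int((a[ok] != b[ok]).sum()), int(ok.sum())


def nucleotide_diversity(aln: SequenceAlignment) -> float:
    """Mean per-site pairwise difference over all n(n-1)/2 pairs.

    Pairwise deletion: each pair is compared over its own comparable sites.
    """
    if aln.n < 2:
        raise ValueError("nucleotide diversity needs n >= 2")
    arr = aln.as_array()
    total = 0.0
    pairs = 0
    for i in range(aln.n):
        for j in range(i + 1, aln.n):
            d, L = _pair_diff_and_len(arr[i], arr[j])
            if L > 0:
                total += d / L
            pairs += 1
    return total / pairs


def k80_distance(P: float, Q: float) -> float:
    """Kimura two-parameter distance from transition (P) and transversion (Q)
    proportions: d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

    Returns ``inf`` when the observed proportions are beyond the model's
    validity (saturation).
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("inf")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def _pair_P_Q(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    ok = np.isin(a, BASES) & np.isin(b, BASES)
    a, b = a[ok], b[ok]
    L = int(ok.sum())
    if L == 0:
        return 0.0, 0.0, 0
    diff = a != b
    ts = sum(1 for x, y in zip(a[diff], b[diff]) if (x, y) in TRANSITION_PAIRS)
    tv = int(diff.sum()) - ts
    return ts / L, tv / L, L


def distance_matrix(aln: SequenceAlignment, model: str = "K80") -> DistanceMatrix:
    """Pairwise distances under 'differences', 'p' or 'K80' with pairwise
    deletion of non-comparable sites."""
    if model not in ("differences", "p", "K80"):
        raise ValueError(f"unknown distance model: {model!r}")
    arr = aln.as_array()
    n = aln.n
    d = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if model == "differences":
                val, _ = _pair_diff_and_len(arr[i], arr[j])
                val = float(val)
            elif model == "p":
                diff, L = _pair_diff_and_len(arr[i], arr[j])
                val = diff / L if L else 0.0
            else:
                P, Q, L = _pair_P_Q(arr[i], arr[j])
                val = k80_distance(P, Q) if L else 0.0
                if not np.isfinite(val):
                    saturated[i, j] = saturated[j, i] = True
            d[i, j] = d[j, i] = val
    return DistanceMatrix(aln.sample_ids, d, model, saturated)


def diversity_summary(
    aln: SequenceAlignment, popmap: PopulationMap, level: str = "site"
) -> pd.DataFrame:
    """Per-site (or per-group) diversity table: n, H, PH, h, pi.

    PH counts haplotypes private to one site within its group when
    ``level='site'`` (matching how regional tables are usually reported) and
    haplotypes private to the group when ``level='group'``.
    """
    ht = collapse_haplotypes(aln, popmap)
    table = ht.counts if level == "site" else ht.group_counts
    private = ht.private_haplotypes(level=level)
    rows = []
    labels = (
        popmap.site_labels(aln.sample_ids)
        if level == "site"
        else popmap.group_labels(aln.sample_ids)
    )
    for unit in table.columns:
        counts = table[unit].to_numpy()
        n = int(counts.sum())
        if n == 0:
            continue
        sub_ids = [sid for sid, lab in zip(aln.sample_ids, labels) if lab == unit]
        sub = aln.subset(sub_ids)
        rows.append(
            {
                "unit": unit,
                "n": n,
                "H": int((counts > 0).sum()),
                "PH": len(private[unit]),
                "h": haplotype_diversity(counts) if n >= 2 else float("nan"),
                "pi": nucleotide_diversity(sub) if n >= 2 else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("unit")
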