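"""Neutrality tests, mismatch-distribution expansion inference and the
mutation-scaled rate/size conversions.

Tajima's D compares the pairwise (pi) and segregating-sites estimators of
theta; Fu's F_S is built on the Ewens sampling probability of observing at
least the sampled number of distinct haplotypes given theta = pi. Past sudden
growth leaves both statistics negative and produces a smooth unimodal
mismatch distribution, fitted here by least squares to the sudden-expansion
model F_j(tau, theta0, theta1); tau converts to calendar time through the
lineage divergence rate of the marker and the generation time of the
population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from benguela.io_formats import SequenceAlignment
from benguela.mtdna_diversity import BASES, _pair_diff_and_len
from benguela.rng import derive_rng


# ---------------------------------------------------------------------------
# Neutrality tests
# ---------------------------------------------------------------------------

@dataclass
class NeutralityResult:
    n: int
    segregating_sites: int
    theta_pi: float          # mean pairwise differences (per sequence)
    tajimas_d: float
    fus_fs: float
    p_tajimas_d: float | None = None
    p_fus_fs: float | None = None


def _segregating_sites(aln: SequenceAlignment) -> int:
    arr = aln.as_array()
    s = 0
    for j in range(arr.shape[1]):
        col = arr[:, j]
        col = col[np.isin(col, BASES)]
        if len(np.unique(col)) >= 2:
            s += 1
    return s


def mean_pairwise_differences(aln: SequenceAlignment) -> float:
    """theta_pi: mean number of differences over all pairs (per sequence,
    pairwise deletion)."""
    arr = aln.as_array()
    n = aln.n
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d, _ = _pair_diff_and_len(arr[i], arr[j])
            total += d
    return total / (n * (n - 1) / 2)


def tajimas_d_from_counts(n: int, s: int, theta_pi: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise
    differences, using the standard a1..e2 constants."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if s < 1:
        raise ValueError("Tajima's D undefined with S = 0")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    return float((theta_pi - s / a1) / np.sqrt(var))


def log_stirling_first(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n.

    Recurrence |s(n+1, k)| = n |s(n, k)| + |s(n, k-1)| evaluated in log space.
    """
    log_s = np.full(n + 1, -np.inf)
    log_s[1] = 0.0  # |s(1,1)| = 1
    for m in range(1, n):
        new = np.full(n + 1, -np.inf)
        new[1:] = np.logaddexp(np.log(m) + log_s[1:], log_s[:-1])
        log_s = new
    return log_s


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k | theta) for k = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    log_s = log_stirling_first(n)
    k = np.arange(n + 1)
    log_rising = special.gammaln(theta + n) - special.gammaln(theta)
    logp = log_s + k * np.log(theta) - log_rising
    p = np.exp(logp)
    p[0] = 0.0
    return p / p.sum()


def fus_fs(n: int, k_obs: int, theta_pi: float) -> float:
    """Fu's F_S = ln(S' / (1 - S')) with S' = P(K >= k_obs | theta = theta_pi).

    ``k_obs`` is the observed number of distinct haplotypes. Returns +inf for
    k_obs = 1 (S' = 1) and raises for theta_pi = 0.
    """
    if not (1 <= k_obs <= n):
        raise ValueError("k_obs must be in [1, n]")
    if k_obs == 1:
        return float("inf")
    if theta_pi <= 0:
        raise ValueError("F_S undefined for theta_pi = 0")
    p = ewens_k_distribution(n, theta_pi)
    s_prime = float(p[k_obs:].sum())
    s_prime = min(max(s_prime, 1e-300), 1 - 1e-15)
    return float(np.log(s_prime / (1.0 - s_prime)))


def neutrality_tests(
    aln: SequenceAlignment,
    n_sims: int = 1000,
    seed: int = 0,
) -> NeutralityResult:
    """Tajima's D and Fu's F_S for one population sample, with significance by
    neutral coalescent simulation conditioned on theta = theta_pi.

    The D test is two-sided (|D_sim| >= |D_obs|); the F_S test one-sided
    (F_S_sim <= F_S_obs), matching the directional interpretation of star-like
    genealogies.
    """
    n = aln.n
    s = _segregating_sites(aln)
    theta_pi = mean_pairwise_differences(aln)
    arr = aln.as_array()
    cols = np.nonzero(np.isin(arr, BASES).all(axis=0))[0]
    k_obs = len({"".join(row) for row in arr[:, cols]})
    d = tajimas_d_from_counts(n, s, theta_pi) if s >= 1 and n >= 4 else float("nan")
    fs = fus_fs(n, k_obs, theta_pi) if theta_pi > 0 else float("nan")
    p_d = p_fs = None
    if n_sims > 0 and np.isfinite(d) and np.isfinite(fs):
        from benguela.synthetic_data import simulate_coalescent_pairwise

        rng = derive_rng(seed, "neutrality", n)
        d_null = []
        fs_null = []
        for _ in range(n_sims):
            sim = simulate_coalescent_pairwise(n, theta_pi, rng)
            s_sim = sim["segregating_sites"]
            if s_sim < 1:
                continue
            d_null.append(tajimas_d_from_counts(n, s_sim, sim["theta_pi"]))
            if sim["theta_pi"] > 0:
                fs_null.append(fus_fs(n, sim["k"], sim["theta_pi"]))
        d_null = np.asarray(d_null)
        fs_null = np.asarray(fs_null)
        p_d = float((1 + (np.abs(d_null) >= abs(d)).sum()) / (1 + len(d_null)))
        p_fs = float((1 + (fs_null <= fs).sum()) / (1 + len(fs_null)))
    return NeutralityResult(n, s, theta_pi, d, fs, p_d, p_fs)


# ---------------------------------------------------------------------------
# Mismatch distribution and sudden-expansion fit
# ---------------------------------------------------------------------------

def mismatch_observed(aln: SequenceAlignment) -> np.ndarray:
    """Normalised histogram of pairwise difference counts (pairwise deletion)."""
    if aln.n < 2:
        raise ValueError("mismatch distribution needs n >= 2")
    arr = aln.as_array()
    diffs = []
    for i in range(aln.n):
        for j in range(i + 1, aln.n):
            d, _ = _pair_diff_and_len(arr[i], arr[j])
            diffs.append(d)
    diffs = np.asarray(diffs)
    hist = np.bincount(diffs)
    return hist / hist.sum()


def expected_mismatch(tau: float, theta0: float, theta1: float, max_diff: int) -> np.ndarray:
    """Sudden-expansion expected mismatch probabilities F_j for j = 0..max_diff.

    F_j = Fhat_j(theta1) + exp(-tau (theta1 + 1)/theta1) *
          sum_{i<=j} tau^i/i! [Fhat_{j-i}(theta0) - Fhat_{j-i}(theta1)]
    with Fhat_j(theta) = theta^j / (1 + theta)^{j+1}, the equilibrium
    geometric curve. The tau = 0 limit is the equilibrium curve at theta0.
    """
    j = np.arange(max_diff + 1)

    def fhat(theta):
        if theta <= 0:
            out = np.zeros(max_diff + 1)
            out[0] = 1.0
            return out
        return np.exp(j * np.log(theta) - (j + 1) * np.log1p(theta))

    f0, f1 = fhat(theta0), fhat(theta1)
    if tau <= 0:
        return f0
    if theta1 <= 0:
        return f0
    decay = np.exp(-tau * (theta1 + 1.0) / theta1)
    log_pois = j * np.log(tau) - special.gammaln(j + 1)
    pois = np.exp(log_pois)
    conv = np.convolve(pois, f0 - f1)[: max_diff + 1]
    return f1 + decay * conv


@dataclass
class ExpansionFit:
    theta0: float
    theta1: float
    tau: float
    ssd: float
    p_ssd: float | None = None
    tau_ci: tuple[float, float] | None = None
    converged: bool = True


def _fit_curve(observed: np.ndarray, theta1_cap: float = 2000.0) -> tuple[float, float, float, float, bool]:
    """Grid search + Nelder-Mead least-squares fit of (tau, theta0, theta1)."""
    max_diff = len(observed) - 1
    mean_diff = float(np.sum(np.arange(len(observed)) * observed))

    def ssd(params):
        tau, th0, th1 = params
        if tau < 0 or th0 < 0 or th1 < th0:
            return np.inf
        exp = expected_mismatch(tau, th0, th1, max_diff)
        return float(np.sum((observed - exp) ** 2))

    best = None
    tau_grid = np.linspace(0.0, max(max_diff, 1), 12)
    th0_grid = np.linspace(0.0, max(mean_diff, 0.5), 6)
    th1_grid = np.unique(np.concatenate([
        np.linspace(max(mean_diff, 0.5), 4 * max(mean_diff, 1.0), 5),
        [50.0, 200.0, 1000.0],
    ]))
    for t in tau_grid:
        for a in th0_grid:
            for b in th1_grid:
                if b < a:
                    continue
                val = ssd((t, a, b))
                if best is None or val < best[1]:
                    best = ((t, a, b), val)
    x0 = np.array(best[0])
    res = optimize.minimize(
        ssd, x0, method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-12},
    )
    tau, th0, th1 = res.x
    tau = max(tau, 0.0)
    th0 = min(max(th0, 0.0), max(th1, 0.0))
    th1 = min(max(th1, th0), theta1_cap)
    return tau, th0, th1, float(res.fun), bool(res.success or res.fun <= best[1])


def fit_sudden_expansion(
    observed: np.ndarray,
    n: int,
    n_boot: int = 1000,
    seed: int = 0,
) -> ExpansionFit:
    """Least-squares sudden-expansion fit with a parametric bootstrap.

    The goodness-of-fit p is the fraction of bootstrap replicates (coalescent
    samples of size ``n`` simulated under the fitted expansion, then refitted)
    whose SSD is >= the observed SSD; a non-small p means the sudden-expansion
    model cannot be rejected. The bootstrap also yields a percentile 95% CI
    for tau.
    """
    observed = np.asarray(observed, dtype=float)
    if (observed > 0).sum() < 2:
        raise ValueError("need >= 2 distinct difference counts to fit")
    tau, th0, th1, ssd_obs, ok = _fit_curve(observed)
    fit = ExpansionFit(th0, th1, tau, ssd_obs, converged=ok)
    if n_boot > 0:
        from benguela.synthetic_data import simulate_expansion_pairwise

        rng = derive_rng(seed, "mismatch_boot")
        ssd_null = []
        taus = []
        for _ in range(n_boot):
            diffs = simulate_expansion_pairwise(n, th0, th1, tau, rng)
            hist = np.bincount(diffs)
            hist = hist / hist.sum()
            if (hist > 0).sum() < 2:
                continue
            t_b, _, _, ssd_b, _ = _fit_curve(hist)
            ssd_null.append(ssd_b)
            taus.append(t_b)
        ssd_null = np.asarray(ssd_null)
        fit.p_ssd = float((1 + (ssd_null >= ssd_obs).sum()) / (1 + len(ssd_null)))
        if len(taus) >= 20:
            fit.tau_ci = (
                float(np.percentile(taus, 2.5)),
                float(np.percentile(taus, 97.5)),
            )
    return fit


# ---------------------------------------------------------------------------
# Clock conversions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClockConfig:
    """Molecular clock: between-lineage divergence rate in % per million
    years, sequence length in bp, and generation time in years."""

    divergence_rate_pct_per_my: float
    sequence_length: int
    generation_time_years: float

    def __post_init__(self) -> None:
        if self.divergence_rate_pct_per_my <= 0:
            raise ValueError("divergence rate must be positive")
        if self.sequence_length <= 0:
            raise ValueError("sequence length must be positive")
        if self.generation_time_years <= 0:
            raise ValueError("generation time must be positive")

    @property
    def mutations_per_sequence_per_year(self) -> float:
        """Per-lineage whole-sequence substitution rate per year (u).

        The divergence rate accrues along two lineages, so the per-lineage
        per-site rate is r/2; u = (r/2) * L.
        """
        r_per_site_per_year = self.divergence_rate_pct_per_my / 100.0 / 1e6
        return r_per_site_per_year / 2.0 * self.sequence_length


@dataclass(frozen=True)
class ExpansionTime:
    years: float
    generations: float
    years_ci: tuple[float, float] | None = None
    generations_ci: tuple[float, float] | None = None


def time_since_expansion(
    tau: float, clock: ClockConfig, tau_ci: tuple[float, float] | None = None
) -> ExpansionTime:
    """Convert mutation-scaled expansion time tau = 2 u t to calendar time.

    Reported both in years (u per year) and in generations (u per
    generation = u per year x generation time); the two scales differ by the
    generation time and both are returned because literature values mix the
    conventions.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    u_year = clock.mutations_per_sequence_per_year
    years = tau / (2.0 * u_year)
    generations = years / clock.generation_time_years
    ci_y = ci_g = None
    if tau_ci is not None:
        ci_y = (tau_ci[0] / (2 * u_year), tau_ci[1] / (2 * u_year))
        ci_g = (ci_y[0] / clock.generation_time_years, ci_y[1] / clock.generation_time_years)
    return ExpansionTime(years, generations, ci_y, ci_g)


@dataclass(frozen=True)
class RateConversions:
    theta: float
    M: float
    x: float
    mu: float
    m: float                     # migration rate per generation
    ne: float                    # effective size (total, from theta = x Ne mu)
    migrants_theta_M: float      # theta * M
    migrants_x_theta_M: float    # x * theta * M  (= x Ne m convention)


def rate_conversions(theta: float, M: float, x: float, mu: float) -> RateConversions:
    """Convert mutation-scaled coalescent-sampler outputs to natural units.

    theta = x Ne mu gives Ne = theta / (x mu); M = m / mu gives m = M mu;
    effective migrants per generation are reported both as theta*M and
    x*theta*M (the latter equals x Ne m) since both products appear in the
    literature.
    """
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if theta < 0 or M < 0 or x <= 0:
        raise ValueError("inputs must be non-negative (x positive)")
    m = M * mu
    ne = theta / (x * mu)
    return RateConversions(theta, M, x, mu, m, ne, theta * M, x * theta * M)


def net_divergence_time(
    dxy: float, d_within_1: float, d_within_2: float, divergence_rate_pct_per_my: float
) -> tuple[float, bool]:
    """Net-divergence dating surrogate: T = d_a / (r/100) in My with
    d_a = d_xy - (d_1 + d_2)/2.

    This is a simple point surrogate for a calibrated coalescent divergence
    time; it ignores ancestral polymorphism variance and lineage sorting.
    Returns (T_My, flagged) with ``flagged`` True when d_a < 0 (T clamped to 0).
    """
    if dxy < 0:
        raise ValueError("dxy must be non-negative")
    da = dxy - (d_within_1 + d_within_2) / 2.0
    if da < 0:
        return 0.0, True
    return da / (divergence_rate_pct_per_my / 100.0), False
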