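"""Mutation-rate estimation from fluctuation assays under the Lea-Coulson model.

A fluctuation assay grows many parallel cultures from small inocula and plates
each on selective media; the heavy-tailed ("jackpot") distribution of resistant
colony counts identifies the expected number of mutation events per culture, m.
The per-gene, per-division mutation rate is m / Nt, with Nt the number of cells
per culture at plating.

The Lea-Coulson distribution is a compound Poisson law: mutation events arrive
Poisson(m) and each founds a clone whose size K follows P(K = k) = 1/(k(k+1)),
the limit of exponential clone growth at the wild-type rate.  Its probability
mass function is computed by the Ma-Sandri-Sarkar recursion

    p_0 = exp(-m),   p_n = (m/n) * sum_{i=0}^{n-1} p_i / (n - i + 1),

which is the Panjer recursion for that compound Poisson.  Partial plating
(only a fraction ``efficiency`` of each culture plated) thins each clone
binomially; the thinned clone-size law feeds the same recursion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FluctuationExperiment",
    "NtEstimate",
    "RateEstimate",
    "lea_coulson_pmf",
    "log_likelihood",
    "estimate_m",
    "estimate_nt",
    "mutation_rate",
    "rate_fold_change",
]

#: Counts above this cap are binned into a right tail P(K >= cap) when
#: evaluating likelihoods, keeping jackpot cultures numerically stable.
DEFAULT_COUNT_CAP = 150

_CHI2_95_1DF = stats.chi2.ppf(0.95, df=1)  # 3.8415; LRT cutoff for 95% profile CI


@dataclass
class FluctuationExperiment:
    """Per-culture resistant-mutant counts from one fluctuation assay.

    ``plated_fraction`` is the fraction of each culture plated on selective
    media (1.0 = whole culture); values below 1 trigger the plating-efficiency
    adjusted likelihood.
    """

    mutant_counts: list[int]
    culture_ids: list[str] | None = None
    plated_fraction: float = 1.0
    strain: str = ""

    def __post_init__(self) -> None:
        self.mutant_counts = [int(c) for c in self.mutant_counts]
        if len(self.mutant_counts) < 2:
            raise ValueError("a fluctuation experiment needs at least 2 cultures")
        if any(c < 0 for c in self.mutant_counts):
            raise ValueError("mutant counts must be non-negative")
        if not (0 < self.plated_fraction <= 1):
            raise ValueError("plated_fraction must be in (0, 1]")
        if self.culture_ids is None:
            self.culture_ids = [f"c{i+1}" for i in range(len(self.mutant_counts))]
        if len(self.culture_ids) != len(self.mutant_counts):
            raise ValueError("culture_ids and mutant_counts lengths differ")

    @property
    def n_cultures(self) -> int:
        return len(self.mutant_counts)


@dataclass
class NtEstimate:
    """Cells per culture, from colony counts of a known dilution."""

    colony_count: int
    dilution_factor: float
    warning: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if self.colony_count < 0:
            raise ValueError("colony_count must be >= 0")
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be > 0")
        if self.colony_count == 0:
            self.warning = True
            warnings.warn("zero colonies: Nt = 0, mutation rate undefined downstream")

    @property
    def nt(self) -> float:
        return self.colony_count * self.dilution_factor


@dataclass
class RateEstimate:
    """A mutation rate m/Nt with confidence bounds on the same scale."""

    m_hat: float
    nt: float
    rate: float
    ci_low: float
    ci_high: float
    method: str = "lea-coulson-mle"

    def __post_init__(self) -> None:
        if self.m_hat < 0:
            raise ValueError("m_hat must be >= 0")
        if not (self.ci_low <= self.rate <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def _thinned_clone_pmf(k_max: int, efficiency: float) -> np.ndarray:
    """Clone-size pmf q[0..k_max] observed after binomial plating.

    The full-plating clone-size law is q_k = 1/(k(k+1)), k >= 1.  Plating a
    fraction eps of the culture thins each clone Binomial(k, eps); q[0] is the
    probability a mutation event leaves no plated mutant.  Computed by a
    truncated sum; accurate for efficiency >= ~0.01.
    """
    if efficiency == 1.0:
        q = np.zeros(k_max + 1)
        k = np.arange(1, k_max + 1)
        q[1:] = 1.0 / (k * (k + 1.0))
        return q
    # sum over true clone sizes k of q_k * Binom(k, eps).pmf(j)
    big_k = max(2000, 20 * max(k_max, 1))
    k = np.arange(1, big_k + 1)
    qk = 1.0 / (k * (k + 1.0))
    q = np.zeros(k_max + 1)
    # binomial pmf over j computed in log space, vectorized over k per j
    log1m = math.log1p(-efficiency)
    loge = math.log(efficiency)
    logk = np.concatenate(([0.0], np.cumsum(np.log(k))))  # log(k!)
    for j in range(0, k_max + 1):
        kk = k[k >= max(j, 1)]
        logc = logk[kk] - logk[j] - logk[kk - j]
        logp = logc + j * loge + (kk - j) * log1m
        q[j] = np.sum(qk[k >= max(j, 1)] * np.exp(logp))
    return q


def lea_coulson_pmf(m: float, k_max: int, efficiency: float = 1.0) -> np.ndarray:
    """P(0..k_max mutants per culture) under the Lea-Coulson model.

    Parameters
    ----------
    m
        Expected number of mutation events per culture (>= 0).
    k_max
        Largest count to evaluate; the returned vector has length k_max + 1.
    efficiency
        Fraction of the culture plated; 1.0 gives the plain Ma-Sandri-Sarkar
        recursion.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    if not (0 < efficiency <= 1):
        raise ValueError("efficiency must be in (0, 1]")
    if m == 0:
        p = np.zeros(k_max + 1)
        p[0] = 1.0
        return p
    q = _thinned_clone_pmf(k_max, efficiency)
    p = np.zeros(k_max + 1)
    p[0] = math.exp(-m * (1.0 - q[0]))
    # Panjer recursion for compound Poisson with jump law q
    j = np.arange(1, k_max + 1)
    jq = j * q[1:]
    for n in range(1, k_max + 1):
        p[n] = (m / n) * np.dot(jq[:n], p[n - 1::-1])
    return p


def log_likelihood(m: float, counts: np.ndarray, efficiency: float = 1.0,
                   cap: int = DEFAULT_COUNT_CAP) -> float:
    """Lea-Coulson log-likelihood of per-culture counts at parameter m.

    Counts above ``cap`` contribute the right-tail probability P(K >= cap),
    so jackpot cultures do not force evaluation of enormous pmf vectors.
    """
    counts = np.asarray(counts, dtype=int)
    capped = np.minimum(counts, cap)
    k_max = int(capped.max(initial=0))
    if m == 0:
        return 0.0 if np.all(counts == 0) else -np.inf
    p = lea_coulson_pmf(m, k_max, efficiency)
    ll = 0.0
    tail = None
    for c, craw in zip(capped, counts):
        if craw >= cap:
            if tail is None:
                tail = max(1.0 - p[:cap].sum(), 1e-300) if cap <= k_max else None
            prob = tail if tail is not None else max(1.0 - p.sum(), 1e-300)
        else:
            prob = max(p[c], 1e-300)
        ll += math.log(prob)
    return ll


def estimate_m(exp: FluctuationExperiment, cap: int = DEFAULT_COUNT_CAP,
               tol: float = 1e-6, confidence: float = 0.95) -> tuple[float, float, float]:
    """Maximum-likelihood m with a profile-likelihood confidence interval.

    Returns ``(m_hat, ci_low, ci_high)``.  All-zero counts give m_hat = 0
    with a one-sided interval [0, upper].
    """
    counts = np.asarray(exp.mutant_counts, dtype=int)
    eps = exp.plated_fraction
    chi2_cut = stats.chi2.ppf(confidence, df=1)
    n = len(counts)

    if np.all(counts == 0):
        # L(m) = exp(-C m q_eff); one-sided upper bound from the LRT
        q0 = _thinned_clone_pmf(0, eps)[0] if eps < 1 else 0.0
        upper = (chi2_cut / 2.0) / (n * (1.0 - q0))
        return 0.0, 0.0, upper

    def nll(m: float) -> float:
        return -log_likelihood(m, counts, eps, cap)

    # bracket: mean count is an upper-scale guide; LC mean is infinite but
    # the MLE sits well below the sample mean for realistic data
    hi = max(5.0, float(np.mean(np.minimum(counts, cap))) * 2 + 5)
    while nll(hi) < nll(hi * 0.7) and hi < 1e4:
        hi *= 2
    res = optimize.minimize_scalar(nll, bounds=(1e-9, hi), method="bounded",
                                   options={"xatol": tol})
    m_hat = float(res.x)
    ll_max = -float(res.fun)
    # score at 0+: if likelihood is decreasing from the origin, the MLE is 0
    if nll(1e-8) <= res.fun:
        m_hat, ll_max = 0.0, -nll(1e-8)

    target = ll_max - chi2_cut / 2.0

    def diff(m: float) -> float:
        return log_likelihood(m, counts, eps, cap) - target

    if m_hat == 0.0 or diff(max(m_hat * 1e-3, 1e-9)) > 0:
        lo_ci = 0.0
    else:
        lo_ci = float(optimize.brentq(diff, max(m_hat * 1e-3, 1e-9), m_hat, xtol=tol))
    hi_bracket = max(m_hat * 2, 1.0)
    while diff(hi_bracket) > 0 and hi_bracket < 1e6:
        hi_bracket *= 2
    hi_ci = float(optimize.brentq(diff, max(m_hat, 1e-9), hi_bracket, xtol=tol))
    return m_hat, lo_ci, hi_ci


def estimate_nt(colony_count: int, dilution_factor: float) -> NtEstimate:
    """Cells per culture from a dilution plate count: nt = colonies x dilution."""
    return NtEstimate(colony_count=int(colony_count), dilution_factor=float(dilution_factor))


def mutation_rate(m_hat: float, nt: float, ci: tuple[float, float] | None = None,
                  method: str = "lea-coulson-mle") -> RateEstimate:
    """Convert an m estimate into a per-gene per-division rate m/Nt."""
    if nt <= 0:
        raise ValueError("nt must be > 0")
    lo, hi = ci if ci is not None else (m_hat, m_hat)
    return RateEstimate(m_hat=m_hat, nt=nt, rate=m_hat / nt,
                        ci_low=lo / nt, ci_high=hi / nt, method=method)


def rate_fold_change(rate_a: float, rate_b: float) -> float:
    """Fold difference rate_a / rate_b between two mutation rates."""
    if rate_b <= 0:
        raise ValueError("rate_b must be > 0")
    return rate_a / rate_b
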