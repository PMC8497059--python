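"""Monte-Carlo exact comparison of mutation spectra and target-size estimation.

Two spectra are compared by arranging their class counts in a 2 x K
contingency table (K = 6 substitution classes, or 8 with single-bp indels)
and asking how probable the observed table is among all tables sharing its
margins.  The null distribution is the multivariate hypergeometric law on
row 1 conditional on both margins; significance is the probability of drawing
a table at least as improbable as the one observed, estimated from B random
margin-preserving tables with add-one smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .spectra import SpectrumCounts

__all__ = [
    "ContingencyTable",
    "SpectrumTestResult",
    "TargetSizeEstimate",
    "build_table",
    "table_log_probability",
    "table_probability",
    "spectrum_test",
    "bonferroni",
    "nonsense_target_size",
    "target_size",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


@dataclass
class ContingencyTable:
    """A 2 x K table of class counts for two spectra."""

    counts: np.ndarray  # shape (2, K), non-negative ints
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != 2:
            raise ValueError("table must be 2 x K")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape[1] != len(self.classes):
            raise ValueError("classes must label every column")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())


@dataclass
class SpectrumTestResult:
    """Output of the Monte-Carlo margin-conditional spectrum test."""

    observed_log_prob: float
    p_raw: float
    p_corrected: float
    n_random_tables: int
    n_tests: int
    seed: int | None


@dataclass
class TargetSizeEstimate:
    """Mutational target size of a reporter ORF, in base-pair equivalents.

    ``nonsense_target`` counts stop-creating substitution opportunities (each
    position contributes #stop-making-changes / 3); the effective target
    scales it by the observed total-to-nonsense point-mutation ratio.
    """

    nonsense_target: float
    effective_target: float
    n_nonsense: int
    n_point_total: int


def build_table(spec_a: SpectrumCounts, spec_b: SpectrumCounts,
                include_indels: bool = False) -> ContingencyTable:
    """Arrange two spectra as a 2 x K contingency table (zero columns kept).

    An 8-class spectrum may be reduced to the 6 substitution classes, but
    requesting indel columns from indel-free spectra is an error.
    """
    if include_indels and not (spec_a.include_indels and spec_b.include_indels):
        raise ValueError("indel categories requested but absent from a spectrum")
    from .spectra import ALL_CLASSES, SUB_CLASSES

    classes = ALL_CLASSES if include_indels else SUB_CLASSES
    a = np.array([spec_a.counts.get(c, 0.0) for c in classes])
    b = np.array([spec_b.counts.get(c, 0.0) for c in classes])
    if np.any(a != np.round(a)) or np.any(b != np.round(b)):
        raise ValueError("contingency tables need integer counts")
    return ContingencyTable(np.stack([a, b]).astype(np.int64), classes)


def table_log_probability(t: ContingencyTable) -> float:
    """Log multivariate hypergeometric probability of the table given margins.

    P = [prod_j C(c_j, a_j)] / C(n, r1) with c_j column totals, a_j row-1
    cells, r1 the row-1 total and n the grand total.
    """
    a = t.counts[0]
    c = t.col_totals
    r1 = t.row_totals[0]
    n = t.grand_total
    if n == 0:
        return 0.0

    def logchoose(top, bot):
        return gammaln(top + 1) - gammaln(bot + 1) - gammaln(top - bot + 1)

    return float(np.sum(logchoose(c, a)) - logchoose(n, r1))


def table_probability(t: ContingencyTable) -> float:
    """Multivariate hypergeometric probability of the observed table."""
    return float(np.exp(table_log_probability(t)))


def _random_table_log_probs(col_totals: np.ndarray, r1: int, B: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Log-probabilities of B random tables with the given margins."""
    draws = rng.multivariate_hypergeometric(col_totals, r1, size=B)  # (B, K)
    c = col_totals[None, :]
    n = int(col_totals.sum())
    logc = (gammaln(c + 1) - gammaln(draws + 1) - gammaln(c - draws + 1)).sum(axis=1)
    denom = gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1)
    return logc - denom


def spectrum_test(t: ContingencyTable, B: int = 10_000,
                  seed: int | None = None, n_tests: int = 1) -> SpectrumTestResult:
    """Monte-Carlo exact test of spectrum homogeneity on a 2 x K table.

    Samples B tables uniformly from the margin-conditional null and reports
    p = (1 + #{tables with probability <= observed}) / (B + 1), Bonferroni
    corrected over ``n_tests`` comparisons.  Deterministic given ``seed``.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    obs_lp = table_log_probability(t)
    r1 = int(t.row_totals[0])
    cols = t.col_totals
    # degenerate margins: only one table exists
    if r1 == 0 or int(t.row_totals[1]) == 0 or np.count_nonzero(cols) <= 1:
        p = 1.0
    else:
        rng = np.random.default_rng(seed)
        lps = _random_table_log_probs(cols, r1, B, rng)
        n_extreme = int(np.sum(lps <= obs_lp + 1e-9))
        p = (1 + n_extreme) / (B + 1)
    corrected = min(1.0, p * n_tests)
    return SpectrumTestResult(observed_log_prob=obs_lp, p_raw=p,
                              p_corrected=corrected, n_random_tables=B,
                              n_tests=n_tests, seed=seed)


def bonferroni(p_raw: float, n_tests: int) -> tuple[float, float]:
    """Bonferroni-corrected p and the alpha=0.05 significance cutoff.

    Returns ``(min(1, p_raw * n_tests), 0.05 / n_tests)``.
    """
    if not (0 <= p_raw <= 1):
        raise ValueError("p_raw must be in [0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p_raw * n_tests), 0.05 / n_tests


def nonsense_target_size(cds: str) -> float:
    """Stop-creating substitution opportunities of an ORF, in bp-equivalents.

    Every position of every non-stop codon is checked against its three
    possible substitutions; each premature-stop-creating change contributes
    1/3 bp.  The ORF's own terminal stop codon is excluded.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    n_codons = len(cds) // 3
    hits = 0
    for ci in range(n_codons):
        codon = cds[3 * ci: 3 * ci + 3]
        if codon in STOP_CODONS:
            continue  # the natural stop (or an internal stop) is not a target
        for off in range(3):
            for b in _BASES:
                if b == codon[off]:
                    continue
                mutated = codon[:off] + b + codon[off + 1:]
                if mutated in STOP_CODONS:
                    hits += 1
    return hits / 3.0


def target_size(n_missense: int, n_nonsense: int, cds: str,
                n_synonymous: int = 0) -> TargetSizeEstimate:
    """Effective mutational target size from missense/nonsense counts.

    The nonsense target is exactly enumerable from the CDS; scaling by the
    observed ratio of all point mutations to nonsense mutations gives the
    effective number of base pairs at which a point mutation inactivates
    the reporter.
    """
    if n_nonsense <= 0:
        raise ValueError("target size is undefined without nonsense observations")
    t_nonsense = nonsense_target_size(cds)
    n_total = n_missense + n_nonsense + n_synonymous
    return TargetSizeEstimate(
        nonsense_target=t_nonsense,
        effective_target=t_nonsense * n_total / n_nonsense,
        n_nonsense=n_nonsense,
        n_point_total=n_total,
    )
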