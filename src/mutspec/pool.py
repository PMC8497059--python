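"""Mutation calling from pooled-mutant amplicon pileups.

Independently derived reporter-gene mutants (e.g. canavanine-resistant CAN1
mutants) are pooled in roughly equal proportions and the reporter amplicon is
deep-sequenced.  With N mutants pooled, each true mutation is expected near
frequency 1/N; alleles in the window [0.65/N, 0.95] are called as mutations,
alleles below it are treated as sequencing error and alleles above it as
fixed strain-specific variants.  Multinucleotide mutations (MNMs) are
recognised as nearby same-frequency calls that co-occur on the same read
pairs; outlier frequencies reveal mutations carried by several pooled
mutants (multiplicity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from Bio.Seq import Seq

from .spectra import SpectrumCounts, collapse_substitution, complement

__all__ = [
    "PoolConfig",
    "PileupSite",
    "MutationCall",
    "MnmCall",
    "CooccurrenceRecord",
    "AmpliconMap",
    "filter_sites",
    "call_point_mutations",
    "merge_adjacent_indels",
    "detect_mnms",
    "estimate_multiplicity",
    "map_to_genome",
    "annotate_consequence",
    "strain_identity_check",
    "pool_spectrum",
    "call_pool",
]


@dataclass
class PoolConfig:
    """Thresholds governing pooled-amplicon mutation calling.

    Defaults are the operating point validated against Sanger sequencing of a
    38-mutant pool: allele-frequency window [0.65/N, 0.95], depth >= 200,
    pool fails QC if under 40% of the amplicon is callable, MNM partners
    within 10 bp at +/-9% frequency supported by >=70% read-pair
    co-occurrence, adjacent indels merged under a 10% frequency gap, and
    multiplicity assigned above mean + 2 SD of the pool's call frequencies.
    """

    n_mutants: int
    lower_factor: float = 0.65
    upper_freq: float = 0.95
    min_depth: int = 200
    min_callable_fraction: float = 0.40
    callable_interval: tuple[int, int] | None = None  # 1-based inclusive
    mnm_window: int = 10
    mnm_freq_tol: float = 0.09
    mnm_cooccur_min: float = 0.70
    indel_merge_tol: float = 0.10
    multiplicity_sd_k: float = 2.0
    identity_min_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.n_mutants < 1:
            raise ValueError("n_mutants must be >= 1")
        if not (0 < self.lower_factor / self.n_mutants < self.upper_freq < 1):
            raise ValueError("need 0 < lower_factor/N < upper_freq < 1")
        for name in ("mnm_freq_tol", "mnm_cooccur_min", "indel_merge_tol",
                     "min_callable_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def min_freq(self) -> float:
        return self.lower_factor / self.n_mutants


@dataclass
class PileupSite:
    """Per-position allele counts at one amplicon coordinate (1-based)."""

    pos: int
    ref: str
    depth: int
    counts: dict[str, int]  # A/C/G/T substitution-allele read counts
    ins: int = 0  # reads supporting an insertion event at this position
    dels: int = 0  # reads supporting a deletion event at this position

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        if self.ref not in "ACGT":
            raise ValueError(f"ref base must be A/C/G/T, got {self.ref!r}")
        for a, c in self.counts.items():
            if c > self.depth:
                raise ValueError(f"pos {self.pos}: count of {a} exceeds depth")


@dataclass
class MutationCall:
    """One called mutation in a pool."""

    amplicon_pos: int
    ref: str
    alt: str  # base for SNVs; "ins"/"del" for indels
    kind: str  # SNV | insertion | deletion
    frequency: float
    length: int = 1  # merged span for indels; 1 for SNVs
    multiplicity: int = 1
    in_mnm: bool = False
    consequence: str | None = None
    genome_chrom: str | None = None
    genome_pos: int | None = None
    spectrum_class: str | None = None

    @property
    def key(self) -> tuple[int, str]:
        return (self.amplicon_pos, self.alt)


@dataclass
class MnmCall:
    """A multinucleotide mutation: >=2 member calls phased by co-occurrence."""

    members: list[MutationCall]
    support: dict[tuple, float] = field(default_factory=dict)
    complex: bool = False

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("an MNM needs at least 2 member calls")
        self.members = sorted(self.members, key=lambda c: c.key)
        self.complex = len(self.members) > 2


@dataclass(frozen=True)
class CooccurrenceRecord:
    """Read-pair phasing evidence for an ordered pair of alleles."""

    pos_i: int
    alt_i: str
    pos_j: int
    alt_j: str
    reads_both: int
    reads_any: int

    def __post_init__(self) -> None:
        if self.reads_both > self.reads_any:
            raise ValueError("reads_both cannot exceed reads_any")

    @property
    def support(self) -> float:
        return self.reads_both / self.reads_any if self.reads_any else 0.0


@dataclass
class AmpliconMap:
    """Mapping between 1-based amplicon coordinates and the genome.

    The amplicon sequence is given on the forward genome strand starting at
    ``genome_start``.  ``orf_strand`` is the reporter ORF's strand relative
    to the amplicon; ``cds_start``/``cds_end`` delimit the CDS in amplicon
    coordinates (inclusive), read left-to-right for ``+`` and as the reverse
    complement for ``-``.
    """

    chrom: str
    genome_start: int
    amplicon_length: int
    orf_strand: str = "+"
    cds_start: int = 1
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.orf_strand not in "+-":
            raise ValueError("orf_strand must be '+' or '-'")
        if self.cds_end is None:
            self.cds_end = self.amplicon_length
        if (self.cds_end - self.cds_start + 1) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")

    def to_genome(self, amplicon_pos: int) -> int:
        if not (1 <= amplicon_pos <= self.amplicon_length):
            raise ValueError(f"position {amplicon_pos} outside amplicon")
        return self.genome_start + amplicon_pos - 1

    def cds_index(self, amplicon_pos: int) -> int | None:
        """0-based CDS coordinate in reading direction, or None outside CDS."""
        if not (self.cds_start <= amplicon_pos <= self.cds_end):
            return None
        if self.orf_strand == "+":
            return amplicon_pos - self.cds_start
        return self.cds_end - amplicon_pos


def filter_sites(pileup: list[PileupSite], cfg: PoolConfig) -> tuple[list[PileupSite], str]:
    """Depth/interval filter; returns (callable sites, pool QC verdict).

    Sites outside the callable interval or under ``min_depth`` are dropped;
    the pool FAILs QC when fewer than ``min_callable_fraction`` of amplicon
    positions survive.
    """
    if not pileup:
        raise ValueError("empty pileup")
    lo, hi = cfg.callable_interval or (1, max(s.pos for s in pileup))
    in_interval = [s for s in pileup if lo <= s.pos <= hi]
    passing = [s for s in in_interval if s.depth >= cfg.min_depth]
    amplicon_span = hi - lo + 1
    verdict = "PASS" if len(passing) / amplicon_span >= cfg.min_callable_fraction else "FAIL"
    return passing, verdict


def call_point_mutations(sites: Iterable[PileupSite], cfg: PoolConfig
                         ) -> tuple[list[MutationCall], list[MutationCall]]:
    """Call alleles in the pool frequency window; returns (calls, fixed_alleles).

    Alleles with f in [0.65/N, 0.95] become mutation calls; f > 0.95 are
    fixed strain variants routed to the identity check; lower frequencies
    are discarded as sequencing error.
    """
    f_min = cfg.min_freq
    calls: list[MutationCall] = []
    fixed: list[MutationCall] = []
    for s in sites:
        if s.depth <= 0:
            continue
        events: list[tuple[str, str, int]] = [
            (alt, "SNV", c) for alt, c in s.counts.items() if alt != s.ref and c > 0
        ]
        if s.ins > 0:
            events.append(("ins", "insertion", s.ins))
        if s.dels > 0:
            events.append(("del", "deletion", s.dels))
        for alt, kind, count in events:
            f = count / s.depth
            call = MutationCall(amplicon_pos=s.pos, ref=s.ref, alt=alt,
                                kind=kind, frequency=f)
            if f_min <= f <= cfg.upper_freq:
                calls.append(call)
            elif f > cfg.upper_freq:
                fixed.append(call)
    return calls, fixed


def merge_adjacent_indels(calls: list[MutationCall], cfg: PoolConfig) -> list[MutationCall]:
    """Merge runs of same-kind indels at adjacent positions with similar f.

    A run extends while the next call sits at the previous position + 1, has
    the same kind, and its frequency differs from the previous member by less
    than ``indel_merge_tol``.  The merged call sits at the leftmost position
    with the mean frequency and records the span length.
    """
    calls = sorted(calls, key=lambda c: (c.amplicon_pos, c.alt))
    out: list[MutationCall] = []
    run: list[MutationCall] = []

    def flush() -> None:
        if not run:
            return
        if len(run) == 1:
            out.append(run[0])
        else:
            mean_f = float(np.mean([c.frequency for c in run]))
            out.append(replace(run[0], frequency=mean_f, length=len(run)))
        run.clear()

    for c in calls:
        if c.kind == "SNV":
            flush()
            out.append(c)
            continue
        if (run and c.kind == run[-1].kind
                and c.amplicon_pos == run[-1].amplicon_pos + 1
                and abs(c.frequency - run[-1].frequency) < cfg.indel_merge_tol):
            run.append(c)
        else:
            flush()
            run.append(c)
    flush()
    return sorted(out, key=lambda c: c.key)


def detect_mnms(calls: list[MutationCall],
                cooccurrence: Iterable[CooccurrenceRecord],
                cfg: PoolConfig) -> tuple[list[MnmCall], list[MutationCall]]:
    """Group calls into MNMs by proximity, frequency match and read phasing.

    A pair becomes an MNM when the calls lie within ``mnm_window`` bp, their
    frequencies agree within ``mnm_freq_tol``, and at least
    ``mnm_cooccur_min`` of informative read pairs carry both alleles.  MNMs
    sharing a member are merged transitively into complex MNMs.  Candidate
    pairs without a co-occurrence record are left unresolved (no MNM).
    Returns (mnms, non-member calls); member calls are flagged ``in_mnm``.
    """
    cooc: dict[tuple, CooccurrenceRecord] = {}
    for r in cooccurrence:
        cooc[(r.pos_i, r.alt_i, r.pos_j, r.alt_j)] = r
        cooc[(r.pos_j, r.alt_j, r.pos_i, r.alt_i)] = r

    order = sorted(range(len(calls)), key=lambda i: calls[i].key)
    parent = list(range(len(calls)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    support: dict[tuple, float] = {}
    for ai in range(len(order)):
        for bi in range(ai + 1, len(order)):
            i, j = order[ai], order[bi]
            a, b = calls[i], calls[j]
            if abs(a.amplicon_pos - b.amplicon_pos) > cfg.mnm_window:
                continue
            if abs(a.frequency - b.frequency) > cfg.mnm_freq_tol:
                continue
            rec = cooc.get((a.amplicon_pos, a.alt, b.amplicon_pos, b.alt))
            if rec is None:
                continue  # unresolvable pair: never promoted to an MNM
            if rec.support >= cfg.mnm_cooccur_min:
                parent[find(i)] = find(j)
                support[(a.key, b.key)] = rec.support

    groups: dict[int, list[int]] = {}
    for i in range(len(calls)):
        groups.setdefault(find(i), []).append(i)

    mnms: list[MnmCall] = []
    singles: list[MutationCall] = []
    for members in groups.values():
        if len(members) >= 2:
            mcalls = [replace(calls[i], in_mnm=True) for i in members]
            keyset = {c.key for c in mcalls}
            sup = {k: v for k, v in support.items() if k[0] in keyset and k[1] in keyset}
            mnms.append(MnmCall(members=mcalls, support=sup))
        else:
            singles.append(calls[members[0]])
    mnms.sort(key=lambda m: m.members[0].key)
    singles.sort(key=lambda c: c.key)
    return mnms, singles


def estimate_multiplicity(calls: list[MutationCall],
                          cfg: PoolConfig) -> list[MutationCall]:
    """Assign multiplicities from frequency outliers.

    With mean mu and population SD sigma of all call frequencies in the pool,
    a call with f > mu + k*sigma represents round(f/mu) pooled mutants; all
    other calls have multiplicity 1.
    """
    if not calls:
        return []
    freqs = np.array([c.frequency for c in calls])
    if len(calls) == 1:
        import warnings

        warnings.warn("single call in pool: multiplicity defaults to 1")
        return [replace(calls[0], multiplicity=1)]
    mu = float(freqs.mean())
    sigma = float(freqs.std())  # population SD
    threshold = mu + cfg.multiplicity_sd_k * sigma
    out = []
    for c in calls:
        if sigma > 0 and c.frequency > threshold:
            mult = max(1, int(round(c.frequency / mu)))
        else:
            mult = 1
        out.append(replace(c, multiplicity=mult))
    return out


def map_to_genome(call: MutationCall, amap: AmpliconMap) -> MutationCall:
    """Attach genome coordinates and the strand-collapsed spectrum class."""
    gpos = amap.to_genome(call.amplicon_pos)
    if call.kind == "SNV":
        cls = collapse_substitution(call.ref, call.alt)
    elif call.length == 1:
        cls = "ins1" if call.kind == "insertion" else "del1"
    else:
        cls = None  # multi-bp indels carry no single-class label
    return replace(call, genome_chrom=amap.chrom, genome_pos=gpos, spectrum_class=cls)


def annotate_consequence(call: MutationCall, cds: str, amap: AmpliconMap) -> MutationCall:
    """Classify a call as missense/nonsense/synonymous/indel/noncoding.

    SNVs inside the CDS are translated through the standard code on the ORF
    strand; indels anywhere in the CDS are "indel"; calls outside the CDS
    are "noncoding".
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    idx = amap.cds_index(call.amplicon_pos)
    if idx is None:
        return replace(call, consequence="noncoding")
    if call.kind != "SNV":
        return replace(call, consequence="indel")
    alt = call.alt if amap.orf_strand == "+" else complement(call.alt)
    if cds[idx] != (call.ref if amap.orf_strand == "+" else complement(call.ref)):
        raise ValueError(f"pileup ref at amplicon pos {call.amplicon_pos} "
                         "disagrees with the CDS sequence")
    codon_i = idx // 3
    codon = cds[3 * codon_i: 3 * codon_i + 3]
    mutated = codon[: idx % 3] + alt + codon[idx % 3 + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    if aa_alt == "*" and aa_ref != "*":
        cons = "nonsense"
    elif aa_alt == aa_ref:
        cons = "synonymous"
    else:
        cons = "missense"
    return replace(call, consequence=cons)


def strain_identity_check(fixed_alleles: list[MutationCall],
                          expected_snps: set[tuple[int, str]],
                          cfg: PoolConfig | None = None) -> tuple[float, str]:
    """Compare fixed (f > 0.95) alleles against the strain's known SNPs.

    Returns (match fraction, verdict): PASS when at least
    ``identity_min_fraction`` of fixed alleles appear in the expected set,
    WARN when nothing fixed was observed but SNPs were expected.
    """
    min_frac = cfg.identity_min_fraction if cfg else 0.9
    if not fixed_alleles:
        return (1.0, "PASS") if not expected_snps else (0.0, "WARN")
    matched = sum(1 for c in fixed_alleles if c.key in expected_snps)
    frac = matched / len(fixed_alleles)
    return frac, ("PASS" if frac >= min_frac else "FAIL")


def pool_spectrum(calls: Iterable[MutationCall],
                  include_indels: bool = True) -> SpectrumCounts:
    """De novo spectrum over a strain's pooled calls.

    Each non-MNM call contributes its multiplicity to its strand-collapsed
    class; MNM members and multi-bp indels are excluded.  Single-bp indels
    are included unless ``include_indels`` is false.
    """
    import warnings

    spec = SpectrumCounts(include_indels=include_indels)
    used = 0
    for c in calls:
        if c.in_mnm:
            continue
        cls = c.spectrum_class
        if cls is None and c.kind == "SNV":
            cls = collapse_substitution(c.ref, c.alt)
        elif cls is None and c.length == 1:
            cls = "ins1" if c.kind == "insertion" else "del1"
        if cls is None or (not include_indels and cls in ("ins1", "del1")):
            continue
        spec.add(cls, c.multiplicity)
        used += 1
    if used == 0:
        warnings.warn("no usable calls: empty spectrum")
    return spec


def call_pool(pileup: list[PileupSite],
              cooccurrence: Iterable[CooccurrenceRecord],
              cfg: PoolConfig,
              amap: AmpliconMap | None = None,
              cds: str | None = None) -> dict:
    """Run the full calling pipeline on one pool.

    Returns a dict with keys ``calls`` (multiplicity-annotated single calls),
    ``mnms``, ``fixed``, ``qc`` and ``spectrum``.
    """
    sites, qc = filter_sites(pileup, cfg)
    raw_calls, fixed = call_point_mutations(sites, cfg)
    merged = merge_adjacent_indels(raw_calls, cfg)
    mnms, singles = detect_mnms(merged, cooccurrence, cfg)
    singles = estimate_multiplicity(singles, cfg) if singles else []
    if amap is not None:
        singles = [map_to_genome(c, amap) for c in singles]
        if cds is not None:
            singles = [annotate_consequence(c, cds, amap) for c in singles]
    spectrum = pool_spectrum(singles) if singles else SpectrumCounts(include_indels=True)
    return {"calls": singles, "mnms": mnms, "fixed": fixed, "qc": qc,
            "spectrum": spectrum}
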