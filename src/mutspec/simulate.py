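"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the three experimental inputs: Luria-Delbrück
fluctuation experiments (synchronous doubling with Poisson-thinned mutation
events per generation), pooled-mutant amplicon pileups with sequencing error
and optional MNMs, and a polymorphism panel of clade-structured strains in
which one clade's rare variants carry a C>A excess.  All generators are pure
functions of their configuration plus a seed, and return truth objects
sufficient to score downstream recovery without rerunning them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .fluctuation import FluctuationExperiment
from .panel import MISSING, PanelData, StrainMeta
from .pool import AmpliconMap, CooccurrenceRecord, PileupSite
from .spectra import SUB_CLASSES, complement

__all__ = [
    "SimTruth",
    "PlantedMutation",
    "simulate_fluctuation",
    "simulate_pool",
    "simulate_panel",
    "make_cds_fixture",
    "write_panel_vcf",
    "write_strain_metadata",
    "write_outgroup_table",
]

_CLASS_TO_BASES = {
    # class -> (pyrimidine-strand ref, alt); purine-strand handled by complement
    "A>C": ("A", "C"), "A>G": ("A", "G"), "A>T": ("A", "T"),
    "C>A": ("C", "A"), "C>G": ("C", "G"), "C>T": ("C", "T"),
}


@dataclass
class PlantedMutation:
    """Ground truth for one planted pool mutation."""

    pos: int
    ref: str
    alt: str
    kind: str  # SNV | insertion | deletion
    cls: str | None
    frequency: float
    mnm_partner: int | None = None  # amplicon pos of the paired MNM member


@dataclass
class SimTruth:
    """Ground truth of a simulation run; fully determines expected outputs."""

    seed: int
    kind: str
    params: dict = field(default_factory=dict)
    m_true: float | None = None
    planted: list[PlantedMutation] = field(default_factory=list)
    mutator_strains: list[str] = field(default_factory=list)
    clade_spectra: dict[str, list[float]] | None = None


def simulate_fluctuation(rate: float, n0: int, nt: int, n_cultures: int,
                         seed: int, strain: str = "sim") -> tuple[FluctuationExperiment, SimTruth]:
    """Simulate per-culture mutant counts under Luria-Delbrück dynamics.

    Cultures grow by synchronous doubling from n0 cells; each division
    mutates with probability ``rate`` (Poisson-thinned per generation) and
    mutant lineages double deterministically thereafter.  ``nt`` is rounded
    down to the nearest n0 * 2^G; the realised expected mutation count is
    m_true = rate * (nt_eff - n0).
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    if n0 >= nt:
        raise ValueError("n0 must be smaller than nt")
    generations = int(math.floor(math.log2(nt / n0)))
    nt_eff = n0 * 2 ** generations
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_cultures, dtype=np.int64)
    if rate > 0:
        for g in range(generations):
            # divisions during generation g -> g+1; each mutant daughter
            # founds a clone of final size 2^(G - g - 1)
            lam = rate * n0 * (2 ** g)
            new_mut = rng.poisson(lam, size=n_cultures)
            counts += new_mut * (2 ** (generations - g - 1))
    m_true = rate * (nt_eff - n0)
    exp = FluctuationExperiment(mutant_counts=counts.tolist(), strain=strain)
    truth = SimTruth(seed=seed, kind="fluctuation", m_true=m_true,
                     params={"rate": rate, "n0": n0, "nt": nt_eff,
                             "n_cultures": n_cultures})
    return exp, truth


def _random_amplicon(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _alt_for_class(ref: str, cls: str) -> str:
    """The alt base realising a strand-collapsed class at a given ref base."""
    pyr_ref, pyr_alt = _CLASS_TO_BASES[cls]
    if ref == pyr_ref:
        return pyr_alt
    if ref == complement(pyr_ref):
        return complement(pyr_alt)
    raise ValueError(f"ref {ref} incompatible with class {cls}")


def simulate_pool(n_mutants: int, class_probs: dict[str, float], depth: int,
                  error_rate: float, seed: int, amplicon_length: int = 1500,
                  mnm_fraction: float = 0.0,
                  callable_interval: tuple[int, int] | None = None,
                  sequence: str | None = None
                  ) -> tuple[list[PileupSite], list[CooccurrenceRecord], SimTruth]:
    """Simulate a pooled-amplicon pileup of ``n_mutants`` with planted truth.

    Each mutant carries one planted mutation: class drawn from
    ``class_probs`` (six substitution classes, optionally ins1/del1),
    position uniform in the callable interval, read support binomial at
    expected frequency 1/n_mutants.  Per-base substitution errors are
    uniform at ``error_rate`` (split over the three non-reference bases).
    A fraction ``mnm_fraction`` of mutants instead carries a two-site MNM
    within 10 bp with near-complete read co-occurrence.  Co-occurrence
    records are emitted for every pair of planted mutations within 10 bp.
    """
    if depth < 200:
        raise ValueError("depth must be >= 200")
    if 1.0 / n_mutants <= 2 * error_rate:
        raise ValueError("expected mutant frequency within noise floor; "
                         "inputs would be uncallable by design")
    rng = np.random.default_rng(seed)
    classes = list(class_probs)
    probs = np.array([class_probs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    seq = sequence if sequence is not None else _random_amplicon(amplicon_length, rng)
    amplicon_length = len(seq)
    lo, hi = callable_interval or (1, amplicon_length)

    n_mnm = int(round(mnm_fraction * n_mutants))
    planted: list[PlantedMutation] = []
    used: set[int] = set()

    def draw_site(cls: str, near: int | None = None) -> tuple[int, str, str]:
        for _ in range(10_000):
            if near is None:
                pos = int(rng.integers(lo, hi + 1))
            else:
                pos = int(np.clip(near + rng.integers(-10, 11), lo, hi))
            if pos in used:
                continue
            ref = seq[pos - 1]
            if cls in ("ins1", "del1"):
                used.add(pos)
                return pos, ref, cls
            try:
                alt = _alt_for_class(ref, cls)
            except ValueError:
                continue
            used.add(pos)
            return pos, ref, alt
        raise RuntimeError("could not place a planted mutation")

    for mi in range(n_mutants):
        is_mnm = mi < n_mnm
        cls = classes[int(rng.choice(len(classes), p=probs))]
        f = 1.0 / n_mutants
        pos, ref, alt = draw_site(cls)
        kind = ("insertion" if cls == "ins1"
                else "deletion" if cls == "del1" else "SNV")
        first = PlantedMutation(pos=pos, ref=ref,
                                alt=alt if kind == "SNV" else kind[:3],
                                kind=kind, cls=cls, frequency=f)
        planted.append(first)
        if is_mnm:
            cls2 = classes[int(rng.choice(len(classes), p=probs))]
            while cls2 not in SUB_CLASSES:
                cls2 = classes[int(rng.choice(len(classes), p=probs))]
            pos2, ref2, alt2 = draw_site(cls2, near=pos)
            planted.append(PlantedMutation(pos=pos2, ref=ref2, alt=alt2, kind="SNV",
                                           cls=cls2, frequency=f, mnm_partner=pos))
            first.mnm_partner = pos2

    by_pos: dict[int, list[PlantedMutation]] = {}
    for p in planted:
        by_pos.setdefault(p.pos, []).append(p)

    err_each = error_rate / 3.0
    bases = "ACGT"
    pileup: list[PileupSite] = []
    for pos in range(1, amplicon_length + 1):
        ref = seq[pos - 1]
        counts = {b: 0 for b in bases if b != ref}
        ins = dels = 0
        for p in by_pos.get(pos, []):
            k = int(rng.binomial(depth, p.frequency))
            if p.kind == "SNV":
                counts[p.alt] += k
            elif p.kind == "insertion":
                ins += k
            else:
                dels += k
        for b in counts:
            counts[b] += int(rng.binomial(depth, err_each))
        total_alt = sum(counts.values()) + ins + dels
        counts[ref] = max(depth - total_alt, 0)
        pileup.append(PileupSite(pos=pos, ref=ref, depth=depth,
                                 counts=counts, ins=ins, dels=dels))

    cooc: list[CooccurrenceRecord] = []
    snvs = [p for p in planted if p.kind == "SNV"]
    for i in range(len(snvs)):
        for j in range(i + 1, len(snvs)):
            a, b = snvs[i], snvs[j]
            if abs(a.pos - b.pos) > 10:
                continue
            reads_any = int(rng.binomial(depth, min(a.frequency + b.frequency, 1.0)))
            reads_any = max(reads_any, 1)
            if a.mnm_partner == b.pos:
                reads_both = int(rng.binomial(reads_any, 0.98))
            else:
                reads_both = int(rng.binomial(reads_any, 0.01))
            cooc.append(CooccurrenceRecord(pos_i=a.pos, alt_i=a.alt,
                                           pos_j=b.pos, alt_j=b.alt,
                                           reads_both=min(reads_both, reads_any),
                                           reads_any=reads_any))
    truth = SimTruth(seed=seed, kind="pool", planted=planted,
                     params={"n_mutants": n_mutants, "depth": depth,
                             "error_rate": error_rate,
                             "callable_interval": (lo, hi),
                             "sequence": seq})
    return pileup, cooc, truth


def simulate_panel(n_clades: int = 8, strains_per_clade: int = 20,
                   n_variants: int = 2000, mutator_clade: int = 0,
                   ca_multiplier: float = 3.0, max_carriers: int = 20,
                   base_spectrum: dict[str, float] | None = None,
                   rare_carrier_max: int = 2,
                   seed: int = 0) -> tuple[PanelData, SimTruth]:
    """Simulate a clade-structured polymorphism panel with a mutator clade.

    Variants are assigned an originating clade and a carrier count k drawn
    with probability proportional to 1/k (k <= ``max_carriers``); carriers
    are drawn within the originating clade first, spilling over at random.
    Strains are haploid, represented as homozygous diploids (AC = 2 per
    carrier).  Rare variants (k <= ``rare_carrier_max``, i.e. AC <= 4)
    originating in the mutator clade are drawn from the base spectrum with
    its C>A probability multiplied by ``ca_multiplier`` and renormalized.
    Every variant's ref allele is ancestral; 10% of VCF records are emitted
    with ref/alt swapped to exercise polarization downstream.
    """
    if ca_multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    base = base_spectrum or {"A>C": 0.08, "A>G": 0.28, "A>T": 0.08,
                             "C>A": 0.10, "C>G": 0.08, "C>T": 0.38}
    probs = np.array([base[c] for c in SUB_CLASSES], dtype=float)
    probs = probs / probs.sum()
    if probs[list(SUB_CLASSES).index("C>A")] == 0 and ca_multiplier > 1:
        raise ValueError("cannot multiply a zero-probability class")
    boosted = probs.copy()
    ica = list(SUB_CLASSES).index("C>A")
    boosted[ica] *= ca_multiplier
    boosted = boosted / boosted.sum()

    rng = np.random.default_rng(seed)
    n_strains = n_clades * strains_per_clade
    max_carriers = min(max_carriers, n_strains)
    clades = [f"clade{c+1}" for c in range(n_clades)]
    strains = [StrainMeta(name=f"{clades[c]}_s{i+1:02d}", clade=clades[c],
                          ploidy=1, zygosity="haploid")
               for c in range(n_clades) for i in range(strains_per_clade)]
    clade_of = np.repeat(np.arange(n_clades), strains_per_clade)

    k_support = np.arange(1, max_carriers + 1)
    k_probs = (1.0 / k_support) / np.sum(1.0 / k_support)
    mean_k = float(np.sum(k_support * k_probs))
    n_total = int(round(n_strains * n_variants / mean_k))

    origin = rng.integers(0, n_clades, size=n_total)
    kvals = rng.choice(k_support, size=n_total, p=k_probs)
    is_rare = kvals <= rare_carrier_max
    use_boost = is_rare & (origin == mutator_clade)
    cls_idx = np.empty(n_total, dtype=np.int64)
    n_boost = int(use_boost.sum())
    cls_idx[use_boost] = rng.choice(len(SUB_CLASSES), size=n_boost, p=boosted)
    cls_idx[~use_boost] = rng.choice(len(SUB_CLASSES), size=n_total - n_boost, p=probs)

    geno = np.zeros((n_total, n_strains), dtype=np.int8)
    members_by_clade = [np.where(clade_of == c)[0] for c in range(n_clades)]
    all_idx = np.arange(n_strains)
    for vi in range(n_total):
        k = int(kvals[vi])
        home = members_by_clade[origin[vi]]
        if k <= len(home):
            carriers = rng.choice(home, size=k, replace=False)
        else:
            extra = rng.choice(np.setdiff1d(all_idx, home), size=k - len(home),
                               replace=False)
            carriers = np.concatenate([home, extra])
        geno[vi, carriers] = 2  # haploid represented homozygous

    # reference genome alleles: ancestral on the pyrimidine or purine strand
    strand_flip = rng.random(n_total) < 0.5
    anc = np.empty(n_total, dtype="U1")
    der = np.empty(n_total, dtype="U1")
    for ci, c in enumerate(SUB_CLASSES):
        sel = cls_idx == ci
        a, d = _CLASS_TO_BASES[c]
        anc[sel] = a
        der[sel] = d
    flip = strand_flip
    anc[flip] = [complement(b) for b in anc[flip]]
    der[flip] = [complement(b) for b in der[flip]]

    # 10% of records encode the derived allele as REF
    swap = rng.random(n_total) < 0.10
    ref = np.where(swap, der, anc)
    alt = np.where(swap, anc, der)
    geno = np.where(swap[:, None], 2 - geno, geno).astype(np.int8)

    variants = pd.DataFrame({
        "chrom": "chrI",
        "pos": np.arange(1, n_total + 1) * 3,  # spaced, strictly increasing
        "ref": ref,
        "alt": alt,
    })
    panel = PanelData(variants=variants, genotypes=geno, strains=strains)
    # attach truth-polarized columns (the outgroup table regenerates these)
    panel.variants["ancestral"] = anc
    panel.variants["derived"] = der
    panel.variants["cls"] = [SUB_CLASSES[i] for i in cls_idx]
    from .panel import _recompute_ac

    _recompute_ac(panel)

    truth = SimTruth(
        seed=seed, kind="panel",
        params={"n_clades": n_clades, "strains_per_clade": strains_per_clade,
                "n_variants": n_variants, "ca_multiplier": ca_multiplier,
                "mutator_clade": clades[mutator_clade]},
        mutator_strains=[s.name for s in strains if s.clade == clades[mutator_clade]],
        clade_spectra={clades[c]: (boosted if c == mutator_clade else probs).tolist()
                       for c in range(n_clades)},
    )
    return panel, truth


def make_cds_fixture(n_codons: int, seed: int, flank: int = 30
                     ) -> tuple[str, str, AmpliconMap]:
    """Random ORF fixture: (cds, amplicon sequence, amplicon map).

    The ORF starts ATG, ends TAA, and contains no internal stop; the
    amplicon adds ``flank`` random bases on each side.
    """
    if n_codons < 10:
        raise ValueError("need at least 10 codons")
    rng = np.random.default_rng(seed)
    stop = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in stop:
            codons.append(c)
    codons.append("TAA")
    cds = "".join(codons)
    assert "*" not in str(Seq(cds[:-3]).translate())
    left = _random_amplicon(flank, rng)
    right = _random_amplicon(flank, rng)
    amplicon = left + cds + right
    amap = AmpliconMap(chrom="chrV", genome_start=30_000,
                       amplicon_length=len(amplicon), orf_strand="+",
                       cds_start=flank + 1, cds_end=flank + len(cds))
    return cds, amplicon, amap


def write_panel_vcf(panel: PanelData, path) -> None:
    """Write the panel as a plain-text VCF 4.2 with GT fields."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    names = panel.strain_names
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chrI>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        v = panel.variants
        for i in range(len(v)):
            gts = "\t".join(gt_map[int(g)] for g in panel.genotypes[i])
            fh.write(f"{v.chrom.iat[i]}\t{v.pos.iat[i]}\t.\t{v.ref.iat[i]}\t"
                     f"{v.alt.iat[i]}\t.\tPASS\t.\tGT\t{gts}\n")


def write_strain_metadata(panel: PanelData, path) -> None:
    rows = [{"name": s.name, "clade": s.clade, "ploidy": s.ploidy,
             "zygosity": s.zygosity, "include": int(s.include)}
            for s in panel.strains]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_outgroup_table(panel: PanelData, path, n_outgroup: int = 5,
                         support: int = 5) -> None:
    """Emit an outgroup allele table whose consensus is the true ancestral state.

    ``support`` of the ``n_outgroup`` strains carry the ancestral allele;
    the rest carry the derived allele (so support=4 exercises the 4-of-5
    rule's boundary).
    """
    v = panel.variants
    cols = {"chrom": v["chrom"], "pos": v["pos"]}
    for k in range(n_outgroup):
        allele = v["ancestral"] if k < support else v["derived"]
        cols[f"og{k+1}"] = allele
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
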