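"""Mutation-spectrum analysis of a polymorphism panel.

Rare segregating variants record the recent mutational input of each strain's
lineage.  After polarizing alleles against an outgroup (a variant's ancestral
state is accepted when at least 4 of 5 outgroup genomes are fixed for it) and
filtering to well-behaved biallelic SNPs at derived allele frequency < 0.5,
each strain's derived alleles are tallied into the six strand-collapsed
substitution classes.  PCA of per-strain spectra reveals clade structure and
outliers; strains whose rare variants are enriched for C>A (the signature of
unrepaired 8-oxo-guanine) are detected by rank and by a bootstrap test
against the panel-pooled class distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .spectra import SUB_CLASSES, collapse_substitution

__all__ = [
    "PanelData",
    "StrainMeta",
    "PcaResult",
    "EnrichmentResult",
    "polarize_variants",
    "filter_variants",
    "exclude_relatives",
    "strain_spectrum",
    "spectra_matrix",
    "spectrum_pca",
    "ca_enrichment",
    "ca_by_ac_bin",
    "candidate_mutator_scan",
]

MISSING = -1  # genotype code for ./.


@dataclass
class StrainMeta:
    """Panel strain metadata: clade, ploidy and zygosity class."""

    name: str
    clade: str = ""
    ploidy: int = 1
    zygosity: str = "haploid"  # haploid | homozygous-diploid | heterozygous
    include: bool = True


@dataclass
class PanelData:
    """A polymorphism panel: variant table + genotype dosage matrix.

    ``variants`` holds one row per biallelic SNP (chrom, pos, ref, alt, and
    after polarization: ancestral, derived, cls, ac, daf).  ``genotypes`` is
    an int8 matrix (variants x strains) of ALT-dosages 0/1/2 with -1 for
    missing.  ``strains`` is a list of :class:`StrainMeta` aligned with the
    matrix columns.
    """

    variants: pd.DataFrame
    genotypes: np.ndarray
    strains: list[StrainMeta]

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.variants), len(self.strains)):
            raise ValueError("genotype matrix shape mismatch")

    @property
    def strain_names(self) -> list[str]:
        return [s.name for s in self.strains]

    def subset_variants(self, mask: np.ndarray) -> "PanelData":
        return PanelData(self.variants.loc[mask].reset_index(drop=True),
                         self.genotypes[np.asarray(mask)], self.strains)

    def subset_strains(self, names: list[str]) -> "PanelData":
        idx = [self.strain_names.index(n) for n in names]
        return PanelData(self.variants.copy(), self.genotypes[:, idx],
                         [self.strains[i] for i in idx])


@dataclass
class PcaResult:
    """Spectrum PCA output: orthonormal loadings, projections, variance."""

    loadings: np.ndarray  # (n_components, n_classes)
    projections: pd.DataFrame  # strains x components
    explained_variance_ratio: np.ndarray
    sampled_strains: list[str] = field(default_factory=list)


@dataclass
class EnrichmentResult:
    """Per-strain C>A enrichment: fraction, rank percentile, bootstrap p."""

    strain: str
    ca_fraction: float
    rank_percentile: float
    p_boot: float
    n_variants: int
    flagged_top: bool


def polarize_variants(panel: PanelData, outgroup: pd.DataFrame,
                      min_support: int = 4) -> PanelData:
    """Infer ancestral alleles from an outgroup allele table.

    ``outgroup`` has columns chrom, pos and one column per outgroup strain
    holding its allele ('.' or 'N' = missing).  A site is callable when at
    least ``min_support`` outgroup strains are fixed for one allele and that
    allele matches the panel ref or alt; outgroup alleles matching neither
    leave the site uncallable.  Adds columns ancestral, derived, cls (the
    strand-collapsed ancestral>derived class), ac and daf (diploid-convention
    derived allele count/frequency).
    """
    og_strains = [c for c in outgroup.columns if c not in ("chrom", "pos")]
    og = outgroup.set_index(["chrom", "pos"])
    v = panel.variants.copy()
    anc = []
    for chrom, pos, ref, alt in zip(v["chrom"], v["pos"], v["ref"], v["alt"]):
        try:
            row = og.loc[(chrom, pos)]
        except KeyError:
            anc.append(None)
            continue
        alleles = [str(row[s]).upper() for s in og_strains]
        alleles = [a for a in alleles if a in "ACGT"]
        call = None
        for base in set(alleles):
            if alleles.count(base) >= min_support and base in (ref, alt):
                call = base
                break
        anc.append(call)
    v["ancestral"] = anc
    v["derived"] = [
        (alt if a == ref else ref) if a is not None else None
        for a, ref, alt in zip(v["ancestral"], v["ref"], v["alt"])
    ]
    v["cls"] = [
        collapse_substitution(a, d) if a is not None else None
        for a, d in zip(v["ancestral"], v["derived"])
    ]
    out = PanelData(v, panel.genotypes, panel.strains)
    _recompute_ac(out)
    return out


def derived_dosage(panel: PanelData) -> np.ndarray:
    """Derived-allele dosage matrix (variants x strains), 0 where missing.

    Uncallable (unpolarized) variants get all-zero rows.
    """
    g = panel.genotypes
    anc_is_ref = (panel.variants["ancestral"] == panel.variants["ref"]).to_numpy()
    callable_ = panel.variants["ancestral"].notna().to_numpy()
    d = np.where(anc_is_ref[:, None], g, 2 - g).astype(np.int16)
    d[g == MISSING] = 0
    d[~callable_] = 0
    return d


def _recompute_ac(panel: PanelData) -> None:
    """Recompute diploid-convention AC and DAF in place (missing -> 0)."""
    d = derived_dosage(panel)
    ac = d.sum(axis=1)
    n_called = (panel.genotypes != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        daf = np.where(n_called > 0, ac / (2.0 * n_called), np.nan)
    panel.variants["ac"] = ac
    panel.variants["daf"] = daf


def filter_variants(panel: PanelData,
                    mappable: pd.DataFrame | None = None,
                    repeats: pd.DataFrame | None = None,
                    max_missing: float = 0.20,
                    max_daf: float = 0.5) -> PanelData:
    """Apply the panel variant filters.

    Keeps biallelic SNPs with missingness strictly below ``max_missing``,
    inside the mappable-region include mask, outside the repeat mask, with a
    callable ancestral state and derived allele frequency strictly below
    ``max_daf``.  Masks are BED-convention DataFrames (chrom, start, end;
    0-based half-open); a None mappable mask keeps everything.
    """
    v = panel.variants
    n_strains = panel.genotypes.shape[1]
    missing_frac = (panel.genotypes == MISSING).sum(axis=1) / n_strains
    is_snp = (v["ref"].str.len() == 1) & (v["alt"].str.len() == 1) \
        & v["ref"].str.upper().isin(list("ACGT")) & v["alt"].str.upper().isin(list("ACGT"))
    keep = is_snp.to_numpy() & (missing_frac < max_missing)
    keep &= v["ancestral"].notna().to_numpy()
    daf = v["daf"].to_numpy()
    keep &= np.nan_to_num(daf, nan=1.0) < max_daf
    for mask_df, include in ((mappable, True), (repeats, False)):
        if mask_df is None:
            continue
        inside = np.zeros(len(v), dtype=bool)
        for chrom, sub in mask_df.groupby("chrom"):
            sel = (v["chrom"] == chrom).to_numpy()
            if not sel.any():
                continue
            inside[sel] = _positions_in_intervals(v["pos"].to_numpy()[sel], sub)
        keep &= inside if include else ~inside
    return panel.subset_variants(keep)


def _positions_in_intervals(pos_1based: np.ndarray, sub: pd.DataFrame) -> np.ndarray:
    if np.any(sub["end"].to_numpy() <= sub["start"].to_numpy()):
        raise ValueError("malformed interval: end <= start")
    sub = sub.sort_values("start")
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    p0 = pos_1based - 1
    idx = np.searchsorted(starts, p0, side="right") - 1
    ok = idx >= 0
    res = np.zeros(len(p0), dtype=bool)
    res[ok] = p0[ok] < ends[idx[ok]]
    return res


def exclude_relatives(distance: pd.DataFrame, threshold: float = 8000) -> list[str]:
    """Drop close relatives until no pair is nearer than ``threshold``.

    ``distance`` is a symmetric strain-by-strain matrix.  Iteratively, the
    closest remaining pair is found and the member with more close relatives
    is dropped (ties broken by dropping the lexicographically later name).
    Returns the retained strain names, in input order.
    """
    d = distance.to_numpy().astype(float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    names = list(distance.index)
    alive = np.ones(len(names), dtype=bool)
    np.fill_diagonal(d, np.inf)
    while True:
        sub = np.where(alive[:, None] & alive[None, :], d, np.inf)
        i, j = np.unravel_index(np.argmin(sub), sub.shape)
        if sub[i, j] >= threshold:
            break
        close_i = np.sum(sub[i] < threshold)
        close_j = np.sum(sub[j] < threshold)
        if close_i != close_j:
            drop = i if close_i > close_j else j
        else:
            drop = i if names[i] > names[j] else j
        alive[drop] = False
    return [n for n, a in zip(names, alive) if a]


def _mode_weights(panel: PanelData, mode: str) -> np.ndarray:
    """Per-variant, per-strain spectrum weights for the given counting mode."""
    d = derived_dosage(panel)
    ac = panel.variants["ac"].to_numpy()
    if mode == "all":
        return d.astype(float)  # hom-derived 2, het 1
    if mode == "rare":
        w = (d > 0).astype(float)  # hom and het both weight 1
        w[~np.isin(ac, (2, 3, 4))] = 0.0
        return w
    if mode == "singleton":
        carriers = (d > 0).sum(axis=1)
        w = (d > 0).astype(float)
        w[carriers != 1] = 0.0
        # zygosity requirement: hom for haploid/homozygous-diploid, het otherwise
        needs_hom = np.array([s.zygosity in ("haploid", "homozygous-diploid")
                              for s in panel.strains])
        hom = d == 2
        het = d == 1
        w *= np.where(needs_hom[None, :], hom, het)
        return w
    raise ValueError(f"unknown mode {mode!r}")


def spectra_matrix(panel: PanelData, mode: str = "rare") -> pd.DataFrame:
    """Per-strain spectrum counts (strains x 6 classes) for a counting mode.

    Modes: ``all`` (every derived allele, hom weight 2 / het weight 1),
    ``rare`` (AC in {2,3,4}, hom and het weight 1), ``singleton`` (variants
    private to one strain, zygosity-aware).
    """
    if panel.variants["ancestral"].isna().any():
        raise ValueError("panel must be polarized before spectrum counting")
    w = _mode_weights(panel, mode)
    cls = panel.variants["cls"].to_numpy()
    out = np.zeros((len(panel.strains), len(SUB_CLASSES)))
    for k, c in enumerate(SUB_CLASSES):
        sel = cls == c
        if sel.any():
            out[:, k] = w[sel].sum(axis=0)
    return pd.DataFrame(out, index=panel.strain_names, columns=list(SUB_CLASSES))


def strain_spectrum(panel: PanelData, strain: str, mode: str = "rare"):
    """One strain's spectrum under a counting mode; see :func:`spectra_matrix`."""
    from .spectra import SpectrumCounts

    row = spectra_matrix(panel, mode).loc[strain]
    return SpectrumCounts(dict(row), include_indels=False)


def spectrum_pca(spectra: pd.DataFrame, populations: pd.Series | None = None,
                 population_cap: int = 30, min_variants: int = 8,
                 n_components: int = 2, seed: int | None = None) -> PcaResult:
    """PCA of per-strain normalized spectra.

    Strains with fewer than ``min_variants`` counted variants are excluded;
    each population is randomly subsampled to at most ``population_cap``
    strains to balance representation.  Columns are mean-centered before
    eigendecomposition.  The sign of each loading is fixed so its
    largest-magnitude entry is positive, making results reproducible.
    """
    totals = spectra.sum(axis=1)
    keep = spectra.index[totals >= min_variants]
    spectra = spectra.loc[keep]
    rng = np.random.default_rng(seed)
    if populations is not None:
        chosen: list = []
        pops = populations.loc[spectra.index]
        for pop in sorted(pops.unique()):
            members = sorted(spectra.index[pops == pop])
            if len(members) > population_cap:
                members = list(rng.choice(members, size=population_cap, replace=False))
            chosen.extend(members)
        spectra = spectra.loc[sorted(chosen, key=list(spectra.index).index)]
    if len(spectra) < max(3, n_components):
        raise ValueError("not enough strains for the requested components")
    x = spectra.to_numpy(dtype=float)
    x = x / x.sum(axis=1, keepdims=True)
    pca = PCA(n_components=n_components, svd_solver="full")
    with np.errstate(invalid="ignore"):  # all-identical spectra: zero variance
        proj = pca.fit_transform(x)  # sklearn centers internally
    loadings = pca.components_
    for k in range(loadings.shape[0]):
        jmax = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, jmax] < 0:
            loadings[k] = -loadings[k]
            proj[:, k] = -proj[:, k]
    cols = [f"PC{i+1}" for i in range(n_components)]
    evr = np.nan_to_num(pca.explained_variance_ratio_)  # 0 for zero-variance input
    return PcaResult(
        loadings=loadings,
        projections=pd.DataFrame(proj, index=spectra.index, columns=cols),
        explained_variance_ratio=evr,
        sampled_strains=list(spectra.index),
    )


def ca_enrichment(spectra: pd.DataFrame, top_fraction: float = 0.05,
                  B: int = 10_000, seed: int | None = None,
                  min_variants: int = 8) -> list[EnrichmentResult]:
    """Rank strains by C>A fraction and bootstrap each against the pooled null.

    The null resamples each strain's variant count from the panel-pooled
    rare-variant class distribution; since only the C>A fraction is scored,
    the resampled C>A count is drawn from its exact binomial marginal.
    p = (1 + #{resampled fraction >= observed}) / (B + 1).  Strains in the
    top ``top_fraction`` by rank are flagged.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    spectra = spectra.loc[spectra.sum(axis=1) >= min_variants]
    totals = spectra.sum(axis=1).to_numpy()
    ca = spectra["C>A"].to_numpy()
    frac = ca / totals
    pooled_p = ca.sum() / totals.sum()
    order = np.argsort(-frac, kind="stable")
    ranks = np.empty(len(frac), dtype=int)
    ranks[order] = np.arange(len(frac))
    n_top = max(1, int(np.floor(top_fraction * len(frac))))
    rng = np.random.default_rng(seed)
    results = []
    for i, strain in enumerate(spectra.index):
        n = int(totals[i])
        boot = rng.binomial(n, pooled_p, size=B) / n
        p = (1 + int(np.sum(boot >= frac[i]))) / (B + 1)
        results.append(EnrichmentResult(
            strain=strain, ca_fraction=float(frac[i]),
            rank_percentile=float(1.0 - ranks[i] / len(frac)),
            p_boot=p, n_variants=n, flagged_top=bool(ranks[i] < n_top)))
    return results


def ca_by_ac_bin(panel: PanelData, strains: list[str] | None = None,
                 cutoffs: tuple[int, ...] = (2, 4, 6, 8)) -> pd.DataFrame:
    """C>A fraction and variant totals stratified by derived allele count.

    Bins are (AC <= c1, c1 < AC <= c2, ..., AC > c_last).  Only variants
    carried by the given strains (default: all) enter the tally; each
    variant counts once per bin regardless of how many focal strains carry
    it.  Empty bins report NaN fractions.
    """
    v = panel.variants
    if v["ancestral"].isna().any():
        raise ValueError("panel must be polarized")
    d = derived_dosage(panel)
    if strains is not None:
        idx = [panel.strain_names.index(s) for s in strains]
        carried = (d[:, idx] > 0).any(axis=1)
    else:
        carried = (d > 0).any(axis=1)
    ac = v["ac"].to_numpy()
    cls = v["cls"].to_numpy()
    sel = carried & (ac > 0)
    edges = [0, *cutoffs, np.inf]
    labels = [f"AC<={cutoffs[0]}"] + [
        f"{edges[i]+1}-{edges[i+1]}" for i in range(1, len(cutoffs))
    ] + [f">{cutoffs[-1]}"]
    rows = []
    for lo, hi, lab in zip(edges[:-1], edges[1:], labels):
        in_bin = sel & (ac > lo) & (ac <= hi)
        total = int(in_bin.sum())
        n_ca = int((in_bin & (cls == "C>A")).sum())
        rows.append({"bin": lab, "ca_fraction": (n_ca / total) if total else np.nan,
                     "n_ca": n_ca, "n_total": total})
    return pd.DataFrame(rows)


def candidate_mutator_scan(panel: PanelData, consequences: pd.Series,
                           genes: pd.DataFrame, carriers: list[str],
                           controls: list[str], max_maf: float = 0.05) -> pd.DataFrame:
    """Scan candidate genes for rare damaging alleles private to carriers.

    ``consequences`` aligns with the panel variants; ``genes`` is a BED-like
    (chrom, start, end, name) table.  A site is reported when it lies in a
    candidate gene, its consequence is missense or nonsense, its panel minor
    allele frequency is below ``max_maf``, all ``carriers`` carry the allele
    and no ``control`` does.
    """
    if not carriers:
        raise ValueError("carrier set must be non-empty")
    v = panel.variants
    d = derived_dosage(panel)
    nm = panel.strain_names
    ci = [nm.index(s) for s in carriers]
    xi = [nm.index(s) for s in controls]
    damaging = consequences.isin(["missense", "nonsense"]).to_numpy()
    n_called = (panel.genotypes != MISSING).sum(axis=1)
    daf = v["daf"].to_numpy()
    maf = np.minimum(np.nan_to_num(daf, nan=1.0), 1 - np.nan_to_num(daf, nan=1.0))
    in_gene = np.zeros(len(v), dtype=bool)
    gene_name = np.array([""] * len(v), dtype=object)
    for _, g in genes.iterrows():
        hit = (v["chrom"] == g["chrom"]).to_numpy() \
            & (v["pos"].to_numpy() - 1 >= g["start"]) & (v["pos"].to_numpy() - 1 < g["end"])
        in_gene |= hit
        gene_name[hit] = g.get("name", "")
    all_carriers = (d[:, ci] > 0).all(axis=1)
    no_controls = ~(d[:, xi] > 0).any(axis=1) if xi else np.ones(len(v), dtype=bool)
    sel = in_gene & damaging & (maf < max_maf) & all_carriers & no_controls \
        & (n_called > 0)
    out = v.loc[sel, ["chrom", "pos", "ref", "alt", "ac", "daf"]].copy()
    out["gene"] = gene_name[sel]
    out["consequence"] = consequences.to_numpy()[sel]
    return out.reset_index(drop=True)
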