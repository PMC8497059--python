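"""Polarization, filtering, spectra, PCA and C>A enrichment on panels."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from mutspec.panel import (MISSING, PanelData, StrainMeta, ca_by_ac_bin,
                           ca_enrichment, candidate_mutator_scan,
                           exclude_relatives, filter_variants,
                           polarize_variants, spectra_matrix, spectrum_pca,
                           strain_spectrum)
from mutspec.simulate import simulate_panel
from mutspec.spectra import SUB_CLASSES


def tiny_panel(variants, genotypes, strains=None):
    n = np.asarray(genotypes).shape[1]
    metas = strains or [StrainMeta(name=f"s{i}", clade="c1", zygosity="haploid")
                        for i in range(n)]
    return PanelData(pd.DataFrame(variants), np.asarray(genotypes, dtype=np.int8),
                     metas)


def outgroup_table(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "og1", "og2", "og3",
                                       "og4", "og5"])


class TestPolarization:
    def test_four_of_five_rule(self):
        panel = tiny_panel(
            {"chrom": ["chrI"] * 3, "pos": [10, 20, 30],
             "ref": ["A", "A", "A"], "alt": ["C", "C", "C"]},
            [[0, 2], [0, 2], [0, 2]])
        og = outgroup_table([
            ["chrI", 10, "A", "A", "A", "A", "C"],  # 4/5 A -> ancestral A
            ["chrI", 20, "A", "A", "C", "C", "A"],  # 3/5 max -> uncallable
            ["chrI", 30, "G", "G", "G", "G", "G"],  # third allele -> uncallable
        ])
        out = polarize_variants(panel, og)
        assert out.variants["ancestral"].tolist() == ["A", None, None]
        assert out.variants["derived"].tolist() == ["C", None, None]

    def test_derived_dosage_flips_when_alt_is_ancestral(self):
        panel = tiny_panel({"chrom": ["chrI"], "pos": [10],
                            "ref": ["C"], "alt": ["A"]},
                           [[0, 2, 1]])
        og = outgroup_table([["chrI", 10, "A", "A", "A", "A", "A"]])
        out = polarize_variants(panel, og)
        # ancestral is ALT, so hom-ref strains are hom-derived
        assert out.variants["ac"].iloc[0] == 2 + 0 + 1
        assert out.variants["cls"].iloc[0] == "A>C"


def polarized_panel(variants, genotypes, anc, strains=None):
    panel = tiny_panel(variants, genotypes, strains)
    panel.variants["ancestral"] = anc
    panel.variants["derived"] = [
        (alt if an == ref else ref) if an is not None else None
        for an, ref, alt in zip(anc, panel.variants["ref"], panel.variants["alt"])]
    from mutspec.panel import _recompute_ac
    from mutspec.spectra import collapse_substitution

    panel.variants["cls"] = [
        collapse_substitution(a, d) if a is not None else None
        for a, d in zip(panel.variants["ancestral"], panel.variants["derived"])]
    _recompute_ac(panel)
    return panel


class TestFiltering:
    def test_missingness_and_daf_boundaries(self):
        # 4 strains; v1 has 1/4 missing (excluded at <0.20), v2 has DAF 0.5
        panel = polarized_panel(
            {"chrom": ["chrI"] * 3, "pos": [10, 20, 30],
             "ref": ["A"] * 3, "alt": ["C"] * 3},
            [[MISSING, 2, 0, 0], [2, 2, 0, 0], [2, 0, 0, 0]],
            ["A", "A", "A"])
        out = filter_variants(panel)
        assert out.variants["pos"].tolist() == [30]

    def test_repeat_mask_excludes(self):
        panel = polarized_panel(
            {"chrom": ["chrI", "chrI"], "pos": [10, 50],
             "ref": ["A", "A"], "alt": ["C", "C"]},
            [[2, 0, 0, 0], [2, 0, 0, 0]], ["A", "A"])
        repeats = pd.DataFrame({"chrom": ["chrI"], "start": [5], "end": [15]})
        out = filter_variants(panel, repeats=repeats)
        assert out.variants["pos"].tolist() == [50]

    def test_mappable_mask_includes(self):
        panel = polarized_panel(
            {"chrom": ["chrI", "chrI"], "pos": [10, 50],
             "ref": ["A", "A"], "alt": ["C", "C"]},
            [[2, 0, 0, 0], [2, 0, 0, 0]], ["A", "A"])
        mappable = pd.DataFrame({"chrom": ["chrI"], "start": [0], "end": [20]})
        out = filter_variants(panel, mappable=mappable)
        assert out.variants["pos"].tolist() == [10]

    def test_malformed_interval_is_an_error(self):
        panel = polarized_panel(
            {"chrom": ["chrI"], "pos": [10], "ref": ["A"], "alt": ["C"]},
            [[2, 0]], ["A"])
        bad = pd.DataFrame({"chrom": ["chrI"], "start": [20], "end": [20]})
        with pytest.raises(ValueError):
            filter_variants(panel, repeats=bad)

    def test_uncallable_ancestral_excluded(self):
        panel = polarized_panel(
            {"chrom": ["chrI"], "pos": [10], "ref": ["A"], "alt": ["C"]},
            [[2, 0, 0, 0]], [None])
        assert len(filter_variants(panel).variants) == 0


class TestRelativeExclusion:
    @staticmethod
    def dmat(names, entries):
        n = len(names)
        d = np.full((n, n), 50_000.0)
        np.fill_diagonal(d, 0.0)
        for (a, b), v in entries.items():
            i, j = names.index(a), names.index(b)
            d[i, j] = d[j, i] = v
        return pd.DataFrame(d, index=names, columns=names)

    def test_close_pair_drops_one(self):
        d = self.dmat(["A", "B"], {("A", "B"): 5000})
        assert exclude_relatives(d) == ["A"]

    def test_distant_strains_all_kept(self):
        d = self.dmat(["A", "B", "C"], {})
        assert exclude_relatives(d) == ["A", "B", "C"]

    def test_chain_drops_the_hub(self):
        # A-B 5k, B-C 5k, A-C 20k: B has two close relatives and is dropped
        d = self.dmat(["A", "B", "C"], {("A", "B"): 5000, ("B", "C"): 5000,
                                        ("A", "C"): 20_000})
        assert exclude_relatives(d) == ["A", "C"]

    def test_asymmetric_matrix_rejected(self):
        d = self.dmat(["A", "B"], {})
        d.iloc[0, 1] = 1.0
        with pytest.raises(ValueError):
            exclude_relatives(d)


class TestStrainSpectrum:
    def panel(self):
        # strain s0: hom-derived at two C>T sites, het at one A>G site
        return polarized_panel(
            {"chrom": ["chrI"] * 3, "pos": [10, 20, 30],
             "ref": ["C", "C", "A"], "alt": ["T", "T", "G"]},
            [[2, 2, 0], [2, 0, 2], [1, 0, 2]],
            ["C", "C", "A"],
            strains=[StrainMeta("s0", zygosity="heterozygous"),
                     StrainMeta("s1", zygosity="haploid"),
                     StrainMeta("s2", zygosity="haploid")])

    def test_all_mode_weights_hom_twice(self):
        spec = strain_spectrum(self.panel(), "s0", mode="all")
        assert spec.counts["C>T"] == 4 and spec.counts["A>G"] == 1
        assert spec.normalized()[list(SUB_CLASSES).index("C>T")] == pytest.approx(0.8)

    def test_rare_mode_weights_equal(self):
        # all three sites have AC in {2,3,4}
        panel = self.panel()
        assert set(panel.variants["ac"]) <= {2, 3, 4}
        spec = strain_spectrum(panel, "s0", mode="rare")
        assert spec.counts["C>T"] == 2 and spec.counts["A>G"] == 1

    def test_derived_g_to_a_collapses_to_c_to_t(self):
        panel = polarized_panel(
            {"chrom": ["chrI"], "pos": [10], "ref": ["G"], "alt": ["A"]},
            [[2, 0]], ["G"])
        spec = strain_spectrum(panel, "s0", mode="all")
        assert spec.counts["C>T"] == 2

    def test_singleton_mode_requires_private_and_zygosity(self):
        panel = polarized_panel(
            {"chrom": ["chrI"] * 3, "pos": [10, 20, 30],
             "ref": ["C", "C", "C"], "alt": ["T", "T", "T"]},
            # v0: private hom to s1 (haploid -> counts);
            # v1: private het to s1 (haploid -> rejected);
            # v2: shared -> not a singleton
            [[0, 2, 0], [0, 1, 0], [2, 2, 0]],
            ["C", "C", "C"],
            strains=[StrainMeta("s0"), StrainMeta("s1"), StrainMeta("s2")])
        spec = strain_spectrum(panel, "s1", mode="singleton")
        assert spec.counts["C>T"] == 1

    def test_unpolarized_panel_is_an_error(self):
        panel = tiny_panel({"chrom": ["chrI"], "pos": [10],
                            "ref": ["C"], "alt": ["T"]}, [[2, 0]])
        panel.variants["ancestral"] = [None]
        panel.variants["cls"] = [None]
        with pytest.raises(ValueError):
            spectra_matrix(panel, "all")


class TestSpectrumPca:
    def spectra(self, rows, names=None):
        names = names or [f"s{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=names, columns=list(SUB_CLASSES)) * 10

    def test_identical_spectra_have_zero_projections(self):
        sp = self.spectra([[1, 2, 3, 1, 1, 2]] * 5)
        res = spectrum_pca(sp, n_components=2)
        assert np.allclose(res.projections.to_numpy(), 0)
        assert np.allclose(res.explained_variance_ratio, 0)

    def test_two_cluster_ca_contrast_loads_pc1_on_ca(self):
        """Two groups differing only in C>A fraction: PC1 must align with the
        C>A axis; cross-checked against a direct eigendecomposition."""
        base = np.array([1.0, 2.0, 1.0, 1.0, 1.0, 2.0])
        shifted = base.copy()
        shifted[3] *= 4
        rows = [base] * 4 + [shifted] * 4
        sp = self.spectra(rows)
        res = spectrum_pca(sp, n_components=2)
        ica = list(SUB_CLASSES).index("C>A")
        assert np.argmax(np.abs(res.loadings[0])) == ica
        x = sp.to_numpy() / sp.to_numpy().sum(axis=1, keepdims=True)
        cov = np.cov((x - x.mean(0)).T)
        w, v = np.linalg.eigh(cov)
        lead = v[:, np.argmax(w)]
        lead = lead if lead[np.argmax(np.abs(lead))] > 0 else -lead
        assert np.allclose(np.abs(res.loadings[0]), np.abs(lead), atol=1e-8)

    def test_orthonormal_loadings_and_variance_budget(self):
        rng = np.random.default_rng(0)
        sp = self.spectra(rng.uniform(1, 5, size=(12, 6)))
        res = spectrum_pca(sp, n_components=3)
        assert np.allclose(res.loadings @ res.loadings.T, np.eye(3), atol=1e-10)
        assert res.explained_variance_ratio.sum() <= 1 + 1e-12

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        sp = self.spectra(rng.uniform(1, 5, size=(40, 6)))
        pops = pd.Series(["p1"] * 20 + ["p2"] * 20, index=sp.index)
        a = spectrum_pca(sp, populations=pops, population_cap=10, seed=9)
        b = spectrum_pca(sp, populations=pops, population_cap=10, seed=9)
        assert a.sampled_strains == b.sampled_strains
        assert np.array_equal(a.projections.to_numpy(), b.projections.to_numpy())
        assert len(a.sampled_strains) == 20

    def test_too_few_strains_is_an_error(self):
        with pytest.raises(ValueError):
            spectrum_pca(self.spectra([[1, 2, 3, 1, 1, 2]] * 2))


class TestCaEnrichment:
    def test_top_fraction_flags_exact_count(self, rng):
        counts = rng.integers(5, 30, size=(100, 6)) + 10
        sp = pd.DataFrame(counts, columns=list(SUB_CLASSES),
                          index=[f"s{i}" for i in range(100)])
        res = ca_enrichment(sp, B=200, seed=0)
        assert sum(r.flagged_top for r in res) == 5

    def test_strain_at_pooled_fraction_has_central_p(self):
        rows = [[10, 20, 10, 10, 10, 30]] * 30  # every strain at pooled C>A
        sp = pd.DataFrame(rows, columns=list(SUB_CLASSES),
                          index=[f"s{i}" for i in range(30)])
        res = ca_enrichment(sp, B=10_000, seed=1)
        # discrete binomial: P(X >= n*p) with p=1/9, n=90 is ~0.54
        assert 0.4 < res[0].p_boot < 0.7

    def test_bootstrap_p_matches_binomial_tail(self):
        """A strain 1.5x above a pooled fraction of ~0.10: the empirical p
        must agree with the exact binomial tail oracle."""
        rows = [[90_000, 250_000, 90_000, 100_000, 90_000, 380_000],
                [40, 85, 40, 45, 45, 45]]  # focal: n=300, 45 C>A
        sp = pd.DataFrame(rows, columns=list(SUB_CLASSES), index=["bulk", "focal"])
        pooled = sp["C>A"].sum() / sp.sum().sum()
        res = {r.strain: r for r in ca_enrichment(sp, B=20_000, seed=2)}
        p_exact = binom.sf(44, 300, pooled)
        se = np.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert res["focal"].p_boot == pytest.approx(p_exact, abs=3 * se + 1e-4)

    def test_threefold_excess_is_extreme(self):
        """A strain with 3x the pooled C>A fraction at n=300 has a tail
        probability far below the add-one floor, so p collapses to ~1/(B+1)."""
        rows = [[90_000, 250_000, 90_000, 100_000, 90_000, 380_000],
                [30, 60, 30, 90, 30, 60]]  # focal: 90/300 = 0.30 vs ~0.10
        sp = pd.DataFrame(rows, columns=list(SUB_CLASSES), index=["bulk", "focal"])
        res = {r.strain: r for r in ca_enrichment(sp, B=10_000, seed=3)}
        assert binom.sf(89, 300, 0.1) < 1e-20
        assert res["focal"].p_boot <= 2 / 10_001

    def test_small_b_rejected(self):
        sp = pd.DataFrame([[2, 2, 2, 2, 2, 2]] * 3, columns=list(SUB_CLASSES))
        with pytest.raises(ValueError):
            ca_enrichment(sp, B=50)


class TestCaByAcBin:
    def test_single_bin_occupancy(self):
        panel = polarized_panel(
            {"chrom": ["chrI"] * 4, "pos": [10, 20, 30, 40],
             "ref": ["C", "C", "C", "C"], "alt": ["A", "A", "T", "T"]},
            [[2, 0], [0, 2], [2, 0], [0, 2]],
            ["C", "C", "C", "C"])
        df = ca_by_ac_bin(panel)
        assert df.loc[df["bin"] == "AC<=2", "ca_fraction"].iloc[0] == pytest.approx(0.5)
        assert df.loc[df["bin"] == ">8", "n_total"].iloc[0] == 0
        assert np.isnan(df.loc[df["bin"] == ">8", "ca_fraction"].iloc[0])

    def test_ac_nine_falls_in_top_bin(self):
        genos = np.zeros((1, 5), dtype=np.int8)
        genos[0, :4] = 2
        genos[0, 4] = 1  # AC = 9
        panel = polarized_panel(
            {"chrom": ["chrI"], "pos": [10], "ref": ["C"], "alt": ["A"]},
            genos, ["C"])
        df = ca_by_ac_bin(panel)
        assert df.loc[df["bin"] == ">8", "n_total"].iloc[0] == 1

    def test_invariant_to_variant_order(self):
        panel, _ = simulate_panel(n_clades=2, strains_per_clade=5,
                                  n_variants=100, seed=4)
        a = ca_by_ac_bin(panel)
        perm = np.random.default_rng(0).permutation(len(panel.variants))
        shuffled = PanelData(panel.variants.iloc[perm].reset_index(drop=True),
                             panel.genotypes[perm], panel.strains)
        b = ca_by_ac_bin(shuffled)
        pd.testing.assert_frame_equal(a, b)


class TestCandidateScan:
    def scan_panel(self):
        return polarized_panel(
            {"chrom": ["chrI"] * 3, "pos": [100, 200, 300],
             "ref": ["C", "C", "C"], "alt": ["T", "T", "T"]},
            # 10 strains; carriers = s0, s1
            [[2, 2] + [0] * 8,
             [2, 2, 2] + [0] * 7,   # also in control s2
             [2, 2] + [0] * 8],
            ["C", "C", "C"],
            strains=[StrainMeta(f"s{i}") for i in range(10)])

    def test_private_rare_damaging_allele_reported(self):
        panel = self.scan_panel()
        genes = pd.DataFrame({"chrom": ["chrI"], "start": [0], "end": [1000],
                              "name": ["GENE1"]})
        cons = pd.Series(["missense", "missense", "synonymous"])
        hits = candidate_mutator_scan(panel, cons, genes, carriers=["s0", "s1"],
                                      controls=[f"s{i}" for i in range(2, 10)],
                                      max_maf=0.3)
        assert hits["pos"].tolist() == [100]  # 200 in control, 300 synonymous

    def test_empty_carrier_set_is_an_error(self):
        panel = self.scan_panel()
        genes = pd.DataFrame({"chrom": ["chrI"], "start": [0], "end": [1000]})
        with pytest.raises(ValueError):
            candidate_mutator_scan(panel, pd.Series(["missense"] * 3), genes,
                                   carriers=[], controls=["s1"])


class TestEncodingInvariance:
    def test_spectra_invariant_to_ref_alt_swap(self):
        """Re-encoding every record with ref/alt exchanged (and genotypes
        complemented) must leave polarized spectra untouched."""
        panel, _ = simulate_panel(n_clades=2, strains_per_clade=6,
                                  n_variants=300, seed=8)
        flipped_variants = panel.variants[["chrom", "pos"]].copy()
        flipped_variants["ref"] = panel.variants["alt"]
        flipped_variants["alt"] = panel.variants["ref"]
        g = panel.genotypes.copy()
        swapped = np.where(g == MISSING, MISSING, 2 - g).astype(np.int8)
        flipped = PanelData(flipped_variants, swapped, panel.strains)
        og = pd.DataFrame({"chrom": panel.variants["chrom"],
                           "pos": panel.variants["pos"],
                           **{f"og{k}": panel.variants["ancestral"]
                              for k in range(1, 6)}})
        a = spectra_matrix(polarize_variants(_strip(panel), og), "all")
        b = spectra_matrix(polarize_variants(_strip(flipped), og), "all")
        pd.testing.assert_frame_equal(a, b)


def _strip(panel: PanelData) -> PanelData:
    v = panel.variants[["chrom", "pos", "ref", "alt"]].copy()
    return PanelData(v, panel.genotypes, panel.strains)
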