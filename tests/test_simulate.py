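import numpy as np
import pandas as pd
import pytest

import admixscan as ax
from admixscan.genmap import GeneticMap
from admixscan.simulate import (
    SimConfig,
    make_snv_table,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_structure,
    simulate_tracts,
)


class TestStructure:
    def test_unrelated_cohort_has_zero_offdiagonal_kinship(self):
        st = simulate_structure(50, n_sib_pairs=0)
        K = st.kinship.toarray()
        assert np.allclose(np.diag(K), 0.5)
        assert np.all(K[~np.eye(50, dtype=bool)] == 0)

    def test_sib_pairs_get_quarter_kinship(self):
        st = simulate_structure(40, n_sib_pairs=10)
        K = st.kinship.toarray()
        off = K[~np.eye(40, dtype=bool)]
        assert (off == 0.25).sum() == 20  # 10 symmetric pairs
        assert np.all(np.isin(off, [0.0, 0.25]))

    def test_households_nest_in_blocks_and_sibs_cohabit(self):
        st = simulate_structure(60, n_sib_pairs=8, household_size=4,
                                households_per_block=3)
        hb = pd.DataFrame({"h": st.household, "b": st.block})
        assert (hb.groupby("h")["b"].nunique() == 1).all()
        for p in range(8):
            assert st.household[2 * p] == st.household[2 * p + 1]

    def test_incompatible_configuration_rejected(self):
        with pytest.raises(ValueError):
            simulate_structure(10, n_sib_pairs=6)
        with pytest.raises(ValueError):
            simulate_structure(10, household_size=0)


class TestTracts:
    def test_zero_generations_gives_whole_chromosome_tracts(self):
        cfg = SimConfig(n_samples=20, generations=0)
        gm = GeneticMap.uniform(2, 80.0)
        tr = simulate_tracts(cfg, gm, np.random.default_rng(0))
        for chrom in gm.chromosomes:
            for ends, anc in tr.tracts[chrom]:
                assert len(ends) == 1 and len(anc) == 1

    def test_degenerate_simplex_gives_single_ancestry(self):
        cfg = SimConfig(n_samples=10, groups={"only": (1.0, 0.0, 0.0)},
                        group_weights={"only": 1.0})
        gm = GeneticMap.uniform(1, 200.0)
        tr = simulate_tracts(cfg, gm, np.random.default_rng(1))
        for ends, anc in tr.tracts["1"]:
            assert np.all(anc == 0)

    def test_tracts_tile_each_chromosome_exactly(self):
        cfg = SimConfig(n_samples=30, generations=15)
        gm = GeneticMap.uniform(2, 120.0)
        tr = simulate_tracts(cfg, gm, np.random.default_rng(2))
        for chrom in gm.chromosomes:
            lo, hi = gm.cm_span(chrom)
            for ends, anc in tr.tracts[chrom]:
                starts = np.concatenate(([lo], ends[:-1]))
                assert ends[-1] == hi
                assert np.all(ends > starts - 1e-12)
                assert np.sum(ends - starts) == pytest.approx(hi - lo)

    @pytest.mark.parametrize("g", [5.0, 15.0, 30.0])
    def test_mean_tract_length_matches_switch_rate(self, g):
        # mean length of a rate-g-per-Morgan switch process on a finite
        # chromosome: L / (g*L_morgan + 1) cM per haplotype on average
        L = 1000.0
        cfg = SimConfig(n_samples=150, generations=g)
        gm = GeneticMap.uniform(1, L)
        tr = simulate_tracts(cfg, gm, np.random.default_rng(int(g)))
        lengths = tr.tract_lengths()
        expected = L / (g * L / 100.0 + 1)
        se = lengths.std() / np.sqrt(len(lengths))
        assert abs(lengths.mean() - expected) < 3 * max(se, 0.02)

    def test_realized_fractions_converge_to_proportions(self):
        cfg = SimConfig(n_samples=100, generations=15)
        gm = GeneticMap.uniform(1, 3000.0)
        rng = np.random.default_rng(5)
        from admixscan.simulate import simulate_proportions
        _, props = simulate_proportions(cfg, rng)
        tr = simulate_tracts(cfg, gm, rng, proportions=props)
        err = np.abs(tr.realized_fractions() - props)
        # per-individual binomial-ish SE at ~450 tracts per genome
        assert err.mean() < 0.05

    def test_empty_map_rejected(self):
        cfg = SimConfig(n_samples=5)
        with pytest.raises(ValueError):
            GeneticMap(pd.DataFrame(columns=["chrom", "bp", "cM"]))


@pytest.fixture(scope="module")
def tracts():
    cfg = SimConfig(n_samples=300, generations=15)
    gm = GeneticMap.uniform(1, 100.0)
    return simulate_tracts(cfg, gm, np.random.default_rng(7))


class TestGenotypes:

    def _snv(self, tracts, freqs):
        gm = tracts.genmap
        return pd.DataFrame({
            "snv_id": ["s1"], "chrom": ["1"], "bp": [gm.bp_at("1", 50.0)],
            "cM": [50.0], "freq_AFR": [freqs[0]], "freq_EUR": [freqs[1]],
            "freq_NAM": [freqs[2]],
        })

    def test_zero_frequency_gives_zero_genotypes(self, tracts):
        tab = self._snv(tracts, (0, 0, 0))
        g = simulate_genotypes(tracts, tab, np.random.default_rng(0))
        assert np.all(g == 0)

    def test_fixed_ancestral_allele_equals_ancestry_dosage(self, tracts):
        tab = self._snv(tracts, (1, 0, 0))
        g = simulate_genotypes(tracts, tab, np.random.default_rng(0))
        anc = tracts.ancestry_at("1", np.array([50.0]))
        afr_dosage = (anc == 0).reshape(tracts.n_samples, 2).sum(axis=1)
        assert np.array_equal(g[0], afr_dosage)

    def test_frequencies_recovered_within_binomial_error(self):
        cfg = SimConfig(n_samples=5000, generations=15)
        gm = GeneticMap.uniform(1, 100.0)
        tracts = simulate_tracts(cfg, gm, np.random.default_rng(9))
        tab = self._snv(tracts, (0.8, 0.1, 0.1))
        rng = np.random.default_rng(10)
        anc = tracts.ancestry_at("1", np.array([50.0]))[:, 0]
        g = simulate_genotypes(tracts, tab, rng)
        alleles = g[0]
        # allele frequency among samples whose both haplotypes are AFR
        both_afr = (anc.reshape(-1, 2) == 0).all(axis=1)
        if both_afr.sum() > 50:
            p_hat = alleles[both_afr].mean() / 2
            se = np.sqrt(0.8 * 0.2 / (2 * both_afr.sum()))
            assert abs(p_hat - 0.8) < 3 * se

    def test_snv_outside_map_rejected(self, tracts):
        tab = self._snv(tracts, (0.5, 0.5, 0.5))
        tab["cM"] = [150.0]
        with pytest.raises(ValueError, match="outside map span"):
            simulate_genotypes(tracts, tab, np.random.default_rng(0))


class TestPhenotypes:
    def test_pure_residual_gives_iid_standard_normal(self):
        cfg = SimConfig(n_samples=5000, sigma_g=0, sigma_h=0, sigma_c=0,
                        sigma_e=1.0, n_regions=4)
        c = ax.simulate_cohort(cfg)
        y = c.phenotypes.iloc[:, 0].to_numpy()
        assert abs(y.mean()) < 3 / np.sqrt(5000)
        assert abs(y.var() - 1.0) < 0.08

    def test_household_intraclass_correlation(self):
        cfg = SimConfig(n_samples=4000, sigma_g=0, sigma_h=4.0, sigma_c=0,
                        sigma_e=1.0, household_size=4, sib_pair_fraction=0,
                        n_regions=4, seed=3)
        c = ax.simulate_cohort(cfg)
        df = pd.DataFrame({"y": c.phenotypes.iloc[:, 0].to_numpy(),
                           "h": c.structure.household})
        between = df.groupby("h")["y"].mean().var()
        total = df["y"].var()
        icc_expected = 4.0 / 5.0
        # between-household variance of means ~ sigma_h + sigma_e/4
        icc_hat = (between - 1.0 / 4) / total
        assert abs(icc_hat - icc_expected) < 0.06

    def test_ancestry_effect_recovered_by_regression(self):
        cfg = SimConfig(n_samples=3000, n_regions=20, seed=21,
                        ancestry_effects=[(7, "NAM", -0.5)],
                        sigma_g=0, sigma_h=0, sigma_c=0, sigma_e=1.0)
        c = ax.simulate_cohort(cfg)
        y = c.phenotypes.iloc[:, 0].to_numpy()
        d = c.dosages.region_dosage(7)[:, 2]
        X = np.column_stack([np.ones(3000), d])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        se = np.sqrt(resid.var() / ((d - d.mean()) ** 2).sum())
        assert abs(beta[1] - (-0.5)) < 2 * se

    def test_dimension_mismatch_rejected(self):
        st = simulate_structure(10)
        cfg = SimConfig(n_samples=10)
        cov = pd.DataFrame({"age": np.zeros(5), "sex": np.zeros(5),
                            "egfr": np.zeros(5)})
        with pytest.raises(ValueError):
            simulate_phenotypes(st, cov, cfg, np.random.default_rng(0))


def test_same_seed_reproduces_cohort_bytewise():
    cfg = SimConfig(n_samples=120, n_regions=10, n_snvs=15, seed=42,
                    missing_rate=0.1)
    a = ax.simulate_cohort(cfg)
    b = ax.simulate_cohort(cfg)
    assert np.array_equal(a.calls.codes, b.calls.codes)
    assert np.array_equal(a.genotypes, b.genotypes)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    pd.testing.assert_frame_equal(a.covariates, b.covariates)


def test_missingness_injected_at_requested_rate():
    cfg = SimConfig(n_samples=2000, n_regions=4, missing_rate=0.3,
                    n_metabolites=4, seed=8)
    c = ax.simulate_cohort(cfg)
    frac = c.phenotypes.isna().to_numpy().mean()
    assert abs(frac - 0.3) < 0.02
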