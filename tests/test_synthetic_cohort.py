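import numpy as np
import pytest
from scipy.special import logit

from cpgset_ewas.kinship import kinship_from_pedigree
from cpgset_ewas.synthetic_cohort import (
    ConfigError,
    SimConfig,
    causal_cpgs,
    founder_pedigree,
    simulate_cohort,
    simulate_methylation,
    simulate_pedigree,
    simulate_phenotypes,
    write_cohort,
)
from cpgset_ewas.univariate import cpg_lm_test


class TestSimConfig:
    def test_unknown_structure_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(family_structure="clan")

    def test_variance_budget_enforced(self):
        with pytest.raises(ConfigError, match="noise"):
            SimConfig(meth_h2=0.6, block_rho=0.5)


class TestSimulatePedigree:
    @pytest.mark.parametrize(
        "structure,n_fam,expected",
        [("trio", 1, 3), ("nuclear2", 60, 240), ("three_gen", 2, 14)],
    )
    def test_family_sizes(self, structure, n_fam, expected):
        ped = simulate_pedigree(SimConfig(n_families=n_fam,
                                          family_structure=structure))
        assert len(ped) == expected

    def test_trio_child_has_both_parents(self):
        ped = simulate_pedigree(SimConfig(n_families=1, family_structure="trio"))
        f, m = ped.parents_of("F0001-03")
        assert f == "F0001-01" and m == "F0001-02"

    def test_deterministic(self):
        cfg = SimConfig(n_families=5, seed=7)
        p1 = simulate_pedigree(cfg)
        p2 = simulate_pedigree(cfg)
        assert p1.table.equals(p2.table)


class TestSimulateMethylation:
    def run(self, n=500, **kw):
        cfg = SimConfig(n_genes=3, cpgs_per_gene=10, **kw)
        ped = founder_pedigree(n)
        kin = kinship_from_pedigree(ped)
        return cfg, simulate_methylation(ped, kin, cfg)

    def test_beta_range(self):
        _, (meth, annot, regions) = self.run(n=100, seed=0)
        assert meth.values.min() > 0 and meth.values.max() < 1
        assert len(annot) == meth.n_cpgs == 30
        assert len(regions) == 3

    def test_positions_within_flanked_gene_window(self):
        _, (meth, annot, regions) = self.run(n=20, seed=1)
        lookup = {r.gene_id: r for r in regions}
        for _, row in annot.iterrows():
            gene = lookup[row["cpg_id"].split(":")[0]]
            assert gene.start - 20_000 < row["pos"] <= gene.end + 20_000

    def test_independent_cpgs_when_structure_off(self):
        _, (meth, _, _) = self.run(n=500, block_rho=0.0, meth_h2=0.0,
                                   n_latent=0, seed=2)
        corr = np.corrcoef(logit(meth.values[:, :10]).T)
        off = np.abs(corr[np.triu_indices(10, 1)])
        assert off.mean() < 0.05

    def test_exchangeable_block_correlation(self):
        cfg = SimConfig(n_genes=2, cpgs_per_gene=15, block_rho=0.5,
                        meth_h2=0.0, n_latent=0, seed=3)
        ped = founder_pedigree(2000)
        kin = kinship_from_pedigree(ped)
        meth, _, _ = simulate_methylation(ped, kin, cfg)
        corr = np.corrcoef(logit(meth.values[:, :15]).T)
        mean_off = corr[np.triu_indices(15, 1)].mean()
        assert 0.45 <= mean_off <= 0.55

    def test_deterministic_given_seed(self):
        _, (m1, a1, _) = self.run(n=50, seed=9)
        _, (m2, a2, _) = self.run(n=50, seed=9)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert a1.equals(a2)

    def test_cpgs_per_gene_range(self):
        cfg = SimConfig(n_genes=5, cpgs_per_gene=(5, 30), seed=4)
        ped = founder_pedigree(10)
        kin = kinship_from_pedigree(ped)
        meth, annot, _ = simulate_methylation(ped, kin, cfg)
        counts = annot["cpg_id"].str.split(":").str[0].value_counts()
        assert counts.min() >= 5 and counts.max() <= 30
        assert counts.nunique() > 1


class TestSimulatePhenotypes:
    def test_unknown_effect_gene_rejected(self):
        cfg = SimConfig(n_genes=2, cpgs_per_gene=5,
                        effect_blocks=[("NOPE", 0.3, 0.5)], seed=0)
        ped = founder_pedigree(30)
        kin = kinship_from_pedigree(ped)
        meth, _, _ = simulate_methylation(ped, kin, cfg)
        with pytest.raises(ConfigError, match="NOPE"):
            simulate_phenotypes(ped, kin, meth, cfg)

    def test_causal_cpg_selection(self):
        cfg = SimConfig(n_genes=1, cpgs_per_gene=10, seed=0)
        ped = founder_pedigree(10)
        kin = kinship_from_pedigree(ped)
        meth, _, _ = simulate_methylation(ped, kin, cfg)
        assert len(causal_cpgs(meth, "G0001", 0.5)) == 5

    def test_covariate_ranges(self):
        _, _, _, _, _, pheno = simulate_cohort(SimConfig(n_families=20, seed=5))
        assert pheno["age"].between(20, 70).all()
        assert set(pheno["sex"]) <= {0, 1}
        assert set(pheno["center"]) <= {"C1", "C2", "C3"}
        assert pheno["fast_time_pre"].between(8, 14).all()
        assert (pheno[["hdl_pre", "hdl_post", "tg_pre", "tg_post"]] > 0).all().all()

    def test_null_type_one_calibration(self):
        # with no effects, no familial trait variance and no confounders,
        # per-CpG regressions of the TG change reject at ~5%
        cfg = SimConfig(n_genes=100, cpgs_per_gene=10, n_latent=0,
                        pheno_h2=0.0, effect_blocks=[], seed=6)
        ped = founder_pedigree(500)
        _, kin, meth, _, _, pheno = simulate_cohort(cfg, ped=ped)
        x = np.log(pheno["tg_post"] / pheno["tg_pre"]).to_numpy()
        C = np.ones((500, 1))
        rej = np.mean(
            [cpg_lm_test(x, C, meth.values[:, j]).pvalue < 0.05
             for j in range(1000)]
        )
        assert 0.03 <= rej <= 0.07

    def test_alternating_sign_pattern(self):
        base = dict(n_genes=1, cpgs_per_gene=10, n_latent=0, pheno_h2=0.0,
                    effect_blocks=[("G0001", 0.4, 1.0)], seed=8)
        ped = founder_pedigree(300)
        _, _, meth, _, _, ph_c = simulate_cohort(SimConfig(**base), ped=ped)
        _, _, _, _, _, ph_a = simulate_cohort(
            SimConfig(effect_sign_pattern="alternating", **base), ped=ped)
        lat = logit(np.clip(meth.values, 1e-6, 1 - 1e-6))
        lat = (lat - lat.mean(0)) / lat.std(0, ddof=1)
        x_c = np.log(ph_c["tg_post"] / ph_c["tg_pre"]).to_numpy()
        x_a = np.log(ph_a["tg_post"] / ph_a["tg_pre"]).to_numpy()
        slopes_c = lat.T @ x_c / 300
        slopes_a = lat.T @ x_a / 300
        # constant signs: all marginal slopes positive; alternating: mixed
        assert (slopes_c > 0).all()
        assert (slopes_a > 0).any() and (slopes_a < 0).any()

    def test_invalid_sign_pattern_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(effect_sign_pattern="random")

    def test_effect_shifts_tg_change(self):
        base = dict(n_genes=1, cpgs_per_gene=20, n_latent=0, pheno_h2=0.0, seed=7)
        ped = founder_pedigree(400)
        _, kin, meth0, _, _, ph0 = simulate_cohort(SimConfig(**base), ped=ped)
        cfg1 = SimConfig(effect_blocks=[("G0001", 0.3, 0.5)], **base)
        _, _, meth1, _, _, ph1 = simulate_cohort(cfg1, ped=ped)
        x1 = np.log(ph1["tg_post"] / ph1["tg_pre"]).to_numpy()
        r = cpg_lm_test(x1, np.ones((400, 1)), meth1.values[:, 0])
        assert r.pvalue < 1e-6  # causal CpG strongly associated


class TestWriteCohort:
    def test_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(n_families=4, n_genes=2, cpgs_per_gene=5, seed=11)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_cohort(cfg, d1)
        p2 = write_cohort(cfg, d2)
        for key in p1:
            b1 = open(p1[key], "rb").read()
            b2 = open(p2[key], "rb").read()
            assert b1 == b2, f"{key} differs between identical runs"
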