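import numpy as np
import pytest
from scipy import stats

from driftfa import (
    FAConfig,
    WFScenario,
    admixture_scenario,
    brownian_covariance,
    center_rows,
    davies_bouldin,
    divergence_scenario,
    fit_fa,
    hudson_fst,
    simulate_generative,
    simulate_wf_serial,
    spectral_basis,
    transform_ages,
    wf_admixture,
    wf_divergence,
    wf_single_population,
)


class TestGenerative:
    def test_seeded_determinism(self):
        a = simulate_generative(divergence_scenario(s1=4, seed=9, n=40, p=200))
        b = simulate_generative(divergence_scenario(s1=4, seed=9, n=40, p=200))
        assert np.array_equal(a.genotypes.values, b.genotypes.values)
        assert a.genotypes.sample_ids == b.genotypes.sample_ids
        c = simulate_generative(divergence_scenario(s1=4, seed=10, n=40, p=200))
        assert not np.array_equal(a.genotypes.values, c.genotypes.values)

    def test_huge_lambda_suppresses_drift_term(self, rng):
        """lambda -> inf means alpha -> 0: the latent matrix reduces to the
        pure factor model plus residual noise."""
        sc = divergence_scenario(
            s1=4, lam=1e12, seed=5, n=60, p=800, output="continuous"
        )
        ds = simulate_generative(sc)
        U = ds.truth["factors"]
        # regress the latent data on the true factors; residual variance
        # should match sigma^2 = 1 with no drift inflation
        Y = ds.genotypes.values
        coef, *_ = np.linalg.lstsq(U, Y, rcond=None)
        resid = Y - U @ coef
        # sigma^2 = 1 less the regression degrees of freedom, K/n per column
        expected = 1.0 - U.shape[1] / U.shape[0]
        assert resid.var() == pytest.approx(expected, rel=0.05)

    def test_admixture_layout(self):
        ds = simulate_generative(admixture_scenario(admix_a=0.3, seed=2, n=40, p=100))
        lab = ds.labels
        assert (lab == "adm").sum() == 20
        assert (lab == "src1").sum() == 10
        assert np.all(ds.ages[lab == "adm"] == 0.0)
        assert ds.truth["admix_a"] == 0.3

    def test_divergence_fst_tracks_s1(self):
        """Larger factor-1 divergence means larger F_ST between the two
        simulated populations."""
        out = {}
        for s1 in (2, 10):
            ds = simulate_generative(divergence_scenario(s1=s1, seed=21))
            lab = ds.labels
            out[s1] = hudson_fst(
                ds.genotypes.values[lab == "pop1"],
                ds.genotypes.values[lab == "pop2"],
            )
        assert out[10] > 5 * out[2]
        assert 0.1 < out[10] < 0.4

    def test_fa_factor_explains_hidden_factor_better_than_pca(self):
        wins = 0
        for seed in range(5):
            ds = simulate_generative(
                divergence_scenario(s1=4, lam=1e-2, seed=seed, n=150, p=2000)
            )
            gc = center_rows(ds.genotypes)
            ts = transform_ages(ds.ages, gc)
            basis = spectral_basis(brownian_covariance(ts).C)
            res = fit_fa(gc, basis, FAConfig(K=2, lam=1e-2))
            u_true = ds.truth["factors"][:, 0]
            U, _, _ = np.linalg.svd(gc.values, full_matrices=False)
            r2_fa = np.corrcoef(res.U[:, 0], u_true)[0, 1] ** 2
            r2_pc = np.corrcoef(U[:, 0], u_true)[0, 1] ** 2
            wins += r2_fa > r2_pc
        assert wins >= 4

    def test_fa_clusters_better_than_pca_davies_bouldin(self):
        wins = 0
        for seed in range(5):
            ds = simulate_generative(
                divergence_scenario(s1=6, lam=1e-2, seed=seed, n=150, p=2000)
            )
            gc = center_rows(ds.genotypes)
            ts = transform_ages(ds.ages, gc)
            basis = spectral_basis(brownian_covariance(ts).C)
            res = fit_fa(gc, basis, FAConfig(K=2, lam=1e-2))
            U, s, _ = np.linalg.svd(gc.values, full_matrices=False)
            db_fa = davies_bouldin(res.scores[:, :2], ds.labels)
            db_pc = davies_bouldin(U[:, :2] * s[:2], ds.labels)
            wins += db_fa < db_pc
        assert wins >= 4


class TestWrightFisher:
    def test_seeded_determinism(self):
        sc = wf_single_population(n_snps=500, age_max=400, seed=3)
        a = simulate_wf_serial(sc)
        b = simulate_wf_serial(wf_single_population(n_snps=500, age_max=400, seed=3))
        assert np.array_equal(a.genotypes.values, b.genotypes.values)

    def test_polymorphic_marker_count(self):
        ds = simulate_wf_serial(wf_single_population(n_snps=800, age_max=500, seed=1))
        G = ds.genotypes.values
        assert G.shape[1] == 800
        assert np.all(G.std(axis=0) > 0)

    def test_sample_covariance_matches_brownian_structure(self):
        """Off-diagonal sample covariance of a serial single population
        mirrors the min(t_i, t_j) kernel."""
        ds = simulate_wf_serial(wf_single_population(n_snps=4000, seed=2))
        gc = center_rows(ds.genotypes)
        ts = transform_ages(ds.ages, gc)
        C = brownian_covariance(ts).C
        S = gc.values @ gc.values.T / gc.n_markers
        iu = np.triu_indices_from(C, k=1)
        mantel = stats.pearsonr(C[iu], S[iu])[0]
        assert mantel > 0.8

    def test_drift_free_limit(self):
        """With an enormous population, samples are exchangeable across
        time: no factor-time association and near-zero temporal F_ST."""
        sc = WFScenario(
            Ne=10_000_000,
            sample_schedule=[(a, "pop", 1) for a in range(0, 2001, 100)],
            n_snps=1500,
            seed=4,
        )
        ds = simulate_wf_serial(sc)
        old = ds.genotypes.values[ds.ages >= 1000]
        new = ds.genotypes.values[ds.ages < 1000]
        assert abs(hudson_fst(old, new)) < 0.01

    def test_divergence_fst_matches_drift_expectation(self):
        """Two populations T generations apart drift to F_ST ~ T/(T+2Ne)."""
        sc = WFScenario(
            Ne=2000, split_time=400,
            sample_schedule=[(0, "p1", 30), (0, "p2", 30)],
            n_snps=6000, seed=5, init_freq_range=(0.2, 0.8),
        )
        ds = simulate_wf_serial(sc)
        lab = ds.labels
        fst = hudson_fst(
            ds.genotypes.values[lab == "p1"], ds.genotypes.values[lab == "p2"]
        )
        expected = 400 / (400 + 2 * 2000)
        assert fst == pytest.approx(expected, rel=0.25)

    def test_admixture_truth_recorded(self):
        sc = wf_admixture(n_snps=300, n_admixed=10, n_source=5, seed=6)
        ds = simulate_wf_serial(sc)
        assert ds.truth["admix_a"] == 0.75
        lab = ds.labels
        assert (lab == "adm").sum() == 10
        assert np.all(ds.ages[lab == "p1"] == 1000.0)

    def test_divergence_builder_schedule(self):
        sc = wf_divergence(n_snps=200, seed=7)
        assert len(sc.sample_schedule) == 24

    def test_schedule_validation(self):
        with pytest.raises(ValueError, match="contact"):
            WFScenario(
                Ne=100, split_time=200, contact_time=300,
                sample_schedule=[(0, "p1", 1), (0, "p2", 1)],
            )
        with pytest.raises(ValueError, match="does not exist"):
            WFScenario(
                Ne=100, split_time=200,
                sample_schedule=[(500, "p1", 1), (0, "p2", 1)],
            )
        with pytest.raises(ValueError, match="postdate"):
            WFScenario(
                Ne=100, split_time=500, contact_time=200,
                sample_schedule=[(300, "adm", 1)],
            )

    def test_matches_coalescent_engine_on_admixture_geometry(self):
        """Cross-check the forward engine against msprime on the admixture
        scenario: the frequency-space projection of the admixed population
        onto the sampled-source axis agrees between engines."""
        msprime = pytest.importorskip("msprime")

        def msp_q(seed):
            dem = msprime.Demography()
            dem.add_population(name="P1", initial_size=10_000)
            dem.add_population(name="P2", initial_size=10_000)
            dem.add_population(name="ADM", initial_size=10_000)
            dem.add_population(name="ANC", initial_size=10_000)
            dem.add_admixture(
                time=500, derived="ADM", ancestral=["P1", "P2"],
                proportions=[0.75, 0.25],
            )
            dem.add_population_split(time=1300, derived=["P1", "P2"], ancestral="ANC")
            samples = [
                msprime.SampleSet(50, population="P1", time=1000),
                msprime.SampleSet(50, population="P2", time=1000),
                msprime.SampleSet(100, population="ADM", time=0),
            ]
            ts = msprime.sim_ancestry(
                samples=samples, demography=dem, sequence_length=8e6,
                recombination_rate=1e-8, random_seed=seed,
            )
            ts = msprime.sim_mutations(ts, rate=1e-8, random_seed=seed + 1)
            G = ts.genotype_matrix()
            Gd = (G[:, ::2] + G[:, 1::2]).T.astype(float)
            return _axis_q(Gd)

        def _axis_q(G):
            p1 = G[:50].mean(0) / 2
            p2 = G[50:100].mean(0) / 2
            padm = G[100:].mean(0) / 2
            axis = p1 - p2
            return float((padm - p2) @ axis / (axis @ axis))

        q_msp = np.mean([msp_q(s) for s in (11, 23)])
        q_wf = np.mean(
            [
                _axis_q(simulate_wf_serial(wf_admixture(seed=s)).genotypes.values)
                for s in (11, 23)
            ]
        )
        assert q_wf == pytest.approx(q_msp, abs=0.05)
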