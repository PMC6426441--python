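"""Coalescent engine: neutral expectations, selfing, balanced loci, studies."""

import numpy as np
import pytest
from scipy import stats as sps

from tspoly.diversity import pi_pairwise
from tspoly.simulate import (
    BalancedLocusSpec,
    DemographicModel,
    MigrationEpoch,
    Population,
    Split,
    StudyConfig,
    default_capsella_model,
    make_diploids,
    scaled_capsella_model,
    simulate_balanced_segment,
    simulate_segment,
    synthetic_study,
)


def _pi_total(hs):
    if hs.n_sites == 0:
        return 0.0
    n = hs.n_hap
    p = hs.haplotypes.mean(axis=0)
    return float((2 * p * (1 - p) * n / (n - 1)).sum())


class TestModelValidation:
    def test_must_coalesce_to_single_root(self):
        with pytest.raises(ValueError, match="coalesce"):
            DemographicModel(
                [Population("a", [(0.0, 100.0)]), Population("b", [(0.0, 100.0)])]
            )

    def test_selfing_rate_bounds(self):
        with pytest.raises(ValueError):
            Population("p", [(0.0, 100.0)], selfing_rate=1.2)

    def test_seed_is_mandatory(self, one_pop_model):
        with pytest.raises(ValueError, match="seed"):
            simulate_segment(one_pop_model, {"p": 4}, 1000)


class TestDefaultModel:
    def test_paper_anchored_values(self):
        m = default_capsella_model()
        split_times = {s.derived: s.time for s in m.splits}
        assert split_times["selfer1_E"] == 170_000
        assert split_times["selfer1_W"] == 10_000
        assert split_times["selfer2"] == 1.8e6
        assert m.mu == 7e-9
        bott = min(n for _, n in m.population("selfer1_E").sizes)
        assert 1 <= bott <= 7 and bott == 7
        assert m.population("outcrosser").sizes[0][1] == 694_643
        assert m.population("selfer2").sizes[0][1] == 14_643

    def test_bottleneck_range_enforced(self):
        with pytest.raises(ValueError):
            default_capsella_model(n_bottleneck=20)

    def test_scaling_preserves_theta(self):
        m = default_capsella_model()
        s = scaled_capsella_model(300.0)
        theta = m.population("outcrosser").sizes[0][1] * m.mu
        theta_s = s.population("outcrosser").sizes[0][1] * s.mu
        assert theta_s == pytest.approx(theta)


class TestNeutralExpectations:
    @pytest.fixture(scope="class")
    def replicates(self, one_pop_model):
        out = []
        for seed in range(2000):
            hs = simulate_segment(one_pop_model, {"p": 10}, 10_000, seed=seed)
            out.append(hs)
        return out

    def test_watterson_and_pi_match_theta(self, replicates):
        theta = 10.0
        a9 = sum(1 / i for i in range(1, 10))
        S = np.array([h.n_sites for h in replicates])
        pi = np.array([_pi_total(h) for h in replicates])
        assert abs(S.mean() - theta * a9) < 3 * S.std() / np.sqrt(len(S))
        assert abs(pi.mean() - theta) < 3 * pi.std() / np.sqrt(len(pi))

    def test_sfs_proportional_to_one_over_i(self, replicates):
        """E[xi_i] = theta / i; sites within a segment share a genealogy, so
        the test uses across-replicate variance rather than Poisson counts."""
        n, theta = 10, 10.0
        per_rep = np.zeros((len(replicates), n - 1))
        for r, h in enumerate(replicates):
            if h.n_sites:
                k = h.haplotypes.sum(axis=0)
                per_rep[r] = np.bincount(k, minlength=n)[1:n]
        mean = per_rep.mean(axis=0)
        se = per_rep.std(axis=0) / np.sqrt(len(replicates))
        expected = theta / np.arange(1, n)
        chi2 = float(np.sum(((mean - expected) / se) ** 2))
        p = sps.chi2.sf(chi2, df=n - 1)
        assert p > 0.001

    def test_folded_sfs_invariant_under_allele_relabel(self, replicates):
        n = 10
        folded = np.zeros(n // 2 + 1)
        folded_flip = np.zeros(n // 2 + 1)
        for h in replicates[:300]:
            if h.n_sites:
                k = h.haplotypes.sum(axis=0)
                for arr, kk in ((folded, k), (folded_flip, n - k)):
                    arr += np.bincount(np.minimum(kk, n - kk), minlength=n // 2 + 1)
        np.testing.assert_array_equal(folded, folded_flip)


class TestDeterminism:
    def test_same_seed_identical_segment(self, one_pop_model):
        a = simulate_segment(one_pop_model, {"p": 6}, 5000, seed=11)
        b = simulate_segment(one_pop_model, {"p": 6}, 5000, seed=11)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)

    def test_same_seed_identical_study_vcf(self, tmp_path):
        from tspoly.genomeio import write_vcf

        cfg = StudyConfig(n_windows=3, n_balanced=1, balanced_span=1, include_selfer2=False)
        for name in ("a", "b"):
            study = synthetic_study(cfg, seed=5)
            write_vcf(study.gm, tmp_path / f"{name}.vcf")
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()


class TestSelfing:
    def test_full_selfing_kills_recombination_four_gamete(self):
        model = DemographicModel(
            [Population("p", [(0.0, 1000.0)], selfing_rate=1.0)],
            mu=2.5e-7,
            rho=1e-5,
        )
        # with sigma = 1, F = 1, r_eff = 0: a single genealogy for the whole
        # segment, so no pair of sites shows all four gametes
        for seed in range(5):
            hs = simulate_segment(model, {"p": 12}, 5000, seed=seed)
            h = hs.haplotypes
            for i in range(min(hs.n_sites, 25)):
                for j in range(i + 1, min(hs.n_sites, 25)):
                    pats = {(int(a), int(b)) for a, b in zip(h[:, i], h[:, j])}
                    assert len(pats) <= 3

    def test_diploid_heterozygosity_under_selfing(self, one_pop_model):
        rng_seed = 3
        hs = simulate_segment(one_pop_model, {"p": 400}, 10_000, seed=rng_seed)
        p = hs.haplotypes.mean(axis=0)
        expected_het = float((2 * p * (1 - p)).sum())

        gm0 = make_diploids(hs, 0.0, seed=1)
        het0 = float((gm0.genotypes == 1).sum(axis=1).sum()) / 200
        assert het0 == pytest.approx(expected_het, rel=0.12)

        gm1 = make_diploids(hs, 1.0, seed=1)
        assert int((gm1.genotypes == 1).sum()) == 0

        sigma = 0.97
        F = sigma / (2 - sigma)
        assert F == pytest.approx(0.9417, abs=5e-4)
        het97 = np.mean(
            [
                float((make_diploids(hs, sigma, seed=s).genotypes == 1).sum()) / 200
                for s in range(20)
            ]
        )
        assert het97 == pytest.approx((1 - F) * expected_het, rel=0.25)

    def test_odd_haplotype_count_rejected(self, one_pop_model):
        hs = simulate_segment(one_pop_model, {"p": 5}, 1000, seed=0)
        with pytest.raises(ValueError, match="odd"):
            make_diploids(hs, 0.0, seed=0)


@pytest.fixture(scope="module")
def balanced_toy_model():
    return DemographicModel(
        [
            Population("a", [(0.0, 800.0)], 0.0),
            Population("b", [(0.0, 800.0)], 0.0),
        ],
        splits=[Split(800.0, "b", "a")],
        mu=5e-7,
        rho=1e-7,
    )


class TestBalancedLocus:
    def test_focal_site_polymorphic_in_every_population(self, balanced_toy_model):
        spec = BalancedLocusSpec(focal_pos=2500, t_bal=20_000.0, class_freq=0.4)
        hs = simulate_balanced_segment(
            balanced_toy_model, spec, {"a": 10, "b": 10}, 5000, seed=0
        )
        j = int(np.searchsorted(hs.positions, 2500))
        assert hs.positions[j] == 2500
        for pop in ("a", "b"):
            f = hs.haplotypes[hs.pop_of == pop, j].mean()
            assert 0 < f < 1

    def test_tbal_must_exceed_oldest_split(self, balanced_toy_model):
        spec = BalancedLocusSpec(focal_pos=100, t_bal=500.0)
        with pytest.raises(ValueError, match="t_bal"):
            simulate_balanced_segment(balanced_toy_model, spec, {"a": 4, "b": 4}, 1000, seed=0)

    def test_diversity_elevated_near_focal_site(self, balanced_toy_model):
        """Deep allelic-class coalescence inflates linked diversity."""
        near, far = [], []
        spec = BalancedLocusSpec(focal_pos=2500, t_bal=20_000.0)
        for seed in range(200):
            hs = simulate_balanced_segment(
                balanced_toy_model, spec, {"a": 8, "b": 8}, 5000, seed=seed
            )
            if hs.n_sites < 2:
                continue
            d = np.abs(hs.positions - 2500)
            focal_j = np.searchsorted(hs.positions, 2500)
            keep = np.ones(hs.n_sites, bool)
            keep[focal_j] = False  # the diagnostic site itself is excluded
            n = hs.n_hap
            p = hs.haplotypes.mean(axis=0)
            site_pi = 2 * p * (1 - p) * n / (n - 1)
            m_near = keep & (d <= 100)
            m_far = keep & (d > 100)
            if m_near.any() and m_far.any():
                near.append(site_pi[m_near].mean())
                far.append(site_pi[m_far].mean())
        res = sps.wilcoxon(near, far, alternative="greater")
        assert np.mean(near) > np.mean(far)
        assert res.pvalue < 1e-4

    def test_footprint_grows_with_balancing_age(self, balanced_toy_model):
        """Near-focal diversity is monotone over a 3-point t_bal grid."""
        means = []
        for t_bal in (900.0, 4000.0, 40_000.0):
            spec = BalancedLocusSpec(focal_pos=2500, t_bal=t_bal)
            vals = []
            for seed in range(150):
                hs = simulate_balanced_segment(
                    balanced_toy_model, spec, {"a": 8, "b": 8}, 5000, seed=seed
                )
                if hs.n_sites < 2:
                    continue
                d = np.abs(hs.positions - 2500)
                keep = d <= 250
                keep[np.searchsorted(hs.positions, 2500)] = False
                if keep.any():
                    n = hs.n_hap
                    p = hs.haplotypes.mean(axis=0)
                    vals.append(float((2 * p * (1 - p) * n / (n - 1))[keep].mean()))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestCrossCheckOracle:
    def test_summary_stats_match_msprime(self):
        """Independent coalescent oracle: same constant-size model with
        recombination; mean S and pi must be statistically indistinguishable."""
        msprime = pytest.importorskip("msprime")
        N, mu, r, L, n = 1000.0, 2.5e-7, 2e-8, 10_000, 10
        model = DemographicModel([Population("p", [(0.0, N)], 0.0)], mu=mu, rho=r)
        S_ours, pi_ours = [], []
        for seed in range(400):
            hs = simulate_segment(model, {"p": n}, L, seed=seed)
            S_ours.append(hs.n_sites)
            pi_ours.append(_pi_total(hs))
        S_ms, pi_ms = [], []
        # n haploid lineages = n/2 diploid individuals on the 2N timescale
        for k, ts in enumerate(
            msprime.sim_ancestry(
                samples=n // 2,
                ploidy=2,
                population_size=N,
                sequence_length=L,
                recombination_rate=r,
                num_replicates=400,
                random_seed=1234,
            )
        ):
            mts = msprime.sim_mutations(
                ts, rate=mu, random_seed=k + 1, discrete_genome=False
            )
            S_ms.append(mts.num_sites)
            pi_ms.append(mts.diversity(span_normalise=False))
        for ours, ms in ((S_ours, S_ms), (pi_ours, pi_ms)):
            t = sps.ttest_ind(ours, ms, equal_var=False)
            assert t.pvalue > 0.001


class TestSyntheticStudy:
    def test_truth_bookkeeping(self, tiny_study):
        assert len(tiny_study.truth) == 2
        assert set(tiny_study.truth["window"]).issubset(range(12))
        # every balanced window has an NLR cluster over its focal position
        for _, row in tiny_study.truth.iterrows():
            nlr = tiny_study.genes[tiny_study.genes["is_nlr"]]
            hit = (nlr["start"] <= row["focal_pos"]) & (nlr["end"] > row["focal_pos"])
            assert hit.any()

    def test_config_inconsistencies_rejected_before_simulation(self):
        with pytest.raises(ValueError):
            StudyConfig(n_windows=5, balanced_windows=[7]).resolve()
        with pytest.raises(ValueError):
            StudyConfig(n_windows=5, balanced_windows=[1], mask_windows=[1]).resolve()

    def test_study_files_written(self, tiny_study, tmp_path):
        tiny_study.write(tmp_path)
        for name in ("study.vcf", "samples.tsv", "mask.bed", "truth.tsv", "genes.gff3"):
            assert (tmp_path / name).exists() or name == "mask.bed"

    def test_migration_pulls_lineages_across_species(self):
        """With migration on, some windows share variants between species."""
        from tspoly.classify import classify_sites

        cfg = StudyConfig(
            n_windows=8,
            n_balanced=0,
            include_selfer2=False,
            model=scaled_capsella_model(migration_rate=2e-6, include_selfer2=False),
        )
        study = synthetic_study(cfg, seed=9)
        sct = classify_sites(study.gm.split_by_species(), "2way", ancestral=study.ancestral)
        assert (sct["site_class"] == "ts_outcrosser_selfer1").sum() > 0
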