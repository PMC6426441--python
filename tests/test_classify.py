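"""Site sharing classes, spectra, resampling, the hq filter."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tspoly.classify import (
    SharedPolyParams,
    classify_sites,
    daf_spectrum,
    hq_ts_filter,
    matched_resample_fraction,
    neutral_ts_probability,
    rarefaction,
    ts_fraction_by_daf,
)
from tspoly.genomeio import MaskSet

from conftest import make_gm


def three_species_fixture():
    """Sites crafted to hit every class.

    Columns: 2 outcrosser, 2 selfer1, 2 selfer2 diploids.
    """
    g = np.array(
        [
            [0, 1, 0, 0, 0, 0],  # ss_outcrosser
            [0, 0, 1, 0, 0, 0],  # ss_selfer1
            [0, 0, 0, 0, 1, 0],  # ss_selfer2
            [1, 0, 1, 0, 0, 0],  # ts pair outcrosser/selfer1
            [1, 0, 1, 0, 1, 0],  # ts_3way
            [2, 2, 0, 0, 0, 0],  # fixed difference
            [0, 0, 0, 0, 0, 0],  # invariant
            [2, 2, 2, 2, 2, 2],  # invariant (all alt)
        ],
        dtype=np.int8,
    )
    gm = make_gm(g, species=["cg", "cg", "cr", "cr", "co", "co"])
    return gm


class TestClassify:
    def test_every_class_assigned(self):
        gm = three_species_fixture()
        anc = np.full(gm.n_sites, "ref", dtype=object)
        sct = classify_sites(gm.split_by_species(), "3way", ancestral=anc)
        assert list(sct["site_class"]) == [
            "ss_outcrosser",
            "ss_selfer1",
            "ss_selfer2",
            "ts_outcrosser_selfer1",
            "ts_3way",
            "fixed_difference",
            "invariant",
            "invariant",
        ]

    def test_classes_are_exhaustive_over_accessible_sites(self, tiny_study):
        sct = classify_sites(
            tiny_study.gm.split_by_species(), "3way", ancestral=tiny_study.ancestral
        )
        acc = (
            tiny_study.gm.accessible["outcrosser"]
            & tiny_study.gm.accessible["selfer1"]
            & tiny_study.gm.accessible["selfer2"]
        )
        assert (sct.loc[acc, "site_class"] != "excluded").all()
        assert (sct.loc[~acc, "site_class"] == "excluded").all()

    def test_symmetric_under_species_relabeling(self):
        gm = three_species_fixture()
        gms = gm.split_by_species()
        a = classify_sites(gms, "3way")
        b = classify_sites(dict(reversed(list(gms.items()))), "3way")
        assert list(a["site_class"]) == list(b["site_class"])

    def test_coordinate_mismatch_rejected(self):
        gm = three_species_fixture()
        gms = gm.split_by_species()
        bad = gms["selfer1"].subset_sites(np.arange(3))
        gms["selfer1"] = bad
        with pytest.raises(ValueError, match="coordinates"):
            classify_sites(gms, "3way")

    def test_derived_counts_follow_ancestral_state(self):
        gm = make_gm([[2, 2, 1, 0]], species=["cg", "cg", "cr", "cr"])
        anc = np.array(["alt"], dtype=object)
        sct = classify_sites(gm.split_by_species(), "2way", ancestral=anc)
        # ancestral = alt: derived copies = total - alt copies
        assert sct["derived_outcrosser"].iloc[0] == 0
        assert sct["derived_selfer1"].iloc[0] == 3


class TestSpectra:
    def test_single_site_lands_in_right_bin(self):
        gm = make_gm([[1, 1, 0, 0]], species=["cg"] * 4)
        anc = np.array(["ref"], dtype=object)
        sct = classify_sites({"outcrosser": gm}, "2way", ancestral=anc) if False else None
        # build the table directly: one segregating site at freq 0.25? use 0.5
        sct = pd.DataFrame(
            {
                "site_class": ["ss_outcrosser"],
                "derived_freq_outcrosser": [0.5],
            }
        )
        h = daf_spectrum(sct, "outcrosser", "ss_outcrosser", n_bins=10)
        assert h["count"].sum() == 1
        assert h.loc[h["count"] == 1, "bin_start"].iloc[0] == pytest.approx(0.5)

    def test_ts_fraction_is_one_without_ss_sites(self):
        sct = pd.DataFrame(
            {
                "site_class": ["ts_3way", "ts_3way"],
                "derived_freq_outcrosser": [0.3, 0.7],
            }
        )
        out = ts_fraction_by_daf(sct, "outcrosser")
        occupied = out["ts_fraction"].dropna()
        assert (occupied == 1.0).all()

    def test_neutral_spectrum_is_monotone_decreasing(self, one_pop_model):
        """Neutral derived-allele counts follow the 1/i shape."""
        from tspoly.simulate import simulate_segment

        counts = np.zeros(10)
        for seed in range(400):
            hs = simulate_segment(one_pop_model, {"p": 10}, 10_000, seed=seed)
            if hs.n_sites:
                counts += np.bincount(hs.haplotypes.sum(axis=0), minlength=10)
        assert all(np.diff(counts[1:]) < 0)

    def test_ts_sites_at_higher_derived_frequency_than_ss(self, tiny_study):
        """Trans-specific variants are older, hence commoner (Fig 3A logic)."""
        sct = classify_sites(
            tiny_study.gm.split_by_species(), "3way", ancestral=tiny_study.ancestral
        )
        f_ts = sct.loc[sct["site_class"] == "ts_3way", "derived_freq_selfer1"]
        f_ss = sct.loc[sct["site_class"] == "ss_selfer1", "derived_freq_selfer1"]
        assert f_ts.mean() > f_ss.mean()


class TestRarefaction:
    def test_full_panel_equals_full_count_with_zero_variance(self):
        gm_a = make_gm([[1, 0, 1, 0], [0, 0, 1, 2]], species=["cr"] * 4)
        gm_b = make_gm([[0, 0, 0, 0], [1, 0, 0, 0]], species=["cg"] * 4)
        out = rarefaction(
            {"selfer1": gm_a, "outcrosser": gm_b}, "selfer1", [4], n_reps=5, seed=0
        )
        assert out["ts_mean"].iloc[0] + out["ss_mean"].iloc[0] == 2
        assert out["ts_sd"].iloc[0] == 0 and out["ss_sd"].iloc[0] == 0

    def test_discovery_monotone_in_subsample_size(self, tiny_study):
        gms = tiny_study.gm.split_by_species()
        out = rarefaction(
            {"selfer1": gms["selfer1"], "outcrosser": gms["outcrosser"]},
            "selfer1",
            [2, 4, 8, 16],
            n_reps=5,
            seed=1,
        )
        totals = (out["ts_mean"] + out["ss_mean"]).to_numpy()
        assert all(np.diff(totals) >= 0)

    def test_matches_enumeration_oracle_for_doubleton(self):
        """P(site segregates in a subsample) by exhaustive enumeration."""
        g = np.array([[2, 2, 0, 0]], dtype=np.int8)  # 2 hom-alt carriers of 4
        gm = make_gm(g, species=["cr"] * 4)
        other = make_gm([[0, 0]], species=["cg", "cg"])
        expected = np.mean(
            [
                0 < g[0, list(combo)].sum() < 2 * 2
                for combo in itertools.combinations(range(4), 2)
            ]
        )
        out = rarefaction(
            {"selfer1": gm, "outcrosser": other}, "selfer1", [2], n_reps=4000, seed=3
        )
        assert out["ss_mean"].iloc[0] == pytest.approx(expected, abs=0.03)

    def test_size_below_two_rejected(self):
        gm = make_gm([[0, 1]], species=["cr", "cr"])
        with pytest.raises(ValueError):
            rarefaction({"selfer1": gm}, "selfer1", [1])


class TestMatchedResample:
    @pytest.fixture()
    def sct_and_annotations(self):
        rng = np.random.default_rng(0)
        n = 600
        sct = pd.DataFrame(
            {
                "chrom": ["chr1"] * n,
                "pos": np.arange(n),
                "site_class": ["ts_3way"] * (n // 2) + ["ss_selfer1"] * (n // 2),
                "derived_freq_selfer1": rng.random(n) * 0.98 + 0.01,
            }
        )
        ann = pd.DataFrame(
            {
                "chrom": ["chr1"] * n,
                "pos": np.arange(n),
                "genic": rng.random(n) < 0.5,
                "cds": [True] * n,
                "effect": np.where(rng.random(n) < 0.3, "nonsynonymous", "synonymous"),
            }
        )
        return sct, ann

    def test_null_self_consistency(self, sct_and_annotations):
        """Same underlying flag distribution in both classes: mean difference ~0."""
        sct, ann = sct_and_annotations
        out = matched_resample_fraction(
            sct, ann, "selfer1", "ts_3way", "ss_selfer1",
            statistic="genic_fraction", n_draw=150, n_reps=200, seed=1,
        )
        assert abs(out["target"].mean() - out["reference"].mean()) < 0.05
        assert out["p_two_sided"] > 0.05

    def test_zero_nonsyn_reference(self, sct_and_annotations):
        sct, ann = sct_and_annotations
        ann = ann.copy()
        ref_rows = sct["site_class"] == "ss_selfer1"
        ann.loc[ref_rows.to_numpy(), "effect"] = "synonymous"
        out = matched_resample_fraction(
            sct, ann, "selfer1", "ts_3way", "ss_selfer1",
            statistic="nonsyn_fraction", n_draw=150, n_reps=50, seed=2,
        )
        assert (out["reference"] == 0).all()
        assert out["target"].mean() > 0

    def test_replicate_statistic_matches_hand_count(self, sct_and_annotations):
        """Recompute one replicate's statistic by direct enumeration."""
        sct, ann = sct_and_annotations
        out = matched_resample_fraction(
            sct, ann, "selfer1", "ts_3way", "ss_selfer1",
            statistic="genic_fraction", n_draw=100, n_reps=1, seed=7,
        )
        # oracle: redo the same seeded draw
        merged = sct.merge(ann, on=["chrom", "pos"])
        rng = np.random.default_rng(7)
        f = merged["derived_freq_selfer1"].to_numpy()
        usable = np.isfinite(f) & (f > 0) & (f < 1)
        tgt = np.flatnonzero(usable & (merged["site_class"] == "ts_3way").to_numpy())
        draw_t = rng.choice(tgt, size=100, replace=False)
        assert out["target"][0] == pytest.approx(
            merged["genic"].to_numpy()[np.sort(draw_t)].mean(), abs=0.05
        )


def brute_force_hq(sct, gm, masks, ancestral, ld_r2_min=0.2, seed=0):
    """Independent oracle: direct evaluation of all five criteria with
    fixed-point iteration, written set-wise rather than matrix-wise."""
    from tspoly.diversity import pair_ld
    from tspoly.genomeio import random_haploidize

    cand = [i for i, c in enumerate(sct["site_class"]) if c == "ts_3way"]
    hap = random_haploidize(gm, seed)
    alleles = {}
    for i in cand:
        row = hap[i].astype(np.int8).copy()
        if ancestral is not None and ancestral[i] == "alt":
            row[row >= 0] = 1 - row[row >= 0]
        alleles[i] = row
    static = {}
    for i in cand:
        okm = True
        if masks is not None:
            for c, s, e in masks.intervals:
                if c == gm.chrom[i] and s <= gm.pos[i] < e:
                    okm = False
        ok_carrier = True
        for sp in gm.species_present:
            cols = gm.columns_for(sp)
            g = gm.genotypes[i, cols]
            ok = g >= 0
            alt = g[ok].sum()
            tot = 2 * ok.sum()
            minor_alt = 2 * alt <= tot
            carriers = (g > 0).sum() if minor_alt else (ok & (g < 2)).sum()
            if carriers < 2:
                ok_carrier = False
        static[i] = okm and ok_carrier
    active = {i for i in cand if static[i]}
    while True:
        keep = set()
        for i in active:
            good = True
            for sp in gm.species_present:
                cols = gm.columns_for(sp)
                if not any(
                    (lambda r2d: np.isfinite(r2d[0]) and r2d[0] > ld_r2_min and r2d[1] > 0)(
                        pair_ld(alleles[i][cols], alleles[j][cols])
                    )
                    for j in active
                    if j != i
                ):
                    good = False
                    break
            if good:
                keep.add(i)
        if keep == active:
            return active
        active = keep


class TestHQFilter:
    def test_perfect_coupling_pair_passes(self):
        # two candidates in identical state across three species, 3 carriers each
        g = np.array(
            [[2, 2, 0, 0, 2, 2, 0, 0, 2, 2, 0, 0]] * 2 + [[0] * 12], dtype=np.int8
        )
        gm = make_gm(g, species=["cg"] * 4 + ["cr"] * 4 + ["co"] * 4)
        anc = np.full(3, "ref", dtype=object)
        sct = classify_sites(gm.split_by_species(), "3way", ancestral=anc)
        assert list(sct["site_class"][:2]) == ["ts_3way", "ts_3way"]
        rep = hq_ts_filter(sct, gm, None, seed=0, ancestral=anc)
        assert rep["pass"].all()

    def test_masked_candidate_fails_not_masked(self):
        g = np.array([[1, 0, 1, 0, 1, 0]] * 3, dtype=np.int8)
        gm = make_gm(g, species=["cg", "cg", "cr", "cr", "co", "co"], pos=[5, 6, 7])
        anc = np.full(3, "ref", dtype=object)
        sct = classify_sites(gm.split_by_species(), "3way", ancestral=anc)
        masks = MaskSet([("chr1", 0, 6)], "repeat")
        rep = hq_ts_filter(sct, gm, masks, seed=0, ancestral=anc)
        assert not rep["not_masked"].iloc[0]
        assert rep["not_masked"].iloc[1]

    def test_matches_brute_force_on_random_fixtures(self, tiny_study):
        keep = np.arange(0, tiny_study.gm.n_sites, 6)
        gm = tiny_study.gm.subset_sites(keep)
        anc = tiny_study.ancestral[keep]
        sct = classify_sites(gm.split_by_species(), "3way", ancestral=anc)
        masks = MaskSet([("chr1", 100_000, 101_000)], "repeat")
        rep = hq_ts_filter(sct, gm, masks, seed=0, ancestral=anc)
        oracle = brute_force_hq(sct, gm, masks, anc, seed=0)
        cand_idx = sct.index[sct["site_class"] == "ts_3way"].to_numpy()
        ours = set(cand_idx[rep["pass"].to_numpy()])
        assert ours == oracle
        assert len(cand_idx) > 10  # the comparison is not vacuous


class TestNeutralTsProbability:
    def test_printed_inputs_give_vanishing_probability(self):
        p = SharedPolyParams(N1=14_643, N2=694_643, T=1.8e6, L=1.348e8, mu=7e-9)
        E, P = neutral_ts_probability(p)
        assert P < 4e-19

    def test_t_zero_reduces_to_theta(self):
        p = SharedPolyParams(N1=100, N2=200, T=1e-30, L=1000, mu=1e-8)
        E, P = neutral_ts_probability(p)
        assert E == pytest.approx(1000 * 4 * 200 * 1e-8, rel=1e-6)
        assert P == pytest.approx(-np.expm1(-E), rel=1e-12)

    def test_doubling_time_scales_expectation(self):
        N, T = 5000.0, 8000.0
        E1, _ = neutral_ts_probability(SharedPolyParams(N, N, T, 1e6, 1e-8))
        E2, _ = neutral_ts_probability(SharedPolyParams(N, N, 2 * T, 1e6, 1e-8))
        assert E2 / E1 == pytest.approx(np.exp(-T / N), rel=1e-9)

    def test_overflow_safe(self):
        p = SharedPolyParams(N1=10, N2=10, T=1e9, L=1e8, mu=1e-8)
        E, P = neutral_ts_probability(p)
        assert E == 0.0 and P == 0.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SharedPolyParams(N1=-1, N2=1, T=1, L=1, mu=1)
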