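"""Coalescent-simulator checks against analytic and brute-force oracles."""

import numpy as np
import pytest

from divabc.scenarios import PriorConfig, ScenarioParams
from divabc.simulate import (SimLayout, apply_misorientation, simulate_counts,
                             simulate_dataset, simulate_summary)
from divabc.summaries import aggregate_mscalc, bin_jsfs, build_jsfs, locus_stats

from oracles import structured_coalescent_classes

THETA_REF = 4 * 1e5 * 2.763e-8  # per bp


def panmictic(theta_ratio: float) -> ScenarioParams:
    return ScenarioParams("SI", "none", theta_anc=theta_ratio,
                          theta_1=theta_ratio, theta_2=theta_ratio, t_split=0.0)


class TestWattersonOracle:
    def test_mean_segregating_sites(self):
        # constant-size panmixia: E[S] = theta_locus * a_{m-1}
        n_loci, L, ratio = 600, 500, 1.0
        lay = SimLayout(n_loci=n_loci, locus_length=L, rho_over_theta=0.0)
        st = simulate_counts(panmictic(ratio), lay, 11)
        m = 8
        a = sum(1 / i for i in range(1, m))
        theta_locus = ratio * THETA_REF * L
        expected = theta_locus * a
        a2 = sum(1 / i**2 for i in range(1, m))
        var_per_locus = theta_locus * a + theta_locus**2 * a2
        se = np.sqrt(var_per_locus / n_loci)
        assert abs(st.n_snp / n_loci - expected) < 3 * se

    def test_pi_close_to_theta(self):
        # within-species coalescence is unaffected by an isolated sister
        # species, so E[pi1] equals theta_1 per bp under constant size
        ratio, L, n_loci = 2.0, 500, 150
        sp = ScenarioParams("SI", "none", ratio, ratio, ratio, t_split=20.0)
        lay = SimLayout(n_loci=n_loci, locus_length=L, rho_over_theta=0.0)
        _, loci = simulate_dataset(sp, lay, 13)
        stats = []
        for loc in loci:
            g = loc.genotypes
            full1 = np.zeros((4, L), dtype=int)
            full2 = np.zeros((4, L), dtype=int)
            if len(loc.positions):
                full1[:, loc.positions] = g[:, :4].T
                full2[:, loc.positions] = g[:, 4:].T
            stats.append(locus_stats(full1, full2, L))
        agg = aggregate_mscalc(stats)
        expected = ratio * THETA_REF
        se = agg.sd["pi1"] / np.sqrt(n_loci)
        assert abs(agg.mean["pi1"] - expected) < 3 * se

    def test_neutral_tajimas_d_near_zero(self):
        ratio, L, n_loci = 4.0, 500, 150
        lay = SimLayout(n_loci=n_loci, locus_length=L, rho_over_theta=0.0)
        _, loci = simulate_dataset(panmictic(ratio), lay, 17)
        stats = []
        for loc in loci:
            g = loc.genotypes
            full1 = np.zeros((4, L), dtype=int)
            full2 = np.zeros((4, L), dtype=int)
            if len(loc.positions):
                full1[:, loc.positions] = g[:, :4].T
                full2[:, loc.positions] = g[:, 4:].T
            stats.append(locus_stats(full1, full2, L))
        agg = aggregate_mscalc(stats)
        n_def = agg.n_defined["D1"]
        se = agg.sd["D1"] / np.sqrt(n_def)
        assert abs(agg.mean["D1"]) < 4 * max(se, 0.05)


class TestDirectionalChecks:
    def test_deep_si_has_no_shared_polymorphism(self):
        sp = ScenarioParams("SI", "none", 2, 2, 2, t_split=20.0)
        st = simulate_counts(sp, SimLayout(n_loci=200, rho_over_theta=0.0), 19)
        b = bin_jsfs(build_jsfs(st), "jsfs4").values
        assert b.sum() > 0
        assert b["Ss"] / b.sum() < 0.01
        assert b["Sf"] > 0

    def test_high_migration_im_is_opposite(self):
        sp = ScenarioParams("IM", "homo", 2, 2, 2, t_split=20.0, m12=30, m21=30)
        st = simulate_counts(sp, SimLayout(n_loci=200, rho_over_theta=0.0), 23)
        b = bin_jsfs(build_jsfs(st), "jsfs4").values
        assert b["Ss"] / b.sum() > 0.05
        assert b["Sf"] / b.sum() < 0.01

    def test_sf_increases_ss_decreases_with_split_depth(self):
        lay = SimLayout(n_loci=300, rho_over_theta=0.0)
        fractions = []
        for k, t in enumerate((0.5, 2.0, 8.0)):
            sp = ScenarioParams("SI", "none", 2, 2, 2, t_split=t)
            b = bin_jsfs(build_jsfs(simulate_counts(sp, lay, 29 + k)), "jsfs4").values
            fractions.append((b["Sf"] / b.sum(), b["Ss"] / b.sum()))
        sf, ss = zip(*fractions)
        assert sf[0] < sf[1] < sf[2]
        assert ss[0] > ss[1] >= ss[2]  # Ss hits exact 0 once the split is deep

    def test_panmictic_limit_symmetric_jsfs(self):
        st = simulate_counts(panmictic(3.0), SimLayout(n_loci=400, rho_over_theta=0.0), 31)
        j = build_jsfs(st).matrix.astype(float)
        asym = np.abs(j - j.T).sum() / j.sum()
        assert asym < 0.12  # sampling noise only


class TestMsStyleOracle:
    @pytest.mark.parametrize("model,m", [("SI", 0.0), ("IM", 4.0)])
    def test_wakeley_hey_class_means(self, model, m):
        """Simulator means match an independent structured-coalescent
        implementation run with the same demography (3 SE tolerance)."""
        mode = "none" if model == "SI" else "homo"
        theta, T = 1.5, 2.0
        sp = ScenarioParams(model, mode, theta, theta, theta, t_split=T,
                            m12=m, m21=m)
        n_rep = 3000
        lay = SimLayout(n_loci=n_rep, locus_length=300, rho_over_theta=0.0)
        st = simulate_counts(sp, lay, 37)
        b = bin_jsfs(build_jsfs(st), "jsfs4").values / n_rep

        rng = np.random.default_rng(41)
        # mutation rate per branch time unit (4 Nref generations) is
        # theta_ref * L; population sizes enter through branch lengths only
        theta_locus = THETA_REF * 300
        cls = np.array([structured_coalescent_classes(
            2, 2, theta, theta, theta, T, m, m, theta_locus, rng)
            for _ in range(n_rep)], dtype=float)
        mean = cls.mean(axis=0)
        se = cls.std(axis=0) / np.sqrt(n_rep)
        for k, name in enumerate(("Sf", "Sx1", "Sx2", "Ss")):
            tol = 3 * np.sqrt(2) * max(se[k], 0.02)
            assert abs(b[name] - mean[k]) < tol, (name, b[name], mean[k], tol)


class TestMisorientation:
    def test_identity_at_zero(self, rng):
        from conftest import random_site_table
        st = random_site_table(rng, 500)
        out = apply_misorientation(st, 0.0, 1)
        assert out.data.equals(st.data)

    def test_full_flip_is_reflection_and_involution(self):
        from conftest import make_site_table
        st = make_site_table([("l", 0, 3, 1)])
        once = apply_misorientation(st, 1.0, 2)
        assert tuple(once.data.iloc[0][["dac1", "dac2"]]) == (1, 3)
        twice = apply_misorientation(once, 1.0, 3)
        assert twice.data.equals(st.data)

    def test_flip_fraction_matches_e(self, rng):
        from conftest import random_site_table
        st = random_site_table(rng, 100_000)
        e = 0.1
        _, flips = apply_misorientation(st, e, 5, return_flips=True)
        se = np.sqrt(e * (1 - e) / len(flips))
        assert abs(flips.mean() - e) < 3 * se

    def test_e_out_of_range(self, rng):
        from conftest import random_site_table
        with pytest.raises(ValueError):
            apply_misorientation(random_site_table(rng, 10), 1.5, 0)


class TestSimulateSummary:
    def test_deterministic_under_seed(self):
        sp = ScenarioParams("SC", "hetero", 3, 3, 3, t_split=8, t_sc=2,
                            m12=10, m21=10, p=0.4, alpha=1, beta=2, e=0.05)
        lay = SimLayout(n_loci=30, rho_over_theta=0.0)
        a = simulate_summary(sp, lay, "jsfs23", 55)
        b = simulate_summary(sp, lay, "jsfs23", 55)
        assert a.values.equals(b.values)

    def test_conservation_across_schemes(self):
        sp = ScenarioParams("IM", "homo", 2, 2, 2, t_split=3, m12=5, m21=5)
        lay = SimLayout(n_loci=20, rho_over_theta=0.0)
        totals = {s: simulate_summary(sp, lay, s, 7).total
                  for s in ("jsfs4", "jsfs7", "jsfs23")}
        # same seed, same scheme-independent simulation path
        assert totals["jsfs4"] == totals["jsfs7"] == totals["jsfs23"]

    def test_recombination_path_runs(self):
        sp = ScenarioParams("IM", "homo", 2, 2, 2, t_split=3, m12=5, m21=5)
        lay = SimLayout(n_loci=10, rho_over_theta=1.0)
        b = simulate_summary(sp, lay, "jsfs4", 9)
        assert b.total >= 0

    def test_mscalc_scheme(self):
        sp = ScenarioParams("IM", "homo", 2, 2, 2, t_split=3, m12=5, m21=5)
        lay = SimLayout(n_loci=15, rho_over_theta=0.0)
        b = simulate_summary(sp, lay, "mscalc", 12)
        assert b.scheme == "mscalc"
        assert "S_avg" in b.values.index and "FST_std" in b.values.index
        assert b.values["S_avg"] >= 0
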