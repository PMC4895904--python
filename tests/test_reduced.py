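"""Reduced toggle-switch model: parameterization, fixed points, scans."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect

from litrswitch.reduced import (ReducedGeneParams, classify_reduced,
                                derive_dimensionless, find_fixed_points,
                                reduced_birth_death_network, reduced_jacobian,
                                reduced_rhs, scan_phase_plane)
from litrswitch.ssa import simulate
from litrswitch.stability import classify, delta_series


def gene(**kw):
    base = dict(s=0.01, u=3.0, beta=17.5, r=25.0, sigma=10.0, K1=10.0, K2=20.0)
    base.update(kw)
    return ReducedGeneParams(**base)


class TestDeriveDimensionless:
    def test_reference_values(self):
        d = derive_dimensionless(gene())
        assert d.mu == pytest.approx(0.7525, abs=1e-12)
        assert d.nu == pytest.approx(74.25, rel=1e-12)
        assert d.lam == pytest.approx(17.5 / 301.0, rel=1e-12)
        assert d.theta == pytest.approx(2.0)
        assert d.kappa == pytest.approx(5.0)

    def test_no_leak_limit_kills_repression_depth(self):
        for u in (0.1, 1.0, 3.0, 50.0):
            d = derive_dimensionless(gene(s=1.0, u=u))
            assert d.nu == 0.0
            assert d.mu == pytest.approx(1.0)

    def test_hand_evaluated_point(self):
        d = derive_dimensionless(gene(s=0.5, u=1.0))
        assert d.mu == pytest.approx(0.75)
        assert d.nu == pytest.approx(0.5)

    @pytest.mark.parametrize("field", ["s", "u", "beta", "r", "sigma", "K1", "K2"])
    def test_nonpositive_parameter_names_offender(self, field):
        with pytest.raises(ValueError, match=field):
            gene(**{field: 0.0})

    def test_leakage_above_one_rejected(self):
        with pytest.raises(ValueError):
            gene(s=1.5)


class TestRhs:
    def test_origin_is_a_fixed_point(self):
        assert reduced_rhs((0.0, 0.0), gene(), gene()) == (0.0, 0.0)

    def test_symmetric_params_give_equal_components_on_diagonal(self):
        for x in (0.01, 0.5, 3.0, 40.0):
            f1, f2 = reduced_rhs((x, x), gene(), gene())
            assert f1 == f2

    def test_against_single_expression_oracle(self):
        # independent one-line transcription of the governing equations
        d1 = derive_dimensionless(gene())
        d2 = derive_dimensionless(gene(beta=5.0, s=0.05))
        T1 = T2 = 1.0
        expected1 = (2 * math.sqrt(d1.theta * T1) * d1.lam
                     * (1 + d1.nu / (1 + d1.mu * T2 * (1 + d1.r * T2)))
                     - 2 * (T1 + 2 / (d1.kappa * math.sqrt(d1.theta)) * T1 ** 1.5))
        expected2 = (2 * math.sqrt(d2.theta * T2) * d2.lam
                     * (1 + d2.nu / (1 + d2.mu * T1 * (1 + d2.r * T1)))
                     - 2 * (T2 + 2 / (d2.kappa * math.sqrt(d2.theta)) * T2 ** 1.5))
        f1, f2 = reduced_rhs((T1, T2), d1, d2)
        assert f1 == pytest.approx(expected1, rel=1e-14)
        assert f2 == pytest.approx(expected2, rel=1e-14)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            reduced_rhs((-0.1, 1.0), gene(), gene())

    def test_jacobian_matches_finite_differences(self):
        p1, p2 = derive_dimensionless(gene()), derive_dimensionless(gene(beta=3.0))
        x = np.array([2.0, 0.3])
        J = reduced_jacobian(x, p1, p2)
        eps = 1e-7
        for k in range(2):
            dx = np.zeros(2); dx[k] = eps
            fd = (np.array(reduced_rhs(x + dx, p1, p2))
                  - np.array(reduced_rhs(x - dx, p1, p2))) / (2 * eps)
            assert J[:, k] == pytest.approx(fd, rel=1e-5)


class TestFixedPoints:
    def test_reference_point_is_bistable_with_two_stable_states(self):
        fps = find_fixed_points(gene(), gene())
        stable = [fp for fp in fps if fp.stable]
        assert len(stable) == 2
        assert len(fps) >= 3  # the saddle between the wells is found too
        assert all(fp.residual < 1e-9 for fp in fps)

    def test_decoupled_limit_matches_1d_bisection_oracle(self):
        g = gene(s=1.0)
        d = derive_dimensionless(g)
        fps = find_fixed_points(g, g)
        stable = [fp for fp in fps if fp.stable]
        assert len(stable) == 1

        def f(T):
            return (2 * math.sqrt(d.theta * T) * d.lam
                    - 2 * (T + 2 / (d.kappa * math.sqrt(d.theta)) * T ** 1.5))

        root = bisect(f, 1e-8, 1e4, xtol=1e-14)
        assert stable[0].state[0] == pytest.approx(root, abs=1e-8)
        assert stable[0].state[1] == pytest.approx(root, abs=1e-8)

    def test_stability_flags_match_eigenvalues(self):
        for fp in find_fixed_points(gene(), gene()):
            max_re = max(e.real for e in fp.eigenvalues)
            assert fp.stable == (max_re < 0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(s2=st.floats(0.002, 0.9), beta2=st.floats(1.0, 300.0))
    def test_gene_swap_mirrors_the_fixed_point_set(self, s2, beta2):
        g1, g2 = gene(), gene(s=s2, beta=beta2)
        fwd = find_fixed_points(g1, g2)
        rev = find_fixed_points(g2, g1)
        assert len(fwd) == len(rev)
        mirrored = sorted((fp.state[1], fp.state[0], fp.stable) for fp in rev)
        for (a, b, stable), fp in zip(mirrored,
                                      sorted((f.state[0], f.state[1], f.stable)
                                             for f in fwd)):
            assert a == pytest.approx(fp[0], rel=1e-9, abs=1e-12)
            assert b == pytest.approx(fp[1], rel=1e-9, abs=1e-12)
            assert stable == fp[2]


class TestClassifyAndScan:
    def test_reference_bistable_no_leak_monostable(self):
        assert classify_reduced(gene(), gene()) == "bistable"
        assert classify_reduced(gene(s=1.0), gene(s=1.0)) == "monostable"

    def test_classification_agrees_with_integration_oracle(self, rng):
        # brute force: relax the ODEs from many random states and cluster
        from scipy.integrate import solve_ivp
        for beta in (3.0, 17.5, 100.0):
            g = gene(beta=beta, s=0.1)
            expected = classify_reduced(g, g)
            ends = []
            for _ in range(60):
                x0 = 10 ** rng.uniform(-3, 2, size=2)
                sol = solve_ivp(lambda t, x: reduced_rhs(np.clip(x, 0, None), g, g),
                                (0, 400.0), x0, rtol=1e-8, atol=1e-10)
                ends.append(np.log10(np.clip(sol.y[:, -1], 1e-12, None)))
            ends = np.array(ends)
            distinct = 1
            for pt in ends:
                if np.linalg.norm(pt - ends[0]) > 0.3:
                    distinct = 2
                    break
            assert expected == ("bistable" if distinct == 2 else "monostable")

    def test_leakage_scan_symmetric_about_diagonal(self):
        vals = np.geomspace(1e-3, 1.0, 5)
        grid = scan_phase_plane(("s1", vals), ("s2", vals))
        assert (grid.classes == grid.classes.T).all()

    def test_single_cell_scan_equals_direct_classification(self):
        grid = scan_phase_plane(("s1", [0.01]), ("s2", [0.01]))
        assert grid.classes[0, 0] == classify_reduced(gene(), gene())

    def test_bistable_region_shrinks_with_increasing_leakage(self):
        betas = np.geomspace(0.5, 500, 6)
        lo = scan_phase_plane(("beta1", betas), ("beta2", betas),
                              gene(s=0.002), gene(s=0.002))
        hi = scan_phase_plane(("beta1", betas), ("beta2", betas),
                              gene(s=0.1), gene(s=0.1))
        assert hi.count("bistable") <= lo.count("bistable")

    def test_unknown_axis_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="unknown axis"):
            scan_phase_plane(("volume", [1.0]), ("s2", [0.01]))


class TestBirthDeathApproximation:
    def test_origin_is_absorbing(self):
        net = reduced_birth_death_network(gene(), gene(), omega=50.0)
        compiled = net.compile()
        zero = np.zeros(2)
        births = [compiled.custom[i](zero) for i in (0, 2)]
        assert births == [0.0, 0.0]

    def test_birth_equals_death_at_the_deterministic_fixed_points(self):
        omega = 100.0
        net = reduced_birth_death_network(gene(), gene(), omega=omega)
        compiled = net.compile()
        for fp in find_fixed_points(gene(), gene()):
            n = np.array([fp.state[0] * omega, fp.state[1] * omega])
            for b_idx, d_idx in ((0, 1), (2, 3)):
                birth = compiled.custom[b_idx](n)
                death = compiled.custom[d_idx](n)
                assert birth == pytest.approx(death, rel=1e-8)

    def test_two_well_separated_modes_at_the_reference_point(self):
        omega = 30.0
        net = reduced_birth_death_network(gene(), gene(), omega=omega)
        stable = [fp for fp in find_fixed_points(gene(), gene()) if fp.stable]
        hi = int(round(omega * max(max(fp.state) for fp in stable)))
        tr_a = simulate(net.with_initial_counts({"T1": hi, "T2": 0}),
                        50.0, 0.05, seed=3)
        tr_b = simulate(net.with_initial_counts({"T1": 0, "T2": hi}),
                        50.0, 0.05, seed=4)
        agg = (("T1",), ("T2",))
        res = classify(delta_series(tr_a, agg), delta_series(tr_b, agg))
        assert res.stability_class in ("bistable", "joint_bistable")
        da = delta_series(tr_a, agg).delta[100:]
        db = delta_series(tr_b, agg).delta[100:]
        assert da.mean() > omega and db.mean() < -omega

    def test_omega_must_be_positive(self):
        with pytest.raises(ValueError):
            reduced_birth_death_network(gene(), gene(), omega=0.0)
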