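"""Mixing-model solvers: exact barycentric inversion and the MCMC sampler."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plumemix.endmember import (
    EndMember,
    EndMemberSet,
    MCMCConfig,
    barycentric_coordinates,
    bundled_endmembers,
    in_mixing_triangle,
    load_endmember_set,
    mean_posterior_sd,
    solve_bayesian,
    solve_exact,
    unmix_cruise,
)


def grid_search_fractions(T_obs, S_obs, ems, step=0.001, refine=True):
    """Independent oracle: minimize squared T-S misfit by brute-force
    grid search over the simplex at the given step; with ``refine`` the
    grid winner seeds a constrained convex polish (SLSQP on the
    simplex), so anisotropic triangles cannot blur the minimizer.  No
    step of this path shares code with the barycentric inversion."""
    from scipy.optimize import minimize

    axis = np.arange(0, 1 + step / 2, step)
    g1, g2 = np.meshgrid(axis, axis, indexing="ij")
    mask = g1 + g2 <= 1 + 1e-12
    f = np.column_stack([g1[mask], g2[mask], 1 - g1[mask] - g2[mask]])

    def misfit(fr):
        return (fr @ ems.T - T_obs) ** 2 + (fr @ ems.S - S_obs) ** 2

    best = f[np.argmin((f @ ems.T - T_obs) ** 2 + (f @ ems.S - S_obs) ** 2)]
    if refine:
        res = minimize(
            misfit, best, method="SLSQP",
            bounds=[(0, 1)] * 3,
            constraints=[{"type": "eq", "fun": lambda fr: fr.sum() - 1}],
            options={"ftol": 1e-16, "maxiter": 200},
        )
        if res.success:
            best = res.x
    return best


def make_ems(T, S, sd=0.1):
    members = tuple(
        EndMember(name=n, temperature_C=t, temperature_sd=sd, salinity=s, salinity_sd=sd,
                  nox_umolL=1.0, dip_umolL=0.1)
        for n, t, s in zip(("CDW", "TSW", "KSSW"), T, S)
    )
    return EndMemberSet(members=members)


class TestSolveExact:
    def test_vertex_identity(self, spring_ems):
        r = solve_exact(17.67, 26.85, spring_ems)
        assert r.in_triangle
        np.testing.assert_allclose(r.fractions, [1, 0, 0], atol=1e-9)
        assert r.sds.tolist() == [0, 0, 0]

    def test_centroid(self, spring_ems):
        T, S = spring_ems.T.mean(), spring_ems.S.mean()
        r = solve_exact(T, S, spring_ems)
        np.testing.assert_allclose(r.fractions, [1 / 3] * 3, atol=1e-9)

    def test_known_interior_point(self, spring_ems):
        # forward-mixed from fractions (0.5, 0.3, 0.2) through the spring vertices
        r = solve_exact(19.53, 30.601, spring_ems)
        assert r.in_triangle
        np.testing.assert_allclose(r.fractions, [0.5, 0.3, 0.2], atol=1e-9)

    def test_matches_grid_oracle_random_triangles(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            T = rng.uniform(5, 30, 3)
            S = rng.uniform(20, 36, 3)
            ems = make_ems(T, S)
            for _ in range(5):
                f_true = rng.dirichlet([2, 2, 2])
                T_obs, S_obs = f_true @ T, f_true @ S
                exact = solve_exact(T_obs, S_obs, ems).fractions
                oracle = grid_search_fractions(T_obs, S_obs, ems)
                assert np.max(np.abs(exact - oracle)) <= 0.002

    def test_forward_inverse_round_trip(self, spring_ems):
        rng = np.random.default_rng(11)
        for f in rng.dirichlet(np.ones(3), size=50):
            T_obs = f @ spring_ems.T
            S_obs = f @ spring_ems.S
            rec = solve_exact(T_obs, S_obs, spring_ems).fractions
            assert np.max(np.abs(rec - f)) < 1e-6

    def test_closure(self, spring_ems):
        rng = np.random.default_rng(3)
        for _ in range(100):
            f = rng.dirichlet(np.ones(3))
            r = solve_exact(f @ spring_ems.T, f @ spring_ems.S, spring_ems)
            assert abs(sum(r.fractions) - 1) <= 1e-6

    def test_collinear_endmembers_rejected(self):
        with pytest.raises(ValueError, match="[Cc]ollinear"):
            make_ems([10, 20, 30], [30, 31, 32])


class TestInMixingTriangle:
    def test_interior_point(self, spring_ems):
        assert in_mixing_triangle(19.53, 30.601, spring_ems, tol=0.0)

    def test_outside_point(self, spring_ems):
        # fresher and colder than the river end-member
        assert not in_mixing_triangle(17.0, 25.0, spring_ems, tol=0.03)

    def test_vertices_inside_at_zero_tol(self, spring_ems):
        for m in spring_ems.members:
            assert in_mixing_triangle(m.temperature_C, m.salinity, spring_ems, tol=0.0)

    def test_negative_tol_rejected(self, spring_ems):
        with pytest.raises(ValueError):
            in_mixing_triangle(19.0, 30.0, spring_ems, tol=-0.1)


class TestSolveBayesian:
    def test_vertex_posterior_concentrates(self, spring_ems):
        r = solve_bayesian(17.67, 26.85, spring_ems)
        assert r.f_cdw >= 0.97
        assert np.all(r.sds <= 0.03)
        assert abs(sum(r.fractions) - 1) <= 1e-6

    def test_interior_matches_exact(self, spring_ems):
        r = solve_bayesian(19.53, 30.601, spring_ems)
        assert np.max(np.abs(r.fractions - [0.5, 0.3, 0.2])) <= 0.02

    def test_inflated_endmember_sds_widen_posterior(self, spring_ems):
        base = solve_bayesian(19.53, 30.601, spring_ems)
        wide = solve_bayesian(19.53, 30.601, spring_ems.with_inflated_sds(10))
        assert np.all(wide.sds > base.sds)

    def test_small_sd_limit_converges_to_exact(self, spring_ems):
        # as observation and end-member SDs shrink the posterior mean
        # must collapse onto the barycentric solution
        cfg = MCMCConfig(sigma_T_obs=1e-3, sigma_S_obs=1e-3)
        r = solve_bayesian(19.53, 30.601, spring_ems.with_inflated_sds(0.01), cfg)
        assert np.max(np.abs(r.fractions - [0.5, 0.3, 0.2])) <= 0.01

    def test_reproducible_for_fixed_seed(self, spring_ems):
        a = solve_bayesian(19.53, 30.601, spring_ems)
        b = solve_bayesian(19.53, 30.601, spring_ems)
        assert a.fractions.tolist() == b.fractions.tolist()
        assert a.sds.tolist() == b.sds.tolist()


class TestUnmixCruise:
    def test_all_outside_flagged(self, spring_ems):
        results = unmix_cruise([(10.0, 22.0), (5.0, 20.0)], spring_ems)
        assert all(not r.in_triangle for r in results)
        assert mean_posterior_sd(results) is None

    def test_duplicate_station_identical(self, spring_ems):
        res = unmix_cruise([(19.53, 30.601), (19.53, 30.601)], spring_ems, method="exact")
        assert res[0].fractions.tolist() == res[1].fractions.tolist()

    def test_empty_input_rejected(self, spring_ems):
        with pytest.raises(ValueError):
            unmix_cruise([], spring_ems)


class TestEndMemberConfig:
    def test_yaml_round_trip(self, tmp_path, spring_ems):
        p = tmp_path / "ems.yaml"
        p.write_text(
            "season: spring\nmembers:\n"
            + "\n".join(
                f"  - {{name: {m.name}, season: spring, layer: {m.layer}, "
                f"T_mean: {m.temperature_C}, T_sd: {m.temperature_sd}, "
                f"S_mean: {m.salinity}, S_sd: {m.salinity_sd}, "
                f"NOx: {m.nox_umolL}, DIP: {m.dip_umolL}}}"
                for m in spring_ems.members
            )
        )
        loaded = load_endmember_set(p)
        np.testing.assert_allclose(loaded.T, spring_ems.T)
        np.testing.assert_allclose(loaded.nox, spring_ems.nox)

    def test_summer_set_loads(self, summer_ems):
        assert summer_ems["CDW"].temperature_C == pytest.approx(28.26)
        assert summer_ems["TSW"].salinity == pytest.approx(33.73)

    def test_duplicate_names_rejected(self):
        m = EndMember(name="CDW", temperature_C=10, temperature_sd=0.1,
                      salinity=30, salinity_sd=0.1, nox_umolL=1, dip_umolL=0.1)
        with pytest.raises(ValueError):
            EndMemberSet(members=(m, m, m))

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            EndMember(name="CDW", temperature_C=10, temperature_sd=0.0,
                      salinity=30, salinity_sd=0.1, nox_umolL=1, dip_umolL=0.1)


@given(st.integers(0, 10_000))
def test_any_simplex_point_round_trips(seed):
    """Forward-mix then invert recovers any simplex point (property)."""
    ems = bundled_endmembers("spring")
    f = np.random.default_rng(seed).dirichlet(np.ones(3))
    r = solve_exact(f @ ems.T, f @ ems.S, ems)
    assert np.max(np.abs(r.fractions - f)) < 1e-6
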