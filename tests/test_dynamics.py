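"""Simulators: stepping, trajectories, equivalences and batch parity."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import fsolve

from coevodyn import (
    HostParams,
    ParasitoidParams,
    SimConfig,
    batch_two_species,
    classify_outcome,
    make_state,
    simulate,
    step_three_species,
    step_two_species,
)
from coevodyn.sensitivity import default_parameter_ranges, latin_hypercube_sample


def _hand_step(N, P, n, p, lam_star, K, eta_star, c, a, kappa, Cn, Cp):
    """Spreadsheet-style transcription of one ecological step (oracle)."""
    lam_t = lam_star - Cn * n
    g = 1.0 / (1.0 + N * (lam_t - 1.0) / K)
    alpha = 1.0 - math.exp(-(n - p) ** 2)
    eta_t = eta_star - Cp * p
    f = (1.0 + a * P / (kappa * (1.0 + a * N * g * (1.0 - alpha) / eta_t))
         ) ** (-kappa)
    N1 = lam_t * N * g * (alpha + (1.0 - alpha) * f)
    P1 = c * N * g * (1.0 - alpha) * (1.0 - f)
    return N1, P1


class TestStepTwoSpecies:
    def test_tabulated_initial_step_matches_hand_composition(
            self, lb_host, lb_parasitoid, config):
        st = make_state(0, 720.0, [10.0], 1.0, [0.9], lb_host,
                        [lb_parasitoid], config)
        nxt = step_two_species(st, lb_host, lb_parasitoid, config)
        N1, P1 = _hand_step(720.0, 10.0, 1.0, 0.9, 10.0, 720.0, 42.0, 0.92,
                            4.14, 0.5, 1.0, 1.0)
        assert nxt.N == pytest.approx(N1, abs=1e-10)
        assert nxt.parasitoid_densities[0] == pytest.approx(P1, abs=1e-10)
        # the recorded transition rate is the infected share of all hosts
        assert st.parasitism_rates[0] == pytest.approx(
            (1 - st.alphas[0]) * (1 - st.escapes[0]), rel=1e-12)

    def test_parasitoid_free_host_has_fixed_point_at_K(self, lb_parasitoid,
                                                       config):
        host = HostParams(lambda_star=10.0, K=720.0, Gamma_n=0.0, N0=300.0)
        st = make_state(0, 720.0, [0.0], 1.0, [0.9], host, [lb_parasitoid],
                        config)
        nxt = step_two_species(st, host, lb_parasitoid, config)
        assert nxt.N == pytest.approx(720.0, rel=1e-12)
        assert nxt.parasitoid_densities[0] == 0.0
        # and the map is attracting towards K from below
        st = make_state(0, 100.0, [0.0], 1.0, [0.9], host, [lb_parasitoid],
                        config)
        assert 100.0 < step_two_species(st, host, lb_parasitoid,
                                        config).N < 720.0

    def test_full_resistance_shuts_down_the_parasitoid(self, lb_host,
                                                       lb_parasitoid, config):
        # A huge character gap: alpha -> 1, parasitoid recruits nothing.
        st = make_state(0, 720.0, [10.0], 30.0, [0.9], lb_host,
                        [lb_parasitoid], config)
        nxt = step_two_species(st, lb_host, lb_parasitoid, config)
        assert nxt.parasitoid_densities[0] == 0.0
        assert nxt.N == pytest.approx(st.lambda_t * st.N * st.g, rel=1e-9)


class TestStepThreeSpecies:
    def test_reduces_to_two_species_when_second_absent(self, lb_host,
                                                       lb_parasitoid, config):
        second = ParasitoidParams(eta_star=84.0, c=0.92, a=4.14, kappa=0.5,
                                  P0=10.0, p0=0.9, introduction_generation=5)
        st2 = make_state(0, 720.0, [10.0], 1.0, [0.9], lb_host,
                         [lb_parasitoid], config)
        st3 = make_state(0, 720.0, [10.0, 0.0], 1.0, [0.9, 0.9], lb_host,
                         [lb_parasitoid, second], config)
        nxt2 = step_two_species(st2, lb_host, lb_parasitoid, config)
        nxt3 = step_three_species(st3, lb_host, lb_parasitoid, second, config)
        # bit-for-bit identical
        assert nxt3.N == nxt2.N
        assert nxt3.parasitoid_densities[0] == nxt2.parasitoid_densities[0]
        assert nxt3.n_bar == nxt2.n_bar
        assert nxt3.x_bars[0] == nxt2.x_bars[0]
        assert nxt3.parasitoid_densities[1] == 0.0

    def test_identical_parasitoids_stay_identical(self, lb_host, config):
        par = ParasitoidParams(eta_star=42.0, c=0.92, a=4.14, kappa=0.5,
                               Gamma_p=0.01, P0=10.0, p0=0.9)
        traj = simulate(lb_host, [par, par], SimConfig(generations=200))
        for st in traj.states:
            assert st.parasitoid_densities[0] == st.parasitoid_densities[1]
            assert st.x_bars[0] == st.x_bars[1]
            assert st.parasitism_rates[0] == st.parasitism_rates[1]


class TestSimulate:
    def test_single_generation_equals_one_step(self, lb_host, lb_parasitoid):
        cfg = SimConfig(generations=1)
        traj = simulate(lb_host, [lb_parasitoid], cfg)
        assert len(traj) == 2
        st0 = make_state(0, 720.0, [10.0], 1.0, [0.9], lb_host,
                         [lb_parasitoid], cfg)
        nxt = step_two_species(st0, lb_host, lb_parasitoid, cfg)
        assert traj.final.N == nxt.N
        assert traj.final.parasitoid_densities == nxt.parasitoid_densities

    def test_three_species_with_never_introduced_second_is_bit_exact(
            self, lb_host, lb_parasitoid):
        cfg = SimConfig(generations=400)
        ghost = ParasitoidParams(eta_star=84.0, c=0.92, a=4.14, kappa=0.5,
                                 Gamma_p=0.01, P0=0.0, p0=0.9)
        two = simulate(lb_host, [lb_parasitoid], cfg)
        three = simulate(lb_host, [lb_parasitoid, ghost], cfg)
        for s2, s3 in zip(two.states, three.states):
            assert s3.N == s2.N
            assert s3.parasitoid_densities[0] == s2.parasitoid_densities[0]
            assert s3.n_bar == s2.n_bar
            assert s3.x_bars[0] == s2.x_bars[0]
            assert s3.parasitoid_densities[1] == 0.0

    def test_mid_run_introduction_event_and_state(self, lb_host,
                                                  lb_parasitoid):
        cfg = SimConfig(generations=50)
        second = ParasitoidParams(eta_star=42.0, c=0.92, a=4.14, kappa=0.5,
                                  Gamma_p=0.01, P0=7.0, p0=0.8,
                                  introduction_generation=20)
        traj = simulate(lb_host, [lb_parasitoid, second], cfg)
        assert (20, "introduction:parasitoid_1") in traj.events
        assert traj.state_at(19).parasitoid_densities[1] == 0.0
        assert traj.state_at(20).parasitoid_densities[1] == 7.0
        assert traj.state_at(20).x_bars[1] == 0.8

    def test_inherited_introduction_character(self, lb_host, lb_parasitoid):
        cfg = SimConfig(generations=50)
        second = ParasitoidParams(eta_star=42.0, c=0.92, a=4.14, kappa=0.5,
                                  Gamma_p=0.01, P0=7.0, p0=0.8,
                                  introduction_generation=20,
                                  inherit_character=True)
        traj = simulate(lb_host, [lb_parasitoid, second], cfg)
        assert traj.state_at(20).x_bars[1] == traj.state_at(19).x_bars[0]

    def test_densities_stay_bounded_and_rates_sum_below_one(self, lb_host):
        par = ParasitoidParams(eta_star=42.0, c=0.92, a=4.14, kappa=0.5,
                               Gamma_p=0.01, P0=10.0, p0=0.9)
        traj = simulate(lb_host, [par, par], SimConfig(generations=300))
        bound = max(lb_host.N0, lb_host.K * 10.0 / 9.0)
        for st in traj.states:
            assert 0.0 <= st.N <= bound
            assert all(d >= 0.0 for d in st.parasitoid_densities)
            assert sum(st.parasitism_rates) <= 1.0 + 1e-12

    def test_extinction_sets_density_to_exact_zero(self, lb_host):
        # A hopeless parasitoid (tiny attack rate) dies out and stays at 0.
        par = ParasitoidParams(eta_star=20.0, c=0.5, a=0.001, kappa=0.5,
                               P0=1e-4, p0=0.9)
        traj = simulate(lb_host, [par], SimConfig(generations=100))
        assert traj.final.parasitoid_densities[0] == 0.0
        ext = [t for t, e in traj.events if e == "extinction:parasitoid_0"]
        assert ext
        for st in traj.states[ext[0]:]:
            assert st.parasitoid_densities[0] == 0.0

    def test_introduction_after_end_rejected(self, lb_host, lb_parasitoid):
        late = ParasitoidParams(eta_star=42.0, c=0.92, a=4.14, kappa=0.5,
                                P0=10.0, introduction_generation=500)
        with pytest.raises(ValueError):
            simulate(lb_host, [lb_parasitoid, late], SimConfig(generations=100))


class TestEcologicalFixedPoint:
    def test_frozen_characters_match_root_finder(self):
        # With both AGVs zero the ecological subsystem's attractor must be
        # a root of the two-species map (oracle: fsolve applied directly).
        host = HostParams(lambda_star=4.0, K=720.0, Gamma_n=0.0, N0=720.0,
                          n0=1.0)
        par = ParasitoidParams(eta_star=42.0, c=0.92, a=4.14, kappa=0.5,
                               Gamma_p=0.0, P0=10.0, p0=0.9)
        cfg = SimConfig(generations=3000)
        traj = simulate(host, [par], cfg)
        last, prev = traj.final, traj.state_at(len(traj) - 2)
        # converged to a fixed point
        assert last.N == pytest.approx(prev.N, rel=1e-8)

        alpha = 1.0 - math.exp(-(1.0 - 0.9) ** 2)
        lam_t, eta_t = 4.0 - 1.0, 42.0 - 0.9

        def residual(v):
            N, P = v
            g = 1.0 / (1.0 + N * (lam_t - 1.0) / 720.0)
            f = (1.0 + 4.14 * P / (0.5 * (1.0 + 4.14 * N * g * (1 - alpha)
                                          / eta_t))) ** -0.5
            return [lam_t * N * g * (alpha + (1 - alpha) * f) - N,
                    0.92 * N * g * (1 - alpha) * (1 - f) - P]

        root = fsolve(residual, [last.N, last.parasitoid_densities[0]])
        assert last.N == pytest.approx(root[0], rel=1e-6)
        assert last.parasitoid_densities[0] == pytest.approx(root[1],
                                                             rel=1e-6)


class TestOutcomeAndIO:
    def test_outcome_flags_and_window_means(self, lb_host, lb_parasitoid):
        traj = simulate(lb_host, [lb_parasitoid], SimConfig(generations=300))
        out = classify_outcome(traj, window=50)
        assert not out.host_extinct
        rates = [s.parasitism_rates[0] for s in traj.states[-50:]]
        assert out.parasitoids[0].mean_parasitism == pytest.approx(
            np.mean(rates))
        d = out.to_dict()
        assert set(d) == {"host_extinct", "window", "parasitoids"}

    def test_trajectory_tidy_frame(self, lb_host, lb_parasitoid, tmp_path):
        traj = simulate(lb_host, [lb_parasitoid], SimConfig(generations=10))
        df = traj.to_dataframe()
        assert set(df.species) == {"host", "parasitoid_0"}
        assert len(df) == 2 * 11
        path = tmp_path / "traj.csv"
        traj.write_csv(path)
        back = pd.read_csv(path)
        assert list(back.columns) == ["generation", "species", "density",
                                      "character", "alpha", "parasitism_rate"]


class TestBatchParity:
    def test_batch_kernel_bit_exact_with_scalar_simulator(self):
        ranges = default_parameter_ranges()
        matrix = latin_hypercube_sample(ranges, 10, seed=11)
        params = pd.DataFrame(matrix, columns=[r.name for r in ranges])
        cfg = SimConfig(generations=150)
        batch = batch_two_species(params, 150, cfg)
        for i, row in params.iterrows():
            host = HostParams(lambda_star=row["lambda"], K=row["K"],
                              C_n=row["C_n"], Gamma_n=row["Gamma_n"],
                              N0=row["N0"], n0=row["n0"])
            par = ParasitoidParams(eta_star=row["eta"], c=row["c"],
                                   a=row["a"], kappa=row["kappa"],
                                   C_p=row["C_p"], Gamma_p=row["Gamma_p"],
                                   P0=row["P0"], p0=row["p0"])
            st = simulate(host, [par], cfg).final
            assert st.N == batch.N[i]
            assert st.parasitoid_densities[0] == batch.P[i]
            assert st.n_bar == batch.n_bar[i]
            assert st.x_bars[0] == batch.p_bar[i]
            assert st.alphas[0] == batch.alpha[i]

    def test_batch_respects_character_floor(self):
        ranges = default_parameter_ranges()
        matrix = latin_hypercube_sample(ranges, 6, seed=3)
        params = pd.DataFrame(matrix, columns=[r.name for r in ranges])
        cfg = SimConfig(generations=150, character_floor=0.0)
        batch = batch_two_species(params, 150, cfg)
        assert np.all(batch.n_bar >= 0.0)
        assert np.all(batch.p_bar >= 0.0)
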