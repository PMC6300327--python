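"""Discrete-generation simulators for the coupled eco-evolutionary system.

One general step function serves both the two-species (host + one
parasitoid) and three-species (host + two parasitoids) models; a second
parasitoid can enter mid-run at its ``introduction_generation``. The
update is synchronous: densities and mean characters at t+1 are all
computed from the generation-t state.

Host and parasitoid maps (two parasitoids, escape functions f and h):

    N_{t+1} = lambda_t N_t g (alpha_p + (1-alpha_p) f)(alpha_y + (1-alpha_y) h)
    P_{t+1} = c_p N_t g (1-alpha_p)(1-f) h
    Y_{t+1} = c_y N_t g (1-alpha_y)(1-h) f

A parasitoid's realised parasitism rate is the proportion of *all* hosts
it infects, ``(1-alpha_i)(1-f_i) prod_{j!=i} f_j``, so rates of
co-occurring parasitoids sum to the total infected proportion.

``batch_two_species`` vectorises the two-species model across rows of
independent parameter sets; it executes the same floating-point
operations in the same order as the scalar path, so the two agree
bit-for-bit (this is asserted in the test suite).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .evolution import update_characters
from .model_core import (
    HostParams,
    ParasitoidParams,
    SimConfig,
    SystemState,
    make_state,
)

logger = logging.getLogger("coevodyn")


# ---------------------------------------------------------------------------
# Trajectory container and outcome classification
# ---------------------------------------------------------------------------

@dataclass
class ParasitoidOutcome:
    persisted: bool
    extinction_generation: int | None
    mean_parasitism: float
    mean_alpha: float


@dataclass
class Outcome:
    """Summary of a completed run (means over the last ``window`` states)."""

    host_extinct: bool
    parasitoids: list[ParasitoidOutcome]
    window: int

    def to_dict(self) -> dict:
        return {
            "host_extinct": self.host_extinct,
            "window": self.window,
            "parasitoids": [
                {
                    "persisted": p.persisted,
                    "extinction_generation": p.extinction_generation,
                    "mean_parasitism": p.mean_parasitism,
                    "mean_alpha": p.mean_alpha,
                }
                for p in self.parasitoids
            ],
        }


@dataclass
class Trajectory:
    """Ordered system states from generation 0 to T plus run events."""

    states: list[SystemState]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def final(self) -> SystemState:
        return self.states[-1]

    def state_at(self, t: int) -> SystemState:
        st = self.states[t]
        assert st.t == t, "trajectory states must be consecutive generations"
        return st

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy per-generation, per-species table."""
        rows = []
        for st in self.states:
            rows.append({"generation": st.t, "species": "host",
                         "density": st.N, "character": st.n_bar,
                         "alpha": np.nan, "parasitism_rate": np.nan})
            for i in range(len(st.parasitoid_densities)):
                rows.append({"generation": st.t, "species": f"parasitoid_{i}",
                             "density": st.parasitoid_densities[i],
                             "character": st.x_bars[i],
                             "alpha": st.alphas[i],
                             "parasitism_rate": st.parasitism_rates[i]})
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def classify_outcome(traj: Trajectory, window: int = 50) -> Outcome:
    """Flag persistence/extinction and summarise the final ``window``.

    A parasitoid is extinct when its density reached exactly 0 after its
    introduction (densities below the extinction threshold are zeroed by
    the simulator); extinct parasitoids report the generation of the
    first zero after introduction.
    """
    last = traj.states[-window:]
    parasitoids = []
    n_par = len(traj.final.parasitoid_densities)
    intro = {i: None for i in range(n_par)}
    for t, ev in traj.events:
        for i in range(n_par):
            if ev == f"introduction:parasitoid_{i}":
                intro[i] = t
    for i in range(n_par):
        introduced_at = intro[i] if intro[i] is not None else 0
        extinct_gen = None
        for st in traj.states:
            if st.t >= introduced_at and st.parasitoid_densities[i] == 0.0:
                extinct_gen = st.t
                break
        parasitoids.append(ParasitoidOutcome(
            persisted=traj.final.parasitoid_densities[i] > 0.0,
            extinction_generation=extinct_gen,
            mean_parasitism=float(np.mean([s.parasitism_rates[i] for s in last])),
            mean_alpha=float(np.mean([s.alphas[i] for s in last])),
        ))
    return Outcome(host_extinct=traj.final.N == 0.0, parasitoids=parasitoids,
                   window=window)


def write_outcome_json(outcome: Outcome, path) -> None:
    with open(path, "w") as fh:
        json.dump(outcome.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Stepping
# ---------------------------------------------------------------------------

def _step_densities(state: SystemState, parasitoids: Sequence[ParasitoidParams]
                    ) -> tuple[float, list[float]]:
    """Raw t -> t+1 densities from the state's derived quantities."""
    host_factor = 1.0
    for i in range(len(parasitoids)):
        if state.present(i):
            host_factor = host_factor * (
                state.alphas[i] + (1.0 - state.alphas[i]) * state.escapes[i])
    N_new = state.lambda_t * state.N * state.g * host_factor

    dens_new = []
    for i, par in enumerate(parasitoids):
        if not state.present(i):
            dens_new.append(0.0)
            continue
        recruit = (par.c * state.N * state.g
                   * (1.0 - state.alphas[i]) * (1.0 - state.escapes[i]))
        for j in range(len(parasitoids)):
            if j != i and state.present(j):
                recruit = recruit * state.escapes[j]
        dens_new.append(recruit)
    return N_new, dens_new


def step(state: SystemState, host: HostParams,
         parasitoids: Sequence[ParasitoidParams], config: SimConfig,
         events: list[tuple[int, str]] | None = None) -> SystemState:
    """Advance the system one generation (no introductions applied here).

    Densities falling below ``config.extinction_threshold`` are set to
    exactly 0 and recorded in ``events`` when a list is given.
    """
    N_new, dens_new = _step_densities(state, parasitoids)
    n_new, x_new = update_characters(state, host, parasitoids, config)

    t1 = state.t + 1
    if 0.0 < N_new < config.extinction_threshold:
        N_new = 0.0
    if N_new == 0.0 and state.N > 0.0 and events is not None:
        events.append((t1, "extinction:host"))
    for i in range(len(dens_new)):
        if 0.0 < dens_new[i] < config.extinction_threshold:
            dens_new[i] = 0.0
        if dens_new[i] == 0.0 and state.present(i) and events is not None:
            events.append((t1, f"extinction:parasitoid_{i}"))
    return make_state(t1, N_new, dens_new, n_new, x_new, host, parasitoids,
                      config)


def step_two_species(state: SystemState, host: HostParams,
                     parasitoid: ParasitoidParams,
                     config: SimConfig) -> SystemState:
    """One generation of the host + single-parasitoid model."""
    return step(state, host, [parasitoid], config)


def step_three_species(state: SystemState, host: HostParams,
                       parasitoid_p: ParasitoidParams,
                       parasitoid_y: ParasitoidParams,
                       config: SimConfig) -> SystemState:
    """One generation of the host + two-parasitoid model.

    With the second parasitoid absent (density 0) this reproduces
    :func:`step_two_species` exactly.
    """
    return step(state, host, [parasitoid_p, parasitoid_y], config)


# ---------------------------------------------------------------------------
# Full simulation
# ---------------------------------------------------------------------------

def simulate(host: HostParams, parasitoids: Sequence[ParasitoidParams],
             config: SimConfig) -> Trajectory:
    """Run the system for ``config.generations`` generations.

    Generation 0 is the initial condition. Each parasitoid enters at its
    ``introduction_generation`` with density ``P0`` and character ``p0``;
    the host character at that moment is whatever coevolution with any
    earlier parasitoid has produced. Host extinction is recorded, not
    raised.
    """
    if not 1 <= len(parasitoids) <= 2:
        raise ValueError("simulate supports 1 or 2 parasitoids")
    for par in parasitoids:
        if par.introduction_generation >= config.generations:
            raise ValueError("introduction_generation must precede the end "
                             "of the simulation")

    events: list[tuple[int, str]] = []
    dens0 = [par.P0 if par.introduction_generation == 0 else 0.0
             for par in parasitoids]
    for i, par in enumerate(parasitoids):
        if par.introduction_generation == 0:
            events.append((0, f"introduction:parasitoid_{i}"))
    states = [make_state(0, host.N0, dens0, host.n0,
                         [p.p0 for p in parasitoids], host, parasitoids,
                         config)]
    for t in range(1, config.generations + 1):
        nxt = step(states[-1], host, parasitoids, config, events)
        intro = [i for i, par in enumerate(parasitoids)
                 if par.introduction_generation == t]
        if intro:
            dens = list(nxt.parasitoid_densities)
            chars = list(nxt.x_bars)
            for i in intro:
                dens[i] = parasitoids[i].P0
                if parasitoids[i].inherit_character and i > 0:
                    chars[i] = states[-1].x_bars[0]
                else:
                    chars[i] = parasitoids[i].p0
                events.append((t, f"introduction:parasitoid_{i}"))
            nxt = make_state(t, nxt.N, dens, nxt.n_bar, chars, host,
                             parasitoids, config)
        states.append(nxt)
    return Trajectory(states=states, events=events)


# ---------------------------------------------------------------------------
# Vectorised two-species batch kernel (used by the sensitivity analysis)
# ---------------------------------------------------------------------------

@dataclass
class BatchResult:
    """Final-generation arrays of a vectorised two-species run."""

    N: np.ndarray
    P: np.ndarray
    n_bar: np.ndarray
    p_bar: np.ndarray
    alpha: np.ndarray
    parasitism_rate: np.ndarray


def batch_two_species(params: pd.DataFrame, generations: int,
                      config: SimConfig = SimConfig()) -> BatchResult:
    """Run one two-species trajectory per row of ``params``, vectorised.

    ``params`` must have columns lambda, K, eta, c, kappa, a, Gamma_n,
    Gamma_p, C_n, C_p, N0, P0, n0, p0 (the life-history parameter-table
    names). Hosts or parasitoids that fall below the extinction threshold
    are zeroed; characters of absent species are frozen, so the reported
    resistant proportion of a row whose populations collapsed is the last
    defined value.

    The arithmetic mirrors the scalar simulator operation-for-operation.
    """
    col = {k: params[k].to_numpy(dtype=float) for k in params.columns}
    lam_s, K, eta_s, c = col["lambda"], col["K"], col["eta"], col["c"]
    kap, a = col["kappa"], col["a"]
    Gn, Gp, Cn, Cp = col["Gamma_n"], col["Gamma_p"], col["C_n"], col["C_p"]
    N, P = col["N0"].copy(), col["P0"].copy()
    n, p = col["n0"].copy(), col["p0"].copy()
    floor, thr, h = config.rate_floor, config.extinction_threshold, config.gradient_step

    def host_ln_w(n_pert, lam_t_ignored, g, f_base_ignored, P, p, eta_t, N):
        # ln W_n at a perturbed host character; g frozen, alpha/f re-evaluated.
        lam = np.maximum(lam_s - Cn * n_pert, floor)
        d = n_pert - p
        al = -np.expm1(-(d * d))
        f = np.power(1.0 + a * P / (kap * (1.0 + a * N * g * (1.0 - al) / eta_t)),
                     -kap)
        term = np.log(al + (1.0 - al) * f)
        return np.log(lam) + np.log(g) + np.where(P > 0.0, term, 0.0)

    def par_ln_w(p_pert, g, N, P, n):
        # ln W_p at a perturbed parasitoid character; same accumulation
        # order as the scalar log_fitness.
        eta_t = np.maximum(eta_s - Cp * p_pert, floor)
        d = n - p_pert
        al = -np.expm1(-(d * d))
        f = np.power(1.0 + a * P / (kap * (1.0 + a * N * g * (1.0 - al) / eta_t)),
                     -kap)
        return (np.log(c) + np.log(N) + np.log(g) + np.log(1.0 - al)
                + np.log(1.0 - f)) - np.log(P)

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        for _ in range(generations):
            lam_t = np.maximum(lam_s - Cn * n, floor)
            g = 1.0 / (1.0 + N * (lam_t - 1.0) / K)
            eta_t = np.maximum(eta_s - Cp * p, floor)
            d = n - p
            alpha = -np.expm1(-(d * d))
            f = np.power(
                1.0 + a * P / (kap * (1.0 + a * N * g * (1.0 - alpha) / eta_t)),
                -kap)
            f = np.where(P > 0.0, f, 1.0)

            # Densities (same association order as the scalar step).
            host_factor = np.where(P > 0.0, 1.0 * (alpha + (1.0 - alpha) * f),
                                   1.0)
            N_new = lam_t * N * g * host_factor
            P_new = np.where(P > 0.0,
                             c * N * g * (1.0 - alpha) * (1.0 - f), 0.0)

            # Characters: central-difference selection gradients.
            gn = (host_ln_w(n + h, lam_t, g, f, P, p, eta_t, N)
                  - host_ln_w(n - h, lam_t, g, f, P, p, eta_t, N)) / (2.0 * h)
            gp = (par_ln_w(p + h, g, N, P, n)
                  - par_ln_w(p - h, g, N, P, n)) / (2.0 * h)
            n = np.where((N > 0.0) & (Gn > 0.0) & np.isfinite(gn),
                         np.maximum(n + Gn * gn, config.character_floor), n)
            p = np.where((P > 0.0) & (Gp > 0.0) & np.isfinite(gp),
                         np.maximum(p + Gp * gp, config.character_floor), p)

            N = np.where(N_new < thr, 0.0, N_new)
            P = np.where(P_new < thr, 0.0, P_new)

        lam_t = np.maximum(lam_s - Cn * n, floor)
        g = 1.0 / (1.0 + N * (lam_t - 1.0) / K)
        eta_t = np.maximum(eta_s - Cp * p, floor)
        d = n - p
        alpha = -np.expm1(-(d * d))
        f = np.power(
            1.0 + a * P / (kap * (1.0 + a * N * g * (1.0 - alpha) / eta_t)),
            -kap)
        f = np.where(P > 0.0, f, 1.0)
        rate = np.where(P > 0.0, (1.0 - alpha) * (1.0 - f), 0.0)
    return BatchResult(N=N, P=P, n_bar=n, p_bar=p, alpha=alpha,
                       parasitism_rate=rate)
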