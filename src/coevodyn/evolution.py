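"""Character dynamics: log-fitness, fitness gradients, character update.

Each species' population-mean quantitative character advances by the
breeder's-equation-like rule

    x_{t+1} = x_t + Gamma * d(ln W)/dx |_{x = x_t}

where ``W`` is the species' per-capita growth over one generation and
``Gamma`` its (constant) additive genetic variance. The gradient is taken
with every density held at its generation-t value: evolution sees the
current ecological state, and densities and characters then update
synchronously.

The density-dependence factor ``g{N_t}`` is treated as a property of the
current state and is *not* re-evaluated when a character is perturbed;
the cost-adjusted rates (lambda_t, eta_t), the resistant proportions and
the escape probabilities are. With no parasitoids present this makes the
host gradient exactly the analytic ``-C_n / lambda_t``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .model_core import (
    HostParams,
    ParasitoidParams,
    SimConfig,
    SystemState,
    cost_adjusted_eta,
    cost_adjusted_lambda,
    escape_probability,
    resistance_alpha,
)

logger = logging.getLogger("coevodyn")


@dataclass
class FitnessContext:
    """Everything needed to evaluate one species' fitness at generation t.

    ``species`` selects whose mean character is perturbed: the host, or
    the parasitoid at position ``index`` in ``parasitoids``.
    """

    state: SystemState
    host: HostParams
    parasitoids: Sequence[ParasitoidParams]
    species: Literal["host", "parasitoid"]
    index: int = 0
    config: SimConfig = SimConfig()

    def __post_init__(self) -> None:
        if self.species == "parasitoid":
            if not (0 <= self.index < len(self.parasitoids)):
                raise ValueError("focal parasitoid index out of range")
            if not self.state.present(self.index):
                raise ValueError("fitness undefined for an absent parasitoid")
        elif self.species == "host":
            if self.state.N <= 0:
                raise ValueError("fitness undefined for an absent host")
        else:
            raise ValueError(f"unknown species {self.species!r}")


def _safe_log(value: float) -> float:
    """ln(value), reported as -inf (with a warning) when value <= 0."""
    if value <= 0.0:
        logger.warning("log-fitness factor <= 0; reporting -inf")
        return -np.inf
    return float(np.log(value))


def log_fitness(ctx: FitnessContext, character_value: float) -> float:
    """ln of the focal species' per-capita growth over one generation.

    The focal species' mean character is set to ``character_value``; all
    densities and the other species' characters stay at their
    generation-t values. Costs, resistance and escape are re-evaluated at
    the perturbed character; ``g`` is frozen at the state's value.
    """
    st, host, pars, cfg = ctx.state, ctx.host, ctx.parasitoids, ctx.config
    g = st.g
    n_bar = character_value if ctx.species == "host" else st.n_bar

    lambda_t = float(cost_adjusted_lambda(host, n_bar, cfg.rate_floor))

    # Per-parasitoid resistance and escape at the (possibly) perturbed
    # characters; absent parasitoids contribute nothing.
    alphas: dict[int, float] = {}
    escapes: dict[int, float] = {}
    for i, par in enumerate(pars):
        if not st.present(i):
            continue
        x_bar = st.x_bars[i]
        if ctx.species == "parasitoid" and i == ctx.index:
            x_bar = character_value
        al = float(resistance_alpha(n_bar, x_bar))
        eta_t = float(cost_adjusted_eta(par, x_bar, cfg.rate_floor))
        f = float(escape_probability(st.N, st.parasitoid_densities[i], par.a,
                                     par.kappa, eta_t, al, g))
        alphas[i], escapes[i] = al, f

    if ctx.species == "host":
        # W_n = lambda_t * g * prod_i (alpha_i + (1 - alpha_i) f_i)
        ln_w = _safe_log(lambda_t) + _safe_log(g)
        for i in alphas:
            ln_w += _safe_log(alphas[i] + (1.0 - alphas[i]) * escapes[i])
        return ln_w

    # W_p = c * N * g * (1 - alpha_j)(1 - f_j) * prod_{i != j} f_i / P_j
    j = ctx.index
    par = pars[j]
    ln_w = (_safe_log(par.c) + _safe_log(st.N) + _safe_log(g)
            + _safe_log(1.0 - alphas[j]) + _safe_log(1.0 - escapes[j]))
    for i in escapes:
        if i != j:
            ln_w += _safe_log(escapes[i])
    ln_w -= _safe_log(st.parasitoid_densities[j])
    return ln_w


def fitness_gradient(ctx: FitnessContext, h: float | None = None) -> float:
    """Central-difference selection gradient d(ln W)/dx at the current mean.

    Returns NaN (gradient undefined) if either evaluation point has
    non-positive fitness.
    """
    if h is None:
        h = ctx.config.gradient_step
    if h <= 0:
        raise ValueError("gradient step h must be > 0")
    x0 = ctx.state.n_bar if ctx.species == "host" else ctx.state.x_bars[ctx.index]
    hi = log_fitness(ctx, x0 + h)
    lo = log_fitness(ctx, x0 - h)
    if not (np.isfinite(hi) and np.isfinite(lo)):
        logger.warning("fitness gradient undefined at t=%d", ctx.state.t)
        return float("nan")
    return (hi - lo) / (2.0 * h)


def update_characters(state: SystemState, host: HostParams,
                      parasitoids: Sequence[ParasitoidParams],
                      config: SimConfig) -> tuple[float, tuple[float, ...]]:
    """One generation of character evolution for every present species.

    Species with ``Gamma = 0`` keep their character exactly unchanged
    (no gradient is evaluated); absent/extinct species' characters are
    frozen. An undefined gradient freezes the character for that
    generation. Updated characters are clipped at
    ``config.character_floor`` (zero investment by default).
    """
    n_new = state.n_bar
    if state.N > 0 and host.Gamma_n > 0:
        grad = fitness_gradient(
            FitnessContext(state, host, parasitoids, "host", config=config))
        if np.isfinite(grad):
            n_new = max(state.n_bar + host.Gamma_n * grad,
                        config.character_floor)

    x_new = list(state.x_bars)
    for i, par in enumerate(parasitoids):
        if state.present(i) and par.Gamma_p > 0:
            grad = fitness_gradient(
                FitnessContext(state, host, parasitoids, "parasitoid", i,
                               config=config))
            if np.isfinite(grad):
                x_new[i] = max(state.x_bars[i] + par.Gamma_p * grad,
                               config.character_floor)
    return n_new, tuple(x_new)
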