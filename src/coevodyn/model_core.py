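"""Ecological skeleton of the host-parasitoid coevolution model.

This module holds the domain types (parameter sets, simulation
configuration, per-generation system state) and the four pure functions
every simulator in the package is built from:

* Beverton-Holt style density dependence ``g(N) = [1 + N(lambda-1)/K]^-1``,
* the resistant proportion ``alpha = 1 - exp(-(n - x)^2)`` set by the gap
  between the host's and a parasitoid's mean quantitative character,
* the negative-binomial escape function (aggregated parasitoid attacks with
  a type-II saturating attack rate),
* linear character costs deducted from the cost-free intrinsic rates
  (``lambda_t = lambda* - C_n * n``, ``eta_t = eta* - C_p * p``).

All numerical kernels are written as numpy ufunc expressions so that the
same code path serves scalar simulation and vectorised batch runs
bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("coevodyn")

#: Default smallest admissible cost-adjusted rate (lambda_t, eta_t).
DEFAULT_RATE_FLOOR = 1e-9
#: Default density below which a population is declared extinct (m^-2).
DEFAULT_EXTINCTION_THRESHOLD = 1e-6
#: Default finite-difference step for fitness gradients (character units).
DEFAULT_GRADIENT_STEP = 1e-5


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HostParams:
    """Ecological and evolutionary constants of the host (weevil) population.

    Parameters
    ----------
    lambda_star : float
        Cost-free intrinsic growth rate lambda* (offspring per adult per
        generation); must exceed 1 for persistence in a parasitoid-free
        system.
    K : float
        Carrying capacity (adults m^-2).
    C_n : float
        Cost coefficient: growth-rate units lost per unit of the resistance
        character.
    Gamma_n : float
        Additive genetic variance of the resistance character
        (character-units^2). 0 means the character cannot evolve.
    N0 : float
        Initial density (adults m^-2).
    n0 : float
        Initial mean character value.
    """

    lambda_star: float
    K: float
    C_n: float = 1.0
    Gamma_n: float = 0.01
    N0: float = 0.0
    n0: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_star <= 0:
            raise ValueError("lambda_star must be > 0")
        if self.K <= 0:
            raise ValueError("carrying capacity K must be > 0")
        if self.Gamma_n < 0:
            raise ValueError("additive genetic variance Gamma_n must be >= 0")
        if self.N0 < 0:
            raise ValueError("initial density N0 must be >= 0")


@dataclass(frozen=True)
class ParasitoidParams:
    """Constants of one parasitoid population.

    ``Gamma_p = 0`` encodes strict asexuality (a clonal, thelytokous line
    whose counter-adaptation character cannot respond to selection).
    ``introduction_generation`` allows a parasitoid to enter mid-run, as in
    the two-parasitoid introduction experiments. A mid-run introduction
    with ``inherit_character=True`` starts from the resident (first)
    parasitoid's current mean character instead of ``p0`` — the protocol
    for introducing a new strain of an already-established parasitoid
    species, whose counter-adaptation machinery matches the resident's.
    """

    eta_star: float
    c: float
    a: float
    kappa: float
    C_p: float = 1.0
    Gamma_p: float = 0.0
    P0: float = 0.0
    p0: float = 0.9
    introduction_generation: int = 0
    inherit_character: bool = False

    def __post_init__(self) -> None:
        if self.eta_star <= 0:
            raise ValueError("eta_star must be > 0")
        if not 0 < self.c <= 1:
            raise ValueError("larval survival c must be in (0, 1]")
        if self.a < 0:
            raise ValueError("searching efficiency a must be >= 0")
        if self.kappa <= 0:
            raise ValueError("spatial heterogeneity kappa must be > 0")
        if self.Gamma_p < 0:
            raise ValueError("Gamma_p must be >= 0")
        if self.P0 < 0:
            raise ValueError("initial density P0 must be >= 0")
        if self.introduction_generation < 0:
            raise ValueError("introduction_generation must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Numerical configuration shared by all simulators.

    ``character_floor`` is an optional lower bound on every mean
    character. By default the characters are unbounded reals; because
    the linear costs reward *lowering* a character, coupled
    host-parasitoid pairs can then drift downward together without
    limit while their gap (and hence every observable rate) stays
    well-defined. Setting the floor to 0 treats the characters as
    non-negative investment traits and gives the system genuine
    character equilibria; the two-parasitoid introduction experiments
    use that variant (see the experiments module).
    """

    generations: int = 300
    gradient_step: float = DEFAULT_GRADIENT_STEP
    extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD
    rate_floor: float = DEFAULT_RATE_FLOOR
    character_floor: float = float("-inf")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.gradient_step <= 0:
            raise ValueError("gradient_step must be > 0")
        if self.extinction_threshold < 0:
            raise ValueError("extinction_threshold must be >= 0")
        if self.rate_floor <= 0:
            raise ValueError("rate_floor must be > 0")


@dataclass
class SystemState:
    """Densities, mean characters and derived quantities at one generation.

    ``parasitoid_densities``, ``x_bars``, ``alphas``, ``eta_ts``,
    ``escapes`` and ``parasitism_rates`` are tuples with one entry per
    parasitoid (a single entry for the two-species model). A parasitoid
    that is not yet introduced, or extinct, has density exactly 0; its
    derived per-parasitoid quantities are reported as ``alpha`` computed
    from the stored character, escape 1 and parasitism 0.
    """

    t: int
    N: float
    parasitoid_densities: tuple[float, ...]
    n_bar: float
    x_bars: tuple[float, ...]
    lambda_t: float = 0.0
    g: float = 1.0
    alphas: tuple[float, ...] = ()
    eta_ts: tuple[float, ...] = ()
    escapes: tuple[float, ...] = ()
    parasitism_rates: tuple[float, ...] = ()

    # Convenience accessors used throughout tests and the experiment layer.
    @property
    def p_bar(self) -> float:
        return self.x_bars[0]

    @property
    def y_bar(self) -> float:
        return self.x_bars[1]

    def present(self, i: int) -> bool:
        """Whether parasitoid *i* currently has positive density."""
        return self.parasitoid_densities[i] > 0.0

    def validate(self) -> None:
        if self.N < 0 or any(d < 0 for d in self.parasitoid_densities):
            raise ValueError("densities must be non-negative")
        for al in self.alphas:
            if not 0.0 <= al <= 1.0:
                raise ValueError("alpha out of [0, 1]")
        for f in self.escapes:
            if not 0.0 < f <= 1.0:
                raise ValueError("escape probability out of (0, 1]")
        if self.parasitism_rates:
            if any(not 0.0 <= r <= 1.0 for r in self.parasitism_rates):
                raise ValueError("parasitism rate out of [0, 1]")
            if sum(self.parasitism_rates) > 1.0 + 1e-12:
                raise ValueError("parasitism rates must sum to <= 1")


# ---------------------------------------------------------------------------
# Core functions (numpy-ufunc based; accept scalars or arrays)
# ---------------------------------------------------------------------------

def density_dependence(N, lambda_t, K):
    """Density-dependent survival factor ``g = [1 + N(lambda-1)/K]^-1``.

    Strictly decreasing in N; equals 1 for an empty population and
    ``1/lambda`` at carrying capacity.
    """
    if np.any(np.asarray(K) <= 0):
        raise ValueError("carrying capacity K must be > 0")
    return 1.0 / (1.0 + N * (lambda_t - 1.0) / K)


def resistance_alpha(n_bar, x_bar):
    """Resistant proportion ``alpha = 1 - exp(-(n - x)^2)``.

    Depends only on the squared gap between the host's and the
    parasitoid's mean character, so it is symmetric in the sign of the
    difference and invariant under joint translation of both characters.
    """
    d = n_bar - x_bar
    return -np.expm1(-(d * d))


def escape_probability(N, X, a, kappa, eta_t, alpha, g):
    """Probability that a susceptible host escapes parasitism.

    Negative-binomial (aggregated) attacks with a type-II saturating
    per-parasitoid attack rate::

        f = [1 + a X / (kappa (1 + a N g (1 - alpha) / eta_t))]^(-kappa)

    ``g`` is the density-dependence factor already evaluated at the current
    host density. ``f = 1`` exactly when ``X = 0`` or ``a = 0``; f is
    strictly decreasing in the attacking density X.
    """
    saturation = 1.0 + a * N * g * (1.0 - alpha) / eta_t
    return np.power(1.0 + a * X / (kappa * saturation), -kappa)


def cost_adjusted_rates(host: HostParams, par: ParasitoidParams, n_bar, p_bar,
                        rate_floor: float = DEFAULT_RATE_FLOOR):
    """Cost-adjusted intrinsic rates ``(lambda_t, eta_t)``.

    ``lambda_t = max(lambda* - C_n n, floor)`` and
    ``eta_t = max(eta* - C_p p, floor)``. Hitting the floor is logged as a
    warning, not an error.
    """
    lambda_t = host.lambda_star - host.C_n * n_bar
    eta_t = par.eta_star - par.C_p * p_bar
    if np.any(lambda_t < rate_floor) or np.any(eta_t < rate_floor):
        logger.warning("cost-adjusted rate clamped to floor %.3g", rate_floor)
    return np.maximum(lambda_t, rate_floor), np.maximum(eta_t, rate_floor)


def cost_adjusted_lambda(host: HostParams, n_bar, rate_floor=DEFAULT_RATE_FLOOR):
    """Host growth rate after the resistance-character cost, floored."""
    return np.maximum(host.lambda_star - host.C_n * n_bar, rate_floor)


def cost_adjusted_eta(par: ParasitoidParams, p_bar, rate_floor=DEFAULT_RATE_FLOOR):
    """Parasitoid attack rate after the virulence-character cost, floored."""
    return np.maximum(par.eta_star - par.C_p * p_bar, rate_floor)


# ---------------------------------------------------------------------------
# State construction
# ---------------------------------------------------------------------------

def make_state(t: int, N: float, densities: Sequence[float], n_bar: float,
               x_bars: Sequence[float], host: HostParams,
               parasitoids: Sequence[ParasitoidParams],
               config: SimConfig) -> SystemState:
    """Build a :class:`SystemState`, filling in all derived quantities.

    The per-parasitoid parasitism rate is the proportion of *all* hosts a
    parasitoid infects this generation:
    ``(1 - alpha_i)(1 - f_i) * prod_{j != i} f_j``, so the rates of the two
    parasitoids sum to the total infected proportion.
    """
    densities = tuple(float(d) for d in densities)
    x_bars = tuple(float(x) for x in x_bars)
    lambda_t = float(cost_adjusted_lambda(host, n_bar, config.rate_floor))
    g = float(density_dependence(N, lambda_t, host.K))
    alphas, eta_ts, escapes = [], [], []
    for par, X, x_bar in zip(parasitoids, densities, x_bars):
        al = float(resistance_alpha(n_bar, x_bar))
        eta_t = float(cost_adjusted_eta(par, x_bar, config.rate_floor))
        if X > 0.0:
            f = float(escape_probability(N, X, par.a, par.kappa, eta_t, al, g))
        else:
            f = 1.0
        alphas.append(al)
        eta_ts.append(eta_t)
        escapes.append(f)
    rates = []
    for i in range(len(densities)):
        other = 1.0
        for j in range(len(densities)):
            if j != i:
                other = other * escapes[j]
        rates.append((1.0 - alphas[i]) * (1.0 - escapes[i]) * other)
    return SystemState(
        t=t, N=float(N), parasitoid_densities=densities, n_bar=float(n_bar),
        x_bars=x_bars, lambda_t=lambda_t, g=g, alphas=tuple(alphas),
        eta_ts=tuple(eta_ts), escapes=tuple(escapes),
        parasitism_rates=tuple(rates),
    )


# ---------------------------------------------------------------------------
# Parameter I/O
# ---------------------------------------------------------------------------

def _params_from_dict(d: dict):
    host = HostParams(**d["host"])
    parasitoids = [ParasitoidParams(**p) for p in d["parasitoids"]]
    sim = SimConfig(**d.get("sim", {}))
    return host, parasitoids, sim


def load_config(path) -> tuple[HostParams, list[ParasitoidParams], SimConfig]:
    """Read host/parasitoid/simulation parameters from a YAML or JSON file."""
    text = open(path).read()
    if str(path).endswith(".json"):
        d = json.loads(text)
    else:
        d = yaml.safe_load(text)
    return _params_from_dict(d)


def dump_config(host: HostParams, parasitoids: Sequence[ParasitoidParams],
                sim: SimConfig, path) -> None:
    """Write a parameter set to YAML (or JSON if the path ends in .json)."""
    d = {"host": asdict(host), "parasitoids": [asdict(p) for p in parasitoids],
         "sim": asdict(sim)}
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(d, fh, indent=2)
        else:
            yaml.safe_dump(d, fh, sort_keys=False)


def load_parameter_table() -> pd.DataFrame:
    """Packaged life-history parameter table for the two study systems.

    Columns: parameter, definition, the Argentine stem weevil /
    M. hyperodae system, the lucerne weevil / M. aethiopoides (Moroccan
    strain) system, and the low/high bounds of the range explored in the
    sensitivity analysis. System entries are kept verbatim ("1-18",
    "42±22", "?", "-", "K"); use :func:`parse_table_entry` to interpret
    them.
    """
    with resources.files("coevodyn.data").joinpath(
            "system_parameters.csv").open() as fh:
        return pd.read_csv(fh)


def parse_table_entry(entry, K: float | None = None):
    """Interpret one system-column entry of the parameter table.

    Returns ``(low, high)`` (equal for a point value), or ``None`` for an
    unknown ("?") or unassigned ("-") entry. "K" resolves to the system's
    carrying capacity when given.
    """
    s = str(entry).strip()
    if s in {"?", "-", "", "nan"}:
        return None
    if s == "K":
        if K is None:
            raise ValueError("entry 'K' needs the carrying capacity")
        return (K, K)
    if "±" in s:
        mid, half = (float(v) for v in s.split("±"))
        return (mid - half, mid + half)
    if "-" in s[1:]:
        lo, hi = s.split("-", 1)
        return (float(lo), float(hi))
    v = float(s)
    return (v, v)
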