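"""Headline computational experiments, as reproducible pipeline stages.

* the AGV-ratio sweep: how the ratio of parasitoid to host additive
  genetic variance sets long-run parasitism and host resistance;
* the two-parasitoid introduction grid: a second parasitoid (sexual or
  asexual) enters an established host-parasitoid system at generation
  500 and the competitive outcome is classified;
* per-system long-term predictions with parameter uncertainty (uniform
  draws over each system's empirical ranges);
* the model-vs-field statistical comparison (F-test for equal variances,
  then a pooled-variance Student or Welch two-sample t-test).

The documented baseline fixes every parameter of the Argentine stem
weevil system at a single value inside its empirical range (see
``BASELINE``); host additive genetic variance is held at 0.01
throughout. The parasitism-aggregation parameter kappa, reported only
as a field-measured range (0.23-0.87), is the one knob the two
experiment families pin differently: the ratio-sweep endpoints
calibrate to kappa = 0.30 and the two-parasitoid introduction outcomes
to kappa = 0.42; both values are exposed as arguments. The
introduction experiments additionally run the variant with the
character floor at zero investment (see the methods note for why the
unbounded variant cannot hold a resident pair at a character
equilibrium for an invader to meet).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import Trajectory, classify_outcome, simulate
from .model_core import (
    HostParams,
    ParasitoidParams,
    SimConfig,
    load_parameter_table,
    parse_table_entry,
)

#: Baseline parameter set for the sweep/grid experiments. All values sit
#: inside the empirical ranges of the Argentine stem weevil system; the
#: host growth rate, reported only as a range (1-18), is pinned at 13.
BASELINE: dict[str, float] = {
    "lambda_star": 13.0,
    "K": 720.0,
    "eta_star": 42.0,
    "c": 0.92,
    "a": 4.14,
    "kappa": 0.42,
    "C_n": 1.0,
    "C_p": 1.0,
    "N0": 720.0,
    "P0": 10.0,
    "n0": 1.0,
    "p0": 0.9,
    "Gamma_n": 0.01,
}

#: Parasitism aggregation used by the ratio-sweep experiments (the value
#: within the measured 0.23-0.87 range that reproduces the published
#: sweep endpoints; the introduction experiments use BASELINE's 0.42).
SWEEP_KAPPA: float = 0.30


def baseline_host(**overrides) -> HostParams:
    """Host parameters at the documented baseline (host starts at K)."""
    d = {k: BASELINE[k] for k in
         ("lambda_star", "K", "C_n", "Gamma_n", "N0", "n0")}
    d.update(overrides)
    return HostParams(**d)


def baseline_parasitoid(Gamma_p: float, double_eta: bool = False,
                        introduction_generation: int = 0,
                        **overrides) -> ParasitoidParams:
    """Parasitoid parameters at the documented baseline.

    ``double_eta`` doubles the cost-free intrinsic attack rate; the
    two-parasitoid experiments use it for asexual (Gamma = 0) lines,
    whose all-female clonal broods are credited with twice the effective
    attack rate of a sexual line with a 1:1 sex ratio.
    """
    d = {k: BASELINE[k] for k in ("c", "a", "kappa", "C_p", "P0", "p0")}
    d["eta_star"] = BASELINE["eta_star"] * (2.0 if double_eta else 1.0)
    d["Gamma_p"] = Gamma_p
    d["introduction_generation"] = introduction_generation
    d.update(overrides)
    return ParasitoidParams(**d)


# ---------------------------------------------------------------------------
# AGV-ratio sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Endpoint of one 300-generation run at a given AGV ratio."""

    ratio: float
    final_parasitism: float
    final_resistance: float


def agv_ratio_sweep(ratios: Sequence[float],
                    config: SimConfig | None = None,
                    host: HostParams | None = None,
                    kappa: float = SWEEP_KAPPA) -> list[SweepResult]:
    """Final parasitism and resistance vs the AGV ratio Gamma_p : Gamma_n.

    One two-species run per ratio, host AGV fixed at the baseline 0.01,
    parasitoid AGV = ratio * 0.01; endpoints are read at the final
    generation (300 by default).
    """
    if config is None:
        config = SimConfig(generations=300)
    if host is None:
        host = baseline_host()
    out = []
    for ratio in ratios:
        if ratio < 0:
            raise ValueError("AGV ratio must be >= 0")
        par = baseline_parasitoid(Gamma_p=ratio * host.Gamma_n, kappa=kappa)
        traj = simulate(host, [par], config)
        out.append(SweepResult(ratio=float(ratio),
                               final_parasitism=traj.final.parasitism_rates[0],
                               final_resistance=traj.final.alphas[0]))
    return out


def resistance_threshold_ratio(results: Sequence[SweepResult],
                               alpha_threshold: float = 0.05) -> float | None:
    """Smallest swept ratio from which resistance stays below threshold.

    Returns the smallest ratio r* such that every swept ratio >= r* ends
    with final resistance < ``alpha_threshold``; None if resistance
    emerges even at the largest ratio.
    """
    ordered = sorted(results, key=lambda r: r.ratio)
    threshold = None
    for res in ordered:
        if res.final_resistance < alpha_threshold:
            if threshold is None:
                threshold = res.ratio
        else:
            threshold = None
    return threshold


def sweep_to_frame(results: Sequence[SweepResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# Two-parasitoid introduction grid
# ---------------------------------------------------------------------------

@dataclass
class GridCell:
    """Outcome of one second-parasitoid introduction scenario."""

    gamma_first: float
    gamma_second: float
    pre_introduction_rate: float
    final_rates: tuple[float, float]
    extinct: tuple[bool, bool]


def introduction_scenario(gamma_first: float, gamma_second: float,
                          introduction_generation: int = 500,
                          config: SimConfig | None = None) -> Trajectory:
    """Run one host + two-parasitoid scenario at the documented baseline.

    The first parasitoid is present from generation 0; the second enters
    at ``introduction_generation`` with density P0, inheriting the
    resident parasitoid's current mean character (a new strain of the
    same species shares its counter-adaptation machinery; for an
    asexual resident this equals the original p0). Asexual lines
    (Gamma = 0) get a doubled intrinsic attack rate. The default
    configuration runs 2000 generations with the character floor at
    zero investment, the variant under which the system has genuine
    character equilibria for the invader to engage with.
    """
    if config is None:
        config = SimConfig(generations=2000, character_floor=0.0)
    host = baseline_host()
    first = baseline_parasitoid(gamma_first, double_eta=(gamma_first == 0.0))
    second = baseline_parasitoid(
        gamma_second, double_eta=(gamma_second == 0.0),
        introduction_generation=introduction_generation,
        inherit_character=True)
    return simulate(host, [first, second], config)


def introduction_grid(gamma_values: Sequence[float] = (0.0, 0.01, 0.1),
                      introduction_generation: int = 500,
                      config: SimConfig | None = None) -> list[GridCell]:
    """All AGV combinations of first and second parasitoid.

    The pre-introduction rate is the first parasitoid's parasitism rate
    in the generation before the second enters; final rates are read at
    the last generation.
    """
    cells = []
    for g1 in gamma_values:
        for g2 in gamma_values:
            traj = introduction_scenario(g1, g2, introduction_generation,
                                         config)
            outcome = classify_outcome(traj)
            pre = traj.state_at(introduction_generation - 1).parasitism_rates[0]
            cells.append(GridCell(
                gamma_first=float(g1), gamma_second=float(g2),
                pre_introduction_rate=pre,
                final_rates=tuple(traj.final.parasitism_rates),
                extinct=tuple(not p.persisted for p in outcome.parasitoids),
            ))
    return cells


def grid_to_frame(cells: Sequence[GridCell]) -> pd.DataFrame:
    rows = []
    for c in cells:
        rows.append({
            "gamma_first": c.gamma_first, "gamma_second": c.gamma_second,
            "pre_introduction_rate": c.pre_introduction_rate,
            "final_rate_first": c.final_rates[0],
            "final_rate_second": c.final_rates[1],
            "first_extinct": c.extinct[0], "second_extinct": c.extinct[1],
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# System-specific long-term predictions
# ---------------------------------------------------------------------------

#: Study systems: host / parasitoid pair, generations per year, and which
#: table column holds their life-history values.
SYSTEMS = {
    "argentine_stem_weevil": {
        "column": "argentine_stem_weevil", "generations_per_year": 3,
        "Gamma_n": 0.01, "Gamma_p": 0.0,
    },
    "lucerne_weevil": {
        "column": "lucerne_weevil", "generations_per_year": 1,
        "Gamma_n": 0.01, "Gamma_p": 0.01,
    },
}

#: Values unavailable for one system and assumed shared with the other
#: (larval survival c and searching efficiency a are only measured in the
#: Argentine stem weevil system).
_SHARED_FALLBACK = {"c": 0.92, "a": 4.14}


def system_parameter_draws(system: str, n_draws: int, seed: int = 0
                           ) -> pd.DataFrame:
    """``n_draws`` parameter sets for a study system.

    Parameters with a single measured value are used as-is; parameters
    reported as a range are drawn uniformly (one independent draw per
    parameter set). An unmeasured cost coefficient means no cost is
    deducted (C_p = 0 for the asexual parasitoid whose character cannot
    evolve anyway).
    """
    if system not in SYSTEMS:
        raise ValueError(f"unknown system {system!r}; choose from "
                         f"{sorted(SYSTEMS)}")
    spec = SYSTEMS[system]
    table = load_parameter_table().set_index("parameter")
    K = float(table.loc["K", spec["column"]])
    rng = np.random.default_rng(seed)
    cols = {}
    for name in table.index:
        bounds = parse_table_entry(table.loc[name, spec["column"]], K=K)
        if bounds is None:
            if name in _SHARED_FALLBACK:
                value = _SHARED_FALLBACK[name]
            elif name in ("C_n", "C_p"):
                value = 0.0
            else:
                raise ValueError(f"no value for parameter {name!r}")
            cols[name] = np.full(n_draws, value)
        elif bounds[0] == bounds[1]:
            cols[name] = np.full(n_draws, bounds[0])
        else:
            cols[name] = rng.uniform(bounds[0], bounds[1], n_draws)
    cols["Gamma_n"] = np.full(n_draws, spec["Gamma_n"])
    cols["Gamma_p"] = np.full(n_draws, spec["Gamma_p"])
    return pd.DataFrame(cols)


def system_prediction(system: str, years: Sequence[int] = (3, 24, 100),
                      n_draws: int = 20, seed: int = 0,
                      config: SimConfig | None = None) -> pd.DataFrame:
    """Predicted parasitism-rate distribution at the requested years.

    Each draw is one full two-species run; the parasitism rate is read
    at year * generations-per-year. Returns a tidy frame with columns
    draw, year, generation, parasitism_rate.
    """
    spec = SYSTEMS[system]
    gpy = spec["generations_per_year"]
    horizon = max(years) * gpy
    if config is None:
        config = SimConfig(generations=horizon, seed=seed)
    elif config.generations < horizon:
        raise ValueError("config.generations shorter than the horizon")
    draws = system_parameter_draws(system, n_draws, seed)
    rows = []
    for d, row in draws.iterrows():
        host = HostParams(lambda_star=row["lambda"], K=row["K"],
                          C_n=row["C_n"], Gamma_n=row["Gamma_n"],
                          N0=row["N0"], n0=row["n0"])
        par = ParasitoidParams(eta_star=row["eta"], c=row["c"], a=row["a"],
                               kappa=row["kappa"], C_p=row["C_p"],
                               Gamma_p=row["Gamma_p"], P0=row["P0"],
                               p0=row["p0"])
        traj = simulate(host, [par], config)
        for year in years:
            st = traj.state_at(year * gpy)
            rows.append({"draw": d, "year": year, "generation": year * gpy,
                         "parasitism_rate": st.parasitism_rates[0]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model vs field comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Two-sample comparison of model and field parasitism proportions."""

    model_mean: float
    field_mean: float
    f_statistic: float
    f_p_value: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    welch_used: bool
    model_normality_p: float
    field_normality_p: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compare_model_to_field(model_samples, field_samples,
                           alpha_level: float = 0.05) -> ComparisonResult:
    """F-test for equal variances, then Student or Welch two-sample t-test.

    The pooled-variance Student t-test is used unless the two-sided
    F-test rejects variance equality at ``alpha_level``, in which case
    the Welch modification to the degrees of freedom is applied. Samples
    are screened for normality (Shapiro-Wilk); the result is reported,
    not enforced.
    """
    x = np.asarray(model_samples, dtype=float)
    y = np.asarray(field_samples, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("degenerate input: both samples have zero variance")

    F = vx / vy if vy > 0 else np.inf
    dfn, dfd = x.size - 1, y.size - 1
    cdf = stats.f.cdf(F, dfn, dfd)
    f_p = 2.0 * min(cdf, 1.0 - cdf)
    welch = f_p < alpha_level

    t_res = stats.ttest_ind(x, y, equal_var=not welch)
    if welch:
        se2x, se2y = vx / x.size, vy / y.size
        dof = (se2x + se2y) ** 2 / (se2x ** 2 / (x.size - 1)
                                    + se2y ** 2 / (y.size - 1))
    else:
        dof = x.size + y.size - 2

    def _shapiro_p(v):
        return float(stats.shapiro(v).pvalue) if np.ptp(v) > 0 else np.nan

    return ComparisonResult(
        model_mean=float(x.mean()), field_mean=float(y.mean()),
        f_statistic=float(F), f_p_value=float(f_p),
        t_statistic=float(t_res.statistic), degrees_of_freedom=float(dof),
        p_value=float(t_res.pvalue), welch_used=bool(welch),
        model_normality_p=_shapiro_p(x), field_normality_p=_shapiro_p(y),
    )
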