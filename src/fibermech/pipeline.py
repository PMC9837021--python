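"""End-to-end driver: database predictions, sensitivity sweeps, reports.

The functions here tie the composition pipeline, the four-RVE
homogenization chain and the elastic-limit downscaling together and
present results as tidy pandas DataFrames (one row per fiber x scenario).
Everything is deterministic: rerunning with the same inputs reproduces
output byte for byte.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import (
    CW_PHASES,
    MASS_PHASES,
    SCENARIOS,
    FiberRecord,
    RVEFractions,
    ScenarioInput,
    _shift_cellulose,
    build_scenarios,
    cellwall_volume_fractions,
    crystallinity_mass,
    load_fibers,
    load_phases,
    normalize_masses,
)
from .homogenize import ModelConfig, predict_stiffness
from .limit import FailureModel, tensile_elastic_limit

logger = logging.getLogger(__name__)

__all__ = [
    "predict_fiber",
    "predict_all",
    "sensitivity_sweep",
    "SweepResult",
    "degenerate_scenario",
    "composition_summary",
    "volume_fraction_table",
    "validate_report",
]

SWEEP_PARAMS = ("cellulose", "crystallinity", "mfa", "lumen")


def degenerate_scenario() -> ScenarioInput:
    """A fiber of 100 % aligned crystalline cellulose: no polymer network,
    zero microfibril angle, zero lumen porosity.  The whole concentration
    chain collapses to the identity, so the prediction must return the bare
    nanofibril axial modulus and strength (useful as an analytic anchor)."""
    f_cw = {p: 0.0 for p in CW_PHASES}
    f_cw["NF"] = 1.0
    rve = RVEFractions(
        f_pn_cw=0.0,
        f_MF_cw=1.0,
        f_pn={p: 0.0 for p in ("hemcel", "lig", "pec", "ash", "npor")},
        f_cel={"NF": 1.0, "amcel": 0.0},
    )
    rho = load_phases().densities["NF"]
    return ScenarioInput(
        name="pure crystalline cellulose",
        scenario="avg",
        f_cw=f_cw,
        rve=rve,
        theta=0.0,
        f_lum=0.0,
        rho_cw=rho,
        rho_fib=rho,
    )


def predict_fiber(
    rec: FiberRecord,
    scenarios=SCENARIOS,
    config: ModelConfig = ModelConfig(),
) -> pd.DataFrame:
    """Predict axial modulus and elastic limit for one fiber's scenarios."""
    props = load_phases(pectin_poisson=config.pectin_poisson)
    built = build_scenarios(rec, props)
    fm = FailureModel(config.sigma_ult_NF)
    rows = []
    for s in scenarios:
        h = predict_stiffness(built[s], props, config)
        rows.append(
            {
                "name": rec.name,
                "type": rec.type,
                "scenario": s,
                "E_fib_GPa": h.E_fib,
                "Sigma_ult_MPa": tensile_elastic_limit(h, fm),
                "rho_cw_g_cm3": built[s].rho_cw,
                "f_lum": built[s].f_lum,
                "theta_deg": built[s].theta,
                "sc_iterations": h.sc_iterations,
                "asymmetry_cw": h.asymmetry_cw,
            }
        )
        logger.info(
            "%s/%s: E=%.2f GPa, Sigma_ult=%.0f MPa (SC %d iters)",
            rec.name, s, rows[-1]["E_fib_GPa"], rows[-1]["Sigma_ult_MPa"],
            h.sc_iterations,
        )
    return pd.DataFrame(rows)


def predict_all(
    fibers: list[str] | None = None,
    scenarios=SCENARIOS,
    config: ModelConfig = ModelConfig(),
) -> pd.DataFrame:
    """Predictions for all (or the named) fibers of the packaged database."""
    db = load_fibers()
    if fibers is None:
        fibers = list(db)
    unknown = [f for f in fibers if f not in db]
    if unknown:
        raise KeyError(
            f"unknown fiber(s) {unknown}; valid names: {sorted(db)}"
        )
    frames = [predict_fiber(db[name], scenarios, config) for name in fibers]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# sensitivity sweeps


@dataclass
class SweepResult:
    """One-parameter sensitivity sweep with min/max envelope band."""

    name: str
    param: str
    grid: np.ndarray
    curve: pd.DataFrame  # other inputs at their averages
    band_low: pd.DataFrame  # other inputs at their unfavorable extremes
    band_high: pd.DataFrame  # other inputs at their favorable extremes


def _scenario_with(
    rec: FiberRecord,
    base: str,
    param: str,
    value: float,
) -> ScenarioInput:
    """Scenario ``base`` of ``rec`` with one swept parameter overridden."""
    from .composition import rve_fractions

    props = load_phases()
    built = build_scenarios(rec, props)
    s = built[base]
    m_avg = normalize_masses({p: rec.masses[p].avg for p in MASS_PHASES})
    if param == "mfa":
        return ScenarioInput(s.name, base, s.f_cw, s.rve, float(value), s.f_lum,
                             s.rho_cw, s.rho_fib)
    if param == "lumen":
        return ScenarioInput(s.name, base, s.f_cw, s.rve, s.theta, float(value),
                             s.rho_cw, s.rho_fib)
    # composition-level parameters require re-running the volume pipeline
    if param == "cellulose":
        masses = _shift_cellulose(m_avg, float(value))
        xi_M = _base_xi_M(rec, base, props)  # crystallinity of the base scenario
    elif param == "crystallinity":
        masses = _base_masses(rec, base, m_avg)
        xi_M = crystallinity_mass(float(value) / 100.0, props)
    else:
        raise ValueError(f"unknown sweep parameter {param!r}; use one of {SWEEP_PARAMS}")
    f_cw = cellwall_volume_fractions(masses, xi_M, props)
    return ScenarioInput(s.name, base, f_cw, rve_fractions(f_cw), s.theta,
                         s.f_lum, s.rho_cw, s.rho_fib)


def _base_xi_M(rec: FiberRecord, base: str, props) -> float:
    xi = {
        "avg": rec.xi_V.avg,
        "max": min(100.0, max(rec.xi_V.hi if rec.xi_V.hi is not None else rec.xi_V.avg,
                              rec.xi_V.avg + 5.0)),
        "min": max(0.0, min(rec.xi_V.lo if rec.xi_V.lo is not None else rec.xi_V.avg,
                            rec.xi_V.avg - 5.0)),
    }[base]
    return crystallinity_mass(xi / 100.0, props)


def _base_masses(rec: FiberRecord, base: str, m_avg) -> dict[str, float]:
    if base == "avg":
        return dict(m_avg)
    tc = rec.masses["totcel"]
    if base == "max":
        hi = tc.hi if tc.hi is not None else tc.avg
        target = min(100.0, max(hi, m_avg["totcel"] + 5.0))
    else:
        lo = tc.lo if tc.lo is not None else tc.avg
        target = max(0.0, min(lo, m_avg["totcel"] - 5.0))
    return _shift_cellulose(m_avg, target)


def _sweep_bounds(rec: FiberRecord, param: str) -> tuple[float, float]:
    props = load_phases()
    built = build_scenarios(rec, props)
    if param == "cellulose":
        m = {s: _base_masses(rec, s, normalize_masses(
            {p: rec.masses[p].avg for p in MASS_PHASES}))["totcel"] for s in ("min", "max")}
        return m["min"], m["max"]
    if param == "crystallinity":
        lo = max(0.0, min(rec.xi_V.lo if rec.xi_V.lo is not None else rec.xi_V.avg,
                          rec.xi_V.avg - 5.0))
        hi = min(100.0, max(rec.xi_V.hi if rec.xi_V.hi is not None else rec.xi_V.avg,
                            rec.xi_V.avg + 5.0))
        return lo, hi
    if param == "mfa":
        return built["max"].theta, built["min"].theta  # small angle = stiff
    if param == "lumen":
        return built["max"].f_lum, built["min"].f_lum
    raise ValueError(f"unknown sweep parameter {param!r}; use one of {SWEEP_PARAMS}")


def sensitivity_sweep(
    fiber: str,
    param: str,
    n_grid: int = 15,
    config: ModelConfig = ModelConfig(),
) -> SweepResult:
    """Sweep one physicochemical property over its reported interval.

    The solid curve keeps all other inputs at their representative
    averages; the band re-evaluates the sweep with the remaining inputs at
    their unfavorable (band_low) and favorable (band_high) extremes,
    mirroring how the min/max prediction scenarios combine features.
    """
    db = load_fibers()
    if fiber not in db:
        raise KeyError(f"unknown fiber {fiber!r}; valid names: {sorted(db)}")
    rec = db[fiber]
    lo, hi = _sweep_bounds(rec, param)
    if np.isclose(lo, hi):
        warnings.warn(f"{fiber}: degenerate {param} interval [{lo}, {hi}]; "
                      "single-point sweep")
        grid = np.array([lo])
    else:
        grid = np.linspace(lo, hi, n_grid)

    props = load_phases(pectin_poisson=config.pectin_poisson)
    fm = FailureModel(config.sigma_ult_NF)

    def run(base: str) -> pd.DataFrame:
        rows = []
        for g in grid:
            s = _scenario_with(rec, base, param, g)
            h = predict_stiffness(s, props, config)
            rows.append({"value": g, "E_fib_GPa": h.E_fib,
                         "Sigma_ult_MPa": tensile_elastic_limit(h, fm)})
        return pd.DataFrame(rows)

    return SweepResult(
        name=fiber,
        param=param,
        grid=grid,
        curve=run("avg"),
        band_low=run("min"),
        band_high=run("max"),
    )


# ---------------------------------------------------------------------------
# derived composition tables


def composition_summary() -> pd.DataFrame:
    """Per fiber: average cell-wall density and min/avg/max lumen porosity [%]."""
    db = load_fibers()
    rows = []
    for name, rec in db.items():
        built = build_scenarios(rec)
        rows.append(
            {
                "name": name,
                "type": rec.type,
                "rho_cw_g_cm3": built["avg"].rho_cw,
                # stiff (max) scenario has the smallest lumen porosity
                "f_lum_min_pct": 100.0 * built["max"].f_lum,
                "f_lum_avg_pct": 100.0 * built["avg"].f_lum,
                "f_lum_max_pct": 100.0 * built["min"].f_lum,
            }
        )
    return pd.DataFrame(rows)


def volume_fraction_table() -> pd.DataFrame:
    """Cell-wall volume fractions [%] per fiber and scenario (7 phases)."""
    db = load_fibers()
    rows = []
    for name, rec in db.items():
        built = build_scenarios(rec)
        for s in SCENARIOS:
            row = {"name": name, "scenario": s}
            row.update({p: 100.0 * built[s].f_cw[p] for p in CW_PHASES})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# validation report


def validate_report(
    predictions: pd.DataFrame | None = None,
    reference: pd.DataFrame | None = None,
    plot_path: str | None = None,
) -> pd.DataFrame:
    """Per-fiber report of predicted intervals and invariant checks.

    ``reference``, if given, is a DataFrame with columns
    (name, E_min_GPa, E_max_GPa, S_min_MPa, S_max_MPa) of experimental
    intervals to draw next to the predictions; fibers without reference
    data are rendered with predictions only.
    """
    if predictions is None:
        predictions = predict_all()
    wide_E = predictions.pivot(index="name", columns="scenario", values="E_fib_GPa")
    wide_S = predictions.pivot(index="name", columns="scenario", values="Sigma_ult_MPa")
    report = pd.DataFrame(
        {
            "E_min_GPa": wide_E["min"],
            "E_avg_GPa": wide_E["avg"],
            "E_max_GPa": wide_E["max"],
            "S_min_MPa": wide_S["min"],
            "S_avg_MPa": wide_S["avg"],
            "S_max_MPa": wide_S["max"],
        }
    )
    report["ordering_ok"] = (
        (report["E_min_GPa"] <= report["E_avg_GPa"] + 1e-9)
        & (report["E_avg_GPa"] <= report["E_max_GPa"] + 1e-9)
        & (report["S_min_MPa"] <= report["S_avg_MPa"] + 1e-9)
        & (report["S_avg_MPa"] <= report["S_max_MPa"] + 1e-9)
    )
    if reference is not None:
        required = {"name", "E_min_GPa", "E_max_GPa", "S_min_MPa", "S_max_MPa"}
        missing = required - set(reference.columns)
        if missing:
            raise ValueError(f"reference file lacks columns {sorted(missing)}")
        report = report.join(reference.set_index("name"), rsuffix="_ref")
    if plot_path is not None:
        _plot_intervals(report, plot_path)
    return report.reset_index()


def _plot_intervals(report: pd.DataFrame, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(12, 8), sharex=True)
    x = np.arange(len(report))
    for ax, lo, avg, hi, ref_lo, ref_hi, label in (
        (axes[0], "E_min_GPa", "E_avg_GPa", "E_max_GPa",
         "E_min_GPa_ref", "E_max_GPa_ref", "axial modulus [GPa]"),
        (axes[1], "S_min_MPa", "S_avg_MPa", "S_max_MPa",
         "S_min_MPa_ref", "S_max_MPa_ref", "tensile elastic limit [MPa]"),
    ):
        ax.bar(x, report[hi] - report[lo], bottom=report[lo], width=0.6,
               alpha=0.6, label="predicted interval")
        ax.scatter(x, report[avg], marker="_", s=300, color="k",
                   label="predicted average")
        if ref_lo in report.columns:
            ok = report[ref_lo].notna()
            ax.vlines(x[ok], report.loc[ok, ref_lo], report.loc[ok, ref_hi],
                      color="C3", lw=2, label="reference interval")
        ax.set_ylabel(label)
        ax.legend(loc="upper right", fontsize=8)
    axes[1].set_xticks(x)
    axes[1].set_xticklabels(report.index, rotation=75, ha="right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
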