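"""From raw physicochemical fiber data to homogenization-ready inputs.

Plant fibers are described in the literature by cell-wall mass fractions of
total cellulose, hemicellulose, lignin, pectin, ash and nanoporosity
(wax/fat extractives), a volumetric cellulose crystallinity index, the
microfibril angle, and the fiber bulk density -- each reported as a
min / representative-average / max triple.  This module converts such
records into the volume fractions the four-RVE homogenization chain needs:

1. normalize mass fractions to a 100 % total (proportional down-scaling if
   the raw sum exceeds 100; unassigned mass counted as nanoporosity if it
   falls short),
2. convert the volumetric crystallinity index to a mass-based one and split
   total cellulose into crystalline (NF) and amorphous parts,
3. convert masses to cell-wall volume fractions via phase densities,
4. derive per-RVE fractions (polymer network, cellulose, cell wall),
5. back-calculate lumen porosity from the fiber density and the
   composition-dependent cell-wall density,
6. assemble min/avg/max scenarios: the extreme scenarios move cellulose
   content and crystallinity by at least 5 percentage points off the
   average (or to the reported extreme, whichever is further), take the
   favorable/unfavorable ends of the microfibril-angle and density
   intervals, and fall back to +/-3 degrees and +/-10 % when no interval
   is reported.

A packaged database of 26 common plant fibers (bast, grass, leaf,
fruit/seed and straw types) ships with the module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .kelvin import iso_stiffness

__all__ = [
    "PhaseProps",
    "Triple",
    "FiberRecord",
    "ScenarioInput",
    "load_phases",
    "load_fibers",
    "normalize_masses",
    "crystallinity_mass",
    "cellwall_volume_fractions",
    "rve_fractions",
    "cellwall_density",
    "lumen_porosity",
    "build_scenarios",
    "random_fiber_record",
]

MASS_PHASES = ("totcel", "hemcel", "lig", "pec", "ash", "npor")
CW_PHASES = ("NF", "amcel", "hemcel", "lig", "pec", "ash", "npor")
PN_PHASES = ("hemcel", "lig", "pec", "ash", "npor")
SCENARIOS = ("min", "avg", "max")


# ---------------------------------------------------------------------------
# intrinsic phase properties


@dataclass(frozen=True)
class PhaseProps:
    """Intrinsic per-phase densities [g/cm^3] and stiffnesses [GPa]."""

    densities: Mapping[str, float]
    bulk: Mapping[str, float]
    shear: Mapping[str, float]
    nf_stiffness: np.ndarray  # 6x6, local frame

    def stiffness(self, phase: str) -> np.ndarray:
        """6x6 Kelvin-Mandel stiffness of a phase (NF: anisotropic, local frame)."""
        if phase == "NF":
            return self.nf_stiffness.copy()
        return iso_stiffness(self.bulk[phase], self.shear[phase])


@lru_cache(maxsize=8)
def load_phases(pectin_poisson: float = 0.35) -> PhaseProps:
    """Load the packaged intrinsic phase properties.

    Pectin's shear modulus is derived from its bulk modulus and an assumed
    Poisson ratio (default 0.35, the convention used for the other
    amorphous cell-wall polymers).
    """
    with resources.files("fibermech.data").joinpath("phases.json").open() as fh:
        raw = json.load(fh)["phases"]
    dens, bulk, shear = {}, {}, {}
    nf = None
    for name, rec in raw.items():
        dens[name] = float(rec["density"])
        if "stiffness" in rec:
            nf = np.asarray(rec["stiffness"], dtype=float)
            continue
        k = float(rec["k"])
        mu = rec["mu"]
        if mu is None:
            nu = float(rec.get("poisson_assumed", pectin_poisson))
            mu = 3.0 * k * (1.0 - 2.0 * nu) / (2.0 * (1.0 + nu))
        bulk[name], shear[name] = k, float(mu)
    return PhaseProps(densities=dens, bulk=bulk, shear=shear, nf_stiffness=nf)


# ---------------------------------------------------------------------------
# fiber records


@dataclass(frozen=True)
class Triple:
    """min / representative-average / max of one reported property.

    Missing extremes are stored as None and resolved by scenario rules.
    """

    lo: float | None
    avg: float
    hi: float | None

    def __post_init__(self):
        if self.avg is None or np.isnan(self.avg):
            raise ValueError("average value is required")
        # note: the literature compilation occasionally reports min > avg
        # (a quirk of combining sources); triples are stored as reported and
        # scenario rules decide how extremes are used


@dataclass(frozen=True)
class FiberRecord:
    """One plant's raw literature values (unnormalized percentages)."""

    name: str
    type: str
    masses: Mapping[str, Triple]  # keys MASS_PHASES, percent
    xi_V: Triple  # volumetric crystallinity, percent
    mfa: Triple  # microfibril angle, degrees
    rho_fib: Triple  # fiber density, g/cm^3
    assumed: frozenset = frozenset()  # provenance flags: {"mfa","xi","rho"}

    def __post_init__(self):
        for key in MASS_PHASES:
            if key not in self.masses:
                raise ValueError(f"{self.name}: missing mass-fraction entry {key!r}")
            t = self.masses[key]
            for v in (t.lo, t.avg, t.hi):
                if v is not None and not 0.0 <= v <= 100.0:
                    raise ValueError(f"{self.name}: {key} fraction {v} outside [0, 100] %")
        for v in (self.mfa.lo, self.mfa.avg, self.mfa.hi):
            if v is not None and not 0.0 <= v <= 90.0:
                raise ValueError(f"{self.name}: microfibril angle {v} outside [0, 90] deg")
        for v in (self.xi_V.lo, self.xi_V.avg, self.xi_V.hi):
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"{self.name}: crystallinity {v} outside [0, 100] %")
        if self.rho_fib.avg <= 0:
            raise ValueError(f"{self.name}: non-positive fiber density")


def _triple(row, stem: str) -> Triple:
    def get(col):
        v = row[f"{stem}_{col}"]
        return None if pd.isna(v) else float(v)

    avg = get("avg")
    if avg is None:
        raise ValueError(f"missing average value for {stem!r}")
    return Triple(get("min"), avg, get("max"))


def load_fibers() -> dict[str, FiberRecord]:
    """Load the packaged 26-fiber database, keyed by fiber name."""
    with resources.files("fibermech.data").joinpath("fibers.csv").open() as fh:
        df = pd.read_csv(fh)
    records = {}
    for _, row in df.iterrows():
        masses = {p: _triple(row, p) for p in MASS_PHASES}
        flags = frozenset(
            str(row["assumed"]).split(";") if not pd.isna(row["assumed"]) else ()
        )
        rec = FiberRecord(
            name=row["name"],
            type=row["type"],
            masses=masses,
            xi_V=_triple(row, "xi"),
            mfa=_triple(row, "mfa"),
            rho_fib=_triple(row, "rho"),
            assumed=flags,
        )
        records[rec.name] = rec
    return records


# ---------------------------------------------------------------------------
# composition pipeline


def normalize_masses(raw: Mapping[str, float]) -> dict[str, float]:
    """Normalize raw mass fractions [%] to sum exactly 100.

    Sums above 100 are scaled down proportionally; a deficit below 100 is
    counted as unassigned extractive matter and added to the nanoporosity.
    """
    masses = {p: float(raw.get(p, 0.0)) for p in MASS_PHASES}
    for p, v in masses.items():
        if v < 0:
            raise ValueError(f"negative mass fraction for {p!r}: {v}")
    total = sum(masses.values())
    if total > 100.0:
        masses = {p: v * 100.0 / total for p, v in masses.items()}
    else:
        masses["npor"] += 100.0 - total
    return masses


def crystallinity_mass(xi_V: float, props: PhaseProps | None = None) -> float:
    """Mass-based crystallinity index from the volumetric one (fractions in [0,1]).

    xi_M = 1 / (1 + (1/xi_V - 1) * rho_amcel / rho_NF); since amorphous
    cellulose is lighter than the crystal, xi_M >= xi_V.
    """
    if not 0.0 <= xi_V <= 1.0:
        raise ValueError(f"volumetric crystallinity must be in [0, 1], got {xi_V}")
    if xi_V == 0.0:
        return 0.0
    props = props or load_phases()
    ratio = props.densities["amcel"] / props.densities["NF"]
    return 1.0 / (1.0 + (1.0 / xi_V - 1.0) * ratio)


def cellwall_volume_fractions(
    masses: Mapping[str, float], xi_M: float, props: PhaseProps | None = None
) -> dict[str, float]:
    """Cell-wall volume fractions of the seven phases (sum 1).

    ``masses`` are normalized mass fractions [%]; total cellulose is split
    into crystalline (NF) and amorphous parts by the mass crystallinity
    xi_M, then all masses are converted to volumes via phase densities and
    renormalized.
    """
    props = props or load_phases()
    if not 0.0 <= xi_M <= 1.0:
        raise ValueError(f"mass crystallinity must be in [0, 1], got {xi_M}")
    split = {
        "NF": xi_M * masses["totcel"],
        "amcel": (1.0 - xi_M) * masses["totcel"],
        **{p: masses[p] for p in MASS_PHASES if p != "totcel"},
    }
    volumes = {p: m / props.densities[p] for p, m in split.items()}
    total = sum(volumes.values())
    return {p: v / total for p, v in volumes.items()}


@dataclass(frozen=True)
class RVEFractions:
    """Volume fractions regrouped per representative volume element."""

    f_pn_cw: float  # polymer network within the cell wall
    f_MF_cw: float  # cellulose microfibrils within the cell wall
    f_pn: Mapping[str, float]  # within the polymer network (5 phases)
    f_cel: Mapping[str, float]  # within the microfibril (NF, amcel)


def rve_fractions(f_cw: Mapping[str, float]) -> RVEFractions:
    """Regroup cell-wall fractions into per-RVE fractions (each summing to 1)."""
    f_pn_cw = sum(f_cw[p] for p in PN_PHASES)
    f_MF_cw = f_cw["NF"] + f_cw["amcel"]
    if f_pn_cw <= 0.0:
        raise ValueError("degenerate RVE: polymer-network fraction is zero")
    if f_MF_cw <= 0.0:
        raise ValueError("degenerate RVE: microfibril fraction is zero")
    return RVEFractions(
        f_pn_cw=f_pn_cw,
        f_MF_cw=f_MF_cw,
        f_pn={p: f_cw[p] / f_pn_cw for p in PN_PHASES},
        f_cel={p: f_cw[p] / f_MF_cw for p in ("NF", "amcel")},
    )


def cellwall_density(f_cw: Mapping[str, float], props: PhaseProps | None = None) -> float:
    """Cell-wall density [g/cm^3] as the volume-fraction-weighted phase density."""
    props = props or load_phases()
    return sum(props.densities[p] * f_cw[p] for p in CW_PHASES)


def lumen_porosity(rho_fib: float, rho_cw: float) -> float:
    """Lumen volume fraction from the fiber/cell-wall density ratio, clamped to [0, 1)."""
    if rho_fib <= 0 or rho_cw <= 0:
        raise ValueError("densities must be positive")
    return float(np.clip(1.0 - rho_fib / rho_cw, 0.0, 1.0))


# ---------------------------------------------------------------------------
# scenarios


@dataclass(frozen=True)
class ScenarioInput:
    """Fully resolved single-scenario model input."""

    name: str
    scenario: str  # "min" | "avg" | "max"
    f_cw: Mapping[str, float]  # 7 cell-wall fractions, sum 1
    rve: RVEFractions
    theta: float  # microfibril angle, degrees
    f_lum: float  # lumen porosity at the fiber scale
    rho_cw: float  # average-composition cell-wall density [g/cm^3]
    rho_fib: float

    @property
    def f_cw_fib(self) -> float:
        return 1.0 - self.f_lum


def _shift_cellulose(m_avg: Mapping[str, float], target_totcel: float) -> dict[str, float]:
    """Move the cellulose mass to ``target_totcel`` %, rescaling the other
    phases proportionally so the total stays at 100 %."""
    rest_avg = 100.0 - m_avg["totcel"]
    scale = (100.0 - target_totcel) / rest_avg if rest_avg > 0 else 0.0
    out = {p: m_avg[p] * scale for p in MASS_PHASES if p != "totcel"}
    out["totcel"] = target_totcel
    return out


def build_scenarios(
    rec: FiberRecord, props: PhaseProps | None = None
) -> dict[str, ScenarioInput]:
    """Resolve a fiber record into min / avg / max model inputs.

    The max (stiffest/strongest) scenario combines the favorable extremes:
    cellulose mass and crystallinity at their reported maxima but at least
    5 percentage points above the average, the smallest microfibril angle,
    and the largest fiber density (hence smallest lumen porosity).  The min
    scenario mirrors this.  Interval fallbacks where only an average is
    reported: +/-3 degrees on the angle, +/-10 % on the density, and the
    average itself for the mass fractions.  Lumen porosities for all three
    scenarios use the average-composition cell-wall density.
    """
    props = props or load_phases()
    m_avg = normalize_masses({p: rec.masses[p].avg for p in MASS_PHASES})

    # cellulose mass per scenario (normalized percent)
    tc = rec.masses["totcel"]
    tc_hi = tc.hi if tc.hi is not None else tc.avg
    tc_lo = tc.lo if tc.lo is not None else tc.avg
    totcel = {
        "avg": m_avg["totcel"],
        "max": min(100.0, max(tc_hi, m_avg["totcel"] + 5.0)),
        "min": max(0.0, min(tc_lo, m_avg["totcel"] - 5.0)),
    }
    # crystallinity per scenario (percent)
    xi_hi = rec.xi_V.hi if rec.xi_V.hi is not None else rec.xi_V.avg
    xi_lo = rec.xi_V.lo if rec.xi_V.lo is not None else rec.xi_V.avg
    xi = {
        "avg": rec.xi_V.avg,
        "max": min(100.0, max(xi_hi, rec.xi_V.avg + 5.0)),
        "min": max(0.0, min(xi_lo, rec.xi_V.avg - 5.0)),
    }
    # microfibril angle: small angle -> stiff fiber, so max scenario takes the
    # reported minimum angle (fallback avg -/+ 3 degrees)
    theta = {
        "avg": rec.mfa.avg,
        "max": rec.mfa.lo if rec.mfa.lo is not None else max(0.0, rec.mfa.avg - 3.0),
        "min": rec.mfa.hi if rec.mfa.hi is not None else min(90.0, rec.mfa.avg + 3.0),
    }
    # fiber density: dense fiber -> little lumen -> stiff, so max scenario
    # takes the largest density (fallback +/-10 %)
    rho = {
        "avg": rec.rho_fib.avg,
        "max": rec.rho_fib.hi if rec.rho_fib.hi is not None else 1.1 * rec.rho_fib.avg,
        "min": rec.rho_fib.lo if rec.rho_fib.lo is not None else 0.9 * rec.rho_fib.avg,
    }

    # cell-wall density is an average-composition quantity for all scenarios
    f_cw_avg = cellwall_volume_fractions(
        m_avg, crystallinity_mass(rec.xi_V.avg / 100.0, props), props
    )
    rho_cw = cellwall_density(f_cw_avg, props)

    out = {}
    for s in SCENARIOS:
        masses = _shift_cellulose(m_avg, totcel[s]) if s != "avg" else dict(m_avg)
        xi_M = crystallinity_mass(xi[s] / 100.0, props)
        f_cw = cellwall_volume_fractions(masses, xi_M, props)
        out[s] = ScenarioInput(
            name=rec.name,
            scenario=s,
            f_cw=f_cw,
            rve=rve_fractions(f_cw),
            theta=theta[s],
            f_lum=lumen_porosity(rho[s], rho_cw),
            rho_cw=rho_cw,
            rho_fib=rho[s],
        )
    return out


# ---------------------------------------------------------------------------
# synthetic records for property tests


def random_fiber_record(rng: np.random.Generator, name: str = "synthetic") -> FiberRecord:
    """Generate a random but physically valid fiber record.

    Masses are drawn uniformly and renormalized to at most 100 %,
    crystallinity in [20, 100] %, microfibril angle in [0, 50] degrees, and
    the fiber density is drawn below the implied cell-wall density so the
    lumen porosity stays in [0, 1).  Intended for property-based tests, not
    as a model of any real plant.
    """
    w = rng.uniform(0.05, 1.0, size=6)
    w = w / w.sum() * rng.uniform(60.0, 100.0)
    masses = dict(zip(MASS_PHASES, w))
    masses["totcel"] = max(masses["totcel"], 20.0)  # keep the cellulose RVE non-trivial
    xi_avg = rng.uniform(20.0, 100.0)
    theta_avg = rng.uniform(0.0, 50.0)

    props = load_phases()
    m_norm = normalize_masses(masses)
    f_cw = cellwall_volume_fractions(m_norm, crystallinity_mass(xi_avg / 100.0, props), props)
    rho_cw = cellwall_density(f_cw, props)
    rho_avg = rng.uniform(0.3 * rho_cw, rho_cw)

    def spread(avg, lo_cap, hi_cap, frac=0.1):
        lo = max(lo_cap, avg * (1 - frac * rng.uniform(0, 1)))
        hi = min(hi_cap, avg * (1 + frac * rng.uniform(0, 1)))
        return Triple(lo, avg, hi)

    return FiberRecord(
        name=name,
        type="synthetic",
        masses={p: spread(v, 0.0, 100.0) for p, v in masses.items()},
        xi_V=spread(xi_avg, 0.0, 100.0),
        mfa=Triple(max(0.0, theta_avg - 3.0), theta_avg, min(90.0, theta_avg + 3.0)),
        rho_fib=spread(rho_avg, 0.01, rho_cw),
        assumed=frozenset({"synthetic"}),
    )
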