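"""Four-RVE stiffness upscaling chain for plant fibers.

The chain mirrors the hierarchical fiber microstructure:

1. *polymer network*: hemicellulose, lignin, pectin, ash and (empty)
   nanopores as mutually interacting spherical phases -- self-consistent
   scheme, solved as a fixed point;
2. *cellulose microfibril*: crystalline nanofibrils as infinitely long
   aligned cylinders in an amorphous-cellulose matrix -- Mori-Tanaka;
3. *cell wall*: microfibrils tilted by the microfibril angle theta off the
   fiber axis, uniformly distributed in azimuth, embedded in the polymer
   network -- Mori-Tanaka with an azimuthal orientation average;
4. *technical fiber*: cylindrical lumen pores along the fiber axis in a
   cell-wall matrix -- Mori-Tanaka with void inclusions.

All algebra happens on 6x6 Kelvin-Mandel matrices; strain concentration
operators are cached per level so the elastic-limit module can downscale a
macroscopic stress to the nanofibril without re-running the chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import hill
from .composition import PN_PHASES, PhaseProps, ScenarioInput, load_phases
from .kelvin import (
    Orientation,
    asymmetry,
    axial_modulus,
    iso_moduli,
    iso_stiffness,
    km_rotation,
    rotation_matrix,
    symmetrize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "HomogenizationResult",
    "sc_polymer_network",
    "mt_microfibril",
    "mt_cellwall",
    "mt_fiber",
    "predict_stiffness",
]

_I6 = np.eye(6)


@dataclass(frozen=True)
class ModelConfig:
    """Numerical and physical knobs of the upscaling chain.

    n_azimuth: trapezoid points of the azimuthal orientation average (the
        integrand is 2*pi-periodic and smooth, so convergence is spectral).
    sc_tol / sc_maxiter: fixed-point control of the self-consistent scheme.
    eq11_denominator: normalization of the orientation-averaged Mori-Tanaka
        step.  "standard_mt" uses the bare concentration tensors in the
        normalizing bracket (consistent with the general concentration
        rule); "as_printed" keeps the inclusion stiffness inside it.
    sigma_ult_NF: axial tensile strength of the cellulose nanofibril [MPa].
    pectin_poisson: Poisson ratio assumed to close pectin's elasticity.
    """

    n_azimuth: int = 72
    sc_tol: float = 1e-10
    sc_maxiter: int = 500
    eq11_denominator: str = "standard_mt"
    sigma_ult_NF: float = 2300.0
    pectin_poisson: float = 0.35

    def __post_init__(self):
        if self.eq11_denominator not in ("standard_mt", "as_printed"):
            raise ValueError(f"unknown eq11_denominator {self.eq11_denominator!r}")


@dataclass
class HomogenizationResult:
    """Stiffnesses of the four RVEs plus the cached concentration operators
    needed to downscale a macroscopic stress to the nanofibril."""

    scenario: ScenarioInput | None
    C_pn: np.ndarray
    C_MF: np.ndarray  # local (r,t,l) frame
    C_cw: np.ndarray
    C_fib: np.ndarray
    E_fib: float  # axial Young's modulus [GPa]
    # cached operators (see elastic_limit):
    A0_NF: np.ndarray  # nanofibril dilute concentration, local frame
    cel_norm: np.ndarray  # (f_am I + f_NF A0_NF)^-1, local frame
    phis: np.ndarray  # azimuth samples
    A0_MF: np.ndarray  # (n_azimuth, 6, 6) dilute microfibril concentrations, global
    cw_norm: np.ndarray  # cell-wall-level normalizing bracket, inverted
    A_cw: np.ndarray  # cell-wall strain concentration within the fiber RVE
    D_fib: np.ndarray  # fiber compliance [1/GPa]
    theta: float
    sc_iterations: int = 0
    asymmetry_cw: float = 0.0  # pre-symmetrization relative asymmetry


def sc_polymer_network(
    fractions: Mapping[str, float],
    props: PhaseProps,
    config: ModelConfig = ModelConfig(),
    start: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Self-consistent stiffness of the polymer network (5 spherical phases).

    The scheme embeds every phase in the (unknown) homogenized medium
    itself; the resulting implicit equation is solved by direct fixed-point
    iteration started from the Voigt average (or ``start``, any positive
    definite guess -- the fixed point does not depend on it).  Returns
    (C_pn, iterations).
    """
    fr = {p: float(fractions[p]) for p in PN_PHASES}
    total = sum(fr.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"polymer-network fractions must sum to 1, got {total}")
    stiff = {p: props.stiffness(p) for p in PN_PHASES}
    porosity = sum(f for p, f in fr.items() if np.allclose(stiff[p], 0.0))
    if porosity >= 1.0 - 1e-12:
        raise ValueError("polymer network consists of pores only")

    C = start.copy() if start is not None else sum(f * stiff[p] for p, f in fr.items())
    for it in range(1, config.sc_maxiter + 1):
        # isotropic phases + spherical shapes keep C isotropic; projecting
        # onto (k, mu) removes quadrature-level anisotropy noise
        k, mu = iso_moduli(C)
        C = iso_stiffness(k, mu)
        P = hill.hill_sphere(C, check=False)
        num = np.zeros((6, 6))
        den = np.zeros((6, 6))
        for p, f in fr.items():
            A0 = np.linalg.inv(_I6 + P @ (stiff[p] - C))
            num += f * stiff[p] @ A0
            den += f * A0
        C_new = num @ np.linalg.inv(den)
        C_new = symmetrize(C_new)
        err = np.linalg.norm(C_new - C) / max(np.linalg.norm(C_new), 1e-30)
        C = C_new
        if err < config.sc_tol:
            return C, it
    raise RuntimeError(
        f"self-consistent scheme did not converge in {config.sc_maxiter} iterations"
    )


def mt_microfibril(
    f_NF: float, f_amcel: float, props: PhaseProps
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mori-Tanaka stiffness of the cellulose microfibril, local frame.

    Crystalline nanofibrils are infinitely long cylinders along the local
    axis l in an amorphous-cellulose matrix.  Returns
    (C_MF, A0_NF, cel_norm) with cel_norm = (f_am I + f_NF A0_NF)^-1.
    """
    if abs(f_NF + f_amcel - 1.0) > 1e-9:
        raise ValueError("cellulose fractions must sum to 1")
    C_am = props.stiffness("amcel")
    C_NF = props.stiffness("NF")
    if f_NF == 0.0:
        return C_am, _I6.copy(), _I6.copy()
    P = hill.hill_cylinder(C_am, check=False)
    A0 = np.linalg.inv(_I6 + P @ (C_NF - C_am))
    cel_norm = np.linalg.inv(f_amcel * _I6 + f_NF * A0)
    C_MF = symmetrize((f_amcel * C_am + f_NF * C_NF @ A0) @ cel_norm)
    return C_MF, A0, cel_norm


def mt_cellwall(
    C_MF: np.ndarray,
    C_pn: np.ndarray,
    f_MF: float,
    f_pn: float,
    theta: float,
    config: ModelConfig = ModelConfig(),
) -> tuple[np.ndarray, dict]:
    """Azimuthally averaged Mori-Tanaka stiffness of the cell wall.

    Microfibrils are tilted by the constant microfibril angle ``theta``
    [degrees] off the fiber axis L and uniformly distributed in azimuth;
    the orientation integrals are evaluated by an N-point trapezoid rule.
    Returns (C_cw, cache) where the cache carries the per-azimuth dilute
    concentrations and the normalizing bracket for strain downscaling.
    """
    if abs(f_MF + f_pn - 1.0) > 1e-9:
        raise ValueError("cell-wall fractions must sum to 1")
    n = config.n_azimuth
    phis = 2.0 * np.pi * np.arange(n) / n

    # the polymer network is isotropic: compute the tilted-cylinder Hill
    # tensor once at phi=0 and rotate it around L for the other azimuths
    P0 = hill.hill_cylinder_rotated(C_pn, Orientation(theta, 0.0), check=False)

    A0_list = np.empty((n, 6, 6))
    T_sum = np.zeros((6, 6))
    A_sum = np.zeros((6, 6))
    for i, phi in enumerate(phis):
        Q = km_rotation(rotation_matrix(Orientation(theta, phi)))
        C_MF_g = Q @ C_MF @ Q.T
        Qz = km_rotation(rotation_matrix(Orientation(0.0, phi)))
        P = Qz @ P0 @ Qz.T
        A0 = np.linalg.inv(_I6 + P @ (C_MF_g - C_pn))
        A0_list[i] = A0
        T_sum += C_MF_g @ A0
        A_sum += A0
    T_avg = T_sum / n
    A_avg = A_sum / n

    num = f_pn * C_pn + f_MF * T_avg
    if config.eq11_denominator == "standard_mt":
        den = f_pn * _I6 + f_MF * A_avg
    else:  # as_printed
        den = f_pn * _I6 + f_MF * T_avg
    cw_norm = np.linalg.inv(den)
    C_raw = num @ cw_norm
    asym = asymmetry(C_raw)
    C_cw = symmetrize(C_raw)
    logger.info("cell wall: pre-symmetrization asymmetry %.3e", asym)
    cache = {"phis": phis, "A0_MF": A0_list, "cw_norm": cw_norm, "asymmetry": asym}
    return C_cw, cache


def mt_fiber(C_cw: np.ndarray, f_lum: float) -> tuple[np.ndarray, float, np.ndarray]:
    """Mori-Tanaka stiffness of the technical fiber with cylindrical lumens.

    Lumens are infinitely long voids along the fiber axis L.  Returns
    (C_fib, E_fib, A_cw) with A_cw the cell-wall strain concentration.
    """
    if not 0.0 <= f_lum < 1.0:
        raise ValueError(f"lumen porosity must be in [0, 1), got {f_lum}")
    f_cw = 1.0 - f_lum
    if f_lum == 0.0:
        return C_cw.copy(), axial_modulus(C_cw), _I6.copy()
    P = hill.hill_cylinder(C_cw, check=False)
    A0_lum = np.linalg.inv(_I6 - P @ C_cw)  # void inclusion: C_i = 0
    A_cw = np.linalg.inv(f_cw * _I6 + f_lum * A0_lum)
    C_fib = symmetrize(f_cw * C_cw @ A_cw)
    return C_fib, axial_modulus(C_fib), A_cw


def predict_stiffness(
    s: ScenarioInput,
    props: PhaseProps | None = None,
    config: ModelConfig = ModelConfig(),
) -> HomogenizationResult:
    """Run the four-RVE chain for one scenario and cache the operators."""
    props = props or load_phases(pectin_poisson=config.pectin_poisson)
    if s.rve.f_pn_cw == 0.0:
        # degenerate all-cellulose cell wall: the polymer network carries no
        # volume; a placeholder reference keeps the (theta = 0) Hill tensor
        # well defined and the chain collapses exactly onto C_MF
        C_pn, iters = props.stiffness("amcel"), 0
    else:
        C_pn, iters = sc_polymer_network(s.rve.f_pn, props, config)
    C_MF, A0_NF, cel_norm = mt_microfibril(
        s.rve.f_cel["NF"], s.rve.f_cel["amcel"], props
    )
    C_cw, cache = mt_cellwall(C_MF, C_pn, s.rve.f_MF_cw, s.rve.f_pn_cw, s.theta, config)
    C_fib, E_fib, A_cw = mt_fiber(C_cw, s.f_lum)
    return HomogenizationResult(
        scenario=s,
        C_pn=C_pn,
        C_MF=C_MF,
        C_cw=C_cw,
        C_fib=C_fib,
        E_fib=E_fib,
        A0_NF=A0_NF,
        cel_norm=cel_norm,
        phis=cache["phis"],
        A0_MF=cache["A0_MF"],
        cw_norm=cache["cw_norm"],
        A_cw=A_cw,
        D_fib=np.linalg.inv(C_fib),
        theta=s.theta,
        sc_iterations=iters,
        asymmetry_cw=cache["asymmetry"],
    )
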