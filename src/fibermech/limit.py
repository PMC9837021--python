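"""Elastic-limit upscaling: from nanofibril strength to fiber strength.

Plant fibers rupture quasi-brittly, and failure is attributed to tensile
failure of the crystalline cellulose nanofibrils.  The fiber therefore
stays intact as long as the axial nanofibril stress, obtained by elastic
downscaling of the macroscopic uniaxial tension, remains below the
nanofibril strength (2300 MPa by default, from sonication-induced
fragmentation of wood nanofibrils):

    F = sigma_NF_ll - sigma_NF_ll_ult <= 0.

Since the whole concentration chain is linear in the macroscopic stress,
the elastic limit follows in closed form as
sigma_ult / (axial nanofibril stress per unit macrostress); under the
elasto-brittle assumption it equals the fiber tensile strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .homogenize import HomogenizationResult
from .kelvin import Orientation, km_rotation, rotation_matrix

__all__ = ["FailureModel", "nanofibril_axial_stress", "tensile_elastic_limit"]

#: relative tolerance on the azimuth-invariance of the axial nanofibril stress
AZIMUTH_TOL = 1e-6


@dataclass(frozen=True)
class FailureModel:
    """Brittle nanofibril failure: axial tensile strength in MPa."""

    sigma_ult_NF: float = 2300.0

    def __post_init__(self):
        if self.sigma_ult_NF <= 0:
            raise ValueError("nanofibril strength must be positive")


def _unit_concentration(h: HomogenizationResult) -> np.ndarray:
    """Nanofibril stress per unit macroscopic axial stress, per azimuth.

    Downscaling chain: macrostress -> macrostrain (fiber compliance) ->
    cell-wall strain -> microfibril strain at azimuth phi -> rotation into
    the local fibril frame -> nanofibril strain -> nanofibril stress.
    Returns an (n_azimuth, 6) array of local-frame stress components per
    unit macrostress (dimensionless concentration factors).
    """
    for attr in ("D_fib", "A_cw", "cw_norm", "A0_MF", "cel_norm", "A0_NF"):
        if getattr(h, attr, None) is None:
            raise ValueError(f"homogenization result lacks cached operator {attr!r}")
    from .composition import load_phases

    C_NF = load_phases().nf_stiffness
    sigma_macro = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0.0])
    eps_cw = h.A_cw @ (h.D_fib @ sigma_macro)
    out = np.empty((len(h.phis), 6))
    for i, phi in enumerate(h.phis):
        eps_mf_global = h.A0_MF[i] @ (h.cw_norm @ eps_cw)
        Q = km_rotation(rotation_matrix(Orientation(h.theta, phi)))
        eps_mf_local = Q.T @ eps_mf_global
        eps_nf = h.A0_NF @ (h.cel_norm @ eps_mf_local)
        out[i] = C_NF @ eps_nf
    return out


def nanofibril_axial_stress(h: HomogenizationResult, Sigma: float) -> float:
    """Axial (ll) nanofibril stress [MPa] under macroscopic tension Sigma [MPa].

    The ll component is azimuth-independent; this is asserted (relative
    tolerance 1e-6) and the azimuth mean is returned.
    """
    conc = _unit_concentration(h)[:, 2]
    mean = float(conc.mean())
    spread = np.ptp(conc)
    if spread > AZIMUTH_TOL * max(abs(mean), 1e-12):
        raise RuntimeError(
            "axial nanofibril stress varies with azimuth "
            f"(relative spread {spread / abs(mean):.2e}); check quadrature"
        )
    return mean * Sigma


def tensile_elastic_limit(
    h: HomogenizationResult, fm: FailureModel = FailureModel()
) -> float:
    """Fiber tensile elastic limit [MPa].

    Exploits linearity: Sigma_ult = sigma_ult_NF / (axial nanofibril stress
    per unit macrostress).  Raises for non-positive concentration (which
    would mean axial tension unloads the fibrils -- a pathological input).
    """
    c = nanofibril_axial_stress(h, 1.0)
    if c <= 0:
        raise ValueError(f"non-positive nanofibril stress concentration {c}")
    return fm.sigma_ult_NF / c
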