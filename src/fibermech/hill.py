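"""Hill polarization tensors for spheres and infinitely long cylinders.

The Hill tensor P of an ellipsoidal inclusion in an infinite reference
medium of stiffness C0 encodes the inclusion shape and the matrix
elasticity; P : C0 is the Eshelby tensor.  Here P is evaluated numerically
from the Green-operator (acoustic tensor) representation:

* sphere:   P = <Gamma(n)> averaged over the unit sphere of wave normals,
* infinite cylinder: the average localizes onto the great circle of
  normals perpendicular to the cylinder axis, a 1-D periodic integral,

with Gamma_ijkl(n) the symmetrized n (x) K^-1(n) (x) n and
K_ik(n) = C0_ijkl n_j n_l the acoustic tensor.  Both integrands are smooth,
so Gauss-Legendre x trapezoid (sphere) and uniform trapezoid (circle)
converge spectrally; every public entry point self-checks convergence by
doubling the quadrature order.  This numeric route covers isotropic and
fully anisotropic reference media uniformly and is validated in the test
suite against the classical isotropic closed forms (Eshelby sphere,
infinite cylinder).

Units: P in 1/GPa for C0 in GPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kelvin import (
    Orientation,
    km_matrix_from_tensor,
    rotation_matrix,
    tensor_from_km_matrix,
)

__all__ = ["InclusionShape", "hill_numeric", "hill_sphere", "hill_cylinder",
           "hill_cylinder_rotated", "eshelby_sphere_iso"]

#: default quadrature orders (polar x azimuth for the sphere; points on the
#: transverse circle for the cylinder)
SPHERE_ORDER = (16, 32)
CYLINDER_ORDER = 256
#: relative Frobenius tolerance of the order-doubling self-check
CONV_TOL = 1e-8


@dataclass(frozen=True)
class InclusionShape:
    """Inclusion geometry: ``kind`` in {"sphere", "cylinder"}; cylinders are
    infinitely long with axis given by ``orientation`` (default: along the
    frame's 3-axis)."""

    kind: str
    orientation: Orientation = Orientation(0.0, 0.0)

    def __post_init__(self):
        if self.kind not in ("sphere", "cylinder"):
            raise ValueError(f"unknown inclusion kind {self.kind!r}")


def _check_reference(C0: np.ndarray) -> None:
    if C0.shape != (6, 6):
        raise ValueError("reference stiffness must be a 6x6 Kelvin-Mandel matrix")
    sym = 0.5 * (C0 + C0.T)
    eig = np.linalg.eigvalsh(sym)
    if eig.min() <= 0:
        raise ValueError(
            "reference stiffness must be positive definite "
            f"(smallest eigenvalue {eig.min():.3e})"
        )


def _gamma_average(C0: np.ndarray, normals: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted average of the Green operator Gamma(n) over wave normals.

    normals: (M, 3) unit vectors; weights: (M,) summing to 1.
    """
    T0 = tensor_from_km_matrix(C0)
    K = np.einsum("ijkl,mj,ml->mik", T0, normals, normals)
    N = np.linalg.inv(K)
    nNn = np.einsum("mj,mik,ml->mijkl", normals, N, normals)
    # symmetrize over (ij) and (kl)
    G = 0.25 * (
        nNn
        + nNn.transpose(0, 2, 1, 3, 4)
        + nNn.transpose(0, 1, 2, 4, 3)
        + nNn.transpose(0, 2, 1, 4, 3)
    )
    P = np.einsum("m,mijkl->ijkl", weights, G)
    return km_matrix_from_tensor(P)


def _sphere_nodes(order: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    n_polar, n_azim = order
    x, w = np.polynomial.legendre.leggauss(n_polar)  # x = cos(polar angle)
    phi = 2.0 * np.pi * np.arange(n_azim) / n_azim
    ct, cphi = np.meshgrid(x, phi, indexing="ij")
    st = np.sqrt(1.0 - ct**2)
    normals = np.stack(
        [st * np.cos(cphi), st * np.sin(cphi), ct * np.ones_like(cphi)], axis=-1
    ).reshape(-1, 3)
    weights = np.repeat(w, n_azim) / (2.0 * n_azim)  # integrates to 1 over S^2/4pi
    return normals, weights


def _circle_nodes(axis: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    # any unit vector not parallel to the axis
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(a, helper)
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    psi = 2.0 * np.pi * np.arange(n) / n
    normals = np.outer(np.cos(psi), u) + np.outer(np.sin(psi), v)
    weights = np.full(n, 1.0 / n)
    return normals, weights


def hill_sphere(C0: np.ndarray, order: tuple[int, int] = SPHERE_ORDER,
                check: bool = True) -> np.ndarray:
    """Hill tensor of a spherical inclusion in reference medium C0.

    With ``check`` the quadrature order is doubled until the result is
    converged (strongly anisotropic references need finer grids than the
    default, which suffices for isotropic media).
    """
    _check_reference(C0)
    P = _gamma_average(C0, *_sphere_nodes(order))
    if check:
        for _ in range(4):
            order = (2 * order[0], 2 * order[1])
            P2 = _gamma_average(C0, *_sphere_nodes(order))
            err = np.linalg.norm(P - P2) / np.linalg.norm(P2)
            P = P2
            if err < CONV_TOL:
                break
        else:
            raise RuntimeError(
                "Hill-tensor quadrature for the sphere did not converge: "
                f"order doubling to {order} still changed P by {err:.2e} "
                f"relative (tol {CONV_TOL})"
            )
    return 0.5 * (P + P.T)


def hill_cylinder(C0: np.ndarray, axis=(0.0, 0.0, 1.0), n: int = CYLINDER_ORDER,
                  check: bool = True) -> np.ndarray:
    """Hill tensor of an infinitely long cylinder with the given axis in C0.

    The infinite-aspect-ratio limit reduces the normal-space average to the
    circle of directions perpendicular to the axis.
    """
    _check_reference(C0)
    P = _gamma_average(C0, *_circle_nodes(np.asarray(axis, float), n))
    if check:
        P2 = _gamma_average(C0, *_circle_nodes(np.asarray(axis, float), 2 * n))
        _assert_converged(P, P2, "cylinder")
        P = P2
    return 0.5 * (P + P.T)


def _assert_converged(P: np.ndarray, P2: np.ndarray, label: str) -> None:
    ref = np.linalg.norm(P2)
    err = np.linalg.norm(P - P2) / ref if ref > 0 else 0.0
    if err > CONV_TOL:
        raise RuntimeError(
            f"Hill-tensor quadrature for the {label} did not converge: "
            f"order doubling changed P by {err:.2e} relative (tol {CONV_TOL})"
        )


def hill_numeric(C0: np.ndarray, shape: InclusionShape, check: bool = True) -> np.ndarray:
    """Hill tensor for the given inclusion shape embedded in C0."""
    if shape.kind == "sphere":
        return hill_sphere(C0, check=check)
    o = shape.orientation
    axis = rotation_matrix(o) @ np.array([0.0, 0.0, 1.0])
    return hill_cylinder(C0, axis=axis, check=check)


def hill_cylinder_rotated(C0: np.ndarray, o: Orientation, check: bool = True) -> np.ndarray:
    """Hill tensor of an infinite cylinder tilted by (theta, phi) in C0.

    Evaluated directly in the global frame; for isotropic C0 this equals
    rotating the axis-aligned cylinder tensor (checked in the test suite).
    """
    return hill_numeric(C0, InclusionShape("cylinder", o), check=check)


def eshelby_sphere_iso(k0: float, mu0: float) -> np.ndarray:
    """Closed-form Eshelby tensor S = P : C0 of a sphere in an isotropic
    medium: independent oracle for the numeric route (not used by it)."""
    from .kelvin import unity_projectors

    _, I_vol, I_dev = unity_projectors()
    alpha = 3.0 * k0 / (3.0 * k0 + 4.0 * mu0)
    beta = 6.0 * (k0 + 2.0 * mu0) / (5.0 * (3.0 * k0 + 4.0 * mu0))
    return alpha * I_vol + beta * I_dev
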