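"""Fourth-order tensor algebra in 6x6 Kelvin-Mandel matrix representation.

Symmetric fourth-order tensors (stiffnesses, compliances, Hill tensors,
strain concentration tensors) are represented as 6x6 matrices in the
orthonormal Kelvin-Mandel basis, with component order

    (11, 22, 33, 23, 13, 12)

and a factor of sqrt(2) on the mixed basis tensors.  In this convention the
6x6 representation of a tensor contraction is the plain matrix product, the
representation of the inverse tensor is the matrix inverse, and frame
rotations act by orthogonal congruence -- which is why the whole
homogenization chain can be written in terms of ordinary linear algebra.

Two frames appear throughout the package: the *local* microfibril frame
(r, t, l) with l the fibril axis in slot 3, and the *global* fiber frame
(R, T, L) with L the fiber axis in slot 3.  Functions here are
frame-agnostic; callers track which frame a matrix lives in.

All stiffness entries are in GPa unless noted otherwise.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = [
    "Orientation",
    "unity_projectors",
    "iso_stiffness",
    "iso_moduli",
    "nanofibril_stiffness",
    "rotation_matrix",
    "km_rotation",
    "rotate_stiffness",
    "axial_modulus",
    "km_matrix_from_tensor",
    "tensor_from_km_matrix",
]

# Kelvin-Mandel component order: pairs of (0-based) tensor indices.
KM_PAIRS = ((0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1))
_SQRT2 = np.sqrt(2.0)
# weight of each Kelvin-Mandel slot (1 for direct, sqrt(2) for mixed)
KM_WEIGHTS = np.array([1.0, 1.0, 1.0, _SQRT2, _SQRT2, _SQRT2])


class Orientation(NamedTuple):
    """Inclusion axis orientation: tilt ``theta`` of the local fibril axis l
    away from the global fiber axis L, and azimuth ``phi`` about L.

    theta is in degrees in [0, 90]; phi in radians in [0, 2*pi).
    """

    theta: float
    phi: float = 0.0

    def validate(self) -> "Orientation":
        if not 0.0 <= self.theta <= 90.0:
            raise ValueError(f"microfibril angle must be in [0, 90] deg, got {self.theta}")
        if not 0.0 <= self.phi < 2.0 * np.pi:
            raise ValueError(f"azimuth must be in [0, 2*pi), got {self.phi}")
        return self


def _km_basis() -> np.ndarray:
    """The six orthonormal symmetric basis tensors B_I, shape (6, 3, 3)."""
    basis = np.zeros((6, 3, 3))
    for idx, (i, j) in enumerate(KM_PAIRS):
        if i == j:
            basis[idx, i, j] = 1.0
        else:
            basis[idx, i, j] = basis[idx, j, i] = 1.0 / _SQRT2
    return basis


_BASIS = _km_basis()


def km_matrix_from_tensor(T: np.ndarray) -> np.ndarray:
    """6x6 Kelvin-Mandel matrix of a (minor-symmetric) 3x3x3x3 tensor."""
    M = np.empty((6, 6))
    for a, (i, j) in enumerate(KM_PAIRS):
        for b, (k, l) in enumerate(KM_PAIRS):
            M[a, b] = KM_WEIGHTS[a] * KM_WEIGHTS[b] * T[i, j, k, l]
    return M


def tensor_from_km_matrix(M: np.ndarray) -> np.ndarray:
    """Inverse of :func:`km_matrix_from_tensor` (with minor symmetries)."""
    T = np.zeros((3, 3, 3, 3))
    for a, (i, j) in enumerate(KM_PAIRS):
        for b, (k, l) in enumerate(KM_PAIRS):
            v = M[a, b] / (KM_WEIGHTS[a] * KM_WEIGHTS[b])
            T[i, j, k, l] = T[j, i, k, l] = T[i, j, l, k] = T[j, i, l, k] = v
    return T


def unity_projectors() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Identity and its volumetric/deviatoric projectors, as 6x6 matrices.

    Returns (I, I_vol, I_dev) with I = I_vol + I_dev, I_vol = (1/3) J x J
    (J the second-order identity), both idempotent and mutually orthogonal.
    """
    I = np.eye(6)
    J = np.zeros(6)
    J[:3] = 1.0
    I_vol = np.outer(J, J) / 3.0
    return I, I_vol, I - I_vol


def iso_stiffness(k: float, mu: float) -> np.ndarray:
    """Isotropic stiffness 3k*I_vol + 2mu*I_dev from bulk and shear moduli [GPa].

    Raises ValueError for negative moduli.  Note the Kelvin-Mandel shear
    diagonal equals 2*mu (twice the tensor component C_2323 = mu).
    """
    if k < 0 or mu < 0:
        raise ValueError(f"bulk and shear moduli must be non-negative, got k={k}, mu={mu}")
    _, I_vol, I_dev = unity_projectors()
    return 3.0 * k * I_vol + 2.0 * mu * I_dev


def iso_moduli(C: np.ndarray) -> tuple[float, float]:
    """Extract (k, mu) of an isotropic stiffness by projector contraction."""
    k = C[:3, :3].sum() / 9.0
    mu = (np.trace(C) - 3.0 * k) / 10.0
    return k, mu


def nanofibril_stiffness() -> np.ndarray:
    """Transversely isotropic stiffness of the crystalline cellulose
    nanofibril in its local (r, t, l) frame [GPa].

    Molecular-simulation values for crystalline I-beta cellulose: axial
    (chain-direction) modulus 167.8 GPa, transverse modulus 34.86 GPa,
    Kelvin-Mandel shear diagonal 11.61 (= 2 x 5.805 GPa shear modulus).
    Off-diagonal (Poisson) couplings are zero in this dataset.
    """
    return np.diag([34.86, 34.86, 167.8, 11.61, 11.61, 34.86])


def rotation_matrix(o: Orientation) -> np.ndarray:
    """3x3 rotation mapping local (r, t, l) axes into the global frame.

    The local fibril axis e_l is tilted by theta toward the global fiber
    axis e_L (right-handed rotation about e_T), then rotated by the azimuth
    phi about e_L; the fibril axis ends up at
    (sin(theta) cos(phi), sin(theta) sin(phi), cos(theta)).
    """
    th = np.deg2rad(o.theta)
    ct, st = np.cos(th), np.sin(th)
    cp, sp = np.cos(o.phi), np.sin(o.phi)
    Ry = np.array([[ct, 0.0, st], [0.0, 1.0, 0.0], [-st, 0.0, ct]])
    Rz = np.array([[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]])
    return Rz @ Ry


def km_rotation(R: np.ndarray) -> np.ndarray:
    """6x6 Kelvin-Mandel representation Q of a 3x3 rotation R.

    Q is orthogonal and acts on stiffness matrices by congruence:
    C_global = Q @ C_local @ Q.T.
    """
    rotated = np.einsum("ia,nab,jb->nij", R, _BASIS, R)
    return np.einsum("mij,nij->mn", _BASIS, rotated)


def rotate_stiffness(C: np.ndarray, o: Orientation) -> np.ndarray:
    """Express a local-frame stiffness in the global frame for orientation o."""
    Q = km_rotation(rotation_matrix(o))
    return Q @ C @ Q.T


def axial_modulus(C: np.ndarray) -> float:
    """Young's modulus along axis 3 (l or L): 1 / compliance_(33) [GPa].

    Raises numpy.linalg.LinAlgError for singular C (void-dominated input).
    """
    D = np.linalg.inv(C)
    return 1.0 / D[2, 2]


def symmetrize(C: np.ndarray) -> np.ndarray:
    """Major-symmetrized copy (C + C.T)/2."""
    return 0.5 * (C + C.T)


def asymmetry(C: np.ndarray) -> float:
    """Relative Frobenius magnitude of the skew part, ||C - C.T|| / ||C||."""
    n = np.linalg.norm(C)
    return 0.0 if n == 0 else np.linalg.norm(C - C.T) / n
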