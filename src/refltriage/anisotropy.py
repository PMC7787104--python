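"""Maximum-likelihood anisotropic scaling constrained to the Laue class.

The correction multiplies the expected intensity by
A(h) = exp(-1/2 s^T B s) with s = M h; B is symmetric, traceless (the
isotropic part lives in the binned mean curve) and invariant under every
Laue rotation expressed in the orthogonal frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from . import intensity_stats as istats
from .symmetry import PointGroup

__all__ = [
    "AnisoTensor",
    "constrained_basis",
    "wilson_loglik",
    "refine_anisotropy",
    "apply_correction",
]

# orthonormal basis of 3x3 symmetric matrices (Frobenius inner product)
_SYM6 = [
    np.diag([1.0, 0, 0]),
    np.diag([0, 1.0, 0]),
    np.diag([0, 0, 1.0]),
    np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]]) / np.sqrt(2),
    np.array([[0, 0, 1], [0, 0, 0], [1, 0, 0]]) / np.sqrt(2),
    np.array([[0, 0, 0], [0, 0, 1], [0, 1, 0]]) / np.sqrt(2),
]


@dataclass
class AnisoTensor:
    B: np.ndarray                     # symmetric traceless, A^2, orthogonal frame
    basis: list[np.ndarray]
    coefficients: np.ndarray

    def norm(self) -> float:
        return float(np.linalg.norm(self.B))

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.B)

    def __neg__(self) -> "AnisoTensor":
        return AnisoTensor(B=-self.B, basis=self.basis, coefficients=-self.coefficients)


def _s_rotations(pg: PointGroup, cell) -> list[np.ndarray]:
    # s(R h) = M R h = (M R M^-1) s(h)
    M = cell.M
    Minv = np.linalg.inv(M)
    return [M @ np.asarray(R, float) @ Minv for R in pg.rotations]


def constrained_basis(pg: PointGroup, cell) -> list[np.ndarray]:
    """Orthonormal basis of traceless symmetric tensors invariant under
    every rotation of the Laue class (in the orthogonal frame)."""
    rots = _s_rotations(pg, cell)
    # constraints: R B R^T - B = 0 for each R, plus tr B = 0
    rows = []
    for R in rots:
        for E in _SYM6:
            T = R @ E @ R.T - E
            rows.append([np.tensordot(T, F) for F in _SYM6])
    rows.append([np.trace(F) for F in _SYM6])
    Amat = np.array(rows)
    _, s, vt = np.linalg.svd(Amat)
    rank = int(np.sum(s > 1e-9))
    null = vt[rank:]
    basis = []
    for coeffs in null:
        T = sum(c * E for c, E in zip(coeffs, _SYM6))
        basis.append(T / np.linalg.norm(T))
    return basis


def _tensor_from_coeffs(coeffs: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    if len(basis) == 0:
        return np.zeros((3, 3))
    return np.tensordot(coeffs, np.stack(basis), axes=1)


def aniso_factors(dataset, B: np.ndarray) -> np.ndarray:
    """A(h) = exp(-1/2 s^T B s) per reflection."""
    s = dataset.cell.s_vectors(dataset.hkl)
    q = np.einsum("ni,ij,nj->n", s, B, s)
    return np.exp(-0.5 * q)


def wilson_loglik(dataset, state: istats.NormalizationState, B) -> float:
    """Wilson log-likelihood of the intensities given expected intensities
    mu = eps_sym * eps_tncs * A(h) * Sigma(s): exponential density for
    acentrics, chi-squared(1)-type density for centrics."""
    Bmat = B.B if isinstance(B, AnisoTensor) else np.asarray(B, float)
    A = aniso_factors(dataset, Bmat)
    mu = state.eps_sym * state.eps_tncs * A * state.Sigma[state.binning.assignments]
    centric = state.centric
    I = dataset.I
    mask = state.mask & np.isfinite(I)
    ll = np.zeros(dataset.n)
    Ipos = np.maximum(I, 1e-12)
    acen = ~centric
    ll[acen] = -np.log(mu[acen]) - Ipos[acen] / mu[acen]
    ll[centric] = (
        -0.5 * np.log(2 * np.pi * mu[centric] * Ipos[centric])
        - 0.5 * Ipos[centric] / mu[centric]
    )
    return float(np.sum(ll[mask]))


def refine_anisotropy(
    dataset,
    binning: istats.Binning | None = None,
    eps_tncs: np.ndarray | None = None,
    low_res_s: float = 0.1,
    min_low_res: int = 100,
    grad_tol: float = 1e-4,
    max_iter: int = 100,
) -> dict:
    """BFGS maximization of the Wilson log-likelihood over the symmetry-
    constrained tensor coefficients, alternating with re-estimation of the
    binned mean curve.

    A harmonic restraint toward B = 0 is switched on when the dataset is
    thin at low resolution (fewer than ``min_low_res`` reflections below
    ``low_res_s``), where the tensor is poorly determined.
    """
    if dataset.n < 500:
        raise ValueError("refine_anisotropy needs at least 500 reflections")
    if binning is None:
        binning = istats.make_binning(dataset.s_squared())
    pg = dataset.point_group
    basis = constrained_basis(pg, dataset.cell)
    eps_sym = dataset.epsilon()

    s2 = dataset.s_squared()
    n_low = int(np.sum(s2 < low_res_s**2))
    deficit = max(0, min_low_res - n_low)
    restraint_w = deficit * 0.01  # per A^4

    coeffs = np.zeros(len(basis))
    state = istats.estimate_sigma_curve(dataset, binning, eps_sym=eps_sym, eps_tncs=eps_tncs)
    converged = True
    if len(basis) > 0:
        for _outer in range(4):
            def neg_ll(c):
                Bmat = _tensor_from_coeffs(c, basis)
                return -wilson_loglik(dataset, state, Bmat) + restraint_w * float(c @ c)

            res = optimize.minimize(
                neg_ll,
                coeffs,
                method="L-BFGS-B",
                options={"maxiter": max_iter, "gtol": grad_tol},
            )
            coeffs = res.x
            A = aniso_factors(dataset, _tensor_from_coeffs(coeffs, basis))
            new_state = istats.estimate_sigma_curve(
                dataset, binning, eps_sym=eps_sym, eps_tncs=eps_tncs, aniso=A
            )
            if np.max(np.abs(new_state.Sigma - state.Sigma) / new_state.Sigma) < 1e-6:
                state = new_state
                break
            state = new_state
        converged = bool(res.success) or np.linalg.norm(res.jac) < 10 * grad_tol * max(
            1.0, abs(res.fun)
        )
    tensor = AnisoTensor(
        B=_tensor_from_coeffs(coeffs, basis), basis=basis, coefficients=coeffs
    )
    return {"B": tensor, "state": state, "converged": converged}


def apply_correction(dataset, B):
    """Divide I and sigI by A(h); append 'aniso' to provenance."""
    Bmat = B.B if isinstance(B, AnisoTensor) else np.asarray(B, float)
    A = aniso_factors(dataset, Bmat)
    return dataset.copy_with(
        I=dataset.I / A,
        sigI=dataset.sigI / A,
        provenance=list(dataset.provenance) + ["aniso"],
    )
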