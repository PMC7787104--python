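"""Synthetic-pathology reflection data with known ground truth.

Two generators are provided. ``simulate_dataset`` builds intensities by
direct summation over random point scatterers (no form factors, no
solvent — sufficient for intensity statistics), with optional TNCS
copies, anisotropic attenuation, twin mixing and measurement noise.
``simulate_intensity_draws`` samples Wilson intensities directly from
their limiting distributions for large-n statistical calibration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import symmetry
from .reflection_data import ReflectionDataset, UnitCell

__all__ = [
    "SimulationTruth",
    "simulate_dataset",
    "simulate_intensity_draws",
    "scenario_4n3e",
    "unique_reflections",
]


@dataclass
class SimulationTruth:
    seed: int = 0
    cell: tuple = (40.0, 40.0, 60.0, 90.0, 90.0, 90.0)
    laue: str = "1"
    n_atoms: int = 40
    B_true: tuple = ((0.0,) * 3,) * 3
    tncs_m: int = 1
    tncs_t: tuple = (0.0, 0.0, 0.0)
    tncs_f0: float = 1.0
    tncs_beta: float = 0.0
    tncs_sigma_rmsd: float = 0.0
    tncs_rot: tuple = (0.0, 0.0, 0.0)   # axis-angle degrees, order 2 only
    twin_alpha: float = 0.0
    noise_frac: float = 0.02
    d_min: float = 2.5

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def unique_reflections(cell: UnitCell, pg: symmetry.PointGroup, d_min: float) -> np.ndarray:
    """All canonical-ASU Miller indices with d >= d_min."""
    lims = [int(np.floor(L / d_min)) + 1 for L in (cell.a, cell.b, cell.c)]
    h = np.arange(-lims[0], lims[0] + 1)
    k = np.arange(-lims[1], lims[1] + 1)
    l = np.arange(-lims[2], lims[2] + 1)
    grid = np.stack(np.meshgrid(h, k, l, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid[np.any(grid != 0, axis=1)]
    s = cell.s_vectors(grid)
    s2 = np.einsum("ni,ni->n", s, s)
    grid = grid[s2 <= 1.0 / d_min**2]
    canon = symmetry.canonicalize_indices(grid, pg)
    return np.unique(canon, axis=0)


def _axis_angle_matrix(rot_deg) -> np.ndarray:
    v = np.asarray(rot_deg, float)
    theta = np.linalg.norm(v)
    if theta < 1e-12:
        return np.eye(3)
    k = v / theta
    th = np.radians(theta)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def _build_atoms(truth: SimulationTruth, cell: UnitCell, rng) -> np.ndarray:
    """Fractional coordinates of all scatterers: the motif, its TNCS
    copies, and the point-group images of everything."""
    motif = rng.random((truth.n_atoms, 3))
    A = cell.orthogonalization()
    Ainv = np.linalg.inv(A)
    copies = [motif]
    t = np.asarray(truth.tncs_t, float)
    rot = _axis_angle_matrix(truth.tncs_rot) if truth.tncs_m == 2 else np.eye(3)
    for k in range(1, truth.tncs_m):
        xk = motif.copy()
        if truth.tncs_m == 2:
            # rotate about the motif centroid in Cartesian space
            cart = (xk - xk.mean(0)) @ A.T
            xk = (cart @ rot.T) @ Ainv.T + xk.mean(0)
        # per-copy coordinate scatter with r.m.s. sigma_rmsd (Cartesian)
        if truth.tncs_sigma_rmsd > 0:
            noise = rng.normal(scale=truth.tncs_sigma_rmsd / np.sqrt(3), size=xk.shape)
            xk = xk + noise @ Ainv.T
        # fraction (1 - f0) of the copy is unrelated to the motif
        unrelated = rng.random(truth.n_atoms) > truth.tncs_f0
        xk[unrelated] = rng.random((int(unrelated.sum()), 3))
        copies.append(xk + k * t)
    atoms = np.concatenate(copies)
    # point-group images: x -> R^T x replicates the Laue symmetry in |F|
    pg = symmetry.point_group(truth.laue)
    images = [atoms @ np.asarray(R, float) for R in pg.rotations]
    return np.concatenate(images)


def _structure_factors(hkl: np.ndarray, atoms: np.ndarray, chunk: int = 256) -> np.ndarray:
    F = np.zeros(len(hkl), dtype=complex)
    for lo in range(0, len(atoms), chunk):
        phase = 2j * np.pi * (hkl @ atoms[lo : lo + chunk].T)
        F += np.exp(phase).sum(axis=1)
    return F


def _twin_permutation(hkl: np.ndarray, s2: np.ndarray,
                      phase: np.ndarray | None = None) -> np.ndarray:
    """Disjoint pairing of reflections adjacent in resolution: a stand-in
    twin law mixing intensities of near-identical d-spacing.

    When a TNCS phase class is given (h.t mod 1), pairing stays within a
    class — real merohedral twin operators preserve the TNCS modulation,
    so the simulated law must too.
    """
    n = len(s2)
    perm = np.arange(n)
    if phase is None:
        classes = np.zeros(n, dtype=int)
    else:
        classes = np.round(np.mod(phase, 1.0) * 1000).astype(int)
    for cls in np.unique(classes):
        members = np.flatnonzero(classes == cls)
        order = members[np.argsort(s2[members], kind="stable")]
        for i in range(0, len(order) - 1, 2):
            perm[order[i]] = order[i + 1]
            perm[order[i + 1]] = order[i]
    return perm


def simulate_dataset(truth: SimulationTruth) -> dict:
    """Deterministic synthetic dataset for the given ground truth."""
    if not 0.0 <= truth.twin_alpha <= 0.5:
        raise ValueError("twin_alpha must lie in [0, 0.5]")
    if not 0.0 <= truth.tncs_f0 <= 1.0:
        raise ValueError("tncs_f0 must lie in [0, 1]")
    if truth.tncs_m < 1:
        raise ValueError("tncs_m must be >= 1")
    rng = np.random.default_rng(truth.seed)
    cell = UnitCell(*truth.cell)
    pg = symmetry.point_group(truth.laue)
    hkl = unique_reflections(cell, pg, truth.d_min)

    atoms = _build_atoms(truth, cell, rng)
    F = _structure_factors(hkl, atoms)
    I = np.abs(F) ** 2

    svec = cell.s_vectors(hkl)
    s2 = np.einsum("ni,ni->n", svec, svec)
    B = np.asarray(truth.B_true, float)
    if np.linalg.norm(B) > 0:
        I = I * np.exp(-0.5 * np.einsum("ni,ij,nj->n", svec, B, svec))

    if truth.twin_alpha > 0:
        phase = hkl @ np.asarray(truth.tncs_t, float) if truth.tncs_m > 1 else None
        perm = _twin_permutation(hkl, s2, phase)
        I = (1.0 - truth.twin_alpha) * I + truth.twin_alpha * I[perm]

    scale = float(np.mean(I))
    sigI = truth.noise_frac * (np.abs(I) + 0.05 * scale)
    I_obs = I + rng.normal(size=len(I)) * sigI

    dataset = ReflectionDataset(
        hkl=hkl,
        I=I_obs,
        sigI=sigI,
        cell=cell,
        laue_symbol=truth.laue,
        provenance=["simulated"],
    )
    return {"dataset": dataset, "truth": truth}


def simulate_intensity_draws(
    n_acentric: int = 100_000,
    n_centric: int = 0,
    alpha: float = 0.0,
    seed: int = 0,
    scale: float = 100.0,
    noise_frac: float = 0.0,
) -> ReflectionDataset:
    """Wilson-limit intensity draws on a synthetic monoclinic index set.

    Acentric intensities are unit-mean exponential, centric ones are
    squared standard normals; twin fraction ``alpha`` mixes each draw with
    an independent one. Intensities carry the symmetry epsilon factor so
    downstream normalization is exact.
    """
    if not 0.0 <= alpha <= 0.5:
        raise ValueError("alpha must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    hkl = _monoclinic_indices(n_acentric, n_centric)
    cell = UnitCell(150.0, 150.0, 150.0)
    ds_tmp = ReflectionDataset(
        hkl=hkl, I=np.ones(len(hkl)), sigI=np.zeros(len(hkl)),
        cell=cell, laue_symbol="2", _skip_canonicalization=True,
    )
    centric = ds_tmp.centric()
    eps = ds_tmp.epsilon()

    def draw(n_needed, centric_class):
        if centric_class:
            x = rng.normal(size=n_needed) ** 2
            y = rng.normal(size=n_needed) ** 2
        else:
            x = rng.exponential(size=n_needed)
            y = rng.exponential(size=n_needed)
        return (1.0 - alpha) * x + alpha * y

    z = np.empty(len(hkl))
    z[~centric] = draw(int((~centric).sum()), False)
    z[centric] = draw(int(centric.sum()), True)
    I = scale * eps * z
    sigI = noise_frac * (np.abs(I) + 0.05 * scale)
    if noise_frac > 0:
        I = I + rng.normal(size=len(I)) * sigI
    return ReflectionDataset(
        hkl=hkl, I=I, sigI=sigI, cell=cell, laue_symbol="2",
        provenance=["simulated:draws"], _skip_canonicalization=True,
    )


def _monoclinic_indices(n_acentric: int, n_centric: int) -> np.ndarray:
    """Canonical-ASU indices for Laue class 2/m (b unique): acentric rows
    have k >= 1, centric rows k = 0; (h, l) lexicographically positive."""
    out = []
    # acentric block: k >= 1
    need = n_acentric
    k = 1
    while need > 0:
        side = int(np.ceil(np.sqrt(need))) + 1
        for h in range(0, side):
            lmin = 0 if h == 0 else -side
            for l in range(lmin, side):
                out.append((h, k, l))
                need -= 1
                if need == 0:
                    break
            if need == 0:
                break
        k += 1
    cen = []
    need = n_centric
    h = 1
    while need > 0:
        for l in range(-h, h + 1):
            cen.append((h, 0, l))
            need -= 1
            if need == 0:
                break
        h += 1
    return np.array(out + cen, dtype=int)


def scenario_4n3e(seed: int = 0) -> dict:
    """Preset emulating a tetragonally merged crystal with sevenfold TNCS
    along c, partial tetartohedral-style twinning and mild anisotropy."""
    truth = SimulationTruth(
        seed=seed,
        cell=(45.0, 45.0, 77.0, 90.0, 90.0, 90.0),
        laue="422",
        n_atoms=30,
        B_true=((2.0, 0, 0), (0, 2.0, 0), (0, 0, -4.0)),
        tncs_m=7,
        tncs_t=(0.0, 0.0, 1.0 / 7.0),
        tncs_f0=0.95,
        tncs_beta=0.0,
        tncs_sigma_rmsd=0.3,
        twin_alpha=0.25,
        noise_frac=0.02,
        d_min=2.5,
    )
    return simulate_dataset(truth)
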