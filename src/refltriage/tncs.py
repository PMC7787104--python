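"""Translational-NCS detection and expected-intensity-factor refinement.

Detection inspects the Patterson map of the normalized intensities for
off-origin peaks; a commensurate family of colinear peaks at multiples of
a fractional vector indicates TNCS of the corresponding order. The
expected intensity factor for order m with pairwise correlation rho is

    eps_raw(h) = m + 2 rho(h) sum_{d=1}^{m-1} (m - d) cos(2 pi d h.t)

with rho(h) combining a resolution-dependent scattering fraction, a
Debye-type r.m.s.-displacement damping, and a sphere-interference term
for the rotational mismatch of order-2 pairs. Factors are normalized to
unit mean per resolution shell before use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import intensity_stats as istats

__all__ = [
    "PattersonMap",
    "TncsPeak",
    "TncsModel",
    "patterson_map",
    "find_tncs_vectors",
    "infer_tncs_orders",
    "interference_G",
    "tncs_epsilon",
    "refine_tncs",
]


@dataclass
class PattersonMap:
    values: np.ndarray               # real map on a fractional grid
    origin_value: float              # full z-Patterson origin, normalization
    cell: object
    laue_symbol: str
    d_max: float
    d_min: float
    coefficients: str = "z - 1"

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class TncsPeak:
    u: tuple[float, float, float]    # fractional, in [0, 1)
    height_rel: float                # fraction of origin height


@dataclass
class TncsModel:
    m: int
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))
    r_eff: float = 20.0
    sigma_rmsd: float = 0.0
    f0: float = 0.0
    beta: float = 0.0
    rot: np.ndarray = field(default_factory=lambda: np.zeros(3))  # axis-angle, deg
    warning: str | None = None
    loglik: float | None = None

    def is_trivial(self) -> bool:
        return self.m <= 1


def _grid_size(length: float, step: float) -> int:
    return max(4, int(np.ceil(length / step)))


def patterson_map(
    dataset,
    d_max: float = 10.0,
    d_min: float = 4.0,
    grid_step: float | None = None,
    state: istats.NormalizationState | None = None,
) -> PattersonMap:
    """Origin-removed Patterson synthesis with coefficients (z - 1) from
    symmetry/anisotropy-normalized intensities in a resolution window."""
    if grid_step is None:
        grid_step = d_min / 3.0
    d = dataset.d_spacings()
    window = (d <= d_max) & (d >= d_min)
    if int(window.sum()) < 200:
        raise ValueError(
            f"only {int(window.sum())} reflections in the {d_max}-{d_min} A window; "
            "widen the resolution limits"
        )
    if state is None:
        binning = istats.make_binning(dataset.s_squared())
        state = istats.estimate_sigma_curve(dataset, binning, eps_sym=dataset.epsilon())
    z = state.z

    rots = dataset.point_group.rotation_array()
    hkl_w = dataset.hkl[window]
    z_w = z[window]

    shape = tuple(
        _grid_size(L, grid_step) for L in (dataset.cell.a, dataset.cell.b, dataset.cell.c)
    )
    F = np.zeros(shape, dtype=complex)
    filled = set()
    coeffs = z_w - 1.0
    for R in rots:
        hr = hkl_w @ R.T
        for sign in (1, -1):
            hs = sign * hr
            for (h, k, l), c in zip(map(tuple, hs.tolist()), coeffs):
                if (h, k, l) in filled:
                    continue
                filled.add((h, k, l))
                F[h % shape[0], k % shape[1], l % shape[2]] += c
    # per-reflection scale: map(0) = <z - 1>; the full z-Patterson origin
    # (the normalization reference for relative peak heights) is then <z>
    values = np.real(np.fft.ifftn(F)) * F.size / len(filled)
    origin_value = float(np.mean(z_w))
    return PattersonMap(
        values=values,
        origin_value=origin_value,
        cell=dataset.cell,
        laue_symbol=dataset.laue_symbol,
        d_max=d_max,
        d_min=d_min,
    )


def _frac_to_cart(u: np.ndarray, cell) -> np.ndarray:
    return cell.orthogonalization() @ u


def _min_image_dist(u: np.ndarray, cell) -> float:
    """Shortest Cartesian distance of fractional vector u to any lattice
    point."""
    best = np.inf
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                v = u - np.array([dx, dy, dz], float)
                best = min(best, float(np.linalg.norm(_frac_to_cart(v, cell))))
    return best


def find_tncs_vectors(
    pmap: PattersonMap,
    threshold_rel: float = 0.20,
    origin_radius: float = 5.0,
) -> list[TncsPeak]:
    """Local maxima above a fraction of the origin height, outside the
    origin exclusion sphere, deduplicated under inversion symmetry."""
    vals = pmap.values
    shape = vals.shape
    thresh = threshold_rel * pmap.origin_value
    # 26-neighbour local maxima via rolls
    is_max = np.ones(shape, dtype=bool)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                is_max &= vals >= np.roll(vals, (dx, dy, dz), axis=(0, 1, 2))
    cand = np.argwhere(is_max & (vals > thresh))
    peaks = []
    seen = set()
    for ijk in cand:
        u = ijk / np.array(shape, float)
        if _min_image_dist(u, pmap.cell) < origin_radius:
            continue
        # deduplicate u ~ -u (mod 1)
        key = tuple(np.round(u * np.array(shape)).astype(int) % np.array(shape))
        ikey = tuple((-np.array(key)) % np.array(shape))
        if key in seen or ikey in seen:
            continue
        seen.add(key)
        peaks.append(
            TncsPeak(
                u=tuple(float(x) for x in u),
                height_rel=float(vals[tuple(ijk)] / pmap.origin_value),
            )
        )
    peaks.sort(key=lambda p: -p.height_rel)
    return peaks


def _mod_half(x: np.ndarray) -> np.ndarray:
    """Map to the representative in [-1/2, 1/2)."""
    return (x + 0.5) % 1.0 - 0.5


def infer_tncs_orders(
    peaks: list[TncsPeak],
    m_max: int = 8,
    grid_tol: float = 0.05,
) -> list[dict]:
    """Rank candidate (order, translation) hypotheses from Patterson peaks.

    The no-TNCS hypothesis (m=1) is always present. A family of colinear
    peaks near k*t for k=1..m-1 with m*t commensurate proposes order m;
    a lone peak proposes order 2.
    """
    hypotheses = []
    for peak in peaks:
        u = np.array(peak.u)
        for m in range(2, m_max + 1):
            t = u.copy()
            # interpret the peak as the k=1 member of the family of order m
            if np.max(np.abs(_mod_half(m * t))) > m * grid_tol:
                continue
            score = 0.0
            matched = 0
            for k in range(1, m):
                target = _mod_half(k * t)
                best = 0.0
                for q in peaks:
                    du = _mod_half(np.array(q.u) - target)
                    du2 = _mod_half(np.array(q.u) + target)  # inversion mate
                    if min(np.max(np.abs(du)), np.max(np.abs(du2))) < grid_tol:
                        best = max(best, q.height_rel)
                if best > 0:
                    matched += 1
                    score += best
            if matched == m - 1:
                # report the family generator closest to the origin, e.g.
                # t = 1/m when the found peak was a higher multiple
                gens = [
                    _mod_half(k * t)
                    for k in range(1, m)
                    if np.gcd(k, m) == 1
                ]
                t_best = min(gens, key=lambda g: float(np.linalg.norm(g)))
                for comp in t_best:  # sign convention: leading component > 0
                    if abs(comp) > 1e-9:
                        if comp < 0:
                            t_best = _mod_half(-t_best)
                        break
                t_best = np.where(np.abs(t_best + 0.5) < 1e-9, 0.5, t_best)
                hypotheses.append(
                    {"m": m, "t": tuple(float(x) for x in t_best), "score": score}
                )
    # dedupe identical (m, t-family); keep best score per order
    best_by_m: dict[int, dict] = {}
    for hyp in hypotheses:
        cur = best_by_m.get(hyp["m"])
        if cur is None or hyp["score"] > cur["score"]:
            best_by_m[hyp["m"]] = hyp
    ranked = sorted(best_by_m.values(), key=lambda h: -h["score"])
    ranked = _prune_colinear(ranked, tol=grid_tol)
    ranked.append({"m": 1, "t": (0.0, 0.0, 0.0), "score": 0.0})
    return ranked


def _prune_colinear(ranked: list[dict], tol: float) -> list[dict]:
    """Drop hypotheses whose translation is an integer multiple (mod 1) of
    a higher-scoring hypothesis's — they explain the same peak family."""
    kept: list[dict] = []
    for hyp in ranked:
        t = np.array(hyp["t"])
        dominated = False
        for other in kept:
            to = np.array(other["t"])
            for k in range(1, other["m"] + 1):
                if np.max(np.abs(_mod_half(t - k * to))) < tol or np.max(
                    np.abs(_mod_half(t + k * to))
                ) < tol:
                    dominated = True
                    break
            if dominated:
                break
        if not dominated:
            kept.append(hyp)
    return kept


def interference_G(x) -> np.ndarray | float:
    """Sphere interference function G(x) = 3 (sin x - x cos x) / x^3."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x < 0):
        raise ValueError("interference_G requires x >= 0")
    out = np.empty_like(x)
    small = x < 0.1  # series below the cancellation-prone region
    xs = x[small]
    out[small] = 1.0 - xs**2 / 10.0 + xs**4 / 280.0 - xs**6 / 15120.0
    xl = x[~small]
    out[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    return float(out[0]) if scalar else out


def _axis_angle_matrix(rot_deg: np.ndarray) -> np.ndarray:
    """Rotation matrix from an axis-angle vector in degrees."""
    v = np.asarray(rot_deg, float)
    theta = np.linalg.norm(v)
    if theta < 1e-12:
        return np.eye(3)
    k = v / theta
    th = np.radians(theta)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def _raw_epsilon(hkl, s2, svec, model: TncsModel, cell) -> np.ndarray:
    m = model.m
    if m <= 1:
        return np.ones(len(hkl))
    frac = model.f0 * np.exp(-model.beta * s2)
    damp = np.exp(-(2.0 * np.pi**2 / 3.0) * model.sigma_rmsd**2 * s2)
    if m == 2 and np.linalg.norm(model.rot) > 1e-9:
        R = _axis_angle_matrix(model.rot)
        ds = svec @ (R - np.eye(3)).T
        g = interference_G(2.0 * np.pi * model.r_eff * np.linalg.norm(ds, axis=1))
    else:
        g = 1.0
    rho = np.clip(frac * damp * g, 0.0, 1.0)
    phase = hkl @ np.asarray(model.t, float)
    acc = np.zeros(len(hkl))
    for d in range(1, m):
        acc += (m - d) * np.cos(2.0 * np.pi * d * phase)
    eps = m + 2.0 * rho * acc
    return np.maximum(eps, 1e-6)


def tncs_epsilon(
    dataset_or_hkl,
    model: TncsModel,
    cell=None,
    binning: istats.Binning | None = None,
    normalized: bool = True,
) -> np.ndarray:
    """TNCS expected-intensity factor per reflection, shell-normalized to
    unit mean unless ``normalized=False`` (raw factor, mean m)."""
    if cell is None:
        ds = dataset_or_hkl
        hkl = ds.hkl
        cell = ds.cell
    else:
        hkl = np.asarray(dataset_or_hkl, int)
    svec = np.asarray(hkl, float) @ cell.M.T
    s2 = np.einsum("ni,ni->n", svec, svec)
    eps = _raw_epsilon(hkl, s2, svec, model, cell)
    if model.m <= 1 or not normalized:
        return eps
    if binning is None:
        binning = istats.make_binning(s2)
    assign = binning.assignments
    means = np.bincount(assign, weights=eps, minlength=binning.nbins) / np.maximum(
        np.bincount(assign, minlength=binning.nbins), 1
    )
    means = np.where(means > 0, means, 1.0)
    return eps / means[assign]


def _tncs_loglik(dataset, model: TncsModel, binning, eps_sym, centric) -> float:
    eps_t = tncs_epsilon(dataset, model, binning=binning)
    state = istats.estimate_sigma_curve(
        dataset, binning, eps_sym=eps_sym, eps_tncs=eps_t, centric=centric
    )
    mu = state.expected_intensity()
    I = np.maximum(dataset.I, 1e-12)
    ll = np.where(
        centric,
        -0.5 * np.log(2 * np.pi * mu * I) - 0.5 * I / mu,
        -np.log(mu) - I / mu,
    )
    return float(np.sum(ll[state.mask]))


def refine_tncs(
    dataset,
    candidate: dict,
    binning: istats.Binning | None = None,
    grid_step_frac: float | None = None,
) -> TncsModel:
    """Refine the TNCS intensity-factor model for one (m, t) hypothesis by
    BFGS maximization of the Wilson log-likelihood.

    For order 2 the rotational mismatch is also refined, started from five
    states: unperturbed, and +/-2 degrees about each of two axes
    orthogonal to the translation.
    """
    m = int(candidate["m"])
    if m <= 1:
        model = TncsModel(m=1)
        model.loglik = None
        return model
    t0 = np.asarray(candidate.get("t", (0, 0, 0)), float)
    if binning is None:
        binning = istats.make_binning(dataset.s_squared())
    eps_sym = dataset.epsilon()
    centric = dataset.centric()
    if grid_step_frac is None:
        grid_step_frac = 1.0 / (3.0 * max(dataset.cell.a, dataset.cell.b, dataset.cell.c) / 4.0)
        grid_step_frac = min(0.05, grid_step_frac)

    ll_null = _tncs_loglik(dataset, TncsModel(m=1), binning, eps_sym, centric)

    bounds = [
        (t0[0] - grid_step_frac, t0[0] + grid_step_frac),
        (t0[1] - grid_step_frac, t0[1] + grid_step_frac),
        (t0[2] - grid_step_frac, t0[2] + grid_step_frac),
        (5.0, 100.0),     # r_eff
        (0.0, 3.0),       # sigma_rmsd
        (0.0, 1.0),       # f0
        (0.0, 200.0),     # beta
    ]

    def build(x, rot):
        return TncsModel(
            m=m,
            t=np.asarray(x[:3]),
            r_eff=x[3],
            sigma_rmsd=x[4],
            f0=x[5],
            beta=x[6],
            rot=rot,
        )

    def starts():
        x0 = np.array([t0[0], t0[1], t0[2], 20.0, 0.5, 0.5, 0.0])
        if m != 2:
            yield x0, np.zeros(3)
            return
        # two axes orthogonal to t (Cartesian)
        tc = dataset.cell.orthogonalization() @ t0
        if np.linalg.norm(tc) < 1e-9:
            tc = np.array([0.0, 0.0, 1.0])
        tc = tc / np.linalg.norm(tc)
        a1 = np.cross(tc, [1.0, 0.0, 0.0])
        if np.linalg.norm(a1) < 1e-6:
            a1 = np.cross(tc, [0.0, 1.0, 0.0])
        a1 /= np.linalg.norm(a1)
        a2 = np.cross(tc, a1)
        delta = 2.0
        yield x0, np.zeros(3)
        yield x0, delta * a1
        yield x0, -delta * a1
        yield x0, delta * a2
        yield x0, -delta * a2

    best = None
    for x0, rot0 in starts():
        rot_holder = {"rot": rot0}

        def neg_ll(x):
            return -_tncs_loglik(
                dataset, build(x, rot_holder["rot"]), binning, eps_sym, centric
            )

        res = optimize.minimize(
            neg_ll, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": 60}
        )
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x, rot_holder["rot"])

    model = build(best[1], best[2])
    model.loglik = -best[0]
    # AIC-style support criterion: the extra parameters must buy more
    # log-likelihood than expected by chance
    n_params = 7 + (3 if m == 2 else 0)
    if model.loglik - ll_null < 2.0 * n_params:
        model.warning = "tncs_not_supported"
    return model
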