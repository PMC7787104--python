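"""Point-group algebra for merged reflection data.

Only the proper-rotation part of each Laue class acts on merged
intensities (Friedel symmetry is implied), so groups are represented as
sets of 3x3 integer matrices acting on Miller index columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PointGroup",
    "SubgroupDescriptor",
    "point_group",
    "laue_class_symbol",
    "epsilon_factor",
    "is_centric",
    "canonical_index",
    "enumerate_proper_subgroups",
    "expand_to_subgroup",
    "score_axial_absences",
]

_I3 = np.eye(3, dtype=int)

# Generators in the Miller-index basis (columns h,k,l). Trigonal and
# hexagonal groups use hexagonal axes.
_GENERATORS: dict[str, list[list[list[int]]]] = {
    "1": [],
    "2": [[[-1, 0, 0], [0, 1, 0], [0, 0, -1]]],  # 2 along b
    "222": [
        [[-1, 0, 0], [0, -1, 0], [0, 0, 1]],
        [[-1, 0, 0], [0, 1, 0], [0, 0, -1]],
    ],
    "4": [[[0, -1, 0], [1, 0, 0], [0, 0, 1]]],
    "422": [
        [[0, -1, 0], [1, 0, 0], [0, 0, 1]],
        [[1, 0, 0], [0, -1, 0], [0, 0, -1]],
    ],
    "3": [[[-1, -1, 0], [1, 0, 0], [0, 0, 1]]],
    "32": [
        [[-1, -1, 0], [1, 0, 0], [0, 0, 1]],
        [[0, 1, 0], [1, 0, 0], [0, 0, -1]],
    ],
    "6": [[[1, 1, 0], [-1, 0, 0], [0, 0, 1]]],
    "622": [
        [[1, 1, 0], [-1, 0, 0], [0, 0, 1]],
        [[0, 1, 0], [1, 0, 0], [0, 0, -1]],
    ],
    "23": [
        [[-1, 0, 0], [0, -1, 0], [0, 0, 1]],
        [[0, 0, 1], [1, 0, 0], [0, 1, 0]],
    ],
    "432": [
        [[0, 0, 1], [1, 0, 0], [0, 1, 0]],
        [[0, -1, 0], [1, 0, 0], [0, 0, 1]],
    ],
}

# Laue-class and common space-group style aliases.
_ALIASES = {
    "-1": "1",
    "2/m": "2",
    "mmm": "222",
    "4/m": "4",
    "4/mmm": "422",
    "-3": "3",
    "-3m": "32",
    "-31m": "32",
    "-3m1": "32",
    "6/m": "6",
    "6/mmm": "622",
    "m-3": "23",
    "m3": "23",
    "m-3m": "432",
    "m3m": "432",
}

_LAUE_OF = {
    "1": "-1",
    "2": "2/m",
    "222": "mmm",
    "4": "4/m",
    "422": "4/mmm",
    "3": "-3",
    "32": "-3m",
    "6": "6/m",
    "622": "6/mmm",
    "23": "m-3",
    "432": "m-3m",
}


def _normalize_symbol(symbol: str) -> str:
    s = symbol.strip().replace(" ", "")
    if s in _GENERATORS:
        return s
    if s in _ALIASES:
        return _ALIASES[s]
    # strip a leading lattice letter (space-group style, e.g. "P422", "C2")
    if s and s[0] in "PABCIFRH":
        body = s[1:]
        # drop screw-axis subscripts: digits following a digit (e.g. 41 -> 4,
        # 21 -> 2) only when the undecorated symbol is known
        candidates = [body]
        stripped = []
        i = 0
        while i < len(body):
            stripped.append(body[i])
            if body[i] in "2346" and i + 1 < len(body) and body[i + 1].isdigit():
                i += 2
            else:
                i += 1
        candidates.append("".join(stripped))
        for c in candidates:
            if c in _GENERATORS:
                return c
            if c in _ALIASES:
                return _ALIASES[c]
    raise ValueError(f"unsupported point-group/Laue symbol: {symbol!r}")


def _closure(mats: list[np.ndarray]) -> list[np.ndarray]:
    seen = {tuple(_I3.ravel())}
    out = [_I3.copy()]
    frontier = list(mats)
    while frontier:
        m = frontier.pop()
        key = tuple(int(x) for x in m.ravel())
        if key in seen:
            continue
        seen.add(key)
        out.append(m)
        for g in list(out):
            frontier.append(m @ g)
            frontier.append(g @ m)
        if len(out) > 48:
            raise RuntimeError("group closure exceeded maximum order")
    return out


def _sort_mats(mats: list[np.ndarray]) -> list[np.ndarray]:
    return sorted(mats, key=lambda m: tuple(int(x) for x in m.ravel()))


@dataclass(frozen=True)
class PointGroup:
    """Proper rotation group of a Laue class, acting on Miller indices."""

    symbol: str
    rotations: tuple = field(repr=False)

    @property
    def order(self) -> int:
        return len(self.rotations)

    @property
    def laue_symbol(self) -> str:
        return _LAUE_OF[self.symbol]

    def rotation_array(self) -> np.ndarray:
        """All rotations stacked into an (n, 3, 3) integer array."""
        return np.stack([np.asarray(r) for r in self.rotations])


@dataclass(frozen=True)
class SubgroupDescriptor:
    parent: str
    rotations: tuple
    index: int
    label: str

    @property
    def order(self) -> int:
        return len(self.rotations)

    def as_point_group(self) -> PointGroup:
        """View the subgroup as a standalone group (for ASU mapping)."""
        return PointGroup(symbol=self.label, rotations=self.rotations)


_PG_CACHE: dict[str, PointGroup] = {}


def point_group(symbol: str) -> PointGroup:
    """Build the rotation group for a point-group or Laue symbol."""
    norm = _normalize_symbol(symbol)
    if norm not in _PG_CACHE:
        gens = [np.array(g, dtype=int) for g in _GENERATORS[norm]]
        mats = _sort_mats(_closure(gens))
        _PG_CACHE[norm] = PointGroup(
            symbol=norm, rotations=tuple(tuple(map(tuple, m)) for m in mats)
        )
    return _PG_CACHE[norm]


def laue_class_symbol(symbol: str) -> str:
    return point_group(symbol).laue_symbol


def group_from_rotations(symbol: str, rotations) -> PointGroup:
    """Point group from explicit matrices (e.g. a subgroup in a
    nonstandard setting); closure is verified."""
    mats = [np.asarray(r, dtype=int) for r in rotations]
    closed = _sort_mats(_closure(mats))
    if len(closed) != len(mats):
        raise ValueError("rotation list is not closed under multiplication")
    return PointGroup(symbol=symbol, rotations=tuple(tuple(map(tuple, m)) for m in closed))


def _rot_arrays(pg: PointGroup) -> np.ndarray:
    return pg.rotation_array()


def epsilon_factor(h, pg: PointGroup) -> int:
    """Number of rotations fixing h (symmetry enhancement of <I>)."""
    h = np.asarray(h, dtype=int)
    if not h.any():
        raise ValueError("epsilon undefined for (0,0,0)")
    rots = _rot_arrays(pg)
    return int(np.sum(np.all(rots @ h == h, axis=1)))


def epsilon_factors(hkl: np.ndarray, pg: PointGroup) -> np.ndarray:
    """Vectorized epsilon over an (n, 3) index array."""
    rots = _rot_arrays(pg)
    rh = np.einsum("rij,nj->rni", rots, hkl)
    return np.sum(np.all(rh == hkl[None], axis=2), axis=0)


def is_centric(h, pg: PointGroup) -> bool:
    """True when a rotation maps h to -h (phase-restricted reflection)."""
    h = np.asarray(h, dtype=int)
    if not h.any():
        raise ValueError("centricity undefined for (0,0,0)")
    rots = _rot_arrays(pg)
    return bool(np.any(np.all(rots @ h == -h, axis=1)))


def centric_flags(hkl: np.ndarray, pg: PointGroup) -> np.ndarray:
    rots = _rot_arrays(pg)
    rh = np.einsum("rij,nj->rni", rots, hkl)
    return np.any(np.all(rh == -hkl[None], axis=2), axis=0)


def canonical_index(h, pg: PointGroup) -> tuple[int, int, int]:
    """Canonical ASU representative: lexicographically greatest member of
    the orbit of h under the group including Friedel inversion."""
    h = np.asarray(h, dtype=int)
    rots = _rot_arrays(pg)
    orbit = np.concatenate([rots @ h, -(rots @ h)])
    best = max(map(tuple, orbit.tolist()))
    return tuple(int(x) for x in best)


def canonicalize_indices(hkl: np.ndarray, pg: PointGroup) -> np.ndarray:
    """Vectorized canonical ASU mapping of an (n, 3) index array."""
    hkl = np.asarray(hkl, dtype=int)
    rots = _rot_arrays(pg)
    cand = np.einsum("rij,nj->nri", rots, hkl)
    cand = np.concatenate([cand, -cand], axis=1)  # Friedel mates
    # lexicographic maximum over each orbit
    n = hkl.shape[0]
    best = np.zeros((n, 3), dtype=int)
    alive = np.ones(cand.shape[:2], dtype=bool)
    sentinel = np.iinfo(np.int32).min
    for comp in range(3):
        col = np.where(alive, cand[:, :, comp], sentinel)
        best[:, comp] = col.max(axis=1)
        alive &= cand[:, :, comp] == best[:, comp][:, None]
    return best


def _axis_of(rot: np.ndarray) -> tuple[int, int, int] | None:
    """Integer rotation axis (eigenvector for eigenvalue 1), normalized to
    smallest integers with first nonzero positive; None for the identity."""
    if np.array_equal(rot, _I3):
        return None
    m = rot - _I3
    # integer nullspace via sympy-free adjugate trick: use SVD then rationalize
    u, s, vt = np.linalg.svd(m.astype(float))
    v = vt[-1]
    v = v / np.max(np.abs(v))
    ints = np.round(v * 6).astype(int)
    g = np.gcd.reduce(ints[ints != 0]) if ints.any() else 1
    ints = ints // g
    for x in ints:
        if x != 0:
            if x < 0:
                ints = -ints
            break
    return tuple(int(x) for x in ints)


def _element_order(rot: np.ndarray) -> int:
    m = rot.copy()
    for k in range(1, 7):
        if np.array_equal(m, _I3):
            return k
        m = m @ rot
    raise RuntimeError("element order exceeds 6")


def _subgroup_label(mats: list[np.ndarray]) -> str:
    n = len(mats)
    orders = sorted(_element_order(m) for m in mats)
    axes = {}
    for m in mats:
        o = _element_order(m)
        if o > 1:
            ax = _axis_of(m)
            axes.setdefault(o, set()).add(ax)

    def fmt(ax):
        return "[" + "".join(str(x) for x in ax) + "]"

    if n == 1:
        return "1"
    if n == 2:
        return f"2 along {fmt(next(iter(axes[2])))}"
    if n == 3:
        return f"3 along {fmt(next(iter(axes[3])))}"
    if n == 4 and 4 in axes:
        return f"4 along {fmt(next(iter(axes[4])))}"
    if n == 4:
        ax = sorted(axes[2])
        return "222 axes " + ",".join(fmt(a) for a in ax)
    if n == 6 and 6 in axes:
        return f"6 along {fmt(next(iter(axes[6])))}"
    if n == 6:
        twofolds = ",".join(fmt(a) for a in sorted(axes[2]))
        return f"32 threefold {fmt(next(iter(axes[3])))} twofolds {twofolds}"
    if n == 8:
        return f"422 fourfold {fmt(next(iter(axes[4])))}"
    if n == 12 and 4 not in axes and max(orders) == 3:
        return "23"
    if n == 12 and 6 in axes:
        return f"622 sixfold {fmt(next(iter(axes[6])))}"
    if n == 12:
        return f"422-like order 12"
    return f"group of order {n}"


def enumerate_proper_subgroups(pg: PointGroup) -> list[SubgroupDescriptor]:
    """All strict subgroups, one descriptor per conjugacy class.

    Subgroups related by conjugation within the parent (the same symmetry
    along a symmetry-equivalent direction) are reported once, through a
    canonical representative.
    """
    mats = [np.asarray(r) for r in pg.rotations]
    full = frozenset(tuple(int(x) for x in m.ravel()) for m in mats)
    by_key = {tuple(int(x) for x in m.ravel()): m for m in mats}

    # grow closed subsets breadth-first from the trivial group
    id_key = tuple(_I3.ravel())
    found = {frozenset([id_key])}
    frontier = [frozenset([id_key])]
    while frontier:
        base = frontier.pop()
        for key in full - base:
            new_mats = [by_key[k] for k in base] + [by_key[key]]
            closed = _closure(new_mats)
            new = frozenset(tuple(int(x) for x in m.ravel()) for m in closed)
            if new not in found:
                found.add(new)
                frontier.append(new)

    # group into conjugacy classes under the parent; keep the canonical
    # (lexicographically smallest) representative of each class
    classes: list[frozenset] = []
    seen: set[frozenset] = set()
    for subset in sorted(found, key=lambda s: sorted(s)):
        if subset == full or subset in seen:
            continue
        conj_class = set()
        for gk in full:
            g = by_key[gk]
            ginv = np.linalg.inv(g).round().astype(int)
            conj = frozenset(
                tuple(int(x) for x in (g @ by_key[k] @ ginv).ravel()) for k in subset
            )
            conj_class.add(conj)
        seen |= conj_class
        classes.append(subset)

    subs = []
    for subset in classes:
        sub_mats = _sort_mats([by_key[k] for k in subset])
        label = _subgroup_label(sub_mats)
        subs.append(
            SubgroupDescriptor(
                parent=pg.symbol,
                rotations=tuple(tuple(map(tuple, m)) for m in sub_mats),
                index=pg.order // len(subset),
                label=label,
            )
        )
    subs.sort(key=lambda s: (-s.order, s.label))
    return subs


def expand_to_subgroup(dataset, sub: SubgroupDescriptor):
    """Re-index a merged dataset into the ASU of a subgroup of its Laue
    group; intensities are copied onto every orbit member."""
    from . import reflection_data as rd

    parent = dataset.point_group
    if parent.symbol != sub.parent:
        raise ValueError(
            f"subgroup parent {sub.parent!r} does not match dataset Laue "
            f"group {parent.symbol!r}"
        )
    sub_pg = sub.as_point_group()
    rots = parent.rotation_array()

    records = {}
    for i in range(dataset.n):
        h = dataset.hkl[i]
        orbit = np.concatenate([rots @ h, -(rots @ h)])
        seen = set()
        for member in map(tuple, orbit.tolist()):
            canon = canonical_index(member, sub_pg)
            if canon not in seen:
                seen.add(canon)
                records[canon] = (dataset.I[i], dataset.sigI[i])

    keys = sorted(records)
    hkl = np.array(keys, dtype=int)
    I = np.array([records[k][0] for k in keys])
    sigI = np.array([records[k][1] for k in keys])
    return rd.ReflectionDataset(
        hkl=hkl,
        I=I,
        sigI=sigI,
        cell=dataset.cell,
        laue_symbol=sub.label,
        rotations=sub.rotations,
        spacegroup_symbol=None,
        wavelength=dataset.wavelength,
        amplitudes_converted=dataset.amplitudes_converted,
        french_wilson_suspected=dataset.french_wilson_suspected,
        provenance=list(dataset.provenance) + [f"expand:{sub.label}"],
        _skip_canonicalization=True,
    )


def score_axial_absences(dataset, axis: str, period: int) -> dict:
    """Screen axial reflections for a screw-axis extinction pattern.

    Looks at reflections on the given axis whose index is NOT divisible by
    the period; a screw axis of that period forbids them.
    """
    ax = {"a": 0, "b": 1, "c": 2}[axis]
    others = [i for i in range(3) if i != ax]
    hkl = dataset.hkl
    on_axis = (hkl[:, others[0]] == 0) & (hkl[:, others[1]] == 0)
    # orbit under the Laue group may have put axials on the negative side
    idx = np.abs(hkl[:, ax])
    screened = on_axis & (idx % period != 0)
    n = int(screened.sum())
    if n < 3:
        return {"n_observed": n, "mean_I_over_sig": float("nan"), "verdict": "unmeasured"}
    with np.errstate(divide="ignore", invalid="ignore"):
        ios = dataset.I[screened] / np.where(
            dataset.sigI[screened] > 0, dataset.sigI[screened], np.nan
        )
    mean_ios = float(np.nanmean(ios))
    verdict = "absent" if mean_ios < 2.0 else "present"
    return {"n_observed": n, "mean_I_over_sig": mean_ios, "verdict": verdict}
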