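"""Data model and I/O for merged reflection datasets.

Two on-disk forms are supported: the binary MTZ layout (see ``_mtz``) and
a plain-text tab-separated dialect with ``# key = value`` header lines
followed by ``h k l I sigI`` rows.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from . import symmetry
from . import _mtz

__all__ = [
    "UnitCell",
    "ReflectionDataset",
    "read_reflections",
    "write_reflections",
    "resolution",
]


@dataclass(frozen=True)
class UnitCell:
    """Unit cell with the reciprocal orthogonalization matrix ``M`` such
    that ``M @ (h,k,l)`` is the reciprocal-space vector in 1/Angstrom."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0 < v < 180:
                raise ValueError(f"cell angle {name} must lie in (0, 180)")
        if self.volume() <= 0 or not math.isfinite(self.volume()):
            raise ValueError("degenerate unit cell (non-positive metric)")

    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg
        if arg <= 0:
            return -1.0
        return self.a * self.b * self.c * math.sqrt(arg)

    def orthogonalization(self) -> np.ndarray:
        """Real-space orthogonalization matrix A (columns = a, b, c in a
        Cartesian frame with a along x, b in the xy plane)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = self.volume() / (self.a * self.b * self.c)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def M(self) -> np.ndarray:
        """Reciprocal orthogonalization: s = M @ h, |s| = 1/d."""
        return np.linalg.inv(self.orthogonalization()).T

    def s_vectors(self, hkl: np.ndarray) -> np.ndarray:
        return np.asarray(hkl, dtype=float) @ self.M.T

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        s = np.linalg.norm(self.s_vectors(np.atleast_2d(hkl)), axis=1)
        return 1.0 / s

    def as_tuple(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


def resolution(h, cell: UnitCell) -> dict:
    """Resolution of one reflection: s = |M h| (1/A), d = 1/s (A)."""
    h = np.asarray(h, dtype=int)
    if not h.any():
        raise ValueError("resolution undefined for (0,0,0)")
    s = float(np.linalg.norm(cell.M @ h))
    return {"d": 1.0 / s, "s": s}


@dataclass
class ReflectionDataset:
    """Merged unique reflections in the canonical ASU of a Laue group."""

    hkl: np.ndarray
    I: np.ndarray
    sigI: np.ndarray
    cell: UnitCell
    laue_symbol: str
    spacegroup_symbol: str | None = None
    wavelength: float | None = None
    amplitudes_converted: bool = False
    french_wilson_suspected: bool = False
    provenance: list[str] = field(default_factory=list)
    rotations: tuple | None = None     # explicit matrices for nonstandard settings
    _skip_canonicalization: bool = False

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.I = np.asarray(self.I, dtype=float).ravel()
        self.sigI = np.asarray(self.sigI, dtype=float).ravel()
        if not (len(self.hkl) == len(self.I) == len(self.sigI)):
            raise ValueError("hkl, I and sigI must have equal length")
        if np.any(self.sigI < 0):
            raise ValueError("sigI must be non-negative")
        if self.rotations is not None:
            self._point_group = symmetry.group_from_rotations(
                self.laue_symbol, self.rotations
            )
            self.rotations = self._point_group.rotations
        else:
            self._point_group = symmetry.point_group(self.laue_symbol)
            self.laue_symbol = self._point_group.symbol
        if not self._skip_canonicalization:
            self._canonicalize()

    def _canonicalize(self):
        canon = symmetry.canonicalize_indices(self.hkl, self._point_group)
        keys = [tuple(row) for row in canon.tolist()]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate reflections after ASU mapping")
        order = np.lexsort((canon[:, 2], canon[:, 1], canon[:, 0]))
        self.hkl = canon[order]
        self.I = self.I[order]
        self.sigI = self.sigI[order]

    @property
    def n(self) -> int:
        return len(self.I)

    @property
    def point_group(self) -> symmetry.PointGroup:
        return self._point_group

    def s_squared(self) -> np.ndarray:
        s = self.cell.s_vectors(self.hkl)
        return np.einsum("ni,ni->n", s, s)

    def d_spacings(self) -> np.ndarray:
        return 1.0 / np.sqrt(self.s_squared())

    def centric(self) -> np.ndarray:
        return symmetry.centric_flags(self.hkl, self._point_group)

    def epsilon(self) -> np.ndarray:
        return symmetry.epsilon_factors(self.hkl, self._point_group).astype(float)

    def copy_with(self, **kw) -> "ReflectionDataset":
        base = dict(
            hkl=self.hkl.copy(),
            I=self.I.copy(),
            sigI=self.sigI.copy(),
            cell=self.cell,
            laue_symbol=self.laue_symbol,
            spacegroup_symbol=self.spacegroup_symbol,
            wavelength=self.wavelength,
            amplitudes_converted=self.amplitudes_converted,
            french_wilson_suspected=self.french_wilson_suspected,
            provenance=list(self.provenance),
            rotations=self.rotations,
            _skip_canonicalization=True,
        )
        base.update(kw)
        ds = ReflectionDataset(**base)
        ds._point_group = self._point_group
        return ds


class FormatError(ValueError):
    """Fatal reflection-file format problem."""


_DEFAULT_HINTS = {
    "I": ("I", "IMEAN", "IOBS", "I-obs"),
    "SIGI": ("SIGI", "SIGIMEAN", "SIGIOBS", "SIGI-obs"),
    "F": ("F", "FP", "FOBS", "F-obs"),
    "SIGF": ("SIGF", "SIGFP", "SIGFOBS", "SIGF-obs"),
}


def _resolve_columns(labels: list[str], column_hints: dict | None):
    hints = dict(_DEFAULT_HINTS)
    if column_hints:
        for k, v in column_hints.items():
            hints[k.upper()] = (v,) if isinstance(v, str) else tuple(v)
    upper = {lab.upper(): i for i, lab in enumerate(labels)}

    def find(kind):
        for cand in hints[kind]:
            if cand.upper() in upper:
                return upper[cand.upper()]
        return None

    for req in ("H", "K", "L"):
        if req not in upper:
            raise FormatError(f"missing index column {req}")
    idx = (upper["H"], upper["K"], upper["L"])
    i_col, sigi_col = find("I"), find("SIGI")
    f_col, sigf_col = find("F"), find("SIGF")
    if i_col is None and f_col is None:
        raise FormatError("no intensity (I) or amplitude (F) column found")
    return idx, i_col, sigi_col, f_col, sigf_col


def read_reflections(path, column_hints: dict | None = None) -> ReflectionDataset:
    """Read a merged reflection file (MTZ or the text dialect).

    Amplitude columns are converted on input with I = F^2 and
    sigI = 2 F sigF; indices are mapped to the canonical ASU of the
    declared Laue group, and duplicate observations are rejected.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic == b"MTZ ":
        raw = _mtz.read_mtz(path)
    else:
        raw = _read_tsv(path)

    labels = raw["labels"]
    idx, i_col, sigi_col, f_col, sigf_col = _resolve_columns(labels, column_hints)
    data = raw["data"]
    hkl = data[:, idx].astype(int)
    amplitudes_converted = False
    if i_col is not None:
        I = data[:, i_col].astype(float)
        sigI = data[:, sigi_col].astype(float) if sigi_col is not None else np.zeros(len(I))
    else:
        F = data[:, f_col].astype(float)
        sigF = data[:, sigf_col].astype(float) if sigf_col is not None else np.zeros(len(F))
        I = F * F
        sigI = 2.0 * F * sigF
        amplitudes_converted = True

    meta = raw["meta"]
    cell = UnitCell(*meta["cell"])
    laue = meta.get("laue") or meta.get("spacegroup")
    if laue is None:
        raise FormatError("no Laue or space-group symbol in file")
    flags = meta.get("flags", {})
    rotations = meta.get("rotations")
    if rotations is not None:
        # explicit matrices are only needed for nonstandard settings
        try:
            symmetry.point_group(laue)
            rotations = None
        except ValueError:
            pass
    return ReflectionDataset(
        hkl=hkl,
        I=I,
        sigI=sigI,
        cell=cell,
        laue_symbol=laue,
        spacegroup_symbol=meta.get("spacegroup"),
        wavelength=meta.get("wavelength"),
        amplitudes_converted=amplitudes_converted or flags.get("amplitudes_converted", False),
        french_wilson_suspected=flags.get("french_wilson_suspected", False),
        provenance=list(meta.get("provenance", [])),
        rotations=rotations,
    )


def _read_tsv(path) -> dict:
    meta: dict = {"flags": {}, "provenance": []}
    rows = []
    labels = ["H", "K", "L", "I", "SIGI"]
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    continue
                key, _, value = body.partition("=")
                key, value = key.strip().lower(), value.strip()
                if key == "cell":
                    meta["cell"] = tuple(float(x) for x in value.split())
                elif key == "laue":
                    meta["laue"] = value
                elif key == "spacegroup":
                    meta["spacegroup"] = value
                elif key == "wavelength":
                    meta["wavelength"] = float(value)
                elif key == "columns":
                    labels = value.split()
                elif key == "provenance":
                    meta["provenance"] = [v for v in value.split(";") if v]
                elif key == "rotations":
                    ops = []
                    for op in value.split("|"):
                        nums = [int(x) for x in op.split(",")]
                        ops.append(tuple(tuple(nums[i : i + 3]) for i in (0, 3, 6)))
                    meta["rotations"] = tuple(ops)
                elif key in ("amplitudes_converted", "french_wilson_suspected"):
                    meta["flags"][key] = value.lower() in ("1", "true", "yes")
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != len(labels):
                raise FormatError(f"{path}:{lineno}: expected {len(labels)} fields")
            rows.append([float(x) for x in parts])
    if "cell" not in meta:
        raise FormatError(f"{path}: missing '# cell = a b c alpha beta gamma' header")
    if not rows:
        raise FormatError(f"{path}: no reflection records")
    return {"labels": labels, "data": np.array(rows), "meta": meta}


def write_reflections(dataset: ReflectionDataset, path, format: str = "tsv") -> str:
    """Write a dataset; provenance labels are stored in the file header
    (text dialect) or history records (MTZ)."""
    path = os.fspath(path)
    if format == "tsv":
        _write_tsv(dataset, path)
    elif format == "mtz":
        _mtz.write_mtz(dataset, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _write_tsv(dataset: ReflectionDataset, path):
    with open(path, "w") as fh:
        fh.write("# cell = %.6f %.6f %.6f %.6f %.6f %.6f\n" % dataset.cell.as_tuple())
        fh.write(f"# laue = {dataset.laue_symbol}\n")
        if dataset.spacegroup_symbol:
            fh.write(f"# spacegroup = {dataset.spacegroup_symbol}\n")
        if dataset.wavelength:
            fh.write(f"# wavelength = {dataset.wavelength:.6f}\n")
        fh.write(f"# amplitudes_converted = {str(dataset.amplitudes_converted).lower()}\n")
        fh.write(
            f"# french_wilson_suspected = {str(dataset.french_wilson_suspected).lower()}\n"
        )
        if dataset.provenance:
            fh.write("# provenance = " + ";".join(dataset.provenance) + "\n")
        if dataset.rotations is not None:
            ops = "|".join(
                ",".join(str(x) for row in op for x in row) for op in dataset.rotations
            )
            fh.write(f"# rotations = {ops}\n")
        fh.write("# columns = H K L I SIGI\n")
        for (h, k, l), I, sig in zip(dataset.hkl.tolist(), dataset.I, dataset.sigI):
            fh.write(f"{h}\t{k}\t{l}\t{I:.10g}\t{sig:.10g}\n")
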