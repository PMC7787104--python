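"""Minimal MTZ reflection-file codec.

Implements the standard layout — ``MTZ `` magic, header-location word,
machine stamp, float32 reflection records, then 80-character ASCII header
records (VERS/NCOL/CELL/SYMINF/COLUMN/.../END) and a history block.
Covers merged single-dataset files only, which is all this package emits.
"""

from __future__ import annotations

import struct

import numpy as np

_MACHINE_STAMP = struct.pack("4B", 0x44, 0x41, 0x00, 0x00)  # little-endian IEEE

_AXES = ("H", "K", "L")


def _encode_rotation(op) -> str:
    """Rotation matrix acting on (h,k,l) -> 'H+K,-H,L' style record."""
    parts = []
    for row in op:
        term = ""
        for coef, axis in zip(row, _AXES):
            if coef == 0:
                continue
            sign = "-" if coef < 0 else ("+" if term else "")
            mag = "" if abs(coef) == 1 else str(abs(coef)) + "*"
            term += f"{sign}{mag}{axis}"
        parts.append(term or "0")
    return ",".join(parts)


def _decode_rotation(text: str):
    rows = []
    for comp in text.replace(" ", "").upper().split(","):
        row = [0, 0, 0]
        sign, mag = 1, ""
        for ch in comp:
            if ch == "+":
                sign = 1
            elif ch == "-":
                sign = -1
            elif ch.isdigit():
                mag += ch
            elif ch == "*":
                continue
            elif ch in _AXES:
                row[_AXES.index(ch)] = sign * (int(mag) if mag else 1)
                sign, mag = 1, ""
        rows.append(tuple(row))
    return tuple(rows)


def _records(text_block: bytes):
    for i in range(0, len(text_block), 80):
        yield text_block[i : i + 80].decode("ascii", "replace").rstrip()


def read_mtz(path) -> dict:
    with open(path, "rb") as fh:
        blob = fh.read()
    if blob[:4] != b"MTZ ":
        raise ValueError("not an MTZ file")
    header_word = struct.unpack_from("<i", blob, 4)[0]
    header_off = (header_word - 1) * 4
    ncol = nref = None
    cell = None
    labels: list[str] = []
    meta: dict = {"flags": {}, "provenance": []}
    in_history = False
    for rec in _records(blob[header_off:]):
        tag, _, rest = rec.partition(" ")
        rest = rest.strip()
        if tag == "NCOL":
            parts = rest.split()
            ncol, nref = int(parts[0]), int(parts[1])
        elif tag == "CELL":
            cell = tuple(float(x) for x in rest.split())
        elif tag == "SYMINF":
            # ... nsym nsymp lattice sgnum 'spacegroup name' laue/pointgroup
            toks = rest.split("'")
            if len(toks) >= 2:
                meta["spacegroup"] = toks[1].strip()
            if len(toks) >= 3 and toks[2].strip():
                meta["laue"] = toks[2].strip()
            elif len(toks) >= 2:
                meta["laue"] = toks[1].strip()
        elif tag == "SYMM":
            meta.setdefault("rotations", []).append(_decode_rotation(rest))
        elif tag == "COLUMN":
            labels.append(rest.split()[0])
        elif tag == "DWAVEL":
            toks = rest.split()
            if len(toks) >= 2 and float(toks[-1]) > 0:
                meta["wavelength"] = float(toks[-1])
        elif tag == "MTZHIST":
            in_history = True
        elif in_history and rec.startswith("PROV "):
            meta["provenance"].append(rec[5:].strip())
        elif in_history and rec.startswith("FLAG "):
            key, _, val = rec[5:].partition("=")
            meta["flags"][key.strip()] = val.strip() == "true"
        elif tag == "END" and not in_history:
            pass
        elif tag == "MTZENDOFHEADERS":
            break
    if ncol is None or cell is None:
        raise ValueError("MTZ header missing NCOL or CELL record")
    meta["cell"] = cell
    data = np.frombuffer(blob, dtype="<f4", count=ncol * nref, offset=80)
    return {"labels": labels, "data": data.reshape(nref, ncol).astype(float), "meta": meta}


def write_mtz(dataset, path):
    labels = ["H", "K", "L", "I", "SIGI"]
    types = ["H", "H", "H", "J", "Q"]
    table = np.column_stack(
        [dataset.hkl.astype(float), dataset.I, dataset.sigI]
    ).astype("<f4")
    nref, ncol = table.shape
    d = dataset.d_spacings()
    smin2, smax2 = float((1 / d.max()) ** 2), float((1 / d.min()) ** 2)

    header_word = 21 + nref * ncol  # 1-based word index of first header record
    recs = []
    recs.append("VERS MTZ:V1.1")
    recs.append("TITLE refltriage output")
    recs.append(f"NCOL {ncol:12d} {nref:12d} {0:8d}")
    recs.append("CELL  " + " ".join(f"{x:9.4f}" for x in dataset.cell.as_tuple()))
    recs.append("SORT    1   2   3   0   0")
    sg = dataset.spacegroup_symbol or dataset.laue_symbol
    rots = dataset.point_group.rotations
    recs.append(f"SYMINF {len(rots):3d} {len(rots):2d} P {1:5d} '{sg}' {dataset.laue_symbol}")
    for op in rots:
        recs.append(f"SYMM {_encode_rotation(op)}")
    recs.append(f"RESO {smin2:-20.10f} {smax2:-20.10f}")
    recs.append("NDIF        1")
    recs.append("PROJECT       1 project")
    recs.append("CRYSTAL       1 crystal")
    recs.append("DATASET       1 dataset")
    recs.append("DCELL         1 " + " ".join(f"{x:9.4f}" for x in dataset.cell.as_tuple()))
    recs.append(f"DWAVEL        1 {dataset.wavelength or 0.0:10.5f}")
    for lab, typ in zip(labels, types):
        lo = float(table[:, labels.index(lab)].min())
        hi = float(table[:, labels.index(lab)].max())
        recs.append(f"COLUMN {lab:<30s} {typ} {lo:17.4f} {hi:17.4f}    1")
    recs.append("END")
    history = [f"PROV {p}" for p in dataset.provenance]
    history.append(f"FLAG amplitudes_converted = {str(dataset.amplitudes_converted).lower()}")
    history.append(
        f"FLAG french_wilson_suspected = {str(dataset.french_wilson_suspected).lower()}"
    )
    recs.append(f"MTZHIST {len(history):3d}")
    recs.extend(history)
    recs.append("MTZENDOFHEADERS")

    with open(path, "wb") as fh:
        fh.write(b"MTZ ")
        fh.write(struct.pack("<i", header_word))
        fh.write(_MACHINE_STAMP)
        fh.write(b"\x00" * (80 - 12))
        fh.write(table.tobytes())
        for rec in recs:
            fh.write(rec.encode("ascii").ljust(80))
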