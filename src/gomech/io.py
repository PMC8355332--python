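"""Readers and writers shared across the pipeline.

Formats are deliberately plain: two-column whitespace text for force
curves, CSV for tracks and topologies, single-channel TIFF for images,
fixed-column GRO (via MDAnalysis) and multi-frame XYZ for bead frames, and
JSON sidecars for ground truth.  Every writer emits exactly what the
corresponding reader consumes.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from gomech.afm import ForceCurve
from gomech.cgmd import BeadFrame, FELandscape, Topology
from gomech.errors import InvalidParameterError, ParseError
from gomech.migration import TRACK_COLUMNS, TrackSet

# ---------------------------------------------------------------------------
# force curves: two-column whitespace text, '#' comments

def parse_force_curve_file(path, **curve_kwargs) -> ForceCurve:
    """Read a two-column (z_nm, force_nN) text file into a ForceCurve.

    Lines starting with '#' are comments; rows must hold exactly two
    numeric fields.  Samples are sorted by z ascending.
    """
    z, f = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                z.append(float(parts[0]))
                f.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value") from exc
    if not z:
        raise ParseError(f"{path}: no data rows")
    order = np.argsort(z, kind="stable")
    return ForceCurve(
        z_nm=np.asarray(z)[order], force_nN=np.asarray(f)[order], **curve_kwargs
    )


def write_force_curve(path, curve: ForceCurve) -> None:
    with open(path, "w") as fh:
        fh.write("# z_nm force_nN\n")
        for z, f in zip(curve.z_nm, curve.force_nN):
            fh.write(f"{float(z)!r} {float(f)!r}\n")


# ---------------------------------------------------------------------------
# migration tracks: CSV

def read_tracks_csv(path, channel_axis=(1.0, 0.0)) -> TrackSet:
    data = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in data.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return TrackSet(data=data[TRACK_COLUMNS], channel_axis=channel_axis)


def write_tracks_csv(path, tracks: TrackSet) -> None:
    tracks.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# images: single-channel TIFF

def read_image(path) -> np.ndarray:
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ParseError(f"{path}: expected a single-channel image")
    return img


def write_image(path, image: np.ndarray, as_uint16: bool = True) -> None:
    """Write a single-channel TIFF; float input is rescaled to uint16."""
    img = np.asarray(image)
    if as_uint16 and img.dtype.kind == "f":
        lo, hi = img.min(), img.max()
        scale = 65535.0 / (hi - lo) if hi > lo else 0.0
        img = ((img - lo) * scale).astype(np.uint16)
    tifffile.imwrite(path, img)


# ---------------------------------------------------------------------------
# bead frames: GRO (fixed-column, nm, 3 decimals) and multi-frame XYZ

def parse_gro(path):
    """Read a GRO file; returns (BeadFrame, records).

    ``records`` is a list of (resname, atomname) per bead.  Positions are
    nm; the cubic box edge comes from the final box line.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:
            raise ParseError(f"{path}: not a readable GRO file ({exc})") from exc
    if u.dimensions is None or not np.all(u.dimensions[:3] > 0):
        raise ParseError(f"{path}: missing or invalid box line")
    box_nm = u.dimensions[:3] / 10.0
    if not np.allclose(box_nm, box_nm[0]):
        raise ParseError(f"{path}: box is not cubic")
    frame = BeadFrame(positions=u.atoms.positions / 10.0, box=float(box_nm[0]))
    records = [(a.resname, a.name) for a in u.atoms]
    return frame, records


def write_gro(path, frame: BeadFrame, names=None, resname="BEAD", title="gomech frame"):
    """Write a BeadFrame as GRO (3-decimal nm precision)."""
    n = frame.n_beads
    if names is None:
        names = [f"B{i + 1}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write(f"{title}\n{n:5d}\n")
        for i in range(n):
            x, y, z = frame.positions[i]
            fh.write(
                f"{1:5d}{resname:<5s}{names[i][:5]:>5s}{i + 1 if i < 99999 else 0:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        fh.write(f"{frame.box:10.5f}{frame.box:10.5f}{frame.box:10.5f}\n")


def read_xyz_frames(path, box: float):
    """Read a multi-frame XYZ file (coordinates in nm) into BeadFrames.

    XYZ carries no box information, so the cubic edge is supplied by the
    caller; the comment line may carry ``time_ns=<t>``.
    """
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    k = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}:{i + 1}: expected atom count") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        time_ns = float(k)
        for tok in comment.split():
            if tok.startswith("time_ns="):
                time_ns = float(tok.split("=", 1)[1])
        rows = lines[i + 2 : i + 2 + n]
        if len(rows) < n:
            raise ParseError(f"{path}:{i + 1}: truncated frame")
        pos = np.empty((n, 3))
        for j, row in enumerate(rows):
            parts = row.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{i + 3 + j}: expected 'name x y z'")
            pos[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(BeadFrame(positions=pos, box=box, time_ns=time_ns))
        i += 2 + n
        k += 1
    if not frames:
        raise ParseError(f"{path}: no frames")
    return frames


def write_xyz_frames(path, frames, names=None) -> None:
    with open(path, "w") as fh:
        for frame in frames:
            n = frame.n_beads
            labels = names if names is not None else [f"B{i + 1}" for i in range(n)]
            fh.write(
                f"{n}\ntime_ns={float(frame.time_ns)!r} box_nm={float(frame.box)!r}\n"
            )
            for i in range(n):
                x, y, z = frame.positions[i]
                fh.write(f"{labels[i]} {float(x)!r} {float(y)!r} {float(z)!r}\n")


# ---------------------------------------------------------------------------
# topology: bead CSV + LJ-parameter CSV

def read_topology(bead_csv, lj_csv=None) -> Topology:
    """Topology from ``bead_index,type,charge_e,group`` (+ optional LJ CSV).

    The LJ CSV has columns ``type_a,type_b,sigma_nm,epsilon_kjmol``; pairs
    are stored symmetrically.
    """
    beads = pd.read_csv(bead_csv)
    required = ["bead_index", "type", "charge_e", "group"]
    missing = [c for c in required if c not in beads.columns]
    if missing:
        raise ParseError(f"{bead_csv}: missing columns {missing}")
    beads = beads.sort_values("bead_index")
    lj = {}
    if lj_csv is not None:
        table = pd.read_csv(lj_csv)
        for _, row in table.iterrows():
            lj[(row["type_a"], row["type_b"])] = (
                float(row["sigma_nm"]),
                float(row["epsilon_kjmol"]),
            )
    return Topology(
        types=beads["type"].to_numpy(dtype=object),
        charges=beads["charge_e"].to_numpy(dtype=float),
        groups=beads["group"].to_numpy(dtype=object),
        lj_params=lj,
    )


def write_topology(bead_csv, topology: Topology, lj_csv=None) -> None:
    pd.DataFrame(
        {
            "bead_index": np.arange(topology.n_beads),
            "type": topology.types,
            "charge_e": topology.charges,
            "group": topology.groups,
        }
    ).to_csv(bead_csv, index=False)
    if lj_csv is not None:
        rows = []
        for key, (sigma, eps) in topology.lj_params.items():
            pair = sorted(key)
            a = pair[0]
            b = pair[-1]
            rows.append({"type_a": a, "type_b": b, "sigma_nm": sigma, "epsilon_kjmol": eps})
        pd.DataFrame(rows).to_csv(lj_csv, index=False)


# ---------------------------------------------------------------------------
# landscapes and ground truth

def write_landscape_csv(path, landscape: FELandscape) -> None:
    """Free-energy grid as tidy CSV: x_center,y_center,count,F_kjmol."""
    xc, yc = np.meshgrid(landscape.x_centers, landscape.y_centers, indexing="ij")
    pd.DataFrame(
        {
            "x_center": xc.ravel(),
            "y_center": yc.ravel(),
            "count": landscape.counts.ravel().astype(int),
            "F_kjmol": landscape.F.ravel(),
        }
    ).to_csv(path, index=False)


def write_ground_truth(path, ground_truth) -> None:
    """Ground truth as a JSON sidecar."""
    payload = (
        dataclasses.asdict(ground_truth)
        if dataclasses.is_dataclass(ground_truth)
        else dict(ground_truth)
    )
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())
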