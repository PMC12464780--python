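"""Readers and writers for the package's tabular text formats.

Three dialects cover the inputs:

* isotherms — CSV with header ``area_A2,pressure_mN_m`` and optional
  ``# key: value`` metadata comment lines (``temperature_K``, ``x_cer``,
  ``label``);
* stress profiles — xvg-style whitespace tables (comment lines start
  with ``#`` or ``@``) with columns z [nm], Pxx, Pyy, Pzz [bar], or a CSV
  equivalent with a header row;
* lipid frames — CSV ``x_nm,y_nm,z_nm,leaflet`` with a ``# box Lx Ly``
  comment line, or GRO coordinate files (parsed with MDAnalysis, leaflet
  assigned by median z split).

The synthetic generators write through the same functions the analysis
stages read with, so generated fixtures exercise the real I/O path.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import Isotherm, LipidFrame, MixtureSpec, StressProfile
from .errors import ValidationError


def _parse_comment_metadata(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def write_isotherm_csv(iso: Isotherm, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# temperature_K: {iso.temperature}\n")
        if iso.composition is not None:
            fh.write(f"# x_cer: {iso.composition.fraction_cer}\n")
        if iso.label:
            fh.write(f"# label: {iso.label}\n")
        fh.write("area_A2,pressure_mN_m\n")
        for a, pi in zip(iso.area, iso.pressure):
            fh.write(f"{a:.10g},{pi:.10g}\n")


def read_isotherm_csv(path) -> Isotherm:
    path = Path(path)
    meta = _parse_comment_metadata(path)
    df = pd.read_csv(path, comment="#")
    for col in ("area_A2", "pressure_mN_m"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    comp = None
    if "x_cer" in meta:
        comp = MixtureSpec.from_cer(float(meta["x_cer"]))
    return Isotherm(
        pressure=df["pressure_mN_m"].to_numpy(float),
        area=df["area_A2"].to_numpy(float),
        temperature=float(meta.get("temperature_K", 298.15)),
        composition=comp,
        label=meta.get("label", path.stem),
        provenance={"path": str(path)},
    )


def write_stress_xvg(profile: StressProfile, path, comment: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# stress-tensor profile: z [nm], Pxx Pyy Pzz [bar]\n")
        if comment:
            fh.write(f"# {comment}\n")
        fh.write('@    title "Stress profile"\n')
        fh.write('@    xaxis  label "z (nm)"\n')
        for row in zip(profile.z, profile.pxx, profile.pyy, profile.pzz):
            # full precision: the reader re-checks grid uniformity at 1e-9
            fh.write("  ".join(f"{v: .17g}" for v in row) + "\n")


def read_stress_xvg(path, columns=(0, 1, 2, 3)) -> StressProfile:
    """Read an xvg-dialect stress table.

    ``columns`` maps (z, Pxx, Pyy, Pzz) onto file column indices for
    files that carry extra columns.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith(("#", "@")):
                continue
            rows.append([float(tok) for tok in s.split()])
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    iz, ixx, iyy, izz = columns
    return StressProfile(
        z=data[:, iz], pxx=data[:, ixx], pyy=data[:, iyy], pzz=data[:, izz]
    )


def read_stress_csv(path, columns=None) -> StressProfile:
    """CSV stress table with header; default column names
    z_nm, pxx_bar, pyy_bar, pzz_bar, overridable via ``columns`` mapping.
    """
    names = {"z": "z_nm", "pxx": "pxx_bar", "pyy": "pyy_bar", "pzz": "pzz_bar"}
    if columns:
        names.update(columns)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in names.values() if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return StressProfile(
        z=df[names["z"]].to_numpy(float),
        pxx=df[names["pxx"]].to_numpy(float),
        pyy=df[names["pyy"]].to_numpy(float),
        pzz=df[names["pzz"]].to_numpy(float),
    )


def write_stress_csv(profile: StressProfile, path) -> None:
    pd.DataFrame(
        {
            "z_nm": profile.z,
            "pxx_bar": profile.pxx,
            "pyy_bar": profile.pyy,
            "pzz_bar": profile.pzz,
        }
    ).to_csv(path, index=False)


def write_frame_csv(frame: LipidFrame, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# box {frame.box[0]:.10g} {frame.box[1]:.10g}\n")
        if frame.time is not None:
            fh.write(f"# time_ps: {frame.time}\n")
        fh.write("x_nm,y_nm,z_nm,leaflet\n")
        for (x, y, z), lab in zip(frame.positions, frame.leaflet):
            fh.write(f"{x:.10g},{y:.10g},{z:.10g},{lab}\n")


def read_frame_csv(path) -> LipidFrame:
    path = Path(path)
    box = None
    time = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if body.startswith("box"):
                parts = body.split()
                box = (float(parts[1]), float(parts[2]))
            elif body.startswith("time_ps"):
                time = float(body.partition(":")[2])
    if box is None:
        raise ValidationError(f"{path}: missing '# box Lx Ly' header line")
    df = pd.read_csv(path, comment="#")
    for col in ("x_nm", "y_nm", "z_nm", "leaflet"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return LipidFrame(
        positions=df[["x_nm", "y_nm", "z_nm"]].to_numpy(float),
        leaflet=df["leaflet"].to_numpy(str),
        box=box,
        time=time,
    )


def read_frame_gro(path, atom_name: str | None = None) -> LipidFrame:
    """Read a GRO coordinate file as a lipid frame (via MDAnalysis).

    One reference point per lipid is expected; optionally restrict to
    atoms named ``atom_name`` (e.g. a head bead). Leaflets are assigned by
    a median split on z, the standard heuristic for planar bilayers.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    atoms = u.atoms
    if atom_name is not None:
        atoms = atoms.select_atoms(f"name {atom_name}")
    if len(atoms) < 8:
        raise ValidationError("too few reference atoms in coordinate file")
    pos_nm = atoms.positions / 10.0  # MDAnalysis uses Å
    box_nm = u.dimensions[:2] / 10.0
    z_median = np.median(pos_nm[:, 2])
    leaflet = np.where(pos_nm[:, 2] >= z_median, "upper", "lower")
    return LipidFrame(
        positions=pos_nm,
        leaflet=leaflet,
        box=(float(box_nm[0]), float(box_nm[1])),
    )


def read_frame(path, **kwargs) -> LipidFrame:
    """Dispatch on file extension (.csv or .gro)."""
    path = Path(path)
    if path.suffix == ".gro":
        return read_frame_gro(path, **kwargs)
    return read_frame_csv(path)


def read_stress(path, **kwargs) -> StressProfile:
    """Dispatch on file extension (.csv or xvg-dialect text)."""
    path = Path(path)
    if path.suffix == ".csv":
        return read_stress_csv(path, **kwargs)
    return read_stress_xvg(path, **kwargs)
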