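"""Readers and writers for particle frames, curve/table files and config.

Frames use a small extended-XYZ dialect: line 1 is the particle count,
line 2 a key=value comment carrying the box, surface geometry and the
species→charge map, and each following line is ``species x y z`` in nm.
A reader shim for LAMMPS-dump-style column files is available behind the
``format: lammps-dump`` config switch.  Parsers are strict by default
(fail loudly with line numbers); pass ``lenient=True`` to coerce unknown
species to "other".
"""

from __future__ import annotations

import shlex
from pathlib import Path
from typing import Dict, Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .datatypes import DEFAULT_CHARGES, DoseResponse, ParticleFrame, TransferCurve
from .surfaces import SurfaceModel


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


class SchemaError(KeyError):
    """Input table lacks a required column."""


# --- units ----------------------------------------------------------------

CONCENTRATION_UNITS = {
    "M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9,
    "pM": 1e-12, "fM": 1e-15, "aM": 1e-18, "zM": 1e-21,
}
VOLTAGE_UNITS = {"V": 1.0, "mV": 1e-3}
CURRENT_UNITS = {"A": 1.0, "mA": 1e-3, "uA": 1e-6, "µA": 1e-6, "nA": 1e-9}


def convert(value, unit: str, table: Mapping[str, float]):
    if unit not in table:
        raise SchemaError(f"unknown unit {unit!r}; expected one of {sorted(table)}")
    return np.asarray(value, dtype=float) * table[unit]


# --- config ---------------------------------------------------------------

def load_config(path: Union[str, Path]) -> dict:
    """Load the structured (YAML) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"config {path} must be a mapping at top level")
    return cfg


# --- frames ---------------------------------------------------------------

def _format_comment(frame: ParticleFrame) -> str:
    parts = ['box="%g %g %g"' % tuple(frame.box)]
    charges = ",".join(f"{s}:{q:g}" for s, q in sorted(frame.charge_per_species.items()))
    parts.append(f'charges="{charges}"')
    if frame.surface is not None:
        s = frame.surface
        parts.append(f"surface_kind={s.kind}")
        parts.append(f"sigma={s.sigma:g}")
        if s.kind == "sinusoid":
            parts.append(f"wavelength={s.wavelength:g} amplitude={s.amplitude:g}")
        elif s.kind == "trench":
            parts.append(f"trench_radius={s.trench_radius:g} "
                         f"trench_length={s.trench_length:g} trench_x0={s.trench_x0:g}")
    return " ".join(parts)


def _parse_comment(line: str) -> dict:
    out: dict = {}
    for token in shlex.split(line):
        if "=" not in token:
            continue
        key, value = token.split("=", 1)
        out[key] = value
    return out


def write_frame(frame: ParticleFrame, path: Union[str, Path]) -> None:
    """Write a frame in the extended-XYZ dialect (6 decimals, nm)."""
    lines = [str(len(frame)), _format_comment(frame)]
    for sp, pos in zip(frame.species, frame.positions):
        lines.append(f"{sp} {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _surface_from_meta(meta: dict) -> Optional[SurfaceModel]:
    if "surface_kind" not in meta:
        return None
    kind = meta["surface_kind"]
    kwargs = {"kind": kind}
    for key in ("wavelength", "amplitude", "sigma", "trench_radius",
                "trench_length", "trench_x0"):
        if key in meta:
            kwargs[key] = float(meta[key])
    return SurfaceModel(**kwargs)


def read_frame(path: Union[str, Path], config: Optional[Mapping] = None) -> ParticleFrame:
    """Read a particle frame (extended-XYZ by default).

    ``config`` keys: ``charges`` (species→e map; defaults merged in),
    ``lenient`` (map unknown species to "other" instead of failing),
    ``format`` ("xyz" or "lammps-dump"), ``box`` (required for dumps
    without box metadata).
    """
    config = dict(config or {})
    if config.get("format", "xyz") == "lammps-dump":
        return _read_lammps_dump(path, config)

    text = Path(path).read_text().splitlines()
    if len(text) < 2:
        raise ParseError(f"{path}: truncated XYZ file")
    try:
        n = int(text[0].strip())
    except ValueError as exc:
        raise ParseError(f"{path} line 1: expected particle count") from exc
    meta = _parse_comment(text[1])

    charges: Dict[str, float] = dict(DEFAULT_CHARGES)
    if "charges" in meta:
        for item in meta["charges"].split(","):
            sp, q = item.rsplit(":", 1)
            charges[sp] = float(q)
    charges.update(config.get("charges", {}))
    lenient = bool(config.get("lenient", False))

    species, positions = [], []
    for ln, raw in enumerate(text[2:2 + n], start=3):
        cols = raw.split()
        if len(cols) < 4:
            raise ParseError(f"{path} line {ln}: expected 'species x y z'")
        sp = cols[0]
        try:
            xyz = [float(c) for c in cols[1:4]]
        except ValueError as exc:
            raise ParseError(f"{path} line {ln}: non-numeric coordinate") from exc
        if sp not in charges:
            if lenient:
                sp = "other"
            else:
                raise ParseError(
                    f"{path} line {ln}: species {sp!r} has no configured charge")
        species.append(sp)
        positions.append(xyz)
    if len(species) != n:
        raise ParseError(f"{path}: header announced {n} particles, found {len(species)}")

    box = np.array([float(v) for v in meta["box"].split()]) if "box" in meta \
        else np.asarray(config.get("box", [0.0, 0.0, 0.0]), dtype=float)
    return ParticleFrame(np.asarray(positions, dtype=float).reshape(len(species), 3),
                         np.asarray(species, dtype=object), charges, box,
                         surface=_surface_from_meta(meta))


def _read_lammps_dump(path: Union[str, Path], config: Mapping) -> ParticleFrame:
    """Minimal LAMMPS text-dump reader (single frame, id/type/x/y/z columns)."""
    lines = Path(path).read_text().splitlines()
    type_map = config.get("type_map")  # int type -> species label
    if type_map is None:
        raise SchemaError("lammps-dump format requires config['type_map']")
    charges = dict(DEFAULT_CHARGES)
    charges.update(config.get("charges", {}))

    i, box, rows, cols = 0, [], [], None
    while i < len(lines):
        line = lines[i]
        if line.startswith("ITEM: BOX BOUNDS"):
            for j in range(3):
                lo, hi = (float(v) for v in lines[i + 1 + j].split()[:2])
                box.append(hi - lo)
            i += 4
            continue
        if line.startswith("ITEM: ATOMS"):
            cols = line.split()[2:]
            i += 1
            while i < len(lines) and not lines[i].startswith("ITEM:"):
                rows.append(lines[i].split())
                i += 1
            continue
        i += 1
    if cols is None:
        raise ParseError(f"{path}: no 'ITEM: ATOMS' section found")
    idx = {c: k for k, c in enumerate(cols)}
    for need in ("type", "x", "y", "z"):
        if need not in idx:
            raise SchemaError(f"dump lacks column {need!r}")
    species, positions = [], []
    for ln, row in enumerate(rows, start=1):
        try:
            t = int(row[idx["type"]])
            xyz = [float(row[idx[a]]) for a in "xyz"]
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: malformed atom row {ln}") from exc
        sp = type_map.get(t, type_map.get(str(t)))
        if sp is None:
            if config.get("lenient"):
                sp = "other"
            else:
                raise ParseError(f"{path}: atom type {t} not in type_map")
        species.append(sp)
        positions.append(xyz)
    return ParticleFrame(np.asarray(positions, float).reshape(len(species), 3),
                         np.asarray(species, dtype=object), charges,
                         np.asarray(box or config.get("box", [0, 0, 0]), float))


# --- curve / dose tables --------------------------------------------------

def _read_delimited(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [str(c).strip() for c in df.columns]
    return df


def read_table(path: Union[str, Path], schema: str,
               units: Optional[Mapping[str, str]] = None):
    """Read a delimited text table as a TransferCurve or DoseResponse.

    ``units`` declares per-column units (e.g. ``{"v_gs": "mV"}``);
    defaults are v_gs in V, i_ds in A, concentration in M, shift in mV.
    """
    units = dict(units or {})
    df = _read_delimited(path)
    lower = {c.lower(): c for c in df.columns}

    if schema == "transfer_curve":
        for col in ("v_gs", "i_ds"):
            if col not in lower:
                raise SchemaError(f"{path}: transfer_curve needs column {col!r}")
        v = convert(df[lower["v_gs"]], units.get("v_gs", "V"), VOLTAGE_UNITS)
        i = convert(df[lower["i_ds"]], units.get("i_ds", "A"), CURRENT_UNITS)
        v_ds = float(df[lower["v_ds"]].iloc[0]) if "v_ds" in lower else 0.05
        return TransferCurve(v, i, v_ds=v_ds, label=str(path))

    if schema == "dose_response":
        if "concentration" not in lower or not (
                "shift_mv" in lower or "shift" in lower):
            raise SchemaError(f"{path}: dose_response needs 'concentration' and 'shift_mV'")
        conc = convert(df[lower["concentration"]],
                       units.get("concentration", "M"), CONCENTRATION_UNITS)
        shift_col = lower.get("shift_mv", lower.get("shift"))
        shift = convert(df[shift_col], units.get("shift", "mV"), VOLTAGE_UNITS) / 1e-3
        rep = df[lower["replicate_id"]].astype(int) if "replicate_id" in lower \
            else np.zeros(len(df), dtype=int)
        if "is_negative_control" in lower:
            nc = df[lower["is_negative_control"]].astype(bool)
        else:
            nc = conc == 0.0
        return DoseResponse(pd.DataFrame({
            "concentration": conc, "shift_mV": shift,
            "replicate_id": np.asarray(rep), "is_negative_control": np.asarray(nc)}))

    raise SchemaError(f"unknown schema {schema!r}")


def write_table(obj, path: Union[str, Path]) -> None:
    """Write a TransferCurve or DoseResponse as CSV (SI units: V, A, M, mV)."""
    if isinstance(obj, TransferCurve):
        pd.DataFrame({"v_gs": obj.v_gs, "i_ds": obj.i_ds,
                      "v_ds": obj.v_ds}).to_csv(path, index=False,
                                                float_format="%.9g")
    elif isinstance(obj, DoseResponse):
        obj.table.to_csv(path, index=False, float_format="%.10g")
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
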