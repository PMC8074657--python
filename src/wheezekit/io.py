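"""Delimited-text I/O for tube-law curves and pressure runs.

Curves are stored one per file as CSV with columns ``p_c_pa``, ``A_c_m2``
(optionally ``sigma_A_m2``), preceded by a ``#``-prefixed JSON header block
carrying the geometry and material metadata.  Values are written with
17 significant digits, so a write/read cycle is exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .geometry import Material, TubeGeometry
from .onset import PressureRun
from .tube_law import TubeLawCurve

__all__ = [
    "write_tube_law_curve",
    "read_tube_law_curve",
    "write_tube_law_dataset",
    "read_tube_law_dataset",
    "write_pressure_run",
    "read_pressure_run",
]

_FMT = "%.17g"


def write_tube_law_curve(path, curve: TubeLawCurve) -> None:
    path = Path(path)
    meta = {
        "geometry": {"l": curve.geometry.l, "l0": curve.geometry.l0,
                     "a": curve.geometry.a, "h": curve.geometry.h},
        "material": {"E": curve.material.E, "nu": curve.material.nu,
                     "rho_s": curve.material.rho_s},
    }
    cols = {"p_c_pa": curve.p_c, "A_c_m2": curve.A_c}
    if curve.sigma_A is not None:
        cols["sigma_A_m2"] = curve.sigma_A
    lines = ["# " + json.dumps(meta), ",".join(cols)]
    for row in zip(*cols.values()):
        lines.append(",".join(_FMT % v for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_tube_law_curve(path) -> TubeLawCurve:
    path = Path(path)
    header = None
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                header = json.loads(line[1:])
                break
    if header is None:
        raise ValueError(f"{path}: missing JSON metadata header ('# {{...}}' line)")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return TubeLawCurve(
        geometry=TubeGeometry(**header["geometry"]),
        material=Material(**header["material"]),
        p_c=df["p_c_pa"].to_numpy(),
        A_c=df["A_c_m2"].to_numpy(),
        sigma_A=df["sigma_A_m2"].to_numpy() if "sigma_A_m2" in df else None,
    )


def write_tube_law_dataset(directory, curves: Iterable[TubeLawCurve]) -> list[Path]:
    """One ``curve_NNN.csv`` per curve in ``directory`` (created if needed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, c in enumerate(curves):
        p = directory / f"curve_{i:03d}.csv"
        write_tube_law_curve(p, c)
        paths.append(p)
    return paths


def read_tube_law_dataset(directory) -> list[TubeLawCurve]:
    directory = Path(directory)
    paths = sorted(directory.glob("curve_*.csv")) or sorted(directory.glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no curve CSV files found in {directory}")
    return [read_tube_law_curve(p) for p in paths]


def write_pressure_run(path, run: PressureRun) -> None:
    """Run as CSV (t_s + channel columns) with a JSON metadata header."""
    path = Path(path)
    meta = {"fs": run.fs, "markers": run.markers, "meta": run.meta}
    cols = {"t_s": run.t, "p_u_pa": run.p_u, "p_1_pa": run.p_1,
            "p_2_pa": run.p_2, "p_a_pa": run.p_a}
    if run.Q is not None:
        cols["Q_m3s"] = run.Q
    df = pd.DataFrame(cols)
    with path.open("w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        df.to_csv(fh, index=False, float_format=_FMT)


def read_pressure_run(path) -> PressureRun:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise ValueError(f"{path}: missing JSON metadata header")
    meta = json.loads(first[1:])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return PressureRun(
        fs=float(meta["fs"]),
        p_u=df["p_u_pa"].to_numpy(),
        p_1=df["p_1_pa"].to_numpy(),
        p_2=df["p_2_pa"].to_numpy(),
        p_a=df["p_a_pa"].to_numpy(),
        Q=df["Q_m3s"].to_numpy() if "Q_m3s" in df else None,
        markers=meta.get("markers", {}),
        meta=meta.get("meta", {}),
    )
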