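"""Tabular I/O: truth tables, picks, SAXS profiles, STAR and OBJ text.

CSV is the canonical format (Angstrom units throughout). STAR is read-only
convenience for class-average metadata; membranes can be loaded from
OBJ-style vertex/face text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .discriminate import ClassifiedParticle
from .membranes import MembraneModel
from .saxs import SAXSProfile
from .scene import ParticleTruth

TRUTH_COLUMNS = ["id", "class", "x", "y", "z", "axis_x", "axis_y", "axis_z", "separation"]
PICK_COLUMNS = ["x", "y", "z", "class", "separation", "score"]


class MissingColumnsError(ValueError):
    def __init__(self, missing: list[str]):
        self.missing = missing
        super().__init__(f"missing required columns: {', '.join(missing)}")


def _require(df: pd.DataFrame, columns: list[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise MissingColumnsError(missing)


def write_truth_csv(path: str | Path, truths: list[ParticleTruth]) -> None:
    """Truth table with (z, y, x) internal coordinates written as x/y/z columns."""
    rows = []
    for t in truths:
        z, y, x = t.center
        if t.kind == "dimer":
            az, ay, ax = t.axis
            rows.append([t.id, t.kind, x, y, z, ax, ay, az, t.separation])
        else:
            rows.append([t.id, t.kind, x, y, z, np.nan, np.nan, np.nan, np.nan])
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, index=False)


def read_truth_csv(path: str | Path) -> list[ParticleTruth]:
    df = pd.read_csv(path)
    _require(df, TRUTH_COLUMNS)
    truths = []
    for _, row in df.iterrows():
        kind = row["class"]
        center = np.array([row["z"], row["y"], row["x"]], float)
        if kind == "dimer":
            axis = np.array([row["axis_z"], row["axis_y"], row["axis_x"]], float)
            truths.append(
                ParticleTruth(
                    id=int(row["id"]), kind=kind, center=center,
                    axis=axis, separation=float(row["separation"]),
                )
            )
        else:
            truths.append(ParticleTruth(id=int(row["id"]), kind=kind, center=center))
    return truths


def write_classified_csv(path: str | Path, particles: list[ClassifiedParticle]) -> None:
    rows = []
    for p in particles:
        z, y, x = p.center
        rows.append(
            [x, y, z, p.kind, p.separation if p.separation is not None else np.nan,
             p.dumbbell_score]
        )
    pd.DataFrame(rows, columns=PICK_COLUMNS).to_csv(path, index=False)


def read_picks_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["x", "y", "z", "class"])
    return df


def write_point_list(path: str | Path, centers: np.ndarray) -> None:
    """IMOD-style point list: one 'x y z' line per point, Angstrom."""
    centers = np.atleast_2d(centers)
    with open(path, "w") as fh:
        for z, y, x in centers:
            fh.write(f"{x:.2f} {y:.2f} {z:.2f}\n")


def write_profile_csv(path: str | Path, profile: SAXSProfile) -> None:
    data = {"q": profile.q, "intensity": profile.intensity}
    if profile.sigma is not None:
        data["sigma"] = profile.sigma
    pd.DataFrame(data).to_csv(path, index=False)


def read_profile(path: str | Path) -> SAXSProfile:
    """(q, I[, sigma]) from CSV or whitespace-delimited text."""
    text = Path(path).read_text()
    sep = "," if "," in text.splitlines()[min(1, text.count('\n'))] else r"\s+"
    df = pd.read_csv(path, sep=sep, comment="#")
    if "q" not in df.columns:  # headerless table
        df = pd.read_csv(path, sep=sep, comment="#", header=None)
        df.columns = ["q", "intensity", "sigma"][: len(df.columns)]
    sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
    return SAXSProfile(q=df["q"].to_numpy(), intensity=df["intensity"].to_numpy(), sigma=sigma)


def read_star(path: str | Path) -> dict[str, pd.DataFrame]:
    """Minimal STAR parser: loop_ blocks to DataFrames keyed by block name."""
    blocks: dict[str, pd.DataFrame] = {}
    name = ""
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("data_"):
            name = line[5:]
            i += 1
        elif line == "loop_":
            i += 1
            cols = []
            while i < len(lines) and lines[i].strip().startswith("_"):
                cols.append(lines[i].strip().split()[0].lstrip("_"))
                i += 1
            rows = []
            while i < len(lines) and lines[i].strip() and not lines[i].startswith(("data_", "loop_")):
                rows.append(lines[i].split())
                i += 1
            df = pd.DataFrame(rows, columns=cols)
            for col in df.columns:
                try:
                    df[col] = pd.to_numeric(df[col])
                except (ValueError, TypeError):
                    pass
            blocks[name] = df
        else:
            i += 1
    return blocks


def read_obj_membrane(path: str | Path) -> MembraneModel:
    """OBJ-style text: 'v x y z' vertices and 'f i j k' 1-based faces."""
    vertices, faces = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            x, y, z = map(float, parts[1:4])
            vertices.append([z, y, x])
        elif parts[0] == "f":
            faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    return MembraneModel(
        kind="mesh", vertices=np.array(vertices), faces=np.array(faces, int)
    )
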