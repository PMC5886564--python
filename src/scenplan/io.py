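"""Readers and writers: ESRI ASCII grids, CSV tables, MARXAN-dialect inputs.

The MARXAN dialect is the classic four-table layout — ``pu.dat`` (id, cost,
status), ``spec.dat`` (id, target, spf, name), ``puvspr.dat`` (species, pu,
amount) and ``bound.dat`` (id1, id2, boundary; rows with id1 == id2 carry a
PU's exposed study-area edge) — plus a minimal ``input.dat`` holding the
BLM. Headers are required; comma and tab separators are both accepted.
Floats are written with full ``repr`` precision, so a write/read round trip
reproduces a :class:`~scenplan.reserve.SelectionProblem` bit-exactly and
the tables can be cross-checked against a real MARXAN installation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .landcover import ClassRegistry, LandCoverGrid
from .reserve import SelectionProblem
from .synthetic import SpeciesHabitatModel

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_registry",
    "read_registry",
    "write_landcover",
    "read_landcover",
    "write_associations",
    "read_associations",
    "write_marxan",
    "read_marxan",
    "load_config",
]


# ---------------------------------------------------------------------------
# rasters


def write_ascii_grid(
    path, array: np.ndarray, cell_size: float, nodata: int = -9999
) -> None:
    """ESRI ASCII grid; boolean arrays are written as 0/1."""
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.int64)
    rows, cols = arr.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cell_size!r}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, arr, fmt="%d")


def read_ascii_grid(path) -> tuple[np.ndarray, float]:
    """Returns (int array, cell_size)."""
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = val
        arr = np.loadtxt(fh, dtype=np.int64, ndmin=2)
    if arr.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape {arr.shape} does not match header in {path}")
    return arr, float(header["cellsize"])


def write_registry(path, registry: ClassRegistry) -> None:
    with open(path, "w") as fh:
        json.dump(registry.to_records(), fh, indent=1)


def read_registry(path) -> ClassRegistry:
    with open(path) as fh:
        return ClassRegistry.from_records(json.load(fh))


def write_landcover(directory, grid: LandCoverGrid, stem: str = "landcover") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(directory / f"{stem}.asc", grid.classes, grid.cell_size)
    write_registry(directory / f"{stem}_classes.json", grid.registry)


def read_landcover(directory, stem: str = "landcover") -> LandCoverGrid:
    directory = Path(directory)
    arr, cs = read_ascii_grid(directory / f"{stem}.asc")
    reg = read_registry(directory / f"{stem}_classes.json")
    return LandCoverGrid(arr, cs, reg)


# ---------------------------------------------------------------------------
# species tables


def write_associations(path, species: list[SpeciesHabitatModel], registry: ClassRegistry) -> None:
    """Species x land-cover association levels as CSV."""
    codes = [int(c) for c in registry.codes]
    rows = []
    for sp in species:
        row = {"species_id": sp.species_id, "atlas_block": sp.atlas_block}
        row.update({str(c): sp.level(c) for c in codes})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_associations(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# MARXAN dialect


def _fmt(x: float) -> str:
    return repr(float(x))


def write_marxan(problem: SelectionProblem, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    with open(directory / "pu.dat", "w") as fh:
        fh.write("id,cost,status\n")
        for pid, c, st in zip(problem.pu_ids, problem.cost, problem.status):
            fh.write(f"{int(pid)},{_fmt(c)},{int(st)}\n")

    with open(directory / "spec.dat", "w") as fh:
        fh.write("id,target,spf,name\n")
        for i, (name, t, f) in enumerate(
            zip(problem.species_ids, problem.targets, problem.spf), start=1
        ):
            fh.write(f"{i},{_fmt(t)},{_fmt(f)},{name}\n")

    with open(directory / "puvspr.dat", "w") as fh:
        fh.write("species,pu,amount\n")
        for pi, si in zip(*np.nonzero(problem.amounts)):
            fh.write(
                f"{int(si) + 1},{int(problem.pu_ids[pi])},{_fmt(problem.amounts[pi, si])}\n"
            )

    with open(directory / "bound.dat", "w") as fh:
        fh.write("id1,id2,boundary\n")
        for a, b, L in zip(problem.edge_a, problem.edge_b, problem.edge_len):
            i, j = int(problem.pu_ids[a]), int(problem.pu_ids[b])
            i, j = min(i, j), max(i, j)
            fh.write(f"{i},{j},{_fmt(L)}\n")
        for pid, L in zip(problem.pu_ids, problem.outer_len):
            if L != 0.0:
                fh.write(f"{int(pid)},{int(pid)},{_fmt(L)}\n")

    with open(directory / "input.dat", "w") as fh:
        fh.write(f"BLM {_fmt(problem.blm)}\n")


def _read_table(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    # round_trip: repr-printed floats must parse back bit-exactly
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_marxan(directory, blm: float | None = None) -> SelectionProblem:
    """Rebuild a :class:`SelectionProblem` from a MARXAN input directory."""
    directory = Path(directory)
    pu = _read_table(directory / "pu.dat")
    spec = _read_table(directory / "spec.dat").sort_values("id")
    puvspr = _read_table(directory / "puvspr.dat")
    bound = _read_table(directory / "bound.dat")

    pu_ids = pu["id"].to_numpy(dtype=np.int64)
    idx = {int(p): i for i, p in enumerate(pu_ids)}
    species_ids = [str(n) for n in spec["name"]]
    sp_index = {int(i): k for k, i in enumerate(spec["id"])}

    amounts = np.zeros((len(pu_ids), len(species_ids)))
    for _, row in puvspr.iterrows():
        amounts[idx[int(row["pu"])], sp_index[int(row["species"])]] = float(row["amount"])

    ea, eb, el = [], [], []
    outer = np.zeros(len(pu_ids))
    for _, row in bound.iterrows():
        i, j = int(row["id1"]), int(row["id2"])
        if i == j:
            outer[idx[i]] = float(row["boundary"])
        else:
            ea.append(idx[i])
            eb.append(idx[j])
            el.append(float(row["boundary"]))

    if blm is None:
        blm_val = 0.0
        input_dat = directory / "input.dat"
        if input_dat.exists():
            for line in input_dat.read_text().splitlines():
                parts = line.split()
                if len(parts) == 2 and parts[0].upper() == "BLM":
                    blm_val = float(parts[1])
    else:
        blm_val = blm

    return SelectionProblem(
        pu_ids=pu_ids,
        species_ids=species_ids,
        cost=pu["cost"].to_numpy(dtype=float),
        amounts=amounts,
        targets=spec["target"].to_numpy(dtype=float),
        spf=spec["spf"].to_numpy(dtype=float),
        status=pu["status"].to_numpy(dtype=np.int8),
        edge_a=np.array(ea, dtype=np.int64),
        edge_b=np.array(eb, dtype=np.int64),
        edge_len=np.array(el, dtype=float),
        outer_len=outer,
        blm=blm_val,
    )


def load_config(path) -> dict:
    """YAML or JSON configuration file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
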