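"""Readers and writers for the package's delimited-text formats.

Column schemas (all CSV, headers required):

* captures: ``shark_id, occasion, date, lat, lon, sex, fork_length_cm``
  (``occasion`` may be empty — occasions are then derived by clustering dates
  with gaps of at least 58 days; ``lat``/``lon`` may be replaced by planar
  ``x``/``y`` in km)
* effort:   ``cell_id, occasion, days``
* grid:     ``cell_id, x_center, y_center, active``
* detections: ``tag_id, time_days, receiver_id, receiver_x, receiver_y``

Readers reject malformed rows loudly; captures recorded in zero-effort
cell-occasions are a hard validation error.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import EncounterData
from .geometry import StudyGrid, project_coords, unproject_coords
from .telemetry import DetectionSeries

__all__ = [
    "read_captures",
    "read_effort",
    "write_captures",
    "write_effort",
    "read_detections",
    "write_detections",
    "write_fixture",
    "RunConfig",
]

logger = logging.getLogger("gridscr")

MIN_OCCASION_GAP_DAYS = 58

CAPTURE_COLUMNS = ["shark_id", "occasion", "date", "lat", "lon", "sex", "fork_length_cm"]


def derive_occasions(dates: pd.Series, min_gap_days: int = MIN_OCCASION_GAP_DAYS):
    """Cluster capture dates into occasions separated by >= min_gap_days."""
    d = pd.to_datetime(dates)
    uniq = np.sort(d.unique())
    occ_of_date = {}
    occ = -1
    prev = None
    starts = []
    for t in uniq:
        if prev is None or (t - prev) >= np.timedelta64(min_gap_days, "D"):
            occ += 1
            starts.append(t)
        occ_of_date[t] = occ
        prev = t
    return (
        d.map(occ_of_date).to_numpy(),
        [np.datetime_as_string(np.datetime64(s), unit="D") for s in starts],
    )


def read_effort(path, grid: StudyGrid):
    """Read the per-cell-per-occasion effort table -> ((J, K) array, None)."""
    df = pd.read_csv(path)
    required = {"cell_id", "occasion", "days"}
    if not required.issubset(df.columns):
        raise ValueError(f"effort file must have columns {sorted(required)}")
    if df.empty:
        raise ValueError("effort file is empty")
    K = int(df["occasion"].max())
    effort = np.zeros((grid.n_cells, K))
    for _, row in df.iterrows():
        j = int(row["cell_id"]) - 1
        k = int(row["occasion"]) - 1
        if not (0 <= j < grid.n_cells):
            raise ValueError(f"effort row references unknown cell_id {row['cell_id']}")
        if row["days"] < 0:
            raise ValueError("negative effort")
        effort[j, k] += float(row["days"])
    return effort, None


def read_captures(
    path,
    grid: StudyGrid,
    effort: np.ndarray,
    occasion_dates=None,
) -> EncounterData:
    """Load a capture table, project, assign cells and binarize.

    Repeat captures of an individual in the same cell and occasion collapse
    to a single binary encounter.  Captures outside the active grid are
    dropped with a warning; captures in zero-effort cell-occasions raise.
    """
    df = pd.read_csv(path, dtype={"shark_id": str})
    if df.empty:
        raise ValueError("capture file is empty")
    has_latlon = {"lat", "lon"}.issubset(df.columns)
    has_xy = {"x", "y"}.issubset(df.columns)
    if not (has_latlon or has_xy):
        raise ValueError("capture file needs lat/lon or x/y columns")
    if "shark_id" not in df.columns:
        raise ValueError("capture file needs a shark_id column")

    if has_latlon:
        if grid.ref_latlon is None:
            raise ValueError("grid has no reference lat/lon to project captures")
        x, y = project_coords(
            df["lat"].to_numpy(float), df["lon"].to_numpy(float), *grid.ref_latlon
        )
    else:
        x = df["x"].to_numpy(float)
        y = df["y"].to_numpy(float)

    cells = grid.assign(x, y)
    off = cells < 0
    if off.any():
        warnings.warn(
            f"dropping {int(off.sum())} capture(s) outside the active grid "
            f"(rows {df.index[off].tolist()})",
            stacklevel=2,
        )
        logger.warning("off-grid captures dropped: rows %s", df.index[off].tolist())
        df = df[~off].reset_index(drop=True)
        cells = cells[~off]
    if df.empty:
        raise ValueError("no captures remain after off-grid filtering")

    K = effort.shape[1]
    if "occasion" in df.columns and df["occasion"].notna().all():
        occ = df["occasion"].astype(int).to_numpy() - 1
        if occ.min() < 0 or occ.max() >= K:
            raise ValueError("occasion index outside the effort table's range")
    else:
        if "date" not in df.columns:
            raise ValueError("need either an occasion column or capture dates")
        occ, starts = derive_occasions(df["date"])
        if occ.max() >= K:
            raise ValueError(
                f"derived {occ.max() + 1} occasions but effort table has {K}"
            )
        if occasion_dates is None:
            occasion_dates = starts

    bad = effort[cells, occ] <= 0
    if bad.any():
        rows = df.index[bad].tolist()
        raise ValueError(
            "captures recorded in zero-effort cell-occasions (the encounter "
            f"probability there is necessarily 0): rows {rows}"
        )

    ids = df["shark_id"].astype(str).tolist()
    uniq = list(dict.fromkeys(ids))
    row_of = {u: i for i, u in enumerate(uniq)}
    n = len(uniq)
    y = np.zeros((n, grid.n_cells, K), dtype=np.uint8)
    sex = np.full(n, -1, dtype=np.int8)
    size = np.full(n, np.nan)
    if "sex" in df.columns:
        sexcol = df["sex"].astype(str).str.strip().str.upper()
    else:
        sexcol = pd.Series([""] * len(df))
    sizecol = df["fork_length_cm"] if "fork_length_cm" in df.columns else pd.Series(
        [np.nan] * len(df)
    )
    unknown_sex = 0
    for r in range(len(df)):
        i = row_of[ids[r]]
        y[i, cells[r], occ[r]] = 1
        sv = sexcol.iloc[r]
        if sv in ("F", "M"):
            code = 0 if sv == "F" else 1
            if sex[i] == -1:
                sex[i] = code
        elif sv not in ("", "NAN", "NA", "NONE"):
            unknown_sex += 1
        fl = sizecol.iloc[r]
        if np.isfinite(fl) and not np.isfinite(size[i]):
            size[i] = float(fl)
    if unknown_sex:
        warnings.warn(
            f"{unknown_sex} capture row(s) with unknown sex code treated as missing",
            stacklevel=2,
        )
    return EncounterData(
        y=y, effort=effort, sex=sex, size=size, ids=uniq, occasion_dates=occasion_dates
    )


def write_effort(path, effort: np.ndarray, sparse: bool = True) -> None:
    rows = []
    J, K = effort.shape
    for j in range(J):
        for k in range(K):
            if sparse and effort[j, k] == 0:
                continue
            rows.append({"cell_id": j + 1, "occasion": k + 1, "days": effort[j, k]})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_captures(path, data: EncounterData, grid: StudyGrid) -> None:
    """Write one row per binary encounter, positioned at the cell center."""
    rows = []
    dates = data.occasion_dates
    for i in range(data.n_individuals):
        jj, kk = np.nonzero(data.y[i])
        for j, k in zip(jj, kk):
            cx, cy = grid.cell_centers[j]
            row = {
                "shark_id": data.ids[i],
                "occasion": k + 1,
                "date": dates[k] if dates is not None else "",
                "sex": {0: "F", 1: "M", -1: ""}[int(data.sex[i])],
                "fork_length_cm": data.size[i] if np.isfinite(data.size[i]) else "",
            }
            if grid.ref_latlon is not None:
                lat, lon = unproject_coords(cx, cy, *grid.ref_latlon)
                row["lat"], row["lon"] = lat, lon
            else:
                row["x"], row["y"] = cx, cy
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_detections(path, series_list) -> None:
    rows = []
    for s in series_list:
        pos = s.receiver_positions
        for t, r in zip(s.times, s.receiver_ids):
            rx, ry = pos[int(r)] if not isinstance(r, str) else pos[r]
            rows.append(
                {
                    "tag_id": s.tag_id,
                    "time_days": t,
                    "receiver_id": r,
                    "receiver_x": rx,
                    "receiver_y": ry,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_detections(path) -> list:
    df = pd.read_csv(path)
    required = {"tag_id", "time_days", "receiver_id", "receiver_x", "receiver_y"}
    if not required.issubset(df.columns):
        raise ValueError(f"detections file must have columns {sorted(required)}")
    out = []
    for tag, g in df.groupby("tag_id", sort=True):
        g = g.sort_values("time_days")
        positions = {}
        for _, row in g.iterrows():
            positions[row["receiver_id"]] = (row["receiver_x"], row["receiver_y"])
        out.append(
            DetectionSeries(
                tag_id=str(tag),
                times=g["time_days"].to_numpy(float),
                receiver_ids=g["receiver_id"].to_numpy(),
                receiver_positions=positions,
            )
        )
    return out


def write_fixture(outdir, fixture) -> dict:
    """Write a simulated study bundle (grid/effort/captures) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "grid": outdir / "grid.csv",
        "effort": outdir / "effort.csv",
        "captures": outdir / "captures.csv",
    }
    fixture.grid.to_csv(paths["grid"])
    write_effort(paths["effort"], fixture.cfg.effort)
    write_captures(paths["captures"], fixture.data, fixture.grid)
    truth = {
        "N_true": fixture.truth["N_true"],
        "params": {
            k: float(v)
            for k, v in vars(fixture.truth["params"]).items()
        },
        "n_observed": fixture.data.n_individuals,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return {k: str(v) for k, v in paths.items()}


@dataclass
class RunConfig:
    """Structured run configuration; CLI flags override file values.

    All defaults are materialized before saving so a written config fully
    reproduces the run.
    """

    captures: str | None = None
    effort: str | None = None
    grid: str | None = None
    detections: str | None = None
    outdir: str = "gridscr_out"
    effects: tuple = ("effort", "sex", "size")
    sex_sigma: bool = True
    n_iter: int = 12000
    n_burn: int = 2000
    n_chains: int = 3
    M: int | None = None
    thin: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "effects" in raw:
            raw["effects"] = tuple(raw["effects"])
        return cls(**raw)

    def validate_paths(self, need=("captures", "effort", "grid")) -> None:
        for key in need:
            val = getattr(self, key)
            if val is None or not Path(val).exists():
                raise FileNotFoundError(f"config path {key!r} missing: {val}")

    def to_yaml(self, path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(self).items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def digest(self) -> str:
        payload = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v for k, v in vars(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
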