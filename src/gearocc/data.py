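"""Site tables, detection histories and design matrices.

A *site* is one simultaneous deployment of a baited chevron trap and an
outward-looking video camera.  The chevron trap yields a single replicate
sample (the catch); the camera yields 41 one-second snapshots which can be
treated either *pooled* (a single binary sample: any snapshot positive) or
*disaggregated* (41 replicate binary samples).

Tables are plain CSV with one row per site.  Continuous covariates are
centred and scaled before model fitting; squared terms are formed from the
standardized base covariate and then re-standardized themselves, so
coefficients are directly comparable across covariates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_SNAPSHOTS = 41

LMH = ("l", "m", "h")
CDIR_LEVELS = ("toward", "perpendicular", "away")
LOWHIGH = ("low", "high")
YEARS = (2010, 2011)

#: column order of the occupancy / abundance design matrix
OCC_COLUMNS = (
    "yr2011", "depth", "depth2", "lat", "lat2", "temp", "temp2",
    "livebot.l", "livebot.m", "livebot.h",
    "hardsub.l", "hardsub.m", "hardsub.h",
    "relief.m", "relief.h",
)
#: column order of the chevron-trap detection design matrix
CHEV_COLUMNS = ("temp", "temp2", "soak", "cdir.p", "cdir.a", "cspeed")
#: column order of the camera-trap detection design matrix
CAM_COLUMNS = ("turb.h", "cdir.p", "cdir.a", "cspeed")

REQUIRED_FIELDS = (
    "site_id", "year", "chevron_count", "camera_snapshot_hits",
    "depth_m", "lat_deg", "temp_c", "livebot", "hardsub", "relief",
    "soak_min", "cdir", "cspeed", "turb",
)


class SiteTableError(ValueError):
    """Raised when a site table fails validation."""


@dataclass
class SiteRecord:
    """One sampling event: two-gear detections plus covariates."""

    site_id: str
    year: int
    chevron_count: int
    camera_snapshot_hits: int
    depth_m: float
    lat_deg: float
    temp_c: float
    livebot: str
    hardsub: str
    relief: str
    soak_min: float
    cdir: str
    cspeed: str
    turb: str

    def validate(self) -> None:
        if self.year not in YEARS:
            raise SiteTableError(f"year must be one of {YEARS}, got {self.year}")
        if self.chevron_count < 0:
            raise SiteTableError("chevron_count must be non-negative")
        if not 0 <= self.camera_snapshot_hits <= N_SNAPSHOTS:
            raise SiteTableError(
                f"camera_snapshot_hits must lie in [0, {N_SNAPSHOTS}], "
                f"got {self.camera_snapshot_hits}"
            )
        if self.depth_m <= 0:
            raise SiteTableError("depth_m must be positive")
        if self.soak_min <= 0:
            raise SiteTableError("soak_min must be positive")
        for name, value, levels in (
            ("livebot", self.livebot, LMH),
            ("hardsub", self.hardsub, LMH),
            ("relief", self.relief, LMH),
            ("cdir", self.cdir, CDIR_LEVELS),
            ("cspeed", self.cspeed, LOWHIGH),
            ("turb", self.turb, LOWHIGH),
        ):
            if value not in levels:
                raise SiteTableError(
                    f"{name} must be one of {levels}, got {value!r}"
                )


@dataclass
class DetectionData:
    """Detection histories for both gears.

    ``y`` has shape (S, 2): column 0 is the chevron trap, column 1 the
    camera.  ``k`` gives the replicate count per gear: the chevron trap is
    always a single replicate; the camera contributes one replicate when
    pooled and 41 when disaggregated.
    """

    mode: str                      # "pooled" | "disaggregated"
    y: np.ndarray                  # (S, 2) int
    k: np.ndarray                  # (2,) int

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def any_detection(self) -> np.ndarray:
        return (self.y > 0).any(axis=1)

    def validate(self) -> None:
        if self.mode not in ("pooled", "disaggregated"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if np.any(self.y < 0) or np.any(self.y > self.k[None, :]):
            raise ValueError("detection counts must satisfy 0 <= y[i,j] <= k[j]")


@dataclass
class DesignMatrices:
    """Standardized design matrices for the three sub-models.

    ``scaling`` maps each standardized column name to its (mean, sd) on the
    scale it was standardized from, so that predictions on raw covariate
    grids can reuse the training transformation exactly.
    """

    X_occ: np.ndarray              # (S, 15)
    X_chev: np.ndarray             # (S, 6)
    X_cam: np.ndarray              # (S, 4)
    scaling: dict[str, tuple[float, float]]
    square_standardized: bool = True

    @property
    def n_sites(self) -> int:
        return self.X_occ.shape[0]

    def save_scaling(self, path: str | Path) -> None:
        payload = {
            "scaling": {k: list(v) for k, v in self.scaling.items()},
            "square_standardized": self.square_standardized,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def load_scaling(path: str | Path) -> tuple[dict[str, tuple[float, float]], bool]:
        payload = json.loads(Path(path).read_text())
        scaling = {k: (float(v[0]), float(v[1])) for k, v in payload["scaling"].items()}
        return scaling, bool(payload["square_standardized"])


def _coerce_record(row: dict, index: int) -> SiteRecord:
    try:
        rec = SiteRecord(
            site_id=str(row["site_id"]),
            year=int(row["year"]),
            chevron_count=int(row["chevron_count"]),
            camera_snapshot_hits=int(row["camera_snapshot_hits"]),
            depth_m=float(row["depth_m"]),
            lat_deg=float(row["lat_deg"]),
            temp_c=float(row["temp_c"]),
            livebot=str(row["livebot"]).strip(),
            hardsub=str(row["hardsub"]).strip(),
            relief=str(row["relief"]).strip(),
            soak_min=float(row["soak_min"]),
            cdir=str(row["cdir"]).strip(),
            cspeed=str(row["cspeed"]).strip(),
            turb=str(row["turb"]).strip(),
        )
        rec.validate()
    except (KeyError, TypeError, ValueError) as exc:
        raise SiteTableError(f"row {index}: {exc}") from exc
    return rec


def read_site_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str = ",",
) -> list[SiteRecord]:
    """Read and validate a site table from delimited text.

    ``column_map`` maps required field names to the headers actually used in
    the file, allowing arbitrary source headers.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in REQUIRED_FIELDS if c not in df.columns]
    if missing:
        raise SiteTableError(f"missing required column(s): {', '.join(missing)}")
    return [_coerce_record(row, i) for i, row in enumerate(df.to_dict("records"))]


def write_site_table(records: Sequence[SiteRecord], path: str | Path) -> None:
    """Write records as CSV in the dialect ``read_site_table`` reads."""
    df = pd.DataFrame([asdict(r) for r in records])
    df = df[list(REQUIRED_FIELDS)]
    df.to_csv(path, index=False, float_format="%.17g")


def records_to_frame(records: Sequence[SiteRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def build_detection_data(records: Sequence[SiteRecord], mode: str) -> DetectionData:
    """Assemble per-gear detection histories.

    Pooled: both gears reduce to a binary detected/not sample (k = 1 each).
    Disaggregated: the camera keeps its 41 snapshot replicates, so y for the
    camera is the number of positive snapshots with k = 41.
    """
    if mode not in ("pooled", "disaggregated"):
        raise ValueError(f"mode must be 'pooled' or 'disaggregated', got {mode!r}")
    chev = np.array([r.chevron_count for r in records], dtype=np.int64)
    cam = np.array([r.camera_snapshot_hits for r in records], dtype=np.int64)
    if mode == "pooled":
        y = np.stack([(chev > 0).astype(np.int64), (cam > 0).astype(np.int64)], axis=1)
        k = np.array([1, 1], dtype=np.int64)
    else:
        y = np.stack([(chev > 0).astype(np.int64), cam], axis=1)
        k = np.array([1, N_SNAPSHOTS], dtype=np.int64)
    data = DetectionData(mode=mode, y=y, k=k)
    data.validate()
    return data


def _standardize(x: np.ndarray, name: str, scaling: dict) -> np.ndarray:
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=0))
    if sd == 0.0:
        raise SiteTableError(f"covariate {name!r} has zero variance; cannot standardize")
    scaling[name] = (mu, sd)
    return (x - mu) / sd


def _quadratic(z_base: np.ndarray, raw: np.ndarray, name: str, scaling: dict,
               square_standardized: bool) -> np.ndarray:
    sq = z_base ** 2 if square_standardized else raw ** 2
    return _standardize(sq, name, scaling)


def build_design_matrices(
    records: Sequence[SiteRecord],
    square_standardized: bool = True,
) -> DesignMatrices:
    """Build the standardized occupancy/abundance, chevron and camera design
    matrices.

    Continuous covariates are centred on their sample mean and scaled by one
    sample standard deviation.  With ``square_standardized`` (default) the
    quadratic terms square the standardized covariate before being
    standardized themselves; the alternative squares the raw covariate first.
    """
    if len(records) < 2:
        raise SiteTableError("need at least 2 records to standardize covariates")
    df = records_to_frame(records)
    scaling: dict[str, tuple[float, float]] = {}

    depth = _standardize(df["depth_m"].to_numpy(float), "depth", scaling)
    lat = _standardize(df["lat_deg"].to_numpy(float), "lat", scaling)
    temp = _standardize(df["temp_c"].to_numpy(float), "temp", scaling)
    soak = _standardize(df["soak_min"].to_numpy(float), "soak", scaling)
    depth2 = _quadratic(depth, df["depth_m"].to_numpy(float), "depth2", scaling,
                        square_standardized)
    lat2 = _quadratic(lat, df["lat_deg"].to_numpy(float), "lat2", scaling,
                      square_standardized)
    temp2 = _quadratic(temp, df["temp_c"].to_numpy(float), "temp2", scaling,
                       square_standardized)

    def dummy(col: str, level: str) -> np.ndarray:
        return (df[col] == level).to_numpy(float)

    X_occ = np.column_stack([
        (df["year"] == 2011).to_numpy(float),
        depth, depth2, lat, lat2, temp, temp2,
        dummy("livebot", "l"), dummy("livebot", "m"), dummy("livebot", "h"),
        dummy("hardsub", "l"), dummy("hardsub", "m"), dummy("hardsub", "h"),
        dummy("relief", "m"), dummy("relief", "h"),
    ])
    X_chev = np.column_stack([
        temp, temp2, soak,
        dummy("cdir", "perpendicular"), dummy("cdir", "away"),
        dummy("cspeed", "high"),
    ])
    X_cam = np.column_stack([
        dummy("turb", "high"),
        dummy("cdir", "perpendicular"), dummy("cdir", "away"),
        dummy("cspeed", "high"),
    ])
    return DesignMatrices(X_occ=X_occ, X_chev=X_chev, X_cam=X_cam,
                          scaling=scaling, square_standardized=square_standardized)


def standardize_grid(
    raw: np.ndarray,
    name: str,
    scaling: dict[str, tuple[float, float]],
    square_standardized: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize a raw covariate grid with stored training scaling.

    Returns the standardized base column and its standardized quadratic
    partner, following the same pipeline as training.
    """
    mu, sd = scaling[name]
    z = (np.asarray(raw, dtype=float) - mu) / sd
    mu2, sd2 = scaling[name + "2"]
    sq = z ** 2 if square_standardized else np.asarray(raw, dtype=float) ** 2
    return z, (sq - mu2) / sd2


def destandardize(z: np.ndarray, name: str,
                  scaling: dict[str, tuple[float, float]]) -> np.ndarray:
    mu, sd = scaling[name]
    return np.asarray(z, dtype=float) * sd + mu


def naive_occupancy(records: Sequence[SiteRecord], gear: str) -> float:
    """Fraction of sites with at least one detection by the stated gear,
    uncorrected for imperfect detection."""
    if len(records) == 0:
        raise SiteTableError("naive occupancy of an empty table is undefined")
    if gear == "chevron":
        hits = [r.chevron_count > 0 for r in records]
    elif gear == "camera":
        hits = [r.camera_snapshot_hits > 0 for r in records]
    else:
        raise ValueError(f"gear must be 'chevron' or 'camera', got {gear!r}")
    return float(np.mean(hits))
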