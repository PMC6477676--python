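"""File formats: spot tables, annotations, curves, sensorgrams, results.

Conventions (enforced by the readers): coordinates in µm with the
origin at the lower-left, intensities in arbitrary units >= 0,
concentrations serialised in nM, responses in RU. Spot tables are CSV
with header ``id,x_um,y_um,channel,intensity``; annotations are JSON
with ``outline`` (list of [x, y]), ``anterior`` and ``posterior``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from stau_rnaloc.annotation import OocyteAnnotation
from stau_rnaloc.binding import Sensorgram
from stau_rnaloc.errors import InvalidParameterError

SPOT_COLUMNS = ["id", "x_um", "y_um", "channel", "intensity"]
CURVE_COLUMNS = ["conc_nM", "response_RU"]
SENSORGRAM_COLUMNS = ["time_s", "response_RU", "conc_nM"]


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidParameterError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def _require_numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            rows = (bad[:5] + 2).tolist()  # +2: header line and 1-based rows
            raise InvalidParameterError(
                f"{path}: non-numeric values in column {col!r} at file row(s) {rows}"
            )
        if coerced.isna().any():
            rows = (df.index[coerced.isna()][:5] + 2).tolist()
            raise InvalidParameterError(
                f"{path}: empty values in column {col!r} at file row(s) {rows}"
            )
        df[col] = coerced
    return df


def read_spot_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a spot-table CSV (µm positions, a.u. intensity)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, SPOT_COLUMNS, path)
    df = _require_numeric(df, ["id", "x_um", "y_um", "intensity"], path)
    if not np.all(np.isfinite(df[["x_um", "y_um"]].to_numpy())):
        raise InvalidParameterError(f"{path}: non-finite coordinates")
    if (df["intensity"] < 0).any():
        rows = (df.index[df["intensity"] < 0][:5] + 2).tolist()
        raise InvalidParameterError(f"{path}: negative intensities at row(s) {rows}")
    for channel, grp in df.groupby("channel"):
        dup = grp["id"][grp["id"].duplicated()]
        if len(dup):
            raise InvalidParameterError(
                f"{path}: duplicate ids within channel {channel!r}: "
                f"{dup.unique()[:5].tolist()}"
            )
    df["id"] = df["id"].astype(int)
    return df[SPOT_COLUMNS]


def write_spot_table(df: pd.DataFrame, path: str | Path) -> None:
    df[SPOT_COLUMNS].to_csv(path, index=False)


def read_annotation(path: str | Path) -> OocyteAnnotation:
    return OocyteAnnotation.load(path)


def write_annotation(annot: OocyteAnnotation, path: str | Path) -> None:
    annot.save(path)


def read_curve(path: str | Path) -> pd.DataFrame:
    """Read a steady-state curve CSV ``conc_nM,response_RU``."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, CURVE_COLUMNS, path)
    df = _require_numeric(df, CURVE_COLUMNS, path)
    if (df["conc_nM"] <= 0).any():
        raise InvalidParameterError(f"{path}: concentrations must be positive")
    return df[CURVE_COLUMNS]


def write_curve(df: pd.DataFrame, path: str | Path) -> None:
    df[CURVE_COLUMNS].to_csv(path, index=False)


def read_sensorgrams(path: str | Path, t_assoc: float) -> list[Sensorgram]:
    """Read ``time_s,response_RU,conc_nM`` rows into per-concentration series."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, SENSORGRAM_COLUMNS, path)
    df = _require_numeric(df, SENSORGRAM_COLUMNS, path)
    out = []
    for conc, grp in df.groupby("conc_nM"):
        grp = grp.sort_values("time_s")
        out.append(
            Sensorgram(
                time_s=grp["time_s"].to_numpy(),
                response=grp["response_RU"].to_numpy(),
                conc_nm=float(conc),
                t_assoc=t_assoc,
            )
        )
    return out


def write_sensorgrams(sensorgrams, path: str | Path) -> None:
    pd.concat([s.to_frame() for s in sensorgrams], ignore_index=True).to_csv(
        path, index=False
    )


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a single-plane image as TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(image))


def read_image(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, matrix, delimiter=",")


def read_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder, sort_keys=True))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
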