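"""File formats: PLY / XYZ point clouds, landmark JSON, CSV tables.

Point clouds are stored as PLY (ascii or binary little-endian) with float
``x, y, z`` vertex properties in centimetres plus an optional integer
``view`` property carrying the capture-view tag, or as plain whitespace XYZ
text.  The PLY reader/writer here is intentionally minimal: vertex-only
clouds with scalar properties, which is all this pipeline produces or
consumes.

Tape series travel as ``station_cm,circumference_cm`` CSV, landmarks as
``{"wrist": [x,y,z], "axilla": [x,y,z]}`` JSON, and visit/pair tables as
flat CSV via pandas.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .geometry import CircumferenceSeries, VolumeResult
from .scan_pipeline import LimbScan
from .screening import Visit

__all__ = [
    "write_ply",
    "read_ply",
    "write_xyz",
    "read_xyz",
    "write_landmarks",
    "read_landmarks",
    "read_scan",
    "write_series_csv",
    "read_series_csv",
    "write_volume_json",
    "read_volume_json",
    "load_visits_csv",
    "load_pairs_csv",
]

_PLY_DTYPES = {
    "float": "<f4",
    "float32": "<f4",
    "double": "<f8",
    "float64": "<f8",
    "char": "i1",
    "int8": "i1",
    "uchar": "u1",
    "uint8": "u1",
    "short": "<i2",
    "int16": "<i2",
    "ushort": "<u2",
    "uint16": "<u2",
    "int": "<i4",
    "int32": "<i4",
    "uint": "<u4",
    "uint32": "<u4",
}


def write_ply(
    path,
    points: np.ndarray,
    view_labels: np.ndarray | None = None,
    binary: bool = False,
) -> None:
    """Write a vertex-only PLY cloud (cm), optionally with a ``view`` tag."""
    pts = np.asarray(points, dtype="<f4")
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidParameterError("points must be (N, 3)")
    fields = [("x", "<f4"), ("y", "<f4"), ("z", "<f4")]
    if view_labels is not None:
        fields.append(("view", "<i4"))
    rec = np.empty(pts.shape[0], dtype=fields)
    rec["x"], rec["y"], rec["z"] = pts[:, 0], pts[:, 1], pts[:, 2]
    if view_labels is not None:
        rec["view"] = np.asarray(view_labels, dtype="<i4")

    fmt = "binary_little_endian" if binary else "ascii"
    header = [
        "ply",
        f"format {fmt} 1.0",
        f"element vertex {pts.shape[0]}",
        "property float x",
        "property float y",
        "property float z",
    ]
    if view_labels is not None:
        header.append("property int view")
    header.append("end_header")

    path = Path(path)
    if binary:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            fh.write(rec.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            for row in rec:
                fh.write(
                    " ".join(
                        f"{row[name]:.6f}" if dt.startswith("<f") else str(int(row[name]))
                        for name, dt in fields
                    )
                    + "\n"
                )


def read_ply(path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read a vertex-only PLY cloud; returns ``(points, view_labels_or_None)``.

    Supports ascii and binary little-endian files with scalar vertex
    properties; ``x, y, z`` are required.
    """
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise InvalidParameterError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise InvalidParameterError(f"{path}: truncated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise InvalidParameterError("list properties are not supported")
                if tokens[1] not in _PLY_DTYPES:
                    raise InvalidParameterError(f"unsupported PLY type {tokens[1]!r}")
                props.append((tokens[2], _PLY_DTYPES[tokens[1]]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise InvalidParameterError(f"unsupported PLY format {fmt!r}")
        if n_vertex is None or not props:
            raise InvalidParameterError(f"{path}: no vertex element")
        dtype = np.dtype(props)
        if fmt == "ascii":
            data = np.array([fh.readline().split() for _ in range(n_vertex)])
            rec = np.empty(n_vertex, dtype=dtype)
            for idx, (name, dt) in enumerate(props):
                rec[name] = data[:, idx].astype(np.dtype(dt))
        else:
            rec = np.frombuffer(fh.read(dtype.itemsize * n_vertex), dtype=dtype)

    names = rec.dtype.names
    for required in ("x", "y", "z"):
        if required not in names:
            raise InvalidParameterError(f"{path}: missing vertex property {required}")
    pts = np.column_stack(
        [rec["x"].astype(float), rec["y"].astype(float), rec["z"].astype(float)]
    )
    views = rec["view"].astype(int) if "view" in names else None
    return pts, views


def write_xyz(path, points: np.ndarray) -> None:
    """Write a cloud as plain whitespace-separated XYZ text."""
    np.savetxt(path, np.asarray(points, dtype=float), fmt="%.6f")


def read_xyz(path) -> np.ndarray:
    pts = np.loadtxt(path, dtype=float)
    return np.atleast_2d(pts)[:, :3]


def write_landmarks(path, wrist, axilla) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "wrist": [float(v) for v in np.asarray(wrist).reshape(3)],
                "axilla": [float(v) for v in np.asarray(axilla).reshape(3)],
            },
            fh,
            indent=2,
        )


def read_landmarks(path) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        data = json.load(fh)
    return np.asarray(data["wrist"], float), np.asarray(data["axilla"], float)


def read_scan(cloud_path, landmarks_path, patient_ref: str | None = None) -> LimbScan:
    """Assemble a :class:`LimbScan` from a cloud file plus a landmark file."""
    cloud_path = Path(cloud_path)
    if cloud_path.suffix.lower() == ".ply":
        points, views = read_ply(cloud_path)
    else:
        points, views = read_xyz(cloud_path), None
    if views is None:
        views = np.full(points.shape[0], -1, dtype=int)
    wrist, axilla = read_landmarks(landmarks_path)
    return LimbScan(
        points=points,
        view_labels=views,
        wrist_landmark=wrist,
        axilla_landmark=axilla,
        patient_ref=patient_ref,
    )


def write_series_csv(path, series: CircumferenceSeries) -> None:
    pd.DataFrame(
        {"station_cm": series.stations, "circumference_cm": series.circumferences}
    ).to_csv(path, index=False)


def read_series_csv(path, side=None) -> CircumferenceSeries:
    df = pd.read_csv(path)
    for col in ("station_cm", "circumference_cm"):
        if col not in df.columns:
            raise InvalidParameterError(f"{path}: missing column {col!r}")
    return CircumferenceSeries(
        stations=df["station_cm"].to_numpy(float),
        circumferences=df["circumference_cm"].to_numpy(float),
        side=side,
    )


def write_volume_json(path, result: VolumeResult) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)


def read_volume_json(path) -> VolumeResult:
    with open(path) as fh:
        data = json.load(fh)
    if data["quality"] == "low_quality":
        return VolumeResult.low_quality(data["method"], data.get("reasons", ()))
    return VolumeResult(
        total_volume_ml=float(data["total_volume_ml"]),
        segment_volumes_ml=tuple(data["segment_volumes_ml"]),
        method=data["method"],
        quality=data["quality"],
    )


_VISIT_COLUMNS = (
    "patient_code",
    "weeks_post_op",
    "affected_side",
    "side",
    "method",
    "total_volume_ml",
    "quality",
)


def load_visits_csv(path) -> dict[str, list[Visit]]:
    """Load a long-format visit table into per-patient visit lists.

    One row per (patient, visit, side, method); rows with
    ``quality = low_quality`` may leave ``total_volume_ml`` empty.
    """
    df = pd.read_csv(path)
    for col in _VISIT_COLUMNS:
        if col not in df.columns:
            raise InvalidParameterError(f"{path}: missing column {col!r}")
    cohort: dict[str, list[Visit]] = {}
    for (code, weeks), group in df.groupby(["patient_code", "weeks_post_op"], sort=True):
        volumes = {}
        affected = str(group["affected_side"].iloc[0])
        for _, row in group.iterrows():
            quality = str(row["quality"])
            if quality == "ok":
                vr = VolumeResult(
                    total_volume_ml=float(row["total_volume_ml"]),
                    segment_volumes_ml=(),
                    method=str(row["method"]),
                )
            else:
                vr = VolumeResult.low_quality(str(row["method"]), ("from-file",))
            volumes[(str(row["side"]), str(row["method"]))] = vr
        cohort.setdefault(str(code), []).append(
            Visit(
                patient_code=str(code),
                weeks_post_op=float(weeks),
                affected_side=affected,
                volumes=volumes,
            )
        )
    for visits in cohort.values():
        visits.sort(key=lambda v: v.weeks_post_op)
    return cohort


def load_pairs_csv(path):
    """Load a ``patient_code,visit,operator,tape_ml,scan_ml`` pair table."""
    from .agreement import PairedMeasurements

    df = pd.read_csv(path)
    for col in ("tape_ml", "scan_ml"):
        if col not in df.columns:
            raise InvalidParameterError(f"{path}: missing column {col!r}")
    operators = (
        tuple(str(o) for o in df["operator"]) if "operator" in df.columns else None
    )
    return PairedMeasurements(
        tape_ml=df["tape_ml"].to_numpy(float),
        scan_ml=df["scan_ml"].to_numpy(float),
        operators=operators,
    )
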