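"""CSV dialects and round-trip plumbing for time courses and titrations.

All files are UTF-8, "." decimal, "," separator.  Metadata rides in
commented header lines of the form ``# key=value`` before the column header.
Column layouts by kind:

* state trajectory:       ``time_s,A_uM,AT_uM,AS_uM,T_uM,S_uM``
* anisotropy trace:       ``time_s,anisotropy``
* bound concentration:    ``time_s,bound_uM``
* titration:              ``g_actin_uM,anisotropy`` (needs ``# abp_total_uM=``)

Floats are written at full precision (repr round-trip), so
``read(write(x)) == x`` to the last bit.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .anisotropy import AnisotropyCalibration
from .errors import ValidationError
from .fitting import TitrationDataset
from .kinetics import (
    STATE_COLUMNS,
    ExchangeExperiment,
    ScenarioModifiers,
    TimeCourse,
)

__all__ = [
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_titration_csv",
    "write_titration_csv",
    "calibration_from_meta",
    "experiment_from_timecourse",
]

_STATE_HEADER = ["time_s"] + [f"{c}_uM" for c in STATE_COLUMNS]
_KIND_COLUMNS = {
    "state": _STATE_HEADER,
    "anisotropy": ["time_s", "anisotropy"],
    "bound_concentration": ["time_s", "bound_uM"],
}
_COLUMNS_KIND = {tuple(v): k for k, v in _KIND_COLUMNS.items()}


def _fmt(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _parse_meta_value(raw: str):
    try:
        f = float(raw)
    except ValueError:
        return raw
    if raw.strip().lstrip("+-").isdigit():
        return int(raw)
    return f


def _read_commented_header(path: Path) -> tuple[dict, int]:
    """Metadata dict and the 0-based line index of the column header."""
    meta: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh):
            stripped = line.strip()
            if not stripped.startswith("#"):
                return meta, lineno
            body = stripped.lstrip("#").strip()
            if not body:
                continue
            if "=" not in body:
                raise ValidationError(
                    f"{path}:{lineno + 1}: malformed metadata line {stripped!r} "
                    "(expected '# key=value')"
                )
            key, _, raw = body.partition("=")
            meta[key.strip()] = _parse_meta_value(raw.strip())
    raise ValidationError(f"{path}: no column header found after metadata")


def write_timecourse_csv(tc: TimeCourse, path: Union[str, Path]) -> Path:
    """Write a TimeCourse in its kind's dialect; returns the path."""
    path = Path(path)
    cols = _KIND_COLUMNS[tc.kind]
    buf = _io.StringIO()
    meta = {"kind": tc.kind, **tc.meta}
    for k, v in meta.items():
        buf.write(f"# {k}={_fmt(v)}\n")
    buf.write(",".join(cols) + "\n")
    data = tc.values if tc.kind == "state" else tc.values[:, None]
    for t, row in zip(tc.times, data):
        buf.write(",".join(repr(float(x)) for x in (t, *row)) + "\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_timecourse_csv(path: Union[str, Path]) -> TimeCourse:
    """Read a TimeCourse written by :func:`write_timecourse_csv`.

    The kind is taken from the ``# kind=`` metadata when present, otherwise
    inferred from the column header.  Non-monotone time and missing columns
    are rejected with line-numbered messages.
    """
    path = Path(path)
    meta, header_line = _read_commented_header(path)
    df = pd.read_csv(path, skiprows=header_line, float_precision="round_trip")
    cols = tuple(df.columns)
    kind = meta.pop("kind", None)
    if kind is None:
        kind = _COLUMNS_KIND.get(cols)
        if kind is None:
            raise ValidationError(
                f"{path}:{header_line + 1}: unrecognized column header {cols!r}"
            )
    expected = _KIND_COLUMNS.get(kind)
    if expected is None:
        raise ValidationError(f"{path}: unknown kind {kind!r} in metadata")
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}:{header_line + 1}: missing column(s) {missing} for kind "
            f"{kind!r}"
        )
    times = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"{path}:{header_line + 2 + int(bad[0]) + 1}: time_s not strictly "
            "increasing"
        )
    if kind == "state":
        values = df[[f"{c}_uM" for c in STATE_COLUMNS]].to_numpy(dtype=float)
    else:
        values = df[expected[1]].to_numpy(dtype=float)
    return TimeCourse(times, values, kind=kind, meta=meta)


def calibration_from_meta(meta: dict) -> AnisotropyCalibration:
    """Build the r_MIN/r_MAX calibration from time-course metadata.

    Raises a :class:`ValidationError` naming the missing key when a fit in
    anisotropy space is requested on a file lacking calibration metadata.
    """
    for key in ("r_MIN", "r_MAX"):
        if key not in meta:
            raise ValidationError(
                f"missing '# {key}=' metadata: cannot fit in anisotropy space "
                "without the calibration"
            )
    return AnisotropyCalibration(r_min=float(meta["r_MIN"]), r_max=float(meta["r_MAX"]))


def experiment_from_timecourse(tc: TimeCourse) -> ExchangeExperiment:
    """Reconstruct the ExchangeExperiment from a trace's metadata and grid.

    Requires the totals written by the simulator/generators and a uniform
    sampling grid.
    """
    meta = tc.meta
    for key in ("A_total_uM", "T_total_uM", "S_total_uM"):
        if key not in meta:
            raise ValidationError(
                f"missing '# {key}=' metadata: cannot reconstruct the experiment"
            )
    dts = np.diff(tc.times)
    if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-9):
        raise ValidationError("non-uniform sampling grid; cannot infer dt")
    chase = None
    if "chase_time_s" in meta:
        chase = (float(meta["chase_time_s"]), float(meta.get("chase_T_add_uM", 0.0)))
    scenario = ScenarioModifiers(
        exchange_multiplier=float(meta.get("exchange_multiplier", 1.0)),
        label=str(meta.get("scenario", "Mg_baseline")),
    )
    return ExchangeExperiment(
        A_total=float(meta["A_total_uM"]),
        T_total=float(meta["T_total_uM"]),
        S_total=float(meta["S_total_uM"]),
        duration=float(tc.times[-1]),
        dt=float(dts[0]),
        chase=chase,
        scenario=scenario,
    )


def write_titration_csv(data: TitrationDataset, path: Union[str, Path]) -> Path:
    path = Path(path)
    buf = _io.StringIO()
    meta = {"abp_total_uM": data.ABP_total, **data.meta}
    for k, v in meta.items():
        buf.write(f"# {k}={_fmt(v)}\n")
    buf.write("g_actin_uM,anisotropy\n")
    for g, r in zip(data.G_totals, data.r_observed):
        buf.write(f"{float(g)!r},{float(r)!r}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_titration_csv(path: Union[str, Path]) -> TitrationDataset:
    path = Path(path)
    meta, header_line = _read_commented_header(path)
    if "abp_total_uM" not in meta:
        raise ValidationError(
            f"{path}: missing required metadata key 'abp_total_uM'"
        )
    df = pd.read_csv(path, skiprows=header_line, float_precision="round_trip")
    missing = [c for c in ("g_actin_uM", "anisotropy") if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}:{header_line + 1}: missing column(s) {missing}"
        )
    abp = float(meta.pop("abp_total_uM"))
    return TitrationDataset(
        ABP_total=abp,
        G_totals=df["g_actin_uM"].to_numpy(dtype=float),
        r_observed=df["anisotropy"].to_numpy(dtype=float),
        meta=meta,
    )
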