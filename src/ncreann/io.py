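"""Plain-text interchange formats.

Time series travel as tab-delimited matrices (header row of channel
labels, one row per sample) with a JSON sidecar holding the metadata
(``fs_hz``, ``band``, ``trial_boundaries``, optional ``seed``); volumes as
CSV voxel tables (i, j, k, x_mm, y_mm, z_mm, value); behavior and
connectivity as CSV.  Values are written with 12 significant digits so a
round trip preserves them to ~1e-9 relative precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ConnectivityResult, SourceVolume, SurrogateNull, TimeSeriesMatrix, ValidationError
from .model import NMVARModel

_FLOAT_FMT = "%.12g"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_timeseries(series: TimeSeriesMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(series.channel_labels) + "\n")
        np.savetxt(fh, series.values, fmt=_FLOAT_FMT, delimiter="\t")
    meta = {
        "fs_hz": series.fs,
        "band": series.band,
        "n_trials": int(series.trial_boundaries.size),
        "trial_boundaries": series.trial_boundaries.tolist(),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_timeseries(path: str | Path) -> TimeSeriesMatrix:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"time-series file not found: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValidationError(f"sidecar not found: {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in ("fs_hz", "trial_boundaries"):
        if key not in meta:
            raise ValidationError(f"sidecar {sidecar} is missing field {key!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        labels = header.split("\t")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != len(labels):
                raise ValidationError(
                    f"{path}: ragged row at line {lineno}: "
                    f"{len(parts)} values for {len(labels)} channels"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise ValidationError(f"{path}: non-numeric value at line {lineno}") from exc
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    return TimeSeriesMatrix(
        values=np.asarray(rows),
        fs=float(meta["fs_hz"]),
        channel_labels=labels,
        band=meta.get("band"),
        trial_boundaries=np.asarray(meta["trial_boundaries"], dtype=int),
    )


def write_volume(volume: SourceVolume, path: str | Path) -> None:
    idx = np.argwhere(np.ones(volume.dims, dtype=bool))
    coords = volume.voxel_coordinates_mm(idx)
    df = pd.DataFrame(
        {
            "i": idx[:, 0], "j": idx[:, 1], "k": idx[:, 2],
            "x_mm": coords[:, 0], "y_mm": coords[:, 1], "z_mm": coords[:, 2],
            "value": volume.values[idx[:, 0], idx[:, 1], idx[:, 2]],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_volume(path: str | Path) -> SourceVolume:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"volume file not found: {path}")
    df = pd.read_csv(path)
    required = {"i", "j", "k", "x_mm", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    dims = tuple(int(df[c].max()) + 1 for c in ("i", "j", "k"))
    vals = np.full(dims, np.nan)
    vals[df["i"], df["j"], df["k"]] = df["value"]
    if np.any(np.isnan(vals)):
        raise ValidationError(f"{path}: voxel table does not cover the full grid")
    nz = df[df["i"] > 0]
    spacing = float(nz["x_mm"].iloc[0] / nz["i"].iloc[0]) if len(nz) else 5.0
    return SourceVolume(values=vals, spacing=spacing)


def write_behavior(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_behavior(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"behavior file not found: {path}")
    df = pd.read_csv(path)
    required = {"subject", "response_relation", "overlap", "correct_r2"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


def connectivity_to_frame(
    result: ConnectivityResult, null: SurrogateNull | None = None
) -> pd.DataFrame:
    """Long-format edge table: condition, band, source, target, measure, value, significant."""
    rows = []
    labels = result.channel_labels
    m = result.n_channels
    for measure, mat in (("lC", result.lc), ("NC", result.nc)):
        sig = None
        if null is not None:
            sig = null.significant_lc if measure == "lC" else null.significant_nc
        for i in range(m):
            for j in range(m):
                val = mat[i, j]
                rows.append(
                    {
                        "condition": result.condition, "band": result.band,
                        "source": labels[i], "target": labels[j],
                        "measure": measure,
                        "value": val if np.isfinite(val) else np.nan,
                        "significant": bool(sig[i, j]) if sig is not None else None,
                        "self_influence": i == j,
                    }
                )
    return pd.DataFrame(rows)


def write_connectivity(
    result: ConnectivityResult, path: str | Path, null: SurrogateNull | None = None
) -> None:
    connectivity_to_frame(result, null).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_model(model: NMVARModel, path: str | Path) -> None:
    """Serialize a trained network to JSON (shapes + flat weight arrays)."""
    payload = {
        "activation": model.activation,
        "p": model.p,
        "n_channels": model.n_channels,
        "channel_labels": model.channel_labels,
        "hidden_weights": {"shape": list(model.hidden_weights.shape),
                           "data": model.hidden_weights.ravel().tolist()},
        "hidden_biases": model.hidden_biases.tolist(),
        "output_weights": {"shape": list(model.output_weights.shape),
                           "data": model.output_weights.ravel().tolist()},
        "output_biases": model.output_biases.tolist(),
        "channel_mean": model.channel_mean.tolist(),
        "channel_sd": model.channel_sd.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)
        fh.write("\n")


def read_model(path: str | Path) -> NMVARModel:
    with open(path) as fh:
        payload = json.load(fh)
    def arr(entry):
        return np.asarray(entry["data"], dtype=float).reshape(entry["shape"])
    return NMVARModel(
        hidden_weights=arr(payload["hidden_weights"]),
        hidden_biases=np.asarray(payload["hidden_biases"], dtype=float),
        output_weights=arr(payload["output_weights"]),
        output_biases=np.asarray(payload["output_biases"], dtype=float),
        activation=payload["activation"],
        p=int(payload["p"]),
        n_channels=int(payload["n_channels"]),
        channel_mean=np.asarray(payload["channel_mean"], dtype=float),
        channel_sd=np.asarray(payload["channel_sd"], dtype=float),
        channel_labels=list(payload["channel_labels"]),
    )
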