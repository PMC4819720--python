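"""Reading and writing matrices, time series, and run configurations.

Connectivity matrices travel as labelled TSV (header row and first
column carry region labels) with a JSON sidecar (``<file>.meta.json``)
recording metric and band.  Time series are TSV with one region per row
and a sidecar carrying the sampling rate.  Floats are written with 17
significant digits so round trips are bit-exact.  Region order is always
the file's order; labels are never re-sorted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    CANONICAL_BANDS,
    ConnectivityMatrix,
    FrequencyBand,
    RegionalTimeSeries,
    ValidationError,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_timeseries",
    "write_timeseries",
    "read_stack_dir",
    "write_stack_dir",
    "RunConfig",
]

FLOAT_FMT = "%.17g"


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".meta.json")


def _band_to_dict(band: FrequencyBand | None) -> dict | None:
    if band is None:
        return None
    return {"name": band.name, "low": band.low, "high": band.high}


def _band_from_dict(d: dict | None) -> FrequencyBand | None:
    if d is None:
        return None
    return FrequencyBand(d["name"], float(d["low"]), float(d["high"]))


def write_matrix(path: str | Path, cm: ConnectivityMatrix) -> Path:
    """Write a labelled TSV plus its metadata sidecar."""
    path = Path(path)
    frame = pd.DataFrame(cm.weights, index=cm.region_labels, columns=cm.region_labels)
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="region")
    meta = {"metric": cm.metric, "band": _band_to_dict(cm.band)}
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_matrix(path: str | Path, check_range: bool = True) -> ConnectivityMatrix:
    """Read a labelled TSV adjacency matrix (sidecar metadata if present).

    Round-trip float noise below 1e-12 is symmetrized away; larger
    asymmetry is an error.  A nonzero diagonal is zeroed with a warning.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[0] != frame.shape[1]:
        raise ValidationError(f"{path}: non-square body {frame.shape}")
    rows = [str(x) for x in frame.index]
    cols = [str(x) for x in frame.columns]
    if rows != cols:
        raise ValidationError(f"{path}: row labels do not match column labels")
    try:
        w = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = _first_non_numeric(frame)
        raise ValidationError(f"{path}: non-numeric cell at {bad}") from exc
    if not np.all(np.isfinite(w)):
        i, j = np.argwhere(~np.isfinite(w))[0]
        raise ValidationError(f"{path}: non-finite cell at ({rows[i]}, {cols[j]})")
    asym = np.max(np.abs(w - w.T)) if w.size else 0.0
    if asym > 1e-12:
        raise ValidationError(f"{path}: asymmetric beyond tolerance (max {asym:g})")
    w = 0.5 * (w + w.T)
    if np.max(np.abs(np.diag(w))) > 0:
        warnings.warn(f"{path}: nonzero diagonal forced to zero")
        np.fill_diagonal(w, 0.0)
    metric, band = "generic", None
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        metric = meta.get("metric", "generic")
        band = _band_from_dict(meta.get("band"))
    return ConnectivityMatrix(
        w, metric=metric, band=band, region_labels=rows, check_range=check_range
    )


def _first_non_numeric(frame: pd.DataFrame) -> tuple[str, str]:
    for i, row in enumerate(frame.index):
        for j, col in enumerate(frame.columns):
            try:
                float(frame.iloc[i, j])
            except (TypeError, ValueError):
                return (str(row), str(col))
    return ("?", "?")


def write_timeseries(path: str | Path, ts: RegionalTimeSeries) -> Path:
    """TSV (one region per row, label in first column) + metadata sidecar."""
    path = Path(path)
    frame = pd.DataFrame(ts.data, index=ts.region_labels)
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT, header=False)
    meta = {
        "sampling_rate": ts.sampling_rate,
        "modality": ts.modality,
        "band": _band_to_dict(ts.band),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_timeseries(path: str | Path, meta_path: str | Path | None = None) -> RegionalTimeSeries:
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _sidecar(path)
    if not meta_path.exists():
        raise ValidationError(f"missing metadata sidecar for {path}: {meta_path}")
    meta = json.loads(meta_path.read_text())
    if "sampling_rate" not in meta:
        raise ValidationError(f"{meta_path}: sampling_rate missing")
    frame = pd.read_csv(
        path, sep="\t", index_col=0, header=None, float_precision="round_trip"
    )
    data = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"{path}: NaN/inf cells in time series")
    return RegionalTimeSeries(
        data=data,
        sampling_rate=float(meta["sampling_rate"]),
        region_labels=[str(x) for x in frame.index],
        band=_band_from_dict(meta.get("band")),
        modality=meta.get("modality", "electrophysiological"),
    )


def write_stack_dir(out_dir: str | Path, mats) -> list[Path]:
    """One TSV per matrix, named ``<metric>_<band>.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in mats:
        band = m.band.name if m.band is not None else "broadband"
        paths.append(write_matrix(out_dir / f"{m.metric}_{band}.tsv", m))
    return paths


def read_stack_dir(stack_dir: str | Path, check_range: bool = True):
    """All ``*.tsv`` matrices in a directory, sorted by filename."""
    from .core import MatrixStack

    stack_dir = Path(stack_dir)
    files = sorted(stack_dir.glob("*.tsv"))
    if not files:
        raise ValidationError(f"no .tsv matrices in {stack_dir}")
    return MatrixStack([read_matrix(f, check_range=check_range) for f in files])


def _default_band_dicts() -> list[dict]:
    return [
        {"name": b.name, "low": b.low, "high": b.high} for b in CANONICAL_BANDS
    ]


@dataclass
class RunConfig:
    """Validated configuration of an end-to-end pipeline run.

    Either ``synthetic`` (P, D, noise_sd, ...) or ``inputs`` (paths to a
    target matrix plus a stack directory, or a raw time series) must be
    given.  Bands default to the five canonical ones and must be ordered
    and non-overlapping.
    """

    out_dir: str = "taylornet_out"
    seed: int = 0
    n_perm: int = 1000
    metrics: list[str] = field(default_factory=lambda: ["AEC"])
    bands: list[dict] = field(default_factory=_default_band_dicts)
    synthetic: dict | None = None
    inputs: dict | None = None
    verbosity: int = 1

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValidationError("exactly one of 'synthetic' or 'inputs' is required")
        bands = self.band_objects
        for b1, b2 in zip(bands, bands[1:]):
            if b2.low < b1.high:
                raise ValidationError(f"bands {b1.name}/{b2.name} overlap or are unordered")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if self.inputs is not None:
            has_stack = "target" in self.inputs and "stack_dir" in self.inputs
            has_ts = "timeseries" in self.inputs and "target" in self.inputs
            if not (has_stack or has_ts):
                raise ValidationError(
                    "inputs must provide target+stack_dir or target+timeseries"
                )
            for key in ("target", "stack_dir", "timeseries"):
                if key in self.inputs and not Path(self.inputs[key]).exists():
                    raise ValidationError(f"input path missing: {self.inputs[key]}")

    @property
    def band_objects(self) -> list[FrequencyBand]:
        return [FrequencyBand(b["name"], float(b["low"]), float(b["high"])) for b in self.bands]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)
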