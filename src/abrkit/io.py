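"""File formats: epoch CSVs with JSON sidecars, result tables, truth files.

Epoch storage layout (one directory per animal x condition)::

    <root>/<animal>/<condition>/
        sidecar.json        # StimulusSpec, animal, fs, n_epochs, artifacts
        epoch_0000.csv      # header 'time_ms,voltage_aV', one row per sample
        epoch_0001.csv
        ...

All files are UTF-8 with '.' decimal separators; column headers carry units.
Floats are written with ``repr`` (shortest round-trip form), so writing what
was read reproduces the bytes exactly.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .core import EpochSet, StimulusSpec, time_axis_ms


class FormatError(ValueError):
    """A file does not conform to the documented CSV/JSON dialect."""


_EPOCH_HEADER = "time_ms,voltage_aV"


def _condition_dirname(spec: StimulusSpec) -> str:
    return spec.key.replace("|", "_")


def _spec_to_dict(spec: StimulusSpec) -> dict:
    d = dataclasses.asdict(spec)
    return {k: v for k, v in d.items() if v is not None}


def _spec_from_dict(d: Mapping) -> StimulusSpec:
    return StimulusSpec(**d)


def write_epochs(eset: EpochSet, root: Path, animal_dir: bool = True) -> Path:
    """Write one epoch set under ``root``; returns the condition directory."""
    root = Path(root)
    cond = root / eset.animal / _condition_dirname(eset.spec) if animal_dir \
        else root / _condition_dirname(eset.spec)
    cond.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "animal": eset.animal,
        "fs_hz": eset.fs,
        "n_epochs": len(eset),
        "n_samples": int(eset.samples.shape[1]),
        "artifact_epochs": list(eset.artifact_epochs),
        "stimulus": _spec_to_dict(eset.spec),
    }
    (cond / "sidecar.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    t = time_axis_ms(eset.samples.shape[1], eset.fs)
    for i in range(len(eset)):
        lines = [_EPOCH_HEADER]
        lines.extend(
            f"{float(t[j])!r},{float(eset.samples[i, j])!r}"
            for j in range(t.size)
        )
        (cond / f"epoch_{i:04d}.csv").write_text("\n".join(lines) + "\n",
                                                 encoding="utf-8")
    return cond


def read_epochs(cond_dir: Path) -> EpochSet:
    """Read one condition directory back into an :class:`EpochSet`."""
    cond_dir = Path(cond_dir)
    sidecar_path = cond_dir / "sidecar.json"
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar JSON in {cond_dir}")
    sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
    spec = _spec_from_dict(sidecar["stimulus"])
    fs = float(sidecar["fs_hz"])
    n_samples = int(sidecar["n_samples"])
    files = sorted(cond_dir.glob("epoch_*.csv"))
    if len(files) != int(sidecar["n_epochs"]):
        raise FormatError(
            f"{cond_dir}: sidecar promises {sidecar['n_epochs']} epochs, "
            f"found {len(files)} files"
        )
    dt_ms = 1000.0 / fs
    data = np.empty((len(files), n_samples))
    for i, f in enumerate(files):
        with open(f, encoding="utf-8") as fh:
            header = fh.readline().strip()
            if header != _EPOCH_HEADER:
                raise FormatError(
                    f"{f}: header {header!r} lacks the required unit-bearing "
                    f"columns {_EPOCH_HEADER!r}"
                )
            j = -1
            for j, line in enumerate(fh):
                if j >= n_samples:
                    raise FormatError(f"{f}: more samples than declared")
                t_str, v_str = line.rstrip("\n").split(",")
                v = float(v_str)
                if math.isnan(v):
                    raise FormatError(f"{f}: NaN sample at row {j + 2}")
                if abs(float(t_str) - j * dt_ms) > 1e-9:
                    raise FormatError(
                        f"{f}: time axis at row {j + 2} inconsistent with "
                        f"fs={fs} Hz"
                    )
                data[i, j] = v
            if j + 1 != n_samples:
                raise FormatError(f"{f}: fewer samples than declared")
    return EpochSet(
        data, fs, spec, sidecar["animal"],
        artifact_epochs=tuple(sidecar.get("artifact_epochs", ())),
    )


def write_manifest(root: Path, entries: Dict[str, list]) -> Path:
    """Cohort manifest: animal -> list of condition directory names."""
    root = Path(root)
    path = root / "manifest.json"
    path.write_text(json.dumps(entries, indent=1, sort_keys=True) + "\n",
                    encoding="utf-8")
    return path


def read_manifest(root: Path) -> Dict[str, list]:
    path = Path(root) / "manifest.json"
    if not path.exists():
        raise FormatError(f"missing manifest.json in {root}")
    return json.loads(path.read_text(encoding="utf-8"))


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: Path,
                  provenance: Optional[Mapping] = None) -> Dict[str, str]:
    """Write result tables as CSV plus a provenance JSON; returns file hashes.

    Output is deterministic: fixed column order, repr-formatted floats, no
    timestamps, sorted provenance keys.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hashes: Dict[str, str] = {}
    for name in sorted(tables):
        path = out_dir / f"{name}.csv"
        tables[name].to_csv(path, index=False)
        hashes[path.name] = _sha256(path)
    if provenance is not None:
        path = out_dir / "provenance.json"
        path.write_text(json.dumps(provenance, indent=1, sort_keys=True,
                                   default=str) + "\n", encoding="utf-8")
        hashes[path.name] = _sha256(path)
    (out_dir / "hashes.json").write_text(
        json.dumps(hashes, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return hashes


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
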