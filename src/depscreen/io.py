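"""File I/O: cohort manifests, spectrum CSVs, MDV tables, report files.

CSV dialects
------------
* cohort manifest: ``sample_id,arm,file,sex,age``
* per-sample raw spectra: ``frequency_hz,repeat_1..repeat_k``
* single processed spectrum: ``frequency_hz,value[,mask]`` (mask ``1`` = valid)
* MDV results: ``sample_id,arm,low_mean,high_mean,mdv,spectrum_sd,excluded,predicted``

All files are UTF-8 with ``.`` decimal separators; frequencies are
written as integers when exact.  ``write_cohort`` / ``read_cohort``
round-trip losslessly (repr-precision floats).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import ARM_LABELS, CohortDataset, SampleRecord, write_cohort
from .diagnostics import DiagnosticReport
from .mdv import MDVResult
from .shell_model import FrequencyGrid, Spectrum

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "write_mdv_results",
    "read_mdv_results",
    "write_report",
    "load_config",
]


def read_cohort(manifest_path: str | Path) -> CohortDataset:
    """Load a cohort from its manifest; inverse of ``write_cohort``."""
    manifest_path = Path(manifest_path)
    if not manifest_path.is_file():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path, dtype={"sample_id": str, "sex": str})
    required = {"sample_id", "arm", "file"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"{manifest_path}: missing manifest columns {sorted(missing)}")

    samples: list[SampleRecord] = []
    grid: Optional[FrequencyGrid] = None
    for row_no, row in enumerate(manifest.itertuples(index=False), start=2):
        if row.arm not in ARM_LABELS:
            raise ValueError(
                f"{manifest_path}, row {row_no}: arm {row.arm!r} not in {ARM_LABELS}"
            )
        spec_path = manifest_path.parent / row.file
        if not spec_path.is_file():
            raise FileNotFoundError(
                f"{manifest_path}, row {row_no}: spectrum file missing: {spec_path}"
            )
        record = _read_sample_csv(spec_path, row.sample_id, row.arm)
        if grid is None:
            grid = record.grid
        elif not np.allclose(grid.frequencies, record.grid.frequencies, rtol=1e-12):
            raise ValueError(f"{spec_path}: frequency grid differs from cohort grid")
        meta = {}
        sex = getattr(row, "sex", None)
        if isinstance(sex, str) and sex:
            meta["sex"] = sex
        age = getattr(row, "age", None)
        if age is not None and not (isinstance(age, float) and np.isnan(age)):
            meta["age"] = int(age)
        record.metadata.update(meta)
        samples.append(record)
    if grid is None:
        raise ValueError(f"{manifest_path}: empty manifest")
    return CohortDataset(samples=samples, grid=grid, provenance={"manifest": str(manifest_path)})


def _read_sample_csv(path: Path, sample_id: str, arm: str) -> SampleRecord:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"{path}: malformed spectrum CSV: {exc}") from exc
    if "frequency_hz" not in df.columns:
        raise ValueError(f"{path}: missing frequency_hz column")
    repeat_cols = [c for c in df.columns if c.startswith("repeat_")]
    if not repeat_cols:
        raise ValueError(f"{path}: no repeat_* columns")
    if df[repeat_cols].isna().any().any():
        bad = int(df[df[repeat_cols].isna().any(axis=1)].index[0]) + 2
        raise ValueError(f"{path}, row {bad}: repeats of unequal length or missing value")
    grid = FrequencyGrid(df["frequency_hz"].to_numpy(dtype=float))
    repeats = [
        Spectrum(grid=grid, values=df[c].to_numpy(dtype=float)) for c in repeat_cols
    ]
    return SampleRecord(sample_id=sample_id, arm=arm, repeats=repeats)


def read_spectrum_csv(path: str | Path) -> Spectrum:
    """Read a single ``frequency_hz,value[,mask]`` spectrum file."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("frequency_hz", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    grid = FrequencyGrid(df["frequency_hz"].to_numpy(dtype=float))
    mask = (
        df["mask"].to_numpy(dtype=int).astype(bool)
        if "mask" in df.columns
        else np.ones(len(grid), dtype=bool)
    )
    return Spectrum(grid=grid, values=df["value"].to_numpy(dtype=float), mask=mask)


def write_spectrum_csv(spectrum: Spectrum, path: str | Path, with_mask: bool = True) -> None:
    df = pd.DataFrame(
        {
            "frequency_hz": spectrum.frequencies,
            "value": [repr(float(v)) for v in spectrum.values],
        }
    )
    if with_mask:
        df["mask"] = spectrum.mask.astype(int)
    df.to_csv(path, index=False)


MDV_COLUMNS = [
    "sample_id",
    "arm",
    "low_mean",
    "high_mean",
    "mdv",
    "spectrum_sd",
    "excluded",
    "predicted",
]


def write_mdv_results(results: Sequence[MDVResult], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "arm": r.arm,
            "low_mean": r.low_mean,
            "high_mean": r.high_mean,
            "mdv": r.mdv,
            "spectrum_sd": r.spectrum_sd,
            "excluded": int(r.excluded),
            "predicted": r.predicted,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=MDV_COLUMNS).to_csv(path, index=False)


def read_mdv_results(path: str | Path) -> list[MDVResult]:
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = set(MDV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        MDVResult(
            sample_id=row.sample_id,
            arm=row.arm,
            low_mean=float(row.low_mean),
            high_mean=float(row.high_mean),
            mdv=float(row.mdv),
            spectrum_sd=float(row.spectrum_sd),
            excluded=bool(row.excluded),
            predicted=row.predicted,
        )
        for row in df.itertuples(index=False)
    ]


def write_report(report: DiagnosticReport, path_stem: str | Path) -> tuple[Path, Path]:
    """Write a report as JSON summary plus a sweep-table CSV."""
    path_stem = Path(path_stem)
    json_path = path_stem.with_suffix(".json")
    csv_path = path_stem.parent / f"{path_stem.name}_sweep.csv"
    with open(json_path, "w") as fh:
        json.dump(report.summary(), fh, indent=2)
        fh.write("\n")
    report.sweep.table.to_csv(csv_path, index=False)
    return json_path, csv_path


def load_config(path: str | Path) -> dict:
    """Load a flat key-value YAML config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping of keys to values")
    return data
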