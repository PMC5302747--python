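"""Plain-text I/O: TSV matrices and spectra, JSON results, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import META_COLUMNS, LabeledMatrix, PeakMatrix, SpectrumSet
from .evaluate import EvalReport
from .selection import SelectionResult

__all__ = [
    "ParseError",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_spectra",
    "read_spectra",
    "write_peak_matrix_tsv",
    "write_selection_result",
    "write_eval_report",
    "write_stats_table",
    "load_yaml",
]


class ParseError(ValueError):
    """A file violates the declared on-disk format."""


def write_matrix_tsv(m: LabeledMatrix, path: str | Path) -> Path:
    """First column sample_id, then metadata, then one column per feature."""
    path = Path(path)
    df = pd.concat(
        [m.meta.reset_index(drop=True),
         pd.DataFrame(m.values, columns=m.feature_ids)],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_matrix_tsv(path: str | Path) -> LabeledMatrix:
    """Lossless counterpart of :func:`write_matrix_tsv` (up to float repr)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing metadata column(s) {missing}")
    ids = df["sample_id"].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    feature_cols = [c for c in df.columns if c not in META_COLUMNS]
    values = np.empty((len(df), len(feature_cols)))
    for j, col in enumerate(feature_cols):
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() & df[col].notna()
        if bad.any() or num.isna().any():
            i = int(np.flatnonzero(bad.to_numpy() | num.isna().to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric or missing cell at row {i} "
                f"(sample_id={ids.iloc[i]!r}), column {col!r}"
            )
        values[:, j] = num.to_numpy()
    meta = df[META_COLUMNS].copy()
    meta["sample_id"] = ids
    meta["is_qc_pool"] = meta["is_qc_pool"].astype(bool)
    return LabeledMatrix(values, feature_cols, meta)


def write_spectra(spectra: SpectrumSet, outdir: str | Path) -> Path:
    """Per-sample two-column (mz, intensity) TSVs plus a manifest TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sid in enumerate(spectra.sample_ids):
        fname = f"{sid}.tsv"
        pd.DataFrame({"mz": spectra.mz, "intensity": spectra.intensities[i]}).to_csv(
            outdir / fname, sep="\t", index=False
        )
        meta = spectra.meta.iloc[i]
        rows.append([fname, sid, meta["dose_gy"], meta["day"], meta["batch"], meta["is_qc_pool"]])
    manifest = pd.DataFrame(rows, columns=["file"] + META_COLUMNS)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return outdir / "manifest.tsv"


def read_spectra(manifest_path: str | Path) -> SpectrumSet:
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    for col in ["file"] + META_COLUMNS:
        if col not in manifest.columns:
            raise ParseError(f"{manifest_path}: manifest missing column {col!r}")
    base = manifest_path.parent
    grid = None
    traces = []
    for fname in manifest["file"]:
        df = pd.read_csv(base / fname, sep="\t")
        if grid is None:
            grid = df["mz"].to_numpy()
        elif not np.allclose(grid, df["mz"].to_numpy()):
            raise ParseError(f"{fname}: mz grid differs from the shared grid")
        traces.append(df["intensity"].to_numpy())
    meta = manifest[META_COLUMNS].copy()
    meta["is_qc_pool"] = meta["is_qc_pool"].astype(bool)
    return SpectrumSet(grid, np.vstack(traces), meta)


def write_peak_matrix_tsv(pm: PeakMatrix, path: str | Path) -> Path:
    path = Path(path)
    pm.to_frame().to_csv(path, sep="\t", index=False)
    return path


def write_stats_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t")
    return path


def write_selection_result(res: SelectionResult, path: str | Path) -> Path:
    """JSON with method/params/frequencies/selected, plus a sibling
    frequency TSV for spreadsheet audit."""
    path = Path(path)
    path.write_text(json.dumps(res.to_dict(), indent=1, sort_keys=True))
    freq = pd.DataFrame(
        {"feature_id": list(res.frequencies), "count": list(res.frequencies.values())}
    )
    freq.to_csv(path.with_suffix(".freq.tsv"), sep="\t", index=False)
    return path


def write_eval_report(report: EvalReport, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))
    return path


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
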