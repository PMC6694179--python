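"""CSV schemas and readers/writers for samples, truth tables and reports.

Data CSV schema (UTF-8, '.' decimal):
    sample_id, parent_root_id, parent_diameter_mm, ibd_mm
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .analysis import DiameterSplitResult, FitResult, IBDSample
from .errors import SchemaError

__all__ = [
    "SAMPLE_COLUMNS",
    "load_samples",
    "write_samples",
    "write_fit_report",
    "write_split_report",
]

SAMPLE_COLUMNS = ["sample_id", "parent_root_id", "parent_diameter_mm", "ibd_mm"]

log = logging.getLogger("rootbranch")


def load_samples(path: str | Path) -> list[IBDSample]:
    """Load per-sample IBD records from a CSV file.

    Validates the schema and positivity of distances/diameters and logs
    the record count of each sample.
    """
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    for col in ("parent_diameter_mm", "ibd_mm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals <= 0).any():
            raise SchemaError(f"{path}: column {col} must be positive numbers")
        df[col] = vals
    samples = []
    for sid, group in df.groupby("sample_id", sort=True):
        sample = IBDSample(
            sample_id=str(sid),
            records=group[SAMPLE_COLUMNS[1:]].reset_index(drop=True),
        )
        log.info("loaded sample %s: %d records", sid, sample.n_records)
        samples.append(sample)
    return samples


def write_samples(samples: list[IBDSample], path: str | Path) -> None:
    """Write samples back to the standard CSV schema."""
    frames = []
    for s in samples:
        df = s.records.copy()
        df.insert(0, "sample_id", s.sample_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=SAMPLE_COLUMNS
    )
    out.to_csv(path, index=False, float_format="%.6g")


_FIT_COLUMNS = [
    "sample_id", "isd", "cv_d", "p_em", "chi2", "dof", "p_value", "n_obs", "flags",
]


def _fit_frame(fits: list[FitResult]) -> pd.DataFrame:
    return pd.DataFrame([f.to_dict() for f in fits], columns=_FIT_COLUMNS)


def write_fit_report(
    fits: list[FitResult], path_csv: str | Path, summary: dict | None = None
) -> None:
    """Write per-sample fit results to CSV and, alongside, a JSON report.

    The JSON file (``<path>.json``) carries the same per-sample records
    plus the panel summary when given.
    """
    path_csv = Path(path_csv)
    _fit_frame(fits).to_csv(path_csv, index=False, float_format="%.6g")
    payload = {"fits": [f.to_dict() for f in fits]}
    if summary is not None:
        payload["summary"] = summary
    path_csv.with_suffix(path_csv.suffix + ".json").write_text(
        json.dumps(payload, indent=1, default=float)
    )


def write_split_report(
    splits: list[DiameterSplitResult], path_csv: str | Path,
    summary: dict | None = None,
) -> None:
    """Write diameter-split results (one row per sample) to CSV + JSON."""
    path_csv = Path(path_csv)
    rows = []
    for s in splits:
        row = {
            "sample_id": s.sample_id,
            "threshold_mm": s.threshold,
            "rel_diff_isd": s.rel_diff_isd,
            "rel_diff_pem": s.rel_diff_pem,
            "flags": ";".join(s.flags),
        }
        for name, fit in (("fine", s.fine_fit), ("thick", s.thick_fit)):
            d = fit.to_dict()
            d.pop("sample_id")
            d.pop("flags")
            row.update({f"{name}_{k}": v for k, v in d.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path_csv, index=False, float_format="%.6g")
    payload = {"splits": rows}
    if summary is not None:
        payload["summary"] = summary
    path_csv.with_suffix(path_csv.suffix + ".json").write_text(
        json.dumps(payload, indent=1, default=float)
    )
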