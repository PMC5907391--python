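"""TSV / NIfTI / metadata readers and writers.

Series tables are plain TSV with a header row of region labels and two
leading comment lines carrying the sampling interval and the conditioning
log, so a write -> read round trip is lossless (values at full float
precision).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .series import RoiTimeSeries

KNOWN_STAGES = ("acute", "subacute", "early_chronic", "baseline")

__all__ = [
    "write_series_tsv",
    "read_series_tsv",
    "read_nifti",
    "write_metadata_tsv",
    "read_metadata_tsv",
    "write_table_tsv",
]


def write_series_tsv(series: RoiTimeSeries, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# tr_seconds: {series.tr_seconds!r}\n")
        fh.write(f"# conditioning: {','.join(series.conditioning_log)}\n")
        fh.write("\t".join(series.region_labels) + "\n")
        for row in series.values:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_series_tsv(path) -> RoiTimeSeries:
    path = Path(path)
    tr = 2.0
    log: tuple[str, ...] = ()
    labels: list[str] | None = None
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("tr_seconds:"):
                    tr = float(body.split(":", 1)[1])
                elif body.startswith("conditioning:"):
                    items = body.split(":", 1)[1].strip()
                    log = tuple(s for s in items.split(",") if s)
                continue
            fields = line.split("\t")
            if labels is None:
                labels = fields
                continue
            if len(fields) != len(labels):
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                    f"expected {len(labels)})"
                )
            try:
                rows.append([float(v) for v in fields])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if labels is None or not rows:
        raise ValueError(f"{path}: no data rows")
    return RoiTimeSeries(
        np.array(rows), tuple(labels), tr_seconds=tr, conditioning_log=log
    )


def read_nifti(path):
    import nibabel as nib

    return nib.load(str(path))


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_metadata_tsv(path, known_stages=KNOWN_STAGES) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "group", "stage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns {sorted(missing)}")
    bad_stage = set(df.stage) - set(known_stages)
    if bad_stage:
        raise ValueError(f"unknown stage labels {sorted(bad_stage)}")
    bad_group = set(df.group) - {"patient", "control"}
    if bad_group:
        raise ValueError(f"unknown group labels {sorted(bad_group)}")
    if "score" in df.columns:
        finite = df.score.dropna()
        if ((finite < 0) | (finite > 66)).any():
            raise ValueError("behavioral scores outside [0, 66]")
    return df


def write_table_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
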