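"""Readers and writers for profile tables, cohort matrices and segment calls.

Profiles are plain tab-delimited text with a header:

    probe_id  chrom  position  log2ratio

Cohort matrices share the first three columns and carry one additional
column per sample.  Segment calls are written BED-style: both 0-based
half-open genomic coordinates (BED convention) and the 1-based inclusive
probe indices used throughout the library are emitted, to leave no
ambiguity about either dialect.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from bicseg.binarize import CohortMatrix, CopyNumberProfile, chrom_sort_key
from bicseg.core import SegmentationResult

logger = logging.getLogger("bicseg")

PROFILE_COLUMNS = ["probe_id", "chrom", "position", "log2ratio"]

SEGMENT_COLUMNS = [
    "chrom",
    "start",  # BED: 0-based, half-open
    "end",
    "probe_start",  # 1-based inclusive probe index
    "probe_end",
    "direction",
    "rate",
    "mean_log2",
    "n_probes",
]


def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def _parse_positions(df: pd.DataFrame, path) -> np.ndarray:
    pos = pd.to_numeric(df["position"], errors="coerce")
    bad = pos.isna() | (pos != pos.round())
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise ValueError(f"{path}: malformed position at line {line}")
    return pos.to_numpy(dtype=np.int64)


def read_profile(path) -> CopyNumberProfile:
    """Read one sample's tab-delimited profile.

    Non-numeric log2 ratios (e.g. ``NA``) become missing values.  Rows are
    sorted genomically (with a warning if the file was unsorted); duplicate
    (chrom, position) pairs are rejected.
    """
    df = _read_table(path)
    missing_cols = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing column(s) {missing_cols}")
    positions = _parse_positions(df, path)
    values = pd.to_numeric(df["log2ratio"], errors="coerce").to_numpy(dtype=float)
    chroms = df["chrom"].to_numpy(dtype=object)

    order = sorted(
        range(len(df)), key=lambda i: (chrom_sort_key(chroms[i]), positions[i])
    )
    if order != list(range(len(df))):
        warnings.warn(f"{path}: input not in genomic order; sorted", UserWarning)
    chroms = chroms[order]
    positions = positions[order]
    dup = pd.DataFrame({"c": chroms, "p": positions}).duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(
            f"{path}: duplicate probe at chrom {chroms[i]} position {positions[i]}"
        )
    return CopyNumberProfile(
        probe_ids=df["probe_id"].to_numpy(dtype=object)[order],
        chroms=chroms,
        positions=positions,
        values=values[order],
    )


def read_cohort(path) -> CohortMatrix:
    """Read a probes x samples matrix (probe_id, chrom, position, then one
    column per sample); all samples share the probe grid by construction."""
    df = _read_table(path)
    for c in ("probe_id", "chrom", "position"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    sample_cols = [c for c in df.columns if c not in ("probe_id", "chrom", "position")]
    if len(sample_cols) < 2:
        raise ValueError(f"{path}: cohort matrix needs >= 2 sample columns")
    positions = _parse_positions(df, path)
    chroms = df["chrom"].to_numpy(dtype=object)
    order = sorted(
        range(len(df)), key=lambda i: (chrom_sort_key(chroms[i]), positions[i])
    )
    values = np.column_stack(
        [pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float) for c in sample_cols]
    )[order]
    return CohortMatrix(
        values=values,
        probe_ids=df["probe_id"].to_numpy(dtype=object)[order],
        chroms=chroms[order],
        positions=positions[order],
        sample_ids=np.asarray(sample_cols, dtype=object),
    )


def segments_to_frame(
    results: Sequence[tuple[str, SegmentationResult, np.ndarray]],
    direction: str,
) -> pd.DataFrame:
    """Flatten per-chromosome results into a segment table.

    ``results`` holds (chrom, segmentation, positions) triples where
    ``positions`` aligns with the segmented sequence.  Chromosomes with no
    detected change-point (K = 0) contribute no rows; they still appear in
    the log summary.
    """
    rows = []
    for chrom, result, positions in results:
        if result.K == 0:
            continue
        for seg in result.segments:
            start_bp = int(positions[seg.start - 1])
            end_bp = int(positions[seg.end - 1])
            rows.append(
                {
                    "chrom": chrom,
                    "start": start_bp - 1,  # BED 0-based
                    "end": end_bp,
                    "probe_start": seg.start,
                    "probe_end": seg.end,
                    "direction": direction,
                    "rate": seg.rate,
                    "mean_log2": np.nan if seg.mean_log2 is None else seg.mean_log2,
                    "n_probes": seg.n_probes,
                }
            )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def write_segments(frame: pd.DataFrame, path) -> None:
    """Write a segment table as tab-delimited text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    logger.info("wrote %d segment row(s) to %s", len(frame), path)


def read_segments(path) -> pd.DataFrame:
    """Read back a segment table written by :func:`write_segments`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df
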