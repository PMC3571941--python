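"""Orchestration of the four analysis modes.

``single``    — threshold one profile and segment it, per chromosome or
                genome-wide (all chromosomes concatenated in karyotype
                order, so whole-chromosome events that are flat within
                their own chromosome become detectable).
``integrate`` — multi-source consensus for one individual on the union
                probe grid.
``cohort``    — standardize a probes x samples matrix, then threshold and
                segment each sample's z-profile; aberrant intervals are
                cross-referenced between samples (recurrent intervals are
                the interesting ones).
``simulate``  — the power study over the (c, tau+) grid.

Gain and loss searches always run separately and are reported separately.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from bicseg.binarize import (
    CohortMatrix,
    CopyNumberProfile,
    ThresholdSpec,
    binarize_band,
    binarize_cohort,
    binarize_gain,
    binarize_loss,
    standardize_cohort,
)
from bicseg.core import BinarySequence, SegmentationResult, segment, summarize_segments
from bicseg.integrate import SourceProfile, merge_sources, threshold_sources
from bicseg.io import (
    SEGMENT_COLUMNS,
    read_cohort,
    read_profile,
    segments_to_frame,
    write_segments,
)
from bicseg.simulation import SimulationConfig, power_study

logger = logging.getLogger("bicseg")

COHORT_COLUMNS = [
    "sample",
    "chrom",
    "start",
    "end",
    "probe_start",
    "probe_end",
    "direction",
    "rate",
    "mean_z",
    "n_probes",
    "shared_with",
]

# A detected segment is called aberrant when the thresholded indicator is on
# for the majority of its probes; with the sparse background that survives
# tau/gamma thresholds, real events sit near rate 1 and background near 0.
ABERRANT_RATE = 0.5


@dataclass
class RunConfig:
    """Settings for one command-line run."""

    mode: str  # single | integrate | cohort | simulate
    inputs: tuple[str, ...] = ()
    out: str = "."
    direction: str = "both"  # gain | loss | both
    scope: str = "chrom"  # chrom | genome
    thresholds: Optional[ThresholdSpec] = None
    per_source_tau: tuple[float, ...] = ()
    seed: int = 0
    reps: int = 1000
    m: int = 500

    def __post_init__(self) -> None:
        if self.mode not in ("single", "integrate", "cohort", "simulate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.direction not in ("gain", "loss", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.scope not in ("chrom", "genome"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.mode == "single" and len(self.inputs) != 1:
            raise ValueError("single mode takes exactly one input profile")
        if self.mode == "integrate" and len(self.inputs) < 2:
            raise ValueError("integrate mode requires >= 2 input profiles")
        if self.mode == "cohort" and len(self.inputs) != 1:
            raise ValueError("cohort mode takes one matrix file")

    def directions(self) -> tuple[str, ...]:
        return ("gain", "loss") if self.direction == "both" else (self.direction,)


def _binarize(
    profile: CopyNumberProfile, direction: str, spec: ThresholdSpec
) -> BinarySequence:
    if direction == "gain":
        if spec.tau_plus is None:
            raise ValueError("gain search requires tau_plus")
        if spec.epsilon is not None:
            return binarize_band(profile, spec.tau_plus, spec.epsilon, "gain")
        return binarize_gain(profile, spec.tau_plus)
    if spec.tau_minus is None:
        raise ValueError("loss search requires tau_minus")
    if spec.epsilon is not None:
        return binarize_band(profile, spec.tau_minus, spec.epsilon, "loss")
    return binarize_loss(profile, spec.tau_minus)


def segment_single(
    profile: CopyNumberProfile,
    spec: ThresholdSpec,
    direction: str,
    scope: str = "chrom",
) -> pd.DataFrame:
    """Threshold and segment one profile; returns the segment table.

    Per-chromosome scope segments each chromosome as an independent
    sequence.  Genome-wide scope concatenates all chromosomes in karyotype
    order into a single sequence before segmenting; segments crossing a
    chromosome border are reported as one row per overlapped chromosome,
    keeping the whole segment's rate and mean (probe indices are global).
    """
    if scope == "chrom":
        triples = []
        for chrom, sub in profile.by_chromosome():
            seq = _binarize(sub, direction, spec)
            result = summarize_segments(segment(seq), sub.values)
            logger.info("%s %s: K=%d (m=%d)", direction, chrom, result.K, len(sub))
            triples.append((chrom, result, sub.positions))
        return segments_to_frame(triples, direction)

    seq = _binarize(profile, direction, spec)
    result = summarize_segments(segment(seq), profile.values)
    logger.info("%s genome-wide: K=%d (m=%d)", direction, result.K, len(profile))
    chroms = np.asarray([str(c) for c in profile.chroms], dtype=object)
    rows = []
    if result.K == 0:
        return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    for seg in result.segments:
        span = slice(seg.start - 1, seg.end)
        for chrom in pd.unique(chroms[span]):
            inside = np.flatnonzero(chroms[span] == chrom) + seg.start - 1
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(profile.positions[inside[0]]) - 1,
                    "end": int(profile.positions[inside[-1]]),
                    "probe_start": int(inside[0]) + 1,
                    "probe_end": int(inside[-1]) + 1,
                    "direction": direction,
                    "rate": seg.rate,
                    "mean_log2": seg.mean_log2,
                    "n_probes": int(inside.size),
                }
            )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def integrate_sources(
    sources: Sequence[SourceProfile], direction: str
) -> pd.DataFrame:
    """Consensus segmentation of several sources, chromosome by chromosome.

    Each source is thresholded with its own tau, the indicator sequences are
    merged on the union coordinate grid, and the merged sequence is
    segmented.  ``probe_start``/``probe_end`` index the merged sequence;
    ``mean_log2`` averages the originating sources' raw values over the
    merged segment.
    """
    chrom_order: dict[str, None] = {}
    for src in sources:
        for c in src.profile.chromosomes():
            chrom_order.setdefault(c, None)
    rows = []
    for chrom in chrom_order:
        subs = []
        for src in sources:
            mask = np.asarray([str(c) == chrom for c in src.profile.chroms])
            if mask.any():
                subs.append(
                    SourceProfile(
                        source_id=src.source_id,
                        profile=src.profile.subset(mask),
                        tau_plus=src.tau_plus,
                        tau_minus=src.tau_minus,
                    )
                )
        thresholded = threshold_sources(subs, direction)
        merged = merge_sources(thresholded, [s.source_id for s in subs])
        values_by_source = {s.source_id: s.profile.values for s in subs}
        merged_values = np.asarray(
            [
                values_by_source[sid][idx - 1]
                for sid, idx in zip(merged.source_ids, merged.source_index)
            ]
        )
        result = summarize_segments(segment(merged.as_binary_sequence()), merged_values)
        logger.info(
            "%s %s: K=%d (merged m=%d from %d source(s))",
            direction,
            chrom,
            result.K,
            len(merged),
            len(subs),
        )
        if result.K == 0:
            continue
        for seg in result.segments:
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(merged.positions[seg.start - 1]) - 1,
                    "end": int(merged.positions[seg.end - 1]),
                    "probe_start": seg.start,
                    "probe_end": seg.end,
                    "direction": direction,
                    "rate": seg.rate,
                    "mean_log2": seg.mean_log2,
                    "n_probes": seg.n_probes,
                }
            )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def cohort_analysis(
    matrix: CohortMatrix, gamma: float, direction: str
) -> pd.DataFrame:
    """Standardize, threshold at ``gamma`` and segment each sample.

    Returns one row per detected aberrant segment (indicator rate >
    ``ABERRANT_RATE``); ``shared_with`` lists the other samples whose
    aberrant segments overlap it (same chromosome, nonempty probe-index
    intersection) — intervals recurring in two or more samples are the
    strongest candidates for real, shared events.
    """
    z = standardize_cohort(matrix)
    chroms = np.asarray([str(c) for c in z.chroms], dtype=object)
    chrom_list = list(dict.fromkeys(chroms))
    per_sample_bits = binarize_cohort(z, gamma, direction)
    calls: list[dict] = []
    for j, sample in enumerate(z.sample_ids):
        bits_all = per_sample_bits[j].bits
        for chrom in chrom_list:
            mask = chroms == chrom
            idx = np.flatnonzero(mask)
            seq = BinarySequence(bits=bits_all[mask])
            result = summarize_segments(segment(seq), z.values[mask, j])
            if result.K:
                logger.info("%s %s %s: K=%d", direction, sample, chrom, result.K)
            for seg in result.segments:
                if seg.rate <= ABERRANT_RATE:
                    continue
                calls.append(
                    {
                        "sample": str(sample),
                        "chrom": chrom,
                        "start": int(matrix.positions[idx[seg.start - 1]]) - 1,
                        "end": int(matrix.positions[idx[seg.end - 1]]),
                        "probe_start": seg.start,
                        "probe_end": seg.end,
                        "direction": direction,
                        "rate": seg.rate,
                        "mean_z": seg.mean_log2,
                        "n_probes": seg.n_probes,
                    }
                )
    for call in calls:
        others = sorted(
            {
                other["sample"]
                for other in calls
                if other["sample"] != call["sample"]
                and other["chrom"] == call["chrom"]
                and other["probe_start"] <= call["probe_end"]
                and call["probe_start"] <= other["probe_end"]
            }
        )
        call["shared_with"] = ",".join(others)
    return pd.DataFrame(calls, columns=COHORT_COLUMNS)


def run(config: RunConfig) -> int:
    """Execute one configured run; returns a process exit status."""
    t0 = time.time()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.thresholds
    logger.info("mode=%s scope=%s direction=%s", config.mode, config.scope, config.direction)

    if config.mode == "single":
        profile = read_profile(config.inputs[0])
        for direction in config.directions():
            frame = segment_single(profile, spec, direction, config.scope)
            write_segments(frame, out / f"segments_{direction}.tsv")
    elif config.mode == "integrate":
        taus = config.per_source_tau
        profiles = [read_profile(p) for p in config.inputs]
        for direction in config.directions():
            sources = []
            for idx, (path, profile) in enumerate(zip(config.inputs, profiles)):
                if taus:
                    tau = taus[idx] if idx < len(taus) else taus[-1]
                else:
                    tau = spec.tau_plus if direction == "gain" else spec.tau_minus
                if tau is None:
                    raise ValueError(f"no {direction} threshold for source {path}")
                sources.append(
                    SourceProfile(
                        source_id=Path(path).stem,
                        profile=profile,
                        tau_plus=abs(tau) if direction == "gain" else None,
                        tau_minus=-abs(tau) if direction == "loss" else None,
                    )
                )
            frame = integrate_sources(sources, direction)
            write_segments(frame, out / f"consensus_{direction}.tsv")
    elif config.mode == "cohort":
        matrix = read_cohort(config.inputs[0])
        for direction in config.directions():
            gamma = spec.gamma_plus if direction == "gain" else spec.gamma_minus
            if gamma is None:
                gamma = 3.0 if direction == "gain" else -3.0
            frame = cohort_analysis(matrix, gamma, direction)
            path = out / f"cohort_{direction}.tsv"
            frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
            logger.info("wrote %d aberrant call(s) to %s", len(frame), path)
    else:  # simulate
        sim = SimulationConfig(m=config.m, reps=config.reps, seed=config.seed)
        table = power_study(sim)
        table.write(out / "power.tsv")
        logger.info("wrote power table to %s", out / "power.tsv")

    logger.info("done in %.2fs", time.time() - t0)
    return 0
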