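"""Thresholding of log2-ratio profiles into Bernoulli sequences.

Gains and losses are searched separately: a gain sequence marks probes whose
log2 ratio exceeds a positive threshold ``tau+``, a loss sequence marks
probes below a negative ``tau-``.  Band thresholds restrict the indicator to
a window above (below) the threshold so that only low-level, consistent
aberrations light up while spikes are excluded.  For cohort analysis, a
probes x samples matrix is standardized per probe (mean 0, unit variance
across samples) and thresholded on the z scale at ``gamma+`` / ``gamma-``.

Comparisons at thresholds are strict; a value exactly at the threshold maps
to 0.  Missing log2 ratios (NaN) also map to 0 — absence of evidence, never
interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from bicseg.core import BinarySequence

__all__ = [
    "CopyNumberProfile",
    "CohortMatrix",
    "ThresholdSpec",
    "binarize_gain",
    "binarize_loss",
    "binarize_band",
    "standardize_cohort",
    "binarize_cohort",
    "chrom_sort_key",
]

Direction = Literal["gain", "loss"]


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Karyotype ordering: 1..22, X, Y, then other labels alphabetically.

    A leading ``chr`` prefix is ignored.
    """
    name = str(chrom)
    if name.lower().startswith("chr"):
        name = name[3:]
    if name.isdigit():
        return (int(name), "")
    if name.upper() == "X":
        return (23, "")
    if name.upper() == "Y":
        return (24, "")
    return (25, name)


@dataclass(frozen=True)
class CopyNumberProfile:
    """Log2-ratio measurements for one sample, in genomic order.

    ``values`` holds the log2 ratios; missing measurements are NaN.
    Positions must be strictly increasing within each chromosome and
    chromosomes must appear in karyotype order (readers sort on load).
    """

    probe_ids: np.ndarray
    chroms: np.ndarray
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        probe_ids = np.asarray(self.probe_ids)
        chroms = np.asarray(self.chroms)
        positions = np.asarray(self.positions, dtype=np.int64)
        values = np.asarray(self.values, dtype=float)
        n = probe_ids.size
        if not (chroms.size == positions.size == values.size == n):
            raise ValueError("profile arrays must share one length")
        if n == 0:
            raise ValueError("profile must contain at least one probe")
        keys = [chrom_sort_key(c) for c in chroms]
        for i in range(1, n):
            if keys[i] < keys[i - 1]:
                raise ValueError("chromosomes not in karyotype order")
            if keys[i] == keys[i - 1] and positions[i] <= positions[i - 1]:
                raise ValueError(
                    f"positions not strictly increasing within chromosome "
                    f"{chroms[i]} at position {positions[i]}"
                )
        object.__setattr__(self, "probe_ids", probe_ids)
        object.__setattr__(self, "chroms", chroms)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of missing (NaN) log2 ratios."""
        return np.isnan(self.values)

    def chromosomes(self) -> list[str]:
        """Distinct chromosome labels in order of appearance."""
        seen: dict[str, None] = {}
        for c in self.chroms:
            seen.setdefault(str(c), None)
        return list(seen)

    def subset(self, mask: np.ndarray) -> "CopyNumberProfile":
        return CopyNumberProfile(
            self.probe_ids[mask],
            self.chroms[mask],
            self.positions[mask],
            self.values[mask],
        )

    def by_chromosome(self) -> list[tuple[str, "CopyNumberProfile"]]:
        return [
            (c, self.subset(np.asarray([str(x) == c for x in self.chroms])))
            for c in self.chromosomes()
        ]


@dataclass(frozen=True)
class CohortMatrix:
    """Probes x samples log2-ratio matrix on one shared probe grid."""

    values: np.ndarray  # shape (m, n)
    probe_ids: np.ndarray
    chroms: np.ndarray
    positions: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("cohort values must be a 2-D probes x samples matrix")
        m, n = values.shape
        if not (self.probe_ids.size == self.chroms.size == self.positions.size == m):
            raise ValueError("probe metadata must match the number of matrix rows")
        if np.asarray(self.sample_ids).size != n:
            raise ValueError("sample_ids must match the number of matrix columns")
        object.__setattr__(self, "values", values)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ThresholdSpec:
    """Bundle of thresholds for the different binarization modes.

    ``tau_plus`` (> 0) and ``tau_minus`` (< 0) are log2-ratio thresholds for
    gain and loss; ``epsilon`` (> 0) widens them into bands; ``gamma_plus``
    / ``gamma_minus`` are z-scale thresholds for cohort mode.
    """

    tau_plus: Optional[float] = None
    tau_minus: Optional[float] = None
    epsilon: Optional[float] = None
    gamma_plus: Optional[float] = None
    gamma_minus: Optional[float] = None

    def __post_init__(self) -> None:
        present = [
            self.tau_plus,
            self.tau_minus,
            self.epsilon,
            self.gamma_plus,
            self.gamma_minus,
        ]
        if all(v is None for v in present):
            raise ValueError("at least one threshold must be given")
        if self.tau_plus is not None and self.tau_plus <= 0:
            raise ValueError("tau_plus must be > 0")
        if self.tau_minus is not None and self.tau_minus >= 0:
            raise ValueError("tau_minus must be < 0")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def _attach_positions(profile: CopyNumberProfile) -> Optional[np.ndarray]:
    # Positions are attached only when globally strictly increasing, i.e.
    # the profile lives on a single chromosome; multi-chromosome profiles
    # are segmented per chromosome (or concatenated) downstream.
    pos = profile.positions
    if pos.size == 1 or (np.diff(pos) > 0).all():
        return pos
    return None


def binarize_gain(profile: CopyNumberProfile, tau_plus: float) -> BinarySequence:
    """Indicator of gain evidence: 1 where log2 ratio > ``tau_plus``.

    ``tau_plus`` must be positive.  Under the classical aCGH amplification
    bands, tau+ = 0.32, 1 and 1.58 target low, medium and high amplification.
    """
    if tau_plus <= 0:
        raise ValueError(f"tau_plus must be > 0, got {tau_plus}")
    with np.errstate(invalid="ignore"):
        bits = (profile.values > tau_plus).astype(np.int64)
    return BinarySequence(bits=bits, positions=_attach_positions(profile))


def binarize_loss(profile: CopyNumberProfile, tau_minus: float) -> BinarySequence:
    """Indicator of loss evidence: 1 where log2 ratio < ``tau_minus`` (< 0)."""
    if tau_minus >= 0:
        raise ValueError(f"tau_minus must be < 0, got {tau_minus}")
    with np.errstate(invalid="ignore"):
        bits = (profile.values < tau_minus).astype(np.int64)
    return BinarySequence(bits=bits, positions=_attach_positions(profile))


def binarize_band(
    profile: CopyNumberProfile,
    tau: float,
    epsilon: float,
    direction: Direction,
) -> BinarySequence:
    """Band indicator selecting consistent low-level aberrations only.

    For gains, 1 where ``tau < x < tau + epsilon``; for losses, 1 where
    ``tau - epsilon < x < tau``.  Spikes beyond the band are excluded, which
    isolates segments of modest but persistent deviation.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    if direction == "gain":
        if tau <= 0:
            raise ValueError(f"gain band requires tau > 0, got {tau}")
        lo, hi = tau, tau + epsilon
    elif direction == "loss":
        if tau >= 0:
            raise ValueError(f"loss band requires tau < 0, got {tau}")
        lo, hi = tau - epsilon, tau
    else:
        raise ValueError(f"direction must be 'gain' or 'loss', got {direction!r}")
    with np.errstate(invalid="ignore"):
        bits = ((profile.values > lo) & (profile.values < hi)).astype(np.int64)
    return BinarySequence(bits=bits, positions=_attach_positions(profile))


def standardize_cohort(matrix: CohortMatrix) -> CohortMatrix:
    """Standardize each probe row to mean 0 and unit variance across samples.

    The sample standard deviation (n - 1 denominator) is used.  A probe with
    zero variance across samples carries no relative-aberration evidence;
    its z-row is set to all zeros and a warning is emitted.
    """
    if matrix.n < 2:
        raise ValueError("cohort standardization requires n >= 2 samples")
    x = matrix.values
    mean = np.nanmean(x, axis=1, keepdims=True)
    sd = np.nanstd(x, axis=1, keepdims=True, ddof=1)
    degenerate = (sd == 0).ravel() | np.isnan(sd).ravel()
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = (x - mean) / safe_sd
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} probe(s) with zero variance across "
            "samples; their z-scores were set to 0",
            UserWarning,
            stacklevel=2,
        )
        z[degenerate, :] = 0.0
    return CohortMatrix(
        values=z,
        probe_ids=matrix.probe_ids,
        chroms=matrix.chroms,
        positions=matrix.positions,
        sample_ids=matrix.sample_ids,
    )


def binarize_cohort(
    z: CohortMatrix, gamma: float, direction: Direction
) -> list[BinarySequence]:
    """Threshold a standardized cohort at ``gamma``, one sequence per sample.

    Gain: 1 where z > gamma (gamma > 0); loss: 1 where z < gamma (gamma < 0).
    The default used downstream is gamma = +/- 3: probes deviating by three
    standard deviations from the cohort mean.
    """
    if direction == "gain":
        if gamma <= 0:
            raise ValueError(f"gain requires gamma > 0, got {gamma}")
        with np.errstate(invalid="ignore"):
            bits = (z.values > gamma).astype(np.int64)
    elif direction == "loss":
        if gamma >= 0:
            raise ValueError(f"loss requires gamma < 0, got {gamma}")
        with np.errstate(invalid="ignore"):
            bits = (z.values < gamma).astype(np.int64)
    else:
        raise ValueError(f"direction must be 'gain' or 'loss', got {direction!r}")
    pos = z.positions
    attach = pos.size == 1 or (np.diff(pos) > 0).all()
    return [
        BinarySequence(bits=bits[:, j], positions=pos if attach else None)
        for j in range(z.n)
    ]
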