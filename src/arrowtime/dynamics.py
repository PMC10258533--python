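"""Task-epoch masking and time-resolved (sliding-window) measures.

Epoch masking convolves a binarized task paradigm with a canonical
double-gamma hemodynamic response function and thresholds the result at
0.5, so that samples are labelled task or rest only once the haemodynamic
delay has played out.  The sliding-window machinery computes, per window
start, the arrow-of-time statistic (window pooled across subjects, so the
VAR fit stays identified), the moving-average activity, and the summed
Pearson connectivity, all on an identical window grid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .data_model import CohortSeries, SubjectSeries
from .metric import regional_aot
from .var_core import VARFit, pooled_ols

__all__ = [
    "Paradigm",
    "EpochMask",
    "DynamicCourse",
    "canonical_hrf",
    "hrf_epoch_mask",
    "mask_filter",
    "sliding_window_aot",
    "windowed_activity",
    "windowed_connectivity",
]


@dataclass
class Paradigm:
    """Binarized task time course (0 = rest, 1 = task) at the series' period."""

    values: np.ndarray
    sampling_period: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.sampling_period <= 0:
            raise ValueError("sampling_period must be positive (seconds)")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("paradigm values must be 0 or 1")

    @classmethod
    def from_onsets(
        cls,
        onsets: Sequence[float],
        durations: Sequence[float],
        n_time: int,
        sampling_period: float,
    ) -> "Paradigm":
        """Build the 0/1 vector from block onsets/durations in seconds."""
        values = np.zeros(n_time, dtype=int)
        for onset, dur in zip(onsets, durations):
            a = int(np.floor(onset / sampling_period))
            b = int(np.ceil((onset + dur) / sampling_period))
            values[max(a, 0) : min(b, n_time)] = 1
        return cls(values, sampling_period)


@dataclass
class EpochMask:
    """Per-sample task/rest flags (True = task)."""

    task: np.ndarray

    def __post_init__(self) -> None:
        self.task = np.asarray(self.task, dtype=bool)


def canonical_hrf(sampling_period: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the series' period.

    Response peak at 6 s, undershoot peaking at 16 s with ratio 1/6, kernel
    length 32 s, peak-normalized to 1 so that a sustained unit paradigm
    plateaus at the kernel sum relative to its peak and the 0.5 threshold is
    meaningful.
    """
    if sampling_period <= 0:
        raise ValueError("sampling_period must be positive (seconds)")
    t = np.arange(0, duration, sampling_period)
    h = gamma_dist.pdf(t, 6) - gamma_dist.pdf(t, 16) / 6.0
    return h / h.max()


def hrf_epoch_mask(p: Paradigm) -> EpochMask:
    """Convolve the paradigm with the canonical HRF and threshold at 0.5.

    Samples with convolved value strictly greater than 0.5 are task; ties at
    exactly 0.5 count as rest.
    """
    kernel = canonical_hrf(p.sampling_period)
    conv = np.convolve(p.values.astype(float), kernel)[: p.values.size]
    return EpochMask(conv > 0.5)


def mask_filter(
    c: CohortSeries, masks: Sequence[EpochMask], keep: str = "task"
) -> CohortSeries:
    """Retain only task (or rest) samples, splitting blocks at removed gaps.

    Each retained contiguous run becomes its own sub-block, so no transition
    pair is ever formed across a removed gap.  Runs shorter than 2 samples
    are dropped (they carry no transition pair); a warning counts them.
    """
    if keep not in ("task", "rest"):
        raise ValueError(f"keep must be 'task' or 'rest', got {keep!r}")
    blocks = list(c.blocks())
    if len(masks) != len(blocks):
        raise ValueError(f"{len(masks)} masks for {len(blocks)} subject blocks")
    pieces: list[np.ndarray] = []
    boundaries: list[int] = []
    order: list[str] = []
    dropped = 0
    offset = 0
    for (a, b), mask, sid in zip(blocks, masks, c.subject_order):
        flags = mask.task if keep == "task" else ~mask.task
        if flags.size != b - a:
            raise ValueError(
                f"mask length {flags.size} does not match block length {b - a} "
                f"for subject {sid!r}"
            )
        padded = np.concatenate([[False], flags, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        stops = np.flatnonzero(padded[:-1] & ~padded[1:])
        run_idx = 0
        for r0, r1 in zip(starts, stops):
            if r1 - r0 < 2:
                dropped += 1
                continue
            pieces.append(c.data[:, a + r0 : a + r1])
            boundaries.append(offset)
            order.append(f"{sid}/run{run_idx}")
            offset += r1 - r0
            run_idx += 1
    if dropped:
        warnings.warn(f"dropped {dropped} retained run(s) shorter than 2 samples")
    if not pieces:
        raise ValueError(f"no {keep} samples retained; cohort would be empty")
    return CohortSeries(
        np.concatenate(pieces, axis=1),
        np.asarray(boundaries),
        order,
        list(c.region_ids),
    )


@dataclass
class DynamicCourse:
    """Time-resolved regional measure on a shared window grid.

    ``values`` is regions x n_windows; column t corresponds to the window
    starting at sample t (stride 1), identically for all three kinds.
    """

    values: np.ndarray
    window_width: int
    kind: str
    region_ids: list[str] = field(default_factory=list)
    stride: int = 1

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        pd.DataFrame(self.values, index=self.region_ids).to_csv(
            prefix.with_suffix(".tsv"), sep="\t", header=False
        )
        meta = {
            "kind": self.kind,
            "window_width": self.window_width,
            "stride": self.stride,
            "alignment": "window_start",
            "n_windows": self.n_windows,
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _common_length(subjects: Sequence[SubjectSeries]) -> int:
    lengths = {s.n_time for s in subjects}
    if len(lengths) != 1:
        raise ValueError("all subjects must share the same length for windowing")
    return lengths.pop()


def sliding_window_aot(
    subjects: Sequence[SubjectSeries], window_width: int = 20
) -> DynamicCourse:
    """Arrow-of-time strength per region in paradigm-locked sliding windows.

    For each window start t, the W-sample window at t is taken from every
    subject; the windows are pooled (each its own block, so no cross-subject
    pair) and forward/backward VAR(1) models are fitted on the pooled
    transition pairs.  Pooling across subjects is what keeps the fit
    identified despite the short window.
    """
    n_time = _common_length(subjects)
    W = window_width
    n_regions = subjects[0].n_regions
    if W < 2 or W > n_time:
        raise ValueError(f"window width {W} incompatible with series length {n_time}")
    pooled_pairs = len(subjects) * (W - 1)
    if pooled_pairs <= n_regions:
        raise ValueError(
            f"{pooled_pairs} pooled pairs for {n_regions} regions; "
            "use more subjects or a larger window"
        )
    n_windows = n_time - W + 1
    values = np.empty((n_regions, n_windows))
    stack = np.stack([s.data for s in subjects])  # subjects x R x T
    for t in range(n_windows):
        win = stack[:, :, t : t + W]
        pred_f = np.concatenate(win[:, :, :-1], axis=1)
        resp_f = np.concatenate(win[:, :, 1:], axis=1)
        A_f, res_f = pooled_ols(pred_f, resp_f)
        A_b, res_b = pooled_ols(resp_f, pred_f)
        values[:, t] = regional_aot(
            VARFit("forward", A_f, res_f, res_f.shape[1]),
            VARFit("backward", A_b, res_b, res_b.shape[1]),
        )
    return DynamicCourse(values, W, "aot", list(subjects[0].region_ids))


def windowed_activity(
    subjects: Sequence[SubjectSeries], window_width: int = 20
) -> DynamicCourse:
    """Moving-average of the cross-subject mean activity, window-start aligned."""
    n_time = _common_length(subjects)
    W = window_width
    if W > n_time:
        raise ValueError(f"window width {W} exceeds series length {n_time}")
    mean_course = np.mean([s.data for s in subjects], axis=0)
    kernel = np.full(W, 1.0 / W)
    values = np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="valid"), 1, mean_course
    )
    return DynamicCourse(values, W, "activity", list(subjects[0].region_ids))


def windowed_connectivity(
    subjects: Sequence[SubjectSeries], window_width: int = 20
) -> DynamicCourse:
    """Summed Pearson connectivity of each region to all others, per window.

    Samples within a window are pooled over subjects after per-subject
    demeaning (so between-subject offsets do not masquerade as coupling).
    A region with zero variance inside a window has its correlations set to
    0 with a warning.
    """
    n_time = _common_length(subjects)
    W = window_width
    if W < 3:
        raise ValueError("window width must be >= 3 for correlation estimates")
    if W > n_time:
        raise ValueError(f"window width {W} exceeds series length {n_time}")
    n_regions = subjects[0].n_regions
    n_windows = n_time - W + 1
    values = np.empty((n_regions, n_windows))
    stack = np.stack([s.data for s in subjects])
    warned = False
    for t in range(n_windows):
        win = stack[:, :, t : t + W]
        centered = win - win.mean(axis=2, keepdims=True)
        pooled = np.concatenate(centered, axis=1)  # R x (S*W)
        norms = np.sqrt((pooled**2).sum(axis=1))
        zero = norms == 0
        if zero.any() and not warned:
            warnings.warn("zero-variance region inside a window; correlations set to 0")
            warned = True
        safe = np.where(zero, 1.0, norms)
        corr = (pooled @ pooled.T) / np.outer(safe, safe)
        corr[zero, :] = 0.0
        corr[:, zero] = 0.0
        np.fill_diagonal(corr, 0.0)
        values[:, t] = corr.sum(axis=1)
    return DynamicCourse(values, W, "connectivity", list(subjects[0].region_ids))
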