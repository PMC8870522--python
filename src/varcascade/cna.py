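"""Coverage-ratio copy-number calling on exome capture targets.

Per-target mean depths from a tumor/normal pair are turned into log2
tumor-over-normal ratios, median-centered to remove library-size
differences, smoothed with a short running median, and thresholded into
gain/loss segments.  This is a deliberately transparent segmenter: every
step is a documented arithmetic operation with a configurable threshold,
so recovery of injected events can be verified exactly.

Targets follow BED conventions (0-based, half-open), must be sorted and
non-overlapping, and are identical between the two profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

PROFILE_COLUMNS = ["chrom", "start", "end", "depth"]

#: segmentation defaults
MIN_TARGETS = 10
GAIN_THRESHOLD = 0.3
LOSS_THRESHOLD = -0.3
SMOOTH_WINDOW = 5
MIN_GAP = 5
MIN_NORMAL_DEPTH = 10


@dataclass
class TargetCoverageProfile:
    """Per-capture-target mean read depths for one sample."""

    targets: pd.DataFrame          # columns: chrom, start, end, depth
    sample_id: str
    role: str                      # "tumor" | "normal"

    def __post_init__(self) -> None:
        df = self.targets
        missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"coverage profile lacks columns {missing}")
        if (df["depth"] < 0).any():
            raise ValueError("negative depths in coverage profile")
        for _, grp in df.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if not (np.diff(starts) > 0).all() or (starts[1:] < ends[:-1]).any():
                raise ValueError("targets must be sorted and non-overlapping")

    @classmethod
    def read(cls, path: str, sample_id: str, role: str) -> "TargetCoverageProfile":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(targets=df, sample_id=sample_id, role=role)

    def write(self, path: str) -> None:
        self.targets[PROFILE_COLUMNS].to_csv(
            path, sep="\t", index=False, float_format="%.6g", lineterminator="\n"
        )


@dataclass(frozen=True)
class CNASegment:
    chrom: str
    start: int
    end: int
    n_targets: int
    mean_log2_ratio: float
    call: str                      # "gain" | "loss"


def compute_log_ratios(
    tumor: TargetCoverageProfile,
    normal: TargetCoverageProfile,
    min_normal_depth: int = MIN_NORMAL_DEPTH,
) -> pd.DataFrame:
    """Median-centered per-target log2(tumor/normal) ratios.

    Targets where the normal is thinner than ``min_normal_depth`` reads are
    masked (NaN): a ratio against near-zero reference coverage is noise, not
    signal.  A zero tumor depth is floored at half a read to keep the log
    finite.  Median-centering removes global library-size scaling, so a
    uniformly doubled tumor library yields all-zero ratios.
    """
    t, n = tumor.targets, normal.targets
    same = (
        len(t) == len(n)
        and (t["chrom"].to_numpy() == n["chrom"].to_numpy()).all()
        and (t["start"].to_numpy() == n["start"].to_numpy()).all()
        and (t["end"].to_numpy() == n["end"].to_numpy()).all()
    )
    if not same:
        raise ValueError("tumor and normal profiles cover different target sets")
    nd = n["depth"].to_numpy(dtype=float)
    td = np.maximum(t["depth"].to_numpy(dtype=float), 0.5)
    usable = nd >= min_normal_depth
    if usable.mean() < 0.95:
        raise ValueError(
            f"normal sample covers only {usable.mean():.0%} of targets at "
            f">={min_normal_depth} reads; pair unusable for ratio calling"
        )
    ratio = np.full(len(t), np.nan)
    ratio[usable] = np.log2(td[usable] / nd[usable])
    ratio -= np.nanmedian(ratio)
    out = t[["chrom", "start", "end"]].copy()
    out["log2_ratio"] = ratio
    return out


def segment_and_call(
    ratios: pd.DataFrame,
    min_targets: int = MIN_TARGETS,
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
    smooth_window: int = SMOOTH_WINDOW,
    min_gap: int = MIN_GAP,
) -> list[CNASegment]:
    """Threshold the smoothed ratio track into gain/loss segments.

    Per chromosome: a centered running median (window ``smooth_window``)
    absorbs single-target outliers; maximal runs of targets whose smoothed
    ratio exceeds a threshold in the same direction, after merging
    same-direction runs separated by fewer than ``min_gap`` quiet targets,
    become one segment if they span at least ``min_targets`` targets.  The
    reported mean log2 ratio is taken from the raw (unsmoothed) track.
    """
    segments: list[CNASegment] = []
    for chrom, grp in ratios.groupby("chrom", sort=False):
        raw = grp["log2_ratio"].to_numpy()
        smooth = (
            pd.Series(raw)
            .rolling(smooth_window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        state = np.zeros(len(raw), dtype=int)
        state[smooth > gain_threshold] = 1
        state[smooth < loss_threshold] = -1
        runs = _merge_runs(_find_runs(state), min_gap)
        for direction, i0, i1 in runs:
            n = i1 - i0 + 1
            if n < min_targets:
                continue
            block = raw[i0 : i1 + 1]
            segments.append(
                CNASegment(
                    chrom=str(chrom),
                    start=int(grp["start"].iloc[i0]),
                    end=int(grp["end"].iloc[i1]),
                    n_targets=n,
                    mean_log2_ratio=float(np.nanmean(block)),
                    call="gain" if direction > 0 else "loss",
                )
            )
    return segments


def _find_runs(state: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal (direction, first_index, last_index) runs of non-zero state."""
    runs = []
    i = 0
    while i < len(state):
        if state[i] != 0:
            j = i
            while j + 1 < len(state) and state[j + 1] == state[i]:
                j += 1
            runs.append((int(state[i]), i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _merge_runs(
    runs: list[tuple[int, int, int]], min_gap: int
) -> list[tuple[int, int, int]]:
    """Merge consecutive same-direction runs separated by < min_gap targets."""
    merged: list[tuple[int, int, int]] = []
    for run in runs:
        if (
            merged
            and merged[-1][0] == run[0]
            and run[1] - merged[-1][2] - 1 < min_gap
        ):
            merged[-1] = (run[0], merged[-1][1], run[2])
        else:
            merged.append(run)
    return merged


@dataclass
class CNACohortSummary:
    per_case_counts: dict[str, int]
    median_per_affected_case: Optional[float]
    count_range: Optional[tuple[int, int]]
    n_cases_with_cna: int
    total_segments: int


def summarize_cna(case_segments: dict[str, list[CNASegment]]) -> CNACohortSummary:
    """Per-case segment counts plus the cohort median and range.

    Median and range are taken over cases that carry at least one event,
    matching how "per case" statistics are conventionally reported for
    CNA-positive cases; cases with zero events are tallied separately.
    """
    counts = {case: len(segs) for case, segs in case_segments.items()}
    positive = sorted(c for c in counts.values() if c > 0)
    return CNACohortSummary(
        per_case_counts=counts,
        median_per_affected_case=(
            float(np.median(positive)) if positive else None
        ),
        count_range=(positive[0], positive[-1]) if positive else None,
        n_cases_with_cna=len(positive),
        total_segments=sum(counts.values()),
    )


def write_segments(path: str, segments: Sequence[CNASegment]) -> None:
    rows = [
        {
            "chrom": s.chrom, "start": s.start, "end": s.end,
            "n_targets": s.n_targets, "log2": round(s.mean_log2_ratio, 4),
            "call": s.call,
        }
        for s in segments
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_targets", "log2", "call"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
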