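"""Segmentation of recordings into labeled windows.

Two window geometries feed the three classifiers:

* 10 s analysis windows with 50 % overlap (250 samples at 25 Hz) for the
  action model (natural suckling / rumination / feeding / others) and the
  posture model (lying / standing). A window takes the action label that
  occupies strictly more than half of its span, else ``others``; the
  posture label is the state-tier majority.
* 31-sample event windows anchored on acceleration-magnitude peaks
  (15 samples each side of the peak) for the cough model. A window is
  ``coughing`` iff any annotated cough interval intersects its time span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ALL_CHANNELS, AnnotationTrack, IMURecording, attach_magnitudes
from .errors import LabelingError

logger = logging.getLogger(__name__)

EVENT_HALF_WIDTH = 15
EVENT_WINDOW_LEN = 2 * EVENT_HALF_WIDTH + 1  # 31 samples

OTHERS_LABEL = "others"
NON_COUGH_LABEL = "non_coughing"
COUGH_LABEL = "coughing"


@dataclass
class Window:
    """One fixed-length analysis window (half-open sample range)."""

    calf_id: str
    start_index: int
    end_index: int
    start_s: float
    signals: np.ndarray  # (window_len, 8) in ALL_CHANNELS order
    action_label: str | None = None
    state_label: str | None = None

    def __len__(self) -> int:
        return self.end_index - self.start_index


@dataclass
class EventWindow:
    """31-sample window anchored on an acceleration-magnitude peak."""

    calf_id: str
    peak_index: int
    peak_value: float
    peak_s: float
    signals: np.ndarray  # (31, 8)
    label: str | None = None


@dataclass(frozen=True)
class PeakConfig:
    """Peak-detection settings for cough candidate extraction.

    The threshold (g, on the acceleration magnitude) and minimum peak
    spacing are deployment choices; defaults are tuned so the synthetic
    cough transients are always detected while quiescent postures yield
    no candidates.
    """

    threshold: float = 1.3
    min_separation_s: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.min_separation_s < 0:
            raise ValueError("min_separation_s must be nonnegative")


def segment_windows(
    rec: IMURecording, window_s: float = 10.0, overlap: float = 0.5
) -> list[Window]:
    """Cut a recording into fixed windows of ``window_s`` seconds.

    Window starts advance by ``round(window_len * (1 - overlap))`` samples;
    a trailing partial window is dropped to preserve the fixed geometry.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    window_len = int(round(window_s * rec.fs))
    step = int(round(window_len * (1 - overlap)))
    n = len(rec)
    if n < window_len:
        logger.warning(
            "recording %s shorter than one window (%d < %d)", rec.calf_id, n, window_len
        )
        return []
    if rec.am is None or rec.gm is None:
        rec = attach_magnitudes(rec)
    data = rec.stacked(ALL_CHANNELS)
    windows = []
    for start in range(0, n - window_len + 1, step):
        windows.append(
            Window(
                calf_id=rec.calf_id,
                start_index=start,
                end_index=start + window_len,
                start_s=float(rec.t[start]),
                signals=data[start : start + window_len],
            )
        )
    return windows


def _overlap_s(iv_start: float, iv_end: float, w_start: float, w_end: float) -> float:
    return max(0.0, min(iv_end, w_end) - max(iv_start, w_start))


def label_window(window: Window, track: AnnotationTrack, fs: float) -> Window:
    """Assign the action and state labels of one window in place.

    Action: the behavior covering strictly more than 50 % of the window,
    otherwise ``others``. State: strict majority of state-tier coverage;
    an exact 50/50 tie goes to the earlier-starting state (logged).
    """
    w_start = window.start_s
    w_end = window.start_s + len(window) / fs
    span = w_end - w_start

    action = OTHERS_LABEL
    for iv in track.tier_intervals("action"):
        if _overlap_s(iv.start_s, iv.end_s, w_start, w_end) > 0.5 * span:
            action = iv.behavior
            break

    cover: dict[str, float] = {}
    first_start: dict[str, float] = {}
    for iv in track.tier_intervals("state"):
        ov = _overlap_s(iv.start_s, iv.end_s, w_start, w_end)
        if ov > 0:
            cover[iv.behavior] = cover.get(iv.behavior, 0.0) + ov
            first_start.setdefault(iv.behavior, iv.start_s)
    if not cover:
        raise LabelingError(
            f"window at {w_start:.2f}s has no state-tier coverage"
        )
    best = max(cover.values())
    leaders = [b for b, v in cover.items() if v == best]
    if len(leaders) > 1:
        leaders.sort(key=lambda b: first_start[b])
        logger.info(
            "state tie at window %.2fs: choosing earlier-starting %r", w_start, leaders[0]
        )
    window.action_label = action
    window.state_label = leaders[0]
    return window


def label_windows(
    windows: list[Window], track: AnnotationTrack, fs: float
) -> list[Window]:
    return [label_window(w, track, fs) for w in windows]


def detect_peaks(
    am: np.ndarray, cfg: PeakConfig, fs: float
) -> list[tuple[int, float]]:
    """Local maxima of the acceleration magnitude above a threshold, with a
    minimum spacing enforced by keeping the larger peak (earlier on ties).

    A sample i is a candidate when am[i-1] < am[i] >= am[i+1] and
    am[i] >= threshold. Retained peaks are returned in index order.
    """
    am = np.asarray(am, float)
    if len(am) < 3:
        return []
    interior = np.arange(1, len(am) - 1)
    cand = interior[
        (am[interior - 1] < am[interior])
        & (am[interior] >= am[interior + 1])
        & (am[interior] >= cfg.threshold)
    ]
    min_sep = int(round(cfg.min_separation_s * fs))
    # greedy by descending value, ties to the earlier index
    order = sorted(cand, key=lambda i: (-am[i], i))
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_sep for j in kept):
            kept.append(int(i))
    kept.sort()
    return [(i, float(am[i])) for i in kept]


def extract_event_windows(
    rec: IMURecording,
    peaks: list[tuple[int, float]],
    track: AnnotationTrack | None = None,
) -> list[EventWindow]:
    """One 31-sample window per peak with 15 samples on each side.

    Peaks too close to the recording boundary are dropped (logged) so the
    fixed feature geometry is preserved. With annotations present, a window
    is labeled ``coughing`` iff a cough interval intersects its time span.
    """
    n = len(rec)
    if rec.am is None or rec.gm is None:
        rec = attach_magnitudes(rec)
    data = rec.stacked(ALL_CHANNELS)
    coughs = (
        [iv for iv in track.tier_intervals("event") if iv.behavior == COUGH_LABEL]
        if track is not None
        else None
    )
    out = []
    for idx, value in peaks:
        if idx < EVENT_HALF_WIDTH or idx > n - EVENT_HALF_WIDTH - 1:
            logger.info("dropping boundary peak at index %d", idx)
            continue
        lo = idx - EVENT_HALF_WIDTH
        hi = idx + EVENT_HALF_WIDTH + 1
        w = EventWindow(
            calf_id=rec.calf_id,
            peak_index=idx,
            peak_value=value,
            peak_s=float(rec.t[idx]),
            signals=data[lo:hi],
        )
        if coughs is not None:
            w_start, w_end = float(rec.t[lo]), float(rec.t[hi - 1])
            hit = any(
                _overlap_s(iv.start_s, iv.end_s, w_start, w_end) > 0 for iv in coughs
            )
            w.label = COUGH_LABEL if hit else NON_COUGH_LABEL
        out.append(w)
    return out
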