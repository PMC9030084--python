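"""Threshold-free stride segmentation by subsequence DTW template matching.

A stride template is built by resampling a corpus of example strides to a
common length and averaging column-wise.  The continuous sensor stream
(by default the coronal-axis gyroscope) is then matched against the template
with a subsequence DTW whose per-sample distance is computed between small
neighborhood descriptors rather than raw samples, which smooths the
accumulated-distance landscape.  A stride is emitted wherever the
accumulated distance at the final template row attains a local minimum that
beats every competitor sharing its start point, so no amplitude or distance
threshold is involved.  Truncated terminal strides ("half-strides", where a
walking bout ends after roughly half the usual foot travel) are captured by
the same mechanism because the unmatched template tail is absorbed by
vertical warping steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from . import _dtw
from .core import ImuRecording, SampleInterval


@dataclass
class SdatwConfig:
    """Tunables for neighborhood features and match acceptance.

    window_halfwidth:
        Half-width ``w`` of the per-sample neighborhood (descriptor uses
        ``2w + 1`` samples, replication-padded at the edges).
    feature:
        ``"default"`` = (mean gradient, amplitude range, window mean);
        ``"wavelet"`` = single-level Daubechies-1 approximation coefficients
        of the neighborhood.
    normalize:
        Z-score signal and template before feature extraction, making the
        match invariant to positive amplitude rescaling.
    competitor_window:
        Half-width (samples) of the local-minimum acceptance window on the
        accumulated-distance curve; ``None`` = ``L // 2``.
    min_match_frac:
        Matches shorter than this fraction of the template length are
        suppressed as spurious (a genuine half-stride is ~L/2, so the
        default 1/3 keeps it while rejecting single-peak noise).
    close_gap_frac:
        In continuous walking the end of one cycle is the start of the next;
        sensor noise can stop a match a few samples early inside the
        quiescent stance tail.  Gaps between consecutive matches up to this
        fraction of the template length are closed by extending the earlier
        match; larger gaps (genuine pauses) are left open.  0 disables.
    """

    window_halfwidth: int = 3
    feature: str = "default"
    normalize: bool = False
    competitor_window: int | None = None
    min_match_frac: float = 1.0 / 3.0
    close_gap_frac: float = 0.5
    channel_sensor: str = "gyro"
    channel_role: str = "coronal"


@dataclass
class StrideTemplate:
    """Fixed-length average stride shape on one channel."""

    values: np.ndarray
    channel_role: str = "gyro:coronal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 8:
            raise ValueError("template needs at least 8 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("template values must be finite")

    @property
    def L(self) -> int:
        return int(self.values.size)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"values": self.values.tolist(), "channel_role": self.channel_role,
                 "L": self.L}
            )
        )

    @classmethod
    def from_json(cls, path) -> "StrideTemplate":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["values"], dtype=float), d.get("channel_role", "gyro:coronal"))


@dataclass
class StrideMatch:
    """One matched stride: interval, accumulated distance, warping path."""

    interval: SampleInterval
    accumulated_distance: float
    path: list = field(default_factory=list)


def resample_to_length(seq: np.ndarray, L: int) -> np.ndarray:
    """Linearly interpolate/down-sample a sequence to exactly ``L`` samples."""
    seq = np.asarray(seq, dtype=float)
    if seq.size < 2:
        raise ValueError("sequence needs at least 2 samples")
    return np.interp(np.linspace(0.0, 1.0, L), np.linspace(0.0, 1.0, seq.size), seq)


def build_template(
    strides: Sequence[np.ndarray],
    L: int | None = None,
    channel_role: str = "gyro:coronal",
) -> StrideTemplate:
    """Average variable-length strides into a fixed-length template.

    Every stride is linearly resampled to length ``L`` (default: median of
    the input lengths) and the template is the column-wise mean.
    """
    if len(strides) == 0:
        raise ValueError("need at least one stride to build a template")
    if L is None:
        L = max(int(round(float(np.median([len(s) for s in strides])))), 8)
    L = int(L)
    mat = np.vstack([resample_to_length(np.asarray(s, float), L) for s in strides])
    return StrideTemplate(mat.mean(axis=0), channel_role=channel_role)


# ---------------------------------------------------------------------------
# per-sample neighborhood descriptors
# ---------------------------------------------------------------------------


def _feature_matrix(signal: np.ndarray, cfg: SdatwConfig) -> np.ndarray:
    """Descriptor for every sample of ``signal`` (rows = samples)."""
    x = np.asarray(signal, dtype=float)
    if cfg.normalize:
        sd = x.std()
        x = (x - x.mean()) / sd if sd > 0 else x - x.mean()
    w = int(cfg.window_halfwidth)
    if w < 1:
        raise ValueError("window_halfwidth must be >= 1")
    padded = np.pad(x, w, mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(padded, 2 * w + 1)
    if cfg.feature == "default":
        grad = (win[:, -1] - win[:, 0]) / (2 * w)  # mean of first differences
        rng = win.max(axis=1) - win.min(axis=1)
        mean = win.mean(axis=1)
        return np.column_stack([grad, rng, mean])
    if cfg.feature == "wavelet":
        import pywt

        cA, _ = pywt.dwt(win, "db1", axis=1)
        return np.ascontiguousarray(cA)
    raise ValueError(f"unknown feature kind {cfg.feature!r}")


def neighborhood_features(signal: np.ndarray, i: int, cfg: SdatwConfig | None = None) -> np.ndarray:
    """Descriptor of sample ``i``: deterministic, edge-padded by replication."""
    cfg = cfg or SdatwConfig()
    return _feature_matrix(signal, cfg)[int(i)]


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


def sdatw_match(
    stream: np.ndarray,
    template: StrideTemplate,
    cfg: SdatwConfig | None = None,
) -> list[StrideMatch]:
    """Detect strides in ``stream`` by subsequence matching against ``template``.

    Returns ordered, non-overlapping matches.  Accumulated distance along each
    reported warping path is non-decreasing by construction (non-negative
    per-cell costs).
    """
    cfg = cfg or SdatwConfig()
    stream = np.asarray(stream, dtype=float)
    L = template.L
    if stream.size < L / 2:
        raise ValueError(f"stream length {stream.size} < L/2 = {L / 2}")

    F = _feature_matrix(stream, cfg)
    G = _feature_matrix(template.values, cfg)
    cost = cdist(F, G)

    end_dist, end_start, back = _dtw.subsequence_dp(cost)
    n = stream.size
    win = cfg.competitor_window if cfg.competitor_window is not None else max(1, L // 2)

    # Candidate ends come from two channels.  (1) Local minima of the
    # end-row accumulated-distance curve within the competitor window --
    # the strong, well-shaped matches.  (2) The best end among competitors
    # sharing a start point -- required for truncated terminal strides,
    # whose own minimum is shallower than a neighbouring full stride's and
    # would be shadowed inside the window.  Greedy non-overlap acceptance
    # by ascending distance then arbitrates.
    candidates: list[int] = []
    for i in range(n):
        lo, hi = max(0, i - win), min(n, i + win + 1)
        seg = end_dist[lo:hi]
        d = end_dist[i]
        if d > seg.min():
            continue
        # exact ties (e.g. zero-cost quiescent tails) resolve to the last
        # index, so a perfect match spans the whole matching region
        if np.flatnonzero(seg == seg.min())[-1] + lo == i:
            candidates.append(i)

    best_for_start: dict[int, int] = {}
    for i in range(n):  # channel (2): best end per start group
        s = int(end_start[i])
        if s not in best_for_start or end_dist[i] < end_dist[best_for_start[s]]:
            best_for_start[s] = i
    for i in candidates:  # channel (1) wins its start group outright
        s = int(end_start[i])
        if end_dist[i] <= end_dist[best_for_start[s]]:
            best_for_start[s] = i

    min_len = max(2, int(np.ceil(L * cfg.min_match_frac)))
    ranked = sorted(best_for_start.values(), key=lambda i: (end_dist[i], end_start[i]))
    accepted: list[tuple[int, int, int]] = []  # (start, end_exclusive, end_idx)
    for i in ranked:
        s, e = int(end_start[i]), i + 1
        if e - s < min_len:
            continue
        if any(s < ae and ast < e for ast, ae, _ in accepted):
            continue
        accepted.append((s, e, i))
    accepted.sort()

    # stance tails: close small inter-match gaps (end of one cycle = start
    # of the next in continuous walking)
    max_gap = int(cfg.close_gap_frac * L)
    closed = []
    for k, (s, e, i) in enumerate(accepted):
        if k + 1 < len(accepted):
            nxt = accepted[k + 1][0]
            if 0 < nxt - e <= max_gap:
                e = nxt
        closed.append((s, e, i))
    accepted = closed

    return [
        StrideMatch(
            interval=SampleInterval(s, e),
            accumulated_distance=float(end_dist[i]),
            path=_dtw.backtrack_path(back, i),
        )
        for s, e, i in accepted
    ]


def extract_stride_signals(
    rec: ImuRecording,
    strides: Sequence[SampleInterval],
    sensor: str = "gyro",
    role: str = "coronal",
) -> list[np.ndarray]:
    """Pull one channel's samples for each stride interval."""
    sig = rec.channel(sensor, role)
    return [sig[s.start : s.end].copy() for s in strides]


class SdatwSegmenter(BaseEstimator):
    """Estimator-style wrapper: fit a template on example strides, then
    detect stride intervals in new streams.

    Parameters mirror :class:`SdatwConfig`; ``template_length=None`` uses the
    median example-stride length.
    """

    def __init__(
        self,
        template_length: int | None = None,
        window_halfwidth: int = 3,
        feature: str = "default",
        normalize: bool = False,
        competitor_window: int | None = None,
        min_match_frac: float = 1.0 / 3.0,
        channel_sensor: str = "gyro",
        channel_role: str = "coronal",
    ):
        self.template_length = template_length
        self.window_halfwidth = window_halfwidth
        self.feature = feature
        self.normalize = normalize
        self.competitor_window = competitor_window
        self.min_match_frac = min_match_frac
        self.channel_sensor = channel_sensor
        self.channel_role = channel_role

    def _config(self) -> SdatwConfig:
        return SdatwConfig(
            window_halfwidth=self.window_halfwidth,
            feature=self.feature,
            normalize=self.normalize,
            competitor_window=self.competitor_window,
            min_match_frac=self.min_match_frac,
            channel_sensor=self.channel_sensor,
            channel_role=self.channel_role,
        )

    def fit(self, strides: Sequence[np.ndarray], y=None) -> "SdatwSegmenter":
        self.template_ = build_template(
            strides,
            L=self.template_length,
            channel_role=f"{self.channel_sensor}:{self.channel_role}",
        )
        return self

    def predict(self, stream) -> list[StrideMatch]:
        if not hasattr(self, "template_"):
            raise RuntimeError("SdatwSegmenter is not fitted")
        if isinstance(stream, ImuRecording):
            stream = stream.channel(self.channel_sensor, self.channel_role)
        return sdatw_match(stream, self.template_, self._config())

    def predict_intervals(self, stream) -> list[SampleInterval]:
        return [m.interval for m in self.predict(stream)]
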