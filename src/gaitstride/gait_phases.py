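"""Division of each stride into stance, push-off, swing and heel-strike.

The two abrupt foot-ground force changes in a walking cycle -- toe-off and
heel impact -- show up on the sagittal and vertical acceleration channels as
a large peak that crosses zero and decays into a trough (a "major
peak-valley pair").  The stride is segmented by (1) locating the quiescent
stance interval from the volatility (variance and IQR) of a smoothed,
sign-preserving-squared version of both channels, (2) clustering all
acceleration extrema between consecutive stances into a toe-off group and a
heel-impact group with a deterministic 1-D 2-means seeded at the stance
boundaries, (3) extracting the major peak-valley pair of each group on each
channel, and (4) fusing two (peak/valley positions) or four (plus
derivative zero-crossings) reference indices into each boundary, with a
leave-one-out 3-sigma outlier rejection in the four-reference mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

from .core import GaitPhaseLabel, ImuRecording, SampleInterval


class NoStanceFound(RuntimeError):
    """No window inside the stride qualified as static."""


class BoundaryNotFound(RuntimeError):
    """A dynamic-phase boundary could not be located for a stride."""


@dataclass
class GaitConfig:
    """Tunables for stance detection and boundary fusion.

    All volatility thresholds are *relative* to stride-wide statistics
    (absolute thresholds fail across walking speeds): a window is static
    when its variance is below ``variance_frac`` of the stride-wide variance,
    its IQR below ``iqr_frac`` of the stride-wide IQR, and its mean absolute
    level below ``level_frac`` of the stride-wide mean absolute level, on
    both channels.  The level gate excludes locally-flat but high-amplitude
    segments (e.g. the crest of a large oscillation) that spread statistics
    alone cannot distinguish from true quiescence.  ``stance_window_s`` is
    the sliding-window length in seconds (25 ms default); ``smooth_window``
    the mean-filter width (odd samples).
    """

    smooth_window: int = 5
    stance_window_s: float = 0.025
    variance_frac: float = 0.02
    iqr_frac: float = 0.10
    level_frac: float = 0.10
    min_stance_s: float = 0.08
    stance_retry: int = 3          # threshold doublings before giving up
    min_prominence_frac: float = 0.05
    kmeans_eps: float = 0.5
    kmeans_max_iter: int = 50
    merge_span_frac: float = 0.5   # rule (3): companion span > 1/2 major span
    merge_max_gap: int = 5         # rule (3): peak within 5 samples of major valley
    cluster_peaks_only: bool = False


@dataclass(frozen=True)
class PeakValleyPair:
    """A peak and the following valley on one channel, with amplitude span."""

    peak_index: int
    valley_index: int
    channel_role: str
    span: float

    def __post_init__(self) -> None:
        if self.span < 0:
            raise ValueError("span must be non-negative")


@dataclass
class BoundaryEstimate:
    """Fused boundary index with the reference indices that produced it."""

    references: list  # (source tag, index) pairs
    fused_index: int
    boundary_kind: str  # "push_off/swing" | "swing/heel_strike"


@dataclass
class StancePhase:
    """Detected static interval with the volatility statistics that passed."""

    interval: SampleInterval
    variance_v: float
    variance_s: float
    iqr_v: float
    iqr_s: float


@dataclass
class StrideDiagnostics:
    stride: SampleInterval
    ok: bool
    message: str = ""
    references: dict = field(default_factory=dict)
    rejected_refs: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def moving_mean(signal: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean with replication padding; ``window`` must be odd."""
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be an odd integer >= 1")
    x = np.asarray(signal, dtype=float)
    if window == 1:
        return x.copy()
    h = window // 2
    padded = np.pad(x, h, mode="edge")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def preprocess(signal: np.ndarray, window: int = 5) -> np.ndarray:
    """Mean-filter then deflate: ``y = sign(m) * m**2``.

    Squaring stretches the dynamic-phase amplitudes while pushing the
    near-zero stance samples even closer to zero, which sharpens the
    volatility contrast used for stance detection.
    """
    m = moving_mean(signal, window)
    return np.sign(m) * m * m


def moving_average_bank(signal: np.ndarray, windows: Sequence[int] = (3, 6, 12)) -> np.ndarray:
    """Moving averages at several scales (diagnostic utility; columns are
    one centered moving mean per window size, odd sizes enforced by +1)."""
    outs = []
    for w in windows:
        w = int(w)
        outs.append(moving_mean(signal, w if w % 2 == 1 else w + 1))
    return np.column_stack(outs)


def _iqr(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75.0, 25.0])
    return float(q75 - q25)


# ---------------------------------------------------------------------------
# stance detection
# ---------------------------------------------------------------------------


def detect_stance(
    rec: ImuRecording,
    stride: SampleInterval,
    cfg: GaitConfig | None = None,
    _threshold_scale: float = 1.0,
) -> StancePhase:
    """Locate the static interval that closes the stride cycle.

    Slides a short window over the preprocessed sagittal and vertical
    accelerations; a window is static when variance AND IQR fall below the
    relative thresholds on both channels.  The latest maximal run of static
    windows is returned (stance ends the cycle).
    """
    cfg = cfg or GaitConfig()
    sag = preprocess(rec.channel("accel", "sagittal")[stride.start : stride.end], cfg.smooth_window)
    ver = preprocess(rec.channel("accel", "vertical")[stride.start : stride.end], cfg.smooth_window)
    n = len(sag)
    wlen = max(2, int(round(cfg.stance_window_s * rec.sample_rate_hz)))
    if n < wlen:
        raise NoStanceFound(f"stride shorter than stance window ({n} < {wlen})")

    var_thr_s = cfg.variance_frac * float(np.var(sag)) * _threshold_scale
    var_thr_v = cfg.variance_frac * float(np.var(ver)) * _threshold_scale
    iqr_thr_s = cfg.iqr_frac * _iqr(sag) * _threshold_scale
    iqr_thr_v = cfg.iqr_frac * _iqr(ver) * _threshold_scale
    lvl_thr_s = cfg.level_frac * float(np.mean(np.abs(sag))) * _threshold_scale
    lvl_thr_v = cfg.level_frac * float(np.mean(np.abs(ver))) * _threshold_scale

    sw = np.lib.stride_tricks.sliding_window_view(sag, wlen)
    vw = np.lib.stride_tricks.sliding_window_view(ver, wlen)
    ok = (
        (sw.var(axis=1) <= var_thr_s)
        & (vw.var(axis=1) <= var_thr_v)
        & (np.percentile(sw, 75, axis=1) - np.percentile(sw, 25, axis=1) <= iqr_thr_s)
        & (np.percentile(vw, 75, axis=1) - np.percentile(vw, 25, axis=1) <= iqr_thr_v)
        & (np.mean(np.abs(sw), axis=1) <= lvl_thr_s)
        & (np.mean(np.abs(vw), axis=1) <= lvl_thr_v)
    )
    if not ok.any():
        raise NoStanceFound("no static window below volatility thresholds")

    # runs of qualifying window starts; bridge short gaps (noise spikes,
    # much shorter than any dynamic phase), then take the latest run of at
    # least the minimum duration
    idx = np.flatnonzero(ok)
    runs: list[list[int]] = [[int(idx[0]), int(idx[0])]]
    for i in idx[1:]:
        if i - runs[-1][1] <= 3 * wlen:
            runs[-1][1] = int(i)
        else:
            runs.append([int(i), int(i)])
    min_len = max(wlen, int(round(cfg.min_stance_s * rec.sample_rate_hz)))
    runs = [r for r in runs if r[1] + wlen - r[0] >= min_len]
    if not runs:
        raise NoStanceFound(
            f"no static run of at least {min_len} samples"
        )
    run_start, run_end = runs[-1]
    lo, hi = int(run_start), int(run_end) + wlen
    sl = slice(lo, hi)
    return StancePhase(
        interval=SampleInterval(stride.start + lo, stride.start + hi),
        variance_v=float(np.var(ver[sl])),
        variance_s=float(np.var(sag[sl])),
        iqr_v=_iqr(ver[sl]),
        iqr_s=_iqr(sag[sl]),
    )


# ---------------------------------------------------------------------------
# extrema, clustering, peak-valley pairs
# ---------------------------------------------------------------------------


def find_extrema(signal: np.ndarray, cfg: GaitConfig | None = None):
    """Strict local maxima/minima with a minimum prominence (default 5% of
    the signal range).  Plateaus report their first index."""
    cfg = cfg or GaitConfig()
    x = np.asarray(signal, dtype=float)
    rng = float(x.max() - x.min())
    prom = cfg.min_prominence_frac * rng if rng > 0 else None
    if prom is None or prom == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    peaks, pprops = find_peaks(x, prominence=prom, plateau_size=(1, None))
    valleys, vprops = find_peaks(-x, prominence=prom, plateau_size=(1, None))
    return pprops["left_edges"].astype(int), vprops["left_edges"].astype(int)


def cluster_extrema(
    indices: Sequence[int],
    last_stance_end: int,
    current_stance_begin: int,
    cfg: GaitConfig | None = None,
):
    """Deterministic 1-D 2-means split of extrema indices into a toe-off
    (left) and heel-impact (right) group.

    Centers are initialized at the bounding stance edges; assignment is by
    squared distance with ties going left; iteration stops when both centers
    move less than ``kmeans_eps`` or after ``kmeans_max_iter`` rounds.
    """
    cfg = cfg or GaitConfig()
    pts = np.asarray(sorted(int(i) for i in indices), dtype=float)
    if pts.size == 0:
        raise BoundaryNotFound("no extrema between stances")
    c0, c1 = float(last_stance_end), float(current_stance_begin)
    left = right = np.array([])
    for _ in range(cfg.kmeans_max_iter):
        d0 = (pts - c0) ** 2
        d1 = (pts - c1) ** 2
        to_left = d0 <= d1  # tie -> left
        left, right = pts[to_left], pts[~to_left]
        new_c0 = float(left.mean()) if left.size else c0
        new_c1 = float(right.mean()) if right.size else c1
        if abs(new_c0 - c0) < cfg.kmeans_eps and abs(new_c1 - c1) < cfg.kmeans_eps:
            c0, c1 = new_c0, new_c1
            break
        c0, c1 = new_c0, new_c1
    return left.astype(int), right.astype(int)


def _has_zero_crossing(signal: np.ndarray, a: int, b: int) -> bool:
    seg = signal[a : b + 1]
    return bool(seg.size >= 2 and (np.min(seg) < 0.0) and (np.max(seg) > 0.0))


def find_major_pvp(
    signal: np.ndarray,
    peaks: Sequence[int],
    valleys: Sequence[int],
    cfg: GaitConfig | None = None,
    channel_role: str = "",
) -> PeakValleyPair | None:
    """Find the dominant zero-crossing peak->valley excursion.

    Each peak is paired with the nearest valley after it.  Among pairs whose
    signal crosses zero between the two extremes, the one with the largest
    amplitude span is the major pair.  A runner-up pair whose span exceeds
    half the major span and whose peak lies within ``merge_max_gap`` samples
    of the major valley merges with it into one pair spanning (first peak,
    second valley) -- two back-to-back force reversals acting as one event.

    Returns ``None`` when no pair satisfies the zero-crossing condition
    (callers may fall back to the largest-span pair).
    """
    cfg = cfg or GaitConfig()
    signal = np.asarray(signal, dtype=float)
    peaks = sorted(int(p) for p in peaks)
    valleys = np.asarray(sorted(int(v) for v in valleys), dtype=int)

    pairs = []
    for p in peaks:
        later = valleys[valleys > p]
        if later.size == 0:
            continue
        v = int(later[0])
        pairs.append((p, v, float(signal[p] - signal[v])))
    crossing = [pr for pr in pairs if _has_zero_crossing(signal, pr[0], pr[1])]
    if not crossing:
        return None
    major = max(crossing, key=lambda pr: pr[2])
    # merge rule: a strong runner-up hugging the major valley
    for p, v, span in sorted(crossing, key=lambda pr: -pr[2]):
        if (p, v) == major[:2]:
            continue
        if span > cfg.merge_span_frac * major[2] and 0 <= p - major[1] < cfg.merge_max_gap:
            merged_span = float(signal[major[0]] - signal[v])
            major = (major[0], v, max(merged_span, major[2]))
            break
    return PeakValleyPair(major[0], major[1], channel_role, max(major[2], 0.0))


def largest_span_pair(
    signal: np.ndarray, peaks: Sequence[int], valleys: Sequence[int], channel_role: str = ""
) -> PeakValleyPair | None:
    """Fallback pairing ignoring the zero-crossing condition."""
    signal = np.asarray(signal, dtype=float)
    valleys = np.asarray(sorted(int(v) for v in valleys), dtype=int)
    best = None
    for p in sorted(int(p) for p in peaks):
        later = valleys[valleys > p]
        if later.size == 0:
            continue
        v = int(later[0])
        span = float(signal[p] - signal[v])
        if best is None or span > best[2]:
            best = (p, v, span)
    if best is None:
        return None
    return PeakValleyPair(best[0], best[1], channel_role, max(best[2], 0.0))


# ---------------------------------------------------------------------------
# derivative references and outlier rejection
# ---------------------------------------------------------------------------


def derivative(signal: np.ndarray) -> np.ndarray:
    """First difference ``x[i+1] - x[i]`` kept at the input length by
    replicating the last difference."""
    x = np.asarray(signal, dtype=float)
    d = np.diff(x)
    return np.append(d, d[-1])


def zero_crossing_refs(
    deriv: np.ndarray, pvp: PeakValleyPair, polarity: str
) -> int | None:
    """Zero-crossing of the derivative nearest the pair's matching extremum.

    Negative crossings (derivative passes + -> -) mark signal peaks; positive
    crossings (- -> +) mark valleys.  Returns ``None`` when the stride has no
    crossing of the requested polarity.
    """
    d = np.asarray(deriv, dtype=float)
    if polarity == "negative":
        hits = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
        anchor = pvp.peak_index
    elif polarity == "positive":
        hits = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0)) + 1
        anchor = pvp.valley_index
    else:
        raise ValueError("polarity must be 'negative' or 'positive'")
    if hits.size == 0:
        return None
    return int(hits[np.argmin(np.abs(hits - anchor))])


def reject_outliers(refs: Sequence[int], n_sigma: float = 3.0) -> list[int]:
    """Leave-one-out outlier rejection of boundary reference indices.

    For each reference, a mean and (unbiased) SD are fitted on the others;
    references farther than ``n_sigma`` SDs are dropped.  Skipped entirely
    for fewer than 4 references (the SD of 2 points is degenerate), and
    never empties the set.
    """
    refs = [int(r) for r in refs]
    if len(refs) < 4:
        return list(refs)
    keep = []
    for k, r in enumerate(refs):
        others = np.array([x for j, x in enumerate(refs) if j != k], dtype=float)
        mu = others.mean()
        sd = others.std(ddof=1)
        if sd == 0:
            if r != mu:
                continue
        elif abs(r - mu) > n_sigma * sd:
            continue
        keep.append(r)
    return keep if keep else list(refs)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# boundary fusion and full segmentation
# ---------------------------------------------------------------------------


def _channel_pvp(signal, lo, hi, cfg, role, valley_hi=None):
    """Major PVP of one channel with peaks restricted to the cluster range
    [lo, hi]; the paired valley may fall anywhere in the dynamic region up to
    ``valley_hi`` (pairing is nearest-after on the signal, the cluster only
    localizes the force event)."""
    if valley_hi is None:
        valley_hi = hi
    peaks, valleys = find_extrema(signal, cfg)
    peaks = [p for p in peaks if lo <= p <= hi]
    valleys = [v for v in valleys if lo <= v <= valley_hi]
    pvp = find_major_pvp(signal, peaks, valleys, cfg, channel_role=role)
    if pvp is None:
        pvp = largest_span_pair(signal, peaks, valleys, channel_role=role)
    return pvp


def locate_boundaries(
    rec: ImuRecording,
    stride: SampleInterval,
    mode: str = "four_ref",
    cfg: GaitConfig | None = None,
    stance: StancePhase | None = None,
):
    """Fuse reference indices into the two dynamic-phase boundaries.

    Returns ``(b1, b2, diagnostics)`` where ``b1`` separates push-off from
    swing and ``b2`` swing from heel-strike, both :class:`BoundaryEstimate`.

    Two-reference mode fuses, for ``b1``, the sagittal major-pair peak with
    the vertical major-pair valley, and for ``b2`` the sagittal and vertical
    major-pair peaks.  Four-reference mode adds the nearest derivative
    zero-crossings (negative for peaks, positive for valleys) and applies
    leave-one-out outlier rejection before averaging.
    """
    if mode not in ("two_ref", "four_ref"):
        raise ValueError("mode must be 'two_ref' or 'four_ref'")
    cfg = cfg or GaitConfig()
    if stance is None:
        stance = detect_stance(rec, stride, cfg)

    sag = preprocess(rec.channel("accel", "sagittal")[stride.start : stride.end], cfg.smooth_window)
    ver = preprocess(rec.channel("accel", "vertical")[stride.start : stride.end], cfg.smooth_window)
    last_stance_end = 0  # stride-local: previous stance closed at the stride start
    cur_stance_begin = stance.interval.start - stride.start

    ps, vs = find_extrema(sag, cfg)
    pv, vv = find_extrema(ver, cfg)
    if cfg.cluster_peaks_only:
        pool = np.concatenate([ps, pv])
    else:
        pool = np.concatenate([ps, vs, pv, vv])
    pool = pool[(pool > last_stance_end) & (pool < cur_stance_begin)]
    left, right = cluster_extrema(pool, last_stance_end, cur_stance_begin, cfg)
    if left.size == 0 or right.size == 0:
        raise BoundaryNotFound("an extrema cluster is empty")

    def bounds(cluster):
        return int(cluster.min()), int(cluster.max())

    llo, lhi = bounds(left)
    rlo, rhi = bounds(right)

    dyn_end = cur_stance_begin
    sag_l = _channel_pvp(sag, llo, lhi, cfg, "sagittal", valley_hi=dyn_end)
    ver_l = _channel_pvp(ver, llo, lhi, cfg, "vertical", valley_hi=dyn_end)
    sag_r = _channel_pvp(sag, rlo, rhi, cfg, "sagittal", valley_hi=dyn_end)
    ver_r = _channel_pvp(ver, rlo, rhi, cfg, "vertical", valley_hi=dyn_end)
    if sag_l is None or ver_l is None:
        raise BoundaryNotFound("push-off cluster lacks a usable peak-valley pair")
    if sag_r is None or ver_r is None:
        raise BoundaryNotFound("heel-strike cluster lacks a usable peak-valley pair")

    refs1 = [("sag_acc", sag_l.peak_index), ("vert_acc", ver_l.valley_index)]
    refs2 = [("sag_acc", sag_r.peak_index), ("vert_acc", ver_r.peak_index)]
    if mode == "four_ref":
        dsag, dver = derivative(sag), derivative(ver)
        extra1 = [
            ("sag_deriv", zero_crossing_refs(dsag, sag_l, "negative")),
            ("vert_deriv", zero_crossing_refs(dver, ver_l, "positive")),
        ]
        extra2 = [
            ("sag_deriv", zero_crossing_refs(dsag, sag_r, "negative")),
            ("vert_deriv", zero_crossing_refs(dver, ver_r, "negative")),
        ]
        refs1 += [(t, i) for t, i in extra1 if i is not None]
        refs2 += [(t, i) for t, i in extra2 if i is not None]

    def fuse(refs, kind):
        idxs = [i for _, i in refs]
        kept = reject_outliers(idxs) if mode == "four_ref" else idxs
        fused = _round_half_away(float(np.mean(kept)))
        return BoundaryEstimate(references=list(refs), fused_index=fused, boundary_kind=kind), set(
            idxs
        ) - set(kept)

    b1, rej1 = fuse(refs1, "push_off/swing")
    b2, rej2 = fuse(refs2, "swing/heel_strike")
    if not (last_stance_end < b1.fused_index < b2.fused_index < cur_stance_begin):
        raise BoundaryNotFound(
            f"boundary ordering violated: 0 < {b1.fused_index} < "
            f"{b2.fused_index} < {cur_stance_begin} fails"
        )
    # re-express in recording coordinates
    b1.fused_index += stride.start
    b2.fused_index += stride.start
    b1.references = [(t, i + stride.start) for t, i in b1.references]
    b2.references = [(t, i + stride.start) for t, i in b2.references]
    diag = {"rejected_b1": sorted(rej1), "rejected_b2": sorted(rej2)}
    return b1, b2, diag


def segment_gait(
    rec: ImuRecording,
    strides: Sequence[SampleInterval],
    mode: str = "four_ref",
    cfg: GaitConfig | None = None,
):
    """Segment every stride into its four phases.

    Returns ``(labels, diagnostics)``.  For each successful stride the
    emitted phases tile it exactly: ``[start, b1) [b1, b2) [b2, stance_begin)
    [stance_begin, end)``.  Strides where stance or a boundary cannot be
    found contribute no labels but one diagnostic record.
    """
    cfg = cfg or GaitConfig()
    labels: list[GaitPhaseLabel] = []
    diags: list[StrideDiagnostics] = []
    for stride in strides:
        try:
            stance = None
            scale = 1.0
            for attempt in range(cfg.stance_retry + 1):
                try:
                    stance = detect_stance(rec, stride, cfg, _threshold_scale=scale)
                    break
                except NoStanceFound:
                    if attempt == cfg.stance_retry:
                        raise
                    scale *= 2.0
            b1, b2, extra = locate_boundaries(rec, stride, mode=mode, cfg=cfg, stance=stance)
        except (NoStanceFound, BoundaryNotFound) as exc:
            diags.append(StrideDiagnostics(stride=stride, ok=False, message=str(exc)))
            continue
        sb = stance.interval.start
        labels += [
            GaitPhaseLabel("push_off", SampleInterval(stride.start, b1.fused_index)),
            GaitPhaseLabel("swing", SampleInterval(b1.fused_index, b2.fused_index)),
            GaitPhaseLabel("heel_strike", SampleInterval(b2.fused_index, sb)),
            GaitPhaseLabel("stance", SampleInterval(sb, stride.end)),
        ]
        diags.append(
            StrideDiagnostics(
                stride=stride,
                ok=True,
                references={
                    "b1": [(t, int(i)) for t, i in b1.references],
                    "b2": [(t, int(i)) for t, i in b2.references],
                },
                rejected_refs=extra,
            )
        )
    return labels, diags


class GaitPhaseSegmenter(BaseEstimator):
    """Estimator-style front end over :func:`segment_gait` (stateless fit)."""

    def __init__(self, mode: str = "four_ref", **config):
        self.mode = mode
        self.config = config

    def fit(self, X=None, y=None) -> "GaitPhaseSegmenter":
        self.cfg_ = GaitConfig(**self.config)
        return self

    def predict(self, rec: ImuRecording, strides: Sequence[SampleInterval]):
        if not hasattr(self, "cfg_"):
            self.fit()
        return segment_gait(rec, strides, mode=self.mode, cfg=self.cfg_)
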