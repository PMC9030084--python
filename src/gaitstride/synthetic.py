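"""Seeded generator of foot-mounted-IMU walking signals with ground truth.

Each stride cycle is synthesized from smooth per-phase kernels on the
sagittal and vertical acceleration channels that reproduce the canonical
walking morphology: a push-off ramp ending in a sharp force reversal (a
large zero-crossing peak-valley pair at toe-off), a quiescent inertial
swing terminated by the heel-impact spike (a second, larger pair), a
heel-strike deceleration carrying a late sub-peak ("foot slap"), and a
near-zero stance closing the cycle.  The kernels are monotone-cubic
(PCHIP) interpolants through versioned knot tables, so every planted
extremum falls exactly on its knot index and the toe-off / heel-impact
pairs sit exactly on the phase boundaries.  A stride-periodic bump train
on the coronal gyroscope channel provides the template-matching signal.

Signal amplitude grows linearly with cadence, emulating the speed-dependent
magnitude of foot-sensor mutations, and the true stride length follows a
declared map (default: affine in the Weinberg term of the noise-free
vertical kernel), so parameter-recovery experiments are self-describing.
A terminal "half-stride" -- the bout-ending cycle that covers roughly half
the usual foot travel and then rests -- can be appended.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .core import AnnotationSet, GaitPhaseLabel, ImuRecording, SampleInterval

#: cycle order and default duration fractions of the four phases
DEFAULT_PHASE_FRACTIONS = {
    "push_off": 0.20,
    "swing": 0.35,
    "heel_strike": 0.15,
    "stance": 0.30,
}


@dataclass
class WalkConfig:
    """Study conditions for one synthetic walk.

    noise_sd is expressed as a fraction of the per-stride signal amplitude;
    amplitude scales linearly with cadence around ``amplitude_ref_cadence``.
    The true stride length is ``length_intercept + length_slope *
    (vertical range)**0.25`` on the noise-free kernel, plus optional
    Gaussian noise of SD ``length_noise_sd`` (meters).
    """

    n_strides: int = 50
    sample_rate_hz: float = 100.0
    cadence_hz: float = 0.9
    speed_profile: str = "constant"  # constant | alternating | ramp
    cadence_range: tuple = (0.7, 1.1)
    amplitude_base: float = 8.0  # m/s^2 at the reference cadence
    amplitude_ref_cadence: float = 0.9
    noise_sd: float = 0.0
    include_half_stride: bool = False
    seed: int = 0
    phase_fractions: dict = field(default_factory=lambda: dict(DEFAULT_PHASE_FRACTIONS))
    length_intercept: float = 0.3
    length_slope: float = 0.5
    length_noise_sd: float = 0.0
    length_map: Callable[[dict], float] | None = None

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if self.sample_rate_hz <= 0 or self.cadence_hz <= 0:
            raise ValueError("rates must be positive")
        if self.noise_sd < 0 or self.length_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        fr = self.phase_fractions
        if set(fr) != set(DEFAULT_PHASE_FRACTIONS):
            raise ValueError("phase_fractions must cover exactly the four phases")
        if any(v <= 0 for v in fr.values()) or abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("phase fractions must be positive and sum to 1")
        if self.speed_profile not in ("constant", "alternating", "ramp"):
            raise ValueError("speed_profile must be constant | alternating | ramp")

    def stride_cadences(self) -> np.ndarray:
        lo, hi = self.cadence_range
        if self.speed_profile == "constant":
            return np.full(self.n_strides, self.cadence_hz)
        if self.speed_profile == "alternating":
            return np.where(np.arange(self.n_strides) % 2 == 0, lo, hi)
        return np.linspace(lo, hi, self.n_strides)

    def amplitude(self, cadence: float) -> float:
        return self.amplitude_base * cadence / self.amplitude_ref_cadence

    def true_length(self, kernel_features: dict) -> float:
        if self.length_map is not None:
            return float(self.length_map(kernel_features))
        return float(
            self.length_intercept
            + self.length_slope * kernel_features["vertical_range"] ** 0.25
        )

    def length_map_description(self) -> str:
        if self.length_map is not None:
            return "custom callable"
        return (
            f"length = {self.length_intercept} + {self.length_slope}"
            " * vertical_range**0.25 (noise-free kernel)"
            + (f" + N(0, {self.length_noise_sd}**2)" if self.length_noise_sd else "")
        )


@dataclass
class SyntheticWalk:
    recording: ImuRecording
    truth: AnnotationSet
    injected_events: list  # per stride: planted major-PVP indices per channel
    config: WalkConfig


def _pchip(knots: list[tuple[int, float]], n: int) -> np.ndarray:
    """Monotone cubic through (index, value) knots; flat outside the knots.

    Duplicate indices collapse to the last value given.  PCHIP is used
    because it cannot overshoot, so local extrema land exactly on knots.
    """
    d: dict[int, float] = {}
    for i, v in knots:
        d[int(np.clip(i, 0, n - 1))] = float(v)
    xs = np.array(sorted(d), dtype=float)
    ys = np.array([d[int(x)] for x in xs])
    out = np.zeros(n)
    t = np.arange(n, dtype=float)
    inside = (t >= xs[0]) & (t <= xs[-1])
    if xs.size == 1:
        out[inside] = ys[0]
    else:
        out[inside] = PchipInterpolator(xs, ys)(t[inside])
    out[t < xs[0]] = ys[0]
    out[t > xs[-1]] = ys[-1]
    return out


def _stride_kernel(n: int, fractions: dict, amplitude: float):
    """Noise-free sagittal/vertical/gyro kernels for one stride of ``n``
    samples, plus boundary indices and planted pair positions."""
    b1 = int(round(fractions["push_off"] * n))
    b2 = int(round((fractions["push_off"] + fractions["swing"]) * n))
    b3 = int(round((1.0 - fractions["stance"]) * n))
    b1 = max(4, b1)
    b2 = max(b1 + 4, b2)
    b3 = max(b2 + 4, min(b3, n - 4))
    A = amplitude
    d = max(2, int(round(0.04 * n)))  # peak-to-valley lag of the planted pairs
    sub = b3 - max(3, int(round(0.05 * n)))  # late heel-strike sub-peak

    # sagittal: dip during push-off, toe-off PEAK exactly at b1, quiescent
    # swing, heel-impact peak exactly at b2, recovery ending at stance
    sag = _pchip(
        [
            (0, 0.0),
            (b1 // 2, -0.5 * A),
            (b1, 1.0 * A),
            (b1 + d, -0.8 * A),
            (b1 + 2 * d, 0.0),
            (b2 - d, -0.3 * A),
            (b2, 1.2 * A),
            (b2 + d, -0.9 * A),
            (sub, -0.35 * A),
            (b3 - 1, -0.12 * A),
            (b3, 0.0),
            (n - 1, 0.0),
        ],
        n,
    )
    # vertical: push-off peak then toe-off VALLEY exactly at b1, quiescent
    # swing with a shallow pre-impact dip, heel-impact peak exactly at b2,
    # late sub-peak ("foot slap") decaying into stance
    ver = _pchip(
        [
            (0, 0.0),
            (int(round(0.6 * b1)), 0.9 * A),
            (b1, -1.0 * A),
            (b1 + d, 0.15 * A),
            (b1 + 2 * d, 0.0),
            (b2 - 2 * d, -0.35 * A),
            (b2, 1.3 * A),
            (b2 + d, -1.0 * A),
            (sub, 0.45 * A),
            (b3 - 1, 0.12 * A),
            (b3, 0.0),
            (n - 1, 0.0),
        ],
        n,
    )
    # coronal gyroscope: stride-periodic bump train for template matching
    gyr = _pchip(
        [
            (0, 0.0),
            (b1 // 2, -0.35 * A),
            (b1, 0.1 * A),
            ((b1 + b2) // 2, 1.0 * A),
            (b2, -0.25 * A),
            ((b2 + b3) // 2, -0.45 * A),
            (b3, 0.0),
            (n - 1, 0.0),
        ],
        n,
    )
    events = {
        "sagittal": {"b1_pair": (b1, b1 + d), "b2_pair": (b2, b2 + d)},
        "vertical": {"b1_pair": (int(round(0.6 * b1)), b1), "b2_pair": (b2, b2 + d)},
    }
    return sag, ver, gyr, (b1, b2, b3), events


def generate_walk(cfg: WalkConfig) -> SyntheticWalk:
    """Synthesize one walk; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    cadences = cfg.stride_cadences()

    sag_parts, ver_parts, gyr_parts = [], [], []
    strides: list[SampleInterval] = []
    phases: list[GaitPhaseLabel] = []
    lengths: list[float] = []
    events: list[dict] = []
    pos = 0
    for k, cad in enumerate(cadences):
        n = int(round(cfg.sample_rate_hz / cad))
        A = cfg.amplitude(float(cad))
        sag, ver, gyr, (b1, b2, b3), ev = _stride_kernel(n, cfg.phase_fractions, A)
        kernel_features = {
            "vertical_range": float(ver.max() - ver.min()),
            "sagittal_range": float(sag.max() - sag.min()),
            "cadence": float(cad),
            "amplitude": A,
        }
        length = cfg.true_length(kernel_features)
        if cfg.length_noise_sd > 0:
            length += float(rng.normal(0.0, cfg.length_noise_sd))

        half = cfg.include_half_stride and k == cfg.n_strides - 1
        if half:
            # bout-ending cycle: push-off and swing happen at reduced
            # amplitude, but the foot settles without the heel-impact spike
            # and rests -- a feeble first portion followed by quiescence
            cut = b2
            sag = np.concatenate([sag[:cut] * 0.8, np.zeros(n - cut)])
            ver = np.concatenate([ver[:cut] * 0.8, np.zeros(n - cut)])
            gyr = np.concatenate([gyr[:cut] * 0.8, np.zeros(n - cut)])
            strides.append(SampleInterval(pos, pos + n))
            lengths.append(0.5 * length)
            events.append({"half_stride": True})
        else:
            strides.append(SampleInterval(pos, pos + n))
            phases += [
                GaitPhaseLabel("push_off", SampleInterval(pos, pos + b1)),
                GaitPhaseLabel("swing", SampleInterval(pos + b1, pos + b2)),
                GaitPhaseLabel("heel_strike", SampleInterval(pos + b2, pos + b3)),
                GaitPhaseLabel("stance", SampleInterval(pos + b3, pos + n)),
            ]
            lengths.append(length)
            events.append(
                {
                    "half_stride": False,
                    "boundaries": (pos + b1, pos + b2, pos + b3),
                    "sagittal": {
                        key: (pos + a, pos + b) for key, (a, b) in ev["sagittal"].items()
                    },
                    "vertical": {
                        key: (pos + a, pos + b) for key, (a, b) in ev["vertical"].items()
                    },
                }
            )
        sag_parts.append(sag)
        ver_parts.append(ver)
        gyr_parts.append(gyr)
        pos += n

    sag = np.concatenate(sag_parts)
    ver = np.concatenate(ver_parts)
    gyr = np.concatenate(gyr_parts)
    n_total = sag.size
    mean_amp = cfg.amplitude(float(np.mean(cadences)))
    if cfg.noise_sd > 0:
        sag = sag + rng.normal(0.0, cfg.noise_sd * mean_amp, n_total)
        ver = ver + rng.normal(0.0, cfg.noise_sd * mean_amp, n_total)
        gyr = gyr + rng.normal(0.0, cfg.noise_sd * mean_amp, n_total)

    accel = np.zeros((n_total, 3))
    gyro = np.zeros((n_total, 3))
    accel[:, 1] = sag
    accel[:, 2] = ver
    if cfg.noise_sd > 0:
        accel[:, 0] = rng.normal(0.0, cfg.noise_sd * mean_amp, n_total)
        gyro[:, 1] = rng.normal(0.0, 0.3 * cfg.noise_sd * mean_amp, n_total)
        gyro[:, 2] = rng.normal(0.0, 0.3 * cfg.noise_sd * mean_amp, n_total)
    gyro[:, 0] = gyr

    rec = ImuRecording(
        sample_rate_hz=cfg.sample_rate_hz,
        timestamps=np.arange(n_total) / cfg.sample_rate_hz,
        accel=accel,
        gyro=gyro,
        channel_map={
            "accel": {"coronal": 0, "sagittal": 1, "vertical": 2},
            "gyro": {"coronal": 0, "sagittal": 1, "vertical": 2},
        },
        meta={"accel_unit": "m/s2", "gyro_unit": "deg/s", "synthetic": True},
    )
    truth = AnnotationSet(
        strides=strides,
        phases=phases,
        stride_lengths=lengths,
        meta={
            "length_unit": "m",
            "sample_rate_hz": cfg.sample_rate_hz,
            "length_map": cfg.length_map_description(),
        },
    )
    return SyntheticWalk(recording=rec, truth=truth, injected_events=events, config=cfg)


def generate_dataset(
    cadences: Sequence[float],
    seeds: Sequence[int],
    out_dir=None,
    **cfg_kwargs,
) -> tuple[list[SyntheticWalk], dict]:
    """Walks over a cadence grid (e.g. slow/middle/fast) x seeds, plus a
    reproducibility manifest.  With ``out_dir`` the recordings, truth and
    manifest are also written to disk."""
    if len(cadences) == 0 or len(seeds) == 0:
        raise ValueError("need at least one cadence and one seed")
    walks = []
    entries = []
    for cad in cadences:
        for seed in seeds:
            cfg = WalkConfig(cadence_hz=float(cad), seed=int(seed), **cfg_kwargs)
            walks.append(generate_walk(cfg))
            entries.append(
                {
                    "cadence_hz": float(cad),
                    "seed": int(seed),
                    "n_strides": cfg.n_strides,
                    "sample_rate_hz": cfg.sample_rate_hz,
                    "noise_sd": cfg.noise_sd,
                }
            )
    manifest = {
        "walks": entries,
        "length_map": walks[0].config.length_map_description(),
        "phase_fractions": dict(walks[0].config.phase_fractions),
    }
    if out_dir is not None:
        from .core import save_recording, write_annotations

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, w in enumerate(walks):
            save_recording(w.recording, out / f"walk_{i:03d}.csv")
            write_annotations(w.truth, out / f"walk_{i:03d}.truth.json")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return walks, manifest
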