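"""Fibre-photometry signal conditioning.

The processing chain mirrors standard isosbestic-controlled photometry:

1. ``demux`` — split the interleaved 415/470 nm sample stream into two
   time-aligned series (the two 20 Hz sample combs are offset by half an
   interleave period; nearest-sample pairing, no resampling).
2. ``isosbestic_correct`` — affine least-squares fit of the isosbestic onto
   the activity channel, subtracted, removing shared motion and bleach.
3. ``moving_min_baseline`` — subtract a sliding-window minimum (20 s
   default, centred) to remove residual slow drift.
4. ``dff_normalize`` — ΔF/F_mean = (F - F_mean)/F_mean, then min–max
   scaling to [0, 1].
5. ``align_events`` — peri-event windows around scored bout onsets.

Every step is deterministic; nothing here consumes randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d

from .datatypes import EventLog, PhotometryRecording, warn


@dataclass
class ChannelSeries:
    """One de-interleaved channel: sample times (s) and values."""

    t: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.values = np.asarray(self.values, float)
        if self.t.shape != self.values.shape:
            raise ValueError("t and values must have equal length")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class DffTrace:
    """Normalized ΔF/F trace; ``normalized`` records min–max scaling."""

    t: np.ndarray
    dff: np.ndarray
    normalized: bool = False

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_s": self.t, "dff": self.dff}).to_csv(path, index=False)


def demux(rec: PhotometryRecording) -> tuple[ChannelSeries, ChannelSeries]:
    """Split the interleaved stream into (isosbestic, activity) series.

    Validates strict channel alternation (rejecting with the index of the
    first violation) and truncates the longer channel by one sample when the
    total length is odd, so the returned series have equal length.
    """
    if len(rec) == 0:
        raise ValueError("empty recording")
    ch = rec.samples["channel"].to_numpy()
    same = np.nonzero(ch[1:] == ch[:-1])[0]
    if same.size:
        raise ValueError(f"channel alternation violated at sample index {int(same[0]) + 1}")
    vals = rec.samples["value"].to_numpy(float)
    idx = np.arange(len(rec))
    t_all = idx / (2.0 * rec.rate_hz)  # interleaved clock

    out = {}
    for name in (PhotometryRecording.CH_ISO, PhotometryRecording.CH_ACT):
        mask = ch == name
        out[name] = ChannelSeries(t_all[mask], vals[mask])
    iso, act = out[PhotometryRecording.CH_ISO], out[PhotometryRecording.CH_ACT]
    n = min(len(iso), len(act))
    iso = ChannelSeries(iso.t[:n], iso.values[:n])
    act = ChannelSeries(act.t[:n], act.values[:n])
    return iso, act


def interleave(iso: ChannelSeries, act: ChannelSeries,
               rate_hz: float = 20.0) -> PhotometryRecording:
    """Rebuild an interleaved recording (inverse of :func:`demux`).

    The channel whose first sample time is earlier leads the stream.
    """
    series = sorted(
        [(iso, PhotometryRecording.CH_ISO), (act, PhotometryRecording.CH_ACT)],
        key=lambda s: s[0].t[0] if len(s[0]) else np.inf,
    )
    n = len(series[0][0]) + len(series[1][0])
    values = np.empty(n)
    channels = np.empty(n, dtype=object)
    for k, (s, name) in enumerate(series):
        values[k::2] = s.values
        channels[k::2] = name
    samples = pd.DataFrame(
        {"sample_index": np.arange(n), "channel": channels, "value": values}
    )
    return PhotometryRecording(samples, rate_hz)


def isosbestic_correct(activity: ChannelSeries, isosbestic: ChannelSeries) -> ChannelSeries:
    """Subtract the affine least-squares fit of the isosbestic channel.

    The whole-session fit (slope + intercept) of 415 nm regressed onto the
    470 nm signal captures shared motion and bleach; the corrected trace is
    activity − fitted. A constant isosbestic channel carries no regression
    information, so the fall-back is plain mean subtraction (with warning).
    """
    if len(activity) != len(isosbestic):
        raise ValueError("channel lengths differ")
    x = isosbestic.values
    y = activity.values
    if np.ptp(x) == 0.0:
        warn("constant isosbestic channel; falling back to mean subtraction")
        return ChannelSeries(activity.t, y - y.mean())
    slope, intercept = np.polyfit(x, y, 1)
    return ChannelSeries(activity.t, y - (slope * x + intercept))


def moving_min_baseline(series: ChannelSeries, window_s: float = 20.0,
                        centred: bool = True) -> ChannelSeries:
    """Subtract a sliding-window minimum baseline.

    ``window_s`` is the window width in seconds on the channel's own clock;
    at the edges the window shrinks to the available samples. The trailing
    variant (window ending at the current sample) is available with
    ``centred=False``.
    """
    if window_s <= 0:
        raise ValueError("window must be > 0")
    n = len(series)
    dt = float(np.median(np.diff(series.t))) if n > 1 else 1.0
    w = int(round(window_s / dt))
    if w < 2:
        raise ValueError("window shorter than 2 samples")
    w = min(w, n)
    v = series.values
    if centred:
        # mode='nearest' replicates edge values, equivalent to a shrunken window
        base = minimum_filter1d(v, size=w, mode="nearest")
    else:
        base = minimum_filter1d(v, size=w, origin=(w - 1) // 2, mode="nearest")
    return ChannelSeries(series.t, v - base)


def dff_normalize(series: ChannelSeries, reference_mean: float | None = None,
                  normalize: bool = True) -> DffTrace:
    """ΔF/F_mean = (F − F_mean)/F_mean, then min–max scaling to [0, 1].

    By default the denominator is the series' own mean, matching the stated
    formula. After isosbestic regression (which zeroes the residual mean)
    that denominator loses its meaning as a brightness scale, so the full
    chain passes the raw activity-channel session mean as
    ``reference_mean``; the numerator still subtracts the series' own mean.
    A zero denominator is rejected; a constant series min–max-scales
    degenerately and is returned as all-0.5 with a warning. With
    ``normalize=False`` the unscaled ΔF/F is returned.
    """
    f = series.values
    denom = f.mean() if reference_mean is None else float(reference_mean)
    if denom == 0.0:
        raise ValueError("F_mean = 0; ΔF/F undefined")
    dff = (f - f.mean()) / denom
    if not normalize:
        return DffTrace(series.t, dff, normalized=False)
    lo, hi = dff.min(), dff.max()
    if hi == lo:
        warn("constant series; min-max normalization degenerate (all 0.5)")
        return DffTrace(series.t, np.full_like(dff, 0.5), normalized=True)
    return DffTrace(series.t, (dff - lo) / (hi - lo), normalized=True)


def process_recording(rec: PhotometryRecording, window_s: float = 20.0,
                      centred: bool = True, normalize: bool = True) -> DffTrace:
    """Full chain: demux → isosbestic correction → detrend → ΔF/F.

    The ΔF/F denominator is the raw 470 nm session mean, so a recording
    with no signal (pure bleach and motion) yields a ΔF/F trace that is
    small everywhere instead of amplified residual noise.
    """
    iso, act = demux(rec)
    corrected = isosbestic_correct(act, iso)
    detrended = moving_min_baseline(corrected, window_s, centred)
    return dff_normalize(detrended, reference_mean=act.values.mean(), normalize=normalize)


def align_events(trace: DffTrace, log: EventLog, window_s: float = 5.0) -> dict[str, list]:
    """Peri-event ΔF/F windows per behaviour.

    For each bout onset the nearest sample (round-half-even on the sample
    grid) anchors a ±``window_s`` window; bouts whose window would leave the
    recording are skipped with a warning. Returns
    {behaviour: [(onset_s, t_rel, values), ...]}.
    """
    t = trace.t
    dt = float(np.median(np.diff(t)))
    half = int(round(window_s / dt))
    out: dict[str, list] = {}
    for _, row in log.bouts.iterrows():
        onset = float(row["onset_s"])
        idx = int(np.round((onset - t[0]) / dt))
        if idx - half < 0 or idx + half >= t.size:
            warn(f"bout at {onset:.2f}s outside trace range; skipped")
            continue
        sl = slice(idx - half, idx + half + 1)
        out.setdefault(row["behaviour"], []).append(
            (onset, t[sl] - t[idx], trace.dff[sl])
        )
    return out
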