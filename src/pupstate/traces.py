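"""Single-neuron analyses on calcium trace matrices.

Peri-event z-scores, evoked-response classification and the absolute tuning
index (|t| of an unpaired test between activity and baseline windows),
session baseline activity, and ROC-based selectivity with the
distribution-shape diagnostic that separates persistent state encoding
(indices centred at 0.5) from transient event-locked responses (skewed
indices).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import vocab
from .datatypes import EventLog, TraceMatrix, warn


@dataclass
class ResponseWindowSpec:
    """Per-behaviour (baseline, activity) half-window lengths in seconds.

    The default table matches the bout durations of each behaviour:
    ±2 s for pup sniffing and attacks, ±4 s for pup grooming, ±5 s for male
    intruder sniffing and ±3 s for female intruder sniffing.
    """

    windows_s: dict[str, float] = field(
        default_factory=lambda: dict(vocab.DEFAULT_WINDOWS_S)
    )
    chemoinvestigation: frozenset = vocab.CHEMOINVESTIGATION
    baseline_exempt: frozenset = vocab.BASELINE_EXEMPT

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.windows_s.values()):
            raise ValueError("half-windows must be > 0")

    def half_window(self, behaviour: str) -> float:
        return self.windows_s.get(behaviour, 2.0)


def select_first_bouts(log: EventLog, spec: ResponseWindowSpec | None = None) -> dict[str, float | None]:
    """Choose the analysed bout onset per behaviour.

    For chemoinvestigation behaviours the chosen bout is the first whose
    pre-onset baseline window contains no other scored bout (overlap with
    any other bout disqualifies it); grooming and aggression take the first
    bout of the session regardless of baseline contamination, since those
    behaviours are usually embedded in sequences. Behaviours absent from the
    log map to None.
    """
    spec = spec or ResponseWindowSpec()
    chosen: dict[str, float | None] = {}
    bouts = log.bouts
    for beh in sorted(spec.windows_s):
        sel = bouts[bouts["behaviour"] == beh]
        if sel.empty:
            chosen[beh] = None
            continue
        if beh in spec.baseline_exempt or beh not in spec.chemoinvestigation:
            chosen[beh] = float(sel["onset_s"].iloc[0])
            continue
        half = spec.half_window(beh)
        pick = None
        for _, row in sel.iterrows():
            w0, w1 = row["onset_s"] - half, row["onset_s"]
            others = bouts.drop(index=row.name)
            clean = not ((others["onset_s"] < w1) & (others["offset_s"] > w0)).any()
            if clean:
                pick = float(row["onset_s"])
                break
        if pick is None:
            # no clean bout: fall back to the first, flagged
            warn(f"no baseline-clean {beh} bout in {log.session_id}; using first bout")
            pick = float(sel["onset_s"].iloc[0])
        chosen[beh] = pick
    return chosen


def _windows(traces: TraceMatrix, onset_s: float, half_s: float) -> tuple[np.ndarray, np.ndarray]:
    """(baseline, activity) frame blocks of ``half_s`` seconds around onset."""
    fr = traces.frame_rate
    i = traces.frame_index(onset_s)
    h = int(round(half_s * fr))
    if i - h < 0 or i + h > traces.n_frames:
        raise ValueError("window extends outside the recording")
    return traces.dff[:, i - h:i], traces.dff[:, i:i + h]


def zscore_response(traces: TraceMatrix, onset_s: float, window_s: float = 5.0) -> np.ndarray:
    """Neurons × frames z-matrix over ±``window_s`` around a bout onset.

    Each neuron is z-scored against the mean and s.d. of its own pre-onset
    baseline period; neurons with zero baseline s.d. return NaN rows and are
    excluded downstream.
    """
    base, _ = _windows(traces, onset_s, window_s)
    fr = traces.frame_rate
    i = traces.frame_index(onset_s)
    h = int(round(window_s * fr))
    block = traces.dff[:, i - h:i + h]
    mu = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, ddof=1, keepdims=True)
    bad = (sd == 0).ravel()
    if bad.any():
        warn(f"{int(bad.sum())} neuron(s) with zero baseline s.d.; z undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (block - mu) / sd
    z[bad] = np.nan
    return z


INCREASED, DECREASED, UNCHANGED = "increased", "decreased", "unchanged"


def classify_and_tune(
    traces: TraceMatrix,
    onset_s: float,
    behaviour: str = vocab.PUP_SNIFFING,
    spec: ResponseWindowSpec | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-neuron evoked-response class and absolute tuning index.

    A Welch unpaired t-test compares per-frame ΔF/F between the activity
    window (post-onset) and the baseline window (pre-onset); the tuning
    index is |t|, and neurons are classed increased/decreased by the sign of
    t when p < alpha, else unchanged. Frames are treated as independent
    observations (see methods note for the autocorrelation caveat).
    """
    spec = spec or ResponseWindowSpec()
    half = spec.half_window(behaviour)
    base, act = _windows(traces, onset_s, half)
    if base.shape[1] < 3 or act.shape[1] < 3:
        raise ValueError("both windows must span >= 3 frames")
    rows = []
    for i, nid in enumerate(traces.neuron_ids):
        b, a = base[i], act[i]
        if b.std(ddof=1) == 0.0 and a.std(ddof=1) == 0.0:
            if not np.isclose(a.mean(), b.mean()):
                warn(f"neuron {nid}: degenerate variance with unequal means")
            t_val, p_val = 0.0, 1.0
        else:
            t_val, p_val = stats.ttest_ind(a, b, equal_var=False)
        if p_val < alpha:
            cls = INCREASED if t_val > 0 else DECREASED
        else:
            cls = UNCHANGED
        rows.append(
            {
                "neuron_id": nid,
                "t_value": float(t_val),
                "tuning_index": float(abs(t_val)),
                "p_value": float(p_val),
                "class": cls,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["behaviour"] = behaviour
    out.attrs["alpha"] = alpha
    return out


def baseline_activity(traces: TraceMatrix, intro_time_s: float = 60.0) -> pd.DataFrame:
    """Normalized per-neuron baseline activity before pup introduction.

    The mean raw fluorescence of each neuron over the pre-introduction epoch
    (1 min by default) is min–max normalized across neurons within the
    session. A shorter available epoch is used with a warning; identical
    neurons yield a degenerate normalization flagged the same way.
    """
    t_end = min(intro_time_s, float(traces.frame_times[-1]))
    if t_end < intro_time_s:
        warn(f"baseline epoch shorter than {intro_time_s:.0f}s; using {t_end:.1f}s")
    n = max(int(round(t_end * traces.frame_rate)), 1)
    means = traces.dff[:, :n].mean(axis=1)
    lo, hi = means.min(), means.max()
    if hi == lo:
        warn("all neurons equal in baseline epoch; normalization degenerate")
        norm = np.full_like(means, 0.5)
    else:
        norm = (means - lo) / (hi - lo)
    return pd.DataFrame(
        {"neuron_id": traces.neuron_ids, "baseline_mean": means, "baseline_norm": norm}
    )


def selectivity_index(values_alpha, values_beta) -> float:
    """ROC selectivity index = 1 − AUC, with midrank tie handling.

    Oriented so that a neuron whose activity during behaviour α (e.g. pup
    sniffing) strictly exceeds all of its activity during behaviour β scores
    1, identical distributions score 0.5, and complete preference for β
    scores 0. Equivalent to P(α > β) + ½·P(α = β) over random cross-pairs,
    the Mann-Whitney U statistic scaled by the number of pairs.
    """
    a = np.asarray(values_alpha, dtype=float)
    b = np.asarray(values_beta, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").statistic
    return float(u / (a.size * b.size))


def selectivity_distribution_test(indices, alpha: float = 0.05) -> dict:
    """Shape diagnostic on a population of selectivity indices.

    A distribution centred at 0.5 (two-sided one-sample t location test not
    rejecting) with low skewness indicates persistent state encoding; a
    skewed distribution indicates transient, event-locked responses carried
    by discrete neuronal subsets.
    """
    x = np.asarray(indices, dtype=float)
    if x.size < 10:
        raise ValueError("need >= 10 neurons")
    t_stat, p = stats.ttest_1samp(x, 0.5)
    sk = float(stats.skew(x, bias=False))
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "skewness": sk,
        "t_stat": float(t_stat),
        "p_value": float(p),
        "centred_at_half": bool(p >= alpha),
    }


def behaviour_frame_mask(traces: TraceMatrix, log: EventLog, behaviour: str) -> np.ndarray:
    """Boolean frame mask: True while ``behaviour`` is being scored."""
    mask = np.zeros(traces.n_frames, dtype=bool)
    sel = log.bouts[log.bouts["behaviour"] == behaviour]
    fr = traces.frame_rate
    for _, row in sel.iterrows():
        i0 = int(np.round(row["onset_s"] * fr))
        i1 = int(np.round(row["offset_s"] * fr))
        mask[max(i0, 0):min(i1, traces.n_frames)] = True
    return mask


def epoch_selectivity(
    traces: TraceMatrix,
    log: EventLog,
    behaviour: str,
    epoch: tuple[float, float] | None = None,
) -> np.ndarray:
    """Per-neuron selectivity of behaviour frames vs non-behaviour frames.

    ``epoch`` restricts the comparison to a time interval (seconds); this is
    how the persistent-state diagnostic evaluates aggression selectivity on
    post-aggression epochs and sniff/groom selectivity on pre-aggression
    epochs.
    """
    mask = behaviour_frame_mask(traces, log, behaviour)
    keep = np.ones(traces.n_frames, dtype=bool)
    if epoch is not None:
        keep = (traces.frame_times >= epoch[0]) & (traces.frame_times < epoch[1])
    in_beh = mask & keep
    out_beh = ~mask & keep
    if not in_beh.any() or not out_beh.any():
        raise ValueError(f"no frames for {behaviour} inside/outside the epoch")
    return np.array(
        [selectivity_index(row[in_beh], row[out_beh]) for row in traces.dff]
    )
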