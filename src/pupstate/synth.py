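"""Synthetic behavioural, cohort, photometry and calcium-trace generators.

Every downstream analysis in this package is exercised against data produced
here, with the statistical structure those analyses assume: stage-dependent
Bernoulli aggression outcomes, phenotype-specific behaviour sequences,
bleaching- and motion-contaminated two-channel photometry, and ΔF/F trace
matrices carrying event-locked transients plus an optional persistent
population shift from the first aggression onset to the end of the session.

All generators are pure functions of (parameters, seed): the seed is a
required argument and identical calls return identical data. Ground truth
(planted per-neuron effects, planted state interval) is emitted as a sidecar
table so tests never have to re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import vocab
from .datatypes import EventLog, PhotometryRecording, TraceMatrix, validate_cohort, warn

PHENOTYPES = ("aggressive", "parental", "ignoring")


@dataclass
class BehaviorProfile:
    """Bout statistics for one behavioural phenotype.

    ``bout_rate_per_behaviour`` maps behaviour label -> events/min and
    ``mean_bout_duration`` maps behaviour label -> seconds. For the aggressive
    phenotype ``attack_latency_s`` is either a scalar (point mass) or an
    object with an ``rvs(random_state=...)`` method (e.g. a frozen scipy
    distribution) giving the latency of the first attack.
    """

    phenotype: str
    bout_rate_per_behaviour: dict[str, float] = field(default_factory=dict)
    mean_bout_duration: dict[str, float] = field(default_factory=dict)
    attack_latency_s: object = 120.0
    terminate_on_attack: bool = False  # assay mode ends scoring at first attack

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype: {self.phenotype!r}")
        if any(r < 0 for r in self.bout_rate_per_behaviour.values()):
            raise ValueError("bout rates must be >= 0")
        forbidden = set()
        if self.phenotype != "aggressive":
            forbidden |= {vocab.AGGRESSIVE_CONTACT}
        if self.phenotype == "ignoring":
            forbidden |= vocab.PARENTAL_DEFINING
        bad = forbidden & {
            b for b, r in self.bout_rate_per_behaviour.items() if r > 0
        }
        if bad:
            raise ValueError(f"{self.phenotype} profile may not emit {sorted(bad)}")


def default_profile(phenotype: str, terminate_on_attack: bool = False) -> BehaviorProfile:
    """Packaged bout statistics per phenotype.

    All animals start with a chemoinvestigation/grooming phase; parental
    animals add retrieval, crouching and nest occupancy; ignoring animals add
    only non-pup behaviours; aggressive animals add attack bouts after a
    latency. The 2.1 s mean sniffing bout is the one published duration; the
    remaining rates/durations are package choices documented in the methods
    note.
    """
    common = {
        vocab.PUP_SNIFFING: (1.5, 2.1),
        vocab.PUP_GROOMING: (0.8, 4.0),
        vocab.REARING: (1.0, 3.0),
        vocab.DIGGING: (0.6, 3.0),
    }
    extra = {
        "aggressive": {vocab.AGGRESSIVE_CONTACT: (1.0, 2.5)},
        "parental": {
            vocab.PUP_RETRIEVAL: (0.4, 3.0),
            vocab.CROUCHING: (0.3, 20.0),
            vocab.IN_NEST: (0.25, 30.0),
            vocab.NEST_BUILDING: (0.2, 5.0),
        },
        "ignoring": {},
    }[phenotype]
    table = {**common, **extra}
    return BehaviorProfile(
        phenotype=phenotype,
        bout_rate_per_behaviour={b: r for b, (r, _) in table.items()},
        mean_bout_duration={b: d for b, (_, d) in table.items()},
        attack_latency_s=120.0,
        terminate_on_attack=terminate_on_attack,
    )


@dataclass
class StageModel:
    """Oestrous-stage composition and stage-wise switching probabilities."""

    probs: dict[str, float] = field(
        default_factory=lambda: dict(vocab.DEFAULT_STAGE_PROBS)
    )
    freqs: dict[str, float] = field(
        default_factory=lambda: dict(vocab.DEFAULT_STAGE_FREQS)
    )

    def __post_init__(self) -> None:
        for s, p in self.probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_stage[{s}] outside [0,1]")
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stage frequencies sum to {total}, not 1")
        if set(self.freqs) - set(self.probs):
            raise ValueError("every stage with a frequency needs a probability")


@dataclass
class TuningSpec:
    """Planted per-neuron tuning for trace synthesis.

    ``effects`` maps behaviour label -> length-``n_neurons`` array of signed
    peak ΔF/F changes. ``state_shift`` is a per-neuron signed baseline offset
    applied from the first aggression onset to the end of the session (must
    be zero when the session contains no aggression).
    """

    effects: dict[str, np.ndarray] = field(default_factory=dict)
    kernel_tau_s: float = 1.5
    state_shift: np.ndarray | float = 0.0
    noise_sd: float = 0.1
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.kernel_tau_s <= 0:
            raise ValueError("kernel time constant must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.effects = {b: np.atleast_1d(np.asarray(v, float)) for b, v in self.effects.items()}


# ---------------------------------------------------------------------------
# behaviour sessions
# ---------------------------------------------------------------------------

def _poisson_bouts(rng, rate_per_min, mean_dur, duration):
    """Candidate (onset, offset) pairs from a homogeneous Poisson process."""
    n = rng.poisson(rate_per_min * duration / 60.0)
    onsets = np.sort(rng.uniform(0.0, duration, size=n))
    durs = rng.exponential(mean_dur, size=n)
    durs = np.maximum(durs, 0.2)  # scored bouts are never instantaneous
    offsets = np.minimum(onsets + durs, duration)
    return [(a, b) for a, b in zip(onsets, offsets) if b > a]


def gen_behavior_session(
    profile: BehaviorProfile,
    duration: float = vocab.DEFAULT_ASSAY_DURATION_S,
    seed: int = 0,
    session_id: str = "sess",
    subject_id: str = "mouse",
) -> EventLog:
    """Generate one scored session for the given phenotype.

    Bouts are drawn per behaviour from homogeneous Poisson processes, then
    merged greedily in time with overlapping candidates rejected, so the log
    never contains overlapping bouts. Aggressive profiles always receive at
    least one aggressive-contact bout, whose first onset is drawn from the
    profile's attack-latency distribution (clamped inside the session). With
    ``terminate_on_attack`` the log is truncated at the first attack offset,
    mirroring assay trials where pups are removed; imaging sessions continue.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)

    candidates: list[tuple[float, float, str]] = []
    for beh in sorted(profile.bout_rate_per_behaviour):
        rate = profile.bout_rate_per_behaviour[beh]
        if rate <= 0 or beh == vocab.AGGRESSIVE_CONTACT:
            continue
        mean_dur = profile.mean_bout_duration.get(beh, 3.0)
        for a, b in _poisson_bouts(rng, rate, mean_dur, duration):
            candidates.append((a, b, beh))

    first_attack = None
    if profile.phenotype == "aggressive":
        lat = profile.attack_latency_s
        lat = float(lat) if np.isscalar(lat) else float(lat.rvs(random_state=rng))
        mean_dur = profile.mean_bout_duration.get(vocab.AGGRESSIVE_CONTACT, 2.5)
        first_attack = min(max(lat, 0.0), max(duration - mean_dur, 0.0))
        attack_bouts = [
            (first_attack, min(first_attack + mean_dur, duration), vocab.AGGRESSIVE_CONTACT)
        ]
        rate = profile.bout_rate_per_behaviour.get(vocab.AGGRESSIVE_CONTACT, 1.0)
        for a, b in _poisson_bouts(rng, rate, mean_dur, duration):
            if a > first_attack + mean_dur:
                attack_bouts.append((a, b, vocab.AGGRESSIVE_CONTACT))
        candidates.extend(attack_bouts)

    # greedy non-overlap: attacks first (they are planted), then by onset
    def priority(c):
        return (c[2] != vocab.AGGRESSIVE_CONTACT, c[0])

    accepted: list[tuple[float, float, str]] = []
    occupied: list[tuple[float, float]] = []
    for a, b, beh in sorted(candidates, key=priority):
        if any(a < o2 and b > o1 for o1, o2 in occupied):
            continue
        occupied.append((a, b))
        accepted.append((a, b, beh))

    # guarantee the parental invariant: at least one parental-defining bout
    if profile.phenotype == "parental" and not any(
        beh in vocab.PARENTAL_DEFINING for _, _, beh in accepted
    ):
        t0 = float(rng.uniform(0.0, max(duration - 3.0, 0.0)))
        accepted.append((t0, min(t0 + 3.0, duration), vocab.PUP_RETRIEVAL))
        accepted = [
            (a, b, beh)
            for a, b, beh in accepted
            if (a, b) == (t0, min(t0 + 3.0, duration)) or b <= t0 or a >= t0 + 3.0
        ]

    if profile.terminate_on_attack and first_attack is not None:
        end = min(first_attack + profile.mean_bout_duration.get(vocab.AGGRESSIVE_CONTACT, 2.5), duration)
        accepted = [(a, min(b, end), beh) for a, b, beh in accepted if a < end]

    bouts = pd.DataFrame(accepted, columns=["onset_s", "offset_s", "behaviour"])
    return EventLog(session_id, subject_id, bouts[["behaviour", "onset_s", "offset_s"]], duration)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def gen_cohort(stage_model: StageModel | None = None, n: int = 100, seed: int = 0) -> pd.DataFrame:
    """Draw a cohort: stage ~ stage frequencies, aggression ~ Bernoulli(p_stage)."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    sm = stage_model or StageModel()
    rng = np.random.default_rng(seed)
    stages = sorted(sm.freqs)
    freqs = np.array([sm.freqs[s] for s in stages])
    drawn = rng.choice(stages, size=n, p=freqs / freqs.sum())
    p = np.array([sm.probs[s] for s in drawn])
    agg = (rng.random(n) < p).astype(int)
    table = pd.DataFrame(
        {
            "subject_id": [f"m{i:05d}" for i in range(n)],
            "stage": drawn,
            "aggressive": agg,
        }
    )
    return validate_cohort(table)


# ---------------------------------------------------------------------------
# calcium traces
# ---------------------------------------------------------------------------

def gen_trace_dataset(
    events: EventLog,
    n_neurons: int,
    spec: TuningSpec,
    frame_rate: float = vocab.DEFAULT_FRAME_RATE_HZ,
    seed: int = 0,
) -> tuple[TraceMatrix, pd.DataFrame]:
    """Synthesize a ΔF/F matrix locked to a behavioural log.

    Each neuron is baseline + a sum of event-locked kernels (instantaneous
    rise at bout onset, exponential decay with the spec's time constant,
    amplitude = planted effect) + a persistent state shift from the first
    aggression onset to session end + i.i.d. Gaussian noise.

    Returns the trace matrix and a ground-truth sidecar table with one row
    per neuron (planted effect per behaviour, state shift) plus the planted
    state-interval onset in its ``attrs``.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    n_frames = int(round(events.assay_duration * frame_rate))
    t = np.arange(n_frames) / frame_rate
    rng = np.random.default_rng(seed)

    first_attack = events.first_onset({vocab.AGGRESSIVE_CONTACT})
    shift = np.broadcast_to(np.asarray(spec.state_shift, float), (n_neurons,)).copy()
    if first_attack is None and np.any(shift != 0):
        raise ValueError("state_shift must be 0 for sessions without aggression")

    dff = np.full((n_neurons, n_frames), spec.baseline, dtype=float)
    gt = {"neuron_id": [f"n{i:04d}" for i in range(n_neurons)]}

    for beh, amps in spec.effects.items():
        amps = np.broadcast_to(amps, (n_neurons,))
        gt[f"effect_{beh}"] = np.asarray(amps, float)
        onsets = events.bouts.loc[events.bouts["behaviour"] == beh, "onset_s"].to_numpy()
        if onsets.size == 0:
            warn(f"behaviour {beh!r} in tuning spec absent from log; kernel skipped")
            continue
        kernel = np.zeros(n_frames)
        for onset in onsets:
            i0 = int(np.round(onset * frame_rate))
            if i0 >= n_frames:
                continue
            kernel[i0:] += np.exp(-(t[i0:] - t[i0]) / spec.kernel_tau_s)
        dff += amps[:, None] * kernel[None, :]

    gt["state_shift"] = shift
    if first_attack is not None:
        i0 = int(np.round(first_attack * frame_rate))
        dff[:, i0:] += shift[:, None]

    if spec.noise_sd > 0:
        dff += rng.normal(0.0, spec.noise_sd, size=dff.shape)

    traces = TraceMatrix(t, dff, subject_id=events.subject_id)
    sidecar = pd.DataFrame(gt)
    sidecar.attrs["first_aggression_onset_s"] = first_attack
    sidecar.attrs["kernel_tau_s"] = spec.kernel_tau_s
    sidecar.attrs["noise_sd"] = spec.noise_sd
    return traces, sidecar


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

def gen_photometry(
    events: EventLog,
    bleach_tau: float = 300.0,
    motion_sd: float = 0.05,
    seed: int = 0,
    rate_hz: float = vocab.DEFAULT_FRAME_RATE_HZ,
    transient_amp: float = 0.3,
    transient_tau: float = 1.5,
    noise_sd: float = 0.005,
    f0: float = 1.0,
) -> PhotometryRecording:
    """Interleaved two-channel recording with shared bleach and motion.

    Both channels carry the same exponential bleach envelope and the same
    slow motion artefact (an AR(1) process sampled at the interleaved clock);
    calcium transients locked to pup-directed bout onsets enter the 470 nm
    channel only. Samples strictly alternate isosbestic/activity.
    """
    if bleach_tau <= 0:
        raise ValueError("bleach_tau must be > 0")
    rng = np.random.default_rng(seed)
    n_per = int(round(events.assay_duration * rate_hz))
    n_total = 2 * n_per
    # interleaved clock: iso at even slots, activity at odd slots
    t_all = np.arange(n_total) / (2.0 * rate_hz)

    bleach = np.exp(-t_all / bleach_tau)
    if motion_sd > 0:
        rho = 0.995  # slow artefact at the 40 Hz interleaved clock
        innov = rng.normal(0.0, motion_sd * np.sqrt(1 - rho**2), size=n_total)
        motion = np.empty(n_total)
        acc = 0.0
        for i, e in enumerate(innov):
            acc = rho * acc + e
            motion[i] = acc
    else:
        motion = np.zeros(n_total)

    onsets = events.bouts.loc[
        events.bouts["behaviour"].isin(vocab.PUP_DIRECTED), "onset_s"
    ].to_numpy()
    transients = np.zeros(n_total)
    if transient_amp != 0:
        for onset in onsets:
            mask = t_all >= onset
            transients[mask] += transient_amp * np.exp(-(t_all[mask] - onset) / transient_tau)

    values = f0 * bleach + motion
    odd = np.arange(n_total) % 2 == 1
    values = values + np.where(odd, transients, 0.0)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_total)

    channels = np.where(odd, PhotometryRecording.CH_ACT, PhotometryRecording.CH_ISO)
    samples = pd.DataFrame(
        {"sample_index": np.arange(n_total), "channel": channels, "value": values}
    )
    return PhotometryRecording(samples, rate_hz)


def random_tuning(
    n_neurons: int,
    behaviours: dict[str, tuple[float, float]],
    state_shift: float | np.ndarray = 0.0,
    noise_sd: float = 0.1,
    tuned_fraction: float = 0.5,
    kernel_tau_s: float = 1.5,
    seed: int = 0,
) -> TuningSpec:
    """Convenience factory: per-behaviour effects ~ N(mean, sd) for a random
    tuned subset of neurons, zero elsewhere."""
    rng = np.random.default_rng(seed)
    effects = {}
    for beh, (mean, sd) in behaviours.items():
        amp = np.zeros(n_neurons)
        tuned = rng.random(n_neurons) < tuned_fraction
        amp[tuned] = rng.normal(mean, sd, size=int(tuned.sum()))
        effects[beh] = amp
    return TuningSpec(
        effects=effects, kernel_tau_s=kernel_tau_s, state_shift=state_shift, noise_sd=noise_sd
    )
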