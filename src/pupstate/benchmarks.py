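"""Reference synthetic benchmarks with known ground truth.

These procedures generate fully synthetic sessions whose structure is planted
by construction, run the corresponding analysis chain end to end, and report
recovery scores. They are used by the test suite and the standalone
acceptance script; every random draw is a pure function of the seeds given.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import population, synth, vocab


def strong_state_profile(
    attack_rate_per_min: float = 1.5, attack_bout_s: float = 4.0
) -> synth.BehaviorProfile:
    """Aggressive phenotype with frequent, long attack bouts.

    The elevated rate and 4 s mean bout duration guarantee several scoreable
    aggression episodes (>= 2 s) within a 10 min session, which the
    episode-detection benchmark requires.
    """
    prof = synth.default_profile("aggressive")
    prof.bout_rate_per_behaviour[vocab.AGGRESSIVE_CONTACT] = attack_rate_per_min
    prof.mean_bout_duration[vocab.AGGRESSIVE_CONTACT] = attack_bout_s
    return prof


def _session_with_episodes(
    seed: int,
    duration_s: float,
    min_episode_s: float,
    min_episodes: int,
    max_attempts: int = 20,
):
    """First ethogram (derived sub-seeds) meeting the episode precondition.

    Attempt 0 uses ``seed`` itself, so reference seeds whose first draw
    already satisfies the precondition are unaffected. Redrawing depends only
    on the episode count of the ethogram, never on any downstream fit.
    """
    prof = strong_state_profile()
    for attempt in range(max_attempts):
        session_seed = (seed + attempt * 1_000_003) % (2**31 - 1)
        log = synth.gen_behavior_session(
            prof, duration_s, seed=session_seed, session_id=f"bench{seed}"
        )
        agg = log.bouts[log.bouts["behaviour"] == vocab.AGGRESSIVE_CONTACT]
        n_long = int(((agg["offset_s"] - agg["onset_s"]) >= min_episode_s).sum())
        if n_long >= min_episodes:
            return log, n_long, session_seed
    raise ValueError(
        f"seed {seed}: no ethogram with >= {min_episodes} aggression "
        f"episodes >= {min_episode_s} s in {max_attempts} attempts"
    )


def aggression_state_benchmark(
    seeds=(1, 2, 3, 4, 5),
    n_neurons: int = 50,
    frame_rate: float = 20.0,
    duration_s: float = 600.0,
    noise_sd: float = 1.0,
    state_shift: float = -5.0,
    k_range=range(1, 7),
    n_iter: int = 50,
    min_episode_s: float = 2.0,
    min_episodes: int = 5,
    overlap_threshold: float = 0.5,
) -> pd.DataFrame:
    """Detection of a planted persistent aggression state, one row per seed.

    Per session: generate an aggressive-session ethogram, plant a population
    state shift of ``state_shift`` (5x the noise s.d. by default) from the
    first aggression onset, select the HMM state count at the log-likelihood
    knee, fit the model, align states to the aggression mask, and score the
    fraction of aggression episodes (>= ``min_episode_s``) whose frames are
    majority-covered by the aligned state.

    The benchmark is defined on sessions containing at least ``min_episodes``
    such episodes; ethograms are rejection-sampled deterministically (derived
    sub-seeds) until that precondition holds, before any traces are generated
    or any model is fitted.
    """
    rows = []
    for seed in seeds:
        log, n_long, session_seed = _session_with_episodes(
            int(seed), duration_s, min_episode_s, min_episodes
        )
        seed = session_seed
        spec = synth.TuningSpec(
            effects={}, state_shift=state_shift, noise_sd=noise_sd
        )
        tm, _ = synth.gen_trace_dataset(log, n_neurons, spec, frame_rate, seed=int(seed))
        k_star, _curve = population.select_num_states(
            tm.dff.T, k_range, seed=int(seed), n_iter=n_iter
        )
        model = population.fit_hmm(tm.dff.T, k_star, seed=int(seed), n_iter=n_iter)
        scorable = log.bouts[
            (log.bouts["behaviour"] != vocab.AGGRESSIVE_CONTACT)
            | ((log.bouts["offset_s"] - log.bouts["onset_s"]) >= min_episode_s)
        ]
        scorable_log = synth.EventLog(
            log.session_id, log.subject_id, scorable, log.assay_duration
        )
        rate = population.hmm_detection_rate(
            model,
            scorable_log,
            frame_rate=frame_rate,
            overlap_threshold=overlap_threshold,
        )
        rows.append(
            {
                "seed": int(seed),
                "n_episodes": n_long,
                "K_star": int(k_star),
                "detection_rate": float(rate),
            }
        )
    return pd.DataFrame(rows)
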