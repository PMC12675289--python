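"""Behavioural outcome classification, transition structure and incidence.

Operates on scored event logs: per-animal outcome calls (aggressive /
parental / ignoring) with latencies and total parenting time, behavioural
transition matrices over sequential bout pairs, and cumulative-incidence
curves of aggression across a cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import vocab
from .datatypes import EventLog, warn

AGG_PLUS = "agg_plus"
PARENTAL = "parental"
IGNORING = "ignoring"


@dataclass
class OutcomeRecord:
    """Per-animal behavioural outcome.

    Latencies are seconds; a censored latency (behaviour never shown) is
    recorded as ``inf`` with the matching ``*_censored`` flag set.
    """

    subject_id: str
    outcome: str
    contact_latency: float
    attack_latency: float
    total_parenting_time: float

    @property
    def contact_censored(self) -> bool:
        return math.isinf(self.contact_latency)

    @property
    def attack_censored(self) -> bool:
        return math.isinf(self.attack_latency)


def classify_outcome(
    log: EventLog,
    parental_labels=vocab.PARENTAL_DEFINING,
    parenting_time_labels=vocab.PARENTING_TIME_COMPONENTS,
) -> OutcomeRecord:
    """Classify one animal from its session log.

    Aggressive (``agg_plus``) iff the log contains at least one
    aggressive-contact bout; otherwise parental iff any parental-defining
    behaviour (retrieval, crouching, in-nest by default) occurs; otherwise
    ignoring. Contact latency is the onset of the first pup-directed bout and
    total parenting time sums the durations of grooming, retrieval and
    in-nest bouts.
    """
    if len(log) == 0:
        warn(f"empty log for {log.subject_id}: outcome defaults to ignoring, latencies censored")
        return OutcomeRecord(log.subject_id, IGNORING, math.inf, math.inf, 0.0)

    attack = log.first_onset({vocab.AGGRESSIVE_CONTACT})
    contact = log.first_onset(vocab.PUP_DIRECTED)
    if attack is not None:
        outcome = AGG_PLUS
    elif log.first_onset(parental_labels) is not None:
        outcome = PARENTAL
    else:
        outcome = IGNORING

    keep = log.bouts["behaviour"].isin(set(parenting_time_labels))
    parenting = float(
        (log.bouts.loc[keep, "offset_s"] - log.bouts.loc[keep, "onset_s"]).sum()
    )
    parenting = min(parenting, log.assay_duration)
    return OutcomeRecord(
        log.subject_id,
        outcome,
        math.inf if contact is None else contact,
        math.inf if attack is None else attack,
        parenting,
    )


@dataclass
class TransitionMatrix:
    """Row-stochastic behavioural transition matrix with raw counts."""

    labels: list[str]
    P: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, float)
        self.counts = np.asarray(self.counts, int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def to_dot(self, min_prob: float = 0.0) -> str:
        """DOT digraph; edge penwidth scales with transition probability."""
        lines = ["digraph transitions {"]
        for lab in self.labels:
            lines.append(f'  "{lab}";')
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                p = self.P[i, j]
                if p > min_prob and self.counts[i, j] > 0:
                    lines.append(
                        f'  "{a}" -> "{b}" [label="{p:.2f}", penwidth={0.5 + 4 * p:.2f}];'
                    )
        lines.append("}")
        return "\n".join(lines)


def _pairs(labels_seq: list[str]):
    return list(zip(labels_seq[:-1], labels_seq[1:]))


def transition_matrix(
    logs: list[EventLog],
    vocabulary=None,
    pooled: bool = True,
):
    """Transition probabilities over sequential bout pairs.

    Each log's bouts are filtered to the given vocabulary (default: all
    labels observed across the logs), ordered in time, and parsed into
    sequential pairs; ``P[i, j]`` is the number of i->j occurrences divided
    by the total number of transitions leaving i. Self-transitions count.
    With ``pooled=False`` a matrix per log is returned instead.
    """
    if not logs:
        raise ValueError("need at least one event log")
    if vocabulary is None:
        vocabulary = sorted(
            set().union(*(set(lg.bouts["behaviour"]) for lg in logs))
        )
    labels = sorted(vocabulary)
    if not pooled:
        return [transition_matrix([lg], labels, pooled=True) for lg in logs]

    idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for lg in logs:
        seq = [b for b in lg.bouts["behaviour"] if b in idx]
        if len(seq) < 2:
            warn(f"log {lg.session_id} has <2 retained bouts; contributes no transitions")
            continue
        for a, b in _pairs(seq):
            counts[idx[a], idx[b]] += 1

    P = np.zeros_like(counts, dtype=float)
    row_tot = counts.sum(axis=1)
    nz = row_tot > 0
    P[nz] = counts[nz] / row_tot[nz, None]
    return TransitionMatrix(labels, P, counts)


class CumulativeIncidence:
    """Right-continuous nondecreasing step function t -> fraction attacked by t.

    Censored animals (no attack) never increment the curve; its value at the
    assay end equals the empirical aggression proportion exactly.
    """

    def __init__(self, outcomes: list[OutcomeRecord], assay_duration: float):
        if not outcomes:
            raise ValueError("need at least one outcome record")
        self.n = len(outcomes)
        self.assay_duration = float(assay_duration)
        lat = sorted(
            o.attack_latency
            for o in outcomes
            if o.outcome == AGG_PLUS and not o.attack_censored
        )
        self.jump_times = np.asarray(lat, float)
        self.values = np.arange(1, len(lat) + 1) / self.n

    def __call__(self, t):
        t = np.asarray(t, float)
        k = np.searchsorted(self.jump_times, t, side="right")
        out = np.where(k > 0, k / self.n, 0.0)
        return float(out) if out.ndim == 0 else out

    @property
    def terminal_value(self) -> float:
        return len(self.jump_times) / self.n

    def to_frame(self) -> pd.DataFrame:
        """Step-curve table including the (0, 0) origin and assay-end point."""
        t = np.concatenate([[0.0], self.jump_times, [self.assay_duration]])
        return pd.DataFrame({"t_s": t, "fraction_attacked": self(t)})


def cumulative_incidence(
    outcomes: list[OutcomeRecord],
    assay_duration: float = vocab.DEFAULT_ASSAY_DURATION_S,
) -> CumulativeIncidence:
    return CumulativeIncidence(outcomes, assay_duration)


def outcomes_frame(outcomes: list[OutcomeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [o.subject_id for o in outcomes],
            "outcome": [o.outcome for o in outcomes],
            "contact_latency_s": [o.contact_latency for o in outcomes],
            "attack_latency_s": [o.attack_latency for o in outcomes],
            "total_parenting_time_s": [o.total_parenting_time for o in outcomes],
        }
    )
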