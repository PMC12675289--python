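"""Population-level state analysis.

Standardized PCA and the PC-distance representational metric, Gaussian-
emission hidden-Markov segmentation of population activity with behaviour
alignment and episode detection scoring, and episode-split multiclass
decoding with minority oversampling.

The HMM captures the central population phenomenon in this setting: a
persistent activity state that appears at the first aggression episode and
outlasts individual attacks. Its aligned state is scored against the
behavioural ethogram rather than against frame-level labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from hmmlearn.base import ConvergenceMonitor
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from . import vocab
from .datatypes import EventLog, TraceMatrix, warn

# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCModel:
    """Standardized-PCA model of one session's population activity.

    Stores the per-neuron standardization (mu_i, sigma_i), the covariance
    matrix of the standardized data, its eigendecomposition sorted by
    descending eigenvalue, and the explained-variance fractions. A session
    is flagged usable when the first two PCs explain at least 70% of the
    total variance.
    """

    mu: np.ndarray
    sigma: np.ndarray
    covariance: np.ndarray
    eigenvectors: np.ndarray  # columns = PCs, descending eigenvalue order
    eigenvalues: np.ndarray
    explained: np.ndarray
    neuron_ids: list[str] = field(default_factory=list)
    usable: bool = True

    def n_components_for(self, variance_target: float) -> int:
        """Smallest k whose cumulative explained variance reaches the target."""
        cum = np.cumsum(self.explained)
        return int(np.searchsorted(cum, variance_target - 1e-12) + 1)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mu) / self.sigma

    def project(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        """Project (frames x neurons) data onto the first k PCs."""
        V = self.eigenvectors if k is None else self.eigenvectors[:, :k]
        return self.standardize(X) @ V


def fit_pca(traces: TraceMatrix, usable_threshold: float = 0.70) -> PCModel:
    """Standardize each neuron and eigendecompose the covariance matrix.

    Zero-variance neurons carry no information and are dropped with a
    warning. Eigenvalues sum to the trace of the covariance matrix and the
    explained fractions are eigenvalue / total.
    """
    if traces.n_neurons < 2 or traces.n_frames < 2:
        raise ValueError("need >= 2 neurons and >= 2 frames")
    X = traces.dff.T  # frames x neurons
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=1)
    keep = sigma > 0
    if not keep.all():
        warn(f"dropped {int((~keep).sum())} zero-variance neuron(s) before PCA")
    X = X[:, keep]
    mu, sigma = mu[keep], sigma[keep]
    ids = [nid for nid, k in zip(traces.neuron_ids, keep) if k]

    Z = (X - mu) / sigma
    C = np.cov(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)  # numerical negatives
    explained = evals / evals.sum()
    usable = bool(explained[:2].sum() >= usable_threshold)
    return PCModel(mu, sigma, C, evecs, evals, explained, ids, usable)


def pc_distance(
    episode_a: np.ndarray,
    episode_b: np.ndarray,
    pc_model: PCModel | None = None,
    variance_target: float = 0.90,
    k: int | None = None,
    method: str = "norm",
) -> float:
    """Distance between two equal-length population activity episodes.

    Episodes are (T x neurons) blocks (5 s post-onset by convention). With a
    PC model they are standardized and projected into k dimensions (k is the
    smallest count reaching ``variance_target`` unless given explicitly, with
    k=2 as a common preset); without a model they are taken to be already in
    PC space. The default distance is the Euclidean norm of the flattened
    difference, D = sqrt(sum_t sum_i (a_ti - b_ti)^2); ``method="summed"``
    instead sums the per-timepoint Euclidean distances.
    """
    A = np.atleast_2d(np.asarray(episode_a, float))
    B = np.atleast_2d(np.asarray(episode_b, float))
    if A.shape != B.shape:
        raise ValueError("episodes must have identical shape")
    if pc_model is not None:
        kk = k if k is not None else pc_model.n_components_for(variance_target)
        A = pc_model.project(A, kk)
        B = pc_model.project(B, kk)
    diff = A - B
    if method == "norm":
        return float(np.sqrt(np.sum(diff**2)))
    if method == "summed":
        return float(np.sum(np.sqrt(np.sum(diff**2, axis=1))))
    raise ValueError(f"unknown method {method!r}")


def extract_episode(traces: TraceMatrix, onset_s: float, duration_s: float = 5.0) -> np.ndarray:
    """(T x neurons) activity block starting at a bout onset."""
    i0 = traces.frame_index(onset_s)
    n = int(round(duration_s * traces.frame_rate))
    if i0 + n > traces.n_frames:
        raise ValueError("episode extends beyond the recording")
    return traces.dff[:, i0:i0 + n].T


# ---------------------------------------------------------------------------
# HMM
# ---------------------------------------------------------------------------


class _TraceMonitor(ConvergenceMonitor):
    """Convergence monitor retaining the full per-iteration log-likelihood."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.full_history: list[float] = []

    def report(self, log_prob):
        self.full_history.append(float(log_prob))
        super().report(log_prob)


@dataclass
class StateModel:
    """Fitted Gaussian-emission HMM with its most-likely state path."""

    K: int
    means: np.ndarray
    covars: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    state_path: np.ndarray
    loglik_trace: np.ndarray
    hmm: GaussianHMM

    @property
    def final_loglik(self) -> float:
        return float(self.loglik_trace[-1])


def fit_hmm(
    data: np.ndarray,
    K: int,
    seed: int = 0,
    n_iter: int = 50,
    tol: float = 1e-6,
    covariance_type: str = "diag",
) -> StateModel:
    """Fit a K-state Gaussian HMM to (frames x dims) population data.

    EM runs for up to ``n_iter`` iterations (50 by default) with early stop
    when the log-likelihood improves by less than ``tol``; means are
    initialized by k-means clustering seeded with ``seed``. If the fit
    degenerates (a state losing all support), one reseeded retry is made
    before the error propagates.
    """
    X = np.atleast_2d(np.asarray(data, float))
    if K < 1:
        raise ValueError("K must be >= 1")
    if X.shape[0] < 2 * K:
        raise ValueError("need at least 2*K frames")

    def _fit(rs: int) -> StateModel:
        model = GaussianHMM(
            n_components=K,
            covariance_type=covariance_type,
            n_iter=n_iter,
            tol=tol,
            random_state=rs,
            init_params="stmc",
        )
        model.monitor_ = _TraceMonitor(model.tol, model.n_iter, model.verbose)
        model.fit(X)
        path = model.predict(X)
        return StateModel(
            K=K,
            means=model.means_,
            covars=model.covars_,
            transmat=model.transmat_,
            startprob=model.startprob_,
            state_path=path,
            loglik_trace=np.asarray(model.monitor_.full_history),
            hmm=model,
        )

    try:
        return _fit(seed)
    except ValueError:
        warn("HMM fit degenerated; retrying once with a reseeded initialization")
        return _fit(seed + 1)


def select_num_states(
    data: np.ndarray,
    K_range=range(2, 9),
    seed: int = 0,
    n_iter: int = 50,
) -> tuple[int, pd.DataFrame]:
    """Choose the state count at the knee of the log-likelihood curve.

    One model is fitted per candidate K; the objective is the final
    per-frame log-likelihood. The knee is the interior K with the most
    negative discrete second difference (the sharpest onset of diminishing
    returns). A curve with no concave turning point triggers a warning and
    the smallest K is returned. The full curve comes back alongside K*.
    """
    Ks = sorted(K_range)
    if len(Ks) < 3:
        raise ValueError("K_range must contain >= 3 values")
    n_frames = np.atleast_2d(np.asarray(data)).shape[0]
    ll = []
    for K in Ks:
        sm = fit_hmm(data, K, seed=seed, n_iter=n_iter)
        ll.append(sm.final_loglik / n_frames)
    ll = np.asarray(ll)
    curve = pd.DataFrame({"K": Ks, "loglik_per_frame": ll})
    d2 = ll[2:] - 2 * ll[1:-1] + ll[:-2]
    scale = max(abs(np.ptp(ll)), 1e-12)
    if d2.size == 0 or d2.min() > -1e-6 * scale:
        warn("log-likelihood curve has no knee; returning smallest K")
        return Ks[0], curve
    k_star = Ks[1 + int(np.argmin(d2))]
    return k_star, curve


def _frame_mask(log: EventLog, behaviour: str, n_frames: int, frame_rate: float) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    sel = log.bouts[log.bouts["behaviour"] == behaviour]
    for _, row in sel.iterrows():
        i0 = int(np.round(row["onset_s"] * frame_rate))
        i1 = int(np.round(row["offset_s"] * frame_rate))
        mask[max(i0, 0):min(i1, n_frames)] = True
    return mask


def align_states_to_behaviour(
    model: StateModel,
    log: EventLog,
    frame_rate: float = vocab.DEFAULT_FRAME_RATE_HZ,
    behaviours=None,
) -> dict[str, dict]:
    """Map each behaviour to its most frequently co-occurring hidden state.

    For behaviour b, the aligned state s* maximizes the number of frames
    with (b active and state = s); ties break to the lower state index. The
    conditional probability is #frames(b and s*) / #frames(s*), quantifying
    how specifically the state carries the behaviour. Behaviours never
    observed in the log are reported with ``aligned_state=None``.
    """
    path = model.state_path
    n_frames = path.size
    if behaviours is None:
        behaviours = sorted(set(log.bouts["behaviour"]))
    out: dict[str, dict] = {}
    for beh in behaviours:
        mask = _frame_mask(log, beh, n_frames, frame_rate)
        if not mask.any():
            out[beh] = {"aligned_state": None, "conditional_prob": np.nan}
            continue
        joint = np.bincount(path[mask], minlength=model.K)
        s_star = int(np.argmax(joint))  # argmax takes the lowest index on ties
        occupancy = int((path == s_star).sum())
        out[beh] = {
            "aligned_state": s_star,
            "conditional_prob": float(joint[s_star] / occupancy) if occupancy else np.nan,
        }
    return out


def hmm_detection_rate(
    model: StateModel,
    log: EventLog,
    behaviour: str = vocab.AGGRESSIVE_CONTACT,
    frame_rate: float = vocab.DEFAULT_FRAME_RATE_HZ,
    overlap_threshold: float = 0.5,
    aligned_state: int | None = None,
) -> float | None:
    """Fraction of behaviour episodes detected by the aligned hidden state.

    An episode counts as detected when at least ``overlap_threshold`` of its
    frames carry the behaviour's aligned state. Returns None (reported
    missing) when the log contains no such episodes.
    """
    if aligned_state is None:
        aligned = align_states_to_behaviour(model, log, frame_rate, [behaviour])
        aligned_state = aligned[behaviour]["aligned_state"]
    if aligned_state is None:
        warn(f"no {behaviour} episodes; detection rate undefined")
        return None
    path = model.state_path
    sel = log.bouts[log.bouts["behaviour"] == behaviour]
    detected = total = 0
    for _, row in sel.iterrows():
        i0 = int(np.round(row["onset_s"] * frame_rate))
        i1 = int(np.round(row["offset_s"] * frame_rate))
        i0, i1 = max(i0, 0), min(i1, path.size)
        if i1 <= i0:
            continue
        total += 1
        frac = np.mean(path[i0:i1] == aligned_state)
        if frac >= overlap_threshold:
            detected += 1
    if total == 0:
        warn(f"no scorable {behaviour} episodes; detection rate undefined")
        return None
    return detected / total


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


@dataclass
class Episode:
    """One behavioural episode for decoding: label + frame block."""

    label: str
    start: int  # frame index
    stop: int


def build_episodes(
    log: EventLog,
    behaviours,
    frame_rate: float = vocab.DEFAULT_FRAME_RATE_HZ,
    n_frames: int | None = None,
    min_duration_s: float = 2.0,
) -> list[Episode]:
    """Episodes longer than ``min_duration_s`` for the requested behaviours."""
    eps = []
    for _, row in log.bouts.iterrows():
        if row["behaviour"] not in set(behaviours):
            continue
        if row["offset_s"] - row["onset_s"] <= min_duration_s:
            continue
        i0 = int(np.round(row["onset_s"] * frame_rate))
        i1 = int(np.round(row["offset_s"] * frame_rate))
        if n_frames is not None:
            i0, i1 = max(i0, 0), min(i1, n_frames)
        if i1 > i0:
            eps.append(Episode(str(row["behaviour"]), i0, i1))
    return eps


@dataclass
class DecodingResult:
    """Episode-split decoding performance over repeated iterations."""

    accuracies: np.ndarray  # one accuracy per iteration
    confusion_counts: np.ndarray  # summed over iterations
    classes: list[str]

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def confusion_pct(self) -> np.ndarray:
        """Row-normalized confusion matrix, percentages summing to 100 per row."""
        totals = self.confusion_counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.confusion_counts / totals * 100.0, 0.0)

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion_pct, index=self.classes, columns=self.classes)


def smote_oversample(X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Minority-class oversampling by k-NN interpolation (SMOTE-style).

    Each minority class is grown to the majority-class size with synthetic
    points x + u·(x_nn − x), u ~ U(0,1), where x_nn is one of the k nearest
    same-class neighbours, k = min(5, n_class − 1). Classes with fewer than
    two samples cannot be interpolated and are skipped with a warning.
    """
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    out_X, out_y = [X], [y]
    for cls, cnt in zip(classes, counts):
        need = target - cnt
        if need == 0:
            continue
        if cnt < 2:
            warn(f"class {cls!r} has <2 training samples; SMOTE skipped for it")
            continue
        Xc = X[y == cls]
        k = min(5, cnt - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, nbrs = nn.kneighbors(Xc)
        base = rng.integers(0, cnt, size=need)
        pick = nbrs[base, rng.integers(1, k + 1, size=need)]  # skip self (col 0)
        u = rng.random(need)[:, None]
        synth = Xc[base] + u * (Xc[pick] - Xc[base])
        out_X.append(synth)
        out_y.append(np.full(need, cls, dtype=y.dtype))
    return np.concatenate(out_X), np.concatenate(out_y)


def episode_split(episodes: list[Episode], seed: int, test_size: float = 0.25):
    """Stratified episode-level train/test split (indices into ``episodes``).

    Splitting by episode rather than by frame keeps all frames of any one
    episode on a single side, preventing temporal leakage.
    """
    labels = [e.label for e in episodes]
    idx = np.arange(len(episodes))
    train, test = train_test_split(
        idx, test_size=test_size, stratify=labels, random_state=seed
    )
    return train, test


def decode_behaviour(
    features: np.ndarray,
    episodes: list[Episode],
    n_iter: int = 50,
    seed: int = 0,
    test_size: float = 0.25,
    oversample: bool = True,
) -> DecodingResult:
    """Multiclass decoding of behaviour from population activity.

    Per iteration: a stratified episode-level train/test split; SMOTE-style
    oversampling of minority classes on the training frames only; a linear
    max-margin classifier (SVC, linear kernel, default regularization);
    per-frame accuracy on the held-out episodes. Confusion matrices are
    summed over iterations; ``confusion_pct`` row-normalizes them to
    percentages. Classes with fewer than two episodes cannot be stratified
    and are dropped with a warning.
    """
    features = np.atleast_2d(np.asarray(features, float))
    labels, counts = np.unique([e.label for e in episodes], return_counts=True)
    ok = set(labels[counts >= 2])
    dropped = set(labels) - ok
    if dropped:
        warn(f"classes with <2 episodes dropped: {sorted(dropped)}")
    episodes = [e for e in episodes if e.label in ok]
    classes = sorted(ok)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes with >= 2 episodes each")

    root = np.random.default_rng(seed)
    accs = np.empty(n_iter)
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for it in range(n_iter):
        split_seed = int(root.integers(0, 2**31 - 1))
        tr, te = episode_split(episodes, split_seed, test_size)

        def stack(ids):
            X = np.concatenate([features[episodes[i].start:episodes[i].stop] for i in ids])
            y = np.concatenate(
                [np.full(episodes[i].stop - episodes[i].start, episodes[i].label, dtype=object)
                 for i in ids]
            )
            return X, y

        Xtr, ytr = stack(tr)
        Xte, yte = stack(te)
        if oversample:
            Xtr, ytr = smote_oversample(Xtr, ytr, np.random.default_rng(split_seed))
        clf = SVC(kernel="linear")
        clf.fit(Xtr, ytr.astype(str))
        pred = clf.predict(Xte)
        accs[it] = np.mean(pred == yte.astype(str))
        conf += _sk_confusion(yte.astype(str), pred, labels=classes)
    return DecodingResult(accs, conf, classes)
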