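"""Four-state chromatin HMM: binarization, training, decoding, labeling.

The model is a hidden Markov chain over genome bins whose emissions are
independent Bernoulli variables, one per binarized protein-occupancy track
(the product-Bernoulli emission family used by chromHMM-style segmentations).
Four states reproduce the band/interband chromatin vocabulary: *Aquamarine*
(housekeeping-gene promoters, interbands), *Lazurite* (housekeeping-gene
bodies), and the condensed band states *Malachite* and *Ruby*.

Assembly gaps are carried as a per-bin mask; masked bins split the genome
into independent segments rather than being imputed, so the chain restarts
from the initial distribution after every gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import _hmm_core
from .intervals import BinnedGenome, GenomicInterval, SignalTrack

__all__ = [
    "STATE_LABELS",
    "STATE_RGB",
    "MASKED",
    "BinarizedTrack",
    "BinaryMatrix",
    "Segmentation",
    "BernoulliHMM",
    "binarize",
    "stack_tracks",
    "train_hmm",
    "viterbi_decode",
    "label_states",
    "path_to_segmentation",
    "segmentation_to_path",
]

#: Canonical four-state palette, in no particular model order — states earn a
#: label from their emission profile via :func:`label_states`.
STATE_LABELS = ("Aquamarine", "Lazurite", "Malachite", "Ruby")

#: Fixed label -> RGB for BED itemRgb output.
STATE_RGB = {
    "Aquamarine": "127,255,212",
    "Lazurite": "38,97,156",
    "Malachite": "11,218,81",
    "Ruby": "224,17,95",
}

#: Sentinel state value for masked bins in a decoded path.
MASKED = -1

_EPS = 1e-6  # probability floor: keeps EM away from absorbing zeros


@dataclass
class BinarizedTrack:
    track_id: str
    bits: np.ndarray
    mask: np.ndarray
    threshold: float


@dataclass
class BinaryMatrix:
    """M binarized tracks over n_bins, with a combined observed-data mask."""

    track_ids: list[str]
    data: np.ndarray  # (M, n_bins) uint8
    mask: np.ndarray  # (n_bins,) bool

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.uint8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.track_ids) != len(set(self.track_ids)):
            raise ValueError("track_ids must be unique")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.track_ids):
            raise ValueError("data must be (n_tracks, n_bins)")
        if self.mask.shape != (self.data.shape[1],):
            raise ValueError("mask length must equal n_bins")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one track")
        obs = self.data[:, self.mask]
        if obs.size and obs.max(initial=0) > 1:
            raise ValueError("entries must be 0/1 where mask is true")

    @property
    def n_tracks(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    @property
    def X(self) -> np.ndarray:
        """Samples-by-features view (n_bins, n_tracks)."""
        return self.data.T


@dataclass
class Segmentation:
    """Maximal same-state runs as labeled genomic intervals."""

    intervals: list[tuple[GenomicInterval, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self):
        return len(self.intervals)

    def total_bp(self, label: str | None = None) -> int:
        return sum(len(iv) for iv, lab in self.intervals if label is None or lab == label)

    def to_bed(self, path, rgb: bool = True) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            for iv, lab in self.intervals:
                row = [iv.chrom, str(iv.start), str(iv.end), lab]
                if rgb:
                    row += ["0", ".", str(iv.start), str(iv.end), STATE_RGB.get(lab, "0,0,0")]
                fh.write("\t".join(row) + "\n")


def _segments(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start/end (half-open) indices of maximal unmasked runs."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    padded = np.concatenate(([False], m, [False])).astype(np.int8)
    d = np.diff(padded)
    return np.flatnonzero(d == 1), np.flatnonzero(d == -1)


def binarize(track: SignalTrack, quantile: float = 0.9) -> BinarizedTrack:
    """Threshold a signal track at an empirical quantile of its observed bins.

    A bin is called occupied (bit 1) where value is strictly above the
    threshold; ties at the threshold stay 0, so a constant track binarizes to
    all zeros.  The mask propagates unchanged.
    """
    if not 0 < quantile < 1:
        raise ValueError(f"quantile must be in (0,1), got {quantile}")
    if not track.mask.any():
        raise ValueError(f"track {track.track_id!r} has no unmasked bins")
    threshold = float(np.quantile(track.values[track.mask], quantile))
    bits = np.zeros(track.n_bins, dtype=np.uint8)
    bits[track.mask] = (track.values[track.mask] > threshold).astype(np.uint8)
    return BinarizedTrack(track.track_id, bits, track.mask.copy(), threshold)


def stack_tracks(tracks: list[BinarizedTrack]) -> BinaryMatrix:
    """Stack binarized tracks into an observation matrix; masks are ANDed."""
    if not tracks:
        raise ValueError("no tracks to stack")
    n = tracks[0].bits.size
    for t in tracks:
        if t.bits.size != n:
            raise ValueError(
                f"track {t.track_id!r} has {t.bits.size} bins, expected {n}"
            )
    mask = np.logical_and.reduce([t.mask for t in tracks])
    data = np.stack([t.bits for t in tracks])
    return BinaryMatrix([t.track_id for t in tracks], data, mask)


class BernoulliHMM(BaseEstimator):
    """Hidden Markov model with independent Bernoulli emissions per track.

    Parameters
    ----------
    n_states : int, default 4
        Number of hidden chromatin states.
    n_restarts : int, default 5
        Independent EM restarts; the best converged log-likelihood wins,
        ties broken toward the lowest restart index.
    max_iter : int, default 500
        EM iteration cap per restart.
    tol : float, default 1e-6
        Relative log-likelihood improvement below which EM stops.
    random_state : int, default 17
        Seed for restart initialization (and for :meth:`sample`).

    Attributes
    ----------
    startprob_ : (K,) initial state distribution
    transmat_ : (K, K) row-stochastic transition matrix
    emissionprob_ : (K, M) Bernoulli success probability per (state, track)
    log_likelihood_ : training objective at convergence (best restart)
    loglik_history_ : per-iteration log-likelihood of the best restart
    n_iter_ : EM iterations used by the best restart
    converged_ : whether the best restart met ``tol`` before ``max_iter``
    track_ids_ : track names, when fitted through :func:`train_hmm`
    labels_ : state index -> chromatin state name, set by :func:`label_states`
    """

    def __init__(self, n_states: int = 4, n_restarts: int = 5, max_iter: int = 500,
                 tol: float = 1e-6, random_state: int = 17):
        self.n_states = n_states
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- construction without fitting -------------------------------------
    @classmethod
    def from_params(cls, startprob, transmat, emissionprob, track_ids=None,
                    labels=None, random_state: int = 17) -> "BernoulliHMM":
        """Build a ready model from known parameters (no training)."""
        model = cls(n_states=len(startprob), random_state=random_state)
        model.startprob_ = np.asarray(startprob, dtype=float)
        model.transmat_ = np.asarray(transmat, dtype=float)
        model.emissionprob_ = np.asarray(emissionprob, dtype=float)
        model._validate_params_arrays()
        model.log_likelihood_ = np.nan
        model.converged_ = True
        model.n_iter_ = 0
        if track_ids is not None:
            model.track_ids_ = list(track_ids)
        if labels is not None:
            model.labels_ = dict(labels)
        return model

    def _validate_params_arrays(self):
        K = self.n_states
        if self.startprob_.shape != (K,) or self.transmat_.shape != (K, K):
            raise ValueError("parameter shapes inconsistent with n_states")
        if abs(self.startprob_.sum() - 1) > 1e-9:
            raise ValueError("startprob must sum to 1")
        if np.abs(self.transmat_.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("transmat rows must sum to 1")
        if self.emissionprob_.min() < 0 or self.emissionprob_.max() > 1:
            raise ValueError("emission probabilities must lie in [0,1]")

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _check_X(X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_bins, n_tracks)")
        if X.size and (np.asarray(X) > 1).any():
            raise ValueError("X must be binary")
        return np.ascontiguousarray(X, dtype=np.uint8)

    @staticmethod
    def _mask_segments(n: int, mask) -> tuple[np.ndarray, np.ndarray]:
        if mask is None:
            mask = np.ones(n, dtype=bool)
        starts, ends = _segments(mask)
        if starts.size == 0:
            raise ValueError("no unmasked bins")
        return starts, ends

    def _init_params(self, M: int, rng: np.random.Generator):
        K = self.n_states
        pi = np.full(K, 1.0 / K)
        if K == 1:
            A = np.ones((1, 1))
        else:
            A = np.full((K, K), 0.1 / (K - 1))
            np.fill_diagonal(A, 0.9)
        P = rng.uniform(0.1, 0.9, size=(K, M))
        return pi, A, P

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None, mask=None) -> "BernoulliHMM":
        """Train by Baum–Welch EM over the unmasked segments of ``X``."""
        X = self._check_X(X)
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        starts, ends = self._mask_segments(X.shape[0], mask)
        n_seg = starts.size
        ss = np.random.SeedSequence(self.random_state)
        best = None
        for restart, child in enumerate(ss.spawn(self.n_restarts)):
            rng = np.random.default_rng(child)
            pi, A, P = self._init_params(X.shape[1], rng)
            history = []
            prev = -np.inf
            converged = False
            for _ in range(self.max_iter):
                ll, gamma0, trans_num, emit_num, gamma_sum = _hmm_core.baum_welch_estep(
                    X, starts, ends, pi, A, P
                )
                history.append(ll)
                if np.isfinite(prev) and ll - prev < self.tol * abs(prev):
                    converged = True
                    break
                prev = ll
                # M-step (with probability floors, then exact renormalisation)
                pi = np.clip(gamma0 / n_seg, _EPS, 1 - _EPS)
                pi /= pi.sum()
                if self.n_states == 1:
                    A = np.ones((1, 1))
                else:
                    A = np.clip(trans_num / trans_num.sum(axis=1, keepdims=True),
                                _EPS, 1 - _EPS)
                    A /= A.sum(axis=1, keepdims=True)
                P = np.clip(emit_num / gamma_sum[:, None], _EPS, 1 - _EPS)
            fit_ll = history[-1]
            if best is None or fit_ll > best[0]:
                best = (fit_ll, pi, A, P, history, converged)
        self.log_likelihood_, self.startprob_, self.transmat_, self.emissionprob_, \
            self.loglik_history_, self.converged_ = best
        self.n_iter_ = len(self.loglik_history_)
        return self

    def score(self, X, y=None, mask=None) -> float:
        """Total log-likelihood of ``X`` under the fitted model."""
        check_is_fitted(self, "emissionprob_")
        X = self._check_X(X)
        starts, ends = self._mask_segments(X.shape[0], mask)
        return float(_hmm_core.forward_loglik(
            X, starts, ends, self.startprob_, self.transmat_,
            np.clip(self.emissionprob_, _EPS, 1 - _EPS)))

    def predict(self, X, mask=None) -> np.ndarray:
        """Viterbi state path; masked bins carry the sentinel ``MASKED``."""
        check_is_fitted(self, "emissionprob_")
        X = self._check_X(X)
        starts, ends = self._mask_segments(X.shape[0], mask)
        raw = _hmm_core.viterbi_path(
            X, starts, ends, self.startprob_, self.transmat_,
            np.clip(self.emissionprob_, _EPS, 1 - _EPS))
        path = np.full(X.shape[0], MASKED, dtype=np.int32)
        for s, e in zip(starts, ends):
            path[s:e] = raw[s:e]
        return path

    def sample(self, n_bins: int, random_state=None, mask=None
               ) -> tuple[np.ndarray, np.ndarray]:
        """Draw (X, states) of length ``n_bins`` from the generative model."""
        check_is_fitted(self, "emissionprob_")
        rng = np.random.default_rng(
            self.random_state if random_state is None else random_state)
        if mask is None:
            mask = np.ones(n_bins, dtype=bool)
        starts, ends = self._mask_segments(n_bins, mask)
        uniforms = rng.random(n_bins)
        raw = _hmm_core.sample_path(starts, ends, self.startprob_,
                                    self.transmat_, uniforms)
        states = np.full(n_bins, MASKED, dtype=np.int32)
        for s, e in zip(starts, ends):
            states[s:e] = raw[s:e]
        M = self.emissionprob_.shape[1]
        X = np.zeros((n_bins, M), dtype=np.uint8)
        obs = states >= 0
        p = self.emissionprob_[states[obs]]
        X[obs] = (rng.random((int(obs.sum()), M)) < p).astype(np.uint8)
        return X, states

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "emissionprob_")
        d = {
            "n_states": int(self.n_states),
            "random_state": int(self.random_state),
            "log_likelihood": float(self.log_likelihood_),
            "startprob": [float(v) for v in self.startprob_],
            "transitions": [[float(v) for v in row] for row in self.transmat_],
            "emissions": [[float(v) for v in row] for row in self.emissionprob_],
        }
        if getattr(self, "track_ids_", None) is not None:
            d["track_ids"] = list(self.track_ids_)
        if getattr(self, "labels_", None) is not None:
            d["labels"] = {int(k): v for k, v in self.labels_.items()}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "BernoulliHMM":
        with open(path, "rt", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        model = cls.from_params(d["startprob"], d["transitions"], d["emissions"],
                                track_ids=d.get("track_ids"), labels=d.get("labels"),
                                random_state=d.get("random_state", 17))
        model.log_likelihood_ = d.get("log_likelihood", np.nan)
        return model


def align_states(estimated: BernoulliHMM, truth: BernoulliHMM) -> np.ndarray:
    """Match estimated states to generating states by emission-profile distance.

    Returns ``perm`` with ``perm[j] = i``: estimated state ``j`` corresponds
    to truth state ``i`` (minimum-cost assignment on Euclidean distance
    between emission rows).  Used to compare a trained model against known
    synthetic ground truth, where state order is arbitrary.
    """
    from scipy.optimize import linear_sum_assignment

    cost = np.linalg.norm(
        truth.emissionprob_[:, None, :] - estimated.emissionprob_[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(rows), dtype=np.int64)
    perm[cols] = rows
    return perm


def train_hmm(obs: BinaryMatrix, K: int = 4, seed: int = 17, n_restarts: int = 5,
              max_iter: int = 500, tol: float = 1e-6) -> BernoulliHMM:
    """Fit a :class:`BernoulliHMM` to a stacked binary observation matrix."""
    model = BernoulliHMM(n_states=K, n_restarts=n_restarts, max_iter=max_iter,
                         tol=tol, random_state=seed)
    model.fit(obs.X, mask=obs.mask)
    model.track_ids_ = list(obs.track_ids)
    return model


def viterbi_decode(model: BernoulliHMM, obs: BinaryMatrix) -> np.ndarray:
    """Decode the maximum-probability state path for ``obs``.

    The model's track order must match the observation matrix exactly.
    """
    if getattr(model, "track_ids_", None) is not None \
            and list(model.track_ids_) != list(obs.track_ids):
        raise ValueError(
            f"track mismatch: model has {model.track_ids_}, matrix has {obs.track_ids}")
    return model.predict(obs.X, mask=obs.mask)


def label_states(model: BernoulliHMM, marker_config: dict[str, str]) -> BernoulliHMM:
    """Assign the four chromatin state names from marker emission profiles.

    The state with the highest emission on the promoter/interband marker
    (e.g. CHRIZ) becomes *Aquamarine*; among the rest, the highest emission on
    the elongation marker (e.g. RNA-polII) becomes *Lazurite*; of the last
    two, the one with the lower mean emission across all tracks is *Ruby* (the
    most protein-depleted, condensed state) and the other *Malachite*.
    Deterministic given the model; numpy argmax/argmin tie-breaking (lowest
    state index) applies on exact ties.
    """
    check_is_fitted(model, "emissionprob_")
    if model.n_states != 4:
        raise ValueError(f"state labeling requires a 4-state model, got K={model.n_states}")
    if getattr(model, "track_ids_", None) is None:
        raise ValueError("model has no track_ids_; fit through train_hmm or set them")
    for role in ("promoter", "elongation"):
        if role not in marker_config:
            raise ValueError(f"marker_config missing role {role!r}")
        if marker_config[role] not in model.track_ids_:
            raise ValueError(f"marker track {marker_config[role]!r} not among model tracks")
    tr = list(model.track_ids_)
    prom = tr.index(marker_config["promoter"])
    elon = tr.index(marker_config["elongation"])
    E = model.emissionprob_
    remaining = list(range(4))
    aqua = remaining[int(np.argmax(E[remaining, prom]))]
    remaining.remove(aqua)
    laz = remaining[int(np.argmax(E[remaining, elon]))]
    remaining.remove(laz)
    ruby = remaining[int(np.argmin(E[remaining].mean(axis=1)))]
    remaining.remove(ruby)
    mala = remaining[0]
    model.labels_ = {aqua: "Aquamarine", laz: "Lazurite", mala: "Malachite", ruby: "Ruby"}
    return model


def path_to_segmentation(path: np.ndarray, grid: BinnedGenome,
                         labels: dict[int, str] | None = None) -> Segmentation:
    """Collapse a per-bin state path into maximal-run labeled intervals.

    Masked bins (sentinel state) yield no interval, so the segmentation tiles
    exactly the unmasked part of the genome; the final interval on each
    chromosome is clipped to the chromosome end.
    """
    path = np.asarray(path)
    if path.size != grid.n_bins:
        raise ValueError(f"path length {path.size} != n_bins {grid.n_bins}")
    if labels is None:
        labels = {}
    out: list[tuple[GenomicInterval, str]] = []
    for chrom in grid.chrom_sizes:
        sl = grid.chrom_slice(chrom)
        sub = path[sl]
        clen = grid.chrom_sizes[chrom]
        run_start = 0
        for i in range(1, sub.size + 1):
            if i == sub.size or sub[i] != sub[run_start]:
                state = int(sub[run_start])
                if state != MASKED:
                    start_bp = run_start * grid.bin_size
                    end_bp = min(i * grid.bin_size, clen)
                    lab = labels.get(state, f"state{state}")
                    out.append((GenomicInterval(chrom, start_bp, end_bp), lab))
                run_start = i
    return Segmentation(out)


def segmentation_to_path(seg: Segmentation, grid: BinnedGenome,
                         label_to_state: dict[str, int]) -> np.ndarray:
    """Inverse of :func:`path_to_segmentation` (uncovered bins stay masked)."""
    path = np.full(grid.n_bins, MASKED, dtype=np.int32)
    for iv, lab in seg:
        first = iv.start // grid.bin_size
        last = (iv.end - 1) // grid.bin_size
        lo = grid.bin_index(iv.chrom, first)
        hi = grid.bin_index(iv.chrom, last)
        path[lo:hi + 1] = label_to_state[lab]
    return path
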