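"""HMM training/decoding against brute-force oracles and closed forms."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from chromstates import (
    MASKED,
    BernoulliHMM,
    BinnedGenome,
    ChromSizes,
    SignalTrack,
    binarize,
    label_states,
    path_to_segmentation,
    segmentation_to_path,
    stack_tracks,
    train_hmm,
    viterbi_decode,
)
from chromstates.hmm import BinarizedTrack, BinaryMatrix


def _random_model(rng, K, M):
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    P = rng.uniform(0.05, 0.95, (K, M))
    return BernoulliHMM.from_params(pi, A, P)


def _emit(P, x):
    return np.prod(np.where(x.astype(bool), P, 1 - P), axis=1)


def brute_force_loglik(model, X):
    """Sum of path probabilities over all K^T paths (tiny T only)."""
    K = model.n_states
    T = X.shape[0]
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = model.startprob_[path[0]] * _emit(model.emissionprob_, X[:1])[path[0]]
        for t in range(1, T):
            p *= model.transmat_[path[t - 1], path[t]]
            p *= _emit(model.emissionprob_, X[t:t + 1])[path[t]]
        total += p
    return np.log(total)


def brute_force_viterbi(model, X):
    """Exhaustive maximum-probability path, first (lexicographically lowest)
    path winning exact ties — the documented decoder tie-break."""
    K = model.n_states
    T = X.shape[0]
    best, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        p = np.log(model.startprob_[path[0]]) + \
            np.log(_emit(model.emissionprob_, X[:1])[path[0]])
        for t in range(1, T):
            p += np.log(model.transmat_[path[t - 1], path[t]])
            p += np.log(_emit(model.emissionprob_, X[t:t + 1])[path[t]])
        if p > best:
            best, best_path = p, path
    return np.array(best_path), best


class TestBinarize:
    def _track(self, values, mask=None):
        values = np.asarray(values, dtype=float)
        mask = np.ones(values.size, dtype=bool) if mask is None else np.asarray(mask)
        return SignalTrack("t", values, mask)

    def test_constant_track_all_zero(self):
        bt = binarize(self._track([5.0] * 8), quantile=0.9)
        assert bt.threshold == 5.0 and not bt.bits.any()  # strict >

    def test_linear_interpolated_quantile(self):
        bt = binarize(self._track(np.arange(1, 11)), quantile=0.9)
        assert bt.threshold == pytest.approx(9.1)
        assert bt.bits.tolist() == [0] * 9 + [1]

    def test_presence_track_identity(self):
        vals = [0, 1, 0, 0, 1, 0, 0, 0]
        bt = binarize(self._track(vals), quantile=0.5)
        assert bt.bits.tolist() == vals

    def test_mask_propagates(self):
        mask = [True, True, False, True]
        bt = binarize(self._track([1, 2, 9, 3], mask), quantile=0.5)
        assert bt.mask.tolist() == mask

    def test_all_masked_error(self):
        with pytest.raises(ValueError, match="no unmasked"):
            binarize(self._track([1, 2], [False, False]))

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1])
    def test_bad_quantile(self, q):
        with pytest.raises(ValueError):
            binarize(self._track([1, 2]), quantile=q)


class TestStackTracks:
    def _bt(self, tid, bits, mask=None):
        bits = np.asarray(bits, dtype=np.uint8)
        mask = np.ones(bits.size, bool) if mask is None else np.asarray(mask)
        return BinarizedTrack(tid, bits, mask, 0.0)

    def test_single(self):
        m = stack_tracks([self._bt("a", [0, 1, 0])])
        assert m.data.shape == (1, 3)

    def test_mask_and_rule(self):
        m = stack_tracks([self._bt("a", [0, 1], [True, True]),
                          self._bt("b", [1, 0], [True, False])])
        assert m.mask.tolist() == [True, False]

    def test_track_order_and_wide_panel(self):
        tracks = [self._bt(f"p{i}", [i % 2, 1]) for i in range(14)]
        m = stack_tracks(tracks)
        assert m.n_tracks == 14
        assert m.track_ids == [f"p{i}" for i in range(14)]

    def test_mismatched_bins(self):
        with pytest.raises(ValueError, match="bins"):
            stack_tracks([self._bt("a", [0, 1]), self._bt("b", [0, 1, 0])])

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            BinaryMatrix(["a"], np.array([[0, 2]]), np.ones(2, bool))


class TestTrain:
    def test_k1_closed_form(self, rng):
        X = (rng.random((500, 3)) < [0.2, 0.5, 0.8]).astype(np.uint8)
        m = BinaryMatrix(["a", "b", "c"], X.T, np.ones(500, bool))
        model = train_hmm(m, K=1, n_restarts=1)
        assert model.transmat_.tolist() == [[1.0]]
        np.testing.assert_allclose(model.emissionprob_[0], X.mean(axis=0), atol=1e-6)

    def test_em_monotone_loglik(self, rng):
        X = rng.integers(0, 2, (300, 4)).astype(np.uint8)
        model = BernoulliHMM(n_states=3, n_restarts=2, max_iter=40,
                             random_state=0).fit(X)
        assert np.all(np.diff(model.loglik_history_) >= -1e-8)

    def test_row_stochastic_after_fit(self, rng):
        X = rng.integers(0, 2, (300, 4)).astype(np.uint8)
        model = BernoulliHMM(n_states=3, n_restarts=1, max_iter=30,
                             random_state=0).fit(X)
        assert abs(model.startprob_.sum() - 1) < 1e-9
        np.testing.assert_allclose(model.transmat_.sum(axis=1), 1, atol=1e-9)
        assert model.emissionprob_.min() >= 0 and model.emissionprob_.max() <= 1

    def test_no_unmasked_bins(self):
        with pytest.raises(ValueError, match="unmasked"):
            BernoulliHMM().fit(np.zeros((5, 2), np.uint8), mask=np.zeros(5, bool))

    def test_determinism(self, rng):
        X = rng.integers(0, 2, (200, 3)).astype(np.uint8)
        m1 = BernoulliHMM(n_states=2, n_restarts=3, random_state=7).fit(X)
        m2 = BernoulliHMM(n_states=2, n_restarts=3, random_state=7).fit(X)
        np.testing.assert_array_equal(m1.emissionprob_, m2.emissionprob_)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_sklearn_params_api(self):
        model = BernoulliHMM()
        params = model.get_params()
        assert params["n_states"] == 4 and params["random_state"] == 17
        model.set_params(n_states=2)
        assert model.n_states == 2


class TestForwardBackward:
    @pytest.mark.parametrize("K,T,M,seed", [(2, 6, 2, 0), (3, 8, 2, 1), (3, 5, 3, 2)])
    def test_forward_matches_enumeration(self, K, T, M, seed):
        rng = np.random.default_rng(seed)
        model = _random_model(rng, K, M)
        X = rng.integers(0, 2, (T, M)).astype(np.uint8)
        assert model.score(X) == pytest.approx(brute_force_loglik(model, X),
                                               rel=1e-9)

    def test_masked_gaps_factorize_likelihood(self, rng):
        model = _random_model(rng, 2, 2)
        X = rng.integers(0, 2, (10, 2)).astype(np.uint8)
        mask = np.ones(10, bool)
        mask[4:6] = False
        joint = model.score(X, mask=mask)
        parts = model.score(X[:4]) + model.score(X[6:])
        assert joint == pytest.approx(parts, rel=1e-12)


class TestViterbi:
    @pytest.mark.parametrize("K,T,M,seed", [(3, 8, 2, 3), (2, 7, 2, 4), (3, 6, 3, 5)])
    def test_matches_enumeration(self, K, T, M, seed):
        rng = np.random.default_rng(seed)
        model = _random_model(rng, K, M)
        X = rng.integers(0, 2, (T, M)).astype(np.uint8)
        expect, _ = brute_force_viterbi(model, X)
        np.testing.assert_array_equal(model.predict(X), expect)

    def test_single_bin_argmax(self, rng):
        model = _random_model(rng, 3, 2)
        X = np.array([[1, 0]], dtype=np.uint8)
        lik = model.startprob_ * _emit(model.emissionprob_, X)
        assert model.predict(X)[0] == np.argmax(lik)

    def test_near_deterministic_recovers_pattern(self):
        eps = 1e-4
        model = BernoulliHMM.from_params(
            [0.5, 0.5],
            [[1 - eps, eps], [eps, 1 - eps]],
            [[1 - eps, 1 - eps], [eps, eps]])
        states = np.array([0] * 5 + [1] * 5 + [0] * 3)
        X = np.stack([1 - states, 1 - states], axis=1).astype(np.uint8)
        np.testing.assert_array_equal(model.predict(X), states)

    def test_track_mismatch_error(self, rng):
        model = _random_model(rng, 2, 2)
        model.track_ids_ = ["a", "b"]
        m = BinaryMatrix(["b", "a"], np.zeros((2, 4), np.uint8), np.ones(4, bool))
        with pytest.raises(ValueError, match="track mismatch"):
            viterbi_decode(model, m)

    def test_masked_bins_sentinel(self, rng):
        model = _random_model(rng, 2, 2)
        X = rng.integers(0, 2, (6, 2)).astype(np.uint8)
        mask = np.array([True, True, False, True, True, True])
        path = model.predict(X, mask=mask)
        assert path[2] == MASKED and (path[mask] >= 0).all()


class TestHmmlearnCrossCheck:
    """Independent oracle: the same model expressed as a categorical HMM over
    2^M joint symbols must give the same likelihood and an equally probable
    Viterbi path."""

    def _categorical_twin(self, model, M):
        hl = pytest.importorskip("hmmlearn.hmm")
        n_sym = 1 << M
        emit = np.ones((model.n_states, n_sym))
        for s in range(n_sym):
            bits = np.array([(s >> m) & 1 for m in range(M)])
            emit[:, s] = np.prod(np.where(bits, model.emissionprob_,
                                          1 - model.emissionprob_), axis=1)
        twin = hl.CategoricalHMM(n_components=model.n_states)
        twin.startprob_ = model.startprob_
        twin.transmat_ = model.transmat_
        twin.emissionprob_ = emit
        twin.n_features = n_sym
        return twin

    def test_score_and_path(self, rng):
        M = 3
        model = _random_model(rng, 3, M)
        X = rng.integers(0, 2, (200, M)).astype(np.uint8)
        codes = (X * (1 << np.arange(M))).sum(axis=1).reshape(-1, 1)
        twin = self._categorical_twin(model, M)
        assert model.score(X) == pytest.approx(twin.score(codes), rel=1e-9)
        # tie-breaking may differ; the two Viterbi paths must be equally probable
        p_mine = self._path_logp(model, X, model.predict(X))
        p_twin = self._path_logp(model, X, twin.predict(codes))
        assert p_mine == pytest.approx(p_twin, rel=1e-9)

    @staticmethod
    def _path_logp(model, X, path):
        lp = np.log(model.startprob_[path[0]])
        lp += np.log(_emit(model.emissionprob_, X[:1])[path[0]])
        for t in range(1, len(path)):
            lp += np.log(model.transmat_[path[t - 1], path[t]])
            lp += np.log(_emit(model.emissionprob_, X[t:t + 1])[path[t]])
        return lp


class TestLabelStates:
    def _model(self, emissions, track_ids=("CHRIZ", "PolII")):
        K = len(emissions)
        A = np.full((K, K), 1 / K)
        return BernoulliHMM.from_params(np.full(K, 1 / K), A, emissions,
                                        track_ids=list(track_ids))

    MARKERS = {"promoter": "CHRIZ", "elongation": "PolII"}

    def test_rule_example(self):
        model = self._model([[0.9, 0.5], [0.2, 0.8], [0.05, 0.05], [0.3, 0.3]])
        label_states(model, self.MARKERS)
        assert model.labels_ == {0: "Aquamarine", 1: "Lazurite",
                                 2: "Ruby", 3: "Malachite"}

    def test_permutation_equivariance(self, rng):
        E = np.array([[0.9, 0.5], [0.2, 0.8], [0.05, 0.05], [0.3, 0.3]])
        perm = rng.permutation(4)
        model = self._model(E[perm])
        label_states(model, self.MARKERS)
        base = {0: "Aquamarine", 1: "Lazurite", 2: "Ruby", 3: "Malachite"}
        assert model.labels_ == {i: base[perm[i]] for i in range(4)}

    def test_promoter_tie_falls_to_mean_rule(self):
        # two states tie exactly on CHRIZ; the lowest index wins Aquamarine and
        # the other competes on the remaining rules
        model = self._model([[0.9, 0.5], [0.9, 0.8], [0.05, 0.05], [0.3, 0.3]])
        label_states(model, self.MARKERS)
        assert model.labels_[0] == "Aquamarine"
        assert model.labels_[1] == "Lazurite"

    def test_k_not_4(self):
        model = self._model([[0.9, 0.5], [0.2, 0.8]])
        with pytest.raises(ValueError, match="4-state"):
            label_states(model, self.MARKERS)

    def test_missing_marker(self):
        model = self._model([[0.9, 0.5]] * 4)
        with pytest.raises(ValueError, match="not among"):
            label_states(model, {"promoter": "CHRIZ", "elongation": "nope"})


class TestSegmentation:
    def test_basic_runs(self):
        grid = BinnedGenome(ChromSizes({"chrA": 800}), 200)
        seg = path_to_segmentation(np.array([0, 0, 1, 1]), grid,
                                   {0: "Aquamarine", 1: "Ruby"})
        assert [(iv.start, iv.end, lab) for iv, lab in seg] == \
            [(0, 400, "Aquamarine"), (400, 800, "Ruby")]

    def test_all_masked_empty(self):
        grid = BinnedGenome(ChromSizes({"chrA": 800}), 200)
        assert len(path_to_segmentation(np.full(4, MASKED), grid)) == 0

    def test_terminal_clipping(self):
        grid = BinnedGenome(ChromSizes({"chrA": 900}), 200)
        seg = path_to_segmentation(np.array([0, 0, 0, 0, 0]), grid, {0: "s"})
        assert seg.intervals[-1][0].end == 900

    @given(st.lists(st.integers(-1, 3), min_size=1, max_size=60))
    def test_roundtrip_property(self, states):
        path = np.array(states)
        grid = BinnedGenome(ChromSizes({"chrA": path.size * 100}), 100)
        labels = {k: f"s{k}" for k in range(4)}
        seg = path_to_segmentation(path, grid, labels)
        back = segmentation_to_path(seg, grid, {v: k for k, v in labels.items()})
        np.testing.assert_array_equal(back, path)
        # adjacent intervals never share a label (maximal runs)
        for (a, la), (b, lb) in zip(seg.intervals, seg.intervals[1:]):
            if a.chrom == b.chrom and a.end == b.start:
                assert la != lb

    def test_tiles_unmasked_genome(self, rng):
        grid = BinnedGenome(ChromSizes({"chrA": 10_000, "chrB": 4_100}), 200)
        path = rng.integers(0, 4, grid.n_bins)
        mask = rng.random(grid.n_bins) > 0.2
        path = np.where(mask, path, MASKED)
        seg = path_to_segmentation(path, grid)
        expect_bp = int((grid.bin_widths() * mask).sum())
        assert seg.total_bp() == expect_bp
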