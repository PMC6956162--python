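import numpy as np
import pytest

from dicmflex.aggregation import (
    block_pair_indices,
    dominance,
    feature_vector,
    flexibility,
    flexibility_from_labels,
    fo,
    mss,
)
from dicmflex.coupling import pair_indices
from dicmflex.signal_io import LOBES, LobarLayout, load_table1_spec
from dicmflex.surrogate_stats import Candidate, DicmTensor


def _full_layout(n_per_group=2):
    """Every lobe-hemisphere group populated with n sensors."""
    mapping, names = {}, []
    k = 0
    for lobe in LOBES:
        for hemi in ("L", "R"):
            for _ in range(n_per_group):
                name = f"ch{k}"
                mapping[name] = (lobe, hemi)
                names.append(name)
                k += 1
    return LobarLayout(mapping), names


def _tensor(names, T):
    pairs = pair_indices(len(names))
    return DicmTensor.empty(T, pairs, list(names)), pairs


def _set(tensor, t, p, est, code, strength, p_val=0.001):
    tensor.set_records(t, p, [Candidate(est=est, code=code, strength=strength,
                                        p=p_val, p_raw=0.0)])


class TestDominanceRule:
    """The >75%-of-sensor-pairs and >=50%-of-segments thresholds."""

    def setup_method(self):
        self.layout, self.names = _full_layout(1)
        # frontal L = ch0, frontal R = ch1, temporal L = ch2, temporal R = ch3
        self.tensor, self.pairs = _tensor(self.names, 10)
        self.block = block_pair_indices(self.pairs, self.names, self.layout,
                                        "frontal", "temporal", "both")
        assert len(self.block) == 4

    def _plant(self, pair_positions, windows, est=1, code=1):
        for t in windows:
            for p in pair_positions:
                _set(self.tensor, t, p, est, code, 0.5)

    def test_full_block_in_six_of_ten_windows_dominant(self):
        self._plant(self.block, range(6))
        res = dominance(self.tensor, self.layout, "frontal", "temporal",
                        "both", 1, 1)
        assert res.n_dom == 6 and res.n_ts == 10
        assert res.dominant

    def test_exactly_75_percent_of_pairs_not_dominant(self):
        self._plant(self.block[:3], range(10))  # 3/4 pairs = 75%, not >75%
        res = dominance(self.tensor, self.layout, "frontal", "temporal",
                        "both", 1, 1)
        assert res.n_dom == 0
        assert not res.dominant

    def test_four_of_ten_windows_not_dominant(self):
        self._plant(self.block, range(4))
        res = dominance(self.tensor, self.layout, "frontal", "temporal",
                        "both", 1, 1)
        assert res.n_dom == 4
        assert not res.dominant

    def test_secondary_record_counts_for_presence(self):
        for t in range(6):
            for p in self.block:
                self.tensor.set_records(t, p, [
                    Candidate(est=5, code=9, strength=0.9, p=0.0005, p_raw=0.0),
                    Candidate(est=1, code=1, strength=0.5, p=0.001, p_raw=0.0),
                ])
        res = dominance(self.tensor, self.layout, "frontal", "temporal",
                        "both", 1, 1)
        assert res.dominant


class TestBlockScopes:
    def test_pair_counts_per_scope(self):
        layout, names = _full_layout(2)
        pairs = pair_indices(len(names))
        cross = block_pair_indices(pairs, names, layout, "frontal", "frontal",
                                   "cross")
        within = block_pair_indices(pairs, names, layout, "frontal", "frontal",
                                    "within")
        both_ft = block_pair_indices(pairs, names, layout, "temporal",
                                     "frontal", "both", hemi_a="R")
        assert len(cross) == 4    # 2 left x 2 right
        assert len(within) == 2   # one internal pair per hemisphere
        assert len(both_ft) == 8  # 2 right-temporal x 4 frontal

    def test_empty_block_rejected(self):
        layout, names = _full_layout(1)
        pairs = pair_indices(len(names))
        with pytest.raises(ValueError, match="empty sensor block"):
            block_pair_indices(pairs, names, layout, "frontal", "frontal",
                               "within")  # one sensor per group: no pairs


class TestMssAndFo:
    def test_hand_worked_mss(self):
        """Four sensor pairs at strengths .2/.4/.6/.8 over 3 segments -> 0.5."""
        layout, names = _full_layout(1)
        tensor, pairs = _tensor(names, 3)
        block = block_pair_indices(pairs, names, layout, "frontal", "temporal",
                                   "both")
        strengths = [0.2, 0.4, 0.6, 0.8]
        for t in range(3):
            for p, s in zip(block, strengths):
                _set(tensor, t, p, 1, 1, s)
        value = mss(tensor, layout, "frontal", "temporal", "both", 1, 1)
        assert value == pytest.approx(0.5)

    def test_constant_half_strength(self):
        layout, names = _full_layout(1)
        tensor, pairs = _tensor(names, 4)
        block = block_pair_indices(pairs, names, layout, "frontal", "frontal",
                                   "cross")
        for t in range(4):
            for p in block:
                _set(tensor, t, p, 1, 1, 0.5)
        assert mss(tensor, layout, "frontal", "frontal", "cross", 1, 1) == \
            pytest.approx(0.5)

    def test_never_dominant_gives_zero(self):
        layout, names = _full_layout(1)
        tensor, _ = _tensor(names, 4)
        assert mss(tensor, layout, "frontal", "frontal", "cross", 1, 1) == 0.0

    @pytest.mark.parametrize("n_dom,expected", [(5, 0.5), (10, 1.0), (0, 0.0)])
    def test_fractional_occupancy(self, n_dom, expected):
        layout, names = _full_layout(1)
        tensor, pairs = _tensor(names, 10)
        block = block_pair_indices(pairs, names, layout, "frontal", "frontal",
                                   "cross")
        for t in range(n_dom):
            for p in block:
                _set(tensor, t, p, 2, 3, 0.8)
        assert fo(tensor, layout, "frontal", "frontal", "cross", 2, 3) == \
            pytest.approx(expected)


class TestFlexibility:
    def test_constant_labels_zero(self):
        labels = np.ones((10, 3), dtype=int) * 203
        assert flexibility_from_labels(labels).fi_global == 0.0

    def test_alternating_labels_one(self):
        labels = np.tile([[203], [101]], (5, 1))
        assert flexibility_from_labels(labels).fi_global == 1.0

    def test_hand_worked_three_window_example(self):
        """T=3, 2 pairs, one change in one pair: FI = 1 / ((3-1)*2) = 0.25."""
        labels = np.array([[203, 101],
                           [203, 101],
                           [507, 101]])
        assert flexibility_from_labels(labels).fi_global == pytest.approx(0.25)

    def test_relabeling_invariance(self, rng):
        labels = rng.integers(0, 5, size=(40, 6))
        relabel = {old: new for old, new in zip(range(5),
                                                rng.permutation(100)[:5])}
        mapped = np.vectorize(relabel.get)(labels)
        assert flexibility_from_labels(labels).fi_global == \
            flexibility_from_labels(mapped).fi_global

    def test_transitions_through_no_coupling_count(self):
        labels = np.array([[203], [0], [203], [0]])
        assert flexibility_from_labels(labels).fi_global == 1.0

    def test_single_window_rejected(self):
        names = ["a", "b"]
        tensor, _ = _tensor(names, 1)
        with pytest.raises(ValueError, match="at least 2"):
            flexibility(tensor)

    def test_tensor_flexibility_uses_primary_record(self):
        tensor, _ = _tensor(["a", "b", "c"], 3)
        _set(tensor, 0, 0, 2, 3, 0.5)
        _set(tensor, 1, 0, 2, 3, 0.5)
        _set(tensor, 2, 0, 1, 1, 0.5)
        res = flexibility(tensor)
        assert res.fi_pairs[0] == pytest.approx(0.5)
        assert res.fi_global == pytest.approx(0.5 / 3)


class TestFeatureVector:
    def test_empty_tensor_gives_zero_vector_with_flags(self):
        layout, names = _full_layout(2)
        tensor, _ = _tensor(names, 5)
        spec = load_table1_spec()
        vec = feature_vector(tensor, layout, spec)
        assert len(vec.mss_values) == 12
        assert len(vec.fo_values) == 10
        assert vec.as_array().shape == (22,)
        assert not vec.as_array().any()
        assert len(vec.missing) == 12

    def test_planted_first_row_recovered(self):
        """Frontal cross-hemispheric delta AEC fills row 1, others stay 0."""
        layout, names = _full_layout(2)
        tensor, pairs = _tensor(names, 10)
        block = block_pair_indices(pairs, names, layout, "frontal", "frontal",
                                   "cross")
        for t in range(6):
            for p in block:
                _set(tensor, t, p, 1, 1, 0.5)
        vec = feature_vector(tensor, layout, load_table1_spec())
        row1 = load_table1_spec().rows[0].name
        assert vec.mss_values[row1] == pytest.approx(0.5)
        assert vec.fo_values[row1] == pytest.approx(0.6)
        others = [v for k, v in vec.mss_values.items() if k != row1]
        assert not any(others)

    def test_values_bounded(self, rng):
        layout, names = _full_layout(2)
        tensor, pairs = _tensor(names, 8)
        for t in range(8):
            for p in range(len(pairs)):
                if rng.random() < 0.5:
                    _set(tensor, t, p, int(rng.integers(1, 6)),
                         int(rng.integers(1, 9)), float(rng.random()))
        vec = feature_vector(tensor, layout, load_table1_spec())
        arr = vec.as_array()
        assert np.all(arr >= 0.0) and np.all(arr <= 1.0)
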