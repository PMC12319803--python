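import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tacsalpha import (
    StudyDesign,
    TrialSet,
    flag_artifact_trials,
    grid_layout,
    read_container,
    segment_recording,
    write_container,
)
from tacsalpha.data_core import (
    BASELINE_EPOCH,
    ContainerSchemaError,
    POST_TRIM,
    POST_WINDOW,
)


def _continuous(design, block, n_units=2, fill=None):
    n = int(round(design.block_duration(block) * design.sampling_rate))
    if fill is None:
        # encode the sample index so segment content is checkable
        return np.tile(np.arange(n, dtype=np.float64), (n_units, 1))
    return np.full((n_units, n), fill)


class TestSegmentation:
    def test_protocol_arithmetic(self):
        """110 s retained baseline -> 20 epochs; 3.8-10 s window = 6.2 s;
        trimmed 4.2-9.7 s = 5.5 s = 5500 samples at 1000 Hz."""
        design = StudyDesign()
        assert POST_WINDOW[1] - POST_WINDOW[0] == pytest.approx(6.2)
        assert POST_TRIM[1] - POST_TRIM[0] == pytest.approx(5.5)
        cont = _continuous(design, "train10")
        baseline, post = segment_recording(
            cont, design, design.train_onsets("train10"), "train10"
        )
        assert baseline.n_trials == 20
        assert baseline.data.shape[2] == 5500
        assert post.n_trials == 20
        assert post.data.shape[2] == 5500
        assert post.time_axis[0] == pytest.approx(4.2)
        assert post.time_axis[-1] == pytest.approx(9.7 - 0.001)

    def test_segment_content_and_windows(self):
        """Baseline keeps the FIRST 110 s; post epochs start 4.2 s after
        each train offset."""
        design = StudyDesign(blocks=("train10",))
        cont = _continuous(design, "train10")
        onsets = design.train_onsets("train10")
        baseline, post = segment_recording(cont, design, onsets, "train10")
        assert baseline.data[0, 0, 0] == 0.0
        assert baseline.data[0, -1, -1] == 110.0 * 1000 - 1
        for k, onset in enumerate(onsets):
            start = int(round((onset + 10.0 + 4.2) * 1000))
            assert post.data[0, k, 0] == start

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        jitter=st.lists(
            st.floats(0.0, 0.4), min_size=20, max_size=20
        ),
        block=st.sampled_from(["train10", "train30"]),
    )
    def test_counts_invariant_under_onset_jitter(self, jitter, block):
        """Epoch counts are exact design constants for any onset timing."""
        design = StudyDesign()
        onsets = design.train_onsets(block) + np.cumsum(jitter)
        dur = design.train_durations[block]
        n = int(round((onsets[-1] + dur + 10.0 + 1.0) * 1000))
        cont = np.zeros((1, n))
        baseline, post = segment_recording(cont, design, onsets, block)
        assert baseline.n_trials == 20
        assert post.n_trials == 20
        assert baseline.data.shape[2] == int(BASELINE_EPOCH * 1000)

    def test_short_recording_names_missing_segment(self):
        design = StudyDesign(blocks=("train10",))
        cont = _continuous(design, "train10")[:, :-20000]
        with pytest.raises(ValueError, match="final train"):
            segment_recording(cont, design, design.train_onsets("train10"),
                              "train10")

    def test_non_increasing_onsets_rejected(self):
        design = StudyDesign(blocks=("train10",))
        cont = _continuous(design, "train10")
        onsets = design.train_onsets("train10")
        onsets[5] = onsets[4]
        with pytest.raises(ValueError, match="strictly increasing"):
            segment_recording(cont, design, onsets, "train10")


class TestArtifactFlagging:
    def _trials(self, rng, n_trials=20):
        data = rng.standard_normal((3, n_trials, 500))
        return TrialSet(data, np.arange(500) / 1000.0, "post", 1000.0)

    def test_clean_data_unflagged(self, rng):
        out = flag_artifact_trials(self._trials(rng), zmax=8.0)
        assert out.rejected_trials.sum() == 0

    def test_spike_flags_exactly_that_trial(self, rng):
        trials = self._trials(rng)
        trials.data[1, 7, 100] = 50.0 * np.abs(trials.data).max()
        out = flag_artifact_trials(trials, zmax=8.0)
        assert list(np.flatnonzero(out.rejected_trials)) == [7]
        # robust-z oracle: recompute directly
        med = np.median(trials.data)
        mad = np.median(np.abs(trials.data - med))
        z = np.abs(trials.data - med).max(axis=(0, 2)) / (1.4826 * mad)
        assert np.array_equal(out.rejected_trials, z > 8.0)

    def test_degenerate_threshold_errors(self, rng):
        with pytest.raises(ValueError, match="no usable trials"):
            flag_artifact_trials(self._trials(rng), zmax=0.001)

    def test_flags_preserve_trial_order(self, rng):
        trials = self._trials(rng)
        trials.data[0, 3, 0] = 1e6
        out = flag_artifact_trials(trials, zmax=8.0)
        assert out.n_trials == trials.n_trials
        assert np.array_equal(out.data, trials.data)


class TestLayout:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(rows=st.integers(2, 6), cols=st.integers(2, 6))
    def test_grid_adjacency_symmetric_irreflexive(self, rows, cols):
        lay = grid_layout(rows, cols)
        assert np.array_equal(lay.adjacency, lay.adjacency.T)
        assert not lay.adjacency.diagonal().any()
        # 4-neighbour edge count on a lattice
        assert lay.adjacency.sum() // 2 == rows * (cols - 1) + cols * (rows - 1)

    def test_region_labels_cover_all_units(self):
        lay = grid_layout(4, 4, somatosensory=(slice(0, 2), slice(0, 2)))
        assert len(lay.region_labels) == 16
        assert len(lay.units_in_region("somatosensory")) == 4

    def test_asymmetric_adjacency_rejected(self):
        adj = np.zeros((2, 2), dtype=bool)
        adj[0, 1] = True
        with pytest.raises(ValueError, match="symmetric"):
            from tacsalpha import UnitLayout

            UnitLayout(("a", "b"), np.zeros((2, 2)), adj)


class TestContainer:
    def test_round_trip_bit_identical(self, tmp_path, small_recording):
        path = tmp_path / "p.h5"
        small_recording.save(path)
        design, layout, trialsets, info = read_container(path)
        assert design == small_recording.design
        assert layout.unit_ids == small_recording.layout.unit_ids
        assert np.array_equal(layout.adjacency,
                              small_recording.layout.adjacency)
        for key, ts in small_recording.trialsets.items():
            got = trialsets[key]
            assert np.array_equal(got.data, ts.data)
            assert got.data.dtype == ts.data.dtype
            assert np.allclose(got.time_axis, ts.time_axis)
        assert info["seed"] == small_recording.spec.seed

    def test_missing_segment_group_named(self, tmp_path, small_recording):
        path = tmp_path / "p.h5"
        small_recording.save(path)
        import h5py

        with h5py.File(path, "a") as f:
            del f["tacs/train10/baseline"]
        with pytest.raises(ContainerSchemaError, match="baseline"):
            read_container(path)

    def test_schema_version_mismatch_named(self, tmp_path, small_recording):
        path = tmp_path / "p.h5"
        small_recording.save(path)
        import h5py

        with h5py.File(path, "a") as f:
            f.attrs["schema_version"] = "999"
        with pytest.raises(ContainerSchemaError, match="expected 1.*found 999"):
            read_container(path)

    def test_rewrite_is_stable(self, tmp_path, small_recording):
        """Writing the same content twice yields logically identical
        containers (datasets and non-timestamp attributes)."""
        p1, p2 = tmp_path / "a.h5", tmp_path / "b.h5"
        small_recording.save(p1)
        small_recording.save(p2)
        d1 = read_container(p1)
        d2 = read_container(p2)
        assert d1[0] == d2[0]
        for key in d1[2]:
            assert np.array_equal(d1[2][key].data, d2[2][key].data)
        assert d1[3] == d2[3]
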