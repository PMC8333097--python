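"""Tests for rich-label parsing, cropping, class modes, splits and stats."""

import numpy as np
import pytest

from sincbird import labels as lb
from sincbird.audio import peak_normalize, read_wav, write_wav


def make_events(spec):
    """spec: list of (rec, tag, start, dur)."""
    out = []
    seq = {}
    for rec, tag, start, dur in sorted(spec, key=lambda s: (s[0], s[2])):
        i = seq.get(rec, 0)
        out.append(lb.SoundEvent(rec, tag, start, dur, seq_index=i))
        seq[rec] = i + 1
    return out


class TestParseLabels:
    def test_empty_directory(self, tmp_path):
        assert lb.parse_labels(tmp_path) == []

    def test_sorted_with_consecutive_seq_index(self, tmp_path):
        lb.write_label_csv(tmp_path / "r1.csv",
                           [(1.5, 0.2, "B_song"), (0.3, 0.4, "A_call")])
        events = lb.parse_labels(tmp_path)
        assert [e.seq_index for e in events] == [0, 1]
        assert events[0].tag == "A_call"  # re-sorted by start time

    def test_nuisance_tags_retained_but_flagged(self, tmp_path):
        lb.write_label_csv(tmp_path / "r1.csv",
                           [(0.0, 0.5, "human"), (1.0, 0.5, "A_call")])
        events = lb.parse_labels(tmp_path)
        assert [e.is_nuisance for e in events] == [True, False]

    @pytest.mark.parametrize("row", ["-0.1,0.5,A_call", "0.1,-0.5,A_call",
                                     "abc,0.5,A_call", "0.1,0.5"])
    def test_malformed_rows_name_file_and_row(self, tmp_path, row):
        (tmp_path / "bad.csv").write_text(f"start,duration,tag\n{row}\n")
        with pytest.raises(ValueError, match=r"bad\.csv row 2"):
            lb.parse_labels(tmp_path)


class TestCropAndNormalize:
    @pytest.fixture
    def recording(self, tmp_path, rng):
        fs = 16000
        x = 0.25 * rng.normal(size=fs)  # 1 s
        wav = tmp_path / "rec0.wav"
        write_wav(wav, fs, x, bit_depth=32)
        return wav, fs, x

    def test_full_file_event_equals_normalized_file(self, recording, tmp_path):
        wav, fs, x = recording
        events = [lb.SoundEvent("rec0", "A_call", 0.0, 1.0, 0)]
        (out,) = lb.crop_and_normalize(wav, events, tmp_path / "seg",
                                       bit_depth=32)
        _, seg = read_wav(out)
        _, disk = read_wav(wav)
        assert np.allclose(seg, peak_normalize(disk), atol=1e-6)

    def test_segment_peak_is_one(self, recording, tmp_path):
        wav, fs, _ = recording
        events = [lb.SoundEvent("rec0", "A_call", 0.1, 0.3, 0)]
        (out,) = lb.crop_and_normalize(wav, events, tmp_path / "seg")
        _, seg = read_wav(out)
        assert np.max(np.abs(seg)) == pytest.approx(1.0, abs=1e-3)

    def test_sample_count_is_duration_times_fs(self, tmp_path, rng):
        fs = 44100
        wav = tmp_path / "rec1.wav"
        write_wav(wav, fs, 0.5 * rng.normal(size=fs))
        events = [lb.SoundEvent("rec1", "A_call", 0.2, 0.25, 0)]
        (out,) = lb.crop_and_normalize(wav, events, tmp_path / "seg")
        _, seg = read_wav(out)
        assert seg.size == 11025

    def test_filename_carries_stem_and_sequence(self, recording, tmp_path):
        wav, fs, _ = recording
        events = [lb.SoundEvent("rec0", "A_call", 0.0, 0.2, 0),
                  lb.SoundEvent("rec0", "B_song", 0.5, 0.2, 1)]
        outs = lb.crop_and_normalize(wav, events, tmp_path / "seg")
        assert [o.name for o in outs] == ["rec0_00.wav", "rec0_01.wav"]

    def test_event_past_end_rejected(self, recording, tmp_path):
        wav, fs, _ = recording
        events = [lb.SoundEvent("rec0", "A_call", 0.9, 0.5, 0)]
        with pytest.raises(ValueError, match="extends past"):
            lb.crop_and_normalize(wav, events, tmp_path / "seg")

    def test_silent_segment_warns_and_writes_unnormalized(self, tmp_path):
        fs = 16000
        wav = tmp_path / "rec2.wav"
        write_wav(wav, fs, np.zeros(fs))
        events = [lb.SoundEvent("rec2", "A_call", 0.0, 0.5, 0)]
        with pytest.warns(UserWarning, match="silent"):
            (out,) = lb.crop_and_normalize(wav, events, tmp_path / "seg")
        _, seg = read_wav(out)
        assert np.all(seg == 0)


class TestClassModes:
    TAGS = ["Parma_song", "Parma_call", "Sylca_call", "Denma_drumming",
            "Cicad_song", "Hylme_call", "human", "unknown"]
    TAXONOMY = {"Parma_song": "bird", "Parma_call": "bird",
                "Sylca_call": "bird", "Denma_drumming": "bird",
                "Cicad_song": "insect", "Hylme_call": "amphibian"}

    def test_cardinalities_collapse_monotonically(self):
        n_all = lb.make_class_mode(self.TAGS, "all_classes",
                                   self.TAXONOMY).n_classes
        n_bird = lb.make_class_mode(self.TAGS, "bird_classes",
                                    self.TAXONOMY).n_classes
        n_species = lb.make_class_mode(self.TAGS, "bird_species",
                                       self.TAXONOMY).n_classes
        assert n_all == 6 and n_bird == 4 and n_species == 3
        assert n_all >= n_bird >= n_species

    def test_every_bird_tag_maps_in_all_modes(self):
        for mode in ("all_classes", "bird_classes", "bird_species"):
            cm = lb.make_class_mode(self.TAGS, mode, self.TAXONOMY)
            for tag, group in self.TAXONOMY.items():
                if group == "bird":
                    assert tag in cm.mapping

    def test_indices_dense_and_group_ordered(self):
        cm = lb.make_class_mode(self.TAGS, "all_classes", self.TAXONOMY)
        assert sorted(set(cm.mapping.values())) == list(range(cm.n_classes))
        # insects sort before the amphibian, before birds
        assert cm.class_names[0] == "Cicad_song"
        assert cm.class_names[1] == "Hylme_call"

    def test_species_mode_merges_call_types(self):
        cm = lb.make_class_mode(self.TAGS, "bird_species", self.TAXONOMY)
        assert cm.mapping["Parma_song"] == cm.mapping["Parma_call"]

    def test_nuisance_tags_never_mapped(self):
        cm = lb.make_class_mode(self.TAGS, "all_classes", self.TAXONOMY)
        assert "human" not in cm.mapping and "unknown" not in cm.mapping


class TestBuildFileLists:
    @pytest.fixture
    def events(self):
        spec = []
        for i in range(50):
            spec.append((f"r{i:03d}", "A_call", 0.1, 0.5))
            spec.append((f"r{i:03d}", "B_song", 1.0, 0.5))
        return make_events(spec)

    def test_75_25_partition(self, events):
        mode = lb.make_class_mode({"A_call", "B_song"}, "all_classes")
        split, _ = lb.build_file_lists(events, mode, split_seed=0)
        assert len(split.train) == 75 and len(split.test) == 25
        train_paths = {it.path for it in split.train}
        test_paths = {it.path for it in split.test}
        assert not train_paths & test_paths
        assert len(train_paths | test_paths) == 100

    def test_split_deterministic(self, events):
        mode = lb.make_class_mode({"A_call", "B_song"}, "all_classes")
        s1, _ = lb.build_file_lists(events, mode, split_seed=3)
        s2, _ = lb.build_file_lists(events, mode, split_seed=3)
        assert [i.path for i in s1.train] == [i.path for i in s2.train]
        assert [i.path for i in s1.test] == [i.path for i in s2.test]

    def test_sub_10ms_events_excluded(self):
        events = make_events(
            [("r0", "A_call", 0.0, 0.005), ("r0", "B_song", 1.0, 0.5),
             ("r1", "A_call", 0.0, 0.5), ("r1", "B_song", 1.0, 0.5)])
        mode = lb.make_class_mode({"A_call", "B_song"}, "all_classes")
        split, file_map = lb.build_file_lists(events, mode, split_seed=0)
        all_paths = [i.path for i in split.train + split.test]
        assert len(all_paths) == 3
        assert not any("r0_00" in p for p in all_paths)

    def test_nuisance_events_excluded(self):
        events = make_events(
            [("r0", "human", 0.0, 0.5), ("r0", "A_call", 1.0, 0.5),
             ("r1", "B_song", 0.0, 0.5)])
        mode = lb.make_class_mode({e.tag for e in events}, "all_classes")
        split, _ = lb.build_file_lists(events, mode, split_seed=0)
        assert len(split.train) + len(split.test) == 2

    def test_empty_class_reported(self):
        events = make_events([("r0", "A_call", 0.0, 0.005),
                              ("r1", "B_song", 0.0, 0.5)])
        mode = lb.make_class_mode({"A_call", "B_song"}, "all_classes")
        with pytest.raises(ValueError, match="A_call"):
            lb.build_file_lists(events, mode, split_seed=0)

    def test_uncut_dialect_carries_start_and_length(self):
        events = make_events([("r0", "A_call", 0.25, 0.5),
                              ("r1", "B_song", 0.0, 0.4)])
        mode = lb.make_class_mode({"A_call", "B_song"}, "all_classes")
        split, _ = lb.build_file_lists(events, mode, split_seed=0,
                                       dialect="uncut", audio_dir="audio")
        items = split.train + split.test
        for it in items:
            assert it.path.endswith(".wav") and "audio" in it.path
            assert it.start is not None and it.duration is not None


class TestDatasetStats:
    def test_empty_input_all_zero(self):
        stats = lb.dataset_stats([])
        assert stats["totals"]["n_events"] == 0
        assert stats["overlap_fraction"] == 0.0
        assert len(stats["per_class"]) == 0

    def test_totals_equal_per_class_sums(self):
        events = make_events(
            [("r0", "A_call", 0.0, 0.5), ("r0", "B_song", 0.2, 0.6),
             ("r1", "A_call", 0.0, 1.0), ("r1", "human", 0.1, 0.2)])
        stats = lb.dataset_stats(events)
        assert stats["per_class"]["n_events"].sum() == \
            stats["totals"]["n_events"] == 3
        assert stats["per_class"]["total_duration"].sum() == \
            pytest.approx(stats["totals"]["total_duration"])

    def test_permutation_invariant(self, rng):
        spec = [(f"r{i%5}", f"T{i%3}_call", float(i % 7) * 0.3, 0.2)
                for i in range(30)]
        events = make_events(spec)
        shuffled = list(events)
        rng.shuffle(shuffled)
        a, b = lb.dataset_stats(events), lb.dataset_stats(shuffled)
        assert a["per_class"].equals(b["per_class"])
        assert a["overlap_fraction"] == b["overlap_fraction"]

    def test_overlap_uses_half_open_intervals(self):
        # abutting events do not overlap; intersecting ones do
        events = make_events(
            [("r0", "A_call", 0.0, 0.5), ("r0", "B_song", 0.5, 0.5),
             ("r1", "A_call", 0.0, 0.6), ("r1", "B_song", 0.5, 0.5)])
        stats = lb.dataset_stats(events)
        assert stats["overlap_fraction"] == pytest.approx(0.5)

    def test_same_tag_overlap_not_counted(self):
        events = make_events(
            [("r0", "A_call", 0.0, 1.0), ("r0", "A_call", 0.5, 1.0)])
        assert lb.dataset_stats(events)["overlap_fraction"] == 0.0
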