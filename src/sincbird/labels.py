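"""Rich-label handling: parsing, cropping, class modes, splits, statistics.

A "rich label" gives, for every sound event inside a recording, its class
tag (species + vocalisation type, e.g. ``Sp03_song``), start time and
duration in seconds.  On disk each recording has one CSV file
``<recording>.csv`` with header ``start,duration,tag`` (times in seconds,
decimal point, UTF-8).  Tags ``human`` and ``unknown`` mark nuisance events:
they are parsed and kept, but flagged and excluded from training lists.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import read_wav, write_wav, peak_normalize

__all__ = [
    "SoundEvent", "ClassMode", "DatasetSplit", "ListItem",
    "parse_labels", "write_label_csv", "crop_and_normalize",
    "make_class_mode", "build_file_lists", "write_list", "dataset_stats",
    "overlap_map", "NUISANCE_TAGS",
]

NUISANCE_TAGS = frozenset({"human", "unknown"})

# taxonomic rank used for class ordering (insects, amphibian, birds — the
# order the confusion matrix is displayed in)
_GROUP_RANK = {"insect": 0, "amphibian": 1, "bird": 2}


@dataclass(frozen=True)
class SoundEvent:
    """One labeled sound event inside a recording."""

    recording_id: str
    tag: str
    start: float          # seconds from recording start
    duration: float       # seconds, > 0
    seq_index: int = 0    # order-by-start within recording

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def is_nuisance(self) -> bool:
        return self.tag.lower() in NUISANCE_TAGS

    @property
    def species(self) -> str:
        return self.tag.split("_")[0]

    def overlaps(self, other: "SoundEvent") -> bool:
        """Half-open interval intersection [start, end) — abutting events
        do not count as overlapping."""
        return self.start < other.end and other.start < self.end


def parse_labels(label_dir: str | Path) -> list[SoundEvent]:
    """Parse every ``*.csv`` label table under ``label_dir``.

    Returns events sorted by (recording_id, start), with ``seq_index``
    consecutive from 0 in start-time order within each recording.
    Recordings with an empty table contribute no events.
    """
    label_dir = Path(label_dir)
    events: list[SoundEvent] = []
    for path in sorted(label_dir.glob("*.csv")):
        rec_id = path.stem
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                continue  # empty file -> no events
            if [h.strip() for h in header] != ["start", "duration", "tag"]:
                raise ValueError(f"{path}: expected header 'start,duration,tag', "
                                 f"got {','.join(header)!r}")
            rec_events = []
            for row_no, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != 3:
                    raise ValueError(f"{path} row {row_no}: expected 3 fields")
                try:
                    start, duration = float(row[0]), float(row[1])
                except ValueError as exc:
                    raise ValueError(f"{path} row {row_no}: {exc}") from None
                if start < 0 or duration <= 0 or not (
                        math.isfinite(start) and math.isfinite(duration)):
                    raise ValueError(
                        f"{path} row {row_no}: start must be >= 0 and "
                        f"duration > 0 (got start={start}, duration={duration})")
                rec_events.append((start, duration, row[2].strip()))
        rec_events.sort(key=lambda e: e[0])
        events.extend(
            SoundEvent(rec_id, tag, start, duration, seq_index=i)
            for i, (start, duration, tag) in enumerate(rec_events)
        )
    events.sort(key=lambda e: (e.recording_id, e.start, e.seq_index))
    return events


def write_label_csv(path: str | Path, events: list[tuple[float, float, str]]) -> None:
    """Write one label table; rows are (start_s, duration_s, tag) tuples.

    Times are printed with 6 decimals, which round-trips to the exact
    sample index at any common audio rate."""
    lines = ["start,duration,tag"]
    lines += [f"{s:.6f},{d:.6f},{t}" for s, d, t in events]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def segment_filename(recording_id: str, seq_index: int) -> str:
    return f"{recording_id}_{seq_index:02d}.wav"


def crop_and_normalize(wav_path: str | Path, events: list[SoundEvent],
                       out_dir: str | Path, bit_depth: int = 16) -> list[Path]:
    """Cut each labeled event out of a recording into its own WAV file.

    Each segment is peak-normalized (silent segments are written as-is with
    a warning) and named ``<original stem>_<seq index>.wav`` so tags can be
    re-associated from the file name alone.
    """
    wav_path, out_dir = Path(wav_path), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fs, samples = read_wav(wav_path)
    written = []
    for event in events:
        if event.recording_id != wav_path.stem:
            raise ValueError(f"event {event} does not belong to {wav_path.name}")
        i0 = round(event.start * fs)
        n = round(event.duration * fs)
        if i0 + n > samples.size:
            raise ValueError(
                f"{wav_path.name}: event #{event.seq_index} "
                f"({event.start:.3f}s + {event.duration:.3f}s) extends past "
                f"end of audio ({samples.size / fs:.3f}s)")
        segment = samples[i0:i0 + n]
        if np.all(segment == 0):
            warnings.warn(f"{wav_path.name} event #{event.seq_index} is silent; "
                          "written without normalization")
        else:
            segment = peak_normalize(segment)
        out = out_dir / segment_filename(event.recording_id, event.seq_index)
        write_wav(out, fs, segment, bit_depth=bit_depth)
        written.append(out)
    return written


# ---------------------------------------------------------------------------
# class modes
# ---------------------------------------------------------------------------

@dataclass
class ClassMode:
    """A tag -> dense class-index mapping for one of the three tag modes.

    ``all_classes`` keeps every non-nuisance tag; ``bird_classes`` drops
    insect/amphibian tags; ``bird_species`` additionally merges the call,
    song and drumming tags of each bird species into one class.  Class
    indices are dense, ordered by taxonomic group then alphabetically.
    """

    mode: str
    mapping: dict[str, int]
    class_names: list[str]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


def default_taxonomy(tags: list[str] | set[str]) -> dict[str, str]:
    """All-bird taxonomy, appropriate for the synthetic corpora."""
    return {t: "bird" for t in tags if t.lower() not in NUISANCE_TAGS}


def make_class_mode(tags: list[str] | set[str], mode: str,
                    taxonomy: dict[str, str] | None = None) -> ClassMode:
    """Build the tag mapping for ``mode`` from the set of observed tags.

    ``taxonomy`` maps each tag to its group (bird/insect/amphibian); the
    grouping is dataset knowledge that cannot be computed from tag strings,
    so it must be supplied for real data (defaults to all-bird).
    """
    retained = sorted(t for t in set(tags) if t.lower() not in NUISANCE_TAGS)
    if taxonomy is None:
        taxonomy = default_taxonomy(retained)
    missing = [t for t in retained if t not in taxonomy]
    if missing:
        raise ValueError(f"taxonomy does not cover tags: {missing}")

    def order_key(name: str, group: str) -> tuple[int, str]:
        return (_GROUP_RANK[group], name)

    if mode == "all_classes":
        pairs = [(t, t, taxonomy[t]) for t in retained]
    elif mode == "bird_classes":
        pairs = [(t, t, "bird") for t in retained if taxonomy[t] == "bird"]
    elif mode == "bird_species":
        pairs = [(t, t.split("_")[0], "bird")
                 for t in retained if taxonomy[t] == "bird"]
    else:
        raise ValueError(f"unknown class mode {mode!r}")
    if not pairs:
        raise ValueError(f"no tags retained under mode {mode!r}")

    class_names = sorted({(cls, grp) for _, cls, grp in pairs},
                         key=lambda cg: order_key(cg[0], cg[1]))
    names = [c for c, _ in class_names]
    index = {c: i for i, c in enumerate(names)}
    mapping = {tag: index[cls] for tag, cls, _ in pairs}
    return ClassMode(mode=mode, mapping=mapping, class_names=names)


# ---------------------------------------------------------------------------
# file lists and splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ListItem:
    """One train/test list entry.

    In the cut dialect ``path`` points at a cropped segment file; in the
    uncut dialect it points at the original recording and carries the
    event's (start, duration) so the call is selected at read time.
    """

    path: str
    class_index: int
    event: SoundEvent
    start: float | None = None      # uncut dialect only
    duration: float | None = None


@dataclass
class DatasetSplit:
    train: list[ListItem]
    test: list[ListItem]
    ratio: float
    seed: int


def build_file_lists(
    events: list[SoundEvent],
    mode: ClassMode,
    split_seed: int,
    min_len: float = 0.010,
    dialect: str = "cut",
    segment_dir: str | Path = "segments",
    audio_dir: str | Path = "audio",
    ratio: float = 0.75,
) -> tuple[DatasetSplit, dict[str, int]]:
    """Filter events and split them into train/test item lists.

    Nuisance events, events whose tag is outside the mode mapping, and
    events shorter than ``min_len`` seconds are removed.  The remaining
    events are split ``ratio``:(1-ratio) at random (train gets the floor).
    Returns the split and a path -> class-index mapping.
    """
    if dialect not in ("cut", "uncut"):
        raise ValueError(f"unknown dialect {dialect!r}")
    retained = [e for e in events
                if not e.is_nuisance and e.tag in mode.mapping
                and e.duration >= min_len]
    present = {mode.mapping[e.tag] for e in retained}
    empty = [mode.class_names[i] for i in range(mode.n_classes)
             if i not in present]
    if empty:
        raise ValueError(f"classes with zero events after filtering: {empty}")

    items: list[ListItem] = []
    for e in retained:
        cls = mode.mapping[e.tag]
        if dialect == "cut":
            path = str(Path(segment_dir) / segment_filename(e.recording_id,
                                                            e.seq_index))
            items.append(ListItem(path=path, class_index=cls, event=e))
        else:
            path = str(Path(audio_dir) / f"{e.recording_id}.wav")
            items.append(ListItem(path=path, class_index=cls, event=e,
                                  start=e.start, duration=e.duration))

    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(len(items))
    n_train = int(np.floor(ratio * len(items)))
    train = [items[i] for i in sorted(perm[:n_train])]
    test = [items[i] for i in sorted(perm[n_train:])]
    split = DatasetSplit(train=train, test=test, ratio=ratio, seed=split_seed)
    file_map = {it.path: it.class_index for it in items}
    return split, file_map


def write_list(items: list[ListItem], path: str | Path) -> None:
    lines = []
    for it in items:
        if it.start is None:
            lines.append(f"{it.path} {it.class_index}")
        else:
            lines.append(f"{it.path} {it.start:.6f} {it.duration:.6f} "
                         f"{it.class_index}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def overlap_map(events: list[SoundEvent]) -> dict[tuple[str, int], set[str]]:
    """For every non-nuisance event, the set of *other* species tags whose
    events intersect its [start, end) interval in the same recording."""
    by_rec: dict[str, list[SoundEvent]] = {}
    for e in events:
        by_rec.setdefault(e.recording_id, []).append(e)
    out: dict[tuple[str, int], set[str]] = {}
    for rec_events in by_rec.values():
        for e in rec_events:
            if e.is_nuisance:
                continue
            partners = {o.tag for o in rec_events
                        if o is not e and not o.is_nuisance
                        and o.tag != e.tag and e.overlaps(o)}
            out[(e.recording_id, e.seq_index)] = partners
    return out


def dataset_stats(events: list[SoundEvent],
                  mode: ClassMode | None = None) -> dict:
    """Per-class event counts and durations, plus corpus-level totals.

    If ``mode`` is given, tags are grouped into its classes; otherwise each
    non-nuisance tag is its own row.  The overlap fraction is the share of
    non-nuisance events whose interval intersects an event with a different
    tag in the same recording.
    """
    animal = [e for e in events if not e.is_nuisance]
    if mode is not None:
        animal = [e for e in animal if e.tag in mode.mapping]
        label_of = {t: mode.class_names[i] for t, i in mode.mapping.items()}
        classes = mode.class_names
    else:
        label_of = {e.tag: e.tag for e in animal}
        classes = sorted({e.tag for e in animal})

    rows = pd.DataFrame({
        "class": [label_of[e.tag] for e in animal],
        "duration": [e.duration for e in animal],
    })
    if len(rows):
        per_class = (rows.groupby("class")["duration"]
                     .agg(n_events="count", total_duration="sum",
                          mean_duration="mean")
                     .reindex(classes, fill_value=0.0))
        per_class["n_events"] = per_class["n_events"].fillna(0).astype(int)
    else:
        per_class = pd.DataFrame(
            {"n_events": pd.Series(dtype=int),
             "total_duration": pd.Series(dtype=float),
             "mean_duration": pd.Series(dtype=float)})

    omap = overlap_map(events)
    overlapping = sum(
        1 for e in animal if omap.get((e.recording_id, e.seq_index)))
    n = len(animal)
    return {
        "per_class": per_class,
        "totals": {
            "n_events": n,
            "n_nuisance_events": sum(1 for e in events if e.is_nuisance),
            "total_duration": float(sum(e.duration for e in animal)),
            "n_recordings_tagged": len({e.recording_id for e in events}),
        },
        "overlap_fraction": overlapping / n if n else 0.0,
    }
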