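"""Synthetic labeled soundscapes with field-recording structure.

The generator emulates the statistical shape of a richly annotated
bird-recording corpus: short mono files (1-5 s by default), dozens of
imbalanced classes, event durations from tens of milliseconds to seconds,
a controllable fraction of events overlapping a different species, optional
"human"/"unknown" nuisance events, and white background noise at a target
SNR.  Calls are synthesized as band-limited harmonic stacks with a linear
chirp and an attack/decay envelope — tonal, class-separable signals a small
network can learn, standing in for bird syllables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .audio import write_wav
from .labels import SoundEvent, write_label_csv

__all__ = ["SpeciesTemplate", "CorpusSpec", "make_species_bank",
           "render_call", "synth_recording", "make_corpus"]

_CALL_KINDS = ("song", "call", "drumming")
# fraction of a band's width kept clear at each edge so that spectral
# leakage of short calls stays inside the nominal carrier band
_BAND_MARGIN = 0.15


@dataclass(frozen=True)
class SpeciesTemplate:
    """Acoustic recipe for one class tag."""

    name: str
    carrier_band: tuple[float, float]    # (low Hz, high Hz)
    n_harmonics: int                     # partials above the fundamental
    chirp_rate: float                    # Hz/s, clamped to stay in band
    duration_dist: tuple[float, float]   # uniform (min s, max s)
    call_kind: str

    def __post_init__(self) -> None:
        low, high = self.carrier_band
        if not 0 < low < high:
            raise ValueError(f"invalid carrier band {self.carrier_band}")
        dmin, dmax = self.duration_dist
        if not 0 < dmin <= dmax:
            raise ValueError(f"invalid duration bounds {self.duration_dist}")
        if self.n_harmonics < 0:
            raise ValueError("n_harmonics must be >= 0")
        if self.call_kind not in _CALL_KINDS:
            raise ValueError(f"call_kind must be one of {_CALL_KINDS}")


@dataclass
class CorpusSpec:
    """Parameters of one synthetic corpus."""

    n_species: int
    files_per_class_dist: tuple[int, int] = (9, 60)   # log-uniform bounds
    file_len_range: tuple[float, float] = (1.0, 5.0)  # seconds
    fs: int = 44100
    overlap_prob: float = 0.2
    noise_snr_db: float | None = 10.0
    include_nuisance: bool = False
    seed: int = 0
    events_per_file: tuple[int, int] = (1, 3)
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_prob <= 1.0:
            raise ValueError("overlap_prob must lie in [0, 1]")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")


def make_species_bank(k: int, fs: float, seed: int,
                      f_lo: float = 300.0,
                      f_hi: float | None = None) -> list[SpeciesTemplate]:
    """Deterministically draw ``k`` species templates with distinct bands.

    The usable spectrum (``f_lo`` .. ``f_hi``, default 0.45*fs) is divided
    into ``k`` contiguous log-spaced slots; each template's carrier band is
    jittered inside its slot, so bands are pairwise disjoint and every one
    respects the Nyquist bound.
    """
    if k < 2:
        raise ValueError("classification needs at least 2 classes")
    if f_hi is None:
        f_hi = 0.45 * fs
    if not 0 < f_lo < f_hi < fs / 2:
        raise ValueError(f"need 0 < f_lo < f_hi < fs/2, got "
                         f"({f_lo}, {f_hi}) at fs={fs}")
    rng = np.random.default_rng(seed)
    edges = np.geomspace(f_lo, f_hi, k + 1)
    templates = []
    for i in range(k):
        lo_edge, hi_edge = edges[i], edges[i + 1]
        slot = hi_edge - lo_edge
        low = lo_edge + 0.05 * slot * rng.uniform(0.5, 1.0)
        high = hi_edge - 0.05 * slot * rng.uniform(0.5, 1.0)
        bw = high - low
        dmin = rng.uniform(0.05, 0.12)
        dmax = dmin + rng.uniform(0.10, 0.30)
        templates.append(SpeciesTemplate(
            name=f"Sp{i:02d}_{_CALL_KINDS[i % 3]}",
            carrier_band=(float(low), float(high)),
            n_harmonics=int(rng.integers(0, 3)),
            chirp_rate=float(rng.uniform(-0.5, 0.5) * bw),
            duration_dist=(float(dmin), float(dmax)),
            call_kind=_CALL_KINDS[i % 3],
        ))
    return templates


def render_call(template: SpeciesTemplate, duration: float, fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """Render one call: harmonic stack, linear chirp, attack/decay envelope.

    The fundamental and every retained partial stay inside the carrier band
    (with an interior margin), so call energy is band-limited by design.
    Peak amplitude is 1; every sample inside the call is nonzero.
    """
    n = max(2, round(duration * fs))
    t = np.arange(n) / fs
    low, high = template.carrier_band
    margin = _BAND_MARGIN * (high - low)
    f_min, f_max = low + margin, high - margin
    f0 = rng.uniform(f_min, f_max)
    rate = np.clip(template.chirp_rate,
                   (f_min - f0) / duration, (f_max - f0) / duration)
    f_end = f0 + rate * duration

    wave = np.zeros(n)
    for m in range(1, template.n_harmonics + 2):
        if m > 1 and not (f_min <= m * f0 and m * max(f0, f_end) <= f_max):
            continue  # partial would leave the band
        phase = 2 * np.pi * m * (f0 * t + 0.5 * rate * t * t)
        wave += np.sin(phase + rng.uniform(0, 2 * np.pi)) / m

    # attack/decay: quarter-sine ramps, strictly positive at the endpoints
    env = np.ones(n)
    na, nd = max(1, int(0.15 * n)), max(1, int(0.25 * n))
    env[:na] = np.sin(0.5 * np.pi * (np.arange(na) + 1) / na)
    env[n - nd:] = np.sin(0.5 * np.pi * (np.arange(nd, 0, -1)) / nd)
    wave *= env
    peak = np.max(np.abs(wave))
    return wave / peak if peak > 0 else wave


def _render_nuisance(tag: str, duration: float, fs: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Low-band tonal burst standing in for human voice / unidentified sound."""
    n = max(2, round(duration * fs))
    t = np.arange(n) / fs
    f0 = rng.uniform(90.0, 280.0)
    wave = np.sin(2 * np.pi * f0 * t) + 0.5 * np.sin(2 * np.pi * 2 * f0 * t)
    env = np.sin(np.pi * (np.arange(n) + 0.5) / n)
    return 0.5 * wave * env / np.max(np.abs(wave * env))


def _draw_duration(template: SpeciesTemplate, max_s: float,
                   rng: np.random.Generator) -> float:
    """Draw from the template's duration bounds; redraw (never truncate)
    until the call fits inside the file."""
    dmin, dmax = template.duration_dist
    if dmin >= max_s:
        raise ValueError(
            f"{template.name}: minimum call duration {dmin}s does not fit "
            f"in a {max_s:.2f}s file")
    for _ in range(1000):
        d = rng.uniform(dmin, dmax)
        if d < max_s:
            return d
    return min(dmax, 0.9 * max_s)


def synth_recording(
    templates: list[SpeciesTemplate],
    spec: CorpusSpec,
    rng: np.random.Generator,
    tags: list[str] | None = None,
) -> tuple[np.ndarray, list[SoundEvent]]:
    """Synthesize one labeled recording.

    Event tags are taken from ``tags`` (one event each) or drawn uniformly
    from the templates.  Each event beyond the first is, with probability
    ``overlap_prob``, placed so that its interval intersects a previously
    placed event of a *different* tag; otherwise placement avoids overlap.
    Background white noise is added at ``noise_snr_db`` relative to the
    whole-file signal power.
    """
    if not templates:
        raise ValueError("templates must be nonempty")
    by_name = {t.name: t for t in templates}
    fs = spec.fs
    for t in templates:
        if t.carrier_band[1] >= fs / 2:
            raise ValueError(f"{t.name}: carrier band exceeds Nyquist at fs={fs}")
    file_len = rng.uniform(*spec.file_len_range)
    n_total = round(file_len * fs)

    if tags is None:
        lo, hi = spec.events_per_file
        n_events = int(rng.integers(lo, hi + 1))
        tags = [templates[rng.integers(len(templates))].name
                for _ in range(n_events)]

    placed: list[tuple[int, int, str]] = []  # (start sample, n samples, tag)
    wave = np.zeros(n_total)
    for tag in tags:
        if tag in by_name:
            template = by_name[tag]
            dur_s = _draw_duration(template, file_len, rng)
            call = render_call(template, dur_s, fs, rng)
        else:  # nuisance tag
            dur_s = rng.uniform(0.2, min(1.0, 0.8 * file_len))
            call = _render_nuisance(tag, dur_s, fs, rng)
        n = call.size
        anchors = [p for p in placed if p[2] != tag]
        start = None
        if anchors and rng.random() < spec.overlap_prob:
            a0, an, _ = anchors[rng.integers(len(anchors))]
            lo_s = max(0, a0 - n + 1)
            hi_s = min(n_total - n, a0 + an - 1)
            if hi_s >= lo_s:
                start = int(rng.integers(lo_s, hi_s + 1))
            else:
                start = max(0, min(a0, n_total - n))
        else:
            for _ in range(50):
                cand = int(rng.integers(0, n_total - n + 1))
                if all(cand >= p0 + pn or cand + n <= p0 for p0, pn, _ in placed):
                    start = cand
                    break
            if start is None:  # crowded file: accept an overlapping slot
                start = int(rng.integers(0, n_total - n + 1))
        amp = rng.uniform(0.3, 1.0)
        wave[start:start + n] += amp * call
        placed.append((start, n, tag))

    if spec.include_nuisance and rng.random() < 0.15:
        tag = "human" if rng.random() < 0.5 else "unknown"
        dur_s = rng.uniform(0.2, min(1.0, 0.8 * file_len))
        call = _render_nuisance(tag, dur_s, fs, rng)
        start = int(rng.integers(0, n_total - call.size + 1))
        wave[start:start + call.size] += 0.4 * call
        placed.append((start, call.size, tag))

    if spec.noise_snr_db is not None and np.isfinite(spec.noise_snr_db):
        sig_power = float(np.mean(wave ** 2))
        if sig_power > 0:
            sigma = np.sqrt(sig_power / 10 ** (spec.noise_snr_db / 10.0))
            wave = wave + rng.normal(0.0, sigma, size=n_total)

    peak = np.max(np.abs(wave))
    if peak > 0.99:
        wave *= 0.99 / peak

    placed.sort(key=lambda p: p[0])
    events = [SoundEvent(recording_id="", tag=tag, start=s0 / fs,
                         duration=n / fs, seq_index=i)
              for i, (s0, n, tag) in enumerate(placed)]
    return wave, events


def make_corpus(spec: CorpusSpec, out_dir: str | Path,
                templates: list[SpeciesTemplate] | None = None) -> dict:
    """Write a full corpus (WAVs + per-recording label CSVs + manifest).

    Per-class event counts are drawn log-uniformly between the
    ``files_per_class_dist`` bounds, mimicking the heavy class imbalance of
    field-annotation corpora.  Fully reproducible from ``spec.seed``.
    """
    out_dir = Path(out_dir)
    audio_dir = out_dir / "audio"
    label_dir = out_dir / "labels"
    audio_dir.mkdir(parents=True, exist_ok=True)
    label_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    if templates is None:
        templates = make_species_bank(spec.n_species, spec.fs, seed=spec.seed)

    lo, hi = spec.files_per_class_dist
    counts = {
        t.name: int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        for t in templates
    }
    # recordings mix distinct species (drawn without replacement, weighted
    # by how many events each class still owes), so multi-event files can
    # realize cross-species overlap
    remaining = dict(counts)

    recordings = []
    idx = 0
    ev_lo, ev_hi = spec.events_per_file
    while sum(remaining.values()) > 0:
        avail = [name for name, c in remaining.items() if c > 0]
        n_ev = min(len(avail), int(rng.integers(ev_lo, ev_hi + 1)))
        weights = np.array([remaining[name] for name in avail], dtype=float)
        tags = list(rng.choice(avail, size=n_ev, replace=False,
                               p=weights / weights.sum()))
        for tag in tags:
            remaining[tag] -= 1
        rec_id = f"rec{idx:04d}"
        wave, events = synth_recording(templates, spec, rng, tags=tags)
        events = [SoundEvent(rec_id, e.tag, e.start, e.duration, e.seq_index)
                  for e in events]
        write_wav(audio_dir / f"{rec_id}.wav", spec.fs, wave,
                  bit_depth=spec.bit_depth)
        write_label_csv(label_dir / f"{rec_id}.csv",
                        [(e.start, e.duration, e.tag) for e in events])
        recordings.append({
            "id": rec_id,
            "wav": str(audio_dir / f"{rec_id}.wav"),
            "n_samples": int(wave.size),
            "events": [{"tag": e.tag,
                        "start": round(e.start, 6),
                        "duration": round(e.duration, 6)}
                       for e in events],
        })
        idx += 1

    manifest = {
        "spec": asdict(spec),
        "templates": [asdict(t) for t in templates],
        "class_counts": counts,
        "n_recordings": len(recordings),
        "n_events": sum(len(r["events"]) for r in recordings),
        "recordings": recordings,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
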