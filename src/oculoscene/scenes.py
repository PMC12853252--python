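"""Artificial acoustic scene construction.

Scenes are 9 s "tone clouds": six concurrent streams of pure-tone pips, each
stream with a unique carrier frequency drawn from a fixed 9-value pool spaced
evenly on the ERB-rate (cam) scale between 500 and 3,225 Hz.  In REG scenes
every stream is isochronous (tone duration and inter-tone interval fixed per
stream); in RND scenes the inter-tone intervals vary from gap to gap.  A
scene either gains a stream (CA), loses one (CD), or stays constant (NC);
decoy trials additionally carry a 200 ms global silent gap that participants
respond to.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

# Stimulus constants
TONE_MIN_MS = 10.0
TONE_MAX_MS = 150.0
SCENE_DURATION_S = 9.0
MEAN_ITI_MS = (TONE_MIN_MS + TONE_MAX_MS) / 2.0  # 80 ms
POOL_LOW_HZ = 500.0
POOL_HIGH_HZ = 3225.0
POOL_SIZE = 9
N_STREAMS = 6
CHANGE_TIME_S = 6.0
GAP_DURATION_S = 0.2
GAP_MARGIN_S = 1.0
RAMP_MS = 3.0

REGULARITIES = ("REG", "RND")
CHANGE_TYPES = ("CA", "CD", "NC")
CONDITIONS = tuple(f"{r}-{c}" for r in REGULARITIES for c in CHANGE_TYPES)

TRIALS_PER_CONDITION_PER_BLOCK = 4
N_BLOCKS = 8


def erb_number(f_hz):
    """ERB-rate (cam) of frequency ``f_hz`` (Glasberg & Moore)."""
    return 21.4 * np.log10(4.37 * np.asarray(f_hz, dtype=float) / 1000.0 + 1.0)


def erb_number_to_hz(cam):
    """Inverse of :func:`erb_number`."""
    return (10.0 ** (np.asarray(cam, dtype=float) / 21.4) - 1.0) / 4.37 * 1000.0


def make_frequency_pool() -> np.ndarray:
    """The 9 carrier frequencies: 500–3,225 Hz, equally spaced in cams.

    Endpoints are exact; interior values are equally spaced on the ERB-rate
    scale (the nominal spacing works out to ~2 cams).
    """
    cams = np.linspace(erb_number(POOL_LOW_HZ), erb_number(POOL_HIGH_HZ), POOL_SIZE)
    pool = erb_number_to_hz(cams)
    pool[0] = POOL_LOW_HZ
    pool[-1] = POOL_HIGH_HZ
    return pool


@dataclass
class StreamSpec:
    """One tone-pip stream within a scene."""

    carrier_hz: float
    tone_dur_ms: float
    iti_ms: np.ndarray            # length 1 for REG (reused cyclically), per-gap for RND
    phase_offset_ms: float        # scene-relative time of the first tone onset
    onset_times_ms: np.ndarray = field(default=None)  # derived

    def __post_init__(self):
        self.iti_ms = np.atleast_1d(np.asarray(self.iti_ms, dtype=float))
        if self.onset_times_ms is None:
            self.onset_times_ms = self._schedule()
        else:
            self.onset_times_ms = np.asarray(self.onset_times_ms, dtype=float)

    @property
    def is_regular(self) -> bool:
        return self.iti_ms.size == 1 or bool(np.all(self.iti_ms == self.iti_ms[0]))

    def _schedule(self) -> np.ndarray:
        limit = SCENE_DURATION_S * 1000.0
        onsets = []
        t = self.phase_offset_ms
        k = 0
        while t < limit:
            onsets.append(t)
            t += self.tone_dur_ms + self.iti_ms[k % self.iti_ms.size]
            k += 1
        return np.asarray(onsets, dtype=float)

    def iti_after(self, onset_index: int) -> float:
        """Inter-tone interval following the ``onset_index``-th tone."""
        return float(self.iti_ms[onset_index % self.iti_ms.size])


@dataclass
class SceneSpec:
    """Full parameterization of one scene."""

    regularity: str
    change_type: str
    streams: list            # StreamSpec; 7 entries for CA (last = appearing)
    change_stream_index: Optional[int]
    change_time_s: Optional[float]
    gap_start_s: Optional[float] = None
    duration_s: float = SCENE_DURATION_S

    @property
    def is_decoy(self) -> bool:
        return self.gap_start_s is not None

    @property
    def condition(self) -> str:
        return f"{self.regularity}-{self.change_type}"


def _sample_iti(rng: np.random.Generator, size=None):
    return rng.uniform(TONE_MIN_MS, TONE_MAX_MS, size=size)


def sample_stream(regularity: str, carrier_hz: float, rng: np.random.Generator) -> StreamSpec:
    """Draw one stream: tone duration and ITI(s) uniform on [10, 150] ms.

    Phase randomization: the stream starts either with a tone or partway
    through a silent inter-tone interval (Bernoulli 1/2, then uniform jitter
    within that first interval).
    """
    if regularity not in REGULARITIES:
        raise ValueError(f"unknown regularity {regularity!r}")
    tone_dur = float(_sample_iti(rng))
    if regularity == "REG":
        itis = np.array([float(_sample_iti(rng))])
    else:
        # draw generously; the schedule consumes what it needs cyclically —
        # make the draw long enough that no value is ever reused
        n_max = int(SCENE_DURATION_S * 1000.0 / (TONE_MIN_MS * 2)) + 2
        itis = _sample_iti(rng, size=n_max)
    if rng.random() < 0.5:
        phase = 0.0                                   # start with a tone
    else:
        phase = float(rng.uniform(0.0, itis[0]))      # start inside the first ITI
    return StreamSpec(carrier_hz=carrier_hz, tone_dur_ms=tone_dur,
                      iti_ms=itis, phase_offset_ms=phase)


def _truncate_for_cd(stream: StreamSpec, regularity: str) -> tuple[StreamSpec, float]:
    """Schedule a stream deletion near 6 s.

    The change time is the offset of the last pre-change tone plus the
    stream's ITI (REG) or the 80 ms mean ITI (RND) — the expected onset of
    the next (now missing) tone.  The last retained tone is the one whose
    implied change time lands nearest 6 s.
    """
    onsets = stream.onset_times_ms
    if regularity == "REG":
        itis = np.array([stream.iti_after(i) for i in range(onsets.size)])
    else:
        itis = np.full(onsets.size, MEAN_ITI_MS)
    change_ms = onsets + stream.tone_dur_ms + itis
    idx = int(np.argmin(np.abs(change_ms - CHANGE_TIME_S * 1000.0)))
    truncated = replace(stream, onset_times_ms=onsets[: idx + 1])
    return truncated, float(change_ms[idx] / 1000.0)


def build_scene(change_type: str, regularity: str, rng: np.random.Generator,
                pool: Optional[np.ndarray] = None,
                max_resample: int = 100) -> SceneSpec:
    """Construct one scene of the given condition.

    CA: six base streams plus an appearing stream whose first tone onset is
    exactly 6.0 s.  CD: one of the six streams is deleted; its change time is
    the expected onset of the first missing tone, always ~6 s.  NC: no change.
    """
    if change_type not in CHANGE_TYPES:
        raise ValueError(f"unknown change type {change_type!r}")
    if pool is None:
        pool = make_frequency_pool()

    for _ in range(max_resample):
        n_carriers = N_STREAMS + 1 if change_type == "CA" else N_STREAMS
        carriers = rng.choice(pool, size=n_carriers, replace=False)
        streams = [sample_stream(regularity, c, rng) for c in carriers[:N_STREAMS]]

        if change_type == "NC":
            return SceneSpec(regularity, "NC", streams, None, None)

        if change_type == "CA":
            appearing = sample_stream(regularity, carriers[-1], rng)
            appearing = replace(
                appearing,
                phase_offset_ms=CHANGE_TIME_S * 1000.0,
                onset_times_ms=None,
            )
            streams.append(appearing)
            return SceneSpec(regularity, "CA", streams, N_STREAMS, CHANGE_TIME_S)

        # CD
        d = int(rng.integers(N_STREAMS))
        truncated, change_s = _truncate_for_cd(streams[d], regularity)
        # the deletion must be schedulable near 6 s (within one maximal period)
        if abs(change_s - CHANGE_TIME_S) <= (TONE_MAX_MS * 2) / 1000.0:
            streams[d] = truncated
            return SceneSpec(regularity, "CD", streams, d, change_s)
    raise RuntimeError("could not schedule a change near 6 s")  # pragma: no cover


def insert_gap(scene: SceneSpec, rng: np.random.Generator) -> SceneSpec:
    """Return a copy of ``scene`` with a 200 ms global silent gap.

    Gap start is uniform between 1 s post onset and 1 s pre offset.
    """
    if scene.gap_start_s is not None:
        raise ValueError("scene already contains a gap")
    lo = GAP_MARGIN_S
    hi = scene.duration_s - GAP_MARGIN_S - GAP_DURATION_S
    start = float(rng.uniform(lo, hi))
    return replace(scene, gap_start_s=start)


@dataclass
class TrialSpec:
    block: int
    trial: int
    scene: SceneSpec

    @property
    def condition(self) -> str:
        return self.scene.condition

    @property
    def is_decoy(self) -> bool:
        return self.scene.is_decoy


@dataclass
class SessionDesign:
    """Ordered trial list for one participant's session."""

    rng_seed: int
    trials: list          # TrialSpec
    n_blocks: int = N_BLOCKS

    def trial_table(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            s = t.scene
            rows.append(dict(block=t.block, trial=t.trial, condition=s.condition,
                             regularity=s.regularity, change_type=s.change_type,
                             change_time_s=s.change_time_s, gap_start_s=s.gap_start_s,
                             is_decoy=s.is_decoy))
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        def scene_dict(s: SceneSpec):
            return dict(
                regularity=s.regularity, change_type=s.change_type,
                change_stream_index=s.change_stream_index,
                change_time_s=s.change_time_s, gap_start_s=s.gap_start_s,
                duration_s=s.duration_s,
                streams=[dict(carrier_hz=st.carrier_hz, tone_dur_ms=st.tone_dur_ms,
                              iti_ms=st.iti_ms.tolist(),
                              phase_offset_ms=st.phase_offset_ms,
                              onset_times_ms=st.onset_times_ms.tolist())
                         for st in s.streams],
            )
        return json.dumps(dict(
            rng_seed=self.rng_seed, n_blocks=self.n_blocks,
            trials=[dict(block=t.block, trial=t.trial, scene=scene_dict(t.scene))
                    for t in self.trials]))

    @classmethod
    def from_json(cls, text: str) -> "SessionDesign":
        obj = json.loads(text)
        trials = []
        for t in obj["trials"]:
            sd = t["scene"]
            streams = [StreamSpec(carrier_hz=s["carrier_hz"], tone_dur_ms=s["tone_dur_ms"],
                                  iti_ms=np.asarray(s["iti_ms"]),
                                  phase_offset_ms=s["phase_offset_ms"],
                                  onset_times_ms=np.asarray(s["onset_times_ms"]))
                       for s in sd["streams"]]
            scene = SceneSpec(sd["regularity"], sd["change_type"], streams,
                              sd["change_stream_index"], sd["change_time_s"],
                              sd["gap_start_s"], sd["duration_s"])
            trials.append(TrialSpec(t["block"], t["trial"], scene))
        return cls(rng_seed=obj["rng_seed"], trials=trials, n_blocks=obj["n_blocks"])


def build_session(rng_seed: int, n_blocks: int = N_BLOCKS,
                  trials_per_condition: int = TRIALS_PER_CONDITION_PER_BLOCK,
                  decoys_per_condition: int = 1) -> SessionDesign:
    """Assemble a full session.

    Each block holds ``trials_per_condition`` main trials of each of the six
    REG/RND × CA/CD/NC conditions plus one gap-containing decoy per
    condition (30 trials per block at the defaults), in random order.
    """
    rng = np.random.default_rng(rng_seed)
    pool = make_frequency_pool()
    trials = []
    for block in range(1, n_blocks + 1):
        scenes = []
        for regularity in REGULARITIES:
            for change_type in CHANGE_TYPES:
                for _ in range(trials_per_condition):
                    scenes.append(build_scene(change_type, regularity, rng, pool))
                for _ in range(decoys_per_condition):
                    scenes.append(insert_gap(
                        build_scene(change_type, regularity, rng, pool), rng))
        order = rng.permutation(len(scenes))
        for i, j in enumerate(order):
            trials.append(TrialSpec(block=block, trial=i + 1, scene=scenes[j]))
    return SessionDesign(rng_seed=rng_seed, trials=trials, n_blocks=n_blocks)


def render_scene(scene: SceneSpec, sample_rate_hz: int = 44100) -> np.ndarray:
    """Additively synthesize a scene: pure-tone pips with 3 ms raised-cosine
    ramps, diotic (mono), with the decoy gap (if any) silencing all streams.
    """
    for st in scene.streams:
        if st.carrier_hz >= sample_rate_hz / 2.0:
            raise ValueError(
                f"carrier {st.carrier_hz} Hz at or above Nyquist for fs={sample_rate_hz}")
    n = int(round(scene.duration_s * sample_rate_hz))
    out = np.zeros(n)
    for st in scene.streams:
        out += render_stream(st, sample_rate_hz, n)
    if scene.gap_start_s is not None:
        i0 = int(round(scene.gap_start_s * sample_rate_hz))
        i1 = int(round((scene.gap_start_s + GAP_DURATION_S) * sample_rate_hz))
        out[i0:i1] = 0.0
    return out


def render_stream(stream: StreamSpec, sample_rate_hz: int, n_samples: int) -> np.ndarray:
    out = np.zeros(n_samples)
    n_tone = int(round(stream.tone_dur_ms / 1000.0 * sample_rate_hz))
    if n_tone < 1:
        return out
    t = np.arange(n_tone) / sample_rate_hz
    env = np.ones(n_tone)
    n_ramp = int(round(RAMP_MS / 1000.0 * sample_rate_hz))
    n_ramp = min(n_ramp, n_tone // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    for onset_ms in stream.onset_times_ms:
        i0 = int(round(onset_ms / 1000.0 * sample_rate_hz))
        seg = min(n_tone, n_samples - i0)
        if seg <= 0:
            continue
        phase = 2.0 * np.pi * stream.carrier_hz * t[:seg]
        out[i0:i0 + seg] += env[:seg] * np.sin(phase)
    return out
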