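"""Synthetic binocular eye-tracking sessions with known ground truth.

The study's deposited recordings are not required: this module emulates
1,000 Hz binocular traces whose generative parameters encode the effects the
analysis pipeline is meant to recover — tonic pupil decline that is steeper
in REG than RND scenes, change-evoked phasic dilations (earlier/larger for
CA than CD), Poisson-like microsaccades whose rate transiently dips after a
scene change (microsaccadic inhibition), fixational drift, and blinks with
partial-closure edge artifacts.

The waveform shapes used here (gamma-family pupil kernels, raised-cosine
microsaccade steps, Ornstein–Uhlenbeck drift) are generator-private
stand-ins: the analysis side never assumes them, and every simulated session
is emitted together with its :class:`GroundTruth` so that downstream stages
have parameter-recovery tests rather than plot comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
import json

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .scenes import SessionDesign, TrialSpec, SCENE_DURATION_S
from .trace import SampleTrace
from . import pdr


@dataclass
class SynthParams:
    """Generator configuration.  Defaults define the emulated study conditions."""

    fs_hz: int = 1000
    pad_pre_s: float = 1.5        # pre-onset recording per trial segment
    pad_post_s: float = 2.0       # post-offset recording per trial segment

    # tonic + sequence-evoked pupil dynamics (arbitrary tracker units)
    pupil_base: float = 1200.0
    onset_amp1: float = 30.0      # first onset bump, peaking at 0.8 s
    onset_peak1_s: float = 0.8
    onset_amp2: float = 20.0      # broader bump, peaking ~3 s
    onset_peak2_s: float = 3.0
    tonic_onset_s: float = 3.0    # sustained decline begins here
    tonic_slope_reg: float = -12.0   # units/s; steeper (more negative) for REG
    tonic_slope_rnd: float = -6.0
    slope_jitter_sd: float = 1.5  # between-participant slope variability
    offset_tau_s: float = 2.0     # relaxation back to baseline after offset

    # change-evoked phasic dilation
    phasic_amp_ca: float = 25.0
    phasic_delay_ca_s: float = 0.45
    phasic_amp_cd: float = 12.0
    phasic_delay_cd_s: float = 1.0
    phasic_scale_s: float = 0.3   # gamma time scale (peak 0.3 s after response onset)

    # nuisance pupil structure
    osc_amp: float = 3.0
    osc_freq_hz: float = 0.2
    hippus_sd: float = 6.0        # band-limited pupillary unrest (a.u.)
    hippus_tau_ms: float = 150.0  # Gaussian correlation scale of the unrest
    pupil_noise_sd: float = 4.0
    eye_offset: float = -5.0      # right-eye constant offset

    # gaze / fixational drift (pixels, screen coordinates)
    center_x_px: float = 960.0
    center_y_px: float = 540.0
    drift_theta_hz: float = 2.0   # OU mean-reversion rate
    drift_sigma_px: float = 6.0   # OU diffusion (px / sqrt(s))
    vergence_noise_px: float = 0.3
    gaze_noise_px: float = 0.2    # white measurement noise

    # microsaccades
    ms_base_rate_hz: float = 1.5
    msi_depth: float = 0.8        # fractional rate suppression after a change
    msi_latency_ms: float = 200.0
    msi_halfwidth_ms: float = 100.0
    onset_msi_depth: float = 0.5  # inhibition after scene onset (all conditions)
    ms_amp_min_px: float = 6.0
    ms_amp_max_px: float = 30.0
    ms_dur_min_ms: float = 8.0
    ms_dur_max_ms: float = 25.0
    ms_disparity_max_ms: float = 4.0
    ms_min_isi_ms: float = 50.0

    # blinks
    blink_rate_hz: float = 0.10
    blink_dur_min_ms: float = 100.0
    blink_dur_max_ms: float = 300.0
    blink_edge_min_ms: float = 20.0
    blink_edge_max_ms: float = 50.0

    # decoy-task behavior
    hit_prob: float = 0.95
    rt_median_s: float = 0.45
    rt_log_sd: float = 0.3
    fa_prob_per_trial: float = 0.01

    @property
    def segment_s(self) -> float:
        return self.pad_pre_s + SCENE_DURATION_S + self.pad_post_s

    @property
    def segment_samples(self) -> int:
        return int(round(self.segment_s * self.fs_hz))


@dataclass
class ParticipantTraits:
    """Per-participant draws of the generative parameters."""

    slope_reg: float
    slope_rnd: float
    pupil_base: float
    ms_base_rate_hz: float
    msi_depth: float


def draw_traits(params: SynthParams, rng: np.random.Generator) -> ParticipantTraits:
    return ParticipantTraits(
        slope_reg=params.tonic_slope_reg + rng.normal(0, params.slope_jitter_sd),
        slope_rnd=params.tonic_slope_rnd + rng.normal(0, params.slope_jitter_sd),
        pupil_base=params.pupil_base + rng.normal(0, 50.0),
        ms_base_rate_hz=params.ms_base_rate_hz * float(np.exp(rng.normal(0, 0.1))),
        msi_depth=float(np.clip(params.msi_depth + rng.normal(0, 0.05), 0.0, 1.0)),
    )


@dataclass
class GroundTruth:
    """True injected events and parameters for one simulated block.

    All times are in seconds on the block clock; the ``trials`` table maps
    them back to trial segments.
    """

    trials: pd.DataFrame       # trial, condition, change_time_s, onset_s, osc_phase, ...
    ms_events: pd.DataFrame    # trial, onset_s, duration_ms, amplitude_px, disparity_ms
    dilation_events: pd.DataFrame  # trial, time_s
    blinks: pd.DataFrame       # trial, start_s, end_s
    traits: ParticipantTraits
    params: SynthParams

    def to_json(self) -> str:
        return json.dumps(dict(
            trials=self.trials.to_dict(orient="list"),
            ms_events=self.ms_events.to_dict(orient="list"),
            dilation_events=self.dilation_events.to_dict(orient="list"),
            blinks=self.blinks.to_dict(orient="list"),
            traits=asdict(self.traits),
            params=asdict(self.params),
        ))

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(trials=pd.DataFrame(obj["trials"]),
                   ms_events=pd.DataFrame(obj["ms_events"]),
                   dilation_events=pd.DataFrame(obj["dilation_events"]),
                   blinks=pd.DataFrame(obj["blinks"]),
                   traits=ParticipantTraits(**obj["traits"]),
                   params=SynthParams(**obj["params"]))


@dataclass
class BlockData:
    """One simulated block: the raw trace plus its ground truth."""

    block: int
    trace: SampleTrace
    trial_onsets_ms: np.ndarray   # scene-onset time of each trial on the block clock
    truth: GroundTruth

    @property
    def trial_table(self) -> pd.DataFrame:
        return self.truth.trials


def _gamma_bump(t_s: np.ndarray, peak_s: float, shape: int = 2) -> np.ndarray:
    """Gamma-family bump, zero for t<=0, unit peak at ``peak_s``."""
    k = shape - 1
    theta = peak_s / k
    u = np.clip(t_s, 0.0, None) / theta
    return (u / k) ** k * np.exp(k - u)


def pupil_template(t_s: np.ndarray, regularity: str, change_type: str,
                   change_time_s, traits: ParticipantTraits,
                   params: SynthParams) -> np.ndarray:
    """Deterministic (noise- and oscillation-free) pupil time course.

    ``t_s`` is scene-relative time; the template is flat at baseline before
    onset and relaxes back to baseline after scene offset.
    """
    t = np.asarray(t_s, dtype=float)
    out = np.full(t.shape, traits.pupil_base)
    evoked = (params.onset_amp1 * _gamma_bump(t, params.onset_peak1_s, shape=2)
              + params.onset_amp2 * _gamma_bump(t, params.onset_peak2_s, shape=3))
    slope = traits.slope_reg if regularity == "REG" else traits.slope_rnd
    tonic = slope * np.clip(t - params.tonic_onset_s, 0.0, SCENE_DURATION_S - params.tonic_onset_s)
    if change_type in ("CA", "CD") and change_time_s is not None:
        amp = params.phasic_amp_ca if change_type == "CA" else params.phasic_amp_cd
        delay = params.phasic_delay_ca_s if change_type == "CA" else params.phasic_delay_cd_s
        u = t - change_time_s - delay
        phasic = np.where(u > 0,
                          amp * _gamma_bump(u, params.phasic_scale_s, shape=2), 0.0)
    else:
        phasic = 0.0
    out = out + evoked + tonic + phasic
    # post-offset relaxation toward baseline
    after = t > SCENE_DURATION_S
    if np.any(after):
        end_val = (out[~after][-1] if np.any(~after) else traits.pupil_base)
        decay = np.exp(-(t[after] - SCENE_DURATION_S) / params.offset_tau_s)
        out[after] = traits.pupil_base + (end_val - traits.pupil_base) * decay
    return out


def simulate_pupil(trial: TrialSpec, traits: ParticipantTraits, params: SynthParams,
                   rng: np.random.Generator, osc_phase: float = None):
    """Simulate left/right pupil series for one trial segment.

    Returns ``(pl, pr, clean, osc_phase)`` where ``clean`` is the noise-free
    trace (template + slow oscillation) used for ground-truth dilation events.
    """
    fs = params.fs_hz
    n = params.segment_samples
    t = np.arange(n) / fs - params.pad_pre_s
    scene = trial.scene
    base = pupil_template(t, scene.regularity, scene.change_type,
                          scene.change_time_s, traits, params)
    if osc_phase is None:
        osc_phase = float(rng.uniform(0, 2 * np.pi))
    osc = params.osc_amp * np.sin(2 * np.pi * params.osc_freq_hz * t + osc_phase)
    clean = base + osc + _hippus(n, params, rng)
    pl = clean + rng.normal(0, params.pupil_noise_sd, n)
    pr = clean + params.eye_offset + rng.normal(0, params.pupil_noise_sd, n)
    return pl, pr, clean, osc_phase


def _hippus(n: int, params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Slow pupillary unrest: Gaussian-filtered white noise at the target SD.

    This gives the clean trace dilation-onset events at a realistic ~1/s
    rate (the deterministic template alone would be implausibly smooth).
    """
    if params.hippus_sd <= 0:
        return np.zeros(n)
    from scipy.ndimage import gaussian_filter1d
    sigma = params.hippus_tau_ms / 1000.0 * params.fs_hz
    gain = np.sqrt(2.0 * sigma * np.sqrt(np.pi))   # filter attenuates SD by 1/gain
    return gaussian_filter1d(rng.normal(0, params.hippus_sd * gain, n), sigma,
                             mode="reflect")


def _raised_cosine_step(n: int) -> np.ndarray:
    """Increments of a unit raised-cosine position step over n samples."""
    s = 0.5 * (1.0 - np.cos(np.pi * np.arange(n + 1) / n))
    return np.diff(s)


def _ms_rate_profile(t_s: np.ndarray, scene, traits: ParticipantTraits,
                     params: SynthParams) -> np.ndarray:
    """Inhomogeneous microsaccade rate r(t) for one trial segment."""
    rate = np.full(t_s.shape, traits.ms_base_rate_hz)

    def bump(center_s, depth):
        hw = params.msi_halfwidth_ms / 1000.0
        u = (t_s - center_s) / hw
        g = np.where(np.abs(u) < 1.0, 0.5 * (1.0 + np.cos(np.pi * u)), 0.0)
        return 1.0 - depth * g

    rate = rate * bump(params.msi_latency_ms / 1000.0, params.onset_msi_depth)
    if scene.change_type in ("CA", "CD") and scene.change_time_s is not None:
        rate = rate * bump(scene.change_time_s + params.msi_latency_ms / 1000.0,
                           traits.msi_depth)
    return rate


def simulate_gaze(trial: TrialSpec, traits: ParticipantTraits, params: SynthParams,
                  rng: np.random.Generator):
    """Simulate binocular gaze for one trial segment.

    Returns ``(xl, yl, xr, yr, events)`` with ``events`` a DataFrame of true
    microsaccades (onset_s segment-relative to scene onset, duration_ms,
    amplitude_px, disparity_ms).
    """
    fs = params.fs_hz
    n = params.segment_samples
    dt = 1.0 / fs
    t = np.arange(n) / fs - params.pad_pre_s

    # --- draw microsaccade times from the inhomogeneous Poisson profile
    rate = _ms_rate_profile(t, trial.scene, traits, params)
    rmax = traits.ms_base_rate_hz
    n_cand = rng.poisson(rmax * params.segment_s)
    cand = np.sort(rng.uniform(0, params.segment_s, n_cand))
    accept = rng.uniform(0, rmax, n_cand) < rate[np.minimum((cand * fs).astype(int), n - 1)]
    times = cand[accept]
    kept = []
    last = -np.inf
    for ti in times:
        if ti - last > params.ms_min_isi_ms / 1000.0:
            kept.append(ti)
            last = ti
    times = np.asarray(kept)

    # --- event kinematics
    events = []
    incr = {("l", "x"): np.zeros(n), ("l", "y"): np.zeros(n),
            ("r", "x"): np.zeros(n), ("r", "y"): np.zeros(n)}
    for ti in times:
        amp = rng.uniform(params.ms_amp_min_px, params.ms_amp_max_px)
        frac = (amp - params.ms_amp_min_px) / (params.ms_amp_max_px - params.ms_amp_min_px)
        dur_ms = params.ms_dur_min_ms + frac * (params.ms_dur_max_ms - params.ms_dur_min_ms)
        dur_ms *= float(np.exp(rng.normal(0, 0.08)))
        dur_ms = float(np.clip(dur_ms, params.ms_dur_min_ms, params.ms_dur_max_ms))
        ndur = max(2, int(round(dur_ms / 1000.0 * fs)))
        phi = rng.uniform(0, 2 * np.pi)
        disparity_ms = rng.uniform(0, params.ms_disparity_max_ms)
        lead_left = rng.random() < 0.5
        i0 = int(round(ti * fs))     # ti is segment-relative
        ioff = int(round(disparity_ms / 1000.0 * fs))
        step = _raised_cosine_step(ndur)
        for eye, start in (("l", i0 if lead_left else i0 + ioff),
                           ("r", i0 + ioff if lead_left else i0)):
            if start + ndur >= n:
                continue
            incr[(eye, "x")][start:start + ndur] += amp * np.cos(phi) * step
            incr[(eye, "y")][start:start + ndur] += amp * np.sin(phi) * step
        if i0 + ndur < n:
            events.append(dict(onset_s=float(ti - params.pad_pre_s), duration_ms=dur_ms,
                               amplitude_px=amp, disparity_ms=disparity_ms))

    # --- Ornstein-Uhlenbeck fixational drift; microsaccade steps feed the
    # same leaky state so gaze remains centered over the block
    theta = params.drift_theta_hz
    a = 1.0 - theta * dt
    noise_x = rng.normal(0, params.drift_sigma_px * np.sqrt(dt), n)
    noise_y = rng.normal(0, params.drift_sigma_px * np.sqrt(dt), n)
    out = {}
    for eye in ("l", "r"):
        verg_x = rng.normal(0, params.vergence_noise_px * np.sqrt(dt), n)
        verg_y = rng.normal(0, params.vergence_noise_px * np.sqrt(dt), n)
        ex = lfilter([1.0], [1.0, -a], noise_x + verg_x + incr[(eye, "x")])
        ey = lfilter([1.0], [1.0, -a], noise_y + verg_y + incr[(eye, "y")])
        out[(eye, "x")] = params.center_x_px + ex + rng.normal(0, params.gaze_noise_px, n)
        out[(eye, "y")] = params.center_y_px + ey + rng.normal(0, params.gaze_noise_px, n)

    ev = pd.DataFrame(events, columns=["onset_s", "duration_ms", "amplitude_px",
                                       "disparity_ms"])
    return out[("l", "x")], out[("l", "y")], out[("r", "x")], out[("r", "y")], ev


def inject_blinks(pl, pr, xl, yl, xr, yr, vl, vr, params: SynthParams,
                  rng: np.random.Generator):
    """Insert eye closures with partial-closure edge artifacts (in place).

    Closures set validity false and pupil to zero; flanking edges keep the
    sample nominally valid but artifactually reduce the pupil (the reason the
    pipeline pads closures by 250 ms).  Returns a list of (start, end) sample
    index pairs of the full closures.
    """
    n = pl.size
    fs = params.fs_hz
    n_blinks = rng.poisson(params.blink_rate_hz * n / fs)
    intervals = []
    for _ in range(n_blinks):
        dur = int(rng.uniform(params.blink_dur_min_ms, params.blink_dur_max_ms) * fs / 1000)
        e1 = int(rng.uniform(params.blink_edge_min_ms, params.blink_edge_max_ms) * fs / 1000)
        e2 = int(rng.uniform(params.blink_edge_min_ms, params.blink_edge_max_ms) * fs / 1000)
        start = int(rng.integers(e1, max(e1 + 1, n - dur - e2)))
        end = min(start + dur, n)
        if start >= end:
            continue
        for p in (pl, pr):
            ramp_in = np.linspace(1.0, 0.4, e1)
            ramp_out = np.linspace(0.4, 1.0, e2)
            p[start - e1:start] *= ramp_in[: start - max(start - e1, 0)]
            p[end:end + e2] *= ramp_out[: max(min(end + e2, n) - end, 0)]
            p[start:end] = 0.0
        for g in (xl, yl, xr, yr):
            g[start:end] = g[start - 1] if start > 0 else g[end] if end < n else 0.0
        vl[start:end] = False
        vr[start:end] = False
        intervals.append((start, end))
    intervals.sort()
    return intervals


def simulate_block(block: int, trials: list, traits: ParticipantTraits,
                   params: SynthParams, rng: np.random.Generator) -> BlockData:
    """Simulate one block: per-trial segments concatenated on a block clock."""
    fs = params.fs_hz
    nseg = params.segment_samples
    n = nseg * len(trials)
    arrays = {k: np.empty(n) for k in ("xl", "yl", "pl", "xr", "yr", "pr")}
    vl = np.ones(n, dtype=bool)
    vr = np.ones(n, dtype=bool)

    trial_rows, ms_rows, dil_rows, blink_rows = [], [], [], []
    onsets_ms = []
    for i, trial in enumerate(trials):
        s0 = i * nseg
        seg_onset_s = s0 / fs + params.pad_pre_s        # scene onset, block clock
        onsets_ms.append(seg_onset_s * 1000.0)
        pl, pr, clean, osc_phase = simulate_pupil(trial, traits, params, rng)
        xl, yl, xr, yr, ev = simulate_gaze(trial, traits, params, rng)
        iv = inject_blinks(pl, pr, xl, yl, xr, yr,
                           vl[s0:s0 + nseg], vr[s0:s0 + nseg], params, rng)
        arrays["pl"][s0:s0 + nseg] = pl
        arrays["pr"][s0:s0 + nseg] = pr
        arrays["xl"][s0:s0 + nseg] = xl
        arrays["yl"][s0:s0 + nseg] = yl
        arrays["xr"][s0:s0 + nseg] = xr
        arrays["yr"][s0:s0 + nseg] = yr

        scene = trial.scene
        trial_rows.append(dict(
            trial=trial.trial, block=block, condition=scene.condition,
            regularity=scene.regularity, change_type=scene.change_type,
            change_time_s=scene.change_time_s, gap_start_s=scene.gap_start_s,
            is_decoy=scene.is_decoy, onset_s=seg_onset_s, osc_phase=osc_phase))
        for _, r in ev.iterrows():
            ms_rows.append(dict(trial=trial.trial, onset_s=r.onset_s + seg_onset_s,
                                duration_ms=r.duration_ms, amplitude_px=r.amplitude_px,
                                disparity_ms=r.disparity_ms))
        # ground-truth dilation events live on the smoothed clean trace: the
        # event definition itself (local minimum + 100 ms rise) presupposes
        # the 150 ms smoothing stage
        from .pupil import smooth as _smooth
        dil_idx = pdr.detect_dilation_events(_smooth(clean, fs_hz=fs), fs_hz=fs)
        for di in dil_idx:
            dil_rows.append(dict(trial=trial.trial,
                                 time_s=seg_onset_s - params.pad_pre_s + di / fs))
        for a, b in iv:
            blink_rows.append(dict(trial=trial.trial, start_s=(s0 + a) / fs,
                                   end_s=(s0 + b) / fs))

    trace = SampleTrace(time_ms=np.arange(n), vl=vl, vr=vr, **arrays)
    truth = GroundTruth(
        trials=pd.DataFrame(trial_rows),
        ms_events=pd.DataFrame(ms_rows, columns=["trial", "onset_s", "duration_ms",
                                                 "amplitude_px", "disparity_ms"]),
        dilation_events=pd.DataFrame(dil_rows, columns=["trial", "time_s"]),
        blinks=pd.DataFrame(blink_rows, columns=["trial", "start_s", "end_s"]),
        traits=traits, params=params)
    return BlockData(block=block, trace=trace,
                     trial_onsets_ms=np.asarray(onsets_ms), truth=truth)


def simulate_responses(design: SessionDesign, params: SynthParams,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Key presses for the decoy gap-detection task (block, trial, press_time_s)."""
    rows = []
    for t in design.trials:
        if t.scene.is_decoy and rng.random() < params.hit_prob:
            rt = float(np.exp(np.log(params.rt_median_s)
                              + rng.normal(0, params.rt_log_sd)))
            rows.append(dict(block=t.block, trial=t.trial,
                             press_time_s=t.scene.gap_start_s + min(rt, 1.99)))
        elif not t.scene.is_decoy and rng.random() < params.fa_prob_per_trial:
            rows.append(dict(block=t.block, trial=t.trial,
                             press_time_s=float(rng.uniform(0, SCENE_DURATION_S + 0.5))))
    return pd.DataFrame(rows, columns=["block", "trial", "press_time_s"])


def simulate_participant(design: SessionDesign, params: SynthParams,
                         rng: np.random.Generator):
    """Simulate all blocks of one participant.

    Returns ``(blocks, traits, responses)`` where ``blocks`` is a list of
    :class:`BlockData` in block order.
    """
    traits = draw_traits(params, rng)
    by_block = {}
    for t in design.trials:
        by_block.setdefault(t.block, []).append(t)
    blocks = [simulate_block(b, sorted(ts, key=lambda t: t.trial), traits, params, rng)
              for b, ts in sorted(by_block.items())]
    responses = simulate_responses(design, params, rng)
    return blocks, traits, responses
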