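"""End-to-end orchestration: simulate -> preprocess -> detect -> analyze.

Per participant, the pipeline preprocesses each block's pupil trace (one
analyzed eye, left preferred), detects dilation events on the continuous
smoothed trace and microsaccades on the raw binocular gaze, epochs
everything around scene onsets (sequence-evoked) and change times
(change-locked, with 6 s as the nominal lock for no-change trials), and
averages per condition.  Group-level statistics stack the per-participant
series and run the bootstrap machinery from :mod:`.stats`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import microsaccades as ms
from . import pdr, pupil, stats, synth
from .config import RunConfig
from .scenes import build_session, CHANGE_TIME_S, REGULARITIES
from .trace import SampleTrace

SEQUENCE_CONDITIONS = ("REG-NC", "RND-NC")
CHANGE_CONDITIONS = ("REG-CA", "REG-CD", "REG-NC", "RND-CA", "RND-CD", "RND-NC")


def choose_eye(trace: SampleTrace, preference: str = "left") -> str:
    """Prefer the configured eye; fall back when it is mostly untracked."""
    order = ("left", "right") if preference == "left" else ("right", "left")
    for which in order:
        valid = trace.eye(which)[3]
        if valid.mean() > 0.5:
            return which
    return order[0]


@dataclass
class BlockPrep:
    """Preprocessed signals for one block."""

    eye: str
    pupil_smooth: np.ndarray      # masked -> interpolated -> smoothed
    pupil_missing: np.ndarray     # pre-interpolation missing mask (analyzed eye)
    ms_events: list               # binocular MsEvent list (block clock, samples)
    ms_missing: np.ndarray        # either-eye closure mask used for MS epoch rejection
    dilation_idx: np.ndarray      # dilation onsets (samples) on the continuous trace
    trial_table: pd.DataFrame


def preprocess_block(block: synth.BlockData, cfg: RunConfig) -> BlockPrep:
    p = cfg.pipeline
    center = (cfg.synth.center_x_px, cfg.synth.center_y_px)
    trace = block.trace
    eye = choose_eye(trace, p.eye_preference)
    gx, gy, pup, valid = trace.eye(eye)
    missing = pupil.mask_missing(gx, gy, valid, center,
                                 radius_px=p.fixation_radius_px,
                                 pad_ms=p.closure_pad_ms, fs_hz=trace.fs_hz)
    filled = pupil.interpolate_missing(pup, missing)
    smoothed = pupil.smooth(filled, window_ms=p.smooth_window_ms, fs_hz=trace.fs_hz)
    dil = pdr.detect_dilation_events(smoothed, fs_hz=trace.fs_hz,
                                     min_dilation_ms=p.min_dilation_ms)
    events = ms.detect_block(trace.xl, trace.yl, trace.xr, trace.yr,
                             missing_left=~trace.vl, missing_right=~trace.vr,
                             fs_hz=trace.fs_hz, lam=p.lam)
    return BlockPrep(eye=eye, pupil_smooth=smoothed, pupil_missing=missing,
                     ms_events=events, ms_missing=~(trace.vl & trace.vr),
                     dilation_idx=dil, trial_table=block.trial_table)


def _lock_times_ms(table: pd.DataFrame, lock: str) -> np.ndarray:
    """Lock-event times (block clock, ms) for each trial row."""
    onset_ms = table.onset_s.to_numpy() * 1000.0
    if lock == "onset":
        return onset_ms
    change = table.change_time_s.to_numpy(dtype=float)
    change = np.where(np.isnan(change), CHANGE_TIME_S, change)
    return onset_ms + change * 1000.0


def _analyzable(table: pd.DataFrame, scored: pd.DataFrame) -> pd.Series:
    """Trials usable for ocular analysis: non-decoy, no press of any kind."""
    pressed = scored.set_index(["block", "trial"]).any_press
    keys = list(zip(table.block, table.trial))
    has_press = np.array([bool(pressed.get(k, False)) for k in keys])
    return (~table.is_decoy.astype(bool)) & ~has_press


def participant_pupil(preps: list, scored: pd.DataFrame, cfg: RunConfig,
                      lock: str = "onset", conditions=SEQUENCE_CONDITIONS,
                      normalize: bool = True):
    """Per-condition z-normalized pupil averages for one participant.

    Returns ``{condition: (mean, sem, time_s, n_epochs, n_rejected)}``.
    ``normalize=False`` skips the per-block z-scoring and averages raw
    tracker units — only meaningful when units are comparable across
    participants (synthetic ground-truth recovery).
    """
    p = cfg.pipeline
    window = pupil.SEQUENCE_WINDOW_S if lock == "onset" else pupil.CHANGE_WINDOW_S
    baseline = pupil.SEQUENCE_BASELINE_S if lock == "onset" else pupil.CHANGE_BASELINE_S
    out = {}
    for cond in conditions:
        datas, misses, blocks = [], [], []
        time_s = None
        for prep in preps:
            table = prep.trial_table
            ok = _analyzable(table, scored) & (table.condition == cond)
            if not ok.any():
                continue
            locks = _lock_times_ms(table[ok], lock)
            d, m, t, _ = pupil.extract_epochs(prep.pupil_smooth, prep.pupil_missing,
                                              locks, window)
            if d.shape[0] == 0:
                continue
            datas.append(d)
            misses.append(m)
            blocks.append(np.full(d.shape[0], table[ok].block.iloc[0]))
            time_s = t
        if not datas:
            continue
        eps = pupil.epoch_and_reject(
            np.vstack(datas), np.vstack(misses), time_s, condition=cond,
            baseline_window_s=baseline, blocks=np.concatenate(blocks),
            missing_max=p.missing_max_fraction,
            outlier_fraction=p.outlier_fraction, outlier_sd=p.outlier_sd)
        if eps.data.shape[0] == 0:
            continue
        if normalize:
            eps = pupil.znormalize(eps)
            if eps.data.shape[0] == 0:
                continue
        mean, sem = pupil.average_condition(eps)
        out[cond] = dict(mean=mean, sem=sem, time_s=eps.time_s,
                         n_epochs=eps.data.shape[0], n_rejected=eps.n_rejected,
                         epochs=eps)
    return out


def _epoch_event_rate(event_times_s: np.ndarray, preps_tables, lock, window,
                      baseline, kernel, missing, cond):
    raise NotImplementedError  # pragma: no cover


def participant_rate(preps: list, scored: pd.DataFrame, cfg: RunConfig,
                     kind: str = "ms", lock: str = "change",
                     conditions=CHANGE_CONDITIONS):
    """Per-condition microsaccade or pupil-dilation rate for one participant.

    Returns ``{condition: RateSeries}``.  Epochs with more than 50% missing
    data (closure-based for MS, mask-based for PDR) are discarded.
    """
    p = cfg.pipeline
    fs = 1000
    kernel = pdr.causal_kernel(fs, alpha_ms=p.alpha_ms)
    if kind == "ms":
        window = ms.SEQUENCE_WINDOW_S if lock == "onset" else ms.CHANGE_WINDOW_S
        baseline = ms.SEQUENCE_BASELINE_S if lock == "onset" else ms.CHANGE_BASELINE_S
    else:
        window = pupil.SEQUENCE_WINDOW_S if lock == "onset" else pupil.CHANGE_WINDOW_S
        baseline = ((-1.0, 0.0) if lock == "onset" else p.pdr_baseline_s)
    out = {}
    for cond in conditions:
        trains, t0 = [], window[0]
        for prep in preps:
            fs = 1000
            if kind == "ms":
                ev = np.array([e.onset / fs for e in prep.ms_events])
                miss = prep.ms_missing
            else:
                ev = prep.dilation_idx / fs
                miss = prep.pupil_missing
            table = prep.trial_table
            ok = _analyzable(table, scored) & (table.condition == cond)
            if not ok.any():
                continue
            locks = _lock_times_ms(table[ok], lock) / 1000.0
            n = miss.size
            for lk in locks:
                a = int(round((lk + window[0]) * fs))
                b = int(round((lk + window[1]) * fs))
                if a < 0 or b > n:
                    continue
                if miss[a:b].mean() > 0.5:
                    continue
                rel = ev[(ev >= lk + window[0]) & (ev < lk + window[1])] - lk
                trains.append(np.sort(rel))
        if not trains:
            continue
        train = pdr.EventTrain(trials=trains, t_start_s=window[0],
                               duration_s=window[1] - window[0], fs_hz=fs)
        out[cond] = pdr.event_rate(train, kernel, baseline_window_s=baseline,
                                   condition=cond)
    return out


def participant_trial_matrix(preps: list, scored: pd.DataFrame, cfg: RunConfig,
                             kind: str, cond: str, lock: str = "change") -> np.ndarray:
    """Trial-level matrix (trials x time) for one participant and condition.

    For ``kind='pd'``: z-scored pupil epochs.  For ``kind='ms'``/``'pdr'``:
    per-trial kernel-smoothed, baseline-corrected rate rows (the rate
    estimator is linear in trials, so surrogate-half means of these rows
    equal the half's rate series).  Used by the noise-floor control.
    """
    from scipy.signal import fftconvolve
    p = cfg.pipeline
    fs = 1000
    if kind == "pd":
        per = participant_pupil(preps, scored, cfg, lock=lock, conditions=(cond,))
        if cond not in per:
            return np.empty((0, 0))
        return per[cond]["epochs"].data
    kernel = pdr.causal_kernel(fs, alpha_ms=p.alpha_ms)
    if kind == "ms":
        window = ms.SEQUENCE_WINDOW_S if lock == "onset" else ms.CHANGE_WINDOW_S
        baseline = ms.SEQUENCE_BASELINE_S if lock == "onset" else ms.CHANGE_BASELINE_S
    else:
        window = pupil.SEQUENCE_WINDOW_S if lock == "onset" else pupil.CHANGE_WINDOW_S
        baseline = (-1.0, 0.0) if lock == "onset" else p.pdr_baseline_s
    n_t = int(round((window[1] - window[0]) * fs))
    rows = []
    for prep in preps:
        if kind == "ms":
            ev = np.array([e.onset / fs for e in prep.ms_events])
            miss = prep.ms_missing
        else:
            ev = prep.dilation_idx / fs
            miss = prep.pupil_missing
        table = prep.trial_table
        ok = _analyzable(table, scored) & (table.condition == cond)
        if not ok.any():
            continue
        locks = _lock_times_ms(table[ok], lock) / 1000.0
        for lk in locks:
            a = int(round((lk + window[0]) * fs))
            b = a + n_t
            if a < 0 or b > miss.size or miss[a:b].mean() > 0.5:
                continue
            counts = np.zeros(n_t)
            idx = np.round((ev[(ev >= lk + window[0]) & (ev < lk + window[1])]
                            - lk - window[0]) * fs).astype(int)
            np.add.at(counts, np.clip(idx, 0, n_t - 1), 1.0)
            rows.append(counts)
    if not rows:
        return np.empty((0, 0))
    pulse = np.asarray(rows) * fs
    rate = fftconvolve(pulse, kernel.weights[None, :], axes=1)[:, :n_t]
    time_s = window[0] + np.arange(n_t) / fs - kernel.peak_lag_s
    sel = (time_s >= baseline[0]) & (time_s < baseline[1])
    return rate - rate[:, sel].mean(axis=1, keepdims=True)


def stack_condition(per_participant: list, cond: str, key: str = "mean"):
    """Stack one condition's series across participants -> (N, T) + time."""
    rows, time_s = [], None
    for d in per_participant:
        if cond not in d:
            continue
        entry = d[cond]
        if isinstance(entry, pdr.RateSeries):
            rows.append(entry.rate_hz)
            time_s = entry.time_s
        else:
            rows.append(entry[key])
            time_s = entry["time_s"]
    if not rows:
        raise ValueError(f"no participant has condition {cond}")
    return np.vstack(rows), time_s


def collect_event_trains(preps: list, scored: pd.DataFrame,
                         change_types=("CA", "CD"), lock: str = "change",
                         window_s: tuple = ms.CHANGE_WINDOW_S,
                         kind: str = "ms") -> list:
    """Epoch detected event onsets (lock-relative seconds) for one participant.

    Returns one sorted array per analyzable trial of the requested change
    types; used by the parameter-recovery estimators.
    """
    fs = 1000
    trains = []
    for prep in preps:
        if kind == "ms":
            ev = np.array([e.onset / fs for e in prep.ms_events])
        else:
            ev = prep.dilation_idx / fs
        table = prep.trial_table
        ok = _analyzable(table, scored) & table.change_type.isin(change_types)
        if not ok.any():
            continue
        locks = _lock_times_ms(table[ok], lock) / 1000.0
        for lk in locks:
            rel = ev[(ev >= lk + window_s[0]) & (ev < lk + window_s[1])] - lk
            trains.append(np.sort(rel))
    return trains


def stack_pair(per_participant: list, cond_a: str, cond_b: str):
    """Stack two conditions across the participants who have both."""
    rows_a, rows_b, time_s = [], [], None
    for d in per_participant:
        if cond_a not in d or cond_b not in d:
            continue
        for cond, rows in ((cond_a, rows_a), (cond_b, rows_b)):
            entry = d[cond]
            if isinstance(entry, pdr.RateSeries):
                rows.append(entry.rate_hz)
                time_s = entry.time_s
            else:
                rows.append(entry["mean"])
                time_s = entry["time_s"]
    if len(rows_a) < 2:
        raise ValueError(f"fewer than 2 participants have both {cond_a} and {cond_b}")
    return np.vstack(rows_a), np.vstack(rows_b), time_s


def decimate(data: np.ndarray, time_s: np.ndarray, k: int):
    if k <= 1:
        return data, time_s
    return data[..., ::k], time_s[::k]


@dataclass
class RunResult:
    behavior: stats.BehaviorSummary
    pupil_sequence: dict          # stacked arrays + bootstrap for REG vs RND
    change_locked: dict           # measure -> comparison -> results
    manifest: dict


def run_pipeline(cfg: RunConfig, write: bool = True) -> RunResult:
    """Execute the full synthetic-session pipeline under ``cfg``."""
    rng_root = np.random.SeedSequence(cfg.seed)
    part_seeds = rng_root.spawn(cfg.n_participants)
    stats_rng = np.random.default_rng(rng_root.spawn(1)[0])

    out_dir = Path(cfg.out_dir)
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)

    per_pupil_seq, per_pupil_chg, per_ms, per_pdr = [], [], [], []
    scored_by_p = {}
    rejection_rows = []
    controls = {}       # (measure, condition) -> per-participant trial matrices
    for pi, ss in enumerate(part_seeds):
        rng = np.random.default_rng(ss)
        design = build_session(int(rng.integers(2 ** 31)), n_blocks=cfg.n_blocks,
                               trials_per_condition=cfg.trials_per_condition,
                               decoys_per_condition=cfg.decoys_per_condition)
        blocks, traits, responses = synth.simulate_participant(design, cfg.synth, rng)
        table = pd.concat([b.trial_table for b in blocks], ignore_index=True)
        scored = stats.score_trial_presses(table, responses)
        scored_by_p[f"P{pi:02d}"] = scored
        preps = [preprocess_block(b, cfg) for b in blocks]
        if cfg.keep_traces and write:
            tdir = out_dir / "traces" / f"P{pi:02d}"
            tdir.mkdir(parents=True, exist_ok=True)
            for b in blocks:
                b.trace.to_csv(tdir / f"block{b.block}.csv")
                (tdir / f"block{b.block}.truth.json").write_text(b.truth.to_json())
        seq = participant_pupil(preps, scored, cfg, lock="onset",
                                conditions=SEQUENCE_CONDITIONS)
        chg = participant_pupil(preps, scored, cfg, lock="change",
                                conditions=CHANGE_CONDITIONS)
        per_pupil_seq.append(seq)
        per_pupil_chg.append(chg)
        per_ms.append(participant_rate(preps, scored, cfg, kind="ms", lock="change"))
        per_pdr.append(participant_rate(preps, scored, cfg, kind="pdr", lock="change"))
        for cond, d in {**seq}.items():
            rejection_rows.append(dict(participant=f"P{pi:02d}", condition=cond,
                                       n_epochs=d["n_epochs"],
                                       n_rejected=d["n_rejected"]))
        # trial-level control matrices for the surrogate-split noise floor
        seq_nc = [seq[c]["epochs"].data for c in SEQUENCE_CONDITIONS if c in seq]
        if seq_nc:
            controls.setdefault(("pd_seq", "NC"), []).append(np.vstack(seq_nc))
        for cond in ("REG-NC", "RND-NC", "REG-CD", "RND-CD"):
            if cond in chg:
                controls.setdefault(("pd", cond), []).append(chg[cond]["epochs"].data)
            for kind in ("ms", "pdr"):
                mat = participant_trial_matrix(preps, scored, cfg, kind, cond)
                if mat.size:
                    controls.setdefault((kind, cond), []).append(mat)

    behavior = stats.score_behavior(scored_by_p)

    sc = cfg.stats
    # sustained REG vs RND pupil difference
    reg, rnd, t = stack_pair(per_pupil_seq, "REG-NC", "RND-NC")
    reg_d, t_d = decimate(reg, t, sc.decimate)
    rnd_d, _ = decimate(rnd, t, sc.decimate)
    seq_boot = stats.bootstrap_difference(reg_d - rnd_d, t_d, n_iter=sc.n_boot,
                                          consistency=sc.consistency, rng=stats_rng)
    pupil_sequence = dict(time_s=t_d, reg_mean=reg_d.mean(0), rnd_mean=rnd_d.mean(0),
                          bootstrap=seq_boot)
    seq_floor = _floor_from_controls(controls.get(("pd_seq", "NC")), t_d, sc,
                                     stats_rng)
    if seq_floor is not None:
        pupil_sequence["noise_floor_s"] = seq_floor.threshold_s
        pupil_sequence["robust_intervals"] = stats.robust_intervals(seq_boot,
                                                                    seq_floor)

    # change-locked comparisons per measure; the control condition for the
    # noise floor is NC for the vs-NC comparisons and CD for CA-vs-CD
    comparisons = [("CA", "NC"), ("CD", "NC"), ("CA", "CD")]
    change_locked = {}
    floors = {}
    for name, per in (("pd", per_pupil_chg), ("pdr", per_pdr), ("ms", per_ms)):
        change_locked[name] = {}
        for regu in REGULARITIES:
            for a, b in comparisons:
                ca, cb = f"{regu}-{a}", f"{regu}-{b}"
                try:
                    xa, xb, tt = stack_pair(per, ca, cb)
                except ValueError:
                    continue
                xa_d, tt_d = decimate(xa, tt, sc.decimate)
                xb_d, _ = decimate(xb, tt, sc.decimate)
                boot = stats.bootstrap_difference(xa_d - xb_d, tt_d,
                                                  n_iter=sc.n_boot,
                                                  consistency=sc.consistency,
                                                  rng=stats_rng)
                entry = dict(bootstrap=boot, time_s=tt_d,
                             mean_a=xa_d.mean(0), mean_b=xb_d.mean(0),
                             comparison=f"{ca} vs {cb}")
                control = f"{regu}-NC" if b == "NC" else f"{regu}-CD"
                if (name, control) not in floors:
                    floors[(name, control)] = _floor_from_controls(
                        controls.get((name, control)), tt_d, sc, stats_rng)
                floor = floors[(name, control)]
                if floor is not None:
                    entry["noise_floor_s"] = floor.threshold_s
                    entry["robust_intervals"] = stats.robust_intervals(boot, floor)
                sig = boot.sig_mask & (tt_d >= 0)
                if sig.any():
                    sel = sig
                    entry["effect_size_r"] = stats.wilcoxon_effect_size(
                        xa_d[:, sel].mean(axis=1), xb_d[:, sel].mean(axis=1))
                    if name in ("ms", "pdr"):
                        first = tt_d[np.flatnonzero(sig)[0]]
                        lo, hi = ms.ROI_WINDOW_S
                        entry["roi_label"] = ("primary" if lo <= first <= hi
                                              else "exploratory")
                if cfg.run_latency_analysis and name == "pd":
                    entry["latency"] = stats.divergence_latency(
                        xa_d, xb_d, tt_d, n_iter=sc.n_latency_iter,
                        boot_iter=sc.n_boot, consistency=sc.consistency,
                        rng=stats_rng)
                change_locked[name][f"{ca}_vs_{cb}"] = entry

    manifest = dict(seed=cfg.seed, n_participants=cfg.n_participants,
                    n_blocks=cfg.n_blocks, config=json.loads(
                        json.dumps(cfg.to_yaml())))
    result = RunResult(behavior=behavior, pupil_sequence=pupil_sequence,
                       change_locked=change_locked, manifest=manifest)
    if write:
        _write_artifacts(result, rejection_rows, out_dir, cfg)
    return result


def _floor_from_controls(mats, time_s, sc, rng):
    """Surrogate-split noise floor from per-participant control matrices."""
    if not mats:
        return None
    usable = [m[:, ::sc.decimate] for m in mats if m.shape[0] >= 2]
    if len(usable) < 2:
        return None
    return stats.noise_floor(usable, time_s, n_iter=sc.noise_floor_iter,
                             boot_iter=sc.n_boot, consistency=sc.consistency,
                             quantile=sc.noise_floor_quantile, rng=rng)


def _jsonable(x):
    if isinstance(x, stats.BootstrapResult):
        return dict(sig_intervals=[[float(x.time_s[a]), float(x.time_s[b - 1])]
                                   for a, b in x.runs()],
                    longest_run_s=x.longest_run_s(),
                    n_iterations=x.n_iterations)
    if isinstance(x, stats.LatencyDistribution):
        return dict(mean_s=x.mean_s, ci_s=list(x.ci_s),
                    missing_rate=x.missing_rate, n_iterations=x.n_iterations)
    if isinstance(x, (np.floating, np.integer)):
        return float(x)
    return x


def _write_artifacts(result: RunResult, rejection_rows, out_dir: Path,
                     cfg: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.behavior.per_participant.to_csv(out_dir / "behavior.tsv", sep="\t",
                                           index=False)
    pd.DataFrame(rejection_rows).to_csv(out_dir / "rejections.tsv", sep="\t",
                                        index=False)
    seq = result.pupil_sequence
    pd.DataFrame(dict(time_s=seq["time_s"], reg=seq["reg_mean"],
                      rnd=seq["rnd_mean"],
                      significant=seq["bootstrap"].sig_mask.astype(int))
                 ).to_csv(out_dir / "pupil_sequence.tsv", sep="\t", index=False)
    sustained = _jsonable(seq["bootstrap"])
    if "robust_intervals" in seq:
        sustained["noise_floor_s"] = seq["noise_floor_s"]
        sustained["robust_intervals"] = seq["robust_intervals"]
    summary = dict(
        behavior=dict(hit_rate_test=result.behavior.hit_rate_test,
                      rt_test=result.behavior.rt_test),
        sustained_pd=sustained,
        change_locked={
            m: {k: {kk: _jsonable(vv) for kk, vv in v.items()
                    if kk in ("effect_size_r", "roi_label", "bootstrap",
                              "latency", "comparison", "noise_floor_s",
                              "robust_intervals")}
                for k, v in d.items()}
            for m, d in result.change_locked.items()})
    (out_dir / "results.json").write_text(json.dumps(summary, indent=2,
                                                     default=_jsonable))
    config_text = cfg.to_yaml()
    (out_dir / "config.yaml").write_text(config_text)
    manifest = dict(result.manifest)
    manifest["checksums"] = {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest()
        for f in sorted(out_dir.glob("*.tsv")) + [out_dir / "results.json"]}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
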