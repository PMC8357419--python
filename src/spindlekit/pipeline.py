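"""Pipeline configuration and stage orchestration.

A PipelineConfig names the synthetic inputs, the thresholds of each stage and
a mandatory random seed; ``run_pipeline`` executes the requested stages in
order on a synthetic recording, writing event tables and summaries as CSV
plus a JSON run manifest (config hash, seed, per-stage counts). Outputs are a
pure function of (config, seed): running twice writes byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import spindles as sp
from .coupling import comodulogram, coupling_auc, detect_coupling_peaks, spindle_coupling_curve
from .spikes import SpikeTrain, autocorrelogram_ci, event_triggered_rate, isi
from .states import emg_envelope, score_states, twitch_times
from .synth import CohortSpec, SynthLFPSpec, SynthSpikesSpec, generate_cohort, generate_emg, generate_lfp, generate_spikes
from .trajectory import bootstrap_nadir, fit_trajectory

logger = logging.getLogger("spindlekit")

ALL_STAGES = (
    "simulate",
    "score-states",
    "detect-spindles",
    "characterize",
    "comodulate",
    "spikes",
    "trajectory",
)


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str = "spindlekit_out"
    stages: tuple[str, ...] = ALL_STAGES
    lfp: dict = field(default_factory=lambda: {"duration": 60.0, "fs": 1250.0, "event_rate": 0.2})
    emg: dict = field(default_factory=lambda: {"duration": 60.0, "fs": 5000.0})
    spikes: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    detection: dict = field(default_factory=lambda: {"mad_multiplier": 3.0})
    coupling: dict = field(default_factory=lambda: {"window": 4.0})

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}; known: {ALL_STAGES}")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    def digest(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config, rejecting unknown keys before any computation."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; known: {sorted(known)}")
    if "stages" in raw:
        raw = dict(raw, stages=tuple(raw["stages"]))
    return PipelineConfig(**raw)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages, writing per-stage outputs under out_dir.

    Returns the manifest dict (also written as manifest.json). Any stage
    failure aborts with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    subseeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(8)]
    manifest: dict = {"seed": config.seed, "config_hash": config.digest(), "stages": {}}
    state: dict = {}

    for stage in config.stages:
        try:
            counts = _STAGE_FUNCS[stage](config, state, subseeds, out)
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = counts
        logger.info("stage=%s hash=%s counts=%s", stage, config.digest(), counts)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, state: dict, seeds: list[int], out: Path) -> dict:
    lfp_spec = SynthLFPSpec(**config.lfp)
    rec, truth = generate_lfp(lfp_spec, seed=seeds[0])
    state["rec"], state["truth"] = rec, truth
    _write_csv(truth, out / "ground_truth_events.csv")
    emg_kwargs = dict(config.emg)
    duration = emg_kwargs.pop("duration", rec.duration)
    fs_emg = emg_kwargs.pop("fs", 5000.0)
    emg, emg_truth = generate_emg(duration, fs_emg, seed=seeds[1], **emg_kwargs)
    state["emg"], state["fs_emg"], state["emg_truth"] = emg, fs_emg, emg_truth
    if config.spikes:
        spec = SynthSpikesSpec(**config.spikes)
        state["spike_truth"] = generate_spikes(spec, rec, truth, seed=seeds[2])
        state["spike_zones"] = spec.zones
    return {"events": int(len(truth)), "emg_samples": int(emg.size)}


def _stage_states(config: PipelineConfig, state: dict, seeds: list[int], out: Path) -> dict:
    env = emg_envelope(state["emg"], state["fs_emg"])
    segs = score_states(env)
    state["segments"] = segs
    df = pd.DataFrame(segs.intervals, columns=["start_s", "end_s", "label"])
    _write_csv(df, out / "states.csv")
    tw = twitch_times(segs)
    _write_csv(pd.DataFrame({"twitch_s": tw}), out / "twitches.csv")
    return {"segments": int(len(df)), "twitches": int(tw.size)}


def _sleep_mask(state: dict, duration: float) -> list[tuple[float, float]]:
    segs = state.get("segments")
    if segs is not None:
        atonia = segs.by_label("atonia")
        if atonia:
            return atonia
    return [(0.0, duration)]


def _stage_detect(config: PipelineConfig, state: dict, seeds: list[int], out: Path) -> dict:
    rec = state["rec"]
    mask = _sleep_mask(state, rec.duration)
    all_events = {}
    for ch in range(rec.n_channels):
        par, powers = sp.compute_par(rec.signal[ch], rec.fs, species=rec.subject.species)
        all_events[ch] = sp.detect_spindle_events(
            par, powers, mask, channel=ch, **config.detection
        )
    state["events_by_channel"] = all_events
    rows = [
        {
            "recording_id": rec.subject.recording_id,
            "channel": ch,
            "start_s": ev.start_s,
            "end_s": ev.end_s,
            "start_idx": int(round(ev.start_s * rec.fs)),
            "end_idx": int(round(ev.end_s * rec.fs)),
            "peak_par": ev.peak_par,
        }
        for ch, evs in all_events.items()
        for ev in evs
    ]
    df = pd.DataFrame(rows, columns=["recording_id", "channel", "start_s", "end_s", "start_idx", "end_idx", "peak_par"])
    _write_csv(df, out / "events.csv")
    (out / "events.json").write_text(
        json.dumps({"mad_multiplier": config.detection.get("mad_multiplier", 3.0), "n_events": len(df)}, indent=1)
    )
    return {"events": int(len(df))}


def _stage_characterize(config: PipelineConfig, state: dict, seeds: list[int], out: Path) -> dict:
    rec = state["rec"]
    evs_by_ch = state["events_by_channel"]
    n_functional = sum(c.functional for c in rec.channels)
    rows = []
    for ch, evs in evs_by_ch.items():
        for ev in evs:
            ev.power = sp.event_power(ev.start_s, ev.end_s, rec.signal[ch], rec.fs)
            try:
                ev.esr = sp.waveform_asymmetry(ev.start_s, ev.end_s, rec.signal[ch], rec.fs).esr
            except ValueError:
                ev.esr = np.nan
            ev.extent = sp.spatial_extent(ev, evs_by_ch, n_functional)
            rows.append(
                {
                    "channel": ch,
                    "start_s": ev.start_s,
                    "end_s": ev.end_s,
                    "peak_par": ev.peak_par,
                    "power_uv": ev.power,
                    "esr": ev.esr,
                    "extent": ev.extent,
                }
            )
    df = pd.DataFrame(rows, columns=["channel", "start_s", "end_s", "peak_par", "power_uv", "esr", "extent"])
    _write_csv(df, out / "event_features.csv")
    return {"characterized": int(len(df))}


def _stage_comodulate(config: PipelineConfig, state: dict, seeds: list[int], out: Path) -> dict:
    rec = state["rec"]
    evs = state.get("events_by_channel", {}).get(0, [])
    mids = np.array([e.midpoint for e in evs])
    if mids.size < 5:
        _write_csv(pd.DataFrame(columns=["f_c", "value", "prominence", "width", "coupling_index"]), out / "coupling_peaks.csv")
        return {"peaks": 0, "skipped": "fewer than 5 events"}
    cmg = comodulogram(rec.signal[0], rec.fs, mids, window=config.coupling.get("window", 4.0))
    curve = spindle_coupling_curve(cmg)
    peaks = detect_coupling_peaks(curve)
    auc = coupling_auc(curve, (25.0, 35.0))
    _write_csv(
        pd.DataFrame({"freq_hz": curve.freqs, "coupling": curve.curve}),
        out / "coupling_curve.csv",
    )
    _write_csv(
        pd.DataFrame(
            [
                {"f_c": p.f_c, "value": p.value, "prominence": p.prominence, "width": p.width, "coupling_index": p.coupling_index}
                for p in peaks
            ],
            columns=["f_c", "value", "prominence", "width", "coupling_index"],
        ),
        out / "coupling_peaks.csv",
    )
    (out / "coupling.json").write_text(json.dumps({"auc_25_35": auc, "n_events": cmg.n_events}, indent=1))
    return {"peaks": len(peaks), "auc_25_35": auc}


def _stage_spikes(config: PipelineConfig, state: dict, seeds: list[int], out: Path) -> dict:
    truth = state.get("spike_truth")
    if truth is None or truth.empty:
        return {"skipped": "no spikes simulated"}
    counts = {}
    for zone in sorted(truth["zone"].unique()):
        t = truth.loc[truth["zone"] == zone, "time_s"].to_numpy()
        train = SpikeTrain(times=np.sort(t), zone=zone)
        _write_csv(pd.DataFrame({"time_s": train.times}), out / f"spikes_{zone}.csv")
        counts[zone] = int(train.n)
        if train.n >= 50:
            acg = autocorrelogram_ci(train)
            _write_csv(
                pd.DataFrame(
                    {"lag_s": acg.lags, "count": acg.counts, "ci_low": acg.ci_low, "ci_high": acg.ci_high}
                ),
                out / f"acg_{zone}.csv",
            )
        evs = state.get("events_by_channel", {}).get(0, [])
        onsets = np.array([e.start_s for e in evs])
        if train.n >= 20 and onsets.size >= 5:
            psth = event_triggered_rate(train, onsets, seed=seeds[4])
            _write_csv(
                pd.DataFrame(
                    {"lag_s": psth.lags, "rate_norm": psth.rate, "ci_low": psth.ci_low, "ci_high": psth.ci_high}
                ),
                out / f"psth_{zone}.csv",
            )
    return counts


def _stage_trajectory(config: PipelineConfig, state: dict, seeds: list[int], out: Path) -> dict:
    cfg = dict(config.cohort)
    n_boot = int(cfg.pop("n_boot", 2000))
    spec = CohortSpec(**cfg) if cfg else CohortSpec()
    cohort, true_nadir = generate_cohort(spec, seed=seeds[5])
    _write_csv(cohort, out / "cohort.csv")
    best, _ = fit_trajectory(cohort)
    result: dict = {
        "degree": best.degree,
        "family": best.family,
        "loocv_mse": best.loocv_mse,
        "true_nadir": true_nadir,
    }
    if best.degree >= 2:
        nad = bootstrap_nadir(cohort, best.degree, n_boot=n_boot, seed=seeds[6])
        _write_csv(
            pd.DataFrame(
                {"age": nad.ages, "within_mass": nad.within_mass, "null_mass": nad.null_mass}
            ),
            out / "nadir.csv",
        )
        result |= {"mode_age": nad.mode_age, "exceedance": nad.exceedance}
    (out / "trajectory_model.json").write_text(json.dumps(result, indent=1, sort_keys=True))
    return {"degree": best.degree, "mode_age": result.get("mode_age")}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "score-states": _stage_states,
    "detect-spindles": _stage_detect,
    "characterize": _stage_characterize,
    "comodulate": _stage_comodulate,
    "spikes": _stage_spikes,
    "trajectory": _stage_trajectory,
}
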