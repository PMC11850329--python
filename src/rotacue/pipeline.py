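"""End-to-end orchestration of a simulated experiment.

Runs the full study protocol on synthetic data: an eye-movement
calibration recording, three cue-based training runs and one
self-paced evaluation run are simulated; signals are band-passed,
EOG-cleaned and reduced to 10 Hz low-frequency features; movement
onsets are labeled from the motion trace; decoder hyperparameters are
selected by run-wise cross-validation; the final detector is calibrated
at several FP/min bounds on the self-paced run; and the neural-
correlate analyses (MRCP comparison, waveform NRMSE, ERDS map) are
computed.  The report is a plain dictionary keyed by stage.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np

from . import neural_analysis as na
from .channels import CENTRAL_CHANNELS, EEG_CHANNELS
from .decoder import score_run, select_hyperparameters
from .evaluation import EvalConfig, calibrate_threshold
from .io import ExperimentConfig, save_recording, write_events_tsv
from .onset_detection import compute_speed, detect_onsets
from .paradigm import generate_cue_schedule, schedule_statistics
from .preprocessing import (apply_eog_removal, bandpass, common_average,
                            extract_lowfreq_features, fit_eog_removal)
from .synthetic import (SubjectModel, simulate_cued_run,
                        simulate_eye_calibration, simulate_self_paced_run,
                        simulate_self_paced_timeline)

logger = logging.getLogger("rotacue")

__all__ = ["run_experiment", "derive_seeds"]


def derive_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (< 2**31) from one base seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Simulate, decode and analyze one full experiment.

    Deterministic given ``cfg`` (all randomness is derived from
    ``cfg.seed``).  Returns a machine-readable report; if
    ``cfg.output_dir`` is set, recordings, event tables and the report
    are also written there.
    """
    t_start = time.perf_counter()
    seeds = derive_seeds(cfg.seed, 6)
    report: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash()}

    _stage("simulate")
    schedule = generate_cue_schedule(cfg.paradigm)
    report["schedule"] = schedule_statistics(schedule)
    subject = SubjectModel.default(seed=seeds[0], **cfg.subject)
    calibration = simulate_eye_calibration(cfg.calibration_duration, subject,
                                           seed=seeds[1])
    cued = [simulate_cued_run(schedule, subject, seed=seeds[2 + k])
            for k in range(cfg.n_cued_runs)]
    sp_onsets = simulate_self_paced_timeline(cfg.self_paced_duration, subject,
                                             seed=seeds[5])
    self_paced = simulate_self_paced_run(sp_onsets, subject, seed=seeds[5],
                                         duration=cfg.self_paced_duration)

    _stage("preprocess")
    eog_model = fit_eog_removal(bandpass(calibration))
    clean = [apply_eog_removal(eog_model, bandpass(rec))
             for rec in cued + [self_paced]]
    features = [extract_lowfreq_features(rec) for rec in clean]
    features_car = [common_average(f) for f in features]

    _stage("label onsets")
    detected = []
    for rec in cued + [self_paced]:
        trace = compute_speed(rec.motion_xy, rec.motion_rate)
        detected.append(detect_onsets(trace, cfg.onset))
    report["onsets"] = {
        "per_run": [len(o) for o in detected],
        "ground_truth_per_run": [len(r.event_times("movement_onset"))
                                 for r in cued + [self_paced]],
    }

    _stage("hyperparameter selection")
    train_sets = list(zip(features_car[:cfg.n_cued_runs],
                          detected[:cfg.n_cued_runs]))
    selection = select_hyperparameters(train_sets, cfg.decoder)
    report["decoder"] = {
        "n_window": selection.n_window,
        "d": selection.d,
        "cv_mcc": {f"{k[0]},{k[1]}": v for k, v in selection.cv_mcc.items()},
        "shrinkage_method": cfg.decoder.shrinkage_method,
        "shrinkage_intensity": selection.model.shrinkage_intensity,
    }

    _stage("evaluate self-paced run")
    scores = score_run(selection.model, features_car[-1])
    sp_true = detected[-1]
    duration = self_paced.duration
    report["evaluation"] = {}
    for level in cfg.fppm_levels:
        ecfg = EvalConfig(hit_window=cfg.eval.hit_window,
                          refractory=cfg.eval.refractory, max_fppm=level)
        threshold, metrics = calibrate_threshold(scores, sp_true, ecfg,
                                                 duration)
        report["evaluation"][f"max_fppm_{level:g}"] = {
            "threshold": threshold, **metrics.as_dict()}

    _stage("neural analysis")
    # waveform analyses use un-referenced low-frequency features
    cued_epochs = _pooled_epochs(features[:cfg.n_cued_runs],
                                 detected[:cfg.n_cued_runs], (-2.0, 2.0),
                                 "cued")
    sp_epochs = na.epoch(features[-1].values, features[-1].rate, sp_true,
                         (-2.0, 2.0), condition="self_paced")
    stat = na.compare_conditions(
        _crop(cued_epochs, (-1.0, 1.0)), _crop(sp_epochs, (-1.0, 1.0)))
    report["mrcp_comparison"] = {
        "n_significant": int(stat.significant.sum()),
        "n_comparisons": stat.n_comparisons,
    }
    nrmse_central = {}
    for ch in CENTRAL_CHANNELS:
        i = EEG_CHANNELS.index(ch)
        nrmse_central[ch] = na.nrmse(cued_epochs.mean()[i],
                                     sp_epochs.mean()[i])
    report["nrmse_central"] = nrmse_central

    erds_cfg = na.ERDSConfig(n_boot=cfg.erds_n_boot)
    c1 = EEG_CHANNELS.index("C1")
    erds_epochs = na.epoch(clean[-1].eeg, self_paced.eeg_rate, sp_true,
                           (-4.0, 4.0), condition="self_paced")
    erds = na.erds_map(erds_epochs, erds_cfg, channel=c1,
                       rng=np.random.default_rng(seeds[4]))
    band10 = int(np.argmin(np.abs(erds.freqs - 10.0)))
    post = (erds.times >= 0) & (erds.times <= 1.0)
    report["erds"] = {
        "alpha_erd_postonset": float(erds.values[band10][post].mean()),
        "n_freqs": len(erds.freqs),
        "fraction_significant": float(erds.significant.mean()),
    }

    report["wall_clock_s"] = time.perf_counter() - t_start

    if cfg.output_dir:
        _write_outputs(cfg, report, cued, self_paced, calibration,
                       selection.model,
                       figures=(cued_epochs, sp_epochs, stat, erds))
    return report


def _pooled_epochs(feature_list, onset_list, window, condition):
    parts = [na.epoch(f.values, f.rate, o, window, condition=condition)
             for f, o in zip(feature_list, onset_list)]
    data = np.concatenate([p.data for p in parts])
    return na.EpochSet(data=data, times=parts[0].times, rate=parts[0].rate,
                       condition=condition)


def _crop(epochs, window):
    mask = (epochs.times >= window[0]) & (epochs.times <= window[1])
    return na.EpochSet(data=epochs.data[:, :, mask], times=epochs.times[mask],
                       rate=epochs.rate, condition=epochs.condition)


def _write_outputs(cfg, report, cued, self_paced, calibration, model,
                   figures=None) -> None:
    import json

    from .io import save_model

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, rec in enumerate(cued):
        save_recording(rec, out / f"cued_run{k + 1}.h5")
        write_events_tsv(rec.events, out / f"cued_run{k + 1}_events.tsv")
    save_recording(self_paced, out / "self_paced.h5")
    write_events_tsv(self_paced.events, out / "self_paced_events.tsv")
    save_recording(calibration, out / "eye_calibration.h5")
    save_model(model, out / "model.h5")
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    if figures is not None:
        from .figures import plot_erds_map, plot_mrcp_comparison

        cued_epochs, sp_epochs, stat, erds = figures
        c1 = EEG_CHANNELS.index("C1")
        plot_mrcp_comparison(cued_epochs, sp_epochs, c1, "C1",
                             path=out / "mrcp_C1.png")
        plot_erds_map(erds, "C1", path=out / "erds_C1.png")
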