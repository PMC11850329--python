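"""Recording container and event-table I/O plus experiment configuration.

Recordings are stored in a single HDF5 file (datasets ``eeg``, ``eog``,
``motion_xy``; rates and channel labels as attributes; events as two
aligned datasets).  Event tables interchange as BIDS-like TSV (one row
per event, onset in seconds).  Real recordings in BrainVision or EDF
format can be loaded through MNE when it is installed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .decoder import DecoderConfig
from .evaluation import EvalConfig
from .onset_detection import OnsetConfig
from .paradigm import ParadigmConfig
from .synthetic import SyntheticRecording

__all__ = [
    "save_recording",
    "load_recording",
    "save_model",
    "load_model",
    "read_events_tsv",
    "write_events_tsv",
    "ExperimentConfig",
    "load_experiment_config",
    "save_experiment_config",
]


def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "onset_s" not in df.columns:
        # tolerate plain BIDS naming
        if "onset" in df.columns:
            df = df.rename(columns={"onset": "onset_s",
                                    "trial_type": "kind"})
        else:
            raise ValueError("events file lacks an onset_s/onset column")
    return df


def save_recording(recording: SyntheticRecording, path) -> None:
    """Write a recording to a single HDF5 container file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=recording.eeg)
        f.create_dataset("eog", data=recording.eog)
        f.create_dataset("motion_xy", data=recording.motion_xy)
        f.create_dataset("events/onset_s",
                         data=recording.events["onset_s"].to_numpy())
        f.create_dataset("events/kind",
                         data=recording.events["kind"].to_numpy(dtype="S"))
        f.attrs["eeg_rate"] = recording.eeg_rate
        f.attrs["motion_rate"] = recording.motion_rate
        f.attrs["run_kind"] = recording.run_kind
        f.attrs["channel_labels"] = [str(c) for c in recording.channel_labels]
        f.attrs["eog_labels"] = [str(c) for c in recording.eog_labels]


def load_recording(path, format: str = "container",
                   events_path=None, expected_channels: int | None = 60
                   ) -> SyntheticRecording:
    """Load a recording (container, BrainVision or EDF).

    BrainVision/EDF need MNE and a TSV event sidecar; channel units are
    normalized to microvolts.  ``expected_channels`` validates the EEG
    channel count (None disables the check).
    """
    if format == "container":
        rec = _load_container(path)
    elif format in ("brainvision", "edf"):
        rec = _load_mne(path, format, events_path)
    else:
        raise ValueError(f"unknown format: {format}")
    if expected_channels is not None and rec.eeg.shape[0] != expected_channels:
        raise ValueError(
            f"expected {expected_channels} EEG channels, found "
            f"{rec.eeg.shape[0]}")
    return rec


def _load_container(path) -> SyntheticRecording:
    with h5py.File(path, "r") as f:
        events = pd.DataFrame({
            "onset_s": f["events/onset_s"][()],
            "kind": [k.decode() for k in f["events/kind"][()]],
        })
        return SyntheticRecording(
            eeg=f["eeg"][()], eog=f["eog"][()],
            motion_xy=f["motion_xy"][()], events=events,
            run_kind=str(f.attrs["run_kind"]),
            eeg_rate=float(f.attrs["eeg_rate"]),
            motion_rate=float(f.attrs["motion_rate"]),
            channel_labels=tuple(f.attrs["channel_labels"]),
            eog_labels=tuple(f.attrs["eog_labels"]),
        )


def _load_mne(path, format: str, events_path) -> SyntheticRecording:
    try:
        import mne
    except ImportError as exc:   # pragma: no cover - optional dependency
        raise ImportError("loading BrainVision/EDF requires mne") from exc
    if events_path is None:
        raise ValueError("BrainVision/EDF loading requires a TSV event sidecar")
    reader = (mne.io.read_raw_brainvision if format == "brainvision"
              else mne.io.read_raw_edf)
    raw = reader(path, preload=True, verbose="error")
    picks_eog = [ch for ch in raw.ch_names
                 if ch.upper().startswith("EOG")]
    picks_eeg = [ch for ch in raw.ch_names if ch not in picks_eog]
    data = raw.get_data() * 1e6          # volts -> microvolts
    idx = {ch: i for i, ch in enumerate(raw.ch_names)}
    events = read_events_tsv(events_path)
    return SyntheticRecording(
        eeg=data[[idx[ch] for ch in picks_eeg]],
        eog=data[[idx[ch] for ch in picks_eog]] if picks_eog
        else np.zeros((4, data.shape[1])),
        motion_xy=np.zeros((2, 0)),
        events=events, run_kind="external",
        eeg_rate=float(raw.info["sfreq"]),
        channel_labels=tuple(picks_eeg),
        eog_labels=tuple(picks_eog) or ("EOGL", "EOGR", "EOGU", "EOGD"),
    )


def save_model(model, path) -> None:
    """Serialize an SLDA model (statistics, weights, config) to HDF5."""
    with h5py.File(path, "w") as f:
        for name in ("class_means", "shrunk_cov", "weights", "priors"):
            f.create_dataset(name, data=getattr(model, name))
        f.attrs["bias"] = model.bias
        f.attrs["n_window"] = model.n_window
        f.attrs["d"] = model.d
        f.attrs["shrinkage_method"] = model.shrinkage_method
        if model.shrinkage_intensity is not None:
            f.attrs["shrinkage_intensity"] = model.shrinkage_intensity


def load_model(path):
    from .decoder import SLDAModel

    with h5py.File(path, "r") as f:
        return SLDAModel(
            class_means=f["class_means"][()], shrunk_cov=f["shrunk_cov"][()],
            weights=f["weights"][()], priors=f["priors"][()],
            bias=float(f.attrs["bias"]), n_window=int(f.attrs["n_window"]),
            d=float(f.attrs["d"]),
            shrinkage_method=str(f.attrs["shrinkage_method"]),
            shrinkage_intensity=(float(f.attrs["shrinkage_intensity"])
                                 if "shrinkage_intensity" in f.attrs else None),
        )


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration of a simulated experiment.

    ``subject`` holds keyword arguments for
    :meth:`rotacue.synthetic.SubjectModel.default`.  The decoder grid
    defaults here are a condensed version of the full search grid so an
    end-to-end experiment stays interactive; pass a custom
    ``DecoderConfig`` for an exhaustive search.
    """

    paradigm: ParadigmConfig = ParadigmConfig()
    subject: dict = dataclasses.field(default_factory=dict)
    decoder: DecoderConfig = DecoderConfig(
        n_window_grid=(5, 8, 10, 12, 15), d_grid=(0.0, 0.1, 0.2, 0.3))
    eval: EvalConfig = EvalConfig()
    onset: OnsetConfig = OnsetConfig()
    seed: int = 0
    n_cued_runs: int = 3
    self_paced_duration: float = 334.0
    calibration_duration: float = 420.0
    fppm_levels: tuple = (0.5, 1.0, 2.0)
    erds_n_boot: int = 200
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["onset"] = dataclasses.asdict(self.onset)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_experiment_config(cfg: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_experiment_config(path) -> ExperimentConfig:
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError:
        raw = json.loads(text)
    kwargs = dict(raw or {})
    for key, cls in (("paradigm", ParadigmConfig), ("decoder", DecoderConfig),
                     ("eval", EvalConfig), ("onset", OnsetConfig)):
        if key in kwargs and isinstance(kwargs[key], dict):
            sub = kwargs[key]
            for field_ in ("n_window_grid", "d_grid", "hit_window"):
                if field_ in sub and isinstance(sub[field_], list):
                    sub[field_] = tuple(sub[field_])
            kwargs[key] = cls(**sub)
    if "fppm_levels" in kwargs:
        kwargs["fppm_levels"] = tuple(kwargs["fppm_levels"])
    return ExperimentConfig(**kwargs)
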