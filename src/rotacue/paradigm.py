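"""Continuous-rotation cue schedule generation.

The training paradigm displays a cross rotating over a fixed cross; the
participant executes a brief hand movement each time the two crosses
overlap.  Because a cross is 4-fold symmetric, overlaps occur every 90
degrees of rotation.  The angular velocity is modulated slowly over the
run,

    omega(t) = 90 / T_ITI + A * sin(2*pi*a_base*t) * sin(2*pi*a_mod*t + phi)

(degrees per second, ``t`` measured from the start of the rotation), so
that the inter-trial interval (ITI) between successive overlap cues
varies smoothly around the mean ``T_ITI`` without abrupt velocity
changes.  This module integrates that velocity law deterministically and
reports the resulting cue times and timing statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParadigmConfig",
    "CueSchedule",
    "angular_velocity",
    "generate_cue_schedule",
    "schedule_statistics",
    "traditional_paradigm_duration",
    "write_schedule_tsv",
]


@dataclass(frozen=True)
class ParadigmConfig:
    """Parameters of the rotating-cue velocity law and run layout.

    Attributes
    ----------
    T_ITI : float
        Mean inter-trial interval in seconds; sets the base angular
        velocity ``90 / T_ITI`` deg/s.
    A : float
        Spread of the velocity modulation, deg/s.
    a_base, a_mod : float
        Frequencies (Hz) of the two sinusoids whose product modulates
        the velocity.
    phi : float
        Phase of the modulation sinusoid, radians.
    n_trials : int
        Number of overlap cues per run.
    static_hold : float
        Seconds the crosses are shown statically before rotation starts.
    initial_tilt : float
        Initial offset (degrees) of the rotating cross from the fixed
        cross.  The tilt is taken in the direction such that the first
        overlap occurs after ``symmetry_angle - initial_tilt`` degrees
        of rotation, giving the participant preparation time.
    fadeout_angle : float
        Degrees before the (n_trials+1)-th overlap at which the crosses
        fade out and the run ends.
    symmetry_angle : float
        Rotation (degrees) between successive overlaps; 90 for a cross.
    integration_step : float
        Time step (seconds) of the velocity integration grid.
    """

    T_ITI: float = 3.3
    A: float = 10.24
    a_base: float = 0.032
    a_mod: float = 0.016
    phi: float = 28.1
    n_trials: int = 100
    static_hold: float = 1.5
    initial_tilt: float = 10.0
    fadeout_angle: float = 10.0
    symmetry_angle: float = 90.0
    integration_step: float = 0.001

    def __post_init__(self) -> None:
        if not self.T_ITI > 0:
            raise ValueError("T_ITI must be positive")
        if self.A < 0:
            raise ValueError("A must be non-negative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not self.integration_step > 0:
            raise ValueError("integration_step must be positive")
        if not 0 <= self.initial_tilt < self.symmetry_angle:
            raise ValueError("initial_tilt must lie in [0, symmetry_angle)")


@dataclass(frozen=True)
class CueSchedule:
    """Cue times and angle trajectory of one cue-based run.

    ``cue_times`` are seconds from run start (the static hold is
    included, so the first cue time exceeds ``static_hold``).
    ``angle_trace`` / ``omega_trace`` are sampled on ``time_grid``,
    which is measured from rotation start.
    """

    cue_times: np.ndarray
    itis: np.ndarray
    time_grid: np.ndarray
    angle_trace: np.ndarray
    omega_trace: np.ndarray
    run_duration: float
    config: ParadigmConfig = field(repr=False)

    @property
    def n_trials(self) -> int:
        return len(self.cue_times)


def angular_velocity(t, cfg: ParadigmConfig):
    """Angular velocity (deg/s) of the rotating cross at time ``t``.

    ``t`` is measured from the start of the rotation (after the static
    hold).  Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    if np.any(t < 0):
        raise ValueError("t must be non-negative (measured from rotation start)")
    omega = 90.0 / cfg.T_ITI + cfg.A * np.sin(2 * np.pi * cfg.a_base * t) * np.sin(
        2 * np.pi * cfg.a_mod * t + cfg.phi
    )
    return omega if omega.ndim else float(omega)


def generate_cue_schedule(cfg: ParadigmConfig) -> CueSchedule:
    """Integrate the velocity law and emit overlap cues.

    The cumulative rotation angle starts at the initial tilt offset;
    a cue is emitted each time the angle crosses a multiple of the
    symmetry angle (linearly interpolated between grid points), until
    ``n_trials`` cues have been emitted.  The run ends when the angle
    reaches ``fadeout_angle`` before the (n_trials+1)-th overlap.
    """
    # Sanity horizon: even at the slowest admissible velocity the
    # required angle is covered within this time.
    omega_min = 90.0 / cfg.T_ITI - cfg.A
    total_angle = (cfg.n_trials + 1) * cfg.symmetry_angle
    if omega_min <= 0:
        horizon = 100.0 * total_angle / (90.0 / cfg.T_ITI)
    else:
        horizon = 1.5 * total_angle / omega_min
    dt = cfg.integration_step
    t = np.arange(0.0, horizon + dt, dt)
    omega = angular_velocity(t, cfg)

    # Cumulative trapezoidal integration of omega -> rotated angle.
    rotated = np.concatenate(([0.0], np.cumsum(0.5 * (omega[1:] + omega[:-1]) * dt)))

    # First overlap after (symmetry_angle - initial_tilt) degrees.
    first_target = cfg.symmetry_angle - cfg.initial_tilt
    targets = first_target + cfg.symmetry_angle * np.arange(cfg.n_trials)
    fade_target = first_target + cfg.symmetry_angle * cfg.n_trials - cfg.fadeout_angle
    if rotated[-1] < fade_target:
        raise RuntimeError(
            "configuration error: %d cues not reachable within the sanity "
            "horizon of %.1f s" % (cfg.n_trials, horizon)
        )
    if np.any(np.diff(rotated) <= 0):
        raise RuntimeError(
            "configuration error: angular velocity is not strictly positive; "
            "cue times are ambiguous (A >= 90/T_ITI)"
        )

    cross_times = np.interp(targets, rotated, t)
    fade_time = float(np.interp(fade_target, rotated, t))
    cue_times = cfg.static_hold + cross_times
    itis = np.diff(cue_times)

    keep = t <= fade_time + dt
    return CueSchedule(
        cue_times=cue_times,
        itis=itis,
        time_grid=t[keep],
        angle_trace=rotated[keep],
        omega_trace=omega[keep],
        run_duration=cfg.static_hold + fade_time,
        config=cfg,
    )


def schedule_statistics(schedule: CueSchedule) -> dict:
    """Summary timing statistics of a schedule.

    Returns mean/SD/min/max ITI, the run duration and trial count.  For
    a single-trial schedule the ITI statistics are undefined and
    reported as NaN with ``degenerate=True``.
    """
    itis = schedule.itis
    if len(itis) == 0:
        return {
            "n_trials": schedule.n_trials,
            "mean_iti": float("nan"),
            "sd_iti": float("nan"),
            "min_iti": float("nan"),
            "max_iti": float("nan"),
            "run_duration": schedule.run_duration,
            "degenerate": True,
        }
    return {
        "n_trials": schedule.n_trials,
        "mean_iti": float(np.mean(itis)),
        "sd_iti": float(np.std(itis, ddof=1)) if len(itis) > 1 else 0.0,
        "min_iti": float(np.min(itis)),
        "max_iti": float(np.max(itis)),
        "run_duration": schedule.run_duration,
        "degenerate": False,
    }


def traditional_paradigm_duration(n_trials: int, trial_duration: float = 8.5) -> float:
    """Seconds needed for ``n_trials`` under a conventional discrete-cue
    paradigm whose per-trial duration is at least ``trial_duration`` s.

    Used to contrast the continuous-rotation schedule with classical
    designs in which cues appear and disappear between trials.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be non-negative")
    return n_trials * trial_duration


def write_schedule_tsv(schedule: CueSchedule, path) -> None:
    """Write cue times as a TSV with columns onset_s, trial_index, iti_s.

    ``iti_s`` of trial k is the interval to the *previous* cue (NaN for
    the first trial).
    """
    itis = np.concatenate(([np.nan], schedule.itis))
    df = pd.DataFrame(
        {
            "onset_s": schedule.cue_times,
            "trial_index": np.arange(schedule.n_trials),
            "iti_s": itis,
        }
    )
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.6f")


def config_to_dict(cfg: ParadigmConfig) -> dict:
    return asdict(cfg)
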