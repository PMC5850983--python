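"""Cursor control laws: AEN position mode and the sequential (SOA) baseline.

Two controllers turn feature frames into 2-D cursor kinematics in a
normalized workspace [-1, 1]^2 at the 10 Hz feature frame rate:

**Position mode (AEN).**  The cursor position *is* the pair of calibrated
control signals: x = c1 (flexion/extension), y = c2 (radial/ulnar
deviation), clamped to the workspace.  Both DoFs act simultaneously, so
diagonal movement is possible within a single step.  When no EMG activity
is detected (channel-mean RMS below a rest threshold) the cursor returns
immediately to the origin.

**Velocity mode (SOA baseline).**  The industry-standard sequential
proportional scheme: two bipolar measuring sites drive one DoF at a time.
When a site's RMS exceeds its threshold the cursor moves along the active
DoF's axis at a speed proportional to the supra-threshold amplitude; below
threshold the cursor holds its last position.  A co-contraction (both sites
above a co-contraction threshold) toggles the active DoF, with a refractory
period so one sustained co-contraction produces one switch.  Diagonal
movement within a step is impossible by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import CalibratedModel, control_signal
from .features import FeatureSeries

__all__ = [
    "CursorState",
    "SOAConfig",
    "clamp_position",
    "aen_position_update",
    "detect_rest",
    "bipolar_rms",
    "soa_velocity_update",
    "detect_cocontraction",
    "AENPositionController",
    "SOAVelocityController",
]

WORKSPACE_BOUND = 1.0


@dataclass
class CursorState:
    """Cursor position (workspace units), time, and the SOA active DoF."""

    x: float = 0.0
    y: float = 0.0
    t: float = 0.0
    active_dof: int = 1

    def __post_init__(self) -> None:
        if self.active_dof not in (1, 2):
            raise ValueError("active_dof must be 1 or 2")

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


def clamp_position(x: float, y: float) -> tuple[float, float]:
    b = WORKSPACE_BOUND
    return (min(max(x, -b), b), min(max(y, -b), b))


def aen_position_update(c1: float, c2: float, rest: bool) -> tuple[float, float]:
    """Position-mode map: (x, y) = clamp(c1, c2); origin when at rest."""
    if rest:
        return (0.0, 0.0)
    return clamp_position(c1, c2)


def detect_rest(frame: np.ndarray, rest_threshold: float) -> bool:
    """True when the channel-mean RMS falls below ``rest_threshold``."""
    if rest_threshold < 0:
        raise ValueError("rest_threshold must be >= 0")
    return bool(np.mean(frame) < rest_threshold)


@dataclass
class SOAConfig:
    """Configuration of the sequential velocity controller.

    ``channel_pos``/``channel_neg`` are the monopolar channel index pairs
    whose difference forms each bipolar measuring site.  ``gain`` converts
    supra-threshold RMS into workspace units per second.
    """

    channel_pos: tuple[int, int]
    channel_neg: tuple[int, int]
    threshold_pos: float
    threshold_neg: float
    gain: float
    cocontraction_threshold: float
    cocontraction_refractory: float = 0.5

    def __post_init__(self) -> None:
        if not (self.threshold_pos > 0 and self.threshold_neg > 0):
            raise ValueError("thresholds must be positive")
        if not self.gain > 0:
            raise ValueError("gain must be positive")
        if not self.cocontraction_threshold > 0:
            raise ValueError("cocontraction_threshold must be positive")
        if self.cocontraction_refractory < 0:
            raise ValueError("cocontraction_refractory must be >= 0")


def bipolar_rms(frame: np.ndarray, pair: tuple[int, int]) -> float:
    """Site amplitude: magnitude of the difference of two monopolar channels."""
    return float(abs(frame[pair[0]] - frame[pair[1]]))


def detect_cocontraction(rms_pos: float, rms_neg: float, cfg: SOAConfig) -> bool:
    """True when both sites simultaneously exceed the co-contraction threshold."""
    return (
        rms_pos > cfg.cocontraction_threshold
        and rms_neg > cfg.cocontraction_threshold
    )


def soa_velocity_update(
    state: CursorState,
    rms_pos: float,
    rms_neg: float,
    cfg: SOAConfig,
    dt: float,
    last_switch_time: float = -np.inf,
) -> tuple[CursorState, float]:
    """One sequential-control step.

    Returns the new state and the (possibly updated) last switch time.
    Priority: a co-contraction outside the refractory period toggles the
    active DoF and suppresses motion for the step; both sites above their
    individual thresholds without a co-contraction also freeze the cursor
    (ambiguous command); otherwise the supra-threshold site drives the
    active axis at ``gain * (rms - threshold)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t_new = state.t + dt
    if detect_cocontraction(rms_pos, rms_neg, cfg):
        if t_new - last_switch_time >= cfg.cocontraction_refractory:
            return (
                CursorState(
                    x=state.x, y=state.y, t=t_new,
                    active_dof=3 - state.active_dof,
                ),
                t_new,
            )
        return (replace(state, t=t_new), last_switch_time)

    above_pos = rms_pos > cfg.threshold_pos
    above_neg = rms_neg > cfg.threshold_neg
    if above_pos and above_neg:
        # both sites active but below the co-contraction level: no translation
        return (replace(state, t=t_new), last_switch_time)
    v = 0.0
    if above_pos:
        v = cfg.gain * (rms_pos - cfg.threshold_pos)
    elif above_neg:
        v = -cfg.gain * (rms_neg - cfg.threshold_neg)
    dx, dy = (v * dt, 0.0) if state.active_dof == 1 else (0.0, v * dt)
    x, y = clamp_position(state.x + dx, state.y + dy)
    return (
        CursorState(x=x, y=y, t=t_new, active_dof=state.active_dof),
        last_switch_time,
    )


class AENPositionController:
    """Stateful wrapper: feature frame -> cursor position in position mode.

    The mapping is memoryless in (c1, c2, rest); the object only tracks
    time so trial logs carry consistent timestamps.
    """

    def __init__(self, model: CalibratedModel, rest_threshold: float | None = None):
        self.model = model
        self.rest_threshold = (
            model.rest_threshold if rest_threshold is None else rest_threshold
        )
        self.state = CursorState()

    def reset(self) -> None:
        self.state = CursorState()

    def update(self, frame: np.ndarray, dt: float) -> tuple[float, float]:
        frame = np.asarray(frame, dtype=float)
        fs = FeatureSeries(
            values=frame[:, None],
            frame_rate=self.model.frame_rate,
            window_seconds=1.0 / self.model.frame_rate,
        )
        c1 = float(control_signal(self.model.mappings[0], fs)[0])
        c2 = float(control_signal(self.model.mappings[1], fs)[0])
        rest = detect_rest(frame, self.rest_threshold)
        x, y = aen_position_update(c1, c2, rest)
        self.state = CursorState(x=x, y=y, t=self.state.t + dt, active_dof=1)
        return (x, y)


class SOAVelocityController:
    """Stateful wrapper: feature frame -> cursor position in velocity mode."""

    def __init__(self, cfg: SOAConfig):
        self.cfg = cfg
        self.state = CursorState()
        self._last_switch = -np.inf

    def reset(self) -> None:
        self.state = CursorState()
        self._last_switch = -np.inf

    @property
    def active_dof(self) -> int:
        return self.state.active_dof

    def site_amplitudes(self, frame: np.ndarray) -> tuple[float, float]:
        frame = np.asarray(frame, dtype=float)
        return (
            bipolar_rms(frame, self.cfg.channel_pos),
            bipolar_rms(frame, self.cfg.channel_neg),
        )

    def update(self, frame: np.ndarray, dt: float) -> tuple[float, float]:
        rms_pos, rms_neg = self.site_amplitudes(frame)
        self.state, self._last_switch = soa_velocity_update(
            self.state, rms_pos, rms_neg, self.cfg, dt, self._last_switch
        )
        return (self.state.x, self.state.y)
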