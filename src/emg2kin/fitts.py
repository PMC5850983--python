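"""Fitts'-law target-acquisition task: headless trial engine and metrics.

The virtual task presents circular targets in a normalized workspace.  A
trial succeeds when the cursor stays continuously inside the target for the
dwell time (300 ms); it fails at the 20 s timeout.  Task difficulty follows
the Shannon formulation of Fitts' law,

    ID = log2(A / W + 1)        [bits]

with target width W = 0.08 (the target radius in task units) and amplitude

    A = (0.5 * gamma1 + 0.5 * gamma2)^2

where gamma1, gamma2 are the wrist angles (task units) the target demands on
the two DoFs.  The studied amplitudes A in {0.8, 1.2, 1.4} give the
difficulty levels 3.4, 4.0 and 4.2 bits (one decimal, truncated): small
displacements on both DoFs, a large displacement on one DoF, and large
displacements on both.

Six metrics summarize performance: completion rate, completion time,
overshoots, throughput ID/CT, speed (path length / CT) and path efficiency
(straight-line distance / path length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TargetSpec",
    "TrialLog",
    "MetricsReport",
    "target_amplitude",
    "index_of_difficulty",
    "truncate_id",
    "make_target",
    "generate_target_set",
    "run_trial",
    "log_from_trajectory",
    "count_overshoots",
    "path_length",
    "path_efficiency",
    "trial_speed",
    "throughput",
    "summarize",
    "rm_anova",
    "DEFAULT_WIDTH",
    "DEFAULT_AMPLITUDES",
    "DEFAULT_DWELL",
    "DEFAULT_TIMEOUT",
    "FRAME_RATE",
]

DEFAULT_WIDTH = 0.08
DEFAULT_AMPLITUDES = (0.8, 1.2, 1.4)
DEFAULT_DWELL = 0.3
DEFAULT_TIMEOUT = 20.0
FRAME_RATE = 10.0
#: Workspace distance per task-unit amplitude: target center sits at
#: distance_scale * (0.5*gamma1 + 0.5*gamma2) from the origin.
DEFAULT_DISTANCE_SCALE = 0.8


def target_amplitude(gamma1: float, gamma2: float) -> float:
    """Target amplitude A = (0.5*gamma1 + 0.5*gamma2)^2."""
    if gamma1 < 0 or gamma2 < 0:
        raise ValueError("required angles must be nonnegative")
    return (0.5 * gamma1 + 0.5 * gamma2) ** 2


def index_of_difficulty(amplitude: float, width: float) -> float:
    """Shannon index of difficulty ID = log2(A/W + 1), in bits."""
    if width <= 0:
        raise ValueError("target width must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    return math.log2(amplitude / width + 1.0)


def truncate_id(id_bits: float) -> float:
    """ID at one decimal, truncated toward zero (log2(11)=3.459... -> 3.4).

    Values are rounded at the ninth decimal first so that quantities that
    are exact in real arithmetic (log2(16) = 4.0) are not pulled down a
    notch by floating-point representation error.
    """
    return math.trunc(round(id_bits * 10.0, 9)) / 10.0


@dataclass
class TargetSpec:
    """One circular target of the task.

    ``width`` is the target radius; ``gamma1``/``gamma2`` the task-unit
    angles demanded of the two DoFs; ``center`` the workspace position.
    """

    center: tuple[float, float]
    width: float
    gamma1: float
    gamma2: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ValueError("gamma angles must be nonnegative")

    @property
    def amplitude(self) -> float:
        return target_amplitude(self.gamma1, self.gamma2)

    @property
    def id_bits(self) -> float:
        return index_of_difficulty(self.amplitude, self.width)

    @property
    def id_truncated(self) -> float:
        return truncate_id(self.id_bits)

    def contains(self, x: float, y: float) -> bool:
        return math.hypot(x - self.center[0], y - self.center[1]) <= self.width

    def to_dict(self) -> dict:
        return {
            "center": list(self.center),
            "width": self.width,
            "gamma1": self.gamma1,
            "gamma2": self.gamma2,
            "amplitude": self.amplitude,
            "id_bits": self.id_bits,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TargetSpec":
        return cls(
            center=tuple(d["center"]),
            width=d["width"],
            gamma1=d["gamma1"],
            gamma2=d["gamma2"],
        )


def make_target(
    gamma1: float,
    gamma2: float,
    signs: tuple[int, int] = (1, 1),
    width: float = DEFAULT_WIDTH,
    distance_scale: float = DEFAULT_DISTANCE_SCALE,
) -> TargetSpec:
    """Place a target for the demanded angles.

    The center lies at workspace distance ``distance_scale * sqrt(A)`` from
    the origin, along the direction given by the (signed) angle pair; a
    single-DoF target lies on its axis.
    """
    norm = math.hypot(gamma1, gamma2)
    if norm == 0:
        raise ValueError("at least one gamma must be positive")
    dist = distance_scale * (0.5 * gamma1 + 0.5 * gamma2)
    ux, uy = signs[0] * gamma1 / norm, signs[1] * gamma2 / norm
    return TargetSpec(
        center=(dist * ux, dist * uy), width=width, gamma1=gamma1, gamma2=gamma2
    )


def generate_target_set(
    a_values: Sequence[float] = DEFAULT_AMPLITUDES,
    n_targets: int = 20,
    width: float = DEFAULT_WIDTH,
    seed: int | None = None,
    distance_scale: float = DEFAULT_DISTANCE_SCALE,
) -> list[TargetSpec]:
    """Generate the session's target set (default: 20 targets, A in {0.8, 1.2, 1.4}).

    Amplitude levels cycle through the list; within a level, targets rotate
    through the four quadrants (or the four axis directions for single-DoF
    targets) and, for two-DoF targets, through several gamma1:gamma2 splits,
    so that completing the set demands activity on all DoFs and directions.
    The order is shuffled by ``seed``; the set itself is deterministic.
    """
    quadrants = [(1, 1), (-1, 1), (-1, -1), (1, -1)]
    axes = [(1, 1), (-1, 1), (1, 1), (-1, 1)]  # sign of the active axis
    splits = [0.5, 0.65, 0.35]
    targets: list[TargetSpec] = []
    counters = {a: 0 for a in a_values}
    for i in range(n_targets):
        a = a_values[i % len(a_values)]
        k = counters[a]
        counters[a] += 1
        root = 2.0 * math.sqrt(a)  # gamma1 + gamma2 for this amplitude
        if abs(a - 1.2) < 1e-12:
            # large displacement along only one DoF
            on_dof1 = k % 2 == 0
            sign = axes[k % 4][0] if k % 4 < 2 else -axes[k % 4][0]
            g1, g2 = (root, 0.0) if on_dof1 else (0.0, root)
            signs = (sign, 1) if on_dof1 else (1, sign)
        else:
            s = splits[k % len(splits)]
            g1, g2 = root * s, root * (1.0 - s)
            signs = quadrants[k % 4]
        targets.append(
            make_target(g1, g2, signs=signs, width=width,
                        distance_scale=distance_scale)
        )
    if seed is not None:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(targets))
        targets = [targets[i] for i in order]
    return targets


# ---------------------------------------------------------------------------
# Trial engine
# ---------------------------------------------------------------------------

@dataclass
class TrialLog:
    """Timestamped cursor trajectory plus task events for one trial.

    ``samples`` rows are (t, x, y) starting with the cursor position at the
    cue (t = 0).  ``entries``/``exits`` are the times of target entry and
    exit events; a successful trial ends at ``success_time`` (>= dwell after
    its final entry), a failed one at the timeout or at stream exhaustion.
    """

    target: TargetSpec
    samples: np.ndarray
    entries: list[float]
    exits: list[float]
    success: bool
    success_time: float | None
    timed_out: bool
    dwell_required: float = DEFAULT_DWELL
    timeout: float = DEFAULT_TIMEOUT
    cue_time: float = 0.0
    pinned_warning: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array of (t, x, y)")
        t = self.samples[:, 0]
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def xy(self) -> np.ndarray:
        return self.samples[:, 1:3]

    @property
    def completion_time(self) -> float | None:
        if not self.success:
            return None
        return self.success_time - self.cue_time

    def to_dict(self) -> dict:
        return {
            "target": self.target.to_dict(),
            "entries": self.entries,
            "exits": self.exits,
            "success": self.success,
            "success_time": self.success_time,
            "timed_out": self.timed_out,
            "dwell_required": self.dwell_required,
            "timeout": self.timeout,
            "pinned_warning": self.pinned_warning,
        }


FrameSource = Callable[[float, tuple[float, float]], np.ndarray]


def _as_frame_source(stream: Iterable[np.ndarray] | FrameSource):
    """Accept an iterable of frames (open loop) or a callable(t, pos) (closed loop)."""
    if callable(stream):
        return stream
    it: Iterator[np.ndarray] = iter(stream)

    def source(t: float, pos: tuple[float, float]) -> np.ndarray | None:
        return next(it, None)

    return source


def run_trial(
    controller,
    feature_stream: Iterable[np.ndarray] | FrameSource,
    target: TargetSpec,
    dwell: float = DEFAULT_DWELL,
    timeout: float = DEFAULT_TIMEOUT,
    frame_rate: float = FRAME_RATE,
) -> TrialLog:
    """Step ``controller`` against the task until success or timeout.

    ``feature_stream`` is either an iterable of feature frames (open loop)
    or a callable ``(t, cursor_pos) -> frame`` for a closed loop with a
    simulated user.  The trial starts at the cue (t = 0) from the
    controller's current position; success requires one continuous in-target
    interval of at least ``dwell`` seconds.  An open-loop stream that ends
    before success or timeout yields a failed, non-timed-out trial; an
    empty stream is an error.
    """
    if dwell <= 0 or timeout <= 0 or frame_rate <= 0:
        raise ValueError("dwell, timeout and frame_rate must be positive")
    source = _as_frame_source(feature_stream)
    dt = 1.0 / frame_rate

    x, y = getattr(controller, "state", None).position if hasattr(
        controller, "state"
    ) else (0.0, 0.0)
    rows = [(0.0, x, y)]
    entries: list[float] = []
    exits: list[float] = []
    inside = target.contains(x, y)
    entry_t = 0.0 if inside else None
    if inside:
        entries.append(0.0)
    success = False
    success_time: float | None = None
    timed_out = False
    t = 0.0
    n_steps = 0
    pinned_run = 0.0

    while True:
        frame = source(t, (x, y))
        if frame is None:
            if n_steps == 0:
                raise ValueError("empty feature stream: no frames to run")
            break
        t = round((n_steps + 1) * dt, 12)
        x, y = controller.update(np.asarray(frame, dtype=float), dt)
        rows.append((t, x, y))
        n_steps += 1

        if abs(x) >= WORKSPACE_BOUND_INTERNAL or abs(y) >= WORKSPACE_BOUND_INTERNAL:
            pinned_run += dt
        else:
            pinned_run = 0.0

        now_inside = target.contains(x, y)
        if now_inside and not inside:
            entries.append(t)
            entry_t = t
        elif not now_inside and inside:
            exits.append(t)
            entry_t = None
        inside = now_inside
        if inside and entry_t is not None and t - entry_t >= dwell - 1e-12:
            success = True
            success_time = t
            break
        if t >= timeout - 1e-12:
            timed_out = not success
            break

    return TrialLog(
        target=target,
        samples=np.array(rows),
        entries=entries,
        exits=exits,
        success=success,
        success_time=success_time,
        timed_out=timed_out,
        dwell_required=dwell,
        timeout=timeout,
        pinned_warning=pinned_run > 5.0,
    )


WORKSPACE_BOUND_INTERNAL = 1.0


class _ReplayController:
    """Replays a recorded (x, y) trajectory; lets the engine build a TrialLog."""

    def __init__(self, xy: np.ndarray, start: tuple[float, float]):
        self._xy = xy
        self._i = 0
        self.state = type("S", (), {"position": tuple(start)})()

    def update(self, frame: np.ndarray, dt: float) -> tuple[float, float]:
        x, y = self._xy[self._i]
        self._i += 1
        return (float(x), float(y))


def log_from_trajectory(
    xy: np.ndarray,
    target: TargetSpec,
    dwell: float = DEFAULT_DWELL,
    timeout: float = DEFAULT_TIMEOUT,
    frame_rate: float = FRAME_RATE,
) -> TrialLog:
    """Build a TrialLog from a precomputed trajectory.

    ``xy[0]`` is the position at the cue; the remaining rows are replayed at
    the frame rate through the same engine as a live trial, so dwell,
    timeout and event semantics are identical.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or len(xy) < 1:
        raise ValueError("xy must be an (n, 2) array with n >= 1")
    controller = _ReplayController(xy[1:], start=(xy[0, 0], xy[0, 1]))
    frames = [np.zeros(1)] * (len(xy) - 1)
    return run_trial(
        controller, frames, target, dwell=dwell, timeout=timeout,
        frame_rate=frame_rate,
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _inside_runs(log: TrialLog) -> list[tuple[float, float, bool]]:
    """Maximal in-target runs as (start_t, end_t, ended_by_exit)."""
    t = log.times
    inside = np.array([log.target.contains(px, py) for px, py in log.xy])
    runs: list[tuple[float, float, bool]] = []
    start: float | None = None
    for i in range(len(t)):
        if inside[i] and start is None:
            start = t[i]
        elif not inside[i] and start is not None:
            runs.append((start, t[i - 1], True))
            start = None
    if start is not None:
        runs.append((start, t[-1], False))
    return runs


def count_overshoots(log: TrialLog) -> int:
    """Entries into the target that ended (by exit) before the dwell completed.

    The terminal successful dwell is never counted; a run cut short by the
    end of the trial (timeout) did not pass *through* the target and is not
    counted either.
    """
    n = 0
    for start, end, ended_by_exit in _inside_runs(log):
        if not ended_by_exit:
            continue
        if end - start < log.dwell_required - 1e-12:
            n += 1
    return n


def _trajectory_to_success(log: TrialLog) -> np.ndarray:
    if log.success:
        mask = log.times <= log.success_time + 1e-12
        return log.xy[mask]
    return log.xy


def path_length(log: TrialLog) -> float:
    """Polyline length of the trajectory (up to success for completed trials)."""
    xy = _trajectory_to_success(log)
    if len(xy) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))


def path_efficiency(log: TrialLog) -> float:
    """Percent ratio of the straight-line distance to the realized path.

    The optimal path runs from the cursor position at the cue to the target
    center.  Capped at 100% (a trajectory that stops on the target perimeter
    travels marginally less than the center distance).
    """
    if not log.success:
        raise ValueError("path efficiency is defined for successful trials only")
    xy = _trajectory_to_success(log)
    straight = math.hypot(
        log.target.center[0] - xy[0, 0], log.target.center[1] - xy[0, 1]
    )
    length = path_length(log)
    if length <= 0:
        raise ValueError("zero trajectory length: cursor never moved")
    return min(100.0, 100.0 * straight / length)


def trial_speed(log: TrialLog) -> float:
    """Average cursor speed: path length / completion time (successful trials)."""
    if not log.success:
        raise ValueError("speed is defined for successful trials only")
    ct = log.completion_time
    if ct is None or ct <= 0:
        raise ValueError("completion time must be positive")
    return path_length(log) / ct


def throughput(id_bits: float, completion_time: float) -> float:
    """Information throughput TP = ID / CT, in bit/s."""
    if completion_time <= 0:
        raise ValueError("completion time must be positive")
    return id_bits / completion_time


@dataclass
class MetricsReport:
    """The six aggregate performance metrics over a set of trials."""

    n_trials: int
    n_successful: int
    completion_rate: float          # %
    completion_time: float          # s, mean over successful trials
    overshoots_total: int
    overshoots_per_trial: float
    throughput: float               # bit/s, mean over successful trials
    speed: float                    # workspace units / s
    path_efficiency: float          # %

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "n_successful": self.n_successful,
            "completion_rate": self.completion_rate,
            "completion_time": self.completion_time,
            "overshoots_total": self.overshoots_total,
            "overshoots_per_trial": self.overshoots_per_trial,
            "throughput": self.throughput,
            "speed": self.speed,
            "path_efficiency": self.path_efficiency,
        }


def summarize(logs: Sequence[TrialLog]) -> MetricsReport:
    """Aggregate the six metrics: rates over all trials, means over successes."""
    if not logs:
        raise ValueError("need at least one trial log")
    succ = [lg for lg in logs if lg.success]
    overshoots = [count_overshoots(lg) for lg in logs]
    ct = [lg.completion_time for lg in succ]
    tp = [throughput(lg.target.id_bits, lg.completion_time) for lg in succ]
    sp = [trial_speed(lg) for lg in succ]
    pe = [path_efficiency(lg) for lg in succ]
    mean = lambda v: float(np.mean(v)) if v else float("nan")
    return MetricsReport(
        n_trials=len(logs),
        n_successful=len(succ),
        completion_rate=100.0 * len(succ) / len(logs),
        completion_time=mean(ct),
        overshoots_total=int(np.sum(overshoots)),
        overshoots_per_trial=float(np.mean(overshoots)),
        throughput=mean(tp),
        speed=mean(sp),
        path_efficiency=mean(pe),
    )


def rm_anova(
    df: pd.DataFrame,
    dv: str,
    subject: str = "subject",
    within: Sequence[str] = ("method", "id"),
):
    """Two-way repeated-measures ANOVA (thin convenience wrapper).

    Expects one row per (subject, method, difficulty) cell with the metric in
    column ``dv``.  Delegates to ``statsmodels.stats.anova.AnovaRM`` and
    returns its fitted result; offered for exploratory comparisons of
    controller metrics, with no further validation.
    """
    from statsmodels.stats.anova import AnovaRM

    return AnovaRM(df, depvar=dv, subject=subject, within=list(within)).fit()
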