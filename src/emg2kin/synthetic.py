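"""Synthetic data: synergy-mixed EMG features, calibration sessions, users.

No public recordings accompany this control problem, so everything the
pipeline consumes can be generated here from a muscle-synergy model: the
R-channel RMS feature vector is a nonnegative mixture

    P(t) = H . g(t) + rest + noise,   clipped at 0

of four direction-specific activation time courses g(t) >= 0 (flexion,
extension, radial, ulnar — DoF1's then DoF2's directions) through an
R x 4 nonnegative mixing matrix H with smooth circular tuning around the
forearm.  Crosstalk leaks a fraction of each direction's drive into the
others.  Noise has two components: the sampling error of an RMS estimate
over a finite window, whose standard deviation is level / sqrt(2 L) for L
independent samples (heteroscedastic: quiet channels are quiet), plus a
small additive floor for electrode/electronics noise.  Noise is applied at
the feature level because the controller consumes RMS features; an
amplitude-modulated colored-noise generator for raw EMG is included for
exercising the feature-extraction stage.

A simulated user closes the loop for the target-acquisition task.  For
position control the user behaves like a practiced subject: a short
familiarization estimates the affine cursor response to signed drive on
each DoF (the adaptation real users perform), each reach starts with a
ballistic feedforward ramp toward the drive that should land on the target,
and a delayed visual feedback loop integrates corrections through the
inverted response.  For the sequential (SOA) baseline the user plays the
standard strategy — drive one axis at a time with the two measuring sites,
co-contract to switch DoF, relax to dwell — but entirely under delayed
visual servoing of an integrated cursor, with bang-bang drive and late
braking, which is what makes velocity control less path-efficient in
practice.  Muscle drive passes through first-order activation dynamics in
both modes.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .calibration import CalibrationSession
from .control import AENPositionController, SOAConfig, SOAVelocityController
from .features import EMGRecording, FeatureSeries
from .fitts import (
    DEFAULT_DWELL,
    DEFAULT_TIMEOUT,
    FRAME_RATE,
    TargetSpec,
    TrialLog,
    run_trial,
)

__all__ = [
    "DIRECTIONS",
    "SynergyGenerator",
    "SimulatedUser",
    "PlantModel",
    "default_mixing_matrix",
    "generate_features",
    "ramp_and_hold",
    "generate_calibration_session",
    "generate_raw_emg",
    "soa_config_from_generator",
    "familiarize_position_control",
    "simulate_trial",
    "simulate_session",
]

#: Direction order of the generator: DoF1 (+, -), then DoF2 (+, -).
DIRECTIONS = ("flexion", "extension", "radial", "ulnar")

#: Channel of peak response per direction on the default 16-channel ring.
_PEAK_CHANNELS = (0, 8, 4, 12)


def default_mixing_matrix(
    n_channels: int = 16, seed: int = 0, tuning_width: float = 2.0
) -> np.ndarray:
    """Smooth circular synergy tuning around the forearm.

    Each direction activates a Gaussian bump of channels centered on its
    peak channel (flexors and extensors on opposite sides of the ring, the
    deviators in between), with a small seeded gain jitter per entry so no
    two channels are exactly proportional.
    """
    rng = np.random.default_rng(seed)
    chan = np.arange(n_channels)
    centers = [round(c * n_channels / 16) for c in _PEAK_CHANNELS]
    cols = []
    for c in centers:
        d = np.minimum(np.abs(chan - c), n_channels - np.abs(chan - c))
        cols.append(np.exp(-0.5 * (d / tuning_width) ** 2))
    h = np.column_stack(cols)
    h *= rng.uniform(0.85, 1.15, size=h.shape)
    return h


@dataclass
class SynergyGenerator:
    """Feature-level generative model of a 16-channel forearm recording.

    ``rms_window_samples`` sets the heteroscedastic RMS-estimator noise
    (std = level / sqrt(2 L); 0 disables it), ``noise_sigma`` the additive
    noise floor, ``crosstalk`` the fraction of each direction's drive leaked
    uniformly into the other three, and ``rest_level`` the baseline RMS of
    an inactive channel (all in the same arbitrary RMS units; full-range
    drive is g = 1).
    """

    n_channels: int = 16
    noise_sigma: float = 0.005
    rms_window_samples: int = 204
    crosstalk: float = 0.05
    rest_level: float = 0.05
    seed: int = 0
    frame_rate: float = FRAME_RATE
    mixing: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.rms_window_samples < 0:
            raise ValueError("rms_window_samples must be >= 0")
        if not 0 <= self.crosstalk < 1:
            raise ValueError("crosstalk must be in [0, 1)")
        if self.rest_level < 0:
            raise ValueError("rest_level must be >= 0")
        if self.mixing is None:
            self.mixing = default_mixing_matrix(self.n_channels, self.seed)
        self.mixing = np.asarray(self.mixing, dtype=float)
        if self.mixing.shape != (self.n_channels, 4):
            raise ValueError(f"mixing must have shape ({self.n_channels}, 4)")
        if np.any(self.mixing < 0):
            raise ValueError("mixing matrix must be nonnegative")
        if np.any(self.mixing.sum(axis=0) == 0):
            raise ValueError("every direction needs a nonzero mixing column")

    @property
    def crosstalk_matrix(self) -> np.ndarray:
        ct = self.crosstalk
        return (1.0 - ct) * np.eye(4) + (ct / 3.0) * (np.ones((4, 4)) - np.eye(4))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def generate_features(
    gen: SynergyGenerator,
    g: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[FeatureSeries, np.ndarray]:
    """Mix direction drives into a feature series; returns (features, true g).

    ``g`` has shape (4, N) with nonnegative drives in direction order
    ``DIRECTIONS``.  Crosstalk is applied to the drives, then mixing, rest
    baseline and noise (RMS-estimator noise proportional to the level plus
    the additive floor); the result is clipped at zero.
    """
    g = np.atleast_2d(np.asarray(g, dtype=float))
    if g.shape[0] != 4:
        raise ValueError("g must have shape (4, N)")
    if np.any(g < 0):
        raise ValueError("direction drives must be nonnegative")
    if rng is None:
        rng = gen.rng()
    p = gen.mixing @ (gen.crosstalk_matrix @ g) + gen.rest_level
    sigma = np.full_like(p, gen.noise_sigma)
    if gen.rms_window_samples > 0:
        sigma = sigma + p / np.sqrt(2.0 * gen.rms_window_samples)
    if np.any(sigma > 0):
        p = p + rng.normal(0.0, 1.0, size=p.shape) * sigma
    p = np.clip(p, 0.0, None)
    fs = FeatureSeries(
        values=p,
        frame_rate=gen.frame_rate,
        window_seconds=1.0 / gen.frame_rate,
    )
    return fs, g


def ramp_and_hold(
    ramp_seconds: float,
    hold_seconds: float,
    frame_rate: float = FRAME_RATE,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Raised-cosine ramp up, hold, raised-cosine ramp down (one contraction)."""
    n_ramp = max(1, int(round(ramp_seconds * frame_rate)))
    n_hold = max(1, int(round(hold_seconds * frame_rate)))
    up = 0.5 * (1.0 - np.cos(np.pi * np.arange(1, n_ramp + 1) / n_ramp))
    hold = np.ones(n_hold)
    return amplitude * np.concatenate([up, hold, up[::-1]])


def generate_calibration_session(
    gen: SynergyGenerator,
    contractions_per_dof: int = 6,
    ramp_seconds: float = 2.5,
    hold_seconds: float = 5.0,
    rest_seconds: float = 5.0,
    amplitude: float = 1.0,
    label_threshold: float = 0.1,
) -> tuple[CalibrationSession, list[np.ndarray]]:
    """Synthesize the calibration protocol: per DoF, alternating full-range
    ramp-and-hold contractions separated by rest gaps.

    With the default timing each contraction occupies 15 s (2.5 s ramps,
    5 s hold, 5 s rest), so the default 6-contraction-per-DoF session lasts
    about 3 minutes in total.  Returns the session (with direction
    annotations derived from the generator's own drives) and the
    ground-truth drives, one (4, N) array per DoF, for recovery tests.
    """
    if contractions_per_dof < 1:
        raise ValueError("need at least one contraction per DoF")
    rng = gen.rng()
    profile = ramp_and_hold(ramp_seconds, hold_seconds, gen.frame_rate, amplitude)
    n_rest = max(1, int(round(rest_seconds * gen.frame_rate)))
    feats, anns, truths = [], [], []
    for dof in (0, 1):
        chunks = []
        for k in range(contractions_per_dof):
            direction = 2 * dof + (k % 2)  # alternate +, -, +, - ...
            seg = np.zeros((4, len(profile) + n_rest))
            seg[direction, : len(profile)] = profile
            chunks.append(seg)
        g = np.concatenate(chunks, axis=1)
        fs, _ = generate_features(gen, g, rng=rng)
        pos, neg = 2 * dof, 2 * dof + 1
        ann = np.zeros(g.shape[1], dtype=int)
        ann[g[pos] > label_threshold * amplitude] = 1
        ann[g[neg] > label_threshold * amplitude] = -1
        feats.append(fs)
        anns.append(ann)
        truths.append(g)
    return CalibrationSession(features=feats, annotations=anns), truths


def generate_raw_emg(
    gen: SynergyGenerator,
    g: np.ndarray,
    sampling_rate: float = 2048.0,
    band: tuple[float, float] = (20.0, 450.0),
    rng: np.random.Generator | None = None,
) -> EMGRecording:
    """Raw-EMG analogue of :func:`generate_features`.

    Band-limited white noise per channel, amplitude-modulated by the
    synergy-mixed envelope upsampled to the sampling rate; the RMS of a
    window tracks the envelope, so feeding the result through the
    feature-extraction stage recovers (approximately) the feature series the
    generator would emit directly.
    """
    g = np.atleast_2d(np.asarray(g, dtype=float))
    if g.shape[0] != 4:
        raise ValueError("g must have shape (4, N)")
    if rng is None:
        rng = gen.rng()
    envelope = gen.mixing @ (gen.crosstalk_matrix @ g) + gen.rest_level
    spw = int(round(sampling_rate / gen.frame_rate))  # samples per window
    env_up = np.repeat(envelope, spw, axis=1)
    n = env_up.shape[1]
    sos = _signal.butter(
        4, band, btype="bandpass", fs=sampling_rate, output="sos"
    )
    carrier = _signal.sosfiltfilt(
        sos, rng.standard_normal((gen.n_channels, n)), axis=1
    )
    carrier /= np.std(carrier, axis=1, keepdims=True)
    return EMGRecording(samples=env_up * carrier, sampling_rate=sampling_rate)


# ---------------------------------------------------------------------------
# Closed-loop simulated user
# ---------------------------------------------------------------------------

@dataclass
class SimulatedUser:
    """Feedback model of a practiced subject driving the cursor.

    Shared parameters: ``motor_noise`` (std of drive noise entering before
    the activation dynamics), ``saturation`` (maximum drive; 1 is the
    calibrated full range, brief efforts above it are allowed), and
    ``gain`` (integral feedback gain, 1/s).

    Position mode rides fast proprioception: a short ``reaction_delay``,
    quick ``activation_tau`` muscle dynamics and a ``ballistic_ramp``
    feedforward phase.  Velocity (SOA) mode is servoed visually over an
    integrated state, hence the longer ``soa_reaction_delay`` and
    ``soa_activation_tau``, with full drive until ``soa_brake_distance``
    from the axis goal, then ``soa_brake_level`` drive until within
    tolerance.
    """

    gain: float = 2.0
    reaction_delay: float = 0.2
    motor_noise: float = 0.02
    saturation: float = 1.5
    ballistic_ramp: float = 0.4
    activation_tau: float = 0.12
    soa_reaction_delay: float = 0.3
    soa_activation_tau: float = 0.2
    soa_brake_distance: float = 0.25
    soa_brake_level: float = 0.6

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.reaction_delay < 0 or self.soa_reaction_delay < 0:
            raise ValueError("reaction delays must be >= 0")
        if self.motor_noise < 0:
            raise ValueError("motor_noise must be >= 0")
        if self.saturation <= 0:
            raise ValueError("saturation must be positive")
        if self.activation_tau <= 0 or self.soa_activation_tau <= 0:
            raise ValueError("activation time constants must be positive")


@dataclass
class PlantModel:
    """User's internal affine model of the cursor response, from familiarization.

    ``offset`` and ``gain`` satisfy cursor ~ gain @ s + offset for signed
    per-DoF drive s; ``gain_inv`` is the user's inverse model.
    """

    offset: np.ndarray
    gain: np.ndarray
    gain_inv: np.ndarray


def _signed_to_drive(s: np.ndarray) -> np.ndarray:
    """Signed per-DoF drive (2,) -> nonnegative per-direction drive (4,)."""
    return np.array(
        [max(s[0], 0.0), max(-s[0], 0.0), max(s[1], 0.0), max(-s[1], 0.0)]
    )


def familiarize_position_control(
    user: SimulatedUser,
    gen: SynergyGenerator,
    controller: AENPositionController,
    rng: np.random.Generator,
    amplitudes: tuple[float, ...] = (0.4, 0.8),
    n_average: int = 5,
) -> PlantModel:
    """The user's practice phase: probe each DoF direction, fit an affine model.

    Applies steady signed drives of the given amplitudes on each DoF in both
    directions, averages the observed cursor position over ``n_average``
    frames, and least-squares fits cursor ~ G s + c0.  Mirrors the brief
    familiarization run real subjects get before the test.
    """
    dt = 1.0 / gen.frame_rate
    probes, observed = [], []
    for axis in (0, 1):
        for sign in (1.0, -1.0):
            for amp in amplitudes:
                s = np.zeros(2)
                s[axis] = sign * amp
                u = _signed_to_drive(s)
                pos = []
                for _ in range(n_average):
                    fs, _ = generate_features(gen, u[:, None], rng=rng)
                    pos.append(controller.update(fs.values[:, 0], dt))
                probes.append(s)
                observed.append(np.mean(pos, axis=0))
    controller.reset()
    x = np.column_stack([np.array(probes), np.ones(len(probes))])
    coef, *_ = np.linalg.lstsq(x, np.array(observed), rcond=None)
    g = coef[:2].T
    return PlantModel(offset=coef[2], gain=g, gain_inv=np.linalg.inv(g))


def _aen_frame_source(
    user: SimulatedUser,
    gen: SynergyGenerator,
    plant: PlantModel,
    target: TargetSpec,
    rng: np.random.Generator,
    frames_out: list[np.ndarray],
):
    """Closed-loop source for position mode: ballistic ramp + delayed correction."""
    dt = 1.0 / gen.frame_rate
    sat = user.saturation
    s_ff = np.clip(
        plant.gain_inv @ (np.array(target.center) - plant.offset), -sat, sat
    )
    corr = np.zeros(2)
    act = np.zeros(4)
    n_lag = int(round(user.reaction_delay / dt)) + 1
    buf = deque([(0.0, 0.0)] * n_lag, maxlen=n_lag)
    ramp_s = user.ballistic_ramp

    def source(t: float, pos: tuple[float, float]) -> np.ndarray:
        buf.append(pos)
        err = np.array(target.center) - np.array(buf[0])
        if t >= ramp_s + user.reaction_delay:
            corr[:] = corr + dt * user.gain * (plant.gain_inv @ err)
        ramp = min(1.0, t / ramp_s) if ramp_s > 0 else 1.0
        s = np.clip(ramp * s_ff + corr, -sat, sat)
        u = _signed_to_drive(s)
        if user.motor_noise > 0:
            u = np.clip(u + rng.normal(0.0, user.motor_noise, 4), 0.0, sat)
        act[:] = act + (dt / user.activation_tau) * (u - act)
        fs, _ = generate_features(gen, np.clip(act, 0.0, sat)[:, None], rng=rng)
        frame = fs.values[:, 0]
        frames_out.append(frame)
        return frame

    return source


def _soa_frame_source(
    user: SimulatedUser,
    gen: SynergyGenerator,
    controller: SOAVelocityController,
    target: TargetSpec,
    rng: np.random.Generator,
    frames_out: list[np.ndarray],
    position_tolerance: float,
):
    """Closed-loop source for the sequential baseline.

    The user moves the active axis toward its target coordinate with the
    two measuring sites (always the DoF1 muscles — the whole point of
    sequential control is that the same two sites drive whichever DoF is
    active), co-contracts to switch DoF when the active axis is done, and
    relaxes to dwell.  Co-contraction onset is imperfectly synchronized
    (one site leads by a frame), and braking is late and bang-bang, both of
    which real velocity-mode users exhibit.
    """
    dt = 1.0 / gen.frame_rate
    sat = user.saturation
    act = np.zeros(4)
    n_lag = int(round(user.soa_reaction_delay / dt)) + 1
    buf = deque([(0.0, 0.0)] * n_lag, maxlen=n_lag)
    cocon_frames = [0]

    def source(t: float, pos: tuple[float, float]) -> np.ndarray:
        buf.append(pos)
        ex = target.center[0] - buf[0][0]
        ey = target.center[1] - buf[0][1]
        err_active, err_other = (ex, ey) if controller.active_dof == 1 else (ey, ex)
        u = np.zeros(4)
        if abs(err_active) > position_tolerance:
            level = sat if abs(err_active) > user.soa_brake_distance else user.soa_brake_level
            u[0 if err_active > 0 else 1] = level
            cocon_frames[0] = 0
        elif abs(err_other) > position_tolerance:
            u[0] = sat  # leading site
            if cocon_frames[0] >= 1:
                u[1] = sat  # trailing site completes the co-contraction
            cocon_frames[0] += 1
        else:
            cocon_frames[0] = 0
        if user.motor_noise > 0:
            u = np.clip(u + rng.normal(0.0, user.motor_noise, 4), 0.0, sat)
        act[:] = act + (dt / user.soa_activation_tau) * (u - act)
        fs, _ = generate_features(gen, np.clip(act, 0.0, sat)[:, None], rng=rng)
        frame = fs.values[:, 0]
        frames_out.append(frame)
        return frame

    return source


def soa_config_from_generator(
    gen: SynergyGenerator,
    threshold_fraction: float = 0.15,
    cocontraction_fraction: float = 0.55,
    traverse_seconds: float = 2.5,
) -> SOAConfig:
    """Fit the sequential controller to the generator, mimicking prosthesis fitting.

    The two bipolar sites straddle the peak channels of the flexion and
    extension synergies.  Thresholds are a fraction of each site's response
    to a full single-direction contraction; the gain is chosen so a full
    drive traverses one workspace unit in ``traverse_seconds``.
    """
    r = gen.n_channels
    peaks = [int(np.argmax(gen.mixing[:, d])) for d in (0, 1)]
    pairs = [(p, (p + 2) % r) for p in peaks]
    responses = []
    for d, (a, b) in enumerate(pairs):
        g = np.zeros((4, 1))
        g[d, 0] = 1.0
        mixed = gen.mixing @ (gen.crosstalk_matrix @ g)
        responses.append(float(abs(mixed[a, 0] - mixed[b, 0])))
    thr = [threshold_fraction * v for v in responses]
    full = float(np.mean(responses))
    gain = 1.0 / (traverse_seconds * max(full - float(np.mean(thr)), 1e-9))
    return SOAConfig(
        channel_pos=pairs[0],
        channel_neg=pairs[1],
        threshold_pos=thr[0],
        threshold_neg=thr[1],
        gain=gain,
        cocontraction_threshold=cocontraction_fraction * full,
        cocontraction_refractory=0.5,
    )


def simulate_trial(
    user: SimulatedUser,
    gen: SynergyGenerator,
    controller,
    target: TargetSpec,
    dwell: float = DEFAULT_DWELL,
    timeout: float = DEFAULT_TIMEOUT,
    rng: np.random.Generator | None = None,
    plant: PlantModel | None = None,
) -> tuple[list[np.ndarray], TrialLog]:
    """Run one closed-loop trial; returns (feature frames, trial log).

    Deterministic under a fixed ``rng`` seed.  The controller is reset to
    the origin before the cue.  For position control a ``plant`` model from
    :func:`familiarize_position_control` can be passed (one per session);
    without it a fresh familiarization is run first.
    """
    if rng is None:
        rng = np.random.default_rng(gen.seed)
    frames: list[np.ndarray] = []
    if isinstance(controller, SOAVelocityController):
        controller.reset()
        source = _soa_frame_source(
            user, gen, controller, target, rng, frames,
            position_tolerance=0.6 * target.width,
        )
    elif isinstance(controller, AENPositionController):
        if plant is None:
            plant = familiarize_position_control(user, gen, controller, rng)
        controller.reset()
        source = _aen_frame_source(user, gen, plant, target, rng, frames)
    else:
        raise TypeError(f"unsupported controller type: {type(controller).__name__}")
    log = run_trial(
        controller, source, target, dwell=dwell, timeout=timeout,
        frame_rate=gen.frame_rate,
    )
    return frames, log


def simulate_session(
    user: SimulatedUser,
    gen: SynergyGenerator,
    controller,
    targets: list[TargetSpec],
    dwell: float = DEFAULT_DWELL,
    timeout: float = DEFAULT_TIMEOUT,
    seed: int = 0,
) -> list[TrialLog]:
    """Simulate a full session: one familiarization, then one trial per target.

    Each trial uses an independent child seed of ``seed``, so single trials
    can be reproduced without replaying the whole session.
    """
    children = np.random.SeedSequence(seed).spawn(len(targets) + 1)
    plant = None
    if isinstance(controller, AENPositionController):
        plant = familiarize_position_control(
            user, gen, controller, np.random.default_rng(children[0])
        )
    logs = []
    for target, child in zip(targets, children[1:]):
        _, log = simulate_trial(
            user, gen, controller, target, dwell=dwell, timeout=timeout,
            rng=np.random.default_rng(child), plant=plant,
        )
        logs.append(log)
    return logs
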