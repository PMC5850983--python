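"""Calibration: from fitted autoencoders to a signed, scaled 2-DoF control map.

A fitted autoencoder delivers two nonnegative hidden activations per DoF,
but leaves two things undetermined:

* **direction** — which hidden unit corresponds to the positive movement
  direction (flexion for DoF1, radial deviation for DoF2);
* **scale** — the rectified projection ``|IW . P|`` has arbitrary gain
  (scaling a row of IW up and the matching column of LW down leaves the
  reconstruction unchanged).

Both are resolved here from the calibration contractions.  Direction is
assigned from per-window direction annotations (+1 / -1 / 0 = rest) by mean
activation; scale via correction factors tau computed so that a high
quantile (default 0.95) of each unit's activation, over the windows where
that unit dominates, maps to the desired workspace range.  The signed
control signal for DoF i is then

    c_i(t) = tau_pos * a_pos(t) - tau_neg * a_neg(t)

which is positive for the "+" direction and spans roughly
[-target_range, +target_range] over the calibrated range of motion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autoencoder import (
    AENParams,
    ActivationSeries,
    FitResult,
    TrainConfig,
    extract_activations,
    fit_autoencoder,
    forward_hidden,
)
from .features import FeatureSeries

__all__ = [
    "CalibrationError",
    "CalibrationSession",
    "DoFMapping",
    "CalibratedModel",
    "compute_correction_factors",
    "assign_directions",
    "control_signal",
    "refine_range",
    "calibrate_dof",
    "calibrate_session",
    "save_model",
    "load_model",
]

#: Human-readable names of the positive/negative direction per DoF index.
DOF_DIRECTIONS = {1: ("flexion", "extension"), 2: ("radial", "ulnar")}


class CalibrationError(RuntimeError):
    """Raised when a calibration step cannot produce a usable mapping."""


@dataclass
class CalibrationSession:
    """Pooled calibration recordings for both DoFs.

    ``features[i]`` is the concatenation of the six calibration contractions
    of DoF ``i+1``; ``annotations[i]`` optionally labels each window with the
    intended direction (+1, -1, or 0 for rest).
    """

    features: list[FeatureSeries]
    annotations: list[np.ndarray | None] = field(default_factory=lambda: [None, None])

    def __post_init__(self) -> None:
        if len(self.features) != 2:
            raise ValueError("a calibration session covers exactly two DoFs")
        r0 = self.features[0].n_channels
        if self.features[1].n_channels != r0:
            raise ValueError("DoF feature series disagree on channel count")
        if len(self.annotations) != 2:
            raise ValueError("annotations must be given per DoF (use None)")
        for i, ann in enumerate(self.annotations):
            if ann is None:
                continue
            ann = np.asarray(ann, dtype=int)
            if ann.shape != (self.features[i].n_frames,):
                raise ValueError(
                    f"DoF{i + 1} annotations must label every window"
                )
            if not np.all(np.isin(ann, (-1, 0, 1))):
                raise ValueError("annotations must be in {-1, 0, +1}")
            self.annotations[i] = ann

    @property
    def n_channels(self) -> int:
        return self.features[0].n_channels


@dataclass
class DoFMapping:
    """Calibrated control map for one DoF.

    ``unit_for_positive`` names the hidden unit (0 or 1) assigned to the
    positive direction; the other unit drives the negative direction.
    ``direction_unverified`` is set when no annotations were available and
    the assignment is an arbitrary default (override with sign-flip flags).
    """

    dof_index: int
    iw: np.ndarray
    unit_for_positive: int
    tau_pos: float
    tau_neg: float
    direction_unverified: bool = False

    def __post_init__(self) -> None:
        self.iw = np.asarray(self.iw, dtype=float)
        if self.iw.ndim != 2 or self.iw.shape[0] != 2:
            raise ValueError("iw must have shape (2, R)")
        if self.unit_for_positive not in (0, 1):
            raise ValueError("unit_for_positive must be 0 or 1")
        if not (self.tau_pos > 0 and self.tau_neg > 0):
            raise ValueError("correction factors must be positive")

    @property
    def n_channels(self) -> int:
        return self.iw.shape[1]

    def flipped(self) -> "DoFMapping":
        """Mapping with the direction assignment reversed (manual override)."""
        return DoFMapping(
            dof_index=self.dof_index,
            iw=self.iw,
            unit_for_positive=1 - self.unit_for_positive,
            tau_pos=self.tau_neg,
            tau_neg=self.tau_pos,
            direction_unverified=self.direction_unverified,
        )


def _dominance_masks(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale-invariant unit dominance.

    Each unit's activation is normalized by its own peak before comparison:
    the raw scales of the two hidden units are arbitrary (the very
    indeterminacy the tau factors correct), so comparing them directly would
    let a small-scale unit "never dominate".  A window belongs to the unit
    whose normalized activation is larger.
    """
    peaks = a.max(axis=1)
    if np.any(peaks <= 0):
        dead = int(np.argmin(peaks))
        raise CalibrationError(
            f"hidden unit {dead + 1} is silent over the whole calibration "
            "set; cannot scale a dead unit"
        )
    rel = a / peaks[:, None]
    return rel[0] > rel[1], rel[1] > rel[0]


def compute_correction_factors(
    act: ActivationSeries,
    target_range: float = 1.0,
    quantile: float = 0.95,
) -> tuple[float, float]:
    """Correction factors (tau for unit 1, tau for unit 2).

    For each hidden unit j, tau_j = target_range / q, where q is the
    ``quantile``-th quantile of a_j over the calibration windows in which
    unit j dominates (see :func:`_dominance_masks`).  Using a high quantile
    rather than the maximum makes the scale robust to single outlier windows
    while still mapping a near-maximal contraction to ``target_range``.
    """
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    if target_range <= 0:
        raise ValueError("target_range must be positive")
    a = act.stacked
    masks = _dominance_masks(a)
    taus = []
    for j in (0, 1):
        mask = masks[j]
        if not np.any(mask):
            raise CalibrationError(
                f"hidden unit {j + 1} never dominates: dead or entangled unit"
            )
        q = float(np.quantile(a[j][mask], quantile))
        if q <= 0:
            raise CalibrationError(
                f"hidden unit {j + 1} has zero activation at the "
                f"{quantile:g} quantile; cannot scale a dead unit"
            )
        taus.append(target_range / q)
    return taus[0], taus[1]


def assign_directions(
    act: ActivationSeries,
    annotations: np.ndarray | None = None,
) -> tuple[int, bool]:
    """Map hidden units to movement directions.

    Returns ``(unit_for_positive, unverified)``.  With annotations, each
    unit goes to the direction over whose windows its mean activation is
    largest; if both units peak on the same direction the network is
    entangled and refitting is advised.  Without annotations the identity
    assignment (unit 0 -> positive) is returned with ``unverified=True``.
    """
    if annotations is None:
        return 0, True
    annotations = np.asarray(annotations, dtype=int)
    if annotations.shape != (act.n_frames,):
        raise ValueError("annotations must label every window")
    pos_mask = annotations == 1
    neg_mask = annotations == -1
    if not (np.any(pos_mask) and np.any(neg_mask)):
        raise CalibrationError(
            "annotations must include windows for both directions"
        )
    a = act.stacked
    # preferred direction of each unit: +1 if its mean activation is larger
    # on positive-direction windows
    prefer = [
        1 if float(a[j][pos_mask].mean()) >= float(a[j][neg_mask].mean()) else -1
        for j in (0, 1)
    ]
    if prefer[0] == prefer[1]:
        raise CalibrationError(
            "both hidden units respond maximally to the same direction; "
            "the network is entangled — refit with a different seed"
        )
    return (0 if prefer[0] == 1 else 1), False


def control_signal(mapping: DoFMapping, features: FeatureSeries) -> np.ndarray:
    """Signed control series c_i(t) = tau_pos * a_pos - tau_neg * a_neg."""
    act = extract_activations(mapping.iw, features)
    a = act.stacked
    jp = mapping.unit_for_positive
    return mapping.tau_pos * a[jp] - mapping.tau_neg * a[1 - jp]


def refine_range(
    mapping: DoFMapping,
    features: FeatureSeries,
    target_range: float = 1.0,
    quantile: float = 0.95,
    iterations: int = 12,
    relaxation: float = 0.5,
) -> DoFMapping:
    """Trim tau so the *realized* control signal spans the target range.

    The per-unit quantile rule scales each activation in isolation, but the
    signed control signal also carries the opposite unit's response during a
    contraction (the two rectified projections are not perfectly exclusive),
    so the realized range of c(t) undershoots the target.  This refinement
    — the automated counterpart of the per-subject fine-tuning a clinician
    performs — multiplies tau_pos (tau_neg) by the factor that brings the
    ``quantile``-th quantile of c (of -c) over the positive-unit-dominated
    (negative-unit-dominated) calibration windows to ``target_range``.
    Because each tau also enters the other direction's quantile through the
    cross-response, the full-step iteration can oscillate; the update is
    under-relaxed (factor raised to ``relaxation``), which converges in a
    handful of iterations.
    """
    m = mapping
    act = extract_activations(m.iw, features).stacked
    masks = _dominance_masks(act)
    for _ in range(iterations):
        jp = m.unit_for_positive
        dom_pos, dom_neg = masks[jp], masks[1 - jp]
        if not (np.any(dom_pos) and np.any(dom_neg)):
            raise CalibrationError(
                "one hidden unit dominates every calibration window; "
                "cannot calibrate the control range"
            )
        c = m.tau_pos * act[jp] - m.tau_neg * act[1 - jp]
        q_pos = float(np.quantile(c[dom_pos], quantile))
        q_neg = float(np.quantile(-c[dom_neg], quantile))
        if q_pos <= 0 or q_neg <= 0:
            raise CalibrationError(
                "realized control signal does not reach into both "
                "directions; refit advised"
            )
        m = DoFMapping(
            dof_index=m.dof_index,
            iw=m.iw,
            unit_for_positive=jp,
            tau_pos=m.tau_pos * (target_range / q_pos) ** relaxation,
            tau_neg=m.tau_neg * (target_range / q_neg) ** relaxation,
            direction_unverified=m.direction_unverified,
        )
    return m


def calibrate_dof(
    features: FeatureSeries,
    annotations: np.ndarray | None,
    config: TrainConfig,
    dof_index: int,
    target_range: float = 1.0,
    quantile: float = 0.95,
    refine: bool = True,
) -> tuple[DoFMapping, FitResult]:
    """Fit one DoF's autoencoder and derive its control map.

    ``refine`` applies :func:`refine_range` after the per-unit quantile
    rule so the realized signed control signal covers the target range.
    """
    fit = fit_autoencoder(features, config)
    act = forward_hidden(fit.params, features)
    unit_pos, unverified = assign_directions(act, annotations)
    tau1, tau2 = compute_correction_factors(act, target_range, quantile)
    taus = (tau1, tau2)
    mapping = DoFMapping(
        dof_index=dof_index,
        iw=fit.params.iw,
        unit_for_positive=unit_pos,
        tau_pos=taus[unit_pos],
        tau_neg=taus[1 - unit_pos],
        direction_unverified=unverified,
    )
    if refine:
        mapping = refine_range(mapping, features, target_range, quantile)
    return mapping, fit


@dataclass
class CalibratedModel:
    """Both DoF mappings plus the underlying networks and fit metadata."""

    mappings: list[DoFMapping]
    params: list[AENParams]
    frame_rate: float
    rest_threshold: float
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.mappings[0].n_channels

    def control_signals(self, features: FeatureSeries) -> np.ndarray:
        """2 x N array of signed control signals (c1; c2)."""
        return np.vstack(
            [control_signal(m, features) for m in self.mappings]
        )


def _rest_threshold_from_session(
    session: CalibrationSession, factor: float = 3.0
) -> float:
    """Rest threshold = ``factor`` x mean rest-window RMS (mean over channels).

    Falls back to ``factor`` x the 5th percentile of the channel-mean feature
    when no rest annotations exist.
    """
    rest_means = []
    for fs, ann in zip(session.features, session.annotations):
        chan_mean = fs.values.mean(axis=0)
        if ann is not None and np.any(ann == 0):
            rest_means.append(chan_mean[ann == 0].mean())
        else:
            rest_means.append(np.quantile(chan_mean, 0.05))
    return float(factor * np.mean(rest_means))


def calibrate_session(
    session: CalibrationSession,
    config: TrainConfig,
    target_range: float = 1.0,
    quantile: float = 0.95,
    refine: bool = True,
) -> CalibratedModel:
    """Calibrate both DoFs from a pooled calibration session.

    Each DoF gets its own multi-restart fit (DoF ``i`` uses child seed
    ``config.seed + i`` so the two fits are independent but reproducible).
    """
    mappings: list[DoFMapping] = []
    params: list[AENParams] = []
    meta: dict = {"seed": config.seed, "dofs": []}
    for i, (fs, ann) in enumerate(zip(session.features, session.annotations)):
        cfg_i = TrainConfig(
            **{**config.__dict__, "seed": config.seed + i}
        )
        mapping, fit = calibrate_dof(
            fs, ann, cfg_i, dof_index=i + 1, target_range=target_range,
            quantile=quantile, refine=refine,
        )
        mappings.append(mapping)
        params.append(fit.params)
        meta["dofs"].append(
            {
                "dof_index": i + 1,
                "sse": fit.sse,
                "selection_correlation": fit.selection_correlation,
                "restart_correlations": fit.restart_correlations,
                "n_failed_restarts": fit.n_failed,
                "seed": cfg_i.seed,
            }
        )
    return CalibratedModel(
        mappings=mappings,
        params=params,
        frame_rate=session.features[0].frame_rate,
        rest_threshold=_rest_threshold_from_session(session),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Model persistence (JSON)
# ---------------------------------------------------------------------------

_MODEL_FORMAT = "emg2kin-model"
_MODEL_VERSION = 1


def save_model(model: CalibratedModel, path: str | Path) -> None:
    doc = {
        "format": _MODEL_FORMAT,
        "version": _MODEL_VERSION,
        "n_channels": model.n_channels,
        "frame_rate": model.frame_rate,
        "rest_threshold": model.rest_threshold,
        "meta": model.meta,
        "dofs": [
            {
                "dof_index": m.dof_index,
                "unit_for_positive": m.unit_for_positive,
                "tau_pos": m.tau_pos,
                "tau_neg": m.tau_neg,
                "direction_unverified": m.direction_unverified,
                "params": p.to_dict(),
            }
            for m, p in zip(model.mappings, model.params)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> CalibratedModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path}: not an {_MODEL_FORMAT} file")
    mappings, params = [], []
    for d in doc["dofs"]:
        p = AENParams.from_dict(d["params"])
        mappings.append(
            DoFMapping(
                dof_index=d["dof_index"],
                iw=p.iw,
                unit_for_positive=d["unit_for_positive"],
                tau_pos=d["tau_pos"],
                tau_neg=d["tau_neg"],
                direction_unverified=d["direction_unverified"],
            )
        )
        params.append(p)
    return CalibratedModel(
        mappings=mappings,
        params=params,
        frame_rate=doc["frame_rate"],
        rest_threshold=doc["rest_threshold"],
        meta=doc.get("meta", {}),
    )
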