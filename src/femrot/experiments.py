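"""Verification and validation harnesses, agreement metrics, and reporting.

Two protocols establish the accuracy of the rotation-change pipeline
against the twist simulator's ground truth:

* **verification** — each later-scan bone is compared against its own
  artificially twisted copy, isolating the registration machinery from
  growth and inter-subject shape differences;
* **validation** — every earlier scan is compared against every (possibly
  other-subject) twisted later scan; the growth/shape baseline measured on
  the untwisted pair is removed before comparing with the nominal twist.
  With ``n`` subjects and ``k`` twist angles this is ``n * n * k``
  registration experiments (484 for n=11, k=4).

Twists are simultaneous tri-axial (a, a, a) by default; per-axis single
twists are available for comparison. Detected angles are summarized as
percentages of the true angle (mean, sd, detection error, mean absolute
error, coefficient of variation) and as Bland-Altman agreement statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .delta_fr import assess_delta_fr, growth_correct
from .mesh_core import EULER_XYZ, RotationTriple, principal_frame
from .registration import IcpParams
from .synthetic_bone import Subject
from .twist import TwistSpec, apply_virtual_twist

__all__ = [
    "ExperimentRecord",
    "MetricsSummary",
    "BlandAltman",
    "validation_plan",
    "run_verification",
    "run_validation",
    "normalized_detection",
    "records_to_dataframe",
    "summarize",
    "bland_altman",
    "coefficient_of_variation",
    "save_bland_altman_plot",
]

_AXES = ("x", "y", "z")


@dataclass
class ExperimentRecord:
    """One registration experiment: a (bone pair, twist angle) trial."""

    protocol: str  # "verification" | "validation"
    subject_w0: str
    subject_w12: str
    same_subject: bool
    nominal_angle: float
    true_angles: RotationTriple
    detected_angles: RotationTriple
    corrected_angles: RotationTriple
    baseline_angles: RotationTriple | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def normalized_pct(self) -> dict[str, float]:
        return normalized_detection(self)


def normalized_detection(record: ExperimentRecord) -> dict[str, float]:
    """Detected angle as a percentage of the true angle, per axis.

    Axes with a zero true angle are omitted (the ratio is undefined).
    Uses the growth-corrected angles, which for verification equal the
    raw detected angles.
    """
    true = record.true_angles.as_array()
    detected = record.corrected_angles.as_array()
    return {
        axis: 100.0 * float(detected[i]) / float(true[i])
        for i, axis in enumerate(_AXES)
        if true[i] != 0.0
    }


def _twist_specs(angle: float, tri_axial: bool) -> list[tuple[float, float, float]]:
    if tri_axial:
        return [(angle, angle, angle)]
    return [(angle, 0.0, 0.0), (0.0, angle, 0.0), (0.0, 0.0, angle)]


def run_verification(
    subjects: list[Subject],
    angles: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0),
    params: IcpParams | None = None,
    tri_axial: bool = True,
) -> list[ExperimentRecord]:
    """Same-bone twist recovery: W12 vs artificially twisted W12.

    For each subject's later scan and each nominal angle, applies the
    virtual twist (tri-axial ``(a, a, a)`` by default), measures the
    rotation change between the untwisted and twisted bone, and records
    the detected angles. Angles are reported in the frame of the
    untwisted bone — the frame the twist itself was defined in.
    """
    if any(a <= 0 for a in angles):
        raise ValueError("twist angles must be positive")
    params = params or IcpParams()
    records: list[ExperimentRecord] = []
    for subject in subjects:
        w12 = subject.w12
        frame = principal_frame(w12)
        for angle in angles:
            for ax, ay, az in _twist_specs(angle, tri_axial):
                twisted = apply_virtual_twist(w12, frame, TwistSpec(angles=(ax, ay, az)))
                delta = assess_delta_fr(w12, twisted, params=params, reference_frame=frame)
                records.append(
                    ExperimentRecord(
                        protocol="verification",
                        subject_w0=subject.subject_id,
                        subject_w12=subject.subject_id,
                        same_subject=True,
                        nominal_angle=angle,
                        true_angles=RotationTriple(ax, ay, az, EULER_XYZ),
                        detected_angles=delta.components_euler,
                        corrected_angles=delta.components_euler,
                        diagnostics=_diagnostics(delta),
                    )
                )
    return records


def validation_plan(
    n_subjects: int, angles: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)
) -> list[tuple[int, int, float]]:
    """Experiment design of the validation protocol: every ordered pair of
    subjects crossed with every angle — ``n * n * len(angles)`` trials."""
    return [
        (i, j, float(a))
        for i in range(n_subjects)
        for j in range(n_subjects)
        for a in angles
    ]


def run_validation(
    subjects: list[Subject],
    angles: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0),
    params: IcpParams | None = None,
    tri_axial: bool = True,
    correction_mode: str = "compose",
) -> list[ExperimentRecord]:
    """Cross-subject, cross-time-point twist recovery with growth correction.

    For each ordered subject pair (i, j): measure the untwisted baseline
    rotation change between W0 of subject i and W12 of subject j once,
    then for each angle measure the change against the twisted W12 and
    remove the baseline. The baseline is computed once per pair and
    shared across angles, and each twisted assessment is warm-started
    from the baseline's initial alignment so that the shape-mismatch
    bias of a cross-subject pair repeats between the two measurements
    and cancels in the correction. Pairs with i == j are flagged
    ``same_subject``.
    """
    if any(a <= 0 for a in angles):
        raise ValueError("twist angles must be positive")
    params = params or IcpParams()
    records: list[ExperimentRecord] = []
    frames = [principal_frame(s.w12) for s in subjects]
    for i, si in enumerate(subjects):
        for j, sj in enumerate(subjects):
            frame = frames[j]
            baseline = assess_delta_fr(si.w0, sj.w12, params=params, reference_frame=frame)
            for angle in angles:
                for ax, ay, az in _twist_specs(angle, tri_axial):
                    twisted = apply_virtual_twist(sj.w12, frame, TwistSpec(angles=(ax, ay, az)))
                    delta = assess_delta_fr(
                        si.w0,
                        twisted,
                        params=params,
                        reference_frame=frame,
                        warm_start=baseline,
                    )
                    corrected = growth_correct(delta, baseline, mode=correction_mode)
                    records.append(
                        ExperimentRecord(
                            protocol="validation",
                            subject_w0=si.subject_id,
                            subject_w12=sj.subject_id,
                            same_subject=i == j,
                            nominal_angle=angle,
                            true_angles=RotationTriple(ax, ay, az, EULER_XYZ),
                            detected_angles=delta.components_euler,
                            corrected_angles=corrected,
                            baseline_angles=baseline.components_euler,
                            diagnostics=_diagnostics(delta),
                        )
                    )
    return records


def _diagnostics(delta) -> dict:
    return {
        "rms_initial": delta.initial_result.rms,
        "rms_proximal": delta.proximal_result.rms,
        "rms_distal": delta.distal_result.rms,
        "iterations_initial": delta.initial_result.iterations,
        "warnings": "; ".join(delta.warnings),
    }


def records_to_dataframe(records: list[ExperimentRecord]) -> pd.DataFrame:
    """One row per trial with per-axis true/detected/baseline/corrected
    columns plus normalized percentages and registration diagnostics."""
    rows = []
    for rec in records:
        row = {
            "protocol": rec.protocol,
            "subject_w0": rec.subject_w0,
            "subject_w12": rec.subject_w12,
            "same_subject": rec.same_subject,
            "nominal_angle": rec.nominal_angle,
        }
        for i, axis in enumerate(_AXES):
            row[f"true_{axis}"] = rec.true_angles.as_array()[i]
            row[f"detected_{axis}"] = rec.detected_angles.as_array()[i]
            row[f"corrected_{axis}"] = rec.corrected_angles.as_array()[i]
            if rec.baseline_angles is not None:
                row[f"baseline_{axis}"] = rec.baseline_angles.as_array()[i]
        for axis, pct in rec.normalized_pct.items():
            row[f"norm_{axis}"] = pct
        row.update(rec.diagnostics)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float


def bland_altman(
    true_values: np.ndarray, detected_values: np.ndarray, relative: bool = False
) -> BlandAltman:
    """Mean difference and 95% limits of agreement (mean +/- 1.96 sd).

    Differences are ``true - detected`` in degrees, or as a percentage of
    the true value when ``relative`` (used for the same-bone protocol,
    where errors scale with the angle). Sample (n-1) standard deviation.
    """
    t = np.asarray(true_values, dtype=np.float64)
    d = np.asarray(detected_values, dtype=np.float64)
    if t.shape != d.shape or t.ndim != 1:
        raise ValueError("true and detected must be equal-length 1D arrays")
    if t.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    diff = t - d
    if relative:
        diff = 100.0 * diff / t
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltman(mean, mean - 1.96 * sd, mean + 1.96 * sd)


def coefficient_of_variation(values: np.ndarray) -> float:
    """100 * sample sd / mean of a measurement distribution."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("coefficient of variation needs at least 2 values")
    return 100.0 * float(v.std(ddof=1)) / float(v.mean())


@dataclass(frozen=True)
class MetricsSummary:
    """Aggregate accuracy statistics over a group of trials.

    All percentages refer to normalized detection (detected/true * 100):
    ``detection_error_pct`` is the absolute deviation of the *mean*
    normalized angle from 100%, ``mean_absolute_error_pct`` averages the
    per-trial absolute deviations. Bland-Altman statistics are over
    (true, detected) pairs in degrees (or relative percent).
    """

    group: tuple
    n: int
    mean_normalized_pct: float
    sd_normalized_pct: float
    detection_error_pct: float
    mean_absolute_error_pct: float
    sd_absolute_error_pct: float
    cov_pct: float
    bland_altman_mean: float
    bland_altman_loa_low: float
    bland_altman_loa_high: float

    def __post_init__(self) -> None:
        if not self.bland_altman_loa_low <= self.bland_altman_mean <= self.bland_altman_loa_high:
            raise ValueError("limits of agreement must bracket the mean")
        if self.cov_pct < 0 and not math.isnan(self.cov_pct):
            raise ValueError("cov_pct must be non-negative")


def _long_table(records: list[ExperimentRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-(trial, axis) rows with true, detected and normalized values."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_dataframe(records)
    parts = []
    for axis in _AXES:
        if f"norm_{axis}" not in df.columns:
            continue
        sub = df[df[f"true_{axis}"] != 0.0]
        parts.append(
            pd.DataFrame(
                {
                    "protocol": sub["protocol"],
                    "same_subject": sub["same_subject"],
                    "axis": axis,
                    "true_angle": sub[f"true_{axis}"],
                    "detected": sub[f"corrected_{axis}"],
                    "normalized": sub[f"norm_{axis}"],
                }
            )
        )
    if not parts:
        raise ValueError("no axes with non-zero true angles")
    return pd.concat(parts, ignore_index=True)


def _summary_from_long(long: pd.DataFrame, group: tuple, ba_relative: bool) -> MetricsSummary:
    if len(long) < 2:
        raise ValueError("summary group needs at least 2 trials")
    norm = long["normalized"].to_numpy()
    mean = float(norm.mean())
    sd = float(norm.std(ddof=1))
    abs_err = np.abs(norm - 100.0)
    ba = bland_altman(long["true_angle"].to_numpy(), long["detected"].to_numpy(), relative=ba_relative)
    return MetricsSummary(
        group=group,
        n=len(long),
        mean_normalized_pct=mean,
        sd_normalized_pct=sd,
        detection_error_pct=abs(mean - 100.0),
        mean_absolute_error_pct=float(abs_err.mean()),
        sd_absolute_error_pct=float(abs_err.std(ddof=1)),
        cov_pct=coefficient_of_variation(norm),
        bland_altman_mean=ba.mean_diff,
        bland_altman_loa_low=ba.loa_low,
        bland_altman_loa_high=ba.loa_high,
    )


def summarize(
    records: list[ExperimentRecord] | pd.DataFrame,
    group_by: tuple[str, ...] | None = None,
    ba_relative: bool | None = None,
) -> MetricsSummary | dict[tuple, MetricsSummary]:
    """Accuracy statistics over trials, optionally grouped.

    ``group_by`` may name any of ``axis``, ``true_angle``, ``protocol``,
    ``same_subject``. ``ba_relative`` chooses relative (percent) versus
    absolute (degree) Bland-Altman differences; by default it is relative
    exactly when all records are from the verification protocol.
    """
    long = _long_table(records)
    if ba_relative is None:
        ba_relative = bool((long["protocol"] == "verification").all())
    if not group_by:
        return _summary_from_long(long, group=(), ba_relative=ba_relative)
    for key in group_by:
        if key not in long.columns:
            raise ValueError(f"unknown group key {key!r}")
    out: dict[tuple, MetricsSummary] = {}
    for key, sub in long.groupby(list(group_by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        out[key] = _summary_from_long(sub, group=key, ba_relative=ba_relative)
    return out


def save_bland_altman_plot(
    records: list[ExperimentRecord] | pd.DataFrame, path: str, relative: bool | None = None
) -> None:
    """Simple Bland-Altman scatter (difference vs true angle) to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    long = _long_table(records)
    if relative is None:
        relative = bool((long["protocol"] == "verification").all())
    t = long["true_angle"].to_numpy()
    d = long["detected"].to_numpy()
    diff = 100.0 * (t - d) / t if relative else t - d
    ba = bland_altman(t, d, relative=relative)
    fig, ax = plt.subplots(figsize=(6, 4))
    for axis, marker in zip(_AXES, ("o", "s", "^")):
        m = (long["axis"] == axis).to_numpy()
        ax.scatter(t[m], diff[m], s=12, marker=marker, label=axis.upper(), alpha=0.6)
    ax.axhline(ba.mean_diff, color="k", lw=1)
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="grey", ls="--", lw=1)
    ax.set_xlabel("true angle (deg)")
    ax.set_ylabel("true - detected (%)" if relative else "true - detected (deg)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
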