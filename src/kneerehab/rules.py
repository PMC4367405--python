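"""Rule-based detection of improper exercise postures.

Each exercise has a nominal target posture; a repetition is flagged when a
measured angle leaves the clinically tolerated band around that nominal.
Tolerances (degrees):

===============================  =======  =========
measure                          nominal  tolerance
===============================  =======  =========
SAE initial knee flexion           25        7
SAE shank terminal angle            0        7
SLR thigh raising angle            45       10
SLR knee flexion                    0       20
SLR hip external rotation           0       20
QSM trunk bent forward              0       15
QSM squat angle                    45       15
===============================  =======  =========

All applicable checks run on every repetition, so multiple simultaneous
errors are reported together; the hierarchical check order only fixes how
errors are listed, never whether they are reported.  Flagging uses strict
inequality: a measure exactly at the tolerance is still acceptable.
"""

from __future__ import annotations

import dataclasses
import logging

from .kinematics import AngleMeasures

logger = logging.getLogger(__name__)

#: exercise-scoped error labels, in hierarchical reporting order
ERROR_LABELS: dict[str, tuple[str, ...]] = {
    "SAE": ("initial_flexion_excess", "knee_not_extended"),
    "SLR": ("knee_not_extended", "hip_external_rotation", "raise_angle_deviation"),
    "QSM": ("trunk_bent_forward", "squat_angle_deviation"),
}


@dataclasses.dataclass
class ThresholdConfig:
    """Error tolerances and nominal reference angles, degrees.

    ``sae_initial_flexion_additive`` selects whether the SAE initial-flexion
    rule flags above nominal + tolerance (25 + 7, the default) or above the
    bare nominal (25).
    """

    shank_terminal_sae: float = 7.0
    knee_initial_flexion_sae: float = 7.0
    thigh_raise_slr: float = 10.0
    trunk_bend_qsm: float = 15.0
    squat_qsm: float = 15.0
    knee_flexion_slr: float = 20.0
    hip_external_rotation_slr: float = 20.0

    slr_raise_nominal: float = 45.0
    qsm_squat_nominal: float = 45.0
    sae_initial_flexion_nominal: float = 25.0
    full_extension_nominal: float = 0.0
    upright_trunk_nominal: float = 0.0

    sae_initial_flexion_additive: bool = True

    def validate(self) -> None:
        for name in (
            "shank_terminal_sae",
            "knee_initial_flexion_sae",
            "thigh_raise_slr",
            "trunk_bend_qsm",
            "squat_qsm",
            "knee_flexion_slr",
            "hip_external_rotation_slr",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"tolerance {name} must be > 0")


@dataclasses.dataclass
class AssessmentResult:
    """Predicted exercise type, detected posture errors and the raw measures."""

    exercise: str
    errors: tuple[str, ...]
    measures: AngleMeasures

    @property
    def is_proper(self) -> bool:
        return not self.errors

    @property
    def error_set(self) -> frozenset[str]:
        return frozenset(self.errors)


def assess_repetition(
    exercise: str,
    measures: AngleMeasures,
    thresholds: ThresholdConfig | None = None,
) -> AssessmentResult:
    """Apply the exercise's posture rules to one repetition's angle measures.

    Every applicable rule is evaluated (multiple errors may be reported);
    the returned error tuple follows the hierarchical reporting order of
    :data:`ERROR_LABELS`.
    """
    t = thresholds or ThresholdConfig()
    t.validate()
    flagged: set[str] = set()

    if exercise == "SAE":
        limit = t.sae_initial_flexion_nominal
        if t.sae_initial_flexion_additive:
            limit += t.knee_initial_flexion_sae
        if measures.knee_initial_flexion > limit:
            flagged.add("initial_flexion_excess")
        if abs(measures.shank_terminal - t.full_extension_nominal) > t.shank_terminal_sae:
            flagged.add("knee_not_extended")
    elif exercise == "SLR":
        if measures.knee_flexion > t.knee_flexion_slr:
            flagged.add("knee_not_extended")
        if abs(measures.hip_external_rotation) > t.hip_external_rotation_slr:
            flagged.add("hip_external_rotation")
        if abs(measures.thigh_raise - t.slr_raise_nominal) > t.thigh_raise_slr:
            flagged.add("raise_angle_deviation")
    elif exercise == "QSM":
        if measures.trunk_bend - t.upright_trunk_nominal > t.trunk_bend_qsm:
            flagged.add("trunk_bent_forward")
        if abs(measures.squat_angle - t.qsm_squat_nominal) > t.squat_qsm:
            flagged.add("squat_angle_deviation")
    else:
        raise ValueError(f"unknown exercise '{exercise}'")

    ordered = tuple(lbl for lbl in ERROR_LABELS[exercise] if lbl in flagged)
    return AssessmentResult(exercise=exercise, errors=ordered, measures=measures)


def assess_session(session, model, thresholds=None, pipeline_config=None) -> list:
    """Full per-repetition pipeline on one raw session.

    preprocess -> segment -> angle measures -> features -> classify exercise
    type -> posture rules.  ``model`` is a trained
    :class:`~kneerehab.classifier.TreeModel` (or any object with a
    compatible ``predict_one``); results are ordered by repetition.  Returns
    an empty list (with a warning) when no repetitions are found.
    """
    from .config import PipelineConfig
    from .features import build_feature_vector
    from .kinematics import angle_measures
    from .preprocess import preprocess_session
    from .segmentation import segment_session
    from . import classifier as _clf

    config = pipeline_config or PipelineConfig()
    thresholds = thresholds or config.thresholds
    prepped = preprocess_session(session, config.filters)
    reps = segment_session(prepped, config.segmentation)
    if not reps:
        logger.warning("assess_session: no repetitions in session, nothing to assess")
        return []
    results = []
    for rep in reps:
        measures = angle_measures(prepped, rep, params=config.kinematics)
        fv = build_feature_vector(prepped, rep, measures, config.features)
        exercise = _clf.predict(model, fv)
        result = assess_repetition(exercise, measures, thresholds)
        results.append((rep, result))
    return results
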