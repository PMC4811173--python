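"""The dramatyping decision cascade.

The cascade classifies one medication episode into ``temporal correlation``,
``no change`` or ``no assessment`` by running up to 18 ordered tests; each
test is only evaluated if every previous test ended without a classification,
so the sequential order is essential.

Step layout (the step index reported in results):

====  ===========================  ==========================================
step  data variant                 test → label on fire
====  ===========================  ==========================================
1     observed values              optional pre-check: all in [0..1] → no change
2–5   gap-filled raw values        main loop pass 1 (ML1–ML4)
6–9   low-pass filtered values     main loop pass 2
10–13 outliers removed + low-pass  main loop pass 3
14    low-pass filtered values     pre-phase edge, mid & post flat → no change
15    low-pass filtered values     pre-phase edge + mid/post edge → no assessment
16    outliers removed             no deviation from the mean → no change
17    gap-filled raw values        zig-zag → no assessment
18    —                            default → temporal correlation
====  ===========================  ==========================================

The four main-loop tests are, in order:

ML1
    curve constant in the pre-phase but no longer on that level in
    mid/post, and the phase means differ → temporal correlation;
ML2
    whole curve linear → no change;
ML3
    mid/post curve linear → no change;
ML4
    phase means differ → temporal correlation.

A main-loop test whose data requirements fail (empty pre-phase, too few
points) is skipped, not fired, and the cascade continues.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    NO_ASSESSMENT,
    NO_CHANGE,
    TEMPORAL_CORRELATION,
    AlgorithmParameters,
    ClassificationResult,
    LabValueEpisode,
    PhasePartition,
    TraceRecord,
    partition_phases,
)
from .signal_ops import (
    FLAT,
    NotEnoughDataError,
    WeightedSeries,
    constant_residual_about,
    detect_edge,
    deviates_from_mean,
    fill_gaps,
    fit_and_test,
    gaussian_lowpass,
    is_zigzag,
    phase_means_differ,
    remove_outliers,
)

__all__ = [
    "STEP_TABLE",
    "MIN_OBSERVED_VALUES",
    "precheck_in_reference_range",
    "main_loop_pass",
    "classify_episode",
    "classify_corpus",
]

logger = logging.getLogger(__name__)

#: Fixed step → resulting-label mapping of the 18-step cascade.
STEP_TABLE: Dict[int, str] = {
    1: NO_CHANGE,
    2: TEMPORAL_CORRELATION,
    3: NO_CHANGE,
    4: NO_CHANGE,
    5: TEMPORAL_CORRELATION,
    6: TEMPORAL_CORRELATION,
    7: NO_CHANGE,
    8: NO_CHANGE,
    9: TEMPORAL_CORRELATION,
    10: TEMPORAL_CORRELATION,
    11: NO_CHANGE,
    12: NO_CHANGE,
    13: TEMPORAL_CORRELATION,
    14: NO_CHANGE,
    15: NO_ASSESSMENT,
    16: NO_CHANGE,
    17: NO_ASSESSMENT,
    18: TEMPORAL_CORRELATION,
}

#: Episodes with fewer observed values are assigned "no assessment" outright.
MIN_OBSERVED_VALUES = 3

_ML_NAMES = (
    "ML1 pre-phase constant, shifted in mid/post",
    "ML2 whole curve linear",
    "ML3 mid/post curve linear",
    "ML4 phase means differ",
)


def precheck_in_reference_range(
    episode: LabValueEpisode, params: AlgorithmParameters
) -> Optional[Tuple[str, int]]:
    """Optional step 1: every observed value inside the reference range [0..1].

    Only active when ``params.no_change_if_in_reference_range`` is on
    (off by default); a positive check yields ``no change`` at step 1.
    """
    if not params.no_change_if_in_reference_range:
        return None
    values = np.asarray(episode.values)
    if np.all((values >= 0.0) & (values <= 1.0)):
        return NO_CHANGE, 1
    return None


def _phase_masks(series: WeightedSeries, episode: LabValueEpisode):
    first, last = episode.first_admin_day, episode.last_admin_day
    pre = series.days < first
    later = series.days >= first
    mid = later & (series.days <= last)
    post = series.days > last
    return pre, mid, post, later


def main_loop_pass(
    series_variant: WeightedSeries,
    episode: LabValueEpisode,
    params: AlgorithmParameters,
    base_step: int,
    trace: Optional[List[TraceRecord]] = None,
) -> Optional[Tuple[str, int]]:
    """Run the four main-loop tests on one data variant.

    ``base_step`` anchors the pass in the global step table (2 for the raw
    pass, 6 for the low-pass pass, 10 for the outlier-removed low-pass pass).
    Returns ``(label, step)`` for the first test that fires, else ``None``.
    """
    if trace is None:
        trace = []
    pre_m, _, _, later_m = _phase_masks(series_variant, episode)
    pre_sub = series_variant.subset(pre_m)
    later_sub = series_variant.subset(later_m)
    n_pre = int(np.count_nonzero(pre_sub.observed_mask))
    n_later = int(np.count_nonzero(later_sub.observed_mask))

    def record(offset: int, outcome: str) -> None:
        trace.append(TraceRecord(base_step + offset, _ML_NAMES[offset], outcome))

    # ML1: pre-phase constant, mid/post no longer on the pre level, means differ
    if n_pre < params.min_pre_points or n_later < 1:
        record(0, "skipped: pre-phase too short")
    else:
        pre_fit = fit_and_test(pre_sub, "constant", params.constant_fit_tol)
        fired = False
        if pre_fit.within_tolerance:
            later_residual = constant_residual_about(later_sub, pre_fit.level)
            if later_residual > params.constant_fit_tol and phase_means_differ(
                pre_sub.values,
                later_sub.values,
                params.mean_diff_tol,
                pre_sub.weights,
                later_sub.weights,
            ):
                fired = True
        if fired:
            record(0, f"fired: {TEMPORAL_CORRELATION}")
            return TEMPORAL_CORRELATION, base_step
        record(0, "no classification")

    # ML2: whole curve linear
    if int(np.count_nonzero(series_variant.observed_mask)) < 2:
        record(1, "skipped: too few points")
    else:
        whole_fit = fit_and_test(series_variant, "linear", params.linear_fit_tol)
        if whole_fit.within_tolerance:
            record(1, f"fired: {NO_CHANGE}")
            return NO_CHANGE, base_step + 1
        record(1, "no classification")

    # ML3: mid/post curve linear
    if n_later < 2:
        record(2, "skipped: too few mid/post points")
    else:
        later_fit = fit_and_test(later_sub, "linear", params.linear_fit_tol)
        if later_fit.within_tolerance:
            record(2, f"fired: {NO_CHANGE}")
            return NO_CHANGE, base_step + 2
        record(2, "no classification")

    # ML4: phase means differ
    if n_pre < params.min_pre_points or n_later < 1:
        record(3, "skipped: pre-phase too short")
    else:
        if phase_means_differ(
            pre_sub.values,
            later_sub.values,
            params.mean_diff_tol,
            pre_sub.weights,
            later_sub.weights,
        ):
            record(3, f"fired: {TEMPORAL_CORRELATION}")
            return TEMPORAL_CORRELATION, base_step + 3
        record(3, "no classification")

    return None


def classify_episode(
    episode: LabValueEpisode, params: Optional[AlgorithmParameters] = None
) -> ClassificationResult:
    """Run the full 18-step cascade on one (valid) episode.

    Episodes with fewer than :data:`MIN_OBSERVED_VALUES` observations do not
    enter the cascade: their data basis does not allow an assessment, so they
    are labeled ``no assessment`` with a degenerate-input marker
    (``step is None``).
    """
    if params is None:
        params = AlgorithmParameters()
    trace: List[TraceRecord] = []

    if len(episode.observations) < MIN_OBSERVED_VALUES:
        trace.append(
            TraceRecord(None, "degenerate input (< 3 observed values)", f"fired: {NO_ASSESSMENT}")
        )
        return ClassificationResult(episode.episode_id, NO_ASSESSMENT, None, tuple(trace))

    # step 1: optional reference-range pre-check
    pre = precheck_in_reference_range(episode, params)
    if params.no_change_if_in_reference_range:
        if pre is not None:
            trace.append(TraceRecord(1, "all values in reference range", f"fired: {NO_CHANGE}"))
            return ClassificationResult(episode.episode_id, NO_CHANGE, 1, tuple(trace))
        trace.append(TraceRecord(1, "all values in reference range", "no classification"))

    raw = fill_gaps(episode, params.gap_weight)
    lowpass = gaussian_lowpass(raw, params.gaussian_sigma)
    outlier_removed = remove_outliers(raw)
    ro_lowpass = gaussian_lowpass(outlier_removed, params.gaussian_sigma)

    # three passes of the main loop: raw, low-pass, outliers-removed + low-pass
    for variant, base in ((raw, 2), (lowpass, 6), (ro_lowpass, 10)):
        hit = main_loop_pass(variant, episode, params, base, trace)
        if hit is not None:
            label, step = hit
            return ClassificationResult(episode.episode_id, label, step, tuple(trace))

    # steps 14/15: per-phase edges on the low-pass data
    pre_m, mid_m, post_m, _ = _phase_masks(lowpass, episode)
    edges = {}
    for name, mask in (("pre", pre_m), ("mid", mid_m), ("post", post_m)):
        sub = lowpass.subset(mask)
        edges[name] = detect_edge(sub.values, params.slope_threshold, sub.weights)
    pre_has_edge = edges["pre"] != FLAT
    later_has_edge = edges["mid"] != FLAT or edges["post"] != FLAT
    if pre_has_edge and not later_has_edge:
        trace.append(TraceRecord(14, "pre-phase edge only", f"fired: {NO_CHANGE}"))
        return ClassificationResult(episode.episode_id, NO_CHANGE, 14, tuple(trace))
    trace.append(TraceRecord(14, "pre-phase edge only", "no classification"))
    if pre_has_edge and later_has_edge:
        trace.append(TraceRecord(15, "pre-phase and mid/post edges", f"fired: {NO_ASSESSMENT}"))
        return ClassificationResult(episode.episode_id, NO_ASSESSMENT, 15, tuple(trace))
    trace.append(TraceRecord(15, "pre-phase and mid/post edges", "no classification"))

    # step 16: outlier-removed values stay close to their mean → no change
    ro_observed = outlier_removed.values[outlier_removed.observed_mask]
    if not deviates_from_mean(ro_observed, params.mean_dev_tol):
        trace.append(TraceRecord(16, "no deviation from mean", f"fired: {NO_CHANGE}"))
        return ClassificationResult(episode.episode_id, NO_CHANGE, 16, tuple(trace))
    trace.append(TraceRecord(16, "no deviation from mean", "no classification"))

    # step 17: strong alternation → no assessment
    if is_zigzag(raw.values, params.zigzag_amp, params.zigzag_frac):
        trace.append(TraceRecord(17, "zig-zag", f"fired: {NO_ASSESSMENT}"))
        return ClassificationResult(episode.episode_id, NO_ASSESSMENT, 17, tuple(trace))
    trace.append(TraceRecord(17, "zig-zag", "no classification"))

    # step 18: everything else is a temporal correlation
    trace.append(TraceRecord(18, "default", f"fired: {TEMPORAL_CORRELATION}"))
    return ClassificationResult(episode.episode_id, TEMPORAL_CORRELATION, 18, tuple(trace))


def classify_corpus(
    episodes: Sequence[LabValueEpisode],
    params: Optional[AlgorithmParameters] = None,
    errors: Optional[List[Tuple[str, Exception]]] = None,
) -> List[ClassificationResult]:
    """Classify every episode of a corpus, preserving order.

    Per-episode failures are collected (appended to ``errors`` when given,
    and logged), never fatal for the rest of the corpus.
    """
    results: List[ClassificationResult] = []
    for episode in episodes:
        try:
            results.append(classify_episode(episode, params))
        except Exception as exc:  # pragma: no cover - defensive collection
            logger.warning("episode %s failed: %s", episode.episode_id, exc)
            if errors is not None:
                errors.append((episode.episode_id, exc))
    return results
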