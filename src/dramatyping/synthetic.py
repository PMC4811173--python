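"""Seeded generator of medication episodes with known intended routing.

Every branch of the classification cascade should be testable without any
external corpus, so this module builds episodes from *archetypes*: parametric
curve shapes (level shift at drug start, straight line, zig-zag, isolated
outliers, pre-phase edges, …) whose intended classification — and the set of
cascade steps allowed to produce it — is known by construction.

The default geometry of each archetype (length, admin window, effect size,
noise amplitude) is part of the study conditions: episodes are 19–40 daily
observations with the administration window inside the observation window,
effect sizes of 0.4–3 normalized units (reference-interval widths), and
observation noise of 0.08–0.12 where the archetype is intentionally noisy.
These were fixed once so each archetype routes through the intended cascade
branch under the default algorithm parameters; see ``docs/methods.md``.

The labeled suite (:func:`generate_labeled_suite`) covers all archetypes,
includes gapped episodes emulating interrupted observation series, and can
write the episode and ground-truth XML documents consumed by the CLI.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core import (
    NO_ASSESSMENT,
    NO_CHANGE,
    TEMPORAL_CORRELATION,
    LabValueEpisode,
    validate_episode,
)
from .xml_io import write_episodes_xml, write_results_xml

__all__ = [
    "ARCHETYPE_KINDS",
    "ArchetypeSpec",
    "SyntheticCorpus",
    "generate_archetype_episode",
    "generate_labeled_suite",
]


@dataclass(frozen=True)
class ArchetypeSpec:
    """Recipe for one synthetic episode.

    ``None`` geometry fields fall back to the archetype's calibrated default.
    ``noise`` is the SD of additive Gaussian observation noise *on top of*
    any noise intrinsic to the archetype; ``gap_days`` are observation days
    removed from the daily grid (emulating interrupted series).
    """

    kind: str
    length: Optional[int] = None
    admin_start: Optional[int] = None
    admin_end: Optional[int] = None
    effect: Optional[float] = None
    noise: float = 0.0
    gap_days: Tuple[int, ...] = ()
    seed: int = 0
    episode_id: Optional[str] = None


def _wiggle(days: np.ndarray, amp: float, period: float, phase: float = 0.0) -> np.ndarray:
    return amp * np.sin(2.0 * math.pi * (days - phase) / period)


# ---------------------------------------------------------------------------
# archetype builders: days -> (values, admin window, intended label, steps)
#
# Each builder receives the resolved geometry and the full daily grid and
# returns the noise-free base curve; intrinsic noise (for the *_noisy kinds)
# is described by the "intrinsic_noise" registry entry and added centrally.
# ---------------------------------------------------------------------------


def _flat(days, admin_start, admin_end, effect):
    return np.full(len(days), 0.5)


def _level_shift_at_admin(days, admin_start, admin_end, effect):
    return np.where(days < admin_start, 0.5, 0.5 + effect)


def _linear_trend(days, admin_start, admin_end, effect):
    return 0.1 + effect * (days - days[0])


def _linear_after_admin(days, admin_start, admin_end, effect):
    # wiggly (non-constant, non-linear) pre-phase, exact mean-centred ramp
    # from the first administration on
    base = 0.5 + _wiggle(days, 0.25, 7.0)
    later = days >= admin_start
    n_later = int(np.count_nonzero(later))
    ramp = 0.5 + effect * (np.arange(n_later) - (n_later - 1) / 2.0)
    out = base.copy()
    out[later] = ramp
    return out


def _pre_edge_only(days, admin_start, admin_end, effect):
    # transient: steep rise during the pre-phase, then settles to a flat but
    # slightly wiggly level equal to the pre-phase mean (so no mean shift)
    pre = days < admin_start
    n_pre = int(np.count_nonzero(pre))
    ramp = effect * np.arange(n_pre)
    level = float(ramp.mean())
    # wiggle phased so the mid/post windows centre on sine extrema: the
    # mid/post curve is clearly non-linear yet its fitted slope stays ~0
    out = level + _wiggle(days, 0.35, 12.0, phase=admin_start - 1.0)
    out[pre] = ramp
    return out


def _pre_and_post_edge(days, admin_start, admin_end, effect):
    out = _pre_edge_only(days, admin_start, admin_end, effect)
    pre = days < admin_start
    level = float((effect * np.arange(int(np.count_nonzero(pre)))).mean())
    post = days > admin_end
    n_post = int(np.count_nonzero(post))
    # mean-centred rising edge after the last administration
    out[post] = level + 0.22 * (np.arange(n_post) - (n_post - 1) / 2.0)
    return out


def _low_noise_flat(days, admin_start, admin_end, effect):
    return np.full(len(days), 0.5)


def _zigzag(days, admin_start, admin_end, effect):
    return 1.0 + effect * np.where(np.arange(len(days)) % 2 == 0, 1.0, -1.0)


def _outlier_pair(days, admin_start, admin_end, effect):
    out = np.full(len(days), 0.5)
    spikes = (admin_start + 1, admin_start + 3)
    for d in spikes:
        out[np.searchsorted(days, d)] += effect
    return out


def _gapped(days, admin_start, admin_end, effect):
    return np.where(days < admin_start, 0.5, 0.5 + effect)


def _in_reference_range(days, admin_start, admin_end, effect):
    return np.where(days < admin_start, 0.25, 0.25 + effect)


def _mean_shift_noisy(days, admin_start, admin_end, effect):
    # noisy level shift with an undulating plateau: the noisy pre-phase defeats
    # the constancy test, so the shift is caught by the mean-difference test
    out = np.where(days < admin_start, 0.3, 0.3 + effect)
    later = days >= admin_start
    out[later] += _wiggle(days[later], 0.25, 10.0)
    return out


def _mid_ramp_noisy(days, admin_start, admin_end, effect):
    return _linear_after_admin(days, admin_start, admin_end, effect)


def _outliers_mask_level_shift(days, admin_start, admin_end, effect):
    # flat pre-phase whose constancy is masked by two large spikes; the
    # mid/post level shift becomes detectable only after outlier removal
    out = np.where(days < admin_start, 0.5, 0.9)
    out[days >= admin_start] += _wiggle(days[days >= admin_start], 0.25, 10.0)
    for d in (5, 11):
        out[np.searchsorted(days, d)] = 0.5 + effect
    return out


def _pre_outlier_shift(days, admin_start, admin_end, effect):
    # one huge pre-phase spike inflates the pre mean; removing it unmasks the
    # mean shift (mean-difference test fires only in the outlier-removed pass);
    # the sustained pre wiggle keeps the pre-phase non-constant in every pass
    out = np.where(days < admin_start, 0.5, 0.95) + _wiggle(days, 0.25, 10.0)
    out[np.searchsorted(days, 3)] = 0.5 + effect
    return out


def _outlier_ramp(days, admin_start, admin_end, effect):
    # wiggly pre-phase + mid/post ramp contaminated by two spikes; the ramp
    # is recognized as linear only after outlier removal and smoothing
    out = 0.5 + _wiggle(days, 0.25, 10.0)
    later = days >= admin_start
    n_later = int(np.count_nonzero(later))
    out[later] = 0.5 + 0.05 * (np.arange(n_later) - (n_later - 1) / 2.0)
    for d in (admin_start + 2, admin_start + 6):
        out[np.searchsorted(days, d)] += effect
    return out


def _smooth_wiggle_small(days, admin_start, admin_end, effect):
    return 0.5 + _wiggle(days, effect, 12.0)


def _irregular_wiggle(days, admin_start, admin_end, effect):
    return 0.55 + _wiggle(days, effect, 9.0) + _wiggle(days, effect, 13.0, phase=2.0)


@dataclass(frozen=True)
class _Archetype:
    build: Callable
    label: str
    steps: frozenset
    length: int = 20
    admin_start: int = 8
    admin_end: int = 12
    effect: float = 1.5
    intrinsic_noise: float = 0.0
    gap_days: Tuple[int, ...] = ()


_REGISTRY: Dict[str, _Archetype] = {
    "flat": _Archetype(_flat, NO_CHANGE, frozenset({3})),
    "level_shift_at_admin": _Archetype(_level_shift_at_admin, TEMPORAL_CORRELATION, frozenset({2})),
    "linear_trend": _Archetype(_linear_trend, NO_CHANGE, frozenset({3}), effect=0.05),
    "linear_after_admin": _Archetype(_linear_after_admin, NO_CHANGE, frozenset({4}), effect=0.05),
    "pre_edge_only": _Archetype(
        _pre_edge_only, NO_CHANGE, frozenset({14}), length=20, admin_start=9, admin_end=13, effect=0.25
    ),
    "pre_and_post_edge": _Archetype(
        _pre_and_post_edge, NO_ASSESSMENT, frozenset({15}), length=20, admin_start=9, admin_end=13, effect=0.25
    ),
    "low_noise_flat": _Archetype(
        _low_noise_flat, NO_CHANGE, frozenset({3, 4, 7, 8, 11, 12, 16}), intrinsic_noise=0.08
    ),
    "zigzag": _Archetype(
        _zigzag, NO_ASSESSMENT, frozenset({17}), length=40, admin_start=21, admin_end=25, effect=1.8
    ),
    "outlier_pair": _Archetype(_outlier_pair, NO_CHANGE, frozenset({11})),
    "gapped": _Archetype(_gapped, TEMPORAL_CORRELATION, frozenset({2}), gap_days=(3, 4, 15)),
    "in_reference_range": _Archetype(
        _in_reference_range, TEMPORAL_CORRELATION, frozenset({2}), effect=0.5
    ),
    "mean_shift_noisy": _Archetype(
        _mean_shift_noisy, TEMPORAL_CORRELATION, frozenset({2, 5}), effect=0.9, intrinsic_noise=0.12
    ),
    "mid_ramp_noisy": _Archetype(
        _mid_ramp_noisy, NO_CHANGE, frozenset({4, 8, 12}), effect=0.05, intrinsic_noise=0.12
    ),
    "outliers_mask_level_shift": _Archetype(
        _outliers_mask_level_shift,
        TEMPORAL_CORRELATION,
        frozenset({10}),
        length=28,
        admin_start=19,
        admin_end=23,
        effect=2.0,
    ),
    "pre_outlier_shift": _Archetype(
        _pre_outlier_shift,
        TEMPORAL_CORRELATION,
        frozenset({13}),
        length=23,
        admin_start=11,
        admin_end=15,
        effect=2.5,
    ),
    "outlier_ramp": _Archetype(
        _outlier_ramp,
        NO_CHANGE,
        frozenset({12}),
        length=22,
        admin_start=11,
        admin_end=15,
        effect=1.5,
    ),
    "smooth_wiggle_small": _Archetype(
        _smooth_wiggle_small, NO_CHANGE, frozenset({16}), effect=0.22
    ),
    "irregular_wiggle": _Archetype(
        _irregular_wiggle,
        TEMPORAL_CORRELATION,
        frozenset({18}),
        length=26,
        admin_start=10,
        admin_end=16,
        effect=0.25,
    ),
}

ARCHETYPE_KINDS: Tuple[str, ...] = tuple(_REGISTRY)


def generate_archetype_episode(
    spec: ArchetypeSpec,
) -> Tuple[LabValueEpisode, str, Set[int]]:
    """Build one synthetic episode from its recipe.

    Deterministic given ``spec`` (including ``seed``).  Returns the validated
    episode, the label the default-parameter classifier must produce, and the
    set of cascade steps allowed to produce it.
    """
    if spec.kind not in _REGISTRY:
        raise ValueError(f"unknown archetype kind {spec.kind!r}")
    arch = _REGISTRY[spec.kind]
    length = spec.length if spec.length is not None else arch.length
    admin_start = spec.admin_start if spec.admin_start is not None else arch.admin_start
    admin_end = spec.admin_end if spec.admin_end is not None else arch.admin_end
    effect = spec.effect if spec.effect is not None else arch.effect
    if not (1 <= admin_start <= admin_end <= length):
        raise ValueError(
            f"administration window {admin_start}..{admin_end} outside 1..{length}"
        )
    if spec.noise < 0:
        raise ValueError("noise must be >= 0")
    gap_days = spec.gap_days if spec.gap_days else arch.gap_days

    days = np.arange(1, length + 1)
    values = np.asarray(arch.build(days, admin_start, admin_end, effect), dtype=float)
    total_noise = math.hypot(arch.intrinsic_noise, spec.noise)
    if total_noise > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, total_noise, size=len(values))
    keep = ~np.isin(days, np.asarray(gap_days, dtype=int))
    episode_id = spec.episode_id or f"{spec.kind}-{spec.seed:04d}"
    episode = validate_episode(
        (
            episode_id,
            list(zip(days[keep].tolist(), values[keep].tolist())),
            list(range(admin_start, admin_end + 1)),
        )
    )
    return episode, arch.label, set(arch.steps)


@dataclass(frozen=True)
class SyntheticCorpus:
    """A labeled synthetic corpus: episodes + ground-truth labels + routing."""

    episodes: Tuple[LabValueEpisode, ...]
    truth: Tuple[Tuple[str, str], ...]  # (episode_id, intended label)
    intended_steps: Dict[str, Set[int]]

    def __len__(self) -> int:
        return len(self.episodes)


#: replicates per archetype in the labeled suite
_SUITE_REPLICATES = 3
#: extra replicates for the most common clinical shapes
_SUITE_EXTRA = ("flat", "level_shift_at_admin", "linear_trend", "low_noise_flat")


def generate_labeled_suite(
    master_seed: int,
    out_dir=None,
    extra_noise: float = 0.0,
) -> SyntheticCorpus:
    """Generate the full labeled archetype suite (≥ 50 episodes).

    Covers every archetype kind (including gapped episodes) with
    ``_SUITE_REPLICATES`` seeded replicates each plus extras for the common
    shapes.  ``extra_noise`` adds Gaussian observation noise on top of every
    archetype (used to probe the noise robustness of the parameter defaults).
    When ``out_dir`` is given, writes ``episodes.xml`` and the ground-truth
    ``ground_truth.xml`` there.  Deterministic given ``master_seed``.
    """
    plan: List[str] = []
    for kind in ARCHETYPE_KINDS:
        plan.extend([kind] * _SUITE_REPLICATES)
    plan.extend(_SUITE_EXTRA)

    episodes: List[LabValueEpisode] = []
    truth: List[Tuple[str, str]] = []
    intended: Dict[str, Set[int]] = {}
    for idx, kind in enumerate(plan):
        seed = (int(master_seed) * 100003 + idx * 7919) % (2**31)
        spec = ArchetypeSpec(
            kind=kind,
            noise=extra_noise,
            seed=seed,
            episode_id=f"{kind}-{idx:03d}",
        )
        episode, label, steps = generate_archetype_episode(spec)
        episodes.append(episode)
        truth.append((episode.episode_id, label))
        intended[episode.episode_id] = steps

    corpus = SyntheticCorpus(tuple(episodes), tuple(truth), intended)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_episodes_xml(corpus.episodes, os.path.join(out_dir, "episodes.xml"))
        write_results_xml(list(corpus.truth), os.path.join(out_dir, "ground_truth.xml"))
    return corpus
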