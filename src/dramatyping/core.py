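"""Domain types for drug/lab-value medication episodes.

A *medication episode* pairs the normalized laboratory values observed for one
patient over a contiguous stretch of days with the days on which one drug was
administered.  Lab values are expected on the normalized scale where the
patient-specific reference interval maps to ``[0, 1]`` (0 = lower reference
bound, 1 = upper bound); values outside ``[0, 1]`` are legal and meaningful.

The observation window is split into three phases relative to the drug:

pre-phase
    days strictly before the first administration,
mid-phase
    days from the first administration up to and including the last,
post-phase
    days strictly after the last administration.

The classifier (:mod:`dramatyping.classifier`) is intentionally blind to the
drug's identity, the lab parameter and any patient covariates — it sees only
the normalized curve and the administration days.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

__all__ = [
    "TEMPORAL_CORRELATION",
    "NO_CHANGE",
    "NO_ASSESSMENT",
    "LABELS",
    "EpisodeValidationError",
    "EmptyObservationsError",
    "NoAdministrationDaysError",
    "AdministrationOutsideSpanError",
    "DuplicateDayError",
    "NonFiniteValueError",
    "InvalidParameterError",
    "LabValueEpisode",
    "PhasePartition",
    "AlgorithmParameters",
    "TraceRecord",
    "ClassificationResult",
    "validate_episode",
    "partition_phases",
]

#: The three-way nominal classification scale.
TEMPORAL_CORRELATION = "temporal correlation"
NO_CHANGE = "no change"
NO_ASSESSMENT = "no assessment"
LABELS = (TEMPORAL_CORRELATION, NO_CHANGE, NO_ASSESSMENT)


class EpisodeValidationError(ValueError):
    """An episode record violates an invariant."""


class EmptyObservationsError(EpisodeValidationError):
    """Episode carries no lab-value observations."""


class NoAdministrationDaysError(EpisodeValidationError):
    """Episode carries no drug-administration days."""


class AdministrationOutsideSpanError(EpisodeValidationError):
    """An administration day lies outside the observation window."""


class DuplicateDayError(EpisodeValidationError):
    """Two observations share the same day."""


class NonFiniteValueError(EpisodeValidationError):
    """A lab value is NaN or infinite."""


class InvalidParameterError(ValueError):
    """An algorithm parameter violates its constraint."""


@dataclass(frozen=True)
class LabValueEpisode:
    """One medication episode: day-indexed normalized lab values + drug days.

    Parameters
    ----------
    episode_id
        Opaque identifier, unique within a corpus.
    observations
        Ordered ``(day, value)`` pairs; days are 1-based integers, strictly
        increasing.  Gaps (missing days) are allowed.
    admin_days
        Days on which the drug was administered, within the observation span.
        An administration day need not carry a lab observation.
    """

    episode_id: str
    observations: Tuple[Tuple[int, float], ...]
    admin_days: Tuple[int, ...]

    @property
    def days(self) -> Tuple[int, ...]:
        return tuple(d for d, _ in self.observations)

    @property
    def values(self) -> Tuple[float, ...]:
        return tuple(v for _, v in self.observations)

    @property
    def first_day(self) -> int:
        return self.observations[0][0]

    @property
    def last_day(self) -> int:
        return self.observations[-1][0]

    @property
    def first_admin_day(self) -> int:
        return self.admin_days[0]

    @property
    def last_admin_day(self) -> int:
        return self.admin_days[-1]


@dataclass(frozen=True)
class PhasePartition:
    """Observation days split by their position relative to the drug window.

    ``pre_days`` < first administration ≤ ``mid_days`` ≤ last administration
    < ``post_days``; the three lists are disjoint and together contain every
    observation day.  Empty pre- or post-phases are legal.
    """

    pre_days: Tuple[int, ...]
    mid_days: Tuple[int, ...]
    post_days: Tuple[int, ...]


def validate_episode(raw_episode) -> LabValueEpisode:
    """Validate and canonicalize an episode record.

    Accepts a :class:`LabValueEpisode`, a mapping with keys ``episode_id`` /
    ``observations`` / ``admin_days``, or a ``(episode_id, observations,
    admin_days)`` triple.  Observations are sorted by day; administration
    days are sorted and de-duplicated.  Idempotent on valid episodes.

    Raises
    ------
    EmptyObservationsError, NoAdministrationDaysError,
    AdministrationOutsideSpanError, DuplicateDayError, NonFiniteValueError
    """
    if isinstance(raw_episode, LabValueEpisode):
        episode_id = raw_episode.episode_id
        observations = raw_episode.observations
        admin_days = raw_episode.admin_days
    elif isinstance(raw_episode, Mapping):
        episode_id = str(raw_episode["episode_id"])
        observations = raw_episode["observations"]
        admin_days = raw_episode["admin_days"]
    else:
        episode_id, observations, admin_days = raw_episode
        episode_id = str(episode_id)

    obs = sorted((int(d), float(v)) for d, v in observations)
    if not obs:
        raise EmptyObservationsError(f"episode {episode_id!r}: no observations")
    admins = tuple(sorted({int(d) for d in admin_days}))
    if not admins:
        raise NoAdministrationDaysError(
            f"episode {episode_id!r}: no administration days"
        )
    days = [d for d, _ in obs]
    for a, b in zip(days, days[1:]):
        if a == b:
            raise DuplicateDayError(f"episode {episode_id!r}: duplicate day {a}")
    for d, v in obs:
        if not math.isfinite(v):
            raise NonFiniteValueError(
                f"episode {episode_id!r}: non-finite value {v!r} on day {d}"
            )
    if admins[0] < days[0] or admins[-1] > days[-1]:
        raise AdministrationOutsideSpanError(
            f"episode {episode_id!r}: administration days {admins[0]}..{admins[-1]} "
            f"outside observation span {days[0]}..{days[-1]}"
        )
    return LabValueEpisode(episode_id, tuple(obs), admins)


def partition_phases(episode: LabValueEpisode) -> PhasePartition:
    """Split the episode's observation days into pre-, mid- and post-phase.

    The mid-phase includes both boundary administration days, so a single
    administration day always yields a non-empty mid-phase window (it may
    still contain no observation if no lab value was taken that day).
    """
    first, last = episode.first_admin_day, episode.last_admin_day
    pre = tuple(d for d in episode.days if d < first)
    mid = tuple(d for d in episode.days if first <= d <= last)
    post = tuple(d for d in episode.days if d > last)
    return PhasePartition(pre, mid, post)


@dataclass
class AlgorithmParameters:
    """Every tunable of the classification cascade.

    All tolerances are expressed in normalized lab-value units (a tolerance of
    0.05 is 5 % of the patient-specific reference interval).  Residual-type
    tolerances bound the weighted RMS deviation of the data from a fitted
    curve; ``slope_threshold`` is per day.

    The shipped defaults were calibrated once so that the canonical curve
    archetypes (level shift at drug start, straight line, strong zig-zag, …)
    route to their intended cascade steps; see ``docs/methods.md``.
    """

    constant_fit_tol: float = 0.08
    linear_fit_tol: float = 0.08
    mean_diff_tol: float = 0.3
    slope_threshold: float = 0.1
    zigzag_amp: float = 0.5
    zigzag_frac: float = 0.8
    mean_dev_tol: float = 0.3
    gaussian_sigma: float = 1.5
    gap_weight: float = 1e-6
    min_pre_points: int = 2
    no_change_if_in_reference_range: bool = False

    def __post_init__(self) -> None:
        for name in (
            "constant_fit_tol",
            "linear_fit_tol",
            "mean_diff_tol",
            "slope_threshold",
            "zigzag_amp",
            "mean_dev_tol",
            "gaussian_sigma",
        ):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not 0 < self.zigzag_frac <= 1:
            raise InvalidParameterError("zigzag_frac must be in (0, 1]")
        if not 0 < self.gap_weight < 1:
            raise InvalidParameterError("gap_weight must be in (0, 1)")
        if self.min_pre_points < 1:
            raise InvalidParameterError("min_pre_points must be >= 1")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "AlgorithmParameters":
        """Build parameters from a flat key→value mapping (e.g. a config file).

        Unknown keys raise :class:`InvalidParameterError`.
        """
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        unknown = set(mapping) - set(known)
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter(s): {', '.join(sorted(unknown))}"
            )
        return cls(**dict(mapping))

    def replace(self, **changes) -> "AlgorithmParameters":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class TraceRecord:
    """One evaluated cascade step: ``(step, test name, outcome)``."""

    step: Optional[int]
    test: str
    outcome: str  # "fired: <label>" | "no classification" | "skipped: <why>"


@dataclass(frozen=True)
class ClassificationResult:
    """The cascade's verdict for one episode.

    ``step`` is the 1–18 index of the first test that fired; it is ``None``
    only for degenerate episodes (fewer than 3 observed values) which are
    assigned ``no assessment`` without running the cascade.  ``trace``
    records every step that was evaluated, in order.
    """

    episode_id: str
    label: str
    step: Optional[int]
    trace: Tuple[TraceRecord, ...] = field(default_factory=tuple, repr=False)

    @property
    def degenerate(self) -> bool:
        return self.step is None
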