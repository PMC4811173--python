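"""XML input/output for episodes and assessment results.

Two document kinds are handled:

* **episode documents** — one element per medication episode carrying an id,
  a sequence of day/value lab observations and the drug administration days;
* **result documents** — one element per episode carrying the id and the
  assessed category (``temporal correlation`` / ``no change`` /
  ``no assessment``).

Tag and attribute names are configurable through :class:`XmlDialect` so that
corpora serialized with different element names can be ingested without code
changes; the name of the root element is always ignored on read.  The default
result filename, used when only a directory is given, is
``algorithm_assesssment_result.xml``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple, Union
from xml.etree import ElementTree as ET

from .core import LABELS, ClassificationResult, LabValueEpisode, validate_episode

__all__ = [
    "DEFAULT_RESULT_FILENAME",
    "XmlDialect",
    "XmlFormatError",
    "UnknownLabelError",
    "DuplicateResultIdError",
    "read_episodes_xml",
    "write_episodes_xml",
    "read_results_xml",
    "write_results_xml",
]

#: Default output filename (historical spelling kept verbatim).
DEFAULT_RESULT_FILENAME = "algorithm_assesssment_result.xml"


class XmlFormatError(ValueError):
    """Malformed or semantically invalid document; message names the element."""


class UnknownLabelError(XmlFormatError):
    """A result element carries a category string outside the three-way scale."""


class DuplicateResultIdError(XmlFormatError):
    """Two result elements share an episode id."""


@dataclass(frozen=True)
class XmlDialect:
    """Configurable element/attribute names for both document kinds."""

    episodes_root: str = "episodes"
    episode_tag: str = "episode"
    id_attr: str = "id"
    labvalue_tag: str = "labvalue"
    day_attr: str = "day"
    value_attr: str = "value"
    medication_tag: str = "medication"
    medication_day_tag: str = "day"
    medication_days_attr: str = "days"
    results_root: str = "results"
    result_tag: str = "result"
    classification_attr: str = "classification"
    step_attr: str = "step"


DEFAULT_DIALECT = XmlDialect()


def _parse_number(text: str, what: str, where: str) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        raise XmlFormatError(f"non-numeric {what} {text!r} at {where}") from None


def read_episodes_xml(path, dialect: XmlDialect = DEFAULT_DIALECT) -> List[LabValueEpisode]:
    """Parse an episode document into validated episodes.

    The root element name is arbitrary; every ``episode`` element anywhere
    below the root is read.  Administration days may be given either as
    ``<medication><day>4</day>…</medication>`` children or as a
    space/comma-separated ``days`` attribute on the medication element.
    """
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise XmlFormatError(f"malformed XML in {path}: {exc}") from exc
    episodes = []
    for i, elem in enumerate(root.iter(dialect.episode_tag)):
        where = f"{dialect.episode_tag}[{i}]"
        episode_id = elem.get(dialect.id_attr)
        if episode_id is None:
            raise XmlFormatError(f"missing {dialect.id_attr!r} attribute at {where}")
        observations = []
        for j, lv in enumerate(elem.iter(dialect.labvalue_tag)):
            lv_where = f"{where}/{dialect.labvalue_tag}[{j}]"
            day = _parse_number(lv.get(dialect.day_attr), "day", lv_where)
            value = _parse_number(lv.get(dialect.value_attr), "value", lv_where)
            observations.append((int(day), value))
        admin_days: List[int] = []
        for med in elem.iter(dialect.medication_tag):
            attr = med.get(dialect.medication_days_attr)
            if attr:
                for tok in attr.replace(",", " ").split():
                    admin_days.append(int(_parse_number(tok, "administration day", where)))
            for d in med.iter(dialect.medication_day_tag):
                admin_days.append(
                    int(_parse_number(d.text, "administration day", where))
                )
        episodes.append(
            validate_episode({"episode_id": episode_id, "observations": observations, "admin_days": admin_days})
        )
    return episodes


def _indent_and_write(root: ET.Element, path) -> None:
    tree = ET.ElementTree(root)
    ET.indent(tree, space="  ")
    tree.write(path, encoding="utf-8", xml_declaration=True)


def write_episodes_xml(
    episodes: Sequence[LabValueEpisode], path, dialect: XmlDialect = DEFAULT_DIALECT
) -> str:
    """Serialize episodes to an episode document; returns the written path."""
    root = ET.Element(dialect.episodes_root)
    for ep in episodes:
        elem = ET.SubElement(root, dialect.episode_tag, {dialect.id_attr: ep.episode_id})
        for day, value in ep.observations:
            ET.SubElement(
                elem,
                dialect.labvalue_tag,
                {dialect.day_attr: str(day), dialect.value_attr: repr(value)},
            )
        med = ET.SubElement(elem, dialect.medication_tag)
        for day in ep.admin_days:
            ET.SubElement(med, dialect.medication_day_tag).text = str(day)
    _indent_and_write(root, path)
    return os.fspath(path)


def write_results_xml(
    results: Sequence[Union[ClassificationResult, Tuple[str, str]]],
    path,
    dialect: XmlDialect = DEFAULT_DIALECT,
) -> str:
    """Serialize classification results to a result document.

    ``path`` may be a directory, in which case the default filename
    :data:`DEFAULT_RESULT_FILENAME` is used.  Accepts either
    :class:`ClassificationResult` objects (the cascade step is stored as an
    extension attribute) or plain ``(episode_id, label)`` pairs.  Returns the
    written path.
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        path = os.path.join(path, DEFAULT_RESULT_FILENAME)
    root = ET.Element(dialect.results_root)
    seen = set()
    for r in results:
        if isinstance(r, ClassificationResult):
            episode_id, label, step = r.episode_id, r.label, r.step
        else:
            (episode_id, label), step = r, None
        if label not in LABELS:
            raise UnknownLabelError(f"unknown classification {label!r} for {episode_id!r}")
        if episode_id in seen:
            raise DuplicateResultIdError(f"duplicate episode id {episode_id!r}")
        seen.add(episode_id)
        attrs = {dialect.id_attr: episode_id, dialect.classification_attr: label}
        if step is not None:
            attrs[dialect.step_attr] = str(step)
        ET.SubElement(root, dialect.result_tag, attrs)
    _indent_and_write(root, path)
    return path


def read_results_xml(path, dialect: XmlDialect = DEFAULT_DIALECT) -> List[Tuple[str, str]]:
    """Parse a result document into ordered ``(episode_id, label)`` pairs.

    Unknown category strings and duplicate ids are rejected.
    """
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise XmlFormatError(f"malformed XML in {path}: {exc}") from exc
    pairs: List[Tuple[str, str]] = []
    seen = set()
    for i, elem in enumerate(root.iter(dialect.result_tag)):
        where = f"{dialect.result_tag}[{i}]"
        episode_id = elem.get(dialect.id_attr)
        if episode_id is None:
            raise XmlFormatError(f"missing {dialect.id_attr!r} attribute at {where}")
        label = elem.get(dialect.classification_attr)
        if label not in LABELS:
            raise UnknownLabelError(f"unknown classification {label!r} at {where}")
        if episode_id in seen:
            raise DuplicateResultIdError(f"duplicate episode id {episode_id!r} at {where}")
        seen.add(episode_id)
        pairs.append((episode_id, label))
    return pairs
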