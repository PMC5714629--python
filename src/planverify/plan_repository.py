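"""Plan corpora and active-plan lists.

A corpus is a directory of canonical plan XML documents laid out as
``<patient>/<course>/<plan>.xml`` (path components percent-encoded so any
identifier the source database held is representable).  Status metadata
lives inside each document, so the "which plans are active?" query runs on
the corpus without any database.

Active plans are plans in an active course whose status is Unapproved,
Planning Approved or Treatment Approved — the plans that will migrate and
likely be used afterwards, hence the ones targeted for migration QA.  A
user-supplied list can add anything else (e.g. Completed plans); the
user-supplied flag travels into the reports so readers know the list may be
incomplete.
"""

from __future__ import annotations

import time
import urllib.parse
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from lxml import etree

from .plan_io import (
    PlanDocument,
    PlanParseError,
    PlanReadError,
    read_plan_xml,
    write_plan_xml,
)
from .plan_model import CourseStatus, PlanKey, PlanStatus

__all__ = [
    "PlanList",
    "PlanListError",
    "InMemoryCorpus",
    "DirectoryCorpus",
    "ACTIVE_PLAN_STATUSES",
    "is_active",
    "list_active_plans",
    "read_plan_list",
    "write_plan_list",
]

ACTIVE_PLAN_STATUSES = frozenset(
    {PlanStatus.UNAPPROVED, PlanStatus.PLANNING_APPROVED, PlanStatus.TREATMENT_APPROVED}
)


class PlanListError(Exception):
    """Plan-list document is invalid (e.g. duplicate entries)."""


@dataclass
class PlanList:
    """An ordered, duplicate-free list of plan keys to compare."""

    entries: list[PlanKey]
    generated_from: str = ""
    generated_at: str = ""
    user_supplied: bool = False
    load_failures: list[str] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[PlanKey] = set()
        for key in self.entries:
            if key in seen:
                raise PlanListError(f"duplicate plan list entry: {key.render()}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# corpora


def _quote(component: str) -> str:
    # keep filenames readable but reversible for arbitrary identifiers
    return urllib.parse.quote(component, safe=" ._-()")


def _unquote(component: str) -> str:
    return urllib.parse.unquote(component)


def key_to_relpath(key: PlanKey) -> Path:
    return Path(_quote(key.patient_id)) / _quote(key.course_id) / (
        _quote(key.plan_id) + ".xml"
    )


def relpath_to_key(rel: Path) -> PlanKey:
    return PlanKey(
        patient_id=_unquote(rel.parts[0]),
        course_id=_unquote(rel.parts[1]),
        plan_id=_unquote(rel.stem),
    )


class InMemoryCorpus:
    """Corpus backed by a dict; used for generated corpora and testing."""

    def __init__(self, documents: Iterable[PlanDocument], source_system: str = ""):
        self._docs: dict[PlanKey, PlanDocument] = {}
        for doc in documents:
            self._docs[doc.plan.key] = doc
        self.source_system = source_system or next(
            (d.source_system for d in self._docs.values()), "empty-corpus"
        )

    def keys(self) -> list[PlanKey]:
        return sorted(self._docs)

    def __contains__(self, key: PlanKey) -> bool:
        return key in self._docs

    def load(self, key: PlanKey) -> PlanDocument:
        return self._docs[key]

    def iter_documents(self) -> Iterator[tuple[PlanKey, Optional[PlanDocument], Optional[str]]]:
        for key in self.keys():
            yield key, self._docs[key], None


class DirectoryCorpus:
    """Corpus backed by a ``<patient>/<course>/<plan>.xml`` directory tree."""

    def __init__(self, path, source_system: str = ""):
        self.path = Path(path)
        if not self.path.is_dir():
            raise FileNotFoundError(f"corpus directory not found: {self.path}")
        self._source = source_system

    @property
    def source_system(self) -> str:
        if self._source:
            return self._source
        for key in self.keys():
            try:
                self._source = self.load(key).source_system
                return self._source
            except PlanReadError:
                continue
        return self.path.name

    def keys(self) -> list[PlanKey]:
        keys = []
        for xml_path in self.path.glob("*/*/*.xml"):
            keys.append(relpath_to_key(xml_path.relative_to(self.path)))
        return sorted(keys)

    def __contains__(self, key: PlanKey) -> bool:
        return (self.path / key_to_relpath(key)).is_file()

    def load(self, key: PlanKey) -> PlanDocument:
        return read_plan_xml((self.path / key_to_relpath(key)).read_bytes())

    def store(self, doc: PlanDocument) -> Path:
        target = self.path / key_to_relpath(doc.plan.key)
        target.parent.mkdir(parents=True, exist_ok=True)
        target.write_text(write_plan_xml(doc), encoding="utf-8")
        return target

    def iter_documents(self) -> Iterator[tuple[PlanKey, Optional[PlanDocument], Optional[str]]]:
        """Yield (key, document, error) with error set when a load fails."""
        for key in self.keys():
            try:
                yield key, self.load(key), None
            except (PlanReadError, OSError) as exc:
                yield key, None, str(exc)


def write_corpus(documents: Iterable[PlanDocument], path) -> "DirectoryCorpus":
    """Materialise documents as a directory corpus at *path*."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    corpus = DirectoryCorpus(root)
    for doc in documents:
        corpus.store(doc)
    return corpus


# ---------------------------------------------------------------------------
# active-plan listing


def is_active(doc: PlanDocument) -> bool:
    """The active-plan predicate: active course + in-preparation/approved status."""
    return (
        doc.plan.course_status is CourseStatus.ACTIVE
        and doc.plan.plan_status in ACTIVE_PLAN_STATUSES
    )


def list_active_plans(corpus) -> PlanList:
    """List every active plan in the corpus, sorted by rendered key.

    Documents that fail to load are recorded in ``load_failures`` rather
    than silently dropped — a corrupt document is a finding, not a gap.
    """
    entries: list[PlanKey] = []
    failures: list[str] = []
    for key, doc, error in corpus.iter_documents():
        if error is not None:
            failures.append(f"{key.render()}: {error}")
        elif is_active(doc):
            entries.append(key)
    entries.sort(key=lambda k: k.render())
    return PlanList(
        entries=entries,
        generated_from=corpus.source_system,
        generated_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
        user_supplied=False,
        load_failures=failures,
    )


# ---------------------------------------------------------------------------
# plan-list XML round trip


def write_plan_list(plan_list: PlanList) -> str:
    root = etree.Element(
        "PlanList",
        generated_from=plan_list.generated_from,
        generated_at=plan_list.generated_at,
        user_supplied="true" if plan_list.user_supplied else "false",
    )
    for key in plan_list.entries:
        etree.SubElement(
            root,
            "Entry",
            patient_id=key.patient_id,
            course_id=key.course_id,
            plan_id=key.plan_id,
        )
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def read_plan_list(text: str | bytes) -> PlanList:
    if isinstance(text, str):
        text = text.encode("utf-8")
    try:
        root = etree.fromstring(text)
    except etree.XMLSyntaxError as exc:
        raise PlanParseError(f"malformed plan list XML: {exc}") from exc
    if root.tag != "PlanList":
        raise PlanListError(f"root element is {root.tag!r}, expected PlanList")
    entries = [
        PlanKey(
            patient_id=e.get("patient_id") or "",
            course_id=e.get("course_id") or "",
            plan_id=e.get("plan_id") or "",
        )
        for e in root.findall("Entry")
    ]
    return PlanList(  # duplicate entries raise PlanListError in __post_init__
        entries=entries,
        generated_from=root.get("generated_from", ""),
        generated_at=root.get("generated_at", ""),
        user_supplied=(root.get("user_supplied", "false").lower() == "true"),
    )
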