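"""Cause lists and many-to-one cause mappings.

Verbal autopsy evaluations compare cause-of-death assignments on a collapsed
*analysis cause list*: source codes (ICD-10, a WHO VA cause list, ...) are
mapped many-to-one onto a short list of substantive causes, plus at most one
distinguished *undetermined* category for deaths the coder could not
classify. The number of substantive causes ``C`` enters the chance-correction
terms of the agreement metrics, so the undetermined category is tracked
separately and never counted in ``C``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Cause",
    "CauseList",
    "CauseMap",
    "CauseFormatError",
    "UnmappedCodeError",
    "CompositionError",
    "load_cause_list",
    "map_cause",
    "compose_maps",
    "identity_map",
]


class CauseFormatError(ValueError):
    """A cause-list or cause-map definition violates its format contract."""


class UnmappedCodeError(KeyError):
    """A source code has no entry in the cause map."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"source code {self.code!r} is not present in the cause map"


class CompositionError(ValueError):
    """Two cause maps cannot be chained because their lists do not line up."""


@dataclass(frozen=True)
class Cause:
    """One analysis cause: a short stable code, a label, and whether it is
    the undetermined (non-informative) category."""

    code: str
    label: str
    is_undetermined: bool = False

    def __post_init__(self) -> None:
        if not self.code:
            raise CauseFormatError("cause code must be non-empty")


@dataclass(frozen=True)
class CauseList:
    """Ordered list of causes defining the axes of every downstream table.

    ``C`` counts the substantive (non-undetermined) causes and is the value
    used by the chance-corrected concordance. Order is significant: confusion
    tables, CSMF vectors and rank reports all follow it.
    """

    name: str
    causes: tuple[Cause, ...]

    def __post_init__(self) -> None:
        codes = [c.code for c in self.causes]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise CauseFormatError(f"duplicate cause codes in {self.name!r}: {dupes}")
        undet = [c for c in self.causes if c.is_undetermined]
        if len(undet) > 1:
            raise CauseFormatError(
                f"cause list {self.name!r} declares {len(undet)} undetermined causes; at most one is allowed"
            )

    # -- basic container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[Cause]:
        return iter(self.causes)

    def __len__(self) -> int:
        return len(self.causes)

    def __contains__(self, code: object) -> bool:
        return any(c.code == code for c in self.causes)

    def __getitem__(self, code: str) -> Cause:
        for c in self.causes:
            if c.code == code:
                return c
        raise KeyError(code)

    # -- derived views ------------------------------------------------------------
    @property
    def C(self) -> int:
        """Number of substantive causes (excludes undetermined)."""
        return sum(not c.is_undetermined for c in self.causes)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(c.code for c in self.causes)

    @property
    def substantive_codes(self) -> tuple[str, ...]:
        return tuple(c.code for c in self.causes if not c.is_undetermined)

    @property
    def undetermined(self) -> Cause | None:
        for c in self.causes:
            if c.is_undetermined:
                return c
        return None

    @property
    def undetermined_code(self) -> str | None:
        u = self.undetermined
        return None if u is None else u.code

    # -- IO -----------------------------------------------------------------------
    @classmethod
    def from_records(
        cls, name: str, records: Iterable[tuple[str, str, bool]]
    ) -> "CauseList":
        return cls(name, tuple(Cause(code, label, bool(u)) for code, label, u in records))

    def write(self, path: str | Path) -> None:
        """Write as delimited text ``code,label,undetermined`` (0/1 flag)."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["code", "label", "undetermined"])
            for c in self.causes:
                w.writerow([c.code, c.label, int(c.is_undetermined)])


def load_cause_list(path: str | Path, name: str | None = None) -> CauseList:
    """Read a cause list from delimited text with columns
    ``code,label,undetermined`` (undetermined in {0,1}); file order is kept."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"code", "label", "undetermined"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise CauseFormatError(
                f"{path}: cause list needs columns {sorted(required)}, found {reader.fieldnames}"
            )
        causes = []
        for row in reader:
            flag = str(row["undetermined"]).strip()
            if flag not in {"0", "1"}:
                raise CauseFormatError(
                    f"{path}: undetermined flag must be 0 or 1, got {flag!r} for code {row['code']!r}"
                )
            causes.append((row["code"].strip(), row["label"].strip(), flag == "1"))
    return CauseList.from_records(name or path.stem, causes)


@dataclass(frozen=True)
class CauseMap:
    """Many-to-one map from source codes to causes of a target list.

    ``source_list`` is either a :class:`CauseList` (when the source side is
    itself an analysis list, enabling composition checks) or a plain string
    naming an external code system such as ``"icd10"``.
    """

    source_list: CauseList | str
    target_list: CauseList
    entries: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = sorted(t for t in self.entries.values() if t not in self.target_list)
        if missing:
            raise CauseFormatError(
                f"cause map targets not in target list {self.target_list.name!r}: {missing}"
            )

    @property
    def source_name(self) -> str:
        return self.source_list if isinstance(self.source_list, str) else self.source_list.name

    def __call__(self, code: str) -> Cause:
        return map_cause(code, self)

    @classmethod
    def read(
        cls,
        path: str | Path,
        target_list: CauseList,
        source_list: CauseList | str | None = None,
    ) -> "CauseMap":
        """Read from delimited text with header ``source_code,target_code``."""
        path = Path(path)
        entries: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"source_code", "target_code"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise CauseFormatError(
                    f"{path}: cause map needs columns {sorted(required)}, found {reader.fieldnames}"
                )
            for row in reader:
                src = row["source_code"].strip()
                tgt = row["target_code"].strip()
                if src in entries and entries[src] != tgt:
                    raise CauseFormatError(
                        f"{path}: source code {src!r} maps to both {entries[src]!r} and {tgt!r}"
                    )
                entries[src] = tgt
        return cls(source_list or path.stem, target_list, entries)

    def write(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["source_code", "target_code"])
            for src, tgt in self.entries.items():
                w.writerow([src, tgt])


def map_cause(code: str, cause_map: CauseMap) -> Cause:
    """Look up the target cause for a source code.

    Raises :class:`UnmappedCodeError` (carrying the code) when absent; the
    caller decides whether that is fatal or routed to undetermined.
    """
    try:
        target_code = cause_map.entries[code]
    except KeyError:
        raise UnmappedCodeError(code) from None
    return cause_map.target_list[target_code]


def compose_maps(first: CauseMap, second: CauseMap) -> CauseMap:
    """Chain two maps (source → intermediate → target) into one.

    ``first.target_list`` must be ``second``'s source list so every
    intermediate code is resolvable.
    """
    second_source = second.source_list
    if isinstance(second_source, CauseList):
        if second_source is not first.target_list and second_source.codes != first.target_list.codes:
            raise CompositionError(
                f"cannot compose: {first.target_list.name!r} != {second_source.name!r}"
            )
    elif second_source != first.target_list.name:
        raise CompositionError(
            f"cannot compose: {first.target_list.name!r} != {second_source!r}"
        )
    entries = {}
    for src, mid in first.entries.items():
        try:
            entries[src] = second.entries[mid]
        except KeyError:
            raise CompositionError(
                f"intermediate code {mid!r} (from {src!r}) missing from second map"
            ) from None
    return CauseMap(first.source_list, second.target_list, entries)


def identity_map(cause_list: CauseList) -> CauseMap:
    """The identity map of a cause list onto itself."""
    return CauseMap(cause_list, cause_list, {c.code: c.code for c in cause_list})
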