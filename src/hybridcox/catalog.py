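"""Variable catalogs and clinical codelists.

A :class:`VariableCatalog` governs a wide cohort table: it names every
covariate, its type (numeric lab/score vs binary flag), its clinical group,
and whether it is *mandatory* (forced into every fitted model) or
*mandatory-imputable* (clinically important fields that are filled with
derivation-cohort population means at prediction time when absent).

A :class:`Codelist` is a named set of code prefixes on one record channel
(diagnosis, dispensing, lab, ...) with a role in cohort construction:
outcome component, exposure flag, exclusion rule, or entry marker.  No code
dictionaries are shipped; users supply their own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import yaml

CHANNELS = ("lab", "vitals", "diagnosis", "procedure", "dispensing", "attendance", "death")
GROUPS = ("demographic", "lab", "disease_history", "medication", "family_history", "utilization")
KINDS = ("numeric", "binary")
CODELIST_ROLES = ("outcome_component", "exposure", "exclusion", "entry_marker")


@dataclass(frozen=True)
class Variable:
    """One covariate in a wide cohort table."""

    name: str
    kind: str
    group: str
    mandatory: bool = False
    mandatory_imputable: bool = False
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"variable {self.name!r}: unknown kind {self.kind!r}")
        if self.group not in GROUPS:
            raise ValueError(f"variable {self.name!r}: unknown group {self.group!r}")


@dataclass
class VariableCatalog:
    """Ordered collection of :class:`Variable` with unique names."""

    variables: list[Variable]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate variable names in catalog: {dupes}")

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self):
        return iter(self.variables)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def numeric_names(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == "numeric"]

    @property
    def binary_names(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == "binary"]

    @property
    def mandatory_names(self) -> list[str]:
        return [v.name for v in self.variables if v.mandatory]

    @property
    def mandatory_imputable_names(self) -> list[str]:
        return [v.name for v in self.variables if v.mandatory_imputable]

    def to_records(self) -> list[dict]:
        return [
            dict(
                name=v.name,
                kind=v.kind,
                group=v.group,
                mandatory=v.mandatory,
                mandatory_imputable=v.mandatory_imputable,
                units=v.units,
            )
            for v in self.variables
        ]

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "VariableCatalog":
        return cls([Variable(**r) for r in records])

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({"variables": self.to_records()}, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VariableCatalog":
        payload = yaml.safe_load(Path(path).read_text())
        return cls.from_records(payload["variables"])

    def to_json(self) -> str:
        return json.dumps({"variables": self.to_records()})

    @classmethod
    def from_json(cls, payload: str) -> "VariableCatalog":
        return cls.from_records(json.loads(payload)["variables"])


@dataclass(frozen=True)
class Codelist:
    """Named set of code prefixes on one record channel."""

    name: str
    channel: str
    patterns: tuple[str, ...]
    role: str

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"codelist {self.name!r}: unknown channel {self.channel!r}")
        if self.role not in CODELIST_ROLES:
            raise ValueError(f"codelist {self.name!r}: unknown role {self.role!r}")
        if not self.patterns:
            raise ValueError(f"codelist {self.name!r}: patterns must be non-empty")
        object.__setattr__(self, "patterns", tuple(self.patterns))

    def matches(self, channel: str, code: str) -> bool:
        return channel == self.channel and any(str(code).startswith(p) for p in self.patterns)


def validate_codelists(codelists: Iterable[Codelist]) -> None:
    names = [c.name for c in codelists]
    if len(set(names)) != len(names):
        raise ValueError("codelist names must be unique within a configuration")
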