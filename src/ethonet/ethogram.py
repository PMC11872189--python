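"""Ethogram: the inventory of discrete behavioral elements used to code video.

An ethogram assigns every element a *functional role* used downstream by the
technique miner: termite-fishing techniques are element combinations that
contain a probing element (tool inserted into the nest) followed by an
extraction element (tool withdrawn and harvested).  Two ready-made
inventories are bundled, one for fishing at aerial (epigeal) termite mounds
and one for underground nests; the role map for each is an editable fixture,
not a fact of nature — users with their own ethograms load them from CSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Union

from .errors import ConfigurationError, LookupError_, ValidationError

OTHER_LABEL = "Other"


class Role(str, Enum):
    """Functional role of a behavioral element."""

    PROBE = "probe"
    EXTRACT = "extract"
    TOOL_MAKING = "tool_making"
    POSTURE = "posture"
    INGESTION = "ingestion"
    OTHER = "other"


@dataclass(frozen=True)
class ElementDef:
    label: str
    role: Role
    description: str = ""


@dataclass(frozen=True)
class Ethogram:
    """An ordered, label-unique inventory of behavioral elements.

    The catch-all ``Other`` code is always resolvable even when it is not
    listed explicitly; unknown labels in coded data map onto it.
    """

    elements: tuple[ElementDef, ...]
    _by_label: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        by_label = {}
        for el in self.elements:
            if el.label in by_label:
                raise ValidationError(f"duplicate element label {el.label!r}")
            by_label[el.label] = el
        by_label.setdefault(OTHER_LABEL, ElementDef(OTHER_LABEL, Role.OTHER, "catch-all"))
        object.__setattr__(self, "_by_label", by_label)

    # -- lookups ---------------------------------------------------------
    @property
    def labels(self) -> list[str]:
        return [el.label for el in self.elements]

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def role(self, label: str) -> Role:
        try:
            return self._by_label[label].role
        except KeyError:
            raise LookupError_(f"unknown behavioral element {label!r}")

    def labels_with_role(self, role: Union[Role, str]) -> list[str]:
        role = Role(role)
        return [el.label for el in self.elements if el.role is role]

    def require_functional_roles(self) -> None:
        """Technique mining needs at least one probe and one extract element."""
        if not self.labels_with_role(Role.PROBE) or not self.labels_with_role(Role.EXTRACT):
            raise ConfigurationError(
                "ethogram must contain at least one probe-role and one "
                "extract-role element for technique mining"
            )

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "Ethogram":
        return cls(tuple(ElementDef(lab, Role(role), desc) for lab, role, desc in records))

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "Ethogram":
        """Read an ethogram CSV with header ``label,role,description``."""
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"label", "role"} <= set(reader.fieldnames):
                raise ValidationError("ethogram CSV must have columns label,role[,description]")
            recs = [(r["label"], r["role"], r.get("description", "") or "") for r in reader]
        return cls.from_records(recs)

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "role", "description"])
            for el in self.elements:
                w.writerow([el.label, el.role.value, el.description])


# ---------------------------------------------------------------------------
# Bundled inventories.
#
# Roles follow the published grouping of each inventory (general / tool
# making / tool use / non-tool use), refined by element semantics: insertion
# elements (Probe*, Penetrate*, Elbow insert) are probes; withdrawal /
# harvest-assist elements (Extract*, Wrist/Forearm/Hand help, Help tool) are
# extracts; stick selection and modification are tool making; body
# orientations are postures; mouth-directed elements are ingestion.  Edit or
# replace via Ethogram.from_csv for other coding schemes.
# ---------------------------------------------------------------------------

_AERIAL = [
    ("Rigid stick", "tool_making", "selects a rigid stem as tool material"),
    ("Soft stick", "tool_making", "selects a soft/flexible stem as tool material"),
    ("Sit", "posture", "fishes while seated"),
    ("Lean", "posture", "fishes while leaning on the mound"),
    ("Fray bite", "tool_making", "frays the tool tip with the teeth"),
    ("Fray pull", "tool_making", "frays the tool tip by pulling fibers"),
    ("Probe 1h", "probe", "inserts the tool one-handed"),
    ("Probe 2h", "probe", "inserts the tool two-handed"),
    ("Shake side", "other", "shakes the inserted tool side to side"),
    ("Oscillate", "other", "oscillates the inserted tool"),
    ("Extract 1h", "extract", "withdraws the tool one-handed"),
    ("Extract 2h", "extract", "withdraws the tool two-handed"),
    ("Wrist help", "extract", "guides the withdrawn tool with the opposite wrist"),
    ("Forearm help", "extract", "guides the withdrawn tool along the forearm"),
    ("Sweep", "extract", "sweeps termites off the tool"),
    ("Scratch ground", "other", "scratches the mound surface before fishing"),
]

_UNDERGROUND = [
    ("Long stick", "tool_making", "selects a long stem as tool material"),
    ("Lay", "posture", "fishes lying down"),
    ("Lean", "posture", "fishes while leaning"),
    ("Sit", "posture", "fishes while seated"),
    ("Reduce", "tool_making", "shortens or thins the tool"),
    ("Fray bite", "tool_making", "frays the tool tip with the teeth"),
    ("Fray pull", "tool_making", "frays the tool tip by pulling fibers"),
    ("Tap ground", "other", "taps the ground above the nest"),
    ("Penetrate 1h", "probe", "drives the tool into the nest one-handed"),
    ("Penetrate 2h", "probe", "drives the tool into the nest two-handed"),
    ("Lip shake", "other", "vibrates the tool with the lips"),
    ("Elbow insert", "probe", "inserts the tool braced at the elbow"),
    ("Probe 2h", "probe", "inserts the tool two-handed"),
    ("Hand help", "extract", "guides the withdrawn tool with the free hand"),
    ("Wrist help", "extract", "guides the withdrawn tool with the opposite wrist"),
    ("Eat termite from wrist", "ingestion", "eats termites off the wrist"),
    ("Eat termite by moving head", "ingestion", "eats termites by mouthing along the tool"),
    ("Head to stick", "ingestion", "brings the head to the held tool"),
    ("Leave tool", "other", "abandons the tool in the nest"),
    ("Help tool", "extract", "assists tool withdrawal with a second grip"),
    ("Mop", "other", "mops termites with the back of the hand"),
]


def aerial_ethogram() -> Ethogram:
    """The 16-element inventory for fishing at aerial (epigeal) mounds."""
    return Ethogram.from_records(_AERIAL)


def underground_ethogram() -> Ethogram:
    """The 21-element inventory for fishing at underground nests."""
    return Ethogram.from_records(_UNDERGROUND)


def default_ethogram(mound_type: str) -> Ethogram:
    if mound_type == "aerial":
        return aerial_ethogram()
    if mound_type == "underground":
        return underground_ethogram()
    raise LookupError_(f"unknown mound type {mound_type!r}")
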