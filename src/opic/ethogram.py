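"""The coding vocabulary (ethogram) for overnight parent-child interaction coding.

An ethogram is a structured catalogue of behavior codes. Each code is either a
*state* event (has duration: start and stop) or a *point* event (instantaneous),
belongs to exactly one category, and may carry modifier vocabularies (e.g. the
body position of a subject in bed, or whether an activity was soothing).

The packaged default, :func:`default_opic_ethogram`, is the final Overnight
Parent-Child Interaction Coding (OPIC) system: 26 codes in 6 categories
(time domains, physical environment, child global state, location, activity,
physical interaction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import EthogramError

__all__ = [
    "EventType",
    "Subjects",
    "ModifierSet",
    "EventCode",
    "Ethogram",
    "default_opic_ethogram",
    "load_ethogram",
    "save_ethogram",
]


class EventType(str, Enum):
    """Whether a behavior is ongoing (STATE) or instantaneous (POINT)."""

    STATE = "STATE"
    POINT = "POINT"


class Subjects(str, Enum):
    """Which subject a code may be applied to."""

    CHILD = "child"
    PARENT = "parent"
    EITHER = "either"


def _canon(label: str) -> str:
    """Canonical key for case/whitespace-insensitive label matching."""
    return " ".join(str(label).split()).casefold()


@dataclass(frozen=True)
class ModifierSet:
    """A named modifier vocabulary attached to an event code.

    Parameters
    ----------
    name:
        Label of the modifier (e.g. ``"Position"``).
    allowed_values:
        Ordered, non-empty, unique vocabulary of values.
    """

    name: str
    allowed_values: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "allowed_values", tuple(self.allowed_values))
        if not self.name or not str(self.name).strip():
            raise EthogramError("modifier set needs a non-empty name")
        if not self.allowed_values:
            raise EthogramError(f"modifier set {self.name!r}: allowed_values is empty")
        keys = [_canon(v) for v in self.allowed_values]
        if len(set(keys)) != len(keys):
            raise EthogramError(
                f"modifier set {self.name!r}: duplicate values after case-normalization"
            )

    def resolve(self, value: str) -> str | None:
        """Return the canonical stored form of *value*, or None if not allowed."""
        key = _canon(value)
        for v in self.allowed_values:
            if _canon(v) == key:
                return v
        return None


@dataclass(frozen=True)
class EventCode:
    """One behavior code: name, category, state/point type, modifiers, subjects."""

    name: str
    category: str
    event_type: EventType
    modifier_sets: tuple[ModifierSet, ...] = ()
    applicable_subjects: Subjects = Subjects.EITHER

    def __post_init__(self) -> None:
        object.__setattr__(self, "event_type", EventType(self.event_type))
        object.__setattr__(self, "applicable_subjects", Subjects(self.applicable_subjects))
        object.__setattr__(self, "modifier_sets", tuple(self.modifier_sets))
        if not self.name or not str(self.name).strip():
            raise EthogramError("event code needs a non-empty name")
        mkeys = [_canon(m.name) for m in self.modifier_sets]
        if len(set(mkeys)) != len(mkeys):
            raise EthogramError(f"code {self.name!r}: duplicate modifier set names")

    def modifier_set(self, name: str) -> ModifierSet | None:
        key = _canon(name)
        for m in self.modifier_sets:
            if _canon(m.name) == key:
                return m
        return None


@dataclass(frozen=True)
class Ethogram:
    """A complete coding vocabulary: ordered categories and their codes."""

    version_label: str
    categories: tuple[str, ...]
    codes: tuple[EventCode, ...]
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", tuple(self.categories))
        object.__setattr__(self, "codes", tuple(self.codes))
        cat_keys = [_canon(c) for c in self.categories]
        if len(set(cat_keys)) != len(cat_keys):
            raise EthogramError("duplicate category labels")
        index: dict[str, EventCode] = {}
        for code in self.codes:
            key = _canon(code.name)
            if key in index:
                raise EthogramError(f"duplicate code name: {code.name!r}")
            if _canon(code.category) not in cat_keys:
                raise EthogramError(
                    f"code {code.name!r} references unknown category {code.category!r}"
                )
            index[key] = code
        object.__setattr__(self, "_index", index)

    # -- lookups ---------------------------------------------------------

    def get(self, code_name: str) -> EventCode | None:
        """Look up a code by name, case/whitespace-insensitively."""
        return self._index.get(_canon(code_name))

    def __contains__(self, code_name: str) -> bool:
        return _canon(code_name) in self._index

    def category_of(self, code_name: str) -> str:
        code = self.get(code_name)
        if code is None:
            raise EthogramError(f"unknown code: {code_name!r}")
        return code.category

    def codes_in_category(self, category: str) -> tuple[EventCode, ...]:
        key = _canon(category)
        return tuple(c for c in self.codes if _canon(c.category) == key)

    # -- (de)serialization -----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version_label": self.version_label,
            "categories": list(self.categories),
            "codes": [
                {
                    "name": c.name,
                    "category": c.category,
                    "type": c.event_type.value,
                    "subjects": c.applicable_subjects.value,
                    "modifiers": [
                        {"name": m.name, "values": list(m.allowed_values)}
                        for m in c.modifier_sets
                    ],
                }
                for c in self.codes
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Ethogram":
        for key in ("version_label", "categories", "codes"):
            if key not in d:
                raise EthogramError(f"ethogram file missing required field {key!r}")
        codes = []
        for i, cd in enumerate(d["codes"]):
            if not isinstance(cd, Mapping):
                raise EthogramError(f"codes[{i}] is not an object")
            for key in ("name", "category", "type"):
                if key not in cd:
                    raise EthogramError(f"codes[{i}] missing required field {key!r}")
            try:
                etype = EventType(str(cd["type"]).upper())
            except ValueError:
                raise EthogramError(
                    f"codes[{i}] ({cd['name']!r}): type must be STATE or POINT, "
                    f"got {cd['type']!r}"
                ) from None
            try:
                subjects = Subjects(str(cd.get("subjects", "either")).lower())
            except ValueError:
                raise EthogramError(
                    f"codes[{i}] ({cd['name']!r}): subjects must be child/parent/either"
                ) from None
            mods = tuple(
                ModifierSet(m["name"], tuple(m["values"]))
                for m in cd.get("modifiers", [])
            )
            codes.append(
                EventCode(
                    name=cd["name"],
                    category=cd["category"],
                    event_type=etype,
                    modifier_sets=mods,
                    applicable_subjects=subjects,
                )
            )
        return cls(
            version_label=str(d["version_label"]),
            categories=tuple(d["categories"]),
            codes=tuple(codes),
        )


# ---------------------------------------------------------------------------
# Packaged default: the final 26-code, 6-category coding system
# ---------------------------------------------------------------------------

POSITION_MODIFIER = ModifierSet(
    "Position",
    ("lying", "sitting", "standing", "on all fours", "crouching", "mobile"),
)

SOOTHING_MODIFIER = ModifierSet(
    "Helpful to sleep?",
    ("soothing", "non-soothing", "neutral"),
)

_CATEGORIES = (
    "Time domains",
    "Physical environment",
    "Child global state",
    "Location",
    "Activity",
    "Physical interaction",
)

TIME_DOMAINS = "Time domains"
PHYSICAL_ENVIRONMENT = "Physical environment"
CHILD_GLOBAL_STATE = "Child global state"
LOCATION = "Location"
ACTIVITY = "Activity"
PHYSICAL_INTERACTION = "Physical interaction"

# Anchor code names used by the sleep-metrics derivation.
SETTLING_ROUTINE = "Settling routine"
LIGHTS_OUT = "Lights out"
SLEEP_ONSET = "Sleep onset"
MORNING_WAKING = "Morning waking"
SLEEP = "Sleep"
NIGHT_WAKING = "Night waking"
MOVEMENT_AROUSAL = "Movement arousal"


def default_opic_ethogram() -> Ethogram:
    """The packaged final coding system: 26 codes in 6 categories.

    Time domains (4), physical environment (3), child global state (3),
    location (2, with a 6-value position modifier), activity (12, with a
    3-value soothing modifier), physical interaction (2). Child-global-state
    codes apply to the child only; location, activity and physical-interaction
    codes apply to either subject; time domains are properties of the night
    itself and carry no subject restriction.
    """
    S, P = EventType.STATE, EventType.POINT
    child, either = Subjects.CHILD, Subjects.EITHER
    codes = (
        # Time domains
        EventCode(SETTLING_ROUTINE, TIME_DOMAINS, S),
        EventCode(LIGHTS_OUT, TIME_DOMAINS, P),
        EventCode(SLEEP_ONSET, TIME_DOMAINS, P),
        EventCode(MORNING_WAKING, TIME_DOMAINS, P),
        # Physical environment
        EventCode("Noise intrusion", PHYSICAL_ENVIRONMENT, S),
        EventCode("Music", PHYSICAL_ENVIRONMENT, S),
        EventCode("Bright lighting", PHYSICAL_ENVIRONMENT, S),
        # Child global state (child only)
        EventCode(SLEEP, CHILD_GLOBAL_STATE, S, applicable_subjects=child),
        EventCode(NIGHT_WAKING, CHILD_GLOBAL_STATE, S, applicable_subjects=child),
        EventCode(MOVEMENT_AROUSAL, CHILD_GLOBAL_STATE, S, applicable_subjects=child),
        # Location (position modifier on both codes)
        EventCode("In bed", LOCATION, S, (POSITION_MODIFIER,), either),
        EventCode("Out of bed", LOCATION, S, (POSITION_MODIFIER,), either),
        # Activity (soothing modifier on all 12; "Laughing" is the single point code)
        EventCode("Laughing", ACTIVITY, P, (SOOTHING_MODIFIER,), either),
        EventCode("Reading", ACTIVITY, S, (SOOTHING_MODIFIER,), either),
        EventCode("Singing", ACTIVITY, S, (SOOTHING_MODIFIER,), either),
        EventCode("Playing", ACTIVITY, S, (SOOTHING_MODIFIER,), either),
        EventCode("Eating", ACTIVITY, S, (SOOTHING_MODIFIER,), either),
        EventCode("Drinking", ACTIVITY, S, (SOOTHING_MODIFIER,), either),
        EventCode("Verbalization", ACTIVITY, S, (SOOTHING_MODIFIER,), either),
        EventCode("Rocking", ACTIVITY, S, (SOOTHING_MODIFIER,), either),
        EventCode("Tidying/housekeeping", ACTIVITY, S, (SOOTHING_MODIFIER,), either),
        EventCode("Personal care", ACTIVITY, S, (SOOTHING_MODIFIER,), either),
        EventCode("Electronics", ACTIVITY, S, (SOOTHING_MODIFIER,), either),
        EventCode("Self-stimulating", ACTIVITY, S, (SOOTHING_MODIFIER,), either),
        # Physical interaction
        EventCode("Brief close physical contact", PHYSICAL_INTERACTION, P),
        EventCode("Extended close physical contact", PHYSICAL_INTERACTION, S),
    )
    return Ethogram(version_label="OPIC final", categories=_CATEGORIES, codes=codes)


def default_ethogram_path() -> Path:
    """Path of the canonical default ethogram JSON file shipped in the package."""
    return Path(str(resources.files("opic").joinpath("data/opic_ethogram.json")))


def load_ethogram(config_path: str | Path) -> Ethogram:
    """Load an ethogram from a JSON file, validating all invariants.

    Raises
    ------
    EthogramError
        On parse failure (naming the offending field), duplicate code names,
        or a code referencing an unknown category.
    """
    path = Path(config_path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise EthogramError(f"cannot read ethogram file {path}: {exc}") from exc
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise EthogramError(f"ethogram file {path} is not valid JSON: {exc}") from exc
    if not isinstance(data, Mapping):
        raise EthogramError(f"ethogram file {path}: top level must be a JSON object")
    return Ethogram.from_dict(data)


def save_ethogram(e: Ethogram, path: str | Path) -> Path:
    """Serialize an ethogram to JSON such that load_ethogram round-trips it."""
    path = Path(path)
    path.write_text(
        json.dumps(e.to_dict(), indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )
    return path
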