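"""Declarative per-attribute de-identification policy.

A :class:`Policy` maps attributes to one of the de-identification actions
(keep / clear / overwrite / remove / remap-UID / randomise date or time) at
one of the two stages: stage 1 emulates the source (PACS export)
de-identification, stage 2 is the attribute-level pass run by this tool.
Every policy is validated against the attribute-type registry before use so
that no rule can violate the standard (e.g. removing a Type 1 attribute).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import yaml

from .core import (
    ConfigError,
    ElementType,
    REGISTRY,
    Tag,
    lookup_attribute,
    tag_for,
)


class ActionKind(enum.Enum):
    KEEP = "keep"            # SAFE: leave the attribute alone
    CLEAR = "clear"          # keep the element, zero-length value
    OVERWRITE = "overwrite"  # keep the element, replace the value
    REMOVE = "remove"        # delete the element entirely
    REMAP_UID = "remap_uid"  # deterministic salted Instance-UID remapping
    RANDOM_DATE = "random_date"  # per-study random date (date+time for DT)
    RANDOM_TIME = "random_time"  # per-study random time


@dataclass(frozen=True)
class Action:
    kind: ActionKind
    replacement: str | None = None

    def __post_init__(self) -> None:
        if self.kind is ActionKind.OVERWRITE:
            if not self.replacement:
                raise ConfigError("OVERWRITE action requires a non-empty replacement")
        elif self.replacement is not None:
            raise ConfigError(f"{self.kind.name} action forbids a replacement value")


class Stage(enum.Enum):
    STAGE1 = 1
    STAGE2 = 2


@dataclass(frozen=True)
class PolicyRule:
    target: str                 # registry keyword
    stage: Stage
    action: Action
    rationale: str = ""

    @property
    def tag(self) -> Tag:
        return tag_for(self.target)


KEEP = Action(ActionKind.KEEP)
CLEAR = Action(ActionKind.CLEAR)
REMOVE = Action(ActionKind.REMOVE)
REMAP_UID = Action(ActionKind.REMAP_UID)
RANDOM_DATE = Action(ActionKind.RANDOM_DATE)
RANDOM_TIME = Action(ActionKind.RANDOM_TIME)


def _ow(text: str) -> Action:
    return Action(ActionKind.OVERWRITE, text)


@dataclass
class Policy:
    """A validated set of per-attribute rules plus randomisation parameters.

    ``date_window`` bounds the random replacement dates; ``salt`` feeds the
    UID remapper so the same cohort always remaps consistently.
    """

    rules: list[PolicyRule] = field(default_factory=list)
    default_private_action: Action = REMOVE
    salt: str = ""
    date_window: tuple[date, date] = (date(2000, 1, 1), date(2020, 12, 31))

    def rule_for(self, tag: Tag | str, stage: Stage) -> PolicyRule | None:
        tag = tag_for(tag)
        for rule in self.rules:
            if rule.stage is stage and rule.tag == tag:
                return rule
        return None

    def merged_rules(self) -> dict[Tag, PolicyRule]:
        """Final-state rule per tag (a stage-2 rule supersedes stage 1)."""
        merged: dict[Tag, PolicyRule] = {}
        for stage in (Stage.STAGE1, Stage.STAGE2):
            for rule in self.rules:
                if rule.stage is stage:
                    merged[rule.tag] = rule
        return merged


def builtin_policy(salt: str = "", date_window: tuple[date, date] | None = None) -> Policy:
    """The two-stage policy of the source-export + attribute-level process.

    Stage 1 reproduces the PACS export at the clinical site: Instance UIDs
    remapped hierarchy-consistently, identifying names/IDs overwritten with
    ``CONFIDENTIAL`` (Patient ID with ``!T000``), obvious patient attributes
    cleared, and every acquisition date/time replaced by a random one.
    Stage 2 removes private elements, the Request Attributes Sequence, the
    Irradiation Event UID and private file-meta information, randomises the
    calibration date/time, and clears institution/physician/comment fields.
    """
    s1, s2 = Stage.STAGE1, Stage.STAGE2
    rules = [
        # stage 1: Instance UIDs, hierarchy-preserving
        PolicyRule("MediaStorageSOPInstanceUID", s1, REMAP_UID),
        PolicyRule("SOPInstanceUID", s1, REMAP_UID),
        PolicyRule("StudyInstanceUID", s1, REMAP_UID),
        PolicyRule("SeriesInstanceUID", s1, REMAP_UID),
        # stage 1: equipment / network identifiers
        PolicyRule("StationName", s1, _ow("CONFIDENTIAL")),
        PolicyRule("SourceApplicationEntityTitle", s1, _ow("CONFIDENTIAL")),
        # stage 1: IDs
        PolicyRule("PatientID", s1, _ow("!T000")),
        PolicyRule("StudyID", s1, _ow("CONFIDENTIAL")),
        PolicyRule("ScheduledProcedureStepID", s1, _ow("CONFIDENTIAL")),
        # stage 1: sensitive numbers
        PolicyRule("AccessionNumber", s1, _ow("CONFIDENTIAL")),
        # stage 1: obvious patient information
        PolicyRule("PatientName", s1, _ow("CONFIDENTIAL")),
        PolicyRule("PatientBirthDate", s1, CLEAR),
        PolicyRule("PatientSex", s1, CLEAR),
        PolicyRule("PatientAge", s1, CLEAR),
        # stage 1: dates and times
        PolicyRule("StudyDate", s1, RANDOM_DATE),
        PolicyRule("SeriesDate", s1, RANDOM_DATE),
        PolicyRule("AcquisitionDate", s1, RANDOM_DATE),
        PolicyRule("ContentDate", s1, RANDOM_DATE),
        PolicyRule("AcquisitionDateTime", s1, RANDOM_DATE),  # DT: date+time
        PolicyRule("StudyTime", s1, RANDOM_TIME),
        PolicyRule("SeriesTime", s1, RANDOM_TIME),
        PolicyRule("AcquisitionTime", s1, RANDOM_TIME),
        PolicyRule("ContentTime", s1, RANDOM_TIME),
        # stage 2: private attributes
        PolicyRule("PrivateCreator", s2, REMOVE),
        PolicyRule("AnonymizationStatus", s2, REMOVE),
        # stage 2: sequences (Requested Procedure ID is Type 1C inside the
        # Type 3 sequence, so the whole sequence is removed instead)
        PolicyRule("RequestAttributesSequence", s2, REMOVE),
        # stage 2: dates and times
        PolicyRule("DateOfLastCalibration", s2, RANDOM_DATE),
        PolicyRule("TimeOfLastCalibration", s2, RANDOM_TIME),
        # stage 2: names
        PolicyRule("InstitutionName", s2, CLEAR),
        PolicyRule("InstitutionAddress", s2, CLEAR),
        PolicyRule("ReferringPhysicianName", s2, CLEAR),
        # stage 2: comments
        PolicyRule("ImageComments", s2, CLEAR),
        # stage 2: UIDs
        PolicyRule("IrradiationEventUID", s2, REMOVE),
        PolicyRule("PrivateInformationCreatorUID", s2, REMOVE),
        PolicyRule("PrivateInformation", s2, REMOVE),
    ]
    policy = Policy(rules=rules, salt=salt)
    if date_window is not None:
        policy.date_window = date_window
    return policy


def action_for(policy: Policy, tag: Tag | str | int, stage: Stage) -> Action:
    """Resolve the action for *tag* at *stage*.

    An explicit rule wins; otherwise unlisted private tags fall under the
    fail-closed ``default_private_action`` at stage 2; everything else is
    SAFE and kept.
    """
    tag = Tag(tag_for(tag)) if isinstance(tag, str) else Tag(tag)
    rule = policy.rule_for(tag, stage)
    if rule is not None:
        return rule.action
    if stage is Stage.STAGE2 and tag.is_private:
        return policy.default_private_action
    return KEEP


def validate_policy(policy: Policy, registry: dict | None = None) -> list[str]:
    """Check every rule against the data-element types.

    Returns one violation string per rule that removes a Type 1/1C/2/2C
    attribute, clears a Type 1 attribute, or duplicates a (target, stage)
    pair.  An empty list means the policy is safe to apply.
    """
    registry = registry if registry is not None else REGISTRY
    violations: list[str] = []
    seen: set[tuple[Tag, Stage]] = set()
    for rule in policy.rules:
        spec = registry.get(rule.tag) or lookup_attribute(rule.tag)
        key = (rule.tag, rule.stage)
        if key in seen:
            violations.append(
                f"duplicate rule for {rule.target} at {rule.stage.name}"
            )
        seen.add(key)
        et = spec.element_type
        if rule.action.kind is ActionKind.REMOVE and et in (
            ElementType.T1, ElementType.T1C, ElementType.T2, ElementType.T2C
        ):
            violations.append(
                f"REMOVE on Type {et.value} attribute {rule.target} "
                "violates the DICOM standard"
            )
        if rule.action.kind is ActionKind.CLEAR and et is ElementType.T1:
            violations.append(
                f"CLEAR on Type 1 attribute {rule.target} "
                "violates the DICOM standard"
            )
    return violations


# ---------------------------------------------------------------------------
# config loading

_RESERVED_KEYS = {"salt", "date_window", "default_private_action"}
_ACTION_KINDS = {k.value: k for k in ActionKind}


def _parse_rule(keyword: str, entry: dict) -> PolicyRule:
    try:
        stage = Stage[str(entry["stage"]).upper()]
    except KeyError:
        raise ConfigError(f"{keyword}: missing or unknown stage {entry.get('stage')!r}")
    kind_name = str(entry.get("action", "")).lower()
    if kind_name not in _ACTION_KINDS:
        raise ConfigError(f"{keyword}: unknown action {entry.get('action')!r}")
    action = Action(_ACTION_KINDS[kind_name], entry.get("replacement"))
    tag_for(keyword)  # raises ConfigError on unknown keyword
    return PolicyRule(keyword, stage, action, entry.get("rationale", "user override"))


def load_policy_config(path: str | Path) -> Policy:
    """Load a YAML/JSON policy config and merge it onto the builtin policy.

    The format is a flat mapping ``keyword -> {stage, action, replacement}``
    (or a list of such entries per keyword, one per stage), plus the reserved
    keys ``salt``, ``date_window`` (``{earliest, latest}`` ISO dates) and
    ``default_private_action``.  The merged policy is re-validated; any
    violation aborts with a config error listing the offending entries.
    """
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    doc = doc or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"policy config {path} must be a mapping")

    policy = builtin_policy()
    errors: list[str] = []
    overrides: list[PolicyRule] = []
    for keyword, entry in doc.items():
        if keyword in _RESERVED_KEYS:
            continue
        entries = entry if isinstance(entry, list) else [entry]
        for one in entries:
            try:
                overrides.append(_parse_rule(keyword, one))
            except ConfigError as exc:
                errors.append(str(exc))
    if errors:
        raise ConfigError("invalid policy config entries: " + "; ".join(errors))

    for override in overrides:
        policy.rules = [
            r for r in policy.rules
            if not (r.stage is override.stage and r.tag == override.tag)
        ]
        policy.rules.append(override)

    if "salt" in doc:
        policy.salt = str(doc["salt"])
    if "date_window" in doc:
        win = doc["date_window"]
        try:
            policy.date_window = (
                date.fromisoformat(str(win["earliest"])),
                date.fromisoformat(str(win["latest"])),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid date_window: {exc}") from exc
    if "default_private_action" in doc:
        kind_name = str(doc["default_private_action"]).lower()
        if kind_name not in _ACTION_KINDS:
            raise ConfigError(f"unknown default_private_action {doc['default_private_action']!r}")
        policy.default_private_action = Action(_ACTION_KINDS[kind_name])

    violations = validate_policy(policy)
    if violations:
        raise ConfigError("policy config fails validation: " + "; ".join(violations))
    return policy
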