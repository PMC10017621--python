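"""Hierarchical phase/step annotation ontology.

A surgical procedure is decomposed into *phases* (first-level temporal
components executed sequentially) which consist of finer-grained *steps*.
Facultative elements may legitimately be absent from an individual procedure.
The packaged laparoscopic Roux-en-Y gastric bypass (LRYGB) schema has 12
phases and 46 steps; any procedure can be described by authoring a YAML file
with the same structure.

This is an annotation label schema, not a description-logic ontology: the
only structure is the label vocabulary, canonical ordering, facultative
flags, and phase->step parentage.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import yaml

__all__ = [
    "PhaseDef",
    "StepDef",
    "Ontology",
    "OntologyError",
    "load_ontology",
    "save_ontology",
    "validate_ontology",
    "labels_at_level",
    "load_packaged_lrygb",
]

Level = Literal["phase", "step"]

#: Default label for un-annotated time.  The metrics operate on a *total*
#: labelling of the video timeline, so gaps are made explicit.
DEFAULT_IDLE_LABEL = "idle"


class OntologyError(ValueError):
    """Raised on schema parse failures or invariant violations."""


@dataclass(frozen=True)
class PhaseDef:
    """One first-level temporal component of the procedure."""

    id: int
    name: str
    facultative: bool = False


@dataclass(frozen=True)
class StepDef:
    """One action accomplished within a parent phase."""

    id: int
    name: str
    parent_phase_id: int
    facultative: bool = False


@dataclass(frozen=True)
class Ontology:
    """An ordered phase/step label vocabulary with parentage.

    Parameters
    ----------
    name
        Schema identifier (e.g. ``"lrygb-v1"``).
    phases, steps
        Definitions in canonical order; ids must be contiguous from 1.
    idle_label
        Reserved label for un-annotated time; must not collide with any
        phase or step name.
    """

    name: str
    phases: tuple[PhaseDef, ...]
    steps: tuple[StepDef, ...]
    idle_label: str = DEFAULT_IDLE_LABEL

    def phase_by_id(self, pid: int) -> PhaseDef:
        return self._phase_index[pid]

    def parent_phase_of_step(self, step_name: str) -> PhaseDef:
        """Phase owning the step with this name."""
        step = self._step_by_name[step_name]
        return self._phase_index[step.parent_phase_id]

    def steps_of_phase(self, pid: int) -> tuple[StepDef, ...]:
        return tuple(s for s in self.steps if s.parent_phase_id == pid)

    @property
    def _phase_index(self) -> dict[int, PhaseDef]:
        return {p.id: p for p in self.phases}

    @property
    def _step_by_name(self) -> dict[str, StepDef]:
        return {s.name: s for s in self.steps}

    def labels(self, level: Level) -> list[str]:
        return labels_at_level(self, level)

    def is_facultative(self, label: str, level: Level) -> bool:
        defs: Iterable = self.phases if level == "phase" else self.steps
        for d in defs:
            if d.name == label:
                return d.facultative
        raise KeyError(label)


def validate_ontology(o: Ontology) -> list[str]:
    """Check every schema invariant; return violation descriptions.

    Reports, never raises.  Empty result means the ontology is valid.
    """
    violations: list[str] = []

    phase_ids = [p.id for p in o.phases]
    if phase_ids != list(range(1, len(phase_ids) + 1)):
        violations.append(
            f"phase ids must be contiguous from 1 in order, got {phase_ids}"
        )
    seen: dict[str, int] = {}
    for p in o.phases:
        if not p.name:
            violations.append(f"phase {p.id}: empty name")
        if p.name in seen:
            violations.append(
                f"duplicate phase name {p.name!r} (ids {seen[p.name]} and {p.id})"
            )
        seen[p.name] = p.id

    step_ids = [s.id for s in o.steps]
    if len(set(step_ids)) != len(step_ids):
        violations.append("step ids are not unique")
    valid_pids = set(phase_ids)
    seen_steps: dict[str, int] = {}
    for s in o.steps:
        if not s.name:
            violations.append(f"step {s.id}: empty name")
        if s.name in seen_steps:
            violations.append(
                f"duplicate step name {s.name!r} (ids {seen_steps[s.name]} and {s.id})"
            )
        seen_steps[s.name] = s.id
        if s.parent_phase_id not in valid_pids:
            violations.append(
                f"step {s.id} ({s.name!r}): parent_phase_id {s.parent_phase_id} "
                "does not resolve to a phase"
            )

    all_names = {p.name for p in o.phases} | {s.name for s in o.steps}
    if o.idle_label in all_names:
        violations.append(
            f"idle_label {o.idle_label!r} collides with a phase or step name"
        )
    if not o.idle_label:
        violations.append("idle_label must be non-empty")
    return violations


def labels_at_level(o: Ontology, level: Level) -> list[str]:
    """Canonical ordered label list at one level (idle excluded)."""
    if level == "phase":
        return [p.name for p in o.phases]
    if level == "step":
        return [s.name for s in o.steps]
    raise ValueError(f"level must be 'phase' or 'step', got {level!r}")


def _parse(doc: object, source: str) -> Ontology:
    if not isinstance(doc, dict):
        raise OntologyError(f"{source}: top level must be a mapping")
    try:
        phases = tuple(
            PhaseDef(
                id=int(p["id"]),
                name=str(p["name"]),
                facultative=bool(p.get("facultative", False)),
            )
            for p in doc.get("phases", [])
        )
        steps = tuple(
            StepDef(
                id=int(s["id"]),
                name=str(s["name"]),
                facultative=bool(s.get("facultative", False)),
                parent_phase_id=int(s["parent_phase_id"]),
            )
            for s in doc.get("steps", [])
        )
    except (KeyError, TypeError) as exc:
        raise OntologyError(f"{source}: missing or malformed key: {exc}") from exc
    return Ontology(
        name=str(doc.get("name", "unnamed")),
        idle_label=str(doc.get("idle_label", DEFAULT_IDLE_LABEL)),
        phases=phases,
        steps=steps,
    )


def load_ontology(path: str | Path) -> Ontology:
    """Load and validate an ontology from a YAML schema file.

    Raises
    ------
    OntologyError
        On YAML parse failure (with the parser's location message) or when
        any invariant is violated (all violations listed).
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise OntologyError(f"{path}: not valid YAML: {exc}") from exc
    onto = _parse(doc, str(path))
    violations = validate_ontology(onto)
    if violations:
        raise OntologyError(
            f"{path}: invalid ontology:\n  " + "\n  ".join(violations)
        )
    return onto


def save_ontology(o: Ontology, path: str | Path) -> None:
    """Write an ontology in the canonical YAML schema (round-trips exactly)."""
    doc = {
        "name": o.name,
        "idle_label": o.idle_label,
        "phases": [
            {"id": p.id, "name": p.name, "facultative": p.facultative}
            for p in o.phases
        ],
        "steps": [
            {
                "id": s.id,
                "name": s.name,
                "facultative": s.facultative,
                "parent_phase_id": s.parent_phase_id,
            }
            for s in o.steps
        ],
    }
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False, allow_unicode=True), encoding="utf-8"
    )


def load_packaged_lrygb() -> Ontology:
    """The packaged LRYGB schema: 12 phases, 46 steps."""
    ref = importlib.resources.files("surgagree.data").joinpath("lrygb.yaml")
    with importlib.resources.as_file(ref) as p:
        return load_ontology(p)
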