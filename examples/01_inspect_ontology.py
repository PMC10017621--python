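"""Load the packaged LRYGB annotation schema and show its structure.

Prints the 12 phases in canonical order with their step counts and
facultative flags.  Facultative elements may legitimately be absent from an
individual procedure (e.g. mesenteric defect closure is routine in some
centers and rare in others).
"""

from surgagree import load_packaged_lrygb, validate_ontology

onto = load_packaged_lrygb()
print(f"ontology {onto.name!r}: {len(onto.phases)} phases, "
      f"{len(onto.steps)} steps, idle label {onto.idle_label!r}")
print(f"violations: {validate_ontology(onto) or 'none'}\n")

for phase in onto.phases:
    steps = onto.steps_of_phase(phase.id)
    flag = " (facultative)" if phase.facultative else ""
    print(f"{phase.id:2d}. {phase.name}{flag} — {len(steps)} steps")
    for s in steps:
        sflag = " (facultative)" if s.facultative else ""
        print(f"      {s.id:2d}. {s.name}{sflag}")
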