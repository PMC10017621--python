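import pytest

from surgagree import (
    AnnotationTrack, Interval, Ontology, PhaseDef, StepDef, VideoAnnotation,
    load_packaged_lrygb, totalize,
)


@pytest.fixture(scope="session")
def lrygb():
    return load_packaged_lrygb()


@pytest.fixture()
def toy_ontology():
    """Two phases / three steps, one facultative element per level."""
    return Ontology(
        name="toy",
        idle_label="idle",
        phases=(
            PhaseDef(1, "Access", facultative=False),
            PhaseDef(2, "Resection", facultative=True),
        ),
        steps=(
            StepDef(1, "Trocar placement", parent_phase_id=1),
            StepDef(2, "Dissection", parent_phase_id=2),
            StepDef(3, "Stapling", parent_phase_id=2, facultative=True),
        ),
    )


def make_track(segments, duration_ms=None, level="phase", video_id="v",
               total=True):
    """Build a track from (label, start, end) triples; totalized by default."""
    ivs = tuple(Interval(lab, s, e) for lab, s, e in segments)
    dur = duration_ms if duration_ms is not None else (ivs[-1].end_ms if ivs else 0)
    tr = AnnotationTrack(video_id, level, ivs, dur)
    return totalize(tr) if total else tr


@pytest.fixture()
def track_factory():
    return make_track
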