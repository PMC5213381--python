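import pytest

from paddle_ire.field_model import MidplaneModel, PaddleGeometry
from paddle_ire.records_io import AblationSite, Group, HistologySection


@pytest.fixture(scope="session")
def geometry_h7() -> PaddleGeometry:
    """The reference configuration: 25 mm paddles, 7 mm tissue."""
    return PaddleGeometry(paddle_radius=12.5, separation=7.0)


@pytest.fixture(scope="session")
def model() -> MidplaneModel:
    return MidplaneModel(paddle_radius=12.5)


def make_site(
    pig_id="pig01",
    group=Group.SINGLE_50J,
    thickness=7.0,
    currents=(25.3,),
    voltages=None,
    arcing=False,
    sections=(),
) -> AblationSite:
    if voltages is None:
        voltages = tuple(30.0 * c for c in currents)
    return AblationSite(
        pig_id=pig_id,
        group=group,
        thickness=thickness,
        peak_voltages=tuple(voltages),
        peak_currents=tuple(currents),
        arcing=arcing,
        sections=tuple(sections),
    )


def make_section(necrotic=5.0, transition=None, spans=True, vital_inside=False) -> HistologySection:
    return HistologySection(
        necrotic_halfwidth=necrotic,
        transition_halfwidth=transition if transition is not None else necrotic + 1.0,
        contains_vital_inside=vital_inside,
        spans_between_paddles=spans,
    )
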