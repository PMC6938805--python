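import pytest

from sprayrisk.data_tables import (
    ApplicationEvent,
    CropInterceptionRow,
    Scenario,
    SubstanceRecord,
)
from sprayrisk.fixtures import FixtureSpec, make_fixture, make_reference_apple_scenario


@pytest.fixture(scope="session")
def apple_example():
    """Apple spray series shaped like the published six-column PEC excerpt."""
    return make_reference_apple_scenario()


@pytest.fixture
def fixture_trio(tmp_path):
    """A default synthetic table trio on disk, plus its ground-truth sidecar."""
    return make_fixture(FixtureSpec(seed=1), tmp_path)


def make_substance(cid=0, name="sub", dt50=20.0, lc50=100.0, noec=10.0, kfoc=200.0,
                   chem_class="classA", chem_use="fungicide"):
    return SubstanceRecord(
        compound_id=cid, name=name, cas_nr="0-0-0", chemical_class=chem_class,
        chemical_use=chem_use, degt50_soil=dt50, lc50_earthworm=lc50,
        noec_earthworm=noec, kfoc=kfoc,
    )


def make_event(i=0, cid=0, day=91, rate=1.0, bbch=5, factor=1.0, depth="mix",
               name="sub"):
    from sprayrisk.calendar365 import month_of_day

    return ApplicationEvent(
        event_index=i, compound_id=cid, compound_name=name, application_day=day,
        application_month=month_of_day(day), rate_kg_ai_ha=rate, bbch=bbch,
        degradation_factor=factor, mixing_depth_spec=depth,
    )


def make_scenario(events, days=365, temps=(20.0,) * 12, **kw):
    return Scenario(
        description="test", crop_id=1, events=events,
        monthly_temperature=(tuple(temps),), simulation_days=days, **kw,
    )


FLAT_CROPTAB = [CropInterceptionRow(1, "crop", 0, 99, 0.0)]
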