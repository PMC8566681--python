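import pytest

from oxishelf import CurveParams, KineticLaw, simulate_curve
from oxishelf.io import (
    build_oil_records,
    load_reference_classes,
    load_reference_ips,
    load_reference_kinetics,
    load_reference_profiles,
    load_reference_properties,
)


@pytest.fixture(scope="session")
def reference_profiles():
    return {p.oil_id: p for p in load_reference_profiles()}


@pytest.fixture(scope="session")
def reference_classes():
    return load_reference_classes()


@pytest.fixture(scope="session")
def reference_properties():
    return load_reference_properties()


@pytest.fixture(scope="session")
def reference_ips():
    return load_reference_ips()


@pytest.fixture(scope="session")
def reference_kinetics():
    return load_reference_kinetics()


@pytest.fixture(scope="session")
def oil_records():
    """The nine oils entering the correlation/regression stage."""
    return build_oil_records()


@pytest.fixture()
def clean_curve():
    """Noiseless sigmoid curve with a known two-tangent IP of 34.6 h."""
    params = CurveParams(m1=0.5, d=200.0, s=1.0, t_c=36.6, noise_sd=0.0)
    return simulate_curve(params, 70.0)


@pytest.fixture(scope="session")
def almond_law():
    """Temperature law matching a real almond-oil accelerated series."""
    return KineticLaw(log_ip0=4.2126, k0=0.0325)
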