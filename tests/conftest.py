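import pytest

from edaffinity.binding import BindingSystem, DialysisGeometry
from edaffinity.simulate import AssayDesign


@pytest.fixture
def geometry() -> DialysisGeometry:
    return DialysisGeometry()


@pytest.fixture
def worked_system() -> BindingSystem:
    """2.4 nM antibody sites, K = 2 nM, 5 nM tracer in 100 µL — the
    monoclonal reference condition whose equilibrium is known from an
    independent 1-D bisection of the tracer mass balance."""
    return BindingSystem.standard(site_conc=2.4, tracer_kd=2.0, tracer_conc=5.0)


@pytest.fixture
def worked_design() -> AssayDesign:
    """Noiseless self-competition assay at the worked-system condition."""
    return AssayDesign(
        site_conc=2.4,
        tracer_kd=2.0,
        inhibitor_kd=2.0,
        replicates=1,
        noise_cv=0.0,
    )
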