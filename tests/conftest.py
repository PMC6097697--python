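import pytest

import catpot as cp


@pytest.fixture(scope="session")
def nominal_ref():
    return cp.nominal_reference_state()


@pytest.fixture(scope="session")
def base_model(nominal_ref):
    """Glycolysis + RL shunt + hemoglobin, no enzyme modules."""
    return cp.build_rbc_model(nominal_ref)


@pytest.fixture(scope="session")
def full_model(nominal_ref):
    """Base model with all three kinase modules spliced in."""
    return cp.build_rbc_model(nominal_ref, ("PFK", "HEX", "PYK"))


@pytest.fixture(scope="session")
def full_perturbation(full_model):
    """The 1.5x ATP-load step on the three-module model (shared: one stiff
    simulation feeds several analyses)."""
    return cp.perturb_atp_utilization(full_model, 1.5)


@pytest.fixture(scope="session")
def single_module_perturbations(nominal_ref):
    """factor-1.5 responses of the three single-module models."""
    out = {}
    for enzyme in ("PFK", "HEX", "PYK"):
        model = cp.build_rbc_model(nominal_ref, (enzyme,))
        out[enzyme] = cp.perturb_atp_utilization(model, 1.5)
    return out
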