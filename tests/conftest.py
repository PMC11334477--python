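import itertools

import numpy as np
import pytest

from eutflux import bmc_fba, isotopic_mfa, physiology, synthetic_data


@pytest.fixture(scope="session")
def core_model():
    return bmc_fba.build_core_model()


@pytest.fixture(scope="session")
def eut_model(core_model):
    return bmc_fba.add_eut_bmc(core_model)


@pytest.fixture(scope="session")
def eut_network():
    return isotopic_mfa.build_eut_network()


@pytest.fixture(scope="session")
def reference_fluxes():
    return isotopic_mfa.tracer_reference_parameters()


@pytest.fixture(scope="session")
def exometabolome_params():
    """Measured exponential-phase physiology on glycerol + EA + B12."""
    return physiology.PhysioParams(
        x0=0.026,
        mu=0.45,
        substrates={"glycerol": (30.0, 14.7), "ethanolamine": (20.0, 7.8)},
        products={
            "acetate": (0.0, 1.7, 0.0),
            "ethanol": (0.0, 2.6, physiology.ETHANOL_EVAPORATION_H),
        },
    )


@pytest.fixture(scope="session")
def exponential_design():
    """Hourly sampling restricted to the exponential phase (substrates last
    ~8 h at the reference parameters)."""
    return synthetic_data.SamplingDesign(
        t_start=0.0, t_end=7.0, n_points=8, n_replicates=1,
        noise_cv=0.0, noise_floor=0.0, rng_seed=0,
    )


def brute_force_mass_shift(counts: dict[str, int], abundances) -> np.ndarray:
    """Exhaustive enumeration oracle for natural-abundance convolution.

    Iterates over every assignment of an isotope to every atom and
    accumulates probability mass by total mass shift.  Exponential cost —
    small molecules only.
    """
    atoms = []
    for elem, n in counts.items():
        atoms.extend([tuple(abundances[elem])] * n)
    max_shift = sum(len(a) - 1 for a in atoms)
    out = np.zeros(max_shift + 1)
    for combo in itertools.product(*[range(len(a)) for a in atoms]):
        prob = 1.0
        for a, k in zip(atoms, combo):
            prob *= a[k]
        out[sum(combo)] += prob
    return out
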