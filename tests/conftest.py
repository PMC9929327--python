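import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from topform.masses import NTerminalForm, ProteoformSpec, Shift, proteoform_neutral_mass
from topform.prsm_io import PrSMRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_record(
    prsm_id: int,
    sequence: str = "AKMDEFGHIW",
    shifts: tuple = (),
    accession: str = "P00001",
    nterm: NTerminalForm = NTerminalForm.NONE,
    e_value: float = 1e-8,
    first_residue: int = 1,
) -> PrSMRecord:
    """Minimal well-formed PrSM for summary/FDR tests."""
    spec = ProteoformSpec(
        sequence,
        nterm_form=nterm,
        shifts=tuple(Shift(*s) for s in shifts),
        first_residue=first_residue,
    )
    return PrSMRecord(
        prsm_id=prsm_id,
        spectrum_id=f"scan_{prsm_id}",
        protein_accession=accession,
        first_residue=first_residue,
        last_residue=first_residue + len(sequence) - 1,
        proteoform=spec,
        precursor_mass_observed=proteoform_neutral_mass(spec),
        n_shifts=len(shifts),
        e_value=e_value,
        is_decoy=accession.startswith("DECOY_"),
    )


@pytest.fixture
def record_factory():
    return make_record
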