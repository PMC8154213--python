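import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from spotscreen.chem import AdductSpec, parse_formula
from spotscreen.platemap import SpeciesEntry, SpeciesTable, build_layout
from spotscreen.synthetic import (
    GroundTruthManifest,
    InstrumentParams,
    ResponseModel,
)

IMINE = "C12H15NO2"  # dihydroisoquinoline substrate, [M+H]+ 206.118
AMINE = "C12H17NO2"  # reduced amine product, [M+H]+ 208.133


@pytest.fixture(scope="session")
def imine_amine():
    H = AdductSpec.protonated()
    return parse_formula(IMINE), parse_formula(AMINE), H


@pytest.fixture
def small_plate(imine_amine):
    """4x6 plate with substrate/product species in every well."""
    sub, prod, H = imine_amine
    layout = build_layout(4, 6)
    entries = []
    for w in layout.well_labels():
        entries.append(SpeciesEntry(w, "substrate", sub, H, drift_ms=5.0))
        entries.append(SpeciesEntry(w, "product", prod, H, drift_ms=8.0))
    return layout, SpeciesTable(entries, layout)


def make_truth(layout, conversions, total_mM=0.1, noise_scale=0.0, seed=0,
               instrument=None):
    model = ResponseModel(noise_scale=noise_scale)
    return GroundTruthManifest.from_conversions(
        conversions, total_mM=total_mM,
        responses={"substrate": model, "product": model, "other": model},
        instrument=instrument or InstrumentParams(), seed=seed)
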