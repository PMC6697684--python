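import pandas as pd
import pytest

from cytophylo import aggregate_pairs, miscanthus_fixture
from cytophylo.synthetic import default_karyotype_spec, simulate_measurements


def make_karyotype(arm_pairs, sat_pairs=(), species="synthetic"):
    """Build a Karyotype directly from (short, long) µm tuples (one cell,
    identical homologs); pairs are ordered/renumbered by the constructor."""
    rows = []
    for i, (s, l) in enumerate(arm_pairs, start=1):
        for hom in (1, 2):
            rows.append(
                {
                    "cell_id": "c1",
                    "pair_id": i,
                    "homolog": hom,
                    "short_arm_um": s,
                    "long_arm_um": l,
                    "satellite_um": 0.4 if i in sat_pairs else 0.0,
                    "satellite_arm": "long" if i in sat_pairs else "none",
                }
            )
    return aggregate_pairs(pd.DataFrame(rows), species_label=species)


@pytest.fixture(scope="session")
def bundle():
    """The packaged deterministic fixture dataset."""
    return miscanthus_fixture()


@pytest.fixture(scope="session")
def zero_noise():
    """Zero-noise, unit-scale synthetic measurements with their ledger."""
    spec = default_karyotype_spec(noise_cv=0.0, seed=1)
    measurements, ledger = simulate_measurements(spec)
    return spec, measurements, ledger


@pytest.fixture(scope="session")
def zero_noise_karyotype(zero_noise):
    _, measurements, _ = zero_noise
    return aggregate_pairs(measurements, species_label="zero-noise")
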