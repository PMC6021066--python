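import numpy as np
import pytest

from phenodelim import SpecimenRecord, reference


@pytest.fixture(scope="session")
def biometric_fixture():
    """Moment-matched biometric fixture reconstructed from the packaged
    per-pool summary tables (one fixed seed, shared across tests)."""
    return reference.reference_fixture(seed=11)


@pytest.fixture
def make_records():
    """Factory: records for one pool with one character split live/skin."""

    def _make(char, live_vals, skin_vals, pool="NZ"):
        records = []
        for i, v in enumerate(np.asarray(live_vals, float)):
            records.append(
                SpecimenRecord(f"{pool}-L{i}", pool, "live", pool=pool, values={char: float(v)})
            )
        for i, v in enumerate(np.asarray(skin_vals, float)):
            records.append(
                SpecimenRecord(f"{pool}-S{i}", pool, "skin", pool=pool, values={char: float(v)})
            )
        return records

    return _make
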