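import numpy as np
import pytest

from cnevol.profiles import AlleleProfile, PatientDataset, SampleRecord, Segment


def make_profile(sample_id, major, minor, chrom="1", seg_len=1000):
    n = len(major)
    segments = tuple(
        Segment(chrom, i * seg_len + 1, (i + 1) * seg_len) for i in range(n)
    )
    return AlleleProfile(sample_id, segments, tuple(major), tuple(minor))


@pytest.fixture
def two_sample_patient():
    """Two samples on a shared 3-segment grid, plus metadata."""
    p1 = make_profile("S1", [2, 3, 2], [1, 1, 0])
    p2 = make_profile("S2", [2, 2, 2], [1, 1, 1])
    records = [
        SampleRecord("S1", "P1", site="Om", timepoint="biopsy", cellularity=0.8),
        SampleRecord("S2", "P1", site="P", timepoint="surgery", cellularity=0.7),
    ]
    return PatientDataset("P1", [p1, p2], records)


@pytest.fixture
def simulated_patient():
    from cnevol.simulate import SimulationConfig, simulate_patient

    cfg = SimulationConfig(
        seed=42, samples_per_patient=6, n_segments=30, het_fraction=0.3, events_per_branch=5
    )
    return simulate_patient(cfg, patient_id="P42")
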