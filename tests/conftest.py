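"""Shared fixtures: small hand-built cohorts and presence matrices."""

from __future__ import annotations

import numpy as np
import pytest

from plasmapattern import CohortTable, PresenceMatrix, Sample, assign_group, compute_bmi


def make_sample(sample_id: str, bmi: float, height: float = 170.0, sex: str = "f",
                age: float = 30.0, **clinical) -> Sample:
    """Sample with weight derived from BMI and height (always consistent)."""
    weight = bmi * (height / 100.0) ** 2
    return Sample(
        sample_id=sample_id,
        group=assign_group(bmi),
        sex=sex,
        age=age,
        height=height,
        weight=weight,
        bmi=bmi,
        clinical=dict(clinical),
    )


@pytest.fixture
def toy_cohort() -> CohortTable:
    """Four samples spanning NORM..OB3 with one clinical parameter."""
    return CohortTable(
        [
            make_sample("s1", 22.0, glucose=5.0),
            make_sample("s2", 27.0, glucose=5.2),
            make_sample("s3", 33.0, glucose=5.9),
            make_sample("s4", 41.0, glucose=6.4),
        ]
    )


@pytest.fixture
def toy_matrix(toy_cohort) -> PresenceMatrix:
    """4 samples x 5 proteins with column counts (4, 1, 2, 3, 0)."""
    values = np.array(
        [
            [1, 1, 1, 1, 0],
            [1, 0, 1, 1, 0],
            [1, 0, 0, 1, 0],
            [1, 0, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    return PresenceMatrix(
        toy_cohort.sample_ids, ["P00001", "P00002", "P00003", "P00004", "P00005"], values
    )
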