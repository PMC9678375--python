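from __future__ import annotations

import numpy as np
import pytest

from ckdpipe.phenotyping import EgfrSeries, GuidelineThresholds
from ckdpipe.synthetic import CohortConfig, generate_cohort


def day(datestr: str) -> int:
    return int(np.datetime64(datestr, "D").astype(int))


def series(pairs, equation: str = "mdrd", pid: str = "p1") -> EgfrSeries:
    """Build an EgfrSeries from (date-or-day, value) pairs."""
    days = [day(d) if isinstance(d, str) else int(d) for d, _ in pairs]
    return EgfrSeries(pid, equation, days, [v for _, v in pairs])


@pytest.fixture
def thresholds() -> GuidelineThresholds:
    return GuidelineThresholds()


@pytest.fixture(scope="session")
def small_cohort():
    """A 1,500-patient noisy cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(n_patients=1500, seed=11))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Dense, noise-free cohort: observed eGFR equals the latent trajectory."""
    cfg = CohortConfig(
        n_patients=400,
        seed=3,
        noise_cv=0.0,
        visit_rate={c: 6.5 for c in CohortConfig().visit_rate},
    )
    return generate_cohort(cfg)
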