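import numpy as np
import pytest

from sealkin.demography import LifeHistorySchedules, PopulationTrajectory
from sealkin.kernels import KinKernelContext, SampleRecord


@pytest.fixture(scope="session")
def default_schedules():
    return LifeHistorySchedules.from_raw()


@pytest.fixture(scope="session")
def knife_edge_schedules():
    return LifeHistorySchedules.from_raw(fecundity_spec="knife_edge", maturity_spec="knife_edge")


def constant_trajectory(schedules, n_total, start_year, end_year):
    """Flat trajectory on the stable age distribution (lambda pinned to 1)."""
    from sealkin.demography import stable_trajectory

    return stable_trajectory(
        schedules, n_total, start_year, end_year, ref_year=end_year, lam_override=1.0
    )


@pytest.fixture
def toy_context(default_schedules):
    traj = constant_trajectory(default_schedules, 10_000, 1950, 2025)
    return KinKernelContext(traj, default_schedules, pi=0.5)


def rec(id, sex, birth, death, hap=None):
    return SampleRecord(id=str(id), sex=sex, birth_year=birth, death_year=death, mtdna=hap)
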