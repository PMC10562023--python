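import numpy as np
import pytest

from vmatqa.rtplan_io import ArcPlan, ControlPoint
from vmatqa.synthetic import desk_scale_kwargs, generate_dataset


def make_plan(bank_a_cols, bank_b_cols, weights=None, plan_id="toy", gantry=None):
    """Build an ArcPlan from per-control-point bank arrays (lists of 60-vectors)."""
    n = len(bank_a_cols)
    if weights is None:
        weights = np.linspace(0.0, 1.0, n)
    if gantry is None:
        gantry = np.linspace(181.0, -179.0, n) % 360.0
    cps = tuple(
        ControlPoint(
            index=j,
            gantry_angle=float(gantry[j]),
            meterset_weight=float(weights[j]),
            bank_a=np.asarray(bank_a_cols[j], dtype=float),
            bank_b=np.asarray(bank_b_cols[j], dtype=float),
        )
        for j in range(n)
    )
    return ArcPlan(plan_id=plan_id, control_points=cps, isocenter=np.zeros(3),
                   prescription_dose=74.0)


@pytest.fixture(scope="session")
def toy_open_plan():
    """3 control points; pair 30 opens 0 -> 5 -> 10 mm symmetrically about 0."""
    a = np.zeros((3, 60))
    b = np.zeros((3, 60))
    a[1, 29], b[1, 29] = -2.5, 2.5
    a[2, 29], b[2, 29] = -5.0, 5.0
    return make_plan(list(a), list(b), weights=[0.0, 0.5, 1.0])


@pytest.fixture(scope="session")
def closed_plan():
    """2 control points, every pair closed (at staggered junctions)."""
    junction = np.linspace(-10, 10, 60)
    return make_plan([junction, junction], [junction, junction], weights=[0.0, 1.0])


@pytest.fixture(scope="session")
def desk_dataset():
    """96-plan labelled cohort at reduced problem sizes (shared across tests)."""
    return generate_dataset(96, **desk_scale_kwargs(seed=20260926))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small 10-plan cohort for fast pipeline checks."""
    return generate_dataset(10, **desk_scale_kwargs(seed=77))
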