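import numpy as np
import pandas as pd
import pytest

from lamscore import CohortData, Trajectory

#: Printed population estimates (estimate, SE) used across tests.
TABLE_ESTIMATES = {
    "log_theta0": (2.07, 0.025),
    "log_theta1": (-1.95, 0.158),
    "theta2": (1.16, 0.081),
    "sigma": (0.99, 0.045),
}


@pytest.fixture
def hand_cohort() -> CohortData:
    """Four-horse cohort with hand-computable medians."""
    return CohortData(
        [
            Trajectory("a", np.array([0, 14]), np.array([8, 1])),
            Trajectory("b", np.array([0, 14]), np.array([10, 3])),
            Trajectory("c", np.array([0, 14]), np.array([7, 0])),
            Trajectory("d", np.array([0, 14]), np.array([9, 6])),
        ]
    )


@pytest.fixture
def signed_cohort() -> CohortData:
    """Four-horse single-visit cohort with one positive sign in one horse."""
    zeros = {"weight_shifting_pts": 0, "foot_lift_pts": 0, "walk_pts": 0,
             "circle_pts": 0, "pulse_pts": 0}
    trajs = []
    for hid, circle in [("a", 1), ("b", 0), ("c", 0), ("d", 0)]:
        signs = pd.DataFrame([{**zeros, "circle_pts": circle}])
        trajs.append(
            Trajectory(hid, np.array([0]), np.array([circle]), signs=signs)
        )
    return CohortData(trajs)
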