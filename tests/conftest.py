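import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dyntrack as dt

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def step_model():
    """Default single-motor calibration: d = 8 nm, v = 96 nm^2 (phi_1 = 0.1/nm)."""
    return dt.MotorStepModel.from_moments(8.0, 96.0, 150.0)


@pytest.fixture(scope="session")
def pure8_model():
    """Resolved-stepping model: every step 8 nm (the step-size histogram mode)."""
    return dt.MotorStepModel.from_moments(8.0, 0.0, 150.0)


def transport_config(n_motors=1, seed=0, duration_s=60.0, sd_nm=2.0,
                     velocity_nm_s=1200.0, dt_s=0.01):
    """Single constant retrograde transport state (no switching)."""
    return dt.CargoConfig(
        n_motors=n_motors,
        localization_sd_nm=sd_nm,
        frame_interval_s=dt_s,
        duration_s=duration_s,
        states=(dt.MotionState("retrograde", velocity_nm_s=velocity_nm_s),),
        initial_state=0,
        seed=seed,
    )


def label_accuracy_up_to_sign(traj, annotation):
    """Fraction of correctly labeled frames, allowing the global DV+/DV- swap
    (the principal-axis projection cannot know which direction is retrograde)."""
    true = np.asarray(traj.meta["true_state"])
    names = np.asarray(traj.meta["state_names"])
    to_label = {"diffusive": "D", "retrograde": "DV+", "anterograde": "DV-"}
    true_lab = np.array([to_label[names[s]] for s in true])
    acc = float((annotation.labels == true_lab).mean())
    swap = {"D": "D", "DV+": "DV-", "DV-": "DV+"}
    acc_swapped = float(
        (np.array([swap[l] for l in annotation.labels]) == true_lab).mean()
    )
    return max(acc, acc_swapped)
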