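#!/usr/bin/env python
"""Motion-estimate quality of the two emulated tracking modalities.

Part A: the high-rate tracker stream — RMSE against the prescribed trace
before and after the 1 Hz zero-phase low-pass filter, averaged over
seeds, for a stepwise scenario.

Part B: navigator registration on large pitch-wise motion with the
non-rigid neck (coupling 0.3) — per-parameter RMSE of the estimated
trace with and without the geometric neck mask, reproducing the
"only the pitch estimate deviates" masking signature.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mocosim.motion import lowpass_filter_trace
from mocosim.phantom import build_default_phantom
from mocosim.recon import AcquisitionSpec
from mocosim.registration import build_geometric_neck_mask, estimate_trace_from_navigators
from mocosim.scenarios import ScenarioSpec, generate_scenario_trace
from mocosim.tracking import emulate_tracker, navigator_series

OUT = Path(__file__).resolve().parent.parent / "results"
PARAMS = ["theta_x", "theta_y", "theta_z", "t_x", "t_y", "t_z"]


def tracker_filtering(spec):
    true = generate_scenario_trace(
        ScenarioSpec.named("stepwise-small", scan_duration_s=spec.scan_duration_s), 30.0
    )
    raw_r, filt_r = [], []
    for seed in range(10):
        obs = emulate_tracker(true, seed=seed)
        truth = true.sample_at(obs.times)
        filt = lowpass_filter_trace(obs, 1.0)
        raw_r.append(np.sqrt(((obs.poses - truth) ** 2).mean()))
        filt_r.append(np.sqrt(((filt.poses - truth) ** 2).mean()))
    return pd.DataFrame(
        {
            "stage": ["tracker_raw", "tracker_filtered_1hz"],
            "rmse_mixed_units": [np.mean(raw_r), np.mean(filt_r)],
        }
    )


def navigator_masking(spec, phantom):
    true = generate_scenario_trace(
        ScenarioSpec.named("pitch-large", scan_duration_s=spec.scan_duration_s), 30.0
    )
    navs = navigator_series(phantom, true, tr_s=spec.tr_s, matrix=40)
    truth = true.sample_at(navs.times)
    mask = build_geometric_neck_mask(phantom, 40)
    rows = []
    for label, est in (
        ("fatnav_nomask", estimate_trace_from_navigators(navs)),
        ("fatnav_mask", estimate_trace_from_navigators(navs, mask=mask)),
    ):
        rmse = np.sqrt(((est.poses - truth) ** 2).mean(axis=0))
        rows.append({"arm": label, **{p: r for p, r in zip(PARAMS, rmse)}})
    return pd.DataFrame(rows)


def main():
    OUT.mkdir(exist_ok=True)
    spec = AcquisitionSpec(matrix=64, fov_mm=200.0)
    phantom = build_default_phantom(64, 200.0)

    tf = tracker_filtering(spec)
    tf.to_csv(OUT / "tracker_filtering.csv", index=False)
    print("Tracker stream (stepwise-small), RMSE vs truth:")
    print(tf.to_string(index=False))
    print("-> the 1 Hz zero-phase filter removes most measurement noise.\n")

    nm = navigator_masking(spec, phantom)
    nm.to_csv(OUT / "navigator_masking.csv", index=False)
    print("Navigator estimation (pitch-large, neck coupling 0.3), per-parameter RMSE:")
    print(nm.to_string(index=False))
    print(
        "-> the neck mask cuts the pitch (theta_x) error several-fold while "
        "every other parameter is essentially unchanged."
    )


if __name__ == "__main__":
    main()
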