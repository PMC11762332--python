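"""Simulate one standardized driving session and inspect its geometry.

A healthy subject drives the default closed circuit (540 m lap: two
U-turns, two left and two right quarter turns, straights in between) for
10 laps under the normal condition.  The printout checks that the
simulated trajectory honors the protocol: total heading change of
10 x 2*pi, ~540 m per lap, 10 Hz IMU and 1 Hz GPS streams.
"""

import math

import numpy as np

from drivecog.synthetic import SubjectProfile, build_circuit, simulate_session

circuit = build_circuit()
profile = SubjectProfile("S01", 72, "Male", "Healthy")
session = simulate_session(profile, circuit, condition="normal", seed=42)

imu, gps, truth = session.imu, session.gps, session.truth
print(f"session duration: {imu.t.iloc[-1]:.1f} s")
print(f"IMU samples: {len(imu)} (median dt {np.median(np.diff(imu.t)):.3f} s)")
print(f"GPS samples: {len(gps)} (median dt {np.median(np.diff(gps.t)):.3f} s)")

total_heading = np.trapezoid(imu.gz, imu.t)
print(f"integrated yaw: {total_heading / (2 * math.pi):.3f} revolutions "
      "(one per lap)")

starts = truth.lap_start_times
i1, i2 = round(starts[1] / 0.1), round(starts[2] / 0.1)
lap = truth.path_xy[i1 : i2 + 1]
lap_len = np.hypot(*np.diff(lap, axis=0).T).sum()
print(f"lap 2 path length: {lap_len:.1f} m (design: {circuit.lap_length_m} m)")
print(f"turns executed: {len(truth.turns)} "
      f"({circuit.turns_per_lap} per lap x {circuit.laps} laps)")
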