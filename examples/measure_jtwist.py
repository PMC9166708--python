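"""Measure the signed interhelical angle (J_twist) of stacked-X junctions.

Builds ideal junctions at known angles and both handedness, then a noisy
100-frame trajectory, and recovers the construction values.  The sign
encodes handedness: left-handed junctions are normalized by -1.
"""

from hjkit.geometry import jtwist, jtwist_series, summarize_angles
from hjkit.synth import SynthSpec, build_junction, build_trajectory

for angle in (40.0, 60.0, 75.0):
    for handedness in ("right", "left"):
        s, truth = build_junction(
            SynthSpec.from_quartet("AACC", angle=angle, handedness=handedness)
        )
        r = jtwist(s)
        print(f"built {truth.signed_angle:+6.1f} deg ({handedness:5s}) -> "
              f"recovered {r.signed_angle:+7.2f} deg")

spec = SynthSpec.from_quartet("AACC", angle=55.0, n_frames=100,
                              noise_sigma=0.3, seed=7)
traj, _ = build_trajectory(spec)
summ = summarize_angles(jtwist_series(traj))
print(f"\n100 noisy frames at 55 deg: median {summ.median:.2f}, "
      f"mean {summ.mean:.2f}, sigma {summ.std:.2f}")
print("(median near 55 shows the estimator is unbiased; sigma > 0 reflects "
      "the 0.3 A atomic noise)")
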