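#!/usr/bin/env python
"""Track the bundle per subject and build along-tract population profiles.

Runs deterministic RK4 streamline tracking from the eroded central ROI,
computes per-fiber descriptors (tangent, elevation/azimuth, curvature),
aligns each subject's fibers to its reference fiber (+/- 12 mm window),
and aggregates the two-stage along-tract statistics. Writes the tract
profile and the scalar descriptor summary as CSVs, plus the example
subject's streamlines in CSV and TrackVis formats.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from axonvar import fiber_descriptors as fd
from axonvar import io as avio
from axonvar import pipeline as pl
from axonvar import synthetic_data as sd
from axonvar import tensor_fit as tf
from axonvar import tractography as tr


def main() -> None:
    common.RESULTS.mkdir(exist_ok=True)
    gtab = common.gradient_table()
    subjects = common.cohort()

    profiles = []
    for s in subjects:
        vol, _ = s.build()
        dwi = sd.simulate_dwi(vol, gtab, seed=s.subject_id)
        fit = tf.fit_tensor_wlls(dwi, gtab, vol.affine)
        labels = pl.central_roi_labels(fit.shape, half=2)  # 5^3 -> 27 seeds
        sset = tr.track_roi(fit, labels, common.ROI_LABEL, subject_id=str(s.subject_id))
        profiles.append(fd.subject_profile(sset, roi_centroid=np.zeros(3)))
        if s.subject_id == 0:
            avio.write_streamlines_csv(sset, common.RESULTS / "subject000_streamlines.csv")
            avio.write_trk(sset, str(common.RESULTS / "subject000_streamlines.trk"))

    profile_df, summary = fd.population_profile(profiles)
    profile_df.to_csv(common.RESULTS / "tract_profile.csv", index=False)
    summary.to_csv(common.RESULTS / "descriptor_summary.csv", index=False)

    print("scalar descriptor summary across subjects:")
    for _, r in summary.iterrows():
        print(
            f"  {r['descriptor']:<16} mean {r['mean']:8.3f}  SD {r['sd']:7.3f}  "
            f"CV {r['cv_percent']:6.2f}%"
        )
    # the bundle runs along z, so the elevation angle is the unsigned tilt
    # magnitude: for tilts ~ N(0, s) it follows a folded normal with
    # mean 0.798 s and SD 0.603 s
    row = summary.set_index("descriptor").loc["theta_deg"]
    s = float(np.std([sub.rotation_angle_deg for sub in subjects], ddof=1))
    print(
        f"elevation angle: mean {row['mean']:.2f} deg (folded-normal "
        f"expectation {0.798 * s:.2f}), SD {row['sd']:.2f} deg "
        f"(expectation {0.603 * s:.2f})"
    )


if __name__ == "__main__":
    main()
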