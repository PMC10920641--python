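"""Demonstrate frame-differencing motion energy on a rendered toy video.

The clinical pipeline starts from video; here a blob video is rendered in
which each region of interest (ROI) holds a moving square driven by a known
signal, and per-ROI motion energy (pixels changing by more than 8 gray
levels between frames) is extracted back. The extracted series should
rank-correlate strongly with the absolute frame-to-frame change of each
driver, and cross-ROI contamination should be exactly zero.

Writes the extracted series to results/video_demo/.
"""

import argparse
from pathlib import Path

import numpy as np
from scipy.signal import lfilter
from scipy.stats import spearmanr

from dyadsync.motion_energy import MEAConfig, extract_motion_energy, write_series_csv
from dyadsync.synthetic import VideoSimConfig, default_video_rois, render_synthetic_video


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--outdir", default="results/video_demo")
    args = parser.parse_args()

    cfg = VideoSimConfig(fps=10.0, seed=args.seed)
    rois = default_video_rois(cfg)
    rng = np.random.default_rng(args.seed)
    driving = {role: lfilter([1.0], [1.0, -0.95], rng.standard_normal(600))
               for role in rois}
    video = render_synthetic_video(rois, driving, cfg)
    series = extract_motion_energy(video, rois.values(), MEAConfig(8))

    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_series_csv(series, outdir / "extracted.csv",
                     sidecar={"source": "rendered blob video", "threshold": 8})
    print(f"rendered {video.n_frames} frames, extracted {len(rois)} ROI series")
    for role in rois:
        rho = spearmanr(series[role].values,
                        np.abs(np.diff(driving[role]))).statistic
        print(f"  {role}: rank correlation with |driver change| = {rho:.3f}")


if __name__ == "__main__":
    main()
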