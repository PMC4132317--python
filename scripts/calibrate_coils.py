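"""One-off, reproducible calibration of the coiled-coil score Gaussians.

Fits the (mean, sd) of max-over-frame window scores for (a) sequences
drawn from the heptad propensity model and (b) sequences drawn from
the background residue distribution, for each supported window size.
The window-28 numbers are frozen into scsurvey.coiledcoil
(GAUSS_CC_28 / GAUSS_GLOB_28).

Run from the repository root:  python scripts/calibrate_coils.py
"""

from scsurvey.coiledcoil import calibrate_gaussians
from scsurvey.synthetic_data import background_frequencies


def main() -> None:
    bg = background_frequencies()
    for window in (14, 21, 28):
        (cc_mean, cc_sd), (gl_mean, gl_sd) = calibrate_gaussians(
            window, bg, n_windows=4000, seed=20260924
        )
        print(
            f"window {window}: cc=({cc_mean:.3f}, {cc_sd:.3f}) "
            f"glob=({gl_mean:.3f}, {gl_sd:.3f})"
        )


if __name__ == "__main__":
    main()
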