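#!/usr/bin/env python
"""Compare the arm-averaged DEP spectra of the simulated cohort.

Loads results/cohort/, takes per-sample medians with dead points
masked, averages each arm, and writes the two mean spectra (plus
window-2 rolling-average trendlines) to results/. A figure goes to
scratch/figures/.  The expected signature: the cancer arm reads lower
below ~80 kHz and higher at the top of the band.
"""

from pathlib import Path

import numpy as np

from depscreen.io import read_cohort, write_spectrum_csv
from depscreen.processing import arm_mean_spectrum, process_sample, rolling_average

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    dataset = read_cohort(RESULTS / "cohort" / "manifest.csv")
    processed = [process_sample(rec) for rec in dataset.samples]
    n_masked = sum((~p.median_spectrum.mask).sum() for p in processed)
    print(f"processed {len(processed)} samples; {n_masked} dead points masked")

    means = {}
    for arm in ("cancer", "control"):
        mean = arm_mean_spectrum(processed, arm)
        means[arm] = mean
        write_spectrum_csv(mean, RESULTS / f"arm_mean_{arm}.csv")

    freqs = dataset.grid.frequencies
    low = freqs < 8e4
    high = freqs > 1e5
    canc, ctrl = means["cancer"].values, means["control"].values
    print("all samples (low-cell spectra dilute the cancer arm towards zero):")
    print(f"  mean below 80 kHz : cancer {canc[low].mean():+.3f}, "
          f"control {ctrl[low].mean():+.3f}")
    print(f"  mean above 100 kHz: cancer {canc[high].mean():+.3f}, "
          f"control {ctrl[high].mean():+.3f}")

    # restrict to curve-bearing samples (SD >= 0.4) to see the clean contrast
    from depscreen.mdv import MDVConfig, exclusion_filter

    kept = [p for p in processed if not exclusion_filter(p, MDVConfig())]
    canc_k = arm_mean_spectrum(kept, "cancer").values
    ctrl_k = arm_mean_spectrum(kept, "control").values
    print("curve-bearing samples only:")
    print(f"  mean below 80 kHz : cancer {canc_k[low].mean():+.3f}, "
          f"control {ctrl_k[low].mean():+.3f}")
    print(f"  mean above 100 kHz: cancer {canc_k[high].mean():+.3f}, "
          f"control {ctrl_k[high].mean():+.3f}")

    fig_dir = ROOT / "scratch" / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for arm, color, marker in (("cancer", "tab:blue", "o"),
                               ("control", "tab:red", "D")):
        spec = means[arm]
        ax.plot(spec.valid_frequencies, spec.valid_values, marker,
                color=color, label=arm, ms=5)
        trend = rolling_average(spec, window=2)
        mid_f = np.sqrt(spec.valid_frequencies[:-1] * spec.valid_frequencies[1:])
        ax.plot(mid_f, trend, ":", color=color)
    ax.set_xscale("log")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("DEP response (gain x Re[CM])")
    ax.legend()
    fig.tight_layout()
    fig.savefig(fig_dir / "arm_mean_spectra.png", dpi=150)
    print(f"figure: {fig_dir / 'arm_mean_spectra.png'}")


if __name__ == "__main__":
    main()
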