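#!/usr/bin/env python
"""Simulate the startle experiment: ~270 trials with latent labels.

Generates the synthetic counterpart of the fast-start data set (207
fish, up to three trials each, about one third of trials genuine
responses) and writes the trajectory table plus per-trial ground truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import fastkin as fk
from fastkin import io as fio

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    params = fk.FastStartSimParams(
        n_fish=207, trials_per_fish=3, trial_completion_prob=0.242, seed=1
    )
    trials = fk.simulate_fast_start_trials(params)
    fio.write_tracks_csv(
        [t.track for t in trials], OUT / "faststart_tracks.csv",
        trial_ids=[t.trial_index for t in trials],
    )
    truth = pd.DataFrame(
        {
            "fish_id": [t.fish_id for t in trials],
            "trial_index": [t.trial_index for t in trials],
            "responder": [t.truth for t in trials],
            "true_peak_speed_mm_s": [t.meta["true_peak_speed"] for t in trials],
            "latency_s": [t.meta["latency_s"] for t in trials],
        }
    )
    truth.to_csv(OUT / "faststart_truth.csv", index=False)
    print(f"simulated {len(trials)} trials from {params.n_fish} fish")
    print(f"latent responder fraction: {truth.responder.mean():.3f}")
    print(
        "responder peak speeds: "
        f"{truth.loc[truth.responder, 'true_peak_speed_mm_s'].mean():.0f} "
        f"+/- {truth.loc[truth.responder, 'true_peak_speed_mm_s'].std():.0f} mm/s"
    )
    print(f"wrote {OUT/'faststart_tracks.csv'} and {OUT/'faststart_truth.csv'}")


if __name__ == "__main__":
    main()
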