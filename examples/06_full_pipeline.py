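"""Complete dataset-to-results run on a synthetic two-ROI dataset.

Writes a dataset directory (stimuli, masks, two-subject responses for a
whole-image "early" ROI and a foreground-selective "higher" ROI), runs
the full analysis at smoke-test sizes, and prints where each result
landed.  The same layout works for real data: drop in your PNGs and an
HDF5 of voxel responses.
"""
import json
from pathlib import Path

from prefilt import (
    ObserverSpec,
    RunConfig,
    generate_stimuli,
    run_full,
    simulate_observer,
    write_dataset,
)

root = Path("scratch_example_out")
stimuli, masks = generate_stimuli(15, 64, seed=0)
responses = {
    "early": simulate_observer(stimuli, masks, ObserverSpec("full_image", noise_sd=0.3), seed=0),
    "higher": simulate_observer(
        stimuli, masks, ObserverSpec("foreground_only", noise_sd=0.3), seed=0
    ),
}
ds = write_dataset(root / "dataset", stimuli, masks, responses, seed=0)

config = RunConfig(
    dataset=str(ds),
    out=str(root / "results"),
    seed=0,
    n_perm_enhancement=30,
    n_boot=100,
    n_perm_suppression=500,
    run_control_voxel=False,
)
out = run_full(config)

enh = json.loads((out / "enhancement.json").read_text())
print("enhancement test (one-tailed rank p, shuffled-mask null):")
for roi, rec in enh.items():
    print(f"  {roi:>7}: rho {rec['observed_rho']:+.3f}, p = {rec['p_value']:.3f}")
print(f"\nper-step suppression table: {out / 'suppression.csv'}")
print(f"correlation images:         {out / 'corr_images'}")
print("The foreground-selective ROI rejects the shuffled-mask null and its"
      "\nbackground steps read 'increase'; the whole-image ROI reads 'decay'.")
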