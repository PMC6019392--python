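"""Foreground-enhancement permutation test on a foreground-selective observer.

The observer responds only to the segmented foreground, so the true
behavioral masks should explain its representational geometry better
than any shuffled re-assignment of the same masks (which preserves mask
sizes and is contrast-matched per stimulus).
"""
from prefilt import (
    ObserverSpec,
    compute_rdm,
    foreground_enhancement_test,
    generate_stimuli,
    mean_rdm,
    simulate_observer,
)

stimuli, masks = generate_stimuli(30, 64, seed=0)
r1, r2 = simulate_observer(
    stimuli, masks, ObserverSpec("foreground_only", noise_sd=0.3), seed=0
)
ids = tuple(s.id for s in stimuli)
target = mean_rdm([compute_rdm(r1.T, ids), compute_rdm(r2.T, ids)])

res = foreground_enhancement_test(stimuli, masks, target, n_perm=100, seed=0)
print(f"observed rho (true masks):  {res.observed_rho:.3f}")
print(f"null rho (shuffled masks):  max {res.null_rhos.max():.3f}, "
      f"mean {res.null_rhos.mean():.3f}")
print(f"one-tailed rank p = {res.p_value:.4f}  (100 permutations)")
print(
    "\np near 1/101 means the true segmentation beat every shuffled one:"
    "\nforeground information is enhanced beyond size/location/contrast."
)
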