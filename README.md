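# prefilt

Pre-filtering representational similarity analysis of figure–ground
segmentation in visual cortex.

## What it is for

Foreground–background segmentation leaves two fingerprints in visual
cortex: *foreground enhancement* (the behaviorally segmented foreground
explains a region's representational geometry better than chance) and
*background suppression* (removing the background from the stimuli
**raises** a stimulus model's correlation with the region — the
background was only noise to it).  Testing either with natural images is
hard because no explicit computational model of scene segmentation
exists to compare against.

`prefilt` implements the *pre-filtering* alternative: keep one fixed,
biologically transparent stimulus model and manipulate the stimuli
instead.  The fixed model is a cross-validated weighted sum of four
low-level descriptor RDMs (Gabor spectral summary, dense gradient
histograms, pyramid edge-orientation histograms, local binary patterns).
Stimuli are parametrically filtered — contrast fading toward gray,
low-pass and high-pass Butterworth filtering (5th order, cutoffs
log-sampled 0.05–25 cycles/degree), four steps each, applied to the
foreground or the background only, with the region's RMS contrast held
fixed.  Correlating the fixed model of each filtered set with a region's
RDM (Spearman ρ over the n(n−1)/2 dissimilarities) traces out what that
region keeps and what it discards; the best-correlating steps compose a
per-region **correlation image**.

Inference is fully non-parametric: a shuffled-mask permutation test for
enhancement (mask sizes and contrasts preserved under the null), a
bootstrap-difference permutation test for suppression vs decay at each
filtering step, and a control-voxel null whose draws are accepted only
inside the region's inter-subject noise band.  A synthetic-observer
module generates textured stimuli with exact ground-truth masks and
two-"subject" voxel responses with known selectivity (whole image /
foreground only / background only), so every procedure can be validated
end-to-end against a known answer.

The package is aimed at visual/computational neuroscientists running RSA
on stimulus-evoked response patterns (fMRI ROIs or simulated units) who
want segmentation-related effects without committing to an explicit
segmentation model.

## A worked example

```python
from prefilt import (ObserverSpec, compute_rdm, foreground_enhancement_test,
                     generate_stimuli, mean_rdm, simulate_observer)

stimuli, masks = generate_stimuli(30, 64, seed=0)         # textured blobs + masks
r1, r2 = simulate_observer(stimuli, masks,
                           ObserverSpec("foreground_only", noise_sd=0.3), seed=0)
ids = tuple(s.id for s in stimuli)
target = mean_rdm([compute_rdm(r1.T, ids), compute_rdm(r2.T, ids)])

res = foreground_enhancement_test(stimuli, masks, target, n_perm=100, seed=0)
print(res.observed_rho, res.null_rhos.max(), res.p_value)
```

prints

```
observed rho (true masks):  0.526
null rho (shuffled masks):  max 0.266, mean 0.142
one-tailed rank p = 0.0099  (100 permutations)
```

The observer only encodes the segmented foreground, so the true mask
assignment (ρ = 0.53) beats all 100 shuffled assignments — the add-one
rank p is 1/101.  The shuffled masks keep the same size distribution and
are contrast-matched per stimulus, so size, location and contrast cannot
explain the gap.  Running the same test against a whole-image observer
with unrelated masks yields p ≈ uniform (the null is exact by
exchangeability).

The `examples/` directory has one short script per capability: the
12-step filter series, the fixed-model fit with bootstrap SE and noise
ceiling, the enhancement test above, the suppression-vs-decay verdicts,
correlation images, and a complete dataset-to-results pipeline run.
`prefilt --help` exposes the same stages as subcommands (`synthesize`,
`filter`, `features`, `rdm`, `fit`, `test-enhancement`,
`test-suppression`, `null-control-voxels`, `corrimage`, `run-full`).

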