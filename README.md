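# phagoquant

Quantification of microglial phagocytosis efficiency, apoptotic-cell
clearance, and 3-D process motility.

Microglia are the brain's resident phagocytes: in healthy tissue they
engulf apoptotic cells (e.g. surplus newborn neurons in the hippocampal
neurogenic niche) almost as fast as they appear.  Whether that efficiency
survives an insult — excitotoxicity, inflammation, seizures — is a
quantitative question, and this package implements the measurement
toolkit needed to answer it from standard experimental readouts:

* **Census metrics** (`phagoquant.census`) — from stereological cell
  counts per region:
  - Ph index = apoᴾʰ / apoᵗᵒᵗ, the fraction of apoptotic cells inside a
    closed microglial pouch;
  - Ph capacity = Σₙ n·mgᴾʰⁿ / mg, the mean number of phagocytic pouches
    per microglia (parts per unit, ppu); the same weighted formula gives
    the phagoptosis (engulfment of nonapoptotic cells) capacity;
  - net phagocytosis = mg × Ph capacity;
  - Ph/A coupling = net phagocytosis / apoᵗᵒᵗ, reported as fold change
    against a baseline group (1 ⇒ phagocytosis scales with apoptosis);
  - cell densities, distance-to-process histograms, OLS R².
* **Clearance** (`phagoquant.clearance`) — the steady-state clearance
  time τ = present(t₂)·Δt / cleared, its inversion, and the two-group
  inference that recovers a slowed clearance time from pulse-chase
  (BrdU-labeled) cohort counts under the equal-cohort-total assumption.
* **Motility** (`phagoquant.motility`) — a 3-D centerline algorithm for
  fine fluorescent processes in two-photon time-lapse stacks: per
  z-slice intensity-profile border detection (background, half-max
  prominence, inflexion points), center points zC = (z_U+z_B)/2 and
  xC = (x_R+x_L)/2 with virtual-slice interpolation, skeleton length as
  the summed 3-D distance between per-line centers (anisotropic voxels
  honoured), and motility = |Δlength| / frame interval with protraction
  and retraction means.  Also area-fraction occupancy of labeled
  microglia per z-stack.
* **qPCR** (`phagoquant.qpcr`) — amplification efficiency from dilution
  standard curves (eff = 10^(−1/slope) − 1) and the efficiency-corrected
  relative amount (1+eff_target)^ΔCt_target / (1+eff_ref)^ΔCt_ref.
* **Synthetic data** (`phagoquant.synthetic`) — seed-deterministic
  generators with ground truth for every input type: Poisson/binomial
  censuses in coupled/uncoupled regimes, exponential-clearance pulse-chase
  cohorts, tubular fluorescent phantoms with known centerlines at the
  real acquisition geometry (0.1 × 0.1 × 1 µm voxels, 1.5 min frames),
  and Ct tables from known fold changes.

Counts, registered stacks and Ct tables are the inputs; segmentation,
image registration and hypothesis testing are out of scope.

## Worked example

```python
from phagoquant import ClearanceInputs, infer_clearance_time

result = infer_clearance_time(
    ClearanceInputs(apo_present_ref=10, apo_present_test=35.3,
                    tau_ref=1.5, delta_t=24)
)
print(result)
```

With 10 labeled apoptotic cells present in the reference group, a
reference clearance time of 1.5 h and a 24 h window, the cohort total is
10 + 10·24/1.5 = **170 cells**.  The test group still holds 35.3 cells,
so it cleared only 134.7, giving a clearance time of
35.3·24/134.7 ≈ **6.29 h** — apoptotic cells linger roughly four times
longer than under the reference condition.

The `examples/` directory holds one short script per capability; e.g.
`python examples/03_process_motility.py` renders a phantom process that
elongates 3 µm per 1.5 min frame and prints

```
mean motility    : 2.00 um/min (truth 2.00)
noisy curved phantom (SNR 5): worst length error 0.3 %
```

i.e. the centerline pipeline recovers the commanded kinematics, and
intensity noise at SNR 5 moves the recovered lengths by well under a
percent on that phantom.

A thin CLI mirrors the library
(`phagoquant census|clearance|motility|occupancy|qpcr|simulate`); see
`phagoquant --help`.

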