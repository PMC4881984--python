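"""Phagocytosis/apoptosis coupling metrics from a cell census.

Builds a small hand-sized census, then a simulated two-group experiment in
which apoptosis triples but microglia keep up (the "coupled" regime), and
prints the metrics.
"""

from phagoquant import (
    CellCensus,
    generate_census,
    net_phagocytosis,
    ph_a_coupling,
    ph_index,
    summarize_censuses,
    weighted_capacity,
)

# One region: 30 apoptotic cells of which 15 are inside microglial pouches;
# 100 microglia, 15 carrying one pouch and 5 carrying two.
census = CellCensus(
    sample_id="demo",
    group="control",
    apo_total=30,
    apo_phagocytosed=15,
    microglia_total=100,
    pouch_histogram={1: 15, 2: 5},
    region_volume_mm3=0.05,
)

print(f"Ph index           : {ph_index(census):.2f}  (fraction of apoptotic cells engulfed)")
print(f"Ph capacity        : {weighted_capacity(census.pouch_histogram, 100):.2f} ppu  (mean pouches per microglia)")
print(f"Net phagocytosis   : {net_phagocytosis(census):.0f} cells  (microglia x capacity)")
print(f"Ph/A coupling (raw): {ph_a_coupling(census)[0]:.2f}  (net phagocytosis / apoptosis)")

# A coupled challenge: apoptosis x3, engulfment probability unchanged.
censuses = generate_census(seed=1, scenario="coupled", n_samples=200, challenge_factor=3.0)
summary = summarize_censuses(censuses, baseline_group="control")
fold = summary.groupby("group")["ph_a_fold_change"].mean()
print("\nCoupled challenge (200 samples/group, apoptosis x3):")
print(fold.to_string(float_format="%.3f"))
print("A fold change near 1 in the challenge group means microglia scaled")
print("their net phagocytosis to match the extra apoptosis.")
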