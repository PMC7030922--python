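"""Peptide-array quantification, binding-region calling, and cross-link
proximity.

Simulates a tiling array over a 300-residue target with one planted binding
region, quantifies it against a nonspecific-binding control, calls regions
supported by at least two overlapping positive peptides, and measures how far
simulated cross-linked sites fall from the called region.
"""

from xlmap.binding import (
    call_binding_regions,
    negative_control_threshold,
    quantify_array,
    region_link_proximity,
)
from xlmap.io import CrossLink
from xlmap.synthetic import make_array_experiment

exp, control, truth = make_array_experiment(
    target_length=300, true_regions=[(101, 160)], amplitude=0.6,
    noise_sd=0.03, seed=6, target="STX1B",
)
signals = quantify_array(exp, control)
threshold = negative_control_threshold(exp) + 0.1
regions = call_binding_regions(signals, exp.peptides, threshold, target="STX1B")

print(f"spots quantified:  {len(signals)}")
print(f"positivity cutoff: {threshold:.3f} (negative controls + margin)")
for r in regions:
    print(f"binding region:    {r.start}-{r.end} ({r.support} supporting peptides)")

links = [CrossLink("STX1B", 120, "PARTNER", 33), CrossLink("STX1B", 81, "PARTNER", 70)]
table = region_link_proximity(regions, links, "STX1B")
for row in table.itertuples():
    print(f"cross-linked site {row.site}: {row.distance_to_region} residues from nearest region")

# The planted region is recovered as the union of its supporting peptides;
# cross-linked sites inside it score distance 0, nearby ones a small offset -
# cross-links cluster around true binding interfaces without marking them
# exactly.
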