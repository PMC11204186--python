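"""Probe-panel geometry: sizes, overlaps, and genomic distance labels.

Builds the default five-BAC panel on 15q12-q13.1 and prints the arithmetic
that fixes the coordinate convention: each probe's length, the partial
overlap of probes #4 and #5, and the Mb distance labels of the three
hybridized pairs.
"""

from loopdist import coords

panel = coords.default_probe_panel()
loops = coords.default_loop_annotation()

print("Probe panel (1-based closed coordinates):")
for i, (probe, role) in enumerate(zip(panel.probes, panel.roles), start=1):
    loop = coords.assign_loop(probe.midpoint, loops)
    print(
        f"  #{i} {probe.name:12s} {probe.chrom}:{probe.start:,}-{probe.end:,}"
        f"  length {coords.interval_length(probe):>8,} bp  role {role:15s} loop {loop}"
    )

print(f"\nOverlap of #4 and #5: {coords.overlap_bp(panel.probe(4), panel.probe(5)):,} bp")
for a, b in ((2, 3), (1, 4), (4, 5)):
    span = coords.pair_span(panel.probe(a), panel.probe(b))
    label = coords.distance_label(panel.probe(a), panel.probe(b))
    print(f"Pair #{a}#{b}: span {span:,} bp -> genomic distance label {label} Mb")

# The labels (0.0, 1.3, 2.6 Mb) are the panel's three separation classes:
# overlapping, loop-interior, and across-the-region anchor-to-anchor.
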