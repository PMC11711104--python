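"""Discover the diagnostic SNP panel and compare it with the planted truth.

Runs the three selection stages (QUAL > 500, reciprocal fixation with
group coverage > 20x, one SNP per contig > 20 kb) on a simulated cohort.
"""

import sebpanel as sp

matrix, groups, truth = sp.simulate_cohort(sp.SimulationConfig(seed=1))

panel = sp.discover_panel(matrix, groups)  # default DiscoveryConfig
planted = truth.diagnostic_pairs()
found = {p.locus.id for p in panel}

sens = 100 * len(found & set(planted)) / len(planted)
print(f"panel size: {len(panel)}  (planted: {len(planted)})")
print(f"sensitivity {sens:.0f}%, false positives {len(found - set(planted))}")
for entry in panel[:3]:
    c = entry.candidates[0]
    print(f"  {entry.locus.id} on {entry.locus.contig}: "
          f"{c.pair[0]}={c.allele_g1}{c.allele_g1} vs "
          f"{c.pair[1]}={c.allele_g2}{c.allele_g2} "
          f"(depth {c.mean_depth_g1:.0f}x/{c.mean_depth_g2:.0f}x)")
# Every retained SNP separates one species pair by genotype alone; raising
# any threshold can only shrink this list.
high = sp.DiscoveryConfig(min_depth=80)
print(f"panel with a 80x coverage gate: {len(sp.discover_panel(matrix, groups, high))} SNPs")
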