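"""Detect microsatellites and select genetic-marker candidates.

Plants SSRs in a synthetic assembly, detects them MISA-style, fuses
compounds, and applies the four marker criteria (perfect di/tri/tetra at
minimum units, SSR-free 2-kb neighbourhood, outside the repeat mask,
unique 200-bp flanks).
"""

from asmcurate import (
    SimulationParams,
    find_compound_ssrs,
    find_ssrs,
    motif_frequency_table,
    select_markers,
    simulate_diploid_assembly,
)

params = SimulationParams(
    seed=42,
    planted_ssrs=[("A", 12, 4), ("AC", 8, 6), ("AAT", 6, 6), ("ACGT", 5, 4)],
)
sim = simulate_diploid_assembly(params)

perfect = find_ssrs(sim.contigs)
compounds, surviving = find_compound_ssrs(perfect)
print(f"{len(perfect)} perfect SSRs detected "
      f"({len(sim.truth.ssr_loci)} planted); {len(compounds)} compound loci")

counts, best = motif_frequency_table(perfect)
print(f"most frequent SSR type with unit >= 2 bp: ({best[0]}){best[1]}")

markers = select_markers(surviving + compounds, sim.contigs)
selected = [m for m in markers if m.selected]
print(f"\n{len(selected)} of {len(markers)} loci pass all four marker criteria")
for m in selected[:3]:
    L = m.locus
    print(f"  ({L.motif}){L.n_units} at {L.contig_id}:{L.start}-{L.end}  "
          f"flanks {m.flank5[:12]}.../...{m.flank3[-12:]}")
# failures are explained per criterion:
fails = [m for m in markers if not m.selected]
if fails:
    m = fails[0]
    why = [c for c, ok in m.criteria.items() if not ok]
    print(f"e.g. ({m.locus.motif}){m.locus.n_units} fails: {', '.join(why)}")
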