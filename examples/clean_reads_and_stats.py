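"""Clean short reads with the five-rule filter and summarise an assembly.

Simulates reads (some duplicated to mimic PCR), cleans them, then prints
the assembly statistics table (N50/N90 with ranks, GC) and a consensus QV.
"""

from asmcurate import (
    ReadPair,
    SimulationParams,
    assembly_stats,
    consensus_qv,
    filter_read_pairs,
    simulate_diploid_assembly,
    simulate_reads,
)

sim = simulate_diploid_assembly(SimulationParams(seed=5))
reads = simulate_reads(sim.contigs[:4], coverage=2, read_len=150,
                       error_rate=0.01, seed=5)
pairs = [ReadPair(r) for r in reads]
pairs += pairs[:50]  # duplicate some pairs, as PCR would

kept, report = filter_read_pairs(pairs)
print(f"{report.input_reads} read pairs in, {report.kept_reads} kept")
for rule, n in report.discarded_by_rule.items():
    if n:
        print(f"  discarded by {rule}: {n}")
print(f"  bases trimmed: {report.bases_trimmed}")

stats = assembly_stats(sim.contigs)
print(f"\nassembly: {stats.n_contigs} contigs, {stats.total_len:,} bp total")
print(f"  N50 {stats.n50_len:,} bp (rank {stats.n50_count}); "
      f"N90 {stats.n90_len:,} bp (rank {stats.n90_count})")
print(f"  longest {stats.longest:,} bp, GC {stats.gc_percent}%")

qv = consensus_qv(homozygous_variant_sites=12, assembly_len=stats.total_len)
print(f"\n12 homozygous variant sites over the assembly -> rate "
      f"{qv.rate:.2e}, QV{qv.qv}")
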