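"""Plan homologous genome windows and filter the resulting alignments.

Segments of fixed length are tiled with fixed gaps from a random start
between 100 kb and 1 Mb on each contig (never closer than 100 kb to a
contig end's potential telomere).  Each extracted alignment is then kept
only if it has more than 5 parsimony-informative sites, under 10%
missing data, and GC content strictly between 30% and 70%.
"""

from islandrad import qc, simulate as sim, windows

tree = sim.SpeciesTreeSpec(
    newick="((A:0.004,B:0.004):0.002,C:0.006);",
    theta={s: 0.001 for s in "ABC"},
    n_individuals={s: 2 for s in "ABC"},
)
config = sim.SimulationConfig(
    tree=tree, contig_lengths={"contig_1": 400_000},
    missing_rate=0.03, missing_run_mean=200.0, seed=7,
)
genomes, _ = sim.simulate(config)
sequences = sim.pseudo_haploidize(genomes, seed=8)

plan = windows.plan_segments(genomes.contigs, length=2_000, gap=8_000, seed=9)
print(f"sampled start on contig_1: {plan.starts['contig_1']:,} bp")
print(f"planned segments: {len(plan.segments)} x {plan.length:,} bp, gap {plan.gap:,} bp")

alignments = windows.extract_alignments(sequences, plan)
retained, reports = qc.apply_filters(alignments)
print(f"retained {len(retained)}/{len(alignments)} alignments\n")
print("first five QC reports (PI sites | missing | GC | pass):")
for rep in reports[:5]:
    print(f"  {rep.alignment_id}: {rep.pi_sites:3d} | {rep.missing_frac:.3f} "
          f"| {rep.gc_frac:.3f} | {rep.passed}")
print("\nan alignment fails when it carries too little phylogenetic signal")
print("(PI <= 5), too many N bases, or a skewed base composition")
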