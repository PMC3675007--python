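"""Generate a synthetic world and cohort, then assign genes to CNVs.

A gene counts as affected only if the CNV overlaps at least one coding exon
of every transcript of the gene; genes copy-number variable in the same
direction in the control cohort are removed.
"""

import numpy as np

import cnvnet

world = cnvnet.generate_world(cnvnet.SimConfig(rng_seed=1))
print(
    f"world: {len(world.catalog)} genes on {len(world.chrom_sizes)} chromosomes, "
    f"{len(world.pheno_onto)} phenotype terms under "
    f"{len(world.pheno_onto.roots)} categories, "
    f"{len(world.pheno_table.genes)} genes with phenotype annotations"
)

cohort = cnvnet.generate_cohort(world, rng=np.random.default_rng(2))
print(f"cohort: {len(cohort.case)} case CNVs, {len(cohort.control)} control CNVs")

assignment = cnvnet.assign_genes_to_cnvs(cohort.case, world.catalog)
control = cnvnet.assign_genes_to_cnvs(cohort.control, world.catalog)
filtered = cnvnet.filter_control_genes(assignment, control)

print(
    f"assigned genes: {len(assignment.gene_set('all'))} "
    f"({len(assignment.gene_set('gain'))} in gains, "
    f"{len(assignment.gene_set('loss'))} in losses)"
)
print(
    f"after removing control-polymorphic genes: {len(filtered.gene_set('all'))}"
)
# The drop from the first to the second count is the number of genes whose
# copy change also occurs, in the same direction, in unaffected controls.
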