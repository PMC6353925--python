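"""Post-hoc analyses of a discovered combination set.

After discovery, three sanity checks argue the combinations are not
artifacts: the genes inside each pair should be uncorrelated across normal
samples (Pearson r below 0.25), they should rarely share a chromosome, and
the overlap structure (tumors carrying several combinations) hints at
deeper, 3+-hit combinations. A per-position tumor/normal contrast then
separates candidate driver loci from passengers within one gene.
"""

from multihit import analysis
from multihit.io_maf import VariantRecord
from multihit.pipeline import RunConfig, run_pipeline
from multihit.synthetic import (PlantedModel, gene_location_table,
                                simulate_cohort)

matrix, labels, _ = simulate_cohort(PlantedModel(seed=5, p_multi=0.4))
result = run_pipeline(matrix, labels, RunConfig(seed=5))
solution = result.solution

stats = result.statistics
print("combination occurrence in tumors (may sum past 100%):")
for genes, frac in sorted(stats.occurrence.items(), key=lambda kv: -kv[1]):
    print(f"  {'+'.join(genes):<12} {frac:6.1%}")
print(f"tumors with >= 2 combinations: {stats.multi_combination_fraction:.1%}")

flagged = [row for row in result.correlations if row["correlated"]]
print(f"\nin-combination gene pairs with |r| >= 0.25 in normals: "
      f"{len(flagged)} of {len(result.correlations)}")

locations = dict(zip(*[gene_location_table(matrix)[c]
                       for c in ("gene", "chromosome")]))
coloc = analysis.chromosome_colocation(solution, locations)
print(f"combinations with both genes on one chromosome: "
      f"{coloc['n_same_chromosome']} of {coloc['n_known']}")

# locus contrast on a toy record set: position 132 mutated only in tumors
combo = solution.combinations[0].genes
gene = combo[0]
covered = [s for s in matrix.samples
           if matrix.sample_row(s)[matrix.gene_indices(combo)].all()]
records = [VariantRecord(s, gene, "2", 132 if labels.is_tumor(s) else 900,
                         "Missense_Mutation", labels.is_tumor(s))
           for s in covered]
profile = analysis.locus_contrast(gene, combo, records, matrix, labels)
print(f"\nlocus contrast for {gene} within {'+'.join(combo)}:")
print(f"  tumor-exclusive positions (candidate drivers): "
      f"{sorted(p for _, p in profile.tumor_exclusive)}")
print(f"  shared positions (candidate passengers): "
      f"{sorted(p for _, p in profile.shared)}")
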