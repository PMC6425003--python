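# Example configuration for `fstatkit run --config analysis/pipeline_config.yaml
#   --out results/run`.
#
# Schema (all stages optional; a stage runs only when configured):
#   seed            mandatory master seed; per-stage seeds are derived from it
#   scenario        name of a registered synthetic scenario, OR
#   dataset_prefix  path prefix of an EIGENSTRAT triplet (.geno/.snp/.ind)
#   n_snps          SNPs to simulate when a scenario is named
#   pseudo_haploid  individual ids with single-allele genotypes (dataset mode)
#   dstats          list of {w, x, y, z} population quadruples
#   permutations    list of {scheme, group1, group2, test, outgroup, n_perm}
#   qpadm           list of {target, sources, outgroups}
#   nested          list of {target, full_sources, reduced_sources, outgroups}
#   alpha           list of {target, nonbasal_source, basal_proxy, outgroups}
#   compose         list of composition requests (explicit numbers or
#                   {target, source, alpha_of} references into qpadm/alpha)
#   pca             {fit_populations, project_populations, n_components}
#   min_snps        reporting threshold for f-statistics (default 30000)

seed: 11
scenario: aaf_two_way
n_snps: 50000

dstats:
  - {w: AAF, x: AHG, y: Iran_N, z: Mbuti}
  - {w: AAF, x: AHG, y: CHG, z: Mbuti}
  - {w: AHG, x: Kostenki14, y: Levant_N, z: Mbuti}

qpadm:
  - target: AAF
    sources: [AHG, Iran_N]
    outgroups: [Mbuti, Han, Onge, Kostenki14, Levant_N, CHG]

nested:
  - target: AAF
    full_sources: [AHG, Iran_N]
    reduced_sources: [AHG]
    outgroups: [Mbuti, Han, Onge, Kostenki14, Levant_N, CHG]

pca:
  fit_populations: [Mbuti, Han, Onge]
  project_populations: [AHG, AAF, Iran_N, Levant_N, CHG, Kostenki14]
  n_components: 2
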