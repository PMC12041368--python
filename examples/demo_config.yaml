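# Annotated germsoma run configuration.
#
# Run with:  germsoma run --config examples/demo_config.yaml
#
# This demo generates every input synthetically (stage `simulate`) and
# then runs all analysis stages on it.  For real data, drop `simulate`
# and point the `inputs:` block at your own files instead.

seed: 1                 # single global seed; per-stage sub-seeds derive
                        # from it, so reruns are byte-identical
outdir: scratch/demo_run

stages:
  simulate:             # omit this stage entirely in real-data mode
    n_expr_samples: 89  # RNA-seq cohort size
    n_snv_samples: 40   # whole-genome SNV cohort size
    n_genes: 300
    background_rate: 2.0e-5   # somatic SNVs / bp / sample
    hotspot_multiplier: 25.0  # planted hotspot fold-increase
  assoc:
    alpha: 0.05         # nominal per-pair significance threshold
    n_permutations: 500 # 10,000 for production runs
  loci: {}              # builds index-SNP +- 500 kb regions
  hotspots:
    fdr: 0.05           # BH threshold per annotation track
  cna:
    t_amp: 0.3          # log2 ratio threshold for amplification
    t_del: -0.3
    bin_bp: 10000
    n_perm: 300         # circular-permutation null iterations
    fdr: 0.25
  tfbs:
    strong_site_threshold: 0.85  # normalized PWM score for a binding site
    delta_threshold: 0.10        # allele score difference for disruption
    min_mutations: 3             # somatic burden filter per element
  report: {}

# Real-data mode: uncomment and fill in, and remove `simulate` above.
# inputs:
#   genome: genome.tsv                # chrom<TAB>size
#   expression: expression.tsv        # samples x genes
#   activities: activities.tsv        # samples x signatures
#   genes_multixcan: multixcan.txt    # any number of genes_* lists
#   snvs: snvs.tsv                    # chrom pos ref alt sample
#   track_coding: coding.bed          # any number of track_* BEDs
#   loci: risk_loci.tsv               # locus_id chrom pos histotype
#   seg: tumors.seg
#   states_HGSOC_active_enhancer: hg_enh.bed   # states_<celltype>_<state>
#   pwms: motifs.jaspar
#   fasta: sequence.fa
#   germline_variants: credible_variants.tsv
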