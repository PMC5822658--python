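# Published detection thresholds, as shipped defaults. Deviate explicitly.
seed: 1
species_id: synthetic_species

# synthetic inputs
simulate: true
n_contigs: 1
contig_length: 1000000
gc: 0.45
n_host_genes: 20
host_gene_length: 1500
transposase_placement: internal
tir_length: 13
spacer_length: 150
subtype_spec:
  - [5, 0.17, 0.02]
  - [5, 0.17, 0.02]
degrade: []
insertion_min_separation: 2000
mean_depth: 30.0
read_length: 100
error_rate: 0.002

# detection thresholds (translated search + classification)
evalue: 1.0e-3        # significance filter on translated-search hits
merge_distance: 60000 # loci within 60 kb merge into one candidate element
flank: 40000          # extracted flank around each merged locus
min_genes: 8          # >= 8 of the 13 core genes -> species positive

# subtype rules
subtype_identity: 0.90          # > 90% pairwise identity -> same subtype
within_subtype_identity: 0.95   # sanity floor within a subtype

# divergence / phylogenetics
ts_tv_bias: 2.0   # transition/transversion bias for modified Nei-Gojobori
n_bootstrap: 1000
run_phylo: true

# annotation
orf_min_length_aa: 100
intact_fraction: 0.8
tir_min_len: 10
tir_max_len: 40
tir_max_mismatch: 1

# read mapping / copy number
seed_kmer: 21
max_mismatches: 8
copy_number_bootstrap: 200

word_size: 4
gap_open: -11.0
gap_extend: -1.0
x_drop: 20.0
ungapped_trigger: 30.0
genome_fasta: null
queries_fasta: null
host_bed: null
reads_fastq: null
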