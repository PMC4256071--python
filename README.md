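# draftgauge

Draft-genome assemblies are fragmented, and fragmentation distorts gene
annotation: genes cleaved across contigs are predicted as several genes,
heterozygous loci assembled twice ("split alleles") inflate counts further,
and collapsed paralogs deflate them. `draftgauge` simulates these effects on
synthetic genomes with known ground truth and quantifies/corrects them:

- **synthetic_data** — seeded generators for multi-scaffold genomes with
  valid multi-exon ORFs, heavy-tailed template contig-length lists,
  artifact-bearing draft annotations (split alleles, collapsed paralogs)
  and paired-end cDNA read pairs with known gene of origin.
- **fragmenter** — cut scaffolds at long N-runs, or cut a genome into
  exactly *x* contigs with lengths matched to a template distribution via a
  replayable, JSON-serializable `FragmentationPlan`; assembly stats (N50).
- **prediction_emulator** — project a truth annotation onto contigs,
  clipping exons at contig edges; model predictor behaviour on fragments
  (`p_invent` for invented start/stop codons); complete-model filtering and
  exons-per-gene histograms.
- **family_clustering** — in-process all-vs-all similarity (best local
  alignment with a k-mer prescreen, or k-mer Jaccard), Markov clustering
  into gene families, per-family size deltas against a reference assembly.
- **error_classifier** — classify excess draft genes per family as
  *cleaved* (complementary fragments of the full-length reference model) or
  *split* (near-identical full-length copies), with explicit evidence.
- **rnaseq_linker** — filter paired alignments by MAPQ/uniqueness, build a
  cross-contig connection graph from exon-overlapping read pairs, merge
  models by union-find at a read-support threshold, and report correction
  curves plus truth-based accuracy.
- **pipeline / cli** — orchestrated, fully seeded experiments.

## CLI

```sh
# synthetic genome + truth annotation
draftgauge simulate --n-genes 200 --n-scaffolds 4 --seed 1 \
    --out-fasta genome.fa --out-gff truth.gff3

# cut into exactly 5000 contigs with template-matched lengths
draftgauge fragment --genome genome.fa --template lengths.txt -x 5000 \
    --seed 11 --out contigs.fa --plan plan.json

# or split an existing gapped assembly at N-runs >= 50
draftgauge fragment --genome scaffolds.fa --min-gap 50 --out contigs.fa

# emulate prediction on the fragmented assembly
draftgauge predict-emulate --truth truth.gff3 --plan plan.json \
    --p-invent 1.0 --out models.gff3

# cluster models from two assemblies into families
draftgauge cluster --models draft models.gff3 --models ref ref_models.gff3 \
    --contigs contigs.fa --contigs genome.fa --out families.tsv

# merge cross-contig models with paired-end evidence
draftgauge link-rnaseq --models models.gff3 --sam reads.sam --k 1 \
    --out merged.gff3

# everything, from a YAML config
draftgauge run-all --config experiment.yaml --out results/
```

Exit codes: 2 usage/config error, 3 data error, 1 internal error.

## Conventions

Coordinates are 0-based half-open everywhere in memory and 1-based
inclusive only inside GFF3 files. All randomness flows through explicit
seeds; rerunning any generator, plan or experiment with the same seed is
byte-identical. All interchange formats (FASTA, GFF3, SAM, plan JSON, TSV)
round-trip byte-stably.
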