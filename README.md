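# bactsig

Mutational-signature analysis for bacterial mutagenesis experiments.

Reversion (Ames-type) assays followed by whole-genome sequencing of revertant
clones are a compact way to read out the mutational fingerprint of a chemical:
each sequenced clone carries a handful to a few dozen single-nucleotide
variants, and the distribution of those variants over trinucleotide contexts
is the chemical's signature. `bactsig` implements the full analysis path for
such experiments:

- **Catalogs** — PASS-filtered SNVs from per-clone VCFs are classified into
  the 96 pyrimidine-collapsed single-base-substitution (SBS) channels
  (`A[C>T]G`, …: six substitution classes × 16 flanking-base combinations,
  canonical COSMIC order), or into 192 strand-aware channels using a gene
  annotation (transcribed = pyrimidine of the mutated pair on the template
  strand, by the COSMIC convention; configurable).
- **Signature extraction** — non-negative matrix factorization of the
  samples × channels catalog, V ≈ W·H, minimizing the generalized
  Kullback–Leibler divergence by multiplicative updates. The number of
  signatures k is selected by bootstrap stability: per-sample multinomial
  resampling, repeated factorization, cosine-distance clustering of all
  bootstrap signature vectors, and the mean silhouette per cluster as the
  stability score.
- **Exposures** — per-clone non-negative least-squares attribution of
  mutation counts to the extracted signatures, reported as counts and
  relative contributions.
- **Genome renormalization** — signatures can be re-weighted between
  trinucleotide frequency backgrounds (e.g. bacterial genome → human genome)
  before cross-species comparison.
- **COSMIC comparison** — cosine-similarity ranking of extracted signatures
  against a COSMIC-format SBS catalog.
- **Strand bias** — per-channel exact binomial tests of transcribed vs
  untranscribed counts with Benjamini–Hochberg correction.
- **Enrichment** — Enrichr-style gene-set over-representation (one-sided
  Fisher/hypergeometric p, BH adjustment, odds ratio, combined score
  = OR × (−ln p)) for companion expression experiments.
- **Synthetic data** — a generator that plants known signatures, burdens,
  strand biases and reversion-target mutations into simulated genomes and
  clone VCFs, so every stage is testable against ground truth without any
  external download.

## Worked example

Simulate the default two-signature experiment (48 clones in 5 treatment
groups; control clones ≈0.2 SNVs, glycine-conjugate-like groups 14 SNVs,
taurine-conjugate-like groups 27 SNVs per clone; 4:1 transcribed-strand bias
on the glycine-like signature), then run the analysis:

```sh
bactsig simulate --outdir sim --seed 7
# simulated 48 clones, 747 mutations -> sim

bactsig catalog --vcf-dir sim/vcf --fasta sim/genome.fa --gff sim/genes.gff3 \
    --out catalog96.tsv
bactsig catalog --vcf-dir sim/vcf --fasta sim/genome.fa --gff sim/genes.gff3 \
    --stranded --out catalog192.tsv

bactsig extract --catalog catalog96.tsv --k-range 1:4 \
    --bootstraps 30 --restarts 3 --seed 11 --out sig
# recommended k = 2 -> sig

bactsig compare --signatures sig/signatures.tsv \
    --cosmic sim/planted_signatures.tsv --top 2
# S1    taurine-like    0.99
# S1    glycine-like    0.04
# S2    glycine-like    1.00
# S2    taurine-like    0.02

bactsig strandbias --catalog catalog192.tsv --out bias.tsv
# 3 channels flagged at q < 0.05 -> bias.tsv
```

The extraction report (`sig/extraction_report.json`) shows why k = 2 was
chosen: mean bootstrap stability stays above the 0.8 threshold up to k = 2
(0.996 at k = 1, 0.988 at k = 2) and collapses at k = 3 (0.66). Both
recovered signatures match the planted profiles at cosine ≥ 0.99, and the
flagged strand-bias channels are the G[C>T]N channels carrying the planted
4:1 template-strand excess.

The same stages are available as library functions (`bactsig.simulate_clones`,
`build_catalog`, `select_k`, `fit_exposures`, `rank_matches`,
`strand_bias_table`, `fisher_enrich`, …), and `bactsig run --config run.yaml
--outdir out --seed N` drives the whole pipeline from one YAML file, writing
a manifest with per-output SHA-256 checksums (identical config + seed gives
identical checksums).

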