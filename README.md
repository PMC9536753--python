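# regnetrank

Systems-level identification of key transcription factors (TFs) from matched
open-chromatin (ATAC-seq) and expression (RNA-seq) data across a panel of
cell types. The package builds a weighted, directed TF → gene regulatory
network per cell type, scores every TF's global regulatory influence with
personalized PageRank, and runs the downstream analyses that turn those
scores into biology: constitutively active TFs, lineage- / memory- /
tissue-residency-specific TFs, "transcriptional waves" of coordinated TF
activity, and cross-species overlap tests. A synthetic-data module generates
complete inputs with planted driver TFs, so every stage is testable without
any external download.

Intended users: computational biologists studying cell-fate regulators in
multi-lineage systems (e.g. immune cell compendia), who start from peak
calls and an expression matrix rather than raw reads.

## The model

**Network construction.** For each cell type, PWM motifs are scanned inside
open-chromatin peaks; a match is called where the exact p-value of its
log-odds score (computed by dynamic programming over the integerized score
lattice) falls below a threshold (default 1e-5). Sites are linked to target
genes through a strand-aware promoter window (default −5000/+1000 bp of the
TSS) or a user-supplied enhancer→gene link table.

**Weighting.** With z_i the gene's expression z-score across cell types,
node weights are

&nbsp;&nbsp;&nbsp;&nbsp;s_i = e^{z_i}

and the edge from TF to gene j with n supporting binding sites is

&nbsp;&nbsp;&nbsp;&nbsp;e_ij = g · Σ_{k=1..n} p_k · m_k

where g is the TF's expression, p_k = σ(x_k − 5) rescales the peak's
−log10 p intensity x_k to (0,1), and m_k applies the same sigmoid to the
−log10 of the motif match p-value.

**Ranking.** The walk runs against the direction of regulation
(gene → regulator), so TFs accumulate rank from the genes they regulate.
The score vector solves

&nbsp;&nbsp;&nbsp;&nbsp;v = (1 − d)·s + d·W·v,&nbsp;&nbsp;d = 0.85

with W column-stochastic, s normalized to sum 1, and dangling nodes
teleporting to s; solved by power iteration to an L1 tolerance of 1e-10 and
verified in the tests against a dense linear solve.

**Downstream statistics.** PageRank scores are treated as log-normal
(Shapiro–Wilk-checked); specific TFs are called by Welch's t-test on log10
scores (one-sample t-test when the target group has < 3 samples) with tiered
cutoffs — lineage (p<0.001, log2FC>1), sub-lineage (0.005, 0.5), memory
(0.1, –), tissue-resident (0.1, 0.5). A balanced-resampling scheme guards
small-target contrasts; Fisher's exact test quantifies cross-species list
overlap; and TFs are clustered into activity waves by k-means under five
candidate distance metrics with silhouette-based selection of metric and k.

## Worked example

`examples/01_end_to_end_pipeline.py` simulates a 3-lineage panel (9 cell
types, 20 TFs with two planted drivers per lineage, 120 genes), runs the
pipeline and prints:

```
PageRank matrix: 20 TFs x 9 cell types
L1: called ['TF001', 'TF002']  (planted drivers: ['TF001', 'TF002'])
L2: called ['TF003', 'TF004']  (planted drivers: ['TF003', 'TF004'])
L3: called ['TF005', 'TF006']  (planted drivers: ['TF005', 'TF006'])
```

Every TF called lineage-specific at the strict tier is a planted driver of
that lineage: the network weighting plus PageRank concentrates influence on
exactly the TFs whose motifs sit in the open promoters of their lineage's
up-regulated genes. The other examples cover motif scanning with exact
p-values (`02`), the PageRank equation on a 5-node network (`03` — TF_A
scores 0.42 vs TF_B's 0.10 because its exclusive target carries node weight
e^2), memory-TF calling with balanced resampling and Fisher overlap (`04`),
and transcriptional-wave discovery (`05` — Pearson wins the silhouette
comparison at k = 8 with ARI 1.0 vs the planted patterns).

A thin CLI wraps the same library:

```bash
regnet-rank simulate --out data --seed 1
regnet-rank run-all --input-dir data --out run --seed 1
```

## Layout

- `src/regnetrank/io.py` — FASTA / narrowPeak / MEME / TSV readers-writers
- `src/regnetrank/motifs.py` — exact-DP score models, peak scanning
- `src/regnetrank/network.py` — weighting scheme and network assembly
- `src/regnetrank/pagerank.py` — walk matrix and personalized PageRank
- `src/regnetrank/specificity.py` — specific / active TF statistics
- `src/regnetrank/clustering.py` — waves (PCA, metric k-means, silhouette)
- `src/regnetrank/synthetic.py` — planted-truth data generator
- `src/regnetrank/pipeline.py`, `cli.py` — orchestration and `regnet-rank`
- `docs/methods.md` — modeling choices, defaults and limitations
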