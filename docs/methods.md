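# Methods

## Model and assumptions

bootbin bins metagenomic sequences purely by composition. The working
assumption is the classical genomic-signature one: oligonucleotide usage
is roughly homogeneous along a genome and differs between genomes, so
fragments of the same organism cluster in k-mer frequency space. The
method needs no reference database and no coverage information, which is
what makes it applicable to unassembled long reads and to communities
with poor database representation — but it also means organisms with
very similar composition (e.g. closely related species) can merge into
one bin, and intra-genomic compositional outliers (rRNA operons, recent
horizontal transfers, plasmids) can detach from their host bin.

### Signatures

Each sequence is represented by the frequencies of its canonical k-mers
(default k = 5, 512 features: for odd k there are 4^k/2 canonical k-mers
because no k-mer equals its own reverse complement). Strand pooling is
used because contig orientation is arbitrary. Windows containing N or
another IUPAC ambiguity code are skipped deterministically rather than
randomized. Frequencies are compositional, so by default they are mapped
to centered log-ratio (CLR) coordinates after adding a per-row
pseudo-frequency of max(1/(2W), 1e-6), where W is the row's count of
valid windows: a sequence with W windows cannot resolve frequencies
below ~1/W, so half that value is a natural prior mass, and the floor
keeps very long sequences from degenerate log arguments. `transform
="none"` bypasses the CLR for comparability experiments. Rows with W = 0
(no valid window) stay zero and are flagged.

### Point roles and thresholds

Three length thresholds control which sequences participate in which
stage: min_len (default 500 bp) discards fragments whose pentamer
profiles are too noisy to place at all; t_b and t_c (defaults both
1000 bp) split the rest into remaining points ([min_len, t_b): classified
only), border points ([t_b, t_c): embedded to push clusters apart, never
clustered) and cluster points (≥ t_c: embedded and clustered). All lower
edges are inclusive. t_b = t_c is legal and right for narrow length
distributions such as raw long reads (the preset used in the long-read
tests is t_b = t_c = 500).

### Compression / decompression

With factor c > 0 the pipeline repeatedly draws an unassigned point
uniformly at random as a representative and assigns its c nearest
unassigned neighbours (Euclidean distance in CLR signature space; ties
broken by lower row index) as its associates, so c = 1 roughly halves
the point count. Only representatives are embedded and clustered;
afterwards every associate inherits its representative's cluster label,
so the classifier trains on the full compressed set, not just the
sample. Compression is applied per role (cluster points among
themselves, border points among themselves): decompression propagates
*cluster* labels, and border points must never receive one. The
trade-off is real: if c is large and minPts is not lowered, small
clusters fall under the density threshold and are missed. The greedy
"exactly c nearest unassigned neighbours" rule is this package's
definition of the factor; a radius-based alternative would also be
defensible.

### Embedding

Barnes–Hut t-SNE (scikit-learn) with perplexity 30 (clamped to (n−1)/3
with a warning), theta = 0.5, 1000 iterations, PCA initialisation, and a
PCA pre-reduction of the 512-D CLR features to ≤ 50 dimensions — the
standard recipe for stabilising Barnes–Hut t-SNE on high-dimensional
inputs. The embedding is stochastic but fully determined by its seed;
the suite asserts byte-level reproducibility.

### Clustering

DBSCAN on the 2D coordinates of cluster points only, with standard
semantics (core point: ≥ minPts points within eps, self included).
minPts defaults to 20 and is the user-facing knob; smaller values admit
smaller clusters. eps is automated as the 95th percentile of each
point's distance to its (minPts−1)-th nearest neighbour (the k-distance
heuristic): inside a cluster the k-distance is small and roughly
constant, so a high percentile sits just above the within-cluster
scale. A degenerate all-identical coordinate set falls back to a
machine-epsilon-scaled eps with a warning. Cluster numbering is made
deterministic by ordering clusters by their lowest member row index.
Noise (−1) is a first-class label: excluded from classifier training,
but noise points still receive a final bin.

### Classification

A random forest (500 trees, seeded, single-threaded) is trained on the
CLR signatures of all non-noise cluster points plus their decompressed
associates, with the cluster label as response. Features are signatures,
not 2D coordinates, because remaining points are never embedded yet must
be classified — signature space is the only space all retained sequences
share. Every retained sequence is then predicted, including the training
sequences themselves (a cluster point's bin may therefore differ from
its de novo cluster; pinning training points to their cluster would be
the alternative). An optional minimum vote share (`min_vote`) can leave
low-confidence sequences unbinned; it is off by default because the
method's contract is that every retained sequence gets a label.

### Chunking

With `chunk_length` = 3000 bp, sequences are cut into consecutive
non-overlapping chunks before anything else; a trailing remainder
shorter than min_len is merged into the preceding chunk so long contigs
never shed discarded tails. Chunking makes the number of cluster points
per genome proportional to recovered genome bp rather than to contig
count, which normalizes cluster density when assemblies are uneven.
Chunk bins are aggregated back to their parent by bp-weighted majority
(ties to the smaller bin label), with the winning fraction reported as a
per-parent agreement score. The aggregation rule is this package's
choice.

## Evaluation

For genome g, best-bin(g) is the bin holding the largest bp share of g;
sensitivity(g) is that share of g's binned bp; precision(b) is the bp
share of b's majority genome; F1(g) is the harmonic mean of
sensitivity(g) and precision(best-bin(g)). Aggregates are means and
medians over genomes, in percent. bp weighting is the default (binning
quality is about recovered genome fraction); `weight="count"` suits
chunk-level scoring. By default discarded and unbinned sequences are
excluded from denominators (the binner is scored on what it claims to
bin); `strict=True` counts them against sensitivity.

## Synthetic communities

The generator emulates the one property the method relies on — distinct
per-genome composition — with order-2 Markov genomes (contexts =
dinucleotides, enough to induce realistic pentamer structure) whose
per-context transition probabilities are drawn from a symmetric
Dirichlet(1.0). Defaults: 5 genomes of 200 kbp, 150 fragments each.
Fragment lengths are log-normal truncated to [500, 50 000] bp with two
presets: "contigs" (μ = ln 8000, σ = 0.8, error-free) and "nanopore"
(μ = ln 6000, σ = 1.0, 10% per-base error as i.i.d. substitutions,
insertions and deletions in 2:1:1 ratio). Everything is deterministic
per seed, with genome sampling and fragmentation on independent streams.

What this does *not* emulate matters for interpreting green tests:
Dirichlet(1.0) genomes are far more compositionally distinct than real
congeneric species, there is no shared core of conserved genes, no
repeats, no chimeric contigs, and no coverage structure. Passing the
recovery tests therefore shows the pipeline machinery is correct and
well-calibrated on separable input, not that real communities of close
relatives would resolve equally well — on the synthetic defaults the
pipeline recovers all five genomes at F1 = 100%, which should be read as
a ceiling, not a typical field result.

## Problem sizes and numerical choices

The test and acceptance workloads use 750-fragment communities (5 × 150,
~7 Mbp) and a 210-fragment uneven community — sizes at which the full
pipeline runs in seconds while still exercising every stage, including
densities comfortably above minPts = 20. The uneven community
(150/15/15/15/15 fragments) is constructed so that the rare genomes fall
*below* minPts without chunking and above it with 3 kbp chunking, which
is exactly the density-normalization scenario chunking exists for.

Tie-breaking is deterministic everywhere randomness is not explicit:
compression neighbour ties by row index, chunk-aggregation ties by
smaller bin label, best-bin ties by smaller bin label, cluster numbering
by lowest member index. One master seed derives the per-stage seeds
(compression, embedding, forest) at fixed offsets, so stages are
independently reproducible and two runs with the same configuration are
byte-identical on all tabular and JSON outputs.

## Known limitations

- Composition alone cannot separate near-identical signatures; there is
  deliberately no coverage- or abundance-based refinement.
- t-SNE coordinates have no absolute meaning across runs with different
  seeds; only the derived labels are comparable.
- The automatic eps is a heuristic; pathological density gradients may
  need a manual `--eps`.
- Bin quality estimation (completeness/contamination), taxonomic and
  functional annotation are out of scope; the annotation TSV overlay is
  the generic hook for externally computed labels.
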