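# Methods

## Problem setting

A compound's mechanism of action is read out in two modalities: a
transcriptional perturbation signature over a fixed panel of landmark genes,
and the molecule's 2D structure. The model scores every pathway in a curated
label space and returns a descending ranking; the quantity of interest is
top-N accuracy — the fraction of evaluated compounds with at least one true
pathway among the N best-ranked predictions.

## Curation chain

**Pathways.** Gene sets are read from GMT (name, description, genes; one set
per line, load order preserved, genes deduplicated). Two filters define the
label space: a size cutoff (`max_genes`, default 65 — sets with more genes
describe general biology rather than a specific mechanism and are removed;
the boundary is inclusive, a 65-gene set is kept, a 66-gene set is not) and a
name blacklist, seeded with the substrate-organised cytochrome-P450
collection (a metabolism catalogue, not a mechanism). Only that one name is
built in; the blacklist is a config list with exact-name matching by default
and an optional substring mode, because "mechanistically uninformative" is a
judgement call the user may extend.

**PPI graph.** A symbol-mapped edge list (TSV: `gene_a`, `gene_b`,
`combined_score` on the STRING 0–1000 scale) is restricted to the landmark
gene space, thresholded at `score_threshold` (default 800, inclusive),
deduplicated to undirected edges, and given a self-connection per node.
Scores are used only for thresholding; the adjacency is binary, as no
edge-weighting rule is part of the method. Edges touching unknown genes are
dropped silently but tallied in a load report. Mapping protein identifiers
to gene symbols is out of scope: the loader expects a pre-mapped edge list.

**Compounds.** Replicate signatures sharing one gene space are grouped per
compound. A compound is retained iff it has (i) non-empty target-gene
annotations, (ii) at least `min_signatures` replicates (default 5,
inclusive), and (iii) a SMILES rdkit can parse (the empty string counts as
unparseable). Its profile is the unweighted mean of all its replicate
profiles — plate, dose, treatment time and cell line are deliberately
ignored, so the averaging is invariant to replicate order and metadata.

**Labels.** (compound, pathway) is positive iff the compound's targets
intersect the pathway's genes. Compounds with zero positives are kept (they
can be scored at inference) but contribute nothing to the loss. For each
compound with k positives, `ratio * k` (default 3k) distinct negatives are
drawn uniformly without replacement from its non-positive pathways; when too
few exist, all are taken and a warning is emitted. Negatives are drawn per
compound rather than by global compound × pathway cross-combination — the
per-compound view guarantees no pair ever carries both labels.

**Split.** Compounds are permuted under a seed and sliced 80/10/10. Train
and validation sizes are the fractions rounded half-up with the remainder to
test; this rounding reproduces conventional cohort sizes exactly (2338
compounds → 1870/234/234) where flooring does not. The rule is configurable
(`rounding="floor"`).

## Network

With `S = D^(-1/2) A D^(-1/2)` (self-connections included, spectrum within
[-1, 1]), the graph-convolution layer computes
`H = ReLU(Σ_{k≤K} S^k x W_k + b)` with `C` output channels, i.e. a
polynomial spectral filter of order `K` (default K = 1, C = 4). The
flattened `n_genes × C` latent — no pooling, so the dense stack sees
gene-resolved features — is concatenated with the Morgan fingerprint
(radius 2, 2048 bits, binarised counts; community-standard ECFP4-equivalent
settings, both configurable) and passed through dense layers of widths
4096/3016/2048/1024 with ReLU on every layer except the last dense output.
Dropout rates map in order [graph-conv, dense1..dense4] =
[0.2, 0.5, 0.5, 0.5, 0.2]; the placement of the graph-conv rate at the head
of the list is a documented assumption. The output head is a linear layer of
width `n_pathways` with a per-pathway sigmoid — the 3:1 positive/negative
pair construction makes per-pair binary cross-entropy the natural loss, and
the loss is masked to the labeled pairs only (mean over labeled entries;
unlabeled pathway scores cannot move it). A grouped softmax over each
positive with its own negatives is a noted alternative, not implemented.

Training uses Adam (standard moments β₁ = 0.9, β₂ = 0.999, ε = 1e-8) over
mini-batches of compounds, and early stopping on validation loss: training
halts when the monitor fails to improve for `patience` successive epochs and
the best-validation weights are returned. Defaults at paper scale: learning
rate 1e-4, batch 32, patience 10. All arithmetic is float64 numpy; the seed
drives initialisation, shuffling and dropout, so runs are exactly
reproducible and a saved checkpoint (single `.npz` with weights, config,
label space and operator) reloads to bit-identical predictions. Non-finite
losses abort with a diagnostic rather than training through divergence.

### Numerical choices

- **Spectral-mixing initialisation.** The graph-conv mixing weights start at
  the identity polynomial basis (channel c reads `S^(c mod (K+1)) x`, bias
  0) rather than at random Gaussians: under ReLU, an unlucky random mixing
  can zero out the profile direction entirely, leaving gradient descent on a
  marginal-rate plateau it does not escape. Dense weights are He-scaled
  random draws, which also break the symmetry between channels that share a
  basis vector.
- **Tie-breaking.** Rankings sort by descending score with ties broken by
  pathway index ascending (stable argsort), so predictions are deterministic.
- **Sigmoid/BCE stability.** Scores are computed with the two-branch sigmoid
  and the training loss with `logaddexp` on logits; the standalone masked
  cross-entropy clips probabilities at 1e-15.
- **Degenerate inputs.** Empty pair lists, missing rankings, non-square or
  asymmetric operators, dimension mismatches and dropout-rate/width
  mismatches all raise immediately; splits of fewer than three compounds are
  rejected; tiny splits are adjusted so the test set is never empty.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, with
no downloads:

- genes `G001..Gn` with a sparse background interaction graph (edge
  probability `graph_edge_prob`, scores 800–1000) plus sub-threshold decoy
  edges (scores 150–799) so score filtering is actually exercised, and
  elevated connectivity (`pathway_edge_prob`) among each pathway's members so
  graph propagation is informative;
- pathways built as a distinctive **core** (the gene space partitioned
  across pathways) plus randomly drawn shared periphery up to the sampled
  size. Cores make target annotations point at few pathways, mirroring real
  label spaces where a drug's targets are characteristic members of its
  mechanism pathway and positives are sparse relative to the label space —
  fully random subsets at this scale would put every gene in several
  pathways and drive the positive rate far above anything realistic;
- compounds with one planted true pathway each: targets are drawn from the
  true pathway's core (a configurable fraction has none), SMILES come from a
  bundled catalogue of 373 valid structures indexed by compound number (a
  fraction is corrupted into unparseable strings), and each replicate
  signature is `Normal(0, noise_sd)` per gene plus `effect_size` on the true
  pathway's members;
- a `truth.tsv` mapping each compound to its planted pathway.

Defaults define the standard study regime used by the test-bench and the
acceptance script: 60 genes, 15 pathways of 4–8 genes, 300 compounds with
3–8 replicates (straddling the ≥5 cutoff), effect 3 on unit noise, 5%
missing targets, 5% bad SMILES. Regeneration under an equal seed is
byte-identical. `expected_curation_counts` gives the analytic expectation of
compounds surviving the three filters (the three defects are drawn
independently per compound).

What the generator does **not** emulate: L1000 covariance structure between
genes, dose–time kinetics, realistic marginals, multi-mechanism compounds
(one planted pathway each keeps top-N semantics unambiguous), and any real
correlation between chemical structure and mechanism — fingerprints vary
across compounds but are uninformative of the planted pathway by
construction. Passing the planted-signal benchmarks therefore shows that the
architecture, loss masking, optimisation and evaluation are correct and that
the network can extract a pathway-localised expression signal through the
graph; it does not certify performance on real LINCS/Reactome/STRING data.

## Benchmark configuration

The scaled-down configuration (`ModelConfig.small()`: 2 graph-conv channels,
dense widths 64/48/32/16, the same dropout pattern, learning rate 3e-3,
batch 16, patience 30, max 300 epochs) is sized for single-CPU runs on the
default synthetic regime; the learning rate and batch size were chosen for
robust convergence of the small network, where the paper-scale defaults
(lr 1e-4, batch 32) converge needlessly slowly. On this regime the
planted-pathway evaluation is scored against `truth.tsv` (one true pathway
per compound), for which the analytic chance level of top-3 accuracy among
15 pathways is 3/15 = 0.2. A model-free nearest-centroid baseline (score
each pathway by the mean profile over its member genes) provides the
independent reference for how recoverable the planted signal is.

## Known limitations

- The exact spectral filter of the original graph-convolution module is not
  pinned by its summary description; this implementation provides the
  polynomial filter in `S` with configurable order and treats K = 1 as the
  default reading.
- The paper-scale counts (1001 curated Reactome pathways; 978-node /
  8320-edge STRING graph; 2348 curated molecules and the 1870/234/234 split;
  specific compounds' ranked lists) depend on pinned external downloads and
  the original trained weights; they are integration checks against real
  data, not unit tests, and are out of scope here. The printed 2348 valid
  molecules and the 1870+234+234 = 2338 split sizes do not reconcile; the
  implementation reports sizes and does not attempt to explain the gap.
- Signature profiles are treated as opaque real vectors; no assumption about
  which processing level produced them is made or checked.
- The dense stack at paper scale (4096-wide first layer over
  `n_genes × C + 2048` inputs) is memory- and compute-heavy in pure numpy;
  the small configuration exists precisely so the method is exercisable
  end-to-end on one CPU.
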