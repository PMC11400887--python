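# Methods

## Model

`flamscan` segments a genome assembly into three per-bin hidden states —
background (0), flam-like unistrand piRNA cluster (1) and
centromere-like region (2) — with a categorical hidden Markov model
whose only observable is the discretised, strand-resolved *Gypsy*-family
TE content of each bin. The modelling assumptions are:

* a bin's state depends on its neighbours only through the first-order
  Markov chain (runs of cluster/centromere bins are long relative to the
  bin size, so strong self-transitions encode segment persistence);
* the *Gypsy* coverage signature is informative per strand: clusters are
  dense on one strand, centromere-like regions on both, background on
  neither;
* contigs are independent sequences — transitions never cross contig
  boundaries and the start distribution π is estimated from one
  observation per contig, the only choice consistent with decoding
  fragmented assemblies.

### Coordinates and binning

All coordinates are 0-based half-open (BED convention). Contigs are
tiled into consecutive `bin_size` windows (2 500, 5 000 or 10 000 bp by
convention; any positive size is accepted); the trailing window is
truncated at the contig end and kept, and all coverage fractions are
normalised by the true bin width.

### Emissions

Per strand, the covered fraction of each bin is the unioned base
coverage of selected features divided by the bin width — overlapping or
fragmented annotations can never push a fraction above 1, which also
makes the pipeline insensitive to whether nested TE annotations were
pre-merged upstream. *Gypsy* selection is a case-insensitive substring
match (`"gypsy"`) against the family label, covering both EDTA
(`Gypsy_LTR_retrotransposon`) and RepeatMasker (`LTR/Gypsy`) dialects;
an exact-match mode exists for curated label sets. Unstranded features
are dropped (with a logged count) because the emission alphabet is
strictly per-strand. Discretisation against threshold *t* ∈ (0, 1] is
the symmetric rule: both strands ≥ *t* → 2, exactly one → 1, else 0.
The comparison is inclusive (≥) so that documented threshold values are
attainable boundaries; thresholds in 0.025–0.100 work best in practice,
with 0.075 the shipped default.

### Training

Supervised maximum likelihood with additive pseudocounts, applied per
matrix cell before row normalisation: 0.001 for transitions, 1 for
emissions and starts. The small transition pseudocount keeps unobserved
transitions possible but strongly discouraged — the asymmetry versus the
emission pseudocount matters, because states are rare and transitions
between non-background states essentially unobserved. Multi-species
models are built by fitting one model per species and taking the
element-wise arithmetic mean (rows renormalised to machine precision);
averaging probabilities rather than pooling counts prevents a large
genome from dominating the combined model.

### Decoding

Viterbi (the maximum a-posteriori joint path) per contig, computed in
natural-log space — with 3 states no scaling tricks are needed. Ties at
the traceback are broken toward the lower state index, a deterministic
rule that biases toward the background state. Posterior marginals via
scaled forward-backward are exposed for diagnostics
(`posterior_marginals`) but do not drive calling.

### Calls

Maximal runs of identical non-zero state become interval calls. Optional
smoothing (`max_gap_bins` bridges same-state runs across short
background gaps, `min_bins` drops short runs) is off by default: the
defaults are faithful to the raw per-bin decoder output. Cluster strand
is a derived annotation: the emission alphabet is strand-symmetric, so
the HMM cannot call strand; instead the call's TE-majority strand is
computed from the coverage track and the cluster strand reported as its
opposite (unistrand clusters carry *Gypsy* fragments predominantly
antisense to the precursor transcript). Centromere-like calls get `.`.

### Evaluation

Truth tracks are built from cluster/centromere BED intervals; a bin is
labelled when ≥ `min_overlap_frac` (default 0.5 — a bin belongs to the
class covering most of it; exposed as a parameter since any cut-off is
somewhat arbitrary) of its width overlaps an interval, cluster taking
precedence over centromere with a warning. Metrics are one-vs-rest per
class: precision TP/(TP+FP), recall TP/(TP+FN), FPR FP/(FP+TN),
F₁ = 2TP/(2TP+FP+FN). Degenerate 0/0 ratios are defined as 0; classes
with TP+FP+FN = 0 (absent from both truth and prediction) are excluded
from macro means so a vacuous class cannot inflate them, and macro
averaging covers precision/recall/F₁ only — FPR is reported per class,
with class-1 FPR the headline number for cluster predictions. Evaluation
is restricted to contigs retained by an NX cut-off (default N90; N100
keeps everything), because false positives concentrate on short,
fragmented contigs. NX is computed from the verbatim definition with
ties resolved by including all contigs of equal length in the cumulative
sum before testing the X% threshold.

Leave-one-species-out cross-validation sweeps (bin_size, threshold)
settings, trains per-species-then-average inside every fold, and ranks
settings by median macro-F₁ across folds, ties broken toward the lower
threshold then the smaller bin size. Training and decoding contain no
randomness, so the table and ranking are deterministic given the corpus.

## Synthetic data generator

The simulator emulates exactly the data regime the model exploits, with
no nucleotide sequence (nothing in the pipeline reads sequence): each
species gets 3 contigs of 0.5–2 Mb, one planted cluster of 100–200 kb
(*Gypsy* fragment density 0.5, strand bias 0.95 toward a randomly chosen
TE strand), one centromere-like region of 150–300 kb (density 0.5, even
strands), background density 0.02 per strand-pair, fragment lengths
uniform in 300–3 000 bp (clusters contain TE *fragments*, not intact
elements), plus a genome-wide Copia decoy family at density 0.02 that
must be removed by the family filter. Fragments are placed by a
non-overlapping walk in which each gap is proportional to the preceding
fragment's length with a bounded uniform multiplier; this concentrates
the realised covered fraction tightly around the requested density
(within a few percent even for 100-kb regions), which matters because
the planted densities define the contrast the model is trained on. The
default corpus is 6 training + 2 held-out species with per-species seeds
derived deterministically from one corpus seed; it is sized so the full
test suite runs in well under a minute on one CPU while every contig
still holds hundreds of bins.

What the generator does **not** emulate: assembly gaps and collapsed
repeats, TE nesting and age structure, dual-strand (germline) piRNA
clusters, Y-chromosome repeat deserts, annotation noise from de-novo TE
callers, and genuinely ambiguous boundary regions. Passing the
end-to-end synthetic checks therefore demonstrates that the estimator,
decoder and evaluation machinery are correct and that the model resolves
the intended signature at realistic contrast — not that real-assembly
accuracy will match the synthetic operating point, which on real data is
also limited by assembly and annotation quality.

## Numerical choices

* All decoding in natural-log space; probabilities are strictly positive
  by construction (pseudocounts), so no flooring is needed.
* Row-stochasticity is enforced to 1e−9 on load and restored exactly
  after model averaging.
* NX threshold comparisons subtract a 1e−6 slack so integer cumulative
  sums that hit X% exactly are not lost to floating-point rounding of
  the target.
* Viterbi and argmax tie-breaks always pick the lowest state index.
* The calls-BED score is min(1000, round(1000 · (mean_plus + mean_minus)))
  over the call's bins, clamped to the BED score range.
* Sampling uses a single `numpy` Generator per call; inverse-CDF draws
  via `searchsorted` are clipped defensively at the alphabet edge.

## Bundled parameters

`src/flamscan/data/` ships six parameter files — 5-kb bins at
thresholds 0.025/0.05/0.075 and 10-kb bins at 0.05/0.075/0.1, the six
settings the cross-validation sweep favours — trained on the synthetic
corpus (seed 7); their filenames carry `synthetic` and their metadata
records the provenance. They make `flamscan predict` usable out of the
box and pin the package's expected qualitative structure (strongly
diagonal transition matrix, state-concentrated emission rows); for real
assemblies, train on curated annotations with `flamscan train`.

## Known limitations

* Only *Gypsy*-family content is observed; other TE-rich features
  (dual-strand clusters, large repeat-rich Y chromosomes) can be
  absorbed into the centromere-like state, so state-2 calls should be
  treated as "TE-dense on both strands", not as validated centromeres.
* The 3-symbol alphabet discards coverage magnitude above the threshold;
  a multivariate or continuous-emission extension is out of scope.
* Single-species training data with one cluster per genome makes π
  estimates coarse (few contigs per species); decoding is dominated by
  A and B, so this has little practical effect.
* Assembly-level "re-identification" is reported with a minimal
  criterion (≥ 1 true-positive cluster bin); stricter reciprocal-overlap
  criteria can be computed from the calls BED downstream.
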