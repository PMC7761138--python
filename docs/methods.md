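# Methods

## The prediction problem

Pupylation marks substrate lysines with the prokaryotic ubiquitin-like
protein Pup. The predictor treats site identification as binary
classification of individual lysine residues, using only per-residue
*structural* predictions as input — no sequence-composition features.
The working assumption is that pupylated lysines sit in a structurally
distinctive local context (solvent exposure, secondary-structure state,
backbone geometry) that a short window around the site captures.

## Window encoding

Each candidate lysine K is encoded from a window of `flank` residues on
each side (default 6, width 13). Per residue the eight channels are, in
frozen canonical order: `asa` (predicted accessible surface area, Å²),
`ph`, `pe`, `pc` (helix/strand/coil probabilities, each in [0, 1]),
`phi`, `psi`, `theta`, `tau` (backbone angles, degrees, wrapped into
[−180, 180] on ingest). The flattened vector is slot-major,
channel-minor — `slot-6_asa, slot-6_ph, …, slot+6_tau` — an arbitrary
but fixed convention so serialized datasets are stable. Default length:
13 × 8 = 104.

**Mirror padding.** When the window overruns a terminus, the slot at
offset −i is filled with the residue *and all its features* at offset
+i (reflection about the central K), and symmetrically downstream. If a
protein is so short that both ±i are absent, remaining slots copy the
central lysine's own features and a warning is logged; this degenerate
case only occurs for proteins shorter than `flank + 1` residues on both
sides.

**Normalization** is per-feature min-max to [0, 1]. Values outside the
fitted range clip to 0/1; a constant feature maps to 0. Inside
cross-validation the scaling is always fit on the training folds only.
The cleaning stage, which precedes cross-validation, fits on the whole
dataset (it has no train/test divide); the returned cleaned dataset
keeps raw values so CV can re-fit per fold without double scaling.

## k-NN cleaning of the negative class

The curated data the procedure targets have ≈12 negatives per positive.
Cleaning removes every negative with at least one positive among its k
nearest neighbors (Euclidean distance on min-max-normalized features),
sweeping k upward from 12 until, under the default `neg_le_pos` rule,
at most as many negatives as positives survive. `closest_balance`
instead picks the swept k minimizing |negatives − positives|.

Implementation: each negative's removal depends only on the *rank* of
its nearest positive among all other samples (ties broken by ascending
dataset index) — it is removed at cut-off k iff that rank ≤ k. Ranks
are computed once against the original dataset, which makes removal
monotone in k, the sweep deterministic, and the whole procedure one
O(n²) distance computation. The neighbor pool is all other samples by
default; restricting it to positives only is available as
`neighbor_pool="positives"` (then removal reduces to a distance
threshold to the positive class). The pool choice matters: with the
all-samples pool, surviving negatives shield each other and thinning is
gradual as k grows, which is what makes an incrementing-k sweep
meaningful.

## Classifier

C-support-vector classification with RBF kernel exp(−γ‖u−v‖²), γ = 0.5
and C = 3 by default (scikit-learn's `SVC`, which wraps libsvm). Class
weights are deliberately not used — imbalance is handled by cleaning,
not by the loss. ROC analysis uses the signed decision margins
directly; no probability calibration is fitted. The dual optimum is
unique for an RBF kernel, so training is deterministic and predictions
are invariant to sample order up to the solver's stopping tolerance
(~1e−3 on the duality gap; tests allow 5e−3 on scores).

## Evaluation

Stratified n-fold cross-validation: within each class, a seeded
generator shuffles the samples and deals them round-robin, so per-class
fold sizes differ by at most one. Per fold the pipeline fits
normalization and the SVM on the training folds and scores the held-out
fold. Reported are:

- the five metrics Sn, Sp, Pre, Acc, MCC per fold and as arithmetic
  fold-averages (the headline numbers), plus the same metrics computed
  from pooled confusion counts for transparency. For equal-sized folds
  the ratio metrics Sn/Sp/Acc coincide between the two; precision and
  MCC need not, being nonlinear in the per-fold counts — both variants
  are therefore always emitted.
- per-fold ROC curves (thresholds over unique descending scores, ties
  as one step, trapezoidal AUC — equal to the pairwise concordance
  statistic), the arithmetic mean of per-fold AUCs, and a mean curve by
  vertical averaging of TPR on a fixed 101-point FPR grid.

Any metric with a zero denominator reports 0 with a warning rather than
raising, so sweeps keep running visibly on degenerate folds.

Two harnesses reuse this machinery: `ablation_run` cross-validates one
channel subset at a time (ASA; SSpre = ph+pe+pc; each single channel;
the torsion group; ASA+SSpre; all), holding the fold assignment fixed
across subsets; `window_scan` reruns the full pipeline per window
width (widths must be odd).

A leakage caveat: running cleaning once before CV (the default, matching
the procedure's canonical order) lets held-out samples influence which
negatives are removed. `fold_cleaning=True` in the pipeline config (or
`fold_cleaning=` in `cross_validate`) re-runs cleaning inside each fold
on the training portion only, at the cost of a different training set
per fold.

## Synthetic data

The generator emulates the three real inputs (FASTA, per-residue
profiles, site labels). Baselines: every residue is K with probability
`lysine_rate` (default 0.05), otherwise uniform over the other 19 amino
acids; ASA ~ Normal(60, 25) truncated at 0 (Å²); (ph, pe, pc) ~
Dirichlet(1, 1, 1); angles ~ Uniform(−180, 180)°. These baselines are
fixed, field-plausible defaults, all config-exposed. The default
`positive_fraction` 0.076 reproduces the ≈12:1 imbalance of curated
pupylation data.

The class signal shifts designated channels by `signal_delta` baseline
standard deviations for residues within `signal_halfwidth` (default 2)
of a positive site. Default signal channels are `(asa, pc, tau)` —
solvent exposure, coil propensity and the Cα dihedral, the channels
most plausibly informative for pupylation (exposed, disordered
contexts). Domain handling: ASA clips at 0; probability shifts are
renormalized back onto the simplex (so a pc shift trades against
ph/pe); angle shifts clip to [−180, 180] — wrapping would leave a
uniform angle unchanged in law, i.e. no signal, so saturation is the
only way a mean shift can act on a uniform circular baseline.

What the generator does **not** emulate: autocorrelation of structural
features along the chain, realistic secondary-structure segment
lengths, amino-acid composition bias, sequence motifs around sites, or
any coupling between residue identity and features. Passing tests
therefore demonstrate that the pipeline's machinery is correct and can
recover a planted structural signal of known size — not that the
predictor attains any particular accuracy on real proteomes.

Negative sites that happen to lie within `signal_halfwidth` of a
positive site inherit shifted residues in their windows; this
deliberate label-noise-like overlap makes recovery slightly harder than
an idealized two-cluster problem.

## Problem sizes and numerical choices

- Parameter-recovery experiments use ~72 proteins of length 60–160 at
  5% lysine rate (≈400 sites, ≈200 per class balanced), 6-fold CV —
  large enough for stable fold metrics, small enough to iterate on
  quickly.
- Distances: exact O(n²) Euclidean (`scipy.spatial.distance.cdist`);
  no approximate index, as n is small.
- Ties in neighbor ordering break by ascending dataset index; fold
  dealing is round-robin after a seeded shuffle — both documented so
  results are bit-reproducible.
- Profile probability triples may deviate from summing to 1 by up to
  0.05 (predicted profiles are not exactly normalized); larger
  deviations warn.
- Dataset/report serializations use fixed float formatting, so
  re-running any stage with the same config and seed reproduces files
  byte for byte.

## Known limitations

- The structural channels must come from an external predictor (e.g.
  SPIDER2); the package parses its `.spd3` table or a generic TSV but
  does not predict structure itself.
- Fixed γ with window-width scans: as the feature count grows the RBF
  kernel dilutes and wide windows degrade toward chance unless γ is
  re-tuned per width; the scan intentionally holds hyperparameters
  fixed to isolate the effect of width.
- The single-channel `.spd3` dialect supported is the 11-column layout
  (index, AA, SS, ASA, φ, ψ, θ, τ, P(C), P(E), P(H)); other variants
  should be converted to the TSV dialect.
- MCC and precision are reported as 0 (with a warning) on degenerate
  folds; fold-averages including such folds are conservative.
- With 104 min-max features and γ = 0.5, typical pairwise squared
  distances put the kernel in a diluted regime (values ≪ 1). Ranking
  by margin stays excellent there, but the decision threshold (the
  SVM intercept) becomes sensitive to modest class imbalance: a
  training set drawn, say, 188:232 can push sensitivity far below
  specificity while AUC stays above 0.98. Accuracy-type metrics on
  such draws should be read together with AUC, and class counts
  checked before interpreting a low sensitivity as inseparability.
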