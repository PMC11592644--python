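# Methods

## Problem setting

ACE-inhibitory peptides (ACEiPs) are short natural peptides (2–19 residues,
most 2–10) that inhibit the angiotensin-converting enzyme; potency is
summarised by IC50 in µM, and a peptide is treated as active when its IC50
is below 1000 µM.  The toolkit frames discovery as binary sequence
classification over physicochemically encoded peptides, plus an upstream
benchmark-construction procedure and a downstream proteome-screening
procedure.

## Descriptor encoding

Every residue maps to a fixed numeric vector under a named descriptor set;
peptides become residue-by-feature matrices, and combinations of sets
concatenate column-wise.  The registry is table-driven: each set is one CSV
(header = feature names, 20 rows keyed by residue) listed in
`registry.json` with its per-feature pattern tag, provenance note and a
`synthetic` flag.

Two tables carry real published values: One-hot (exact by definition) and
the five Sandberg z-scales.  The remaining 20 sets are
**dimensionality-correct synthetic stand-ins** — seeded orthogonal
projections of a classical property compilation (Kyte–Doolittle hydropathy,
residue mass, Zamyatnin volume, Grantham polarity, pI, net charge,
aromatic/aliphatic indicators, H-bond donor/acceptor counts, Chou–Fasman
helix/sheet propensities), z-scored per column.  They reproduce the shape
and statistical character of the published descriptor families (correlated,
standardized, physicochemically grounded) without claiming their exact
numbers; any table can be replaced by dropping in a CSV.  Widths follow the
published sets where those are fixed (Z-scales 5, FASGAI 6, VHSE 8,
ST-scales 8); the packaged Lin's scales (3) and VSW (7) were chosen so the
six-set optimal combination VVSFZL37 totals exactly 37 features.  The full
22-set concatenation (CodeSet22) totals 155 features with the packaged
tables; the registry always reports its own true total.

Pattern tags partition VVSFZL37's 37 features into 12 geometrical, 11
electronic, 6 hydrophobic, 4 steric and 4 composition features.  The
per-feature assignment is a documented data-file choice (e.g. ST-scales
tagged geometrical; VHSE split 2 hydrophobic / 2 steric / 4 electronic);
analyses that depend only on the partition sizes are unaffected by the
specific assignment.

No per-feature rescaling is applied by default: published scales are
already standardized, and the synthetic stand-ins are z-scored at build
time.  Sequences are upper-cased before validation; any character outside
the 20-residue alphabet is a hard error naming the position — descriptor
tables cover only natural residues, so silent skipping would corrupt
encodings.

## Benchmark construction

Positives: records with IC50 strictly below the 1000 µM threshold; a
sequence reported on both sides of the threshold is treated as
experimentally inconsistent and dropped entirely; duplicates keep the first
report.  Negatives: random sequences with lengths drawn from the positives'
empirical length distribution and residues uniform, filtered to remove any
candidate with > 90 % global-alignment identity to a positive, topped up
until the classes balance.  Identity is matched positions of an optimal
Needleman–Wunsch alignment (match 1, mismatch −1, gap −1) divided by the
shorter sequence's length; at these lengths exact alignment is cheap, so no
heuristic clustering (word filtering, coverage rules) is needed — a
deliberate simplification relative to greedy clustering tools, and strictly
more accurate.  The split is stratified by class only, with
train = round(0.7 · n) per class; 1043 per class yields 730 train / 313
test per class.

## Classifier

Architecture: three LSTM layers (tanh activations, hidden width 128,
dropouts 0.4, 0.4, 0.25) and a two-unit sigmoid head; the input width
equals the combination's feature total.  Peptides are fed N→C terminus and
the head reads the final time step — final-state classification is the
natural choice for whole-peptide labels.  The positive-class probability is
the positive unit's sigmoid renormalised so the two units sum to one, which
makes the 0.5 decision threshold well defined; the loss is the
cross-entropy of that renormalised probability.

The network is implemented directly in NumPy: masked-carry forward pass,
full backpropagation through time, inverted dropout, global-norm gradient
clipping (5.0) and Adam.  Variable lengths in a batch use right-padding
with a masked state carry — once a sequence ends its hidden/cell states
pass through unchanged — so batched predictions equal single-peptide
predictions exactly (asserted in the tests, along with a finite-difference
check of every gradient).

Training hyperparameters (all exposed in `ModelConfig`): Adam at 1e-3,
batch 32, up to 300 epochs with early stopping on a 10 % stratified
validation holdout (patience 30), seeded end to end.  Inference disables
dropout and is deterministic.  A non-finite loss aborts with a diagnostic
rather than silently continuing.

`MeanPoolLogistic` — logistic regression on per-column means over residues
— implements the same prediction interface and serves as the fast proxy for
the selection search and for smoke tests; it deliberately discards residue
order, which is exactly why the LSTM exists, so it is a speed/fidelity
trade-off, not an equivalent model.

## Metrics and importance

Sn, Sp, Acc and MCC follow the standard confusion-table formulas; MCC with
a zero denominator is reported as 0; AUC uses rank-based integration with
mid-rank ties and is NaN for single-class label vectors.  Cross-validation
is stratified k-fold (default 5), each fold trained from scratch.

Importance is pure masking of a fixed model (no retraining): encode the
evaluation set, zero the target columns for all samples, predict, and
report the error rate (FP+FN)/total.  The empty mask therefore equals
1 − Acc exactly.  Importance is computed on the independent test split by
default (configurable) — measuring on training data would conflate
memorisation with information content.  Group scores can exceed or fall
below single-feature scores; no monotonicity is assumed, and only the
recovery ranking on planted data is asserted.

## Leave-Group-Out selection

Each round evaluates one candidate per single-set removal from the carried
subset.  Ties break toward fewer features, then lexicographic member
order.  The search stops when one set remains, or after a configurable
number of non-improving rounds.  The final combination is the
best-accuracy candidate anywhere in the trace, since the greedy path can
overshoot.  Per-candidate evaluation defaults to accuracy on a held-out
split (a full cross-validation per candidate multiplies training cost by
k; both modes are available).  All evaluated candidates are recorded, so
accuracy-vs-feature-count curves can be reconstructed from the trace.

## Virtual digestion

Cleavage rules are pure predicates over a local window around the scissile
bond, in the style of the ExPASy PeptideCutter tables, simplified to their
dominant specificities: trypsin (after K/R, not before P), chymotrypsin
high-specificity (after F/Y/W, not before P), pepsin pH 1.3 (around F/L,
proline blocks; a pH > 2 variant adds W/Y), thermolysin (before
A/F/I/L/M/V, not after D/E), papain (after K/R with hydrophobic P2, not
before P), proteinase K (after A/E/F/I/L/T/V/W/Y).  Digestion is complete
— every predicted site is cut — reflecting idealised optimal-activity
conditions; a missed-cleavage parameter exists but defaults to 0.
Fragments carry 1-based inclusive coordinates and always concatenate back
to the parent.  Multi-protein, multi-enzyme pools digest each protein with
each enzyme separately and take the union (no sequential multi-enzyme
digestion), deduplicated by sequence with full provenance, filtered to
2–19 residues by default.

## Synthetic data

The generators define the study conditions for all tests:

* **Biased-composition sets** mimic the sequence statistics of validated
  inhibitors: lengths 2–10 with most mass on tri- to octapeptides
  (weights 0.06/0.18/0.14/0.18/0.12/0.10/0.10/0.06/0.06 for lengths 2–10),
  positives enriched in P/L/V/G/A/Y overall (bias 1.5, i.e. enriched
  residues get 2.5× uniform weight before renormalisation), C-termini
  biased toward P/F/R/K/Y and N-termini toward L/V/A/G/I (bias 2.0);
  negatives are uniform.  Biases are parameters, so the null regime
  (bias 0) is testable.
* **Planted-rule sets** label uniform random peptides by a logistic on the
  batch-standardised peptide-mean of one descriptor column (default
  z-scale 1, slope 6, Gaussian noise SD 0.25) — strongly but not perfectly
  separable, with stored ground truth for recovery tests.
* **Embedded-peptide proteins** place one peptide per protein at the
  C-terminus behind an enzyme-appropriate flank inside a site-free
  background, so complete digestion releases it exactly.  Exact release of
  an *internal* fragment under, e.g., trypsin would require the peptide to
  end in K/R, so C-terminal placement is the only general construction;
  peptides with internal sites for the chosen enzyme are rejected into the
  manifest rather than silently altered.

What the generators do **not** emulate: real IC50 scales (labels are
binary), homology structure among positives, database noise and annotation
errors, or any coupling between activity and digestibility.  Passing the
recovery tests shows the pipeline recovers signal it is pointed at under
controlled conditions; it does not certify accuracy on real peptide
databases.

## Problem sizes and numerical choices

Tests and the acceptance script run scaled-down networks (hidden width
24–48, 2 LSTM layers, ≤ 60–250 epochs) on planted-rule sets of 400–1000
peptides, digestion checks on 1000 random proteins × 6 enzymes, and
selection searches over 3–5 descriptor groups with the fast proxy — sizes
chosen so the full suite completes in minutes on one CPU while still
exercising every code path at meaningful statistical power.  The capacity
(random-label overfit) check uses 64 peptides with
`validation_fraction = 0`, which switches the early-stopping monitor to
training accuracy — the appropriate monitor when memorisation itself is the
property under test, since a tiny holdout would select weights from an
arbitrary early epoch.  The reference architecture constants are unchanged
defaults throughout.

Other numerical conventions: sigmoid outputs are clipped to
[1e-9, 1 − 1e-9] before renormalisation; pattern ranking breaks ties
alphabetically; selection tie-breaks are documented above; empty feature
groups, out-of-range mask indices, single-class training sets, k larger
than a class, and degenerate split ratios are all hard errors.

## Known limitations

* The packaged non-z-scale descriptor tables are labelled synthetic
  stand-ins; analyses about *specific published scales* require dropping in
  the corresponding published CSVs.
* Cleavage rules are simplified dominant specificities, not full
  position-specific probability tables; digestion is all-or-none.
* The LSTM is CPU-only and single-threaded by design; at the reference
  width (128, three layers) training on thousands of peptides takes
  minutes to tens of minutes.
* The greedy selection search records only one carried path; global optima
  off that path are visible in the trace only at feature counts the path
  visited.
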