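# Methods

This note documents the models, parameter choices and numerical conventions
behind `fconnet`, and what the synthetic validation does and does not
establish about real EEG.

## Synthetic cohort model

Each channel is a unit-variance stochastic alpha-band oscillation plus white
Gaussian sensor noise, in microvolts. Oscillations are produced by
band-pass-filtering white noise (4th-order Butterworth, applied
forward–backward) to a band of width `oscillator_bw_hz` (default 4 Hz)
centred on `oscillator_freq_hz` (default 10 Hz). Stochastic narrowband
oscillators — rather than pure sinusoids — are essential: two independent
sinusoids at the same frequency stay at a fixed phase lag forever and would
register as spuriously coupled by every estimator, whereas independent
narrowband processes decorrelate on the 1/bandwidth timescale.

Coupling is planted by common drive: each coupling edge (i, j, s) has its
own shared latent oscillation that enters both endpoint channels with weight
s. Channel i mixes its incident latents with a private oscillator weighted
`sqrt(max(0, 1 − Σ s²))`; when incident couplings alone exceed unit power
the oscillatory mixture is renormalized to unit variance. Consequences that
the test suite relies on:

- a single edge with s = 1 and no noise makes the two channels identical
  (correlation exactly 1);
- a single edge contributes a noise-free correlation of s²;
- in a clique of coupled channels the per-edge correlation is diluted,
  because each channel's unit power budget is split across its incident
  latents — e.g. in a 4-clique at s = 0.8 each pair shares 1/3 of the
  oscillatory power.

Defaults (chosen once, as a realistic desk-scale resting-EEG condition):
16 channels, 500 Hz, 60 one-second epochs per subject, oscillator RMS
10 µV, sensor noise SD 5 µV. Oscillator phases and noise are independent
across subjects; per-subject seeds derive deterministically from the cohort
seed, so cohorts are exactly reproducible.

The two-group study condition used by the statistical validation is a
modular topology — four modules of four channels, all within-module pairs
coupled — with the groups differing only in coupling strength (0.8 vs 0.4)
at 14 vs 16 subjects. Modular coupling is the standard generative caricature
of functional brain networks and produces a topological (not merely scalar)
group difference after density binarization, which is what fixed-density
comparisons can detect.

What the generator does **not** emulate: volume conduction and field spread
(each sensor sees only its own sources), non-stationarity across the
recording, 1/f broadband background, ocular/muscle artifact morphology
(injected artifacts are rectangular transients), and realistic sensor
geometry. Passing tests therefore demonstrate the correctness and the
method-sensitivity of the *analysis machinery*, not fidelity to any clinical
population.

## Preprocessing

Default order: segment → reject → common-average re-reference → band-pass;
the applied order is recorded in the epoch-set log. Artifact rejection flags
an epoch when any channel exceeds 100 µV absolute voltage or any
consecutive-sample step exceeds 50 µV. The transition criterion compares
adjacent samples (the simplest reading of a "transition"); an epoch-wise
peak-to-peak variant is available (`transition="peak_to_peak"`).

The band-pass is a Hamming-window FIR applied forward–backward (zero phase),
so downstream Hilbert phases carry no group delay. The default length is
`2·fs/low` taps (143 taps at 500 Hz for a 7 Hz low edge): a literal
5th-order FIR (6 taps) cannot isolate a 6 Hz-wide band at 500 Hz — its
transition bandwidth exceeds the whole passband — so the order is exposed as
a parameter (`fir_order=5` is accepted for literal fidelity) with the
practical default above. Filtering is per epoch; with 143 taps on 500-sample
epochs the forward–backward edge transients are non-negligible, which is one
reason phase averages exclude epoch edges (below).

## Dependency estimators

All four estimators return symmetric matrices with zero diagonal and entries
in [0, 1].

**Correlation.** Absolute Pearson correlation per epoch, averaged over clean
epochs. The absolute value is taken because the binarizers rank dependency
*strengths*; a signed-positive mode (negatives clipped to 0) is available.
A consequence worth knowing: for 1-s epochs of narrowband signals the
per-epoch |r| of *independent* channels has mean ≈ 0.2–0.3 (few effective
degrees of freedom per epoch), and epoch-averaging does not shrink this
floor — only the variance around it. Weak true couplings can sit below this
floor and be invisible to correlation while remaining visible to coherence.

**Coherence.** Auto- and cross-spectra are estimated per epoch (Hann taper,
mean removed) and pooled across clean epochs; coherence is formed from the
pooled spectra per frequency bin and then averaged over all FFT bins whose
centre lies in the analysis band, endpoints inclusive. Pooling is the only
sound reading of an epoch-based protocol: single-segment coherence is
identically 1, so at least two clean epochs are required. Pooled K-segment
coherence of independent channels has the known ≈ 1/K bias, which the tests
verify. By the Cauchy–Schwarz inequality every value is ≤ 1.

**Phase order parameter.** Instantaneous phases from the analytic signal
(Hilbert transform) per channel per epoch; the order parameter is the
modulus of the time-averaged phase-difference phasor, averaged over epochs.
The first and last 10% of each epoch's samples are excluded from the
average — Hilbert phases are unreliable near segment edges. For independent
uniform phases the expected value is the mean resultant length
√π/(2√T) of T unit vectors, a floor the tests verify by simulation.

**Synchronization likelihood.** Each channel's epoch is delay-embedded
(lag L = 10 samples, dimension e = 10, so a 500-sample epoch yields 410
state vectors). For each channel a critical radius is chosen as the
P_ref-quantile of the Euclidean distances between Theiler-admissible vector
pairs (|t − s| > ⌈w·N⌉ with w = 0.1 as a fraction; an absolute-sample
reading is available), so that the correlation integral at that radius
equals P_ref = 0.01 to within 1/n_pairs. SL of an ordered pair (i|j) is the
fraction of j-recurrent admissible pairs that are also i-recurrent; the
matrix entry is the mean of the two directions. Identical channels give
exactly 1; independent channels give ≈ P_ref (the conditional collapses to
the marginal), with a small positive bias of order the ratio-estimator
(Jensen) correction, well inside the ±0.003 validation tolerance.
Implementation note: per epoch, each channel's recurrence indicator over
admissible pairs is computed once and all pairwise joint counts are obtained
with a single Gram-matrix product, so the full-matrix cost is linear in
channel pairs only through a BLAS call.

## Binarization conventions

- Threshold keeps weights strictly greater than th.
- Density keeps the round(κ·N(N−1)/2) strongest edges; ties at the cut break
  by lexicographic (i, j), making edge counts identical across subjects.
- MST runs Kruskal on distances d = 1 − w, so the tree keeps the *strongest*
  dependencies — the convention of MST brain-network practice (a literal
  minimum over raw dependency weights would keep the weakest links, which no
  study intends); d = 1/w is available and yields the same tree for distinct
  weights.
- MCC adds edges in descending weight order, including edges internal to an
  existing component, until the graph is connected; at the connecting weight
  the whole tie group is admitted. This equals thresholding at the
  percolation-critical weight, a property the tests check exhaustively.
- All tie-breaking is descending weight then lexicographic (i, j):
  deterministic outputs everywhere.

## Graph metrics

Shortest-path metrics use unweighted BFS distances with the 1/∞ = 0
convention for disconnected pairs. Betweenness values are unnormalized
counts over unordered node pairs (endpoints excluded for node betweenness,
endpoint pairs included for edge betweenness — a single-edge graph scores
1); group comparisons are rank-based, so the normalization convention cannot
affect any p-value. Local efficiency of a node is the global efficiency of
its neighbour-induced subgraph (0 for degree < 2); on any tree — hence on
every MST network — it is exactly 0, so MST binarization is structurally
blind to local-connectivity effects. Modularity Q = Σ(q_mm − a_m²) is
maximized by seeded Louvain with 10 restarts plus greedy single-node
refinement, taking the best partition (also comparing the agglomerative CNM
candidate); on graphs small enough for exhaustive partition enumeration the
optimizer attains the true optimum in the test suite. Assortativity is the
Pearson correlation of end degrees over edges; it is undefined on
degree-regular graphs and reported as missing-with-reason rather than as a
number.

## Group statistics

Wilcoxon's rank-sum test, two-sided, at every binarizer parameter value,
α = 0.05. Exact enumeration of the null is used for combined sample sizes
≤ 12 without ties; otherwise the normal approximation with tie correction.
No correction for multiple comparisons across the grid is applied by
default — matching the pointwise-asterisk convention of the figure-style
reports — with Benjamini–Hochberg available. Subjects whose network fails
at a grid point (disconnected graph, undefined assortativity) are recorded
as missing with a reason and excluded pairwise, never silently dropped.
Default sweep grids: threshold 0.05–0.95 in steps of 0.05, clipped to the
observed weight range; density 0.05–0.50 in steps of 0.05.

## Statistical validation design

Power: 50 replicate cohorts under the two-group study condition above,
coherence estimator, density binarization at κ = 0.25 (mid-grid), global
efficiency; the group difference must reach p < 0.05 in at least 80% of
replicates. Coherence is the designated estimator for this check because
its epoch-pooled noise floor (≈1/K) lies far below the weak group's coupling
expression while the correlation floor does not — itself an instance of the
method-dependence the package is about.

Type-I error: one null cohort (identical coupling in both groups) is run
through the full pipeline once; its 30 per-subject global-efficiency values
are then relabelled at random 2000 times (group labels are exchangeable
under the null, so permutation draws exactly from the test's null
distribution) and the rejection rate at α = 0.05 must lie in [0.03, 0.07].
Permutation over one pipeline cohort, rather than thousands of full
pipeline runs, keeps the check honest and tractable.

Method dependence: on a single fixed cohort the full 4 × 4
estimator-by-binarizer grid of significance flags at mid-grid must be
non-constant — some cells detect the planted difference, others do not.

Problem sizes throughout (16 channels, 60 epochs, 14 + 16 subjects, 50
replicates) are the package's desk-scale defaults; the machinery accepts the
111-channel scale of full EEG nets unchanged.

## Known limitations

- No volume-conduction control: zero-lag-insensitive estimators (phase lag
  index, imaginary coherence) are deliberately out of scope.
- Surface-Laplacian/current-source-density re-referencing is not
  implemented; the common average reference stands in. Note that CAR mixes
  a small amount of every channel into every other, which slightly couples
  otherwise independent channels (and makes 2-channel CAR degenerate).
- Coherence pooling assumes epochs are exchangeable realizations
  (stationarity across the recording).
- The SL independence baseline has the small positive ratio-estimator bias
  discussed above.
- EDF files can be read (via the optional `mne` dependency) but not
  written; the CSV + JSON sidecar format is the canonical round-trip.
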