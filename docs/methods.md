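# Methods

This note documents the models, conventions, defaults and simulation sizes
behind `grkbret`, and what the synthetic benchmarks do and do not show.

## Reduction model and conventions

A well is a dual-channel time series: donor (luciferase) and acceptor
(fluorophore) counts on a shared grid with one plate-wide stimulation time.
The reduction chain is ratio → mock subtraction → window means → fold
change → vehicle normalisation (see README for the formulas). Conventions:

* **Mock subtraction** is per-timepoint across the mock wells of the same
  condition and experimental session; a scalar mode (grand mean of the mock
  ratios) is available (`mock_mode="scalar"`) for instruments where only a
  window-averaged mock value is trusted. Which of the two an original
  instrument script uses is rarely documented; per-timepoint uses all the
  information and is the default.
* **Windows**: baseline `[t_stim − 180 s, t_stim)`, stimulated
  `(t_stim, t_stim + 300 s]`. The sample at the stimulation time itself is
  excluded from both windows because injection transients contaminate it.
* **Vehicle normalisation** is within-session (same condition, same
  replicate index), then statistics are taken across independent sessions.
  A consequence used as an exactness check: a session's vehicle well
  normalised against itself is exactly 1.
* **Gating before fitting** uses the *pre-normalisation* fold changes of
  top-dose vs vehicle wells, since after within-session normalisation the
  vehicle values are identically 1 and carry no variance.
* **SEM** is sample SD / √n over independent sessions throughout.
* Degenerate wells (non-positive corrected baseline) raise; there is no
  outlier rejection or drift/photobleaching correction.

## Statistical machinery

* **Gate**: one-sided two-sample t, pooled variance by default. The pooled
  test is exactly calibrated at n = 3 under equal variances (measured
  empirical size 0.0496 at 200 000 null simulations), whereas the
  Welch/Satterthwaite variant is conservative at this depth (size ≈ 0.039);
  Welch remains available (`gate_test="welch"`) for heteroscedastic data.
* **Bonferroni contrasts** use the one-way-ANOVA residual variance pooled
  over all conditions of the family (df = N − k), i.e. the classical
  "ANOVA followed by Bonferroni's multiple-comparison test"; a plain
  two-sample-t mode exists (`pooled_error=False`). Adjusted p = min(1, m·p)
  with m the number of contrasts supplied.
* **Dunnett** many-to-one comparisons evaluate the multivariate-t reference
  distribution (via `scipy.stats.dunnett`) with a fixed internal seed, so
  adjusted p-values are reproducible to ~1e-3; one- and two-sided.
* **Tukey HSD** is computed directly from the studentized-range
  distribution (Tukey–Kramer standard errors for unbalanced groups) and is
  cross-checked against `scipy.stats.tukey_hsd` in the unit tests; the
  direct form vectorises, which the null-calibration simulations need.
* **Heatmap transform**: signed −log10 of the *unadjusted* p per contrast,
  capped at ±16 (p = 0 maps to the cap); the sign carries the direction of
  the mean difference so gain- and loss-of-recruitment contrasts separate.
* **Clustering**: Canberra distance (0/0 terms contribute 0), complete
  linkage by default, deterministic leaf order.
* **Selectivity rule** (adjusted p < 0.05 and positive direction =
  "significant-positive", each GRK rescue vs knockout + empty vector):
  GRK2/3/5/6-regulated iff {GRK2 or GRK3} and {GRK5 or GRK6} are
  significant-positive; GRK2/3-regulated iff {GRK2 or GRK3} is and neither
  GRK5 nor GRK6 is; otherwise unclassified. The dendrogram is reported
  alongside but the call comes from the rule.
* **Pre-coupling**: one-sided Dunnett on session-level baseline ratios
  normalised to the knockout + empty-vector condition, with a companion
  "dampened dynamics" flag when the condition's Δ net fold change does not
  exceed the reference's.
* **Fisher's exact test**: conditional on fixed margins; the two-sided p
  sums hypergeometric point probabilities not exceeding the observed
  table's, with a relative tie tolerance of 1e-7. The implementation is
  validated against both `scipy.stats.fisher_exact` and an exhaustive
  enumeration oracle over every 2×2 table with N ≤ 8.

## Concentration–response fitting

Log-logistic with Hill slope fixed at 1 by default (free-slope and
fixed-bottom variants available). Concentrations are log10-transformed;
vehicle (c = 0) is excluded from fitting and used only for gating and
normalisation. Default "per-experiment" mode fits one curve per session and
reports the across-session logEC50 mean ± SEM; pooled mode reports the
asymptotic SEM. Initialisation: plateaus from the data range, logEC50 from
the half-maximal response; logEC50 is bounded to the tested range ± 4 log
units, and fits landing outside the tested range are flagged
`extrapolated`. Flat responses (span ≤ 1e-9 relative) raise a
degenerate-fit error; optimiser failure returns a flagged, non-raising
result. DMR concentration–effect fits constrain bottom = 0 and normalise
AUCs to a reference response (the top-concentration mean in the bundled
analysis).

## Motif conventions

P ∈ {S, T, D, E}, X = any residue; Ser/Thr only count as *sites* (Asp/Glu
are phospho-mimics inside motifs, not sites). Overlapping matches are all
counted by default — the deterministic superset — with a greedy
non-overlapping mode for sensitivity analysis. Relative position is the
0-based index of the match's first residue divided by (L − 1), so 0 and 1
are exactly attainable at the segment ends; a 1-based/L variant exists. The
0.25/0.75 breakpoints are assigned *central* by default (configurable), and
contingency tables count motif occurrences pooled across receptors.
Receptor exclusions (e.g. unphysiological chimeras) are an input flag, not
hard-coded. Because counting policy, index base and breakpoint assignment
all shift discrete counts, published single-table p-values can only be
reproduced when those conventions and the exact sequence table are known.

## Synthetic-data generator

What it emulates: ≥3 independent sessions per condition; 3-min baseline /
5-min stimulation at 10-s sampling; mock and vehicle wells per session;
Hill-shaped concentration dependence (default logEC50 −7 to −8);
mono-exponential response onset (τ = 30 s — only the window mean matters,
and τ = 0 gives the analytic limit used in exactness tests);
condition-specific baseline elevation (pre-coupling factor ≥ 1);
multiplicative log-normal channel noise, independent per timepoint and
channel, unit mean, default CV 0.05 (instrument noise magnitudes are not
published; 5 % is a conventional plate-reader figure). The measured ratio is
composed as bleed-through + specific signal (`mock_ratio +
basal·pre·(1 + (top_fold − 1)·h(c)·rise)`), so mock subtraction recovers
the specific signal exactly and the zero-noise round trip returns the
planted fold change to round-off. A `top_is_absolute` mode caps the
stimulated plateau at `basal·top_fold` regardless of pre-coupling,
reproducing the elevated-baseline/dampened-dynamics signature. One integer
seed drives a splittable per-well generator, so datasets are byte-stable.

Segment generation plants motifs at group-controlled relative positions
(central: [0.30, 0.70]; peripheral: [0, 0.20] ∪ [0.80, 1]) on a background
drawn from the 16 residues outside {S, T, D, E}, fills X slots from the same
background, spaces plants by at least a motif length, and verifies by
scanning (regenerating on any collision) — the truth is exactly the hit set
a correct scanner must return.

What the generator does **not** emulate: photobleaching/drift, plate-edge
effects, donor-level variation between conditions, receptor internalisation
kinetics, correlated well noise, and the residue composition biases of real
intracellular loops. Passing benchmarks therefore demonstrates correctness
of the *computation* under the stated noise model, not robustness to every
artefact of real plates.

## Simulation sizes and design choices in the benchmarks

* logEC50 recovery: 7 concentrations, n = 3 sessions, 5 % channel CV,
  200 seeds; the median absolute error criterion is 0.1 log units.
* Null calibrations: 10 000 simulations for the gate, 5 000 each for Tukey
  and for one-/two-sided Dunnett (k = 4, n = 3), ±0.01 around α = 0.05.
  The gate and Tukey nulls are evaluated through vectorized decision rules
  proven equivalent to the per-call API in the unit tests; Dunnett loops
  the real API.
* Selectivity recovery: 8 pairs per simulation (4 per planted group),
  effect = 3 replicate SDs, n = 4 sessions per cell, 200 seeds. The n = 4
  depth is a design choice within the study convention of "at least n = 3":
  a noncentral-t power analysis gives per-contrast power 0.75 at n = 3 vs
  0.91 at n = 4 for a 3-SD effect under Bonferroni (m = 4) with pooled
  error, and reliable (≥95 %) group recovery requires the latter.
* Pre-coupling: planted factor 1.5 at 5 % baseline CV, n = 3, 500 runs;
  the null rate is the family-wise any-flag rate, expected ≈ α.
* Motif association: 20 receptors per group, 2 PXPP plants per segment,
  200 seeds for power (p < 0.01) and 200 for the null rejection rate —
  Fisher's exact test is conservative on discrete tables, so the null rate
  sits at or somewhat below α.

## Known limitations

* Canberra distance is scale-free, so heatmap coordinates whose underlying
  contrast is null (p uniform, −log10 p roughly exponential) contribute
  ~0.5–1 to the distance between *any* two rows. Rows of the GRK2/3 group
  carry two such noise coordinates (the GRK5 and GRK6 contrasts) and are
  therefore mutually about as distant as they are from GRK2/3/5/6 rows: in
  the synthetic benchmark the dendrogram leaf order separates the two
  planted groups into clean contiguous blocks in only ~55–60 % of
  simulations at 3-SD effects (and under ~82 % for any transform/linkage
  variant). The dendrogram is best read as a visual companion; the
  rule-based group call — which recovers ~98 % of labels under the same
  conditions — is the classification of record.
* The Dunnett p-values carry ~1e-3 Monte-Carlo wobble from the
  multivariate-t evaluation (fixed-seed, hence reproducible).
* The gating test is a declared default, not a reconstruction of any
  specific published analysis; with heteroscedastic data prefer the Welch
  option and expect slight conservatism at n = 3.
* Published headline numbers from screens of this kind (specific EC50
  tables, single-table Fisher p-values, per-receptor baseline p-values)
  depend on unreleased raw plates and sequence tables; this package
  validates the machinery property-wise on synthetic ground truth instead.
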