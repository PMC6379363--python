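# Methods

This note documents the models, algorithms and numerical choices behind
`peptipanel`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Coordinate system and conventions

A urinary peptide is a point (neutral mass *M* in Daltons, CE migration
time in minutes). The proton mass constant is fixed at 1.00728 Da
everywhere; an ion peak at *m/z* with charge *z* maps to
*M = z·(m/z − 1.00728)*. The instrument acquisition window defaults to
m/z 350–3000. Amplitude 0 always means "not detected": amplitude matrices
are dense with a zero sentinel, detection frequency is the fraction of
non-zero cells, and zeros enter rank tests and fold-change means as true
zeros. All tabular I/O is TSV with full-precision floats (decimal point
only), so write → read round-trips bit-exactly.

## Charge-state deconvolution

The grouping algorithm is this package's own definition (vendor
deconvolution tools for CE-TOF data are proprietary): hypothesize masses
for unknown-charge peaks over z = 1..`charge_max` (default 6 — urinary
peptides up to ~15 kDa rarely exceed charge 6 inside the m/z window),
sort all hypotheses by mass, cluster them against a running
intensity-weighted mean (`mass_tol_ppm`, default 25; `mt_tol_min`,
default 0.5), then accept candidate groups deterministically: groups
supported by ≥ 2 distinct charge states first, then higher summed
intensity, then lower mass, each peak explained exactly once. A group
yields one signal with intensity-weighted mean mass and MT and summed
amplitude; unknown-charge singletons are reported at charge 1 and flagged
low-confidence. The procedure is greedy rather than a combinatorial
search — it is deterministic, permutation-invariant, and conserves total
intensity, all of which are tested properties.

## Housekeeping normalization

Selection restates the field's description of housekeeping peptides as an
operational rule: among peptides detected in ≥ `min_freq` (default 0.90)
of samples, take the `n_select` (default 29) with the lowest coefficient
of variation of log-amplitude over detected samples (ties broken by
peptide id); the reference amplitude is the cohort median over detected
samples. Whether the original studies used cohort-internal or external
reference amplitudes is not documented; cohort medians are the default
here, and a saved reference can be supplied to normalize later cohorts
against the same standard.

Per sample, the scale factor is the **median of ratios**
reference/observed over detected housekeeping peptides — robust to a
genuinely differential peptide slipping into the housekeeping set. A
sample detecting fewer than `min_detected` (default 15, a majority of 29)
housekeeping peptides is rejected by name rather than silently
mis-scaled. The estimator is scale-invariant by construction
(normalize(c·row) ≡ normalize(row)).

## Cross-sample matching and annotation

Signals from all samples are sorted by mass and clustered single-linkage
with a cap against the running intensity-weighted cluster mean
(`cluster_mass_tol_ppm` default 50, `cluster_mt_tol_min` default 0.5 —
published database matching rules are not public, so both are mandatory
config fields). Two same-sample signals landing in one cluster are
summed, conserving total amplitude. Validation cohorts are projected onto
a frozen discovery catalogue by nearest-mass assignment under the same
tolerances.

Sequence annotation accepts an MS/MS-sequenced candidate iff its neutral
mass deviates ≤ 5 ppm **and** its predicted migration time falls within
`annotate_mt_window_min` of the consensus MT (the two gates are applied
conjunctively; the literature does not state an order). The MT model is
log-linear: MT = a + b·ln M − c·ln z_eff with effective charge
z_eff = 1 + #K + #R + 0.5·#H (histidine is half-protonated at the acidic
separation pH). The functional form is this package's choice; the
coefficients are never hard-coded — they are least-squares fitted from
calibration (sequence, observed MT) pairs and must all come out positive.
Peptide monoisotopic masses come from pyteomics.

## Differential discovery

The funnel is: frequency filter (≥ 70% detection in at least one group,
boundary inclusive) → per-peptide two-sided Wilcoxon rank-sum → BH
step-up over **exactly the filtered set** (adjusting over all peptides
would change the panel; the multiple-testing universe is the tested set)
→ keep adjusted p < α (strict), sorted by (p_adj, peptide_id). Wilcoxon
uses exact enumeration when min(n, m) ≤ 8 with no ties, otherwise the
normal approximation with tie-corrected variance and 0.5 continuity
correction; groups smaller than 3 are refused with a power warning. Fold
change is signed: r = mean(case)/mean(control) with zeros included,
reported as +r (r ≥ 1) or −1/r, with +∞ / NaN sentinels for zero
denominators. (Published panel tables occasionally print signed mean fold
changes with |FC| < 1, e.g. −0.81, which cannot arise under this
convention; those are averages of mixed-sign per-fragment values and are
deliberately not reproduced.)

## Classifier and cutoff

Panel amplitudes are transformed log(1 + a) (zeros map to zero; raw
amplitudes span orders of magnitude), standardized with training
statistics stored in the model, and fitted with an RBF SVM
(C = 1, γ from the median-pairwise-distance heuristic
γ = 1/(2·median²), class-balanced weights). All hyperparameters are
config-exposed; the published classifier studies do not print theirs, so
these defaults are declared choices, not reconstructions.

**Score recentering.** Raw SVM decision values drift with training class
balance, and leave-one-out folds are imbalanced by one *in the direction
of the held-out sample's own class*: with balanced class weights the
fold's decision function shifts toward the held-out class, which inflates
null CV AUC far above chance (we measured ≈ 0.8 on pure-noise cohorts;
without balancing the artifact reverses to ≈ 0.05). Every trained model
therefore shifts its score origin to the midpoint of the two training
class-mean decision values. Recentered scores are comparable across LOO
folds and across cohorts; with this correction null CV AUC is ≈ 0.5 as it
must be. This is the package's own calibration choice, baked into the
stored intercept.

Cross-validation is complete leave-one-out by default (k-fold available),
with transform statistics recomputed inside every fold — corrupting a
held-out label provably never changes that sample's score. The cutoff is
chosen among midpoints of adjacent distinct CV scores, maximizing
Youden's J (or accuracy), ties broken toward higher specificity then
lower cutoff; `predicted = case iff score ≥ cutoff`. A user-supplied
cutoff (e.g. an externally fixed 0.30) can be passed through config to
freeze the operating point instead. Models serialize to JSON (support
vectors, dual coefficients, standardization vectors, cutoff, training
fingerprint); a loaded model scores by evaluating the kernel expansion
directly, so deserialization never refits and scores are bit-identical.

## Evaluation

Sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP) carry Clopper–
Pearson exact binomial 95% CIs (beta-quantile form; at x = n the lower
bound is (α/2)^(1/n)); a zero-denominator metric is reported as
undefined, never 0. AUC is the Mann–Whitney concordance probability with
ties counted 0.5, computed from midranks, with a DeLong
structural-components variance for its CI — the "exact binomial" phrase
in the clinical-proteomics literature covers the proportions, not the
AUC, and the AUC CI method of the commercial software used there is not
reproducible, so DeLong is the declared substitute. Cohorts pool by
summing confusion counts, which is associative and order-invariant.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes —
it is the stand-in for non-deposited clinical urine data:

- **Amplitudes**: log-normal per peptide (meanlog 7 ± 1 peptide-level
  baseline spread, sdlog 0.8). The distribution family is an assumption,
  not sourced from any measurement.
- **Missingness**: independent Bernoulli per sample × peptide with
  per-peptide probability uniform(0.2, 0.95) for background peptides —
  the simplest mechanism sufficient to exercise the 70% frequency rule.
- **Housekeeping** (29 by default): detection probability 0.98 and
  sdlog 0.25, enforcing by construction a log-amplitude CV at most half
  the background's.
- **Markers**: the case-group meanlog is shifted by ±ln(effect fold), so
  the case mean is exactly fold × control mean; direction is a fair coin.
  Marker detection probabilities are drawn uniform(0.85, 1.0): a marker
  undetectable in both groups could never pass the frequency filter, and
  real panels are by construction made of detectable peptides.
- **Dilution**: each sample's amplitudes are multiplied by a log-uniform
  [0.25, 4] factor, making normalization non-trivial (raw total signal
  varies ≥ 4-fold across a cohort).
- **Mass/MT noise**: observed masses are perturbed by Gaussian 5 ppm
  (TOF-scale accuracy), MTs by 0.05 min. Catalogue masses are drawn
  log-uniform over 800–15 000 Da with a minimum 500 ppm adjacent
  separation so distinct peptides cannot merge at the 50 ppm clustering
  tolerance.
- **Charge ladders**: the forward model emits one peak per in-window
  charge state with the amplitude split equally among emitted charges and
  Gaussian ppm noise on m/z.

All randomness flows through numpy's PCG64; the peptide catalogue and the
sample draws use separate seeded streams, so a validation cohort can share
a discovery cohort's catalogue (`catalogue_seed`) while sampling fresh
subjects — without that, two cohorts would not even contain the same
peptides.

Not emulated: isotope envelopes, co-migration interference, adducts,
migration-time drift between runs, covariate structure (age/sex/eGFR are
generated but carry no signal), and any dependence between detection and
abundance. Passing tests therefore demonstrate the statistical machinery
is correct under the stated model, not that the pipeline is robust to
instrument artifacts absent from that model.

## Problem sizes and default study design

The reference synthetic study is a 22 vs 22 discovery cohort over a
200-peptide catalogue (29 housekeeping, 20 markers at 4-fold) and an
independently sampled 24 vs 20 validation cohort from the same catalogue.
Null-behaviour checks use 100 independent seeds: empty-panel rates on the
22 vs 22 design with zero markers, and chance-level CV AUC on a
10 vs 10 × 40-peptide design with a fixed 20-peptide feature set (the
panel is empty under the null, so the AUC check needs a predetermined
feature set; the smaller design keeps 100 × LOO affordable). Monte-Carlo
bounds asserted in tests (e.g. marker-ratio windows, recovery counts)
were calibrated by direct simulation at the fixed seeds used.

## Known limitations

- The greedy deconvolution can mis-group peaks when distinct peptides
  co-elute within both tolerances; the generator's 500 ppm mass
  separation sidesteps this, real data would not.
- LOO cutoff selection inherits the variance of LOO scores; on small
  cohorts the chosen cutoff can sit close to the case score cloud, and
  sensitivity on an external cohort fluctuates accordingly from seed to
  seed.
- Normalization assumes the housekeeping set is stable across cohorts; no
  inter-laboratory calibration transfer is attempted.
- No covariate adjustment: cohorts are assumed matched by design.
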