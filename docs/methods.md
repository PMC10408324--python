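# Methods

## The diagnostic model

The unit of diagnosis is an individual: an age in years and hearing
threshold levels (HTLs, dB HL) at 1, 2, 3, 4, 6 and 8 kHz for each ear.
The classifier is a fully connected network with tanh hidden layers and a
single sigmoid output interpreted as the probability that the individual
has noise-induced hearing loss (NIHL). The supported architecture family
is 1–5 hidden layers of 2–5 units (all hidden layers share one width); the
published best configuration — one hidden layer of two units on 18 inputs —
ships as a plain-text bundle whose weights are stored at their published
three-decimal precision and load bit-exactly.

Nine input feature sets are supported: per-ear HTLs or age-corrected HTLs
(ACHTL = HTL − AAHL, 6 features), one-ear HTLs plus the age-associated
hearing-loss values (12), both-ear HTLs or ACHTLs (12), and both-ear HTLs
plus AAHLs (18). Canonical ordering is right ear 1→8 kHz, left ear
1→8 kHz, then AAHL 1→8 kHz. All features are z-scored with per-feature
mean and *population* standard deviation (divide by n) computed over the
pooled exposed + control training individuals; the choice of the population
convention matters because the statistics feed the frozen model and is
therefore documented here. Statistics are frozen after fitting and reused
unchanged on evaluation data. During cross-validation they are re-fitted
on each run's training portion (avoiding leakage into the validation fold);
for final-model training they are fitted on *all* training individuals,
including the early-stopping holdout, matching the convention under which
the published statistics were computed.

A probability at or above the decision threshold (default 0.5) is a
positive diagnosis; a tie at the threshold resolves positive, the
sensitivity-favouring direction appropriate to a compensation-claim
setting. The threshold is stored in the bundle and is configurable.

## Age-associated hearing loss table

Age correction and the simulator baseline use an AAHL table: expected HTL
elevation by age and frequency. The packaged default
(`data/aahl_default_synthetic.csv`) is a synthetic stand-in with plausible
male-median values growing quadratically above age 18 (reaching e.g.
28.2 dB at 4 kHz by age 60); it is *not* a transcription of any normative
standard, and analyses that must match one should load their own CSV
(`age,f1,f2,f3,f4,f6,f8`). Tables are validated on load: values must be
non-decreasing in age at every frequency. Between tabulated ages the
default rule is linear interpolation in age; nearest-bracket lookup is
selectable (ties resolve to the younger bracket).

## Training procedure

The loss is a class-weighted binary cross-entropy: exposed samples carry
weight 3, and the weighted mean (normalized by the total weight) equals the
unweighted mean on a dataset with every exposed sample tripled — an
equivalence that is exact for full-batch gradients and is verified in the
test suite. An L2 penalty of 0.01 × (sum of squared connection weights) is
added; biases are excluded from the penalty, the conventional reading of
"sum of all squared weights". Optimization is Adam with learning rate
1e-4 and canonical moment decays (0.9, 0.999, ε = 1e-8). Training stops
after 10 epochs without improvement of the validation error or at 500
epochs, and the parameters from the best-validation epoch are returned.
The validation error monitored is the class-weighted cross-entropy on the
validation fold, without the L2 term (which does not depend on the data).
Initialization is Glorot-uniform for weights, zero for biases, from a
seeded generator; every stochastic step (initialization, batch shuffling,
fold assignment, simulation) derives from explicit integer seeds, and
identical seeds give bit-identical results.

**Batch granularity.** The update mode is configurable; the default is
mini-batches of 4 samples. Full-batch updates (`batch_size=None`) are
supported — and are the mode in which the class-weight/triplication
equivalence is exact — but cannot be the default: with at most 500 epochs,
full-batch training would mean at most 500 Adam steps, and since each Adam
step moves a parameter by at most about the learning rate, total movement
of order 0.05 — an order of magnitude short of the published weight
magnitudes (up to 1.6), and the early-stopping rule would never engage. A
stochastic reading is therefore the only self-consistent one; batches of 4
give ~50 updates per epoch on the study-sized cohorts, which lets training
converge (and early stopping trigger) within the epoch budget.

**Cross-validation.** Ten runs with disjoint validation folds of 14
exposed + 9 control individuals, drawn as a random partition; with the
study sizes (143/93), 140 exposed and 90 controls are each validated
exactly once and 3 + 3 individuals train in every run (the corresponding
training portions are 129 exposed and 84 controls; a published count of 82
controls is arithmetically inconsistent with 93 − 9 and is not used). The
architecture grid search evaluates all 20 (layers × units) combinations,
ranking by mean validation accuracy with ties broken toward the simplest
architecture (fewest layers, then fewest units). Retrain-stability runs
repeat final-model training with per-repeat seeds and report the mean and
SD of test-set sensitivity and specificity.

## Synthetic cohort generator

No generative model of the study populations was ever published, so the
simulator is this package's own design, built to reproduce the *described*
structure of the data rather than any measured distribution:

* **Controls**: HTL(ear, f) = AAHL(age, f) + a per-individual
  susceptibility offset (normal, SD 6 dB, shared across frequencies and
  ears) + independent measurement noise (SD 4 dB), quantized to the
  clinical 5-dB step and clipped to the audiometer range [−10, 130] dB HL.
  Ages are uniform on 29–60 years. No systematic ear asymmetry.
* **Exposed**: the control baseline plus an NIHL component applied to both
  ears — with probability 0.6 an audiometric notch (a Gaussian bump in
  log2-frequency, width 0.5 octave, centered at 3/4/6 kHz with weights
  0.25/0.5/0.25, depth ~N(25, 8²) dB truncated at 0), otherwise a
  progressive high-frequency loss rising linearly above 2 kHz
  (~N(10, 3²) dB/octave truncated at 0) — plus a left-ear excess at
  3–8 kHz (~N(5, 3²) dB), emulating the left-worse asymmetry of
  rifle-fire exposure.
* **Study layout**: four independent cohorts of 143/93 (training) and
  142/92 (test) individuals, with disjoint seed streams and id spaces.

Effect sizes are plausible clinical magnitudes chosen once when the
generator was designed. What passing tests on these cohorts show is that
the *pipeline* — features, normalization, loss, optimizer, early stopping,
cross-validation — correctly recovers a separation that is present by
construction; they do not estimate the accuracy achievable on real
claimants, whose audiogram distributions (co-occurring phenotypes,
exaggeration, measurement practice) the generator does not attempt to
match.

## Numerical choices and degenerate inputs

* Sigmoid and cross-entropy are computed in logit space
  (softplus(z) − y·z), so no probability is ever clipped and losses are
  finite for any finite parameters; a non-finite loss aborts training with
  the offending epoch.
* d′ = z(sens) − z(1 − spec) requires proportions strictly inside (0, 1);
  proportions of exactly 0 or 1 raise unless an explicit sample-size clamp
  to [1/(2N), 1 − 1/(2N)] is requested (off by default).
* Sensitivity (specificity) on a set with no exposed (control) individuals
  is reported as explicitly undefined (`None`), never as 0.
* PPV with a zero denominator (no positive diagnoses possible) is likewise
  undefined rather than 0.
* A feature constant across a training set makes z-scoring degenerate and
  is rejected with the feature named.

## Known limitations

* The original training databases and their normalization statistics are
  unreleased: the packaged published-network bundle carries synthetic
  stand-in statistics (fitted on this package's reference simulated
  cohorts, generator seed 0) and a provenance warning; its per-individual
  outputs will not match the authors' tool on real claimants, though the
  weights themselves are exact to the published precision.
* Published weights are three-decimal roundings of the authors' unrounded
  values, so third-decimal output differences from the original tool are
  expected even with matching inputs.
* The comparator diagnostic methods enter only as published
  (sensitivity, specificity) operating points; their internal decision
  rules are out of scope. The published d′ for one comparator (0.976/0.639
  → 2.37 as printed, 2.33 as computed here) and its PPV at prevalence 0.5
  are not reproducible from its printed operating point under the printed
  formulas; these internal inconsistencies of the source tables are
  documented rather than chased.
* The simulator does not model tinnitus, medical-history covariates,
  exaggerated thresholds, or inter-frequency correlation structure beyond
  the shared susceptibility offset.
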