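# Methods

`zftox` implements a desk-scale version of a single-embryo toxicometabolomics
workflow: zebrafish embryos exposed in a 96-well plate to a wide dose ladder of
a pharmaceutical (the built-in demo uses carbamazepine, CBZ), profiled by
LC-HRMS in a nontarget assay and a targeted lipidomics assay, with
biotransformation products (bioTPs) of the exposure compound elucidated from
the same data. Raw-spectra processing (peak picking, alignment, gap filling) is
out of scope; the pipeline starts from a feature table (features x samples,
with m/z, retention time and assay per feature).

## Synthetic study generator

No raw data are deposited for this kind of study, so the package ships a
generator that emulates the study design with known ground truth; every
downstream stage is tested against that truth.

Design defaults mirror the emulated study: six nominal doses (0.5, 5, 50, 500,
5000, 50000 ug/L — a 10x ladder), 12 embryos per dose, 12 negative and 12
positive controls on one 96-well plate, a concurrent blank plate (8 blanks, 3
QC blanks), and a pooled-embryo QC injected every 5th injection. Apical
endpoints are assigned per group: 11/12 positive-control mortality, 3/12 and
1/12 mortality in the 50 and 500 ug/L groups, pericardial edema in 5/12
top-dose embryos (plus one embryo each in the lowest dose and positive
control), and delayed hatching at 48 hpf in the three lower-dose groups.

Each feature is one of: endogenous null, endogenous with a dose-response shape,
absent-from-QC, blank contaminant, the exposure compound, an in-source fragment
of it, a bioTP at a rule-predicted m/z, or an internal standard. The intensity
model is

```
intensity = baseline x response(shape, dose) x drift(injection) x loading x lognormal noise
```

* **Dose-response shapes.** Monotone shapes are linear in log10(dose) between 1
  and the effect fold; U and inverted-U shapes are quadratic in log10(dose)
  with the extremum at the middle dose; `high_dose_only` is a step at the top
  dose; `edema_marker` applies the fold change to edema-flagged embryos only.
  Responses are clipped to `[1/fold, fold]`. Unexposed controls evaluate at the
  lowest dose rung: an unexposed embryo is the low-exposure limit of the curve,
  so by construction no shape separates the lowest dose from control — which is
  what makes the low-dose classification model elect almost nothing, as a
  low-dose model on real data typically does. The default effect fold is 4, a
  mid-sized metabolomic perturbation; the recovery benchmark in the tests uses
  8 (see below).
* **Noise and drift.** Multiplicative lognormal noise per measurement (default
  CV 10%), a per-sample "loading" factor shared by all features of an injection
  (default CV 15%, cancelled exactly by internal-standard normalization), and a
  per-feature monotone drift over injection order (linear or exponential,
  slopes uniform in +-0.5) shared by all samples — the structure QC-anchored
  batch correction assumes.
* **What is not emulated:** isotope patterns, chromatographic peak shape,
  retention-time shifts, missing-value mechanisms other than true absence,
  censoring at the detection limit, and correlated metabolite modules. Passing
  tests therefore demonstrate the correctness of the bookkeeping, filtering
  logic, model machinery and annotation arithmetic — not performance on real
  instrument data.

MS2 spectra for the annotation demo are synthetic stand-ins: fragment templates
placed at the precursor minus common neutral losses, perturbed with lognormal
noise and random dropout. They exist so similarity scoring and confidence-level
logic can be exercised end to end, not to resemble true fragmentation.

## Preprocessing

Internal-standard normalization divides each sample by its mean IS intensity
(rescaled to the grand mean so units stay comparable). The filter cascade then
separates endogenous features from everything else, in this order for the
nontarget assay:

1. **QC presence** — drop features with zero intensity in every pooled-QC
   injection (this removes the exposure compound, its fragments and bioTPs,
   which are absent from pooled QC). Presence means any nonzero QC intensity.
2. **Drift correction + QC RSD** — per feature, a LOWESS curve is fit through
   QC intensity versus injection index (linear interpolation when fewer than 5
   QC anchors; flat extrapolation outside the anchored range), every sample is
   divided by the curve value at its index and rescaled to the feature's QC
   median; features with a nonpositive fitted curve are flagged and left
   uncorrected. Features whose post-correction QC RSD exceeds 30% are dropped.
   With fewer than 5 anchors the interpolating curve passes through the QC
   points exactly, so the post-correction QC RSD is 0 by construction — the RSD
   filter is only informative with 5 or more QCs.
3. **Noise floor** — drop features whose maximum embryo intensity is below an
   absolute floor, default 3x the median blank intensity of the table.
4. **In-source fragments** — drop features that co-elute with the exposure
   compound (|dRT| <= 5 s), lie below its m/z, and correlate with its intensity
   profile across embryos (Pearson r >= 0.8). The parent profile is taken from
   the raw table because the parent itself is removed at step 1.
5. **bioTP mass windows** — drop features within 5 ppm of any rule-predicted
   bioTP m/z.
6. **Negative intensities** — drop features driven negative by drift
   overcorrection (zero is kept: it denotes non-detection).
7. **Blank fraction** — drop features whose blank maximum exceeds 40% of the
   maximum embryo intensity, or whose QC-blank maximum exceeds 40% of the
   maximum QC intensity.

All threshold comparisons are strict. The lipidomics assay instead keeps only
features with mean negative-control / mean blank intensity >= 10 (a zero blank
counts as infinite ratio). Every step appends `(step, before, after, flagged)`
to an audit trail; counts are non-increasing by construction.

## rdCV random-forest models

Variable selection follows the repeated double cross-validation recipe: an
outer cross-validation (default 6 folds, 10 repetitions) estimates fitness
exclusively from out-of-fold predictions, while within each outer training
partition an inner cross-validation (outer - 1 folds) drives recursive
elimination of the lowest-importance fraction of variables (default: keep 75%
per iteration, impurity importance; permutation importance by configuration).
The candidate model sizes are those whose inner-CV fitness lies within 5% of
the best; the reported size is the minimum, the geometric mid, or the maximum
of that band (default mid; the max rule is preferable when informative features
are redundant, because redundant variables split votes at minimal sizes).
A feature is *elected* when it appears in the chosen model of more than 50% of
(repetition x outer fold) segments. Classification fitness is the
misclassification rate of consensus out-of-fold predictions (probability votes
averaged over repetitions, ties broken toward the lowest dose rung); regression
fitness is Q2 = 1 - PRESS/TSS.

Five standard designs cover the study: `AllRegress` (log10 dose over all six
doses plus controls, controls placed one 10x rung below the lowest dose so the
ladder spacing is preserved), `AllClass` (7-group classification), `HighClass`
(top dose vs control), `LowClass` (lowest dose vs control) and `EdemaClass`
(edema vs non-edema within the top dose). The all-dose models exclude embryos
with lethal or sublethal endpoints; `EdemaClass` necessarily keeps edema
embryos and runs with 4 outer folds because its smaller class has ~5 members.
Models electing fewer than 5 features are flagged for discard. A
"within one order of magnitude" misclassification rate counts only confusions
more than one rung apart on the 10x ladder.

Significance is assessed by refitting the entire rdCV procedure on permuted
responses; both the empirical rank p = (r+1)/(n+1) and a tail probability under
a normal approximation to the permuted-fitness distribution are reported (the
normal approximation is what allows p-values far below 1/(n+1) from ~100
permutations; with fewer than 20 permutations only the empirical p is
reported).

## bioTP annotation

Transformation rules are signed elemental deltas (built-in CBZ library:
epoxidation +O, di-hydroxylation +O2, dihydrodiol +H2O2, glucuronidation
+C6H8O6, carbamoyl loss -CHNO giving iminostilbene); adducts are [M+H], [M+Na],
[M+K] (+1.007276, +22.989218, +38.963158 Da, singly charged). Expected m/z
values feed a 5 ppm match against the raw feature table; matches with any
signal in a negative-control embryo are discarded. MS2 spectra are scored
against a local reference library with

```
score = 0.5 * F + 0.5 * C,
F = 2 * n_matched / (n_a + n_b),
C = cosine of intensity vectors over the fragment union,
```

fragments matched greedily closest-first within 0.01 Da, each used once. The
score is symmetric, in [0, 1], 1 iff identical within tolerance, 0 for disjoint
spectra, and invariant to uniform intensity scaling; weights are configurable.
Confidence levels: CL 1 for similarity > 0.9 against an authentic-standard
spectrum, CL 2 for a spectral-library score > 0.9, CL 3 for a consistent
structure prediction, CL 4 for consistent formulas only, CL 5 otherwise
(including features with no MS2). External in-silico fragmentation and online
library services are represented by a pluggable evidence record; the packaged
MGF library of synthetic reference spectra stands in for both. Candidates that
co-elute with and correlate with the exposure compound are flagged as possible
in-source fragments (the iminostilbene ambiguity); adduct duplicates collapse
to one compound, with an error on conflicting assignments. One predicted-mass
list serves both the cascade's exclusion step and the bioTP matching.

## Endpoints and dose confirmation

Per-group counts of mortality, edema and hatching are reported with
nearest-integer percentages (ties away from zero, so 11/12 prints 92%).
Hatching versus control is a two-sided exact test on the 2x2 table — counts,
not times, are available at 48 hpf; the test matches full hypergeometric
enumeration for all tables up to n = 12 per arm. Exposure-medium doses are
back-calculated from an IS-normalized linear calibration (unweighted least
squares by default, 1/x weighting by configuration), with extrapolation
flagged, replicate RSD = 100*sd/mean, and percent-of-nominal rounded to integer
percent.

## Numerical and design choices

* Determinism: every stochastic step draws from a `numpy` generator seeded from
  the configuration; identical (config, seed) give bit-identical tables and
  model outputs.
* Zero intensity always means non-detection; negative values only arise from
  drift overcorrection and are handled by the dedicated filter.
* Greedy closest-first fragment matching is deterministic and symmetric; ties
  in distance break on fragment order.
* The two assays are simulated on a single injection sequence (one analytical
  run) rather than the two separate runs a real study would use; assay-specific
  filters operate on their assay's features only. This keeps the plumbing small
  without changing any filter's semantics.
* Problem sizes: the default simulation produces ~360 features x ~130
  injections (about one-seventh of the raw feature count a real nontarget run
  yields, chosen so the full pipeline runs in minutes); `scripts/acceptance.py`
  runs the rdCV models with 2 repetitions, 5 outer folds, elimination ratio
  0.4, 30 trees and 30 permutations for the two all-dose models. The test-suite
  benchmarks use 5 informative / 95 null features with 8-fold effects at 12
  embryos per class (20 seeds) for recovery, and 200 null datasets x 50
  permutations for type-I calibration.

## Known limitations

* The rdCV engine fits hundreds of small random forests; it is intended for
  desk-scale feature counts (hundreds), not full-resolution tables.
* Election consensus across segments is conservative with highly redundant
  informative features at the default mid-size rule (votes split); use the
  max-size rule when redundancy is expected.
* The drift model assumes one smooth curve per feature over injection order;
  step changes (batch boundaries) are not modeled.
* Confidence-level assignment implements the decision logic only; the quality
  of CL 3/4 calls depends entirely on the plugged-in structure-prediction
  evidence, for which the package ships no real engine.
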