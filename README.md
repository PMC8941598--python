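# zftox

Toxicometabolomics and biotransformation-product (bioTP) elucidation in single
zebrafish embryos, as a tested, reusable pipeline.

The package is aimed at environmental toxicologists and metabolomics analysts
who run fish embryo tests with LC-HRMS readout: embryos exposed in a 96-well
plate to a wide dose ladder of a chemical (the built-in demo uses carbamazepine:
six nominal doses, 0.5 µg/L–50 mg/L, 12 embryos per dose, 12 negative and 12
positive controls), profiled in a nontarget assay and a targeted lipidomics
assay, with pooled-QC injections every k-th injection and a concurrent blank
plate. Starting from a feature table (features × samples with m/z, RT, assay),
the pipeline

1. **simulates** such a study with known per-feature ground truth (no raw data
   of this kind are publicly deposited, so the generator is a first-class,
   tested module);
2. **preprocesses**: internal-standard normalization, QC-anchored LOWESS drift
   correction, and a seven-step filter cascade that separates endogenous
   metabolite features from the exposure compound, its in-source fragments,
   predicted bioTP masses, blank contamination and drift artifacts — with a
   full audit trail;
3. **models** dose response by repeated double cross-validation (rdCV) random
   forests with recursive variable elimination: a regression over all doses
   (monotonic responses), a 7-group classification (nonmonotonic responses),
   top-dose, low-dose and edema classifications; fitness is computed only from
   out-of-fold predictions, features are *elected* by cross-segment consensus,
   and significance comes from refitting the whole procedure on permuted
   responses, p = (r+1)/(n+1) empirically plus a normal-tail approximation;
4. **annotates bioTPs**: elemental transformation rules (+O, +O₂, +H₂O₂,
   +C₆H₈O₆, −CHNO) × adducts ([M+H]⁺, [M+Na]⁺, [M+K]⁺) predict exact masses,
   features are matched at 5 ppm, filtered on negative-control presence, scored
   against reference MS2 spectra with `0.5·F + 0.5·C` (F = fragment Dice
   overlap, C = intensity cosine), deduplicated across adducts, and assigned
   confidence levels CL 1–5 (CL 1 = similarity > 0.9 vs an authentic standard),
   with co-elution/correlation flags for in-source ambiguity;
5. **summarizes endpoints**: mortality/edema/hatching per group, exact
   hatching-vs-control tests, and exposure-medium dose confirmation from an
   IS-normalized calibration (percent of nominal, replicate RSD).

Key quantities, in the field's notation: QC RSD = 100·sd/mean over QC
injections (drop if > 30% after correction); Q² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² from
out-of-fold predictions; ppm error = 10⁶·|m/z_obs − m/z_exp|/m/z_exp;
misclassification "beyond one order" counts only confusions more than one rung
apart on the 10× dose ladder (controls sit one rung below the lowest dose).

See `docs/methods.md` for the model assumptions, parameter defaults, and what
the synthetic data do and do not emulate.

## Worked example

```python
from zftox.synthetic import SimConfig, make_plate_layout, simulate_feature_table, predicted_biotp_mzs
from zftox.preprocessing import CascadeConfig, normalize_to_is, run_filter_cascade

cfg = SimConfig(seed=1)
layout = make_plate_layout(cfg.n_doses, cfg.n_per_group, cfg.n_neg, cfg.n_pos)
table, truth = simulate_feature_table(layout, cfg)
masses = [mz for rule, _, mz in predicted_biotp_mzs(cfg) if rule != "parent"]
parent_mz = next(mz for r, a, mz in predicted_biotp_mzs(cfg) if r == "parent" and a == "[M+H]")
normed = normalize_to_is(table, truth.ids_with_label("internal_standard"))
filtered, audit = run_filter_cascade(
    normed, CascadeConfig(parent_mz=parent_mz, parent_rt=cfg.parent_rt,
                          predicted_biotp_masses=masses))
for step in audit:
    print(step.step, step.features_before, "->", step.features_after)
```

prints the cascade's audit trail on the simulated study:

```
qc_presence_filter 237 -> 201
drift_correction 201 -> 201
qc_rsd_filter 201 -> 201
noise_floor_filter 201 -> 201
insource_fragment_filter 201 -> 201
biotp_mass_exclusion 201 -> 201
negative_intensity_filter 201 -> 201
blank_fraction_filter 201 -> 180
lipid_blank_ratio_filter 121 -> 102
```

Step 1 removes the 36 features absent from the pooled QC (the exposure
compound, its in-source fragments, the 12 bioTPs and the QC-absent features);
step 7 removes the blank contaminants and internal standards; the lipid
blank:control ratio filter keeps 102 of 121 lipid features. The 282 survivors
are exactly the simulated endogenous features.

The full pipeline is also available from the shell:

```
zftox run-all --seed 1 --out demo_out          # simulate → ... → endpoints
zftox simulate --seed 1 --out demo_out         # just the synthetic study
zftox validate --features demo_out/features_raw.tsv --samples demo_out/samples.tsv
```

`run-all` writes TSV/JSON/MGF artifacts per stage plus a run manifest; identical
config and seed give byte-identical outputs.

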