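# rfdcriteria

QSAR-style toolkit for predicting oral reference doses (RfD) of
pesticide-class chemicals from molecular descriptors, and for carrying
the predictions through to human-health ambient water quality criteria
(AWQC) and hazard-quotient risk screening.

The pipeline:

1. **Descriptor screening** — drop zero-variance columns, columns with
   fewer than 10% non-zero entries, and one member of every pair with
   |Pearson r| > 0.90, with a full audit trail of removals.
2. **Stepwise MLR** — forward–backward selection on `-log10(RfD)` using
   partial-F entry/removal thresholds; a published 12-descriptor model
   ships as a preset (`rfdcriteria.PUBLISHED_RFD_MODEL`).
3. **Validation** — R², adjusted R², RMSEP, Durbin–Watson, VIF,
   cross-validated q² (LOO or k-fold), origin-regression slopes k/k',
   fold-difference coverage, and the adjusted-R²-vs-model-size curve.
4. **Criteria derivation** — freely dissolved fraction from lgKow and
   organic carbon, baseline/final bioaccumulation factors per trophic
   level, and the AWQC aggregation with exposure factors; adopted
   values reported in µg/L at one significant figure.
5. **Risk assessment** — hazard quotients (EEC in ng/L vs AWQC in µg/L)
   binned into no/low/intermediate/high risk with per-site and summary
   reports.
6. **Synthetic data** — generators for descriptor matrices (correlated
   blocks, constant/sparse/duplicated columns), sparse-linear-model
   responses, and lognormal monitoring tables, so everything is
   testable offline.

## CLI

All stages are subcommands of one entry point:

```bash
rfdcriteria make-fixtures --seed 7 --outdir fixtures/
rfdcriteria screen --descriptors fixtures/descriptors.csv \
    --response fixtures/responses.csv --out screened.csv --report report.json
rfdcriteria fit --descriptors screened.csv --response fixtures/responses.csv \
    --seed 7 --out model.json
rfdcriteria validate --model model.json --descriptors screened.csv \
    --response fixtures/responses.csv --seed 7 --out validation.json
rfdcriteria predict --model model.json --descriptors fixtures/descriptors.csv \
    --out predictions.csv
rfdcriteria derive-awqc --params src/rfdcriteria/data/ppDDE.yaml --out awqc.json
rfdcriteria assess-risk --samples fixtures/sites.csv --awqc 0.03 \
    --out risk.csv --summary risk_summary.json
```

`rfdcriteria run --config pipeline.yaml` chains every stage and writes a
manifest with content hashes. Exit codes: 0 success, 2 config error,
3 stage error (earlier artifacts are kept).

Packaged criteria fixtures for the two worked examples live in
`src/rfdcriteria/data/` (`ppDDE.yaml`, `alphaHCH.yaml`); both the
verbatim published BAFs and the BCF-based derivation route are encoded.

## Conventions worth knowing

- Responses are `-log10(RfD)` with RfD in mg·kg⁻¹·d⁻¹; predictions are
  back-transformed and can be "adopted" at a fixed number of
  significant figures (default 1).
- The correlation filter uses absolute Pearson correlation with strict
  inequality; exactly 10% non-zero entries is retained by the sparsity
  rule.
- The multicollinearity diagnostic is the variance inflation factor
  (VIF), even where source tables label it "VIP".
- Risk bins resolve boundary overlaps protectively: [0, 0.1) no risk,
  [0.1, 1) low, [1, 10] intermediate, (10, ∞) high.
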