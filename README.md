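# lactecon

Herd-level dairy economics pipeline comparing two ways of summarizing a
herd's milk production — the shape of the lactation curve versus average
305-d milk production — as explanations of income over feed cost (IOFC).

The pipeline:

1. **synthetic_data** — generates cow test-day records, herd-year
   accounting, herd-year performance and a national milk-price series
   with full ground truth (curve parameters, herd intercepts, economic
   coefficients), so every downstream stage is testable for parameter
   recovery without any external data.
2. **lactation_model** — evaluates and fits the simplified three-parameter
   lactation curve `Y(t) = a(1 − e^(−t/b)/2)e^(−dt)` by bounded nonlinear
   least squares, and derives persistency `ln 2 / d` (the post-peak
   half-life in days).
3. **hlcc_aggregation** — partitions each lactation across calendar years
   by test-day counts (a lactation with 5 records in one year out of a
   herd-year-parity total of n contributes weight 5/n there) and takes
   weighted medians per herd × year × parity group; edge years of the
   record span are dropped.
4. **herd_economics** — IOFC per cow and per 100 kg delivered, herd and
   relative milk price, equity ratio, expansion rate, herd intensity.
5. **data_editing** — merges the three herd-year sources and applies the
   exclusion cascade (consecutive years, direct sellers/organic herds,
   extremely small herds, percentile outliers, missing values) with a
   reconciling audit log.
6. **mixed_models** — random-intercept linear mixed models per outcome and
   predictor family: standardization, VIF screening, a forced calendar-year
   fixed effect, backward AIC selection (ML) with a REML refit, and
   marginal / conditional / part R².
7. **nonnested_tests** — Cox (Pesaran) and J tests in both directions with
   a combined verdict (no difference / one model better / neither
   informative).
8. **pipeline / cli** — orchestrates everything deterministically from a
   single seed and writes every intermediate table plus a manifest.

## CLI

```bash
lactecon run-all --seed 1 --outdir out/            # full synthetic run
lactecon simulate --seed 1 --outdir out/inputs     # tables + ground truth
lactecon fit-curves --test-days out/inputs/test_days.csv --out out/fits.csv
lactecon aggregate --test-days ... --fits ... --first-year 2007 --last-year 2016 --out ...
lactecon economics --accounting ... --national-price ... --out ...
lactecon edit --economics ... --hlcc ... --performance ... --out ... --audit ...
lactecon model --analysis ... --outcome iofc_cow --model-set hlcc --out ...
lactecon compare --analysis ... --outcome iofc_cow --out ...
lactecon summarize --outdir out/
```

A YAML config (`--config`) can override the `synthetic:`, `filters:` and
`pipeline:` sections; see the dataclasses in `lactecon.synthetic_data`,
`lactecon.data_editing` and `lactecon.pipeline` for the field names.

## Layout

```
src/lactecon/      one module per pipeline stage
tests/             pytest suite (unit, property, acceptance)
scripts/           acceptance report generator
```
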