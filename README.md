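# cqscreen

Analysis toolkit for competitive-displacement screens read out by qPCR.
A DNA-tagged detection probe competes with test compounds for a target;
the amount of target-bound probe is quantified as a cycle number (Cq), so a
compound's displacement shows up as a cycle shift (ΔCq) against
uninhibited control wells. The package covers the full workflow:

- **`cqscreen.equilibrium`** — forward model: exact competitive-binding
  equilibrium (any number of 1:1 competitors, bracketed root-finding on the
  free-target mass balance) and the bound-probe → Cq mapping.
- **`cqscreen.affinity`** — single-well dissociation-constant estimation
  from ΔCq (`kd = i_tot / ((2^ΔCq − 1)(1 + p_tot/kd_probe))`), censoring of
  below-floor / saturated shifts, dilution-series averaging, and probe-Kd
  calibration from a titration.
- **`cqscreen.screen`** — plate QC (control means/SDs, assay window,
  Z′-factor), ΔCq tables, threshold hit calling, counter-screen
  interference filtering, pooled-library deconvolution planning, hit
  confirmation and summary statistics.
- **`cqscreen.simulate`** — synthetic screens: libraries with planted
  binders/interferers/inactives, 384- or 96-well pooled or individual
  layouts with control wells, and noisy Cq readouts from the forward model.
- **`cqscreen.pipeline` / `cqscreen.cli` / `cqscreen.io`** — end-to-end
  orchestration, YAML configuration and delimited-text I/O.

## CLI

Each stage runs standalone on the CSV files the previous stage wrote:

```sh
cqscreen simulate --n-compounds 5280 --pool-size 11 \
    --binder-kds 2000,3500 --interferer-shifts 2.0 --seed 1 -o run/
cqscreen qc       --map run/plate_map.csv --cq run/cq_results.csv -o run/qc_report.csv
cqscreen screen   --map run/plate_map.csv --cq run/cq_results.csv --threshold 0.80 -o run/hits.csv
cqscreen counter  --hits run/hits.csv --map run/plate_map.csv \
    --counter-cq run/counter_cq_results.csv -o run/hits_filtered.csv
cqscreen deconvolute --hits run/hits_filtered.csv --map run/plate_map.csv -o run/plan.csv
cqscreen confirm  --map retest_map.csv --cq retest_cq.csv --threshold 0.80 -o run/confirmed.csv
cqscreen kd       --series series.csv --neg-mean-cq 9.89 -o run/kd_report.csv
cqscreen report   --hits run/hits_filtered.csv --library-size 5280 -o run/summary.csv
```

or run everything from a config: `cqscreen run --config pipeline.yaml`
(sections `design`, `library`, `analysis`, `outdir`; every knob has a
documented default — 200 pM probe, probe Kd 1.32 nM, 9 µM screening
concentration, ΔCq ≥ 0.80 pooled hit threshold, 83 nM counter-screen
ligand, 10 µM individual retest).

## File formats

Comma-separated UTF-8 with a header row:
`plate_map.csv` (`plate_id,well,role,content,pool_id,i_tot_nM`; `content`
is a `;`-joined compound list), `cq_results.csv` (`plate_id,well,cq`,
empty `cq` = censored), plus stage outputs (`qc_report.csv`, `hits.csv`,
`deconvolution_plan.csv`, `summary.csv`, `kd_report.csv`,
`ground_truth.csv` for synthetic runs).

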