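# metaboflux

Carbohydrate-metabolism expression profiling of rat cerebellar granule
neurons (CGNs) exposed to patient cerebrospinal fluid (CSF), for
researchers studying how multiple-sclerosis (MS) clinical forms and
neuromyelitis optica (NMO) differ in the metabolic injury they inflict
on neurons. The package implements the full analysis chain for
one-color microarray-style intensity data and the study's summary
statistic, the **Cumulative Flux Index (CFI)** — and ships a seeded
synthetic-data generator with known ground truth, so every stage is
testable without any download.

## The model

For a metabolic pathway *P* (glycolysis, TCA cycle, or the electron
transport chain) and a disease group, each enzyme gene *g* contributes
its linear fold change *r<sub>g</sub>* versus neurological controls if
it is called differentially expressed, and 1 otherwise:

&nbsp;&nbsp;&nbsp;&nbsp;CFI(P) = ∏<sub>g∈P</sub> f<sub>g</sub>,&nbsp;&nbsp;
f<sub>g</sub> = r<sub>g</sub> if called up/down, else 1;&nbsp;&nbsp;
CFI<sub>total</sub> = CFI(glycolysis) · CFI(TCA) · CFI(ETC)

CFI = 1 means flux-neutral transcription; values ≪ 1 quantify a
cumulative collapse of expected pathway flux. A gene is called up
(down) when its fold change is ≥ 2 (≤ 0.5) with omnibus ANOVA and
Tukey-HSD contrast p < 0.01 and Benjamini–Hochberg q < 0.1.

Around that core the pipeline provides: NormExp background correction
(E[signal | observed] under a Normal+Exponential convolution),
75th-percentile inter-array scaling, pooled 30%-quantile expression
filtering, probe collapse by median, geNorm and NormFinder
reference-gene stability (the headline pipeline normalizes to *Tfrc*
and *B2m*), a STRING-format interaction-network overlay, and the
59-patient cohort tables with their summary statistics. See
`docs/methods.md` for assumptions and numerical choices.

## Worked example

Run the whole pipeline on a seeded synthetic experiment that plants the
published disease pattern (120 genes, 6 groups × 4 replicates):

```
metaboflux run --config run.json
```

with `run.json` = `{"out_dir": "demo", "seed": 17, "n_genes": 120}`.
The DE stage reports 415 gene×group tests (35 calls: 29 down, 6 up at
seed 17), and `demo/cfi_report.tsv` contains one row per clinical form,
e.g.:

| group | down (glycolysis \| TCA \| ETC) | CFI (gly, TCA, ETC) | total CFI |
| --- | --- | --- | --- |
| RMS (G+/M−) | Gapdh, Pgam1, Eno1 \| Pdha1, Mdh2 \| Atp5b | 0.0390, 0.0872, 0.3432 | 1.2e-3 |
| Spinal MS | Hk1, Gapdh, Eno1, Pkm \| Pdha1, Mdh2 \| Atp5a1, Atp5b | 0.0075, 0.0820, 0.1412 | 8.7e-5 |

reading: at this seed the pipeline recovers exactly the planted up/down
gene sets, and each pathway CFI is the product of the called genes'
measured fold changes — the Spinal-MS glycolysis collapse (0.0075)
multiplies with the TCA and ETC factors to a near-total predicted flux
shutdown (8.7 × 10⁻⁵), while NMO (all glycolysis/ETC genes up) stays
above 1.

The same computation on the *published* per-pathway indices ranks the
clinical forms G+/M+ (1.6 × 10⁻⁵) < Spinal (6.4 × 10⁻⁵) <
G+/M− (9.4 × 10⁻⁴) < PPMS (2.7 × 10⁻³) < NMO (0.678) — metabolic
collapse tracks clinical aggressiveness, and NMO separates cleanly from
every MS form.

Cohort summaries come from the packaged 59-patient table:

```
metaboflux cohort --grouping coarse
```

prints, per group, n, % female and mean (SD) age/EDSS/progression time
(MS: n=40, 75.0% female, age 30.7 (9.7)).

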