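# scgmp — single-cell cGMP/FRET trace analysis

`scgmp` analyzes single-cell cGMP signaling measured with the ratiometric
FRET biosensor cGi500 in primary vascular smooth muscle cells (VSMCs).
cGMP binding to the sensor raises CFP emission (F480) and lowers YFP
emission (F535), so the CFP/YFP ratio R tracks the intracellular cGMP
concentration with an apparent EC50 of 500 nM.  Cells stimulated
consecutively with the natriuretic peptides ANP and CNP (ligands of the
guanylyl cyclases GC-A and GC-B) and an NO donor reveal which cGMP-producing
pathway dominates in each cell — a functional readout of the contractile
vs. modulated VSMC phenotype.

The package implements the full offline analysis chain plus companions:

| stage | module | what it does |
|---|---|---|
| synthetic data | `scgmp.synthio` | ground-truth-labelled traces, gridded image pairs, count matrices |
| trace processing | `scgmp.traceproc` | background correction, CFP/YFP ratio, baseline normalization, antiparallel validation, QC |
| drift & peaks | `scgmp.driftpeak` | exponential (fallback: piecewise-linear) baseline drift correction, smoothed peak heights |
| classification | `scgmp.classify` | ANP-/CNP-preference rule, NO-response normalization, responder fractions |
| image correlation | `scgmp.mapcorr` | grid-landmark affine registration, mask transfer, IF intensity and roundness per cell |
| statistics | `scgmp.popstats` | Shapiro-Wilk-gated test selection, ANOVA/Kruskal, chi-squared, Bonferroni |
| scRNA-seq QC | `scgmp.scqc` | cell/gene quality filters and the two-gene co-expression rule |

## The core rules

With peak heights measured on drift-corrected, smoothed, baseline-normalized
ratio traces (baseline mean = 1):

* a ratio change is accepted as a cGMP signal only if CFP and YFP move
  **antiparallel** (Pearson r ≤ −0.5 over the event window, CFP up);
* a trace is discarded if its highest signal is **smaller than twice the
  baseline noise** (SD of the normalized ratio over the pre-stimulus
  baseline) or if the baseline moves erratically;
* a cell is **ANP-preferring** if peak(ANP) ≥ 1.5 × peak(CNP) at a matched
  concentration (50 or 250 nM), **CNP-preferring** under the mirrored rule,
  and **ANP ~ CNP** otherwise;
* the NO-induced peak is normalized to the cell's highest ANP/CNP peak;
* scRNA-seq cells with <300 detected genes, <3000 transcripts, or ≥20%
  mitochondrial reads are removed, then genes detected in <10 cells; a cell
  co-expresses two genes iff ≥1 transcript of each is detected.

## Worked example

```python
from scgmp import synthio, pipeline

cfg = synthio.TraceDatasetConfig(n_cells=40)          # SNR ~ 10 cohort
bundle = synthio.generate_trace_dataset(cfg, seed=0)
result = pipeline.run_trace_pipeline(bundle.traces)

table = result.summary()
print(table["label"].value_counts().to_string())
```

```
label
ANP_PREF        10
ANP_CNP         10
CNP_PREF        10
NONRESPONDER     9
EXCLUDED         1
```

The generator planted 10 cells per class; the pipeline recovers the class
structure, with one noisy non-responder excluded for a technical artifact.
Per-cell evidence shows why each call was made — `ratio_50nM` /
`ratio_250nM` are the ANP/CNP peak ratios at the matched doses (≈2.0 for
ANP-preferring cells, well above the 1.5 threshold) and `no_norm` is the
NO peak relative to the best natriuretic-peptide peak:

```
      roi    label qc_status  no_norm  ratio_50nM  ratio_250nM
cell_0000 ANP_PREF      PASS    0.803       2.059        2.061
cell_0001 ANP_PREF      PASS    0.855       2.111        2.014
cell_0002 ANP_PREF      PASS    0.853       2.083        1.986
```

Against the generator's ground truth this run labels 97.5% of the 40 cells
correctly (100% on noiseless data).

The same chain is scriptable from a shell:

```sh
scgmp synth traces --n-cells 40 --seed 0 --out data/
scgmp trace classify --in data/traces.csv --protocol data/protocol.json --out out/
```

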