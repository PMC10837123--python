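# mitoquant

Quantification tools for studying **failure of mitochondrial protein
import and its intercellular rescue**. When a presequence-carrying
precursor is artificially stalled in the TOM/TIM23 translocase (e.g. with
a DHFR domain locked by methotrexate), cells show a characteristic set of
phenotypes: precursor protein enveloping the outside of a subset of
mitochondria, network fragmentation, exchange of mitochondria between
cells, and a measurable loss of import capacity. `mitoquant` implements
the bespoke measurements used to quantify each of these readouts from
fluorescence microscopy and plate-reader data, together with synthetic
generators that produce every input with known ground truth so the whole
pipeline can be validated as a recovery problem.

It is aimed at cell biologists and image analysts who need reproducible,
scriptable versions of analyses that are usually run as one-off FiJi
macros or spreadsheet arithmetic.

## What it computes

| module | measurement |
| --- | --- |
| `preprocess` | cell-ROI clearing, z max-projection, background subtraction → contrast stretch → median → unsharp → Hessian tubeness, binarisation |
| `morphology` | skeleton branch statistics (individuals/networks, branches per network, branch lengths, junctions, endpoints); per-organelle area, perimeter, circularity `4πA/P²`, and width (mean of 5 local diameters `2·EDT` at skeleton points) |
| `association` | per-mitochondrion precursor surface association: mean channel-2 intensity over a 4-px exterior strip minus a 10–14-px background annulus, thresholded (control mean + k·SD) and aggregated to a per-cell *enveloped fraction* |
| `colocalization` | mitochondrial mixing: Otsu threshold of the green+red sum image as a mask, Pearson correlation (PCC) of the channels within it, unpaired t test between groups |
| `traces` | split-luciferase import traces: eqFP670 normalisation → technical-replicate averaging → run-maximum normalisation → percent of control; amplitude = plateau − 30 s baseline; percent reduction; TMRM ΔΨ = mean of (first-10-frame average − final-3-frame post-CCCP average) within the thresholded mitochondrial mask |
| `enrichment` | pulldown TMT statistics: log2 median centring, per-protein unpaired two-tailed t test, Benjamini–Hochberg FDR, volcano classes at ≥2-fold, annotation (e.g. MitoCoP) fractions |
| `synthetic` | ground-truth generators for all of the above: tubular network phantoms, enveloping shells on a chosen fraction of organelles, two-population mixing images, saturating import traces with a 30 s baseline, TMRM collapse movies, protein tables with a planted enriched subset |
| `pipeline` / CLI | YAML-configured, seed-deterministic orchestration with full parameter logging |

## Worked example

Recover a planted enveloped fraction and an import-amplitude reduction:

```python
import mitoquant as mq

# 1. phantom with a planted enveloped fraction
params = mq.PhantomParams(image_shape=(1024, 1024), n_tubes=200,
                          tube_length_range=(15, 30), tube_radius=2, seed=0)
stack, truth = mq.gen_mito_image(params)
ch2 = mq.gen_association_channel(truth, fraction=0.433,
                                 shell_intensity=100, gaussian_sd=10, seed=1)

# 2. calibrate the association threshold on a no-trap control
_, ctrl_truth = mq.gen_mito_image(params)
ctrl = mq.gen_association_channel(ctrl_truth, 0.0, shell_intensity=100,
                                  gaussian_sd=10, seed=2)
threshold = mq.calibrate_threshold(
    mq.edge_strip_score(ctrl_truth.label_map, ctrl), k=2)

# 3. score and aggregate
records = mq.edge_strip_score(truth.label_map, ch2)
result = mq.associated_fraction(records, threshold)
print(f"threshold (control mean + 2 SD): {threshold:.2f}")
print(f"enveloped fraction: {result.fraction:.3f} "
      f"({result.n_associated}/{result.n_objects} mitochondria; "
      f"planted truth {truth.true_association_fraction:.3f})")

# 4. import traces: a trapped condition against its control
run = mq.gen_import_run({"control": 100.0, "trap_2h": 51.9},
                        noise_sd=5.0, seed=3)
_, amps = mq.normalize_traces(run, control_condition="control")
a = {r.condition: r.amplitude for r in amps}
print(f"import reduction: "
      f"{mq.percent_reduction(a['trap_2h'], a['control']):.1f}%")
```

prints

```
threshold (control mean + 2 SD): 1.73
enveloped fraction: 0.450 (90/200 mitochondria; planted truth 0.435)
import reduction: 48.2%
```

The enveloped fraction lands within the binomial sampling error of the
planted truth (0.433 requested, 87/200 after rounding yields 0.435, with
a handful of crowding-induced calls on top), and the 48.1 % reduction
encoded by the amplitude pair (100, 51.9) is recovered to within the
trace noise.

The same analyses are available from the shell:

```sh
mito-rescue-quant run --seed 1 --out results/
mito-rescue-quant traces run.csv --control control --out amplitudes.csv
mito-rescue-quant enrich proteins.csv --annotation mitocop.txt --out stats.csv
```

## Acceptance script

`scripts/acceptance.py` re-runs the complete simulate→quantify pipeline
from scratch under a given seed — phantom morphometrics, association
scoring against a calibrated control, mixing PCC, trace normalisation and
reductions, TMRM correction, and enrichment classification — and writes
the results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The per-stage numbers and every parameter used are logged to
`results/acceptance_run/run_log.json`.

## Documentation

`docs/methods.md` describes the models and estimators, the defaults and
why they were chosen, what the synthetic generators do and do not
emulate, and known limitations.
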