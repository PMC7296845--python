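# endoquant

Quantification toolkit for antibody-internalization microscopy and related
antibody characterization assays:

- **Internalization statistic** (`endoquant.imaging`): per-frame robust
  normalization — centre by the median, scale by the raw median absolute
  deviation (MAD) — followed by the super-threshold pixel sum
  `S_int = Σ x·[x > k]`. The threshold `k` is the 99th percentile of the
  pooled first four normalized frames (time-lapse mode) or of pooled
  normalized control-condition images (static mode). Also: connected-component
  cluster counting and per-ROI positivity calls.
- **One-site binding** (`endoquant.binding`): least-squares fit of
  `y = Bmax·x/(x + Kd)` with log-parameterized positivity, end-point titre
  calling on dilution series (mean(control) + 3 SD rule by default),
  domain-titre ratios, and Spearman rank correlation with permutation
  p-values.
- **Cross-competition** (`endoquant.competition`): two-anchor linear
  normalization of raw fluorescence into percent blocking (control mAb = 0%,
  identical mAb = 100%), and inference of mutual-blocking groups, one-way
  blockers and non-blockers (antibodies that fail to block themselves).
- **Somatic-mutation counting** (`endoquant.shm`): replacement/silent
  classification of V-region nucleotide differences per codon, R:S ratios,
  and cohort comparisons via exact permutation tests.
- **Synthetic data** (`endoquant.synthetic`): seed-deterministic generators
  for every input above with known ground truth — image stacks with planted
  clusters and gain drift, titration curves, raw competition tables with
  planted group structure, dilution series, and germline/mature Ig pairs
  with controlled mutation counts.
- **I/O + CLI** (`endoquant.io`, `endoquant.cli`): multi-page TIFF stacks
  (uint16, JSON sidecar), CSV tables, FASTA sequence pairs, JSON results.

## CLI

All analysis subcommands live under one entry point (`synth` is also
installed standalone):

```sh
# generate inputs with ground truth
synth stack      --spec stack_spec.json      --seed 1 --out out/stack
synth titration  --spec titration_spec.json  --seed 1 --out out/titr
synth competition --spec competition_spec.json --seed 1 --out out/comp
synth igpair     --spec igpair_spec.json     --seed 1 --out out/ig

# quantify
endoquant quant timelapse --stack out/stack/stack.tif --out quant.json
endoquant quant static    --test test.tif --control ctrl.tif --out static.json
endoquant fit kd          --input out/titr/titration.csv --out fit.json
endoquant titre           --input series.csv --out titre.json
endoquant compete normalize --input out/comp/competition.csv --out matrix.csv
endoquant compete groups    --input out/comp/competition.csv --out groups.json
endoquant shm count         --input out/ig/igpair.fasta --out shm.json
```

Every result JSON records the configuration digest and seed; identical
inputs and seeds produce byte-identical outputs.

## Conventions

Pixel coordinates are `(row, col)`, 0-based; frames are 0-indexed, so the
"first four frames" are indices 0–3. The MAD carries no 1.4826 consistency
factor (configurable). Percentiles use linear interpolation between order
statistics (configurable). The Iverson bracket is strict (`x > k`).
Percent-blocking values are not clipped to [0, 100]; out-of-range values
are logged as assay-noise diagnostics.
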