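# cisimc — compressed-sensing multiplexing for antibody-based imaging

Antibody-based imaging methods such as imaging mass cytometry (IMC) are
limited by the number of reporter channels that can be measured at once.
`cisimc` implements composite in situ imaging for protein panels: instead of
giving every antibody its own isotope channel, antibodies are labeled with
*combinations* of isotopes so that `p` protein markers are measured in only
`m < p` composite channels, and the per-protein signals are recovered
computationally. It is aimed at IMC users who want to extend panel size
beyond the available channels, and at methods developers who want a tested
reference implementation of the encoding/decoding machinery.

## Model

Single-cell protein expression `X ∈ R^{p×n}` (proteins × cells, mean ion
counts) is assumed to have modular co-expression structure:

```
X ≈ U W,      U ∈ R^{p×d},  W ∈ R^{d×n}
```

where the columns of the dictionary `U` are unit-L2, nonnegative
protein-expression modules and `W` holds sparse, nonnegative per-cell module
activities — each module involves a few proteins, each cell activates a few
modules. A binary barcoding matrix `A ∈ {0,1}^{m×p}` (channels × proteins)
states which isotopes label each antibody, so a measurement yields composite
data

```
Y = A X ∈ R^{m×n}.
```

Decompression solves the error-constrained Lasso

```
min ‖W‖₁   s.t.   ‖Y − A U W‖²_F ≤ λ ‖Y‖²_F
```

and reconstructs `X̂ = U W`. The pieces are:

* **SMAF** (sparse module activity factorization) learns `U` from training
  data by alternating error-constrained sparse updates of `W` and `U` with
  module-wise L2 normalization (defaults: Lasso, `ldaU = ldaW = 0.02`,
  `d0 = 80` initial modules, 100 iterations, NMF initialization).
* **Barcoding design** searches random constrained designs (≤ 2 channels
  per protein, ≤ 4 single-channel proteins, no empty channel, unique
  barcodes) in a two-round tournament scored by simulated decompression,
  ranking candidates by the *minimum* per-protein Pearson correlation.
* **Image path** converts multichannel TIFF + cell-mask TIFF into the
  expression table (hot-pixel filtering, mean intensity per mask region).
* **Synthetic data** generates ground-truth panels with known modules,
  tissue-varying composition, titration scaling and multiplicative noise.

The main entry points are scikit-learn-style estimators — `SMAF`
(fit/transform dictionary learner), `Decompressor` (composite → expression
transformer), `BarcodingMatrixSearch` — with typed functional equivalents
(`fit_smaf`, `decompress`, `search_barcoding`, …) operating on labeled
matrices, plus the `cisi` command-line tool.

## Worked example

A full workflow on synthetic data — two independent draws from one
simulated 16-marker antibody panel, train the dictionary on the first,
design an 8-channel barcoding and decompress the second:

```
$ cisi synth --p 16 --d 10 --cells 800 --tissues 3 --noise-cv 0.1 \
             --seed 7 --draws 2 --out-prefix sim/
wrote sim/draw0..1_X.csv (16 proteins x 800 cells per draw)

$ cisi train --input sim/draw0_X.csv --d0 20 --iters 15 --seed 0 \
             --out U.csv --report report.json
wrote U.csv: 9 modules, relative error 0.0200

$ cisi design --train sim/draw1_X.csv --dict U.csv --m 8 \
              --candidates 50 --rounds 2 --top 5 --seed 0 --out A.csv
wrote A.csv: best design mean-min protein r = 0.8627

$ cisi simulate --barcoding A.csv --input sim/draw1_X.csv --out Y.csv
wrote Y.csv (8 channels x 800 cells)

$ cisi decompress --input Y.csv --barcoding A.csv --dict U.csv \
                  --lda 0.02 --out Xhat.csv
wrote Xhat.csv

$ cisi eval --truth sim/draw1_X.csv --decompressed Xhat.csv \
            --out report_eval.json
mean protein r = 0.9602, min protein r = 0.8823, mean cell r = 0.9500
```

Reading the numbers: the dictionary explains the training draw to within
the 2% error tolerance using 9 modules; the design search's winning
barcoding matrix scored 0.863 on its held-out evaluation subsamples (mean
over passes of the worst protein's correlation); and decompressing the
independent draw recovers per-protein expression with mean Pearson r of
0.96 across the 16 markers (worst marker 0.88, per-cell profiles 0.95).

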