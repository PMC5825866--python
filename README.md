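# microlens

Tools for two analyses used when validating stem-cell-derived lens tissue:

1. **Transcriptome cell-identity scoring.** Given a bulk RNA-seq profile of a
   purified cell population (for example ROR1⁺ candidate lens epithelial
   cells) and a compendium of tissue transcriptomes, decide which tissue the
   sample is. Two independent arms answer the question:
   - *Ordination:* each profile is discretised to 1 for its top-*k* most
     highly expressed genes (a rank-based guard against batch effects), genes
     marked in more than 20 % of profiles are dropped, pairwise asymmetric
     binary dissimilarity d = (b+c)/(a+b+c) is computed (joint absences
     ignored), and the matrix embedded by classical PCoA; tissues are ranked
     by Euclidean proximity to the query in the positive-eigenvalue space.
   - *Marker enrichment:* each tissue's marker set is its top-*m* genes kept
     only when "highly expressed" in ≤ 5 % of tissues; the query's own marker
     set is built the same way and scored against every tissue with a
     one-sided Fisher exact test on the 2×2 overlap table over the shared
     gene universe, with Benjamini–Hochberg FDR control across tissues.

2. **Micro-lens optics quantification.** Cultured micro-lenses are imaged as
   five-plane focal stacks (the in-focus lens plane plus planes at f/2, f,
   3f/2 and 2f below it, f being the recorded focal distance). Two ratios,
   both normalised to the surrounding culture medium, summarise function:
   *transmittance ratio* (central quarter-diameter ROI at the lens plane /
   medium) and *focus ratio* (brightest below-lens ROI / medium). Treatment
   groups — for instance a dose series of the CFTR potentiator Vx-770, a
   suspected cataractogen — are compared with the pooled two-sample Student
   t-test.

Neither analysis requires external data: `microlens.simulate` generates
tissue compendia with planted marker sets and focal stacks with planted
transmittance and focus gain, so every stage is testable against known truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
inputs (outputs land under `results/`):

```sh
python analysis/01_simulate_inputs.py --seed 0
python analysis/02_cell_identity.py
python analysis/03_optics_quantification.py
python analysis/04_dose_response.py
```

Step 02 prints, for a 20-tissue × 5000-gene compendium and a two-replicate
query drawn from `tissue01`:

```
replicate concordance (log2 Pearson r): 0.9731
nearest tissue by PCoA proximity: tissue01 (distance 0.6577)
top tissue by marker enrichment: tissue01 (overlap a=20, FDR 4.99e-13)
runner-up: tissue16 (FDR 1.08e-05)
```

The two query libraries are near-identical (r = 0.97 on the log scale), and
both arms identify the planted tissue: it is the nearest compendium profile
in the PCoA embedding, and its marker set shares 20 genes with the query's —
an overlap the Fisher test places at FDR ≈ 5×10⁻¹³, eight orders of
magnitude beyond the runner-up.

Step 04 prints the dose-response comparison (15 lenses per dose, planted
transparency loss and focusing failure at 500 ng/ml and above):

```
transmittance_ratio vs dose (pooled t against vehicle control):
        0 ng/ml  mean 0.945 +/- 0.005  p=1.00e+00
      200 ng/ml  mean 0.963 +/- 0.006  p=3.82e-02 *
      500 ng/ml  mean 0.855 +/- 0.005  p=4.12e-13 *
     2000 ng/ml  mean 0.751 +/- 0.006  p=3.30e-21 *

focus_ratio vs dose (pooled t against vehicle control):
        0 ng/ml  mean 1.784 +/- 0.005  p=1.00e+00
      200 ng/ml  mean 1.783 +/- 0.009  p=8.59e-01
      500 ng/ml  mean 1.375 +/- 0.009  p=5.44e-26 *
     2000 ng/ml  mean 1.085 +/- 0.009  p=7.90e-33 *
```

The planted effects at 500 and 2000 ng/ml are detected overwhelmingly on
both metrics; the 200 ng/ml group, which has no planted effect, shows one
borderline p = 0.038 on transmittance in this particular realisation — a
reminder that a single experiment at n = 15 will produce such values at
roughly the nominal rate (step 05 quantifies the rates across 100 repeats).

A `microlens` command-line tool exposes the same stages
(`microlens simulate|compendium|score|optics|run`); `microlens run --seed 0
--out-dir out/` executes the bundled demo configuration end to end and is
byte-for-byte reproducible for a fixed seed.

## Layout

```
src/microlens/      library: simulate, compendium, identity, optics,
                    pipeline, evaluation, io, config, cli
analysis/           numbered study drivers (thin wrappers over the library)
scripts/            acceptance.py
tests/              pytest suite (unit, property and end-to-end checks)
docs/methods.md     models, parameter choices, limitations
```
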