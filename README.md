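# transperon

Simulation and analysis toolkit for three quantitative procedures used in
studies of multiplexed mRNP particles ("transperons"):

1. **Two-channel smFISH co-localization** — spot detection in 3D stacks
   (LoG candidates + Gaussian refinement), per-cell assignment via label
   masks, nuclear/cytoplasmic partitioning, and distance-gated optimal spot
   pairing solved as a linear assignment (Hungarian) problem, summarized as
   per-cell fractions with mean ± SEM and Welch t-test group comparisons.
2. **Pulldown (RaPID-seq style) enrichment scoring** — log2(TPM+1)
   control-subtracted enrichment matrices for heatmaps, plus a from-scratch
   fixed-dispersion negative-binomial exact test (default dispersion 0.1),
   Benjamini–Hochberg FDR, and the "fold ≥ 4, FDR < 0.001" enrichment filter.
3. **Gene-locus apposition classification** — brightest-blob segmentation of
   two-channel locus-tag images and classification into co-localized /
   adjacent / not co-localized by area overlap.

Because the original raw microscopy and sequencing data are not deposited,
the package ships a first-class synthetic-data module that generates
ground-truthed inputs for every stage: cell/nucleus geometry, two-channel
spot fields with a controllable true pairing fraction, rendered image stacks
(Gaussian PSF, Poisson/Gaussian noise), NB count matrices with planted
enriched genes, and locus-pair blob images with controllable overlap.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle agreement,
parameter recovery, detection fidelity, test calibration/power, locus-class
recovery, determinism), each at its stated tolerance. The other test modules
cover units and invariants per module, including brute-force enumeration
oracles for the matcher and the exact test (see `tests/oracles.py`).

## CLI

```bash
# ground-truthed simulation bundle (masks, image stack, truth table)
transperon simulate --out bundle/ --n-cells 150 --true-rho 0.5 --seed 1

# spot detection + cell/compartment assignment on a bundle
transperon detect --bundle bundle/ --out bundle/spots.csv

# per-cell gated-assignment co-localization
transperon coloc --spots bundle/spots.csv --gate-um 0.3 --ref-channel A --out bundle/

# all three steps at once
transperon run --config config.yaml --out bundle/ --seed 1

# NB enrichment test on a TSV count matrix
transperon enrich --matrix counts.tsv --pulldown pull1 --control ctrl \
    --dispersion 0.1 --min-fold 4 --max-fdr 0.001 --out enrich/

# locus-pair classification on a (n_cells, 2, y, x) TIFF
transperon loci --image loci.tif --full-threshold 0.9 --out loci_out/

# figures from any result bundle
transperon report --bundle bundle/
```

A single YAML config may carry per-command blocks (`simulate:`, `detect:`,
`coloc:`, `enrich:`, `loci:`); CLI flags override config values. Every table
written embeds the config hash as a `#` comment line, and rerunning any
command with the same config and seed reproduces byte-identical tables.

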