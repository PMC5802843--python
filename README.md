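# plish

Computational toolkit for **proximity ligation in situ hybridization (PLISH)**:
design of barcoded H-probe panels against target transcripts, quantitative
models of single-molecule RNA detection, and an automated multiplexed
image-quantification and cell-classification pipeline with spatial remapping.

PLISH detects individual RNA molecules in tissue with pairs of DNA "H" probes
that hybridize to adjacent halves of a ~40-nt detection site. Bridge and
circle oligonucleotides assemble on the probe overhangs into an RNA–DNA
Holliday junction; ligation closes the circle and rolling-circle amplification
(RCA) copies it into a bright punctum that a fluorophore-bearing *imager*
oligo reads out via a barcode embedded in the circle. Multiplexing beyond five
fluorophores uses label–image–erase cycles with dU-substituted or short
imagers. This package implements everything computational around that
chemistry; the wet-lab protocol itself is out of scope.

## What's inside

| module | contents |
| --- | --- |
| `plish.probe_design` | detection-site enumeration (AG/TA junctions), nearest-neighbor melting temperatures, arm-length adjustment into a 45–65 °C window, exact k-mer off-target screening, self-complementarity scoring, circle/bridge/imager assembly, full panel design with the 1000 nM pro-rating rule |
| `plish.detection_model` | Poisson copies-per-FPKM calibration (`P(detected) = 1 − e^(−c·FPKM)`), composite vs per-site probe efficiency (`E = 1 − (1 − p)^k`), negative-binomial puncta-intensity fitting, signal-to-background |
| `plish.image_quant` | max projection, cycle registration on the nuclear stain, nuclei detection/segmentation, ~1 µm expansion, per-cell mean-intensity tables, boundary-index images |
| `plish.cell_classify` | 0:10 normalization, `log10(0.1 + x)` transform, k-means / hierarchical clustering, t-SNE, marker-rule cell typing, pseudocolored spatial remaps |
| `plish.synthetic_data` | seeded generators for transcriptomes with planted off-target k-mers, calibration curves, and multi-cycle tissue images with full ground truth |

## Core models

- **Detection sensitivity.** Transcript copies per cell scale linearly with
  FPKM, `λ = c·FPKM` with reference fit `c = 2.5`. Under Poisson sampling the
  fraction of cells with at least one copy is `1 − e^(−c·FPKM)`, fit to
  fraction-positive data by binomial maximum likelihood.
- **Probe efficiency.** `k` independently acting probe sites with per-site
  success probability `p` detect a transcript with composite efficiency
  `E = 1 − (1 − p)^k`; a composite efficiency of 32% over four sites implies a
  per-site efficiency of ~9%.
- **Puncta brightness.** RCA terminates stochastically and irreversibly, so
  punctum intensities follow a negative binomial (mean m, dispersion r,
  variance `m + m²/r`) with coefficients of variation typically between 1
  and 2.

## Worked example

```python
from plish import detection_model as dm, synthetic_data as sd, probe_design as pdn
from plish import image_quant as iq, cell_classify as cc

# design a 4-target panel against a 20-transcript background
targets, background, _ = sd.gen_transcriptome(n_targets=4, n_background=20, seed=0)
panel = pdn.design_panel(targets, background, sites_per_target=4, seed=0)
print(len(panel.order_sheet()))          # 48 oligos (16 HL, 16 HR, 4 circles, ...)

# efficiency algebra and calibration
p = dm.per_site_efficiency(0.32, 4)
print(f"{p:.4f} ({dm.round_percent(p)}%)")            # 0.0919 (9%)
model = dm.CalibrationModel(copies_per_fpkm=2.5)
print(dm.expected_copies(2, model))                   # 5.0 copies/cell
print(f"{dm.detection_fraction(1, model):.4f}")       # 0.9179

# simulate a 300-cell, 8-gene, 2-cycle tissue field and run the full pipeline
tissue = sd.gen_tissue_images(sd.TissueSpec(seed=0))
res = iq.quantify_field(tissue.cycles)
print(len(res.profiles), res.offsets)     # 300 cells, offsets [(0, 0), (3, -2)]
cls, _ = cc.classify_profiles(res.profiles, k=10, seed=0)
```

The quantification recovers all 300 planted cells and the planted (3, −2) px
stage offset of the second cycle exactly; k-means on the log-transformed
profiles recovers the ten planted cell classes at an adjusted Rand index of
0.948 against ground truth on this seed.

The same pipeline is available from the shell:

```
plish simulate tissue -o sim && plish quantify --manifest sim/run.yaml -o quant
plish classify --profiles quant/cell_profiles.csv --k 10 -o classes
plish design --targets targets.fa --background txome.fa --sites 4 -o panel
```

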