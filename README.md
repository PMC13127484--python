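# hetchrom

Quantitative analysis of heterochromatin protein-retention assays, built
around the biology of the mouse Suv39h H3K9 methyltransferases.  Mouse
pericentric heterochromatin appears as DAPI-dense chromocenters formed by
major satellite repeat (MSR) arrays; Suv39h1 and Suv39h2 deposit H3K9me3
there, and Suv39h2 additionally carries an arginine-rich, highly basic
N-terminal "basic domain" (BD, pI ≈ 12) that stabilizes its
heterochromatin association.  This package implements the computational
readouts such a study needs, each paired with a synthetic ground-truth
generator so every pipeline is testable offline:

* **`hetchrom.survey`** — taxon-wide census of basic N-terminal extensions
  in a protein family: name filtering, alignment-anchored extraction of
  N-terminal extensions (start anchored at residue 1 of a short reference
  paralog, boundary at residue 81 of the long one), Henderson–Hasselbalch
  isoelectric points (EMBOSS pKa constants, bisection on the monotone net
  charge Z(pH)), amino-acid-composition PCA and a k-means similar/distinct
  partition around the reference domain.
* **`hetchrom.frap`** — FRAP kinetics: full (double) normalization of
  bleach/reference/background ROI traces, curve averaging, and a
  constrained dual-exponential fit
  `F(t) = A1 (1 − e^(−t/τ1)) + A2 (1 − e^(−t/τ2))`
  yielding mobile/immobile fractions (plateau `A1 + A2`) and the
  half-maximal recovery time t<sub>1/2</sub>.
* **`hetchrom.imaging`** — per-nucleus scoring of marker signal as focal
  (chromocenter-enriched) vs dispersed from two-channel images, via a
  focal-enrichment ratio (mean marker over DAPI-dense foci ÷ nucleoplasm),
  plus per-cell mean intensities normalized to a control condition.
* **`hetchrom.gel`** — MNase nucleosome-ladder metrics from 1-D lane line
  scans: morphological baseline removal, band detection, spacing
  regularity and a ladder score.
* **`hetchrom.qpcr`** — ChIP-qPCR percent-of-input by the ΔCt method with
  input-dilution correction, fold enrichment with first-order error
  propagation, replicate summaries.
* **`hetchrom.synth`** — deterministic generators for all of the above
  with machine-readable truth tables.

## Worked example

Simulate a FRAP experiment with a planted 60% mobile fraction and
t<sub>1/2</sub> = 11.3 s (the Suv39h1-like regime), then fit it:

```python
>>> import hetchrom as hc
>>> traces, truth = hc.gen_frap_traces(mobile_fraction=0.60, t_half=11.3,
...                                    n_traces=30, noise_sd=0.05, seed=21)
>>> curve, fit, summary = hc.frap_pipeline(traces)
>>> print(f"mobile {summary.mobile_fraction:.1f}%  immobile "
...       f"{summary.immobile_fraction:.1f}%  t1/2 {summary.t_half:.2f} s")
mobile 58.9%  immobile 41.1%  t1/2 11.20 s
```

30 bleached foci at 5% frame noise recover the planted 60/40 split and
half-time to within about a percentage point and a percent.  The same works
from the shell:

```sh
hetchrom simulate frap --mobile 0.6 --t-half 11.3 --seed 21 --out sim/
hetchrom frap --manifest sim/manifest.csv --out fits/
```

which writes the averaged curve, the fitted parameters with standard
errors, and a `run_metadata.json` capturing every parameter and input
checksum.  The other stages are exposed the same way (`hetchrom survey`,
`images`, `ladder`, `qpcr`, `simulate {orthologs|images|ladder|qpcr}`).

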