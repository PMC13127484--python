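# Methods

This note documents the models, parameter choices and numerical decisions
behind each analysis stage, what the synthetic generators emulate, and
where the design was genuinely open.

## Basic-domain survey

**Pipeline.** Protein records are kept when the protein name contains
"histone" and none of the exclusion tokens ("prdm", "setmar"),
case-insensitively; matching case handling is our convention since name
conventions vary across databases.  On a user-supplied multiple sequence
alignment (gap `-`; the aligner is deliberately external), two anchors
define the N-terminal extension: a record is *extended* when it has at
least one residue in a column strictly before the column holding residue 1
of the short reference paralog (mouse Suv39h1-style), and every extension
is *truncated* at the column holding residue 81 of the long reference
(mouse Suv39h2-style, whose basic domain is 81 aa).  Extensions longer
than 20 residues (strict inequality) are retained; those with pI ≥ 10
(inclusive) constitute the basic-domain set.  Both anchors, the length
cutoff and the pI threshold are parameters, so the pipeline generalizes to
other families.

**Isoelectric point.** Net charge uses the Henderson–Hasselbalch
sum-over-groups form with the EMBOSS pKa constants (N-terminus 8.6,
C-terminus 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1); the
scale is configurable.  Z(pH) is strictly decreasing because every peptide
carries the two termini, so the pI is the unique root, found by bisection
on [0, 14] to a default tolerance of 0.001 pH.  Ambiguity codes
(B, Z, X, U, O) are excluded from both composition and charge — the
simplest defensible rule; fractional assignment would change pI values by
less than the uncertainty in the pKa constants themselves.  A dense-grid
oracle (0.0001 pH steps) is used in the tests to confirm the bisection
root.

**PCA and clustering.** Composition vectors (fractions over the 20
canonical residues; ambiguity codes excluded from numerator and
denominator) are mean-centered but not variance-scaled — the coordinates
already share one scale, and scaling would inflate rare-residue noise.
Scores and loadings come from an exact SVD; `min(n − 1, 20)` components
are kept, so reconstruction of the centered matrix is exact to numerical
precision.  The similar/distinct partition is k-means with k = 2 on
PC1–PC2, 10 restarts, a fixed seed, with the cluster containing the
reference domain labeled "similar".  This is a stated convention: nothing
in the underlying figures pins down how that boundary was drawn, so the
rule here is deterministic and reported with the outputs.  Degenerate
inputs (all points identical, or fewer points than clusters) collapse to a
single "similar" cluster.

**Open sensitivity.** The headline pI refers to residues 1–81 of the long
reference.  Nearby choices change it little for arginine-rich domains
(removing two N-terminal residues of an 81-mer with ~20 R shifts the
bisection root by < 0.05 pH), but the interval is configurable and
reported.

## FRAP kinetics

**Normalization.**  For each bleached focus three ROI traces are recorded
(bleach, reference, background).  Double normalization

    N(t) = [(Ib − Ibg) / (Iref − Ibg)] · [⟨Iref − Ibg⟩_pre / ⟨Ib − Ibg⟩_pre]

cancels acquisition photobleaching shared by the two fluorescent ROIs and
scales the pre-bleach plateau to 1.  The bleach frames themselves are
transition/saturated frames and are discarded; curves start at the first
post-bleach frame (t = 0).  Full-scale normalization then maps bleach
depth to 0: F(t) = (N(t) − N₀)/(1 − N₀).

**Model and fit.**  Averaged curves are fitted to
F(t) = A1 (1 − e^(−t/τ1)) + A2 (1 − e^(−t/τ2)) by bounded least squares in
(plateau, fast-fraction, log τ1, log τ2) coordinates — the log-τ
parameterization conditions the problem, and the (plateau, fraction) form
makes the physical constraints A ≥ 0 and A1 + A2 ≤ 1.05 structural.  τ is
bounded to [frame interval/10, 10 × total duration]; multi-start from the
fixed grid τ1 ∈ {0.2, 1, 5} s × τ2 ∈ {5, 20, 80} s (τ1 < τ2), amplitudes
seeded from the observed plateau split 70/30.  Parameters are reported in
canonical order τ1 ≤ τ2, ties broken by larger amplitude first.

Two safeguards address a genuine identifiability hazard: when τ2 runs far
beyond the observation window, the slow term degenerates to a linear ramp
whose amplitude (and hence the plateau) is unconstrained by the data.
First, solutions that terminate on the plateau cap are discarded as
unidentifiable extrapolations.  Second, a nested single-exponential fit is
preferred unless the second component improves the fit significantly
(extra-sum-of-squares F test, α = 0.05); for effectively
single-exponential data the amplitude split is unidentifiable anyway, and
the plateau and t½ — the quantities of scientific interest — are what the
reduced model estimates best.  Without these safeguards, plateau estimates
blow out in roughly one seeded replicate in seven under the simulated
acquisition conditions.

**Bleach depth.**  Anchoring the full scale on the single first
post-bleach frame propagates that frame's noise into every point of the
curve as a correlated offset, which inflates half-time errors beyond
±15% in the low-mobile regime (verified against an oracle that anchors on
the true depth).  The pipeline therefore fits the depth as a free nuisance
parameter, N(t) = N₀ + (1 − N₀) F(t), on the averaged double-normalized
curve; the standalone `full_scale_normalize` keeps the simple first-frame
anchoring for display and for noise-free data.

**Summary quantities.**  mobile = 100 · (A1 + A2) clamped to [0, 100];
immobile = 100 − mobile (the pair sums to 100 exactly by construction);
t½ solves F(t) = (A1 + A2)/2 by bisection on [0, 10 τ2] — computed on the
fitted curve rather than the raw average because the raw curve's noise
makes the crossing ill-defined.  Standard errors come from the
residual-variance-scaled inverse Gauss–Newton curvature at the optimum,
evaluated on the averaged curve (not across per-trace fits).

**Generator.**  Traces follow the acquisition protocol of 10 pre-bleach,
2 bleach and 188 post-bleach frames at 0.21 s.  Intensities: constant
background (50 a.u.), reference focus 800 a.u. and bleach focus
1000 a.u. above background, both decaying with a shared mono-exponential
acquisition-photobleaching rate (default 0.005 s⁻¹); bleach depth 0.3 of
the pre-bleach level; Gaussian noise with SD 5% of the pre-bleach signal
added per frame to each ROI (background at one tenth of that — it is a
dim, averaged region).  A planted (mobile, t½) pair maps to
dual-exponential parameters by a 70/30 amplitude split with τ2 = 2 τ1 and
τ1 solved by bisection so the planted half-time is exact.  The modest τ
separation keeps the planted kinetics resolvable within the ~40 s
acquisition window, which is what fitted curves that visibly plateau
within the acquisition imply; truths with τ2 far beyond the window would
make the plateau a pure extrapolation no estimator could pin down at this
noise level.

## Image scoring

Nuclei are segmented on the DAPI channel: Gaussian smoothing (σ = 2 px),
Otsu threshold on log-compressed intensities (the log keeps bright
chromocenters from capturing the split; smoothing suppresses background
shot noise), boundary relocalization at half the interior median level
(half-height edge criterion, since the low log-scale cut otherwise
dilates edges), hole filling, removal of components under 500 px and of
border-touching nuclei.  Chromocenters are pixels above the nucleus mean
plus 2 SD of DAPI intensity, components ≥ 5 px.  The focal-enrichment
ratio is the mean marker intensity over foci divided by the mean over the
nucleoplasm, capped at 100 for cells without nucleoplasmic signal; a cell
is *focal* when the ratio is defined, ≥ 1.5 and at least one focus exists,
else *dispersed*.  The original scoring of such images is by eye; the
ratio threshold is this package's stated surrogate, is a CLI parameter,
and is echoed into the run metadata.  Per-cell mean marker intensities are
normalized by the median of the control condition (the 0-dose / 0.14 M
sample in a challenge series).  Images are treated as single
(maximum-intensity-projected) planes.

The generator draws elliptical nuclei (radii 16–24 px) with ≥ 12 px
clearance, 2–5 non-overlapping Gaussian chromocenters (σ = 3 px, amplitude
2× nucleoplasm), and plants the marker enrichment as a uniform enhancement
over the DAPI-dense region defined by the same mean + 2 SD criterion the
scorer applies — so the planted ratio is the measurable one.  It does not
emulate uneven illumination, out-of-focus light, cell-cycle heterogeneity
or touching nuclei; passing tests therefore validate the scoring logic,
not segmentation performance on real micrographs.

## MNase ladder metrics

Lane line scans are baseline-corrected by subtracting a morphological
(grey) opening with a flat window (default 120 px = 3× the expected
inter-band spacing) — robust against broad smears — and clipped at zero.
Band detection smooths with a 3-px Gaussian, then requires peak prominence
≥ max(5% of the corrected maximum, 6 robust noise SDs) and ≥ 5 px
separation; the noise floor (MAD of the first difference of the unsmoothed
profile) prevents noise wiggles on the residual of a broad smear from
counting as bands.  Spacing regularity is the CV of successive peak
spacings (defined for ≥ 3 peaks); the ladder score is
n_peaks · (1 − min(CV, 1)) — no numeric ladder statistic exists in the
source figures, so this operationalization is the package's own, and lane
comparisons report scores and differences without inferential statistics.

## ΔCt ChIP enrichment

percent input = 100 · 2^(Ct_input − log2(1/input fraction) − Ct_IP).  The
input-dilution adjustment is explicit because only "ΔCt method" is ever
stated in practice; amplification efficiency is fixed at 2.0 (no
standard-curve correction).  Technical replicates average on the Ct scale;
biological replicates are summarized (mean, SD with n − 1, n) after the
exponential transform.  Fold enrichment between samples propagates SDs by
the first-order ratio rule, validated in the tests against a 10⁵-draw
Monte-Carlo estimate.  The Ct generator inverts the formula to plant known
percent-input values and adds Gaussian Ct noise (default SD 0.2 cycles,
typical qPCR replicate scatter).

## Synthetic ortholog families

A conserved core (120 aa) receives i.i.d. point substitutions per record
(rate 0.05).  A designated subset of records gets N-terminal extensions;
the implied alignment left-pads non-extended records with gaps, which is
exact because substitutions never shift coordinates.  Planted strata are
explicit parameters (how many extensions, how many exceed the length
cutoff, how many are basic, how many reference-similar), so count-level
expectations are constructions, not samples.  Basic extensions carry
20–30% arginine on an unionizable background (G/S/A/N/Q for
reference-similar, P/T/V/L/I for distinct), placing their pI near 13;
non-basic ones are D/E-rich with pI near 4 — the margins around the pI 10
threshold are structural, not tuned.  Real ortholog sets differ in having
indels, alignment errors and compositional gradients; tests on this
generator validate coordinate mapping and selection logic, not aligner
robustness.

## Determinism

All generators draw from `numpy.random.default_rng` seeded per call;
per-stage substreams derive from one master seed via SHA-256
(`derive_seed`), keeping every derived seed below 2³¹.  Identical
configurations give identical outputs; every CLI run echoes parameters,
seeds and input checksums to `run_metadata.json`.

## Problem sizes

The test suite and the acceptance script run the study-scale conditions
directly: 30 traces per FRAP condition with 20 seeded replicates per
kinetic regime for the recovery property, 100 scored nuclei, 200 random
peptides for the pI oracle, 40-record families.  These match the source
conditions (n ≥ 30 foci, n ≥ 50–100 cells, n = 3 qPCR replicates) rather
than scaled-down stand-ins.

## Known limitations

* The UniProt-census figures of the original survey (3033 → 888 → 694
  sequences, 23% extended, ~40% basic) depend on a dated database
  snapshot and an external aligner and are not reproducible offline; the
  package reproduces the *procedure* with ground-truth-known synthetic
  families.
* The reference pI check on mouse Suv39h2 requires the UniProt Q9EQQ0
  record (bundled locally or fetched); the package ships no third-party
  sequence data.
* The FRAP model is reaction-dominant; diffusion-coupled recovery and
  bleach-spot geometry corrections are out of scope.
* Image scoring percentages are surrogate readouts validated against
  synthetic truth only; absolute agreement with by-eye scoring of real
  micrographs is not claimed.
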