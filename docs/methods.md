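# Methods

This note documents the models, estimators and numerical choices behind
`platekin`, the assumptions they rest on, and what the synthetic-data
tests do and do not demonstrate about real instrument data.

## 1. Ratiometric calcium calibration

Per-event fluorescence is averaged over fixed 1-s bins (empty bins are
dropped, not interpolated — at low event rates interpolation would
invent data).  The bound/free Fura-Red ratio `R = <FL405>/<FL488>` is
converted to cytosolic calcium with the Grynkiewicz relation

```
[Ca2+] = Kd * (FImax/FImin) * (R - Rmin) / (Rmax - R)
```

* `Kd` (Fura-Red affinity) defaults to 400 nM.  Literature values span
  roughly 140–1100 nM depending on environment; the default is only a
  scale factor because of the anchoring below, and is configurable.
* `FImin` and `Rmax` are medians over the ionomycin plateau (minutes
  5–10 after addition), where the indicator is calcium-saturated.
* `FImax` is the median baseline 488-channel level, corrected for the
  small calcium-bound dye fraction at basal calcium.  The correction is
  solved self-consistently (8 fixed-point iterations, far past
  convergence) because basal calcium is itself a calibration output.
* `Rmin` is estimated from the post-EGTA epoch.  EGTA minimises the
  calcium-bound dye, but the buffered level is not zero: with 2 mM
  total calcium and 10 mM EGTA the mixture holds free calcium at a
  known mark (Section 2).  `Rmin` is therefore solved from the EGTA
  window ratio `R_e` as `Rmin = R_e - mark * (Rmax - R_e)/K_eff`, which
  both uses the epoch and builds the absolute anchor into the
  calibration.
* `normalize_calcium` additionally rescales the whole series by
  `mark / (measured post-EGTA calcium)`.  For self-calibrated traces
  this factor is 1 by construction; for externally supplied constants
  it cancels any multiplicative error (wrong `Kd`, mis-estimated
  `FImax`) exactly, which is the purpose of the EGTA mark.
* Ratios below `Rmin` (noisy baseline bins) clip to 0 nM with a warning
  count; ratios at or above `Rmax` are saturated — the scalar API
  raises, the pipeline marks those bins NaN and excludes them.

**Windows** (configurable, `WindowConfig`): baseline = last 30 s before
the agonist; response = 300 s after it; ionomycin plateau = minutes
5–10 after addition; EGTA window = last 30 s of the run.  The EGTA
window deliberately starts ≥30 s after the addition so the chelation
transient has fully settled.

**Max-statistics and smoothing.** `ca_max`, the fibrinogen maximum and
the SSC step are maxima of a time series; the maximum of raw 1-s bins
is upward-biased by event noise (the expected maximum of ~300 noisy
bins sits ~3 bin-SDs above the truth).  These features are therefore
taken on a centred 15-s moving average — well below the response
timescales (rise ~10–30 s, decay ~120 s), so the peak flattening is
<1% while the noise bias shrinks by √15.  Basal calcium is a window
mean and needs no smoothing.

## 2. Ca–EGTA equilibrium (the 50 nM anchor)

Free calcium of a Ca/EGTA mixture is the positive root of the 1:1
mass-balance quadratic with a pH-corrected apparent dissociation
constant `Kd' = alpha(pH) / K_CaEGTA`,
`alpha = 1 + [H]/Ka1 + [H]^2/(Ka1*Ka2)`.

Published EGTA constant sets disagree substantially (the classic "EGTA
problem": apparent Kd at pH 7.0 varies by an order of magnitude between
the Schwarzenbach/NIST-derived and the Fabiato-school sets, largely
through the first protonation constant and temperature/ionic-strength
corrections).  The defaults here — `log10 K_CaEGTA = 10.00`,
`pKa1 = 9.40`, `pKa2 = 8.58` — are a 37 °C, physiological-ionic-
strength set of the high-Kd school; they put the 2 mM Ca / 10 mM EGTA
Tyrode mark at ≈50 nM free calcium, the anchor this assay is built
around.  No separate ionic-strength correction is applied; its effect
is inside the accuracy of that anchor.  All three constants are keyword
arguments for users who prefer another set.  The implementation is
validated against an independent multi-species speciation solver in the
test suite.

## 3. Donor features and cohort clustering

Each donor contributes four features: basal calcium (baseline-window
mean), maximal calcium within 5 min of the agonist, relative fibrinogen
binding (affine rescaling of the fibrinogen channel with quiescent = 0
and the ionomycin plateau = 1; the donor value is the maximum in the
first 5 min — the maximum, not the endpoint, because responses peak
within the window), and the relative SSC-A step.

Features are centred and scaled per coordinate by median and
normal-consistent MAD (robust, so outlier donors do not dominate the
metric), then clustered with HDBSCAN (`min_cluster_size = 5`,
`min_samples = 2`).  The sizes were chosen once so that subgroups of
~12 and ~21 donors are discoverable while a handful of outliers remain
density noise; the small `min_samples` avoids the very conservative
density estimates that tens-of-donors cohorts otherwise produce.  The
cluster with the higher mean fibrinogen binding is HFB, the other LFB;
noise points are NC; a single cluster is labelled UNSPLIT; with more
than two clusters the two largest are kept.  Partitions are scored with
DBCV (in-package implementation of the Moulavi et al. index, using all
cluster points rather than only MST-internal nodes — a standard
simplification).  Group contrasts are two-sided Mann–Whitney tests.

**What recovery means here.** Density clustering cannot assign every
donor: tail donors of overlapping Gaussian groups are, correctly, low
density.  Two agreement metrics are exposed: `label_agreement` (all
donors, NC counted) and `cluster_purity` (agreement among donors placed
in the two clusters, absorbed true outliers counted as errors).  On
cohorts drawn from the published group statistics the modal number of
clusters is 2 and median purity ≈0.92, while all-donor agreement
plateaus near 0.7 for any hyperparameters — a property of the printed
between-group overlap, not of the implementation.

## 4. Synthetic cohort generator

The generator is the study-conditions oracle: group feature
distributions default to the published means and SDs (healthy basal
8.0 ± 4.7 nM and peak 91 ± 22 nM; ITP basal 15 ± 5 nM; HFB n=12 peak
155 ± 27 nM and binding 0.21 ± 0.05; LFB n=21 peak 101 ± 31 nM and
binding 0.082 ± 0.048; GT binding 0.034 ± 0.009; shape change
0.30–0.32 vs 0.20–0.25; per-donor saturation fibrinogen fluorescence
450 ± 250 m.f.i.).  Draws are truncated to physical ranges
(concentrations ≥ 0, binding in [0, 1.5]) by resampling.  Unassigned
(NC) donors are drawn uniformly over the union of the two subgroup
ranges ±2 SD and rejection-sampled to lie ≥2 SD from both subgroup
centres on every coordinate, so they land in low-density regions.

Event streams are Poisson arrivals (default 500 events/s, matching a
continuous acquisition at ~10^3 platelets/µL) with per-event
multiplicative lognormal noise (CV 0.25 per channel).  The calcium
curve is piecewise: flat baseline; an agonist transient
`(1 - e^(-t/10 s)) * e^(-t/120 s)` normalised to the programmed peak
(CRP uses a slower sustained rise, 60 s); a rise toward the 2 mM
external level under ionomycin (the ionophore equilibrates the cytosol
with the buffer — this also makes the measured `Rmax` nearly exact);
and relaxation to the EGTA mark.  Channels invert the Grynkiewicz
relation: `R(Ca)` from the calibration constants, and the 488 nm level
from the two-state dye (`FI = FImax·(1-b) + FImin·b`, bound fraction
`b = Ca/(Ca+Kd)`), with `FL405 = R · FL488`.  Fibrinogen rises
first-order (τ 45 s) to the programmed relative level after the
agonist and to saturation (τ 60 s) after ionomycin; SSC-A steps up by
the programmed fraction (τ 30 s).

Thrombus tracks: growing objects follow accelerating intensity growth
(`fold^s(t)`, `s = expm1(4 t/T)/expm1(4)`) to a drawn fold change —
recruitment accelerates as a thrombus matures, which also matches the
published growth velocities (a uniform exponential with fold 2.7 over
20 min would sit exactly at the 1.1-per-2-min classification boundary
and show implausibly low velocities).  Non-growing objects fluctuate
about their initial intensity.  Final areas are scaled to the
programmed field coverage.

**Limits of the emulation.** No spillover/compensation, no doublet or
debris populations, no instrument drift or carryover, independent
feature draws within groups, and noise that is exactly lognormal.
Passing recovery tests therefore demonstrates estimator correctness
under the published group statistics, not robustness to instrument
artifacts.

## 5. Signaling model

States (21): cytosolic/store/mitochondrial calcium, IP3, DAG, PIP3,
RASA3 and Rap1-GTP fractions, active/desensitised fractions for P2Y1,
P2Y12, PAR1, PAR4 and GPVI, cAMP, active integrin and bound fibrinogen
fractions.  Kinetic forms: Hill-type IP3R open probability
(cooperative IP3 gate, Hill 4, K 0.4 µM; activating calcium gate Hill 2,
K 150 nM; inhibitory gate Hill 4, K 110 nM), Hill-2 SERCA (K 150 nM)
and PMCA (K 100 nM), linear store and plasma-membrane leaks, a steep
store-operated entry term (Hill 16 in store calcium — STIM1
oligomerisation; steepness chosen so store-leak variants deplete the
store only mildly), saturable uniporter/NCLX with a threshold-gated
mPTP, first-order receptor activation/desensitisation with slow
resensitisation, Michaelis-type PLC and PI3K arms, a mass-action Rap1
cycle driven by CalDAGGEFI and opposed by RASA3, and a two-state
integrin with Rap1-GTP-proportional on-rate; bound fibrinogen follows
integrin activity with a very slow off-rate (bound fibrinogen is
stable on the assay timescale).

Design choices worth flagging:

* **SOCE is load-bearing.** A store-leak change cannot move resting
  cytosolic calcium unless store content feeds back on membrane
  influx; the store-operated term provides exactly the "sustained by
  increased calcium influx through the membrane" behaviour of the
  store-leak (LFB) phenotype.
* **CalDAGGEFI is a Ca/DAG coincidence detector** (steep Hill-4 calcium
  gate, K 300 nM, DAG Michaelis gate).  Without the DAG requirement,
  the 10→15 nM resting difference of the variants leaks into
  fibrinogen binding over the 10-min run; with it, quiescent platelets
  of every variant bind essentially nothing, as observed.
* **Calcium-activated PLC** (Hill 2, K 2 µM) is negligible during
  ~100 nM agonist transients but supplies the DAG under ionomycin
  calcium overload, so the "ionomycin = 1" fibrinogen normalisation is
  generated by the same mechanism as in the experiment.
* **cAMP/PKA tone**: Gα_i (P2Y12) lowers cAMP, relieving PKA
  inhibition of CalDAGGEFI.  Together with PI3K→PIP3→RASA3 inhibition
  this produces the ADP→TRAP synergy: the second stimulus acts on a
  disinhibited Rap1 cycle, doubling the fibrinogen increment at an
  unchanged calcium peak.

**Calibration.** The baseline PM leak is root-found so N rests at
10 nM cytosolic calcium; the LFB store-leak multiplier and the HFB
basal PLC rate are root-found to a 15 nM rest (Brent's method on the
lever, each evaluation an integrate-and-polish steady-state solve).
Remaining rate constants were adjusted once so the baseline ADP
(2 µM) response peaks near 100 nM with relative fibrinogen binding
~0.2, the variant ordering matches the observed phenotypes, and the
synergy fold is ~2; they are declared in `ModelParameters` with units.

**Numerics.** LSODA with rtol 1e-8 (1e-10 for steady-state work) and
per-state atol; the integrator restarts at every addition so stimulus
discontinuities are never stepped across.  Steady states: chunked
integration with a Newton polish (`scipy.optimize.root`, hybr with lm
fallback) and a 100-s probe requiring relative drift <1e-8 — the polish
matters because store filling and fibrinogen unbinding relax over
1e3–1e5 s.  Solutions move <0.5% under halved tolerances; with
plasma-membrane fluxes disabled, volume-weighted total calcium is
conserved to integrator precision.

**Sensitivity.** The cooperative IP3 gate makes the calcium spike
threshold-like; the TRAP response in particular sits within ~30% of
the ignition threshold, so PAR1 drive and desensitisation trade off
sharply.  This is consistent with the all-or-none character of platelet
calcium responses, but users changing receptor parameters should check
`predict_synergy` output against the `adp_response` peak.

## 6. Thrombus analysis

A thrombus is "growing" iff its DiOC6 mean intensity rises at least
1.1-fold over some 2-min window (inclusive threshold); the
field-summary "continuously growing after 20 min" applies the same rule
to the final 2-min window.  Fold change divides the intensity maximum
by the median of the first three frames (robust to a dim first frame —
the denominator is otherwise undefined by the assay description);
growth velocity is the steepest 2-min relative rise per minute.  All
metrics are ratios and hence invariant to uniform gain.  Segmentation
is plain thresholding with connected components; linking is greedy
nearest-centroid within a radius — thrombi are sessile, so nothing
fancier is warranted.  PMN crawling speed is the mean frame-to-frame
displacement rate in nm/s, summarised over early/late 10-min epochs.

## 7. Known limitations

* The cohort-level clinical numbers (patient basal calcium, Table-style
  thrombus statistics of real donors) are represented only through the
  synthetic generator; no instrument data ships with the package.
* FCS support is a minimal float32 list-mode reader/writer with a TIME
  parameter; log-amplified integer data are not parsed.
* The ODE model is deterministic and spatially homogeneous; no granule
  release, thromboxane, or P-selectin module; model fibrinogen binding
  is a fraction of saturable sites, not molecule counts.
* Default analysis windows assume the standard protocol timing
  (agonist ≈50 s, ionomycin ≈350 s, EGTA ≈950 s); other protocols must
  adjust `WindowConfig` accordingly.
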