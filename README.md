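# platekin

Analysis pipeline for **continuous (kinetic) flow cytometry of platelet
calcium signaling and integrin αIIbβ3 activation**, built for studies of
platelet function in immune thrombocytopenia (ITP), with Glanzmann
thrombasthenia (GT) as the fibrinogen-binding negative control and
healthy donors as the positive control.

It is aimed at platelet-biology groups who acquire Fura-Red–loaded
platelets in continuous mode (per-event time stamps) with sequential
additions of an agonist (ADP, TRAP or CRP), 1 µM ionomycin, and 10 mM
EGTA, and who want donor-level phenotypes plus mechanistic
interpretation.

## What it computes

1. **Ratiometric calcium calibration.** Per-second binned channel means
   give the ratio *R* of calcium-bound (ex 405 nm) to calcium-free
   (ex 488 nm) Fura-Red; cytosolic calcium follows the Grynkiewicz
   relation

   `[Ca²⁺] = K_D · (FI_max / FI_min) · (R − R_min) / (R_max − R)`

   with FI_min and R_max taken from the ionomycin plateau and the whole
   series anchored to the known free calcium of the 2 mM Ca / 10 mM
   EGTA buffer (≈50 nM from the pH-corrected Ca–EGTA equilibrium).
2. **Donor features**: basal calcium, maximal post-agonist calcium,
   relative fibrinogen binding (quiescent = 0, ionomycin = 1), and the
   relative SSC-A shape change.
3. **Cohort subgrouping**: hierarchical density-based clustering
   (HDBSCAN) of the four features after robust median/MAD scaling,
   validated with the DBCV index; clusters are named HFB/LFB (high/low
   fibrinogen binding) by their mean binding, density noise becomes NC;
   group contrasts use two-sided Mann–Whitney tests.
4. **Mechanistic ODE model** of calcium homeostasis (DTS store,
   mitochondrion, IP3 receptor, SERCA/PMCA, leaks, store-operated
   entry) coupled to inside-out integrin activation
   (CalDAGGEFI → Rap1-GTP ← RASA3/PI3K, with Gα_i/cAMP/PKA tone), with
   four phenotype variants: **N** (rests at 10 nM cytosolic calcium),
   **LFB** (store-membrane leak ↑, rests at 15 nM), **LFB\*** (LFB with
   75% of normal Rap1), **HFB** (quiescent PLC activity, rests at
   15 nM).  Variant levers are calibrated by deterministic 1-D
   root-finds, and the model reproduces the ADP→TRAP synergy: a second
   stimulus doubles integrin activation at unchanged peak calcium.
5. **Thrombus growth under flow**: per-object DiOC6 area/intensity
   tracks (or thresholded image stacks), the inclusive
   "≥1.1-fold-in-2-min" growing rule, area fraction, fold change,
   growth velocity, and PMN crawling speeds.
6. **Synthetic cohorts**: a seeded generator that emits event streams
   and thrombus tracks with the published group statistics, so every
   stage is testable without instrument data.

## Worked example

```python
from platekin import (ProtocolSpec, extract_features)
from platekin.synthetic_cohort import make_donor_stream
from platekin.trace_processing import FeatureVector

protocol = ProtocolSpec()            # ADP at 50 s, ionomycin 350 s, EGTA 950 s
programmed = FeatureVector(ca_basal_nM=8.0, ca_max_nM=91.0,
                           fib_rel=0.16, ssc_change=0.31)
stream = make_donor_stream(programmed, protocol, seed=0)
print(extract_features(stream, protocol))
```

prints (healthy-donor phenotype recovered from ~500 000 noisy events):

```
FeatureVector(ca_basal_nM=8.414552506693218, ca_max_nM=91.90277616380371,
              fib_rel=0.1610313808134548, ssc_change=0.31846484773787026)
```

i.e. quiescent calcium ≈8 nM, an ADP response peaking near 91 nM,
fibrinogen binding ≈16% of the ionomycin level, and a ≈32% SSC step.

The whole pipeline, end to end:

```bash
platekin full-demo --out demo --seed 0
```

generates a 36-donor synthetic ITP cohort (12 HFB + 21 LFB + 3
outliers), processes every stream, recovers the two subgroups by
density clustering, runs the four model variants, the synergy
experiment and a thrombus field, and writes `demo/report.{json,md}`.
Typical report numbers: 2 clusters with ~0.93 cluster purity; model
rests 10/15/15/15 nM; ADP peaks ~104 nM (N) vs ~183 nM (HFB); synergy
fold ~2.0.

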