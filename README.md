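# dicmflex

Dynamic functional connectivity for multichannel neurophysiological
recordings: per-window identification of **dominant intrinsic coupling
modes** (dICMs), lobar subnetwork features, and a global **flexibility
index**, with age/group modeling on top.

Resting-state brain activity couples neuronal populations through several
distinct mechanisms at once — correlated amplitude envelopes, phase
locking within a band, phase-amplitude modulation across bands, and
delayed directed interactions.  Which mechanism dominates a given sensor
pair changes on the timescale of seconds.  This package implements the
full analysis chain that turns a raw multichannel recording into that
description and into scalar markers of it, and ships a synthetic-data
generator that plants every coupling type the estimators are meant to
detect, so the entire chain is testable without access to neuromagnetic
cohort data.

## The method

1. **Preprocessing** — band-pass into 8 canonical bands
   (δ 0.5–4, θ 4–8, α₁ 8–10, α₂ 10–13, β₁ 13–15, β₂ 15–19, β₃ 20–29,
   γ 30–45 Hz; zero-phase 3rd-order Butterworth), Hilbert envelope and
   phase, sliding 2-s windows stepped by 0.2 s.  A 3-min recording at
   170 Hz (or 150 Hz) yields exactly T = 900 temporal segments.
2. **Five coupling estimators** per window, pair, and frequency code
   (codes 1–8 = within-band, 9–36 = the 28 low<high band pairs):
   amplitude envelope correlation (AEC), same-frequency imaginary
   phase-locking value (iPLV), phase-amplitude coupling (PAC, via
   cross-frequency iPLV), delay symbolic transfer entropy (dSTE, on
   neural-gas-symbolized state vectors), and the directed phase-lag index
   (dPLI).
3. **Statistical filtering** — every candidate is ranked against
   surrogates obtained by circularly shifting one channel over the whole
   recording; Benjamini–Hochberg FDR at q = 0.01 across the frequency
   candidates; when several estimators remain, the stricter threshold
   p < 0.01/4 = 0.0025 applies and up to two coexisting modes are kept
   per cell (frequency code 0 = no coupling).
4. **Topological filtering** — orthogonal minimal spanning trees (OMST):
   edge-disjoint MSTs are extracted iteratively and the union maximizing
   global efficiency minus wiring cost is retained.
5. **Lobar aggregation** — a mode dominates a lobar sensor block when
   shown by >75 % of its sensor pairs in ≥50 % of segments; the packaged
   12-row subnetwork table yields 12 mean-subgraph-strength (MSS) and 10
   fractional-occupancy (FO) features:

   MSS = mean over dominant segments of Σ FCG(s₁,s₂) / (sensors₁·sensors₂),
   FO = N_Dom / N_TS, both in [0, 1].
6. **Flexibility index** — FI = (label changes between consecutive
   segments) / (T − 1), averaged over all sensor pairs; FI ∈ [0, 1].
7. **Modeling** — FI vs age fitted by five families (linear, quadratic,
   log, exponential, Von Bertalanffy) compared by AIC; age prediction by
   linear SVR / multi-class SVM with LOO or 5-fold CV; group contrasts by
   Wilcoxon rank-sum.  Static baselines (relative power, imaginary
   coherence, multiscale entropy) plug into the same model path.

## Worked example

`examples/02_detect_coupling_modes.py` plants a depth-1.0 θ→γ
phase-amplitude coupling on one channel pair of a 12-s synthetic
recording and runs the statistical pipeline:

```
60 temporal segments of 2s (step 0.2s)
surrogate-tested candidates: 8544; FDR-retained: 200

retained coupling-mode records on the pair (windows):
  PAC theta->gamma        50 / 60
  DPLI theta->gamma       43 / 60
  DPLI alpha1->alpha2      5 / 60
  DSTE theta->alpha1       5 / 60
  DPLI beta1->beta3        2 / 60

planted PAC theta->gamma retained in 83% of windows
```

The planted mode is recovered as a retained record in most windows
(more with longer recordings, which dilute the truncated tail windows);
the co-occurring directed phase-lag record reflects the same planted
phase relation seen by a second estimator — exactly the situation the
two-record cells are designed for.  The other examples cover simulation
and I/O (`01`), lobar dominance/MSS/FO (`03`), flexibility and
age modeling (`04` — the fitted quadratic FI–age curve peaks near age 40
with r² ≈ 0.89 on the default synthetic cohort), and the static baseline
measures (`05`).

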