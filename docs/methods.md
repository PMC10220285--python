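# Methods

This note documents the models, parameter choices and numerical decisions
behind `gpxscreen`, and what the synthetic-data tests do and do not
establish about real screening data.

## Coupled-assay kinetics

The primary assays read GPX activity through a GR-coupled cycle: GPX
reduces cumene hydroperoxide (CHP) while oxidising two GSH to GSSG; GR
regenerates GSH at the cost of NADPH, whose 340/450 nm autofluorescence
is the signal. Glutathione peroxidases do not follow Michaelis–Menten
kinetics; we use the ping-pong (Dalziel) rate law

    v_GPX = E·f / (φ1/[CHP] + φ2/[GSH])        [φ in M·s]

and a two-substrate saturable law for GR (kcat 200 s⁻¹, Km,GSSG 65 µM,
Km,NADPH 8.5 µM — textbook-scale constants for human GR). The ODE system
conserves [GSH] + 2[GSSG] exactly; the integrator (LSODA, rtol 1e-8)
holds this to well below 0.5%, and is cross-checked in the tests against
an independent fixed-step explicit-Euler integration at dt = 10 ms.

**Calibration of φ1, φ2.** Dalziel coefficients for these recombinant
constructs are not tabulated, so the defaults are calibrated to the
assay-development behaviour the screen was optimised to: with 10 nM GPX1
(1 mM GSH / 0.5 mM CHP / 0.5 mM NADPH / 50 nM GR) the NADPH decline is
near-linear over the 15 min read window and ≥ 95% complete by 25 min.
φ1 = 1.0e-6, φ2 = 1.8e-5 M·s give 80% consumption at 15 min, 99.6% at
25 min, and < 3% deviation from linearity. GPX4 constants
(φ1 = 2.0e-5, φ2 = 4.2e-4 M·s) are scaled so 200 nM enzyme matches its
20 min endpoint window (90% consumed). GPX2 is treated as GPX1-like with
slightly different constants. GR at 50 nM has flux capacity far above
peak GPX flux, so the coupled readout reports GPX, not GR — except under
strong GR inhibition, which is exactly the false-positive mode the
counter-screen exists to catch.

**GR counter-assay.** The counter-screen is simulated with GSSG in excess
over NADPH (0.4 mM vs 0.16 mM, the dispense stoichiometry) and an
effective GR turnover of 7 s⁻¹ at 25 nM, calibrated so the uninhibited
reaction spans its NADPH window near-linearly over the 20 min read. Both
choices matter: a reaction that completes in the first minute of the
window is blind to partial inhibition (an endpoint read shows full signal
regardless), and a GSSG-limited reaction leaves most of the NADPH signal
unused, collapsing the assay window. With these settings counter plates
show Z′ ≈ 0.75 and apparent IC50s track planted GR potencies.

**TXNRD1.** The selenite assay is modelled as pseudo-first-order NADPH
decay with rate k·f (k = 2.5e-3 s⁻¹ at 90 nM enzyme, f the residual
activity), read kinetically every 60 s for 8 min. The full
selenite→selenide reduction mechanism is out of scope. Because the decay
is exponential rather than linear, apparent IC50s run up to ~2-fold above
planted potencies; this bias is inherent to endpoint reads of saturating
kinetics and is why counter-assay activity calls use the low-quality bar
rather than a potency match.

**mBBr orthogonal assay.** GPX runs against GSH/CHP without GR recycling;
at quench, monobromobimane condenses with the remaining GSH into a
fluorescent adduct, treated as instantaneous and complete (no published
adduct rate constants; the post-quench kinetic read collapses to one
endpoint). Note the orientation: the mBBr signal reports *remaining* GSH,
so active enzyme gives the *smaller* fluorescence increase; control
anchoring in the normalization handles this automatically, and the assay
is used as a confirmatory orthogonal readout only. Its small signal
window reproduces the modest plate statistics of the real mBBr format.

## Noise model

Reads are `rfu = gain·[species] + background`, scaled by a slow
multiplicative drift (1.15e-4 s⁻¹) and per-read multiplicative Gaussian
noise (CV 3%), clipped at zero. The drift term — instrument drift plus
slow NADPH autoxidation — is what gives no-enzyme wells a nonzero
delta-RFU and hence a finite signal:background; its default puts S/B
near 7. The read CV default lands 1536-well primary plates at Z′ 0.7–0.8,
inside the 0.67–0.77 band the real screens reported. (With independent
per-read noise, the noise of the t0 and endpoint reads stack in the
subtraction; a CV of 6% would push delta-RFU Z′ to ~0.45, which is why
3% is the calibrated default.) Optional sinusoidal row/column effects
and per-compound fluorescence interference offsets exist but default to
off/zero. Randomness is rooted in a single seed; per-plate substreams are
derived by counter so plate subsets reproduce exactly.

## Ground-truth panels

`make_truth_panel` plants compounds in seven categories (GPX1/GPX2-
specific, GPX4-specific, pan-GPX, pan-selenoprotein, Sec-cross-reactive,
GR false positive, inactive), drawing potencies log-uniformly from
0.5–5 µM — the range typical of confirmed qHTS actives — with Hill 1 and
floor 0 against every target the category implies. The intended category
is recorded per compound, so a triage run yields a confusion matrix.

What the synthetic data does *not* emulate: compound aggregation,
redox-cycling and autofluorescence artifacts (beyond the optional
interference offset), plate-edge evaporation gradients, carry-over, and
potency drift between primary and follow-up stocks. Passing recovery
tests therefore demonstrate that the *analysis stages* are correct and
well-calibrated, not that the assay is robust to every real-world
artifact.

## Normalization and QC

Percent activity is 100·(ΔRFU − median_neg)/(median_pos − median_neg) on
each plate's own controls, never clipped (clipping biases efficacy
estimates). Medians, not means, are used throughout; controls more than
5 MAD from their group median are masked by default (with a floor on the
cut so a lone bad dispense among otherwise identical controls is still
masked). Z′ uses sample SDs of control ΔRFU around the medians; plates
below the Z′ threshold (default 0.5) are flagged, and the pipeline aborts
only if *every* plate fails. The endpoint time is taken from each plate's
read schedule rather than hard-coded, since assay formats differ
(15/20 min endpoints, 8 min kinetic).

## Curve fitting and classification

4PL fits run in log10-concentration space with bounds top ∈ [50, 150],
bottom ∈ [−20, 100], Hill ∈ [0.3, 5] and IC50 within the tested range
± one dilution step. Multi-start: a 7-point log-IC50 grid × Hill
{0.5, 1, 2}; the five best starts by initial residual are polished with
analytic-Jacobian trust-region least squares, and the best final RSS
wins. IC50 is the inflection of the fitted curve (relative IC50), which
is what the 4PL parameter is. AUC is the trapezoidal integral of fitted
percent inhibition over log10 concentration, normalized by the log-range
so full inhibition scores 100. The exact qHTS curve-class algorithm is
proprietary to its pipeline; the rubric here is a documented
approximation of its verbal definitions — class −3 when activity is
confined to the single top dose (≥30% there, <10% elsewhere, judged on
per-concentration means), class 4 when efficacy < 30% or r² < 0.3,
−1.x vs −2.x by whether the fitted IC50 sits a full dilution step inside
the range *and* the top-dose response is within 10% of the fitted span of
the lower asymptote, and the .1/.2 split at 80% inhibition. All
thresholds are module constants.

With single-replicate 7-point data at realistic noise, the completeness
call is occasionally unstable for sub-µM potencies (the upper plateau is
barely sampled and a shallow-Hill/high-top fit can win on RSS). The
pipeline therefore sends every *low-quality-or-better* primary active to
11-point triplicate follow-up — mirroring the real screen, which carried
377 initial hits into confirmation while reporting hit rates on the
high-quality subset — and all triage decisions are made on the far more
stable follow-up fits.

## Triage

Stage order: primary hit calling → 11-point reconfirmation (class −3
actives flagged top-dose-only and removed) → GR exclusion → TXNRD1/GPX2
specificity. "Active" in counter/isoform assays means low-quality-or-
better. GPX2 annotates but never excludes (every real GPX1 hit also
inhibited GPX2); mBBr failure demotes to inconclusive rather than
inactive. The published intermediate counts are not mutually consistent
(the stage order between weak-active removal and the GR screen is
ambiguous in the source material); this implementation's bookkeeping is
strictly self-consistent under the order above, and the summary exposes
raw stage counts so either reading can be recomputed.

## nanoDSF

Tm is the temperature of a peak in the first derivative of the smoothed
350/330 ratio (Savitzky–Golay, default 2.0 °C window, cubic), refined by
a local quadratic fit over the peak neighbourhood; at most two
transitions are reported (ties resolve toward lower temperature), with a
relative prominence threshold of 20% of the maximum derivative. The
instrument's own algorithm is proprietary; window and prominence are
configurable. ΔTm between replicate groups uses Welch's unequal-variance
two-tailed t-test with strict significance thresholds (0.05/0.01/1e-3/
1e-4); transitions are matched across groups by nearest mean temperature
and count mismatches are flagged, not dropped. Identical degenerate
groups return (t, p) = (0, 1) rather than NaN.

## Problem sizes and determinism

Default study sizes: 7-point primary / 11-point follow-up 1:3 series from
49.8 µM (the five-point library variant shares the same top and fold);
64 + 64 control wells per 1536-well plate; follow-up in triplicate;
recovery studies use ~100-compound panels (14 per category) and 200-curve
fit Monte Carlos. Every pipeline artifact is reproducible from the run
manifest (config + seed + package version) alone; `summary.json` is
byte-identical across repeated runs of the same config.

## Known limitations

- The coupled readout's percent activity is mildly nonlinear in residual
  enzyme activity near full consumption, compressing apparent efficacy at
  the extremes; apparent IC50s in the TXNRD1 assay run up to ~2× planted.
- The 4PL completeness call on sparse primary data is noise-sensitive
  (mitigated by follow-up, see above).
- Two melt transitions closer than ~2 smoothing windows merge into one
  detected peak.
- No spatial detrending beyond control masking; no robust-loss fitting;
  no thermodynamic (ΔG/ΔH) analysis of unfolding.
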