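# Methods

## The analysis chain

The pipeline quantifies, per subject, the coupling of the global
resting-state BOLD signal (gBOLD) to CSF inflow, maps where the global
signal is locally expressed, detects its propagation along the cortical
principal gradient (PG), and relates all of these to staged amyloid
biomarkers.

**Preprocessing.** Sessions arrive as parcel × time matrices (a thin NIfTI
reader converts 4-D volumes + label images to the same representation).
The first and last 5 volumes are discarded (10+10 in the sensitivity
variant), all series are band-pass filtered to 0.01–0.1 Hz, and sessions
whose mean framewise displacement (FD) exceeds 0.5 mm are excluded. The
filter is a 4th-order Butterworth applied forward–backward
(`sosfiltfilt`), i.e. zero-phase: lagged cross-correlations are the core
statistic, so phase distortion is not acceptable. FD uses the Power
convention with rotations converted to arc length on a 50 mm sphere; the
mean-FD threshold is read strictly (exactly 0.5 mm is included). Note the
filter's edge transients reach roughly one period of the low cut-off
(~33 samples at TR = 3 s); trimming before vs after filtering agrees
tightly only deeper than that into the series.

**Coupling.** The cross-correlation function is the Pearson correlation of
x(t) with y(t+τ) computed on the overlapping samples only — zero padding
would bias r toward 0 increasingly with |τ|. The lag grid is the sampling
grid (±12 s window by default); the coupling scalar is the value at +3 s,
where the group-mean function has its negative peak. For sessions whose TR
does not divide 3 s, the nearest grid lag is used and flagged in the
result. The per-subject most-negative lag and value are always recorded.
The gBOLD presence of a parcel is Spearman's ρ between the parcel series
and gBOLD; rank correlation makes the measure invariant to per-parcel
affine (and any monotone) rescaling.

**Hierarchy.** A parcel is higher-order if strictly more than 50 % of its
vertices overlap DMN+FPN, lower-order if strictly more than 50 % overlap
somatomotor+visual, and unassigned otherwise (ties included); unassigned
parcels enter neither regional mean. Parcel means are unweighted. The
cross-hierarchy contrast of a map is mean(higher) − mean(lower).

**Connectivity.** Nuisance series (CSF, the 6 raw motion parameters, and —
in the "gBOLD removed" condition — the global signal) are regressed out of
every parcel in one joint OLS, so the residual space does not depend on
regressor order. FC is the full pairwise Pearson matrix; region summaries
average raw r over unique within-region pairs and over all higher × lower
pairs (no Fisher z — summaries stay on the correlation scale the per-pair
values live on). The change of the Aβ42–FC regression slope after gBOLD
removal is tested with a condition × predictor interaction in a stacked
OLS; the two conditions contain the same subjects, which the result
records but the test does not model (the paired structure would only make
the test conservative under positive dependence).

**Waves.** Units are rank-sorted by PG value into 70 position bins whose
sizes differ by at most one (remainder units go to the highest-PG bins,
deterministically). Parcel series are cubic-spline interpolated 5-fold
(0.6 s at TR = 3 s) and bin-averaged into a time–position graph. The
interpolated gBOLD is cut at troughs — local minima with prominence of at
least 0.25 SD of gBOLD (a config knob; the trough rule is a documented
stand-in, since no exact rule is published). Within a segment, each bin's
local BOLD peak is the highest strictly-interior local maximum (edge
maxima do not count, which is what makes peaks "identified" in only some
bins); its timing relative to the segment's gBOLD peak is correlated with
bin position. Segments with peaks in ≤ 50 bins are invalid; otherwise
r > 0.3 is bottom-up, r < −0.3 top-down, with strict inequalities (the
published threshold is treated as the primitive; its p-value gloss is
commentary). Averaged wave patterns use a 12 s window read as ±6 s
inclusive around the gBOLD peak (21 frames at 0.6 s), with snapshot
extraction at −3, 0, and +3.6 s; group comparison is an element-wise
two-sample t-test (A − B sign convention, uncorrected p-values).

**Statistics.** Staging: CSF+ is Aβ42 < 192 ng/L, PET+ is SUVR > 0.872,
both strict; the empirically unobserved CSF−/PET+ quadrant gets its own
label. Continuous group comparisons use the pooled (Student) two-sample
t-test — the pooled variant, not Welch, reproduces the published age
p-value from the group summaries — with Welch behind a flag. Categorical
comparisons use the exact Fisher test with the min-likelihood two-sided
convention (sum of all conditional tables no more probable than the
observed one), which matches full hypergeometric enumeration exactly. The
stage trend is a cumulative-logit proportional-odds model with stage as
the ordinal outcome and the measure as predictor (Wald p on the slope;
statsmodels `OrderedModel`); under complete separation a ridge-penalized
fit of the same likelihood supplies a finite p and is flagged. The
alternative parameterization (measure regressed on stage scores) is
available behind `reverse=True`. "Adjusted for age and gender" means the
imaging measure is residualized on [1, age, sex] with the grand mean
restored, then rank-correlated against the unadjusted marker —
one-sided residualization, applied within the subject set of each
analysis. FDR is Benjamini–Hochberg, applied per declared family (e.g.
the five marker associations within a stage; the three FC summaries).
`exact_summary_sample` constructs a sample with exactly a requested
(n, mean, SD), which reproduces any statistic that depends on the data
only through those summaries — this is how published summary tables are
re-tested.

## The synthetic cohort generator

The generator is the package's test bench and defines the study
conditions; its defaults are fixed and not analysis knobs.

**Session model.** Global activity is a quasi-periodic train of
raised-cosine bumps: 3 events/min (≈ 0.05 Hz, the center of the infra-slow
band) of width 12 s, drawn on a jittered grid so events stay separated.
The width/rate pair puts > 90 % of the noise-free global signal's power
below 0.1 Hz (verified by periodogram on a finely sampled evaluation).
Each event propagates along the PG: parcel delays are linear in PG rank,
spanning (n_bins − 1)/wave_speed = 69/35 ≈ 2 s across the cortex —
within the range reported for global-wave traversal — so the noise-free
time–position correlation is ±1 by construction. A configurable fraction
(default 0.7) of events is bottom-up. Parcels express the global signal
through presence weights (default: 1.0 at the sensory end tapering to 0.5
at the DMN end, the sensory-dominant pattern). The CSF signal is the
sign-flipped, standardized noise-free global signal evaluated exactly at
t − 3 s, mixed with an independent component: CSF ∝ −(c·G(t−lag) +
√(1−c²)·ε), so the per-subject coupling strength c is the injected ground
truth and, in the noise-free limit, the cross-correlation extremum sits
exactly at the lag. Off-grid lags are rounded to the sampling grid with a
warning. Measurement noise is white with SD 0.2 of the event amplitude;
motion is a random walk rescaled so the session-mean FD equals its target
(0.15 mm) exactly.

**Cohort model.** Stages S1/S2/S3 default to 50/23/71 subjects with
40/19/53 two-year follow-ups (112 total); ages and sex ratios follow the
published per-stage summaries. Within each stage a latent coupling score
anchors a Gaussian copula: each biomarker targets Spearman magnitude 0.65
against coupling strength (Pearson loading 2·sin(πρ/6)), signed so weaker
coupling accompanies lower Aβ42, higher tau, higher SUVR and faster
accumulation. Stage mean coupling strengths are 0.65/0.55/0.45 with SD
0.2 — a spread comparable to the published per-stage scatter, which also
reproduces the published significance pattern (S1 vs S3 separates, S1 vs
S2 does not reliably). The latent effect size 0.65 was set by power
analysis: after the measurement chain attenuates it, the observed
correlations land near the published ≈ 0.5 at n = 23 with adequate
detection probability. Marker values map monotonically into
stage-consistent ranges that straddle the 192 ng/L and 0.872 SUVR
cut-offs strictly.

Two mechanisms tie the imaging phenotypes to Aβ42 (both at copula strength
0.8): (1) a **synchronous global component** — a second, zero-delay event
train expressed through the same presence weights — whose amplitude
(1 ± 0.6 around the wave amplitude) rises with Aβ42; this induces the
FC–Aβ42 association *solely through global-signal amplitude*, so gBOLD
regression removes it; (2) a **higher-order attenuation** (up to 60 %
presence loss, ramping along the PG) that grows as Aβ42 falls; this
produces the reduced presence/coupling of higher-order parcels and the
failure of bottom-up waves to reach high-PG bins in low-Aβ42 subjects.
Two-year SUVR-change maps are proportional to the subject's
presence-deficit profile (plus a small uniform floor and noise), which
realizes accumulation that is concentrated in higher-order parcels and
inversely weighted by the subject's remaining higher-order presence.
Cohort sessions additionally carry intrinsic network fluctuations (latent
per-network signals entering through row-normalized vertex-overlap
loadings, SD 0.3): real cortex has connectivity that does not come from
the global signal, and this intrinsic structure is what residual FC
settles back to after global-signal regression. Standalone-session
defaults omit the synchronous component and intrinsic noise — the clean
single-session configuration at which the recovery properties (exact lag,
presence-rank recovery, direction recovery) are defined.

**What the generator does not emulate.** No volumetric rendering (parcel
and bin level only), no spatial autocorrelation within parcels, no
physiological confounds (cardiac/respiratory), no scanner drift, white
rather than 1/f noise, and real gBOLD is a continuous fluctuation rather
than a clean event train — between events the filtered signal leaves
low-amplitude segments that detect as non-directional, which real data
would not show in the same proportion. Passing tests therefore
demonstrate that the analysis recovers injected structure under the
assumed signal model, not that the model captures all properties of real
rsfMRI.

## Numerical choices and problem sizes

Ties in PG ranks and marker thirds break deterministically (stable sorts;
subject ID). The extreme-third subgroups take round(n/3) subjects each
(23 → 8). Constant series yield flagged missing values (coupling,
presence, FC) rather than errors; degenerate segments classify as
invalid. All randomness flows from one integer seed through
`numpy.random.default_rng`; identical (config, seed) reruns are
bit-identical, and the pipeline writes a config hash with its results.
The test suite and the acceptance script run the full default cohort
(144 subjects, 140 parcels, 140 volumes at TR = 3 s); the end-to-end
replica check uses 10 seeds, the ordinal-trend calibration 1000 null
simulations at n = 144, and the connectivity power check 10 seeds of 23
subjects — sizes chosen to keep the whole suite in the minutes range on
one CPU while leaving the per-run cohort at full scale.

## Known limitations

The proportional-odds trend and the slope-comparison test are asymptotic;
at the n = 23 early-accumulator stratum their p-values are approximate.
The slope-comparison test ignores the subject pairing across conditions
(conservative under positive dependence). The trough-detection rule and
the FD formula are standard conventions where the source methods defer to
prior work; both are config knobs. NIfTI support converts to parcel
matrices immediately — voxel-level analysis is the same code on more rows
but is not exercised at scale in the tests.
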