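# Methods

This note documents the models, estimators, and design choices behind
`cognophen`, in the order the pipeline runs them: behavior, single units,
LFP spectral analysis, inter-areal connectivity, genetics, reporting, and
the synthetic-data generators that feed them.

## Behavioral analyses

### Reversal-learning scoring

The task is a three-target reversal: one target is rewarded for a block of
11–17 trials, then the contingency moves unannounced to one of the two other
targets. Every trial from the second block onward receives a score
s ∈ {−1, 0, +1}: −1 for the previous block's correct target, 0 for the
current one, +1 for the third target. Scores are aggregated by trial index
after the switch (mean, SEM, n); trials of a session's first block have no
preceding contingency and are excluded but counted. Under optimal play the
switch trial is always −1 and trial 2 has expectation +0.5 (uniform over the
two not-previously-correct targets, scoring 0 or +1); a perseverative agent
is pinned at −1 on trial 2. These closed forms are the behavioral oracles in
the test suite.

### Error-case trial selection

Two selectors isolate how an animal uses its partner's errors in the social
task (roles alternate every three trials; reward is shared):

* **Choice-error case** — self-actor trials immediately preceded by a
  partner non-reward in a non-switch trial, restricted to blocks where the
  current correct target had already been selected by either animal before
  the error. The optimal response is exploitation (repeat the known correct
  target). The "selected before" condition is evaluated within the current
  block only: a block boundary resets what either animal can know about the
  contingency.
* **Switch-error case** — self-actor trials immediately preceded by the
  partner's perseverative error in a switch trial (the partner chose the
  previous block's correct target). The optimal response is exploration
  among the two targets the partner did not choose.

The two definitions are disjoint by construction (switch vs non-switch
predecessor), which the suite asserts on simulated data. Accuracy after
selected trials is aggregated per session day (daily sessions are the
natural granularity) with a binomial SEM and an optional centered rolling
mean.

### Licking differentiation and ratios

Anticipatory licking during the stimulus period indexes reward expectation.
The differentiation day is the first day d of two successive days (d, d+1)
on which lick magnitude correlates with the block's variable reward
probability at p < 0.01 (Spearman). P-values use the large-sample
approximation, with an exact permutation fallback below n = 10 trials. The
licking ratio divides the mean lick magnitude of the highest-valued level by
the lowest-valued one; in the partner-variable block the *lowest*
P(partner) is the highest-valued level (another's reward devalues one's own
prospect). Zero lick values are dropped first; values beyond 3 SD of the
remaining mean are excluded in a single pass (mean and SD are not
recomputed after exclusion — the exclusion rule is stated once, and
iterating it would remove progressively more data with no stated stopping
rule). The ratio's SEM is propagated from the two level means by the delta
method.

## Single-unit typing

Units arrive as per-trial firing rates in a pre-target control epoch
(600 ms) and a task epoch, with condition labels. Rates are assumed
non-negative and complete per trial; units with an empty or single-trial
agent × outcome cell are excluded with a reason code rather than forced
through the tests.

**Actor-related typing** (reversal task, α = 0.05) is a fixed decision tree:

1. Two-way ANOVA of peri-action rate on agent × outcome, type-II sums of
   squares. Type-II is used because simulated and real designs are mildly
   unbalanced and no interaction is part of the typing rule.
2. Significant agent main effect → agent-selective candidate. The
   Tukey–Kramer comparison of the two agents' rates must confirm the
   separation; the preferred agent is the one whose peri-action rate departs
   from the control period (paired t-test) — defined this way so that
   *inhibitory* units (peri below control) are typed correctly; when both
   agents depart, the larger modulation wins. If no agent's baseline
   comparison is significant the unit is left untyped ("none"), not demoted
   to mirror.
3. No agent main effect → mirror iff the paired baseline comparison is
   significant *with the same sign* in both agents' trials. Opposite-sign
   responses are not mirror-like and fall to "none".

The response sign (excitatory/inhibitory) is the direction of the
peri-minus-control difference. At the generator's reference effect sizes
(offsets ≥ 2× the trial-level rate SD, 60 trials per agent × outcome cell)
the tree recovers ≥ 90% of each planted type; at zero effect the non-"none"
rate is far below the 5% gateway level because typing requires a conjunction
of independent tests.

**Reward-related typing** (conditioning task, α = 0.01) regresses epoch rate
on the block's variable reward probability separately per block:
self/partner for a single significant slope, mirror for same-sign slopes in
both blocks, value for opposite signs. Blocks with fewer than three
probability levels are rejected (a slope over two levels is a mean
difference, not the intended dose–response).

**ISI quality flag.** A unit is flagged when any inter-spike interval falls
below 2 ms (strict reading); the violating fraction is reported so a
downstream tolerance policy can instead drop individual spikes. Unit-level
flagging is the default because the contaminating spike cannot be
identified after sorting.

**Type-proportion tables** count types per region × subject with
percentages of the typed total, rounded half-up to one decimal — the
rounding that reproduces published table percentages exactly (e.g. 55/217
mirror units → 25.3%).

## LFP spectral analysis

Recordings are 16-contact linear probes (200 µm spacing) sampled at 1 kHz.
The spectral estimator is a complex Morlet wavelet with 7 cycles, evaluated
at 1-Hz centers over 1–50 Hz at the native 1-ms resolution. The transform
reflect-pads each trace by its own length before FFT convolution: without
padding, the multi-second support of the 1–3 Hz wavelets drags
circular-convolution edge taper into the analysis window and biases
low-frequency z-scores by several tenths of an SD (the stationary-noise test
pins this at |mean z| < 0.1).

Spectrograms are averaged over contacts (and trials) and z-scored per
frequency against a pre-event baseline window (default 0–500 ms before the
event). The high-beta index (23–30 Hz) is the mean z over the pre-press
window; a significantly negative index is the operational definition of mu
suppression. Session-level indices are tested against zero with the Wilcoxon
signed-rank test by default and Student's t as an option — both are in
legitimate use for this index and the package reports whichever is
configured. The gamma comparison (31–55 Hz) needs the frequency grid
extended to 55 Hz beyond the default 50 Hz ceiling; `spectrogram_z` takes
`f_range` for exactly this purpose.

**Evoked amplitude and latency.** The contact/trial-averaged raw trace is
z-scored against baseline. Latency is the first bin of the first run of at
least *k* consecutive bins with |z| above the threshold, ignoring an
exclusion window after the event; runs truncated by the data end are not
counted. Two parameter sets are provided: 1.5 SD × 3 bins (reversal-task
flavor, amplitude = mean |z|) and 3 SD × 30 bins (conditioning flavor,
amplitude = integral of |z| in |z|·ms). The detector's false-positive rate
on pure noise is ≤ 1% under the 3-SD/30-bin rule; the 1.5-SD/3-bin rule is
only meaningful on high-SNR averaged responses, since any z-normalized noise
trace crosses 1.5 SD for 3 bins somewhere in a long window. Detected latency
cannot precede the true onset and converges to it as amplitude grows.

Dopamine-neuron latency is simply the argmax bin of the trial-averaged spike
density in the response window, with ties flagged and resolved to the
earlier bin.

**Feature PCA.** Per-contact amplitude/latency features are concatenated
across sessions and subjects, rows with undetected latencies dropped (and
counted), columns centered and scaled to unit variance — amplitudes (SD
units) and latencies (ms) are incommensurate, and unscaled PCA would load
almost entirely on latency variance — then decomposed with PCA; the first
two component scores carry subject labels for separation analysis.

## Inter-areal connectivity

**Bipolar derivation.** Adjacent-contact differences (toward the superficial
end) remove common-mode signal; 16 contacts yield 15 bipolar channels.

**Wavelet coherence.** Single-trial bipolar traces are concatenated per
channel, convolved with complex Morlet wavelets at 24 log-spaced frequencies
from 1 to 128 Hz, and split back into trials. Magnitude-squared coherence
per channel pair uses trial-averaged cross- and auto-spectra, so it lies in
[0, 1]; the per-frequency mean over the baseline window is subtracted, and
band averages are reported over the seven canonical bands (δ 1–3, θ 4–7,
α 8–12, low β 13–20, high β 21–30, low γ 31–49, high γ 50–128 Hz). Fewer
than 8 trials are rejected — a trial-averaged coherence over fewer trials
has a noise floor too high to interpret. Note that a strong component
present only post-stimulus still leaks into the baseline through the
wavelet's temporal extent; baseline-subtracted contrasts are conservative
for signals much larger than the background.

**Pairwise Granger causality.** "Pairwise conditional" is implemented as
conditional GC within each cross-region channel pair's bivariate VAR — the
analysis proceeds region-pair by channel-pair, and conditioning beyond the
tested pair is deliberately out of scope (documented as the chosen reading,
not asserted as the only one). Per pair: the model order is selected by AIC
up to 50 lags (50 ms at 1 kHz); the VAR is fitted by pooled OLS over trial
segments; time-domain GC in each direction is ln(σ²_restricted/σ²_full) of
the target channel's equation, tested with the nested-model F statistic;
Benjamini–Hochberg FDR is applied over all pair × direction tests within the
session/window (the natural family for a per-session flow statistic).
Channels failing an augmented Dickey–Fuller unit-root screen (majority vote
over the first three trial segments — concatenating segments would mask
drifting trials) or pairs with regressor condition number above 1e8 are
excluded with a reason and do not enter the denominator.

**Flow bias.** Per session, the proportion of valid pairs with significant
top-down GC minus the proportion with significant bottom-up GC, in [−1, 1].
Across sessions the bias is tested against zero (Wilcoxon signed-rank) and
between subjects (Welch). On simulated unidirectional coupling
(strength ≥ 0.3, 50 trials) the bias sign matches ground truth in ≥ 95% of
replicates; on null data the significant fraction stays at or below Q.

## Genetics

**Kinship.** The KING-robust between-family estimator
φ̂ = (N_het,het − 2·N_opp_hom)/(N_het(i) + N_het(j)) over autosomal diploid
sites (the standard site set for this estimator), missing genotypes dropped
pairwise. Degree classes follow the power-of-two bins (> 0.354 duplicate;
0.177–0.354 first; 0.0884–0.177 second; 0.0442–0.0884 third degree;
otherwise unrelated). φ̂ is symmetric and invariant to site order; gene-drop
calibration over 20 replicates at 50k SNPs lands within ±0.01 of the
pedigree expectations (0.25 / 0.125 / 0.0625 / 0).

**Frequencies.** Carrier percentages are count/n × 100 rounded half-up to
one decimal. Allele frequency is (2·hom + het)/(2n) on autosomes; on X the
male hemizygote count contributes one allele per male, and with only male
counts available the X allele frequency is reported over the male
population.

**Screening.** Five conjunctive filters (all cases carry; controls clear;
panel membership; loss-of-function or missense consequence under the chosen
annotation model; population frequency below the cap). The frequency filter
defaults to *alternate-allele frequency* < 10%: this is the reading
consistent with a known panel variant whose heterozygote carrier rate
(14.7%) exceeds 10% while its allele frequency (9.6%) does not; carrier-rate
filtering is available as an option. "Absent in controls" means zero
alternate alleles, not merely no homozygotes. Male X genotypes are stored
haploid; diploid-coded hom-alt males are normalized to haploid with a
warning on read. Screening is monotone: lowering the frequency cap or
shrinking the effect set never adds hits.

## Reporting

2×2 proportion comparisons use Pearson chi-square without continuity
correction — recomputing the reference mirror-proportion table (62/158 vs
55/217) without correction reproduces the published p = 0.004 at three
decimals, with correction it does not. Welch's t (Satterthwaite df),
Wilcoxon signed-rank (exact null for n ≤ 25 without ties, normal
approximation with tie correction otherwise), and Spearman correlation are
all two-tailed. Case–control tests are reported uncorrected, test by test,
matching the source protocol; a Benjamini–Hochberg layer is available and
clearly labeled as an extension. Displayed p-values are rounded to three
decimals; full precision is kept in the JSON outputs.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of a `SimConfig`; each draws from its own
named PRNG stream derived from the seed, so identical (seed, config) gives
bit-identical output regardless of call order.

* **Reversal sessions** — uniform block lengths on {11..17} (only the range
  is specified; uniform is the least-informative choice), target switches to
  one of the two other targets, actor alternation every 3 trials in social
  mode. Agent policies: `optimal_social` (belief tracking with ruled-out
  sets), `win_stay_lose_switch` (repeat rewarded target, switch after any
  observed non-reward; optionally ramped in over days to model growing
  strategy pressure), `perseverative` (geometric-length runs on the failed
  target, mean 4 trials, truncated at 6 so a run always resolves within a
  block — untruncated geometric tails would leave the agent's belief stale
  at the next switch and break the closed-form trial-2 score), and
  `random`. The partner plays the optimal policy with its own lapse rate
  (default 0.1): a lapse-free partner never commits a qualifying mid-block
  choice error, and the choice-error selector would be untestable.
* **Conditioning days** — alternating 120-trial self-variable and
  partner-variable blocks; variable probabilities default to
  {0.2, 0.5, 0.75} against an invariable 0.2 (one published statement of the
  low level reads 0.25; the defaults follow the protocol section and are
  configurable). Outcomes are drawn with exclusive recipients (never both
  rewarded); licking is baseline + slope_self·P(self) −
  slope_partner·P(partner) + Gaussian noise, slopes switched on from a
  configurable day; gaze samples are categorical over configured ROI dwell
  proportions.
* **Units** — Poisson spike counts over the epoch durations, rate offsets
  per agent or slopes per probability; the planted label is stored for
  recovery testing.
* **Event LFP** — pink-noise background (50 µV scale), multiplicative
  band-limited gain in a configured window (gain < 1 simulates mu-like
  suppression), and a flat-top evoked pulse calibrated in units of the
  averaged baseline SD so the z-scored detector sees the nominal amplitude.
* **Coupled regions** — stable AR(2) contacts with one-directional lagged
  coupling between matched contacts, applied only in the stimulus window;
  instability (spectral radius ≥ 1) is rejected with a diagnostic.
* **Pedigrees** — founder allele frequencies Uniform(0.1, 0.9) per site,
  Mendelian gene dropping through duplicate / parent–offspring / full-sib /
  half-sib / first-cousin / unrelated topologies, unlinked autosomal sites.
* **Screening fixture** — a deterministic 7-male-sample genotype matrix with
  the three published case-shared variants (their printed genotypes and
  population genotype counts as metadata) plus five decoys, each failing
  exactly one filter. The non-published ref/alt bases are synthetic
  stand-ins consistent with the reported amino-acid changes.

What the generators do **not** emulate: biophysical LFP structure (volume
conduction, laminar profiles), linkage and recombination, read-level
sequencing noise, eye-tracker noise, or reaction times. Passing recovery
tests therefore demonstrates that the estimators recover the statistical
structure they assume, not that real recordings satisfy those assumptions.

## Problem sizes and numerical choices

The test suite and acceptance script run at deliberately moderate sizes —
20–50 LFP trials on 2–4 contacts, 200 units per cohort, 20 pedigree
replicates at 50k SNPs — chosen so the full suite completes in a couple of
minutes while keeping every statistical bound comfortably away from its
threshold. Tie-breaks: dopamine peak ties resolve to the earlier bin with a
flag; degenerate inputs (flat baselines, constant regressors, zero-margin
tables, no heterozygous sites) raise named errors rather than returning
NaNs silently. The Wilcoxon "exact for n ≤ 25 without ties" cut-off follows
the exact-distribution practicability limit; the chi-square test never
applies a continuity correction (see Reporting).

## Known limitations

* The bivariate ("pairwise conditional") GC reading does not condition on
  the remaining channels; fully multivariate conditioning is a non-goal.
* Spectral-domain GC and state-space GC are not implemented.
* The 1.5-SD/3-bin evoked rule is unreliable on low-SNR traces by
  construction (see above); the package reports it faithfully but the
  stricter rule is the default for synthetic validation.
* X-chromosome allele frequencies are computed over males only when female
  counts are unavailable.
* The conditioning generator emits scalar per-trial lick magnitudes;
  epoch-windowed lick traces are supported on input but not generated.
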