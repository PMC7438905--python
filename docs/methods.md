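# Methods

`restmmn` implements a two-block EEG analysis for a three-group design —
schizophrenia patients with auditory verbal hallucinations (AVH),
patients without (NonAVH), and healthy controls (HC) — together with a
synthetic cohort generator that provides ground truth for every stage.

## Resting-state coherence networks

For each channel pair (x, y) the magnitude-squared coherence

    Coh_xy(f) = |S_xy(f)|^2 / (S_xx(f) S_yy(f))

is estimated with Welch averaging: Hann window, 2 s segments
(1000 samples at 500 Hz, 0.5 Hz resolution), 50% overlap, per-segment
mean removal. The estimator was left unspecified in the emulated
protocol; these are field-standard choices, and the 0.5 Hz grid resolves
the 1 Hz lower delta edge. Spectra for all channels are computed once and
every cross-spectrum is formed from them; the per-pair result is
algebraically identical to `scipy.signal.coherence`, which the test suite
asserts. The computation runs in single precision; the error this
introduces in band-averaged coherence (~1e-5) is orders of magnitude
below estimator variance.

Coherence is averaged over the bins of five bands — delta 1–4, theta 4–8,
alpha 8–13, beta 13–30, gamma 30–60 Hz — under a half-open [low, high)
convention so bands printed with shared edges never share a bin. The
band-averaged pairwise values form a symmetric weighted matrix `w` with
zero diagonal. Resting data are analyzed without the 0.5–30 Hz ERP
filter, which would destroy the 30–60 Hz gamma band; only the estimator's
windowing applies.

A single coherence threshold T = 0.200 (the protocol's printed value,
configurable) binarizes `w`: edge iff w_ij >= T, ties included, no
self-edges. On the binary graph with N nodes:

- degree k_i = Σ_j a_ij
- triangles t_i = ½ Σ_{j,h} a_ij a_ih a_jh
- clustering coefficient C = (1/N) Σ_i 2 t_i / (k_i (k_i − 1)), with the
  local term defined as 0 when k_i ≤ 1 (the printed formula is undefined
  there)
- shortest hop distances d_ij by breadth-first search
- characteristic path length L = (1/N) Σ_i L_i with
  L_i = Σ_{j≠i} d_ij / (N − 1)

Distances are unweighted hops: the binarized matrix carries no weights.
Although the protocol asserts the threshold guarantees a connected
network, thresholded empirical matrices can disconnect. The default
`connected-pairs` policy excludes infinite distances, divides each L_i by
that node's count of reachable partners, and logs a warning; a `strict`
policy raises instead. A subject whose graph has no edges yields an
undefined L; the statistics layer drops such subjects listwise from the
repeated-measures model, with a logged count. These implementations are
verified exactly against brute-force triple enumeration, Floyd–Warshall
and networkx on hundreds of random graphs.

## MMN pipeline

The oddball block is processed in a fixed, logged order: zero-phase
4th-order Butterworth band-pass 0.5–30 Hz plus a second-order 50 Hz notch
(zero-phase preserves latencies); re-reference to the mastoid average
(TP9/TP10); epochs −200..450 ms around each onset (onset sample =
round(onset·fs); endpoints inclusive, 326 samples at 500 Hz); baseline
correction over −200..0 ms; amplitude-based artifact rejection (reject if
any scalp channel exceeds ±100 µV absolute or 150 µV peak-to-peak, both
configurable; the mastoid channels are not screened); condition averages;
deviant-minus-standard difference wave.

MMN latency is the time of the minimum of the difference wave at Fz
within 100–250 ms, earliest sample on ties; amplitude is that minimum's
magnitude, reported as a positive number (matching the convention of
reporting positive µV values for a negative component). If the window
minimum is non-negative, a `no_negative_peak` flag is set with amplitude
0. Measuring on the difference wave makes the synthetic ground truth
analytically known; it is the standard MMN definition where the emulated
protocol is ambiguous between the deviant waveform and the difference.
Ocular-artifact removal by ICA is out of scope; threshold rejection is
the testable surrogate.

## Group statistics

Summary-statistics entry points are first class because published tables
report (n, mean, SD): the pooled t, Cochran & Cox approximate t′ and the
summary-path one-way ANOVA reconstruct sums of squares from summaries
exactly, and each equals its raw-data counterpart algebraically (tested).
The Cochran–Cox test judges t′ = (m_a − m_b)/√(s_a²/n_a + s_b²/n_b)
against the weighted critical value (w_a t_a + w_b t_b)/(w_a + w_b),
w_i = s_i²/n_i, with component critical values at n_i − 1 df; the
reported p inverts that relation by bisection. A Welch–Satterthwaite df
variant is available as an option.

The mixed-design (split-plot) ANOVA partitions group (between), band
(within) and their interaction. The Greenhouse–Geisser epsilon is
computed from the pooled within-group covariance of the band scores via
the double-centered form ε = (tr S*)²/((k−1) Σ S*²), bounded in
[1/(k−1), 1]; both within-subject effects carry ε-scaled degrees of
freedom. F statistics match pingouin's mixed ANOVA exactly; the epsilon
matches pingouin's estimator applied to group-centered data (pingouin
itself pools over the total covariance, which conflates group effects
into the sphericity estimate in a mixed design). Bonferroni post-hocs
use family size m = 3 (three pairwise group contrasts) and
p_adj = min(1, m·p). Chi-squared, Kruskal–Wallis and Spearman go through
scipy (`chi2_contingency` without continuity correction, `kruskal`,
`spearmanr` with the t-approximation p, adequate at n ≈ 15).

The full battery on a cohort table: RM-ANOVA (group × band) for C and L,
one-way ANOVA for MMN latency and amplitude with Bonferroni pairwise
post-hocs, and Spearman correlations of MMN amplitude with C and with L
per band within the AVH group.

## Synthetic cohort generator

The generator emulates the study conditions rather than biophysics: no
head model, volume conduction or dipole sources.

**Resting model.** Each channel sums, over the five bands, a shared
band-limited source and a private one:

    x_c(t) = Σ_b a_b [ √κ_b g_c s_b(t) + √(1−κ_b) p_cb(t) ] + n_c(t)

Band-limiting uses the squared-magnitude response of the analysis bands'
own 4th-order zero-phase Butterworth filters, synthesized directly in the
frequency domain (distributionally identical to filtering white noise,
at a fraction of the cost). κ_b ∈ [0, 1) is the band coupling: κ = 0
gives independent channels (coherence at the Welch bias floor ≈ 1/M_eff);
κ → 1 without sensor noise drives in-band coherence to 1; in between the
expected coherence increases monotonically with κ (tested over
κ ∈ {0, 0.2, 0.5, 0.8} across 10 seeds). Fixed per-channel gains
g_c ∈ [0.7, 1.3] spread the pairwise coherence distribution across the
0.200 threshold so that binarized density — hence C and L — responds
smoothly to κ. Band amplitudes a_b (20/12/15/6/3 µV for delta–gamma)
sketch a 1/f-like resting spectrum; they cancel out of coherence. White
sensor noise is 1 µV by default. The default duration is the emulated
7-minute resting block at 500 Hz.

**Oddball model.** 540 standard (100 ms) and 60 deviant (50 ms) stimuli,
a uniform random permutation ("delivered randomly" read as unconstrained;
a minimum-separation option exists but defaults off), onsets spaced by
stimulus duration + 500 ms ISI, 1 s lead-in so no epoch is clipped. Both
conditions receive the same biphasic base template (N1-like trough at
100 ms, P2-like peak at 200 ms); deviants add a negative Gaussian bump of
depth `mmn_amplitude_uv` (default width σ = 35 ms) at `mmn_latency_ms`,
spatially weighted 1.0 at Fz, 0.7 at F3/F4, 0.3 fronto-centrally, 0
posteriorly (fronto-central MMN maximum). Because both conditions share
the base template, the difference wave is analytically the injected bump.
Trial noise is Gaussian white, default 1.5 µV per sample: chosen so the
single-subject measurement error of the amplitude (SD ≈ 0.08 µV, bias
under 1%) is negligible against the between-subject dispersion the cohort
model draws (SD 1.3–1.7 µV), i.e. the reported group SDs are modeled as
true amplitude variation, not measurement noise. An optional 1/f noise
component exists (default off). Blink-like transients (±250–400 µV,
σ = 40 ms, centered 0–150 ms post-onset, frontal maximum) are injected
per trial with probability `artifact_rate`; the emulated protocol reports
no rejection counts, so the rate has no empirical anchor; the default of
0.05 was chosen once as a plausible clean-cohort figure.

**Cohort model.** Three groups of 15. Per-subject MMN amplitudes are
drawn from the group's (mean, SD) — 2.93 ± 1.684 (AVH), 4.48 ± 1.290
(NonAVH), 4.56 ± 1.305 (HC) µV — truncated at 0; latencies from
179.2 ± 12.7 / 177.4 ± 14.8 / 177.2 ± 16.4 ms, clipped inside the search
window. Group coupling defaults: AVH elevated most on delta and beta
(0.62), less on theta/gamma (0.59), barely on alpha (0.52); both control
groups 0.50 on all bands — mirroring the reported contrast pattern
(higher AVH clustering on delta/beta, shorter path length broadly, alpha
indistinct). A per-subject latent trait z ~ N(0,1) shifts all band
couplings (SD 0.06, clipped to [0.02, 0.95]) and correlates with the
subject's amplitude draw (r = 0.85). The trait correlation and coupling
spread were calibrated once, on generator ground truth, so the induced
within-AVH Spearman correlation between measured amplitude and C lands
near the reported ≈ 0.6 after estimator and measurement dilution; they
were not revisited afterwards. Every drawn parameter is recorded in the
cohort manifest. Per-subject seeds derive from the master seed via
`numpy.random.SeedSequence.spawn`, so any subject regenerates
independently.

**What the generator does not model** — and therefore what passing tests
do not establish about real data: volume conduction and reference-field
spread (real scalp coherence is inflated at short distances), non-white
and non-stationary background EEG, ocular/muscle artifact morphology
beyond a stereotyped blink, latency jitter across trials within a
subject, and any true neural coupling mechanism. The end-to-end tests
show the pipeline recovers the structure the generator encodes, not that
the neurophysiological claims hold.

## Numerical choices and degenerate inputs

- Event onsets are seconds; sample conversion rounds to nearest (2 ms
  grid at 500 Hz). Measured latencies are grid-quantized.
- Coherence values are clipped to [0, 1] against round-off only.
- Welch estimation refuses single-segment input (coherence would be
  identically 1).
- Binarization at T = 1 keeps only exact-1 weights; ties at any T map to
  edges.
- k_i ≤ 1 ⇒ local clustering 0; edgeless graph ⇒ L undefined (NaN under
  `connected-pairs`, error under `strict`).
- Peak ties resolve to the earliest sample; a non-negative window minimum
  yields amplitude 0 with a flag rather than a negative "magnitude".
- Degenerate zero-variance inputs raise, except the all-identical ANOVA
  (F = 0, flagged) and all-tied Kruskal–Wallis (H = 0, warned).
- Amplitude draws truncate at 0, adding a small analytic positive bias
  (+0.028 µV at 2.93 ± 1.684) that the Monte-Carlo recovery test accounts
  for.

## Validation problem sizes

The test suite exercises full-scale designs wherever cheap (600-trial
oddball sessions, 19-node graphs, 1000-replicate null calibrations). The
20-seed end-to-end cohort check runs the full 45-subject, three-group
design with the resting block at 210 s rather than 420 s; at 210 s the
coherence estimator still averages ~200 Welch segments, leaving its
variance far below the between-group contrast, and the recovered pattern
is unchanged. Brute-force graph oracles cover 500 random graphs at N ≤ 6
and 200 each at N ∈ {8, 12, 19}.

## Known limitations

- The Cochran–Cox p-value is defined implicitly through the weighted
  critical value; it is a test-inversion p, not a tail probability of a
  single reference distribution.
- Under `connected-pairs`, L values from graphs with different
  connectivity patterns are not strictly comparable (each averages over
  its own reachable pairs).
- The generator's coherence is controlled per band through a single
  shared source; cross-band coupling structure (e.g. phase-amplitude
  relations) is absent.
- EDF support is read-only and assumes uniform sampling across channels.
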