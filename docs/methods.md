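# Methods

This note documents the models implemented in mtxkit, the conventions
and default parameters they use, what the synthetic generators do and do
not emulate, and the numerical choices that matter.

## Peptide masses and ISD fragments

Residue masses are computed from hard-coded elemental formulas with
CODATA monoisotopic nuclide masses and IUPAC 2021 standard atomic
weights, so the arithmetic is auditable and reproduces printed
"calculated mass" values from standard protein tools. A peptide's
neutral mass is Σ residues + H2O − 2·H per disulfide bond; only the
*count* of disulfides affects mass, so cysteine pairing is deliberately
not modeled. Linear-mode MALDI masses of ~5 kDa peptides are treated as
neutral average masses and compared at 1 Da tolerance.

In-source decay with a 1,5-DAN-type matrix cleaves N–Cα bonds to give
c- and z-type ions. Conventions used (monoisotopic, singly protonated):

* c_i = Σ residues(1..i) + NH3 (+ proton for m/z)
* z_j = Σ residues(n−j+1..n) + H2O − NH3 + 2 H — the z+1 ("z-dot + H")
  species that dominates ISD spectra.

These satisfy the complementarity c_i + z_(n−i) = M(reduced) + 2 H at
every cleavage site, which the test suite asserts. Fragments are
reported at reduced-chain masses; charge states above 1+, isotope
envelopes and PTMs other than disulfides are out of scope.

Peak annotation is greedy nearest-mass within a user tolerance (ties:
smaller |Δm|, then lower fragment index, c before z), one ion per peak
and one peak per ion. Coverage is the fraction of the n−1 backbone
bonds supported by at least one matched ion; `terminal_span` is the
longest run of consecutively supported bonds from either terminus —
the length (in residues) of the terminal fragment the spectrum reads
through. Substitution inference brute-forces all 380 ordered residue
pairs against |Δm|; note that Leu/Ile are exactly isobaric and His−Leu
≈ His−Ile ≈ 23.98 Da, so a 24 Da shift always returns both.

Pairwise identity uses a global alignment with match 1, mismatch 0,
linear gap −1 (Biopython's `PairwiseAligner`); identity = identical
columns / alignment length × 100.

## Microtubule dynamic instability

### Generator

Tracks are simulated from a three-state continuous-time Markov chain
over {growth, shortening, pause} with constant speeds +v_g, −v_s, 0 and
six transition rates (events/min). Simulation is exact (Gillespie):
exponential waiting times in each state, then resampling of the
piecewise-linear length history onto the observation grid (default 2-s
intervals for 1 min, the usual live-cell tracking protocol). The hidden
state at each sample time and the full transition log are retained as
ground truth. Microtubule length cannot be negative: a shortening
excursion reaching zero triggers a forced rescue to growth at the
crossing time, logged with `forced=True`, so recovery tests can exclude
boundary-affected tracks. Measurement noise is i.i.d. Gaussian on
length (default SD 0.05 µm — a fixture convention; real tracking noise
is correlated and anisotropic, which is not modeled).

Default chain parameters (v_g = 25.9, v_s = 31.1 µm/min; rates 5.0/9.0
from G, 7.0/12.0 from S, 5.3/3.8 from P, events/min) give a stationary
occupancy of ≈ 29/18/53 % in G/S/P, a rescue rate of 19/min of
shortening time and a catastrophe rate of ≈ 4.2/min of growth+pause
time — the order of magnitude of highly dynamic epithelial-cell
microtubules. They are fixture conventions, not claims about any
particular cell line. The dosed fixture conditions slow both speeds and
lengthen pauses so dynamicity falls dose-dependently.

### Analysis

Segmentation classifies sample intervals by instantaneous rate at a
±`min_rate` threshold (default 2 µm/min), merges same-direction runs,
and accepts a run as growth/shortening only if its net excursion clears
`min_excursion` (default 0.5 µm) *and* its least-squares slope clears
`min_rate`; everything else is pause, and adjacent same-phase runs are
merged. The result is an exact partition of the track (phase durations
sum to track duration; segment length changes sum to the net change).
The thresholds are the standard desk conventions of the
dynamic-instability literature and are exposed as configuration keys.

Statistic conventions (the table cannot disambiguate them, so they are
fixed here): catastrophe frequency per minute is normalized by time in
G + P, rescue frequency by time in S; per-µm frequencies divide by
total length grown (catastrophes) or shortened (rescues); dynamicity is
(length grown + length shortened)/total time in µm/min. Point estimates
pool events and time over all tracks of a condition; SEMs are computed
over per-track values with n = number of microtubules. Quantities whose
denominator is empty (e.g. rescue frequency with no shortening time)
are reported as NaN, never silently zero. Percent changes
(treated − control)/control are rounded half away from zero to integer
percent; p-values are two-tailed Welch t-tests on per-track values
(Mann–Whitney optionally), coded A/B/C at 0.001/0.01/0.05.

### What the recovery study shows

The parameter-recovery acceptance test simulates 200 noiseless tracks
of 60 s on a 50 ms grid (not the 2-s protocol grid) with a 0.05 µm
excursion threshold and recovers ≥ 99% of hidden per-sample states,
both speeds within 2%, and both per-minute transition frequencies
within 3 Monte-Carlo SE of the chain's stationary-flux values (oracle:
eigen-decomposition of the generator). Fine sampling is an analysis
choice, not a tweak: with phases lasting only a few seconds, a 2-s grid
cannot resolve phase boundaries to 1% of samples — a genuine limitation
of sparse live-cell tracking that applies to real data too. At the 2-s
grid the aggregate statistics remain unbiased at the order-of-magnitude
level, but per-sample state assignment is not a meaningful target
there. Absolute statistic values from real cells are consequently not
reproduced by simulation — only printed *ratios* (percent changes) are
checked as arithmetic, and those reproduce exactly.

## Turbidity metrics

Curves are summarized without fitting a kinetic model (nucleation–
elongation modeling is out of scope): baseline = mean of the first 5%
of points, plateau = mean of the last 10%, lag = first time the
smoothed signal (centered moving average, window 5) exceeds baseline +
10% of the amplitude, vmax = maximum finite-difference slope of the
smoothed signal. Lag is undefined (NaN) when the amplitude does not
exceed 3× the baseline noise SD — which also covers exactly flat
curves. All fractions and the window are configuration keys. The
comparison's plateau ratio uses amplitudes (plateau − baseline) so it
is invariant to baseline offsets and exactly linear in curve amplitude.

The generator is a Gompertz sigmoid parameterized *directly* by its
10%-amplitude crossing time, so the generating lag and the measured lag
coincide by construction on noiseless data (recovered within one sample
interval; plateau within 1%). Caveat: the lag estimate assumes the
baseline window precedes the rise; lags shorter than the 5% baseline
window bias the baseline upward. The empirical lag subsumes the
temperature-ramp nucleation delay of the real assay; no temperature
model is included.

## ITC one-set-of-sites model

Concentrations after each injection of volume v into active volume V0
follow the perfusion bookkeeping [M] ← [M](1 − v/V0),
[X] ← [X](1 − v/V0) + [X]_syr(v/V0). The bound site fraction is the
physical root of the one-site quadratic,
θ = (a − √(a² − 4r))/2 with r = [X]/(N[M]), a = 1 + r + 1/(N K_a [M]),
which lies in [0, 1] for all physical inputs (the discriminant
(1 − r)² + c² + 2c(1 + r) is non-negative; a negative value can only
arise from non-finite inputs and raises). The differential heat of
injection i is q_i = ΔH·(B_i − B_{i−1}(1 − v_i/V0)) with bound moles
B_i = N θ_i [M]_i V0 — the displaced-volume correction of the previous
cumulative heat. Heats are in µJ, ΔH in kJ/mol, R = 8.314 J/mol/K,
T defaults to 293.15 K, and the default schedule is 55 µM cell,
2.2 mM syringe, 19 × 2 µL, 200 µL cell (a typical active volume for a
modern perfusion instrument; the value only scales the heat axis).

Fitting estimates (N, log10 K_a, ΔH) by least squares (lmfit) from a
multi-start grid — K_a over 10³–10⁸ M⁻¹ × N over 0.5–4 — because
one-site fits are multimodal at low c-value (c = N·K_a·[M]); the best
chi-square start wins. Asymptotic standard errors come from the
Jacobian, with K_a's obtained from log10 K_a by the delta method. The
c-value is reported and flagged outside [1, 1000]. The first injection
can be excluded from the residuals (syringe-tip diffusion convention)
while keeping its concentration bookkeeping. ΔG = −RT ln K_a,
ΔS = (ΔH − ΔG)/T and K_d = 1/K_a are derived, and ΔG = ΔH − TΔS holds
to machine precision by construction. Noiseless synthetic isotherms are
recovered to better than 0.1% in all three parameters; at 1% heat
noise the median K_d error over 50 seeds is below 10%. The fixture
truth uses N = 2 and K_d = 5.3 µM with a conventional ΔH of
−40 kJ/mol (its magnitude is a fixture choice; only the exothermic
sign is meaningful). Two-site, sequential and competitive models, raw
power-trace integration and global multi-experiment fits are out of
scope.

## Pipeline and formats

All data travel as small plain-text files (CSV with "." decimals,
FASTA, JSON manifests); readers validate headers and numeric content
and report offending columns and line numbers. The YAML pipeline config
is versioned and fail-fast (unknown keys are errors). Reports are
deterministic for a fixed config and seed; wall-clock timestamps appear
only in the run log. The rendered dynamics table is written both as
formatted text and as a full-precision (`%.17g`) CSV whose parse (with
round-trip float precision) recovers the aggregates exactly.

## Problem sizes

Default test and acceptance workloads are desk-scale: 200 tracks ×
60 s at 50 ms for the recovery study, 54/44/44/68 tracks at 2 s for the
fixture conditions (mirroring a typical per-condition tracking yield),
19-injection isotherms with 50-seed Monte-Carlo repeats, and 361-point
turbidity curves. The full suite runs in well under a minute apart from
the Monte-Carlo ITC study (a few seconds per 50 fits).

## Known limitations

* The track generator has constant speeds per phase, exponential phase
  durations and i.i.d. Gaussian noise; real microtubules show
  age-dependent catastrophe, correlated tracking noise and drift, so
  passing recovery tests demonstrates correctness of the estimators
  under the stated model, not robustness to those effects.
* Segmentation thresholds are conventions; absolute phase statistics
  depend on them (and on the sampling interval), which is why only
  ratio/percent-change arithmetic is checked against printed values.
* The ISD generator emits singly charged, unit-resolution sticks with
  uniform intensities; no isotope envelopes, noise peaks or matrix
  adducts.
* Average masses depend on the atomic-weight table at the 0.05 Da
  level for a 5 kDa peptide (e.g. pyteomics' table differs by
  ~0.04 Da); monoisotopic arithmetic agrees with pyteomics to 10⁻⁵ Da.
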