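# Methods

## The binding model

Human neuroglobin rests hexacoordinate: the heme Fe³⁺ is ligated by the
proximal His96 and the distal His64. An external ligand L (cyanide
throughout) binds only through the transient pentacoordinate form:

    hexa  ⇌(k₋H / k_H)  penta  ⇄(k_on,L·[L] / k_off,L)  penta·L

`ngbkin.kinetics` implements this scheme as mass action for an arbitrary
mixture of protein species sharing one ligand pool. A species is one heme
orientation (the A or B isomer; the two orientations differ by a 180° flip
about the α–γ *meso* axis, are chemically distinct, and interconvert far too
slowly to matter on the binding timescale) within one protein state (WT_ox,
WT_red, C120S_ox, C120S_red, TM — wild type and C120S with the Cys46–Cys55
disulfide oxidized/reduced, and the cysteine-free triple mutant).

Assumptions: well-mixed solution; no isomer interconversion; no HCN/CN⁻
ionization chemistry (the supplied k_on,L is the apparent rate constant at
the working pH); ligand is conserved (depletion by binding is the only
sink). Internal units are molar and seconds; user-facing times are minutes
and concentrations carry explicit unit suffixes — conversion happens only at
I/O boundaries.

### Rapid pre-equilibrium limit

When k_on,L·[L] ≪ k_H, k₋H, histidine exchange equilibrates between binding
events and the observed kinetics are pseudo-first-order with

    k_obs = k_on,L / (1 + K_H),    K_H = k_H/k₋H .

`effective_kobs` implements exactly this; it raises on k₋H = 0 (infinite
K_H) rather than returning zero. The experiments determine only the
apparent pair (k_obs, K_d); no microscopic histidine-exchange rates are
known for any state. `collapsed_rates` therefore reconstructs microscopic
rates by *choice*: k₋H = 1 s⁻¹ and K_H = 9 by default (90 % hexacoordinate
at rest — a plausible resting bias for a hexacoordinate globin, and deep in
the rapid pre-equilibrium regime for every measured rate), with
k_on,L = k_obs·(1+K_H) and k_off,L = K_d·k_obs. Any K_H ≥ 0 reproduces the
same observable kinetics in this regime; the choice only fixes the
(unobservable) hexa/penta split.

### Two analysis conventions, kept separate

The published analysis converts a fitted time constant via 1/T = k_obs[CN⁻]
and reads equilibrium free fractions against the *total* ligand
concentration. That ignores (a) ligand depletion (up to ~20 % here: 100 µM
protein binding from a 500 µM pool) and (b) the k_off contribution to the
observed relaxation rate (1/T = k_obs[L] + k_off exactly). The package
implements both:

- mode="paper" — the published convention, used for all headline numbers:
  observed rate k_obs·[L]_total, plateau from the excess-ligand isotherm
  f_free = K_d/(K_d + [L]_total), K_d = f/(1−f)·[L]_total. This mode is
  exactly self-inverse: simulating and refitting recovers the generating
  constants in the noiseless limit.
- mode="reversible" (ODE) — full mass action with depletion; for fits,
  k_obs = (1−f)/(60·T·[L]) which follows from 1/T = k_obs[L] + K_d·k_obs and
  K_d = f/(1−f)·[L]. Reports carry a `mode` field naming the convention.

The two agree within 1 % whenever k_off·T ≪ 1 and depletion is small; the
difference quantifies the approximation error of the published convention.

### Integration and equilibrium

The ODE system is integrated with SciPy's LSODA at rtol 1e−8 / atol 1e−12 M
(stiffness arises from fast His exchange against slow ligation), which holds
per-species protein totals and total ligand conserved to better than 1e−8
relative. The coupled equilibrium with ligand depletion solves

    L + Σᵢ totᵢ·L/(L + K_d,i) = L_total

for free ligand by bisection on [0, L_total] to 1e−10 relative tolerance;
the left side is strictly increasing in L, so the root is unique and no tie
break is needed. Degenerate inputs (zero ligand, zero protein) return exact
trivial states. Air reoxidation of reduced cysteines is available as a
ligation-state-preserving first-order red→ox transfer (default τ = 60 h,
off by default): it is a slow experimental confound, not part of the binding
scheme.

## Synthetic spectra

`generate_experiment` emulates the real-time experiment: 100 µM protein
(A:B = 1:2), 500 µM KCN at t = 0, one spectrum every 20 min, for the
duration of the schedule. Peaks are pure Lorentzians (paramagnetically
broadened lines; default fwhm 0.15 ppm — no linewidths are published, so
this is an assumption, configurable per peak). Met-state peaks track the
unbound protein (hexa + penta) of their isomer, cyanomet peaks the bound
form, with volume = response × concentration. Default met shifts are the
assigned methyl positions (35.4/34.5 ppm oxidized, 36.7/35.4 reduced; the
C120S spectra are indistinguishable from WT; the TM positions 36.5/35.2 are
nominal). Default cyanomet shifts (19.5/18.5 ppm) are invented placements
inside the 18–20 ppm window that is free of met resonances — for the
pipeline only the labels matter. Note the deliberate cross-state overlap
(oxidized M8B and reduced M5A both at 35.4 ppm): quantification windows are
chosen per state, not auto-resolved.

Noise is additive i.i.d. Gaussian with SD equal to 2 % of the tallest
noiseless peak height in the first spectrum (no SNR is published; this
default is an assumption chosen to look like the real data quality, and is
configurable). Identical seeds produce bit-identical spectra. The ppm axis
spans 10–40 ppm at 0.01 ppm spacing — both diagnostic windows; the full
acquisition width would add nothing.

What the generator does *not* emulate: pulse-sequence effects, relaxation
and chemical exchange, water suppression artifacts, baseline roll, field
drift, or shift prediction from structure. Passing recovery tests therefore
demonstrate that the quantification-and-fitting chain is unbiased and
well-calibrated for Lorentzian peaks with white noise — not that it is
robust to every artifact of real spectra.

## Quantification and fitting

`quantify_peak` fits one Lorentzian plus a constant baseline inside a
window (default 0.5 ppm full width) around the expected shift and returns
the analytic volume; if the least-squares fit fails it falls back to
baseline-subtracted trapezoidal integration and flags it. The line position
is constrained to ±0.05 ppm of the expected shift — the resonance position
is known, and letting the center roam makes the fit chase noise spikes once
a peak has decayed away. For series quantification
(`timecourses_from_spectra`) the shape (center and width) is fitted once on
the reference spectrum where the resonance is strongest (first spectrum for
met decays, last for cyanomet buildups) and then held fixed, leaving only
volume and baseline free: the volume estimate stays linear and well
conditioned down to zero signal. The 0.5 ppm default window balances
neighbor-line overlap bias (the met methyls sit 0.9 ppm apart; worst-case
noiseless bias < 0.5 % on the recovered time constant) against baseline
leverage.

`fit_monoexponential` fits I(t) = plateau + (I₀−plateau)·exp(−t/T) by
least squares; initial guesses come from the mean of the last 10 % of
points (plateau), the first point (amplitude) and a log-linear regression on
the plateau-subtracted data (T). Constant series and fits with vanishing
amplitude or non-positive T are rejected as errors. Decays are normalized
to the t = 0 intensity before fitting, matching the published convention;
the equilibrium free fraction is read from the fitted plateau/I₀ ratio, not
the last raw point (noise robustness). A decay whose plateau stays below
5 % of the initial intensity is treated as complete binding (no K_d/k_off:
a plateau that small is indistinguishable from zero at the default noise).
Decay and buildup curves of one isomer are fitted independently; when both
exist the met decay takes precedence for the reported constants.

`bootstrap_uncertainty` resamples residuals around the fit with the
degrees-of-freedom inflation √(n/(n−3)) and builds a studentized
(bootstrap-t) 95 % interval for T; percentile intervals are the fallback
when standard errors are unavailable (noise-free data). Replicate failures
are counted and flagged above a 20 % failure rate.

## Study conditions and the recovery study

The generator defaults *are* the study conditions: 100 µM protein split 1:2
(A:B), 500 µM KCN, 20-min acquisition interval, 2 % noise, and the measured
per-state time constants (19/97, 127/265, 18/119, 138/255, 262/223 min)
with the published K_d where binding was incomplete. The acquisition length
defaults to four time constants of the slower isomer of the state, rounded
to the schedule (e.g. 400 min for WT_ox, 1060 min for WT_red) — long enough
to pin the plateau without inflating runtimes. `recovery_study` re-runs the
full generate → quantify → fit chain across seeds (sub-seeds derived from a
master seed via SHA-256, 31-bit) and compares median recovered time
constants with the generating values; at these conditions every
state/isomer median lands within 5 % of truth over 25 seeds.

## Known limitations and documented inconsistencies

- The published free fractions for the reduced wild type (42 % of the A
  isomer and 24 % of the B isomer unbound at equilibrium) contradict the
  published K_d ordering: K_d,A = 153 µM < K_d,B = 316 µM implies A is
  *more* bound, and the isotherm gives ≈23 % free A and ≈39 % free B.
  Inverting the stated percentages yields K_d values close to the printed
  ones with the isomer labels swapped. The package derives plateaus from
  the K_d values and takes no position on which statement is in error.
- Printed rounding of the slowest rate constants is inconsistent at the
  second decimal (T = 265 min gives 0.1258, printed 0.12; T = 255 min gives
  0.1307, printed 0.13); comparisons use only rows where standard rounding
  reproduces the printed value.
- The pentacoordinate on-rate estimate (6.7 × 10³ M⁻¹ s⁻¹) implies a K_H
  that is never stated; it cannot be reproduced from the published data and
  is excluded.
- Bootstrap intervals for a nonlinear time constant are approximate;
  coverage of the 95 % interval is near but slightly below nominal at the
  default noise level.
- The triple-mutant B isomer (only ~9 % of the signal decays) sits at the
  information limit of the default noise level; its per-seed T estimates
  scatter by ~20 % even though the across-seed median is accurate.
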