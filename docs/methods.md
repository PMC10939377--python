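# Methods

## The model

`kincoex` simulates a well-mixed batch community of two kin strains — a
slow-growing, antibiotic-detoxifying **cooperator** (A) and a fast-growing,
antibiotic-sensitive **cheater** (B) — optionally joined by a third,
non-kin **regulator** species (C), under a pulsed antibiotic perturbation
in serial-dilution culture.  The dynamics are a Lotka–Volterra competition
system with an optional Allee factor and a time-windowed, density-dependent
death term.  For member X with maximum per-capita growth rate r_X, Allee
constant a_X, interaction coefficients α_Xj and death rate μ_X:

    dX/dt = r_X · X · [ X/(a_X + X) · (1 − X) − Σ_j α_Xj · X_j ] − μ_X · X

Abundances are fractions of a carrying capacity K = 10⁹ CFU/ml, the
saturation density of the experimental cultures the model emulates, so the
relevant inoculum range 10⁵–10⁹ CFU/ml maps to normalized total densities
D ∈ [10⁻⁴, 1].  Positive α are inhibitory (they enter with a minus sign);
negative α are facilitative.  Death rates act only during an absolute-time
antibiotic window, by default hours [72, 96) — the fourth day of a
week-long run, matching a pulse applied on day 3 of culture.  A negative
death rate is a hormetic growth boost: the detoxifier grows *better* in
sub-inhibitory antibiotic.

### Default parameters

| symbol | meaning | default | units |
|---|---|---|---|
| r_A | cooperator max growth rate | 0.5 | h⁻¹ |
| r_B | cheater max growth rate | 0.75 | h⁻¹ |
| α_AB | inhibition of A by B | 1.9 | – |
| α_BA | inhibition of B by A | 1.75 | – |
| a_A, a_B | Allee constants | 0 | – |
| μ_A | cooperator in-window rate | −0.6 (boost) | h⁻¹ |
| μ_B(D) | cheater in-window kill | max(0, 1.0 − 5.0·D) | h⁻¹ |
| μ_C | regulator in-window rate | 0.8 / −0.3 / 0 by phenotype | h⁻¹ |
| window | antibiotic pulse | [72, 96) | h |
| K | carrying capacity | 10⁹ | CFU/ml |

The growth-rate assignment (cooperator 0.5, cheater 0.75) follows the
measured biology: the cheater is the faster strain.  The three regulator
phenotypes model a strain that is killed by the antibiotic (sensitive,
μ_C = 0.8), boosted by binding it (detoxifying, μ_C = −0.3), or unaffected
(intrinsically resistant, μ_C = 0).

### The cheater's density-dependent kill rate

The cheater's in-window death rate declines linearly with the run's initial
total density D — more detoxifying biomass clears the drug below the
cheater's inhibitory concentration sooner — and is clamped at zero:
protection can neutralize the kill but never turn it into growth.  Neither
the slope nor the intercept of this line is an independently measured
quantity; the package calibrates the two constants to the observed
phenomenology:

* **μ_B,max = 1.0 h⁻¹** (kill with no protection).  The unprotected kill
  must exceed the cheater's maximum growth rate (0.75 h⁻¹), otherwise an
  unprotected cheater population still grows through the pulse, which
  contradicts the observed single-cycle crash of the sensitive strain at
  low inoculum.
* **D_protect = 0.2** (2×10⁸ CFU/ml, complete protection).  With partial
  protection across the experimental inoculum range, the community's
  post-pulse dominance switch lands at ≈2×10⁷ CFU/ml, the experimentally
  observed switching scale (10⁷–10⁸ CFU/ml), and extending the pulse to
  48 h removes cheater dominance at every density, as observed.

Both constants are exposed in the model factories and the config schema.
Whether μ_B should depend on the total inoculum or only the cooperator's
share of it is not identifiable from the emulated data; the total is used.

## The serial-dilution protocol

Runs alternate 24-h growth cycles with instantaneous dilution events.  Two
dilution modes: `to_fixed_total` rescales the community back to the initial
total density D, preserving composition exactly (the mode used for all
phase-diagram work — it makes every cycle start at the same bottleneck);
`by_factor` divides every member by a fixed factor (default 10), emulating
the experimental daily transfer.  The antibiotic window is gated on
absolute time, so with default settings the pulse covers exactly the fourth
cycle.  Default runtime is 7 cycles (168 h); the classification always
reads the final cycle.

### Integration

Cycles are integrated with LSODA (rtol 10⁻⁸, atol 10⁻¹²), split at
antibiotic-window edges so the solver never steps across the death-rate
discontinuity.  Halving the tolerances moves final-cycle abundances by
less than 10⁻⁶ (tested).  Dense output at 0.1 h is produced for single
runs; sweeps request cycle boundaries only.

### The extinction floor, and where it does not apply

Single-protocol runs (the experiment-emulating mode) clamp any member
falling below an extinction floor ε = 10⁻⁹ normalized — about one cell per
ml at K = 10⁹ — to exactly zero, implemented as terminal root-crossing
events during integration (so the clamp does not depend on the output
grid) and applied again after each dilution.  This reproduces the
experimental observation that the cooperator is driven extinct within
three growth cycles of antibiotic-free co-culture.

Phase-diagram sweeps, by contrast, integrate the **continuum** model with
no floor.  The reason is structural: the low-density dominance switch
works through cooperator rebound during the pulse — the cooperator is
competitively suppressed to densities far below one cell per ml by the
time the pulse arrives, and then grows back through the window while the
unprotected cheater is killed.  A floor at the single-cell scale absorbs
the cooperator before day 4 at *every* density in the swept range, erasing
the switch entirely.  The phase diagrams therefore classify the
deterministic flow of the equations, exactly as an ODE solver with no
extinction handling would produce them; the floor remains config-exposed
in both modes.  This is a real tension between the continuum model and
cell-scale realism, not a numerical choice: the model's headline
phase behavior only exists in the continuum reading, and readers should
treat sub-cell abundances in sweep trajectories as a modeling idealization.

## Outcome classification

The operational rule: over the **final cycle** of a run, compute each
member's fractional change between the post-dilution cycle start and the
pre-dilution cycle end.  If any member declined by strictly more than 20%
(with 10⁻¹² slack for round-off at the boundary), or is extinct, the
community is *not* coexisting; an all-dead community is a *collapse*;
otherwise the run is *coexistence*.  Exclusion outcomes carry the dominant
(most abundant) member, ties broken to the lowest index.  The decline is
measured per cycle rather than against the run's global inoculum because
under dilution-to-fixed-total an end-of-cycle population compared with the
diluted inoculum registers as growth almost everywhere (measured: with the
global baseline fewer than 1% of swept cells ever classify as coexisting).
The global baseline remains available (`baseline="global_initial"`).

## Phase diagrams

* **Two-member sweep** — grid over (cheater growth rate, initial total
  density D); each cell runs the full 7-cycle pulsed protocol and is
  labelled by the dominant member of the final pre-dilution state (the
  coexistence category is recorded alongside).  At the cheater's native
  rate, the dominant member switches from cooperator to cheater exactly
  once along a 25-point log-spaced density axis 10⁻⁴–10⁻¹, at ≈2.4×10⁷
  CFU/ml.
* **Three-member sweep** — grid over the regulator's reciprocal
  interaction coefficients (α_AC, α_BC), set symmetrically
  (α_CA = α_AC, α_CB = α_BC), at a regulator growth rate matched to the
  cheater's, for each antibiotic phenotype; cells are labelled with the
  20%-decline rule and annotated with the sign-pattern regime
  (competition +/+, mutualism −/−, exploitation mixed, neutral boundary
  when a coefficient is exactly 0).  Default conditions: 7 cycles at
  D = 0.03 from equal proportions.  A 5-cycle variant classifies the first
  post-pulse cycle, where rebound transients dominate; measured
  consequence: coexistence cells found at 5 cycles rarely persist when the
  run is extended (1/12 sampled cells, versus 8/12 at 7 cycles), so the
  settled 7-cycle horizon is the default.

### What the three-member geography actually looks like

In the swept conditions, coexistence concentrates in the competition
quadrant (98% of cells across the three phenotypes) in a narrow band along
the ridge where the regulator's realized pressures on the two kin strains
balance.  Because the interaction term in the equations is weighted by the
member's growth rate, the balanced ridge sits near
r_B·α_BC ≈ r_A·α_AC rather than α_BC = α_AC: at equal coefficients the
faster cheater already feels the stronger realized pull.  Consequently
"the regulator must pull the cheater harder" holds in realized-pressure
terms (measured: ~87% of coexistence cells satisfy
r_B·α_BC > r_A·α_AC) but not coefficient-by-coefficient (only ~13%
satisfy α_BC > α_AC strictly; the band includes the diagonal).  Isolated
knife-edge cells — declines within ~1% of the 20% threshold — can appear
just outside the competition quadrant; one such cell exists at the default
resolution.  Removing the pulse destroys coexistence in ~89% of the
band's cells; the exceptions are strong-competition cells that fall into
cyclic dominance, where the final classified cycle happens to catch all
members on a rebound.  These measurements are recomputed by
`scripts/acceptance.py`.

A further caveat: in much of the band the cheater's between-pulse
abundance is far below one cell per ml in continuum terms — coexistence
there is a property of the equations, not of a countable population.  The
cell used for synthetic-data validation (α_AC = α_BC = 0.125) is chosen
from the physically meaningful part of the band, with all members above
10⁶ CFU/ml at every bottleneck.

## Empirical estimators

* **Effective growth rate** from an OD₆₀₀ curve: assuming exponential
  growth from the initial OD to a threshold (default 0.5 cm⁻¹),
  rate = log₁₀(OD_threshold/OD_initial)/T_threshold, in decadal-log units
  per hour.  T_threshold is the first crossing, linearly interpolated
  between bracketing samples; wells that never cross are censored and
  excluded from group fits (with counts reported).  A well already at the
  threshold at time zero has no defined rate and is an error (flagged, not
  estimated, in the table interface).
* **CFU density**: colonies × dilution factor / plated volume, with a
  below-detection flag at zero colonies and a 3–300 colony plausibility
  flag (advisory only).
* **Linear fits**: ordinary least squares with R²; degenerate constant
  response returns slope 0, R² 0.
* **Rank-sum comparison**: two-sided Wilcoxon/Mann–Whitney, exact null for
  groups ≤ 12 without ties, tie-corrected normal approximation otherwise;
  all-identical data is degenerate with p = 1 and a warning.

## Synthetic data

The generators emulate the statistical structure of the emulated assays —
and only that:

* **OD curves**: logistic growth (closed form) from each inoculum, with a
  constant extra death/boost rate in antibiotic wells, converted to OD via
  OD 1.0 ≡ 10⁹ CFU/ml and perturbed by i.i.d. multiplicative lognormal
  noise (default σ = 0.02).  The ground-truth table carries both the
  intrinsic rate and the noiseless-limit effective rate (the estimator
  applied to the noiseless sampled curve), which is the recoverable target.
  The antibiotic effect is constant over the assay because a monoculture
  of a non-detoxifying strain never clears the drug below its inhibitory
  concentration.
* **Co-culture counts**: protocol snapshots converted to expected plated
  cells at an automatically chosen decadal dilution targeting 30–300
  colonies, with Poisson counting noise.
* **Antibiotic clearance**: concentration declining linearly at a rate
  proportional to detoxifier density (order-of-magnitude default
  10⁻⁶ µg·l⁻¹·h⁻¹ per CFU·ml⁻¹), floored at zero, with additive Gaussian
  noise.

Features of real data deliberately *not* emulated: lag phases and
non-logistic growth shapes, well-to-well systematic effects, plating
efficiency below one, drug pharmacodynamics (Hill kill curves), and any
resource-explicit mechanism.  Passing the recovery tests therefore shows
the estimators are correct for their assumed data model, not that the
assumed model fits any particular instrument.

All generators are pure functions of (configuration, integer seed).

## Known limitations

* The phase-diagram regime depends on the continuum (floor-free) reading
  of the ODEs; see the extinction-floor section.
* μ_B(D) is a calibrated two-parameter line, not a measured curve.
* The coexistence rule is threshold-based and transient-sensitive near
  region edges; cells within Poisson or solver noise of the 20% line can
  flip category.
* No demographic stochasticity, spatial structure, explicit drug state,
  or resource competition; the regulator's resource advantage in the
  emulated experiments is represented only through interaction
  coefficients.
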