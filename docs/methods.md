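# Methods

`betacell` couples a compartmental kinetic model of pancreatic β-cell
central carbon metabolism with a data-driven regression layer that links
the model's predicted reaction fluxes to glucose-stimulated insulin
secretion (GSIS). This note documents the model, its assumptions, the
numerical choices, and what the synthetic-data machinery does and does
not establish.

## The kinetic network

The full network (`models/beta_cell.yml`) describes INS1 832/13-style
β-cell metabolism with **56 dynamic, compartment-qualified species and 65
enzyme-catalysed reactions** across cytosol and mitochondria (relative
volumes 3:1) plus the extracellular medium:

* glycolysis — 12 species / 13 reactions (`glut` … `pyk`, `ldh`, `mct`),
  with the glucose transporter and glucokinase acting as the glucose
  sensor (high-Km uptake, Hill-type glucokinase);
* pentose phosphate pathway — 7 / 7, NADPH-generating oxidative branch
  plus a near-equilibrium non-oxidative branch;
* TCA cycle and glutaminolysis — 20 species (13 mitochondrial, 7
  cytosolic) / 25 reactions, including the malate–aspartate and
  citrate–malate shuttles, anaplerosis (`pc`) and cataplerosis
  (`cly`, `me1`, `mmalic`);
* polyol pathway — 2 / 3 (`aldr`, `sodh`, `fruT`), low-affinity glucose
  overflow;
* a phenomenological electron transport chain — 6 / 4 (`complex1` …
  `complex5`), with electrons and protons implicit: each complex is a
  saturating step modulated by its physiological effectors (NADH supply,
  reduced cytochrome c, intracellular oxygen, ADP availability);
* 13 further reactions closing the cofactor circuits: glutathione
  cycling (`gpx`/`gssgr`), oxygen transport (`ox`), FADH2-side electron
  entry (`oxtransfer`), cytosolic NADH oxidases (`dhases`), adenylate
  kinase (`ak`), ATP load and synthesis (`atpase`, `oxphos`), GTP
  recycling (`ndk`), and lumped biosynthetic drains (`prppc`, `glycs`,
  `glux`, `nadphox`).

Extracellular glucose, glutamine, lactate and fructose are clamped
boundary species set by the stimulation protocol; phosphate is treated
as buffered. Intracellular oxygen exchanges with a *dynamic*
extracellular oxygen pool, which is what makes the o2 pair a conserved
moiety.

**Parameter inventory.** The definition carries 385 named parameters:
96 maximal velocities (31 reversible reactions carry forward and
reverse velocities), 27 lumped equilibrium constants, 236
Michaelis/product/cross-binding constants and 26 regulatory constants
(activator/inhibitor half-effects and Hill exponents). Eleven
forward/reverse velocity pairs — the fast near-equilibrium isomerases,
transketolase/transaldolase steps, aconitase, fumarase and succinate
dehydrogenase — are equilibrium-constrained (`Vr = Vf/Keq`), leaving
**85 free maximal velocities** for fitting. The shipped values keep the
`Vr = Vf/Keq` identity exact to the file's printed precision.

### Rate laws

Rate laws are built from a small set of templates (see
`betacell.ratelaws`): saturating irreversible Michaelis–Menten products
with optional Hill exponents, competitive product binding and
saturating activator/inhibitor modifiers; a lumped reversible
Michaelis–Menten whose net rate vanishes exactly when
`prod(P)/prod(S) = Vf/Vr` (so the equilibrium constraint is a Haldane
substitution); symmetric and asymmetric carrier kinetics for
transporters; and mass action. The exact rate equations of the source
models this network descends from are not redistributable, so the
kinetic forms here are the package's own; the structural head-counts,
pathway membership, conserved pairs and source/sink sets are the fixed
points the definition reproduces exactly.

### Parameterization

Nominal parameters were constructed by (1) choosing literature-plausible
resting concentrations at 2.8 mM glucose, (2) assigning a consistent
steady flux vector by least-squares projection of target pathway fluxes
onto the null space of the stoichiometric matrix (glycolysis ≈ 0.3–0.6
mM/min, TCA ≈ 0.8–1.0 mM/min in mitochondrial units, PPP ≈ 5% of
glucose uptake), (3) sizing Michaelis constants as fixed multiples of
the operating concentrations so that every step retains headroom
(substrates ≈ 25% occupancy; product binding and allosteric inhibition
deliberately weak), and (4) iterating velocity assignment against the
relaxed low-glucose steady state until the shipped initial state is
itself the 2.8 mM fixed point. Nucleotide-binding sites (ADP sites of
phosphoglycerate kinase, pyruvate kinase and the ATP synthase) are
high-affinity so the adenylate state modulates rather than strangles
glycolysis.

At 16.7 mM glucose the model roughly triples glucose uptake and
doubles pyruvate oxidation; ATP/ADP and NADPH/NADP rise severalfold and
the NAD pool shifts toward NADH — the qualitative GSIS signature. Known
limitation: a handful of pools (mitochondrial glutamate, succinyl-CoA,
xylulose-5-phosphate) respond more strongly than measured metabolomics
suggests; the network is a stated world for testing the pipeline, not a
re-fit of published data.

## Simulation

The ODE system integrates concentrations of the 56 dynamic species with
LSODA at relative/absolute tolerances 1e-8/1e-10 (fitting uses
1e-4/1e-7; the induced error is far below the noise floor of
fold-change data). Rates are expressed in each reaction's home
compartment and converted through a volume-corrected stoichiometric
matrix, so cross-compartment transport conserves amounts across the 3:1
volume ratio. Negative excursions within 1e-9 mM are clamped with a
warning counter; larger ones raise. Conservation relations are computed
by exact rational elimination on the integer stoichiometric matrix, so
the amount-weighted totals — the four cofactor pairs NADP–NADPH,
GSH–GSSG, o2(extracellular)–o2(intracellular) and mGDP–mGTP, plus the
three pools any closed cofactor network necessarily conserves (adenine
ATP+ADP+AMP, NAD+NADH, total cytochrome c) — hold along trajectories to
solver accuracy.

Steady states are certified over the final hour of a 72-hour constant-
glucose run (`max |dC/dt| / max(C, 1e-9) < 1e-6 /min`), then polished
by a Levenberg–Marquardt root solve restricted to the subspace that
leaves every conserved total untouched; this drops `||S·v||_inf` from
the integrator's tolerance floor (~1e-5) to root-finder accuracy
(~1e-13) without moving the state more than a fraction of a percent.

Observation protocols emulate the three training experiments: a
120-minute 2.8 mM pre-incubation followed by a 16.7 mM step (3/6/10/15
min, fold change vs the continued low-glucose culture), a 60-minute
direct comparison of the two glucose levels, and a 16.7 mM time course
referenced to its own 0-minute state. The vs-t0 simulations start from
the raw initial conditions (a config-switchable choice). Fold changes
of metabolites present in both compartments are pooled amount-weighted
with the 3:1 volume ratio, mirroring what mass spectrometry can
resolve.

## Calibration

* **Identifiability screen.** For every reversible reaction with
  independent velocities, the normalized finite-difference sensitivity
  vectors (±50%) of all training observables are compared; a pair with
  |cosine similarity| > 0.99 moves the data along a single direction and
  is reparameterized through its equilibrium constant. The eleven pairs
  shipped in the definition are the recorded outcome of this screen for
  the full model; the operation itself is exercised on constructed
  fixtures because the screen's outcome is parameter-dependent.
* **eFAST screening.** Total-order indices (interference factor M = 4,
  resampled search curves) over a log-uniform sweep two orders of
  magnitude around baseline; a velocity is fitted when its maximum index
  across outputs exceeds 0.85. The implementation is validated against
  closed-form variance fractions of additive models.
* **Objective.** WSSR with residuals scaled by observation SD *and*
  magnitude, `((pred−obs)/(sd·obs))²`; observations with zero SD fall
  back to the dataset's median relative SD.
* **Optimizer.** Particle swarm (inertia 0.72, accelerations 1.49,
  swarm 50) in log10 parameter space with multiplicative bounds 100×
  above/below the initial estimates; the published budget is 100 runs ×
  2000 iterations with the 8 best kept, and the desk-scale default in
  tests is far smaller. Failures are penalized, never fatal.
* **Evaluation.** Ensemble mean ± SD per observation, Welch two-sample
  t-tests against the measurements (experimental replicate count is a
  config decision, default 3), and sign agreement of the fold-change
  direction relative to 1.
* **Initial conditions.** Resting concentrations with no measured value
  can be selected by the recipe in
  `calibration.select_initial_conditions`: Latin-hypercube candidate
  sets over user-supplied ranges, a (desk-scale) fit per candidate, and
  the best-matching set kept. The published protocol's scale is 50 sets
  with 5 fits each; the defaults here are 5 × 1.

## Flux → insulin regression

Time-averaged fluxes over [0, t] of the high-glucose simulation (1-min
grid; t ∈ {3, 6, 10, 15, 60} min) form the 5 × 65 input matrix; insulin
fold changes are the response. SIMPLS with 3 components on autoscaled
inputs; rows 3/15/60 train and 6/10 validate (the methods-text split;
the alternative 3/10/60 split is a config switch). Reported: R²,
leave-one-out Q²Y (scaling re-estimated per fold, TSS about the full
mean), VIP scores (mean square exactly 1; VIP > 1 = influential) and
standardized coefficients as the user-facing "weights". One model is
fitted per calibrated parameter set and predictions are ensemble
means. The time-resolved variant assumes linearly accumulating insulin
within a single 3/6/10/15-minute course.

Because a single response is used, SIMPLS coincides with PLS1; the test
suite cross-checks coefficients against an independent deflation-based
oracle and scikit-learn's NIPALS implementation, which is never used as
the production path. If the response variance is exhausted before the
requested number of components, the fit truncates with a warning
(requesting more components than the input rank is an error).

## Perturbations

Vmax scans (×2 and ×0.5, both velocities of reversible reactions) and
the registered scenarios — metformin = glucose transport at 20%,
agrimony = glucose-6-phosphate dehydrogenase ×5, adenylate-kinase
knockdown = `ak` at 20% — compare certified steady states under 16.7 mM
glucose. Reported per scenario: per-species and pooled metabolite fold
changes (|log2| < 0.05 flagged "no change"), flux fold changes,
flux-direction reversals, and the ensemble-PLSR insulin effect computed
from 60-minute time-averaged fluxes. On the shipped parameterization,
metformin lowers intracellular glucose and upstream glycolytic
intermediates, and the agrimony perturbation raises NADPH while leaving
ATP, ADP, NADH and NAD essentially unchanged — the qualitative
directions reported for these interventions. The quantitative insulin
effect of the `ak` knockdown depends on fitted ensembles that are not
redistributable, so only its computability is asserted.

## Synthetic data

`betacell.synthetic` generates ground-truth-known studies: velocities
drawn log-normally around nominal (log-sd 0.3, redrawn up to 100 times
to stay within the fitting bounds), noiseless fold changes by direct
simulation, observations as the mean of (default) 3 log-normal
replicates with `sigma = log(1 + CV)` (CV default 0.15) and the sample
SD as the reported uncertainty. Everything is a pure function of
(config, seed).

The synthetic insulin response is a recorded linear combination of
three designated reaction fluxes plus the same noise model. On the
reduced fixture the designated drivers are the pyruvate/malate-cycling
fluxes (`mdhm`, `malt`, `mec`, weights 20/4/−4 with intercept −4),
chosen deliberately: with five nested averaging windows the flux table
is dominated by a single activation mode, and only profile-distinct
fluxes can be identified by VIP at all. The negative intercept gives
the response a fold-change-like dynamic range (≈2–3×) so the driver
signal is not drowned by multiplicative noise. With any driver triple
drawn from the dominant collinear family, top-3 VIP recovery fails even
at zero noise — a property of VIP under collinearity, not of the
implementation — which is why driver designation is part of the
generator's design and is recorded in the study object.

The reduced fixture itself (12 species, 15 reactions) preserves every
structural feature the pipeline exercises: reversibility, two-compartment
transport, a conserved cofactor pair, an anaplerosis/cataplerosis loop
and boundary exchange. What a green test on synthetic data establishes
is that the pipeline recovers a truth *of its own stated form*; it does
not establish anything about measurement artifacts (batch effects,
drift, missingness) or about model misspecification, both of which are
out of scope.

## Known limitations

* The ETC is phenomenological (no explicit protons, membrane potential
  or Q pool) and NAD(H), ATP/ADP are whole-cell pools; mitochondrial
  redox shuttling is therefore structural rather than thermodynamic.
* Several high-glucose pool excursions exceed measured metabolomics
  ranges (see Parameterization); the shipped parameters are a nominal
  stated world, not a data re-fit.
* Insulin enters only through the regression layer — no channel
  electrophysiology, islet architecture or fatty-acid metabolism.
* SBML export covers structure and parameters; kinetic laws are exported
  as MathML only for mass action, other templates are annotated by name.
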