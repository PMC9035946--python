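# Methods

`immunotox` is a desk-scale agent-based simulator of the human immune
response coupled to a chemical immunotoxicity layer, a virtual-patient
generator and in silico trial analytics. This note documents the model, its
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## The immune engine

### Shape space and binding

Receptors, MHC molecules, peptides, epitopes and antibody paratopes are
bit-strings of a common length `l` (default 12, so the potential repertoire
holds `2^l = 4096` specificities). Complementarity between two strings is
measured by their Hamming distance `d`: differing bits are complementary,
so affinity *increases* with `d`. Binding is a Bernoulli event with

```
p(d) = 0                      if d < d_min
p(d) = p_max * alpha^(l - d)  otherwise
```

Defaults: `d_min = l - 3 = 9`, `alpha = 0.7`, `p_max = 1`. The thresholded
exponential is a one-parameter sharpness family that is monotone in the
number of complementary bits; with these defaults a random receptor can
bind a random target with probability ≈ 7.3%, giving ≈ 9 responding B-cell
clones in a naive pool of 120 — enough clonal diversity for a robust
polyclonal response at desk scale.

Peptide loading onto MHC uses the same rule with a *lower* threshold
(`d_min_mhc = 6`, i.e. half-complementarity). MHC grooves are promiscuous
binders compared with antigen receptors; with the receptor threshold
applied to loading, a large fraction of virtual patients would carry
haplotypes unable to present a given antigen at all, which is not the
biology the model is after. At `d_min_mhc = 6` more than 99% of patients
can present each shipped antigen through at least one haplotype-peptide
pair. The MHC-peptide complex string is the bitwise XOR of the MHC and
peptide strings — a deterministic, length-preserving combiner; any fixed
combiner would serve, XOR was chosen and is frozen.

### Space, compartments, diffusion

The secondary lymphoid organ is a 2D hexagonal lattice ("odd-r" offset
coordinates, six neighbours per site) with periodic boundaries; a 3D cubic
lattice with face adjacency and hard walls is available in the config.
Periodic hexagonal lattices require an even side because the odd-r parity
pattern only tiles consistently then. The engine default is `L = 8`
(64 sites): small enough that a 90-day patient run takes about a second on
one CPU, large enough that co-localization is a real constraint. The
`lattice_space` API itself defaults to `L = 16` for stand-alone use.

Bone marrow and thymus are separate staging compartments: haematopoiesis
creates cells only in the marrow, T-cell education happens only in the
thymus, and challenges are injected only into the secondary organ. Cells in
the staging compartments do not interact, so their spatial arrangement is
irrelevant and they are treated as well mixed.

All agents perform a nearest-neighbour random walk with one move per step
(uniform over valid neighbours; at hard walls the draw is over existing
neighbours only, avoiding a sticking bias). Molecular fields (15 cytokines,
clonotyped immunoglobulins) diffuse conservatively — each site keeps
`1 - D` of its mass and sends `D/k` to each of its `k` neighbours — and
decay by `2^(-1/half_life)` per step. Antigen is tracked as integer units
per site with binomial thinning for decay and per-unit random moves.

### Time

One step is 8 hours (3 steps/day); "day 20" is step 60, "day 100" step
300. Time-stamped events (injections, exposure switch points) are resolved
at step boundaries.

### Interactions

Each step, every lattice site with antigen or non-resting agents runs a
randomized interaction schedule: the rule order is permuted uniformly, the
actor list within each rule is permuted uniformly, and each actor attempts
independent Bernoulli trials against the partners in turn until one
succeeds (at most one success per actor and rule per step; consumed
partners are gone for later attempts). This per-site randomization is what
removes serialization bias from nominally simultaneous interactions, and
no interaction ever couples entities at different sites within a step.

The shipped rule set:

1. **Aspecific APC uptake** — macrophages, dendritic cells and monocytes
   engulf antigen units with the fixed TLR-PAMP probability `p' = 0.25`
   (PAMP-free antigens at `0.2 p'`); macrophage uptake is damped by local
   IL-10 (`p / (1 + 0.1 * IL10)`). The damping constant is deliberately
   mild: the chemical layer suppresses IL-10, and its disinhibiting effect
   on uptake must stay smaller than the direct suppression of the B pool
   for the antibody endpoint to fall monotonically with dose. Successful
   uptake triggers endocytic
   processing (class II) and, for dendritic cells, cytosolic
   cross-presentation (class I) with probability 0.3.
2. **T-helper priming** — resting (or memory) TH1/TH2 bind presented
   class-II complexes with the receptor rule; success activates the cell
   and licenses a 2-division expansion burst.
3. **B-cell recognition** — resting, memory or already-activated B cells
   bind the antigen's B epitope. Naive cells that bind a PAMP-free antigen
   at a site without an activated professional APC become anergic
   (permanently); otherwise they activate, process the antigen and present
   it on their own class II. Memory cells skip licensing and expand
   immediately.
4. **Cognate T help** — a presenting B cell receives help from an activated
   helper T cell of the *same antigen* (linked recognition) with a fixed
   probability 0.6, entering a 4-division expansion burst; at licensing
   (and at each division) the IgM→IgG switch fires if local IL-4 exceeds
   the threshold 0.5.
5. **Cytotoxic T priming** — resting TC bind class-I complexes on
   cross-presenting dendritic cells.

Outside the pairwise rules, cytokine fields drive threshold transitions:
IL-18 activates NK cells, IL-2 activates regulatory T cells (which then
secrete IL-10/TGF-beta), IL-8 activates neutrophils, and local IL-4 drives
mast-cell division. Presenting APCs stop presenting at 0.05/step; effector
T cells and activated macrophages/monocytes relax to rest at 0.05/step
once no antigen remains.

### Expansion, memory, antibodies

Clonal expansion is one division per step: a DUPLICATING cell is replaced
by two daughters with `duplication_count + 1`, bounded by the Hayflick
limit (24 — roughly six full activation bursts, keeping replicative
exhaustion from clipping secondary responses while still bounding every
clone's tree). B daughters hypermutate (one receptor bit) with probability
0.2. Only truly naive B cells (zero divisions) can found a primary
response; post-burst cells are spent, and recall goes exclusively through
memory cells — this separation keeps a single antigen window from
re-amplifying its own output autocatalytically. After its burst a B cell
becomes a plasma cell (65%), a memory cell (25%, half-life ×6, binding
threshold relaxed by one bit) or returns to rest; helper T cells leave 10%
memory. Memory recall requires an inflamed context (an engaged
professional APC at the site) but no fresh cognate licensing, so secondary
responses are faster and larger than primaries — the humoral-memory
property the engine is required to exhibit. Plasma cells secrete 1 unit of
immunoglobulin per step into the clonotyped pool of their paratope and
isotype (IgG plasma cells switch to IgA at 0.02/step — the late-switch
rate is the mechanism chosen to populate the IgA compartment, for which no
explicit pathway is modelled). Immunoglobulin binds antigen by the same
complementarity rule and neutralizes it at rate `1 - exp(-0.05 * S)` per
unit, where `S` is the binding-weighted local specific antibody. At most
256 clonotype pools are tracked; overflow aggregates into a bulk pool that
keeps isotype but loses specificity.

### Homeostasis and education

Each lineage's cell count follows a mean-reverting Ornstein-Uhlenbeck
homeostat, advanced by the exact discretization

```
x' = mu + (x - mu) e^{-theta dt} + sigma sqrt((1 - e^{-2 theta dt})/(2 theta)) eps
```

clamped at zero and rounded. The homeostat senses the naive pool plus the
transient effectors — but not the long-lived memory compartment — and
creates or culls only naive cells: a response therefore displaces
production instead of triggering runaway replacement, while accumulated
memory does not starve the naive pool.
Deficits are filled with fresh marrow cells carrying uniformly sampled
receptors; surpluses cull the oldest naive cells first. New TH1/TH2/TC
cells pass two-stage thymic education: positive selection keeps a receptor
iff its best complementarity to any MHC string reaches `theta_pos = 3`;
negative selection deletes it iff its complementarity to any MHC-self-
peptide complex reaches `theta_neg = 11` (4 self peptides per patient).
Surviving thymocytes emigrate at 0.5/step — the rate the chemical layer
suppresses. Cell death is geometric with per-step probability
`1 - 2^(-1/half_life)`; a deterministic maximum age was rejected in favour
of the memoryless model implied by a half-life parameterization.

Initialization fills the secondary organ to the lineage means with naive
(pre-educated) cells before t = 0, sets cytokine fields to the patient's
baselines spread uniformly, and seeds a bulk IgG pool from the patient's
IgG titer. The whole run is a pure function of (config, patient, seed).

## The immunotoxicity layer

A chemical acts through a mechanism-of-action map: each entry names one
engine rate and a Hill suppression curve

```
factor(C) = 1 - Imax * C^h / (C^h + EC50^h)
```

applied multiplicatively every step at the current serum concentration
(step-constant exogenous time course in ng/ml; no pharmacokinetics — serum
level is an input, not a prediction). The default PFOA/PFOS map suppresses
the secretion of IL-6, TNF-alpha, IL-4, IL-8, IL-18, IFN-gamma and IL-10,
the spleen B-cell homeostatic mean, thymic emigration (gland atrophy as
rate suppression, not geometric shrinkage) and IL-4-driven mast-cell
growth. PFOS shares the PFOA map with a single potency multiplier (2×).
Macrophage "stimulation" by PFAS is represented only as disinhibition
through the suppressed IL-10, not as a direct positive term.

The suppressed IL-4 channel deserves emphasis: because the IgM→IgG switch
is IL-4-thresholded, cytokine suppression directly reduces class-switched
antibody — the model's strongest link from exposure to the IgG endpoint,
alongside the shrinking B pool and the thinning helper supply.

**Calibration.** Relative magnitudes across the seven cytokine targets are
unknown, so all entries share one `Imax` (equal-weight assumption), with
`EC50 = 10 ng/ml` and `h = 2`. A moderately cooperative Hill slope was
adopted because the memory-dominated antibody endpoint responds
sublinearly to rate suppression: with `h = 1` the attainable effect per
exposure doubling saturates well short of the calibration target, whereas
`h = 2` places the target inside the reachable range of the single free
parameter. The shared `Imax` is the single calibrated
parameter: `scripts/calibrate_defaults.py` bisects it until the simulated
percent difference in the anti-diphtheria IgG endpoint per 2-fold exposure
increase (child two-dose study, paired seeds, n = 30, seed 20220326)
reaches −39% within 3 percentage points. The resulting value ships in
`params/default_params.yaml`.

## Virtual patients and trials

A virtual patient is the 26-entry personalization vector (serum PFAS
level, baseline Th1/Th2/TC/Treg/macrophage/DC pools, specific IgG titer,
eleven cytokine baselines, vitamin D, age, BMI, and categorical
disease-model / vaccination / MoA references; the list prints IL-10 twice
and both entries alias one value) plus class-I and class-II HLA haplotype
pairs drawn uniformly from a pool of 16 synthetic bit-string alleles (no
real allele identities or frequencies are claimed) and a private seed.

Marginals are truncated normals (uniform for adult age) with typical
values and standard deviations; dependencies are linear location shifts
sampled parent-first (BMI given age; naive T pools declining with age).
Thymic output scales with age as `clip(1.6 - 0.015 * age, 0.5, 2)`, so a
5-year-old exports T cells about twice as fast as a 60-year-old. The
feature vector maps onto the engine by scaling lineage means (ratio to the
population-typical value, clipped to [0.25, 2.5]), setting cytokine
baselines and the initial bulk IgG pool.

Trials run a schedule of antigen injections (doses spread uniformly over
the lattice) over a cohort and tabulate the antigen-specific IgG/IgM/IgA
at the sampling day (peak when unset). Exposed-vs-unexposed contrasts
reuse one cohort, so both arms share every random seed and differ only
through the chemical effect (common random numbers). Vaccines and
bacterial challenges are PAMP-positive antigens; distinct antigen names
(diphtheria, tetanus, hib, h1n1, generic-bacterium) map deterministically
to distinct epitope/peptide sets. The child diphtheria endpoint is the
specific IgG 60 days after the second dose; the child population spec —
not a multi-year simulation — represents the age-5 sampling.

Analytics: pointwise population mean/SD of time series; contiguous
exposure quartiles (remainder to the lowest quartiles, ties broken by
patient id); Spearman rank correlation with a seeded BCa bootstrap CI
(rank-based because the titer scale is arbitrary); the 2-fold effect
`100 * (mean_hi - mean_ref) / mean_ref` with a BCa bootstrap CI (paired
resampling when arms share patients); bisection calibration of the shared
`Imax`; and benchmark-dose search — bisection on a constant serum level
until the mean endpoint reduction versus unexposed hits a target (e.g. 5
or 10%).

## Numerical and testing choices

* Problem sizes: 64-site lattice, ≈ 500 agents, 90-130 day runs; cohorts
  of 50-100 patients for studies, 8-20 for property tests. These sizes
  keep a full paired-cohort study in minutes on one CPU while leaving
  every mechanism (clonal selection, memory, suppression) measurable.
* Monte-Carlo assertions use 3 standard errors with autocorrelation-
  corrected effective sample sizes; paired comparisons use sign tests.
* Degenerate inputs: empty cohorts, empty repertoires, zero doses and
  zero-agent worlds are all defined no-ops; zero serum concentration
  yields multipliers of exactly 1, making an exposed run at C = 0
  bit-identical to an unexposed run.
* Ties in the quartile split and the oldest-first cull are broken by
  patient/agent id for determinism.

## What the generator does and does not emulate

The synthetic cohorts reproduce marginal heterogeneity, a few declared
dependencies, HLA diversity and exposure heterogeneity. They do not model
real HLA frequencies, assay noise in titers, co-morbidities, kinetic
(ADME) variation in serum levels, or correlated multi-cytokine baselines.
Passing tests therefore show that the *mechanisms* behave as specified
under plausible heterogeneity — not that the model is calibrated to any
particular human population beyond the single effect size used for
calibration.

## Known limitations

* Antigens do not replicate; a "bacterial challenge" is a decaying bolus.
* Cytokine action is local and threshold-like; no receptor kinetics.
* IgA arises only through a fixed late-switch rate.
* The bystander activation bonus ships disabled (default 0).
* One calibrated parameter (shared Imax) against one effect size; the
  relative potencies of the ten suppression targets are not identified.
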