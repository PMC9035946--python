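# immunotox default parameters, version 1
#
# Units: time in simulation steps (dt_hours per step, 3 steps = 1 day),
# concentrations in arbitrary model units, serum exposure in ng/ml.
# These are desk-scale defaults: small lattice and cell pools chosen so a
# full virtual-patient run completes in about a second on one CPU while
# preserving the qualitative immunology (clonal selection, memory,
# dose-dependent suppression).
version: 1

shape_space:
  l: 12          # receptor bit-string length; repertoire scales as 2^l
  d_min: 9       # minimum complementary bits for any binding
  d_min_mhc: 6   # looser threshold for peptide-MHC loading (promiscuous MHC)
  alpha: 0.7     # per-missing-complementary-bit penalty
  p_max: 1.0     # binding probability at perfect complementarity

time:
  dt_hours: 8    # 3 steps per day; day 20 = step 60, day 100 = step 300

lattice:         # secondary-organ simulation space
  geometry: hex2d
  side: 8
  boundary: periodic

hayflick_limit: 24
p_prime: 0.25                 # fixed TLR-PAMP aspecific interaction probability
pamp_free_uptake_factor: 0.2  # uptake penalty for PAMP-negative antigens
il10_inhibition: 0.1          # macrophage uptake ~ 1/(1 + k * IL10_local)

interaction:
  th_help_p: 0.6              # cognate T-B help probability (linked recognition)
  cross_present_p: 0.3        # DC cytosolic (class I) routing probability
  il4_switch_threshold: 0.5   # local IL-4 needed for IgM->IgG switch
  il18_nk_threshold: 0.5
  il2_treg_threshold: 0.5
  il8_neu_threshold: 0.5
  mast_growth_rate: 0.02      # per-step division prob per unit local IL-4
  effector_rest_p: 0.05       # ACTIVE T -> RESTING when no antigen remains
  presentation_stop_p: 0.05   # APC stops presenting per step
  bystander_bonus: 0.0        # activation bonus near >=k ACTIVE cells (off)
  bystander_k: 3

expansion:
  b_divisions: 4
  t_divisions: 2
  plb_fraction: 0.65
  b_memory_fraction: 0.25
  t_memory_fraction: 0.10
  hypermutation_prob: 0.2     # per B daughter: flip one receptor bit
  iga_switch_rate: 0.02       # IgG plasma cell -> IgA per step
  memory_half_life_mult: 6.0
  memory_dmin_relax: 1        # memory cells bind at d_min - 1

half_lives:      # steps
  B: 90
  PLB: 9
  TH1: 90
  TH2: 90
  TC: 90
  TREG: 90
  NK: 30
  MONO: 21
  MAC: 120
  DC: 60
  MAST: 120
  NEU: 6

lineages:        # Ornstein-Uhlenbeck homeostasis of naive pools
  B:    {mu: 120, theta: 0.05, sigma: 2.0}
  TH1:  {mu: 60,  theta: 0.05, sigma: 1.0}
  TH2:  {mu: 60,  theta: 0.05, sigma: 1.0}
  TC:   {mu: 60,  theta: 0.05, sigma: 1.0}
  TREG: {mu: 20,  theta: 0.05, sigma: 0.5}
  NK:   {mu: 20,  theta: 0.05, sigma: 0.5}
  MONO: {mu: 25,  theta: 0.05, sigma: 0.5}
  MAC:  {mu: 40,  theta: 0.05, sigma: 0.5}
  DC:   {mu: 30,  theta: 0.05, sigma: 0.5}
  MAST: {mu: 10,  theta: 0.05, sigma: 0.3}
  NEU:  {mu: 25,  theta: 0.05, sigma: 0.5}

marrow:
  emigration_prob: 0.5        # per-step export from bone marrow

thymus:
  theta_pos: 3                # min complementary bits to some MHC string
  theta_neg: 11               # deletion above this vs an MHC-self-peptide complex
  n_self_peptides: 4
  emigration_prob: 0.5        # per-step thymic export (THYMIC_OUTPUT target)

fields:
  diffusion: 0.5              # fraction of site mass shared per step
  half_life: 6                # steps (2 days)

antigen:
  diffusion: 0.3
  half_life: 9                # free-antigen decay, steps
  clearance_rate: 0.05        # per-unit neutralisation ~ 1-exp(-rate*S_Ig)

immunoglobulin:
  secretion_rate: 1.0         # units per plasma cell per step
  half_life: 63               # steps (21 days)
  diffusion: 0.5
  clonotype_cap: 256

secretion:       # "TYPE.STATE": {species: rate per step}
  TH1.ACTIVE:        {IL2: 0.6, IFNG: 0.8, TNFA: 0.2, IL17: 0.2}
  TH1.DUPLICATING:   {IL2: 0.6, IFNG: 0.8, TNFA: 0.2, IL17: 0.2}
  TH2.ACTIVE:        {IL4: 1.0, IL6: 0.5, IL10: 0.2}
  TH2.DUPLICATING:   {IL4: 1.0, IL6: 0.5, IL10: 0.2}
  MAC.ACTIVE:        {IL1: 0.5, IL6: 0.8, TNFA: 0.8, IL12: 0.4, IL18: 0.4, IL8: 0.4, IL23: 0.2}
  MAC.PRESENTING_II: {IL1: 0.5, IL6: 0.8, TNFA: 0.8, IL12: 0.4, IL18: 0.4, IL8: 0.4, IL23: 0.2}
  DC.PRESENTING_II:  {IL12: 0.6, IL6: 0.3, IFNA1: 0.2, IFNB1: 0.2}
  DC.PRESENTING_I:   {IL12: 0.6, IL6: 0.3, IFNA1: 0.2, IFNB1: 0.2}
  MONO.ACTIVE:       {IL1: 0.3, IL6: 0.3, IL8: 0.5}
  NK.ACTIVE:         {IFNG: 0.8}
  TREG.ACTIVE:       {IL10: 0.8, TGFB: 0.6}
  NEU.ACTIVE:        {TNFA: 0.1}

exposure:
  potency: {PFOA: 1.0, PFOS: 2.0}   # single scaling; shared target map
  moa_defaults:
    ec50: 10.0   # ng/ml
    hill: 2.0
    imax: 0.7890625   # shared maximal suppression, calibrated by scripts/calibrate_defaults.py
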