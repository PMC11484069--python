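# Methods

`burnsim` couples four physiological blocks into one stiff ODE system
describing the first 24–48 hours after a large cutaneous burn and the fluid
therapy that follows. This note records the model equations as implemented,
the parameterisation and its rationale, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Volume kinetics (7 ODE states)

Three fluid compartments — plasma, burnt tissue, intact tissue — exchange
water by Starling capillary filtration

    J_C = k_f [(P_C − P_T) − σ (π_C − π_T)]

and lymphatic return, a sigmoid of tissue hydrostatic pressure bounded in
[0, J_max]. Capillary pressure is linear in plasma volume; tissue
pressure–volume curves are continuous piecewise-linear in relative volume
with a stiff limb below baseline (slope 40 mmHg per unit relative volume —
dehydrated interstitium develops strongly negative pressures) and a
compliant limb above (12 mmHg), blended smoothly over a 1 % volume band so
the right-hand side stays C¹. Oncotic pressures are linear in albumin
concentration, anchored to 25 mmHg at the plasma baseline of 40 g/L.

Albumin crosses the capillary by the Patlak convection–diffusion solution

    Q = J(1−σ_a) (C_P − C_T e^(−Pe)) / (1 − e^(−Pe)),  Pe = J(1−σ_a)/PS,

which reduces to pure diffusion PS·(C_P − C_T) at zero filtration and to
convective wash-through J(1−σ_a)C_P at large Péclet number. Lymph returns
albumin freely at tissue concentration. Burnt-tissue albumin additionally
decays through a transient heat-denaturation sink.

The seven states are plasma/burnt/intact water volumes and albumin
contents plus one extracellular sodium pool. Capillary and lymphatic
exchange are isotonic, so sodium changes only through infusion and urine;
dermal losses (constant-rate evaporation proportional to burned area
tbsa·W, plus exudation of the burnt-tissue fluid excess) are treated as
electrolyte-free wound water and are gated by a slowly healing wound
signal. Evaporation is attributed to the burnt compartment, because it
scales with the burned area only.

## Burn perturbations

Each disturbance channel follows a normalized double exponential
A·(e^(−t/τ₂) − e^(−t/τ₁))/peak that is zero pre-injury, peaks at its
subject-specific amplitude A, and vanishes as the inflammatory response
resolves. Channels: burnt-tissue and systemic capillary-conductance
multipliers, reflection-coefficient drops (clipped so σ stays in [0, 1]),
a negative burnt-tissue pressure offset, the albumin denaturation rate,
and vasoconstriction/vasodilation combined multiplicatively into the net
vasoactivity M_MAP (floored at 0.1). Time constants are shared per channel
class to limit the parameter count; amplitudes carry the inter-individual
severity.

## Cardiovascular block (algebraic)

Mean systemic pressure is exponential in blood volume,
MSP = MSP₀ e^(k(V_B−V_B0)/V_B0); total peripheral resistance is a logistic
function of log Ang II bounded in [½, 2]×TPR₀; venous return is linear in
CVP with slope −1/(κ_v·TPR); the cardiac function curve is a logistic
Frank–Starling curve of CVP anchored through (CVP₀, CO₀) with plateau
2·CO₀. Cardiac output is the intersection of the cardiac and
venous-return curves (circulatory equilibrium), solved to |CO − VR| ≤ 1e−6
L/min by warm-started Newton iteration with a bracketed bisection
fallback, and MAP = CO·TPR·M_MAP + CVP. The block is quasi-steady relative
to hourly fluid dynamics and is re-solved inside every ODE right-hand-side
evaluation; whether the supplementary form of the MAP equation includes
the CVP offset is not documented anywhere we could check, so the additive
form is used.

## Kidney

Renal arterial and venous pressures are unit-slope linear maps of MAP and
CVP (human anchor: MAP 93 → P_RA 85 mmHg). Renal plasma flow follows
Poiseuille's law across afferent + efferent + venous resistances;
glomerular pressure is P_G = J_RPF(R_Eff + R_RV) + P_RV (60 mmHg at
baseline); the mean glomerular oncotic pressure uses the
filtration-equilibrium linear estimate π_G = π_C + 0.25·(P_G − P_B) with
Bowman's pressure fixed at 18 mmHg; and GFR = K_f[(P_G − P_B) − π_G],
softplus-floored at zero with 0.1 mL/h width (no reverse filtration,
smooth derivative). Autoregulation adds bounded tanh contributions to the
afferent resistance: a myogenic term in P_RA (zero at 85 mmHg) and a TGF
term in macula-densa sodium (zero at its baseline); the composition is
additive so each mechanism stays separately bounded and testable, with a
2 % floor keeping R_Aff positive. Ang II modulates the efferent
resistance through a bounded tanh anchored at baseline.

Reabsorption follows a four-node chain. Proximal tubule: equal water and
sodium fractions (glomerulotubular balance — the fraction, not the rate,
is controlled), an aldosterone dose-response confined to the 65–75 % band
(baseline 70 %). Thin descending limb: water only, inverse sigmoid in
water inflow — the engine of pressure diuresis. Thick ascending limb:
sodium only, fixed 60 % active fraction. Early distal tubule: sodium
only, inverse sigmoid in sodium inflow; its outflow concentration is the
macula-densa sodium. Collecting duct: ADH sets the water fraction,
aldosterone the sodium fraction, through bounded tanh-in-log
dose-responses. The TGF loop (assumed Na_MD → R_Aff → GFR → realized
Na_MD) is a strictly decreasing composition, so its fixed point is unique;
it is solved per evaluation by warm-started secant iteration with a
brentq fallback.

Baseline calibration proceeds in the order: fix r_P0 = 0.70, p_K = 0.60
and the descending-limb baseline r_N0 = 0.75, then derive the glomerular
K_f from the 20 % filtration fraction and the collecting-duct water
fraction from the 1 %-of-RPF urine flow. Honouring the printed 1 % UO/RPF
fraction with a textbook-scale RPF (514 mL/h/kg) implies a baseline urine
rate (≈360 mL/h for 70 kg) far above typical clinical values; the printed
fraction is kept and the tension documented rather than resolved. The
inverse-sigmoid slopes of the descending limb (s = 0.243·J_PN0) and early
distal tubule (s = 0.2526·F_KE0) were calibrated analytically against two
requirements: the urine response at +50 % GFR reproduces the
pressure-diuresis amplification of roughly 250 %, and log(1−p_E) is
everywhere at least as steep in flow as log(1−r_N), which keeps
macula-densa sodium monotonically increasing in perfusion pressure and
hence renin release monotonically inverse. Below ≈55 mmHg renal arterial
pressure the glomerular Starling balance genuinely closes (anuria), so
sweep quantities saturate there; monotonicity claims are asserted
strictly on the filtering branch.

## Hormones

All four hormones are normalized to baseline = 1 and follow first-order
secretion/clearance ODEs, so (1,1,1,1) is an exact fixed point. Renin
secretion falls linearly with fractional macula-densa sodium (floored at
zero); Ang II follows renin through a first-order lag (τ = 0.25 h)
standing in for the secretion delay — a test verifies the step response
against an explicit delayed-argument reference; aldosterone secretion is
exponential in w_Na·(−ΔNa/Na₀) + w_A·ΔAngII with weights 1 and 2 chosen
so the angiotensin drive dominates the post-burn hypernatremic
dehydration and aldosterone rises after injury, as observed; ADH
secretion is exponential in volume deficit and sodium excess with the
osmoreceptor weight (8) above the baroreceptor weight (5). Clearance
rates are constants; scaling them with hepatic/renal flow is not
attempted. Serum potassium is treated as constant.

## Parameters and constraints

Every parameter carries bounds and a class tag. The shipped registry has
56 subject-invariant, 44 subject-specific, and 45 constraint-derived
entries per species preset (pig, sheep, human — YAML files). The
constraint solver makes the pre-injury state an exact fixed point: it
derives compartment baselines from per-kg values, red-cell volume from
hematocrit, per-tissue filtration coefficients and lymph anchors from the
baseline Starling balance, albumin PS products from the transcapillary
albumin balance (1-D root solve), the CV curve anchors from (CVP₀, CO₀,
MAP₀, MSP₀), the renal resistance split from the P_RA/P_G/P_RV anchors,
the nephron-sigmoid midpoints from their baseline fractions, and
maintenance intake equal to baseline urinary water and sodium losses.
Infeasible combinations raise a named constraint error.

## Simulation

The 12 model states plus four quadrature accumulators (urine volume,
urinary sodium, dermal water, denatured albumin) are integrated with
LSODA at rtol 1e−6 and per-state atol 1e−8 of the state scale, restarting
at every infusion breakpoint; dense output at ≤0.1 h. The quadrature
states make the water/albumin/sodium conservation ledgers close to
machine precision by construction, which the tests assert at 1e−6
relative. Protocol controllers review hourly: "none" gives no fluid;
"fixed_rate" gives a constant 500 mL/h; "uo_titrated" starts from a
4 mL·kg⁻¹·%TBSA⁻¹/24 h formula dose (half in the first 8 h) and
multiplies the rate by 1.25 (below band) or 0.8 (above band) — a generic,
documented stand-in for proprietary titration software. Sheep
resuscitation starts 1 h post-burn.

## Verification sweep

The kidney + RAAS subsystem is isolated by freezing plasma volume, sodium
and oncotic pressure at baseline and prescribing renal arterial pressure
over 40–160 mmHg in 2 mmHg steps (the 85 mmHg baseline inserted). At each
pressure the five hormone states are integrated 400 h to steady state
(residual < 1e−7), warm-started from the neighbouring grid point; steady
states are found by long-horizon integration rather than algebraic
root-finding so the same dynamics code is exercised. The
pressure-diuresis statistic interpolates the pressure where GFR reaches
1.5× its 85 mmHg value and reports the urine increase there (shipped
human preset: ≈261 %).

## Estimation

The cost is Σ_j Σ_k [(y_jk − ŷ_j(t_k,θ))/Y_j]², with Y_j the subject's
baseline value per variable except urine output, which uses the species
target-band midpoint (baseline urine is rarely measured and the band is
the clinical scale). Hourly urine measurements are compared against the
model's true hourly collection (cumulative-urine differences), other
variables against interpolated instantaneous values. Fitting runs a
seeded Latin-hypercube multi-start (default 20) of a bounded
trust-region least-squares solver; during fitting the integrator runs at
rtol 1e−4 with 0.25 h output spacing (the recovery thresholds are far
above the resulting error), and the start loop exits early once a start
reaches cost 1e−5 or after 4 consecutive non-improving starts. NMAE
shares Y_j with the cost; Bland–Altman limits use the sample (n−1) SD and
the literal bias ± 2·SD. The sensitivity reduction fits one regularized
population-average vector (L2 toward preset values scaled by bound width)
and ranks candidates by normalized central-difference cost sensitivity.

## Synthetic cohorts

Virtual subjects draw demographics from the study distributions (pig
31.7 ± 4.2 kg at fixed 40 % TBSA; sheep 40 kg; human 85 ± 18 kg,
42 ± 18 % TBSA, truncated to validity) and ground-truth parameters
uniformly within configurable ranges. The default recovery quintet —
burnt-tissue and systemic leak amplitudes, venous filling gain k_MSP,
vasoconstriction amplitude, evaporation coefficient — was chosen for
distinct observable signatures: the burnt-tissue pressure amplitude was
deliberately excluded because it is nearly collinear with the
burnt-tissue leak amplitude once pig hematocrit is excluded, and no
finite data distinguish them. Default sampling ranges are plausible
physiological sub-intervals of the registered bounds. Measurement
schedules mirror the study designs (pig hourly UO + sparse
HCT/MAP/CO/CVP/Na at hours 0,1,2,3,5,9,12,18,24; sheep 48 h; human
hourly UO only); pig HCT is generated but excluded from fits by default
(contractile spleen). Observation noise is multiplicative Gaussian with
per-variable CVs (UO 10 %, HCT 2 %, CO 5 %, MAP 5 %, CVP 10 %, Na 1 %),
floored at zero.

What passing the synthetic loop shows: the estimation machinery is
consistent — parameters that generated the data are recovered from the
data the model itself produced. It does not show that the model fits real
animals or patients; real data add model misspecification, measurement
artefacts (splenic autotransfusion, catheter noise, clinician overrides)
and biological variation the generator does not emulate.

## Known limitations

No heart-rate or baroreflex chronotropy; no potassium or other
electrolytes; no intracellular water; no inhalation injury or mortality;
no urea/osmolality counter-current mechanism; homogeneous nephrons; LR is
the only infusate composition shipped (Na 130 mEq/L, no albumin). The
supplementary functional forms of the source physiology are pinned here
by shape contracts (bounded, anchored, monotone) rather than exact
coefficient tables, so absolute trajectories are nominal while the
structural ratios, signs and feedback behaviours are the tested content.
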