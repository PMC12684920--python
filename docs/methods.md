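# Methods

`rootga` models how the bioactive gibberellin GA4 becomes spatially graded
along a single file of cells in the *Arabidopsis thaliana* root growth zone,
and how that gradient would be seen by the nuclear-localized nlsGPS FRET
biosensors. This note records the model, the numerical choices, the
parameter fixtures and what the synthetic-data experiments do and do not
demonstrate.

## The biological model

**Geometry and growth.** The axis runs from the quiescent centre (QC, x = 0)
through the quiescent-centre zone (QCZ, 0–43 μm), division zone (DZ,
43–240 μm; QCZ + DZ = meristem), elongation zone (EZ) and maturation zone
(MZ). Growth is kinematically prescribed, not mechanically modelled. In the
meristem every cell elongates at a constant relative elongation rate (RER,
default 0.05 /h) and divides when it reaches twice the prescribed
birth length at its position (a linear 4→10 μm ramp across the meristem).
Both cytoplasm and vacuole expand at the cell RER there, so the vacuolar
volume fraction stays at its meristem value (35%). In the EZ cells stop
dividing; the cytoplasm keeps expanding at the meristem rate while the
vacuole expands five times faster, so the cell RER rises as the vacuole
takes over and the vacuolar fraction climbs from 35% to 90%, at which point
the cell enters the MZ and stops growing. These rules *force* the EZ length:
with the meristem ending at 240 μm, the 35→90% trajectory spans ≈ 710 μm
independent of the meristem RER, so the default EZ end is 950 μm and the
modelled domain ends at 1,100 μm (both configurable). The division threshold
is anchored to the position-dependent birth-length profile because a purely
inherited threshold is dynamically unstable: daughters inherit their
mother's half-length, so any prescribed spatial ramp of cell sizes would
relax to the tip value as tip lineages sweep shootward.

**Metabolism.** Each cytoplasm runs the pathway GA12 →(GA20ox ×3)→ GA15 →
GA24 → GA9 →(GA3ox)→ GA4, each step with Michaelis–Menten kinetics scaled
by a zone-dependent relative activity, plus linear GA2ox catabolism: one
enzyme grouping degrades GA12 (rate δ12), the other degrades GA9 and GA4
(δ9, δ4). Vacuole and apoplast are metabolically inert. GA12 enters in two
ways: local synthesis in the QCZ cytoplasm (s_qcz, nM/h) and phloem
delivery, spatially uniform over the rootward half of the EZ (d_phloem,
nM/h, delivered symplastically into the cytoplasm).

**Transport.** Gibberellins are weak acids: passive membrane permeation
acts on the protonated fraction f = 1/(1+10^(pH−pKa)) on each side
(plasma membrane and tonoplast), while NPF carriers move the anion
unidirectionally — a merged NPF3.1/NPF2.12 influx permeability on the
plasma membrane (apoplast → cytoplasm) and NPF2.14 on the tonoplast
(cytoplasm → vacuole), each with an on/off flag. With apoplast pH 5.3 and
pKa 4.2, ~7% of apoplastic GA4 is protonated; at cytoplasmic pH 7.2 over
99% is anionic, so there is essentially no passive efflux — the weak-acid
trap. Plasmodesmata connect adjacent cytoplasms with flux
P_plas·A·(c_i − c_{i+1}) carrying all ionic forms; adjacent apoplastic
wall compartments communicate by diffusion (D_apo) through the
longitudinal-wall fraction ε_w of the cross-section.

## The discrete cell-file model

State: per cell, cytoplasm and vacuole volumes plus five metabolite
concentrations in each; one shared apoplast interface compartment per
cell–cell junction (plus the two ends), of fixed volume A·h_wall. The ODE
system (~17 unknowns per cell) is integrated with scipy's BDF using a
structural Jacobian sparsity pattern. Division events are located exactly
(terminal event on max(l − 2 b(x))); the mother splits into two equal
halves that inherit her concentrations (intensive split), and the new wall
compartment starts at zero concentration so division never creates
hormone. Cells pushed past the domain end are removed; the removed amounts
are the advective export. Enzyme activities and supply rates for a cell
straddling a zone boundary are overlap-weighted averages of the zone
values, which removes an O(cell size) mismatch against the sharp-boundary
continuum model.

Because the file divides forever, the system is periodic rather than
stationary. `run_to_steady_profile` integrates (starting from the
continuum solution, which shortens the transient without affecting the
attractor), samples the piecewise-constant profile every 0.5 h, and
declares steadiness when consecutive division-cycle (ln 2/RER ≈ 13.9 h)
window averages of every metabolite field differ by < 10⁻⁴ relative L2;
the returned profile is the final window average. Default tolerances:
rtol 10⁻⁸, concentration atol 10⁻⁸ nM. The wild-type run converges in
≈ 140 simulated hours (~10 windows, ~120 divisions, ~40 cells).

Mass bookkeeping is cumulative: supply and degradation rates are
trapezoid-integrated over the samples, export is accounted exactly at
removal events, and storage change is read off the state, so the budget
supply = degradation + export + Δstorage closes to ~10⁻⁴ relative per
window (limited only by the sampling quadrature). In this Eulerian frame
growth dilution is not a separate global sink — it is realized as the
hormone carried out of the domain by the moving tissue.

## The continuum approximation

For each metabolite the cell-scale model homogenizes to steady
one-dimensional balance laws for three macroscale fields: cytoplasmic
c(x), apoplastic a(x) and vacuolar w(x) concentration,

    0 = (P_plas l c′)′ − (v (1−φ) c)′ + (1−φ)(S_j(c) + s_j) + J_ca − J_cv
    0 = (ε_w D_apo a′)′ − (v ε_w a)′ − J_ca
    0 = − (v φ w)′ + J_cv

with l(x) the mean cell length, φ(x) the vacuolar fraction, v(x) = ∫ RER
the growth velocity, and membrane exchanges per unit length
J_ca = (2γ/l)[P_pm(f_a a − f_c c) + P_npf(1−f_a)a],
J_cv = (κγ/l)[P_ton(f_c c − f_v w) + P_214(1−f_c)c] (κ = tonoplast area
factor). γ = (3/2)ln 2 ≈ 1.04 is a length-dispersion factor: the cells
present at one position are spread over the division cycle with length
distribution ∝ 1/l² on [b, 2b], and per-unit-length exchange averages
E[1/l] = γ/E[l]. For the same reason the geometry template uses the
population-mean length E[l] = 2 ln 2 · b(x) in the meristem, and the EZ
fields follow the closed-form Lagrangian transit solution. An early design
treated vacuole and apoplast as quasi-steady local partitions folded into
an effective capacity/dilution coefficient; resolving them as explicit
fields proved both simpler and markedly more accurate (tonoplast exchange
is not fast compared with EZ transit), so the quasi-steady factors survive
only as the interpretive summary in `effective_coefficients`.

Boundary conditions: zero total flux at the QC (v(0) = 0, no diffusive
leak); advective outflow only at the shootward end. Discretization:
node-centred finite volumes, second-order central diffusion, central
advection blended to first-order upwind where the face Péclet number
|v|h/D ≥ 2. The pathway couples strictly downstream, so the five
metabolites are solved sequentially, each as a damped-Newton iteration on
a banded (bandwidth-4) matrix — the Michaelis–Menten conversion is the
only nonlinearity and is extended linearly to negative iterates so the
residual stays C¹ — with implicit-Euler pseudo-time continuation as a
fallback. Default mesh: 551 nodes (h = 2 μm); residual tolerance 10⁻⁸
nM/h. One full solve takes ~10 ms, which is what makes the exhaustive
parameter survey cheap. The scheme is conservative, so the global budget
closes to solver tolerance by construction; a manufactured-solution test
confirms second-order convergence, and the wild-type GA4 profile agrees
with the dynamic cell-file model to ≈ 4% relative L2 over the biosensor
window (0–500 μm) — the residual gap is the homogenization error of a
strongly nonlinear, coarse-grained (cells up to ~70 μm) system.

## Sensor model

Emission ratio R(c) = R_min + (R_max − R_min)·c^h/(K_d^h + c^h), default
Hill coefficient 1, analytically inverted for unsaturated readings.
nlsGPS1 (R 0.55–1.15, K_d 15 nM) and nlsGPS2 (0.50–1.30, 25 nM) are named
fixture calibrations, not published constants; all quantitative claims in
the package are therefore made on gradient *shape* and ordering, which the
strictly monotone titration map preserves.

## Parameter fixtures

Published tables for the kinetic and transport constants were not
available to this implementation, so the defaults are literature-scale
fixtures chosen once to reproduce the documented qualitative behaviour,
and every value is config-overridable:

- pKa 4.2 (all metabolites), pH 5.3/7.2/5.5 (apoplast/cytoplasm/vacuole) —
  chosen to give the ~7% protonated / >99% anionic GA4 chemistry.
- Passive permeabilities 360 μm/h for GA12/GA15/GA9 and 36 μm/h for
  GA24/GA4 (0.1/0.01 μm s⁻¹), with the NPF ordering reversed (3.6 vs
  36 μm/h influx; tonoplast NPF2.14 ten-fold smaller so that losing it
  has only the small EZ effect expected of it).
- P_plas 180 μm/h (0.05 μm s⁻¹), D_apo 10⁵ μm²/h with ε_w = 0.02.
- GA20ox steps V_max 150 nM/h, K_m 100 nM; GA3ox V_max 60 nM/h, K_m
  150 nM. GA3ox is deliberately the pathway bottleneck: GA9 pools upstream
  of it, which is why GA3ox overexpression moves the predicted biosensor
  profile much more than GA20ox overexpression.
- Zone activity multipliers (transcript-shaped): GA20ox (QCZ 0.6, DZ 0.3,
  EZ 1.0, MZ 0.4), GA3ox (0.4, 0.15, 1.0, 0.8) — biosynthesis low in the
  DZ, high in the EZ; GA2ox groupings near-uniform in the meristem and
  elevated shootward (GA12-directed 0.9/0.9/1.0/1.2; GA9/GA4-directed
  0.9/0.9/1.0/1.5).
- δ12 = δ9 = δ4 = 0.4 /h (the three degradation rates equal), s_qcz =
  3 nM/h, d_phloem = 150 nM/h (delivery ≫ local synthesis).

With these defaults the wild-type model predicts GA4 ≈ 3.6 nM near the QC
rising to ≈ 15 nM in the EZ (nlsGPS1 ratio 0.67 → 0.85), i.e. the low-in-
the-meristem, rising-across-the-transition gradient; delivery dominates
the EZ levels, and the gradient steepens/flattens with lower/higher
plasmodesmatal permeability.

## Scenarios and fitting

`ScenarioConfig` declares perturbations declaratively; enzyme transforms
apply in a fixed order (LOF zeroing → uniform OE increment of α× the
wild-type maximum, default α = 5 → DZ/meristem inactivation rescale by 0
or 0.1 → optional flattening to spatially uniform activities). Transport,
growth and supply scalars fold into the parameter bundle; the H₂O₂
treatment (2 h, 0.6 mM) is represented as a new steady state with
P_plas ×3, treating the treatment duration as long compared with the
transport timescale.

Model–data agreement uses one metric everywhere: the mean over nuclei of
the squared difference between the observed emission ratio and the
prediction linearly interpolated at the nucleus position (no binning).
The five unconstrained parameters (s_qcz, d_phloem, δ12, δ9, δ4) are fit
by exhaustively scanning a grid of that MSE with the continuum solver as
the fast path (the survey's "frozen-template" mode — geometry is the
steady template throughout); ranking is deterministic with lexicographic
tie-breaks, per-point solver failures are logged and excluded, and
`reverify_top` re-scores the best points with the dynamic cell-file model.
The standard grid is five half-decade-spaced points per parameter (two
decades of range), the resolution a practitioner would use for an
exploratory survey of rates known only to order of magnitude.

Observed profiles are summarized with loess: local quadratic regression
with tricube weights over the span-nearest neighbours (span 0.75 default),
with pointwise CIs fit ± z·σ‖l(x)‖ from the linear-smoother weights and
residual variance on n − tr(L) degrees of freedom.

## Synthetic data and what the experiments show

`generate_emission_dataset` emulates pooled-nuclei biosensor data: nucleus
positions uniform on 0–500 μm (optional jitter), ratios from the titration
curve on the model's GA4 field plus additive Gaussian noise (default s.d.
0.05 ratio units; noise acts on fluorescence ratios, not concentrations),
fully reproducible from the seed and recorded with its generating truth.
It does not emulate per-cell-layer structure, heteroscedasticity,
segmentation artefacts or saturated nuclei.

The recovery experiment generates 20 datasets (n = 300 nuclei, noise 5% of
the sensor's dynamic range) at a known truth and asks whether the survey's
top point is within one grid step of the truth in all five coordinates;
with zero noise and on-grid truth, recovery is exact. The experiment's
ground truth uses s_qcz = 20 nM/h rather than the wild-type 3 nM/h: at the
wild-type rate the QCZ term contributes only a few percent of the signal
and is genuinely uninformative at this noise level (any estimate of it is
noise-driven), which mirrors how weakly the synthesis rate is constrained
relative to delivery in this kind of fit. Passing recovery therefore shows
the survey machinery is unbiased and well-conditioned where information
exists — not that every parameter is identifiable from wild-type data.

## Known limitations

One-dimensional single-file model: no radial tissue structure, no
cross-section-specific NPF localization, no phloem advection dynamics, no
SWEET transporters, no GA signalling feedback on growth; intracellular
gradients within long EZ cells are averaged away by the well-mixed
compartment assumption. The continuum model inherits the sharp-zone
activity steps, so its convergence order degrades locally at zone
boundaries (globally it remains second-order on smooth problems). All
kinetic and transport constants are fixtures: absolute concentrations are
indicative only, and conclusions should be read at the level of shapes,
orderings and relative responses.
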