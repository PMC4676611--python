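# Methods

## Model structure

The simulator couples three scales on a shared cubic lattice (default
100³ sites, 5 µm spacing — about one myeloma-cell radius — with at most one
cell per site; simulation step Δt = 2 h, default horizon 120 steps):

1. **Intracellular** — each agent's per-step phenotype decision
   (apoptosis / proliferation / migration / quiescence), driven by
   exponential-survival hazards and order-2 Hill responses
   `Hill(x) = x²/(1+x²)` evaluated at concentration/threshold.
2. **Intercellular** — signal integration (DKK1 → Wnt with BHQ880
   neutralisation, OPG:RANKL ratio) and the ranked stochastic choice of a
   migration or division site.
3. **Tissue** — explicit lattice diffusion of four cytokines (DKK1, RANKL,
   OPG, TNFα) and three drugs with secretion sources tied to cell
   positions, first-order degradation/uptake, and configurable boundary
   handling.

Each step executes one consistent sweep: cytokine secretion + diffusion
from the time-t snapshot, then drug influx + diffusion, then every living
agent acts once in a freshly drawn random order on the updated fields.
Population counts include cells currently completing apoptosis (they still
occupy lattice sites until absorbed, 10 steps after entry).

## Parameters

All response constants (basal rates, Hill amplitudes and thresholds) carry
their conventional symbols in the configuration and code
(`E0, beta_W, K_D, P0_ob, beta_ob, K_W, P0_oc, K_O_RL, P0_mm, beta_mm_L,
K_T_mm, lambda0_mm, beta_mm_T, K_L_mm, lambda0_1, beta1_GC, K_GC_1,
lambda0_2, K_GC_2, beta2_GC`). Apoptosis hazards are per hour; proliferation
values are per-step gate probabilities; thresholds and concentrations are in
relative units. Three modelling points deserve comment:

* **MM amplitude binding.** The two myeloma Hill amplitudes are bound by
  the descriptive meaning of the constants — 0.5 is the maximum activation
  of MM *proliferation* (by TNFα) and 0.05 the maximum increase in MM
  *apoptosis* (by Lidamycin). This is the shipped default
  (`beta_binding: labels`). The alternative reading that binds the values
  the other way around (`symbols`) is retained as a configuration switch;
  under it the TNFα drive is too weak (≤ 0.05) ever to let the myeloma
  population overtake the osteoclasts late in an untreated course, which is
  a defining feature of the disease dynamics this model targets.
* **Glucocorticoid asymmetry.** The published OC apoptosis amplitude is 0
  (`beta2_GC = 0`), so GCs act only on osteoblasts; osteoclasts have no
  death process at all in the default parameterisation. This is
  implemented as given and explains several behaviours noted under
  "Limitations".
* **Cell-cycle pacing.** The cycle-phase lengths are free parameters. The
  shipped default is G0/G1 = 51, S = 4, G2 = 2, M = 1 steps (≈ 4.8 days
  total, dominated by a long G0/G1 as in slowly cycling plasma cells).
  A fast 24 h cycle with the published gate probabilities (0.1–0.15 per
  step) would double every population every ~37 h, i.e. ~200-fold growth
  over the 10-day horizon; the long cycle brings the untreated expansion
  into the observed 3–4× range while leaving the per-step decision logic
  untouched.

### Calibrated transport and motility constants

The diffusion/secretion/uptake constants are not fixed by the response
functions; the shipped values were chosen once, by scanning the untreated
disease course for its qualitative signature (OB collapse, 3–4× MM/OC
expansion, MM overtaking OC around step 90) and then frozen:

| constant | value | meaning |
|---|---|---|
| `lambda_C` | 0.5 | cytokine exchange fraction per step |
| `Se_G` | 0.1 | cytokine secretion per source site per step |
| `DEG` | 0.01 | cytokine degradation fraction per step |
| `lambda_d` | 0.5 | drug exchange fraction per step |
| `Pe_d` | 0.5 | vessel permeability (drug influx scale) |
| `U_d` | 0.02 | drug uptake fraction per step |
| `P_pathway_oc` | 0.25 | maximum RANKL-pathway OC proliferation boost |
| `D_mot` | 0.04 | motility constant (lattice units²/h) |

`D_mot` only rescales the motility kernel shared by all unit-distance
candidates, so it cancels in the site-selection normalisation unless the
search radius is raised above one. Reference ("1X") doses are likewise part
of the calibration: BHQ880 1.0, GC 0.035, Lidamycin 1·10⁻⁷ — each on the
scale of its own response threshold (Lidamycin's printed threshold is
1·10⁻⁷, which fixes the absolute scale of its dose). The slow uptake
(`U_d = 0.02`) lets a drug delivered over steps 20–60 persist, decaying, to
the end of the run.

## Initialization and randomness

The requested number of each cell type (default 100 each) is placed
uniformly at random, without collisions, inside the smallest central
lattice ball that holds them; ages are uniform on [0, 24] h; all fields
start at zero. A single master seed spawns three independent RNG streams
(placement, phenotype draws, site selection), so identical configuration
and seed reproduce every run bit-exactly. Trajectories are independent of
the lattice size as long as the colony and its diffusion halo stay inside
the grid (fields are strictly local), which the test suite exploits.

## Numerical choices

* **Stencil.** Both field updates use the same synchronous 6-neighbour
  exchange: `C' = [(1−λ)C + (λ/6)ΣC_nb + χ·S](1−loss)`. Under the default
  no-flux boundary a site keeps the exchange share of missing neighbours,
  so diffusion conserves mass exactly (verified to 1e-9 relative); an
  absorbing boundary is available. Values are clamped at zero after each
  update because float rounding of the exchange term can undershoot by a
  few ulp.
* **Exactness-preserving optimisations.** Cytokine stencils are evaluated
  only on a bounding box dilated one site per step beyond the union of the
  field's support and its sources (outside it the field is identically
  zero, so the restriction is exact, not approximate). A drug delivered
  uniformly to every site under the no-flux boundary stays spatially
  uniform, so its update collapses to the scalar recurrence
  `v' = (v + Pe_d·dose)(1−U_d)`; both shortcuts are tested against the
  explicit update.
* **Site selection.** Candidate scores are normalised into a half-open
  partition of [0, 1); a uniform draw selects the interval, so boundary
  ties cannot occur. An empty candidate list yields reversible quiescence.
* **Dose–response inversion.** Equi-effective doses are found by
  piecewise-linear interpolation in log-dose, restricted to the maximal
  monotone branch of the curve containing the reference dose (simulated
  curves can rebound at extreme doses); targets outside the achieved range
  raise rather than extrapolate, and an anchor sitting exactly on a fold
  resolves to the low-dose limb.
* **Spearman p-values** use the t-approximation with n−2 degrees of
  freedom (scipy). A constant outcome leaves ρ undefined and is reported
  as missing, never as 0.
* **Degenerate inputs.** The OPG:RANKL ratio guards its denominator with
  ε = 1e-9; probabilities are clamped to [0, 1] after the basal+amplitude
  sum (the OB response saturates at 1.1).

## What the simulations do and do not show

All inputs are synthetic: the model emulates the qualitative biology of
myeloma bone disease (DKK1-mediated Wnt suppression, RANKL/OPG balance,
TNFα feedback) on an idealised lattice, not any patient dataset. Passing
tests demonstrate internal consistency, invariance properties and the
calibrated qualitative trends; they say nothing about quantitative
agreement with wet-lab dose–response data, which would require fitting the
relative concentration scales to measurements.

Known limitations worth keeping in mind:

* With `beta2_GC = 0` osteoclasts never die, so no regimen can push the OC
  count below its current value; "rebalancing" the OC lineage can only mean
  slowing its growth.
* Because the basal OB apoptosis hazard (3.5·10⁻² /h) exceeds the fastest
  attainable OB birth rate under any cycle consistent with the untreated
  OB collapse, BHQ880 cannot produce a net osteoblast recovery — it only
  slows the decline. Consequently the three Lidamycin-containing regimens
  all act on the tumour through the same single mechanism and are
  statistically equivalent on the R_drug endpoint: with the shipped doses
  they all eradicate the tumour (R_drug = 0), and the triple combination
  attains the minimum score jointly rather than strictly.
* Growth is division-wave-like (cells synchronise on the long G0/G1), so
  count trajectories are stair-stepped rather than smooth, and the
  MM-over-OC crossing step has a wide seed-to-seed distribution (roughly
  ±15 steps around its median); medians are reported over ≥ 9 seeds.
* The lattice is static: no vasculature geometry, ECM mechanics, off-grid
  positions or pharmacokinetic compartments. Drug "dose" is a relative
  influx scale, not a physical concentration.
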