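# Methods

## Model overview

`tumorca` couples a stochastic cellular automaton on a square
`ncell × ncell` lattice (default 101, periodic boundaries) to five
diffusing concentration fields. One iteration represents `dt_days = 0.1`
days and executes, in order:

1. **Diffusion with sources/sinks.** Each field relaxes toward its shifting
   3×3 block average with weight `α_i`, then receives the signed metabolic
   increment of the resident cell, and is clamped at zero.
2. **Medium replenishment.** Non-tumor sites are restored to at least 95%
   of fresh-medium oxygen/glucose and their proton load is capped near the
   background — the surrounding vasculature in effect.
3. **Environmental necrosis.** Any tumor cell whose local (O₂, glucose, pH)
   falls below the critical thresholds dies; normal cells under the same
   conditions apoptose and leave empty space.
4. **Geometry.** The mean tumor radius `Rt` (average seed-to-boundary-cell
   distance), rim thickness `Wp = b·Rt^(2/3)` and core radius
   `Rn = Rt − (a + b·Rt^(2/3))` are computed once per iteration.
5. **Quiescent updates.** A QC inside `Rn` necroses; one in the rim band or
   with all three nutrient conditions satisfied recovers to PC (keeping its
   phenotype); otherwise it stays quiescent.
6. **Mitosis.** Every PC, in a freshly shuffled random order, first answers
   to its microenvironment (below the quiescence thresholds it stops
   cycling), then attempts division into a uniformly chosen free Moore
   neighbor with the radius- and phenotype-dependent probability.

All stochastic draws flow from one root seed through named independent
streams (iteration shuffling, division draws, neighbor choice, phenotype
assignment, initial jitter), so a `(seed, params)` pair reproduces a run
bit-for-bit, and refactoring one consumer leaves the others unchanged.

## Microenvironment thresholds

| quantity | quiescence | necrosis |
|---|---|---|
| oxygen | < 0.02 mMol | < 0.01 mMol |
| glucose | < 0.06 mMol | < 0.03 mMol |
| pH | < 6.4 | < 6.0 |

The necrosis bounds for O₂/glucose are half the quiescence bounds. The
anaerobic (glycolytic) switch follows the oxygen quiescence threshold:
below 0.02 mMol a tumor cell multiplies glucose uptake by
`k_gl_anaerobic = 5`, proton export by `k_h_anaerobic = 2` and cuts oxygen
uptake to `k_o2_anaerobic = 0.1` of the aerobic rate. Quiescent cells run
the same branch scaled by `quiescent_factor = 0.2`; necrotic cells only
export protons; living normal tissue takes up O₂/glucose at half the
aerobic PC rate and exports no acid; empty sites are inert.

## Block-CA diffusion numerics

The partition origin at iteration `t` is `(t mod 3, t mod 3)` — the tiling
shifts one row down and one column right per step, cycling through three
distinct partitions so a point disturbance escapes its original block
within three iterations. When `ncell` is not a multiple of 3 (the default
101 is not), the periodic wrap defines partial blocks of 3×2, 2×3 and 2×2
sites; because the blocks always partition the lattice exactly, block
averaging conserves each field's global sum to floating rounding
(verified to 1e−9 relative tolerance in the tests, and against a
site-by-site enumerated oracle on a 6×6 lattice).

Mixing weights are tied to the physical diffusion coefficients by
`α_i = alpha_max · D_i / max_j D_j` with `alpha_max = 0.9`, preserving the
monotone relation "faster diffuser, stronger mixing" while keeping every
α in (0,1); all five can be overridden in the configuration. Consumption
is truncated to the locally available amount and the update is clamped at
zero, so fields can never go negative; with zero sinks the step is exactly
mass-conserving.

## Unit conversion and calibrated constants

The published per-cell rates (e.g. `Cr_o2 = 2.3e−16 Mol·cell⁻¹·s⁻¹`) refer
to single biological cells, while a lattice site aggregates an unspecified
number of cells in an unspecified volume. A single conversion factor,
`rate_scale = 5.75e13`, maps per-cell rates to per-site mMol increments per
iteration; under it one aerobic PC consumes 1.65% of the background oxygen
per iteration, in the 1–2% range expected for densely packed tumor tissue.
This constant, the stalling allowance (below) and the proton yield were
fixed once against the reference endpoint behavior of the default
experiment and are frozen as the shipped defaults.

Protons are special: tissue is heavily buffered (bicarbonate and protein
buffers), so only a small fraction of the exported acid persists as free
H⁺. The H⁺ increment therefore carries an additional free-proton yield
`proton_buffering = 5e−3` on top of the mMol→mol/L conversion. Without it,
sustained necrotic acid production under medium-only clearance drives the
core to physically implausible pH ≈ 4; with it the simulated lattice pH
spans ≈ 6.9–7.4, matching the experimentally observed extracellular range.
Growth/inhibitory factors use their own small turnover scale
(`factor_scale = 0.01`); they are transported and consumed/produced but
deliberately gate no transition rule (a stated limitation of this rule
set), so their scale is inconsequential.

## Crowding and the stalling allowance

A PC that keeps failing to divide (no free neighbor, or losing the
probability draw) eventually becomes quiescent. The tolerance to crowding
is modeled as a function of elapsed time:
`allowance(t) = max(stall_limit, stall_growth · t)` with `stall_limit = 26`
and `stall_growth = 0.4`. The time dependence matters: the rim-geometry
power law with `a = 0.42`, `b = 0.11` makes the viable shell
(`Rt − Rn ≈ 1.5` lattice units) razor-thin, so with a constant small
allowance every newly enclosed interior cell would quiesce and be swept
into the core within a few iterations, and the tumor would necrose almost
as fast as it grows from the very beginning. The growing allowance lets
the early interior quiesce on a ~30-iteration clock (producing the first
necrotic cell at iteration ≈ 31 at radius ≈ 14) while sparing the older
interior later, when oxygen depletion rather than crowding should drive
the core's expansion.

## Initialization (the synthetic experiment)

A run starts from spatially uniform background fields — 0.8 mMol O₂,
5.5 mMol glucose, pH 7.4, full growth factor, no inhibitory factor — with
every site living normal tissue and a single mutant PC at the lattice
center. An optional relative uniform jitter (`init_jitter`, default 0)
perturbs the initial fields for readers of the initial condition as a
distribution. This emulates an avascular spheroid seeded in well-perfused
homogeneous tissue. It deliberately omits features of real tumors:
explicit vasculature and angiogenesis, immune interaction, mechanical
pressure and cell pushing, migration/metastasis, 3-D geometry, and
phenotype evolution beyond the single mutant/nonmutant axis. Passing tests
therefore certify the rule set and its emergent layered dynamics, not
quantitative fidelity to any particular in-vivo lesion.

## Emergent behavior of the default experiment

With the shipped defaults (Nmm = 0.2, 200 iterations, 20 replicate seeds;
these are also the problem sizes used by `scripts/acceptance.py` and the
acceptance tests) the model produces: Gompertz-like saturation of the
proliferating population (plateau ≈ 900 cells), first necrosis at
iteration ≈ 31 (mean radius ≈ 14), the critical point NeC ≥ PC at
iteration ≈ 89, final growth fraction ≈ 0.19, final necrotic fraction
≈ 0.81, and a lattice pH floor ≈ 6.92. Mean per-tumor-cell oxygen and pH
decline monotonically once the tumor exceeds ~50 cells; the center is
more hypoxic and acidic than the edge; raising Nmm shrinks the tumor
volume under paired seeds.

One structural property deserves emphasis: because `Rn ≈ Rt − 1.5` and the
core rule executes before any nutrient rescue, a quiescent cell deeper
than ~1.5 units below the mean radius always necroses on its next update.
A thick, persistent quiescent shell therefore cannot exist under this rule
set — the quiescent fraction stays below ~1% and the growth and necrotic
fractions are complementary (GF + NF ≈ 1). A substantially lower necrotic
fraction at fixed growth fraction would require either a thicker geometric
shell (larger `a`, `b`) or rescue-before-necrosis ordering, both of which
would change the rule set itself rather than a parameter.

## Numerical and design choices

- **Radius of a rough cluster.** `Rt` is the mean distance to boundary
  tumor cells (tumor cells with a non-tumor Moore neighbor); a single-cell
  tumor has `Rt = 0`, and a tumor-free lattice raises an error rather than
  returning a sentinel.
- **Critical point.** First iteration with NeC ≥ PC after any positive PC
  count; no interpolation between iterations.
- **p2 normalization.** The nonmutant division probability divides the
  free-neighbor count by the Moore maximum 8 so probabilities stay in
  [0, φ0].
- **Rule-order ties.** PCs are updated in a freshly shuffled order each
  iteration to avoid directional growth bias; QC updates use the geometry
  computed at the start of the iteration; daughters born in an iteration
  do not act until the next one.
- **Normal-cell death** leaves empty space (state 0 with the empty flag)
  rather than a necrotic site, so the necrotic core counts only
  tumor-derived cells; a configuration toggle (`normal_death`) provides
  the alternative.
- **Medium clearance of acid** applies at non-tumor sites only
  (`replenish_mode` also offers a boundary-only variant).
- Geometry spot values are exact: `Rt = 8 → Wp = 0.44, Rn = 7.14`;
  `Rt = 27 → Rn = 25.59`.

## Known limitations

- Lengths are lattice units throughout; no physical site size is fixed, so
  radii are comparable between runs but not directly to millimeters.
- The five-field transport is an isotropic block-averaging scheme, not a
  PDE solve; its effective diffusivity is set by α, not by the literal
  cm²/s values, which enter only through the α ratios.
- Growth/inhibitory factor fields are carried but functionally inert.
- The complementarity GF + NF ≈ 1 discussed above: quiescent-cell counts
  are structurally small, and endpoint necrotic fractions run high
  relative to spheroid systems with thick quiescent shells.
- The radial division-probability factor `(1 − r/Rmax)` imposes saturation
  by fiat; it stands in for pressure and nutrient limitation rather than
  modeling either mechanistically.
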