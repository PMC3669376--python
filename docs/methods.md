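# Methods

## Model summary and assumptions

The simulator couples a vertically resolved dendritic-network model with a
condensed signalling layer on a 2-D (x, z) cross-section of the
substrate-attached cell surface. The structural assumptions, shared with
the modelling tradition this package follows, are:

* filaments are vertical and tethered to the membrane at their barbed
  ends; they are fully described by the density of their pointed ends and
  do not diffuse or exert forces;
* polymerization happens only at barbed ends (at the membrane, consuming
  membrane-bound G-actin) and depolymerization only at free pointed ends;
* barbed-end capping, filament severing, and mother-filament-loss
  debranching are omitted; the effective depolymerization speed is chosen
  high to stand in for the missing disassembly routes;
* the PI3K limb of the signalling pathway is condensed into a single
  diffusible species (Rac) activated at the membrane in proportion to the
  local barbed-end density; PTEN has no dynamics of its own and is
  represented only as a membrane region where that activation is disabled.

Nucleation is either dimerization of membrane G-actin (producing a
length-2 free filament) or branching by the WASP·Arp2/3·G-actin complex
(producing a length-1 Arp2/3-capped filament). The two disassembly routes
are their exact inverses: dissociation of dimers and debranching of
length-1 branches. After branching, the WASP molecule returns to its
activated state (configurable), keeping the complex cycle catalytic.

## Units

Concentrations in µM, lengths in µm, time in s. Membrane species carry
µM·µm (a z-integral of a concentration), which makes every
membrane–cytosol exchange directly a boundary flux of a cytosolic field.
The subunit length is δ = 2.7 nm (half the G-actin monomer length), so a
column of pointed ends P (µM·µm) corresponds to an F-actin concentration
P/δ at the membrane.

## Parameters

Totals and diffusivities sit in physiological ranges: 50 µM total actin,
0.8 µM Arp2/3 (deliberately low — branching is Arp2/3-limited), 2 µM each
coronin and Rac, 0.6 µM·µm WASP; D = 5 (G-actin), 2.5 (Arp2/3, coronin),
1.5 (Rac) µm²/s. The kinetic constants were set by a scale analysis and
then frozen:

* `v_poly = 0.1 (µM·µm)⁻¹ µm/s` with resting `g_m ≈ 2.6 µM·µm` gives a
  barbed-end growth speed ≈ 0.26 µm/s; with cap protection lasting
  ≈ 6 s (`k_cor·Cor ≈ 0.3 s⁻¹`, `k_debranch = 0.35 s⁻¹`) the wave grows
  ≈ 1.3 µm tall, matching the micron-scale height of observed waves.
* `v_depoly = 0.35 µm/s` puts resting treadmilling slightly below balance
  so exposed filaments erode and the rest state holds no standing network.
* The feedback-loop gain (`k_rac_act = 12 (µM·µm)⁻¹ µm/s`,
  `k_rac_deact = 0.6 s⁻¹`, `k_wasp_* = 1 s⁻¹`-scale, `k_branch = 6
  (µM·µm)⁻¹ s⁻¹`) makes the rest state sub-excitable (spontaneous
  background gain ≈ 0.3 of break-even) while a localized precursor ignites
  self-sustaining fronts. The activated-Rac decay length √(D/k_deact)
  ≈ 1.6 µm sets the front speed, which comes out at ≈ 0.09 µm/s — the
  observed scale for these waves.
* `k_poly` and `k_depoly` default to `v_poly/δ` and `v_depoly/δ`, the
  values for which monomer consumption exactly matches advection.

## Numerics

One step is an operator splitting: half-step reactions → filament
transport → implicit diffusion → half-step reactions.

* **Transport**: first-order conservative upwind advection along z with a
  per-column speed, plus the explicit stabilizing diffusion `δ|v|/2` that
  the continuum reduction carries. The membrane G-actin drain and the
  depolymerization release are charged against the *realized* upwind
  fluxes inside the same kernel, so the actin ledger closes exactly
  regardless of dt. The transport kernel sub-steps adaptively so the
  polymerization drain can never overdraw `g_m`.
* **Reactions**: bulk conversions are explicit and flux-limited. The
  membrane layer is sub-stepped adaptively; within a sub-step the stiff
  short-filament ladder (per-filament rates v/δ ~ 10²/s) is integrated
  with exact exponential updates whose realized channel fluxes are
  distributed stoichiometrically — unconditionally stable, positive, and
  exactly conservative.
* **Diffusion**: dimensionally split backward-Euler solves with banded
  tridiagonal systems; unconditionally stable, positivity-preserving, and
  mass-conservative with no-flux walls.
* **Length-3 closure**: the length-3 pool is eliminated by its
  pseudo-steady balance and treated as a flux conduit that passes through
  exactly what enters it each sub-step; its ~3-subunit content is excluded
  from the audit by construction. Because a filament entering the
  continuum at the bottom-cell centre z₀ = dz/2 instantly represents z₀/δ
  subunits while the pool and membrane supplied 4, each 3→4 transition is
  charged (4 − z₀/δ) to G-actin and each 4→3 re-entry returns (z₀/δ − 3);
  together with the column term −(ν/δ)(τ_bottom − τ_top) for the
  stabilizing diffusion these corrections make all four global budgets
  (actin, Arp2/3, coronin, Rac) constant to accumulation round-off
  (measured drift ~10⁻¹² relative per 100 s).
* Degenerate inputs: densities pushed below zero by round-off are clamped
  (tracked in a ledger; a deficit beyond 10⁻⁶ µM·µm aborts the run);
  NaN anywhere aborts with a solver error.

Default grid: 20 × 3 µm at 128 × 48 cells, dt = 25 ms. These resolve the
front (≈ 1.5 µm wide) with ~10 cells and satisfy the advective CFL with a
factor ≈ 5 margin. Test and acceptance runs use this desk scale; the
problem sizes were chosen so the whole suite completes in minutes.

## The discrete oracle

The 1-D monomer-resolved model tracks filament densities per subunit
length and free species per δ-segment, with purely explicit stoichiometric
updates: every reaction moves whole subunit-equivalents, so its budgets
are conserved to ~10⁻¹⁶ per step. It exists to validate the continuum
reduction: on matched smooth cohorts the two models agree to ≲ 2 %
relative L2 once the structure scale is ≳ 10 δ, with the error decreasing
monotonically in the structure scale. Verification runs use an artificial
δ = 0.05 µm (the physical 2.7 nm would need ~10⁷ explicit steps);
profiles are compared above a 6-subunit boundary layer because the
juvenile-filament zone is represented by construction differently
(membrane pools vs resolved cohorts) and coincides only as δ → 0.

## Synthetic scenarios: what they emulate and what they do not

The precursor (a transient local fold-increase of the dimerization
constant) stands in generically for clathrin pits, adhesion sites, or
density fluctuations — the model deliberately does not distinguish them.
The scenarios reproduce: ignition only above a sharp precursor-strength
threshold, with initialization time falling steeply just above threshold
and slowly (≈ linearly in log-fold) far above it; front speed and peak
height independent (< 0.1 %) of ten-fold stimulus changes; no waves
whatsoever when the barbed-end → Rac feedback is disabled; activated Rac
high throughout the enclosed region with its transition slightly outside
the F-actin front; coronin-capped ends decorating filament tops and
trailing the front; fusion of colliding wave regions with annihilation of
the fronts between them; stalling of a front at a static PTEN border into
a standing wave; retraction ahead of an advancing PTEN region with
simultaneous advance into vacated membrane; and splitting of an enclosed
region by a PTEN intrusion, with new fronts forming at the intrusion
borders.

They do not emulate optical artefacts (no point-spread function; TIRF is
an ideal shallow integral with a 0.2 µm default depth), membrane
deformation, or any force balance; and passing tests on this synthetic
physics say nothing about processes the model omits (capping, severing,
myosin, PTEN dynamics).

## Known limitations

With this reaction network — mass action, every budget locally recycled,
no capping or severing — the post-ignition dynamics of a column relax
*monotonically* to a stable active state: a parameter scan over the
branching gain, cap-stripping rate, depolymerization speed, diffusivities
and totals never produced an overshoot of the barbed-end density. The
simulated waves are therefore trigger fronts that leave a persistent
active plateau behind them, rather than solitary bands with a collapsed
interior: at the micron scale of a front, every cytosolic resource
re-equilibrates by diffusion within a second, and every membrane resource
recycles within the filament lifetime, so no locally depleted "refractory"
variable survives behind the front at desk-scale domain sizes. Three
consequences are visible in the test suite: the initiation site does not
collapse after the fronts separate, the fused region after a collision
remains above the front-detection threshold, and the free-Arp2/3 minimum
tracks the consuming fronts instead of sitting strictly inside the
enclosed region (interior depletion is only a few per cent). Region-scale
scarcity — and with it banded profiles — would require domains and
horizons an order of magnitude beyond the desk-scale grids used here.

The tracker's detection threshold is 0.5 of the running peak intensity
(documented knob, used consistently); initiation times use an absolute
detection level of 3 µM·µm at a probe 3 µm outside the stimulus, since a
running-peak fraction is undefined before any wave exists.
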