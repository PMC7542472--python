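# Methods

## Model overview

`tumorshed` simulates a growing, heterogeneously oxygenated tumor as `n`
concentric cylindrical shells ("compartments") of single-cell thickness
around a vascular core, and converts the resulting proliferation/necrosis
dynamics into plasma trajectories of shed proteins. The package trades
spatial fidelity (no PDEs, no cell agents) for a small, interpretable
parameter set and sub-second 12-year simulations, which makes exhaustive
parameter scans cheap.

## Geometry

A vessel of mean diameter `d` defines a core of radius `δ = d/2`. Viable
tissue extends a necrotic cuff `ε` (the oxygen diffusion distance, ~100 μm)
beyond the vessel wall and is partitioned into `n = ε/σ` shells of width
`σ` (~one cell diameter). `ε` must be an integer multiple of `σ`; the
default 100/10 gives `n = 10`. Shell subvolumes at vascular height `h` are

    v₁ = π(σ+δ)²h,    vᵢ = π[(2i−1)σ² + 2σδ]h  (i ≥ 2),

where the innermost subvolume deliberately includes the core term δ²h so
that Σvᵢ = π(nσ+δ)²h exactly; the ratio recurrence
`vᵢ = [((2i−1)σ+2δ)/((2i−3)σ+2δ)]·vᵢ₋₁` therefore holds from i = 3 when
seeded at v₂. Radial distance `r` is measured from the vessel wall, so the
tissue annulus is `0 < r ≤ ε` and compartment membership is `⌈r/σ⌉`.

Vascular height grows linearly, `h_t = k_V·t`, in millimetres: with the
cell density ρ in cells/mm³ this is the unit choice that makes capacities
`K_{i,t} = vᵢ(h_t)·ρ·p` dimensionally consistent (`p` is the tumor-cell
volume fraction). `h` is best read as an abstract vascularization level
with units of length, not a literal vessel length.

## Oxygen and rates

Oxygen falls exponentially from the vessel wall, `C(r) = C₀·0.5^(r/r_½)`
with `r_½ = 0.018 mm`, which leaves the cuff edge (95 μm midpoint) at
~0.4% of a 16% wall concentration — near-anoxic, matching the necrotic-cuff
rationale. Birth and death rates are straight lines through the two
in-vitro anchor measurements (birth 7.8e-4 day⁻¹ at 1% O₂ and 8.2e-3 at
20%; death 1.6e-3 at 1% and 0 at 20%), evaluated at each compartment
midpoint, extrapolated linearly outside the measured span and clamped below
at zero (negative per-capita rates have no meaning in the difference
equations). Fitting each line exactly through its two measured points is
the only reading that reproduces both printed anchor values and gives death
decreasing in oxygen. Net growth `k_G = k_B − k_D` is then positive in inner
compartments and negative in the outermost ones.

Shedding weights are `wᵢ = 1/√sᵢ` with the midpoint `sᵢ` in μm — a
one-dimensional diffusivity attenuation. The unit convention fixes the
absolute scale of `w` (w₁ ≈ 0.447); any rescaling is absorbed by Φ/Ψ.

## Daily update

Each day, in pinned order: (1) capacities refresh from `h` at the new day;
(2) births `k_B·Δt·P` and deaths `k_D·Δt·P` apply (dead cells are cleared
instantly and tracked as instantaneous/cumulative counts); (3) an
inner-to-outer overflow sweep moves strict excess `P−K` one shell outward —
the donor is debited (conservation forces this even though only the credit
appears in the recurrence) and the outermost shell is uncapped, since
deleting its excess would silently destroy cells; (4) deterministic
motility fractions exchange cells between neighbors: 10%/day inward, 5%/day
outward, boosted to 10% outward when the donor is ≥10× its outer neighbor
or that neighbor is empty. All fluxes are computed from the pre-move state
and applied simultaneously, so every exchange conserves cells exactly. The
order of these sub-steps changes results, so it is fixed and documented
rather than configurable.

Populations are real-valued; the seed `P₀ = 1` cell is placed in the
innermost compartment at t = 0, when `h = 0` and all capacities are zero —
capacities first bind on the step to t = 1, so the seed is not instantly
overflowed. Motility is fractional, not a per-cell Bernoulli draw, keeping
the model fully deterministic (a seeded stochastic mode is deliberately out
of scope; the CLI's `--seed` is reserved for it).

## Plasma kinetics

For each protein: `uᵢ = wᵢ·Φ·Pᵢ` (extracellular, EC=1) or
`uᵢ = wᵢ·Ψ·Dᵢ/Δt` (non-extracellular, EC=0), and

    q_{t+1} = Σuᵢ·Δt + u_H·Δt + (1 − k_E·Δt)·q_t,  k_E = ln2/t_½.

`q₀` defaults to the healthy steady state `u_H/k_E` so tumor-free runs are
flat; in xenograft settings `u_H = 0` (the tracked human protein is
non-endogenous to the host) and `q₀ = 0`. For half-lives short enough that
`k_E·Δt ≥ 1` (e.g. t_½ = 0.64 day) the daily Euler step would oscillate;
the plasma recurrence alone is then sub-stepped with the smallest `m`
giving `k_E·Δt/m ≤ 0.5`, while populations stay on the daily grid. Units
`U` are arbitrary and never converted to concentrations.

## Experiments

* **Validity grid scan** over `(k_V, C₀)`: one simulation per pair,
  recording final population and populated-compartment count (threshold:
  >1 cell). A run is valid if it reaches 10⁷ cells with all compartments
  populated at 12 years; among valid runs the smallest final population is
  selected (the most necrotic tumor that still qualifies), with ties broken
  toward smaller `k_V`, then smaller `C₀`. The `C₀` grid defaults to the
  measured-oxygen span [1, 20]% since no other range is established.
* **Sensitivity sweeps**: one-at-a-time families over `k_V`, `C₀`, Φ/Ψ,
  t_½, u_H against the pinned baseline (t_½ = 6.4, Φ = Ψ = 4.5e-4,
  u_H = 456). Protein-side sweeps reuse one cached growth run.
* **Decomposition**: per-day compartment shares of population, deaths and
  outflux; shares sum to 1 wherever the total is positive.
* **Envelope scans**: all (Ψ, t_½) combinations at each u_H level
  (defaults: u_H ∈ {4.56, 456, 4.56e4}, t_½ ∈ {0.64, 20.24, 640},
  Ψ ∈ {1.423e-2, 2.531, 450}); the pointwise min/max trajectories bound
  the dynamic range and, by monotonicity of `q` in Ψ and t_½, coincide
  with the corner trajectories — verified by brute force in the tests.

## Numerical and design notes

* Internal geometry is in mm; μm values are converted once at the config
  boundary, and config field names carry units to prevent silent drift.
* Overflow uses strict inequality (`P = K` sheds nothing).
* The growth-slowdown detector reports the first day the trailing 30-day
  log-growth rate of total population falls below half the initial
  exponential rate, where the initial rate is the maximum trailing rate in
  the first two years (robust to the seeding transient).
* The acceptance script runs the full 12-year baseline (4380 daily steps ×
  10 compartments) and a 5×5 validity grid in seconds; test fixtures use
  shorter horizons (200–2000 days) where the property under test does not
  need the full run.

## What the defaults do and do not emulate

The default parameter set represents a slow-growing solid tumor (ovarian
cancer scale) with literature-derived geometry and rate anchors from
non-small-cell lung cancer cultures. Passing tests demonstrate internal
consistency — conservation, closed forms, monotone responses — and the
qualitative corner structure of the vascularization/oxygen plane; they do
not validate against in-vivo kinetics, which would require tuning `k_V`,
the anchors and the protein parameters to a specific tissue.

## Known limitations

* With the stated motility fractions (0.05–0.10/day, ~20× the net growth
  rates), the quasi-steady radial distribution is broad and the aggregate
  exponential growth rate (~3.5e-3/day at C₀ = 16) sits well below the
  innermost compartment's rate (~5.0e-3/day). Consequently the baseline
  pair grows to ~2.6e6 cells in 12 years and leaves its exponential phase
  at ~11 years; reaching 10⁷ cells within 12 years requires the upper
  corner of the scanned (k_V, C₀) range.
* Linear vascularization imposes a linear capacity ceiling; no angiogenic
  feedback, no metastatic escape, no interstitial degradation, no
  measurement noise, and dead cells occupy no space.
* Oxygen is static in time and purely exponential in distance; rate-oxygen
  response is linear (no Hill/Michaelis–Menten saturation).
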