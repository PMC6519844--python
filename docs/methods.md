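# Methods

## Model structure and assumptions

All five variants describe the mean counts n_i(t) of free bacteria
(i = 1) and linear chains of length i under three competing processes:
replication (each bacterium at rate r, or synchronously every τ),
per-link breaking (rate α, possibly force-weighted), and absorption of
inner-break fragments into complex clusters. The assumptions shared by
every variant:

- Bacterial densities are low enough that unrelated chains never meet;
  every chain evolves independently, so the mean dynamics are linear.
- Complex clusters are absorbing: they never release bacteria or chains.
  They are tracked only as a bacteria counter in the simulator.
- An outermost break always frees the single terminal bacterium (it is
  small and motile); a length-2 chain frees both members.
- Early infection: no carrying capacity, no death (death would act like
  extra breaking), no escape mutants, no buckling of long chains.

The long-time behaviour is N(t) → C e^{λt} P with λ the dominant
eigenvalue of the (Metzler) rate matrix and P ≥ 0 its eigenvector,
normalised to sum to one. For synchronous division the analogue is the
per-interval nonnegative transfer matrix T, whose Perron value N gives
λ = log(N)/τ.

## Parameters

| symbol | meaning | default | units |
|--------|---------|---------|-------|
| r | replication rate per bacterium | 1 | 1/time |
| α | breaking rate per link | 1 | 1/time |
| τ | division interval (`fixed_time`) | log 2 | time |
| δ, δ′, δ″ | escape probabilities on replication (free / tip / interior) | 0 | — |
| c, c′ | loss rates of free bacteria / chains | 0 | 1/time |
| q | inner-break subchain survival probability | 0 | — |
| β | force–breaking coupling | 0 | — |

Only the ratio r/α (or r_eff/α = log 2/(ατ)) matters for stationary
shapes; α sets the clock. Defaults put the system at r = α, the regime
where growth and fragmentation genuinely compete.

## Truncation

The infinite length hierarchy is cut at n_max, with flux past the
boundary dropped — chains that outgrow the truncation are treated as
lost to complex clusters, which is conservative for λ. Adequacy is
checked by recomputing λ at doubled n_max and requiring a relative
change below `convergence_tol` (1e-8 by default). Defaults per variant:
40 (base, escape), 32 (fixed_time), 200 (q_model, whose distribution has
the fattest tail), 10–15 (force, whose tail decays like exp(−βi³/24)).
`solve_eigen` auto-doubles up to a cap of 400 when the check fails.

Force model only: matrix entries grow like exp(βn²/8), and the dense QR
eigensolver loses the O(1) dominant eigenvalue once entries pass roughly
e^250 (measured empirically: wrong eigenvalues appear near e^260 and
complex pairs near e^300). Automatic growth of n_max is therefore capped
at βn²/8 ≤ 250 and the adequacy probe steps *down* by 4 when already at
the cap. Because of the cubic tail decay this cap is physically
inconsequential; λ is stable across n well below it. Explicit
construction beyond βn²/8 = 700 (float overflow) is refused with the
largest safe n_max reported.

## Numerical choices

- **Eigensolve**: dense full-spectrum `scipy.linalg.eig` with left
  eigenvectors; the dominant value (largest real part for generators,
  largest modulus for transfer matrices) is refined by one Rayleigh
  quotient λ = wᵀMv / wᵀv, which removes the QR iteration's
  O(eps·‖M‖) noise. The eigenvector is sign-fixed so its largest entry
  is positive; entries in (−1e-10·max, 0) are clipped to zero, anything
  more negative raises (it would indicate a construction bug, not noise).
- **Within-interval survival** l(n, i, t) = (2^i/i!) e^{−αt(n−1)}
  (e^{αt}−1)^i is evaluated in log space (gammaln, stable log(e^x−1)).
- **Free-bacteria yield** ℵ(n, τ) = 2α Σ_i ∫₀^τ l dt uses the exact
  recurrence I(n,i) = (2α I(n,i−1) + [i=0] − l(n,i,τ)) / (α(n−1−i))
  obtained by integrating the fragmentation ODE term by term; it is
  closed-form, stable (all quantities positive, denominators ≥ α) and
  O(n) per column, where adaptive quadrature would cost O(n) integrand
  evaluations per entry. Quadrature remains available as
  `method="quadrature"` and the two agree to ~1e-10 in the tests.
- **Time integration** of dN/dt = MN uses the matrix exponential
  (propagators cached per step size) — exact for a linear system and
  immune to the force model's stiffness.
- **Argmax search**: a 20-point coarse scan over the bracket (default
  [0.1, 10] in units of α; [0.1, 40] for the force model, whose optimum
  reaches ≈ 12α at β = 3) brackets the maximum, then bounded
  golden-section/Brent minimisation of −λ refines to 1e-3 in r/α. A
  coarse maximum on the bracket edge (monotone regimes: q > 0.5, strong
  escape) is returned as a flagged boundary result, not an error.
- **Force lattice sums** Y = 1 + 2Σ e^{−βj²/2}, Z = 2Σ e^{−β(j−1/2)²/2}
  are truncated when a term drops below 1e-16 (exact for every β ≥ 0.01
  used here).
- The rough fixed-time shape i^{ατ/log2 − 1} e^{−2ατ(i−1)} is anchored
  to equal 1 at i = 1, since its overall constant is undetermined; all
  comparisons against eigenvectors are shape-only (ratios to p_1),
  matching how such approximations are used. It is derived for lengths
  that are powers of two and with the per-interval multiplier at its
  large-ατ limit of 2, so it is an order-of-magnitude guide only.

## Stochastic simulator

The simulator executes the event rules, not the mean-field equations:
Gillespie's direct method with per-length aggregate propensities
(chains of equal length are exchangeable in every variant — force-model
link rates depend only on length and position, and positions are fixed
by length), then a categorical choice of bacterium or link within the
chain, force-weighted where applicable. Synchronous division alternates
deterministic doubling with exponential-clock fragmentation sampled
just before the next division. A population cap (default 10⁶ bacteria)
stops runs that grow exponentially; capped results carry a `truncated`
flag rather than being returned silently.

What the synthetic data does and does not emulate: histograms produced
by `sample_histogram` are ideal multinomial draws from a stationary
shape — they have no optical truncation of long chains, no
misclassification of complex clusters as linear chains, no focal-plane
bias, and no over-dispersion from between-host variation. Parameter
recovery on them demonstrates that the likelihood machinery is correct
and calibrated (coverage ≈ 95% at realistic sample sizes); it does not
demonstrate that a real microscopy histogram satisfies the sampling
model.

## Fitting

The stationary shape has one identifiable parameter, the ratio r/α
(rate variants) or r_eff/α (fixed time). Observed counts of linear
chains of length ≥ 2 are modelled as a multinomial draw from the
dominant eigenvector conditioned on that window — free bacteria are
excluded because image-derived counts of singletons are unreliable, and
the support is left open-ended above (the operator is truncated at
4× the longest observed chain; zero-count lengths contribute nothing).
The MLE comes from bounded scalar optimisation on [0.05, 50]; the 95%
interval collects ratios within χ²₁(0.95)/2 = 1.92 log-likelihood units
of the maximum (profile likelihood), falling back to the search
interval with a warning when the likelihood cannot pin the ratio (all
mass at one length). Goodness of fit is the deviance against the
saturated multinomial with a parametric-bootstrap tail probability.

Inside the likelihood the truncation is held fixed rather than
convergence-checked: a bounded optimiser probes extreme ratios (e.g.
r_eff/α ≈ 30, ατ ≈ 0.02) where the doubling check cannot pass at any
reasonable size, while the conditioned window is insensitive to it.

## Problem sizes used in the checks

The test suite and acceptance script use: n_max = 40/32/200/10–15 per
variant as above; 10³ stochastic replicates against five mean-field
checkpoints; 10⁴-chain histograms for point recovery and 200 replicates
of 500 chains for interval coverage; six β values for the force scaling
law. These sizes hold every Monte-Carlo comparison at 3 standard errors
while keeping the full suite to a couple of minutes.

## Known limitations

- Mean-field λ and P describe expectations; extinction probabilities
  and other stochastic functionals are out of scope (the simulator can
  produce them, but nothing in the package analyses them).
- The escape-variant geometric approximation depends only on δ″; its
  accuracy degrades when δ, δ′ differ from δ″ and at large r/α.
- The q-model growth-rate approximation r(α + (2q−1)r)/(α+r) is
  unreliable below q = 0.5, and the free-fraction decay law inherits
  its error exponentially in t.
- The fitted ratio is only as meaningful as the multinomial sampling
  assumption; real histograms with size-dependent detection need a
  detection model the package does not supply.
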