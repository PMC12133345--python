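# Methods

## The circuit and its deterministic layers

The model is a two-variable auto-regulatory loop: a single gene copy with
active fraction G\* ∈ [0, 1] (so the inactive fraction is G = 1 − G\*) and
its protein product IκBα with copy number I.  NF-κB (level N, molecules)
drives activation through fA(N) = N^nH1/(Km1^nH1 + N^nH1); IκBα controls
the deactivation channel through fR(I) = Km2^nH2/(Km2^nH2 + I^nH2).  Time
is in minutes; in the deterministic layers I is a continuous non-negative
real, in the stochastic layers an integer.

A note on the loop's sign structure: fR multiplies the *deactivation*
rate and decreases with I, so as printed higher IκBα *reduces* gene
shut-off — a positive feedback of I on G\* (the coupling coefficient
q = k2 |fR′| G\* enters the Jacobian with positive sign, and it is this
positive loop that produces the saddle-node structure).  The equations are
implemented exactly as stated; the biological reading of the circuit as a
negative-feedback inhibitor loop is left to the model's originators and
not resolved here.

Default parameters (the reference condition for every experiment):
k1 = 1 min⁻¹, k2 = 3.4 min⁻¹, kP = 0.065 molecules·min⁻¹,
kd = 0.002 min⁻¹, Km1 = Km2 = 12 molecules, nH1 = 1, nH2 = 4, N = 100.
kP/kd is the ceiling of the stationary mean protein number; density grids
default to [0, 1.5 kP/kd] with 4000 points.

**Equilibria.**  Under the quasi-steady-state approximation the scalar
drift is S+(I) − kd I with S+(I) = k1 kP fA/(k1 fA + k2 fR(I)).  Roots are
found by a bracketing scan on a 4096-point uniform grid over
[0, 1.05 kP/kd] followed by Brent refinement to |residual| < 1e-10.  A
dense scan was preferred over arclength continuation because the problem
is scalar with at most three roots; it cannot lose a branch at a fold.
Stability is classified from the 2×2 Jacobian of the full system (not the
QSSA), so the delay analysis reuses the same linearization; a saddle has
real eigenvalues of opposite sign.

**Bifurcation mapping.**  One-parameter branches enumerate all equilibria
per parameter value; folds are bisected on the change of root count to
relative tolerance 1e-6.  Two-parameter saddle-node loci bisect the fold
in the second parameter per grid column and polish each point with a
Newton solve of (f, ∂f/∂I) = (0, 0) (verified to 1e-8 in tests).  Cusps
are reported where a fold pair merges between adjacent columns, refined by
bisection on pair existence; coordinates are grid-refined, not exact
normal-form points.  At the defaults the kd scan has folds at
kd = 0.0018195 and 0.0022649 — these two numbers reappear as the delayed
oscillation boundaries below.

## Delay analysis

With delayed activation G(t−T) the linearization about an equilibrium
(G\*, I\*) gives

    (λ + a + b e^{−λT})(λ + kd) − q kP = 0,

a = k2 fR(I\*), b = k1 fA(N), q = k2 |fR′(I\*)| G\*.  The sign of the
q kP term is fixed empirically rather than assumed: the construction
asserts that at T = 0 the characteristic roots equal the Jacobian
eigenvalues to 1e-8.  Writing the equation as P(λ) + Q(λ) e^{−λT} = 0,
imaginary roots require |P(iω)| = |Q(iω)|, a quadratic in ω² solved in
closed form; each admissible ω yields the delay ladder
T_mj = (θ(ω) + 2πj)/ω with the phase θ ∈ [0, 2π) of −P/Q, j ≤ 10 by
default.  TH = min T_mj.  At kd = 0.0015 this gives TH = 1.788 (≈ 1.8);
at kd = 0.002, TH = 1.884.

The oscillation boundary in kd at fixed T along the upper branch is the
first of (i) the TH(kd) = T crossing and (ii) the branch's fold; at
T = 2.5 the branch is oscillatory all the way to its fold, so the
boundary is the fold itself, 0.0022649 (reported to three significant
figures as 0.00226).  From the low initial history the boundary is the
lower fold, 0.0018195 → 0.00182.

## Delayed integration

Fixed-step RK4 with h = 0.001 min.  The delay is rounded to the nearest
step multiple (error ≤ h/2), so delayed lookups are exact reads from a
ring buffer; all four RK4 stages reuse the same delayed value, which is
O(h⁴)-consistent only for the non-delayed terms.  Step halving changes
post-transient amplitude and period by < 0.1% at the reference settings.
At T = 0 the integrator switches to the standard (stage-updated) RK4 and
matches an independent ODE integration to better than 1e-9.

Two facts about the printed delayed equations that the package preserves
deliberately rather than "fixing":

* they do **not** keep G\* inside [0, 1] — deep in the oscillatory regime
  the gene variable makes large excursions outside the box (stable under
  step refinement and confirmed with an independent Euler integration),
  and consequently the limit cycle of I can exceed kP/kd (≈ 71 vs 43 at
  kd = 0.0015).  Clamping the delayed activation at zero would collapse
  the limit cycle to sub-molecule amplitude, contradicting the circuit's
  known O(10)-molecule oscillations, so no clamping is applied.  I itself
  stays non-negative at all tested settings;
* beyond T ≈ 5.5 at the defaults the oscillation loses boundedness
  entirely (a real property of the unclamped equations).  Amplitude/period
  phenomenology is therefore studied on T ∈ [2, 5], where the amplitude
  rises past onset and saturates (≈ 11.0–11.3 molecules at kd = 0.002).

Attractor classification discards a transient fraction (default 50%),
requires at least five peaks with period CV < 5%, and measures the swing
on the final fifth of the run so a decaying ring-down is classified
steady.  The steady/oscillatory threshold is a relative range of 1e-3 of
the mean level — far below genuine limit cycles, far above integrator
ripple.  Near the lower fold the escape from the saddle-node ghost takes
up to ~2e4 min (it diverges like the inverse square root of the parameter
distance), so the kd-boundary bisection integrates 4e4 min per run and
classifies on the final quarter; with a 2e-6 bisection tolerance the
boundary is accurate to ~0.3%.

## Stochastic kinetics

Three exact-event schemes: the full four-reaction Gillespie direct method
(binary gene), the reduced two-channel birth–death walk with propensities
S+(I) and S−(I) = kd I, and a coloured scheme in which the degradation
rate is kd (1 + ε(t)) with ε an Ornstein–Uhlenbeck process.  The OU
process follows its stated stationary correlator ⟨ε(t)ε(t′)⟩ =
(D/τ) e^{−|t−t′|/τ} (variance D/τ); the SDE prefactor is set to match
this correlator, which is the convention all UCNA formulas below use.
Updates are exact Gaussian steps, so no discretization error enters the
noise itself.

The coloured scheme is a time-dependent-propensity next-reaction method:
each channel carries a unit-exponential internal clock and hazards are
accumulated piecewise-constant over an OU grid of width min(τ/50, 0.1)
min (ε frozen within a cell); the grid width is a convergence knob.  The
modulated rate is clamped at zero when ε < −1; the clamp count is
recorded on the trajectory.  Clamping is negligible for D/τ ≪ 1 and
becomes a real part of the dynamics for σ_ε ≳ 1 (see the bimodality
discussion below).  Identical seeds give bit-identical event sequences.

Stationary histograms weight each visited state by its holding time, so
they estimate the exact occupancy law of the sampled path.  With ~1e6
events the reduced-scheme histogram matches the closed-form FPE density to
a sup-norm of 0.003–0.03 depending on kd, and a χ² test against the exact
birth–death product form π(I) ∝ Π S+(i−1)/S−(i) (on samples decorrelated
by 1500-min spacing) does not reject.

## Stationary densities

**Intrinsic (white) noise.**  The chemical Fokker–Planck stationary
solution with jump moments a1 = S+ + S− (diffusion) and a2 = S+ − S−
(drift): P(I) ∝ (1/a1) exp(2 ∫ a2/a1 dI).  Exponents are accumulated by
cumulative trapezoid; the log-density is shifted by its maximum before
exponentiation; normalization is by trapezoid rule to 1e-8.  The density
mode solves 2 a2 = a1′, not a2 = 0, so modes sit systematically ~1–2
molecules below the deterministic fixed points at these copy numbers
(finite-number skew) — agreement between modes and equilibria is asserted
at a 2.5-molecule tolerance, not one grid cell.

**Coloured noise (UCNA).**  With drift h = a2, coloured coupling
g1 = −S−, intrinsic source g2 = a1 and combined field
g² = D g1² + g2/2, the canonical UCNA correction is
Z(I) = 1 + τ (h g1′/g1 − h′) = 1 + τ (h/I − h′), and

    P(I) ∝ (1/g̃²) exp( ∫ (h̃ + g̃ g̃′)/g̃² dI ),  h̃ = h/Z, g̃ = g/Z.

The g̃ g̃′/g̃² term integrates to log g̃ exactly, so the implementation
evaluates log P = −log g̃ + ∫ h Z/g² dI, which is the same functional
with one less numerical derivative.  This prefactor (1/g̃ after the
cancellation) differs from the standard stationary-FPE prefactor 1/g̃²
by one factor of g̃; the form as stated is kept, and the consequence is
a small, documented offset (sup-norm ≤ 0.02 at the defaults) between the
UCNA density at vanishing noise and the white-noise FPE density.  The
grid starts one cell above I = 0 because Z ~ τ h(0)/I diverges there;
cells with Z ≤ 0 are excluded and the result carries a warning when they
exceed 5% of the support.

Limiting behaviour is the validation contract: as τ → 0 the density
converges monotonically to the Z ≡ 1 reference, and as D → 0 to the
functional's own intrinsic limit; both ladders are tested, as is
agreement with coloured-SSA histograms (sup-norm < 0.2 at moderate
noise).

**Noise-induced bimodality.**  At kd = 1e-3 the deterministic circuit is
monostable and the intrinsic density unimodal; slow, strong degradation
noise (e.g. D = 1000, τ = 1000, i.e. σ_ε = 1 with ~17-min effective
kd stalls) makes both the UCNA density and the coloured-SSA histogram
bimodal, with the extra mode near the low-expression state.  Under the
correlator convention above, the (D, τ) values at which this happens are
numerically larger than they would be under the alternative
variance-2D convention implied by the SDE prefactor as stated; only the
convention, not the phenomenon, differs.

## Spectra

SSA paths are piecewise constant, so they are resampled by zero-order
hold (default dt = 1 min) after a burn-in (default 20% of the horizon).
The autocovariance uses the biased (1/n) estimator — chosen over the
unbiased one to keep the implied spectrum positive semidefinite —
averaged over independently seeded trajectories; the spectrum is the DFT
of the evenly extended autocovariance with the e^{−2πiωt} kernel, so
frequencies are ordinary (cycles/min), not angular.  No taper is applied
by default, matching the bare transform.  Parseval's identity holds to
float precision and is asserted at 2%.  Ensembles of 100 trajectories
(the package's desk-scale default; larger ensembles only tighten error
bars) reproduce the qualitative contrasts: faster autocovariance decay at
higher kd, slower decay under long-correlated noise.

## Synthetic-data scope

Every experiment generates its own inputs from the parameter set above;
there is no external data.  What the stochastic layers emulate is a
single cell's protein-number fluctuations under the stated reaction
scheme with a constant NF-κB input; they do not emulate cell-to-cell
parameter variability, upstream NF-κB dynamics (IKK signalling,
nuclear–cytoplasmic shuttling), transcription/translation as separate
steps, or measurement noise.  Passing tests therefore certify the
numerics and internal consistency of this model family, not the fidelity
of the model to any particular experimental system.

## Known limitations

* The delayed system is integrated as stated, including its excursions of
  G\* outside [0, 1] and its divergence at large delays; results at
  T ≳ 5.5 (defaults) are not meaningful.
* UCNA is an adiabatic approximation; its validity region Z > 0 shrinks
  at very large τ and the rate-clamped simulation departs from it when
  σ_ε = √(D/τ) is large.
* Cusp coordinates are grid-refined estimates, not normal-form solutions.
* The enhancer comparison switches the NF-κB cooperativity nH1 between 1
  (typical enhancer) and 4 (super-enhancer) with nH2 held at 4, since the
  enhancer distinction concerns NF-κB cluster binding at the promoter;
  switching nH2 instead would conflate repressor cooperativity with the
  enhancer class.
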