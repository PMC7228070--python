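# Methods

## Single-bubble melting model

### States and energies

A duplex of N base pairs is a chain of two-state units (intact/melted).
The two terminal base pairs are boundary units that never melt — they are
anchored in the torque-application setup the model emulates — so a bubble
is a contiguous run inside bp 2..N−1 and the admissible macrostates are
the intact duplex plus the O(N²) single bubbles.  States with two or more
simultaneous bubbles are excluded: each additional bubble pays the full
initiation penalty ε = 4.1 kcal/mol, which at N = 50 suppresses their
weight by two orders of magnitude near the transition.

Energy of a bubble of n base pairs at [a, a+n−1] under total untwist Δτ:

    E(a, n, Δτ) = ε
                  − Σ_{i=a-1..a+n-1} E_stack(step i)      (n+1 disrupted steps)
                  − Σ_{i=a..a+n-1}   E_bp(i)              (pairing, charged once)
                  + C·(Δτ − τ₀·(n+1))² / (2n)             (bubble torsion)

and of the intact duplex:

    H(0) = kBT·(P/L)·Δτ²/2,   Δτ in radians.

Sign conventions follow the nearest-neighbour interaction-matrix form in
which the melted side of a step contributes −E_bp − E_stack and the
intact→melted boundary carries +ε: stacking energies are negative, so
−E_stack raises the energy of every disrupted step, and the (positive)
pairing energies enter with a minus sign as part of the same empirical
parameterization (the net cost of melting is carried by ε and the
stacking terms).

`pairing_double_count=True` switches to the literal matrix arithmetic in
which each melted base pair is charged −E_bp once per adjacent step,
i.e. twice in total.  The single-count convention is the default because
it is the one under which the packaged parameter set reproduces the
reference positional-entropy estimates (~0.40/0.09 kcal/mol, see below);
the double-count variant is retained for comparison and is covered by
the same enumeration/transfer machinery and tests.

For n > 0 no residual duplex torsional term is added: the bubble is the
soft element and absorbs the entire imposed untwist.  Consequently F(σ)
equals the harmonic intact form exactly when melting is disabled
(ε → large), a closed-form limit the tests assert.

### Parameters (defaults)

| symbol | meaning | default | unit |
|---|---|---|---|
| E_stack | stacking, 10 canonical steps | −0.57 … −2.55 | kcal/mol |
| E_bp | pairing, A·T / G·C | 0.64 / 0.12 | kcal/mol |
| ε | bubble initiation | 4.1 | kcal/mol |
| C | bubble torsional stiffness | 0.79 | cal/(mol·deg²) |
| τ₀ | equilibrium twist per step | 34.5 | deg |
| P | duplex twist persistence length | 110.8 (AT) / 119.9 (GC) | nm |
| L | contour of the active region | 43 × 0.34 = 14.62 | nm |
| T | temperature | 300 | K |

kB = 0.0019872 kcal·mol⁻¹·K⁻¹.  The sixteen dinucleotide steps map onto
ten representatives by reverse-complement symmetry.  The supercoiling
density is σ = Δτ/(n_active·τ₀) with n_active = 43 steps (the region
between bp 4 and 47 of the packaged 50-mers, matching the torque
coordinate the model emulates); the conversion is exact by construction.
Angles are degrees at every interface; the intact-state constant is
converted to radians internally (dimensional analysis of kBT·P/L, which
is energy per squared radian, fixes this choice).

### Partition sum, two routes

Enumeration evaluates every single-bubble chain energy directly
(incremental extension, O(N²)); the chain part is Δτ-independent, so σ
scans reuse it and only re-weight the torsional factors.  The transfer
route runs left-to-right over base pairs with states (never melted) /
(in bubble, m melted so far) / (closed, m melted), multiplying per-step
Boltzmann factors; its per-n totals W(n), re-weighted by
exp(−β·E_bubble(n, Δτ)), give the same Z.  Because E_bubble depends on n,
a single scalar bubble prefactor cannot be pulled out of the product —
the n-resolved bookkeeping is the only self-consistent formulation.
Both routes work in log space (logsumexp / logaddexp); by default
`partition_function` cross-checks them to 1e−9 absolute in log Z and the
test suite holds them to 1e−10 against an independent exhaustive
2^(N−2)-state oracle on short duplexes.

Derived quantities: p_melt(i) sums the weights of bubbles covering bp i
(zero at the two boundary pairs); the bubble-length spectrum is the
weight per n (n = 0 being the intact state); the melting onset is the
smallest grid σ with P(n ≥ 1) > 0.5 (default grid 0..0.12, step 0.001);
the positional-entropy effect is −kBT·ln(Z_restricted/Z_full) with
bubbles restricted to a region, evaluated by default at σ = 0.067, the
highest pre-melting window, with a sensitivity report over σ ∈
[0.06, 0.08] since the estimate varies by ~0.08 kcal/mol across it.

With the defaults the model gives: melting onsets 0.052 (AT) / 0.053
(GC) on the 0.001 grid; modal bubble length 1 bp just past onset with
p_melt peaking inside the TATA box for both sequences; positional
entropy 0.43 / 0.11 kcal/mol at σ = 0.067.  The two global onsets
differ by a single grid step — the stiffer all-G/C duplex stores
slightly more torsional energy (earlier melting) but the mixed sequence
has more meltable sites (more melting channels), and the two effects
almost cancel.  Region-locally the ordering is clean: the TATA box of
the GC sequence melts earlier than that of the AT sequence
(`transition_sigma(..., region=(17, 22))`).

## Harmonic elastic analysis

The stiffness is K = kBT·C⁻¹ with C the unbiased sample covariance of
the 3·n_steps helical dofs (twist, roll, tilt per step, grouped per
step).  Inversion uses a symmetric eigendecomposition with a relative
eigenvalue floor of 1e−10; near-singular covariances (e.g. fewer frames
than dofs) raise an error naming the offending eigenvalue — no silent
regularization.  A warning is emitted below dim+1 frames.

Per-step energies use the half-split rule: dof i receives
½·Δw_i·(KΔw)_i, i.e. its diagonal term plus half of every coupling
term.  The decomposition is exact (rows sum to ½ΔwᵀKΔw to machine
precision) and satisfies the virial identity ⟨Δw_i(KΔw)_i⟩ = kBT for
samples from the model's own Gaussian, so each dof averages kBT/2 —
the equipartition diagnostic.  Profile summaries use a 3-step running
mean (truncated windows at the edges) and block standard errors over a
configurable number of contiguous frame blocks (default 20; wall-time
bins are data-dependent, block count is not).

Twist persistence length: P = contour / Var(Σ twist), contour in nm
(frame-mean of the summed rises), variance of the end-to-end cumulative
twist in rad² — the only place angles become radians.  The estimator is
invariant to constant twist offsets and halves when every per-step
twist variance doubles.

Long-range coupling is summarized as the mean |correlation| outside the
tridiagonal band of the step×step twist covariance map (0 for nearest-
neighbour-only coupling, ρ for a constant-ρ map).

## Substate and geometry classifiers

BI/BII: sign of the wrapped difference (ε−ζ) mapped to (−180°, 180°];
negative → BI (trans/gauche−), otherwise BII (gauche−/trans), with ties
going to BII and a configurable threshold — the literature names the
regimes but no universal numeric cutoff exists.  Fraying: centre point =
midpoint of the two sugar-ring centres (centroids of the five ring atoms
when atomic coordinates are given, or pre-computed centres); S = distance
of the own sugar to the centre (the partner sugar is a configurable
alternative), B = distance of the base reference atom (N1 purines, N3
pyrimidines — the purine/pyrimidine rule extends the stated A/T atoms to
G/C) to the centre; frayed iff S < B.  Denatured: all Watson–Crick
donor–acceptor distances > 3.0 Å (configurable); monotone in the cutoff.

## Synthetic ensembles

The generator emulates the Gaussian fluctuation statistics of
unrestrained duplex DNA: a block-tridiagonal stiffness (diagonal 3×3
blocks diag(k_twist, k_roll, k_tilt), nearest-neighbour coupling blocks
diag(g_twist, g_roll, g_tilt)) with defaults k_twist = 0.040,
g_twist = 0.010, k_roll = 0.020, g_roll = 0.005, k_tilt = 0.035,
g_tilt = 0.005 kcal·mol⁻¹·deg⁻², means twist 34.37°, roll 2.0°,
tilt 0.0°, rise 3.4 ± 0.1 Å (independent of the angles).  These values
were chosen once so that (i) marginal twist fluctuations are ~4–5° per
step, (ii) nearest-neighbour twist anticorrelation is substantial while
lag>1 correlations are near zero, and (iii) the implied twist
persistence length, contour/(aᵀCa) with a the twist selector, is ≈ 112
nm — inside the 100–120 nm range for B-DNA torsional stiffness.

Global twist restraints are applied in closed form.  Hard constraint
aᵀx = c: conditional covariance C′ = C − C a aᵀC/(aᵀCa) (exactly one
zero eigenvalue, along a) and conditional mean.  Soft harmonic
restraint k_R(aᵀx − t)²: C′ = (C⁻¹ + 2βk_R aaᵀ)⁻¹ via the
Sherman–Morrison rank-one update, converging to the hard result as
k_R → ∞; the sampled ensembles match these formulas within Monte-Carlo
error in the tests.  The restraint target is expressed as a total-twist
offset so σ-like labels can be attached to synthetic ensembles.

What the generator does **not** emulate: anharmonicity, BI/BII-induced
bimodality in the helical parameters (provided separately as an explicit
labelled mixture), sequence-dependent stiffness variation along the
chain, and time correlation between frames (frames are i.i.d., so block
standard errors on synthetic data reflect pure sampling noise).  Tests
passing on these ensembles validate the estimators' algebra and
convergence, not force-field realism.

Randomness: every generator takes an explicit integer seed
(`numpy.random.default_rng`); outputs are bit-reproducible and record
the seed in their metadata.

## Numerical and design choices

- Log-space partition sums throughout; no overflow up to the largest
  meaningful untwists (σ ≫ 0.12).
- Problem sizes in the tests and acceptance script (50-bp duplexes,
  σ grids of ≤ 121 points, synthetic ensembles of 10³–10⁵ frames of ≤
  129 dofs) keep every computation at desk scale — seconds to a few
  minutes — which is the regime the single-bubble approximation is
  built for.
- 1-based inclusive base-pair coordinates everywhere; step i joins bp i
  and i+1; bedGraph export shifts to 0-based half-open.
- Tabular trajectory dialects: long (frame/step rows) and per-parameter
  series matrices; round trips are lossless to 1e−9.

## Known limitations

- Single-bubble restriction: fine for ~50-mers, wrong for plasmid-scale
  sequences where multi-bubble entropy matters.
- No temperature-melting curves: the pairing/stacking set is a
  room-temperature parameterization; T enters only through β and the
  intact-state constant.
- No left-handed/Z-DNA states: past the transition the model keeps
  absorbing untwist in a right-handed-melted bubble description.
- The positional-entropy estimate depends mildly on the evaluation σ
  (hence the sensitivity window); no single "correct" σ exists because
  the transition is a crossover, not a sharp point.
- The elastic model is harmonic; per-step energies reported for melted
  or strongly distorted ensembles are qualitative only.
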