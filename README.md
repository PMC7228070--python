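# torsionmelt

Statistical mechanics of duplex DNA under global torsional stress: a
sequence-dependent single-bubble Ising model that predicts where, when and
how much a globally unwound duplex melts, together with harmonic elastic
analysis of helical-parameter trajectories (stiffness matrices,
equipartition diagnostics, twist persistence length, BI/BII backbone
substates, fraying and denaturation calls) and synthetic Gaussian
ensembles that stand in for molecular-dynamics output.

It is written for structural bioinformaticians and simulators who study
supercoiling-driven duplex destabilization — the physics behind promoter
opening at TATA boxes and stress-induced duplex destabilization scans —
and who want a small, transparent, fully tested model rather than a
genome-scale pipeline.

## The model

A duplex of N base pairs under an imposed untwist Δτ (degrees) is either
fully intact or carries exactly one contiguous denaturation bubble of n
melted base pairs (multi-bubble states are excluded; each extra bubble
costs another initiation penalty ε and is negligible at this length).

- Intact: the untwist is stored as harmonic torsional strain,
  `H(0) = kBT·P/(2L)·Δτ²` (Δτ in radians), with P the duplex twist
  persistence length and L its contour length.
- Bubble at [a, a+n−1]: one initiation penalty ε, loss of the pairing
  energy E_bp of each melted base pair and of the stacking energy E_stack
  of each of the n+1 disrupted steps, plus the soft torsional term
  `E_bubble = C·(Δτ − τ₀(n+1))²/(2n)` with C the single-strand torsional
  stiffness and τ₀ = 34.5° the equilibrium twist per step.

The partition sum `Z(Δτ) = e^{−βH(0)} + Σ_{a,n} e^{−βE(a,n,Δτ)}` yields
the free-energy profile `F(σ) = −kBT·ln Z`, per-base-pair melting
probabilities, and the bubble-length spectrum, all as functions of the
supercoiling density `σ = Δτ/(43·τ₀)` (magnitude convention: positive σ
means unwinding).  Z is computed two independent ways — explicit
enumeration and a melted-count-registered transfer scan — that agree to
1e−10.

The elastic side fits `K = kBT·C⁻¹` from twist/roll/tilt fluctuations
(a 129×129 stiffness for the 43 central steps of a 50-mer), decomposes
per-frame energies as `½Δwᵀ·K·Δw` with half-split assignment of the
coupling terms, and estimates the twist persistence length as
contour / Var(cumulative twist).

## Worked example

```sh
python examples/03_positional_entropy.py
```

prints

```
AT: dF(restrict to TATA) = 0.428 kcal/mol at sigma=0.067 (range 0.351..0.430 over sigma 0.06-0.08)
GC: dF(restrict to TATA) = 0.114 kcal/mol at sigma=0.067 (range 0.082..0.118 over sigma 0.06-0.08)
```

These numbers answer: near the melting transition, how much free energy
does the denaturation bubble gain from being free to open anywhere in the
duplex instead of only at the TATA box (bp 17–22)?  In the mixed ~50%
A/T sequence many alternative soft sites exist and the positional freedom
is worth ≈ 0.43 kcal/mol; in the otherwise all-G/C sequence the TATA box
is essentially the only place that melts, so it is worth only ≈ 0.11.
The other examples scan the free-energy profile (`01`), locate the
melting onset and bubble sizes (`02`), verify equipartition and the
persistence length on synthetic trajectories (`04`), demonstrate
restraint-induced long-range coupling (`05`) and the substate/fraying
classifiers (`06`).

A thin CLI mirrors the library:

```sh
torsionmelt ising-scan --sequence AT --sigma-grid 0:0.12:0.001 --out profile.tsv
torsionmelt entropy-effect --sequence AT --region 17:22 --sigma 0.067
torsionmelt synth --seed 7 --frames 1000 --out traj.tsv
torsionmelt persistence --table traj.tsv
```

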