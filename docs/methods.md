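# Methods

## The model

A chromosome of length N is partitioned into N_seg = ⌊N/150⌋ non-overlapping
segments of L = 150 bp, the DNA persistence length: beyond one persistence
length, segments are mechanically decoupled, which motivates treating the
within-segment arrangement of nucleotides as random (local equilibrium)
while the segment compositions vary.

For a symbol class (strongly bonded S = G,C; weakly bonded W = A,T; or a
single nucleotide) the per-segment count n has genome-wide mean ⟨n⟩ and
standard deviation σₙ; the coefficient of variation ρ = σₙ/⟨n⟩ and the
relative fraction ξ = ⟨n⟩/L summarize it. Empirically σₙ greatly exceeds
the binomial value √(Lξ(1−ξ)) that random shuffling restores, and the count
series is long-range correlated with Hurst exponent H ≈ 0.8.

Writing β = n/L for the local occurrence rate, intervals between
consecutive occurrences of the class are locally exponential with rate β,
and the genome-wide interval law follows from the law of total probability,
P(l) = ∫P(β) β e^(−βl) dβ. Moment-matching a Γ law to the counts
(shape α = 1/ρ², rate λ = α/⟨n⟩ on the count axis, i.e. Γ scale
⟨n⟩/(αL) on the β axis) gives the Lomax closed form
P(l) = α sᵅ(s+l)^−(α+1) with s = αL/⟨n⟩ in bp. Its tail exponent is
α+1; it is exactly a q-exponential with 1/(q−1) = α+1, and for the small ρ
of genomes the two correspondences q = 1+ρ² and α ≈ 1/(q−1) coincide to
O(ρ²). (Sources that print both q = 1+ρ² and α = 1/ρ² simultaneously are
using that asymptotic identification; the package keeps the self-consistent
pair and documents the exact exponent.) The Γ support (0,∞) slightly
exceeds the physical bound β ≤ 1; at genomic parameters the excess mass is
negligible (≲10⁻⁸ at α ≈ 70, ⟨β⟩ = 0.5) and a truncated-Γ variant is
provided where it matters (the discrete mixture below always truncates).

## Discreteness: the lattice form of the interval law

Sequence positions are integers, so the exact in-segment interval law for
randomly placed symbols is geometric, P(l|β) = β(1−β)^(l−1), whose
continuum limit is the exponential above. At genomic mean intervals
(⟨l⟩ ≈ 2 bp for S at GC 0.5) the difference is not a technicality: the
continuum CDF is off by ~0.1 at l = 1. All comparisons with empirical
interval histograms therefore use the discrete mixture
P(l) = ∫₀¹ P(β) β(1−β)^(l−1) dβ (Gauss–Legendre quadrature over β, Γ
density renormalized on (0,1)); the closed-form continuum density is kept
as the analytic object and is validated against adaptive quadrature of the
mixture integral (relative agreement 10⁻⁶ or better over the density's full
dynamic range, including tail values near 10⁻⁶⁵) and against a 10⁶-draw
Monte-Carlo mixture (KS distance < 0.005).

For the same reason the q-exponential's continuous maximum-likelihood fit
is the right estimator only for effectively continuous data (it recovers
q = 1+1/(α+1) on Γ-mixture draws); on integer intervals with small means
the lattice likelihood dominates and the continuous MLE degenerates to
q → 1. The estimator `fit_q_exponential_lattice` fits the Γ-geometric
mixture by maximum likelihood over (α, ⟨β⟩) instead and reports
q = 1 + 1/α̂; on 5 Mb simulated genomes it recovers q within ~0.007 of the
moment value 1+ρ². The small residual downward bias is understood: the
simulator places an *exact* count n per segment (sampling without
replacement), which is slightly underdispersed relative to the geometric
law at fixed β, and the fit absorbs this as a slightly larger α̂.
Goodness-of-fit for the memoryless (shuffled-sequence) case likewise tests
the geometric law, with a parametric bootstrap (500 replicates by default,
parameters re-estimated per replicate) on a subsample of ≤5000 intervals —
at millions of intervals the KS test would otherwise reject the O(1/L)
without-replacement deviations that have nothing to do with correlations.

## Detrended fluctuation analysis

The profile is the cumulative sum of the mean-subtracted track; windows of
size s are detrended by a least-squares polynomial (order 2 by default,
DFA2) and F(s) is the RMS residual averaged over windows taken from both
ends of the profile, so trailing data contribute when N is not a multiple
of s. The scale grid is ~20 logarithmically spaced values from s = 8 to
N/4 (at least 4 windows per scale). Bond-enthalpy encoding maps A/T → −11.8
and G/C → −23.8 kcal/mol, so the track is a two-valued series determined by
the S/W class; F(s) is invariant under adding a constant and scales
linearly under positive multiplication, which the tests assert.

Crossover detection fits every admissible two-piece line in log-log
coordinates (excluding the 2 outermost scales per side, ≥3 points per
branch) and keeps the breakpoint minimizing the total squared residual; if
no breakpoint beats a single line by more than 1% relative (or the single
line is already exact to numerical precision) the result is flagged
single-regime. DFA2 displaces the apparent crossover of a 150 bp
composition process to several hundred bp; the detector reports the
apparent breakpoint and makes no correction. "Large-scale" Hurst estimates
in the closed-loop checks fit log F vs log s from s = 10·L = 1500 bp (well
above the apparent crossover) to N/4.

## Long-range correlated driver

Segment-composition drivers are generated by spectral synthesis: white
Gaussian noise is filtered in the frequency domain by f^(−(2H−1)/2)
(fractional-Gaussian-noise scaling), inverse transformed and standardized
exactly to zero mean and unit variance. The method is O(n log n), exact
under a fixed seed, and unbiased in practice: the 20-seed mean DFA2
estimate at n = 33333 and H = 0.8 is 0.800 (sd 0.02 per series). A
circulant-embedding (exact-covariance) generator was evaluated and gave
indistinguishable DFA behaviour, so the simpler method is kept. Independent
streams for the three drivers (n_S, p_A, p_G) and the placement RNG are
derived from one master seed via fixed spawn keys.

## Simulator

Defaults are the study conditions: L = 150, H = 0.8, σₙ = 9 (the typical
bacterial value), ⟨p_A⟩ = 0.5, σ_pA = 0.05, ⟨p_G⟩ = 0.5,
σ_pG = k·ρ·⟨p_G⟩ with k = 1.75, GC 0.5, 5 Mb genomes for closed-loop
checks (a typical bacterial chromosome size; 20-seed averages for headline
numbers). σ_pA and ⟨p_G⟩ are exposed tunables with documented defaults:
the A/T alternation dispersion is chosen so that per-nucleotide count
dispersion grows with ⟨n⟩ on the weak side while the G/C side is governed
by the k·ρ·⟨p_G⟩ rule. Counts are rounded half-to-even and clipped to
[0, L]; at default parameters the clip rate is ~10⁻¹⁶-rare (|driver| would
need to exceed ~8σ). Within-segment placement samples positions without
replacement. The hierarchical cascade adds independent H = 0.8 drivers at
the 150²- and 150³-bp levels: driver = Σ wᵢ xᵢ with *no* variance
normalization, so upper levels add composition variance
(σ_total = σₙ√Σwᵢ²). Normalizing to unit total variance would make the
cascade statistically identical to the bacterial model at segment scale
(a sum of Gaussians with the same total variance), contradicting the
heavier interval tail the cascade exists to produce; adding variance is
the behaviour the hierarchical description implies, and the tests assert
the resulting ordering q̂_cascade > q̂_bacterial.

What the generator does *not* emulate: codon structure and reading frames
(its "genes" are random), replication-strand GC skew, repeat families, and
any explicit nucleosome/chromatin geometry (the cascade is a statistical
stand-in). Passing closed-loop tests therefore show that the analysis
recovers the generative laws, not that real genomes obey them; empirical
FASTA input is supported but not bundled.

## Translation experiments

The back-and-forth test treats the whole sequence as one frame-0 ORF
(bacterial genomes are >90% coding; gene annotation is out of scope),
translates with the standard code (identical to the bacterial table on the
61 sense codons; in-frame stops are kept as markers and re-encoded as
stops) and reverse-translates with uniform synonymous codon choice. On a
2 Mb simulated genome this reduces σₙ from 9.0 to ~7.4 and the large-scale
DFA2 exponent from ~0.80 to ~0.75 while preserving the protein exactly.
The exponent does not collapse to 0.5: amino-acid identity itself encodes
much of the local GC level (codon first/second positions are fixed), so
randomizing only the synonymous choice leaves a substantial correlated
component — the test quantifies exactly the architecture information
carried by codon *choice*.

Guided reverse translation scores, residue by residue, each synonymous
codon by the squared displacement of the running within-segment S-fraction
from the segment target (the segment of the codon's first base; all three
bases are then tallied into the segments they actually occupy), breaking
ties by the A-among-W and G-among-S displacements and finally by a seeded
uniform choice. Segment targets come from a pluggable one-step-ahead
predictor iterated over the patch (each prediction is appended to the
history); the default is an exponentially weighted moving average with a
5-segment half-life — a deliberate plain-vanilla extrapolator chosen
because it is monotone, range-preserving and parameter-light; any optimal
linear predictor can be injected in its place. Against uniform random
reverse translation the guided chooser reduces the mean squared deviation
from the targets by more than two orders of magnitude on simulated hosts.

## Numerical conventions and edge cases

* Population (divide-by-N_seg) standard deviations throughout, keeping
  ρ⟨n⟩ = σₙ exact and Γ moment matching self-consistent.
* Trailing partial segments are discarded (floor rule); coordinates are
  0-based half-open.
* Ambiguity codes are dropped by default (count logged) or rejected in
  strict mode; statistics treat the remaining positions as contiguous.
* A class absent from a sequence yields ρ = NaN rather than an error;
  interval extraction with <2 occurrences returns an empty series with a
  warning.
* The q-exponential density uses scale s = (2−q)L/⟨n⟩, pinning P(0) to the
  mean rate ⟨n⟩/L; with q = 1+1/(α+1) it then coincides exactly with the
  Lomax mixture of the same mean (a Lomax *is* a q-exponential).
* Quadrature of the mixture integral normalizes the integrand by its peak
  before integrating, so tail densities far below the raw integrand's
  underflow threshold are still computed at full relative precision.

## Problem sizes

Closed-loop checks run on 5 Mb genomes (single seed in the test suite,
20-seed averages in the acceptance script), back-and-forth on 2 Mb, guided
design on a 60 kb host with a 3000-residue protein over 100 seeds, and the
Monte-Carlo oracle on 10⁶ draws — sizes at which every quoted tolerance is
several sampling standard errors wide.
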