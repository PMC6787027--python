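# Methods

## The model

During −1 programmed ribosomal frameshifting (−1PRF) the ribosome pauses on a
slippery heptamer `X XXY YYZ` (positions 1–7) while a downstream secondary
structure delays translocation.  The P-site and A-site tRNAs can re-pair with
the mRNA one nucleotide upstream: the 0-frame codons (positions 2–4 and 5–7)
are exchanged for the −1-frame codons (1–3 and 4–6).  If the pause is long
enough for the two register states to equilibrate, the frameshifting
efficiency FS — the fraction of ribosomes that continue in the −1 frame — is
the Boltzmann occupancy of the −1 state:

    FS(ΔG) = exp(−ΔG/kT) / (1 + exp(−ΔG/kT)),      ΔG = G(−1) − G(0),

a logistic function of the total free-energy difference between the frames.
`kT` is realised as the molar gas constant times temperature (free energies
are molar, kJ/mol); the default `T = 310 K` gives `kT = 2.5773 kJ/mol` and is
overridable through `ThermoConstants`.

The second assumption is additivity: ΔG of a variant is the sum of the
free-energy differences of the individual base-pair changes between the two
frames, with no coupling between codon positions,

    ΔG_i = Σ_j M_ij · ΔG_bp,j ,

where each variable ΔG_bp,j describes one position-specific codon·anticodon
substitution such as `P1 A·U→G·U` (mRNA base written first; anticodons stored
3′→5′ so element k pairs codon position k) and the signed design matrix M
carries +1 for a change in the canonical direction, −1 for its reverse, 0
otherwise.  Identical-frame variants (all seven heptamer bases equal) have an
all-zero row and sit exactly at FS = 50%.

For the combinatorial design shipped with the package — all 64 variants
encoding Lys (AAA/AAG, anticodon 3′UUS5′, S = mnm⁵s²U) or Phe (UUU/UUC,
anticodon 3′AAG5′) codons at both slippery positions — M is 64×16 with
numerical rank 14 (SVD, singular values below 1e−8 of the largest counted as
zero): two groups of variables occur only in fixed sums.

## Inference

The inverse problem (measured FS → per-change free energies) is posed as a
Bayesian posterior: an independent Gaussian likelihood per variant with the
replicate standard deviation of the measurement, and a uniform box prior on
[−25, 25] kJ/mol per variable (closed interval; proposals outside are
rejected through the prior).  The sampler is Metropolis-within-Gibbs: each
step performs one sub-step per free variable, proposing from a Gaussian of
width 0.2 kJ/mol centred on the current value and accepting with probability
min(1, f_new/f_old), where f = likelihood × prior, evaluated in log space.
Defaults: 10⁶ steps, two independent chains seeded `seed` and `seed+1`, 20%
burn-in.  Summaries pool the post-burn-in draws across chains (flagged in
the output).  Replicate σ below 0.005 (half a percentage point, under the
assay's resolution) is floored with a warning because the Gaussian
likelihood is singular at σ = 0.

RNG contract: one `numpy.random.Generator` per chain; each sub-step draws
exactly one proposal normal followed by one acceptance uniform, drawn even
when the decision does not need it, so runs are bit-reproducible.

## Identifiability and pinning

Variables that only ever co-occur are not individually determined: their
marginals spread towards the prior scale (σ ≈ 14 kJ/mol for the box) while
their sum is sharp.  A variable is flagged underdetermined when its posterior
σ exceeds 2 kJ/mol — determined variables come out well below 1 kJ/mol, so
any threshold in 2–8 separates the groups; the value is configurable.
Couplings are read off the Pearson correlation matrix of the sample series
with |r| ≥ 0.9 counted as strong.  Because the determined combinations are
sums, the shared variable of a group is *anti*-correlated with each partner
while the partners correlate positively; the pinning representative is
therefore the variable with the most strong anticorrelations (ties: most
strong couplings, then lexicographic).  On the 64-variant design this selects
the two wobble-position P3 variables, and pinning them to 0 kJ/mol renders
all remaining 14 variables determined; the marginal of a partner variable
then equals the `pinned + variable` combination.  Pinning never alters the
design matrix, only the sampler's free-variable set.  The iterative protocol
(fit all; pin one persistent representative per step; finally pin all
representatives simultaneously) reports per-step determinations and the
combination values.

P-site vs A-site comparisons of first-position mismatches that are not
directly observable (C·A→C·U, G·A→G·U) are derived per posterior sample as
differences of observed (or sum-determined) variables, under the assumption
that A·U and U·A pairs are isoenergetic; shared underdetermined terms cancel
exactly within each sample.

## Kinetic factor

To test the equilibration assumption, a two-state master equation with
Arrhenius rates gives FS_kinetic = FS·(1−κ) with

    κ = exp(−C·[1 + exp(ΔG/kT)]),

where C lumps attempt frequency, pause duration τ and barrier height into a
single nonnegative parameter (its components are not separately
identifiable).  The mean kinetic factor κ̄ over the dataset's variants is
sampled as a nuisance parameter (uniform prior on [0, 1], Gaussian proposal,
default width 0.001, initial value 0.01 — κ̄ = 0 makes C degenerate); at
every likelihood evaluation C is re-solved from κ̄ and the current ΔG vector
by bracketed Brent iteration on the strictly monotone mean-κ curve, and the
per-variant κ enters the likelihood.

Identifiability caveat: near κ̄ = 0 the nuisance is sharply determined (on
equilibrium data its posterior piles against 0).  At larger κ̄ damping can
partly trade against shifted free energies, so the posterior broadens and
skews upward; recovery of κ̄ = 0.3 on synthetic data needs chains of order
10⁵ steps, and for some noise realizations a secondary posterior basin
(large κ̄, strongly shifted ΔG, only a few log-units below the main basin)
can capture a finite chain.  Scaled-down fits in the test suite therefore
widen the κ̄ proposal (0.005–0.01) so the chain can traverse [0, 1] within
the reduced step budget; this is a numerical choice, not a model parameter.

## Validation

Posterior-predictive FS distributions are computed by pushing every retained
draw through the design and the Boltzmann relation (times 1−κ when
kinetic); agreement with measurements is the root-mean-square deviation
between mean model FS and measured FS, reported in percentage points.
Convergence is monitored by the rmsd of chain prefixes (20% of each prefix
discarded), which must plateau at a common value across independent chains.
Leave-one-out cross-validation refits the model N times, each time predicting
the held-out variant; variables unique to the held-out variant remain
prior-distributed, so such predictions honestly carry prior-wide spread.
LOO refits default to reduced chain lengths to stay desk-scale.

## Synthetic data

The generator draws FS tables from a known ground truth through the same
model: total ΔG per variant, Boltzmann occupancy, optional kinetic damping,
plus Gaussian replicate noise (default σ = 0.02, the scale of triplicate
scatter in end-point translation assays), resampled — not clipped — until
inside (0.001, 0.999) to avoid boundary point masses.  The default
16-variable truth uses published posterior means where such values are in
print (P1 A·U→G·U = 5.1, A3 G·S→A·S = −2.9, A3 C·G→U·G = 3.4 kJ/mol, and the
P3+A1 pair sum 3.3 split as 1.5 + 1.8) and otherwise follows the established
first-position stability ordering (pyrimidine·pyrimidine penalties largest,
purine·purine smallest), all within [−6, 6] kJ/mol.

What passing recovery tests do and do not show: the generator reproduces the
statistical structure the analysis assumes — additive energetics, Gaussian
replicate noise, known σ.  Real measurements can violate these (per-variant
σ heterogeneity, systematic assay effects, non-additive coupling for changes
at adjacent codon positions), so recovery on synthetic data validates the
inference machinery, not the biology.  The in-text fixture ships only the
handful of FS values quoted in running text; a user-supplied measured table
(TSV, percent or fraction auto-detected) is required to reproduce
dataset-level numbers.

## Numerical choices

- FS↔ΔG conversions use `scipy.special.expit/logit`; FS of exactly 0 or 1
  raises (such values only bound ΔG).
- Design rank: SVD with relative tolerance 1e−8 (integer matrix,
  well-separated spectrum).
- The C(κ̄) inversion brackets log C in [−700, 700] and solves to near
  machine precision.
- Sampler likelihood omits the constant Gaussian normalisation (only ratios
  enter acceptance); the public `log_likelihood` includes it.
- Histogram summaries use 100 equal bins over the sampled range (one
  unit-mass bin for degenerate, e.g. pinned, series); zero-variance series
  get correlation 0 with a warning.
- Scaled-down problem sizes in tests and analysis scripts: reference fits use
  2 × 30 000 steps on the 64-variant design, toy problems 10³–10⁵ steps;
  statistical tolerances (KS < 0.02 against the prior, total-variation
  < 0.05 against dense-grid posteriors, 3-posterior-σ recovery) were sized
  for these run lengths.

## Known limitations

- Stimulatory elements (stem-loops, pseudoknots), +1/−2 frameshifting and
  non-heptamer sites are out of scope; the model sees only the heptamer and
  the two anticodons.
- Pair identity is literal character equality; wobble/Watson–Crick class is
  not used by the model.
- No adaptive proposals or tempering — fidelity to the reference sampling
  protocol takes precedence, at the cost of slow mixing along flat
  (sum-coupled) directions and the large-κ̄ caveat above.
- The in-vivo 26-variable change catalogue is shipped, but the corresponding
  variant sequences are not in the public record, so that design matrix must
  be supplied by the user.
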