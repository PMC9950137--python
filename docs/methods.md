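# Methods

## Scope

`paleofmo` implements the computational core of an ancestral-protein
resurrection study of flavin-containing monooxygenases (FMOs): marginal
ancestral sequence reconstruction (ASR) on a fixed rooted phylogeny,
alternative-ancestor (AltAll) construction, parsimony-based gap handling, a
three-stage prioritization funnel for historical substitutions, and the
enzyme-kinetics analyses used to characterise resurrected flavoenzymes.
Tree inference itself is out of scope: the tree, its branch lengths and the
gamma shape parameter are inputs.

## Substitution model

The evolutionary model is a reversible empirical amino-acid model: a
symmetric exchangeability matrix S (JTT by default; WAG and LG are also
bundled, all in PAML `.dat` layout with provenance noted in the files) and
equilibrium frequencies π combine into the generator

    Q_ij = S_ij π_j (i ≠ j),   Q_ii = −Σ_{j≠i} Q_ij,

scaled so that −Σ_i π_i Q_ii = 1; branch lengths are then expected
substitutions per site. Reversibility (π_i Q_ij = π_j Q_ji) holds by
construction. Frequencies come either from the matrix file
(`matrix_default`, the default) or from the alignment (`observed`, the +F
convention, floored at 1e−6 and renormalised); both are provided because
empirical-matrix software configurations are ambiguous on this point.

Among-site rate variation uses the discrete-gamma approximation: K
equal-probability categories of Gamma(α, rate α) (mean 1), category rate =
the mean of the distribution within each quantile bin, computed analytically
from the regularised incomplete gamma of shape α+1 and renormalised to
average exactly 1. Median-based rates are available behind a flag. The
defaults α = 1.114, K = 4 are the model-selection estimates the study
conditions prescribe.

Transition matrices P(t) = exp(Qt·r) are computed by eigendecomposition of
the symmetrised generator Π^{1/2} Q Π^{−1/2} (exact for reversible Q, one
decomposition per model); tiny negative entries from round-off are clamped
to zero and rows renormalised.

## Likelihoods and marginal reconstruction

Site likelihoods use Felsenstein pruning, vectorised over sites, with
per-node scaling factors accumulated in log space to prevent underflow.
Gaps and `X` contribute all-ones conditional vectors (missing data).
Categories carry equal prior weight 1/K and are combined by logsumexp.

Marginal posteriors at an internal node v are computed inside–outside: the
downward pass gives the conditional likelihood of the subtree below v; an
upward (preorder) pass gives the likelihood of everything outside v's
subtree jointly with the state at v (root prior π included). Their product,
normalised per site and per category and with categories weighted by their
share of the site likelihood, is the marginal posterior. A second,
independent implementation reroots the tree at v (valid under
reversibility) and reads the root posterior; the two are required to agree
in tests, and exhaustive enumeration over all internal-state assignments on
small trees is the primary oracle.

Per site the maximum a posteriori (MAP) state and the second-best state are
recorded with their posterior probabilities (PP). A site is flagged
ambiguous when the second-best PP exceeds 0.2 (strictly). MAP ties are
broken alphabetically by one-letter code with a logged warning.

## Gap handling and sequence construction

Ancestor length is decided separately from the probabilistic states,
mirroring the two-track convention of resurrection studies: each alignment
column is encoded present/absent at the leaves (gap = absent; `X` =
present, the conservative choice for length) and Fitch parsimony
(bottom-up intersection/union, top-down refinement) calls the state at the
target node. Remaining two-state ties resolve to "present" by default
(configurable, logged) so that sister ancestors receive consistent lengths.

The MAP ancestor emits the MAP state over present columns. The AltAll
ancestor emits the second-best state at every ambiguous site (second-best
PP > 0.2) and the MAP state elsewhere; it never introduces gaps and by
construction differs from the MAP sequence exactly at the flagged sites.
The reported mean PP (`mean_pp`) averages PP(MAP) over present sites only;
averaging over all alignment columns would be the alternative reading, and
is not used.

## Substitution funnel

Candidate historical substitutions on a parent→child branch are the columns,
present in both ancestors, whose MAP states differ; positions are reported
in descendant residue numbering. Three stages follow:

1. **Posterior filter.** A substitution is *true* when PP(MAP) > 0.8 at
   both nodes. When a node is reconstructed below 0.8, the record is still
   *included* if that node's alternative state is plausible (PP > 0.2) and
   differs from the other node's MAP state — otherwise the apparent
   substitution could be a reconstruction artifact and it is *excluded*.
   All comparisons are strict; exact threshold equality excludes and is
   logged.
2. **Conservation.** Per-column modal-residue frequency (gaps excluded)
   over three sequence subsets: the whole dataset, the heteroatom-oxidising
   (S/N) lineage and the Baeyer–Villiger (BV) lineage. A column is
   conserved at modal frequency ≥ 0.8 (configurable); Shannon entropy in
   bits is reported as a diagnostic. Records conserved nowhere are dropped.
   This transparent score replaces server-based conservation grading, whose
   manual judgments are not recoverable.
3. **Structure.** The user-supplied structural annotation (category ∈
   {active_site, tunnel, FAD_proximal, NADPH_shell1, NADPH_shell2, other};
   surface/core; domain) is attached; records that are both surface and
   category `other` are dropped as "likely no role". Surviving records
   missing an annotation are kept unclassified with a warning.

Survivors compose nested mutant sets: `4x` = active-site records, `12x` =
`4x` plus the tunnel/FAD-proximal/first-NADPH-shell group, `16x` = all
survivors (the exact mid-tier membership is a documented reconstruction —
the original study does not itemise it); arbitrary explicit sets (e.g. a
three-residue synergy set) are accepted as position lists. Nesting
4x ⊆ 12x ⊆ 16x is asserted on every output. Every drop is logged with its
stage, so the listed → PP-filtered → conserved → triaged counts are
auditable.

## Kinetics

All fitters are unweighted nonlinear least squares (SciPy) with standard
errors from the covariance at the optimum; exact recovery at zero noise is
enforced in tests.

- **Michaelis–Menten** (`fit_michaelis_menten`): v = V_max·S/(K_M+S), ≥ 4
  distinct concentrations required; k_cat = V_max when rates are turnover
  (s⁻¹); catalytic efficiency always reported in s⁻¹ mM⁻¹ with first-order
  error propagation. Extrapolated K_M (outside the tested range) and
  low-information designs produce warnings.
- **Initial rates at 340 nm** (`rate_from_A340`): the initial window is the
  longest prefix with linear R² ≥ 0.995 spanning ≤ 10% of the total
  observed change (minimum 5 points); within it the slope is taken as the
  derivative at t₀ of a quadratic fit, removing the ≈ d/2 first-order bias
  a straight line picks up on a curved trace. Beer–Lambert conversion uses
  ε₃₄₀ = 6.22 mM⁻¹ cm⁻¹; with an enzyme concentration the result is a
  turnover rate in s⁻¹. Without substrate this measures uncoupling.
- **Single exponentials** (`fit_single_exponential`): A(t) = A_∞ + ΔA e^{−kt},
  used for flavin reduction (k_red) and single-wavelength oxidation phases;
  a Wald–Wolfowitz runs test on the residual signs (p < 0.01) flags
  biphasic traces and suggests the sequential model.
- **Two-step sequential deconvolution** (`fit_sequential_two_step`): species
  fractions of a →(k1) b →(k2) c follow the closed form
  c_a = e^{−k1 t}, c_b = k1/(k2−k1)(e^{−k1 t} − e^{−k2 t}), c_c = 1−c_a−c_b
  (confluent limit k1 t e^{−k1 t} when k1 ≈ k2, switched at relative
  difference 1e−6). Species spectra are linear at fixed rates and solved by
  least squares inside the objective (variable projection); the outer
  optimisation over log(k1, k2) is restarted from a 5×5 log-spaced grid of
  rate pairs spanning [1/t_max, 1/t_min]. The label-swap degeneracy is
  resolved by the k1 > k2 convention. SEs come from the Jacobian of the
  projected residual (delta method from the log scale). The intermediate's
  spectrum and its λ_max are reported — for the oxidative half-reaction of
  a flavoprotein monooxygenase this is the C4a-(hydro)peroxyflavin-like
  species. Time grids spanning < 2 decades and substantially negative
  spectra produce warnings.
- **Oxygen affinity** (`fit_oxygen_affinity`): hyperbolic fit of k_obs vs
  [O₂]; a fitted K_M^O2 below the lowest tested concentration flags the
  design as saturated (the estimate is then an upper bound).
- **Conversions** (`conversion_percent`): 100·(1 − (A_s/A_IS)_sample /
  (A_s/A_IS)_control), clamped to [0, 100] with a warning; invariant under
  common rescaling of all areas.
- **Melting temperature** (`melting_temperature`): T_m is the interior
  maximum of the Savitzky–Golay-smoothed (default 7-point, quadratic) first
  derivative of the melt curve; multiple transitions are ranked by peak
  height, the tallest reported as primary. Curves without an interior peak
  (≥ 20 points required) are flagged "no transition".
- **Holoenzyme quantitation** (`holoenzyme_concentration`): Beer–Lambert at
  450 nm with ε_FAD = 11.3 mM⁻¹ cm⁻¹, reported in μM.

## Synthetic data

Generators emulate every input with recorded ground truth, one seeded
generator per call:

- **Alignments**: root sequence drawn from π; one gamma category per site,
  shared across the tree (the same among-site model the likelihood
  assumes); branch-wise substitution via P(Qtr). Indels are clade-restricted
  contiguous block deletions on named branches, inherited below — enough to
  exercise the Fitch machinery, deliberately not a full insertion–deletion
  process. No attempt is made to mimic real FMO motifs; passing recovery
  tests therefore demonstrates statistical correctness of the machinery,
  not realism of FMO sequence evolution.
- **Stopped-flow matrices**: closed-form two-step concentration profiles ×
  three Gaussian species spectra (intermediate peaking at 380 nm by
  default) + i.i.d. Gaussian noise. Real photodiode-array data have
  wavelength-correlated noise and baseline drift, which are not emulated.
- **Initial-rate designs, exponential traces, melt curves, conversion
  tables**: the corresponding rate laws plus Gaussian noise
  (multiplicative for rates, additive for traces).

A calibration experiment (16-leaf balanced tree, branch lengths 0.05,
JTT+Γ(1.114, K=4), 500 sites) checks that the root MAP sequence recovers
≥ 90% of true states and that mean PP tracks empirical accuracy within 0.1
per PP bin (bins with ≥ 100 sites). These thresholds are regression guards
for the implementation, not claims about any real dataset.

## Problem sizes and numerical choices

The test suite runs small trees (≤ 16 leaves) and ≤ 500 sites; the
enumeration oracle covers all topologies with up to three internal nodes at
1e−10 agreement. The acceptance script replicates each kinetic recovery
experiment (15 replicates for the stopped-flow matrix, 25 for scalar fits)
and reports the median, so the reported value estimates the recovery rather
than a single noise draw; per-experiment designs (8-concentration 3-replicate
saturation grids at 5% noise, 400-point traces at 2% noise, 120×58
stopped-flow matrices at 0.5% noise) match the study conditions.
Optimiser tolerances are tightened to 1e−13/1e−14 so that noiseless
round-trips recover generating parameters to the tolerances asserted in
tests. Posterior normalisation is enforced to 1e−8; transition-matrix rows
to 1e−10.

## Known limitations

- Joint (as opposed to marginal) reconstruction, branch-length/α
  re-optimisation and tree search are not implemented (inputs are fixed).
- Conservation is a frequency/entropy score, not a phylogenetically
  corrected rate estimate; the structural triage rule (drop surface ∧
  other) is an explicit, configurable stand-in for manual structural
  inspection.
- The sequential model assumes irreversible first-order steps and exactly
  three spectrally distinct species; k₂ becomes unidentifiable when the
  time window does not cover the slow phase (a warning is emitted).
- Gamma categories are equal-weight; other rate-variation families
  (invariant sites, free rates) are out of scope.
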