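# Methods

## Problem setting

The package models panel-style kinase profiling data: a matrix of
equilibrium dissociation constants (K_d, µM) for a set of small-molecule
inhibitors against a set of kinases, measured by ATP-site competition
binding. Activity is a binary event, K_d strictly below a cutoff; five
cutoffs (0.1, 0.5, 1, 3, 10 µM) span tight binders to weak binders. A
missing cell is treated as inactive at every cutoff — panels of this kind
report binders only, and the pooled pair counts only add up if every
compound×kinase pair carries a label. One multi-task model is trained per
cutoff; one model predicts all kinases at once from a single molecular
encoding.

## Molecular encoding

### Per-atom properties

Descriptors aggregate per-atom property values p_i. Four are assigned:
identity (≡ 1, making the descriptor a pure pair-count), Pauling
electronegativity and dipole polarizability (Å³) from a versioned
per-element table shipped with the package, and a partial charge.

The partial-charge model is a damped iterative electronegativity
equalization in the PEOE family, σ-framework only: in iteration k
(k = 1..6), each bond (i, j) transfers (χ_j − χ_i)/4 · (1/2)^k electrons
from the less to the more electronegative atom, with fixed per-element χ.
The per-bond antisymmetric transfers conserve total charge exactly at every
iteration; topologically equivalent atoms receive identical charges by
symmetry; the result is conformation-independent. Equalization runs on the
hydrogen-explicit graph (implicit hydrogens are materialized as temporary
nodes) and hydrogen charges are folded back into their heavy atom, so the
heavy-atom charges still partition the total charge. Fixed χ (rather than
PEOE's charge-dependent χ(q) polynomials) keeps the scheme hand-checkable:
the H–F charge is exactly (χ_F − χ_H)/4 · Σ_{k=1..6} (1/2)^k, which the test
suite verifies.

### Descriptor blocks

A `DescriptorConfig` is an ordered list of blocks; the shipped default
totals exactly 400 features:

| block | property | bins | parameters |
|---|---|---|---|
| scalar1d | — | 3 | MW (implicit H included), total formal charge, heavy atoms |
| scalar2d | — | 5 | HBD, HBA, rings, surface area, volume |
| topo2da | identity | 8 | shortest-path bond distance |
| rdf ×4 | identity, charge, χ, α | 48 each | Δr = 0.25 Å, B = 100 Å⁻² |
| 3da ×4 | identity, charge, χ, α | 48 each | Δ = 0.25 Å |

The 48 × 0.25 Å grids span 12 Å, comfortably beyond the diameter of typical
inhibitor-sized molecules. B = 100 Å⁻² gives a Gaussian width of 0.1 Å, so
adjacent RDF bins are nearly independent. Bins are half-open [kΔ, (k+1)Δ)
starting at zero; pairs beyond the grid are dropped (3DA) or contribute
negligibly (RDF). Signed properties are used raw — RDF/3DA values over
partial charge may be negative; no absolute value is taken, preserving the
sign structure of charge–charge correlations. Hydrogens are folded into
heavy atoms by default (counts, masses, charges), which keeps feature
vectors identical across input dialects that differ in explicit-H
conventions.

Ring count is the cyclomatic number E − V + C of the heavy-atom graph,
which equals the SSSR size; surface area and volume are additive per-atom
sphere terms from van der Waals radii. These are deliberately cheap
approximations — the 3D blocks carry most of the information.

All blocks are sums over unordered atom pairs and depend on geometry only
through d_ij, giving exact invariance to atom relabeling and rigid motion
(verified to 1e-9 over random transforms in the tests). Two closed-form
identities tie the implementations down: Σ_k RDF_k·Δr → Σ p_i p_j √(π/B)
when the grid spans all pair distances with ≥ 5/√B margin *and* Δr resolves
the Gaussian width (the check uses Δr = 0.05 Å; at the production 0.25 Å
spacing the Riemann sum aliases), and Σ_k A_k = Σ p_i p_j exactly once the
3DA grid exceeds the molecular diameter.

## Network and training

Architecture 400 → 32 → N (one sigmoid output per kinase), weights
initialized uniformly in ±1/√fan_in from a seeded generator, biases zero.
Training is classic online back-propagation with momentum: per-example
updates Δw(t) = −η ∂E/∂w + α Δw(t−1) with η = 0.1, α = 0.5, sum-of-squares
loss E = ½Σ(y − t)² on the sigmoid outputs (a cross-entropy switch is
available; it only changes the output delta from (y−t)·y·(1−y) to y−t).
Presentation order is reshuffled each epoch from a seeded generator, so a
(seed, config, data) triple reproduces training bitwise. Default 500 epochs;
when a monitoring set is supplied, training stops after 50 epochs without
improvement and restores the best weights. Inputs are z-scored with
statistics fitted on training rows only (constant columns flagged and mapped
to zero); the fitted normalizer is serialized inside the model JSON.

Gradient correctness is enforced by comparing the analytic update against
central finite differences (max relative error < 1e-5) across random small
architectures.

## Evaluation

Metrics follow the standard confusion-count definitions; MCC's zero-
denominator case is reported as 0 with a flag, other undefined ratios as NaN
with a flag. ROC curves sweep descending distinct scores (ties grouped;
scikit-learn backend) and AUC is the trapezoidal area, equal to the
Mann–Whitney U statistic over n_pos·n_neg with ties worth ½ — the tests
check this against brute-force pair counting. Per-kinase thresholds are
chosen by maximizing MCC over midpoints of consecutive distinct scores,
ties broken toward the higher threshold (fewer positive calls). Model
comparison uses the Wilcoxon signed-rank test on per-kinase AUC differences
(the paired analog of the rank-sum test; zero differences dropped, exact
null for ≤ 12 pairs, normal approximation above; the unpaired Mann–Whitney U
is also exposed). The comparison against a random model builds a 2×2 table
of correct vs incorrect calls for the model and for a predictor labeling 50%
of the same cases positive (right on half the actives and half the
inactives), tested with Fisher's exact test; the table construction is
recorded in the report output.

## Synthetic panel generator

`make_fixture_molecules` draws from a curated set of small organic
structures (alkanes, aromatics, H-bonding heteroatom variants, halides)
plus seeded scaffold+substituent variants, embedded in 3D with RDKit ETKDG
and MMFF-relaxed — every structure parses, validates, and featurizes.

`make_planted_kd_matrix` plants a recoverable structure–activity signal:
for each signal kinase, log₁₀ K_d = a_k − β·z + ε with z the standardized
mean of a secret random subset of (variable) descriptor features, ε ~
N(0, σ); noise kinases draw log₁₀ K_d independent of structure. The
intercept a_k is placed between order statistics so the active fraction at
10 µM hits the prevalence target exactly where achievable (error if not);
K_d is floored at 1e-4 µM, matching assay dynamic range. Defaults: β = 2
log-units per SD, σ = 0.3, prevalence 0.25 — the prevalence matches the
≈ 25% active fraction of real 10 µM panel labels, and β/σ give a
signal-to-noise ratio at which a correct learner should reach AUC > 0.8 on
~100 compounds while noise kinases stay near 0.5.

The generator plants signal in descriptor space, not in raw structure: a
recovery failure therefore isolates the learner/normalization path from
descriptor fidelity. Consequences for interpretation: passing recovery
shows the pipeline learns real feature–activity relationships out-of-fold;
it does not show that these descriptors capture kinase pharmacology — the
synthetic molecules are far smaller than real inhibitors, and the linear
log-K_d model has none of the binding-mode structure of real panels.
Reproducing published real-panel AUCs would additionally require the
original external dataset and the original descriptor implementation, and
is out of scope.

## Validation scheme and problem sizes

No train/monitor split is prescribed for this kind of model, so the package
defaults to compound-level 5-fold cross-validation (leakage-safe: all cells
of a compound stay in one fold), with the fold assignment seeded and logged.
The recovery experiment used in tests and the acceptance script runs 120
compounds × 20 kinases (5 signal), 10 replicate seeds, 150 training epochs
per fold — sizes chosen so the full experiment completes in a few minutes on
one core while leaving a wide margin over the AUC 0.8 recovery bar.

## Numerical conventions and degenerate inputs

- Binarization is strict (K_d = cutoff → inactive); cutoff monotonicity
  (actives at c ⊂ actives at c′ > c) is property-tested.
- Sigmoid pre-activations are clipped at ±500 before exp; saturation beyond
  that is below 1e-217 and numerically irrelevant.
- Single-class kinase columns have no defined AUC/threshold: skipped and
  flagged in summaries, error when requested directly.
- Fold sizes differ by at most one; k > n is an error.
- SDF input is V2000 only (V3000 rejected); coordinates round-trip at the
  format's 4-decimal precision and are bit-stable from the second pass on.
- Model JSON serialization is sorted-key with full float repr; reload is
  bit-exact, and the featurize → train → profile pipeline is byte-identical
  across reruns given the same seed.

## Known limitations

- The 400-feature layout is one defensible instantiation of the stated
  descriptor families and input width; the original panel models' exact
  feature composition is unpublished, so block-level agreement with other
  implementations is not expected. The layout is fully config-overridable.
- Fixed-χ equalization charges are cruder than PEOE's charge-dependent
  scheme; they preserve the qualitative ordering (sign, symmetry,
  conservation) that the descriptors need, not quantitative charge accuracy.
- Aromaticity handling is inherited from RDKit's perception; the 2D scalars
  use only ring membership, not aromaticity.
- Online (per-example) training is inherently sequential; no minibatching
  or GPU path is provided, matching the classic algorithm.
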