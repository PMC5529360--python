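# Methods

## The residue-stability statistic

Given a trajectory of J frames over a fixed heavy-atom topology, the
pipeline is:

1. **Hydrogen stripping.** Only non-hydrogen atoms enter any statistic;
   residues left without heavy atoms are dropped.
2. **Best-fit superposition.** Every frame is rigidly fit (least squares,
   unweighted, Kabsch SVD with the determinant correction for the
   reflection branch) onto the *original* structure. The fit mask is all
   protein heavy atoms; the resulting transform moves the whole frame,
   including any ligand partition. Ligand (HETATM) atoms are kept in a
   separate partition and excluded from the fit mask and from residue
   profiles by default; a flag merges them as a pseudo-residue for
   exploration.
3. **Average-structure reference.** The per-atom arithmetic mean of the
   aligned frames is the displacement reference. It is deliberately not
   re-fit or idealized — it can be chemically unphysical; it is a
   statistical reference only.
4. **Per-residue displacement.** For residue *i* in frame *j*,
   `residue_dist(i,j) = (1/K_i) Σ_k ‖A_{i,j,k} − ref_{i,k}‖` with K_i the
   residue's heavy-atom count, atoms paired by atom id. Per residue, the
   mean over frames (`stability_mean_i`) and the sample standard deviation
   with a J−1 denominator (`stability_std_i`) are reported, both in Å.
   Higher values mean a *less* stable residue. With J = 1 the std is
   undefined and reported as missing.
5. **Focal ordering.** Residue centers are unweighted heavy-atom
   centroids per frame; the distance of each residue to the focal residue
   (default 790, the T790 gatekeeper position of the EGFR kinase domain)
   is the center-to-center distance averaged over frames. Residues are
   ranked by ascending mean distance; the focal residue has distance 0 and
   rank 0. Ties break by ascending residue number so outputs are
   deterministic.
6. **Trimming.** Profiles are restricted to residue numbers 716–976 at
   the reporting stage (the default window drops the kinase-domain head and
   tail, whose motion reflects terminal flopping); fitting and the average
   reference always use the full structure.
7. **Cumulative curves.** `c_k` is the running mean of the chosen
   statistic over the k+1 residues closest to the focus. `c_0` is the focal
   residue's own value (the focal residue is *included*); `c_{R−1}` equals
   the plain mean of the trimmed profile. The mean statistic is the
   default; std curves are emitted alongside since both components carry
   the stability signal.
8. **Variant comparison.** Variants are ordered by the mean of
   `c_0..c_{k_window−1}`, higher first (= least stable). The default window
   is 50 ranks; the window used is always reported, and exactly equal
   scores are reported as explicit ties. Cross-variant comparison joins on
   rank position, not residue number, so deletion variants with numbering
   gaps compare naturally.

Profiles are keyed by author residue number throughout, never positional
index, so a deletion variant simply lacks those keys.

### Numerical choices

- Coordinates are always Å; no unit conversion anywhere.
- Kabsch degenerate cases (fewer than 3 mask atoms, collinear
  configurations, detected as a vanishing second singular value at 1e-10
  relative) raise a degenerate-fit error rather than returning an
  arbitrary rotation.
- No mass weighting: the statistic is defined on bare coordinates.
- Per-residue reductions use contiguous residue blocks and segment sums;
  tests pin them to naive per-atom/per-frame loops at 1e-10.
- Equality tolerances in tests default to 1e-8 Å; rigid-body invariance of
  the full pipeline is asserted at 1e-6 Å.
- Alternate PDB locations keep the highest-occupancy conformer (ties: first
  encountered). Multi-chain protein input is rejected — residue identity is
  collapsed to the author residue number, which is only unambiguous for a
  single chain.

## Synthetic trajectories

The generator emulates the statistical structure of the study-scale MD
runs (kinase domain numbered from 697, ~8 heavy atoms per residue, 5000
frames at 2 ps), not their physics: no force field, solvent or
thermostat. A reference structure places residue centroids along a
deterministic coiled space curve (~3.8 Å spacing) with seeded atom
offsets, so focal-distance ordering is nontrivial. Frames add isotropic
per-coordinate Gaussian noise with a per-residue σ (default 0.3 Å, a
typical ordered-domain amplitude), optionally an AR(1) mode with the same
marginal σ (the statistic is frame-order agnostic; the mode exists to
demonstrate that), and optionally per-frame rigid jitter (axis uniform on
the sphere, angle uniform up to a maximum, translation uniform in a cube)
to exercise the alignment step. Frames are i.i.d. by default since the
statistic is order-agnostic. The true σ profile travels in trajectory
provenance metadata and is the ground truth for recovery tests.

Under this model the per-residue displacement of a K-atom residue has a
known limit: each atom's distance to its reference position is σ·chi(3),
so `stability_mean → 2√(2/π)·σ` and
`stability_std → σ·√(3−8/π)/√K`. Tests assert recovery at J = 5000
within 2% (mean) and 5% (std); the small negative bias from estimating
the reference as the trajectory average and from the 6 fitted rigid
degrees of freedom stays well inside those bands at the tested sizes.

What passing these tests does *not* show: real trajectories have
anisotropic, correlated fluctuations, conformational substates and
ligand-coupled motion. The generator validates the estimator, not any
biological claim about a particular protein.

## Cohort analysis

The cohort schema has 24 categorical attributes — six monotone
age-threshold booleans (derived from one latent age in the generator, so
monotonicity holds by construction), sex, smoking, six metastatic-site
booleans, the number of metastatic sites (integer 1–5, treated as a
5-level categorical), the initial EGFR mutation type (delE746_A750 /
other-LRE exon-19 deletion / non-LRE exon-19 deletion / L858R), TKI and
chemotherapy line counts and usage flags — plus the binary acquired-T790M
outcome. Validation enforces age monotonicity, level membership and count
floors, reporting every offending row.

Proportions are reported as exact fractions plus percentages rounded
half-up to one decimal (the clinical-reporting convention); empty
denominators print blank. Fisher's exact test is the two-sided
point-probability rule (sum of all tables with the observed margins whose
point probability does not exceed the observed one), computed via scipy
and pinned in tests to an exact-rational full-enumeration oracle at 1e-12
for all margins ≤ 12. Only 2×2 tables are tested; r×c exact tests are out
of scope.

The packaged fixture (`paper_cohort`) is a synthetic reconstruction of an
unpublished 68-patient registry from its published summary counts; the
module docstring lists every constraint it reproduces exactly. Cells not
pinned by any published count are deterministic arbitrary fill, so any
analysis of the fixture beyond the constrained counts (e.g. ranking it) is
illustrative only. The published margins are not perfectly mutually
consistent (the per-patient TKI-line histogram cannot equal 53/12/3 while
the exposure table holds); the exposure table and per-drug totals, which
the analyses consume, take precedence.

### Attribute ranking

Six evaluators, all reimplemented on categorical encodings and sorted
descending with name tie-breaks:

- **chi2** — Pearson χ² of the attribute × outcome table, no continuity
  correction;
- **info_gain** — H(outcome) − H(outcome|attribute) in bits;
- **symmetrical_uncertainty** — 2·IG/(H(attr)+H(outcome));
- **correlation** — |Pearson r| of indicator encodings; multi-level
  attributes use the frequency-weighted mean over one-hot columns (an
  aggregation choice; no canonical rule exists for nominal attributes);
- **relieff** — Kononenko ReliefF, k = 10 nearest hits/misses under
  Hamming distance, miss contributions weighted by class priors;
  exhaustive over all instances for n ≤ 1000, else a seeded subsample of
  1000 (deterministic given the seed, stable tie-breaks by instance
  order);
- **filtered** — info_gain applied behind the package's validation filter
  (the "filtered evaluator" pattern: same measure, schema-checked input).

Constant attributes score 0 rather than erroring. Ranking on the packaged
fixture is *not* validated against any published ranking — per-patient
data for that comparison does not exist — so ranking recovery is
demonstrated on synthetic cohorts with planted effects only.

### Synthetic cohorts

Attributes are drawn independently from configurable marginals (defaults
mirror the fixture's margins); the outcome follows a logistic model with a
~40% baseline rate and per-attribute odds multipliers. The generator is
bit-reproducible under a fixed seed. Independence across attributes is a
simplification (except age thresholds and derived flags; note that the
site-count attribute is derived from the site flags, so a planted site
effect induces a secondary association there, as a real registry would
show).

## Problem sizes in tests

The suite and the reproduction script run on scaled problem sizes chosen
to keep full runs fast while leaving Monte-Carlo margins wide: 12–60
residues × 4–8 heavy atoms; J = 5000 where the closed-form recovery bands
are asserted, J = 250 × 100 replicates for the variant-ordering check;
cohorts of 68 (fixture) to 5000 (ranking recovery). The statistic is
O(J·N) and sizes can be scaled up freely through the recipes.

## Known limitations

- The average-structure reference absorbs a small O(1/√J) bias and the
  rigid fit removes 6 degrees of freedom; both shrink displacements
  slightly. Negligible at study scale, visible only in the tightest
  closed-form tolerances.
- Ligand atoms never influence the fit mask by default; whether the
  original study included them in its fit mask is unknowable from the
  published description, and the choice is configurable.
- Whether the cumulative curves should summarize the mean or the std
  component is ambiguous in the source figures; both are emitted, the mean
  drives comparisons by default.
- The stability/ordering machinery assumes a single chain and author
  residue numbering; insertion codes are not modelled.
- No binding free energies, B-factor comparisons or survival endpoints:
  the package quantifies displacement statistics and categorical
  associations only.
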