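# Methods

## The problem

Docking engines such as AutoDock Vina explore a user-supplied axis-aligned
search space (the *docking box*). A box that is too narrow cannot contain
the correct binding mode — the pose is never sampled (*sampling failure*);
a box that is too generous admits so many irrelevant placements that a
wrong pose can outscore the right one (*scoring failure*). The classic
default protocol sizes the box from the crystallographic pose of a bound
ligand, which is unavailable for apo structures, homology models and
arbitrary library compounds. `dockbox` implements a ligand-size-adaptive
alternative: a cubic box whose edge is proportional to the query ligand's
own radius of gyration, centered on the (experimental or predicted) pocket.

## Ligand size descriptor

The radius of gyration is computed over heavy atoms only, with no mass
weighting:

    Rg = sqrt( (1/N) * sum_k |r_k - r_center|^2 )

where `N` is the heavy-atom count and `r_center` the unweighted geometric
center. Hydrogens are excluded throughout; elements are never weighted by
mass, so `Rg` is a purely geometric descriptor. An equivalent form used as
an independent test oracle is the pairwise identity
`Rg^2 = (1/2N^2) * sum_i sum_j |r_i - r_j|^2`.

`Rg` of a single low-energy conformer is used operationally. For flexible
molecules `rg_ensemble_summary` reports the mean and SD over a rotamer
ensemble (conformers beyond the first, or a caller-supplied generator
hook, 100 rotamers by default); conformer generation itself is delegated
to external tools because no particular force field is assumed here.

## Box protocols

**Optimized.** `edge = 2.857 x Rg`, cubic, centered exactly on the pocket
center. The multiplier 2.857 is the stored operative constant; the
equivalent Rg-to-edge ratio `1/2.857 = 0.35002` prints as 0.35 at two
decimals. Storing the multiplier (rather than deriving it from a stored
ratio of 0.35) keeps derived edge lengths consistent with the constant as
published at every printed precision, e.g. `Rg = 6.61 A -> 18.88 A`.

**Default (Vina-style emulation).** From the heavy atoms of a bound
ligand: take the axis-aligned bounding box; add 10 A to each dimension,
implemented symmetrically as +5 A per side (the total growth per
dimension is what the protocol fixes; the symmetric split is this
package's reading); per dimension flip a fair seeded coin — three draws
in x, y, z order — and extend one side by a further 5 A, which shifts the
center by +/-2.5 A; finally, any dimension still below 22.5 A is expanded
to exactly 22.5 A *symmetrically about the current center*, so the floor
step does not compound the random shift. Sizes are therefore
seed-independent (`extent + 15`, floored), while the center depends on
the seed. Whether the historical implementation shifts the center during
floor expansion is a dialect choice; the symmetric variant is used here
and documented.

**Sweep.** Cubic boxes with edges 2–36 A in 2 A steps (defaults of
`SweepSpec`), all sharing the pocket center. Results are expressed
against the *relative box size* `Rg / edge`, which makes ligands of
different sizes comparable on one axis.

Pocket centers come either from the bound ligand's geometric center
(`experimental`) or from a pocket predictor (`predicted`); a prediction
counts as successful when it lies strictly within 8.0 A of the
experimental center (a tie at exactly 8.0 fails — the conservative
reading of "below").

## Pose evaluation

* **RMSD** over heavy atoms with a positional 1:1 correspondence and *no
  superposition* — docked poses are compared in the fixed receptor frame.
  No automorphism-aware matching is attempted; highly symmetric ligands
  can therefore over-estimate their RMSD. This is a documented limitation.
* **Specific contacts**: all (protein heavy atom, ligand heavy atom)
  pairs within a distance cutoff, closed ball (`d <= cutoff`), default
  4.5 A. Dedicated surface-complementarity programs (e.g. LPC) define
  contacts more elaborately; the plain cutoff is the documented
  approximation, and the cutoff is a parameter so users can calibrate it
  against their reference tool.
* **Binding residues**: residues with at least one heavy atom within the
  cutoff; all atoms of a residue are equivalent, so each residue counts
  once.
* **Recovery fractions** are `|native ∩ predicted| / |native|`, an error
  when the native set is empty (the fraction is undefined, not zero).

## Screening metrics

Scores are binding affinities, lower = stronger. Libraries are sorted
ascending with stable ties.

* **EF^x%**: active density in the top `ceil(x * N)` compounds (at least
  one) divided by the overall active density — the *normalized* ratio, so
  1.0 is the random expectation. Boundary ties are resolved by the stable
  sort order.
* **BEDROC** (alpha = 20): exponential early weighting, RIE mapped onto
  [0, 1] with the min/max normalization at the observed active fraction.
  At alpha = 20, 80% (rounded) of the total rank weight lies in the top
  8% of a large library (`bedroc_weight_fraction` computes this
  directly). Depends on ranks only, so it is invariant to monotone score
  transforms.
* **AUC**: rank-based ROC convention — the probability that a random
  active outranks a random decoy, ties contributing one half, computed by
  the rank-sum identity with midranks. An accumulation-curve variant of
  "area under the enrichment curve" exists in the literature; the ROC
  convention is implemented because its 0.5 random baseline matches how
  such values are customarily read, and the alternative is noted here.
* **ACT-50%**: smallest top fraction containing `ceil(0.5 * n_actives)`
  actives; lower is better.

**Nonparametric tests.** Mann–Whitney U (unpaired score distributions)
and Wilcoxon signed-rank (paired per-target differences; zeros dropped).
Both use exact enumeration at small sizes — all `C(n, n_a)` rank
assignments up to a combined n of 12, all `2^n` sign patterns up to 15
nonzero differences — computed over the observed midranks so ties are
handled exactly, with two-sided p as the probability of a deviation from
the null mean at least as large as observed. The thresholds keep exact
enumeration in the sub-millisecond range; above them scipy's tie- and
continuity-corrected normal approximations are used, which agree with
enumeration to within 0.02 in the overlap region.

## Synthetic benchmark harness

The harness reproduces the *designs* of the benchmark experiments at desk
scale. Everything below is deliberately synthetic; none of it stands in
for real docking results.

* **Ligands** are self-avoiding random walks with a fixed 1.5 A step,
  non-bonded atoms at least one step apart, and an optional `stiffness`
  in [0, 1) that blends each step direction with the previous one.
  Complexes default to stiffness 0.5, giving elongated shapes (principal
  extents roughly 10 x 4 x 2 A at 12 atoms) comparable to drug-like
  molecules; stiffness 0 is a pure random walk.
* **Complexes** place the ligand's native pose on the pocket center and
  surround it with a wall of single-atom pseudo-residues: a 48-point
  spherical shell just beyond the ligand's reach plus one residue 3.5 A
  outward of each of the outermost ligand atoms, guaranteeing a non-empty
  native contact set at the 4.5 A cutoff. Single-atom residues are
  sufficient for contact-set logic; protein realism is out of scope.
* **Mock docking** draws `n_samples = 50` placements per run: one uniform
  random orientation each (Haar-uniform via normalized 4-normal
  quaternions); if the oriented ligand cannot fit in the box the attempt
  is lost, otherwise the center is placed uniformly over the positions
  that keep every atom inside. The score is RMSD-to-native plus Gaussian
  noise with SD `noise_scale x volume^(1/3)` (`noise_scale = 0.08`).
  Lost attempts reproduce sampling failures — a box that cannot contain
  the native orientation can never return it, and tight boxes dock with
  few effective samples; volume-scaled noise reproduces scoring failures
  in generous boxes. The model is engineered and non-physical: it
  exercises the sweep and evaluation machinery and the two failure
  modes, nothing more. In particular the *location* of its optimum ratio
  is a property of the mock energy model, not of any real docking engine,
  so only the qualitative curve shape (U-shaped RMSD, inverted-U contact
  recovery, interior optimum) is asserted.
* **The sweep driver** evaluates the top pose per (complex, edge), bins
  by relative box size (bin width 0.05) and averages within bins. Bins
  with fewer than 5 evaluable results are dropped: with 20 complexes a
  sparser bin's mean is dominated by one or two docking runs. Per-point
  seeds are derived from the master seed by counter hashing
  (`SeedSequence([master, i, j])`), so any subset of the sweep is
  reproducible in isolation and the whole pipeline is deterministic for a
  fixed master seed.
* **Ranked libraries** draw actives from Normal(-8.70, 2.17) and decoys
  from Normal(-7.85, 2.07) by default — a realistic separation for a
  structure-based campaign against experimental pockets (about 0.4 SD),
  chosen once as the generator's standard conditions. The null case
  (equal means) calibrates AUC to 0.5.
* **Protocol comparison** takes paired per-target metric panels, reports
  mean +/- SD per arm, the Wilcoxon p on paired differences (NaN when no
  target differs), and the percentage of targets the second arm wins,
  ties counting one half; ACT-50% improves downward, all other metrics
  upward.

## Problem sizes and determinism

The standard sweep experiment is 20 complexes x 18 edges x 50 samples per
docking run, about one second end to end; the library generators default
to a few thousand compounds. All stochastic components take either an
explicit integer seed or a `numpy` Generator, and every pipeline output
is bitwise reproducible for a fixed master seed.

## What passing tests do and do not show

The synthetic fixtures validate the machinery: geometry, box arithmetic,
metric definitions, statistical tests, and the qualitative
box-size/accuracy trade-off. They say nothing about docking accuracy on
real protein-ligand complexes, real pocket predictors, or real screening
libraries — those require a docking engine and curated benchmark sets,
which this package deliberately treats as external (`DockingBackend` is
the seam where a real engine plugs in).

## Known limitations

* PDBQT support is coordinate extraction only; charges, atom types and
  torsion trees are never interpreted, and PDBQT is never written.
* No protonation, bond-order perception or SMILES handling; ligand
  curation (6–100 heavy atoms, inclusive; non-covalent) takes covalency
  as an input flag from database annotation rather than inferring it from
  geometry, and no element-composition filter is applied beyond the
  hydrogen/heavy split. Protein curation (50–600 residues, inclusive)
  counts polymer residues only.
* RMSD is not symmetry-corrected.
* The contact definition is a distance cutoff, not a surface calculation.
* The mock backend is rigid-body; real conformational sampling failures
  (ligand crumpling in tight boxes) are represented only through the
  orientation-rejection mechanism.
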