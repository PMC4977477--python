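# Methods

This note documents the models, numerical choices and open design decisions
behind `ancfold`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and what the synthetic test beds do and
do not show.

## Protein model and kinematics

A chain of n residues is a linkage in which only the backbone dihedrals
φ and ψ are flexible. Bond lengths, bond angles and the peptide ω dihedral
are fixed at standard ideal values (N–CA 1.458 Å, CA–C 1.525 Å, C–N
1.329 Å; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°; ω = 180°). Each
residue contributes six atoms — N, H, CA, CB, C, O, with HA standing in
for CB on glycine. The six-atom identity is a modelling choice: backbone
plus one side-chain marker is the coarsest model that still supports
hydrogen-bond geometry (O···N/H) and hydrophobic side-chain contacts
(CB···CB). Coordinates are realized by natural-extension (NeRF) placement;
the first residue sits in a canonical frame (N at the origin, CA on +x,
C in the upper xy half-plane), so raw coordinates are frame-dependent and
rigid-motion-invariant comparison must go through least-RMSD superposition.
The backbone round-trips exactly: measured dihedrals of generated
coordinates reproduce the input torsions to below 1e-6°.

Angles live in degrees on (−180, 180]. The first residue's φ and the last
residue's ψ are geometrically undefined; they hold the placeholder 180°
and are excluded from perturbation. PDB files written by the package carry
3-decimal coordinates, which limits a file round-trip of dihedrals to
about 0.1°; that is a format limit, not a kinematics error.

## Potential and feasibility

The potential is a soft-constraint sum plus a hydrophobic term,

    U = Σ_constraints K_d · { [ (d_i − d_0)² + d_c² ]^(1/2) − d_c } + E_hp,

with defaults K_d = 100 kJ/mol, d_0 = d_c = 2 Å. The constraint set is a
Gō-like choice: all backbone covalent bonds, plus native hydrogen bonds —
carbonyl-O to amide-N pairs, sequence separation ≥ 2, within 3.5 Å in the
native structure with both residues inside a declared secondary-structure
segment. Because covalent bonds (1.0–1.5 Å) sit below d_0, the fully
extended "open chain" has strictly positive energy, which is what makes
the sampling window E_min…2·E_min well-defined.

E_hp is a step contact potential: every hydrophobic residue pair with
sequence separation ≥ 3 whose CB markers are within 6 Å contributes
−1 kJ/mol (both parameters configurable; the per-contact energy must be
≤ 0, which guarantees U ≥ E_hp). Hydrophobicity follows the apolar set
{A, C, F, I, L, M, V}. A continuous distance-dependent E_hp would be a
drop-in replacement; the step form was chosen as the simplest term that
preserves the role of hydrophobic collapse in the landscape.

Feasibility is a hard two-threshold clash test: any non-exempt atom pair
closer than 2.4 Å during sampling, or 1.0 Å during connection checking,
makes the conformation infeasible (energy +∞, so acceptance and transition
probabilities degrade to zero rather than raising). Exempt pairs are those
within four covalent bonds, plus O···N and O···H pairs that are natively
hydrogen-bonded: with ideal geometry the intra-residue H···O pair sits at
2.31 Å and a helix hydrogen bond at 2.10 Å, so a narrower exemption would
declare every native helix infeasible. Hydrogen-bonded pairs are instead
held near their native distance by the soft constraint term.

Every fresh potential evaluation increments a monotone call counter on the
energy model; cached energies (stored on the conformation) are free. This
counter is the cost currency of the learner, on the grounds that potential
evaluations dominate wall time at scale.

## Sampling

Samples grow as a tree rooted at the native state. A parent is drawn
uniformly from the accepted set; a fixed number of flexible torsions
(default 4) is drawn without replacement with rigidity-biased weights
(flexible:rigid = 4:1) and perturbed uniformly within ±30° (default);
the proposal is kept with probability 1 below E_min, 0 above E_max, and
linearly in between, with the boundary E = E_min accepting at 1
(continuity from below — the ramp's branches leave that point open).
E_min is the open-chain energy and E_max = 2·E_min by default. The
uniform-parent rule is the least-informative reading of "iterative
perturbation from the native state"; it biases growth breadth-first over
the accepted set.

## Rigidity

The rigidity map partitions the 2n torsion units (residue-major φ, ψ) into
rigid clusters. The decomposition is deliberately simplified: clusters are
connected components of a graph whose edges chain each declared segment's
units together and join the units of residue pairs whose native hydrogen
bond is currently satisfied (length within 110 % of native). This stands
in for a full pebble-game/body-bar analysis; the downstream consumers —
the cluster distance and the perturbation bias — only need a cluster
partition, and the interface (a label vector) admits an exact
implementation without any consumer change. The cluster distance between
two maps is the number of unordered unit pairs whose same-cluster
indicators disagree, computed from the partition contingency table; it is
a pseudometric (symmetric, zero on identical partitions, triangle
inequality), which the tests check on random partitions.

The unit domain is 2n torsion-level units rather than n residues or 6n
atoms; the pairwise-disagreement sum runs over indices 0…2n−1.

## Metrics, neighbours, local planner

Three metrics drive candidate selection: torsional RMS (differences taken
on the circle, so 179° and −179° are 2° apart — plain subtraction would
break the metric axioms at the wrap), the rigidity-map disagreement count
(maps computed lazily and cached), and least RMSD over the 6n atoms after
Kabsch superposition (`scipy.spatial.transform.Rotation.align_vectors`).
Neighbour search is exact brute force with ascending-(distance, id)
ordering, so results are deterministic under ties; k-nearest sets are
nested in k.

The local planner interpolates all torsions along the minimal angular arc
with at most 5° (default) per torsion per step, evaluates intermediates at
the connecting clash threshold, and scores both directions:
forward/reverse weights are Σ −log P_i with the Metropolis-style step
probability. Failure (any infeasible intermediate) is a result, not an
error; evaluation stops at the first infeasible intermediate and the
calls already spent are charged to the attempt. Both directed edges of a
successful attempt enter the roadmap, since ΔE is antisymmetric and
folding pathways are directional.

## The bandit

Connection methods are arms of an Exp3-style adversarial bandit with
exploration floor γ/m, reward normalization into [α, 1] against running
edge-weight extrema, importance-weighted exponential updates, and
cost-adjusted selection p_i ∝ p*_i/c_i. Defaults γ = 0.1, α = 0.5: γ
small enough that a clearly better arm can reach selection share
(1−γ)+γ/m ≈ 0.95, large enough that no arm starves; α = 0.5 splits the
reward range evenly between "an edge was made" and "how good it was".
Choices fixed in the implementation:

* Failed attempts earn reward 0 and still pay their cost — the reward is
  defined only for produced edges.
* A lone observation (min = max of the extrema) earns reward 1.
* Methods with no cost history are charged an optimistic average cost of
  one energy call, so new arms are not starved by the cost adjustment.
* The cost-adjusted probability is normalized by Σ_j p*_j/c_j.
* Method sampling is inverse-CDF in fixed method order under a seeded
  generator, so runs are reproducible.

ANC-global keeps one persistent state for the whole run. ANC-local keeps
none: for each query it takes the 40 (NF_local) prior attempt records
whose nodes are nearest in torsional RMS, replays them chronologically
through a fresh state — reward extrema are the running extrema over the
replayed neighbourhood — and samples from the result. Replay over a
per-query record set was chosen over persistent per-region states because
it needs no landscape partition, which is precisely the failure mode of
global learning that local learning is meant to remove. Records therefore
store the raw edge weight and success flag alongside the frozen reward,
so replay can re-normalize. With an empty history both regimes reduce to
a uniform draw. Fixed single-metric strategies run through the same
driver with a one-arm method set.

## Roadmap, pathways, SSFO

Construction alternates sampling and connection in batches (default 15–25
samples per batch, k = 20 neighbour attempts per new node). After each
batch the unfolded set is refreshed — the top decile of node energies,
minimum one node, as the model's stand-in for the denatured ensemble (the
choice is configurable; high energy ≈ denatured is the only operational
definition available in this model). Minimum-weight directed paths from
each unfolded state to the native state are extracted with a deterministic
Dijkstra (lexicographic tie-breaks). A segment counts as formed at the
first pathway conformation with ≥ 70 % of its native hydrogen bonds
satisfied (within 110 % of native length); a bond supports every segment
containing one of its endpoints; ties resolve to sequence order and
never-formed segments append last. The build stops when no formation
ordering's pathway share moves by more than 30 percentage points between
successive batches (exactly 30 counts as stable — the rule is "does not
vary by more than"), always comparing consecutive batches only. A hard
batch cap (default 8–12) guards non-convergence: hitting it with at least
one pathway returns the roadmap flagged unstable; with none, it raises a
diagnostic error.

Pathway quality is Σ over edges of weight × number of extracted pathways
traversing the edge (lower is better); the per-method report gives
selection share, local-planner success rate (edges made / attempted) and
cumulative energy-call cost.

## Synthetic test beds — what they show and what they don't

The toy-protein generator builds 4–40-residue chains with ideal
Ramachandran torsions inside declared segments (helix −57/−47, strand
−119/113), seeded random loops regenerated until the native state is
clash-free, and LEU/SER sequences realizing a chosen hydrophobic pattern.
These fixtures exercise every pipeline stage deterministically, but they
are small, single-domain, and have permissive landscapes (local-planner
success rates near 1), so they probe correctness and mechanism — not the
performance rankings one would measure on real 50–120-residue proteins.

The two-region bench isolates the selection mechanism entirely: two mock
connection methods whose success probabilities (0.9/0.2 by default) flip
between two regions of a fake torsion space, five attempts per query,
unit costs. On this bench the localized learner's within-region
correct-method frequency beats the global learner's in paired-seed
comparisons — the core locality claim — and a stationary 0.8-vs-0.2
two-armed bench checks plain bandit regret behaviour (better-arm
frequency well above 0.6 after 500 steps). Passing these benches shows
the learning machinery is correct and locality-sensitive; it does not by
itself predict effect sizes on real folding landscapes.

## Problem sizes and determinism

Default test and pipeline scales are chosen for desk-scale runs: 8-residue
toys, 15–25-sample batches, k = 20, NF_local = 40, which complete an
end-to-end build in seconds while leaving every mechanism (stability rule,
unfolded-set refresh, bandit replay) active. All randomness flows from
explicit `numpy` generators seeded from a single root; identical config
and seed reproduce artifacts byte-for-byte (floating-point values are
serialized via `repr`, giving shortest round-trip representations).

## Known limitations

* The rigid-cluster decomposition is a connected-component surrogate, not
  a pebble-game analysis; it cannot detect rigidity arising from cycle
  counting alone.
* The hydrophobic term is a step potential; landscapes near the cutoff
  are discontinuous.
* The six-atom identity and ideal-geometry constants are conventions; CB
  chirality is consistent but not calibrated against rotamer libraries.
* "Unfolded" is an energy-decile definition, not an experimental ensemble.
* Exact brute-force neighbour search is O(N²) in roadmap size; fine at
  desk scale, the known bottleneck beyond it.
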