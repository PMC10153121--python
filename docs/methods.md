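# Methods

`allonet` implements the trajectory-analysis layer used to study why
nonpolar terpenoids (amorphadiene, α-bisabolene) selectively inhibit the
protein tyrosine phosphatase PTP1B over its close homolog TCPTP: the
isolation of the state-dependent hydrogen-bond network that couples the
active site to the C-terminal allosteric site, the classification of
WPD-loop and α7-helix conformational states, interaction-occupancy
statistics and their disruption by bound ligands, and ligand
binding-site/retention analysis. This note records the models, the
parameters that matter, and the design decisions taken where the
procedure was genuinely open.

## Trajectory preprocessing

**Backbone RMSD.** Computed per frame against the starting structure
after optimal superposition on protein N/Cα/C/O atoms (mdtraj's
quaternion method). Units nm.

**Equilibration pruning.** A reverse-cumulative plateau rule: the
equilibration start is the smallest index whose forward window mean
differs from the mean of the final window by at most one SD of the final
window. The window defaults to 5% of the series (minimum 2 frames).
Probe windows are not allowed to overlap the final reference window —
an overlapping probe trivially matches itself, which would hide monotone
drift. Degenerate cases are defined, not silent: a series shorter than
two windows keeps all frames with a warning; a series that never
plateaus returns `n − window` with a warning so the pipeline continues.

**Decorrelation.** The post-equilibration RMSD series is segmented with
PELT under an L2 (mean-shift) cost; the penalty defaults to
`2·log(n)·Var(series)` and is configurable. PELT is implemented
in-package (exact dynamic programming with cost-based pruning) and is
checked against planted mean-shift series in the tests. Within each
segment, frames are retained every `ceil(τ)` frames, where τ is the
integrated autocorrelation time estimated by summing autocorrelations
`τ = 1 + 2·Σ ρ_k`. The sum truncates at the 99% white-noise
significance floor `2.58/√n` rather than at the first non-positive
term: on an uncorrelated segment the noise in ρ₁ would otherwise push τ
just above 1 and `ceil` would discard every second frame of a series
that carries no redundancy. A zero-variance segment contributes one
frame (one effective sample). On AR(1) series the retained-frame
spacing tracks the analytical `(1+a)/(1−a)` within 50%.

**Clustering.** Gromos-style: iteratively take the frame with the most
neighbors within the cutoff (default 0.2 nm backbone RMSD) as a cluster
leader and remove the cluster. Ties break toward the lowest frame
index, making the procedure deterministic. The centroid is the member
of the largest cluster with the most within-cluster neighbors.

## Conformational states

**WPD loop.** Open iff the Cα–Cα distance between the catalytic acid
and the nucleophile strictly exceeds the threshold; a distance equal to
the threshold is closed. The threshold is a *mandatory* configuration
value: the commonly quoted "1 Å" figure is physically implausible for
this Cα pair (apo closed structures sit near 8–9 Å), so the package
refuses to guess and the reference configuration ships 10 Å (1 nm, the
likely intended unit). The synthetic generator draws closed/open
distances from Gaussians at 8.0 ± 0.25 Å and 12.0 ± 0.25 Å — a 16 SD
separation, so the 10 Å threshold cannot misclassify a fixture frame.

**α7 helicity.** Percent of α7 residues assigned the α-helix class by
DSSP ('H' only; 3₁₀ and π helices do not count). The default backend is
mdtraj's DSSP; a φ/ψ-window backend (φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°],
runs of ≥ 3) is provided and agrees with DSSP on ideal fixtures. A frame
or trajectory is disordered iff helicity is strictly below the
threshold (default 50%; exactly 50% is ordered). Empirically, mdtraj's
DSSP assigns 'H' to exactly the residues given ideal helical dihedrals
(φ = −57°, ψ = −47°) when the run is ≥ 4 residues long and away from
chain termini; the generator exploits this to plant helicity schedules
that are recovered exactly, and rejects schedules implying runs of 1–3
residues, which DSSP cannot represent.

## Interaction detection

All cutoffs are strict inequalities; geometry exactly at a cutoff never
counts.

* **Contacts** — minimum heavy-atom distance between two residues (or a
  residue and the ligand) < 4 Å, computed with mdtraj's closest-heavy
  contact scheme over a declared region-pair scope.
* **H-bonds** — the default follows the Baker–Hubbard geometric model:
  hydrogen···acceptor distance < 2.5 Å and donor–hydrogen–acceptor
  angle > 120°, donors being N/O with a bonded hydrogen and acceptors
  any N/O, same-residue pairs excluded. Criteria in the literature are
  frequently transcribed with the donor–acceptor distance or an
  inverted angle inequality, so both conventions are selectable in
  `HbondCriteria`; the defaults reproduce the model implemented in the
  tooling this analysis descends from. Detection prescreens
  donor–acceptor pairs with per-atom bounding boxes over the whole
  trajectory (an exact lower bound on every per-frame distance) and
  evaluates the surviving pairs exactly in float64, so output is
  bit-identical to exhaustive enumeration.
* **π-stacking** — present between a residue and the ligand iff a
  bonded sp² carbon pair of the residue and a bonded sp² carbon pair of
  the ligand have all four cross-distances < 3.5 Å (the "pair-to-pair"
  reading; an any-single-distance rule is selectable). Worth knowing:
  for ideal rigid hexagons the all-four rule cannot fire at a 3.4 Å
  plane-to-plane gap — two atoms 1.39 Å apart cannot both fit inside
  the 0.83 Å lateral lens — so on idealized fixtures face-to-face
  sandwiches are detected under the any-pair rule. sp² carbons are
  inferred from aromatic residue ring-atom names and, for the ligand,
  from ring membership in its bond graph; explicit atom lists override
  the inference.

**Occupancy.** The fraction of retained frames in which an
interaction is present, one column per trajectory with an ensemble
label (`apo-open`, `apo-closed`, `ligand:<name>`). Interactions never
observed anywhere are dropped; interactions absent from one trajectory
get 0 there.

## Network isolation and statistics

The five-step isolation: detect h-bonds; remove *ubiquitous* bonds
(occupancy > 0.5 in strictly more than half of all trajectories,
pooled over every ensemble) and *sequence-adjacent* bonds
(|Δindex| ≤ 3 within a chain; ligand pairs are exempt since adjacency
is undefined across chains); compute mean occupancy per apo ensemble;
Welch's unequal-variance t-test per bond; assign each bond to its
higher-mean state iff p < 0.01 (two-sided) *and* mean occupancy in that
state ≥ 70%. The statistical unit is the trajectory, never the frame —
frames are autocorrelated, and per-trajectory occupancies are
approximately independent replicates. Both filter sub-thresholds, the
adjacency window, α and the 70% floor are configurable. The two filters
commute (tested), so their order is irrelevant.

Welch's t, the Welch–Satterthwaite df and p are computed from the
closed-form expressions and cross-checked against scipy to 1e-10.
Degenerate inputs are defined: identical zero-variance groups give
p = 1 ("no difference"); zero variance with different means gives
t = ±∞. No multiple-testing correction is applied by default, matching
the per-bond screening practice this implements; Benjamini–Hochberg is
available behind a flag and its use is logged.

Assigned bonds form an undirected residue graph. The connectivity
verdict asks whether any active-site residue (WPD or P loop) reaches
any allosteric-site residue (L-11, α3, α6 or α7) through assigned bonds
of one state; it equals BFS reachability (tested against an independent
BFS).

**Interfaces.** For each of α3–α7, L-11–α7, α3–α6 and α6–α7 the package
counts interactions present per ensemble (mean occupancy across the
ensemble's trajectories > 0.5) and reports the percent difference of
closed over open, `(n_closed − n_open)/n_open × 100`; when the open
state has no interactions the percentage is reported as 0 with an
explicit undefined flag. A ligand *disrupts* an interaction iff it
occurs significantly less in the ligand-bound ensemble than in the apo
baseline (one-sided Welch, p < 0.05) — one-sided because disruption is
a directional claim, unlike network membership.

## Ligand analysis

**Sites.** The α site requires simultaneous contacts with α3 and α7;
the β site requires α3 plus at least two of β8–β10 (the pocket sits at
the sheet/helix interface; a one-sheet reading is selectable). When
both predicates hold the α label wins (configurable precedence) so each
frame has exactly one label; frames contacting the protein without
satisfying a site are `other-bound`, frames without protein contact
`unbound`.

**Retention time** runs from the first frame at a site to the first
departure lasting more than the grace window (default 0 frames — the
strict reading of "remained bound"; real data need a small grace window
because contact flicker at 4 Å is inevitable, which is why the
parameter exists). **Dissociation** is the first frame opening a run of
≥ 10 retained frames with zero protein contacts; a single-frame contact
loss never counts.

**COM RMSD.** Frames are superposed on the protein backbone, then the
ligand's mass-weighted center-of-mass displacement from the reference
frame is bootstrapped over retained frames (default 1000 replicates,
deterministic per seed); the reported SE is the SD of replicate means
and tracks the closed-form SD/√n within 15% on iid data.

**Distinct poses.** Greedy selection in affinity-rank order: keep a
pose iff its COM is ≥ 5 Å from every kept pose. The 5 Å merge radius
reflects that poses closer than that are sampled within a single
trajectory when the ligand's own COM RMSD is ~7 Å.

## Synthetic data: what it emulates, and what it does not

The generator builds poly-alanine chains with ideal backbone internal
coordinates, laid out as rigid extended segments at stations separated
by ~26 Å so that *only planted* interactions exist (plus sequence-local
backbone contacts, which the filters remove, and α7-helix backbone
h-bonds, which are ubiquitous by construction when helicity is constant
across an ensemble). Planted h-bonds toggle between an ideal geometry
and a 90° donor–hydrogen–acceptor violation (≥ 30° margin below the
cutoff) at the acceptor's unchanged position radius, so contact maps
are stable across toggles. The α and β pockets are realized
geometrically: a rigid 6-carbon ring bridges anchor atoms of the
required regions at < 4 Å. Trajectory-level defaults match the scale of
the study conditions the package is tested under: 300 frames at 0.1
ns/frame (the 2–4 uncorrelated frames/ns regime), ensembles of 4
apo-open + 4 apo-closed members, planted occupancies 0.9 vs 0.1 with
0.95 ubiquitous and adjacent decoys.

What passing these tests shows: the detectors, filters, statistics and
classifiers implement their stated rules exactly, with calibrated false
positive behavior under the null. What it does not show: anything about
force-field realism — there is no solvent, no thermal backbone noise,
no partial h-bond geometries near the cutoffs, and state schedules are
planted rather than emergent. Real trajectories will put geometry *at*
the cutoffs, where the strict-inequality conventions and the h-bond
convention flags matter; those choices are therefore all surfaced in
configuration.

## Problem sizes and numerical choices

Benchmarks in the tests and acceptance script use 8-member ensembles of
100-residue chains with 300 frames (the null calibration enlarges the
chain to 308 residues to host 100 planted bonds), 20 independent seeds,
2000 bootstrap replicates, and 50–100 random fixtures per
oracle-equivalence check — sizes chosen so the planted effects are
recovered with overwhelming statistical margin on a single CPU. All
randomness flows through `numpy.random.default_rng` seeds; the pipeline
writes a config-hashed, byte-deterministic summary. Floating point:
detectors evaluate in float64 (coordinates are stored in float32 by the
trajectory formats; comparisons at planted geometries carry ≥ 0.5 Å /
≥ 20° margins); mdtraj's float32 RMSD loses precision on systems with
large spatial extent, which matters for none of the thresholded uses
here but is why oracle comparisons use compact systems.

## Known limitations

* The equilibration and decorrelation contracts are reproducible
  stand-ins pinned by this package, not a restatement of any upstream
  tool's exact penalty and subsampling rules; both are configurable.
* DSSP-based helicity cannot represent helical runs shorter than 4
  residues; fixtures reject such schedules rather than mislabel them.
* The π-stacking pair-to-pair rule is conservative on idealized rings
  (see above); analyses of real aromatic geometry should consider the
  any-pair rule consciously.
* Interface percent differences on fixtures without planted contacts
  are 0-with-flag; the generator does not plant inter-helix contacts.
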