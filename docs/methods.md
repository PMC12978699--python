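# Methods

## Lineage-tree model

A germline cyst is represented as a tree over integer cell ids (founder = 1,
daughters numbered consecutively in creation order, breadth order within a
round). Divisions are synchronous and incomplete: each dividing cell gains
one new bridge to its new daughter, and **all pre-existing bridges remain
with the dividing cell** (the retaining daughter). This inheritance rule is
the one assumption doing real work: it produces the maximally branched
canonical topology whose 8-cell form has bridge counts {3,3,2,2,1,1,1,1}
and exactly two bridges whose removal isolates six cells. Alternative rules
(e.g. splitting old bridges between daughters) produce different degree
sequences and different breakage arithmetic; they are out of scope.

Cells and bridges carry their creation round; the parent map records the
division history, which the undirected bridge tree alone cannot (the
retaining daughter keeps its id). Exports: TAB-separated edge list
(loss-free for the bridge graph, and sufficient to rebuild the history
because ids are creation-ordered), JSON, and a rooted binary newick string
of the division lineage (one internal node per division).

### Partial rounds

Cysts of 7, 9 or 10 cells are modeled as a canonical cyst caught midway
through its next round: the canonical 2^⌊log₂ n⌋-cell cyst plus n − 2^r
single divisions. Which cells have already divided is not observable in the
source data, so two policies are provided:

* `leaf_first` (default, deterministic): cells with the fewest bridges
  divide first, ties by lowest id;
* `random_subset`: a seeded uniform subset.

A consequence worth stating plainly: under `leaf_first` the 7-cell cyst has
p₆ = 3/6 (three of its six bridges are pendant on a 7-cell tree, and a
6-cell fragment requires a pendant cut), while the 9- and 10-cell cysts
admit **no** 6-cell cut at all (the extra daughters land symmetrically in
both halves, so no edge isolates exactly six cells), giving p₆ = 0. Real
9/10-cell cysts evidently can release 6-cell products, so the leaf-first
partial topology is a modeling convention, not a biological claim; the
`random_subset` policy produces topologies that sometimes do admit 6-cell
cuts. This is why the pooled test — not the mixed-size exact test — is the
default and the published procedure.

## Breakage statistics

`p_six` is the exact rational fraction of bridges whose removal yields a
6-cell fragment (2/7 on the canonical 8-cell cyst). The pooled null test
treats each of n observed cysts as a Bernoulli trial at p = 2/7 and reports
both the binomial **point probability** P(X = k) and the **upper tail**
P(X ≥ k); for the 13-of-15 sample these are 4.53 × 10⁻⁶ and 4.80 × 10⁻⁶.
The published figure numerically matches the point probability, so that is
the value labeled as the replication; both are always reported and the
distinction is the caller's to interpret. Binomial terms are computed in
log space via `scipy.stats.binom`.

The exact mixed-size mode gives each record its own p₆ from its size's
partial topology and evaluates the Poisson-binomial pmf by iterative
convolution (O(n²), exact to ~1e-15; validated against full 2ⁿ enumeration
for n ≤ 15). On the 15-cyst sample with leaf-first topologies the four
9/10-cell records have p₆ = 0, so at most 11 successes are possible under
that null and the exact probability at k = 13 is exactly 0 — a degenerate
but faithful consequence of the partial-topology convention discussed
above.

### Power study

`power_curve` simulates datasets under programmed or random gap placement,
runs the pooled test, and tabulates rejection (upper tail ≤ α) at
α ∈ {0.05, 10⁻⁴}. The default size mix is all canonical 8-cell cysts so
that every record can in principle succeed; with the programmed truth and
no miscalls all 15 records predict a 6-cell product and the tail
probability is (2/7)¹⁵ ≈ 7 × 10⁻⁹, hence rejection in every replicate.
Under the random truth the rejection rate stays below the nominal level
because a discrete exact test is conservative. 1000 replicates run in a few
seconds; the per-size bridge pools are memoized across replicates.

## Programmed breakage

The microtubule gap is represented topologically: one designated bridge
lacking a stable microtubule connection. `programmed_break` removes, among
bridges releasing a 6-cell fragment, the one whose 6-cell side contains the
most-branched cell — the multi-bridge, fusome-enriched pro-oocyte — with
ties broken by (creation round, smaller endpoint id). On the canonical
8-cell cyst two bridges qualify and both place the hub on the 6-cell side;
which of the two breaks in vivo is not distinguishable from the data, so
the tie-break is a determinism convention. If no six-yielding bridge's
6-side contains the hub, the tie-break runs over all six-yielding bridges.

Clone-level schedules:

* `quartet` (default for the headline numbers): after round 5, remove the
  three round-1/2 bridges (four 8-cell subtrees), then 6 + 2 break each:
  fragment multiset {6: 4, 2: 4}, four oocytes.
* `eight_cell`: break any fragment of ≥ 7 cells that admits a 6-cell cut as
  soon as a round completes. After round 3 the 8-cell cyst splits 6 + 2;
  the regrown 12- and 24-cell descendants of the 6-cell side admit no
  6-cell cut (component sizes double each round, so only 1/2/4/8-multiples
  occur), while the 2-cell side regrows to a canonical 8-cell cyst by round
  5 and splits again. Final multiset {24: 1, 6: 1, 2: 1} — recorded as a
  regression value.
* `none`: divisions only (one 32-cell cyst).

Oocytes are counted as fragments of ≥ 6 cells by default (configurable
threshold).

## Fusome inheritance

Per-cell fusome volume (μm³) follows each division: the retaining daughter
receives f·V + δ/2, the new daughter (1 − f)·V + δ/2, each then multiplied
by an independent lognormal(0, σ) factor. Defaults V₀ = 1 μm³, f = 0.65,
δ = 0.2 μm³, σ = 0.25: f encodes the consistently unequal sister volumes
seen in 2-cell cysts (chosen as a clear but not extreme bias; the source
quantifications are graphical, not tabulated), δ the new material deposited
at the cytokinesis furrow, and σ the scatter visible in the published
per-cell volume plots (matched qualitatively, not fitted). Lognormal noise
keeps volumes positive. Noise-free, a division conserves V + δ exactly, and
with f > ½ volume is strictly ordered by the number of retained divisions
on a cell's lineage path, so the most-branched cell holds the most fusome —
the property `enrichment_report` quantifies with a mid-rank Spearman
correlation (degenerate constant inputs are flagged and reported as 0).

The model collapses within-cycle timing (the observed asymmetry arises only
in late telophase) into the division event, and models the fusome as a
per-cell scalar rather than a per-bridge field, because per-cell volumes
are what the imaging quantifies.

## Nurse-cell transfer

Within a fragment the oocyte is the most-branched cell. Activation times
are exponential with rate 0.5/day (one cell per two days on average, giving
a mean breakdown time of (n − 1)/rate — 10 days for a 6-cell cyst).
Activation order: current leaves of the shrinking tree, fewest bridges
first (ties by id), or a seeded uniform leaf. A donor passes ε of its
current content to its neighbor toward the oocyte and is removed; the
(1 − ε) remainder is logged as the dying remnant. Transfer is hop-wise, not
teleported, so losses compound with path length: ε = 1 gives fold
enrichment exactly n, ε = 0.9 on a 6-cell fragment ≈ 5 — qualitatively in
the range of the reported ~5-fold organelle increases, which are external
measurements this package does not fit.

## Synthetic data

All fixtures are generated, seeded, and byte-reproducible. Measurement
tables draw cysts of configurable sizes, volumes from the fusome simulator,
Pard3 areas as volume-proportional with independent lognormal noise
(σ = 0.25), and nucleus diameters lognormal around 8 μm. MT-gap datasets
place the gap bridge per the ground truth (`programmed` with a miscall
rate η, or `random`); the six-cell prediction is always *derived* from the
graph, never stored, so records cannot drift out of internal consistency.
When a programmed-truth topology admits no six-yielding bridge the gap
falls uniformly on any bridge. The 10-μm gap-size threshold of the imaging
analysis is metadata only; no spatial geometry is simulated.

Voxelized granules rasterize non-overlapping spheres (a voxel belongs to a
sphere if its center lies inside); measured volume is voxel count × voxel
volume. At 0.2 μm voxels a 5-μm-radius sphere measures within 2% of
4πr³/3, and total absolute error over a fixed multi-sphere set decreases
monotonically across voxel sizes 0.4 → 0.2 → 0.1 μm. Per-sphere error
oscillates with grid alignment, which is why refinement is asserted on a
sphere *set*, not a single sphere.

## Numerical and testing conventions

Problem sizes: Monte-Carlo checks use 10⁵ single-break draws, 10⁴ transfer
runs, and 1000-replicate power tables — sizes at which binomial/normal
standard errors make the stated 3–4 s.e. bands meaningful and the whole
suite runs in under a minute. All randomness flows through
`numpy.random.Generator`; every stochastic API takes a generator or seed,
and fixed seeds reproduce results bit-for-bit (CLI manifests contain the
config echo and seed, never timestamps). Tie-breaks everywhere are
(creation round, smallest cell id). Tests validate against independent
oracles: a hand-written BFS for component sizes, full 2ⁿ enumeration for
the Poisson-binomial, closed-form products for fusome volumes, hand
propagation for transfer folds, and dendropy parsing for newick output.

## Known limitations

* The partial-round topology of 7/9/10-cell cysts is a convention (see
  above); conclusions that depend on it (notably the exact mixed-size test)
  should be read accordingly.
* No spatial embedding, cell movement, male cyst topology, within-cycle
  timing, or organelle identity beyond scalar content.
* The generators emulate the statistical structure of the measurements
  (asymmetry, enrichment, gap placement), not microscopy: passing tests
  validate the combinatorics and estimators, not image segmentation.
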