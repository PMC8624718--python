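# Methods

## Model

A topology is an ordered, directed assignment of sequence-predicted
secondary-structure segments `S0…S(M−1)` to density-detected traces
`L0…L(N−1)`, like type to like type, from the N- to the C-terminus. Each
matched trace carries one of two directions (`L` vs `L′`), reflecting the
two ways a straight axis can be walked by the chain. Per SSE type the
candidate space has `C(max(M,N), min(M,N)) · min(M,N)! · 2^min(M,N)`
members; the counting is symmetric in `(M, N)` so the same machinery covers
cases with more traces than segments (surplus traces are simply left
unused) and cases with more segments than traces (surplus segments are
skipped).

### Initial geometric score

The only geometric quantity that links the 1D and 3D views is the loop
between consecutive matched elements: a loop of `r` residues cannot span
more than `3.8·r` Å (the Cα–Cα virtual bond length), though it can be
arbitrarily compact. Each consecutive pair of matches therefore contributes
a one-sided hinge penalty

    max(0, observed_gap − rise_per_residue · r − loop_slack)

and each unmatched segment adds a flat `skip_penalty`. The observed gap is
measured from the C-side exit endpoint of the earlier trace to the N-side
entry endpoint of the later trace under their assigned directions, so that
direction choices influence the score. When a skeleton is supplied the gap
is a graph geodesic along it (snap to the nearest skeleton point, Dijkstra
over points linked within `link_radius`, plus the two snap distances);
otherwise it is the straight-line distance. Residues of skipped segments
count toward the loop spanning them.

The hinge form is an explicit design choice: loops shorter than their
stretched length are geometrically unremarkable and carry no evidence
against a candidate, whereas a gap exceeding the stretched loop is
physically impossible up to trace-endpoint error, which the slack absorbs.

Defaults: `rise_per_residue` 3.8 Å, `loop_slack` 5.0 Å (about the
positional error of a detected trace endpoint at medium resolution),
`skip_penalty` 10.0 Å-equivalents per unmatched segment (roughly one
helix-packing distance; note that for a fixed instance the number of
unmatched segments is the same in every candidate, so this term shifts all
scores equally), `link_radius` 3.0 Å (about the skeleton sampling interval
at medium resolution), `k_top` 5000 candidates.

### Exact top-k search

The ranking is computed by best-first (uniform-cost) search over the
layered assignment graph: layers follow the segments in sequence order, and
a node extends a partial assignment by either skipping the segment (when
enough same-type segments remain to reach `min(M,N)` matches) or assigning
an unused same-type trace in one of two directions. Every edge weight is
non-negative, so the accumulated cost of a partial path lower-bounds all of
its completions and complete topologies pop from the frontier in
non-decreasing score order. The search therefore returns exactly the top-k
of the full enumeration; the test suite asserts bit-identical agreement
(scores, membership and order) with a brute-force enumerator on random
instances. Ties are broken by the lexicographic match-list key (segment
position, then trace position, then forward before reverse), which makes
ranks reproducible.

An exhaustive enumerator (`enumerate_bruteforce`, guarded at 10^6
candidates) is retained as the independent reference implementation.

### Contact screen

Residue-contact predictors emit confidences for all pairs; only the extreme
long-range tail is reliable enough to constrain packing. The screen (i)
drops pairs below `near_zero_eps` = 0.001 (the predictors' "no contact"
mass), (ii) drops short-range pairs with at most `min_separation` = 3
residues strictly between the partners — i.e. `j − i ≤ 4` — since such
pairs are trivially satisfied within one element or turn, then (iii) keeps
pairs whose confidence exceeds `μ + k·σ` of the filtered list, cascading
k = 3 → 2 → 1 until at least two distinct segment pairs emerge. σ is the
sample (n−1) standard deviation; the comparison is strict, so a
zero-variance input selects nothing at any level and the cascade ends with
a warning. μ and σ are computed after the near-zero and short-range
removal, matching the order in which the steps are applied. Selected
contacts are aggregated to segment pairs: contact `(i, j)` supports
`(Sa, Sb)` when `i ∈ Sa`, `j ∈ Sb`, `Sa ≠ Sb`; contacts touching loops are
counted separately (they dominate in practice) but carry no segment-level
information.

### Re-ranking

For each candidate, `CP` counts screened segment pairs with both segments
assigned traces (a pair touching an unmatched segment has no geometry to
test), and `SP` counts those whose assigned traces lie within
`contact_distance_max` = 13 Å by exact shortest line-to-line distance
(strictly less than; 11 and 12 Å are exposed as configuration). The 13 Å
default reflects two helix radii of about 5 Å plus side-chain contact
reach. Candidates are sorted by `SP/CP` descending (ordinal ranking, ties
broken by initial rank; `CP = 0` takes ratio 0), giving `Rank_update`, and
the final order minimizes

    score = a · Rank_init + (1 − a) · Rank_update,    a = 0.7

with ties again broken by initial rank. With `a = 1` the fusion reduces to
the initial order exactly. Re-ranking operates only on the initial top-k
list: when that list misses the correct topology, contacts cannot recover
it, and when contacts are mapped onto wrongly predicted segments they can
demote the correct candidate — both behaviors are inherent to the design,
not failure modes of the implementation.

### Evaluation

A match is correct when segment, trace and direction all agree with the
ground-truth correspondence; matches involving secondary structures that
are not correctly predicted never count. Truth files may mark a pair
direction-agnostic (`*`) for traces of about one helical turn, whose
orientation is not meaningful; the strict metric is the default. The
maximum-match rank is the smallest rank achieving the maximum correct-pair
count, with a `None`/NA sentinel when no candidate matches anything.

## Geometry primitives

* **Axis fitting** — a segmented helix region (point cloud) is reduced to a
  trace along its first principal axis through the centroid, clipped to the
  cloud's projection extent. A tie between the top two eigenvalues (relative
  tolerance 1e-9) triggers a warning and a deterministic tie-break: the
  direction vector lexicographically largest in (x, y, z). An all-identical
  cloud raises a degenerate-cloud error.
* **Segment distance** — the exact clamped closed-form minimum distance
  between two closed 3D segments, with the near-parallel case handled by a
  two-pass clamp; validated against a dense 1000×1000 sampling oracle.
* **Skeleton distance** — snap + Dijkstra as above. If the two snapped
  points fall in disconnected skeleton components the straight-line
  distance is returned as the weakest consistent lower bound; because of
  this fallback the distance is monotone in `link_radius` only while the
  relevant component stays connected, which is how the property is tested.

## Synthetic data

The generator emulates the *outputs* of the upstream tools — secondary
structure prediction, contact prediction, trace detection, strand
detection, skeletonization — on an idealized fold: helices packed in an
up-down row at 10.5 Å axis spacing (backbone on a 2.3 Å cylinder, 1.5
Å/residue rise, 100°/residue twist), an optional antiparallel sheet at 4.8
Å strand spacing (3.3 Å/residue), 9.0 Å between helix and sheet blocks.
Loop lengths are set to `max(lower_bound, ceil(gap / 3.8))` residues so the
true topology satisfies every hinge constraint while alternatives must pay
for detours measured along the skeleton (sampled every 1 Å along axes and
straight loop paths). Contact truth uses the conventional 8 Å cutoff on
idealized backbone positions: qualifying inter-element pairs draw
confidence around 0.9, everything else around 0.1, both with Gaussian noise
(σ = 0.02) clipped to [0, 1]. Sequences are poly-alanine placeholders since
no operation reads residue identity.

Corruption switches emulate observed error modes: endpoint jitter, spurious
and missing traces, merging the first two predicted helices into one
segment (which yields `M < N` instances), and spurious short helices in
loops. Ground truth is re-derived after corruption by interval overlap: a
segment is a correct prediction only when it overlaps exactly one true
element, with at least 80% mutual coverage and matching type.

What the generator does **not** model: curved or kinked helices, β-sheet
twist, density noise and detection artifacts beyond the explicit corruption
switches, realistic loop conformations, and contact-confidence profiles of
real predictors (which are far less bimodal). Passing the noiseless
recovery tests therefore demonstrates correctness of the search and scoring
machinery under the model's own assumptions, not performance on real maps.

A second engineered case (`make_contact_rescue_case`) places parallel
helices in a row with loops long enough that every candidate satisfies
every hinge constraint: geometry then carries no ranking information, the
initial order degenerates to the deterministic tie-break, and the true
topology lands mid-list. Its sequence-adjacent contacts are satisfied only
by row-adjacent trace pairs (10 Å < 13 Å < 20 Å), so rank fusion pulls the
true topology up — isolating the contact channel from the geometric one.

## Known limitations

* **Mirror degeneracy.** In a spatially symmetric bundle, walking the
  elements in reverse row order with all directions flipped reproduces
  every loop gap; loop-length information cannot distinguish a topology
  from its spatial mirror, which ties at the same score and is separated
  only by the deterministic tie-break (and, when available, by contacts or
  chirality information outside this model's scope).
* The hinge score ignores trace lengths versus segment lengths; two traces
  of very different lengths can be exchanged freely if their endpoints
  agree. Length terms were left out to keep the score a pure loop-agreement
  measure.
* Best-first search is exact but worst-case exponential; it is intended for
  the regime of tens of secondary structures typical of single chains, with
  the enumeration guard and `k_top` bounding work in practice.
* Contact satisfaction is evaluated at the whole-trace level (shortest
  line-to-line distance), a deliberately coarse proxy for residue-level
  contact geometry.

## Problem sizes in the test suite

The suite checks DP/enumeration equivalence on instances with up to 4
segments and 4 traces per type (the regime where exhaustive enumeration is
cheap and exact), noiseless recovery on bundles of 3–6 helices and 0–3
strands over 20 seeds with `k_top` 50, and the enrichment property on the
3840-candidate engineered case; the full suite runs in well under a minute.
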