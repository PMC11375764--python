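# Methods

## Network model

Each residue is represented by its backbone Cα position; two residues are
connected iff their Euclidean Cα–Cα distance is *strictly* below the
threshold (default 8.0 Å). The strict comparison follows the plain reading
of "below the threshold"; distances exactly equal to the threshold are a
measure-zero event for real coordinates, so the convention is practically
inconsequential but is fixed for determinism. Consecutive residues get no
special treatment — at physical backbone geometry (≈3.8 Å virtual bonds)
they are always in contact at 8 Å anyway. Coincident Cα positions of
distinct residues are connected (distance 0 < threshold) but trigger a
warning, since they indicate malformed input. Distances are plain
Euclidean distances on the coordinates as given; no periodic-boundary
images are considered.

The network is stored as a dense 0/1 symmetric adjacency matrix with zero
diagonal, nodes ordered monomer 1 positions 1..N then monomer 2 positions
1..N. Both monomers must have the same length, because every averaging
step pairs position i of monomer 1 with position i of monomer 2; input
with unequal chains is rejected rather than patched.

## Betweenness

β(i) sums σ_uv(i)/σ_uv over unordered node pairs, endpoints excluded, no
normalisation, disconnected pairs contributing zero. Values are computed
with Brandes' dependency-accumulation algorithm, one BFS per source
(O(V·E) for unweighted graphs). Two conventions were genuinely open and
are fixed as follows:

* **Graph scope.** By default shortest paths run over the *full dimer
  graph* (they may cross the interface), and β_k(i) is the value at
  monomer k's copy of position i. This parallels the reach construction,
  which exponentiates the full-dimer matrix before extracting blocks. A
  per-monomer mode (`scope="monomer"`, CLI `--scope monomer`) computes
  each monomer's induced subgraph independently; with zero interface
  contacts the two modes coincide (tested).
* **Pair counting.** Unordered pairs, counted once. An ordered-pair
  convention would double every value and change no ranking.

An `exact=True` mode accumulates path-count ratios as rational numbers
(`fractions.Fraction`), which makes "exact agreement" with the
enumeration oracle a literal statement rather than a floating-point
tolerance. The float path is additionally checked against the exact
values at 1e−12 and against networkx's implementation.

## Reach (communicability)

G = e^A is computed with `scipy.linalg.expm`; correctness is *defined* by
the explicit truncated series Σ_{k≤60} A^k/k!, against which e^A is
checked to 1e−8 per entry on graphs up to 50 nodes, and by a recursive
walk-enumeration oracle establishing that (A^k)_ij counts k-step walks.
The k = 0 identity term is included (G = e^A exactly); dropping it would
shift every ρ by exactly 1 and leave all Δρ and all orderings unchanged
(property-tested). Disconnected graphs are allowed — e^A is then
block-diagonal — and no error is raised.

For a dimer, G is subdivided into four N×N blocks conformal with the
monomer partition. The averaged matrix is Ḡ = (G¹¹ + G²²)/2 by default;
an element-wise *sum* is available (`average="sum"`) and differs only by
the global factor 2, so every ranking is identical (property-tested).
The mean is preferred for unit consistency: Ḡ then has the same scale as
a single monomer block. The cross blocks G¹² and G²¹ are retained on the
`CommunicabilityMatrix` for diagnostics but never used downstream.

ρ(i) is the column sum of Ḡ (diagonal included); ρ_k(i) the column sum of
G^kk. All these matrices are symmetric, so column and row sums coincide.

## Variant comparison

Δβ(i) and Δρ(i) are reference − alternative on the monomer-averaged
values; positive = greater connectivity in the reference. "Most
significant" residues are operationalised as the n largest and n smallest
Δ values (default n = 6), reported separately per end and per measure;
ties break by ascending sequence position so output is deterministic.
Residue-identity disagreements between the two profiles are warnings
unless the position is declared as a mutation site (`--mutations
902:V>L`); declared sites are expected to disagree. No significance test
is attached to Δ values — the analysis is a ranking, not an inference.

## Synthetic structures

The generator emulates only what the analysis consumes: a two-chain
Cα trace whose 8 Å contact graph looks like a folded protein's.

* **Chain model**: a self-avoiding random walk with fixed 3.8 Å steps and
  a 3.0 Å clash floor. Candidate steps are penalised by
  exp(−compactness·overshoot/step − 0.35·crowding), where overshoot is the
  distance beyond a confinement radius of 4.0·N^(1/3) Å (constant-density
  globule, matching the empirical size scaling of globular proteins) and
  crowding is the number of existing beads within 8 Å. The crowding term
  is what keeps the mean contact degree in the folded-protein band of
  ≈4–12 at 8 Å (realized ≈6–10 across chain lengths 50–524, asserted over
  seeds); confinement alone would leave random-walk-like local density.
  Dead ends backtrack, with a 50·N backtrack budget before a
  `GenerationError`.
* **Dimer assembly**: monomer 2 is a rigidly rotated copy (homodimer
  default) or an independently grown chain, translated along a random
  direction until the realized inter-monomer contact count at the
  threshold lands within ±20% of the requested target with no
  inter-monomer clash; up to 40 rotation/direction attempts before a
  diagnostic failure. A target of 0 places the monomers fully apart.
* **Perturbation**: residues within `radius` sequence positions of the
  site, in both monomers, are displaced along seeded random directions
  with a cosine taper (full `magnitude` at the site, →0 at the window
  edge). Only contacts involving displaced residues can change, so every
  edge difference stays within radius+3 positions of the site
  (asserted). Magnitude 0 reproduces the unperturbed network exactly.
* **Determinism**: all randomness flows from one `SeedSequence`; the
  perturbation draws from its own child stream, so a perturbed spec and
  its unperturbed twin share every other coordinate bit-for-bit.

What the generator does *not* emulate: real secondary structure, side
chains, domain architecture, or the actual topology of any particular
protein. Passing tests therefore demonstrate that the pipeline's graph
machinery is correct and that it detects planted, localized connectivity
changes — not that it reproduces the connectivity profile of any real
system, which depends entirely on the input coordinates supplied.

## Numerical and operational choices

* Betweenness at the full dimer scale (1048 nodes, ≈4000 edges) takes a
  few seconds in pure Python; the matrix exponential of the dense
  1048×1048 adjacency takes about a second.
* Test and acceptance problem sizes: dimension and symmetry checks run at
  the full monomer length N = 524; the planted-perturbation recovery runs
  at N = 200 per monomer over 10 seeds (perturbation at position 100,
  magnitude 2.5 Å, radius 5), which is ample for the localisation
  property being measured.
* Profile and delta tables are written with a fixed `%.12g` float format
  and no timestamps, so identical inputs give byte-identical files; the
  run manifest materialises every default, making a run re-executable
  from the manifest alone.
* PDB input follows standard ATOM records: first-listed altLoc wins,
  HETATM and non-amino-acid residues are skipped, insertion codes ride
  along verbatim in the author-number label, and sequence positions are
  assigned by order of appearance. Multi-model files default to the first
  model. A residue without a Cα, a missing chain, or unequal chain
  lengths are hard errors naming the culprit.

## Known limitations

* Binary contacts at a single cutoff: no weighted edges, heavy-atom or
  side-chain contact definitions, or cutoff-free (Delaunay) contact
  models.
* One snapshot per variant; no trajectory averaging or uncertainty on the
  centrality values.
* Exactly two monomers of equal length; no support for heterodimers or
  higher oligomers.
* Δ rankings carry no statistical significance; with only one snapshot
  per variant none can honestly be attached.
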