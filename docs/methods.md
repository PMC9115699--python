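# Methods

This note documents the models and procedures implemented by
`conduitmap`, the parameters that matter, the synthetic data the tests
run on, and the choices made where the design was genuinely open.

## Structure model

All geometry is Cα-based. A structure file (PDB or mmCIF, parsed by
gemmi) is reduced to one record per polymer residue possessing a Cα atom:
chain id, author residue number, insertion code, one-letter code (X for
nonstandard residues), Cα coordinates. Waters and heteroatoms are
dropped; for alternate locations the first-listed Cα is kept (a
deterministic choice that cannot move a Cα by more than the altloc spread,
far below the contact cutoff's discrimination scale). Author numbering is
preserved verbatim — never resequenced — because residue identities in the
protein-engineering literature (H46, D81, C151, S219 for TEV protease)
are author-numbered and chains routinely contain numbering gaps. Within a
chain, residues sort by (author number, insertion code), the blank
insertion code before lettered ones.

## Contact map and conduits

Two residues are in contact when their Cα-Cα distance is ≤ cutoff
(**default 5.0 Å**, the conventional Cα threshold for strand-pairing
contacts; ties at exactly the cutoff are contacts). The implementation
uses a k-d tree but is contract-tested to equal the brute-force all-pairs
scan, including on a 500-residue random model.

Local contacts are removed before clustering: pairs with model-order
separation |i − j| < **min_separation (default 4)** are discarded. Four
excludes helix i → i+3 contacts and turn neighbors while keeping strand
rungs; separation is measured in chain positions, not author numbers, so
numbering gaps cannot make a backbone-adjacent contact look long-range.
The filter is idempotent and configurable.

Remaining contacts are grouped into connected components under
8-adjacency in the half-matrix (contacts (i,j), (k,l) with i<j, k<l are
adjacent iff |i−k| ≤ 1 and |j−l| ≤ 1). Components of ≥
**min_cluster_size (default 3)** contacts become *conduits*; three is the
smallest cluster on which an orientation is defined robustly.
Undersized components are logged and discarded, never merged. A
conduit's two segments are the min–max spans of its contacts' two sides,
reported in author numbers.

Orientation is the algebraic version of the visual
"perpendicular-to-the-diagonal" criterion: Spearman rank correlation ρ
between side-a and side-b positions over the member contacts;
**antiparallel** when ρ ≤ −0.5, **parallel** when ρ ≥ +0.5, **mixed**
otherwise (including single-contact or degenerate one-row clusters).

## Insertion-site search and ranking

Candidate loops are maximal residue runs lying strictly between two
conduit segments — the run's predecessor must end a segment and its
successor start another — with length within **[min_len, max_len]
(defaults 2, 12)**. Runs flanked by the two segments of one antiparallel
conduit are flagged: these are β-hairpin-like turns, the geometry of the
published selection.

Scores:

- **Exposure** (per residue): 1 − min(neighbors within
  **radius 10 Å** / **max_neighbors 24**, 1), averaged over the loop.
  This neighbor-count proxy was chosen over accessible-surface area
  because it is well-defined on Cα-only models and fixtures; 24 neighbors
  within 10 Å is a typical buried-core count, so interior residues score
  near 0 and protruding turns near 1. An ASA-based scorer can be plugged
  in by passing a custom exposure function at the library level.
- **Nonconservation** (optional): per-column Shannon entropy of a
  supplied alignment, gaps excluded, normalized by log of the alphabet
  observed across the whole alignment (so a column uniform over the full
  observed alphabet scores 1, an invariant column 0). Loop residues map
  to columns through the ungapped positions of the reference row. When no
  alignment is supplied the term is dropped (weight zeroed), never
  imputed.
- **Coupling hops**: breadth-first distance on the coupling graph from
  either flanking segment to any named functional residue. Nodes are
  conduit segments plus singletons for functional residues; edges are (i)
  one conduit edge per conduit and (ii) sequence-adjacency edges between
  nodes whose author-number spans overlap or are separated by ≤ 1
  residue. Unreachable functional residues give infinite hops; such
  candidates are demoted below all reachable ones rather than excluded,
  since real coupling can act through contacts not captured as conduits.

Rank score = w_e·exposure + w_c·nonconservation + w_h·1/(1+hops), default
weights (1, 1, 1). The formula is deliberately simple and fully
serialized into every report; the ranking's validation anchors on the
identity of the selected site, not on score magnitudes. Ties break first
toward antiparallel-flanked candidates, then toward the smaller loop
start.

## Sequence engineering

Point substitutions are parsed from letter+digits+letter tokens separated
by `-`, `/` or `,`; the reference residue is checked against the sequence
at application time and no-op tokens are rejected. Motif replacement is
motif-addressed (with an occurrence index when ambiguous) because
published edits of this kind name the motif, not coordinates. Domain
insertion supports the linker registry NL = "", SL = "G", ML = "GGS",
LL = "GGSGGG", each applied on *both* sides of the insert (total added
linker residues 0/2/6/12), or an explicit (left, right) pair. Every edit
is appended to a construct's log with the coordinates it had when
applied; replaying the log on the base sequence must reproduce the final
sequence byte-for-byte, and JSON round-trips re-verify this.

TEV cleavage-site scanning finds `ENLYFQ` followed by a permitted P1′
residue — default {S, M, G}: S is the canonical high-affinity site, M the
deliberately low-affinity variant used to suppress background cleavage, G
a commonly tolerated alternative; the set is configurable and a terminal
`ENLYFQ` is not a site (no scissile bond exists). Digestion cuts between
Q and P1′; n sites yield n+1 fragments whose concatenation is the input.
Fragment masses are average masses by default (gel-band interpretation),
monoisotopic by flag, from the standard residue-mass tables (Biopython's
IUPAC data); X is assigned the mean standard-residue mass so placeholder
sequences remain computable.

The construct builder emits the engineered series — switch-domain
insertions with all four linkers on an S219V background, a secretory
variant (signal peptide prepended, N23Q/C130S/T173G applied, the
stabilizing NEGGLE peptide recorded as an annotation because its placement
is construct metadata rather than a published coordinate edit), and a
proprotein whose MRVRRH convertase junction is swapped for ENLYFQ. Base
sequences are caller inputs; the shipped tests use synthetic placeholders
with the required residues at the required positions, not claimed-authentic
sequences.

## Spine morphometry

The classifier implements the two-branch rule: **thin** iff head < 0.6 µm
and length ≥ 2 × head; **mushroom** iff head > 0.6 µm. The branches are
not exhaustive, so a third class **other** absorbs small-headed short
spines and the measure-zero head = 0.6 µm case (the strict inequalities
are honored rather than silently assigning the boundary). Because
published distributions typically report thin/mushroom only, summaries
provide both of-all-spines and of-classified normalizations. Neck
diameter is accepted in input tables and ignored by the rule. Densities
are counts per µm of dendrite, with 20 µm the conventional segment
length; a percent-of-control helper divides mean treated density by mean
control density.

## Synthetic fixtures: what they do and do not show

All fixtures are seed-deterministic and return their ground truth
(pairings, junction positions) alongside the artifact.

- **Hairpins/sheets**: strands along x with 3.8 Å Cα steps, paired at
  4.8 Å (inside the 5 Å cutoff; diagonal neighbors at √(3.8²+4.8²) ≈ 6.1 Å
  are outside). Sheet strands are joined by short spacer turns lifted out
  of the plane so consecutive rung ladders are not 8-adjacent in the
  contact matrix — with back-to-back numbering, two ladders would merge at
  the strand junction. One geometric interaction worth knowing: a hairpin
  with a 2-residue turn has its innermost rung at sequence separation 3,
  which the default nonlocal filter (4) removes; the detected segments
  then stop one residue short of each strand end. Tests that assert "the
  candidate is exactly the turn" therefore run at min_separation 3; at
  the default the candidate is the turn plus one residue of each strand,
  which is the correct answer to the question the default filter asks.
- **Protease mimic**: a synthetic Cα-only stand-in reproducing the TEV
  protease strand/loop topology with author numbering — strand 106–115
  paired antiparallel with 122–125 across surface loop 116–121, strand
  152–157 paired antiparallel with the start of 106–115, catalytic C151
  sequence-adjacent to G152, H46/D81 distant. It encodes the topology of
  the published selection, not crystal coordinates; validating on it shows
  the pipeline recovers a known answer from known geometry, not that it
  reproduces a deposited structure's contact map. Real analyses should
  load a real structure file.
- **Toy proproteins**: random sequences with exactly one MRVRRH junction
  (followed by S, so the junction swap yields a canonical TEV site) and no
  pre-existing ENLYFQ.

What the fixtures deliberately lack: side chains, realistic φ/ψ
geometry, β-bulges and strand twist, crystallographic noise, multiple
domains. Passing tests demonstrate the algorithmic contracts (contact
completeness, cluster partitioning, orientation labels, ranking
monotonicity), not robustness to real-structure irregularities — that is
what the configurable thresholds are for.

## Numerical and degenerate-input choices

- Contact ties at exactly the cutoff are included (≤, not <).
- Empty models are errors for the contact map; an empty contact map
  yields an empty conduit list; no candidates yields an empty report, not
  an error.
- Orientation of constant-row/column clusters (rank correlation
  undefined) is "mixed".
- Coupling hops of a functional residue inside a flanking segment is 0
  through span overlap; hops satisfy the triangle inequality because they
  are graph distances.
- Problem sizes in the shipped tests and the acceptance script (≤ 500
  residue random models, 1000-sequence digestion sweeps, 25-example
  property cases) were chosen so the whole suite completes in a couple of
  minutes while still exercising each contract well past its corner
  cases.

## Known limitations

- No molecular-dynamics or elastic-network coupling model: hop count on
  the coupling graph is a topological proxy, blind to interaction
  strength.
- Exposure from Cα neighbor counts approximates, but does not equal,
  solvent accessibility; heavily twisted sheets can fool it.
- The ranking weights are heuristics; the tool is a candidate generator
  and auditor, not a substitute for inspecting the top sites on the
  structure.
- Cleavage-site scanning is motif-exact: it does not model the broader
  substrate-specificity landscape or cleavage kinetics.
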