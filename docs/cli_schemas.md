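# CLI output schemas

All outputs are UTF-8. Columns are tab-separated (TSV) or comma-separated
(CSV) as noted.

## `conduitmap contact-map` (TSV)

| column | meaning |
| --- | --- |
| `res_i`, `res_j` | 0-based model-order indices of the contacting residues (i < j) |
| `auth_i`, `auth_j` | the same residues as author (deposited) numbers |

One row per contact at the chosen cutoff.

## `conduitmap conduits` (JSON)

Object with `structure_id`, `parameters` (cutoff Å, min_separation,
min_cluster_size) and `conduits`: a list of
`{segment_a: [start, end], segment_b: [start, end], orientation, size}`
with segments in author numbers, orientation one of
`antiparallel | parallel | mixed`, and `size` the number of member
contacts.

## `conduitmap rank-sites` (TSV and JSON)

TSV columns, one row per candidate, best first:

| column | meaning |
| --- | --- |
| `rank` | 1-based rank |
| `loop_start`, `loop_end` | author numbers of the candidate loop (inclusive) |
| `flank_n`, `flank_c` | author spans `start-end` of the flanking conduit segments |
| `antiparallel` | `yes` if the flanks form an antiparallel conduit |
| `exposure` | mean Cα neighbor-count exposure in [0, 1], higher = more exposed |
| `conservation` | mean normalized column entropy in [0, 1] (empty without an MSA), higher = less conserved |
| `coupling_hops` | graph hops from a flank to the nearest functional residue (`inf` if unreachable) |
| `rank_score` | weighted combined score used for ordering |

The JSON mirrors the TSV plus the full parameter set
(`weights`, loop length bounds, exposure radius/max_neighbors,
functional residues, whether an MSA was supplied).

## `conduitmap scan` (TSV to stdout)

`motif_start` (1-based position of the E of ENLYFQ), `p1_prime`
(residue after Q), `cut_after` (1-based position of Q; the scissile bond
is between `cut_after` and `cut_after + 1`).

## `conduitmap digest` (TSV to stdout)

`start`, `end` (1-based inclusive span in the parent), `length`,
`mass_da` (average mass by default, monoisotopic with `--monoisotopic`).

## `conduitmap build` (JSON)

Construct spec: `{name, base, edits[], final, annotations[]}`. Each edit
records its `type` (`substitution | motif_replacement | insertion`) and
the coordinates it had when applied; replaying `edits` on `base`
reproduces `final` exactly.

## `conduitmap spines` (CSV)

| column | meaning |
| --- | --- |
| `segment_id` (+ `condition` if present) | grouping keys |
| `spine_count` | spines in the segment |
| `density_per_um` | spine_count / segment length (µm) |
| `pct_thin`, `pct_mushroom`, `pct_other` | class percentages over all counted spines |
| `pct_thin_of_classified`, `pct_mushroom_of_classified` | percentages excluding `other` |

Input CSV columns: `id, segment_id, head_diameter_um, length_um`
(required), `neck_diameter_um`, `condition` (optional; neck diameter is
accepted and ignored by the classification rule).
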