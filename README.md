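# conduitmap

Structure-guided selection of allosteric domain-insertion sites in
proteases, plus the sequence-engineering and morphometry utilities that
surround such a design campaign.

## The problem

Turning a constitutively active enzyme into a chemically switchable one by
*domain insertion* requires choosing where to put the switch domain. A good
site is a surface-exposed, nonconserved loop whose flanking β-strands are
mechanically coupled — through strand pairing — to the residues that carry
the enzyme's function (for TEV protease, the catalytic triad His46, Asp81,
Cys151, author numbering). An inserted domain that is disordered without
its ligand then propagates disorder through the paired strands to the
catalytic site, silencing the enzyme; ligand binding orders the domain and
restores activity.

`conduitmap` automates the structural part of that reasoning on Cα-only
models:

1. **Contact map** — residues i, j are in contact when their Cα atoms lie
   within a cutoff (default 5 Å).
2. **Conduits** — after removing local contacts (|i − j| < 4), the
   remaining contacts are clustered by 8-connectivity in the half-matrix.
   Each cluster of ≥ 3 contacts is a *conduit*: two residue segments held
   together by strand pairing. The rank correlation ρ of the cluster's two
   sides labels it antiparallel (ρ ≤ −0.5), parallel (ρ ≥ 0.5) or mixed.
3. **Insertion loops** — residue runs lying strictly between two conduit
   segments are candidate insertion sites, scored by

   `rank = w_e · exposure + w_c · nonconservation + w_h · 1/(1 + hops)`

   where *exposure* is a Cα neighbor-count proxy, *nonconservation* is
   normalized column entropy of an optional alignment, and *hops* is the
   shortest path from the loop's flanks to a functional residue on the
   coupling graph (conduit pairing edges + backbone adjacency edges).

Companion modules build the engineered sequences — point mutations
(`S219V`, `N23Q-C130S-T173G`), cleavage-motif replacement
(`MRVRRH → ENLYFQ`), domain insertion with the NL/SL/ML/LL linker series
("", `G`, `GGS`, `GGSGGG` flanking both sides), TEV cleavage-site scanning
(`ENLYFQ↓X`, X ∈ {S, M, G} by default) and in-silico digestion with
average-mass prediction — and classify dendritic spines (thin/mushroom/
other from head diameter and length) for downstream morphometry tables.

## Worked example

The fixtures module generates a synthetic Cα-only protease-fold mimic that
reproduces the TEV strand/loop topology with author numbering (it is a
labelled synthetic stand-in, not crystal coordinates; the loader accepts
any real PDB/mmCIF file):

```bash
conduitmap fixtures --kind protease-mimic --out mimic.pdb
conduitmap rank-sites --structure mimic.pdb --functional 46,81,151
```

prints

```
rank	loop_start	loop_end	flank_n	flank_c	antiparallel	exposure	conservation	coupling_hops	rank_score
1	116	121	112-115	122-125	yes	0.5972		3	0.8472
```

(the conservation column is empty because no alignment was supplied). Read:
the single candidate insertion loop is residues 116–121, flanked by the
strand ending at N115 and the antiparallel strand starting at S122; its
flanks reach catalytic Cys151 in 3 hops on the coupling graph (strand
112–115 → strand 106–111 by backbone adjacency → strand 152–157 through
their conduit → residue 151 adjacent to Gly152); exposure 0.60 plus the
coupling term 1/(1+3) gives the rank score 0.85.

Sequence-side example:

```python
>>> from conduitmap import parse_mutations, insert_domain, scan_tev_sites
>>> [str(s) for s in parse_mutations("N23Q-C130S-T173G")]
['N23Q', 'C130S', 'T173G']
>>> insert_domain("AB", 1, "XY", "ML").final_sequence
'AGGSXYGGSB'
>>> [s.scissile_index for s in scan_tev_sites("ENLYFQSENLYFQM")]
[6, 13]
```

## Layout

- `src/conduitmap/structure_io.py` — PDB/mmCIF → Cα-only models, author numbering
- `src/conduitmap/conduits.py` — contact maps, nonlocal filter, conduit clustering
- `src/conduitmap/sites.py` — loops, exposure, conservation, coupling graph, ranking
- `src/conduitmap/constructs.py` — mutations, motif swaps, insertions, TEV scanning, digestion
- `src/conduitmap/spines.py` — spine classification and segment summaries
- `src/conduitmap/fixtures.py` — synthetic hairpins, sheets, proproteins, protease mimic
- `src/conduitmap/cli.py` — `conduitmap` command-line entry point
- `docs/methods.md` — model, parameters, numerical choices, limitations
- `docs/cli_schemas.md` — columns of every TSV/CSV the CLI writes
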