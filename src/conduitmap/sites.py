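"""Insertion-loop discovery, scoring and ranking.

A good allosteric insertion site for a switch domain is a loop that (a)
connects two paired strands of a conduit, so the insertion's disorder is
transmitted through the pairing; (b) sits on the protein surface, so the
inserted domain is sterically tolerated; (c) is evolutionarily
nonconserved, so the insertion does not destroy a functional element; and
(d) is mechanically close to the functional residues whose activity is to
be switched (for a protease, the catalytic triad).

The mechanical-coupling proxy used here is the hop count on a coarse
*coupling graph*: nodes are conduit segments plus singleton nodes for
named functional residues; edges join the two segments of each conduit
(through-space pairing) and segments whose author-number spans touch or
overlap (through-backbone adjacency).  Fewer hops from the loop's flanks
to a functional residue means a shorter perturbation path.

Exposure is a Cα neighbor-count proxy (works on Cα-only models); an
accessible-surface calculation can be plugged in, but is deliberately not
the default so the pipeline has no full-atom requirement.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .conduits import Conduit, Segment
from .structure_io import StructureModel

__all__ = [
    "CouplingGraph",
    "LoopCandidate",
    "InsertionSiteReport",
    "build_coupling_graph",
    "find_insertion_loops",
    "exposure_score",
    "conservation_score",
    "coupling_hops",
    "rank_insertion_sites",
]

DEFAULT_MIN_LOOP = 2
DEFAULT_MAX_LOOP = 12
DEFAULT_EXPOSURE_RADIUS = 10.0  # Å
DEFAULT_MAX_NEIGHBORS = 24  # neighbor count treated as fully buried
DEFAULT_WEIGHTS = (1.0, 1.0, 1.0)  # exposure, nonconservation, coupling


@dataclass
class CouplingGraph:
    """Undirected graph over conduit segments and functional residues."""

    graph: nx.Graph
    segments: list[Segment]

    def node_for_auth(self, auth_number: int):
        """Node key for a functional residue's singleton segment."""
        return ("res", auth_number)

    @staticmethod
    def node_for_segment(seg: Segment):
        return ("seg", seg.start_auth, seg.end_auth)


@dataclass
class LoopCandidate:
    """A residue run strictly between two conduit segments."""

    loop_start_auth: int
    loop_end_auth: int
    loop_start_idx: int
    loop_end_idx: int
    flank_n: Segment  # segment whose end abuts the loop
    flank_c: Segment  # segment whose start abuts the loop
    antiparallel_flanked: bool
    exposure: float | None = None
    conservation: float | None = None
    coupling_hops: float | None = None  # math.inf when unreachable
    rank_score: float | None = None

    @property
    def length(self) -> int:
        return self.loop_end_idx - self.loop_start_idx + 1

    def to_dict(self) -> dict:
        d = {
            "loop": [self.loop_start_auth, self.loop_end_auth],
            "flank_n": list(self.flank_n.auth_span),
            "flank_c": list(self.flank_c.auth_span),
            "antiparallel_flanked": self.antiparallel_flanked,
            "exposure": self.exposure,
            "conservation": self.conservation,
            "coupling_hops": None if self.coupling_hops is None
            else ("unreachable" if math.isinf(self.coupling_hops) else int(self.coupling_hops)),
            "rank_score": self.rank_score,
        }
        return d


@dataclass
class InsertionSiteReport:
    """Ranked loop candidates plus every parameter used to produce them."""

    candidates: list[LoopCandidate]
    parameters: dict
    structure_id: str

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "structure_id": self.structure_id,
                "parameters": self.parameters,
                "candidates": [c.to_dict() for c in self.candidates],
            },
            indent=indent,
        )

    def to_tsv(self) -> str:
        header = "rank\tloop_start\tloop_end\tflank_n\tflank_c\tantiparallel\texposure\tconservation\tcoupling_hops\trank_score"
        rows = [header]
        for rank, c in enumerate(self.candidates, start=1):
            hops = "" if c.coupling_hops is None else ("inf" if math.isinf(c.coupling_hops) else str(int(c.coupling_hops)))
            rows.append(
                "\t".join(
                    [
                        str(rank),
                        str(c.loop_start_auth),
                        str(c.loop_end_auth),
                        str(c.flank_n),
                        str(c.flank_c),
                        "yes" if c.antiparallel_flanked else "no",
                        "" if c.exposure is None else f"{c.exposure:.4f}",
                        "" if c.conservation is None else f"{c.conservation:.4f}",
                        hops,
                        "" if c.rank_score is None else f"{c.rank_score:.4f}",
                    ]
                )
            )
        return "\n".join(rows) + "\n"


def _dedup_segments(conduits: Iterable[Conduit]) -> list[Segment]:
    seen: dict[tuple[int, int], Segment] = {}
    for con in conduits:
        for seg in (con.segment_a, con.segment_b):
            seen.setdefault((seg.start_idx, seg.end_idx), seg)
    return sorted(seen.values(), key=lambda s: (s.start_idx, s.end_idx))


def build_coupling_graph(
    conduits: Sequence[Conduit],
    model: StructureModel,
    functional_residues: Sequence[int] = (),
) -> CouplingGraph:
    """Graph of conduit segments, pairing edges and adjacency edges.

    Each conduit contributes one edge between its two segments.  Segments
    (including singleton nodes for ``functional_residues``) are joined by a
    sequence-adjacency edge when their author-number spans overlap or are
    separated by at most one residue.  Node insertion order is
    deterministic (segments sorted by span, then functional residues in
    the order given).
    """
    g = nx.Graph()
    segments = _dedup_segments(conduits)
    for seg in segments:
        g.add_node(CouplingGraph.node_for_segment(seg), span=seg.auth_span, kind="segment")
    for auth in functional_residues:
        model.index_of(auth)  # raises if absent
        g.add_node(("res", auth), span=(auth, auth), kind="functional")
    for con in conduits:
        g.add_edge(
            CouplingGraph.node_for_segment(con.segment_a),
            CouplingGraph.node_for_segment(con.segment_b),
            kind="conduit",
        )
    nodes = list(g.nodes(data=True))
    for i, (u, du) in enumerate(nodes):
        for v, dv in nodes[i + 1:]:
            lo_u, hi_u = du["span"]
            lo_v, hi_v = dv["span"]
            gap = max(lo_u, lo_v) - min(hi_u, hi_v)
            if gap <= 1 and not g.has_edge(u, v):
                g.add_edge(u, v, kind="adjacency")
    return CouplingGraph(graph=g, segments=segments)


def find_insertion_loops(
    model: StructureModel,
    conduits: Sequence[Conduit],
    min_len: int = DEFAULT_MIN_LOOP,
    max_len: int = DEFAULT_MAX_LOOP,
) -> list[LoopCandidate]:
    """Maximal residue runs lying strictly between two conduit segments.

    A run qualifies when the residue immediately before it is the end of
    some segment (the N-flank) and the residue immediately after it is the
    start of another (the C-flank), and its length is within
    ``[min_len, max_len]``.  Runs flanked by the two segments of an
    antiparallel conduit are flagged.
    """
    if min_len < 1 or max_len < min_len:
        raise ValueError("need 1 ≤ min_len ≤ max_len")
    segments = _dedup_segments(conduits)
    covered = np.zeros(len(model), dtype=bool)
    end_of: dict[int, Segment] = {}
    start_of: dict[int, Segment] = {}
    for seg in segments:
        covered[seg.start_idx: seg.end_idx + 1] = True
        end_of[seg.end_idx] = seg
        start_of[seg.start_idx] = seg

    anti_pairs = {
        frozenset(((c.segment_a.start_idx, c.segment_a.end_idx),
                   (c.segment_b.start_idx, c.segment_b.end_idx)))
        for c in conduits
        if c.orientation == "antiparallel"
    }

    candidates: list[LoopCandidate] = []
    i = 0
    n = len(model)
    while i < n:
        if covered[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and not covered[j + 1]:
            j += 1
        run_len = j - i + 1
        flank_n = end_of.get(i - 1)
        flank_c = start_of.get(j + 1)
        if flank_n is not None and flank_c is not None and min_len <= run_len <= max_len:
            key = frozenset(((flank_n.start_idx, flank_n.end_idx),
                             (flank_c.start_idx, flank_c.end_idx)))
            candidates.append(
                LoopCandidate(
                    loop_start_auth=model.auth_number_at(i),
                    loop_end_auth=model.auth_number_at(j),
                    loop_start_idx=i,
                    loop_end_idx=j,
                    flank_n=flank_n,
                    flank_c=flank_c,
                    antiparallel_flanked=key in anti_pairs,
                )
            )
        i = j + 1
    return candidates


def exposure_score(
    model: StructureModel,
    loop_range: tuple[int, int],
    radius: float = DEFAULT_EXPOSURE_RADIUS,
    max_neighbors: int = DEFAULT_MAX_NEIGHBORS,
) -> float:
    """Mean Cα-neighbor-count exposure over a loop (1 = fully exposed).

    ``loop_range`` is (start, end) in model-order indices, inclusive.  Per
    residue, exposure = 1 − min(neighbors within radius / max_neighbors, 1);
    a residue with no neighbors scores 1.0 and one with ≥ max_neighbors
    scores 0.0.
    """
    if radius <= 0 or max_neighbors <= 0:
        raise ValueError("radius and max_neighbors must be positive")
    lo, hi = loop_range
    if lo < 0 or hi >= len(model) or lo > hi:
        raise IndexError(f"loop range {loop_range} outside model of {len(model)} residues")
    coords = model.coords()
    tree = cKDTree(coords)
    scores = []
    for idx in range(lo, hi + 1):
        neighbors = len(tree.query_ball_point(coords[idx], r=radius)) - 1  # exclude self
        scores.append(1.0 - min(neighbors / max_neighbors, 1.0))
    return float(np.mean(scores))


def conservation_score(
    msa: Sequence[str],
    ref_row: int,
    loop_positions: Sequence[int],
) -> float:
    """Mean normalized column entropy over loop positions (1 = nonconserved).

    ``loop_positions`` are 0-based positions in the *ungapped* reference
    row (i.e. model order for a model matching that sequence); they are
    mapped to alignment columns through the reference row's gaps.  Each
    column's Shannon entropy is computed over non-gap characters and
    normalized by log of the alphabet size observed across the whole
    alignment, so a column uniform over the full observed alphabet scores
    1.0 and an invariant column scores 0.0.
    """
    rows = [str(s).upper() for s in msa]
    if not rows:
        raise ValueError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("alignment rows differ in length")
    ref = rows[ref_row]
    gap_chars = {"-", "."}
    col_of: list[int] = [c for c, ch in enumerate(ref) if ch not in gap_chars]
    alphabet = {ch for r in rows for ch in r if ch not in gap_chars}
    denom = math.log(len(alphabet)) if len(alphabet) > 1 else None

    scores = []
    for pos in loop_positions:
        if pos < 0 or pos >= len(col_of):
            raise IndexError(f"position {pos} not mappable to an alignment column")
        col = col_of[pos]
        chars = [r[col] for r in rows if r[col] not in gap_chars]
        if not chars or denom is None:
            scores.append(0.0)
            continue
        counts = np.unique(chars, return_counts=True)[1]
        p = counts / counts.sum()
        entropy = float(-(p * np.log(p)).sum())
        scores.append(entropy / denom)
    return float(np.mean(scores))


def coupling_hops(
    cgraph: CouplingGraph,
    candidate: LoopCandidate,
    functional_residues: Sequence[int],
) -> float:
    """Minimum hop count from either flank to any functional residue node.

    Returns ``math.inf`` when no functional residue is reachable; callers
    demote (never drop) such candidates, since coupling may act through
    contacts not captured as conduits.
    """
    g = cgraph.graph
    sources = [CouplingGraph.node_for_segment(candidate.flank_n),
               CouplingGraph.node_for_segment(candidate.flank_c)]
    best = math.inf
    for auth in functional_residues:
        target = ("res", auth)
        if target not in g:
            continue
        for src in sources:
            if src not in g:
                continue
            try:
                d = nx.shortest_path_length(g, src, target)
            except nx.NetworkXNoPath:
                continue
            best = min(best, d)
    return best


def rank_insertion_sites(
    model: StructureModel,
    conduits: Sequence[Conduit],
    functional_residues: Sequence[int],
    msa: Sequence[str] | None = None,
    ref_row: int = 0,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    min_len: int = DEFAULT_MIN_LOOP,
    max_len: int = DEFAULT_MAX_LOOP,
    exposure_radius: float = DEFAULT_EXPOSURE_RADIUS,
    max_neighbors: int = DEFAULT_MAX_NEIGHBORS,
) -> InsertionSiteReport:
    """Score and rank insertion-loop candidates.

    rank_score = w_e·exposure + w_c·conservation + w_h·1/(1 + hops), with
    the conservation term zeroed when no alignment is supplied (never
    imputed).  Candidates with unreachable functional residues sort below
    all reachable ones; at equal score, antiparallel-flanked candidates
    rank first, then the smaller loop start wins.
    """
    if any(w < 0 for w in weights):
        raise ValueError("weights must be nonnegative")
    w_e, w_c, w_h = weights
    candidates = find_insertion_loops(model, conduits, min_len=min_len, max_len=max_len)
    cgraph = build_coupling_graph(conduits, model, functional_residues)
    for cand in candidates:
        cand.exposure = exposure_score(
            model, (cand.loop_start_idx, cand.loop_end_idx),
            radius=exposure_radius, max_neighbors=max_neighbors,
        )
        if msa is not None:
            cand.conservation = conservation_score(
                msa, ref_row, range(cand.loop_start_idx, cand.loop_end_idx + 1)
            )
        cand.coupling_hops = coupling_hops(cgraph, cand, functional_residues)
        coupling_term = 0.0 if math.isinf(cand.coupling_hops) else 1.0 / (1.0 + cand.coupling_hops)
        cand.rank_score = (
            w_e * cand.exposure
            + (w_c * cand.conservation if cand.conservation is not None else 0.0)
            + w_h * coupling_term
        )
    candidates.sort(
        key=lambda c: (
            math.isinf(c.coupling_hops),  # unreachable last
            -c.rank_score,
            not c.antiparallel_flanked,
            c.loop_start_auth,
        )
    )
    parameters = {
        "weights": {"exposure": w_e, "nonconservation": w_c, "coupling": w_h},
        "min_len": min_len,
        "max_len": max_len,
        "exposure_radius": exposure_radius,
        "max_neighbors": max_neighbors,
        "msa_supplied": msa is not None,
        "functional_residues": list(functional_residues),
    }
    return InsertionSiteReport(candidates=candidates, parameters=parameters, structure_id=model.source_id)
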