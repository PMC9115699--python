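"""Synthetic structures and sequences with known ground truth.

Every generator here is seed-deterministic and returns its ground truth
(strand pairings, junction positions) alongside the artifact, so tests
validate the pipeline against the construction instead of re-deriving
answers from the artifact itself.

Geometry conventions: strands run along x with a Cα step of 3.8 Å;
paired strands are stacked in y at ``strand_gap`` (default 4.8 Å, inside
the 5 Å contact cutoff so the pairing rungs register as contacts while
the diagonal neighbors, at √(3.8² + 4.8²) ≈ 6.1 Å, do not).  Turns arc
out of the strand plane so they create no nonlocal contacts of their
own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import StructureModel, model_from_arrays

__all__ = [
    "HairpinSpec",
    "ToyProprotein",
    "ProteaseMimic",
    "make_hairpin",
    "make_sheet",
    "make_toy_proprotein",
    "make_protease_mimic",
]

CA_STEP = 3.8  # Å, ideal consecutive Cα spacing
STRAND_GAP = 4.8  # Å, paired-strand spacing (inside a 5 Å cutoff)


@dataclass(frozen=True)
class HairpinSpec:
    """Parameters of an ideal two-strand antiparallel hairpin."""

    strand_length: int
    turn_length: int = 2
    ca_step: float = CA_STEP
    strand_gap: float = STRAND_GAP
    jitter: float = 0.0  # σ of optional Gaussian coordinate noise, Å
    seed: int = 0
    start_number: int = 1  # author number of the first residue

    def __post_init__(self) -> None:
        if self.strand_length < 2:
            raise ValueError("strand_length must be ≥ 2")
        if self.turn_length < 1:
            raise ValueError("turn_length must be ≥ 1")

    @property
    def n_residues(self) -> int:
        return 2 * self.strand_length + self.turn_length

    def partner_of(self, i: int) -> int:
        """1-based partner: strand-1 residue i pairs with 2n + t + 1 − i."""
        return 2 * self.strand_length + self.turn_length + 1 - i

    def rung_pairs(self) -> list[tuple[int, int]]:
        """All (i, partner) pairs, 1-based within the hairpin."""
        return [(i, self.partner_of(i)) for i in range(1, self.strand_length + 1)]


def _turn_arc(x_end: float, gap: float, t: int, z_sign: float = 0.0) -> np.ndarray:
    """t points on a semicircular arc joining (x_end, 0) to (x_end, gap).

    The arc bulges in +x (and optionally z) so turn residues stay clear of
    both strands.
    """
    center = np.array([x_end, gap / 2.0, 0.0])
    r = gap / 2.0
    pts = []
    for k in range(1, t + 1):
        alpha = k * math.pi / (t + 1)
        pts.append(center + np.array([r * math.sin(alpha), -r * math.cos(alpha), z_sign * r * math.sin(alpha)]))
    return np.array(pts)


def make_hairpin(spec: HairpinSpec) -> StructureModel:
    """Ideal antiparallel β-hairpin: two strands of ``strand_length``
    joined by a ``turn_length``-residue turn.

    Strand-1 residue i lies exactly ``strand_gap`` from its partner
    ``2n + t + 1 − i`` on strand 2 (zero jitter ⇒ exact rungs).
    """
    n, t = spec.strand_length, spec.turn_length
    coords = np.zeros((spec.n_residues, 3))
    for i in range(n):  # strand 1, residues 1..n
        coords[i] = (i * spec.ca_step, 0.0, 0.0)
    coords[n: n + t] = _turn_arc((n - 1) * spec.ca_step, spec.strand_gap, t)
    for r in range(n + t, spec.n_residues):  # strand 2, residues n+t+1..2n+t
        i_partner = spec.n_residues - r - 1  # 0-based partner on strand 1
        coords[r] = (i_partner * spec.ca_step, spec.strand_gap, 0.0)
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.normal(scale=spec.jitter, size=coords.shape)
    numbers = [spec.start_number + k for k in range(spec.n_residues)]
    return model_from_arrays(numbers, coords, source_id=f"fixture:hairpin(n={n},t={t},seed={spec.seed})")


def make_sheet(
    strand_lengths: list[int],
    orientations: list[str],
    ca_step: float = CA_STEP,
    strand_gap: float = STRAND_GAP,
    spacer_length: int = 2,
    jitter: float = 0.0,
    seed: int = 0,
) -> tuple[StructureModel, list[tuple[int, int, str]]]:
    """Ideal β-sheet of k stacked strands; k−1 pairings with stated
    orientations.

    ``orientations[s]`` ("anti" or "para") is the orientation of strand
    s+1 relative to strand s.  Consecutive strands are joined by
    ``spacer_length`` connecting residues lifted well out of the sheet
    plane: they keep the numbering continuous without contributing
    contacts, and they separate the rung ladders of adjacent pairings in
    the contact matrix (back-to-back numbering would make two ladders
    8-adjacent at the strand junction and merge them into one cluster).
    Returns the model plus the ground truth as a list of
    ``(strand_index_a, strand_index_b, orientation_label)``.
    """
    k = len(strand_lengths)
    if k < 2:
        raise ValueError("a sheet needs at least 2 strands")
    if len(orientations) != k - 1:
        raise ValueError(f"need {k - 1} orientations for {k} strands")
    if any(o not in ("anti", "para") for o in orientations):
        raise ValueError("orientations must be 'anti' or 'para'")

    dirs = [1]
    for o in orientations:
        dirs.append(-dirs[-1] if o == "anti" else dirs[-1])

    coords = []
    for s, (n, d) in enumerate(zip(strand_lengths, dirs)):
        for r in range(n):
            x = r * ca_step if d > 0 else (n - 1 - r) * ca_step
            coords.append((x, s * strand_gap, 0.0))
        if s < k - 1:
            # spacer arc: far above the plane, staggered in z per gap so
            # spacers of neighboring gaps stay outside the contact cutoff
            mid_x = (n - 1) * ca_step / 2.0
            for t in range(spacer_length):
                coords.append((mid_x, (s + 0.5) * strand_gap, 9.0 + 4.0 * t + 7.0 * s))
    coords = np.array(coords)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(scale=jitter, size=coords.shape)
    numbers = list(range(1, len(coords) + 1))
    model = model_from_arrays(
        numbers, coords,
        source_id=f"fixture:sheet(k={k},orients={','.join(orientations)},seed={seed})",
    )
    truth = [
        (s, s + 1, "antiparallel" if o == "anti" else "parallel")
        for s, o in enumerate(orientations)
    ]
    return model, truth


@dataclass(frozen=True)
class ToyProprotein:
    """Synthetic proprotein sequence with one convertase junction."""

    sequence: str
    motif_start: int  # 1-based position of the M of MRVRRH
    seed: int

    @property
    def junction_p1_prime(self) -> str:
        """Residue immediately after the MRVRRH motif."""
        return self.sequence[self.motif_start + 5]


def make_toy_proprotein(seed: int, length: int = 120, p1_prime: str = "S") -> ToyProprotein:
    """Random proprotein-like sequence with exactly one MRVRRH junction.

    The junction is placed at a seed-chosen interior position, followed by
    ``p1_prime`` (default S, so that replacing the junction with ENLYFQ
    yields a canonical high-affinity TEV site).  Guaranteed: exactly one
    MRVRRH, zero ENLYFQ.
    """
    if length < 20:
        raise ValueError("length must be ≥ 20")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    for _ in range(100):
        seq = "".join(rng.choice(alphabet, size=length))
        pos = int(rng.integers(5, length - 15))  # 0-based, interior
        seq = seq[:pos] + "MRVRRH" + p1_prime + seq[pos + 7:]
        if seq.count("MRVRRH") == 1 and "ENLYFQ" not in seq:
            return ToyProprotein(sequence=seq, motif_start=pos + 1, seed=seed)
    raise RuntimeError("could not satisfy motif constraints (pathological seed)")  # pragma: no cover


@dataclass(frozen=True)
class ProteaseMimic:
    """Ground truth of the synthetic protease-fold mimic."""

    model: StructureModel
    triad: tuple[int, int, int]  # catalytic triad author numbers (H, D, C)
    strand_a: tuple[int, int]  # 106–115
    strand_b: tuple[int, int]  # 122–125, antiparallel to the end of A
    strand_c: tuple[int, int]  # 152–157, antiparallel to the start of A
    loop: tuple[int, int]  # 116–121, the insertion loop


def make_protease_mimic() -> ProteaseMimic:
    """Synthetic Cα-only stand-in for the TEV protease fold.

    This is NOT the deposited crystal structure: it is a synthetic model
    that reproduces, with author numbering, the published strand/loop
    topology of TEV protease used for insertion-site selection — the
    strand E106–N115 paired antiparallel with S122–V125 across the
    surface loop 116–121, the strand G152–S157 paired antiparallel with
    the start of E106–N115, the catalytic C151 immediately preceding
    G152, and the remaining triad residues H46/D81 placed far away.  Use a
    real structure file for production analyses; this mimic exists so the
    pipeline's residue-level claims are testable offline.
    """
    step, gap = CA_STEP, STRAND_GAP
    numbers: list[int] = []
    codes: list[str] = []
    coords: list[tuple[float, float, float]] = []

    def add(num: int, code: str, xyz: tuple[float, float, float]) -> None:
        numbers.append(num)
        codes.append(code)
        coords.append(xyz)

    add(46, "H", (-20.0, -20.0, 0.0))
    add(81, "D", (-30.0, -25.0, 5.0))
    # strand A: 106..115 along x at y=0
    seq_a = "EAAAAAAAAN"  # E106 ... N115
    for k in range(10):
        add(106 + k, seq_a[k], (k * step, 0.0, 0.0))
    # loop 116..121: arc far out in +z, clear of all strands
    x_end = 9 * step
    center_y = gap / 2.0
    for k in range(1, 7):
        alpha = k * math.pi / 7.0
        add(115 + k, "A", (x_end, center_y - 6.0 * math.cos(alpha), 6.0 * math.sin(alpha)))
    # strand B: 122..125 antiparallel over the end of A (122 opposite 115)
    seq_b = "SAAV"  # S122 ... V125
    for k in range(4):
        add(122 + k, seq_b[k], (x_end - k * step, gap, 0.0))
    # catalytic C151 just before strand C, off to the side
    add(151, "C", (21.0, -8.0, 1.0))
    # strand C: 152..157 antiparallel under the start of A (152 opposite 111)
    seq_c = "GAAAAS"  # G152 ... S157
    for k in range(6):
        add(152 + k, seq_c[k], ((5 - k) * step, -gap, 0.0))

    model = model_from_arrays(numbers, np.array(coords), aa_codes="".join(codes),
                              source_id="fixture:tev-protease-mimic")
    return ProteaseMimic(
        model=model,
        triad=(46, 81, 151),
        strand_a=(106, 115),
        strand_b=(122, 125),
        strand_c=(152, 157),
        loop=(116, 121),
    )
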