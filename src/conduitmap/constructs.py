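"""Engineered-protein sequence operations.

Covers the edits used when turning a protease into a chemically switchable
single-chain enzyme and when retargeting a proprotein to that protease:

* point substitutions given as strings like ``"S219V"`` or
  ``"N23Q-C130S-T173G"`` (the autoproteolysis-resistant protease mutation
  and the secretory-pathway mutations avoiding N-glycosylation and
  cysteine oxidation in the ER);
* cleavage-motif replacement, e.g. swapping the furin/plasmin site
  ``MRVRRH`` of a proprotein for the TEV protease recognition motif
  ``ENLYFQ``;
* domain insertion with flanking linker variants NL/SL/ML/LL
  ("" / G / GGS / GGSGGG on both sides), the series used to tune how
  tightly an inserted switch domain is mechanically coupled to its host;
* TEV cleavage-site scanning (ENLYFQ followed by a permitted P1′ residue;
  S is the canonical high-affinity site, M the low-affinity variant) and
  in-silico digestion with average-mass prediction for gel-band
  interpretation.

Every edit is recorded in a :class:`ConstructSpec` log with the
coordinates it had when applied, so replaying the log on the base
sequence reproduces the final sequence byte-for-byte.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from Bio.Data.IUPACData import protein_weights, monoisotopic_protein_weights

__all__ = [
    "Substitution",
    "CleavageSite",
    "Fragment",
    "ConstructSpec",
    "LINKERS",
    "parse_mutations",
    "apply_mutations",
    "replace_motif",
    "insert_domain",
    "scan_tev_sites",
    "digest",
    "average_mass",
    "build_construct_series",
]

TEV_MOTIF = "ENLYFQ"
#: P1' residues accepted by default: S (canonical), M (low-affinity), G (tolerant)
DEFAULT_P1_PRIME = frozenset("SMG")
#: linker registry; each linker flanks the insert on BOTH sides
LINKERS = {"NL": "", "SL": "G", "ML": "GGS", "LL": "GGSGGG"}

WATER_AVG = 18.01528
WATER_MONO = 18.0105646863

# Bio's tables are free amino-acid masses; subtract one water for the residue mass.
_RESIDUE_AVG = {aa: w - WATER_AVG for aa, w in protein_weights.items()}
_RESIDUE_MONO = {aa: w - WATER_MONO for aa, w in monoisotopic_protein_weights.items()}
# X (unknown/placeholder): mean residue mass of the 20 standard residues.
_RESIDUE_AVG["X"] = sum(_RESIDUE_AVG.values()) / len(_RESIDUE_AVG)
_RESIDUE_MONO["X"] = sum(_RESIDUE_MONO.values()) / len(_RESIDUE_MONO)

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class Substitution:
    ref_aa: str
    position: int  # 1-based
    alt_aa: str

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"no-op substitution {self.ref_aa}{self.position}{self.alt_aa}")
        if self.position < 1:
            raise ValueError(f"position must be ≥ 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class CleavageSite:
    """An ENLYFQ motif with its scissile bond (between Q and P1′)."""

    motif_start: int  # 1-based position of the E
    p1_prime: str
    scissile_index: int  # cut after this 1-based position (the Q)


@dataclass(frozen=True)
class Fragment:
    sequence: str
    span: tuple[int, int]  # 1-based inclusive in the parent
    average_mass: float


@dataclass
class ConstructSpec:
    """A base sequence plus an ordered, replayable edit log.

    Each edit dict records its type and the coordinates in the sequence
    *as it existed when the edit was applied*, so the log is unambiguous
    under later insertions.
    """

    name: str
    base_sequence: str
    edits: list[dict] = field(default_factory=list)
    final_sequence: str = ""
    annotations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.final_sequence:
            self.final_sequence = self.base_sequence

    def replay(self) -> str:
        """Re-apply the edit log to the base; must equal final_sequence."""
        seq = self.base_sequence
        for edit in self.edits:
            kind = edit["type"]
            if kind == "substitution":
                sub = Substitution(edit["ref"], edit["position"], edit["alt"])
                seq = apply_mutations(seq, [sub])
            elif kind == "motif_replacement":
                start = edit["start"]  # 1-based
                old, new = edit["old"], edit["new"]
                if seq[start - 1: start - 1 + len(old)] != old:
                    raise ValueError(f"replay mismatch at {start}: expected {old}")
                seq = seq[: start - 1] + new + seq[start - 1 + len(old):]
            elif kind == "insertion":
                after = edit["after_position"]
                piece = edit["linker_left"] + edit["insert"] + edit["linker_right"]
                seq = seq[:after] + piece + seq[after:]
            else:
                raise ValueError(f"unknown edit type {kind!r}")
        return seq

    def verify(self) -> None:
        replayed = self.replay()
        if replayed != self.final_sequence:
            raise ValueError(f"edit log of {self.name!r} does not reproduce final sequence")

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "name": self.name,
                "base": self.base_sequence,
                "edits": self.edits,
                "final": self.final_sequence,
                "annotations": self.annotations,
            },
            indent=indent,
        )

    @classmethod
    def from_json(cls, text: str) -> "ConstructSpec":
        d = json.loads(text)
        spec = cls(
            name=d["name"],
            base_sequence=d["base"],
            edits=list(d["edits"]),
            final_sequence=d["final"],
            annotations=list(d.get("annotations", [])),
        )
        spec.verify()
        return spec


def parse_mutations(spec: str) -> list[Substitution]:
    """Parse mutation strings like ``"S219V"`` or ``"N23Q-C130S-T173G"``.

    Tokens may be separated by '-', '/' or ','; each must be
    letter+digits+letter.  A token whose reference and alternate residues
    coincide is rejected as a no-op.
    """
    tokens = [t for t in re.split(r"[-/,]", spec.strip()) if t]
    if not tokens:
        raise ValueError("empty mutation specification")
    subs = []
    for tok in tokens:
        m = _MUTATION_RE.match(tok.upper())
        if m is None:
            raise ValueError(f"malformed mutation token {tok!r}")
        subs.append(Substitution(m.group(1), int(m.group(2)), m.group(3)))
    return subs


def apply_mutations(sequence: str, subs: list[Substitution]) -> str:
    """Apply point substitutions, checking each reference residue."""
    chars = list(sequence)
    for sub in subs:
        if sub.position > len(chars):
            raise IndexError(f"{sub}: position {sub.position} beyond sequence of length {len(chars)}")
        found = chars[sub.position - 1]
        if found != sub.ref_aa:
            raise ValueError(f"reference mismatch at position {sub.position}: expected {sub.ref_aa}, found {found}")
        chars[sub.position - 1] = sub.alt_aa
    return "".join(chars)


def replace_motif(
    sequence: str,
    old_motif: str,
    new_motif: str,
    occurrence: int | str = "unique",
    name: str = "motif-replacement",
) -> ConstructSpec:
    """Replace one occurrence of a motif, logging the edit.

    ``occurrence`` is a 1-based index, or ``"unique"`` to require exactly
    one occurrence (an ambiguity error otherwise).
    """
    starts = [m.start() for m in re.finditer(re.escape(old_motif), sequence)]
    if not starts:
        raise ValueError(f"motif {old_motif!r} not found")
    if occurrence == "unique":
        if len(starts) > 1:
            raise ValueError(f"motif {old_motif!r} occurs {len(starts)} times; pass an occurrence index")
        start = starts[0]
    else:
        if not 1 <= int(occurrence) <= len(starts):
            raise ValueError(f"occurrence {occurrence} out of range (motif occurs {len(starts)} times)")
        start = starts[int(occurrence) - 1]
    final = sequence[:start] + new_motif + sequence[start + len(old_motif):]
    edit = {"type": "motif_replacement", "start": start + 1, "old": old_motif, "new": new_motif}
    spec = ConstructSpec(name=name, base_sequence=sequence, edits=[edit], final_sequence=final)
    spec.verify()
    return spec


def insert_domain(
    host_sequence: str,
    after_position: int,
    insert_sequence: str,
    linker_variant: str | tuple[str, str] = "NL",
    name: str | None = None,
) -> ConstructSpec:
    """Insert a domain after a host position, flanked by linkers.

    ``linker_variant`` is one of the registry keys NL/SL/ML/LL (the same
    linker on both sides) or an explicit ``(left, right)`` pair.
    ``after_position`` is 1-based; 0 prepends.
    """
    if not 0 <= after_position <= len(host_sequence):
        raise IndexError(f"after_position {after_position} outside host of length {len(host_sequence)}")
    if isinstance(linker_variant, str):
        if linker_variant not in LINKERS:
            raise KeyError(f"unknown linker variant {linker_variant!r}; known: {sorted(LINKERS)}")
        left = right = LINKERS[linker_variant]
        tag = linker_variant
    else:
        left, right = linker_variant
        tag = "custom"
    final = host_sequence[:after_position] + left + insert_sequence + right + host_sequence[after_position:]
    edit = {
        "type": "insertion",
        "after_position": after_position,
        "insert": insert_sequence,
        "linker_left": left,
        "linker_right": right,
        "variant": tag,
    }
    spec = ConstructSpec(
        name=name or f"insertion-{tag}",
        base_sequence=host_sequence,
        edits=[edit],
        final_sequence=final,
        annotations=[f"{tag} linker"],
    )
    spec.verify()
    return spec


def scan_tev_sites(sequence: str, p1_prime_set: frozenset[str] | set[str] = DEFAULT_P1_PRIME) -> list[CleavageSite]:
    """Find every ENLYFQ motif followed by a permitted P1′ residue.

    A terminal ENLYFQ with nothing after it is not a site (no scissile
    bond exists).  Sites are returned sorted by position.
    """
    if not p1_prime_set:
        raise ValueError("p1_prime_set must be nonempty")
    sites = []
    for m in re.finditer(f"(?={TEV_MOTIF})", sequence):
        start = m.start()
        nxt = start + len(TEV_MOTIF)
        if nxt < len(sequence) and sequence[nxt] in p1_prime_set:
            sites.append(
                CleavageSite(motif_start=start + 1, p1_prime=sequence[nxt], scissile_index=nxt)
            )
    return sites


def average_mass(sequence: str, monoisotopic: bool = False) -> float:
    """Peptide mass in Da: sum of residue masses plus one water.

    Average masses by default (matches SDS-PAGE interpretation);
    monoisotopic by flag.  X uses the mean standard-residue mass.
    """
    table = _RESIDUE_MONO if monoisotopic else _RESIDUE_AVG
    water = WATER_MONO if monoisotopic else WATER_AVG
    try:
        total = sum(table[aa] for aa in sequence)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in sequence") from None
    return total + water


def digest(sequence: str, sites: list[CleavageSite], monoisotopic: bool = False) -> list[Fragment]:
    """Cut at every scissile bond; n sites yield n+1 fragments.

    Fragment sequences concatenate back to the input, and each fragment
    carries its predicted mass.
    """
    cuts = [s.scissile_index for s in sites]
    if len(set(cuts)) != len(cuts):
        raise ValueError("duplicate scissile indices")
    if cuts != sorted(cuts):
        raise ValueError("sites must be sorted by position")
    if any(c < 1 or c >= len(sequence) for c in cuts):
        raise ValueError("scissile index outside sequence")
    bounds = [0] + cuts + [len(sequence)]
    fragments = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        frag = sequence[lo:hi]
        fragments.append(
            Fragment(sequence=frag, span=(lo + 1, hi), average_mass=average_mass(frag, monoisotopic=monoisotopic))
        )
    return fragments


def build_construct_series(
    tev_sequence: str,
    unirapr_sequence: str,
    signal_peptide: str,
    probdnf_sequence: str,
    insertion_after: int = 115,
) -> list[ConstructSpec]:
    """Assemble the full engineered-construct series from base sequences.

    Emits, each with a complete edit log:

    * ``uniRapR-TEV-{NL,SL,ML,LL}`` — protease with the autoproteolysis
      substitution S219V and the switch domain inserted (default after
      residue 115, within the selected insertion loop) with each linker
      variant;
    * ``uniRapR-secTEV`` — additionally carries N23Q/C130S/T173G and the
      secretion signal prepended (annotated secretory; the stabilizing
      NEGGLE peptide is recorded as an annotation, not a sequence edit,
      since its placement is construct metadata);
    * ``pro-TEVcs-BDNF`` — proprotein with its MRVRRH convertase site
      replaced by ENLYFQ.

    Base sequences are caller-supplied; substitution references are
    checked against them.
    """
    constructs: list[ConstructSpec] = []
    s219v = parse_mutations("S219V")
    sec_muts = parse_mutations("N23Q-C130S-T173G")

    for variant in ("NL", "SL", "ML", "LL"):
        seq = apply_mutations(tev_sequence, s219v)
        edits = [{"type": "substitution", "ref": "S", "position": 219, "alt": "V"}]
        ins = insert_domain(seq, insertion_after, unirapr_sequence, variant)
        edits.extend(ins.edits)
        spec = ConstructSpec(
            name=f"uniRapR-TEV-{variant}",
            base_sequence=tev_sequence,
            edits=edits,
            final_sequence=ins.final_sequence,
            annotations=[f"{variant} linker", "S219V autoproteolysis-resistant"],
        )
        spec.verify()
        constructs.append(spec)

    seq = apply_mutations(tev_sequence, s219v + sec_muts)
    edits = [
        {"type": "substitution", "ref": s.ref_aa, "position": s.position, "alt": s.alt_aa}
        for s in s219v + sec_muts
    ]
    ins = insert_domain(seq, insertion_after, unirapr_sequence, "NL")
    edits.extend(ins.edits)
    sig = insert_domain(ins.final_sequence, 0, signal_peptide, ("", ""))
    edits.extend(sig.edits)
    sec = ConstructSpec(
        name="uniRapR-secTEV",
        base_sequence=tev_sequence,
        edits=edits,
        final_sequence=sig.final_sequence,
        annotations=["secretory", "NL linker", "S219V", "N23Q-C130S-T173G", "NEGGLE peptide"],
    )
    sec.verify()
    constructs.append(sec)

    bdnf = replace_motif(probdnf_sequence, "MRVRRH", TEV_MOTIF, name="pro-TEVcs-BDNF")
    bdnf.annotations.append("convertase site replaced by TEV cleavage site")
    constructs.append(bdnf)
    return constructs
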