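"""Triplex primer system for the bivalve 16S rDNA barcode assay.

The assay amplifies a ~150 bp fragment of mitochondrial 16S rDNA with three
family-specific primer sets run in a single (triplex) PCR: one set each for
Mytilidae (mussels; one forward, two reverse primers), Pectinidae (scallops)
and Ostreidae (oysters). Every target-specific primer carries a constant
Illumina overhang adapter at its 5' end; the overhang is sequencing plumbing
and never part of the biological barcode.

This module holds the primer/assay data model, the packaged default assay,
IUPAC-aware primer matching (binding-site search with a 3'-anchor rule), and
simple primer QC (Wallace-rule melting temperature, self-dimer score).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Literal, Sequence

import yaml

logger = logging.getLogger("bivalveseq")

# ---------------------------------------------------------------------------
# Alphabet
# ---------------------------------------------------------------------------

#: IUPAC nucleotide codes and the unambiguous bases each one stands for.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET: frozenset[str] = frozenset(IUPAC)

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

Direction = Literal["forward", "reverse"]


@dataclass(frozen=True)
class Primer:
    """A single target-specific primer, written 5'->3'.

    ``concentration_uM`` is bookkeeping metadata (the wet-lab final
    concentration); it plays no role in any computation here.
    """

    name: str
    sequence: str
    direction: Direction
    family_target: str
    concentration_uM: float = 0.2

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 15:
            raise ValueError(f"primer {self.name}: sequence shorter than 15 nt")
        bad = set(seq) - IUPAC_ALPHABET
        if bad:
            raise ValueError(f"primer {self.name}: non-IUPAC characters {sorted(bad)}")
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"primer {self.name}: bad direction {self.direction!r}")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class PrimerSet:
    """The primers targeting one bivalve family (>=1 forward, >=1 reverse)."""

    family: str
    forwards: tuple[Primer, ...]
    reverses: tuple[Primer, ...]

    def __post_init__(self) -> None:
        if not self.forwards or not self.reverses:
            raise ValueError(f"primer set {self.family}: needs >=1 forward and >=1 reverse")
        for p in self.forwards + self.reverses:
            if p.family_target != self.family:
                raise ValueError(
                    f"primer {p.name} targets {p.family_target}, not {self.family}"
                )

    @property
    def primers(self) -> tuple[Primer, ...]:
        return self.forwards + self.reverses


@dataclass(frozen=True)
class TriplexAssay:
    """The full triplex assay: three family primer sets plus overhang adapters.

    ``annealing_temp_C`` and ``cycles`` are wet-lab metadata carried along for
    provenance; the in-silico machinery does not use them.
    """

    sets: tuple[PrimerSet, ...]
    overhang_forward: str
    overhang_reverse: str
    annealing_temp_C: float = 62.0
    cycles: int = 25

    def __post_init__(self) -> None:
        if len(self.sets) != 3:
            raise ValueError("triplex assay requires exactly three primer sets")

    @property
    def primers(self) -> tuple[Primer, ...]:
        return tuple(p for s in self.sets for p in s.primers)

    def set_for(self, family: str) -> PrimerSet:
        for s in self.sets:
            if s.family == family:
                return s
        raise KeyError(family)


# ---------------------------------------------------------------------------
# Packaged default assay (the published seven-primer system)
# ---------------------------------------------------------------------------

MYTILIDAE = "Mytilidae"
PECTINIDAE = "Pectinidae"
OSTREIDAE = "Ostreidae"

OVERHANG_FORWARD = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"
OVERHANG_REVERSE = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"


def default_assay() -> TriplexAssay:
    """The packaged seven-primer triplex assay (3 forward + 4 reverse).

    Scallop and oyster primers are named For_Sc/Rev_Sc and For_Oy/Rev_Oy for
    clarity; the mussel forward primer is run at double concentration
    (0.4 uM) in the wet-lab protocol.
    """
    mussel = PrimerSet(
        family=MYTILIDAE,
        forwards=(
            Primer("For_Mu", "CCTTTTGCATAAGGGTTTTTCAAG", "forward", MYTILIDAE, 0.4),
        ),
        reverses=(
            Primer("Rev1_Mu", "CGAATAGTATCTAGCCGCCATTC", "reverse", MYTILIDAE),
            Primer("Rev2_Mu", "GCAAATAGCATATCACTTTCACCTC", "reverse", MYTILIDAE),
        ),
    )
    scallop = PrimerSet(
        family=PECTINIDAE,
        forwards=(
            Primer("For_Sc", "TGCTAAGGTAGCTAAATTATGGCC", "forward", PECTINIDAE),
        ),
        reverses=(
            Primer("Rev_Sc", "CTTCACGGGGTCTTCTCGTC", "reverse", PECTINIDAE),
        ),
    )
    oyster = PrimerSet(
        family=OSTREIDAE,
        forwards=(
            Primer("For_Oy", "GGTAGCGAAATTCCTTGCCTT", "forward", OSTREIDAE),
        ),
        reverses=(
            Primer("Rev_Oy", "AAAGTTGCACGGGGTCTT", "reverse", OSTREIDAE),
        ),
    )
    return TriplexAssay(
        sets=(mussel, scallop, oyster),
        overhang_forward=OVERHANG_FORWARD,
        overhang_reverse=OVERHANG_REVERSE,
    )


def with_overhang(primer: Primer, assay: TriplexAssay) -> str:
    """Full synthesis sequence: Illumina overhang + target-specific primer."""
    if primer not in assay.primers:
        raise ValueError(f"primer {primer.name} is not part of the assay")
    overhang = (
        assay.overhang_forward if primer.direction == "forward" else assay.overhang_reverse
    )
    return overhang + primer.sequence


# ---------------------------------------------------------------------------
# Assay config I/O (flat key-value YAML)
# ---------------------------------------------------------------------------

def save_assay(assay: TriplexAssay, path: str | Path) -> None:
    """Write an assay to a flat YAML config (one mapping per primer)."""
    doc = {
        "overhang_forward": assay.overhang_forward,
        "overhang_reverse": assay.overhang_reverse,
        "annealing_temp_C": assay.annealing_temp_C,
        "cycles": assay.cycles,
        "primers": [
            {
                "name": p.name,
                "sequence": p.sequence,
                "direction": p.direction,
                "family": p.family_target,
                "concentration_uM": p.concentration_uM,
            }
            for p in assay.primers
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_assay(path: str | Path) -> TriplexAssay:
    """Load an assay config written by :func:`save_assay` (or hand-edited)."""
    doc = yaml.safe_load(Path(path).read_text())
    by_family: dict[str, dict[str, list[Primer]]] = {}
    for row in doc["primers"]:
        p = Primer(
            row["name"],
            row["sequence"],
            row["direction"],
            row["family"],
            float(row.get("concentration_uM", 0.2)),
        )
        slot = by_family.setdefault(p.family_target, {"forward": [], "reverse": []})
        slot[p.direction].append(p)
    sets = tuple(
        PrimerSet(family=fam, forwards=tuple(d["forward"]), reverses=tuple(d["reverse"]))
        for fam, d in by_family.items()
    )
    return TriplexAssay(
        sets=sets,
        overhang_forward=doc["overhang_forward"],
        overhang_reverse=doc["overhang_reverse"],
        annealing_temp_C=float(doc.get("annealing_temp_C", 62.0)),
        cycles=int(doc.get("cycles", 25)),
    )


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def mismatch_count(primer_seq: str, window: str) -> int:
    """Number of positions of ``window`` not covered by the primer's IUPAC codes.

    The primer alphabet is expanded (R matches A or G, N matches anything);
    the template window is read literally.
    """
    if len(primer_seq) != len(window):
        raise ValueError(
            f"length mismatch: primer {len(primer_seq)} vs window {len(window)}"
        )
    mm = 0
    for p, w in zip(primer_seq, window):
        if w not in IUPAC[p]:
            mm += 1
    return mm


def _mismatch_positions(primer_seq: str, window: str) -> list[int]:
    return [i for i, (p, w) in enumerate(zip(primer_seq, window)) if w not in IUPAC[p]]


@dataclass(frozen=True)
class BindingSite:
    """One predicted primer annealing site on a template.

    Coordinates are 0-based half-open on the plus strand of the stored
    template regardless of which strand the primer sits on. ``strand`` is
    'plus' when the primer sequence itself occurs at [start, end) and 'minus'
    when its reverse complement does (i.e. the primer anneals pointing
    leftward).
    """

    template_id: str
    strand: Literal["plus", "minus"]
    start: int
    end: int
    mismatches: int
    primer_name: str


#: No mismatches are tolerated in this many bases at the primer 3' end
#: (polymerase extension is intolerant of 3'-terminal mispairs).
THREE_PRIME_ANCHOR = 3


def find_binding_sites(
    template: str,
    primer: Primer,
    max_mm: int = 2,
    *,
    template_id: str = "",
    anchor: int = THREE_PRIME_ANCHOR,
) -> List[BindingSite]:
    """Scan both strands of ``template`` for annealing sites of ``primer``.

    A site is reported when the window has at most ``max_mm`` IUPAC-aware
    mismatches and none of them fall in the ``anchor`` bases at the primer
    3' end. Returns sites sorted by start coordinate.
    """
    template = template.upper()
    n, m = len(template), len(primer.sequence)
    sites: list[BindingSite] = []
    if m > n:
        return sites
    fwd = primer.sequence
    rev = revcomp(primer.sequence)
    anchor = min(anchor, m)
    for i in range(n - m + 1):
        window = template[i : i + m]
        # plus strand: primer 3' end is the window's right end
        pos = _mismatch_positions(fwd, window)
        if len(pos) <= max_mm and all(p < m - anchor for p in pos):
            sites.append(
                BindingSite(template_id, "plus", i, i + m, len(pos), primer.name)
            )
        # minus strand: the primer's reverse complement lies on the plus
        # strand, so the primer 3' end maps to the window's left end
        pos = _mismatch_positions(rev, window)
        if len(pos) <= max_mm and all(p >= anchor for p in pos):
            sites.append(
                BindingSite(template_id, "minus", i, i + m, len(pos), primer.name)
            )
    sites.sort(key=lambda s: (s.start, s.strand, s.primer_name))
    return sites


# ---------------------------------------------------------------------------
# Primer QC
# ---------------------------------------------------------------------------

def tm_wallace(seq: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) degrees C.

    Only defined for unambiguous sequences; ambiguity codes raise.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"ambiguous bases not allowed in Tm calculation: {sorted(bad)}")
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return 2.0 * at + 4.0 * gc


def self_complement_score(seq: str) -> int:
    """Self-dimer score: longest contiguous self-complementary run.

    Two copies of the oligo are slid against each other antiparallel at every
    ungapped offset; the score is the longest run of consecutive
    Watson-Crick pairs observed. A perfect palindrome of length L scores L.
    Advisory only - nothing in the toolkit blocks on it.
    """
    seq = seq.upper()
    rc = revcomp(seq)
    n = len(seq)
    best = 0
    for off in range(-(n - 1), n):
        run = 0
        for i in range(n):
            j = i + off
            if 0 <= j < n and seq[i] == rc[j]:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


def assay_qc(assay: TriplexAssay) -> list[dict[str, object]]:
    """Per-primer QC table: length, Tm (Wallace), self-dimer score."""
    rows = []
    for p in assay.primers:
        rows.append(
            {
                "name": p.name,
                "family": p.family_target,
                "direction": p.direction,
                "length": len(p.sequence),
                "tm_wallace_C": tm_wallace(p.sequence),
                "self_complement_score": self_complement_score(p.sequence),
            }
        )
    return rows
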