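"""Synthetic references and seeded paired-end read simulation.

Two jobs live here. First, a fixture generator that emulates bivalve-like
reference sequences: for each family it embeds the family's exact triplex
primer binding sites around a randomized insert so that the primer-inclusive
product is exactly 150 bp - the assay's designed product size - plus one
off-target "squid-like" record with no binding sites at all. All sequences
are synthetic; the species names are real bivalve binomials only so that
mixture designs read naturally.

Second, a mixture read simulator: given a digested reference database and a
mixture specification (species with proportions), it draws per-component
read-pair counts multinomially, emits 2x151 paired reads from each species'
predicted amplicon with i.i.d. per-base substitution errors, and writes
Phred+33 FASTQ plus a ground-truth table. Off-target components (no
amplicon) simply contribute no read pairs, mirroring their failure to
amplify. Everything is deterministic under the seed.

Amplification efficiency is equal across species by default (real data show
family- and species-level bias; a per-species efficiency knob exists but
defaults to 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .amplicon import predict_amplicons
from .primers import MYTILIDAE, OSTREIDAE, PECTINIDAE, TriplexAssay, default_assay, revcomp
from .refdb import BarcodeDB

logger = logging.getLogger("bivalveseq")

#: Designed primer-inclusive product size in bp.
PRODUCT_LENGTH = 150

#: Off-target control species (a squid; the assay has no binding sites for it).
OFFTARGET_SPECIES = "Sepiella inermis"
OFFTARGET_FAMILY = "Sepiidae"

#: Species pools per family, in the order records are generated. The first
#: entries are the species used by the packaged mixture designs.
FAMILY_SPECIES: dict[str, list[str]] = {
    MYTILIDAE: [
        "Mytilus galloprovincialis",
        "Perna canaliculus",
        "Mytilus edulis",
        "Mytilus chilensis",
        "Modiolus modiolus",
        "Mytilus platensis",
    ],
    PECTINIDAE: [
        "Pecten jacobaeus",
        "Placopecten magellanicus",
        "Mizuhopecten yessoensis",
        "Zygochlamys patagonica",
        "Argopecten purpuratus",
        "Aequipecten opercularis",
    ],
    OSTREIDAE: [
        "Magallana gigas",
        "Ostrea edulis",
        "Magallana bilineata",
        "Saccostrea glomerata",
        "Ostrea lurida",
        "Saccostrea echinata",
    ],
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MixtureSpec:
    """Ground-truth mixture design: species with proportions summing to 1."""

    components: tuple[tuple[str, float], ...]
    total_read_pairs: int
    label: str = "mixture"

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        total = sum(p for _, p in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions sum to {total}, not 1")
        if self.total_read_pairs < 0:
            raise ValueError("negative read count")


@dataclass(frozen=True)
class ErrorModel:
    """Sequencing error model: uniform i.i.d. substitutions, constant quality.

    ``substitution_rate`` is the per-base substitution probability (default
    0.001; indels and quality-profile realism are out of scope).
    ``read_length`` 151 matches a 300-cycle 2x151 kit.
    """

    substitution_rate: float = 0.001
    read_length: int = 151
    quality_char: str = "I"

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate < 0.5:
            raise ValueError("substitution_rate must be in [0, 0.5)")
        if self.read_length < 50:
            raise ValueError("read_length must be >= 50")
        if len(self.quality_char) != 1:
            raise ValueError("quality_char must be a single character")


# ---------------------------------------------------------------------------
# Fixture reference generator
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=n)]).decode()


def _pairwise_far(insert: str, others: Sequence[str], divergence: int) -> bool:
    for o in others:
        if len(o) != len(insert):
            continue
        mm = sum(a != b for a, b in zip(insert, o))
        if mm < divergence:
            return False
    return True


def generate_fixture_refs(
    n_per_family: int = 1,
    divergence: int = 5,
    seed: int = 0,
    *,
    families: Sequence[str] = (MYTILIDAE, PECTINIDAE, OSTREIDAE),
    duplicate_pair: bool = False,
    include_offtarget: bool = True,
    flank: int = 30,
    assay: Optional[TriplexAssay] = None,
) -> tuple[str, str]:
    """Generate synthetic reference FASTA + taxonomy TSV contents.

    Each on-target template is flank + forward-primer site + randomized
    insert + reverse-primer site + flank, sized so the primer-inclusive
    product is exactly 150 bp. Mussel records alternate between the two
    reverse primers. Within a family, inserts differ pairwise by at least
    ``divergence`` substitutions. ``duplicate_pair=True`` adds a second
    Pecten species carrying an insert identical to the first scallop record
    (for exercising genus-level collapse). Deterministic under ``seed``.

    Returns ``(fasta_text, taxonomy_text)``.
    """
    if n_per_family < 1:
        raise ValueError("n_per_family must be >= 1")
    if divergence < 1:
        raise ValueError("divergence must be >= 1")
    assay = assay or default_assay()
    rng = np.random.default_rng(seed)

    fasta_lines: list[str] = []
    tax_rows: list[str] = ["accession\tspecies\tgenus\tfamily\tsynonyms"]
    counter = 0

    def add_record(species: str, family: str, template: str) -> None:
        nonlocal counter
        counter += 1
        acc = f"SYN{counter:04d}"
        fasta_lines.append(f">{acc} {species} synthetic reference\n{template}")
        genus = species.split()[0]
        tax_rows.append(f"{acc}\t{species}\t{genus}\t{family}\t")

    def make_template(pset, rev_idx: int, insert: str) -> str:
        fwd = pset.forwards[0].sequence
        rev = pset.reverses[rev_idx].sequence
        return (
            _random_dna(rng, flank)
            + fwd
            + insert
            + revcomp(rev)
            + _random_dna(rng, flank)
        )

    duplicate_insert: Optional[str] = None
    for family in families:
        if family not in FAMILY_SPECIES:
            raise ValueError(f"unknown family {family!r}")
        pool = FAMILY_SPECIES[family]
        if n_per_family > len(pool):
            raise ValueError(
                f"{family}: at most {len(pool)} fixture species available"
            )
        pset = assay.set_for(family)
        done_inserts: list[str] = []
        for i in range(n_per_family):
            rev_idx = i % len(pset.reverses)
            insert_len = (
                PRODUCT_LENGTH
                - len(pset.forwards[0].sequence)
                - len(pset.reverses[rev_idx].sequence)
            )
            if insert_len < divergence:
                raise ValueError("divergence larger than the insert length")
            for attempt in range(200):
                insert = _random_dna(rng, insert_len)
                if not _pairwise_far(insert, done_inserts, divergence):
                    continue
                template = make_template(pset, rev_idx, insert)
                if len(predict_amplicons(template, assay)) == 1:
                    break
            else:
                raise ValueError(
                    f"could not satisfy pairwise divergence {divergence} for {family}"
                )
            done_inserts.append(insert)
            add_record(pool[i], family, template)
            if family == PECTINIDAE and i == 0:
                duplicate_insert = insert
        if duplicate_pair and family == PECTINIDAE:
            # same genus as Pecten jacobaeus, byte-identical insert
            assert duplicate_insert is not None
            template = make_template(pset, 0, duplicate_insert)
            add_record("Pecten maximus", PECTINIDAE, template)

    if include_offtarget:
        for attempt in range(200):
            template = _random_dna(rng, 2 * flank + PRODUCT_LENGTH)
            if not predict_amplicons(template, assay):
                break
        else:
            raise ValueError("could not generate an off-target template")
        add_record(OFFTARGET_SPECIES, OFFTARGET_FAMILY, template)

    return "\n".join(fasta_lines) + "\n", "\n".join(tax_rows) + "\n"


def write_fixture_refs(outdir: str | Path, **kwargs) -> tuple[Path, Path]:
    """Write :func:`generate_fixture_refs` output to references.fasta/taxonomy.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta, tax = generate_fixture_refs(**kwargs)
    fpath = outdir / "references.fasta"
    tpath = outdir / "taxonomy.tsv"
    fpath.write_text(fasta)
    tpath.write_text(tax)
    return fpath, tpath


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _mutate_reads(
    seq: str, n: int, rate: float, rng: np.random.Generator
) -> list[str]:
    """n copies of ``seq`` with i.i.d. substitution errors at ``rate``."""
    if n == 0:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    if rate == 0:
        return [seq] * n
    mat = np.tile(arr, (n, 1))
    mask = rng.random(mat.shape) < rate
    k = int(mask.sum())
    if k:
        # substitute with one of the three other bases, uniformly
        idx = np.searchsorted(_BASES, mat[mask])
        shift = rng.integers(1, 4, size=k)
        mat[mask] = _BASES[(idx + shift) % 4]
    return [bytes(row).decode() for row in mat]


def simulate_sample(
    db: BarcodeDB,
    mix: MixtureSpec,
    err: ErrorModel,
    seed: int,
    out_r1: str | Path,
    out_r2: str | Path,
    truth_path: Optional[str | Path] = None,
    *,
    efficiency: Optional[Dict[str, float]] = None,
) -> Dict[str, int]:
    """Simulate one paired-end sample; returns emitted pair counts per species.

    Pair counts per component are drawn multinomially from the mixture
    proportions (optionally reweighted by per-species ``efficiency``
    multipliers). On-target components emit R1 from the amplicon 5' end and
    R2 as the reverse complement of its 3' end; off-target components (no
    predicted amplicon) are allocated pairs that are simply never written.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    probs = np.array([p for _, p in mix.components], dtype=float)
    if efficiency:
        weights = np.array(
            [efficiency.get(db.canonical_species(s), 1.0) for s, _ in mix.components]
        )
        probs = probs * weights
        probs = probs / probs.sum()
    counts = rng.multinomial(mix.total_read_pairs, probs)

    products: list[Optional[str]] = []
    for species, _ in mix.components:
        if not db.accessions_for(species):
            raise ValueError(f"mixture component {species!r} is not in the database")
        amp = db.species_amplicon(species)
        products.append(amp.sequence if amp is not None else None)
    if all(p is None for p in products):
        warnings.warn(
            f"mixture {mix.label!r}: every component is off-target; FASTQ will be empty"
        )

    emitted: Dict[str, int] = {}
    out_r1, out_r2 = Path(out_r1), Path(out_r2)
    truth_rows: list[str] = ["read_id\tspecies"]
    with open(out_r1, "w") as f1, open(out_r2, "w") as f2:
        for (species, _), n, product in zip(mix.components, counts, products):
            canonical = db.canonical_species(species)
            if product is None:
                logger.info(
                    "component %s: off-target, %d allocated pairs not emitted",
                    canonical,
                    n,
                )
                emitted[canonical] = 0
                continue
            L = min(err.read_length, len(product))
            r1_tpl = product[:L]
            r2_tpl = revcomp(product)[:L]
            r1s = _mutate_reads(r1_tpl, int(n), err.substitution_rate, rng)
            r2s = _mutate_reads(r2_tpl, int(n), err.substitution_rate, rng)
            qual = err.quality_char * L
            tag = canonical.replace(" ", "_")
            buf1, buf2 = [], []
            for i, (a, b) in enumerate(zip(r1s, r2s)):
                rid = f"{mix.label}|{tag}|{i}"
                buf1.append(f"@{rid}/1\n{a}\n+\n{qual}\n")
                buf2.append(f"@{rid}/2\n{b}\n+\n{qual}\n")
                truth_rows.append(f"{rid}\t{canonical}")
            f1.write("".join(buf1))
            f2.write("".join(buf2))
            emitted[canonical] = int(n)
    if truth_path is not None:
        Path(truth_path).write_text("\n".join(truth_rows) + "\n")
    return emitted


# ---------------------------------------------------------------------------
# Packaged mixture designs
# ---------------------------------------------------------------------------

def _mix(label: str, comps: Sequence[Tuple[str, float]], pairs: int) -> MixtureSpec:
    return MixtureSpec(tuple(comps), pairs, label)


def mixture_presets(total_read_pairs: int = 50_000) -> Dict[str, List[MixtureSpec]]:
    """The packaged mixture study designs.

    ``ternary``: the three-family design - one species per family mixed
    98.0 : 1.5 : 0.5, in all six role permutations. ``scallop``/``oyster``/
    ``mussel``: single-family designs with one main component and 1.0%
    minors. ``squid``: an off-target main component (97%) with three 1.0%
    bivalve minors, which must yield reads for the bivalves only.
    """
    tern_species = ["Magallana gigas", "Mytilus galloprovincialis", "Pecten jacobaeus"]
    ternary = []
    orders = [
        (0, 1, 2), (0, 2, 1), (2, 0, 1), (2, 1, 0), (1, 2, 0), (1, 0, 2),
    ]
    for i, order in enumerate(orders, 1):
        comps = [
            (tern_species[order[0]], 0.98),
            (tern_species[order[1]], 0.015),
            (tern_species[order[2]], 0.005),
        ]
        ternary.append(_mix(f"ternary-{i}", comps, total_read_pairs))

    scallop = _mix(
        "scallop-family",
        [
            ("Placopecten magellanicus", 0.95),
            ("Mizuhopecten yessoensis", 0.01),
            ("Pecten jacobaeus", 0.01),
            ("Zygochlamys patagonica", 0.01),
            ("Argopecten purpuratus", 0.01),
            ("Aequipecten opercularis", 0.01),
        ],
        total_read_pairs,
    )
    oyster = _mix(
        "oyster-family",
        [
            ("Placopecten magellanicus", 0.98),
            ("Magallana gigas", 0.01),
            ("Ostrea edulis", 0.01),
        ],
        total_read_pairs,
    )
    mussel = _mix(
        "mussel-family",
        [
            ("Perna canaliculus", 0.98),
            ("Mytilus galloprovincialis", 0.01),
            ("Mytilus edulis", 0.01),
        ],
        total_read_pairs,
    )
    squid = _mix(
        "squid-offtarget",
        [
            (OFFTARGET_SPECIES, 0.97),
            ("Placopecten magellanicus", 0.01),
            ("Ostrea edulis", 0.01),
            ("Perna canaliculus", 0.01),
        ],
        total_read_pairs,
    )
    return {
        "ternary": ternary,
        "scallop": [scallop],
        "oyster": [oyster],
        "mussel": [mussel],
        "squid": [squid],
    }
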