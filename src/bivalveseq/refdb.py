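"""Reference barcode database: curation, in-silico digestion, resolution groups.

The classifier compares sequencing reads against a customized database of
barcode *inserts* - the primer-free interior of each reference's predicted
PCR product. Because reads are primer-trimmed before classification, the
database inserts exclude the primer-matched bases as well.

Species whose inserts are exactly identical cannot be told apart by this
barcode; they are collected into resolution groups and reported at the
lowest rank that is still unambiguous ("<Genus> spp." when the group is
within one genus, a slash-joined list otherwise). Records on which the
triplex assay predicts no product are flagged non-amplifiable.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from Bio import SeqIO

from .amplicon import DEFAULT_LENGTH_WINDOW, DEFAULT_MAX_MM, Amplicon, predict_amplicons
from .primers import IUPAC_ALPHABET, TriplexAssay

logger = logging.getLogger("bivalveseq")

#: Built-in scientific-name synonymy (former name -> accepted name).
#: Extensible per-record through the taxonomy TSV ``synonyms`` column.
DEFAULT_SYNONYMS: dict[str, str] = {
    "Crassostrea gigas": "Magallana gigas",
    "Crassostrea bilineata": "Magallana bilineata",
    "Patinopecten yessoensis": "Mizuhopecten yessoensis",
}

NON_AMPLIFIABLE_LABEL = "non-amplifiable"

TAXONOMY_COLUMNS = ("accession", "species", "genus", "family", "synonyms")


@dataclass(frozen=True)
class TaxonRecord:
    species: str
    genus: str
    family: str
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("empty species name")
        if self.genus != self.species.split()[0]:
            raise ValueError(
                f"genus {self.genus!r} is not the first token of {self.species!r}"
            )


@dataclass
class BarcodeRecord:
    accession: str
    taxon: TaxonRecord
    sequence: str
    is_complete_reference: bool = False


@dataclass(frozen=True)
class ResolutionGroup:
    """Species indistinguishable by the barcode (identical inserts)."""

    members: frozenset[str]
    label: str

    @staticmethod
    def make(members: Iterable[str]) -> "ResolutionGroup":
        members = frozenset(members)
        if not members:
            raise ValueError("empty resolution group")
        if len(members) == 1:
            label = next(iter(members))
        else:
            genera = {m.split()[0] for m in members}
            if len(genera) == 1:
                label = f"{next(iter(genera))} spp."
            else:
                label = "/".join(sorted(members))
        return ResolutionGroup(members, label)


@dataclass
class BarcodeDB:
    """Reference records plus everything derived from in-silico digestion."""

    records: Dict[str, BarcodeRecord] = field(default_factory=dict)
    inserts: Dict[str, str] = field(default_factory=dict)
    amplicons: Dict[str, List[Amplicon]] = field(default_factory=dict)
    groups: List[ResolutionGroup] = field(default_factory=list)
    non_amplifiable: set[str] = field(default_factory=set)
    ambiguous: set[str] = field(default_factory=set)
    load_report: List[str] = field(default_factory=list)
    synonyms: Dict[str, str] = field(default_factory=dict)

    # -- lookups ----------------------------------------------------------
    def canonical_species(self, name: str) -> str:
        """Resolve a (possibly former) scientific name to its accepted form."""
        return self.synonyms.get(name, name)

    def species_of(self, accession: str) -> str:
        return self.records[accession].taxon.species

    def accessions_for(self, species: str) -> List[str]:
        species = self.canonical_species(species)
        return sorted(
            a for a, r in self.records.items() if r.taxon.species == species
        )

    def group_of(self, species: str) -> Optional[ResolutionGroup]:
        species = self.canonical_species(species)
        for g in self.groups:
            if species in g.members:
                return g
        return None

    def species_insert(self, species: str) -> Optional[str]:
        """The insert of a species' best record (None if non-amplifiable)."""
        for acc in self.accessions_for(species):
            if acc in self.inserts:
                return self.inserts[acc]
        return None

    def species_amplicon(self, species: str) -> Optional[Amplicon]:
        """Shortest predicted product of the species' best record, if any."""
        for acc in self.accessions_for(species):
            if acc in self.inserts and self.amplicons.get(acc):
                return self.amplicons[acc][0]
        return None


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _read_taxonomy(taxonomy_path: str | Path) -> Dict[str, TaxonRecord]:
    taxa: Dict[str, TaxonRecord] = {}
    with open(taxonomy_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(TAXONOMY_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(
                f"taxonomy file {taxonomy_path}: missing columns {sorted(missing)}"
            )
        for row in reader:
            acc = row["accession"].strip()
            if acc in taxa:
                raise ValueError(f"duplicate accession in taxonomy: {acc}")
            syns = tuple(
                s.strip() for s in (row.get("synonyms") or "").split(",") if s.strip()
            )
            taxa[acc] = TaxonRecord(
                species=row["species"].strip(),
                genus=row["genus"].strip(),
                family=row["family"].strip(),
                synonyms=syns,
            )
    return taxa


def load_references(
    fasta_path: str | Path,
    taxonomy_path: str | Path,
    *,
    extra_synonyms: Optional[Dict[str, str]] = None,
) -> BarcodeDB:
    """Load reference sequences plus taxonomy into a BarcodeDB (records only).

    Sequences are uppercased; records with characters outside the IUPAC
    nucleotide alphabet are rejected and listed in the load report. Species
    names are normalized through the synonym table (built-in synonymy plus
    the per-record ``synonyms`` TSV column), so e.g. a record labelled
    "Crassostrea gigas" is stored under "Magallana gigas".

    Raises on a FASTA ID with no taxonomy row and on duplicate accessions.
    """
    taxa = _read_taxonomy(taxonomy_path)

    synonyms = dict(DEFAULT_SYNONYMS)
    if extra_synonyms:
        synonyms.update(extra_synonyms)
    for t in taxa.values():
        canonical = synonyms.get(t.species, t.species)
        for s in t.synonyms:
            synonyms[s] = canonical

    db = BarcodeDB(synonyms=synonyms)
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        acc = rec.id
        if acc in seen:
            raise ValueError(f"duplicate accession in FASTA: {acc}")
        seen.add(acc)
        if acc not in taxa:
            raise ValueError(f"FASTA entry {acc} has no taxonomy row")
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_ALPHABET
        if bad:
            db.load_report.append(
                f"REJECTED {acc}: non-IUPAC characters {''.join(sorted(bad))}"
            )
            continue
        if not seq:
            db.load_report.append(f"REJECTED {acc}: empty sequence")
            continue
        taxon = taxa[acc]
        canonical = synonyms.get(taxon.species, taxon.species)
        if canonical != taxon.species:
            db.load_report.append(f"SYNONYM {acc}: {taxon.species} -> {canonical}")
            taxon = TaxonRecord(
                species=canonical,
                genus=canonical.split()[0],
                family=taxon.family,
                synonyms=taxon.synonyms + (taxon.species,),
            )
        complete = "refseq" in rec.description.lower() or "complete" in rec.description.lower()
        db.records[acc] = BarcodeRecord(acc, taxon, seq, complete)
    extra = set(taxa) - seen
    for acc in sorted(extra):
        db.load_report.append(f"NOTE taxonomy row {acc} has no FASTA entry")
    db.load_report.append(f"LOADED {len(db.records)} records")
    return db


# ---------------------------------------------------------------------------
# Digestion + grouping
# ---------------------------------------------------------------------------

def build_inserts(
    db: BarcodeDB,
    assay: TriplexAssay,
    max_mm: int = DEFAULT_MAX_MM,
    length_window: Tuple[int, int] = DEFAULT_LENGTH_WINDOW,
) -> BarcodeDB:
    """Run in-silico PCR on every record and store the barcode inserts.

    The insert is the sequence strictly between the forward-primer 3' end and
    the reverse-primer binding site. Records with no predicted product are
    flagged non-amplifiable; records with more than one product in the length
    window are flagged ambiguous and the shortest product is kept. A record
    whose insert contains N is dropped from the insert table when another
    record of the same species provides an N-free insert (reference-quality
    preference).
    """
    db.inserts.clear()
    db.amplicons.clear()
    db.non_amplifiable.clear()
    db.ambiguous.clear()
    for acc in sorted(db.records):
        amps = predict_amplicons(db.records[acc], assay, max_mm, length_window)
        db.amplicons[acc] = amps
        if not amps:
            db.non_amplifiable.add(acc)
            db.load_report.append(f"NON-AMPLIFIABLE {acc}")
            continue
        if len(amps) > 1:
            db.ambiguous.add(acc)
            db.load_report.append(
                f"AMBIGUOUS {acc}: {len(amps)} products in window, keeping shortest"
            )
            logger.warning(
                "record %s yields %d products; keeping the shortest", acc, len(amps)
            )
        db.inserts[acc] = amps[0].insert

    # quality preference: drop N-containing inserts when the species has a
    # clean alternative; among equals prefer complete references
    by_species: Dict[str, List[str]] = {}
    for acc in db.inserts:
        by_species.setdefault(db.species_of(acc), []).append(acc)
    for species, accs in by_species.items():
        clean = [a for a in accs if "N" not in db.inserts[a]]
        if clean and len(clean) < len(accs):
            for a in accs:
                if a not in clean:
                    del db.inserts[a]
                    db.load_report.append(
                        f"DROPPED {a}: insert contains N and {species} has a clean record"
                    )
    db.groups = resolution_groups(db)
    return db


def resolution_groups(db: BarcodeDB) -> List[ResolutionGroup]:
    """Partition species into equivalence classes under exact insert identity.

    Species without any insert form a single catch-all non-amplifiable class.
    When a species has several records, its best (first surviving) insert
    defines its class membership.
    """
    by_insert: Dict[str, set[str]] = {}
    no_insert: set[str] = set()
    for species in sorted({r.taxon.species for r in db.records.values()}):
        ins = db.species_insert(species)
        if ins is None:
            no_insert.add(species)
        else:
            by_insert.setdefault(ins, set()).add(species)
    groups = [ResolutionGroup.make(members) for members in by_insert.values()]
    groups.sort(key=lambda g: g.label)
    if no_insert:
        groups.append(ResolutionGroup(frozenset(no_insert), NON_AMPLIFIABLE_LABEL))
    return groups


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

def save_db(db: BarcodeDB, outdir: str | Path) -> Path:
    """Write the database bundle: references + taxonomy + inserts + groups.

    The references.fasta/taxonomy.tsv pair round-trips through
    :func:`load_references`; inserts.fasta, groups.tsv and load_report.txt
    are the derived products used for inspection and downstream tools.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "references.fasta", "w") as fh:
        for acc in sorted(db.records):
            r = db.records[acc]
            tag = " complete" if r.is_complete_reference else ""
            fh.write(f">{acc} {r.taxon.species}{tag}\n{r.sequence}\n")
    with open(outdir / "taxonomy.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TAXONOMY_COLUMNS)
        for acc in sorted(db.records):
            t = db.records[acc].taxon
            w.writerow([acc, t.species, t.genus, t.family, ",".join(t.synonyms)])
    with open(outdir / "inserts.fasta", "w") as fh:
        for acc in sorted(db.inserts):
            fh.write(f">{acc} {db.species_of(acc)}\n{db.inserts[acc]}\n")
    with open(outdir / "groups.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["label", "members"])
        for g in db.groups:
            w.writerow([g.label, ",".join(sorted(g.members))])
    (outdir / "load_report.txt").write_text("\n".join(db.load_report) + "\n")
    return outdir


def build_db(
    fasta_path: str | Path,
    taxonomy_path: str | Path,
    assay: TriplexAssay,
    max_mm: int = DEFAULT_MAX_MM,
    length_window: Tuple[int, int] = DEFAULT_LENGTH_WINDOW,
) -> BarcodeDB:
    """Convenience: load references and digest them in one call."""
    db = load_references(fasta_path, taxonomy_path)
    return build_inserts(db, assay, max_mm, length_window)
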