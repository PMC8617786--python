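"""Reference database loading, curation rules, and resolution groups."""

import pytest

from bivalveseq import (
    ResolutionGroup,
    build_db,
    build_inserts,
    default_assay,
    load_references,
    revcomp,
    save_db,
    write_fixture_refs,
)
from bivalveseq.refdb import NON_AMPLIFIABLE_LABEL
from bivalveseq.simulate import generate_fixture_refs


def _write(tmp_path, fasta, tax):
    f = tmp_path / "refs.fasta"
    t = tmp_path / "tax.tsv"
    f.write_text(fasta)
    t.write_text(tax)
    return f, t


def test_load_preserves_record_count(tmp_path):
    fasta, tax = generate_fixture_refs(n_per_family=2, divergence=5, seed=3)
    f, t = _write(tmp_path, fasta, tax)
    db = load_references(f, t)
    assert len(db.records) == 7  # 2 per family + off-target squid


def test_synonym_resolves_to_canonical_species(tmp_path):
    fasta = ">ACC1 oyster reference\n" + "ACGT" * 50 + "\n"
    tax = (
        "accession\tspecies\tgenus\tfamily\tsynonyms\n"
        "ACC1\tCrassostrea gigas\tCrassostrea\tOstreidae\t\n"
    )
    f, t = _write(tmp_path, fasta, tax)
    db = load_references(f, t)
    assert db.records["ACC1"].taxon.species == "Magallana gigas"
    assert db.records["ACC1"].taxon.genus == "Magallana"
    # symmetric lookup: either name resolves to the accepted one
    assert db.canonical_species("Crassostrea gigas") == "Magallana gigas"
    assert db.accessions_for("Crassostrea gigas") == ["ACC1"]


def test_non_iupac_record_rejected_with_report(tmp_path):
    fasta = ">GOOD a\n" + "ACGT" * 30 + "\n>BAD b\nACGTXACGT\n"
    tax = (
        "accession\tspecies\tgenus\tfamily\tsynonyms\n"
        "GOOD\tOstrea edulis\tOstrea\tOstreidae\t\n"
        "BAD\tOstrea lurida\tOstrea\tOstreidae\t\n"
    )
    f, t = _write(tmp_path, fasta, tax)
    db = load_references(f, t)
    assert "GOOD" in db.records and "BAD" not in db.records
    assert any("REJECTED BAD" in line for line in db.load_report)


def test_missing_taxonomy_row_and_duplicate_accession_are_hard_errors(tmp_path):
    fasta = ">ONLYFASTA x\nACGTACGT\n"
    tax = "accession\tspecies\tgenus\tfamily\tsynonyms\n"
    f, t = _write(tmp_path, fasta, tax)
    with pytest.raises(ValueError, match="ONLYFASTA"):
        load_references(f, t)
    fasta2 = ">DUP a\nACGT\n>DUP b\nACGT\n"
    tax2 = "accession\tspecies\tgenus\tfamily\tsynonyms\nDUP\tOstrea edulis\tOstrea\tOstreidae\t\n"
    f2, t2 = _write(tmp_path, fasta2, tax2)
    with pytest.raises(ValueError, match="duplicate"):
        load_references(f2, t2)


def test_insert_lengths_are_primer_exclusive(fixture_db, assay):
    # product is 150 bp primer-inclusive, so each insert is 150 minus the
    # lengths of the particular primer pair that produced it
    for acc, ins in fixture_db.inserts.items():
        amp = fixture_db.amplicons[acc][0]
        fwd = next(p for p in assay.primers if p.name == amp.primer_pair[0])
        rev = next(p for p in assay.primers if p.name == amp.primer_pair[1])
        assert len(ins) == 150 - len(fwd.sequence) - len(rev.sequence)


def test_offtarget_record_flagged_non_amplifiable(fixture_db):
    accs = fixture_db.accessions_for("Sepiella inermis")
    assert accs and set(accs) <= fixture_db.non_amplifiable
    assert all(a not in fixture_db.inserts for a in accs)
    labels = [g.label for g in fixture_db.groups]
    assert NON_AMPLIFIABLE_LABEL in labels


def test_ambiguous_multi_product_record_keeps_shortest(tmp_path, assay):
    mu = assay.set_for("Mytilidae")
    fwd = mu.forwards[0].sequence
    rev1 = revcomp(mu.reverses[0].sequence)
    rev2 = revcomp(mu.reverses[1].sequence)
    template = "GATC" * 5 + fwd + "AC" * 30 + rev1 + "GT" * 10 + rev2 + "TACG" * 5
    fasta = f">AMB two-product stress case\n{template}\n"
    tax = "accession\tspecies\tgenus\tfamily\tsynonyms\nAMB\tMytilus edulis\tMytilus\tMytilidae\t\n"
    f, t = _write(tmp_path, fasta, tax)
    db = build_db(f, t, assay)
    assert "AMB" in db.ambiguous
    amps = db.amplicons["AMB"]
    assert len(amps) == 2
    assert db.inserts["AMB"] == amps[0].insert  # the shortest product wins


def test_duplicate_inserts_collapse_to_genus_group(dup_db):
    group = dup_db.group_of("Pecten jacobaeus")
    assert group.members == {"Pecten jacobaeus", "Pecten maximus"}
    assert group.label == "Pecten spp."


def test_all_distinct_fixture_gives_singleton_groups(fixture_db):
    for g in fixture_db.groups:
        if g.label == NON_AMPLIFIABLE_LABEL:
            continue
        assert len(g.members) == 1
        assert g.label == next(iter(g.members))


def test_cross_genus_identity_uses_slash_label():
    g = ResolutionGroup.make({"Ostrea angelica", "Saccostrea echinata"})
    assert g.label == "Ostrea angelica/Saccostrea echinata"
    assert "spp." not in g.label


def test_groups_partition_species_with_inserts(fixture_db):
    species_with_inserts = {
        fixture_db.species_of(a) for a in fixture_db.inserts
    }
    covered = set()
    for g in fixture_db.groups:
        if g.label == NON_AMPLIFIABLE_LABEL:
            continue
        assert not (covered & g.members)  # disjoint
        covered |= g.members
    assert covered == species_with_inserts


def test_n_in_insert_dropped_when_species_has_clean_record(tmp_path, assay):
    oy = assay.set_for("Ostreidae")
    fwd = oy.forwards[0].sequence
    rev = revcomp(oy.reverses[0].sequence)
    insert = "AC" * 55 + "A"  # 111 nt -> 150 bp product
    noisy = insert[:50] + "N" + insert[51:]
    fasta = (
        f">CLEAN complete\n{'GT' * 10}{fwd}{insert}{rev}{'CA' * 10}\n"
        f">NOISY partial\n{'GT' * 10}{fwd}{noisy}{rev}{'CA' * 10}\n"
    )
    tax = (
        "accession\tspecies\tgenus\tfamily\tsynonyms\n"
        "CLEAN\tOstrea edulis\tOstrea\tOstreidae\t\n"
        "NOISY\tOstrea edulis\tOstrea\tOstreidae\t\n"
    )
    f, t = _write(tmp_path, fasta, tax)
    db = build_db(f, t, assay)
    assert "CLEAN" in db.inserts and "NOISY" not in db.inserts


def test_roundtrip_write_reload(tmp_path, fixture_db, assay):
    out = save_db(fixture_db, tmp_path / "bundle")
    db2 = load_references(out / "references.fasta", out / "taxonomy.tsv")
    build_inserts(db2, assay)
    assert {a: r.sequence for a, r in db2.records.items()} == {
        a: r.sequence for a, r in fixture_db.records.items()
    }
    assert {a: r.taxon for a, r in db2.records.items()} == {
        a: r.taxon for a, r in fixture_db.records.items()
    }
    assert db2.inserts == fixture_db.inserts
    assert {(g.label, g.members) for g in db2.groups} == {
        (g.label, g.members) for g in fixture_db.groups
    }
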