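"""Fixture generator and seeded mixture read simulator."""

import math

import pytest

from bivalveseq import (
    ErrorModel,
    MixtureSpec,
    build_db,
    default_assay,
    generate_fixture_refs,
    predict_amplicons,
    simulate_sample,
)
from bivalveseq.simulate import OFFTARGET_SPECIES


def test_fixture_contract_and_determinism(tmp_path, assay):
    fa1, tax1 = generate_fixture_refs(n_per_family=1, divergence=5, seed=42)
    fa2, tax2 = generate_fixture_refs(n_per_family=1, divergence=5, seed=42)
    assert fa1 == fa2 and tax1 == tax2  # byte-identical under the same seed
    fa3, _ = generate_fixture_refs(n_per_family=1, divergence=5, seed=43)
    assert fa3 != fa1
    # 3 bivalve records + 1 off-target; bivalves amplifiable, squid not
    entries = [e for e in fa1.split(">") if e]
    assert len(entries) == 4
    for entry in entries:
        header, seq = entry.split("\n")[0], entry.split("\n")[1]
        amps = predict_amplicons(seq, assay)
        if OFFTARGET_SPECIES.split()[0] in header:
            assert amps == []
        else:
            assert len(amps) == 1 and len(amps[0]) == 150


def test_fixture_divergence_unsatisfiable_raises():
    with pytest.raises(ValueError):
        generate_fixture_refs(n_per_family=3, divergence=200, seed=1)


def test_mixture_spec_validation():
    with pytest.raises(ValueError):
        MixtureSpec((("Ostrea edulis", 0.7),), 100)
    with pytest.raises(ValueError):
        MixtureSpec((), 100)
    with pytest.raises(ValueError):
        ErrorModel(substitution_rate=0.6)


def _simulate(db, comps, pairs, rate, seed, tmp_path, tag="s"):
    mix = MixtureSpec(tuple(comps), pairs, tag)
    err = ErrorModel(substitution_rate=rate)
    r1, r2 = tmp_path / f"{tag}_R1.fastq", tmp_path / f"{tag}_R2.fastq"
    emitted = simulate_sample(db, mix, err, seed, r1, r2, tmp_path / f"{tag}.tsv")
    return emitted, r1, r2


def test_multinomial_counts_within_3_sigma(fixture_db, tmp_path):
    pairs = 50_000
    comps = [
        ("Magallana gigas", 0.98),
        ("Mytilus galloprovincialis", 0.015),
        ("Pecten jacobaeus", 0.005),
    ]
    emitted, _, _ = _simulate(fixture_db, comps, pairs, 0.001, 42, tmp_path)
    assert sum(emitted.values()) == pairs
    for species, p in comps:
        sigma = math.sqrt(pairs * p * (1 - p))
        assert abs(emitted[species] - pairs * p) <= 3 * sigma, species


def test_offtarget_main_component_emits_no_reads(fixture_db, tmp_path):
    comps = [
        (OFFTARGET_SPECIES, 0.97),
        ("Placopecten magellanicus", 0.01),
        ("Ostrea edulis", 0.01),
        ("Perna canaliculus", 0.01),
    ]
    emitted, r1, _ = _simulate(fixture_db, comps, 3000, 0.0, 5, tmp_path, "squid")
    assert emitted[OFFTARGET_SPECIES] == 0
    n_emitted = sum(emitted.values())
    # count conservation: emitted = total - pairs allocated off-target
    assert 0 < n_emitted < 3000
    lines = r1.read_text().splitlines()
    assert len(lines) == 4 * n_emitted
    assert all("Sepiella" not in l for l in lines[::4])


def test_all_offtarget_mixture_warns_and_is_empty(fixture_db, tmp_path):
    with pytest.warns(UserWarning):
        emitted, r1, r2 = _simulate(
            fixture_db, [(OFFTARGET_SPECIES, 1.0)], 100, 0.0, 1, tmp_path, "empty"
        )
    assert r1.read_text() == "" and r2.read_text() == ""


def test_zero_error_reads_equal_amplicon(fixture_db, tmp_path):
    emitted, r1, r2 = _simulate(
        fixture_db, [("Ostrea edulis", 1.0)], 50, 0.0, 9, tmp_path, "clean"
    )
    amp = fixture_db.species_amplicon("Ostrea edulis")
    from bivalveseq import revcomp

    r1_seqs = r1.read_text().splitlines()[1::4]
    r2_seqs = r2.read_text().splitlines()[1::4]
    assert set(r1_seqs) == {amp.sequence[:151]}
    assert set(r2_seqs) == {revcomp(amp.sequence)[:151]}
    # reads cannot be longer than the amplicon
    assert all(len(s) == min(151, len(amp.sequence)) for s in r1_seqs)


def test_seed_determinism_of_fastq_bytes(fixture_db, tmp_path):
    mix = MixtureSpec(
        (("Magallana gigas", 0.5), ("Pecten jacobaeus", 0.5)), 500, "det"
    )
    err = ErrorModel(substitution_rate=0.01)
    paths = {}
    for tag, seed in (("a", 77), ("b", 77), ("c", 78)):
        r1, r2 = tmp_path / f"{tag}_R1.fastq", tmp_path / f"{tag}_R2.fastq"
        simulate_sample(fixture_db, mix, err, seed, r1, r2)
        paths[tag] = (r1, r2)
    assert paths["a"][0].read_bytes() == paths["b"][0].read_bytes()
    assert paths["a"][1].read_bytes() == paths["b"][1].read_bytes()
    assert paths["c"][0].read_bytes() != paths["a"][0].read_bytes()


def test_efficiency_knob_shifts_counts(fixture_db, tmp_path):
    mix = MixtureSpec(
        (("Magallana gigas", 0.5), ("Pecten jacobaeus", 0.5)), 10_000, "eff"
    )
    err = ErrorModel(substitution_rate=0.0)
    emitted = simulate_sample(
        fixture_db, mix, err, 3,
        tmp_path / "e1.fastq", tmp_path / "e2.fastq",
        efficiency={"Magallana gigas": 3.0},
    )
    assert emitted["Magallana gigas"] > 2 * emitted["Pecten jacobaeus"]
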