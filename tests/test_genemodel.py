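"""Fixture gene models: printed exon sizes, splice motifs, determinism, I/O."""

import pytest

from kirsplice.genemodel import (FixtureError, GFF3ParseError,
                                 build_fixture_model, read_gene_models,
                                 spliced_sequence, write_gene_models)

from conftest import SEED


def _exon_len(model, k):
    s, e = model.exons[k - 1]
    return e - s


@pytest.mark.parametrize("key,exons,total", [
    # composite deletion sizes as printed in the event tables
    ("KIR3DL20*001", (4, 5), 594),          # 300 + 294
    ("KIR2DL04*001", (6, 7), 155),          # 51 + 104
    ("KIR2DL4*002", (6, 7, 8), 209),        # 51 + 105 + 53
    ("KIR2DL4*002", (7, 8), 158),           # 105 + 53
    ("KIR3DL01*001", (5, 6, 7), 446),       # 294 + 51 + 101
    ("KIR3DL20*001", (5, 6), 345),          # 294 + 51
    ("KIR3DL20*001", (4, 5, 6), 645),       # 300 + 294 + 51
    ("KIR3DL2*001", (6, 7), 155),           # 51 + 104
])
def test_composite_exon_size_arithmetic(model_of, key, exons, total):
    model = model_of(key)
    assert sum(_exon_len(model, k) for k in exons) == total


def test_gdna_level_quirks(model_of):
    """Mamu-KIR1D carries the 5-bp (exon 3) and 7-bp (exon 5) deletions and
    constitutively skips exon 3; the 3DL20 intron 3 is shortened."""
    k1d = model_of("KIR1D*002")
    assert _exon_len(k1d, 3) == 300 - 5
    assert _exon_len(k1d, 5) == 294 - 7
    assert k1d.constitutive_skip == (2,)
    intron2 = k1d.genome_seq[k1d.introns[1][0]:k1d.introns[1][1]]
    assert "GGAAGGGAGG" not in intron2  # purine element absent (lineage III)
    d20 = model_of("KIR3DL20*001")
    i3 = d20.introns[2]
    assert i3[1] - i3[0] == 100  # ~500 bp shorter than the 600 bp default


def test_nine_a_ten_a_alleles_differ_by_one_adenine(model_of):
    a9 = model_of("KIR2DL4*001")
    a10 = model_of("KIR2DL4*002")
    assert _exon_len(a9, 7) == 104 and a9.attributes["polyA_run"] == 9
    assert _exon_len(a10, 7) == 105 and a10.attributes["polyA_run"] == 10
    for m, run in ((a9, 9), (a10, 10)):
        s, e = m.exons[6]
        assert m.genome_seq[e - run:e] == "A" * run
        assert m.genome_seq[e - run - 1] != "A"


def test_all_introns_canonical_gt_ag(human_models, macaque_models):
    for m in human_models + macaque_models:
        for s, e in m.introns:
            assert m.genome_seq[s:s + 2] == "GT"
            assert m.genome_seq[e - 2:e] == "AG"


def test_feature_boundary_motifs(model_of):
    """Alternative acceptors are AG-preceded and alternative donor ends are
    GT-opened, as the splicing mechanism requires."""
    m = model_of("KIR2DL04*001")
    g = m.genome_seq
    for f in m.features:
        if f.mechanism == "alt3ss_inc":
            assert g[f.genome_start - 2:f.genome_start] == "AG"
        elif f.mechanism == "alt5ss_inc":
            assert g[f.genome_end:f.genome_end + 2] == "GT"
        elif f.mechanism == "cryptic_exon":
            assert g[f.genome_start - 2:f.genome_start] == "AG"
            assert g[f.genome_end:f.genome_end + 2] == "GT"


def test_build_is_deterministic(macaque_catalog):
    e = macaque_catalog.entry("KIR3DL20*001")
    m1 = build_fixture_model(e, SEED)
    m2 = build_fixture_model(e, SEED)
    assert m1.genome_seq == m2.genome_seq
    m3 = build_fixture_model(e, SEED + 1)
    assert m3.genome_seq != m1.genome_seq


def test_bad_feature_offset_is_a_configuration_error(toy_entry):
    from dataclasses import replace
    from kirsplice.genemodel import CRYPTIC, Feature
    bad = replace(toy_entry, allele_id="bad", features=(
        Feature("cryploose", CRYPTIC, 6, 300, offset_bp=95),),
        validated_isoforms=())
    with pytest.raises(FixtureError, match="cryploose"):
        build_fixture_model(bad, SEED)


def test_spliced_sequence_contract(toy_model):
    exons = toy_model.exons
    full = spliced_sequence(toy_model, exons)
    assert len(full) == sum(e - s for s, e in exons)
    # omitting exon 6 shortens the transcript by its printed 51 bp
    chain = exons[:5] + exons[6:]
    assert len(full) - len(spliced_sequence(toy_model, chain)) == 51
    assert spliced_sequence(toy_model, []) == ""
    with pytest.raises(ValueError):
        spliced_sequence(toy_model, [(10, 5)][::-1] + [(0, 20)])
    with pytest.raises(ValueError):
        spliced_sequence(toy_model, [(0, len(toy_model.genome_seq) + 10)])


def test_gff3_fasta_round_trip(tmp_path, human_models):
    gff = tmp_path / "models.gff3"
    fa = tmp_path / "models.fasta"
    write_gene_models(human_models, gff, fa)
    back = read_gene_models(gff, fa)
    orig = sorted(human_models, key=lambda m: m.key)
    assert len(back) == len(orig)
    for a, b in zip(orig, back):
        assert a.key == b.key
        assert a.genome_seq == b.genome_seq
        assert a.exons == b.exons
        assert a.exon_phases == b.exon_phases
        assert a.cds_end == b.cds_end
        assert a.constitutive_skip == b.constitutive_skip
    # GFF3 is 1-based inclusive: "101..150" means internal [100, 150)
    line = next(l for l in gff.read_text().splitlines()
                if "\texon\t" in l)
    start_1based = int(line.split("\t")[3])
    model = next(m for m in orig if m.key == line.split("\t")[0])
    assert model.exons[0][0] == start_1based - 1


def test_malformed_gff3_reports_line_number(tmp_path):
    p = tmp_path / "bad.gff3"
    p.write_text("##gff-version 3\nchr1\tonly\tthree\n")
    with pytest.raises(GFF3ParseError, match=":2:"):
        read_gene_models(p, tmp_path / "none.fasta")


def test_catalog_yaml_round_trip(tmp_path, macaque_catalog):
    from kirsplice.genemodel import catalog_from_yaml, catalog_to_yaml
    path = tmp_path / "cat.yaml"
    catalog_to_yaml(macaque_catalog, path)
    back = catalog_from_yaml(path)
    assert back.name == macaque_catalog.name
    assert [e.key for e in back.entries] == \
        [e.key for e in macaque_catalog.entries]
    for a, b in zip(macaque_catalog.entries, back.entries):
        assert a.exon_lengths == b.exon_lengths
        assert [f.name for f in a.features] == [f.name for f in b.features]
        # a model built from the round-tripped entry is identical
        if a.gene_id == "KIR3DL20":
            assert build_fixture_model(a, SEED).genome_seq == \
                build_fixture_model(b, SEED).genome_seq
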