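"""Event classification: taxonomy mapping, merging, naming, conservation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kirsplice import synthdata as sd
from kirsplice.events import (call_events, canonical_name, classify,
                              diff_chains, events_table)
from kirsplice.genemodel import spliced_sequence


def _events_for(model, tokens):
    chain = sd.isoform_chain(model, tokens)
    return classify(diff_chains(chain, model), model), chain


def test_constitutive_chain_yields_no_events(model_of):
    for key in ("KIR2DL4*001", "KIR1D*002", "KIR3DL20*001"):
        m = model_of(key)
        evs, _ = _events_for(m, ())
        assert evs == []


@pytest.mark.parametrize("key,tokens,mech,delta", [
    ("KIR3DL02*001", ("skip:5",), "exon_skipping", -294),
    ("KIR2DL04*001", ("skip:6,7",), "exon_skipping", -155),
    ("KIR3DL20*001", ("skip:4,5",), "exon_skipping", -594),
    ("KIR3DL20*001", ("del115",), "alt3ss_del", -115),
    ("KIR3DL20*001", ("skipalt415",), "skip_plus_altss", -415),
    ("KIR2DL3*001", ("both294",), "alt_both", -294),
    ("KIR3DS02*001", ("both81",), "alt_both", -81),
    ("KIR2DL1*001", ("cryp78",), "cryptic_exon", 78),
    ("KIR2DL4*001", ("inc67",), "alt5ss_inc", 67),
    ("KIR3DL1*001", ("inc170",), "alt3ss_inc", 170),
    ("KIR2DL4*001", ("del73",), "alt5ss_del", -73),
    ("KIR2DL04*001", ("ret8",), "intron_retention", 98),
    ("KIR2DL04*002", ("ret8",), "intron_retention", 99),
])
def test_mechanism_taxonomy_and_sizes(model_of, key, tokens, mech, delta):
    """classify(apply_event(spec)) reproduces each spec's mechanism and size
    (round-trip identity over the fixture repertoire)."""
    m = model_of(key)
    evs, _ = _events_for(m, tokens)
    assert len(evs) == 1
    assert evs[0].mechanism == mech
    assert evs[0].delta_len == delta


def test_every_catalog_feature_round_trips(human_models, macaque_models):
    for m in human_models + macaque_models:
        for f in m.features:
            evs, _ = _events_for(m, (f.name,))
            assert len(evs) == 1, (m.key, f.name)
            ev = evs[0]
            assert ev.mechanism == f.mechanism
            if f.mechanism == "intron_retention":
                intron = m.introns[f.anchor - 1]
                assert ev.delta_len == intron[1] - intron[0]
            elif f.mechanism == "alt_both":
                want = f.length_bp + (f.length2_bp or 0) if not f.within \
                    else f.length_bp
                assert ev.size_bp == want
            elif f.mechanism == "skip_plus_altss":
                skipped = m.exons[f.anchor - 1]
                assert ev.size_bp == (skipped[1] - skipped[0]) + f.length_bp
            else:
                assert ev.size_bp == f.length_bp


def test_multi_exon_skip_merges_to_single_event(model_of):
    m = model_of("KIR2DL4*002")
    evs, _ = _events_for(m, ("skip:6,7,8",))
    assert len(evs) == 1
    assert evs[0].exons == (6, 7, 8)
    assert evs[0].delta_len == -209
    # merging is associative: applying the skips one-by-one gives the same
    evs2, _ = _events_for(m, ("skip:6", "skip:7", "skip:8"))
    assert [e.canonical_id for e in evs2] == [e.canonical_id for e in evs]


def test_skip_adjacent_to_acceptor_shift_merges(model_of):
    m = model_of("KIR3DL20*001")
    evs, _ = _events_for(m, ("skipalt415",))
    assert len(evs) == 1
    assert evs[0].mechanism == "skip_plus_altss"
    assert evs[0].delta_len == -(300 + 115)
    assert set(evs[0].exons) == {4, 5}


def test_constitutively_absent_exon_is_not_a_skip(model_of):
    """KIR1D exon 3 is absent at the transcript level but never called."""
    m = model_of("KIR1D*002")
    evs, chain = _events_for(m, ("skip:5",))
    assert [e.mechanism for e in evs] == ["exon_skipping"]
    assert evs[0].exons == (5,)


def test_delta_conservation_over_isoforms(model_of):
    """Sum of event deltas equals read length minus constitutive length."""
    cases = [("KIR1D*002", t) for t in sd.KIR1D_FIGURE7_STRUCTURES] + \
        [(k, t) for k, t in sd.MACAQUE_TABLE2_ROWS] + \
        [(k, t) for k, t in sd.HUMAN_TABLE1_ROWS]
    for key, tokens in cases:
        m = model_of(key)
        evs, chain = _events_for(m, tuple(tokens))
        const_len = len(m.constitutive_seq())
        read_len = len(spliced_sequence(m, chain))
        assert sum(e.delta_len for e in evs) == read_len - const_len, \
            (key, tokens)


def test_canonical_ids_stable_and_gene_scoped(model_of):
    m = model_of("KIR2DL04*001")
    a, _ = _events_for(m, ("skip:6",))
    b, _ = _events_for(m, ("skip:6",))
    assert a[0].canonical_id == b[0].canonical_id
    other = model_of("KIR2DL1*001")
    c, _ = _events_for(other, ("skip:6",))
    assert c[0].canonical_id != a[0].canonical_id  # same coords, other gene


def test_left_normalized_and_shifted_deletions_share_one_id(model_of):
    """Equivalent placements of one deletion in repeated sequence collapse to
    a single canonical id after aligner normalization."""
    from kirsplice.matcher import spliced_align
    m = model_of("KIR3DL2*001")
    chain = sd.isoform_chain(m, ("skip:6",))
    read = spliced_sequence(m, chain)
    asn = spliced_align("r", read, m)
    evs = call_events(asn.genome_blocks, m, asn.ambiguity)
    direct = classify(diff_chains(chain, m), m)
    assert [e.canonical_id for e in evs] == [e.canonical_id for e in direct]


def test_novel_junction_dinucleotides_recorded(model_of):
    m = model_of("KIR2DL1*001")
    evs, _ = _events_for(m, ("cryp78",))
    (don, acc), (don2, acc2) = evs[0].junction_dinucleotides
    assert don == "GT" and acc == "AG"      # exon6 donor .. cryptic acceptor
    assert don2 == "GT" and acc2 == "AG"    # cryptic donor .. exon7 acceptor


def test_events_table_mirrors_published_layout(model_of):
    m = model_of("KIR3DL20*001")
    evs, _ = _events_for(m, ("skipalt415",))
    df = events_table(evs)
    row = df.iloc[0]
    assert row["deletion_inclusion"] == "Deletion"
    assert row["size_bp"] == 415
    assert row["position"] == "Exon 4 and start exon 5"


@settings(max_examples=25, deadline=None)
@given(subset=st.sets(st.integers(min_value=4, max_value=8), max_size=3))
def test_arbitrary_skip_subsets_conserve_length(model_of, subset):
    m = model_of("KIR3DL01*001")
    tokens = tuple(f"skip:{k}" for k in sorted(subset))
    evs, chain = _events_for(m, tokens)
    const_len = len(m.constitutive_seq())
    read_len = len(spliced_sequence(m, chain))
    assert sum(e.delta_len for e in evs) == read_len - const_len
    assert sum(e.size_bp for e in evs) == const_len - read_len
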