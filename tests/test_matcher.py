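"""Read assignment: exact pass, spliced alignment, DP-oracle equivalence."""

import numpy as np
import pytest

from kirsplice import synthdata as sd
from kirsplice.genemodel import GeneModel, spliced_sequence
from kirsplice.matcher import (MatchParams, ReferenceIndexError, assign_cohort,
                               build_reference_index, exact_match,
                               reference_transcripts, spliced_align)

from dp_oracle import dp_spliced_blocks


def test_exact_match_identity_and_mismatch(human_models):
    refs = reference_transcripts(human_models)
    m = human_models[0]
    seq = m.constitutive_seq()
    asn = exact_match("r", seq, refs)
    assert asn is not None and asn.key == m.key and asn.pass_ == "exact"
    mutated = seq[:100] + ("A" if seq[100] != "A" else "C") + seq[101:]
    assert exact_match("r", mutated, refs) is None  # 0% mismatch rule


def test_exact_match_ambiguity_cap():
    refs = build_reference_index([("A*001", "ACGT" * 200),
                                  ("B*001", "ACGT" * 200)])
    assert exact_match("r", "ACGT" * 200, refs) is None  # ambiguity = 1
    with pytest.raises(ReferenceIndexError):
        build_reference_index([("A*001", "AC"), ("A*001", "GT")])


def test_exact_match_containment_needs_min_overlap():
    refs = build_reference_index([("A*001", "ACGTAGGCT" * 100)])
    probe = ("ACGTAGGCT" * 100)[:450]
    assert exact_match("r", probe, refs) is not None
    assert exact_match("r", probe[:399], refs) is None


def test_spliced_align_recovers_exon_skip_blocks(model_of):
    m = model_of("KIR3DL2*001")
    chain = sd.isoform_chain(m, ("skip:6",))
    read = spliced_sequence(m, chain)
    asn = spliced_align("r", read, m)
    assert asn is not None
    assert asn.genome_blocks == [tuple(b) for b in chain]
    assert asn.covered == len(read)
    assert asn.n_gaps == 1  # one novel junction spanning exon 6


def test_spliced_align_rejects_diverged_gene(toy_model):
    """A read must align to its own gene, not a 5%-diverged paralog."""
    rng = np.random.default_rng(0)
    g = list(toy_model.genome_seq)
    n_mut = int(0.05 * len(g))
    for p in rng.choice(len(g), size=n_mut, replace=False):
        g[p] = "ACGT"[("ACGT".index(g[p]) + 1) % 4]
    paralog = GeneModel(
        gene_id="TOYB", lineage="III", allele_id="001",
        genome_seq="".join(g), exons=list(toy_model.exons),
        domain_of_exon=dict(toy_model.domain_of_exon),
        attributes={"noncanonical": True},
        constitutive_skip=toy_model.constitutive_skip,
        exon_phases=dict(toy_model.exon_phases), cds_end=toy_model.cds_end)
    read = toy_model.constitutive_seq()
    own = spliced_align("r", read, toy_model)
    other = spliced_align("r", read, paralog)
    assert own is not None and own.covered == len(read)
    assert other is None  # mismatch-free coverage impossible at 5% divergence


def test_gap_cap_rejects_hyperfragmented_reads(toy_model):
    """More novel junctions than max_gaps allows -> no assignment."""
    exons = toy_model.exons
    # fabricate a chain with 12 small internal deletions spread over the exons
    chain = []
    for s, e in exons:
        if e - s >= 100:   # two cuts, keeping every block anchorable
            a, b = s + (e - s) // 3, s + 2 * (e - s) // 3
            chain += [(s, a - 2), (a + 2, b - 2), (b + 2, e)]
        elif e - s >= 50:  # one cut
            mid = (s + e) // 2
            chain += [(s, mid - 2), (mid + 2, e)]
        else:
            chain.append((s, e))
    read = spliced_sequence(toy_model, chain)
    params = MatchParams(max_gaps=10)
    assert spliced_align("r", read, toy_model, params) is None
    relaxed = MatchParams(max_gaps=40)
    assert spliced_align("r", read, toy_model, relaxed) is not None


def test_match_params_validation():
    with pytest.raises(ValueError):
        MatchParams(anchor_k=7)
    with pytest.raises(ValueError):
        MatchParams(max_gaps=-1)


def test_assign_cohort_two_pass_partition(human_models):
    refs = reference_transcripts(human_models)
    m = human_models[0]
    const = m.constitutive_seq()
    skip6 = spliced_sequence(m, sd.isoform_chain(m, ("skip:6",)))
    table, assignments, unassigned = assign_cohort(
        [("c1", const), ("c2", const), ("s1", skip6)], refs, human_models)
    assert set(table["read_id"]) == {"c1", "c2", "s1"}
    assert table.set_index("read_id")["pass"].to_dict() == \
        {"c1": "exact", "c2": "exact", "s1": "structural"}
    assert unassigned == []
    empty_table, _, _ = assign_cohort([], refs, human_models)
    assert len(empty_table) == 0


def test_allele_level_assignment_of_twin_alleles(model_of):
    """A 9A read lands on the 9A allele, not its 10A sibling."""
    a9 = model_of("KIR2DL4*001")
    a10 = model_of("KIR2DL4*002")
    refs = reference_transcripts([a9, a10])
    read = spliced_sequence(a9, sd.isoform_chain(a9, ("inc67",)))
    _, assignments, _ = assign_cohort([("r", read)], refs, [a9, a10])
    assert assignments["r"].key == a9.key


@pytest.mark.parametrize("tokens", [
    (), ("skip:6",), ("del30",), ("cryp30",), ("skip:6", "del30")])
def test_chain_equals_dp_alignment_oracle(toy_model, tokens):
    """On a <=3 kb model the anchor-and-chain result matches an affine-gap
    dynamic-programming alignment oracle exactly (after identical junction
    normalization)."""
    from kirsplice.matcher import _snap_junctions
    chain = sd.isoform_chain(toy_model, tokens)
    read = spliced_sequence(toy_model, chain)
    asn = spliced_align("r", read, toy_model)
    assert asn is not None
    oracle = dp_spliced_blocks(read, toy_model.genome_seq)
    exon_ends = {e for _, e in toy_model.exons}
    exon_starts = {s for s, _ in toy_model.exons}
    snapped, _ = _snap_junctions(oracle, toy_model.genome_seq,
                                 exon_ends, exon_starts)
    assert [(gs, ge) for _, _, gs, ge in snapped] == asn.genome_blocks
    assert asn.genome_blocks == [tuple(b) for b in chain]
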