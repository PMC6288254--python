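"""Two-pass read assignment.

Pass 1 (*exact*) matches each read against the known allele transcript
references: a unique reference that equals, contains or is contained in the
read with zero mismatches and sufficient overlap claims the read; zero or
multiple candidates leave it unassigned (the uniqueness rule stands in for a
mapper's mapping-quality/ambiguity filters, which have no analogue for exact
in-memory comparison).

Pass 2 (*structural*) aligns the leftover reads to the genomic gene models:
exact shared anchors of length >= ``anchor_k`` are found with a k-mer index,
merged into maximal exact blocks along each diagonal, and the highest-coverage
collinear subset is chained.  Block edges at genomic deletions are
left-normalized, then snapped onto annotated exon boundaries when the
junction's ambiguity interval allows it (repeated sequence at a junction makes
several placements of a deletion equivalent; the recorded ambiguity range
preserves the "X/Y bp" dual-size reporting convention).  A read is accepted if
it is covered with zero within-block mismatches and at most ``max_gaps`` novel
junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class MatchParams:
    max_gaps: int = 10
    min_overlap_exact: int = 400
    min_overlap_structural: int = 100
    max_mismatch_rate: float = 0.0
    anchor_k: int = 21
    min_overlap_fraction: float = 0.8

    def __post_init__(self):
        if self.anchor_k < 11:
            raise ValueError("anchor_k must be >= 11")
        if min(self.max_gaps, self.min_overlap_exact,
               self.min_overlap_structural) < 0:
            raise ValueError("thresholds must be positive")


@dataclass
class Assignment:
    read_id: str
    gene_id: str = ""
    allele_id: str = ""
    pass_: str = "unassigned"        # exact | structural | unassigned
    blocks: list = field(default_factory=list)   # [((rs, re), (gs, ge)), ...]
    n_gaps: int = 0
    covered: int = 0
    ambiguity: dict = field(default_factory=dict)  # junction index -> range
    note: str = ""

    @property
    def genome_blocks(self):
        return [g for _, g in self.blocks]

    @property
    def key(self):
        return f"{self.gene_id}*{self.allele_id}"


class ReferenceIndexError(ValueError):
    pass


def build_reference_index(references):
    """references: iterable of (id, sequence); duplicate ids are an error."""
    idx = {}
    for rid, seq in references:
        if rid in idx:
            raise ReferenceIndexError(f"duplicate reference id {rid!r}")
        idx[rid] = seq
    return idx


def exact_match(read_id, read_seq, references, params=None):
    """Unique zero-mismatch match against the reference transcripts, or None."""
    params = params or MatchParams()
    cands = []
    for rid, ref in references.items():
        if read_seq == ref:
            cands.append(rid)
        elif len(read_seq) >= params.min_overlap_exact and read_seq in ref:
            cands.append(rid)
        elif len(ref) >= params.min_overlap_exact and ref in read_seq:
            cands.append(rid)
    if len(cands) != 1:
        return None
    gene, _, allele = cands[0].partition("*")
    return Assignment(read_id, gene, allele, "exact",
                      blocks=[((0, len(read_seq)), (0, len(read_seq)))],
                      covered=len(read_seq))


# ---------------------------------------------------------------------------
# pass 2: anchor + chain spliced alignment
# ---------------------------------------------------------------------------

def build_kmer_index(seq, k):
    idx = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i:i + k], []).append(i)
    return idx


def _anchor_blocks(read, index, k):
    """Maximal exact match blocks (rs, re, gs, ge) from k-mer hits per diagonal."""
    by_diag = {}
    for i in range(len(read) - k + 1):
        for g in index.get(read[i:i + k], ()):
            by_diag.setdefault(g - i, []).append(i)
    blocks = []
    for diag, positions in by_diag.items():
        positions.sort()
        rs = prev = positions[0]
        for p in positions[1:]:
            if p == prev + 1:
                prev = p
            else:
                blocks.append((rs, prev + k, rs + diag, prev + k + diag))
                rs = prev = p
        blocks.append((rs, prev + k, rs + diag, prev + k + diag))
    blocks.sort()
    return blocks


def _chain(blocks):
    """Highest-read-coverage collinear chain (classic O(B^2) DP)."""
    n = len(blocks)
    if n == 0:
        return []
    score = [b[1] - b[0] for b in blocks]
    prev = [-1] * n
    for j in range(n):
        rs_j, re_j, gs_j, ge_j = blocks[j]
        for i in range(j):
            rs_i, re_i, gs_i, ge_i = blocks[i]
            if rs_i >= rs_j or re_i >= re_j:
                continue
            ov = max(0, re_i - rs_j)
            if gs_j + ov < ge_i or gs_j - rs_j == gs_i - rs_i:
                continue
            gain = re_j - max(re_i, rs_j)
            if gain <= 0:
                continue
            if score[i] + gain > score[j]:
                score[j] = score[i] + gain
                prev[j] = i
    best = max(range(n), key=lambda j: (score[j], -blocks[j][2]))
    chain = []
    j = best
    while j >= 0:
        chain.append(list(blocks[j]))
        j = prev[j]
    chain.reverse()
    # trim read overlaps: ambiguous bases go to the downstream block
    for i in range(len(chain) - 1):
        ov = chain[i][1] - chain[i + 1][0]
        if ov > 0:
            chain[i][1] -= ov
            chain[i][3] -= ov
    return [tuple(b) for b in chain]


def _snap_junctions(chain, genome, exon_ends, exon_starts):
    """Shift each junction within its sequence-ambiguity interval onto
    annotated exon boundaries when possible; otherwise left-normalize."""
    chain = [list(b) for b in chain]
    ambiguity = {}
    for ji in range(len(chain) - 1):
        left, right = chain[ji], chain[ji + 1]
        l, r = left[3], right[2]
        if left[1] != right[0]:
            continue  # read-side gap: not a pure genomic deletion
        # shifting the junction by s reassigns |s| read bases between the
        # flanking blocks; valid while the sequences on both sides agree
        max_left = left[1] - left[0]
        max_right = right[1] - right[0]
        a = 0
        while (a < max_left and r - a - 1 >= 0
               and genome[l - a - 1] == genome[r - a - 1]):
            a += 1
        b = 0
        while (b < max_right and l + b < len(genome)
               and genome[l + b] == genome[r + b]):
            b += 1
        ambiguity[ji] = a + b
        best = (4, -a)
        for s in range(-a, b + 1):
            left_hit = (l + s) in exon_ends
            right_hit = (r + s) in exon_starts
            if left_hit and right_hit:
                cat = 1
            elif left_hit:
                cat = 2
            elif right_hit:
                cat = 3
            else:
                continue
            if (cat, s) < best:
                best = (cat, s)
        s = best[1] if best[0] < 4 else -a
        left[1] += s
        left[3] += s
        right[0] += s
        right[2] += s
    merged = []
    for b in chain:
        if merged and merged[-1][1] == b[0] and merged[-1][3] == b[2]:
            merged[-1][1] = b[1]
            merged[-1][3] = b[3]
        else:
            merged.append(b)
    return [tuple(b) for b in merged], ambiguity


def normalize_chain(blocks, model):
    """Normalize a genome block chain exactly as the aligner does (snap
    ambiguous junctions onto annotated boundaries, else left-normalize).
    Returns (blocks, ambiguity map); canonical event ids are defined on
    normalized chains."""
    chain = []
    acc = 0
    for gs, ge in blocks:
        chain.append((acc, acc + (ge - gs), gs, ge))
        acc += ge - gs
    exon_ends = {e for _, e in model.exons}
    exon_starts = {s for s, _ in model.exons}
    snapped, ambiguity = _snap_junctions(chain, model.genome_seq,
                                         exon_ends, exon_starts)
    return [(gs, ge) for _, _, gs, ge in snapped], ambiguity


def spliced_align(read_id, read_seq, model, params=None, index=None):
    """Gap-tolerant exact spliced alignment of a read to one gene model."""
    params = params or MatchParams()
    genome = model.genome_seq
    if index is None:
        index = build_kmer_index(genome, params.anchor_k)
    blocks = _anchor_blocks(read_seq, index, params.anchor_k)
    chain = _chain(blocks)
    if not chain:
        return None
    exon_ends = {e for _, e in model.exons}
    exon_starts = {s for s, _ in model.exons}
    chain, ambiguity = _snap_junctions(chain, genome, exon_ends, exon_starts)
    for rs, re_, gs, ge in chain:
        if read_seq[rs:re_] != genome[gs:ge]:
            return None  # within-block mismatch: reject
    covered = sum(re_ - rs for rs, re_, _, _ in chain)
    if covered < params.min_overlap_structural:
        return None
    if covered / len(read_seq) < params.min_overlap_fraction:
        return None
    constitutive = model.constitutive_blocks()
    annotated = {(constitutive[i][1], constitutive[i + 1][0])
                 for i in range(len(constitutive) - 1)}
    n_gaps = 0
    for ji in range(len(chain) - 1):
        l, r = chain[ji][3], chain[ji + 1][2]
        if chain[ji][1] != chain[ji + 1][0]:
            n_gaps += 1  # read-side gap
        if (l, r) not in annotated:
            n_gaps += 1
    if n_gaps > params.max_gaps:
        return None
    return Assignment(
        read_id, model.gene_id, model.allele_id, "structural",
        blocks=[((rs, re_), (gs, ge)) for rs, re_, gs, ge in chain],
        n_gaps=n_gaps, covered=covered, ambiguity=ambiguity)


def assign_cohort(reads, references, models, params=None):
    """Two-pass assignment of a whole cohort.

    ``reads``: iterable of (read_id, sequence); ``references``: dict built by
    :func:`build_reference_index`; ``models``: list of GeneModel.  Returns
    (assignments table, {read_id: Assignment}, unassigned read-id list).
    """
    params = params or MatchParams()
    indexes = {m.key: build_kmer_index(m.genome_seq, params.anchor_k)
               for m in models}
    out = {}
    unassigned = []
    for read_id, seq in reads:
        asn = exact_match(read_id, seq, references, params)
        if asn is None:
            best, best_cov, tie = None, -1, False
            for m in models:
                cand = spliced_align(read_id, seq, m, params, indexes[m.key])
                if cand is None:
                    continue
                if cand.covered > best_cov:
                    best, best_cov, tie = cand, cand.covered, False
                elif cand.covered == best_cov:
                    tie = True
            if best is not None and not tie:
                asn = best
            elif tie:
                asn = Assignment(read_id, note="ambiguous")
        if asn is None:
            asn = Assignment(read_id)
        out[read_id] = asn
        if asn.pass_ == "unassigned":
            unassigned.append(read_id)
    table = pd.DataFrame([{
        "read_id": a.read_id, "gene": a.gene_id, "allele": a.allele_id,
        "pass": a.pass_, "n_gaps": a.n_gaps, "covered": a.covered,
        "blocks": ";".join(f"{gs}-{ge}" for _, (gs, ge) in a.blocks),
        "note": a.note,
    } for a in out.values()], columns=["read_id", "gene", "allele", "pass",
                                       "n_gaps", "covered", "blocks", "note"])
    return table, out, unassigned


def reference_transcripts(models):
    """Constitutive transcript references (id -> sequence) from gene models."""
    return build_reference_index(
        (m.key, m.constitutive_seq()) for m in models)
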