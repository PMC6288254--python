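"""Gene models for a KIR-like multigene receptor family, plus fixture construction.

A :class:`GeneModel` holds one allele's genomic sequence together with its ordered
exon intervals (0-based, half-open), a domain label per exon (leader peptide,
Ig-like domains D0/D1/D2, stem, transmembrane, cytoplasmic tail) and the splice
features annotated on it (alternative donors/acceptors, cryptic exons, retainable
introns).

Fixture models emulate the exon/intron architecture of human and rhesus macaque
KIR genes: nine exons, canonical GT..AG introns, and the printed exon sizes that
make the composite deletion sizes (594, 155, 209, 345, 415, 446, ...) come out
exactly.  Sequence content is synthetic: seeded-random background at ~40% GC with
splice motifs, branch points, polypyrimidine tracts and frame-control elements
stamped in.  Two construction rules make open-reading-frame consequences
deterministic for every seed:

* background sequence is generated *stop-free in all three frames*, so a stop
  codon exists only where the builder deliberately placed one;
* frameshift consequences are realised by "PTC traps" -- short stamped elements
  that read as ordinary codons in the designed frame but contain a termination
  codon in both shifted frames -- placed early in the cytoplasmic-tail exons.

The builder finally verifies every declared isoform's frame outcome with a direct
codon scan and re-samples the background (bounded, seed-derived attempts) if a
chance junction codon violated an expectation.
"""

from __future__ import annotations

import json
import urllib.parse
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# ---------------------------------------------------------------------------
# mechanisms
# ---------------------------------------------------------------------------

EXON_SKIP = "exon_skipping"
ALT3_DEL = "alt3ss_del"
ALT3_INC = "alt3ss_inc"
ALT5_DEL = "alt5ss_del"
ALT5_INC = "alt5ss_inc"
ALT_BOTH = "alt_both"
SKIP_PLUS_ALTSS = "skip_plus_altss"
CRYPTIC = "cryptic_exon"
INTRON_RETENTION = "intron_retention"

MECHANISMS = (
    EXON_SKIP, ALT3_DEL, ALT3_INC, ALT5_DEL, ALT5_INC,
    ALT_BOTH, SKIP_PLUS_ALTSS, CRYPTIC, INTRON_RETENTION,
)

DOMAINS = ("leader", "leader", "D0", "D1", "D2", "stem", "TM", "cyt", "cyt")

STOPS = ("TAA", "TAG", "TGA")

# dual-frame premature-termination trap: in the designed frame it reads
# ATA-AAT-AAA (Ile-Asn-Lys); in either shifted frame the first or second codon
# is TAA.
PTC_TRAP = "ATAAATAAA"

DONOR_CONSENSUS = "GTAAGT"
# frame-safe donor variant (no stop codon in any frame): used where the intron
# start can end up inside mature mRNA, and as the weakened KIR2DL4-like donor.
DONOR_FRAME_SAFE = "GTACGT"
ACCEPTOR_TAIL = "TTTCAG"          # PPT-flavoured acceptor, frame-safe
BRANCH_POINT = "CTCAC"            # fits YUNAY, frame-safe
PURINE_ELEMENT = "GGAAGGGAGGAAGGAAGGGAGGAAGGAGGGAAG"  # 33 bp, intron-2 element


class FixtureError(ValueError):
    """A fixture catalog entry could not be realised as a gene model."""


class GFF3ParseError(ValueError):
    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


# ---------------------------------------------------------------------------
# feature + catalog types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Feature:
    """One annotated splice feature of a fixture gene.

    ``anchor`` is a 1-based exon number (deletion mechanisms) or intron number
    (inclusion mechanisms; intron j lies between exons j and j+1).  ``length_bp``
    is the deleted/included length; for cross-exon ``alt_both`` it is the
    acceptor-side deletion and ``length2_bp`` the donor-side deletion on the
    anchor exon.  ``frame`` declares the expected ORF outcome of the
    single-feature isoform ("in", "stop" or None when allele context decides).
    """

    name: str
    mechanism: str
    anchor: int
    length_bp: int
    offset_bp: int | None = None
    length2_bp: int | None = None
    within: bool = False
    frame: str | None = None
    genome_start: int | None = None
    genome_end: int | None = None

    def resolved(self, exons):
        gs, ge = _feature_interval(exons, self)
        return replace(self, genome_start=gs, genome_end=ge)


@dataclass(frozen=True)
class AlleleEntry:
    """Catalog entry describing one fixture allele (one genomic haplotype)."""

    gene_id: str
    allele_id: str
    lineage: str
    exon_lengths: tuple
    intron_lengths: tuple
    features: tuple = ()
    attributes: dict = field(default_factory=dict)
    constitutive_skip: tuple = ()        # 1-based exons absent from mature mRNA
    orf_baseline_excludes: tuple = ()    # exons outside the designed ORF grid
    design_exon_lengths: tuple | None = None
    trap_exons: tuple = (8, 9)
    validated_isoforms: tuple = ()       # ((token, ...), "in"|"stop")

    @property
    def key(self):
        return f"{self.gene_id}*{self.allele_id}"


@dataclass
class FixtureCatalog:
    name: str
    entries: tuple

    def entry(self, key):
        for e in self.entries:
            if e.key == key:
                return e
        raise KeyError(key)


# ---------------------------------------------------------------------------
# gene model
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    gene_id: str
    lineage: str
    allele_id: str
    genome_seq: str
    exons: list                      # [(start, end), ...] 0-based half-open
    domain_of_exon: dict             # exon index (0-based) -> domain label
    attributes: dict = field(default_factory=dict)
    features: list = field(default_factory=list)
    constitutive_skip: tuple = ()    # 0-based exon indices
    exon_phases: dict = field(default_factory=dict)  # 0-based idx -> design phase
    cds_end: int | None = None       # genomic start of the designed stop codon

    def __post_init__(self):
        self.validate()

    @property
    def key(self):
        return f"{self.gene_id}*{self.allele_id}"

    @property
    def n_exons(self):
        return len(self.exons)

    @property
    def introns(self):
        return [(self.exons[i][1], self.exons[i + 1][0])
                for i in range(len(self.exons) - 1)]

    def constitutive_blocks(self):
        """Exon chain of the constitutive transcript (gDNA-skipped exons omitted)."""
        return [e for i, e in enumerate(self.exons) if i not in self.constitutive_skip]

    def constitutive_seq(self):
        return spliced_sequence(self, self.constitutive_blocks())

    def feature(self, name):
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"{self.key} has no feature {name!r}")

    def validate(self):
        L = len(self.genome_seq)
        if len(self.exons) < 2:
            raise FixtureError(f"{self.key}: at least 2 exons required")
        prev_end = 0
        for s, e in self.exons:
            if not (0 <= s < e <= L):
                raise FixtureError(f"{self.key}: exon [{s},{e}) outside sequence")
            if s < prev_end:
                raise FixtureError(f"{self.key}: exons overlap or are unsorted")
            prev_end = e
        if not self.attributes.get("noncanonical"):
            for i, (s, e) in enumerate(self.introns):
                if self.genome_seq[s:s + 2] != "GT" or self.genome_seq[e - 2:e] != "AG":
                    raise FixtureError(
                        f"{self.key}: intron {i + 1} lacks GT..AG boundaries")


def spliced_sequence(model, chain):
    """Concatenate genomic slices of a sorted, disjoint block chain."""
    seq = model.genome_seq
    prev_end = 0
    parts = []
    for s, e in chain:
        if not (0 <= s <= e <= len(seq)):
            raise ValueError(f"block [{s},{e}) out of range for {model.key}")
        if s < prev_end:
            raise ValueError(f"block [{s},{e}) overlaps previous block")
        parts.append(seq[s:e])
        prev_end = e
    return "".join(parts)


# ---------------------------------------------------------------------------
# chain edits (shared by the fixture builder and the read simulator)
# ---------------------------------------------------------------------------

def _exon_iv(exons, k):
    return exons[k - 1]


def _feature_interval(exons, f):
    """Genomic interval a feature deletes/includes (cross alt_both spans the intron)."""
    if f.mechanism == ALT3_DEL:
        s, _ = _exon_iv(exons, f.anchor)
        return s, s + f.length_bp
    if f.mechanism == ALT5_DEL:
        _, e = _exon_iv(exons, f.anchor)
        return e - f.length_bp, e
    if f.mechanism == ALT3_INC:
        nxt_s, _ = _exon_iv(exons, f.anchor + 1)
        return nxt_s - f.length_bp, nxt_s
    if f.mechanism == ALT5_INC:
        _, e = _exon_iv(exons, f.anchor)
        return e, e + f.length_bp
    if f.mechanism == CRYPTIC:
        _, e = _exon_iv(exons, f.anchor)
        return e + f.offset_bp, e + f.offset_bp + f.length_bp
    if f.mechanism == INTRON_RETENTION:
        _, e = _exon_iv(exons, f.anchor)
        nxt_s, _ = _exon_iv(exons, f.anchor + 1)
        return e, nxt_s
    if f.mechanism == ALT_BOTH:
        if f.within:
            s, _ = _exon_iv(exons, f.anchor)
            return s + f.offset_bp, s + f.offset_bp + f.length_bp
        _, e = _exon_iv(exons, f.anchor)
        nxt_s, _ = _exon_iv(exons, f.anchor + 1)
        return e - f.length2_bp, nxt_s + f.length_bp
    if f.mechanism == SKIP_PLUS_ALTSS:
        s, _ = _exon_iv(exons, f.anchor)
        nxt_s, _ = _exon_iv(exons, f.anchor + 1)
        return s, nxt_s + f.length_bp
    raise ValueError(f"unknown mechanism {f.mechanism!r}")


def edit_chain(exons, constitutive_skip, f):
    """Apply one splice feature to the constitutive exon chain; returns blocks.

    ``exons`` are the annotated (genomic) exon intervals, 1-based anchors.
    Raises FixtureError on edits producing empty or negative blocks.
    """
    chain = [(i + 1, list(iv)) for i, iv in enumerate(exons)
             if (i + 1) not in constitutive_skip]

    def block_of(k):
        for num, iv in chain:
            if num == k:
                return iv
        raise FixtureError(f"exon {k} not in constitutive chain")

    inserts = []  # (after_exon_number, (s, e))
    m = f.mechanism
    if m == EXON_SKIP:
        anchors = f.anchor if isinstance(f.anchor, tuple) else (f.anchor,)
        chain = [(num, iv) for num, iv in chain if num not in anchors]
    elif m == ALT3_DEL:
        iv = block_of(f.anchor)
        iv[0] += f.length_bp
    elif m == ALT5_DEL:
        iv = block_of(f.anchor)
        iv[1] -= f.length_bp
    elif m == ALT3_INC:
        iv = block_of(f.anchor + 1)
        iv[0] -= f.length_bp
    elif m == ALT5_INC:
        iv = block_of(f.anchor)
        iv[1] += f.length_bp
    elif m == CRYPTIC:
        gs, ge = _feature_interval(exons, f)
        inserts.append((f.anchor, (gs, ge)))
    elif m == INTRON_RETENTION:
        left = block_of(f.anchor)
        right = block_of(f.anchor + 1)
        left[1] = right[1]
        chain = [(num, iv) for num, iv in chain if num != f.anchor + 1]
    elif m == ALT_BOTH:
        if f.within:
            iv = block_of(f.anchor)
            s = iv[0] + f.offset_bp
            e = s + f.length_bp
            right = [e, iv[1]]
            iv[1] = s
            chain = [(num, v) for num, v in chain]
            idx = [i for i, (num, _) in enumerate(chain) if num == f.anchor][0]
            chain.insert(idx + 1, (f.anchor, right))
        else:
            block_of(f.anchor)[1] -= f.length2_bp
            block_of(f.anchor + 1)[0] += f.length_bp
    elif m == SKIP_PLUS_ALTSS:
        anchors = f.anchor if isinstance(f.anchor, tuple) else (f.anchor,)
        chain = [(num, iv) for num, iv in chain if num not in anchors]
        block_of(max(anchors) + 1)[0] += f.length_bp
    else:
        raise ValueError(f"unknown mechanism {m!r}")

    blocks = []
    for num, iv in chain:
        blocks.append(tuple(iv))
    for after, iv in inserts:
        pos = 0
        for i, (s, e) in enumerate(blocks):
            if e <= iv[0]:
                pos = i + 1
        blocks.insert(pos, iv)
    blocks.sort()
    merged = []
    for s, e in blocks:
        if e <= s:
            raise FixtureError(f"feature {f.name!r} produced an empty block")
        if merged and s < merged[-1][1]:
            raise FixtureError(f"feature {f.name!r} produced overlapping blocks")
        if merged and s == merged[-1][1]:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    if not merged:
        raise FixtureError(f"feature {f.name!r} produced an empty chain")
    return merged


def apply_features(exons, constitutive_skip, feats):
    """Apply several independent features; anchors must not collide on one block."""
    chain = None
    for f in feats:
        if chain is None:
            chain = edit_chain(exons, constitutive_skip, f)
        else:
            chain = _reapply(chain, exons, constitutive_skip, f)
    if chain is None:
        chain = [iv for i, iv in enumerate(exons) if (i + 1) not in constitutive_skip]
    return chain


def _reapply(chain, exons, constitutive_skip, f):
    """Apply a feature to an already-edited chain by genomic-interval surgery."""
    one = edit_chain(exons, constitutive_skip, f)
    base = [iv for i, iv in enumerate(exons) if (i + 1) not in constitutive_skip]
    # positions removed / added by this feature relative to the constitutive chain
    base_cov = _coverage(base)
    one_cov = _coverage(one)
    cur_cov = _coverage(chain)
    new_cov = (cur_cov - (base_cov - one_cov)) | (one_cov - base_cov)
    return _to_blocks(new_cov)


def _coverage(blocks):
    cov = set()
    for s, e in blocks:
        cov.update(range(s, e))
    return cov


def _to_blocks(cov):
    blocks = []
    for p in sorted(cov):
        if blocks and p == blocks[-1][1]:
            blocks[-1][1] = p + 1
        else:
            blocks.append([p, p + 1])
    return [tuple(b) for b in blocks]


# ---------------------------------------------------------------------------
# fixture construction
# ---------------------------------------------------------------------------

def _layout(entry):
    exons, introns = [], []
    pos = 0
    for i, el in enumerate(entry.exon_lengths):
        exons.append((pos, pos + el))
        pos += el
        if i < len(entry.intron_lengths):
            introns.append((pos, pos + entry.intron_lengths[i]))
            pos += entry.intron_lengths[i]
    return exons, introns, pos


def _design_phases(entry):
    """Reading-frame phase of each exon start on the designed ORF grid."""
    lens = entry.design_exon_lengths or entry.exon_lengths
    excl = set(entry.orf_baseline_excludes) | set(entry.constitutive_skip)
    phases = {}
    acc = 0
    for i, el in enumerate(lens):
        if (i + 1) in excl:
            continue
        phases[i] = acc % 3
        acc += el
    return phases, acc


def _stamp(template, stop_ok, pos, s, name, allow_stop=False):
    for i, ch in enumerate(s):
        p = pos + i
        if p < 0 or p >= len(template):
            raise FixtureError(f"stamp {name!r} outside sequence at {p}")
        if template[p] is not None and template[p] != ch:
            raise FixtureError(
                f"stamp collision for {name!r} at position {p} "
                f"({template[p]!r} vs {ch!r})")
        template[p] = ch
        if allow_stop:
            stop_ok[p] = True


def _mrna_offset(blocks, gpos):
    off = 0
    for s, e in blocks:
        if s <= gpos < e:
            return off + (gpos - s)
        off += e - s
    raise FixtureError(f"genomic position {gpos} not in chain")


_BASES = "ACGT"
_WEIGHTS = {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}


def _sample_background(rng, template, safe, stop_ok):
    """Fill free template positions, avoiding stop codons in every frame
    wherever all three triplet positions lie in the coding-safe zone."""
    L = len(template)
    seq = [None] * L

    def determined(p):
        if p < 0 or p >= L:
            return None
        if seq[p] is not None:
            return seq[p]
        return template[p]

    for i in range(L):
        if template[i] is not None:
            seq[i] = template[i]
            continue
        banned = set()
        for start in (i - 2, i - 1, i):
            ps = (start, start + 1, start + 2)
            if ps[0] < 0 or ps[2] >= L:
                continue
            if not all(safe[p] for p in ps):
                continue
            if any(stop_ok[p] for p in ps):
                continue
            trip = [determined(p) if p != i else None for p in ps]
            known = [b for b in trip if b is not None]
            if len(known) != 2:
                continue
            slot = trip.index(None)
            for b in _BASES:
                trip2 = list(trip)
                trip2[slot] = b
                if "".join(trip2) in STOPS:
                    banned.add(b)
        choices = [b for b in _BASES if b not in banned]
        if not choices:
            raise FixtureError("background sampling over-constrained")
        w = np.array([_WEIGHTS[b] for b in choices])
        seq[i] = choices[int(rng.choice(len(choices), p=w / w.sum()))]
    return "".join(seq)


def _spec_tokens_to_features(entry, exons, tokens):
    feats = []
    for tok in tokens:
        if tok.startswith("skip:"):
            anchors = tuple(int(x) for x in tok[5:].split(","))
            feats.append(Feature(tok, EXON_SKIP, anchors if len(anchors) > 1
                                 else anchors[0], sum(entry.exon_lengths[a - 1]
                                                      for a in anchors)))
        else:
            for f in entry.features:
                if f.name == tok:
                    feats.append(f)
                    break
            else:
                raise FixtureError(f"{entry.key}: unknown feature token {tok!r}")
    return feats


def _first_stop(mrna):
    for i in range(0, len(mrna) - 2, 3):
        if mrna[i:i + 3] in STOPS:
            return i
    return None


def _build_once(entry, rng):
    exons, introns, L = _layout(entry)
    phases, _ = _design_phases(entry)
    lens = entry.design_exon_lengths or entry.exon_lengths

    template = [None] * L
    safe = np.zeros(L, dtype=bool)
    stop_ok = np.zeros(L, dtype=bool)

    for s, e in exons:
        safe[s:e] = True
    insert_zones = []
    for f in entry.features:
        if f.mechanism in (ALT3_INC, ALT5_INC, CRYPTIC, INTRON_RETENTION):
            gs, ge = _feature_interval(exons, f)
            if f.mechanism != INTRON_RETENTION:
                js, je = introns[f.anchor - 1]
                if not (js <= gs and ge <= je):
                    raise FixtureError(
                        f"{entry.key}: feature {f.name!r} exceeds intron {f.anchor}")
            safe[gs:ge] = True
            insert_zones.append((gs, ge))
        elif f.mechanism in (ALT3_DEL, ALT5_DEL) or (f.mechanism == ALT_BOTH and f.within):
            gs, ge = _feature_interval(exons, f)
            es, ee = _exon_iv(exons, f.anchor)
            if not (es <= gs and ge <= ee):
                raise FixtureError(
                    f"{entry.key}: feature {f.name!r} exceeds exon {f.anchor}")

    # --- universal stamps -------------------------------------------------
    _stamp(template, stop_ok, exons[0][0], "ATG", "start codon")

    excl = set(entry.orf_baseline_excludes) | set(entry.constitutive_skip)
    acc = 0
    pre = {}
    for i, el in enumerate(lens):
        if (i + 1) not in excl:
            pre[i] = acc
            acc += el
    last = len(exons) - 1
    t9 = 48 + ((-pre[last] - 48) % 3)
    cds_end = exons[last][0] + t9
    _stamp(template, stop_ok, cds_end, "TAA", "terminal stop", allow_stop=True)

    for k in entry.trap_exons:
        idx = k - 1
        if idx not in pre:
            continue
        t = 3 + ((-pre[idx] - 3) % 3)
        _stamp(template, stop_ok, exons[idx][0] + t, PTC_TRAP,
               f"ptc trap exon {k}", allow_stop=True)

    weak_donor_introns = set(entry.attributes.get("weak_donor_introns", ()))
    for j, (s, e) in enumerate(introns):
        in_mrna = any(gs <= s < ge or s == gs for gs, ge in insert_zones) or \
            any(gs <= s and e <= ge for gs, ge in insert_zones)
        donor = DONOR_FRAME_SAFE if (in_mrna or (j + 1) in weak_donor_introns) \
            else DONOR_CONSENSUS
        _stamp(template, stop_ok, s, donor, f"donor intron {j + 1}",
               allow_stop=not in_mrna)
        _stamp(template, stop_ok, e - len(ACCEPTOR_TAIL), ACCEPTOR_TAIL,
               f"acceptor intron {j + 1}")
        _stamp(template, stop_ok, e - 30, BRANCH_POINT, f"bps intron {j + 1}")
        ppt = "".join("CT"[int(rng.integers(2))] for _ in range(14))
        _stamp(template, stop_ok, e - 20, ppt, f"ppt intron {j + 1}")

    for j in entry.attributes.get("interrupted_ppt_introns", ()):
        e = introns[j - 1][1]
        template[e - 15] = "A"
        template[e - 11] = "A"

    if entry.attributes.get("purine_element", False):
        _stamp(template, stop_ok, introns[1][0] + 80, PURINE_ELEMENT,
               "intron-2 purine element", allow_stop=True)

    run = entry.attributes.get("polyA_run")
    if run:
        _, e7 = _exon_iv(exons, 7)
        _stamp(template, stop_ok, e7 - run - 1, "C" + "A" * run, "polyA run")

    # --- feature stamps ---------------------------------------------------
    for f in entry.features:
        gs, ge = _feature_interval(exons, f)
        m = f.mechanism
        if m == ALT3_DEL:
            _stamp(template, stop_ok, gs + f.length_bp - 4, "CCAG", f.name)
        elif m == ALT5_DEL:
            _stamp(template, stop_ok, gs, "GTAC", f.name)
        elif m == ALT3_INC:
            _stamp(template, stop_ok, gs - 4, "CCAG", f.name)
        elif m == ALT5_INC:
            _stamp(template, stop_ok, ge, "GTAC", f.name)
        elif m == CRYPTIC:
            _stamp(template, stop_ok, gs - 4, "CCAG", f.name)
            _stamp(template, stop_ok, ge, "GTAC", f.name)
        elif m == ALT_BOTH and f.within:
            _stamp(template, stop_ok, gs, "GTAC", f.name)
            _stamp(template, stop_ok, ge - 4, "CCAG", f.name)
        elif m == ALT_BOTH:
            _stamp(template, stop_ok, gs, "GTAC", f.name)
            _stamp(template, stop_ok, ge - 4, "CCAG", f.name)
        # stamped in-frame stop for inclusions whose consequence is a PTC
        if f.frame == "stop" and m in (ALT3_INC, ALT5_INC, CRYPTIC):
            blocks = edit_chain(exons, entry.constitutive_skip, f)
            p = _mrna_offset(blocks, gs) % 3
            t = ((-p) % 3) + 6
            _stamp(template, stop_ok, gs + t, "TAA", f"{f.name} stop",
                   allow_stop=True)

    genome = _sample_background(rng, template, safe, stop_ok)

    model = GeneModel(
        gene_id=entry.gene_id,
        lineage=entry.lineage,
        allele_id=entry.allele_id,
        genome_seq=genome,
        exons=list(exons),
        domain_of_exon={i: DOMAINS[i] for i in range(len(exons))},
        attributes=dict(entry.attributes),
        features=[f.resolved(exons) for f in entry.features],
        constitutive_skip=tuple(k - 1 for k in entry.constitutive_skip),
        exon_phases=phases,
        cds_end=cds_end,
    )
    return model


def _validate_frames(entry, model):
    exons = model.exons
    checks = []
    for f in entry.features:
        if f.frame in ("in", "stop"):
            checks.append(((f.name,), f.frame))
    checks.extend(entry.validated_isoforms)
    for tokens, expect in checks:
        feats = _spec_tokens_to_features(entry, exons, tokens)
        blocks = apply_features(exons, entry.constitutive_skip, feats)
        mrna = spliced_sequence(model, blocks)
        stop = _first_stop(mrna)
        try:
            designed = _mrna_offset(blocks, model.cds_end)
        except FixtureError:
            designed = None
        if expect == "in":
            if stop is None or designed is None or stop != designed:
                return False
        else:  # "stop"
            if stop is None or (designed is not None and stop >= designed):
                return False
    return True


def build_fixture_model(entry, seed, max_attempts=64):
    """Construct a validated gene model; deterministic for a fixed seed."""
    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, _entry_tag(entry), attempt])
        model = _build_once(entry, rng)
        if _validate_frames(entry, model):
            model.attributes["build_attempt"] = attempt
            return model
    raise FixtureError(f"{entry.key}: no valid background in {max_attempts} attempts")


def _entry_tag(entry):
    import zlib
    return zlib.crc32(entry.key.encode()) & 0x7FFFFFFF


def build_catalog_models(catalog, seed):
    return [build_fixture_model(e, seed) for e in catalog.entries]


# ---------------------------------------------------------------------------
# GFF3 + FASTA round trip
# ---------------------------------------------------------------------------

_META_FIELDS = ("lineage", "attributes", "constitutive_skip", "exon_phases",
                "cds_end", "domain_of_exon")


def write_gene_models(models, gff3_path, fasta_path):
    """Write models as GFF3 (1-based inclusive) plus a genomic FASTA."""
    records = []
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            seqid = m.key
            meta = {
                "lineage": m.lineage,
                "attributes": m.attributes,
                "constitutive_skip": list(m.constitutive_skip),
                "exon_phases": {str(k): v for k, v in m.exon_phases.items()},
                "cds_end": m.cds_end,
                "domain_of_exon": {str(k): v for k, v in m.domain_of_exon.items()},
                "features": [
                    {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in f.__dict__.items()} for f in m.features],
            }
            blob = urllib.parse.quote(json.dumps(meta, sort_keys=True))
            fh.write(f"{seqid}\tkirsplice\tgene\t1\t{len(m.genome_seq)}\t.\t+\t.\t"
                     f"ID=gene:{seqid};kir_meta={blob}\n")
            fh.write(f"{seqid}\tkirsplice\tmRNA\t1\t{len(m.genome_seq)}\t.\t+\t.\t"
                     f"ID=mrna:{seqid};Parent=gene:{seqid}\n")
            for i, (s, e) in enumerate(m.exons):
                fh.write(f"{seqid}\tkirsplice\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                         f"ID=exon:{seqid}:{i + 1};Parent=mrna:{seqid}\n")
            records.append(SeqRecord(Seq(m.genome_seq), id=seqid, description=""))
    SeqIO.write(records, fasta_path, "fasta")


def read_gene_models(gff3_path, fasta_path):
    """Parse GFF3 + FASTA into gene models (inverse of :func:`write_gene_models`)."""
    import gffutils

    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise GFF3ParseError(gff3_path, lineno,
                                     "expected 9 tab-separated columns")

    db = gffutils.create_db(str(gff3_path), dbfn=":memory:",
                            merge_strategy="create_unique", keep_order=True)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}

    models = []
    for gene in db.features_of_type("gene"):
        seqid = gene.seqid
        if seqid not in seqs:
            raise ValueError(f"missing FASTA sequence for {seqid!r}")
        meta = json.loads(urllib.parse.unquote(gene.attributes["kir_meta"][0]))
        exons = sorted((f.start - 1, f.end) for f in db.children(
            db[f"mrna:{seqid}"], featuretype="exon"))
        for s, e in exons:
            if e > len(seqs[seqid]):
                raise ValueError(f"{seqid}: exon [{s},{e}) outside sequence bounds")
        gene_id, allele_id = seqid.split("*")
        feats = [Feature(**{k: (tuple(v) if isinstance(v, list) else v)
                            for k, v in d.items()})
                 for d in meta.pop("features")]
        models.append(GeneModel(
            gene_id=gene_id,
            lineage=meta["lineage"],
            allele_id=allele_id,
            genome_seq=seqs[seqid],
            exons=[tuple(iv) for iv in exons],
            domain_of_exon={int(k): v for k, v in meta["domain_of_exon"].items()},
            attributes=meta["attributes"],
            features=feats,
            constitutive_skip=tuple(meta["constitutive_skip"]),
            exon_phases={int(k): v for k, v in meta["exon_phases"].items()},
            cds_end=meta["cds_end"],
        ))
    models.sort(key=lambda m: m.key)
    return models


# ---------------------------------------------------------------------------
# catalog YAML round trip
# ---------------------------------------------------------------------------

def catalog_to_yaml(catalog, path):
    data = {"name": catalog.name, "entries": []}
    for e in catalog.entries:
        d = {k: v for k, v in e.__dict__.items()}
        d["features"] = [
            {k: v for k, v in f.__dict__.items()
             if v is not None and k not in ("genome_start", "genome_end")}
            for f in e.features]
        for k in ("exon_lengths", "intron_lengths", "constitutive_skip",
                  "orf_baseline_excludes", "trap_exons", "design_exon_lengths"):
            if d.get(k) is not None:
                d[k] = list(d[k])
        d["validated_isoforms"] = [[list(t), x] for t, x in e.validated_isoforms]
        data["entries"].append(d)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def catalog_from_yaml(path):
    with open(path) as fh:
        data = yaml.safe_load(fh)
    entries = []
    for d in data["entries"]:
        feats = tuple(Feature(**{**f, "anchor": tuple(f["anchor"])
                                 if isinstance(f["anchor"], list) else f["anchor"]})
                      for f in d.pop("features"))
        for k in ("exon_lengths", "intron_lengths", "constitutive_skip",
                  "orf_baseline_excludes", "trap_exons"):
            d[k] = tuple(d.get(k) or ())
        if d.get("design_exon_lengths") is not None:
            d["design_exon_lengths"] = tuple(d["design_exon_lengths"])
        d["validated_isoforms"] = tuple((tuple(t), x)
                                        for t, x in d.pop("validated_isoforms"))
        entries.append(AlleleEntry(features=feats, **d))
    return FixtureCatalog(name=data["name"], entries=tuple(entries))
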