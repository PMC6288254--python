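"""Classification of splice events from observed exon-block chains.

An aligned read is represented as an ordered chain of genomic blocks.  Diffing
that chain against the gene model's annotated exon chain yields raw edits
(missing exons, shifted exon boundaries, novel intronic blocks, retained
introns), which are then merged and classified into the standard alternative
splicing taxonomy:

* ``exon_skipping``       -- one or more consecutive exons absent
* ``alt3ss_del`` / ``alt5ss_del`` -- exon start/end shifted into the exon
* ``alt3ss_inc`` / ``alt5ss_inc`` -- exon extended contiguously into the intron
* ``alt_both``            -- paired alternative donor+acceptor deletion, either
  across two exons ("parts of exons i and i+1") or within one exon
* ``skip_plus_altss``     -- skipping merged with an adjacent boundary shift
* ``cryptic_exon``        -- novel block strictly inside an intron, spliced on
  both sides
* ``intron_retention``    -- a complete intron present in the mature transcript

The contiguity rule separates alternative-splice-site inclusions (the novel
sequence abuts the annotated exon) from cryptic exons (spliced gaps on both
sides).  Novel junctions are annotated with their donor/acceptor dinucleotides
but never filtered on GT/AG status.  Exons absent from the mature transcript at
the gDNA level (e.g. Mamu-KIR1D exon 3) are excluded from skipping calls via
the model's ``constitutive_skip`` attribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genemodel import (
    ALT3_DEL, ALT3_INC, ALT5_DEL, ALT5_INC, ALT_BOTH, CRYPTIC, EXON_SKIP,
    INTRON_RETENTION, SKIP_PLUS_ALTSS,
)


@dataclass(frozen=True)
class Edit:
    """One raw deviation between an observed chain and the annotated exons."""

    kind: str          # exon_absent | start_shift | end_shift | intron_block |
                       # intron_retained | unclassifiable
    exon: int = 0      # 1-based exon number (0 if n/a)
    intron: int = 0    # 1-based intron number (0 if n/a)
    amount: int = 0    # signed: + into exon (deletion), - into intron (inclusion)
    junction: int = -1  # index of the observed junction this edit belongs to
    interval: tuple = ()
    jcoords: tuple = ()  # (l, r) genomic coordinates of that junction


@dataclass
class SpliceEvent:
    gene_id: str
    mechanism: str
    exons: tuple = ()            # 1-based exon numbers involved
    introns: tuple = ()          # 1-based intron numbers involved
    genome_intervals: tuple = ()
    delta_len: int = 0           # mRNA length change vs constitutive (neg = deletion)
    junction_dinucleotides: tuple = ()
    canonical_id: str = ""
    ambiguity_range: int = 0
    detail: dict = field(default_factory=dict)

    @property
    def size_bp(self):
        return abs(self.delta_len)


def _exon_index(model, pos, side):
    """Locate ``pos`` relative to annotated exons.

    Returns ("end", k) / ("start", k) for exact boundary matches (k 1-based),
    ("exon", k) when strictly inside exon k, ("intron", j) when inside
    intron j (1-based), for the given junction side.
    """
    for i, (s, e) in enumerate(model.exons):
        k = i + 1
        if side == "left":
            if pos == e:
                return ("end", k)
            if s < pos < e:
                return ("exon", k)
        else:
            if pos == s:
                return ("start", k)
            if s < pos < e:
                return ("exon", k)
    for j, (s, e) in enumerate(model.introns):
        if s <= pos <= e:
            return ("intron", j + 1)
    return ("outside", 0)


def diff_chains(blocks, model):
    """Enumerate raw edits of an observed block chain against the gene model."""
    exons = model.exons
    edits = []

    retained = set()
    for j, (is_, ie) in enumerate(model.introns):
        if any(bs < is_ and be > ie for bs, be in blocks):
            retained.add(j + 1)
            edits.append(Edit("intron_retained", intron=j + 1,
                              amount=ie - is_, interval=(is_, ie)))

    # junction-attached edits
    junctions = [(blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1)]
    covered = []
    for k, (s, e) in enumerate(exons):
        covered.append(any(b[0] < e and b[1] > s for b in blocks))

    for ji, (l, r) in enumerate(junctions):
        lk = _exon_index(model, l, "left")
        rk = _exon_index(model, r, "right")
        if lk[0] == "exon":
            k = lk[1]
            edits.append(Edit("end_shift", exon=k, amount=exons[k - 1][1] - l,
                              junction=ji, interval=(l, exons[k - 1][1]),
                              jcoords=(l, r)))
        if rk[0] == "exon":
            k = rk[1]
            edits.append(Edit("start_shift", exon=k, amount=r - exons[k - 1][0],
                              junction=ji, interval=(exons[k - 1][0], r),
                              jcoords=(l, r)))
        for k, (s, e) in enumerate(exons):
            if l <= s and e <= r and not covered[k] \
                    and k not in model.constitutive_skip:
                edits.append(Edit("exon_absent", exon=k + 1, amount=e - s,
                                  junction=ji, interval=(s, e), jcoords=(l, r)))

    # block-attached edits: extensions into introns and novel intronic blocks
    for bs, be in blocks:
        over = [k for k, (s, e) in enumerate(exons) if bs < e and be > s]
        if not over:
            loc = _exon_index(model, bs, "left")
            if loc[0] == "intron" and be <= model.introns[loc[1] - 1][1]:
                edits.append(Edit("intron_block", intron=loc[1],
                                  amount=be - bs, interval=(bs, be)))
            else:
                edits.append(Edit("unclassifiable", interval=(bs, be)))
            continue
        f, g = over[0], over[-1]
        # upstream intron of exon index f is intron number f (1-based)
        if bs < exons[f][0] and f > 0 and f not in retained:
            edits.append(Edit("start_shift", exon=f + 1,
                              amount=-(exons[f][0] - bs),
                              interval=(bs, exons[f][0])))
        if be > exons[g][1] and g < len(exons) - 1 and (g + 1) not in retained:
            edits.append(Edit("end_shift", exon=g + 1,
                              amount=-(be - exons[g][1]),
                              interval=(exons[g][1], be)))
    return edits


def classify(edits, model):
    """Merge raw edits into classified splice events (one per mechanism site)."""
    seq = model.genome_seq
    exons = model.exons
    events = []

    def dinuc(l, r):
        return (seq[l:l + 2], seq[r - 2:r])

    for ed in edits:
        if ed.kind == "intron_retained":
            events.append(SpliceEvent(
                model.gene_id, INTRON_RETENTION, introns=(ed.intron,),
                exons=(ed.intron, ed.intron + 1),
                genome_intervals=(ed.interval,), delta_len=ed.amount))
        elif ed.kind == "intron_block":
            l, r = ed.interval
            events.append(SpliceEvent(
                model.gene_id, CRYPTIC, introns=(ed.intron,),
                genome_intervals=(ed.interval,), delta_len=ed.amount,
                junction_dinucleotides=(dinuc(exons[ed.intron - 1][1], l),
                                        dinuc(r, exons[ed.intron][0])),
                detail={"offset": l - model.introns[ed.intron - 1][0]}))
        elif ed.kind == "unclassifiable":
            events.append(SpliceEvent(
                model.gene_id, "unclassifiable",
                genome_intervals=(ed.interval,),
                delta_len=ed.interval[1] - ed.interval[0],
                detail={"note": "block overlaps no annotated exon or intron"}))

    # junction-grouped deletion-side edits
    by_junction = {}
    for ed in edits:
        if ed.junction >= 0 and ed.kind in ("exon_absent", "start_shift",
                                            "end_shift"):
            by_junction.setdefault(ed.junction, []).append(ed)

    for ji in sorted(by_junction):
        group = by_junction[ji]
        absent = sorted([e for e in group if e.kind == "exon_absent"],
                        key=lambda e: e.exon)
        ends = [e for e in group if e.kind == "end_shift" and e.amount > 0]
        starts = [e for e in group if e.kind == "start_shift" and e.amount > 0]
        x = ends[0].amount if ends else 0
        y = starts[0].amount if starts else 0
        skipped = tuple(e.exon for e in absent)
        ivs = tuple(e.interval for e in absent + ends + starts)
        if not ivs:
            continue  # constitutive junction
        jn = (dinuc(*group[0].jcoords),) if group[0].jcoords else ()
        if skipped:
            if x or y:
                mech = SKIP_PLUS_ALTSS
                delta = -(sum(e.amount for e in absent) + x + y)
                exs = skipped + tuple(e.exon for e in ends + starts)
            else:
                mech = EXON_SKIP
                delta = -sum(e.amount for e in absent)
                exs = skipped
            events.append(SpliceEvent(
                model.gene_id, mech, exons=tuple(sorted(set(exs))),
                genome_intervals=ivs, delta_len=delta,
                junction_dinucleotides=jn,
                detail={"alt_del": x + y} if (x or y) else {}))
        elif x and y:
            within = ends[0].exon == starts[0].exon
            if within:
                # internal deletion strictly inside one exon: the junction
                # coordinates bound the removed span directly
                l0 = ends[0].interval[0]
                r0 = starts[0].interval[1]
                es = model.exons[ends[0].exon - 1][0]
                events.append(SpliceEvent(
                    model.gene_id, ALT_BOTH, exons=(ends[0].exon,),
                    genome_intervals=((l0, r0),), delta_len=-(r0 - l0),
                    junction_dinucleotides=jn,
                    detail={"within": True, "offset": l0 - es}))
            else:
                events.append(SpliceEvent(
                    model.gene_id, ALT_BOTH,
                    exons=tuple(sorted({ends[0].exon, starts[0].exon})),
                    genome_intervals=ivs, delta_len=-(x + y),
                    junction_dinucleotides=jn,
                    detail={"within": False, "donor_side": x,
                            "acceptor_side": y}))
        elif x:
            events.append(SpliceEvent(
                model.gene_id, ALT5_DEL, exons=(ends[0].exon,),
                genome_intervals=ivs, delta_len=-x,
                junction_dinucleotides=jn))
        elif y:
            events.append(SpliceEvent(
                model.gene_id, ALT3_DEL, exons=(starts[0].exon,),
                genome_intervals=ivs, delta_len=-y,
                junction_dinucleotides=jn))

    # extensions (inclusions)
    for ed in edits:
        if ed.junction < 0 and ed.kind == "start_shift" and ed.amount < 0:
            l, r = ed.interval
            events.append(SpliceEvent(
                model.gene_id, ALT3_INC, exons=(ed.exon,),
                introns=(ed.exon - 1,),
                genome_intervals=(ed.interval,), delta_len=-ed.amount,
                junction_dinucleotides=(("", seq[l - 2:l]),)))
        elif ed.junction < 0 and ed.kind == "end_shift" and ed.amount < 0:
            l, r = ed.interval
            events.append(SpliceEvent(
                model.gene_id, ALT5_INC, exons=(ed.exon,), introns=(ed.exon,),
                genome_intervals=(ed.interval,), delta_len=-ed.amount,
                junction_dinucleotides=((seq[r:r + 2], ""),)))

    for ev in events:
        ev.canonical_id = canonical_name(ev, model)
    events.sort(key=lambda e: (e.genome_intervals or ((0, 0),))[0])
    return events


def canonical_name(event, model):
    """Stable textual id: a pure function of gene, mechanism and normalized
    exon/intron-relative coordinates (identical for every read showing the
    same event, regardless of alignment representation)."""
    g = model.gene_id
    m = event.mechanism
    if m == EXON_SKIP:
        label = "e" + "+".join(str(k) for k in event.exons)
    elif m == SKIP_PLUS_ALTSS:
        label = "e" + "+".join(str(k) for k in event.exons) + \
            f"@alt{event.detail.get('alt_del', 0)}"
    elif m in (ALT3_DEL, ALT5_DEL):
        label = f"e{event.exons[0]}"
    elif m == ALT_BOTH:
        d = event.detail
        if d.get("within"):
            label = f"e{event.exons[0]}@{d.get('offset', 0)}"
        else:
            label = ("e" + "-".join(str(k) for k in event.exons) +
                     f":{d.get('donor_side', 0)}/{d.get('acceptor_side', 0)}")
    elif m in (ALT3_INC, ALT5_INC):
        label = f"i{event.introns[0]}"
    elif m == CRYPTIC:
        label = f"i{event.introns[0]}@{event.detail.get('offset', 0)}"
    elif m == INTRON_RETENTION:
        label = f"i{event.introns[0]}"
    else:
        iv = event.genome_intervals[0] if event.genome_intervals else (0, 0)
        label = f"g{iv[0]}-{iv[1]}"
    return f"{g}:{m}:{label}:{event.delta_len:+d}"


def call_events(blocks, model, ambiguity=None):
    """diff + classify in one step; ``ambiguity`` maps junction index to the
    left/right shift range recorded by the aligner."""
    events = classify(diff_chains(blocks, model), model)
    if ambiguity:
        amb = max(ambiguity.values(), default=0)
        for ev in events:
            ev.ambiguity_range = amb
    return events


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

_POSITION_TEXT = {
    EXON_SKIP: lambda ev: "Exon" + ("s " if len(ev.exons) > 1 else " ") +
        _join_exons(ev.exons),
    ALT3_DEL: lambda ev: f"Start exon {ev.exons[0]}",
    ALT5_DEL: lambda ev: f"End exon {ev.exons[0]}",
    ALT3_INC: lambda ev: f"Following exon {ev.exons[0] - 1}",
    ALT5_INC: lambda ev: f"Following exon {ev.exons[0]}",
    CRYPTIC: lambda ev: f"Following exon {ev.introns[0]}",
    INTRON_RETENTION: lambda ev: f"Following exon {ev.introns[0]}",
    ALT_BOTH: lambda ev: (f"Within exon {ev.exons[0]}"
                          if ev.detail.get("within")
                          else "Parts exons " + _join_exons(ev.exons)),
    SKIP_PLUS_ALTSS: lambda ev: "Exon " + _join_exons(ev.exons[:-1]) +
        f" and start exon {ev.exons[-1]}",
}


def _join_exons(exs):
    exs = list(exs)
    if len(exs) == 1:
        return str(exs[0])
    if len(exs) == 2:
        return f"{exs[0]} and {exs[1]}"
    return ", ".join(str(x) for x in exs[:-1]) + f", and {exs[-1]}"


def events_table(events):
    """Tabulate events in the layout of the published event tables."""
    rows = []
    for ev in events:
        pos = _POSITION_TEXT.get(ev.mechanism, lambda e: "")(ev)
        rows.append({
            "canonical_id": ev.canonical_id,
            "gene": ev.gene_id,
            "mechanism": ev.mechanism,
            "deletion_inclusion": "Inclusion" if ev.delta_len > 0 else "Deletion",
            "size_bp": ev.size_bp,
            "position": pos,
            "delta_len": ev.delta_len,
            "ambiguity_range": ev.ambiguity_range,
        })
    return pd.DataFrame(rows, columns=[
        "canonical_id", "gene", "mechanism", "deletion_inclusion", "size_bp",
        "position", "delta_len", "ambiguity_range"])
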