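"""ORF consequence prediction for spliced isoforms.

Each isoform chain is translated codon-by-codon from the gene's annotated
initiator (the ATG opening exon 1).  Frame status is determined by phase
arithmetic: every exon carries its designed reading-frame phase, so comparing
an exon base's phase in the observed transcript with its designed phase yields
the local frameshift directly; the codon scan provides the stop codon itself.
A premature stop is classified as ``frameshift`` when the local shift at the
stop is non-zero and as ``direct_stop`` when novel in-frame sequence
introduced it.  Transcripts whose intermediate shifts cancel (e.g. the 9A
KIR2DL4 allele regaining its cytoplasmic tail through a +67 intron inclusion,
or Mamu-KIR1D recovering from its 7-bp-short exon 5 by skipping exon 7) are
labelled ``restored_orf``.

A nonsense-mediated-decay hint (stop more than 50 nt upstream of the last
exon-exon junction) is annotated but never removes a transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genemodel import STOPS, spliced_sequence


@dataclass
class OrfAnnotation:
    frame_status: str                 # in_frame | frameshift | direct_stop
    stop_location: tuple | None       # (region label, codon offset in region)
    segments_present: tuple = ()      # subset of domain labels, 5'->3'
    itim_retained: bool = False
    class_label: str = ""             # membrane_full | membrane_no_tail |
                                      # soluble_candidate |
                                      # truncated_extracellular | restored_orf
    inserted_residues: int = 0
    premature: bool = False
    nmd_hint: bool = False
    peptide_length: int = 0
    shifts_seen: tuple = ()
    note: str = ""
    detail: dict = field(default_factory=dict)


def brute_force_orf_oracle(sequence, start=0):
    """Direct scan for the first in-frame stop codon; returns
    (stop offset relative to ``start`` or None, peptide length in codons).
    Used as the independent verification path for translate_isoform."""
    for i in range(start, len(sequence) - 2, 3):
        if sequence[i:i + 3] in STOPS:
            return i - start, (i - start) // 3
    return None, (len(sequence) - start) // 3


def _constitutive_premature(model):
    """Whether the allele's own constitutive transcript carries a PTC
    (e.g. 9A KIR2DL4, Mamu-KIR1D with its 7-bp-short exon 5)."""
    cached = model.attributes.get("_constitutive_premature")
    if cached is not None:
        return cached
    blocks = model.constitutive_blocks()
    mrna = spliced_sequence(model, blocks)
    designed = 0
    for bs, be in blocks:
        if bs <= model.cds_end < be:
            designed += model.cds_end - bs
            break
        designed += be - bs
    stop, _ = brute_force_orf_oracle(mrna, 0)
    out = stop is None or stop != designed
    model.attributes["_constitutive_premature"] = out
    return out


def _provenance(model, chain):
    """Per-mRNA-base provenance: ('exon', idx0) or ('insert', label)."""
    prov = []
    exons = model.exons
    for bs, be in chain:
        for g in range(bs, be):
            hit = None
            for i, (s, e) in enumerate(exons):
                if s <= g < e:
                    hit = ("exon", i, g)
                    break
            if hit is None:
                j = next((j for j, (s, e) in enumerate(model.introns)
                          if s <= g < e), -1)
                hit = ("insert", f"i{j + 1}", g)
            prov.append(hit)
    return prov


def translate_isoform(model, chain):
    """Annotate the ORF of the isoform defined by ``chain`` on ``model``."""
    mrna = spliced_sequence(model, chain)
    prov = _provenance(model, chain)
    init = model.exons[0][0]
    mstart = next((i for i, p in enumerate(prov) if p[2] == init), None)
    if mstart is None or not mrna[mstart:mstart + 3] == "ATG":
        return OrfAnnotation(
            frame_status="frameshift", stop_location=None, premature=True,
            class_label="truncated_extracellular",
            note="no annotated initiator in chain")

    stop_off, pep_len = brute_force_orf_oracle(mrna, mstart)
    stop_m = None if stop_off is None else mstart + stop_off

    designed_m = next((i for i, p in enumerate(prov)
                       if p[2] == model.cds_end), None)

    def shift_at(mpos):
        kind, ref, g = prov[mpos]
        if kind == "exon" and ref in model.exon_phases:
            f_base = (model.exon_phases[ref] + (g - model.exons[ref][0])) % 3
            return ((mpos - mstart) % 3 - f_base) % 3
        return None

    end_scan = stop_m if stop_m is not None else len(mrna)

    # shift trajectory: one sample per block, at its first phased exon base
    shifts = []
    acc = 0
    for bs, be in chain:
        for mpos in range(max(acc, mstart), min(acc + (be - bs), end_scan)):
            s = shift_at(mpos)
            if s is not None:
                shifts.append(s)
                break
        acc += be - bs
    final_shift = None
    for mpos in range(end_scan - 1, mstart - 1, -1):
        s = shift_at(mpos)
        if s is not None:
            final_shift = s
            break

    premature = not (stop_m is not None and stop_m == designed_m
                     and (final_shift in (0, None)))
    if not premature:
        frame_status = "in_frame"
    else:
        s_at_stop = shift_at(stop_m) if stop_m is not None else final_shift
        if s_at_stop is None:
            # stop inside novel sequence: frameshift iff upstream shift != 0
            up = None
            if stop_m is not None:
                for mpos in range(stop_m - 1, mstart - 1, -1):
                    up = shift_at(mpos)
                    if up is not None:
                        break
            frame_status = "frameshift" if up not in (0, None) else "direct_stop"
        else:
            frame_status = "frameshift" if s_at_stop != 0 else "direct_stop"

    # domain segments contributed by in-frame exon bases upstream of the stop
    segments = []
    for mpos in range(mstart, end_scan):
        kind, ref, g = prov[mpos]
        if kind == "exon" and shift_at(mpos) == 0:
            dom = model.domain_of_exon.get(ref)
            if dom and (not segments or segments[-1] != dom):
                if dom not in segments:
                    segments.append(dom)

    inserted = sum(1 for mpos in range(mstart, end_scan)
                   if prov[mpos][0] == "insert") // 3

    # stop location label
    stop_location = None
    if stop_m is not None:
        kind, ref, g = prov[stop_m]
        label = f"exon{ref + 1}" if kind == "exon" else str(ref)
        stop_location = (label, (stop_m - mstart) // 3)

    # NMD hint: premature stop >50 nt upstream of the last junction
    junction_offsets = []
    acc = 0
    for bs, be in chain[:-1]:
        acc += be - bs
        junction_offsets.append(acc)
    nmd = bool(premature and stop_m is not None and junction_offsets
               and junction_offsets[-1] - stop_m > 50)

    tm_present = "TM" in segments
    constitutive = model.constitutive_blocks()
    is_constitutive = [tuple(b) for b in chain] == [tuple(b) for b in constitutive]
    restored = not premature and not is_constitutive and (
        any(s != 0 for s in shifts) or _constitutive_premature(model))
    if not premature:
        if not tm_present:
            label = "soluble_candidate"
        elif restored:
            label = "restored_orf"
        else:
            label = "membrane_full"
    else:
        if tm_present:
            label = "membrane_no_tail"
        elif any(d in segments for d in ("D0", "D1", "D2")):
            label = "soluble_candidate"
        else:
            label = "truncated_extracellular"

    itim = bool(model.attributes.get("itim_count", 0)) and not premature \
        and "cyt" in segments

    return OrfAnnotation(
        frame_status=frame_status,
        stop_location=stop_location,
        segments_present=tuple(segments),
        itim_retained=itim,
        class_label=label,
        inserted_residues=inserted,
        premature=premature,
        nmd_hint=nmd,
        peptide_length=pep_len,
        shifts_seen=tuple(shifts),
    )


# ---------------------------------------------------------------------------
# consequence phrases (assembled the way the event tables word them)
# ---------------------------------------------------------------------------

_DOMAIN_TEXT = {"D0": "D0 domain", "D1": "D1 domain", "D2": "D2 domain",
                "stem": "stem region", "TM": "TM region",
                "cyt": "cytoplasmic tail"}


def consequence_label(annotation, model, has_events=True):
    """Deterministic phrase assembly for the consequence column."""
    if not has_events and not annotation.premature:
        return "constitutive"
    expected = [model.domain_of_exon[i] for i in range(model.n_exons)
                if i not in model.constitutive_skip]
    expected = list(dict.fromkeys(d for d in expected if d != "leader"))
    missing = [d for d in expected if d not in annotation.segments_present]
    parts = []
    if missing:
        parts.append("Missing " + _join([_DOMAIN_TEXT[d] for d in missing]))
    if annotation.premature:
        if annotation.frame_status == "frameshift":
            parts.append("Out-frame; stopcodon introduced")
        else:
            parts.append("Stopcodon introduced")
        if "TM" in missing and annotation.class_label in (
                "soluble_candidate", "truncated_extracellular"):
            parts.append("possible soluble receptor")
    else:
        if annotation.class_label == "restored_orf":
            parts.append("frameshift restored ORF")
        else:
            parts.append("In-frame")
        if annotation.inserted_residues:
            parts.append(f"{annotation.inserted_residues} additional AAs")
        if "TM" in missing:
            parts.append("possible soluble receptor")
    return "; ".join(parts)


def _join(items):
    if len(items) == 1:
        return items[0]
    if len(items) == 2:
        return f"{items[0]} and {items[1]}"
    return ", ".join(items[:-1]) + f", and {items[-1]}"


def annotate_read(model, chain, has_events=True):
    ann = translate_isoform(model, chain)
    return ann, consequence_label(ann, model, has_events=has_events)
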