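"""Built-in fixture catalogs.

Exon sizes follow the sizes that can be read off the published event tables for
human and rhesus macaque KIR genes: exon4 = 300, exon5 = 294, exon6 = 51,
KIR2DL4 exon7 = 104/105 (9A/10A alleles), KIR3DL2- and Mamu-KIR2DL04-like
exon7 = 104, macaque lineage-II exon7 = 101, KIR2DL4/2DL04 exon8 = 53.  Leader
and untranslated exon sizes (exon1 = 34, exon2 = 36, exon3 = 300, exon9 = 300)
are fixture choices.  Mamu-KIR1D carries the gDNA-level quirks of the real gene:
a 5-bp deletion in exon 3 (constitutively skipped, explained by the missing
33-bp purine element in intron 2), a 7-bp deletion in exon 5, and the enlarged
introns 5/6 (~3290/4330 bp).  Mamu-KIR3DL20 has a shortened intron 3.

Introns default to 600 bp, which keeps the fixtures desk-scale while preserving
the paper-stated relative intron lengths (macaque lineage-II introns 5/6 of
~2000/914 bp, 3DL20 intron 3 shorter by ~500 bp).
"""

from __future__ import annotations

from .genemodel import (
    ALT3_DEL, ALT3_INC, ALT5_DEL, ALT5_INC, ALT_BOTH, CRYPTIC,
    INTRON_RETENTION, SKIP_PLUS_ALTSS,
    AlleleEntry, Feature, FixtureCatalog,
)

_E = {"e1": 34, "e2": 36, "e3": 300, "e4": 300, "e5": 294,
      "e6": 51, "e8": 53, "e9": 300}


def _exons(e7, e3=None, e5=None, e8=None):
    return (_E["e1"], _E["e2"], e3 or _E["e3"], _E["e4"], e5 or _E["e5"],
            _E["e6"], e7, e8 or _E["e8"], _E["e9"])


def _introns(**over):
    iv = [600] * 8
    for k, v in over.items():
        iv[int(k[1:]) - 1] = v
    return tuple(iv)


def human_catalog():
    """Fixture genes carrying every splice event of the human event table."""
    entries = (
        AlleleEntry(
            gene_id="KIR2DL1", allele_id="001", lineage="III",
            exon_lengths=_exons(e7=105), intron_lengths=_introns(),
            features=(
                Feature("cryp57", CRYPTIC, 5, 57, offset_bp=250, frame="stop"),
                Feature("cryp78", CRYPTIC, 6, 78, offset_bp=250, frame="in"),
                Feature("inc49", ALT3_INC, 7, 49, frame="stop"),
            ),
            attributes={"itim_count": 2, "purine_element": False},
            validated_isoforms=((("skip:6",), "in"),),
        ),
        AlleleEntry(
            gene_id="KIR2DL3", allele_id="001", lineage="III",
            exon_lengths=_exons(e7=105), intron_lengths=_introns(),
            features=(
                Feature("del150", ALT3_DEL, 5, 150, frame="in"),
                Feature("both294", ALT_BOTH, 4, 150, length2_bp=144, frame="in"),
            ),
            attributes={"itim_count": 2, "purine_element": False},
            validated_isoforms=((("skip:5",), "in"), (("skip:6",), "in")),
        ),
        AlleleEntry(
            gene_id="KIR2DL4", allele_id="001", lineage="I",
            exon_lengths=_exons(e7=104), design_exon_lengths=_exons(e7=105),
            intron_lengths=_introns(),
            features=(
                # in-frame deletions in D0; on this 9A allele every isoform that
                # retains full exon 7 still terminates after exon 7, so their
                # frame outcome is validated in combination below.
                Feature("del66", ALT5_DEL, 3, 66),
                Feature("del198", ALT5_DEL, 3, 198),
                Feature("del73", ALT5_DEL, 7, 73, frame="stop"),
                Feature("inc67", ALT5_INC, 7, 67),
            ),
            attributes={"itim_count": 1, "purine_element": True, "polyA_run": 9,
                        "weak_donor_introns": (7,),
                        "interrupted_ppt_introns": (6,)},
            validated_isoforms=(
                ((), "stop"),
                (("inc67",), "in"),
                (("skip:7",), "in"),
                (("skip:6",), "stop"),
                (("del66",), "stop"),
                (("del66", "inc67"), "in"),
                (("del198", "skip:7"), "in"),
            ),
        ),
        AlleleEntry(
            gene_id="KIR2DL4", allele_id="002", lineage="I",
            exon_lengths=_exons(e7=105), intron_lengths=_introns(),
            features=(
                Feature("del74", ALT5_DEL, 7, 74, frame="stop"),
                Feature("inc67", ALT5_INC, 7, 67),
            ),
            attributes={"itim_count": 1, "purine_element": True, "polyA_run": 10,
                        "weak_donor_introns": (7,),
                        "interrupted_ppt_introns": (6,)},
            validated_isoforms=(
                ((), "in"),
                (("inc67",), "stop"),
                (("skip:7",), "in"),
                (("skip:6,7,8",), "stop"),
                (("skip:7,8",), "stop"),
            ),
        ),
        AlleleEntry(
            gene_id="KIR3DL1", allele_id="001", lineage="II",
            exon_lengths=_exons(e7=104), intron_lengths=_introns(),
            features=(
                Feature("inc170", ALT3_INC, 5, 170, frame="stop"),
            ),
            attributes={"itim_count": 2, "purine_element": True},
            validated_isoforms=((("skip:4,5",), "in"), (("skip:5",), "in")),
        ),
        AlleleEntry(
            gene_id="KIR3DL2", allele_id="001", lineage="II",
            exon_lengths=_exons(e7=104), intron_lengths=_introns(),
            features=(
                Feature("inc129", ALT5_INC, 4, 129, frame="stop"),
            ),
            attributes={"itim_count": 2, "purine_element": True,
                        "weak_donor_introns": (7,),
                        "interrupted_ppt_introns": (6,)},
            validated_isoforms=((("skip:6,7",), "stop"), (("skip:6",), "in")),
        ),
    )
    return FixtureCatalog(name="human", entries=entries)


def macaque_catalog():
    """Fixture genes carrying every splice event of the macaque event table."""
    linII = {"e5": 2000, "e6": 914}
    entries = (
        AlleleEntry(
            gene_id="KIR1D", allele_id="002", lineage="III",
            exon_lengths=_exons(e7=104, e3=295, e5=287),
            intron_lengths=_introns(e5=3290, e6=4330),
            constitutive_skip=(3,),
            orf_baseline_excludes=(3, 5),
            trap_exons=(7, 8, 9),
            features=(
                # the 36-bp alternative acceptor is frame-neutral; single-event
                # validation is done in combination since the constitutive KIR1D
                # transcript (7-bp-short exon 5) is itself PTC-bearing.
                Feature("del36", ALT3_DEL, 4, 36),
                Feature("del119", ALT3_DEL, 5, 119, frame="in"),
                Feature("del149", ALT3_DEL, 5, 149, frame="in"),
                Feature("del115", ALT3_DEL, 5, 115, frame="stop"),
                Feature("del82", ALT3_DEL, 5, 82, frame="stop"),
                Feature("cryp47", CRYPTIC, 6, 47, offset_bp=1426, frame="stop"),
                Feature("inc58", ALT5_INC, 6, 58, frame="stop"),
                Feature("inc62", ALT3_INC, 6, 62, frame="stop"),
            ),
            attributes={"itim_count": 2, "purine_element": False},
            validated_isoforms=(
                ((), "stop"),
                (("skip:5",), "in"),
                (("skip:7",), "in"),
                (("skip:5,6",), "in"),
                (("skip:5,6,7",), "stop"),
                (("skip:5", "del36"), "in"),
                (("del119", "del36"), "in"),
            ),
        ),
        AlleleEntry(
            gene_id="KIR2DL04", allele_id="001", lineage="I",
            exon_lengths=_exons(e7=104), intron_lengths=_introns(e8=98),
            features=(
                Feature("del27", ALT3_DEL, 5, 27, frame="in"),
                Feature("inc109x7", ALT3_INC, 7, 109, frame="stop"),
                Feature("inc147x7", ALT3_INC, 7, 147, frame="stop"),
                Feature("inc245x7", ALT3_INC, 7, 245, frame="stop"),
                Feature("inc109x3", ALT5_INC, 3, 109, frame="stop"),
                Feature("cryp147", CRYPTIC, 5, 147, offset_bp=250, frame="stop"),
                Feature("ret8", INTRON_RETENTION, 8, 98, frame="stop"),
            ),
            attributes={"itim_count": 1, "purine_element": True},
            validated_isoforms=(
                ((), "in"),
                (("skip:6",), "in"),
                (("skip:8",), "stop"),
                (("skip:6,7",), "stop"),
            ),
        ),
        AlleleEntry(
            gene_id="KIR2DL04", allele_id="002", lineage="I",
            exon_lengths=_exons(e7=104), intron_lengths=_introns(e8=99),
            features=(
                Feature("ret8", INTRON_RETENTION, 8, 99, frame="in"),
            ),
            attributes={"itim_count": 1, "purine_element": True},
            validated_isoforms=(((), "in"),),
        ),
        AlleleEntry(
            gene_id="KIR3DL01", allele_id="001", lineage="II",
            exon_lengths=_exons(e7=101), intron_lengths=_introns(**linII),
            features=(
                Feature("del36", ALT3_DEL, 4, 36, frame="in"),
                Feature("cryp88", CRYPTIC, 5, 88, offset_bp=250, frame="stop"),
            ),
            attributes={"itim_count": 2, "purine_element": True},
            validated_isoforms=(
                ((), "in"),
                (("skip:5",), "in"),
                (("skip:5,6,7",), "stop"),
                (("skip:6",), "in"),
            ),
        ),
        AlleleEntry(
            gene_id="KIR3DL02", allele_id="001", lineage="II",
            exon_lengths=_exons(e7=101), intron_lengths=_introns(**linII),
            features=(
                Feature("del216", ALT3_DEL, 4, 216, frame="in"),
                Feature("del150e5", ALT3_DEL, 5, 150, frame="in"),
                Feature("del198e3", ALT5_DEL, 3, 198, frame="in"),
            ),
            attributes={"itim_count": 2, "purine_element": True},
            validated_isoforms=(((), "in"), (("skip:5",), "in")),
        ),
        AlleleEntry(
            gene_id="KIR3DL05", allele_id="001", lineage="II",
            exon_lengths=_exons(e7=101), intron_lengths=_introns(**linII),
            features=(
                Feature("del267", ALT3_DEL, 4, 267, frame="in"),
            ),
            attributes={"itim_count": 2, "purine_element": True},
            validated_isoforms=(((), "in"), (("skip:5",), "in")),
        ),
        AlleleEntry(
            gene_id="KIR3DL07", allele_id="001", lineage="II",
            exon_lengths=_exons(e7=101), intron_lengths=_introns(**linII),
            features=(
                Feature("del176", ALT3_DEL, 5, 176, frame="stop"),
                Feature("cryp47", CRYPTIC, 6, 47, offset_bp=250, frame="stop"),
            ),
            attributes={"itim_count": 2, "purine_element": True},
            validated_isoforms=(((), "in"),),
        ),
        AlleleEntry(
            gene_id="KIR3DL08", allele_id="001", lineage="II",
            exon_lengths=_exons(e7=101), intron_lengths=_introns(**linII),
            features=(
                Feature("both141", ALT_BOTH, 4, 141, offset_bp=80, within=True,
                        frame="in"),
            ),
            attributes={"itim_count": 2, "purine_element": True},
            validated_isoforms=(((), "in"),),
        ),
        AlleleEntry(
            gene_id="KIR3DS02", allele_id="001", lineage="II",
            exon_lengths=_exons(e7=101), intron_lengths=_introns(**linII),
            features=(
                Feature("both81", ALT_BOTH, 4, 81, offset_bp=60, within=True,
                        frame="in"),
                Feature("both107", ALT_BOTH, 4, 107, offset_bp=160, within=True,
                        frame="stop"),
            ),
            attributes={"itim_count": 0, "activating_residue": True,
                        "purine_element": True},
            validated_isoforms=(((), "in"),),
        ),
        AlleleEntry(
            gene_id="KIR3DS05", allele_id="001", lineage="II",
            exon_lengths=_exons(e7=101), intron_lengths=_introns(**linII),
            features=(
                Feature("both414", ALT_BOTH, 3, 264, length2_bp=150, frame="in"),
            ),
            attributes={"itim_count": 0, "activating_residue": True,
                        "purine_element": True},
            validated_isoforms=(((), "in"),),
        ),
        AlleleEntry(
            gene_id="KIR3DL20", allele_id="001", lineage="V",
            exon_lengths=_exons(e7=101), intron_lengths=_introns(e3=100),
            features=(
                Feature("del115", ALT3_DEL, 5, 115, frame="stop"),
                Feature("del209", ALT5_DEL, 4, 209, frame="stop"),
                Feature("both324", ALT_BOTH, 4, 115, length2_bp=209, frame="in"),
                Feature("skipalt415", SKIP_PLUS_ALTSS, 4, 115, frame="stop"),
            ),
            attributes={"itim_count": 2, "purine_element": True,
                        "intron3_shortened": True},
            validated_isoforms=(
                ((), "in"),
                (("skip:4",), "in"),
                (("skip:4,5",), "in"),
                (("skip:5,6",), "in"),
                (("skip:4,5,6",), "in"),
                (("both324",), "in"),
            ),
        ),
    )
    return FixtureCatalog(name="macaque", entries=entries)


CATALOGS = {"human": human_catalog, "macaque": macaque_catalog}
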