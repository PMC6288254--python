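"""Synthetic cohorts of full-length KIR transcript reads with a truth table.

The generator emulates the study design behind the real data: families of
individuals, each contributing error-free full-length amplicon reads (the
stand-in for circular-consensus sequencing of tagged, pooled amplicons;
individual identity travels in the read header instead of a barcode).  Each
configured isoform is a gene model plus a list of splice-event specs; read
counts per isoform are fixed integers from the config so cohort-level
confirmation counts are exact.  Optional substitution-error and truncation
rates exist for robustness experiments and default to zero.

The built-in cohort builders realise the published event repertoires:

* :func:`human_table1_cohort` injects every human event row at >=2 individuals
  with >=3 supporting reads plus sub-threshold decoy events,
* :func:`macaque_table2_cohort` does the same for the macaque rows,
* :func:`kir1d_figure7_cohort` realises the nineteen distinct Mamu-KIR1D
  isoform structures, fifteen of which are given to a single individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import events as ev
from .genemodel import Feature, apply_features, spliced_sequence
from .matcher import normalize_chain


@dataclass(frozen=True)
class EventSpec:
    """One splice event to inject, resolvable against a gene model.

    ``token`` is either a feature name annotated on the model ("inc67", ...),
    a skip spec ("skip:6" / "skip:6,7,8"), or a retention spec ("retain:8").
    """

    token: str

    def to_feature(self, model):
        if self.token.startswith("skip:"):
            anchors = tuple(int(x) for x in self.token[5:].split(","))
            length = sum(model.exons[a - 1][1] - model.exons[a - 1][0]
                         for a in anchors)
            return Feature(self.token, "exon_skipping",
                           anchors if len(anchors) > 1 else anchors[0], length)
        if self.token.startswith("retain:"):
            j = int(self.token[7:])
            s, e = model.introns[j - 1]
            return Feature(self.token, "intron_retention", j, e - s)
        return model.feature(self.token)


@dataclass(frozen=True)
class IsoformSpec:
    individual: str
    allele_key: str               # "GENE*ALLELE"
    event_tokens: tuple           # () = constitutive
    read_count: int

    def __post_init__(self):
        if self.read_count < 0:
            raise ValueError("read_count must be >= 0")


@dataclass
class CohortConfig:
    name: str
    individuals: list                     # [(id, father|None, mother|None)]
    genotypes: dict                       # individual -> tuple of allele keys
    isoforms: list                        # [IsoformSpec, ...]
    error_rate: float = 0.0
    truncate_frac: float = 0.0
    seed: int = 0

    def validate(self, models_by_key):
        ped = {i[0] for i in self.individuals}
        for iso in self.isoforms:
            if iso.individual not in ped:
                raise ValueError(f"unknown individual {iso.individual!r}")
            if iso.allele_key not in models_by_key:
                raise ValueError(f"unknown gene/allele {iso.allele_key!r}")
        for ind, parents in ((i[0], i[1:]) for i in self.individuals):
            for p in parents:
                if p is not None and p not in ped:
                    raise ValueError(f"unknown parent {p!r} of {ind!r}")


@dataclass(frozen=True)
class SimRead:
    read_id: str
    individual: str
    seq: str


def apply_event(model, spec):
    """Block chain of the isoform carrying one event spec."""
    return apply_features(model.exons,
                          tuple(k + 1 for k in model.constitutive_skip),
                          [spec.to_feature(model)])


def isoform_chain(model, tokens):
    feats = [EventSpec(t).to_feature(model) for t in tokens]
    return apply_features(model.exons,
                          tuple(k + 1 for k in model.constitutive_skip), feats)


def simulate_cohort(config, models):
    """Generate reads and the per-read truth table.

    Returns (reads: [SimRead], truth: DataFrame).  Truth rows list the source
    allele, the injected event tokens and the canonical ids of the events the
    true chain realises (the latter computed by classifying the true chain
    against its own model).  Deterministic under ``config.seed``.
    """
    by_key = {m.key: m for m in models}
    config.validate(by_key)
    rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
    reads, rows = [], []
    for iso_idx, iso in enumerate(config.isoforms):
        model = by_key[iso.allele_key]
        chain = isoform_chain(model, iso.event_tokens)
        seq = spliced_sequence(model, chain)
        # canonical ids are defined on normalized chains (same convention as
        # the aligner), so ambiguous junction placements collapse to one id
        norm, _ = normalize_chain(chain, model)
        evs = ev.classify(ev.diff_chains(norm, model), model)
        ids = ",".join(e.canonical_id for e in evs)
        for i in range(iso.read_count):
            out = seq
            if config.truncate_frac > 0 and rng.random() < config.truncate_frac:
                keep = int(len(seq) * (0.5 + 0.4 * rng.random()))
                out = out[:keep]
            if config.error_rate > 0:
                arr = list(out)
                n_err = rng.binomial(len(arr), config.error_rate)
                for p in rng.choice(len(arr), size=n_err, replace=False):
                    arr[p] = "ACGT"[(("ACGT".index(arr[p])) +
                                     int(rng.integers(1, 4))) % 4]
                out = "".join(arr)
            rid = f"{iso.individual}|iso{iso_idx}|r{i}"
            reads.append(SimRead(rid, iso.individual, out))
            rows.append({
                "read_id": rid, "individual": iso.individual,
                "gene": model.gene_id, "allele": model.allele_id,
                "event_tokens": ",".join(iso.event_tokens),
                "event_ids": ids, "n_events": len(evs),
            })
    truth = pd.DataFrame(rows, columns=["read_id", "individual", "gene",
                                        "allele", "event_tokens", "event_ids",
                                        "n_events"])
    return reads, truth


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_reads(reads, fasta_path=None, fastq_path=None, quality=40):
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.read_id,
                        description=f"individual={r.individual}")
        rec.letter_annotations["phred_quality"] = [quality] * len(r.seq)
        records.append(rec)
    if fasta_path is not None:
        SeqIO.write(records, fasta_path, "fasta")
    if fastq_path is not None:
        SeqIO.write(records, fastq_path, "fastq")


def read_reads(path, fmt=None):
    fmt = fmt or ("fastq" if str(path).endswith(("fq", "fastq")) else "fasta")
    out = []
    for rec in SeqIO.parse(str(path), fmt):
        ind = rec.id.split("|")[0]
        for part in rec.description.split():
            if part.startswith("individual="):
                ind = part.split("=", 1)[1]
        out.append(SimRead(rec.id, ind, str(rec.seq)))
    return out


def write_truth(truth, path):
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path):
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       dtype={"event_tokens": str, "event_ids": str})


def config_to_yaml(config, path):
    data = {
        "name": config.name,
        "individuals": [list(i) for i in config.individuals],
        "genotypes": {k: list(v) for k, v in config.genotypes.items()},
        "isoforms": [[i.individual, i.allele_key, list(i.event_tokens),
                      i.read_count] for i in config.isoforms],
        "error_rate": config.error_rate,
        "truncate_frac": config.truncate_frac,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def config_from_yaml(path):
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return CohortConfig(
        name=d["name"],
        individuals=[tuple(i) for i in d["individuals"]],
        genotypes={k: tuple(v) for k, v in d["genotypes"].items()},
        isoforms=[IsoformSpec(a, b, tuple(c), n) for a, b, c, n in d["isoforms"]],
        error_rate=d.get("error_rate", 0.0),
        truncate_frac=d.get("truncate_frac", 0.0),
        seed=d.get("seed", 0),
    )


# ---------------------------------------------------------------------------
# built-in cohorts
# ---------------------------------------------------------------------------

HUMAN_TABLE1_ROWS = (
    ("KIR2DL3*001", ("skip:5",)),          # deletion 294, exon 5
    ("KIR2DL1*001", ("skip:6",)),          # deletion 51, exon 6
    ("KIR2DL4*001", ("skip:7",)),          # deletion 104, exon 7 (9A allele)
    ("KIR3DL1*001", ("skip:4,5",)),        # deletion 594
    ("KIR3DL2*001", ("skip:6,7",)),        # deletion 155
    ("KIR2DL4*002", ("skip:7,8",)),        # deletion 158 (10A allele)
    ("KIR2DL4*002", ("skip:6,7,8",)),      # deletion 209
    ("KIR2DL3*001", ("del150",)),          # alt 3'ss, start exon 5
    ("KIR3DL1*001", ("inc170",)),          # alt 3'ss, +170 after exon 5
    ("KIR2DL1*001", ("inc49",)),           # alt 3'ss, +49 after exon 7
    ("KIR2DL4*001", ("del66",)),           # alt 5'ss, end exon 3
    ("KIR2DL4*001", ("del198", "skip:7")),  # 198 only with a TM deletion
    ("KIR3DL2*001", ("inc129",)),          # alt 5'ss, +129 after exon 4
    ("KIR2DL4*001", ("del73",)),           # alt 5'ss, end exon 7
    ("KIR2DL4*001", ("inc67",)),           # alt 5'ss, +67 after exon 7
    ("KIR2DL3*001", ("both294",)),         # alt 3'+5' ss, parts exons 4/5
    ("KIR2DL1*001", ("cryp57",)),          # cryptic exon, intron 5
    ("KIR2DL1*001", ("cryp78",)),          # cryptic exon, intron 6
)

HUMAN_DECOYS = (
    ("KIR2DL3*001", ("skip:6",)),
    ("KIR3DL1*001", ("skip:5",)),
    ("KIR2DL4*002", ("skip:6",)),
)

MACAQUE_TABLE2_ROWS = (
    ("KIR3DL20*001", ("skip:4",)),
    ("KIR3DL01*001", ("skip:5",)),
    ("KIR2DL04*001", ("skip:6",)),
    ("KIR2DL04*001", ("skip:8",)),
    ("KIR3DL20*001", ("skip:4,5",)),
    ("KIR3DL01*001", ("skip:5,6,7",)),
    ("KIR2DL04*001", ("skip:6,7",)),
    ("KIR3DL01*001", ("del36",)),
    ("KIR3DL02*001", ("del216",)),
    ("KIR3DL05*001", ("del267",)),
    ("KIR2DL04*001", ("del27",)),
    ("KIR3DL20*001", ("del115",)),
    ("KIR3DL02*001", ("del150e5",)),
    ("KIR3DL07*001", ("del176",)),
    ("KIR2DL04*001", ("inc109x7",)),
    ("KIR2DL04*001", ("inc147x7",)),
    ("KIR2DL04*001", ("inc245x7",)),
    ("KIR3DL02*001", ("del198e3",)),
    ("KIR2DL04*001", ("inc109x3",)),
    ("KIR3DS02*001", ("both81",)),
    ("KIR3DS02*001", ("both107",)),
    ("KIR3DL08*001", ("both141",)),
    ("KIR3DS05*001", ("both414",)),
    ("KIR3DL20*001", ("both324",)),
    ("KIR3DL20*001", ("skipalt415",)),
    ("KIR3DL01*001", ("cryp88",)),
    ("KIR2DL04*001", ("cryp147",)),
    ("KIR3DL07*001", ("cryp47",)),
    ("KIR2DL04*001", ("ret8",)),
)

MACAQUE_DECOYS = (
    ("KIR3DL01*001", ("skip:6",)),
    ("KIR3DL02*001", ("skip:5",)),
    ("KIR3DL05*001", ("skip:5",)),
)

KIR1D_FIGURE7_STRUCTURES = (
    (),                                  # 1: full exon 5 (constitutive chain)
    ("del36",),                          # 2
    ("skip:7",),                         # 3: ORF-restoring exon-7 skip
    ("cryp47",),                         # 4
    ("inc58",),                          # 5
    ("inc62",),                          # 6
    ("del119",),                         # 7
    ("del149",),                         # 8
    ("del149", "del36"),                 # 9
    ("del115",),                         # 10
    ("del115", "del36"),                 # 11
    ("del82",),                          # 12
    ("del82", "del36"),                  # 13
    ("skip:5",),                         # 14
    ("skip:5", "del36"),                 # 15
    ("skip:5", "inc58"),                 # 16
    ("skip:5,6", "cryp47"),              # 17
    ("skip:5,6,7",),                     # 18
    ("skip:7", "del36"),                 # 19
)


def _family(prefix, n_children, founders=("1", "2")):
    inds = [(f"{prefix}{f}", None, None) for f in founders]
    for c in range(n_children):
        inds.append((f"{prefix}{c + 3}", f"{prefix}{founders[0]}",
                     f"{prefix}{founders[1]}"))
    return inds


def _event_cohort(name, rows, decoys, allele_keys, individuals,
                  reads_per_carrier=2, n_carriers=2, constitutive_reads=2,
                  seed=0):
    ids = [i[0] for i in individuals]
    isoforms = []
    for ind in ids:
        for key in allele_keys:
            isoforms.append(IsoformSpec(ind, key, (), constitutive_reads))
    for i, (key, tokens) in enumerate(rows):
        for c in range(n_carriers):
            ind = ids[(i + c) % len(ids)]
            isoforms.append(IsoformSpec(ind, key, tokens, reads_per_carrier))
    for i, (key, tokens) in enumerate(decoys):
        isoforms.append(IsoformSpec(ids[i % len(ids)], key, tokens, 2))
    return CohortConfig(
        name=name, individuals=individuals,
        genotypes={i: tuple(allele_keys) for i in ids},
        isoforms=isoforms, seed=seed)


def human_table1_cohort(seed=0):
    """Every human event row at 2 individuals x 2 reads, plus decoy singletons."""
    keys = sorted({k for k, _ in HUMAN_TABLE1_ROWS} | {k for k, _ in HUMAN_DECOYS})
    return _event_cohort("human_table1", HUMAN_TABLE1_ROWS, HUMAN_DECOYS,
                         keys, _family("H", 4), seed=seed)


def macaque_table2_cohort(seed=0):
    keys = sorted({k for k, _ in MACAQUE_TABLE2_ROWS} |
                  {k for k, _ in MACAQUE_DECOYS})
    inds = _family("M", 4) + _family("N", 2)
    return _event_cohort("macaque_table2", MACAQUE_TABLE2_ROWS, MACAQUE_DECOYS,
                         keys, inds, seed=seed)


def kir1d_figure7_cohort(seed=0):
    """Nineteen distinct Mamu-KIR1D structures; individual F1 carries fifteen
    of them at 3 reads each (its constitutive structure is among the fifteen
    and further supported only below threshold elsewhere)."""
    key = "KIR1D*002"
    individuals = _family("F", 2)
    isoforms = []
    for tokens in KIR1D_FIGURE7_STRUCTURES[:15]:
        isoforms.append(IsoformSpec("F1", key, tuple(tokens), 3))
    for tokens in KIR1D_FIGURE7_STRUCTURES[15:]:
        isoforms.append(IsoformSpec("F2", key, tuple(tokens), 3))
    # below-threshold sharing so pedigree/confirmation code has mixed support
    isoforms.append(IsoformSpec("F2", key, (), 2))
    isoforms.append(IsoformSpec("F3", key, ("skip:7",), 2))
    isoforms.append(IsoformSpec("F4", key, ("del36",), 2))
    return CohortConfig(
        name="kir1d_figure7", individuals=individuals,
        genotypes={i[0]: (key,) for i in individuals},
        isoforms=isoforms, seed=seed)


COHORTS = {
    "human_table1": (human_table1_cohort, "human"),
    "macaque_table2": (macaque_table2_cohort, "macaque"),
    "kir1d_figure7": (kir1d_figure7_cohort, "macaque"),
}
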