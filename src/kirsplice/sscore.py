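"""Trainable splice-signal strength scoring.

Position-weight-matrix (log-odds) models for donor and acceptor windows, with
a 0-100 consensus value for comparability, plus branch-point (YUNAY) and
polypyrimidine-tract metrics.  Window conventions follow the classical
cis-element definitions: the 5' splice-site window spans 3 exonic + 6 intronic
nucleotides; the 3' splice-site region spans the last 20 intronic + first 3
exonic nucleotides (acceptor AG plus polypyrimidine tract).

Scores are comparative only: they rank related sites (e.g. a weakened
KIR2DL4-like exon-7 donor below the lineage-III consensus donor) and carry no
absolute threshold for whether a splice event occurs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DONOR = "donor"
ACCEPTOR_SITE = "acceptor_site"
ACCEPTOR_REGION = "acceptor_region"

WIDTHS = {DONOR: 9, ACCEPTOR_SITE: 23, ACCEPTOR_REGION: 23}
_BASES = "ACGT"
_PY = set("CT")


@dataclass(frozen=True)
class SiteWindow:
    kind: str
    sequence: str

    def __post_init__(self):
        if self.kind not in WIDTHS:
            raise ValueError(f"unknown window kind {self.kind!r}")
        if len(self.sequence) != WIDTHS[self.kind]:
            raise ValueError(
                f"{self.kind} window must be {WIDTHS[self.kind]} nt, "
                f"got {len(self.sequence)}")

    @property
    def canonical(self):
        """GT after the donor's 3 exonic bases / AG before the acceptor's
        3 exonic bases."""
        if self.kind == DONOR:
            return self.sequence[3:5] == "GT"
        return self.sequence[18:20] == "AG"


@dataclass
class MatrixModel:
    kind: str
    weights: np.ndarray          # (width, 4) log-odds
    background: dict
    score_range: tuple
    low_information: bool = False
    n_training: int = 0

    @property
    def width(self):
        return self.weights.shape[0]

    def to_json(self, path):
        data = {"kind": self.kind, "weights": self.weights.tolist(),
                "background": self.background,
                "score_range": list(self.score_range),
                "low_information": self.low_information,
                "n_training": self.n_training}
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["kind"], np.array(d["weights"]), d["background"],
                   tuple(d["score_range"]), d["low_information"],
                   d["n_training"])


def train_matrix(windows, pseudocount=1.0, background=None):
    """Position-specific log-odds model from aligned site windows (>=10)."""
    windows = list(windows)
    if len(windows) < 10:
        raise ValueError("need at least 10 training windows")
    kinds = {w.kind for w in windows}
    widths = {len(w.sequence) for w in windows}
    if len(kinds) != 1 or len(widths) != 1:
        raise ValueError("training windows must share kind and width")
    kind = kinds.pop()
    width = widths.pop()
    bg = background or {b: 0.25 for b in _BASES}
    counts = np.full((width, 4), float(pseudocount))
    for w in windows:
        for i, ch in enumerate(w.sequence):
            counts[i, _BASES.index(ch)] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    weights = np.log2(freqs / np.array([bg[b] for b in _BASES]))
    score_range = (float(weights.min(axis=1).sum()),
                   float(weights.max(axis=1).sum()))
    info = float((freqs * np.log2(freqs / 0.25)).sum())
    return MatrixModel(kind, weights, dict(bg), score_range,
                       low_information=info < 1.0, n_training=len(windows))


def score_window(model, window):
    """Raw log-odds score and 0-100 consensus value."""
    if len(window.sequence) != model.width:
        raise ValueError(f"window width {len(window.sequence)} does not match "
                         f"model width {model.width}")
    raw = float(sum(model.weights[i, _BASES.index(ch)]
                    for i, ch in enumerate(window.sequence)))
    lo, hi = model.score_range
    cv = 100.0 * (raw - lo) / (hi - lo) if hi > lo else 100.0
    return raw, min(100.0, max(0.0, cv))


# ---------------------------------------------------------------------------
# branch point and polypyrimidine tract
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchPointHit:
    position: int        # offset of the motif start relative to the acceptor
    motif: str
    score: int           # matched positions out of 5 (YUNAY)


def _yunay_matches(s):
    pat = [(lambda c: c in _PY), (lambda c: c == "T"), (lambda c: True),
           (lambda c: c == "A"), (lambda c: c in _PY)]
    return sum(1 for f, c in zip(pat, s) if f(c))


def find_branch_point(upstream, window=(-50, -15)):
    """Best YUNAY match in the window upstream of an acceptor.

    ``upstream`` is the intron sequence ending at the acceptor (its last base
    is position -1).  Ties are broken toward the acceptor; None when no motif
    matches at >=4/5 positions.
    """
    lo, hi = window
    n = len(upstream)
    if n < -lo:
        raise ValueError("upstream sequence shorter than search window")
    best = None
    for pos in range(lo, hi - 4):
        s = upstream[n + pos:n + pos + 5]
        if len(s) < 5:
            continue
        m = _yunay_matches(s)
        if m >= 4 and (best is None or m > best.score
                       or (m == best.score and pos > best.position)):
            best = BranchPointHit(pos, s, m)
    return best


def ppt_metrics(upstream, window=(-20, -5)):
    """(pyrimidine fraction, longest pyrimidine run, purine interruptions)
    over the window; interruptions are purines strictly inside the
    pyrimidine-bounded span."""
    n = len(upstream)
    lo, hi = window
    seg = upstream[n + lo:n + hi]
    if not seg:
        return 0.0, 0, 0
    frac = sum(1 for c in seg if c in _PY) / len(seg)
    longest = run = 0
    for c in seg:
        run = run + 1 if c in _PY else 0
        longest = max(longest, run)
    py_pos = [i for i, c in enumerate(seg) if c in _PY]
    if len(py_pos) < 2:
        inter = 0
    else:
        inter = sum(1 for i in range(py_pos[0], py_pos[-1] + 1)
                    if seg[i] not in _PY)
    return frac, longest, inter


def compare_sites(model, sites):
    """Rank >=2 same-kind windows by score; returns a report table."""
    sites = list(sites)
    if len(sites) >= 2 and len({w.kind for _, w in sites}) != 1:
        raise ValueError("mixed window kinds in comparison")
    rows = []
    for name, w in sites:
        raw, cv = score_window(model, w)
        rows.append({"site": name, "raw_score": raw, "consensus_value": cv,
                     "canonical": w.canonical})
    df = pd.DataFrame(rows).sort_values(
        "raw_score", ascending=False).reset_index(drop=True)
    df["rank"] = df.index + 1
    df["delta_vs_top"] = df["raw_score"] - df["raw_score"].iloc[0]
    return df


# ---------------------------------------------------------------------------
# window extraction from gene models
# ---------------------------------------------------------------------------

def donor_window(model, intron):
    """3 exonic + 6 intronic nt at the start of intron ``intron`` (1-based)."""
    s, _ = model.introns[intron - 1]
    return SiteWindow(DONOR, model.genome_seq[s - 3:s + 6])


def acceptor_window(model, intron, kind=ACCEPTOR_REGION):
    """20 intronic + 3 exonic nt at the end of intron ``intron``."""
    _, e = model.introns[intron - 1]
    return SiteWindow(kind, model.genome_seq[e - 20:e + 3])


def acceptor_upstream(model, intron, length=60):
    _, e = model.introns[intron - 1]
    return model.genome_seq[e - length:e]


def collect_training_windows(models, kind=DONOR):
    """All constitutive splice-site windows across fixture models."""
    out = []
    for m in models:
        skip = set(m.constitutive_skip)
        for j in range(1, m.n_exons):
            # intron j is constitutively spliced unless it borders a
            # gDNA-skipped exon
            if (j - 1) in skip or j in skip:
                continue
            out.append(donor_window(m, j) if kind == DONOR
                       else acceptor_window(m, j, kind))
    return out


def site_windows_to_fasta(sites, path):
    with open(path, "w") as fh:
        for name, w in sites:
            fh.write(f">{name} kind={w.kind}\n{w.sequence}\n")


def site_windows_from_fasta(path, kind):
    from Bio import SeqIO
    return [(rec.id, SiteWindow(kind, str(rec.seq)))
            for rec in SeqIO.parse(str(path), "fasta")]
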