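"""Independent affine-gap dynamic-programming spliced-alignment oracle.

Globally aligns a read against a genome allowing exact matches and genomic
deletions only (score = matched bases - gap_open per deletion; leading and
trailing genomic sequence are free).  This is the brute-force counterpart of
the anchor-and-chain aligner and is only suitable for small (<= ~3 kb) models.
"""

import numpy as np

NEG = -(10 ** 9)


def dp_spliced_blocks(read, genome, gap_open=30):
    """Optimal block chain [(rs, re, gs, ge), ...] for an error-free read."""
    n, m = len(read), len(genome)
    g = np.frombuffer(genome.encode(), dtype=np.uint8)
    M = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    D = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    from_gap = np.zeros((n + 1, m + 1), dtype=bool)
    d_arg = np.zeros((n + 1, m + 1), dtype=np.int32)
    M[0, :] = 0
    for i in range(1, n + 1):
        rb = ord(read[i - 1])
        match = g == rb
        prevM = M[i - 1, :-1]
        prevD = D[i - 1, :-1]
        take_gap = prevD > prevM
        best_prev = np.where(take_gap, prevD, prevM)
        M[i, 1:] = np.where(match, best_prev + 1, NEG)
        from_gap[i, 1:] = take_gap & match
        # D[i, j] = max_{j' <= j} M[i, j'] - gap_open, with argmax tracking
        run = np.maximum.accumulate(M[i, :])
        idx = np.arange(m + 1, dtype=np.int32)
        d_arg[i, :] = np.maximum.accumulate(
            np.where(M[i, :] >= run, idx, 0).astype(np.int32))
        D[i, :] = run - gap_open
    j = int(np.argmax(M[n, :]))
    if M[n, j] <= NEG // 2:
        return []
    blocks = []
    i = n
    re_, ge = i, j
    while i > 0:
        if from_gap[i, j]:
            blocks.append((i - 1, re_, j - 1, ge))
            j = int(d_arg[i - 1, j - 1])
            i -= 1
            re_, ge = i, j
        else:
            i -= 1
            j -= 1
    if re_ > 0:
        blocks.append((0, re_, j, ge))
    blocks.reverse()
    return [(rs, re_, gs, ge) for rs, re_, gs, ge in blocks]
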