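"""Cohort-level confirmation of splice events and isoform inventories.

The confirmation rule mirrors the study's filter: a splice event is confirmed
when it is observed in two or more individuals with at least three supporting
reads.  "At least three supporting reads" is interpreted cohort-wide by
default; the stricter per-individual reading (used when counting isoforms per
animal) is available via ``per_individual=True`` and is the default inside
:func:`isoform_inventory`.  A ``high_coverage`` preset implements the relaxed
rule used for deeply sequenced samples (>=10 reads, or confirmed in two
individuals).
"""

from __future__ import annotations

import json

import pandas as pd

COLUMNS = ["canonical_id", "n_individuals", "total_reads", "per_individual",
           "confirmed"]


def aggregate(calls, individual_of):
    """Aggregate per-read event calls into an event-support table.

    ``calls``: DataFrame with columns ``read_id`` and ``canonical_id`` (one row
    per event observed on a read).  ``individual_of``: mapping read_id ->
    individual; a read without a tag is an error.
    """
    if len(calls) == 0:
        return pd.DataFrame(columns=COLUMNS)
    calls = calls.copy()
    missing = [r for r in calls["read_id"] if r not in individual_of]
    if missing:
        raise ValueError(f"reads without individual tag: {missing[:3]}...")
    calls["individual"] = [individual_of[r] for r in calls["read_id"]]
    rows = []
    for cid, grp in calls.groupby("canonical_id", sort=True):
        per = grp.groupby("individual")["read_id"].nunique().to_dict()
        rows.append({
            "canonical_id": cid,
            "n_individuals": len(per),
            "total_reads": int(sum(per.values())),
            "per_individual": json.dumps(per, sort_keys=True),
            "confirmed": False,
        })
    return pd.DataFrame(rows, columns=COLUMNS)


def confirm(table, min_reads=3, min_individuals=2, preset="default",
            per_individual=False):
    """Apply the confirmation rule; returns the table with ``confirmed`` set
    and the confirmed subset.  Thresholds must be >= 1."""
    if min(min_reads, min_individuals) < 1:
        raise ValueError("thresholds must be >= 1")
    table = table.copy()
    if len(table) == 0:
        return table, table
    counts = table["per_individual"].map(lambda s: json.loads(s))
    if per_individual:
        reads_ok = counts.map(lambda d: max(d.values(), default=0) >= min_reads)
    else:
        reads_ok = table["total_reads"] >= min_reads
    ind_ok = table["n_individuals"] >= min_individuals
    if preset == "high_coverage":
        table["confirmed"] = (table["total_reads"] >= 10) | \
            (table["n_individuals"] >= 2)
    else:
        table["confirmed"] = reads_ok & ind_ok
    return table, table[table["confirmed"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# isoform inventory
# ---------------------------------------------------------------------------

def isoform_inventory(read_calls, min_reads=3):
    """Distinct isoform structures per individual, counted at per-individual
    read support >= ``min_reads``.

    ``read_calls``: DataFrame with one row per read and columns ``read_id``,
    ``individual``, ``gene``, ``signature`` (canonical event ids of the read,
    sorted and comma-joined; "" = constitutive).  Returns a DataFrame with one
    row per (individual, gene, signature) and its read support, with a
    ``counted`` flag for rows meeting the threshold.
    """
    if len(read_calls) == 0:
        return pd.DataFrame(columns=["individual", "gene", "signature",
                                     "reads", "counted"])
    grp = (read_calls.groupby(["individual", "gene", "signature"])["read_id"]
           .nunique().reset_index(name="reads"))
    grp["counted"] = grp["reads"] >= min_reads
    return grp.sort_values(["individual", "gene", "signature"]).reset_index(
        drop=True)


def per_individual_counts(inventory, gene=None):
    inv = inventory[inventory["counted"]]
    if gene is not None:
        inv = inv[inv["gene"] == gene]
    return inv.groupby("individual")["signature"].nunique().to_dict()


def cohort_structures(inventory, gene=None):
    """Cohort-wide distinct structures (union over individuals, counted rows)."""
    inv = inventory[inventory["counted"]]
    if gene is not None:
        inv = inv[inv["gene"] == gene]
    return sorted(set(zip(inv["gene"], inv["signature"])))


def inventory_matrix(inventory):
    """Individuals x isoform-structures read-count matrix."""
    if len(inventory) == 0:
        return pd.DataFrame()
    inv = inventory.copy()
    inv["structure"] = inv["gene"] + "|" + inv["signature"].replace("", "constitutive")
    return inv.pivot_table(index="individual", columns="structure",
                           values="reads", fill_value=0, aggfunc="sum")


# ---------------------------------------------------------------------------
# pedigree consistency
# ---------------------------------------------------------------------------

def pedigree_consistency(read_calls, pedigree, genotypes):
    """Flag reads incompatible with configured genotypes and transmissions.

    ``pedigree``: [(individual, father|None, mother|None), ...];
    ``genotypes``: individual -> iterable of carried "GENE*ALLELE" keys.
    Returns a report dict with ``flags`` (list of dicts) and ``notes``.
    """
    flags, notes = [], []
    geno = {k: set(v) for k, v in genotypes.items()}
    parents = {i[0]: (i[1], i[2]) for i in pedigree}

    for ind in {i[0] for i in pedigree}:
        if ind not in geno:
            flags.append({"kind": "missing_genotype", "individual": ind})

    if len(read_calls):
        for _, row in read_calls.iterrows():
            key = f"{row['gene']}*{row['allele']}"
            ind = row["individual"]
            if ind in geno and key not in geno[ind]:
                flags.append({"kind": "event_on_absent_gene",
                              "individual": ind, "allele": key,
                              "read_id": row["read_id"]})

    offspring = [i for i in pedigree if i[1] or i[2]]
    if not offspring:
        notes.append("founders-only cohort: transmission checks skipped")
    for ind, fa, mo in offspring:
        pool = set()
        for p in (fa, mo):
            pool |= geno.get(p, set())
        for key in geno.get(ind, set()):
            if pool and key not in pool:
                flags.append({"kind": "untransmitted_allele",
                              "individual": ind, "allele": key})
    return {"flags": flags, "notes": notes,
            "consistent": not any(f["kind"] != "missing_genotype"
                                  for f in flags)}
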