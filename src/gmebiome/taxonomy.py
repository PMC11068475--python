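"""Reference assignment, host exclusion, name validation and aggregation.

Each unique amplicon sequence gets a best hit against the 16S reference
collection and a host-genome decoy by ungapped sliding alignment.  Ties at
the top identity are broken in favour of subjects with a validly named
genus, then by earliest reference ID.  Queries matching the host genome
better than any 16S reference are excluded as plant-derived.  Lineage names
absent from the accepted-names list become "NotAssigned", and ASVs sharing
a top hit are aggregated into OTUs (or into genus/family/order bins).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .umi_amplicon import AsvTable

__all__ = [
    "ReferenceHit", "Lineage", "OtuTable", "RANKS",
    "search_reference", "assign_top_hit", "exclude_host", "validate_names",
    "aggregate", "assign_pipeline",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
NOT_ASSIGNED = "NotAssigned"


@dataclass(frozen=True)
class ReferenceHit:
    query: str
    subject: str
    identity: float            # percent of query positions matching
    source: str                # "ribosomal-reference" or "host-genome"


@dataclass
class OtuTable:
    counts: pd.DataFrame       # samples x group
    lineages: pd.DataFrame | None = None   # per group, rank columns

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _best_identity(query: np.ndarray, subject: np.ndarray) -> float:
    """Best ungapped alignment identity of query against subject.

    The query is slid across the subject (all offsets, including overhangs)
    and identity is reported as matching positions over query length.
    """
    lq, ls = len(query), len(subject)
    best = 0
    for off in range(-lq + 1, ls):
        a0, b0 = max(0, -off), max(0, off)
        n = min(lq - a0, ls - b0)
        if n <= best:
            continue
        m = int(np.count_nonzero(query[a0:a0 + n] == subject[b0:b0 + n]))
        if m > best:
            best = m
            if best == lq:
                break
    return 100.0 * best / lq


def search_reference(queries: dict[str, str], reference: dict[str, str],
                     host: dict[str, str] | None = None,
                     min_identity: float = 70.0) -> list[ReferenceHit]:
    """Identity of every query against every reference and host sequence.

    Hits below ``min_identity`` percent are omitted.
    """
    if not queries:
        raise ValueError("query set must be non-empty")
    if not reference:
        raise ValueError("reference must be non-empty")
    hits = []
    subjects = [(sid, _encode(s), "ribosomal-reference")
                for sid, s in reference.items()]
    subjects += [(sid, _encode(s), "host-genome")
                 for sid, s in (host or {}).items()]
    for qid, qseq in queries.items():
        q = _encode(qseq)
        for sid, s, source in subjects:
            ident = _best_identity(q, s)
            if ident >= min_identity:
                hits.append(ReferenceHit(qid, sid, ident, source))
    return hits


def _natural_key(ref_id: str):
    return [int(p) if p.isdigit() else p
            for p in re.split(r"(\d+)", ref_id)]


def _has_named_genus(lineage_row) -> bool:
    g = lineage_row.get("genus", "")
    return bool(g) and g != NOT_ASSIGNED


def assign_top_hit(hits, lineage_table: pd.DataFrame) -> dict[str, ReferenceHit]:
    """Pick each query's assignment among maximal-identity ribosomal hits.

    Ties are broken by (1) preferring subjects whose lineage carries a
    validly named genus and (2) the earliest reference ID under natural
    (numeric-aware) ordering.  Queries with no ribosomal hit are absent from
    the result (they fall through to the host check).
    """
    lin = lineage_table.set_index("reference_id")
    by_query: dict[str, list[ReferenceHit]] = {}
    for h in hits:
        if h.source == "ribosomal-reference":
            by_query.setdefault(h.query, []).append(h)
    out = {}
    for qid, qhits in by_query.items():
        top = max(h.identity for h in qhits)
        tied = [h for h in qhits if h.identity == top]
        named = [h for h in tied
                 if h.subject in lin.index and _has_named_genus(lin.loc[h.subject])]
        pool = named if named else tied
        out[qid] = min(pool, key=lambda h: _natural_key(h.subject))
    return out


def exclude_host(assignments: dict[str, ReferenceHit], hits,
                 queries=None):
    """Split queries into kept assignments and host-derived exclusions.

    A query is excluded iff its best host-genome identity strictly exceeds
    its best ribosomal identity, or it has a host hit but no ribosomal hit.
    Returns (kept_assignments, excluded_query_ids).
    """
    best_host: dict[str, float] = {}
    for h in hits:
        if h.source == "host-genome":
            best_host[h.query] = max(best_host.get(h.query, 0.0), h.identity)
    kept, excluded = {}, []
    ids = set(assignments) | set(best_host) | set(queries or [])
    for qid in ids:
        a = assignments.get(qid)
        if a is None:
            if qid in best_host:
                excluded.append(qid)
            continue
        if best_host.get(qid, -1.0) > a.identity:
            excluded.append(qid)
        else:
            kept[qid] = a
    return kept, sorted(excluded)


def validate_names(lineage: dict[str, str] | pd.Series,
                   accepted_names: pd.DataFrame) -> dict[str, str]:
    """Replace lineage names missing from the accepted list by NotAssigned.

    The lookup is rank-aware: a name counts only if the accepted list
    carries it under the same rank.  All ranks are checked.
    """
    accepted = {(r, n) for r, n in
                zip(accepted_names["rank"], accepted_names["name"])}
    out = {}
    for rank in RANKS:
        name = dict(lineage).get(rank, "")
        if name and name != NOT_ASSIGNED and (rank, name) in accepted:
            out[rank] = name
        else:
            out[rank] = NOT_ASSIGNED
    return out


def _group_key(assignment: ReferenceHit, lineage: dict[str, str], rank: str):
    if rank == "otu":
        return assignment.subject
    name = lineage.get(rank, NOT_ASSIGNED)
    if name != NOT_ASSIGNED:
        return name
    # NotAssigned bins stay distinct per parent lineage
    upto = RANKS[: RANKS.index(rank)]
    parent = "/".join(lineage.get(r, NOT_ASSIGNED) for r in upto)
    return f"{NOT_ASSIGNED}({parent})"


def aggregate(asv_table: AsvTable, assignments: dict[str, ReferenceHit],
              lineages: dict[str, dict[str, str]], rank: str = "otu") -> OtuTable:
    """Sum ASV columns sharing a top hit (rank='otu') or a lineage name.

    ``lineages`` maps ASV id -> validated lineage dict.  Count totals are
    conserved; ASVs without an assignment must have been excluded upstream.
    """
    if rank not in ("otu",) + RANKS[1:]:
        raise ValueError(f"unsupported rank: {rank}")
    cols = {}
    lineage_rows = {}
    for asv in asv_table.counts.columns:
        if asv not in assignments:
            raise ValueError(f"ASV {asv} has no assignment")
        lin = lineages[asv]
        key = _group_key(assignments[asv], lin, rank)
        if key in cols:
            cols[key] = cols[key] + asv_table.counts[asv].to_numpy()
        else:
            cols[key] = asv_table.counts[asv].to_numpy().copy()
            lineage_rows[key] = lin
    counts = pd.DataFrame(cols, index=asv_table.counts.index)
    counts = counts[sorted(counts.columns, key=_natural_key)]
    lintab = pd.DataFrame([lineage_rows[c] for c in counts.columns],
                          index=counts.columns)
    return OtuTable(counts=counts, lineages=lintab)


def assign_pipeline(asv_table: AsvTable, reference: dict[str, str],
                    lineage_table: pd.DataFrame,
                    accepted_names: pd.DataFrame,
                    host: dict[str, str] | None = None,
                    min_identity: float = 70.0):
    """Full assignment chain: search -> top hit -> host exclusion -> names.

    Returns (filtered AsvTable, assignments, validated lineages, excluded).
    """
    queries = {a: asv_table.sequences[a] for a in asv_table.counts.columns}
    hits = search_reference(queries, reference, host, min_identity)
    assignments = assign_top_hit(hits, lineage_table)
    kept, excluded = exclude_host(assignments, hits, queries)
    unassigned = [q for q in queries if q not in kept and q not in excluded]
    keep_cols = [a for a in asv_table.counts.columns if a in kept]
    filtered = AsvTable(counts=asv_table.counts[keep_cols].copy(),
                        sequences={a: asv_table.sequences[a] for a in keep_cols})
    lin = lineage_table.set_index("reference_id")
    lineages = {}
    for asv, hit in kept.items():
        raw = lin.loc[hit.subject].to_dict() if hit.subject in lin.index else {}
        lineages[asv] = validate_names(raw, accepted_names)
    return filtered, kept, lineages, sorted(excluded) + sorted(unassigned)
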