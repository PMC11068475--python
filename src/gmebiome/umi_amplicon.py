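"""Paired FASTQ -> duplicate-free UMI count table of unique target sequences.

Processing mirrors a MAUI-seq style amplicon workflow: 3'-tail quality
trimming (Phred < 20 stripped, reads < 200 bp discarded), ungapped
maximal-overlap pair merging (overlap > 10 bp, merged length > 300 bp),
positional parsing of UMI / forward primer / target / reverse primer, and
per-sample counting of distinct UMIs per unique target sequence so PCR
duplicates collapse to one molecule.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .synthetic_data import IUPAC, revcomp

__all__ = [
    "AmpliconLayout", "MergedRead", "UmiRecord", "AsvTable", "ProcessingLog",
    "quality_trim", "merge_pairs", "parse_amplicon", "count_umis",
    "filter_mean_umi", "process_sample", "process_fastq_pair",
]


@dataclass(frozen=True)
class AmpliconLayout:
    """Positional layout of the merged amplicon.

    Lengths are config-driven: the UMI occupies the first ``umi_length``
    bases, followed by the forward universal primer, the target, and the
    reverse-complemented reverse universal primer at the 3' end.
    """

    umi_length: int = 12
    fwd_universal: str = "AACMGGATTAGATACCCKG"
    rev_universal: str = "ACGTCATCCCCACCTTCC"
    max_primer_mismatches: int = 2
    umi_pattern: str | None = None  # IUPAC pattern; None disables the check


@dataclass
class MergedRead:
    sample: str
    sequence: str
    qualities: np.ndarray

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.qualities))


@dataclass(frozen=True)
class UmiRecord:
    sample: str
    umi: str
    target: str


@dataclass
class AsvTable:
    """Samples x unique-target matrix of duplicate-free UMI counts."""

    counts: pd.DataFrame          # index = samples, columns = ASV ids
    sequences: dict[str, str]     # ASV id -> target sequence

    def to_tsv(self, path):
        out = self.counts.T.copy()
        out.insert(0, "sequence", [self.sequences[a] for a in out.index])
        out.index.name = "asv_id"
        out.to_csv(path, sep="\t")


@dataclass
class ProcessingLog:
    """Per-reason tally of dropped read pairs; input = merged + dropped."""

    input_pairs: int = 0
    merged: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str):
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    @property
    def total_dropped(self) -> int:
        return sum(self.dropped.values())


# --------------------------------------------------------------------------
# read-level operations
# --------------------------------------------------------------------------

def quality_trim(sequence: str, qualities, phred_threshold: int = 20,
                 min_length: int = 200):
    """Strip low-quality 3' tail; return (seq, quals) or None if too short.

    Trailing bases with quality below ``phred_threshold`` are removed from
    the 3' end; reads shorter than ``min_length`` after trimming are
    discarded (returned as None).
    """
    quals = np.asarray(qualities, dtype=int)
    if len(quals) != len(sequence):
        raise ValueError("sequence and quality lengths differ")
    end = len(quals)
    while end > 0 and quals[end - 1] < phred_threshold:
        end -= 1
    if end < min_length:
        return None
    return sequence[:end], quals[:end]


def _best_overlap(fwd: str, rc_rev: str):
    """Best ungapped suffix(fwd)/prefix(rc_rev) overlap.

    Scored as matches - mismatches so that a long, nearly exact overlap
    always beats a short chance-perfect one.  Returns (overlap, matches).
    """
    fa = np.frombuffer(fwd.encode(), dtype=np.uint8)
    ra = np.frombuffer(rc_rev.encode(), dtype=np.uint8)
    best_o, best_m, best_score = 0, 0, -(10 ** 9)
    max_o = min(len(fa), len(ra))
    for o in range(max_o, 0, -1):
        if best_score >= o:      # shorter overlaps cannot score higher
            break
        m = int(np.count_nonzero(fa[-o:] == ra[:o]))
        score = 2 * m - o
        if score > best_score:
            best_o, best_m, best_score = o, m, score
    return best_o, best_m


def merge_pairs(fwd: str, fwd_quals, rev: str, rev_quals,
                min_overlap: int = 10, min_total: int = 300,
                min_overlap_identity: float = 0.8):
    """Merge a trimmed pair into one read, or return None (discard).

    The reverse mate is reverse-complemented and the ungapped overlap with
    the highest match fraction is chosen; pairs whose overlap is not
    strictly greater than ``min_overlap`` or whose merged length is not
    strictly greater than ``min_total`` are discarded.  Disagreeing overlap
    bases take the higher-quality call.
    """
    rc_rev = revcomp(rev)
    rc_quals = np.asarray(rev_quals, int)[::-1]
    fq = np.asarray(fwd_quals, int)
    o, matches = _best_overlap(fwd, rc_rev)
    if o <= min_overlap or matches < min_overlap_identity * o:
        return None
    total = len(fwd) + len(rc_rev) - o
    if total <= min_total:
        return None
    seq = list(fwd + rc_rev[o:])
    quals = np.concatenate([fq, rc_quals[o:]])
    # overlap region: positions len(fwd)-o .. len(fwd)-1
    for k in range(o):
        i = len(fwd) - o + k
        if fwd[i] != rc_rev[k]:
            if rc_quals[k] > fq[i]:
                seq[i] = rc_rev[k]
                quals[i] = rc_quals[k]
        else:
            quals[i] = max(fq[i], rc_quals[k])
    return "".join(seq), quals


def _iupac_match(seq: str, pattern: str) -> int:
    """Number of positions of ``seq`` not matching the IUPAC ``pattern``."""
    return sum(base not in IUPAC.get(p, p) for base, p in zip(seq, pattern))


def parse_amplicon(merged: str, layout: AmpliconLayout, sample: str = "",
                   log: ProcessingLog | None = None):
    """Positional slice of a merged read into a UmiRecord, or None.

    First ``umi_length`` bases are the UMI, the next ``len(fwd_universal)``
    the forward primer (checked against the IUPAC primer at up to
    ``max_primer_mismatches`` mismatches), the trailing
    ``len(rev_universal)`` bases are removed, and the remainder is the
    target.  Failures are dropped and logged.
    """
    u = layout.umi_length
    f = len(layout.fwd_universal)
    r = len(layout.rev_universal)
    if len(merged) <= u + f + r:
        if log:
            log.drop("too_short_for_layout")
        return None
    umi = merged[:u]
    primer = merged[u:u + f]
    if _iupac_match(primer, layout.fwd_universal) > layout.max_primer_mismatches:
        if log:
            log.drop("primer_mismatch")
        return None
    if layout.umi_pattern is not None and _iupac_match(umi, layout.umi_pattern):
        if log:
            log.drop("umi_pattern")
        return None
    target = merged[u + f:len(merged) - r]
    return UmiRecord(sample=sample, umi=umi, target=target)


# --------------------------------------------------------------------------
# counting
# --------------------------------------------------------------------------

def count_umis(records, reassign_shared_umis: bool = False) -> AsvTable:
    """Duplicate-free UMI counting: count(sample, target) = #distinct UMIs.

    PCR duplicates (identical sample, UMI and target) collapse to one.  With
    ``reassign_shared_umis`` a UMI observed with several targets in one
    sample is credited only to that sample's most frequent target (MAUI-seq
    style); by default every (sample, umi, target) triple counts once.
    """
    records = list(records)
    if not records:
        return AsvTable(counts=pd.DataFrame(dtype=int), sequences={})
    df = pd.DataFrame({"sample": [r.sample for r in records],
                       "umi": [r.umi for r in records],
                       "target": [r.target for r in records]})
    df = df.drop_duplicates()
    if reassign_shared_umis:
        reads = pd.DataFrame({"sample": [r.sample for r in records],
                              "target": [r.target for r in records]})
        freq = reads.value_counts()
        df = df.sort_values("target", kind="stable")
        df["freq"] = [freq.get((s, t), 0) for s, t in zip(df["sample"], df["target"])]
        df = (df.sort_values(["freq", "target"], ascending=[False, True], kind="stable")
                .drop_duplicates(["sample", "umi"], keep="first"))
    counts = (df.groupby(["sample", "target"]).size().unstack(fill_value=0))
    seqs = sorted(counts.columns)
    ids = {seq: f"ASV_{i + 1}" for i, seq in enumerate(seqs)}
    counts = counts[seqs]
    counts.columns = [ids[s] for s in seqs]
    counts.index.name = "sample"
    return AsvTable(counts=counts.astype(int),
                    sequences={v: k for k, v in ids.items()})


def filter_mean_umi(table: AsvTable, threshold: float = 0.05) -> AsvTable:
    """Keep targets whose mean UMI count over ALL samples (zeros included)
    is >= ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if table.counts.empty:
        return table
    keep = table.counts.columns[table.counts.mean(axis=0) >= threshold]
    return AsvTable(counts=table.counts[keep].copy(),
                    sequences={a: table.sequences[a] for a in keep})


# --------------------------------------------------------------------------
# file-level pipeline
# --------------------------------------------------------------------------

def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _phred(qual_str: str) -> np.ndarray:
    return np.frombuffer(qual_str.encode(), dtype=np.uint8).astype(int) - 33


def process_fastq_pair(r1_path, r2_path, layout: AmpliconLayout,
                       sample_from_name=None,
                       phred_threshold: int = 20, min_length: int = 200,
                       min_overlap: int = 10, min_total: int = 300):
    """Run trim -> merge -> parse over a FASTQ pair; return (records, log).

    ``sample_from_name`` maps a read name to its sample label; by default
    the part of the name before the first ':' is used (the convention of the
    packaged read simulator).
    """
    if sample_from_name is None:
        def sample_from_name(name):
            return name.split(":")[0]
    records: list[UmiRecord] = []
    log = ProcessingLog()
    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        it1, it2 = FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        for (n1, s1, q1), (n2, s2, q2) in zip(it1, it2):
            log.input_pairs += 1
            t1 = quality_trim(s1, _phred(q1), phred_threshold, min_length)
            t2 = quality_trim(s2, _phred(q2), phred_threshold, min_length)
            if t1 is None or t2 is None:
                log.drop("quality_trim")
                continue
            merged = merge_pairs(*t1, *t2, min_overlap=min_overlap,
                                 min_total=min_total)
            if merged is None:
                log.drop("merge_failed")
                continue
            rec = parse_amplicon(merged[0], layout,
                                 sample=sample_from_name(n1.split("/")[0].lstrip("@")),
                                 log=log)
            if rec is not None:
                log.merged += 1
                records.append(rec)
    return records, log


def process_sample(r1_path, r2_path, layout: AmpliconLayout,
                   umi_filter_threshold: float = 0.05, **kwargs):
    """Convenience wrapper: FASTQ pair -> filtered AsvTable + log."""
    records, log = process_fastq_pair(r1_path, r2_path, layout, **kwargs)
    table = count_umis(records)
    return filter_mean_umi(table, umi_filter_threshold), log
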