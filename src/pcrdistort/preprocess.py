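"""Paired-end FASTQ to barcode-pair count table.

The reads fully span the 101-nt amplicon, so a position-wise full-overlap
consensus is sufficient (and bit-reproducible): R2 is reverse-complemented
and compared base by base with R1; disagreements are resolved toward the
higher-quality base and a quality tie fails the pair.  Passing consensus
reads must match the 46-nt AttL constant region perfectly; the two 20-nt
barcodes and the 15-nt varietal tag are then extracted and tallied.

Varietal tags differing only by a sequencing error are *not* merged; the
distinct-tag count is exact-match based.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .templates import (
    BARCODE_LEN,
    CONSTANT_LEN,
    READ_LEN,
    TAG_LEN,
    AmpliconTemplate,
    reverse_complement,
)


@dataclass
class ConsensusRead:
    sequence: str
    n_disagreements: int
    passed: bool
    reason: str = ""


def merge_pair(
    r1: tuple[str, np.ndarray | list],
    r2: tuple[str, np.ndarray | list],
    max_mismatch: int = 10,
) -> ConsensusRead:
    """Consensus of a fully overlapping read pair.

    ``r1``/``r2`` are (sequence, per-base phred qualities).  R2 is
    reverse-complemented (qualities reversed) and aligned position-wise.
    """
    s1, q1 = r1
    s2, q2 = r2
    if len(s1) != READ_LEN or len(s2) != READ_LEN:
        return ConsensusRead("", 0, False, "length")
    s2 = reverse_complement(s2)
    q1 = np.asarray(q1)
    q2 = np.asarray(q2)[::-1]
    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
    diff = a1 != a2
    n_diff = int(diff.sum())
    if n_diff > max_mismatch:
        return ConsensusRead("", n_diff, False, "too_many_mismatches")
    if n_diff == 0:
        return ConsensusRead(s1, 0, True)
    if (q1[diff] == q2[diff]).any():
        return ConsensusRead("", n_diff, False, "quality_tie")
    out = np.where(q1 >= q2, a1, a2)
    return ConsensusRead(out.tobytes().decode(), n_diff, True)


def extract_fields(
    c: ConsensusRead, template: AmpliconTemplate
) -> tuple[str, str] | None:
    """Barcode pair (40 nt) and tag (15 nt), or None if AttL mismatches.

    The constant region must match the template exactly -- no mismatch is
    tolerated.
    """
    if not c.passed:
        raise ValueError("extract_fields requires a passing consensus read")
    seq = c.sequence
    attl = seq[BARCODE_LEN : BARCODE_LEN + CONSTANT_LEN]
    if attl != template.constant_sequence:
        return None
    bc1 = seq[:BARCODE_LEN]
    bc2 = seq[BARCODE_LEN + CONSTANT_LEN : BARCODE_LEN + CONSTANT_LEN + BARCODE_LEN]
    tag = seq[2 * BARCODE_LEN + CONSTANT_LEN : 2 * BARCODE_LEN + CONSTANT_LEN + TAG_LEN]
    return bc1 + bc2, tag


class CountTable:
    """Rows keyed by 40-nt barcode-pair sequence.

    Wraps a DataFrame with columns ``sequence``, ``read_count``,
    ``distinct_tag_count``, ``tags`` (a Counter, optional) and
    ``class_pair`` (assigned by the switching analysis).  Rows are ordered
    by descending read count, ties broken lexicographically.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"sequence", "read_count"}
        if not required <= set(df.columns):
            raise ValueError(f"CountTable requires columns {sorted(required)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        cols = ["sequence", "read_count", "distinct_tag_count"]
        a = self.df[cols].reset_index(drop=True)
        b = other.df[cols].reset_index(drop=True)
        return a.equals(b)

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        if "tags" in out:
            out["tags"] = out["tags"].map(
                lambda t: ",".join(f"{k}:{v}" for k, v in sorted(t.items()))
                if isinstance(t, Counter)
                else ""
            )
        if "class_pair" in out:
            out["class_pair"] = out["class_pair"].map(
                lambda c: "-".join(x or "NA" for x in c) if isinstance(c, tuple) else c
            )
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        if "tags" in df:
            df["tags"] = df["tags"].map(
                lambda s: Counter(
                    dict(
                        (kv.split(":")[0], int(kv.split(":")[1]))
                        for kv in str(s).split(",")
                    )
                )
                if isinstance(s, str) and ":" in s
                else Counter()
            )
        return cls(df)


def tally(records) -> CountTable:
    """Aggregate (barcode_pair, tag) records into a CountTable.

    Deterministic row order: descending read count, then lexicographic
    sequence.  An empty record stream yields an empty table.
    """
    counts: dict[str, Counter] = {}
    for seq, tag in records:
        counts.setdefault(seq, Counter())[tag] += 1
    rows = [
        (seq, sum(tags.values()), len(tags), tags) for seq, tags in counts.items()
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    df = pd.DataFrame(rows, columns=["sequence", "read_count", "distinct_tag_count", "tags"])
    if df.empty:
        df = pd.DataFrame(
            columns=["sequence", "read_count", "distinct_tag_count", "tags"]
        )
    return CountTable(df)


def _open_maybe_gz(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def process_fastq(
    r1_path,
    r2_path,
    template: AmpliconTemplate,
    max_mismatch: int = 10,
) -> tuple[CountTable, dict[str, int]]:
    """Full preprocessing: merge pairs, AttL filter, extract, tally.

    Returns the count table and the conservation counters
    (reads_in == merged_pass + merge_fail + attl_fail).
    """
    counters = {"reads_in": 0, "merged_pass": 0, "merge_fail": 0, "attl_fail": 0}
    records = []
    with _open_maybe_gz(r1_path) as f1, _open_maybe_gz(r2_path) as f2:
        for rec1, rec2 in zip(SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq")):
            counters["reads_in"] += 1
            c = merge_pair(
                (str(rec1.seq), rec1.letter_annotations["phred_quality"]),
                (str(rec2.seq), rec2.letter_annotations["phred_quality"]),
                max_mismatch=max_mismatch,
            )
            if not c.passed:
                counters["merge_fail"] += 1
                continue
            fields = extract_fields(c, template)
            if fields is None:
                counters["attl_fail"] += 1
                continue
            counters["merged_pass"] += 1
            records.append(fields)
    return tally(records), counters
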