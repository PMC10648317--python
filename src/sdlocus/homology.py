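"""Pairwise homology detection and segmental-duplication block calling.

The internal aligner is a desk-scale anchor aligner for the
substitution-only sequences the generator emits: exact k-mer anchors on
both strands are chained per diagonal (longest colinear runs with a
bounded per-step gap) and identity is measured by gapless comparison
over the chain span.  For indel-bearing or real data the supported path
is importing PAF alignments produced by an external aligner; records
from either source feed the same block-merging and comparison
operations.

Identity is defined as matches / alignment columns (PAF column
arithmetic), not gap-compressed identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, LocusMap
from .synth import encode_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "SDBlock",
    "BPComparison",
    "anchor_align",
    "read_paf",
    "write_paf",
    "merge_to_blocks",
    "compare_bps",
    "classify_region_orientation",
    "duplicated_length",
    "fold_change",
    "blocks_to_bed",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """One pairwise alignment segment with PAF semantics.

    Query and target intervals are 0-based half-open on the forward
    strand of their sequences; ``strand`` gives the relative orientation.
    """

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    matches: int
    block_len: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.block_len <= 0 or not 0 < self.matches <= self.block_len:
            raise ValueError("need 0 < matches <= block_len")
        if (
            self.qend - self.qstart > self.block_len
            or self.tend - self.tstart > self.block_len
        ):
            raise ValueError("interval lengths exceed alignment length")

    @property
    def identity(self) -> float:
        return self.matches / self.block_len

    @property
    def query_interval(self) -> GenomicInterval:
        return GenomicInterval(self.qname, self.qstart, self.qend)

    @property
    def target_interval(self) -> GenomicInterval:
        return GenomicInterval(self.tname, self.tstart, self.tend)


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-mer (2 bits per base; requires k <= 31)."""
    n = len(codes) - k + 1
    out = np.zeros(n, dtype=np.int64)
    for i in range(k):
        out = (out << 2) | codes[i : i + n].astype(np.int64)
    return out


def _chains_from_anchors(
    pos_a: np.ndarray, pos_b: np.ndarray, k: int, max_gap: int, min_chain_bp: int
) -> "list[tuple[int, int, int]]":
    """Maximal same-diagonal anchor runs -> (qstart, qend, tstart) chains."""
    if len(pos_a) == 0:
        return []
    diag = pos_a - pos_b
    order = np.lexsort((pos_a, diag))
    pos_a, pos_b, diag = pos_a[order], pos_b[order], diag[order]
    new = np.empty(len(pos_a), dtype=bool)
    new[0] = True
    new[1:] = (np.diff(diag) != 0) | (np.diff(pos_a) > max_gap)
    starts = np.flatnonzero(new)
    ends = np.append(starts[1:], len(pos_a))
    chains = []
    for s, e in zip(starts, ends):
        qs, qe = int(pos_a[s]), int(pos_a[e - 1]) + k
        if qe - qs >= min_chain_bp:
            chains.append((qs, qe, int(pos_b[s])))
    return chains


def _match_kmers(codes_a: np.ndarray, codes_b: np.ndarray, k: int):
    ka = _kmer_codes(codes_a, k)
    kb = _kmer_codes(codes_b, k)
    left = pd.DataFrame({"code": ka, "pos_a": np.arange(len(ka), dtype=np.int64)})
    right = pd.DataFrame({"code": kb, "pos_b": np.arange(len(kb), dtype=np.int64)})
    hit = left.merge(right, on="code", how="inner")
    return hit["pos_a"].to_numpy(), hit["pos_b"].to_numpy()


def anchor_align(
    seq_a: str,
    seq_b: str,
    k: int = 15,
    max_gap: int = 2000,
    min_chain_bp: int = 1000,
    qname: str = "query",
    tname: str = "target",
    is_self: "bool | None" = None,
) -> "list[AlignmentRecord]":
    """Align two sequences by exact k-mer anchoring and diagonal chaining.

    Anchors are found on both strands; colinear anchors on a common
    diagonal are chained when consecutive anchors are at most ``max_gap``
    apart, and chains spanning at least ``min_chain_bp`` are emitted.
    Identity is the gapless match fraction over the chain span.  A
    self-alignment excludes the trivial main diagonal and deduplicates
    mirrored records, keeping the record with query start <= target
    start; self mode is taken when the same sequence object is passed
    twice (identical *copies* are aligned normally) or forced with
    ``is_self``.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if k > len(seq_a) or k > len(seq_b):
        return []
    if is_self is None:
        is_self = seq_a is seq_b
    codes_a = encode_sequence(seq_a)
    codes_b = codes_a if is_self else encode_sequence(seq_b)
    codes_b_rc = (3 - codes_b)[::-1]
    len_a, len_b = len(codes_a), len(codes_b)

    records: list[AlignmentRecord] = []

    def emit(qs: int, qe: int, ts: int, te: int, strand: str, matches: int) -> None:
        records.append(
            AlignmentRecord(
                qname=qname, qlen=len_a, qstart=qs, qend=qe, strand=strand,
                tname=tname, tlen=len_b, tstart=ts, tend=te,
                matches=matches, block_len=qe - qs,
            )
        )

    # forward strand
    pos_a, pos_b = _match_kmers(codes_a, codes_b, k)
    if is_self:
        keep = pos_a != pos_b
        pos_a, pos_b = pos_a[keep], pos_b[keep]
    for qs, qe, ts in _chains_from_anchors(pos_a, pos_b, k, max_gap, min_chain_bp):
        span = qe - qs
        matches = int((codes_a[qs:qe] == codes_b[ts : ts + span]).sum())
        emit(qs, qe, ts, ts + span, "+", matches)

    # reverse strand: match against the reverse complement of the target
    pos_a, pos_rc = _match_kmers(codes_a, codes_b_rc, k)
    for qs, qe, ts_rc in _chains_from_anchors(
        pos_a, pos_rc, k, max_gap, min_chain_bp
    ):
        span = qe - qs
        matches = int((codes_a[qs:qe] == codes_b_rc[ts_rc : ts_rc + span]).sum())
        ts, te = len_b - (ts_rc + span), len_b - ts_rc
        emit(qs, qe, ts, te, "-", matches)

    if is_self:
        records = [r for r in records if r.qstart <= r.tstart]
    return records


# ---------------------------------------------------------------------------
# PAF I/O (standard columns 1-12)
# ---------------------------------------------------------------------------

def read_paf(path) -> "list[AlignmentRecord]":
    """Read PAF records; malformed rows are skipped with a warning."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 12 or fields[4] not in "+-":
                    raise ValueError("bad column layout")
                block_len = int(fields[10])
                if block_len == 0:
                    raise ValueError("zero alignment length")
                records.append(
                    AlignmentRecord(
                        qname=fields[0], qlen=int(fields[1]),
                        qstart=int(fields[2]), qend=int(fields[3]),
                        strand=fields[4],
                        tname=fields[5], tlen=int(fields[6]),
                        tstart=int(fields[7]), tend=int(fields[8]),
                        matches=int(fields[9]), block_len=block_len,
                    )
                )
            except (ValueError, IndexError) as exc:
                logger.warning("%s line %d skipped: %s", path, lineno, exc)
    return records


def write_paf(records: Iterable[AlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.qname, r.qlen, r.qstart, r.qend, r.strand,
                        r.tname, r.tlen, r.tstart, r.tend,
                        r.matches, r.block_len, 255,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SD blocks
# ---------------------------------------------------------------------------

@dataclass
class SDBlock:
    """A merged duplication block: two intervals with identity/orientation."""

    a: GenomicInterval
    b: GenomicInterval
    identity: float
    orientation: str  # "direct" | "inverted"
    length: int  # bp of the shorter side

    def sides(self) -> "tuple[GenomicInterval, GenomicInterval]":
        return (self.a, self.b)


def merge_to_blocks(
    records: Sequence[AlignmentRecord],
    max_join_gap: int = 2000,
    min_len: int = 1000,
    min_identity: float = 0.90,
) -> "list[SDBlock]":
    """Merge colinear alignment records into duplication blocks.

    Records with the same orientation whose query and target intervals
    are each within ``max_join_gap`` are merged; block identity is the
    length-weighted mean; blocks shorter than ``min_len`` (shorter side)
    or below ``min_identity`` are dropped.  Orientations never merge.
    """
    groups: dict[tuple, list[AlignmentRecord]] = {}
    for r in records:
        groups.setdefault((r.qname, r.tname, r.strand), []).append(r)

    blocks: list[SDBlock] = []
    for (qname, tname, strand), recs in groups.items():
        recs = sorted(recs, key=lambda r: r.qstart)
        merged: list[dict] = []
        for r in recs:
            if merged:
                cur = merged[-1]
                q_gap = r.qstart - cur["qend"]
                t_gap = (
                    r.tstart - cur["tend"]
                    if strand == "+"
                    else cur["tstart"] - r.tend
                )
                # both gaps must be small in absolute value: a large
                # negative gap means the same query re-aligns to another
                # copy of the target, which must not be merged
                if (
                    -max_join_gap <= q_gap <= max_join_gap
                    and -max_join_gap <= t_gap <= max_join_gap
                ):
                    cur["qend"] = max(cur["qend"], r.qend)
                    cur["tstart"] = min(cur["tstart"], r.tstart)
                    cur["tend"] = max(cur["tend"], r.tend)
                    cur["matches"] += r.matches
                    cur["block_len"] += r.block_len
                    continue
            merged.append(
                {
                    "qstart": r.qstart, "qend": r.qend,
                    "tstart": r.tstart, "tend": r.tend,
                    "matches": r.matches, "block_len": r.block_len,
                }
            )
        for m in merged:
            a = GenomicInterval(qname, m["qstart"], m["qend"])
            b = GenomicInterval(tname, m["tstart"], m["tend"])
            identity = m["matches"] / m["block_len"]
            length = min(a.length(), b.length())
            if length < min_len or identity < min_identity:
                continue
            blocks.append(
                SDBlock(
                    a=a, b=b, identity=identity,
                    orientation="direct" if strand == "+" else "inverted",
                    length=length,
                )
            )
    return blocks


@dataclass
class BPComparison:
    """Homology totals between one pair of BP blocks."""

    pair: "tuple[str, str]"
    blocks: "list[SDBlock]" = field(default_factory=list)
    direct_bp: int = 0
    inverted_bp: int = 0

    @property
    def total_bp(self) -> int:
        return self.direct_bp + self.inverted_bp


def compare_bps(
    locus_map: LocusMap, blocks: Sequence[SDBlock]
) -> "list[BPComparison]":
    """Assign duplication blocks to BP-block pairs and rank pairs.

    A block whose two sides fall in two distinct BP intervals (assigned
    by side midpoint; straddling a boundary is logged) contributes its
    length to that pair's direct or inverted total.  Pairs are returned
    ranked by total homology.
    """
    order = {label: i for i, label in enumerate(locus_map.block_labels())}
    comparisons: dict[tuple[str, str], BPComparison] = {}
    for block in blocks:
        labels = []
        for side in block.sides():
            label = locus_map.block_of(side.chrom, side.midpoint())
            if label is not None:
                bp = next(b for b in locus_map.bp_blocks if b.label == label)
                if not bp.contains(side):
                    logger.info(
                        "block side %s straddles %s boundary; assigned by midpoint",
                        side, label,
                    )
            labels.append(label)
        la, lb = labels
        if la is None or lb is None or la == lb:
            continue
        pair = tuple(sorted((la, lb), key=lambda x: order.get(x, 99)))
        cmp = comparisons.setdefault(pair, BPComparison(pair=pair))
        cmp.blocks.append(block)
        if block.orientation == "direct":
            cmp.direct_bp += block.length
        else:
            cmp.inverted_bp += block.length
    return sorted(comparisons.values(), key=lambda c: -c.total_bp)


def classify_region_orientation(
    records: Sequence[AlignmentRecord], region: GenomicInterval
) -> str:
    """Orientation of a region from species-to-reference alignments.

    Aligned bases within the region (target/reference side) are tallied
    by strand; the majority strand wins when it holds at least 80% of the
    aligned bases and the alignments cover at least 50% of the region,
    otherwise "unresolved".
    """
    strand_bp = {"+": 0, "-": 0}
    covered: list[tuple[int, int]] = []
    for r in records:
        ov = region.overlap_len(r.target_interval)
        if ov > 0:
            strand_bp[r.strand] += ov
            covered.append(
                (max(region.start, r.tstart), min(region.end, r.tend))
            )
    total = strand_bp["+"] + strand_bp["-"]
    if total == 0:
        return "unresolved"
    union = 0
    cur_s = cur_e = None
    for s, e in sorted(covered):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                union += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    union += (cur_e - cur_s) if cur_e is not None else 0
    if union < 0.5 * region.length():
        return "unresolved"
    top = max(strand_bp, key=strand_bp.get)
    if strand_bp[top] / total < 0.8:
        return "unresolved"
    return "direct" if top == "+" else "inverted"


def duplicated_length(blocks: Sequence[SDBlock]) -> int:
    """Union bp covered by at least one block side (per sequence)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for block in blocks:
        for side in block.sides():
            by_chrom.setdefault(side.chrom, []).append((side.start, side.end))
    total = 0
    for ivs in by_chrom.values():
        cur_s = cur_e = None
        for s, e in sorted(ivs):
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
    return total


def fold_change(a_bp: float, b_bp: float) -> float:
    """Ratio of duplicated content between two architectures."""
    if b_bp <= 0:
        raise ValueError("zero denominator in fold change")
    return a_bp / b_bp


def blocks_to_bed(blocks: Sequence[SDBlock], path) -> None:
    """SD blocks as paired BED rows (two rows per block, paired by name)."""
    with open(path, "w") as fh:
        for idx, block in enumerate(blocks):
            strand = "+" if block.orientation == "direct" else "-"
            for side_name, side in (("a", block.a), ("b", block.b)):
                fh.write(
                    f"{side.chrom}\t{side.start}\t{side.end}\t"
                    f"sd_block_{idx}_{side_name}\t{block.identity:.4f}\t{strand}\n"
                )


def blocks_to_frame(blocks: Sequence[SDBlock]) -> pd.DataFrame:
    rows = []
    for block in blocks:
        rows.append(
            {
                "chrom_a": block.a.chrom, "start_a": block.a.start,
                "end_a": block.a.end,
                "chrom_b": block.b.chrom, "start_b": block.b.start,
                "end_b": block.b.end,
                "orientation": block.orientation,
                "identity": round(block.identity, 4),
                "length": block.length,
            }
        )
    return pd.DataFrame(rows)
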