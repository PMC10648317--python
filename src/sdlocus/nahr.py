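"""NAHR deletion/duplication susceptibility from flanking duplications.

Unequal crossover between paralogous segmental duplications deletes or
duplicates the sequence between them when the two copies are in direct
orientation.  This module collects, for every ordered pair of BP blocks,
the directly oriented duplication blocks with one side in each, and
flags the flanked interval as susceptible when at least one such block
passes the identity and length thresholds.  Inverted-orientation pairs
relate to inversion formation and are only reported descriptively.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core import GenomicInterval, LocusMap
from .homology import SDBlock

logger = logging.getLogger(__name__)

__all__ = ["SusceptibilityCall", "flanking_direct_pairs", "expansion_fold"]


@dataclass
class SusceptibilityCall:
    """NAHR susceptibility of the interval flanked by one BP pair."""

    pair: "tuple[str, str]"
    flanked: "GenomicInterval | None"
    direct_blocks: "list[SDBlock]" = field(default_factory=list)
    direct_bp: int = 0
    max_identity: float = 0.0
    susceptible: bool = False

    @property
    def region_label(self) -> str:
        return f"{self.pair[0]}..{self.pair[1]}"

    def to_row(self) -> "dict[str, object]":
        return {
            "region": self.region_label,
            "n_direct_blocks": len(self.direct_blocks),
            "direct_bp": self.direct_bp,
            "max_identity": round(self.max_identity, 4),
            "susceptible": self.susceptible,
            "flanked": (
                f"{self.flanked.chrom}:{self.flanked.start}-{self.flanked.end}"
                if self.flanked
                else "."
            ),
        }


def flanking_direct_pairs(
    locus_map: LocusMap,
    blocks: Sequence[SDBlock],
    min_identity: float = 0.95,
    min_len: int = 10_000,
) -> "list[SusceptibilityCall]":
    """Score every BP pair for directly oriented flanking duplications.

    For every ordered BP pair (Bi, Bj), i < j, duplication blocks with
    one side in each (assigned by side midpoint) are collected.  The
    flanked interval spans from the innermost start of the Bi-side
    copies to the outermost start of the Bj-side copies' region, i.e.
    between the blocks' inner edges.  The pair is susceptible when at
    least one *direct* block has identity >= ``min_identity`` and
    shorter-side length >= ``min_len``.
    """
    labels = locus_map.block_labels()
    order = {label: i for i, label in enumerate(labels)}
    per_pair: dict[tuple[str, str], list[SDBlock]] = {}
    for block in blocks:
        la = locus_map.block_of(block.a.chrom, block.a.midpoint())
        lb = locus_map.block_of(block.b.chrom, block.b.midpoint())
        if la is None or lb is None or la == lb:
            continue
        if order[la] > order[lb]:
            la, lb = lb, la
        per_pair.setdefault((la, lb), []).append(block)

    calls = []
    for pair in sorted(per_pair, key=lambda p: (order[p[0]], order[p[1]])):
        pair_blocks = per_pair[pair]
        direct = [b for b in pair_blocks if b.orientation == "direct"]
        qualifying = [
            b for b in direct if b.identity >= min_identity and b.length >= min_len
        ]
        flanked = None
        if direct:
            chrom = direct[0].a.chrom
            # inner edges: end of the proximal-side copies, start of the
            # distal-side copies (sides ordered by coordinate)
            inner_starts, inner_ends = [], []
            for b in direct:
                left, right = sorted(b.sides(), key=lambda s: s.start)
                inner_ends.append(left.end)
                inner_starts.append(right.start)
            lo, hi = min(inner_ends), max(inner_starts)
            if lo < hi:
                flanked = GenomicInterval(
                    chrom, lo, hi, label=f"{pair[0]}..{pair[1]}"
                )
        calls.append(
            SusceptibilityCall(
                pair=pair,
                flanked=flanked,
                direct_blocks=direct,
                direct_bp=sum(b.length for b in qualifying),
                max_identity=max((b.identity for b in direct), default=0.0),
                susceptible=bool(qualifying),
            )
        )
    return calls


def expansion_fold(
    calls_a: Sequence[SusceptibilityCall],
    calls_b: Sequence[SusceptibilityCall],
    region: str,
    high_identity: float = 0.975,
    pseudocount_bp: int = 1000,
) -> float:
    """Fold difference in high-identity direct flanking homology.

    Compares, between two species' susceptibility calls, the total
    length of directly oriented flanking blocks at or above
    ``high_identity`` for the named BP-pair region (e.g. ``BP1..BP3``).
    The threshold defaults half a point below the nominal 98% band
    because printed block identities are rounded to whole percent.  When
    species B has no qualifying homology, a pseudocount of the minimum
    block length is used with a warning.
    """

    def total(calls: Sequence[SusceptibilityCall]) -> "float | None":
        for call in calls:
            if call.region_label == region:
                return float(
                    sum(
                        b.length
                        for b in call.direct_blocks
                        if b.identity >= high_identity
                    )
                )
        return None

    a_bp = total(calls_a)
    b_bp = total(calls_b)
    if a_bp is None or b_bp is None:
        raise ValueError(f"region {region!r} absent from susceptibility calls")
    if b_bp == 0:
        warnings.warn(
            f"no high-identity direct homology for {region} in species B; "
            f"using pseudocount of {pseudocount_bp} bp",
            stacklevel=2,
        )
        b_bp = float(pseudocount_bp)
    return a_bp / b_bp


def calls_to_frame(calls: Sequence[SusceptibilityCall]) -> pd.DataFrame:
    return pd.DataFrame([c.to_row() for c in calls])
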