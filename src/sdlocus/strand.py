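"""Inversion genotyping and deletion detection from strand-state counts.

Input is a per-cell table of binned Watson/Crick read counts from a
single-cell template-strand sequencing experiment.  Cells whose template
state is WW or CC (both homologs inherited the same template strand) are
informative for inversions: an inverted segment reads on the opposite
strand, so a homozygous inversion produces a complete strand switch and
a heterozygous inversion a partial (~50%) switch.  WC cells carry no
orientation signal and are discarded rather than phased.

Genotyping is a per-cell binomial likelihood on the minority-strand
count inside the candidate region, with success probability epsilon
(background strand noise), 1/2, or 1-epsilon under the dir/dir, dir/inv
and inv/inv genotypes respectively.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .core import GenomicInterval, OrientationGenotype

__all__ = [
    "CellCountMatrix",
    "StrandGenotypeCall",
    "SwitchSegment",
    "select_informative_cells",
    "genotype_region",
    "scan_strand_switches",
    "detect_depth_deletion",
]

GENOTYPES = (
    OrientationGenotype.DIR_DIR,
    OrientationGenotype.DIR_INV,
    OrientationGenotype.INV_INV,
)


@dataclass
class CellCountMatrix:
    """Binned Watson/Crick counts, one row per cell.

    ``bins`` tile the locus without overlap; ``W`` and ``C`` are
    ``(n_cells, n_bins)`` non-negative integer arrays.
    """

    bins: "list[GenomicInterval]"
    W: np.ndarray
    C: np.ndarray
    cells: "list[str]" = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.int64)
        self.C = np.asarray(self.C, dtype=np.int64)
        if self.W.shape != self.C.shape or self.W.shape[1] != len(self.bins):
            raise ValueError("count arrays do not match bin list")
        if (self.W < 0).any() or (self.C < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.cells:
            self.cells = [f"cell{idx:03d}" for idx in range(self.W.shape[0])]

    @property
    def n_cells(self) -> int:
        return self.W.shape[0]

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def bin_mask(self, region: GenomicInterval) -> np.ndarray:
        """Bins whose midpoint lies inside ``region``."""
        mids = np.array([b.midpoint() for b in self.bins])
        chrom_ok = np.array([b.chrom == region.chrom for b in self.bins])
        return chrom_ok & (mids >= region.start) & (mids < region.end)

    def total_reads(self) -> np.ndarray:
        """Total simulated reads per cell (W + C over all bins)."""
        return (self.W + self.C).sum(axis=1)

    # -- I/O: one tab-separated table per cell ------------------------------
    def write_dir(self, directory: "str | os.PathLike") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        chrom = self.bins[0].chrom
        for idx, cell in enumerate(self.cells):
            df = pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_start": [b.start for b in self.bins],
                    "bin_end": [b.end for b in self.bins],
                    "W": self.W[idx],
                    "C": self.C[idx],
                }
            )
            df.to_csv(directory / f"{cell}.counts.tsv", sep="\t", index=False)

    @classmethod
    def read_dir(cls, directory: "str | os.PathLike") -> "CellCountMatrix":
        directory = Path(directory)
        paths = sorted(directory.glob("*.counts.tsv"))
        if not paths:
            raise FileNotFoundError(f"no *.counts.tsv files in {directory}")
        bins: list[GenomicInterval] | None = None
        W_rows, C_rows, cells = [], [], []
        for path in paths:
            df = pd.read_csv(path, sep="\t")
            cur = [
                GenomicInterval(str(r.chrom), int(r.bin_start), int(r.bin_end))
                for r in df.itertuples()
            ]
            if bins is None:
                bins = cur
            elif [(b.start, b.end) for b in cur] != [
                (b.start, b.end) for b in bins
            ]:
                raise ValueError(f"{path.name}: bin grid differs between cells")
            W_rows.append(df["W"].to_numpy())
            C_rows.append(df["C"].to_numpy())
            cells.append(path.name.removesuffix(".counts.tsv"))
        return cls(bins=bins, W=np.vstack(W_rows), C=np.vstack(C_rows), cells=cells)


@dataclass
class StrandGenotypeCall:
    """A genotype call for one region with its likelihood support."""

    region: GenomicInterval
    genotype: OrientationGenotype
    log_likelihoods: "dict[str, float]"
    n_cells: int
    margin: float
    reason: str = ""

    def to_row(self) -> "dict[str, object]":
        row: dict[str, object] = {
            "region": self.region.label or f"{self.region.start}-{self.region.end}",
            "genotype": self.genotype.value,
            "n_cells": self.n_cells,
            "margin": round(self.margin, 3),
            "reason": self.reason or ".",
        }
        for key in ("dir/dir", "dir/inv", "inv/inv"):
            row[f"logL[{key}]"] = round(self.log_likelihoods.get(key, float("nan")), 3)
        return row


def _background_mask(
    matrix: CellCountMatrix,
    region: GenomicInterval,
    exclude: "Sequence[GenomicInterval] | None",
) -> np.ndarray:
    outside = ~matrix.bin_mask(region)
    for iv in exclude or ():
        outside &= ~matrix.bin_mask(iv)
    if not outside.any():
        raise ValueError("no background bins left outside the candidate region")
    return outside


def select_informative_cells(
    matrix: CellCountMatrix,
    region: GenomicInterval,
    tau: float = 0.8,
    exclude: "Sequence[GenomicInterval] | None" = None,
) -> np.ndarray:
    """Indices of cells with a clean one-strand background outside ``region``.

    A cell is kept when its majority-strand fraction over bins outside
    the candidate region is at least ``tau`` (template state WW or CC);
    WC cells sit near 1/2 and are excluded.  When several candidate
    regions are assayed on one locus, pass the *other* candidate
    intervals via ``exclude`` so the background is restricted to
    sequence of known direct orientation.
    """
    if not 0.5 < tau <= 1.0:
        raise ValueError("tau must be in (0.5, 1]")
    outside = _background_mask(matrix, region, exclude)
    w = matrix.W[:, outside].sum(axis=1)
    c = matrix.C[:, outside].sum(axis=1)
    total = w + c
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.maximum(w, c) / np.where(total > 0, total, 1)
    return np.flatnonzero((total > 0) & (frac >= tau))


def genotype_region(
    matrix: CellCountMatrix,
    region: GenomicInterval,
    epsilon: float = 0.05,
    min_cells: int = 5,
    min_margin: float = 3.0,
    tau: float = 0.8,
    exclude: "Sequence[GenomicInterval] | None" = None,
) -> StrandGenotypeCall:
    """Genotype a candidate region as dir/dir, dir/inv or inv/inv.

    Per informative cell the minority-strand count inside the region
    (minority relative to the cell's background strand) is modelled as
    Binomial(n, p) with p in {epsilon, 1/2, 1-epsilon}; per-genotype
    log-likelihoods are summed over cells.  The call requires a
    log-likelihood margin of at least ``min_margin`` nats over the
    runner-up, otherwise the genotype is missing.  ``exclude`` restricts
    the background as in :func:`select_informative_cells`.
    """
    keep = select_informative_cells(matrix, region, tau=tau, exclude=exclude)
    if len(keep) < min_cells:
        return StrandGenotypeCall(
            region=region,
            genotype=OrientationGenotype.MISSING,
            log_likelihoods={},
            n_cells=len(keep),
            margin=0.0,
            reason=f"only {len(keep)} informative cells (< {min_cells})",
        )
    inside = matrix.bin_mask(region)
    outside = _background_mask(matrix, region, exclude)
    w_in = matrix.W[keep][:, inside].sum(axis=1)
    c_in = matrix.C[keep][:, inside].sum(axis=1)
    bg_is_w = (
        matrix.W[keep][:, outside].sum(axis=1)
        >= matrix.C[keep][:, outside].sum(axis=1)
    )
    n = w_in + c_in
    minority = np.where(bg_is_w, c_in, w_in)
    probs = {
        OrientationGenotype.DIR_DIR: max(epsilon, 1e-9),
        OrientationGenotype.DIR_INV: 0.5,
        OrientationGenotype.INV_INV: min(1 - epsilon, 1 - 1e-9),
    }
    logls = {
        gt: float(binom.logpmf(minority, n, p).sum()) for gt, p in probs.items()
    }
    ranked = sorted(GENOTYPES, key=lambda g: logls[g], reverse=True)
    margin = logls[ranked[0]] - logls[ranked[1]]
    logl_out = {gt.value: logls[gt] for gt in GENOTYPES}
    if margin < min_margin:
        return StrandGenotypeCall(
            region=region,
            genotype=OrientationGenotype.MISSING,
            log_likelihoods=logl_out,
            n_cells=len(keep),
            margin=margin,
            reason=f"margin {margin:.2f} < {min_margin}",
        )
    return StrandGenotypeCall(
        region=region,
        genotype=ranked[0],
        log_likelihoods=logl_out,
        n_cells=len(keep),
        margin=margin,
    )


@dataclass(frozen=True)
class SwitchSegment:
    """A strand-switch interval with its heterozygosity class."""

    interval: GenomicInterval
    kind: str  # "partial" | "complete"
    mean_fraction: float


def _binary_segmentation(values: np.ndarray, min_gain: float) -> "list[int]":
    """Change-point positions by recursive binary segmentation on SSE."""

    def sse(x: np.ndarray) -> float:
        return float(((x - x.mean()) ** 2).sum()) if len(x) else 0.0

    breakpoints: list[int] = []

    def _recurse(lo: int, hi: int) -> None:
        x = values[lo:hi]
        if len(x) < 2:
            return
        base = sse(x)
        # prefix sums give every split's SSE in one vectorized pass
        csum = np.cumsum(x)
        csum2 = np.cumsum(x * x)
        n = len(x)
        k = np.arange(1, n)
        left = csum2[k - 1] - csum[k - 1] ** 2 / k
        right = (csum2[-1] - csum2[k - 1]) - (csum[-1] - csum[k - 1]) ** 2 / (n - k)
        gains = base - (left + right)
        best = int(np.argmax(gains))
        if gains[best] < min_gain:
            return
        best_k = int(k[best])
        breakpoints.append(lo + best_k)
        _recurse(lo, lo + best_k)
        _recurse(lo + best_k, hi)

    _recurse(0, len(values))
    return sorted(breakpoints)


def scan_strand_switches(
    matrix: CellCountMatrix,
    min_bins: int = 5,
    tau: float = 0.8,
    partial_band: "tuple[float, float]" = (0.35, 0.65),
    complete_min: float = 0.85,
    min_gain: float = 0.3,
) -> "list[SwitchSegment]":
    """Scan the locus for strand-switch intervals.

    Cell template states are read from the per-bin *median* Watson
    fraction (robust against switch regions covering a minority of
    bins, unlike a whole-locus majority): cells with median at least
    ``tau`` or at most ``1 - tau`` are the WW/CC informative set.  The
    aggregated minority-strand fraction per bin is then segmented by
    binary segmentation; maximal segments of at least ``min_bins`` bins
    are classified as "partial" (mean fraction within ``partial_band``,
    the heterozygous signature) or "complete" (mean at or above
    ``complete_min``, homozygous).
    """
    depth_cb = (matrix.W + matrix.C).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        w_frac = np.where(depth_cb > 0, matrix.W / np.maximum(depth_cb, 1), 0.5)
    med = np.median(w_frac, axis=1)
    keep = np.flatnonzero((med >= tau) | (med <= 1 - tau))
    if len(keep) == 0:
        raise ValueError("no informative cells")
    bg_is_w = med[keep] >= 0.5
    minority = np.where(bg_is_w[:, None], matrix.C[keep], matrix.W[keep]).sum(axis=0)
    depth = (matrix.W[keep] + matrix.C[keep]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        bin_frac = minority / np.where(depth > 0, depth, 1)

    cuts = [0, *_binary_segmentation(bin_frac, min_gain=min_gain), matrix.n_bins]
    lo_band, hi_band = partial_band

    def classify(mean: float) -> "str | None":
        if lo_band <= mean <= hi_band:
            return "partial"
        if mean >= complete_min:
            return "complete"
        return None

    # merge adjacent segments of the same class into maximal segments
    raw = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        mean = float(bin_frac[lo:hi].mean())
        raw.append((lo, hi, classify(mean)))
    merged: list[list] = []
    for lo, hi, kind in raw:
        if merged and merged[-1][2] == kind:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi, kind])

    out = []
    for lo, hi, kind in merged:
        if kind is None or hi - lo < min_bins:
            continue
        interval = GenomicInterval(
            matrix.bins[lo].chrom,
            matrix.bins[lo].start,
            matrix.bins[hi - 1].end,
            label=kind,
        )
        out.append(
            SwitchSegment(
                interval=interval,
                kind=kind,
                mean_fraction=float(bin_frac[lo:hi].mean()),
            )
        )
    return out


def detect_depth_deletion(
    matrix: CellCountMatrix,
    min_bins: int = 5,
    het_max: float = 0.6,
    hom_max: float = 0.15,
    min_cells: int = 5,
) -> "list[tuple[GenomicInterval, str]]":
    """Detect deletions as runs of depressed read depth.

    Per-bin depth summed over cells is normalized by the locus median
    (robust to inversions, which preserve depth).  Runs of at least
    ``min_bins`` bins with normalized depth at or below ``het_max`` are
    called; a run mean at or below ``hom_max`` is homozygous, otherwise
    heterozygous.
    """
    if matrix.n_cells < min_cells:
        raise ValueError(f"need at least {min_cells} cells")
    depth = (matrix.W + matrix.C).sum(axis=0).astype(float)
    median = np.median(depth)
    if median <= 0:
        raise ValueError("zero median depth")
    norm = depth / median
    low = norm <= het_max

    calls = []
    idx = 0
    n = len(low)
    while idx < n:
        if not low[idx]:
            idx += 1
            continue
        run_start = idx
        while idx < n and low[idx]:
            idx += 1
        if idx - run_start >= min_bins:
            run = norm[run_start:idx]
            zygosity = "homozygous" if run.mean() <= hom_max else "heterozygous"
            interval = GenomicInterval(
                matrix.bins[run_start].chrom,
                matrix.bins[run_start].start,
                matrix.bins[idx - 1].end,
                label="deletion",
            )
            calls.append((interval, zygosity))
    return calls


def calls_to_frame(calls: Sequence[StrandGenotypeCall]) -> pd.DataFrame:
    return pd.DataFrame([c.to_row() for c in calls])
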