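"""Synthetic multi-species locus generator with full truth records.

The generator emulates, at a configurable down-scale, the three kinds of
evidence the comparative analysis consumes:

* multi-species haplotype sequences of an SD-flanked locus, grown from a
  blueprint of unique segments and duplicated copies at target identity,
  then rearranged along a species tree by per-branch inversion and
  deletion events;
* single-cell template-strand (Watson/Crick) binned read counts, the
  composite-state evidence used for inversion genotyping;
* three-probe interphase hybridization observations (probe-order
  strings), the assay used for regions that strand evidence alone cannot
  resolve.

Divergence between duplicate copies is substitution-only so that the
planted identity stays interpretable.  Inversion events toggle the net
orientation state of a named region; the four disjoint inter-block
regions are realized physically in the emitted sequences
(reverse-complemented in place when net-inverted), while a *span* region
that nests other regions (BP3-BP5) is tracked as its own character and
observed through the probe-order channel only, mirroring how such
regions are assayed in practice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GenomicInterval, LocusMap, SpeciesTree

__all__ = [
    "SegmentSpec",
    "EventSpec",
    "LocusBlueprint",
    "SDPairTruth",
    "TruthSet",
    "Haplotype",
    "build_ancestral_locus",
    "evolve_haplotypes",
    "simulate_strandseq_cells",
    "simulate_fish_observations",
    "human_sd_blueprint",
    "macaque_sd_blueprint",
    "inversion_history_blueprint",
    "table1_history_events",
    "write_haplotypes_fasta",
    "read_haplotypes_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT string -> uint8 code array (A=0, C=1, G=2, T=3)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


@dataclass(frozen=True)
class SegmentSpec:
    """One building block of the ancestral locus.

    ``length`` is in real (unscaled) base pairs; the blueprint scale
    divisor is applied at realization.  ``block`` / ``region`` tag the
    segment as part of a named BP block or inter-block candidate region.
    """

    kind: str  # "unique" | "sd_copy"
    seg_id: str
    length: "int | None" = None
    source_id: "str | None" = None
    identity: "float | None" = None
    orientation: str = "direct"
    block: "str | None" = None
    region: "str | None" = None


@dataclass(frozen=True)
class EventSpec:
    """A structural event planted on one branch of the species tree."""

    branch: str
    kind: str  # "inversion" | "deletion"
    region: "str | None" = None
    interval: "GenomicInterval | None" = None
    zygosity: str = "hom"  # "hom" | "het"
    species: "str | None" = None  # carrier of a het event


@dataclass
class LocusBlueprint:
    """Recipe for an ancestral locus and its evolutionary history."""

    name: str
    segments: "list[SegmentSpec]"
    events: "list[EventSpec]" = field(default_factory=list)
    #: divisor applied to real segment lengths (10 -> 1/10 scale)
    scale: float = 10.0
    #: span regions observed by probe order, given as name -> (block, block)
    spans: "dict[str, tuple[str, str]]" = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for seg in self.segments:
            if seg.kind == "unique":
                if not seg.length or seg.length <= 0:
                    raise ValueError(f"unique segment {seg.seg_id} needs length > 0")
            elif seg.kind == "sd_copy":
                if seg.source_id not in seen:
                    raise ValueError(
                        f"sd_copy {seg.seg_id}: source {seg.source_id!r} must be "
                        "an earlier segment"
                    )
                if seg.identity is None or not 0.8 < seg.identity <= 1.0:
                    raise ValueError(
                        f"sd_copy {seg.seg_id}: identity must be in (0.8, 1.0]"
                    )
                if seg.orientation not in ("direct", "inverted"):
                    raise ValueError(f"bad orientation {seg.orientation!r}")
            else:
                raise ValueError(f"unknown segment kind {seg.kind!r}")
            seen.add(seg.seg_id)
        if self.scale < 1:
            raise ValueError("scale must be >= 1")

    def scaled(self, length: int) -> int:
        return max(1, int(round(length / self.scale)))


@dataclass(frozen=True)
class SDPairTruth:
    """A planted duplication pair: source and copy with target identity."""

    source: GenomicInterval
    copy: GenomicInterval
    identity: float
    orientation: str
    realized_identity: float


@dataclass
class TruthSet:
    """Everything the generator planted, for recovery testing."""

    locus_map: "LocusMap | None" = None
    segments: "dict[str, GenomicInterval]" = field(default_factory=dict)
    sd_pairs: "list[SDPairTruth]" = field(default_factory=list)
    events: "list[EventSpec]" = field(default_factory=list)
    region_states: "dict[tuple[str, int], dict[str, str]]" = field(
        default_factory=dict
    )
    inversions: "dict[tuple[str, int], list[GenomicInterval]]" = field(
        default_factory=dict
    )
    deletions: "dict[tuple[str, int], list[GenomicInterval]]" = field(
        default_factory=dict
    )
    cell_states: "dict[str, list[tuple[str, str]]]" = field(default_factory=dict)

    def duplicated_union_bp(self) -> int:
        """Union length of all planted duplication intervals (both sides)."""
        ivs = sorted(
            (p.start, p.end)
            for pair in self.sd_pairs
            for p in (pair.source, pair.copy)
        )
        total = 0
        cur_s = cur_e = None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        return total

    def planted_genotype(self, species: str, region: str) -> str:
        s0 = self.region_states[(species, 0)][region]
        s1 = self.region_states[(species, 1)][region]
        if s0 == s1:
            return f"{s0}/{s0}"
        return "dir/inv"

    def to_json(self, path) -> None:
        def iv(x: GenomicInterval):
            return [x.chrom, x.start, x.end, x.label]

        payload = {
            "segments": {k: iv(v) for k, v in self.segments.items()},
            "sd_pairs": [
                {
                    "source": iv(p.source),
                    "copy": iv(p.copy),
                    "identity": p.identity,
                    "orientation": p.orientation,
                    "realized_identity": p.realized_identity,
                }
                for p in self.sd_pairs
            ],
            "events": [
                {
                    "branch": e.branch,
                    "kind": e.kind,
                    "region": e.region,
                    "zygosity": e.zygosity,
                    "species": e.species,
                }
                for e in self.events
            ],
            "region_states": {
                f"{sp}_hap{h + 1}": states
                for (sp, h), states in self.region_states.items()
            },
            "deletions": {
                f"{sp}_hap{h + 1}": [iv(d) for d in dels]
                for (sp, h), dels in self.deletions.items()
            },
            "cell_states": self.cell_states,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def build_ancestral_locus(
    blueprint: LocusBlueprint, rng: "np.random.Generator | None" = None
) -> "tuple[str, TruthSet]":
    """Realize the ancestral locus sequence from a blueprint.

    Unique segments are i.i.d. uniform nucleotides.  Each duplication
    copy is its source with per-site substitutions at rate
    ``1 - identity`` (substitution-only), reverse-complemented when the
    copy orientation is inverted.  The truth set records every planted
    copy pair, all realized segment coordinates, and the locus map
    derived from the blueprint's block/region tags.
    """
    rng = np.random.default_rng(blueprint.seed) if rng is None else rng
    chrom = blueprint.name
    chunks: list[np.ndarray] = []
    seg_codes: dict[str, np.ndarray] = {}
    seg_iv: dict[str, GenomicInterval] = {}
    truth = TruthSet()
    pos = 0
    for seg in blueprint.segments:
        if seg.kind == "unique":
            n = blueprint.scaled(seg.length)
            codes = rng.integers(0, 4, size=n, dtype=np.uint8)
        else:
            src = seg_codes[seg.source_id]
            codes = src.copy()
            sub_rate = 1.0 - seg.identity
            mask = rng.random(len(codes)) < sub_rate
            n_sub = int(mask.sum())
            if n_sub:
                codes[mask] = (
                    codes[mask] + rng.integers(1, 4, size=n_sub, dtype=np.uint8)
                ) % 4
            realized = 1.0 - n_sub / len(codes)
            if seg.orientation == "inverted":
                codes = revcomp_codes(codes)
        iv = GenomicInterval(chrom, pos, pos + len(codes), label=seg.seg_id)
        if seg.kind == "sd_copy":
            truth.sd_pairs.append(
                SDPairTruth(
                    source=seg_iv[seg.source_id],
                    copy=iv,
                    identity=seg.identity,
                    orientation=seg.orientation,
                    realized_identity=realized,
                )
            )
        seg_codes[seg.seg_id] = codes
        seg_iv[seg.seg_id] = iv
        chunks.append(codes)
        pos += len(codes)

    truth.segments = seg_iv
    truth.locus_map = _locus_map_from_segments(blueprint, seg_iv, chrom)
    sequence = decode_sequence(np.concatenate(chunks))
    return sequence, truth


def _locus_map_from_segments(
    blueprint: LocusBlueprint,
    seg_iv: Mapping[str, GenomicInterval],
    chrom: str,
) -> LocusMap:
    blocks: dict[str, list[GenomicInterval]] = {}
    regions: dict[str, list[GenomicInterval]] = {}
    for seg in blueprint.segments:
        iv = seg_iv[seg.seg_id]
        if seg.block:
            blocks.setdefault(seg.block, []).append(iv)
        if seg.region:
            regions.setdefault(seg.region, []).append(iv)

    def envelope(ivs: "list[GenomicInterval]", label: str) -> GenomicInterval:
        return GenomicInterval(
            chrom, min(i.start for i in ivs), max(i.end for i in ivs), label=label
        )

    bp_blocks = [envelope(ivs, name) for name, ivs in blocks.items()]
    bp_blocks.sort(key=lambda b: b.start)
    region_map = {name: envelope(ivs, name) for name, ivs in regions.items()}
    block_by_name = {b.label: b for b in bp_blocks}
    for span_name, (left, right) in blueprint.spans.items():
        region_map[span_name] = GenomicInterval(
            chrom,
            block_by_name[left].end,
            block_by_name[right].start,
            label=span_name,
        )
    return LocusMap(bp_blocks=bp_blocks, regions=region_map)


def span_regions(locus_map: LocusMap) -> "set[str]":
    """Regions that nest another region (observed by probe order only)."""
    names = list(locus_map.regions)
    return {
        a
        for a in names
        for b in names
        if a != b and locus_map.regions[a].contains(locus_map.regions[b])
    }


@dataclass
class Haplotype:
    """One haplotype of one species, in ancestral (reference) coordinates.

    ``inversions`` lists the content regions whose net orientation is
    inverted relative to the ancestor (these are physically
    reverse-complemented in ``sequence``); ``region_states`` additionally
    tracks span regions that are not realized in sequence.
    """

    species: str
    hap_index: int  # 0 or 1
    length: int
    sequence: "str | None"
    inversions: "list[GenomicInterval]"
    deletions: "list[GenomicInterval]"
    region_states: "dict[str, str]"
    chrom: str = "locus"

    @property
    def name(self) -> str:
        return f"{self.species}_hap{self.hap_index + 1}"


def evolve_haplotypes(
    tree: SpeciesTree,
    ancestral: str,
    events: Sequence[EventSpec],
    locus_map: LocusMap,
    truth: "TruthSet | None" = None,
    realize_sequence: bool = True,
) -> "tuple[dict[str, tuple[Haplotype, Haplotype]], TruthSet]":
    """Propagate planted events down the tree to per-species haplotypes.

    Every leaf inherits all events on its root path.  A homozygous event
    applies to both haplotypes; a heterozygous event applies to the
    second haplotype of its designated species only.  Inversions toggle
    the net state of their region, so applying the same inversion twice
    along a lineage restores the ancestral orientation.
    """
    truth = truth or TruthSet(locus_map=locus_map)
    truth.events = list(events)
    anc_codes = encode_sequence(ancestral)
    L = len(anc_codes)
    spans = span_regions(locus_map)

    for ev in events:
        if not tree.has_branch(ev.branch):
            raise ValueError(f"event on unknown branch {ev.branch!r}")
        if ev.region is not None and ev.region not in locus_map.regions:
            raise ValueError(f"event names unknown region {ev.region!r}")
        if ev.interval is not None and ev.interval.end > L:
            raise ValueError("event breakpoints outside sequence")
        if ev.zygosity == "het" and ev.species is None and not tree.is_leaf(ev.branch):
            raise ValueError("heterozygous event needs a designated species")

    haplotypes: dict[str, tuple[Haplotype, Haplotype]] = {}
    for sp in tree.leaf_labels:
        path = set(tree.path_to_root(sp))
        haps = []
        for hap_idx in (0, 1):
            toggles: dict[str, int] = {name: 0 for name in locus_map.regions}
            interval_toggles: list[GenomicInterval] = []
            dels: list[GenomicInterval] = []
            for ev in events:
                if ev.branch not in path:
                    continue
                if ev.zygosity == "het":
                    carrier = ev.species or ev.branch
                    if carrier != sp or hap_idx != 1:
                        continue
                if ev.kind == "inversion":
                    if ev.region is not None:
                        toggles[ev.region] += 1
                    else:
                        interval_toggles.append(ev.interval)
                elif ev.kind == "deletion":
                    dels.append(ev.interval or locus_map.regions[ev.region])
                else:
                    raise ValueError(f"unknown event kind {ev.kind!r}")

            region_states = {
                name: ("inv" if toggles[name] % 2 else "dir")
                for name in locus_map.regions
            }
            inverted_content = [
                locus_map.regions[name]
                for name in locus_map.regions
                if region_states[name] == "inv" and name not in spans
            ]
            # ad hoc interval inversions behave like content regions
            for iv in interval_toggles:
                if iv in inverted_content:
                    inverted_content.remove(iv)
                else:
                    inverted_content.append(iv)

            seq = None
            if realize_sequence:
                codes = anc_codes.copy()
                for iv in inverted_content:
                    codes[iv.start : iv.end] = revcomp_codes(
                        codes[iv.start : iv.end]
                    )
                if dels:
                    keep = np.ones(L, dtype=bool)
                    for d in dels:
                        keep[d.start : d.end] = False
                    codes = codes[keep]
                seq = decode_sequence(codes)

            hap = Haplotype(
                species=sp,
                hap_index=hap_idx,
                length=L,
                sequence=seq,
                inversions=sorted(inverted_content, key=lambda i: i.start),
                deletions=sorted(dels, key=lambda i: i.start),
                region_states=region_states,
                chrom=next(iter(locus_map.regions.values())).chrom
                if locus_map.regions
                else "locus",
            )
            haps.append(hap)
            key = (sp, hap_idx)
            truth.region_states[key] = region_states
            truth.inversions[key] = hap.inversions
            truth.deletions[key] = hap.deletions
        haplotypes[sp] = (haps[0], haps[1])
    return haplotypes, truth


def simulate_strandseq_cells(
    haplotypes: "tuple[Haplotype, Haplotype]",
    n_cells: int,
    bin_size: int,
    depth: float,
    epsilon: float,
    rng: np.random.Generator,
):
    """Simulate binned Watson/Crick counts for one diploid individual.

    Per cell and homolog a template strand is drawn with probability 1/2;
    per-bin homolog read counts are Poisson with mean ``depth/2`` (so a
    diploid bin averages ``depth`` reads).  Reads from bins inside an
    inverted interval of a carrier homolog take the opposite strand, and
    every read independently flips strand with probability ``epsilon``.
    Heterozygous deletions silence the carrier homolog's bins (halving
    coverage); homozygous deletions silence both.

    Returns ``(CellCountMatrix, template_states)`` where
    ``template_states[cell] = (hap1_strand, hap2_strand)``.
    """
    from .strand import CellCountMatrix  # analysis-side container

    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not 0 <= epsilon < 0.5:
        raise ValueError("epsilon must be in [0, 0.5)")
    hap1, hap2 = haplotypes
    L = hap1.length
    if bin_size > L:
        raise ValueError("bin_size larger than sequence")
    chrom = hap1.chrom

    starts = np.arange(0, L, bin_size)
    ends = np.minimum(starts + bin_size, L)
    n_bins = len(starts)
    bins = [
        GenomicInterval(chrom, int(s), int(e), label=f"bin{i}")
        for i, (s, e) in enumerate(zip(starts, ends))
    ]

    def bin_fraction(intervals: "list[GenomicInterval]") -> np.ndarray:
        frac = np.zeros(n_bins)
        for iv in intervals:
            ov = np.maximum(
                0, np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
            )
            frac += ov / (ends - starts)
        return np.minimum(frac, 1.0)

    hap_info = []
    for hap in (hap1, hap2):
        inv_mask = bin_fraction(hap.inversions) > 0.5
        present = 1.0 - bin_fraction(hap.deletions)
        hap_info.append((inv_mask, present))

    W = np.zeros((n_cells, n_bins), dtype=np.int64)
    C = np.zeros((n_cells, n_bins), dtype=np.int64)
    templates: list[tuple[str, str]] = []
    for cell in range(n_cells):
        cell_templates = []
        for inv_mask, present in hap_info:
            template = "W" if rng.random() < 0.5 else "C"
            cell_templates.append(template)
            counts = rng.poisson(depth / 2.0 * present)
            is_w = np.full(n_bins, template == "W")
            is_w ^= inv_mask
            flipped = rng.binomial(counts, epsilon)
            w_reads = np.where(is_w, counts - flipped, flipped)
            W[cell] += w_reads
            C[cell] += counts - w_reads
        templates.append(tuple(cell_templates))

    matrix = CellCountMatrix(
        bins=bins,
        W=W,
        C=C,
        cells=[f"cell{idx:03d}" for idx in range(n_cells)],
    )
    return matrix, templates


def simulate_fish_observations(
    haplotypes: "tuple[Haplotype, Haplotype]",
    probes: "Sequence[tuple[str, int]]",
    region: GenomicInterval,
    flip_noise: float = 0.0,
    rng: "np.random.Generator | None" = None,
) -> "list[str]":
    """Three-probe interphase assay for one region of one individual.

    ``probes`` are ``(label, reference_position)`` with exactly two
    probes inside ``region`` and one reference probe outside.  Each
    haplotype yields the left-to-right probe order anchored so the
    reference probe comes last; with probability ``flip_noise`` the inner
    probe pair of an observation is swapped (scoring error).  A probe
    lost to a deletion leaves a two-signal observation.
    """
    if len(probes) != 3:
        raise ValueError("exactly 3 probes are required")
    inside = [p for p in probes if region.contains_point(p[1])]
    outside = [p for p in probes if not region.contains_point(p[1])]
    if len(inside) != 2 or len(outside) != 1:
        raise ValueError("need two probes inside the region and one outside")
    rng = rng or np.random.default_rng(0)
    ref_label = outside[0][0]

    observations = []
    for hap in haplotypes:
        state = hap.region_states.get(region.label)
        if state is None:
            state = "inv" if any(iv.contains(region) for iv in hap.inversions) else "dir"
        placed = []
        for label, pos in probes:
            if any(d.contains_point(pos) for d in hap.deletions):
                continue  # probe deleted: signal lost
            if state == "inv" and region.contains_point(pos):
                pos = region.start + region.end - 1 - pos
            placed.append((pos, label))
        placed.sort()
        labels = [lab for _, lab in placed]
        if labels and labels[0] == ref_label:
            labels.reverse()
        if len(labels) == 3 and flip_noise > 0 and rng.random() < flip_noise:
            labels[0], labels[1] = labels[1], labels[0]
        observations.append("-".join(labels))
    return observations


# ---------------------------------------------------------------------------
# blueprint factories
# ---------------------------------------------------------------------------

def human_sd_blueprint(scale: float = 10.0, seed: int = 0) -> LocusBlueprint:
    """Human-like SD architecture of the locus (real lengths, scaled).

    Plants the published pairwise block structure: a 160 kbp block at 99%
    identity in both orientations plus a 320 kbp direct block at 98%
    between BP1 and BP3; a 100 kbp block at 98% in both orientations
    between BP2 and BP3; and a 35 kbp block at 99% in both orientations
    between BP4 and BP5.  Inter-block region lengths follow the printed
    locus coordinates.
    """
    kb = 1000
    segs = [
        SegmentSpec("unique", "bp1_pad_a", 20 * kb, block="BP1"),
        SegmentSpec("unique", "s160", 160 * kb, block="BP1"),
        SegmentSpec("unique", "s320", 320 * kb, block="BP1"),
        SegmentSpec("unique", "bp1_pad_b", 20 * kb, block="BP1"),
        SegmentSpec("unique", "r12", 720 * kb, region="BP1-BP2"),
        SegmentSpec("unique", "bp2_pad_a", 20 * kb, block="BP2"),
        SegmentSpec("unique", "s100", 100 * kb, block="BP2"),
        SegmentSpec("unique", "bp2_pad_b", 20 * kb, block="BP2"),
        SegmentSpec("unique", "r23", 4686 * kb, region="BP2-BP3"),
        SegmentSpec("unique", "bp3_pad_a", 10 * kb, block="BP3"),
        SegmentSpec("sd_copy", "c160_dir", source_id="s160", identity=0.99,
                    orientation="direct", block="BP3"),
        SegmentSpec("sd_copy", "c160_inv", source_id="s160", identity=0.99,
                    orientation="inverted", block="BP3"),
        SegmentSpec("sd_copy", "c320_dir", source_id="s320", identity=0.98,
                    orientation="direct", block="BP3"),
        SegmentSpec("sd_copy", "c100_dir", source_id="s100", identity=0.98,
                    orientation="direct", block="BP3"),
        SegmentSpec("sd_copy", "c100_inv", source_id="s100", identity=0.98,
                    orientation="inverted", block="BP3"),
        SegmentSpec("unique", "bp3_pad_b", 10 * kb, block="BP3"),
        SegmentSpec("unique", "r34", 1230 * kb, region="BP3-BP4"),
        SegmentSpec("unique", "bp4_pad_a", 10 * kb, block="BP4"),
        SegmentSpec("unique", "s35", 35 * kb, block="BP4"),
        SegmentSpec("unique", "bp4_pad_b", 10 * kb, block="BP4"),
        SegmentSpec("unique", "r45", 1246 * kb, region="BP4-BP5"),
        SegmentSpec("unique", "bp5_pad_a", 10 * kb, block="BP5"),
        SegmentSpec("sd_copy", "c35_dir", source_id="s35", identity=0.99,
                    orientation="direct", block="BP5"),
        SegmentSpec("sd_copy", "c35_inv", source_id="s35", identity=0.99,
                    orientation="inverted", block="BP5"),
        SegmentSpec("unique", "bp5_pad_b", 10 * kb, block="BP5"),
    ]
    return LocusBlueprint(
        name="human_like",
        segments=segs,
        scale=scale,
        spans={"BP3-BP5": ("BP3", "BP5")},
        seed=seed,
    )


def macaque_sd_blueprint(scale: float = 10.0, seed: int = 1) -> LocusBlueprint:
    """Macaque-like architecture: sparse SDs, tandem inverted clusters.

    Total planted duplication content is one third of the human-like
    blueprint (1525 kbp vs ~508 kbp real scale), and the only
    high-identity directly oriented block flanking the BP1..BP3 interval
    is 30 kbp at 98.5% -- one sixteenth of the human-like 480 kbp of
    direct flanking homology.
    """
    kb = 1000
    segs = [
        SegmentSpec("unique", "bpa_pad_a", 20 * kb, block="BP1"),
        SegmentSpec("unique", "mA", 100 * kb, block="BP1"),
        SegmentSpec("unique", "m30", 30 * kb, block="BP1"),
        SegmentSpec("unique", "mB", 37 * kb, block="BP1"),
        SegmentSpec("unique", "bpa_pad_b", 20 * kb, block="BP1"),
        SegmentSpec("unique", "r12", 720 * kb, region="BP1-BP2"),
        SegmentSpec("unique", "bpb_pad_a", 20 * kb, block="BP2"),
        SegmentSpec("sd_copy", "mA_dir", source_id="mA", identity=0.98,
                    orientation="direct", block="BP2"),
        SegmentSpec("sd_copy", "mA_inv", source_id="mA", identity=0.98,
                    orientation="inverted", block="BP2"),
        SegmentSpec("sd_copy", "mB_c1", source_id="mB", identity=0.97,
                    orientation="inverted", block="BP2"),
        SegmentSpec("unique", "bpb_pad_b", 20 * kb, block="BP2"),
        SegmentSpec("unique", "r23", 4686 * kb, region="BP2-BP3"),
        SegmentSpec("unique", "bpc_pad_a", 10 * kb, block="BP3"),
        SegmentSpec("sd_copy", "m30_dir", source_id="m30", identity=0.985,
                    orientation="direct", block="BP3"),
        SegmentSpec("sd_copy", "mB_c2", source_id="mB", identity=0.97,
                    orientation="inverted", block="BP3"),
        SegmentSpec("unique", "bpc_pad_b", 10 * kb, block="BP3"),
        SegmentSpec("unique", "r34", 1230 * kb, region="BP3-BP4"),
        SegmentSpec("unique", "bpd_pad_a", 10 * kb, block="BP4"),
        SegmentSpec("sd_copy", "mB_c3", source_id="mB", identity=0.97,
                    orientation="inverted", block="BP4"),
        SegmentSpec("unique", "bpd_pad_b", 10 * kb, block="BP4"),
        SegmentSpec("unique", "r45", 1246 * kb, region="BP4-BP5"),
        SegmentSpec("unique", "bpe_pad", 30 * kb, block="BP5"),
    ]
    return LocusBlueprint(
        name="macaque_like",
        segments=segs,
        scale=scale,
        spans={"BP3-BP5": ("BP3", "BP5")},
        seed=seed,
    )


def inversion_history_blueprint(scale: float = 10.0, seed: int = 0) -> LocusBlueprint:
    """Compact locus for evolutionary-history simulations.

    Small BP blocks carry copies of one shared core duplication (so each
    candidate region is SD-flanked); inter-block regions use the
    published working sizes.  Pair with :func:`table1_history_events`.
    """
    kb = 1000
    segs = [
        SegmentSpec("unique", "bp1_pad", 20 * kb, block="BP1"),
        SegmentSpec("unique", "core", 40 * kb, block="BP1"),
        SegmentSpec("unique", "r12", 300 * kb, region="BP1-BP2"),
        SegmentSpec("unique", "bp2_pad", 20 * kb, block="BP2"),
        SegmentSpec("sd_copy", "core_b2", source_id="core", identity=0.95,
                    orientation="inverted", block="BP2"),
        SegmentSpec("unique", "r23", 600 * kb, region="BP2-BP3"),
        SegmentSpec("unique", "bp3_pad", 20 * kb, block="BP3"),
        SegmentSpec("sd_copy", "core_b3", source_id="core", identity=0.95,
                    orientation="direct", block="BP3"),
        SegmentSpec("unique", "r34", 400 * kb, region="BP3-BP4"),
        SegmentSpec("unique", "bp4_pad", 20 * kb, block="BP4"),
        SegmentSpec("sd_copy", "core_b4", source_id="core", identity=0.95,
                    orientation="inverted", block="BP4"),
        SegmentSpec("unique", "r45", 400 * kb, region="BP4-BP5"),
        SegmentSpec("unique", "bp5_pad", 20 * kb, block="BP5"),
        SegmentSpec("sd_copy", "core_b5", source_id="core", identity=0.95,
                    orientation="direct", block="BP5"),
    ]
    return LocusBlueprint(
        name="history_locus",
        segments=segs,
        scale=scale,
        spans={"BP3-BP5": ("BP3", "BP5")},
        seed=seed,
    )


def table1_history_events() -> "list[EventSpec]":
    """The published inversion history: five ancestral events plus the
    three extant polymorphisms, expressed as per-branch planted events."""
    return [
        EventSpec("African great ape ancestor", "inversion", region="BP1-BP2"),
        EventSpec("African great ape ancestor", "inversion", region="BP2-BP3"),
        EventSpec("HSA", "inversion", region="BP2-BP3", zygosity="het",
                  species="HSA"),
        EventSpec("great apes ancestor", "inversion", region="BP3-BP5"),
        EventSpec("great apes ancestor", "inversion", region="BP3-BP4"),
        EventSpec("GGO", "inversion", region="BP3-BP4", zygosity="het",
                  species="GGO"),
        EventSpec("Catarrhini ancestor", "inversion", region="BP4-BP5"),
        EventSpec("HSA", "inversion", region="BP4-BP5", zygosity="het",
                  species="HSA"),
    ]


#: the ancestral branch each region's main planted event sits on
TABLE1_PLANTED_BRANCHES = {
    "BP1-BP2": "African great ape ancestor",
    "BP2-BP3": "African great ape ancestor",
    "BP3-BP5": "great apes ancestor",
    "BP3-BP4": "great apes ancestor",
    "BP4-BP5": "Catarrhini ancestor",
}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_haplotypes_fasta(
    haplotypes: "Mapping[str, tuple[Haplotype, Haplotype]]", path
) -> None:
    records = []
    for sp in haplotypes:
        for hap in haplotypes[sp]:
            if hap.sequence is None:
                raise ValueError(f"haplotype {hap.name} has no realized sequence")
            records.append(SeqRecord(Seq(hap.sequence), id=hap.name, description=""))
    SeqIO.write(records, path, "fasta")


def read_haplotypes_fasta(path) -> "dict[str, str]":
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_truth_bed(truth: TruthSet, path) -> None:
    """Planted SD pairs as paired BED rows (two rows per pair)."""
    with open(path, "w") as fh:
        for idx, pair in enumerate(truth.sd_pairs):
            name = f"sd_pair_{idx}"
            for side, iv in (("source", pair.source), ("copy", pair.copy)):
                strand = "+" if pair.orientation == "direct" else "-"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}_{side}\t"
                    f"{pair.identity:.4f}\t{strand}\n"
                )
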