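"""Shared coordinate, region, tree, and genotype types.

All coordinates are 0-based half-open internally.  Printed tables in
UCSC style (1-based, inclusive) are converted at the I/O boundary only;
see :func:`convert_coordinates`.

The module also ships two small fixtures used throughout the package:

* a tab-separated table with the five candidate regions of the
  15q11-q13 locus (chr15, T2T CHM13v2.0 coordinates) and the published
  orientation genotypes of six primate species, and
* the default rooted species tree
  ``(CJA,(MMU,(PPY,(GGO,(HSA,PTR)))))`` with labelled ancestral branches.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator

import dendropy
import pandas as pd

__all__ = [
    "GenomicInterval",
    "CoordinateSystem",
    "convert_coordinates",
    "OrientationGenotype",
    "LocusMap",
    "SpeciesTree",
    "REGION_ORDER",
    "SPECIES_ORDER",
    "load_table1_fixture",
]

#: canonical region order of the locus (proximal to distal); BP3-BP5 spans
#: BP3-BP4 and BP4-BP5 and is listed between them and BP2-BP3 as printed.
REGION_ORDER = ("BP1-BP2", "BP2-BP3", "BP3-BP5", "BP3-BP4", "BP4-BP5")

#: species abbreviations, reference species first, outgroup last.
SPECIES_ORDER = ("HSA", "PTR", "GGO", "PPY", "MMU", "CJA")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_len(other) > 0

    def shift(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        tag = f" ({self.label})" if self.label else ""
        return f"{self.chrom}:{self.start}-{self.end}{tag}"


class CoordinateSystem(str, enum.Enum):
    """Supported genomic coordinate conventions."""

    ZERO_HALF_OPEN = "0-based half-open"
    ONE_INCLUSIVE = "1-based inclusive"

    @classmethod
    def parse(cls, tag: "str | CoordinateSystem") -> "CoordinateSystem":
        if isinstance(tag, cls):
            return tag
        norm = str(tag).strip().lower()
        if norm.startswith("0"):
            return cls.ZERO_HALF_OPEN
        if norm.startswith("1"):
            return cls.ONE_INCLUSIVE
        raise ValueError(f"unknown coordinate system {tag!r}")


def convert_coordinates(
    interval: GenomicInterval,
    from_system: "str | CoordinateSystem",
    to_system: "str | CoordinateSystem",
) -> GenomicInterval:
    """Convert an interval between coordinate conventions.

    The conversion is an involution: converting back restores the
    original interval, and the interval length is preserved.
    """
    src = CoordinateSystem.parse(from_system)
    dst = CoordinateSystem.parse(to_system)
    if src is dst:
        return interval
    if src is CoordinateSystem.ONE_INCLUSIVE:
        # [s, e] 1-based inclusive -> [s-1, e) 0-based half-open
        return replace(interval, start=interval.start - 1, end=interval.end)
    # [s, e) 0-based half-open -> [s+1, e] 1-based inclusive
    return replace(interval, start=interval.start + 1, end=interval.end)


class OrientationGenotype(enum.Enum):
    """Diploid orientation genotype of a candidate region."""

    DIR_DIR = "dir/dir"
    DIR_INV = "dir/inv"
    INV_INV = "inv/inv"
    MISSING = "missing"

    @classmethod
    def from_string(cls, text: str) -> "OrientationGenotype":
        norm = text.strip().lower().rstrip("*").strip()
        if norm in ("n.a.", "na", "n.a", ".", "", "missing"):
            return cls.MISSING
        if norm == "inv/dir":
            norm = "dir/inv"
        for member in cls:
            if member.value == norm:
                return member
        raise ValueError(f"unrecognized orientation genotype {text!r}")

    @property
    def allele_set(self) -> "frozenset[str] | None":
        """Allele set {d}, {i} or {d,i}; ``None`` when missing."""
        return {
            OrientationGenotype.DIR_DIR: frozenset("d"),
            OrientationGenotype.DIR_INV: frozenset("di"),
            OrientationGenotype.INV_INV: frozenset("i"),
            OrientationGenotype.MISSING: None,
        }[self]

    @property
    def alleles(self) -> "tuple[str, str] | None":
        return {
            OrientationGenotype.DIR_DIR: ("d", "d"),
            OrientationGenotype.DIR_INV: ("d", "i"),
            OrientationGenotype.INV_INV: ("i", "i"),
            OrientationGenotype.MISSING: None,
        }[self]

    @property
    def is_het(self) -> bool:
        return self is OrientationGenotype.DIR_INV

    def __str__(self) -> str:
        return self.value


@dataclass
class LocusMap:
    """The five SD breakpoint blocks and the candidate regions between them.

    ``bp_blocks`` are ordered proximal to distal (BP1..BP5; lettered
    BPA..BPE when describing nonhuman primates).  ``regions`` holds the
    inter-block candidate intervals; BP3-BP5 *nests* BP3-BP4 and BP4-BP5,
    all other regions are pairwise disjoint (adjacent printed regions may
    share a single boundary base, which is tolerated).
    """

    bp_blocks: "list[GenomicInterval]"
    regions: "dict[str, GenomicInterval]"

    #: regions that are required to be mutually non-overlapping
    DISJOINT_REGIONS = ("BP1-BP2", "BP2-BP3", "BP3-BP4", "BP4-BP5")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if "BP3-BP5" in self.regions:
            outer = self.regions["BP3-BP5"]
            for inner_name in ("BP3-BP4", "BP4-BP5"):
                if inner_name in self.regions and not outer.contains(
                    self.regions[inner_name]
                ):
                    raise ValueError(f"{inner_name} is not nested in BP3-BP5")
        names = [n for n in self.DISJOINT_REGIONS if n in self.regions]
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                # printed 1-based inclusive tables let adjacent regions
                # share the boundary base; allow exactly that much overlap
                if self.regions[a].overlap_len(self.regions[b]) > 1:
                    raise ValueError(f"regions {a} and {b} overlap")

    def block_labels(self) -> "list[str]":
        return [b.label for b in self.bp_blocks]

    def block_of(self, chrom: str, pos: int) -> "str | None":
        """Label of the BP block containing ``pos``, or None."""
        for block in self.bp_blocks:
            if block.chrom == chrom and block.contains_point(pos):
                return block.label
        return None

    def region(self, name: str) -> GenomicInterval:
        return self.regions[name]


class SpeciesTree:
    """A small rooted species tree with uniquely labelled nodes.

    Every node (leaf or internal) carries a label; a branch is referred
    to by the label of the node it subtends.  The default tree is
    ``(CJA,(MMU,(PPY,(GGO,(HSA,PTR)))))`` with the ancestors of
    {HSA,PTR,GGO}, {..,PPY} and {..,MMU} labelled "African great ape
    ancestor", "great apes ancestor" and "Catarrhini ancestor".
    """

    def __init__(self, newick: str):
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        self._children: dict[str, tuple[str, ...]] = {}
        self._parent: dict[str, str | None] = {}
        self._depth: dict[str, int] = {}
        self.leaf_labels: list[str] = []

        def label_of(node: dendropy.Node) -> str:
            if node.taxon is not None:
                return node.taxon.label
            if node.label:
                return node.label
            raise ValueError("every tree node must be labelled")

        root = tree.seed_node
        self.root_label = label_of(root)
        for node in tree.preorder_node_iter():
            lab = label_of(node)
            if lab in self._children:
                raise ValueError(f"duplicate node label {lab!r}")
            kids = tuple(label_of(c) for c in node.child_nodes())
            self._children[lab] = kids
            parent = node.parent_node
            self._parent[lab] = label_of(parent) if parent is not None else None
            self._depth[lab] = (
                0 if parent is None else self._depth[label_of(parent)] + 1
            )
            if not kids:
                self.leaf_labels.append(lab)

    @classmethod
    def default(cls) -> "SpeciesTree":
        text = (
            resources.files("sdlocus.data").joinpath("species_tree.nwk").read_text()
        )
        return cls(text)

    # -- topology queries ---------------------------------------------------
    def children(self, label: str) -> "tuple[str, ...]":
        return self._children[label]

    def parent(self, label: str) -> "str | None":
        return self._parent[label]

    def depth(self, label: str) -> int:
        return self._depth[label]

    def is_leaf(self, label: str) -> bool:
        return not self._children[label]

    def nodes(self) -> "list[str]":
        return list(self._children)

    def internal_labels(self) -> "list[str]":
        return [n for n in self._children if self._children[n]]

    def branches(self) -> "list[str]":
        """All branch labels (every node except the root)."""
        return [n for n in self._children if n != self.root_label]

    def has_branch(self, label: str) -> bool:
        return label in self._children and label != self.root_label

    def postorder(self) -> Iterator[str]:
        def _walk(label: str) -> Iterator[str]:
            for child in self._children[label]:
                yield from _walk(child)
            yield label

        return _walk(self.root_label)

    def leaves_under(self, label: str) -> "list[str]":
        if self.is_leaf(label):
            return [label]
        out: list[str] = []
        for child in self._children[label]:
            out.extend(self.leaves_under(child))
        return out

    def path_to_root(self, label: str) -> "list[str]":
        """Branch labels from ``label`` up to (excluding) the root."""
        out = []
        cur: str | None = label
        while cur is not None and cur != self.root_label:
            out.append(cur)
            cur = self._parent[cur]
        return out

    def newick(self) -> str:
        def _fmt(label: str) -> str:
            kids = self._children[label]
            quoted = f"'{label}'" if " " in label else label
            if not kids:
                return quoted
            return "(" + ",".join(_fmt(k) for k in kids) + ")" + quoted

        return _fmt(self.root_label) + ";"


def _fixture_frame() -> pd.DataFrame:
    path = resources.files("sdlocus.data").joinpath("table1.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype=str)
    expected = {"region", "chrom", "start", "end", *SPECIES_ORDER, "evolution"}
    if set(df.columns) != expected or len(df) != len(REGION_ORDER):
        raise RuntimeError("packaged locus fixture is corrupted")
    return df


def load_table1_fixture():
    """Load the packaged locus table.

    Returns a ``(LocusMap, CharacterMatrix)`` pair: the five candidate
    regions with coordinates converted from the printed 1-based inclusive
    convention to 0-based half-open, and the 6-species x 5-region
    orientation genotype matrix (chimpanzee BP3-BP5 is missing, being
    interrupted by a *Pan*-specific pericentric inversion).

    BP block intervals are not printed; they are inferred from the gaps
    between consecutive printed regions (and the published locus bounds
    chr15:17,691,439-30,429,130 for the outermost blocks).  The BP2 block
    collapses to a 1 bp placeholder because the flanking regions share
    their printed boundary.
    """
    from .evolution import CharacterMatrix  # local import: avoid a cycle

    df = _fixture_frame()
    regions: dict[str, GenomicInterval] = {}
    genotypes: dict[tuple[str, str], OrientationGenotype] = {}
    for _, row in df.iterrows():
        printed = GenomicInterval(
            row["chrom"], int(row["start"]), int(row["end"]), label=row["region"]
        )
        regions[row["region"]] = convert_coordinates(
            printed, CoordinateSystem.ONE_INCLUSIVE, CoordinateSystem.ZERO_HALF_OPEN
        )
        for sp in SPECIES_ORDER:
            genotypes[(row["region"], sp)] = OrientationGenotype.from_string(row[sp])

    chrom = df["chrom"].iloc[0]
    locus_start, locus_end = 17_691_438, 30_429_130  # 0-based locus bounds
    r = regions
    bp_blocks = [
        GenomicInterval(chrom, locus_start, r["BP1-BP2"].start, label="BP1"),
        # the printed BP1-BP2 and BP2-BP3 regions share their boundary, so
        # the BP2 block has no printed extent; keep a 1 bp placeholder.
        GenomicInterval(chrom, r["BP2-BP3"].start, r["BP2-BP3"].start + 1, label="BP2"),
        GenomicInterval(chrom, r["BP2-BP3"].end, r["BP3-BP4"].start, label="BP3"),
        GenomicInterval(chrom, r["BP3-BP4"].end, r["BP4-BP5"].start, label="BP4"),
        GenomicInterval(chrom, r["BP4-BP5"].end, locus_end, label="BP5"),
    ]
    locus_map = LocusMap(bp_blocks=bp_blocks, regions=regions)
    matrix = CharacterMatrix.from_genotypes(
        genotypes,
        regions=list(REGION_ORDER),
        species=list(SPECIES_ORDER),
        provenance="fixture",
    )
    return locus_map, matrix


def locus_map_to_tsv(locus_map: LocusMap, path) -> None:
    """Write a locus map as a plain table (kind, label, chrom, start, end)."""
    rows = [
        {"kind": "block", "label": b.label, "chrom": b.chrom,
         "start": b.start, "end": b.end}
        for b in locus_map.bp_blocks
    ] + [
        {"kind": "region", "label": name, "chrom": iv.chrom,
         "start": iv.start, "end": iv.end}
        for name, iv in locus_map.regions.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def locus_map_from_tsv(path) -> LocusMap:
    df = pd.read_csv(path, sep="\t")
    blocks, regions = [], {}
    for row in df.itertuples():
        iv = GenomicInterval(str(row.chrom), int(row.start), int(row.end),
                             label=str(row.label))
        if row.kind == "block":
            blocks.append(iv)
        else:
            regions[str(row.label)] = iv
    return LocusMap(bp_blocks=blocks, regions=regions)


def load_evolution_annotations() -> "dict[str, str]":
    """Published per-region ancestral-branch annotations from the fixture."""
    df = _fixture_frame()
    return dict(zip(df["region"], df["evolution"]))
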