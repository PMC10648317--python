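"""Inversion-history reconstruction on a species tree.

Each candidate region is treated as an independent two-state character
(direct ``d`` / inverted ``i``).  Heterozygous species enter parsimony as
the ambiguity set ``{d,i}`` (cheapest-resolution semantics) and are
reported separately as polymorphic; missing species contribute the full
state set at their leaf.  Events are placed by enumerating all
most-parsimonious reconstructions and preferring the reconstruction
whose earliest state change lies on the most basal branch, which encodes
the interpretation "single ancestral event plus later reversions" for
discordant characters (the reversions are reported as recurrent).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import (
    OrientationGenotype,
    REGION_ORDER,
    SPECIES_ORDER,
    SpeciesTree,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CharacterMatrix",
    "EvidenceCall",
    "EventPlacement",
    "build_character_matrix",
    "fitch_min_changes",
    "place_events",
    "summarize_evolution",
    "enumerate_haplotypes",
    "inverted_allele_frequency",
    "genotype_from_probe_order",
]

FULL_SET = frozenset("di")


@dataclass(frozen=True)
class EvidenceCall:
    """One orientation genotype for one region in one species.

    ``source`` records the evidence modality (``strand-seq``,
    ``homology``, ``probe-order`` or ``fixture``).
    """

    region: str
    species: str
    genotype: OrientationGenotype
    source: str


@dataclass
class CharacterMatrix:
    """Per-region x per-species orientation genotypes with provenance."""

    regions: "list[str]"
    species: "list[str]"
    genotypes: "dict[tuple[str, str], OrientationGenotype]"
    provenance: "dict[tuple[str, str], str]" = field(default_factory=dict)
    conflicts: "list[tuple[str, str, str]]" = field(default_factory=list)

    @classmethod
    def from_genotypes(
        cls,
        genotypes: Mapping[tuple[str, str], OrientationGenotype],
        regions: Sequence[str],
        species: Sequence[str],
        provenance: str = "unknown",
    ) -> "CharacterMatrix":
        return cls(
            regions=list(regions),
            species=list(species),
            genotypes=dict(genotypes),
            provenance={key: provenance for key in genotypes},
        )

    def genotype(self, species: str, region: str) -> OrientationGenotype:
        return self.genotypes.get((region, species), OrientationGenotype.MISSING)

    def allele_set(self, species: str, region: str) -> "frozenset[str] | None":
        return self.genotype(species, region).allele_set

    def character(self, region: str) -> "dict[str, frozenset[str] | None]":
        """Leaf allele sets for one region (None = missing)."""
        return {sp: self.allele_set(sp, region) for sp in self.species}

    def polymorphic_species(self, region: str) -> "list[str]":
        return [sp for sp in self.species if self.genotype(sp, region).is_het]

    def to_frame(self) -> pd.DataFrame:
        data = {
            sp: [self.genotype(sp, rg).value for rg in self.regions]
            for sp in self.species
        }
        return pd.DataFrame(data, index=list(self.regions))

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("region").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CharacterMatrix":
        df = pd.read_csv(path, sep="\t", index_col="region", dtype=str)
        genotypes = {
            (region, sp): OrientationGenotype.from_string(df.at[region, sp])
            for region in df.index
            for sp in df.columns
        }
        return cls.from_genotypes(
            genotypes, regions=list(df.index), species=list(df.columns),
            provenance="table",
        )


def build_character_matrix(
    calls: Iterable[EvidenceCall],
    regions: "Sequence[str] | None" = None,
    species: "Sequence[str] | None" = None,
) -> CharacterMatrix:
    """Integrate orientation evidence from multiple modalities.

    Sources that agree yield that genotype; any disagreement between
    non-missing sources yields ``missing`` with the conflict logged.  A
    heterozygous (dir/inv) call from any source marks the cell
    heterozygous (ambiguity set {d,i} downstream).
    """
    calls = list(calls)
    by_cell: dict[tuple[str, str], list[EvidenceCall]] = {}
    for call in calls:
        by_cell.setdefault((call.region, call.species), []).append(call)

    regions = list(regions) if regions is not None else sorted(
        {c.region for c in calls},
        key=lambda r: REGION_ORDER.index(r) if r in REGION_ORDER else 99,
    )
    species = list(species) if species is not None else sorted(
        {c.species for c in calls},
        key=lambda s: SPECIES_ORDER.index(s) if s in SPECIES_ORDER else 99,
    )

    genotypes: dict[tuple[str, str], OrientationGenotype] = {}
    provenance: dict[tuple[str, str], str] = {}
    conflicts: list[tuple[str, str, str]] = []
    for key, cell_calls in by_cell.items():
        informative = [
            c for c in cell_calls if c.genotype is not OrientationGenotype.MISSING
        ]
        if not informative:
            genotypes[key] = OrientationGenotype.MISSING
            provenance[key] = "+".join(sorted({c.source for c in cell_calls}))
            continue
        states = {c.genotype for c in informative}
        if len(states) == 1:
            genotypes[key] = informative[0].genotype
        else:
            detail = ", ".join(f"{c.source}={c.genotype}" for c in informative)
            logger.warning("conflicting evidence for %s/%s: %s", *key, detail)
            conflicts.append((key[0], key[1], detail))
            genotypes[key] = OrientationGenotype.MISSING
        provenance[key] = "+".join(sorted({c.source for c in informative}))

    matrix = CharacterMatrix(
        regions=regions, species=species, genotypes=genotypes,
        provenance=provenance, conflicts=conflicts,
    )
    return matrix


def _leaf_sets(
    character: Mapping[str, "frozenset[str] | None"], tree: SpeciesTree
) -> "dict[str, frozenset[str]]":
    sets = {}
    for leaf in tree.leaf_labels:
        s = character.get(leaf)
        sets[leaf] = FULL_SET if s is None else frozenset(s)
    return sets


def fitch_min_changes(
    tree: SpeciesTree, character: Mapping[str, "frozenset[str] | None"]
) -> int:
    """Minimum number of state changes for one character (Fitch parsimony).

    Leaves carry allele sets ({d}, {i} or the ambiguity set {d,i});
    missing leaves contribute the full set.  Requires at least two
    unambiguously scored leaves.
    """
    sets = _leaf_sets(character, tree)
    scored = [leaf for leaf in tree.leaf_labels if character.get(leaf) is not None]
    if len(scored) < 2:
        raise ValueError("need at least 2 non-missing leaves")
    state: dict[str, frozenset[str]] = {}
    changes = 0
    for node in tree.postorder():
        kids = tree.children(node)
        if not kids:
            state[node] = sets[node]
            continue
        merged = frozenset(FULL_SET)
        for kid in kids:
            inter = merged & state[kid]
            if inter:
                merged = inter
            else:
                merged = merged | state[kid]
                changes += 1
        state[node] = merged
    return changes


def _assignment_cost_and_changes(
    tree: SpeciesTree,
    leaf_sets: Mapping[str, "frozenset[str]"],
    assignment: Mapping[str, str],
) -> "tuple[int, list[tuple[str, str, str]]]":
    """Cost of an internal-state assignment and its implied changes.

    Returns ``(cost, changes)`` where each change is ``(branch, from, to)``;
    a terminal branch changes when the leaf set excludes the parent state
    (the leaf then takes its sole resolvable state).
    """
    changes: list[tuple[str, str, str]] = []
    for node in tree.nodes():
        if node == tree.root_label:
            continue
        parent_state = assignment[tree.parent(node)]
        if tree.is_leaf(node):
            leaf = leaf_sets[node]
            if parent_state not in leaf:
                (only,) = leaf if len(leaf) == 1 else (None,)
                changes.append((node, parent_state, only or "?"))
        else:
            node_state = assignment[node]
            if node_state != parent_state:
                changes.append((node, parent_state, node_state))
    return len(changes), changes


def brute_force_min_changes(
    tree: SpeciesTree, character: Mapping[str, "frozenset[str] | None"]
) -> int:
    """Minimum changes by exhaustion over all internal-state assignments."""
    sets = _leaf_sets(character, tree)
    internals = tree.internal_labels()
    best = None
    for combo in itertools.product("di", repeat=len(internals)):
        assignment = dict(zip(internals, combo))
        cost, _ = _assignment_cost_and_changes(tree, sets, assignment)
        best = cost if best is None else min(best, cost)
    return best


@dataclass
class EventPlacement:
    """An inversion event placed on the species tree for one region."""

    region: str
    branch: str
    flip: str  # e.g. "i->d": ancestral-to-derived state flip
    min_changes: int
    discordant: bool
    recurrent_branches: "list[str]" = field(default_factory=list)
    polymorphic_species: "list[str]" = field(default_factory=list)

    def to_row(self) -> "dict[str, object]":
        return {
            "region": self.region,
            "branch": self.branch,
            "flip": self.flip,
            "min_changes": self.min_changes,
            "discordant": self.discordant,
            "recurrent_branches": ",".join(self.recurrent_branches) or ".",
            "polymorphic_species": ",".join(self.polymorphic_species) or ".",
        }


def place_events(
    tree: SpeciesTree,
    character: Mapping[str, "frozenset[str] | None"],
    region: str = "",
    polymorphic_species: "Sequence[str] | None" = None,
) -> EventPlacement:
    """Place the inversion event of one region on the tree.

    All most-parsimonious reconstructions are enumerated by brute force
    over internal-node states.  The selected reconstruction is the one
    whose earliest change lies on the most basal branch (ties broken by
    fewer terminal-branch changes, then lexicographic branch order); its
    earliest change is the placement and any later changes are reported
    as recurrent.
    """
    sets = _leaf_sets(character, tree)
    internals = tree.internal_labels()
    candidates: list[tuple[int, list[tuple[str, str, str]]]] = []
    best = None
    for combo in itertools.product("di", repeat=len(internals)):
        assignment = dict(zip(internals, combo))
        cost, changes = _assignment_cost_and_changes(tree, sets, assignment)
        if best is None or cost < best:
            best = cost
            candidates = [(cost, changes)]
        elif cost == best:
            candidates.append((cost, changes))
    assert best is not None

    if polymorphic_species is None:
        polymorphic_species = [
            leaf for leaf in tree.leaf_labels if sets[leaf] == FULL_SET and
            character.get(leaf) is not None
        ]

    if best == 0:
        return EventPlacement(
            region=region, branch="none", flip="none", min_changes=0,
            discordant=False, polymorphic_species=list(polymorphic_species),
        )

    def sort_key(entry):
        _, changes = entry
        ordered = sorted(changes, key=lambda c: (tree.depth(c[0]), c[0]))
        earliest_depth = tree.depth(ordered[0][0])
        n_terminal = sum(1 for c in changes if tree.is_leaf(c[0]))
        names = tuple(sorted(c[0] for c in changes))
        return (earliest_depth, n_terminal, names)

    _, changes = min(candidates, key=sort_key)
    ordered = sorted(changes, key=lambda c: (tree.depth(c[0]), c[0]))
    branch, from_state, to_state = ordered[0]
    return EventPlacement(
        region=region,
        branch=branch,
        flip=f"{from_state}->{to_state}",
        min_changes=best,
        discordant=best >= 2,
        recurrent_branches=[c[0] for c in ordered[1:]],
        polymorphic_species=list(polymorphic_species),
    )


def summarize_evolution(
    matrix: CharacterMatrix, tree: "SpeciesTree | None" = None
) -> "dict[str, object]":
    """Event placements and summary counts over all regions of a matrix."""
    tree = tree or SpeciesTree.default()
    placements = {}
    for region in matrix.regions:
        placements[region] = place_events(
            tree,
            matrix.character(region),
            region=region,
            polymorphic_species=matrix.polymorphic_species(region),
        )
    events_per_branch: dict[str, int] = {}
    for placement in placements.values():
        if placement.branch != "none":
            events_per_branch[placement.branch] = (
                events_per_branch.get(placement.branch, 0) + 1
            )
    return {
        "placements": placements,
        "events_per_branch": events_per_branch,
        "n_polymorphic_regions": sum(
            1 for p in placements.values() if p.polymorphic_species
        ),
        "n_discordant": sum(1 for p in placements.values() if p.discordant),
    }


def enumerate_haplotypes(
    matrix: CharacterMatrix,
    include_outgroup: bool = False,
    outgroup: str = "CJA",
) -> "tuple[list[tuple[str, ...]], int]":
    """Enumerate distinct region-orientation haplotypes across species.

    Phasing rule: each heterozygous species contributes two haplotypes;
    the first haplotype carries the direct allele at every heterozygous
    region and the second carries all the inverted (minor) alleles.
    Missing regions are carried as ``?`` and compared literally.  The
    outgroup is excluded from the count by default.
    """
    vectors: list[tuple[str, ...]] = []
    for sp in matrix.species:
        if sp == outgroup and not include_outgroup:
            continue
        hap1, hap2, any_het = [], [], False
        for region in matrix.regions:
            gt = matrix.genotype(sp, region)
            if gt is OrientationGenotype.MISSING:
                hap1.append("?")
                hap2.append("?")
            elif gt.is_het:
                any_het = True
                hap1.append("d")
                hap2.append("i")
            else:
                allele = gt.alleles[0]
                hap1.append(allele)
                hap2.append(allele)
        vectors.append(tuple(hap1))
        if any_het:
            vectors.append(tuple(hap2))
    distinct = sorted(set(vectors))
    return distinct, len(distinct)


def inverted_allele_frequency(
    genotypes: Iterable[OrientationGenotype],
) -> float:
    """Inverted-allele frequency over a cohort of diploid genotypes.

    Computed as (#inverted alleles) / (2 x #non-missing individuals);
    missing individuals are excluded.
    """
    n_ind = 0
    n_inv = 0
    for gt in genotypes:
        if gt is OrientationGenotype.MISSING:
            continue
        n_ind += 1
        n_inv += sum(1 for a in gt.alleles if a == "i")
    if n_ind == 0:
        raise ValueError("all genotypes are missing")
    return n_inv / (2 * n_ind)


def genotype_from_probe_order(
    observations: "Sequence[str]", direct_order: str
) -> OrientationGenotype:
    """Genotype a region from per-haplotype three-probe order strings.

    ``direct_order`` is the probe order of the direct (reference)
    haplotype (e.g. ``"red-green-blue"``); the inverted haplotype swaps
    the two probes internal to the region.  Observations that are neither
    (e.g. a probe lost to a deletion) are uninformative; with no
    informative haplotype the genotype is missing.
    """
    labels = direct_order.split("-")
    if len(labels) != 3:
        raise ValueError("direct_order must name exactly three probes")
    inverted_order = "-".join([labels[1], labels[0], labels[2]])
    states = []
    for obs in observations:
        if obs == direct_order:
            states.append("d")
        elif obs == inverted_order:
            states.append("i")
    if not states:
        return OrientationGenotype.MISSING
    if all(s == "d" for s in states):
        return OrientationGenotype.DIR_DIR
    if all(s == "i" for s in states):
        return OrientationGenotype.INV_INV
    return OrientationGenotype.DIR_INV
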