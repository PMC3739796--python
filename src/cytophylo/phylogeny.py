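"""Polarized binary-character cladistics over cytoform profiles.

Each rearrangement is a binary character: derived ("present") if the cytoform
carries it in any role — fixed, polymorphic, X- or Y-linked — and ancestral
("absent") otherwise.  Polarity comes from outgroup rooting: the outgroup is
the rearrangement-free central sequence, so absence is ancestral and every
gain is derived.  Under gains-only evolution a perfect phylogeny exists iff
no two characters' presence-taxon-sets properly overlap; the cladogram is
then the inclusion hierarchy of presence sets, with each internal node
annotated by its synapomorphies (characters whose presence set equals the
node's leaf set).  Characters that conflict (proper overlap, e.g. a loss or
recurrent gain elsewhere in the group) are excluded from grouping but
reported, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO

import dendropy

from .errors import FormatError
from .popgen import CytoformProfile

logger = logging.getLogger(__name__)

ABSENT_STATE = "absent"


@dataclass
class CharacterMatrix:
    """Taxa x rearrangement state matrix (states are profile roles)."""

    taxa: list[str]
    characters: list[str]
    states: dict[tuple[str, str], str]
    outgroup: str | None = None

    def is_present(self, taxon: str, character: str) -> bool:
        return self.states[(taxon, character)] != ABSENT_STATE

    def presence_set(self, character: str) -> frozenset[str]:
        """Ingroup taxa carrying the character (outgroup excluded)."""
        return frozenset(
            t for t in self.taxa
            if t != self.outgroup and self.is_present(t, character)
        )


@dataclass
class CladeNode:
    """Node of a rooted cladogram; leaves carry a taxon name."""

    taxa: frozenset[str]
    name: str | None = None
    children: list["CladeNode"] = field(default_factory=list)
    synapomorphies: list[str] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def sort_key(self) -> str:
        return min(self.taxa)

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class Cladogram:
    root: CladeNode
    character_status: dict[str, str] = field(default_factory=dict)  # clean|conflicting

    def leaves(self) -> list[str]:
        return sorted(n.name for n in self.root.walk() if n.is_leaf)

    def find_clade(self, taxa: set[str]) -> CladeNode | None:
        want = frozenset(taxa)
        for node in self.root.walk():
            if node.taxa == want:
                return node
        return None


def build_character_matrix(
    profiles: list[CytoformProfile], outgroup_id: str
) -> CharacterMatrix:
    """Polarized matrix from cytoform profiles plus an all-absent outgroup.

    Any presence (fixed, polymorphic, sex-linked) is the derived state: a
    single rearrangement commonly assumes different roles in different taxa
    and still marks the same mutational origin.  If no supplied profile bears
    ``outgroup_id`` an all-absent outgroup row is synthesized.  Characters
    present in no ingroup taxon are dropped (logged).
    """
    ids = [p.cytoform_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise FormatError(f"duplicate cytoform ids in profiles: {ids}")
    by_id = {p.cytoform_id: p for p in profiles}
    if outgroup_id not in by_id:
        by_id[outgroup_id] = CytoformProfile(cytoform_id=outgroup_id)
    out_profile = by_id[outgroup_id]
    if out_profile.present_set():
        raise FormatError(
            f"outgroup {outgroup_id!r} must be rearrangement-free, "
            f"found {sorted(out_profile.present_set())}"
        )
    taxa = sorted(by_id)
    ingroup = [t for t in taxa if t != outgroup_id]
    all_chars = sorted({rid for p in by_id.values() for rid in p.roles})
    characters = []
    for c in all_chars:
        if any(by_id[t].roles.get(c) and by_id[t].roles[c].is_present() for t in ingroup):
            characters.append(c)
        else:
            logger.info("character %s present in no ingroup taxon; dropped", c)
    states = {}
    for t in taxa:
        for c in characters:
            call = by_id[t].roles.get(c)
            states[(t, c)] = call.role if call and call.is_present() else ABSENT_STATE
    return CharacterMatrix(taxa=taxa, characters=characters, states=states,
                           outgroup=outgroup_id)


def check_compatibility(matrix: CharacterMatrix) -> list[tuple[str, str]]:
    """Pairs of characters whose presence sets properly overlap.

    An empty list means a perfect phylogeny exists under gains-only
    evolution (every pair of presence sets is nested or disjoint).
    """
    conflicts = []
    sets = {c: matrix.presence_set(c) for c in matrix.characters}
    chars = matrix.characters
    for i, a in enumerate(chars):
        for b in chars[i + 1:]:
            sa, sb = sets[a], sets[b]
            inter = sa & sb
            if inter and inter != sa and inter != sb:
                conflicts.append((a, b))
    return conflicts


def infer_cladogram(matrix: CharacterMatrix) -> Cladogram:
    """Perfect-phylogeny cladogram as the inclusion hierarchy of presence sets.

    Conflicting characters (any that proper-overlap another) are flagged and
    excluded from grouping.  Characters present in every ingroup taxon attach
    to the ingroup stem.  Children are ordered alphabetically by their
    smallest leaf name, so output is deterministic.
    """
    ingroup = [t for t in matrix.taxa if t != matrix.outgroup]
    if len(ingroup) < 2:
        raise FormatError("need at least 2 ingroup taxa")
    conflicts = check_compatibility(matrix)
    conflicted = {c for pair in conflicts for c in pair}
    status = {
        c: ("conflicting" if c in conflicted else "clean") for c in matrix.characters
    }
    clean_sets: dict[frozenset[str], list[str]] = {}
    for c in matrix.characters:
        if c in conflicted:
            continue
        ps = matrix.presence_set(c)
        if ps:
            clean_sets.setdefault(ps, []).append(c)

    full = frozenset(ingroup)
    clusters = set(clean_sets) | {full} | {frozenset({t}) for t in ingroup}

    def make_node(cluster: frozenset[str]) -> CladeNode:
        if len(cluster) == 1:
            (taxon,) = cluster
            node = CladeNode(taxa=cluster, name=taxon)
        else:
            node = CladeNode(taxa=cluster)
        node.synapomorphies = sorted(clean_sets.get(cluster, []))
        return node

    # Nest clusters: parent of each cluster is the smallest strict superset.
    nodes = {cl: make_node(cl) for cl in clusters}
    ordered = sorted(clusters, key=len)
    for cl in ordered:
        if cl == full:
            continue
        supersets = [s for s in clusters if cl < s]
        parent = min(supersets, key=len)
        nodes[parent].children.append(nodes[cl])
    for node in nodes.values():
        node.children.sort(key=CladeNode.sort_key)

    ingroup_root = nodes[full]
    if matrix.outgroup is not None:
        root = CladeNode(taxa=full | {matrix.outgroup})
        root.children = [nodes[full], CladeNode(taxa=frozenset({matrix.outgroup}),
                                                name=matrix.outgroup)]
        root.children.sort(key=CladeNode.sort_key)
    else:
        root = ingroup_root
    clad = Cladogram(root=root, character_status=status)
    _verify_synapomorphies(clad, matrix)
    return clad


def _verify_synapomorphies(clad: Cladogram, matrix: CharacterMatrix) -> None:
    """Post-hoc check: each synapomorphy is present in all of its node's
    leaves and absent outside (among ingroup taxa)."""
    for node in clad.root.walk():
        for c in node.synapomorphies:
            assert matrix.presence_set(c) == node.taxa, (
                f"synapomorphy {c} inconsistent at node {sorted(node.taxa)}"
            )


def fixed_difference(p: CytoformProfile, q: CytoformProfile) -> int:
    """Count of rearrangements fixed in exactly one of the two profiles."""
    return len(p.fixed_set() ^ q.fixed_set())


def _newick_node(node: CladeNode) -> str:
    if node.is_leaf:
        label = node.name or ".".join(sorted(node.taxa))
    else:
        label = "(" + ",".join(_newick_node(c) for c in node.children) + ")"
    if node.synapomorphies:
        label += "[&syn=" + "|".join(node.synapomorphies) + "]"
    return label


def write_newick(clad: Cladogram) -> str:
    """Newick text with node comments carrying synapomorphy lists."""
    return _newick_node(clad.root) + ";"


def read_newick(text: str) -> Cladogram:
    """Parse newick (dendropy) back into a :class:`Cladogram`.

    Synapomorphy comments written by :func:`write_newick` are recovered from
    node comments; unannotated internal nodes get empty lists.
    """
    tree = dendropy.Tree.get(
        file=StringIO(text), schema="newick", suppress_internal_node_taxa=True,
        extract_comment_metadata=False, preserve_underscores=True,
    )

    def convert(dnode) -> CladeNode:
        syn: list[str] = []
        for comment in dnode.comments:
            if comment.startswith("&syn="):
                syn = comment[len("&syn="):].split("|")
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            return CladeNode(taxa=frozenset({name}), name=name, synapomorphies=syn)
        children = [convert(c) for c in dnode.child_nodes()]
        taxa = frozenset().union(*(c.taxa for c in children))
        return CladeNode(taxa=taxa, children=children, synapomorphies=syn)

    return Cladogram(root=convert(tree.seed_node))


def topology(clad: Cladogram) -> frozenset[frozenset[str]]:
    """Set of non-trivial clades (leaf-name sets), for topology comparison."""
    return frozenset(
        node.taxa for node in clad.root.walk() if not node.is_leaf
    )
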