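"""Clone-tree inference from mutation presence/absence across samples.

Each somatic mutation is a binary character: present or absent in each
sequenced sample, with an explicit third state — indeterminate — when a
sample's locus lacked the coverage to decide (RAD coverage gaps are
detectable and must not masquerade as absence).  The tree is rooted at the
normal sample, which carries zero somatic mutations, and each edge carries
the mutations that arose on it: mutations shared by all tumors sit on the
trunk, sample-private mutations on terminal edges.

For compatible characters (a perfect phylogeny: every carrier set nested or
disjoint with every other) the tree follows directly from the laminar
family of carrier sets.  Otherwise all rooted topologies on the samples are
scored exactly by minimum parsimony (Sankoff dynamic programming with the
root constrained to the all-zero normal genotype); characters that still
require more than one change on the best tree are reported as homoplasy
rather than silently placed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .somatic import SamplePileup, SomaticCall, _BASES, complement

__all__ = [
    "MutationMatrix",
    "CloneNode",
    "CloneTree",
    "build_matrix",
    "infer_tree",
    "write_newick",
]

PRESENT, ABSENT, INDET = "P", "A", "I"


class MutationMatrix:
    """Sample x mutation presence/absence/indeterminate matrix.

    Backed by a DataFrame with mutation ids (``chrom:pos:ref>alt``) as rows
    and sample ids as columns, values in {P, A, I}.
    """

    def __init__(self, frame: pd.DataFrame):
        bad = set(np.unique(frame.to_numpy())) - {PRESENT, ABSENT, INDET}
        if bad:
            raise ValueError(f"matrix entries outside {{P,A,I}}: {sorted(bad)}")
        if frame.index.has_duplicates:
            raise ValueError("duplicate mutation ids")
        all_absent = (frame != PRESENT).all(axis=1)
        if all_absent.any():
            raise ValueError(
                f"rows with no present sample: {list(frame.index[all_absent])}"
            )
        self.frame = frame

    @property
    def samples(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def mutations(self) -> list[str]:
        return list(self.frame.index)

    def carriers(self, mutation: str) -> frozenset[str]:
        row = self.frame.loc[mutation]
        return frozenset(row.index[row == PRESENT])

    def determinate(self, mutation: str) -> frozenset[str]:
        row = self.frame.loc[mutation]
        return frozenset(row.index[row != INDET])

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="mutation_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="mutation_id", dtype=str))


def build_matrix(
    calls_by_sample: Mapping[str, Sequence[SomaticCall]],
    pileups_by_sample: Mapping[str, SamplePileup],
    min_depth: int = 20,
    absent_vaf: float = 0.01,
) -> MutationMatrix:
    """Union of PASS calls scored as P/A/I in every sample.

    A sample not calling a mutation is only scored absent when its pileup
    covers the site at ``min_depth`` with alt VAF at most ``absent_vaf``;
    otherwise the entry is indeterminate and excluded from tree scoring.
    """
    samples = sorted(calls_by_sample)
    union: dict[str, SomaticCall] = {}
    called: dict[str, set[str]] = {s: set() for s in samples}
    for s in samples:
        seen: set[str] = set()
        for c in calls_by_sample[s]:
            if not c.is_pass:
                continue
            if c.mutation_id in seen:
                raise ValueError(f"duplicate mutation id {c.mutation_id} in {s}")
            seen.add(c.mutation_id)
            union.setdefault(c.mutation_id, c)
        called[s] = seen
    data = {}
    for mut_id, c in union.items():
        row = {}
        for s in samples:
            if mut_id in called[s]:
                row[s] = PRESENT
                continue
            pile = pileups_by_sample.get(s)
            status = INDET
            if pile is not None and c.locus_id in pile:
                lp = pile[c.locus_id]
                alt_read = (
                    c.alt if lp.locus.direction == "downstream" else complement(c.alt)
                )
                depth = int(lp.depth[c.offset])
                if depth >= min_depth:
                    vaf = lp.counts[c.offset, _BASES.index(alt_read)] / depth
                    status = ABSENT if vaf <= absent_vaf else INDET
            row[s] = status
        data[mut_id] = row
    frame = pd.DataFrame.from_dict(data, orient="index").reindex(columns=samples)
    frame = frame.sort_index()
    return MutationMatrix(frame)


@dataclass
class CloneNode:
    name: str | None = None  # sample id for leaves, "Normal" for the root
    children: list["CloneNode"] = field(default_factory=list)
    edge_mutations: list[str] = field(default_factory=list)  # on the edge above

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.name])
        return frozenset().union(*(c.leaf_names() for c in self.children))

    def walk(self) -> Iterator["CloneNode"]:
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class CloneTree:
    root: CloneNode  # the normal; zero mutations above it
    homoplasy: dict[str, int] = field(default_factory=dict)  # mutation -> n changes

    @property
    def samples(self) -> frozenset[str]:
        return self.root.leaf_names() - {self.root.name}

    def edge_counts(self) -> dict[frozenset[str], int]:
        """Mutation count per edge, keyed by the leaf set under the edge."""
        return {
            node.leaf_names(): len(node.edge_mutations)
            for node in self.root.walk()
            if node is not self.root
        }

    def n_assigned(self) -> int:
        return sum(
            len(n.edge_mutations) for n in self.root.walk() if n is not self.root
        )


def _set_partitions(items: list) -> Iterator[list[list]]:
    """All partitions of ``items`` into unordered non-empty blocks."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def _rooted_topologies(leaves: list[str]) -> Iterator[CloneNode]:
    """All rooted topologies (multifurcations allowed) on the leaf set."""
    if len(leaves) == 1:
        yield CloneNode(name=leaves[0])
        return
    for part in _set_partitions(leaves):
        if len(part) < 2:
            continue
        for combo in _children_combos([sorted(b) for b in part]):
            yield CloneNode(children=list(combo))


def _children_combos(blocks: list[list[str]]) -> Iterator[tuple[CloneNode, ...]]:
    if not blocks:
        yield ()
        return
    for sub in _rooted_topologies(blocks[0]):
        for rest in _children_combos(blocks[1:]):
            yield (sub,) + rest


def _is_laminar(sets: Iterable[frozenset[str]]) -> bool:
    ss = sorted(set(sets), key=len, reverse=True)
    for i, a in enumerate(ss):
        for b in ss[i + 1 :]:
            if a & b and not (b <= a):
                return False
    return True


def _sankoff_cost(node: CloneNode, states: Mapping[str, int | None]) -> tuple[float, float]:
    """(cost if node=0, cost if node=1); leaves with state None are free."""
    if node.is_leaf:
        s = states.get(node.name)
        if s is None:
            return 0.0, 0.0
        return (0.0, np.inf) if s == 0 else (np.inf, 0.0)
    c0 = c1 = 0.0
    for child in node.children:
        k0, k1 = _sankoff_cost(child, states)
        c0 += min(k0, k1 + 1)
        c1 += min(k0 + 1, k1)
    return c0, c1


def _sankoff_place(
    node: CloneNode,
    states: Mapping[str, int | None],
    parent_state: int,
    gains: list[CloneNode],
    losses: list[CloneNode],
) -> None:
    """Top-down optimal labeling; ties keep the parent state, so a single
    gain lands on the edge above the smallest clade containing all carriers."""
    c0, c1 = _sankoff_cost(node, states)
    cost_keep = (c0, c1)[parent_state]
    cost_flip = (c0, c1)[1 - parent_state] + 1
    state = parent_state if cost_keep <= cost_flip else 1 - parent_state
    if state != parent_state:
        (gains if state == 1 else losses).append(node)
    for child in node.children:
        _sankoff_place(child, states, state, gains, losses)


def _char_states(
    matrix: MutationMatrix, mutation: str
) -> dict[str, int | None]:
    row = matrix.frame.loc[mutation]
    return {
        s: (1 if v == PRESENT else 0 if v == ABSENT else None)
        for s, v in row.items()
    }


def _tree_score(top: CloneNode, patterns: Mapping[tuple, int]) -> float:
    score = 0.0
    for pattern, mult in patterns.items():
        states = dict(pattern)
        c0, c1 = _sankoff_cost(top, states)
        score += mult * min(c0, c1 + 1)  # +1 = the trunk edge from the normal
    return score


def _canonical_newick(node: CloneNode) -> str:
    if node.is_leaf:
        return node.name
    return "(" + ",".join(sorted(_canonical_newick(c) for c in node.children)) + ")"


def _laminar_tree(samples: list[str], clades: set[frozenset[str]]) -> CloneNode:
    """Build the containment tree of a laminar clade family."""
    family = set(clades) | {frozenset([s]) for s in samples} | {frozenset(samples)}
    ordered = sorted(family, key=lambda s: (len(s), sorted(s)), reverse=True)
    nodes: dict[frozenset[str], CloneNode] = {}
    top = None
    for clade in ordered:
        node = CloneNode(name=sorted(clade)[0] if len(clade) == 1 else None)
        nodes[clade] = node
        if top is None:
            top = node
            continue
        parent = min(
            (c for c in nodes if clade < c),
            key=len,
        )
        nodes[parent].children.append(node)
    for n in nodes.values():
        n.children.sort(key=lambda c: sorted(c.leaf_names()))
    return top


def infer_tree(matrix: MutationMatrix, max_exact: int = 8) -> CloneTree:
    """Maximum-parsimony clone tree rooted at the zero-mutation normal.

    Compatible matrices are resolved directly by the perfect-phylogeny
    containment construction; incompatible ones by exhaustive search over
    all rooted topologies (exact up to ``max_exact`` samples; larger inputs
    are rejected rather than silently switching to a heuristic).  Mutations
    are assigned to the edge above the smallest clade containing all their
    carriers; characters needing more than one change on the chosen tree
    are assigned by minimal-change placement and recorded as homoplasy.
    """
    samples = matrix.samples
    if len(samples) == 0:
        return CloneTree(root=CloneNode(name="Normal"))
    if len(samples) > max_exact:
        raise ValueError(
            f"{len(samples)} samples exceeds the exact-search limit {max_exact}"
        )
    carrier_sets = {matrix.carriers(m) for m in matrix.mutations}
    if _is_laminar(carrier_sets):
        top = _laminar_tree(sorted(samples), carrier_sets)
    else:
        patterns: dict[tuple, int] = {}
        for m in matrix.mutations:
            key = tuple(sorted(_char_states(matrix, m).items(), key=lambda kv: kv[0]))
            patterns[key] = patterns.get(key, 0) + 1
        best, best_score, best_key = None, np.inf, None
        for top in _rooted_topologies(sorted(samples)):
            score = _tree_score(top, patterns)
            key = _canonical_newick(top)
            if score < best_score or (score == best_score and key < best_key):
                best, best_score, best_key = top, score, key
        top = best
    root = CloneNode(name="Normal", children=[top])
    tree = CloneTree(root=root)
    for m in matrix.mutations:
        states = _char_states(matrix, m)
        gains: list[CloneNode] = []
        losses: list[CloneNode] = []
        _sankoff_place(top, states, 0, gains, losses)
        # no gain below the trunk means the change sits on the trunk itself
        if not gains and not losses:
            c0, c1 = _sankoff_cost(top, states)
            if c1 + 1 <= c0:
                gains = [top]
        n_changes = len(gains) + len(losses)
        if n_changes == 1 and len(gains) == 1:
            gains[0].edge_mutations.append(m)
        else:
            tree.homoplasy[m] = n_changes
    for n in root.walk():
        n.edge_mutations.sort()
    return tree


def _newick_node(node: CloneNode) -> str:
    label = node.name or ""
    length = len(node.edge_mutations)
    if node.is_leaf:
        return f"{label}:{length}"
    inner = ",".join(
        _newick_node(c)
        for c in sorted(node.children, key=lambda c: sorted(c.leaf_names()))
    )
    return f"({inner}){label}:{length}"


def write_newick(tree: CloneTree, path: str | Path | None = None) -> str:
    """Newick with branch lengths = per-edge mutation counts.

    Child order is deterministic (lexicographic by the leaf names below).
    The root (normal) carries no branch length.
    """
    root = tree.root
    inner = ",".join(
        _newick_node(c)
        for c in sorted(root.children, key=lambda c: sorted(c.leaf_names()))
    )
    text = f"({inner}){root.name or ''};" if root.children else f"{root.name or ''};"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
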