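"""Presence/absence character evolution on a rooted taxon tree.

Fitch (unordered, unweighted) parsimony over binary characters, with a
deterministic top-down resolution that labels every state-changing
branch as a gain (0→1) or a loss (1→0).  Ambiguity at the root is
broken by policy, by default preferring absence so that motifs are
gained late rather than lost repeatedly.  A Dollo mode (single gain,
any number of losses) is available for characters assumed to arise
once.  Polytomies are resolved deterministically (repeatedly pairing
the two leftmost children) before reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional

import dendropy

from .errors import InputError


@dataclass
class Node:
    name: Optional[str]
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self):
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def to_newick(self, comments: Optional[dict] = None) -> str:
        def render(node):
            label = node.name or ""
            tag = ""
            if comments and id(node) in comments:
                tag = f"[&&NHX:{comments[id(node)]}]"
            if node.is_leaf:
                return f"{label}{tag}"
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){label}{tag}"

        return render(self) + ";"


def _convert(dnode, counter) -> Node:
    if dnode.is_leaf():
        if dnode.taxon is None or not dnode.taxon.label:
            raise InputError("tree has an unnamed tip")
        return Node(dnode.taxon.label.replace(" ", "_"))
    name = None
    if dnode.taxon is not None and dnode.taxon.label:
        name = dnode.taxon.label.replace(" ", "_")
    elif dnode.label:
        name = dnode.label.replace(" ", "_")
    node = Node(name, [_convert(c, counter) for c in dnode.child_nodes()])
    # deterministic resolution: fold the leftmost pair until binary
    while len(node.children) > 2:
        a, b = node.children[0], node.children[1]
        node.children = [Node(None, [a, b])] + node.children[2:]
    return node


def read_tree(source: str, is_path: bool = True) -> Node:
    """Parse a rooted Newick tree (polytomies resolved deterministically)."""
    try:
        if is_path:
            dtree = dendropy.Tree.get(path=source, schema="newick")
        else:
            dtree = dendropy.Tree.get(data=source, schema="newick")
    except Exception as exc:
        raise InputError(f"cannot parse Newick tree: {exc}") from exc
    root = _convert(dtree.seed_node, [0])
    counter = 0
    for node in root.preorder():
        if node.name is None:
            node.name = f"N{counter}"
            counter += 1
    names = [n.name for n in root.postorder()]
    if len(names) != len(set(names)):
        raise InputError("tree contains duplicate node names")
    return root


def default_tree() -> Node:
    """The bundled order-level cladogram of insect subgroups."""
    text = resources.files("motifarch").joinpath("data/insect_orders.nwk").read_text(
        "utf-8"
    )
    return read_tree(text, is_path=False)


@dataclass
class FitchResult:
    root: Node
    downpass: Dict[int, frozenset]
    change_count: int
    final_sets: Dict[int, frozenset]


def fitch_reconstruct(
    root: Node, tip_states: Dict[str, Optional[int]], strict: bool = False
) -> FitchResult:
    """Bottom-up/top-down Fitch sets and the parsimony minimum change count.

    ``tip_states`` maps tip name to 0, 1 or ``None``/missing (unknown).
    With ``strict`` a tip absent from the table is an error; otherwise it
    is treated as unknown.
    """
    leaves = root.leaves()
    if len(leaves) < 2:
        raise InputError("tree must have at least two tips")
    known = 0
    down: Dict[int, frozenset] = {}
    count = 0
    for node in root.postorder():
        if node.is_leaf:
            if node.name not in tip_states:
                if strict:
                    raise InputError(f"tip {node.name!r} missing from state table")
                state = None
            else:
                state = tip_states[node.name]
            if state is None:
                down[id(node)] = frozenset((0, 1))
            else:
                if state not in (0, 1):
                    raise InputError(
                        f"tip {node.name!r} has non-binary state {state!r}"
                    )
                down[id(node)] = frozenset((state,))
                known += 1
        else:
            acc = None
            for child in node.children:
                s = down[id(child)]
                if acc is None:
                    acc = s
                else:
                    inter = acc & s
                    if inter:
                        acc = inter
                    else:
                        acc = acc | s
                        count += 1
            down[id(node)] = acc
    if known < 2:
        raise InputError("need at least two tips with known state")

    # textbook Fitch uppass: the union over all most-parsimonious
    # labelings of the states each node can take
    final: Dict[int, frozenset] = {id(root): down[id(root)]}
    for node in root.preorder():
        for child in node.children:
            fp = final[id(node)]
            dc = down[id(child)]
            if fp <= dc:
                final[id(child)] = fp
            elif child.is_leaf:
                final[id(child)] = dc
            else:
                kid_sets = [down[id(g)] for g in child.children]
                inter = kid_sets[0]
                union = kid_sets[0]
                for s in kid_sets[1:]:
                    inter = inter & s
                    union = union | s
                if inter:
                    final[id(child)] = dc | (fp & union)
                else:
                    final[id(child)] = dc | fp
    return FitchResult(root=root, downpass=down, change_count=count, final_sets=final)


def resolve_states(
    result: FitchResult, root_state_policy: str = "prefer_absence"
) -> Dict[int, int]:
    """One minimum-change labeling of every node.

    The root takes its policy-preferred state when ambiguous; each child
    inherits the parent state when compatible with its downpass set and
    otherwise takes the set's single element.
    """
    if root_state_policy not in {"prefer_absence", "prefer_presence"}:
        raise InputError(f"unknown root_state_policy {root_state_policy!r}")
    prefer = 0 if root_state_policy == "prefer_absence" else 1
    states: Dict[int, int] = {}
    root = result.root
    root_set = result.downpass[id(root)]
    states[id(root)] = prefer if prefer in root_set else next(iter(root_set))
    for node in root.preorder():
        ps = states[id(node)]
        for child in node.children:
            cs = result.downpass[id(child)]
            if ps in cs:
                states[id(child)] = ps
            elif len(cs) == 1:
                states[id(child)] = next(iter(cs))
            else:
                states[id(child)] = prefer if prefer in cs else next(iter(cs))
    return states


@dataclass
class BranchEvent:
    parent: str
    child: str
    kind: str  # gain | loss


def count_gain_loss(
    root: Node,
    tip_states: Dict[str, Optional[int]],
    root_state_policy: str = "prefer_absence",
    strict: bool = False,
):
    """Fitch reconstruction plus per-branch gain/loss assignment.

    Returns ``(events, states, change_count)``; ``len(events)`` always
    equals the Fitch minimum.
    """
    result = fitch_reconstruct(root, tip_states, strict=strict)
    states = resolve_states(result, root_state_policy)
    events: List[BranchEvent] = []
    for node in root.preorder():
        for child in node.children:
            a, b = states[id(node)], states[id(child)]
            if a != b:
                events.append(
                    BranchEvent(
                        parent=node.name,
                        child=child.name,
                        kind="gain" if b > a else "loss",
                    )
                )
    return events, states, result.change_count


def dollo_count(root: Node, tip_states: Dict[str, Optional[int]]):
    """Single-origin (Dollo) reconstruction: at most one gain.

    The gain is placed on the most recent common ancestor of all
    present tips; every maximal all-absent subtree below it is one loss.
    Unknown tips follow their parent.  Returns ``(gains, losses)``.
    """
    present = {
        leaf.name for leaf in root.leaves() if tip_states.get(leaf.name) == 1
    }
    if not present:
        return 0, 0

    def has_present(node):
        if node.is_leaf:
            return node.name in present
        return any(has_present(c) for c in node.children)

    def all_known_absent(node):
        if node.is_leaf:
            return tip_states.get(node.name) == 0
        kids = [all_known_absent(c) for c in node.children]
        return all(kids)

    mrca = root
    while not mrca.is_leaf:
        carriers = [c for c in mrca.children if has_present(c)]
        if len(carriers) == 1:
            mrca = carriers[0]
        else:
            break

    losses = 0

    def walk(node):
        nonlocal losses
        for child in node.children:
            if not has_present(child) and all_known_absent(child):
                losses += 1
            elif not child.is_leaf:
                walk(child)

    walk(mrca)
    return 1, losses


def read_states_tsv(path: str):
    """Read a taxon-by-motif presence/absence table.

    First column is the taxon name; remaining header names are motif
    ids.  Cells are 0, 1, or ``?``/empty for unknown.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise InputError(f"empty state table {path!r}")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise InputError("state table needs a taxon column and >=1 motif column")
    motifs = header[1:]
    table: Dict[str, Dict[str, Optional[int]]] = {m: {} for m in motifs}
    for ln in lines[1:]:
        parts = ln.split("\t")
        taxon = parts[0]
        for m, cell in zip(motifs, parts[1:]):
            cell = cell.strip()
            if cell in {"", "?"}:
                table[m][taxon] = None
            elif cell in {"0", "1"}:
                table[m][taxon] = int(cell)
            else:
                raise InputError(
                    f"bad state {cell!r} for taxon {taxon!r}, motif {m!r}"
                )
    return table
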