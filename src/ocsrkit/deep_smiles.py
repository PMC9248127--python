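"""DeepSMILES <-> SMILES conversion (rings and branches both rewritten).

DeepSMILES removes the two syntax features that sequence models most often
get wrong in SMILES:

* **Branches.**  The open parenthesis is dropped.  A close parenthesis is
  kept but repeated: a run of *k* ``)`` characters pops *k* atoms off the
  depth-first traversal stack, returning to the branch point.
  ``CC(C)C`` becomes ``CCC)C``; ``CC(CC)C`` becomes ``CCCC))C``.

* **Ring closures.**  The paired ring-bond digits are replaced by a single
  digit at the closing position whose value is the distance back along the
  traversal stack (equal to the ring size for a simple ring):
  ``c1ccccc1`` becomes ``cccccc6``.  Sizes of 10-99 are written ``%NN``.

Because SMILES is written by a depth-first traversal, every ring closure
bonds the current atom to one of its ancestors, so the referenced atom is
always on the stack.  Inputs violating that (hand-written SMILES with
cross-branch closures) are rejected.

Only the string grammar is handled here; chemical validity of a decoded
string is the caller's concern (see :func:`ocsrkit.chem.canonicalize`).
"""

from __future__ import annotations

import re

__all__ = ["DeepSmilesError", "to_deepsmiles", "from_deepsmiles"]


class DeepSmilesError(ValueError):
    """Malformed SMILES/DeepSMILES input."""


_ATOM_RE = re.compile(
    r"""
    \[[^\]]+\]          # bracket atom
    | Cl | Br           # two-letter organic subset
    | [BCNOPSFI]        # organic subset
    | [bcnops]          # aromatic organic subset
    """,
    re.VERBOSE,
)
_BONDS = set("-=#$:/\\")


def _ring_label(n: int) -> str:
    if n < 10:
        return str(n)
    if n < 100:
        return f"%{n:02d}"
    raise DeepSmilesError(f"ring size {n} too large to encode")


def to_deepsmiles(smiles: str) -> str:
    """Convert a SMILES string to DeepSMILES (rings and branches).

    Raises
    ------
    DeepSmilesError
        On malformed SMILES, or on a ring closure whose partner atom is not
        an ancestor on the traversal stack.
    """
    out: list[str] = []
    stack: list[int] = []           # atom ids, root -> current
    branch_depths: list[int] = []   # stack length at each open '('
    ring_open: dict[str, tuple[int, str]] = {}  # label -> (atom id, bond)
    pending_bond = ""
    atom_id = 0
    i, n = 0, len(smiles)

    def _close_ring(label: str) -> None:
        nonlocal pending_bond
        if not stack:
            raise DeepSmilesError("ring digit before any atom")
        if label not in ring_open:
            ring_open[label] = (stack[-1], pending_bond)
        else:
            open_atom, open_bond = ring_open.pop(label)
            bond = pending_bond or open_bond
            for depth, aid in enumerate(reversed(stack), start=1):
                if aid == open_atom:
                    out.append(bond + _ring_label(depth))
                    break
            else:
                raise DeepSmilesError(
                    f"ring closure {label} does not bond to an ancestor atom"
                )
        pending_bond = ""

    while i < n:
        ch = smiles[i]
        m = _ATOM_RE.match(smiles, i)
        if m:
            out.append(pending_bond + m.group())
            pending_bond = ""
            stack.append(atom_id)
            atom_id += 1
            i = m.end()
        elif ch in _BONDS:
            if pending_bond:
                raise DeepSmilesError(f"two bond symbols in a row at position {i}")
            pending_bond = ch
            i += 1
        elif ch == "(":
            if pending_bond:
                raise DeepSmilesError(f"bond symbol before '(' at position {i}")
            if not stack:
                raise DeepSmilesError("branch opened before any atom")
            branch_depths.append(len(stack))
            i += 1
        elif ch == ")":
            if not branch_depths:
                raise DeepSmilesError(f"unmatched ')' at position {i}")
            depth = branch_depths.pop()
            out.append(")" * (len(stack) - depth))
            del stack[depth:]
            i += 1
        elif ch.isdigit():
            _close_ring(ch)
            i += 1
        elif ch == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise DeepSmilesError(f"malformed %NN ring label at position {i}")
            _close_ring(smiles[i + 1 : i + 3])
            i += 3
        elif ch == ".":
            if branch_depths:
                raise DeepSmilesError("dot inside a branch")
            if ring_open:
                raise DeepSmilesError("dot with unclosed ring bond")
            if not stack:
                raise DeepSmilesError(f"empty component before '.' at position {i}")
            out.append(".")
            stack.clear()
            i += 1
        else:
            raise DeepSmilesError(f"unexpected character {ch!r} at position {i}")

    if branch_depths:
        raise DeepSmilesError("unclosed branch")
    if ring_open:
        raise DeepSmilesError(f"unclosed ring bond(s): {sorted(ring_open)}")
    if pending_bond:
        raise DeepSmilesError("trailing bond symbol")
    return "".join(out)


class _Node:
    __slots__ = ("token", "bond", "children", "rings")

    def __init__(self, token: str, bond: str):
        self.token = token
        self.bond = bond
        self.children: list[_Node] = []
        self.rings: list[tuple[_Node, str]] = []  # (partner, bond), on closing atom


def from_deepsmiles(deepsmiles: str) -> str:
    """Convert a DeepSMILES string back to SMILES.

    Raises
    ------
    DeepSmilesError
        On malformed input: an impossible ring-size digit (larger than the
        number of atoms on the stack, or below 3), a ``)`` run popping past
        the root, a trailing bond, or an unknown character.
    """
    roots: list[_Node] = []
    stack: list[_Node] = []
    pending_bond = ""
    i, n = 0, len(deepsmiles)

    def _close_ring(size: int, pos: int) -> None:
        nonlocal pending_bond
        if size < 3:
            raise DeepSmilesError(f"impossible ring size {size} at position {pos}")
        if size > len(stack):
            raise DeepSmilesError(
                f"ring size {size} at position {pos} exceeds stack depth {len(stack)}"
            )
        current, partner = stack[-1], stack[-size]
        current.rings.append((partner, pending_bond))
        pending_bond = ""

    while i < n:
        ch = deepsmiles[i]
        m = _ATOM_RE.match(deepsmiles, i)
        if m:
            node = _Node(m.group(), pending_bond)
            pending_bond = ""
            if stack:
                stack[-1].children.append(node)
            elif node.bond:
                raise DeepSmilesError(f"bond before first atom at position {i}")
            else:
                roots.append(node)
            stack.append(node)
            i = m.end()
        elif ch in _BONDS:
            if pending_bond:
                raise DeepSmilesError(f"two bond symbols in a row at position {i}")
            pending_bond = ch
            i += 1
        elif ch == ")":
            if pending_bond:
                raise DeepSmilesError(f"bond symbol before ')' at position {i}")
            if len(stack) <= 1:
                raise DeepSmilesError(f"')' at position {i} pops past the root atom")
            stack.pop()
            i += 1
        elif ch.isdigit():
            _close_ring(int(ch), i)
            i += 1
        elif ch == "%":
            if i + 2 >= n or not deepsmiles[i + 1 : i + 3].isdigit():
                raise DeepSmilesError(f"malformed %NN ring size at position {i}")
            _close_ring(int(deepsmiles[i + 1 : i + 3]), i)
            i += 3
        elif ch == ".":
            if pending_bond:
                raise DeepSmilesError("bond symbol before '.'")
            if not stack:
                raise DeepSmilesError(f"empty component before '.' at position {i}")
            stack.clear()
            i += 1
        else:
            raise DeepSmilesError(f"unexpected character {ch!r} at position {i}")
    if pending_bond:
        raise DeepSmilesError("trailing bond symbol")
    if not roots:
        raise DeepSmilesError("no atoms in DeepSMILES string")
    return _serialize(roots)


def _serialize(roots: list[_Node]) -> str:
    """Render the atom tree as SMILES, allocating ring labels with reuse.

    Ring partners always precede the closing atom in output order, so a
    single sweep in atom order can allocate each ring a label at its opening
    atom and free it after the closing atom is written.
    """
    order: dict[int, int] = {}
    nodes_in_order: list[_Node] = []
    pairs: list[tuple[_Node, _Node, str]] = []  # (opening, closing, bond)

    def _plan(node: _Node) -> None:
        order[id(node)] = len(nodes_in_order)
        nodes_in_order.append(node)
        for partner, bond in node.rings:
            pairs.append((partner, node, bond))
        for child in node.children:
            _plan(child)

    for root in roots:
        _plan(root)

    opens_at: dict[int, list[tuple[_Node, str]]] = {}
    closes_at: dict[int, list[tuple[int, str]]] = {}
    for first, second, bond in pairs:
        opens_at.setdefault(order[id(first)], []).append((second, bond))

    ring_marks: dict[int, str] = {i: "" for i in range(len(nodes_in_order))}
    in_use: set[int] = set()
    for pos, node in enumerate(nodes_in_order):
        marks = ""
        freed = []
        for label, bond in closes_at.get(pos, []):
            marks += _ring_label(label)
            freed.append(label)
        for partner, bond in opens_at.get(pos, []):
            label = next(l for l in range(1, 100) if l not in in_use)
            in_use.add(label)
            marks += bond + _ring_label(label)
            closes_at.setdefault(order[id(partner)], []).append((label, bond))
        for label in freed:
            in_use.discard(label)
        ring_marks[pos] = marks

    def _render(node: _Node) -> str:
        s = node.bond + node.token + ring_marks[order[id(node)]]
        kids = node.children
        for child in kids[:-1]:
            s += "(" + _render(child) + ")"
        if kids:
            s += _render(kids[-1])
        return s

    return ".".join(_render(root) for root in roots)
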