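"""Canonical SMILES generation from a molecular graph plus canonical labels.

Given per-atom canonical ranks (from the InChI auxiliary information, or an
identity/random labeling), the writer performs a depth-first traversal and
emits an OpenSMILES-conformant string:

* the traversal starts, per component, at the lowest-labelled atom -- except
  that a negatively charged oxygen start is replaced by a carbonyl oxygen on
  the same neighbour (whose labels the InChI may interchange);
* at branch points, multiple (non-aromatic) bonds are taken before single or
  aromatic ones, then unlabelled explicit hydrogens (deuterium before
  tritium), then ascending canonical label;
* ring-closure digits take the lowest available value and are reused once
  closed; on one atom, openings precede closings, openings ordered by the
  label of the distal atom, closings by when their opening was written;
* every explicit substituent of a configured double bond carries a direction
  symbol, the earliest symbol of each isolated or conjugated cis/trans
  system is a forward slash, and a direction at a ring closure is written
  only at the digit on the double-bond atom;
* atoms use OpenSMILES standard form (bare organic-subset symbols where the
  implied hydrogen count matches, lowercase for aromatic atoms, hydrogen of
  a stereocentre inside the brackets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .auxinfo import CanonicalLabeling
from .errors import StereoConsistencyError
from .molgraph import (
    _DEFAULT_VALENCES,
    _ORGANIC_SUBSET,
    H_PLACEHOLDER,
    Bond,
    MolecularGraph,
    _permutation_parity,
)

_INF = math.inf


@dataclass
class TraversalPlan:
    """Rooted spanning forest with ordered children and ring closures."""

    roots: list[int] = field(default_factory=list)
    order: list[int] = field(default_factory=list)  # atoms in emission order
    pos: dict[int, int] = field(default_factory=dict)
    parent: dict[int, int] = field(default_factory=dict)
    parent_bond: dict[int, Bond] = field(default_factory=dict)
    children: dict[int, list[tuple[Bond, int]]] = field(default_factory=dict)
    closures: list["_Closure"] = field(default_factory=list)


@dataclass
class _Closure:
    bond: Bond
    opening: int  # atom written first
    closing: int
    digit: int = 0
    open_seq: int = 0  # global write order of the opening digit


class _DirSlot:
    """Placeholder piece for a '/' or '\\' symbol, resolved after Rule H."""

    __slots__ = ("key", "from_atom", "to_atom")

    def __init__(self, key: tuple[int, int], from_atom: int, to_atom: int):
        self.key = key
        self.from_atom = from_atom
        self.to_atom = to_atom


# --------------------------------------------------------------------------
# hydrogen folding


def _fold_hydrogens(g: MolecularGraph, lab: CanonicalLabeling):
    """Decide which explicit hydrogens are written implicitly.

    Returns (kept, extra_h, bracket_h) where ``kept`` flags atoms that stay
    in the traversal, ``extra_h`` counts hydrogens folded into a parent's
    hydrogen count and ``bracket_h`` maps a stereocentre to the folded
    hydrogen atom occupying its in-bracket slot.
    """
    stereo_centers = {t.center for t in g.tet_stereo}
    kept = [True] * g.n_atoms
    extra_h = {i: 0 for i in range(g.n_atoms)}
    bracket_h: dict[int, int] = {}
    for atom in g.atoms:
        if not atom.is_explicit_h or atom.index in lab.rank:
            continue
        if atom.isotope != 0 or atom.charge != 0:
            continue
        nbrs = g.neighbors(atom.index)
        if len(nbrs) != 1:
            continue
        parent = nbrs[0][1]
        if g.atoms[parent].is_explicit_h:
            continue  # dihydrogen and friends stay explicit
        if parent in stereo_centers:
            if parent in bracket_h:
                continue  # second H on a "stereocentre": keep explicit
            bracket_h[parent] = atom.index
            kept[atom.index] = False
        else:
            extra_h[parent] += 1
            kept[atom.index] = False
    return kept, extra_h, bracket_h


# --------------------------------------------------------------------------
# traversal (Rules B-E)


def choose_start_atom(
    g: MolecularGraph, comp: list[int], lab: CanonicalLabeling
) -> int:
    """Lowest-labelled atom of the component, redirected from a negatively
    charged oxygen to the lowest-labelled carbonyl oxygen on the same
    neighbour when one exists."""
    ranked = [i for i in comp if i in lab.rank]
    if not ranked:
        return min(comp)
    start = min(ranked, key=lambda i: lab.rank[i])
    a = g.atoms[start]
    if a.element == "O" and a.charge == -1:
        carbonyls = []
        for _, nb in g.neighbors(start):
            for bond, x in g.neighbors(nb):
                if (
                    x != start
                    and bond.order == 2
                    and g.atoms[x].element == "O"
                    and g.atoms[x].charge == 0
                ):
                    carbonyls.append(x)
        if carbonyls:
            start = min(carbonyls, key=lambda i: lab.rank.get(i, _INF))
    return start


def _branch_key(g, lab, bond: Bond, v: int):
    multiple = bond.order >= 2 and not bond.aromatic
    if multiple:
        return (0, -bond.order, lab.rank.get(v, _INF), v)
    if v in lab.h_keys:  # unlabelled explicit hydrogen: Rule D
        return (1, 0, lab.h_keys[v], v)
    return (1, 1, lab.rank.get(v, _INF), v)


def order_branches(
    g: MolecularGraph,
    lab: CanonicalLabeling,
    candidates: list[tuple[Bond, int]],
) -> list[tuple[Bond, int]]:
    """Sort unvisited branches of an atom: multiple bonds first (higher
    order first), then unlabelled explicit hydrogens (D before T), then
    ascending canonical label."""
    return sorted(candidates, key=lambda bv: _branch_key(g, lab, *bv))


def build_traversal(g: MolecularGraph, lab: CanonicalLabeling) -> TraversalPlan:
    """Depth-first plan over the kept atoms; components visited in order of
    their lowest canonical label."""
    kept, _, _ = _fold_hydrogens(g, lab)
    plan = TraversalPlan()
    visited = [False] * g.n_atoms
    used_edges: set[tuple[int, int]] = set()

    def visit(u: int, parent: int | None, pbond: Bond | None) -> None:
        visited[u] = True
        plan.pos[u] = len(plan.order)
        plan.order.append(u)
        plan.children[u] = []
        if parent is not None:
            plan.parent[u] = parent
            plan.parent_bond[u] = pbond
        # ring closures: edges to already-visited atoms (detected at the
        # endpoint written second)
        for bond, v in g.neighbors(u):
            if not kept[v] or not visited[v] or bond.key in used_edges:
                continue
            used_edges.add(bond.key)
            opening, closing = (v, u) if plan.pos[v] < plan.pos[u] else (u, v)
            plan.closures.append(_Closure(bond=bond, opening=opening, closing=closing))
        while True:
            cands = [
                (bond, v)
                for bond, v in g.neighbors(u)
                if kept[v] and not visited[v] and bond.key not in used_edges
            ]
            if not cands:
                break
            bond, v = order_branches(g, lab, cands)[0]
            used_edges.add(bond.key)
            plan.children[u].append((bond, v))
            visit(v, u, bond)

    comps = [
        [i for i in comp if kept[i]]
        for comp in g.components
    ]
    comps = [c for c in comps if c]
    comps.sort(key=lambda c: min(lab.rank.get(i, _INF) for i in c))
    for comp in comps:
        root = choose_start_atom(g, comp, lab)
        plan.roots.append(root)
        visit(root, None, None)
    return plan


def assign_closure_digits(plan: TraversalPlan, lab: CanonicalLabeling) -> None:
    """Allocate ring-closure digits (lowest available, reused once closed;
    openings before closings on an atom, Rules J and K)."""
    openings: dict[int, list[_Closure]] = {}
    closings: dict[int, list[_Closure]] = {}
    for c in plan.closures:
        openings.setdefault(c.opening, []).append(c)
        closings.setdefault(c.closing, []).append(c)
    for atom, lst in openings.items():
        lst.sort(key=lambda c: (lab.rank.get(c.closing, _INF), plan.pos[c.closing]))
    in_use: set[int] = set()
    seq = 0
    for u in plan.order:
        for c in openings.get(u, ()):
            digit = 1
            while digit in in_use:
                digit += 1
            c.digit = digit
            c.open_seq = seq
            seq += 1
            in_use.add(digit)
        closing_here = sorted(closings.get(u, ()), key=lambda c: c.open_seq)
        closings[u] = closing_here
        for c in closing_here:
            in_use.discard(c.digit)
    plan._openings = openings  # type: ignore[attr-defined]
    plan._closings = closings  # type: ignore[attr-defined]


# --------------------------------------------------------------------------
# cis/trans systems (Rules G, H, I)


class _StereoSystems:
    """Orientation assignment for directional single bonds.

    Each variable bond ``k=(lo,hi)`` carries an orientation ``o`` meaning
    "written lo then hi, the symbol is '/'" when ``o=+1``.  Constraints from
    each configured double bond 2-colour the variables; each connected
    constraint component is one isolated/conjugated cis/trans system.
    """

    def __init__(self, g: MolecularGraph, kept, bracket_h):
        self.g = g
        self.adj: dict[tuple[int, int], list[tuple[tuple[int, int], int]]] = {}
        self.orient: dict[tuple[int, int], int] = {}
        self.comp_id: dict[tuple[int, int], int] = {}
        self.double_ends: dict[tuple[int, int], set[int]] = {}

        ds_list = []
        for ds in g.db_stereo:
            ds = self._resolve(ds, kept, bracket_h)
            if ds is not None:
                ds_list.append(ds)

        def sub_bonds(end: int, other_end: int):
            out = []
            for bond, v in g.neighbors(end):
                if v == other_end and bond.order == 2:
                    continue
                if bond.order != 1 or not kept[v]:
                    continue
                out.append((bond, v))
            return out

        def s_expr(bond: Bond, sub: int, end: int):
            # dir(sub -> end) in terms of the bond's orientation variable
            sign = 1 if bond.key == (sub, end) else -1
            return bond.key, sign

        edges: list[tuple[tuple[int, int], int, tuple[int, int], int, int]] = []
        for ds in ds_list:
            ends = ((ds.a, ds.b, ds.ref_a), (ds.b, ds.a, ds.ref_b))
            per_end = []
            for end, other, ref in ends:
                subs = sub_bonds(end, other)
                if not any(v == ref for _, v in subs):
                    per_end = []
                    break
                for bond, v in subs:
                    self.double_ends.setdefault(bond.key, set()).add(end)
                # same-end constraints: opposite orientations
                for i in range(1, len(subs)):
                    k1, s1 = s_expr(subs[0][0], subs[0][1], end)
                    k2, s2 = s_expr(subs[i][0], subs[i][1], end)
                    edges.append((k1, s1, k2, s2, -1))
                ref_bond = next(b for b, v in subs if v == ref)
                per_end.append(s_expr(ref_bond, ref, end))
            if len(per_end) == 2:
                (ka, sa), (kb, sb) = per_end
                rel = 1 if ds.config == "together" else -1
                edges.append((ka, sa, kb, sb, rel))

        for k1, s1, k2, s2, rel in edges:
            # s1*o1 rel== s2*o2  ->  o1 = rel*s1*s2 * o2
            parity = rel * s1 * s2
            self.adj.setdefault(k1, []).append((k2, parity))
            self.adj.setdefault(k2, []).append((k1, parity))

        cid = 0
        for k in self.adj:
            if k in self.orient:
                continue
            self.orient[k] = 1
            self.comp_id[k] = cid
            stack = [k]
            while stack:
                cur = stack.pop()
                for nxt, parity in self.adj[cur]:
                    want = self.orient[cur] * parity
                    if nxt in self.orient:
                        if self.orient[nxt] != want:
                            raise StereoConsistencyError(
                                "contradictory cis/trans constraints around "
                                f"bond {nxt}"
                            )
                    else:
                        self.orient[nxt] = want
                        self.comp_id[nxt] = cid
                        stack.append(nxt)
            cid += 1

    @staticmethod
    def _resolve(ds, kept, bracket_h):
        """Re-anchor a stereo reference that points at a folded hydrogen; drop
        the descriptor if no explicit reference remains."""
        # folded hydrogens cannot carry a direction symbol
        for which in ("ref_a", "ref_b"):
            pass
        if kept[ds.ref_a] and kept[ds.ref_b]:
            return ds
        return None

    def is_variable(self, key: tuple[int, int]) -> bool:
        return key in self.orient

    def direction(self, key: tuple[int, int], frm: int, to: int) -> int:
        o = self.orient[key]
        return o if (frm, to) == key else -o

    def char(self, slot: _DirSlot) -> str:
        return "/" if self.direction(slot.key, slot.from_atom, slot.to_atom) > 0 else "\\"

    def apply_rule_h(self, pieces: list) -> None:
        """Flip whole systems so the earliest symbol of each is '/'."""
        seen: set[int] = set()
        for piece in pieces:
            if isinstance(piece, _DirSlot):
                comp = self.comp_id[piece.key]
                if comp in seen:
                    continue
                seen.add(comp)
                if self.char(piece) == "\\":
                    for k, c in self.comp_id.items():
                        if c == comp:
                            self.orient[k] = -self.orient[k]

    def closure_symbol_end(self, closure: _Closure) -> int:
        """The atom occurrence that carries the direction symbol of a
        directional ring-closure bond: the end attached to the configured
        double bond (the opening occurrence when both ends qualify)."""
        ends = self.double_ends.get(closure.bond.key, set())
        if closure.opening in ends:
            return closure.opening
        if closure.closing in ends:
            return closure.closing
        return closure.opening


# --------------------------------------------------------------------------
# atom tokens (Rule F) and tetrahedral tokens


def _implied_h(g: MolecularGraph, atom_idx: int, kept) -> int:
    a = g.atoms[atom_idx]
    ev = 0.0
    for bond, v in g.neighbors(atom_idx):
        if not kept[v]:
            continue
        ev += 1.5 if bond.aromatic else bond.order
    ev_int = int(math.ceil(ev))
    valences = _DEFAULT_VALENCES.get(a.element, ())
    if not valences:
        return 0
    if a.aromatic:
        # aromatic atoms take only their lowest normal valence (a bare 'n'
        # with three connections implies no hydrogen)
        return max(0, valences[0] - ev_int)
    for val in valences:
        if val >= ev_int:
            return val - ev_int
    return 0


def _charge_text(charge: int) -> str:
    if charge == 0:
        return ""
    sign = "+" if charge > 0 else "-"
    mag = abs(charge)
    return sign if mag == 1 else f"{sign}{mag}"


def _atom_token(
    g: MolecularGraph,
    atom_idx: int,
    kept,
    extra_h,
    has_bracket_h: bool,
    stereo_token: str,
) -> str:
    a = g.atoms[atom_idx]
    eff_h = a.implicit_h + extra_h[atom_idx] + (1 if has_bracket_h else 0)
    symbol = a.element.lower() if a.aromatic else a.element
    bare_ok = (
        a.element in _ORGANIC_SUBSET
        and a.charge == 0
        and a.isotope == 0
        and not stereo_token
        and eff_h == _implied_h(g, atom_idx, kept)
    )
    if bare_ok:
        return symbol
    iso = str(a.isotope) if a.isotope else ""
    if eff_h == 0:
        h_field = ""
    elif eff_h == 1:
        h_field = "H"
    else:
        h_field = f"H{eff_h}"
    return f"[{iso}{symbol}{stereo_token}{h_field}{_charge_text(a.charge)}]"


def _tetra_token(
    g: MolecularGraph,
    u: int,
    plan: TraversalPlan,
    bracket_h: dict[int, int],
) -> str:
    """'@' or '@@' for atom ``u`` given the written neighbor order, or ''."""
    ts = next((t for t in g.tet_stereo if t.center == u), None)
    if ts is None:
        return ""
    written: list[int] = []
    if u in plan.parent:
        written.append(plan.parent[u])
    # In-bracket hydrogen: right after the preceding atom, or first when the
    # stereocentre starts its component.  A lone-pair placeholder instead
    # counts as the *last* reference.
    slot = None
    lone_pair = False
    if u in bracket_h:
        slot = bracket_h[u]
    elif H_PLACEHOLDER in ts.neighbors:
        slot = H_PLACEHOLDER
        lone_pair = g.atoms[u].implicit_h == 0
    if slot is not None and not lone_pair:
        written.append(slot)
    for c in plan._openings.get(u, ()):  # type: ignore[attr-defined]
        written.append(c.closing)
    for c in plan._closings.get(u, ()):  # type: ignore[attr-defined]
        written.append(c.opening)
    for _, v in plan.children[u]:
        written.append(v)
    if slot is not None and lone_pair:
        written.append(slot)
    if sorted(written) != sorted(ts.neighbors):
        return ""  # unresolvable reference (e.g. fewer than 4 neighbors kept)
    flips = _permutation_parity(list(ts.neighbors), written)
    winding = ts.winding if flips % 2 == 0 else ("cw" if ts.winding == "ccw" else "ccw")
    return "@" if winding == "ccw" else "@@"


# --------------------------------------------------------------------------
# assembly


def _bond_symbol(g: MolecularGraph, bond: Bond) -> str:
    if bond.aromatic:
        return ""
    if bond.order == 1:
        aa, ab = g.atoms[bond.a], g.atoms[bond.b]
        return "-" if (aa.aromatic and ab.aromatic) else ""
    if bond.order == 2:
        return "="
    return "#"


def _digit_text(digit: int) -> str:
    return str(digit) if digit < 10 else f"%{digit}"


def write_smiles(g: MolecularGraph, lab: CanonicalLabeling) -> str:
    """Write the canonical SMILES of ``g`` under the labeling ``lab``."""
    if g.n_atoms == 0:
        return ""
    kept, extra_h, bracket_h = _fold_hydrogens(g, lab)
    plan = build_traversal(g, lab)
    assign_closure_digits(plan, lab)
    systems = _StereoSystems(g, kept, bracket_h)

    pieces: list = []

    def bond_piece(bond: Bond, frm: int, to: int):
        if bond.order == 1 and systems.is_variable(bond.key):
            pieces.append(_DirSlot(bond.key, frm, to))
        else:
            sym = _bond_symbol(g, bond)
            if sym:
                pieces.append(sym)

    def closure_pieces(u: int, c: _Closure, opening: bool):
        distal = c.closing if opening else c.opening
        if c.bond.order == 1 and systems.is_variable(c.bond.key):
            if systems.closure_symbol_end(c) == u:
                pieces.append(_DirSlot(c.bond.key, u, distal))
        elif opening:
            sym = _bond_symbol(g, c.bond)
            if sym:
                pieces.append(sym)
        pieces.append(_digit_text(c.digit))

    def emit(u: int) -> None:
        stereo = _tetra_token(g, u, plan, bracket_h)
        pieces.append(_atom_token(g, u, kept, extra_h, u in bracket_h, stereo))
        for c in plan._openings.get(u, ()):  # type: ignore[attr-defined]
            closure_pieces(u, c, opening=True)
        for c in plan._closings.get(u, ()):  # type: ignore[attr-defined]
            closure_pieces(u, c, opening=False)
        kids = plan.children[u]
        for i, (bond, v) in enumerate(kids):
            last = i == len(kids) - 1
            if not last:
                pieces.append("(")
            bond_piece(bond, u, v)
            emit(v)
            if not last:
                pieces.append(")")

    for i, root in enumerate(plan.roots):
        if i:
            pieces.append(".")
        emit(root)

    systems.apply_rule_h(pieces)
    return "".join(
        systems.char(p) if isinstance(p, _DirSlot) else p for p in pieces
    )


__all__ = [
    "TraversalPlan",
    "choose_start_atom",
    "order_branches",
    "build_traversal",
    "assign_closure_digits",
    "write_smiles",
]
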