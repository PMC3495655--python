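"""Molecular-graph data model and I/O.

The graph is deliberately small: atoms, bonds, tetrahedral and double-bond
stereo descriptors, and the connected-component partition.  Bond orders are
always stored in Kekule form; aromaticity is carried as flags on atoms and
bonds so that a valid Kekule assignment is retained at all times.

Reading of the standard formats (SMILES, MDL Mol/SDF) is delegated to RDKit,
whose perception (valence filling, aromatic model, wedge/hash and 2D
double-bond stereo) defines the chemical model of this package.  Explicit
hydrogen atoms present in the input are preserved as graph atoms, because the
InChI auxiliary information numbers input atoms including explicit hydrogens.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from rdkit import Chem
from rdkit import RDLogger

from .errors import KekulizationError, ParseError

RDLogger.DisableLog("rdApp.*")

#: Sentinel used in :class:`TetrahedralStereo` neighbor lists for the implicit
#: hydrogen (or lone pair) of a stereocentre with fewer than four explicit
#: neighbors.  It always occupies the *last* slot of the stored reference
#: order, matching the convention of the backend toolkit.
H_PLACEHOLDER = -1

_ORGANIC_SUBSET = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
_DEFAULT_VALENCES = {
    "B": (3,),
    "C": (4,),
    "N": (3, 5),
    "O": (2,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "F": (1,),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
}


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    isotope: int = 0
    charge: int = 0
    implicit_h: int = 0
    aromatic: bool = False

    @property
    def is_explicit_h(self) -> bool:
        return self.element == "H"


@dataclass(frozen=True)
class Bond:
    a: int
    b: int
    order: int = 1
    aromatic: bool = False

    def other(self, idx: int) -> int:
        if idx == self.a:
            return self.b
        if idx == self.b:
            return self.a
        raise ValueError(f"atom {idx} not on bond {self.a}-{self.b}")

    @property
    def key(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


@dataclass(frozen=True)
class TetrahedralStereo:
    """Winding of four neighbor references around a stereocentre.

    ``winding == "ccw"`` means: viewed from ``neighbors[0]``, the remaining
    three references appear anticlockwise in list order (the ``@`` sense).
    """

    center: int
    neighbors: tuple[int, int, int, int]
    winding: str  # "ccw" | "cw"


@dataclass(frozen=True)
class DoubleBondStereo:
    """Configuration of one substituent at each end of a double bond.

    ``config == "together"`` means ``ref_a`` and ``ref_b`` lie on the same
    side of the ``a``/``b`` double-bond axis (cis); ``"opposite"`` is trans.
    """

    a: int
    b: int
    ref_a: int
    ref_b: int
    config: str  # "together" | "opposite"


@dataclass
class MolecularGraph:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    tet_stereo: list[TetrahedralStereo] = field(default_factory=list)
    db_stereo: list[DoubleBondStereo] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._adj: dict[int, list[Bond]] | None = None

    # -- basic queries ----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, idx: int) -> list[tuple[Bond, int]]:
        if self._adj is None:
            adj: dict[int, list[Bond]] = {i: [] for i in range(self.n_atoms)}
            for b in self.bonds:
                adj[b.a].append(b)
                adj[b.b].append(b)
            self._adj = adj
        return [(b, b.other(idx)) for b in self._adj[idx]]

    def bond_between(self, a: int, b: int) -> Bond | None:
        for bond, nbr in self.neighbors(a):
            if nbr == b:
                return bond
        return None

    @property
    def components(self) -> list[list[int]]:
        """Connected components, each a sorted list of atom indices, ordered
        by smallest member."""
        parent = list(range(self.n_atoms))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for b in self.bonds:
            ra, rb = find(b.a), find(b.b)
            if ra != rb:
                parent[ra] = rb
        groups: dict[int, list[int]] = {}
        for i in range(self.n_atoms):
            groups.setdefault(find(i), []).append(i)
        return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])

    # -- conversions ------------------------------------------------------

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol) -> "MolecularGraph":
        """Convert an RDKit molecule, retaining a Kekule bond-order
        assignment alongside aromatic flags."""
        kek = Chem.Mol(mol)
        try:
            Chem.Kekulize(kek, clearAromaticFlags=False)
        except Chem.KekulizeException as exc:  # pragma: no cover - defensive
            raise KekulizationError(str(exc)) from exc

        atoms = []
        for a in kek.GetAtoms():
            atoms.append(
                Atom(
                    index=a.GetIdx(),
                    element=a.GetSymbol(),
                    isotope=a.GetIsotope(),
                    charge=a.GetFormalCharge(),
                    implicit_h=a.GetTotalNumHs(includeNeighbors=False),
                    aromatic=a.GetIsAromatic(),
                )
            )
        bonds = []
        for b in kek.GetBonds():
            order = int(b.GetBondTypeAsDouble())
            if order not in (1, 2, 3):
                raise ParseError(
                    f"unsupported bond order {b.GetBondTypeAsDouble()} on bond "
                    f"{b.GetBeginAtomIdx()}-{b.GetEndAtomIdx()}"
                )
            bonds.append(
                Bond(
                    a=b.GetBeginAtomIdx(),
                    b=b.GetEndAtomIdx(),
                    order=order,
                    aromatic=b.GetIsAromatic(),
                )
            )

        tet = []
        for a in kek.GetAtoms():
            tag = a.GetChiralTag()
            if tag not in (
                Chem.ChiralType.CHI_TETRAHEDRAL_CW,
                Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
            ):
                continue
            nbrs = [b.GetOtherAtomIdx(a.GetIdx()) for b in a.GetBonds()]
            if len(nbrs) == 3:
                nbrs.append(H_PLACEHOLDER)
            if len(nbrs) != 4:
                continue  # degenerate tag; not a tetrahedral centre
            winding = (
                "ccw" if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CCW else "cw"
            )
            tet.append(
                TetrahedralStereo(
                    center=a.GetIdx(), neighbors=tuple(nbrs), winding=winding
                )
            )

        dbs = []
        for b in kek.GetBonds():
            st = b.GetStereo()
            if st in (
                Chem.BondStereo.STEREOZ,
                Chem.BondStereo.STEREOCIS,
            ):
                config = "together"
            elif st in (
                Chem.BondStereo.STEREOE,
                Chem.BondStereo.STEREOTRANS,
            ):
                config = "opposite"
            else:
                continue
            sa = list(b.GetStereoAtoms())
            if len(sa) != 2:
                continue
            begin, end = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            # GetStereoAtoms gives one neighbor of each end, begin end first
            ra = sa[0] if kek.GetBondBetweenAtoms(sa[0], begin) else sa[1]
            rb = sa[1] if ra == sa[0] else sa[0]
            dbs.append(
                DoubleBondStereo(a=begin, b=end, ref_a=ra, ref_b=rb, config=config)
            )
        return cls(atoms=atoms, bonds=bonds, tet_stereo=tet, db_stereo=dbs)

    def to_rdkit(self, aromatic_flags: bool = True) -> Chem.Mol:
        """Build an RDKit molecule with pinned hydrogen counts.

        Bond orders are written in Kekule form.  Sanitization is *not*
        applied, so expanded-valence groups (e.g. neutral N(=O)=O) survive.
        """
        rw = Chem.RWMol()
        for a in self.atoms:
            ra = Chem.Atom(a.element)
            ra.SetFormalCharge(a.charge)
            ra.SetIsotope(a.isotope)
            ra.SetNumExplicitHs(a.implicit_h)
            ra.SetNoImplicit(True)
            if aromatic_flags:
                ra.SetIsAromatic(a.aromatic)
            rw.AddAtom(ra)
        order_map = {
            1: Chem.BondType.SINGLE,
            2: Chem.BondType.DOUBLE,
            3: Chem.BondType.TRIPLE,
        }
        for b in self.bonds:
            rw.AddBond(b.a, b.b, order_map[b.order])
            if aromatic_flags and b.aromatic:
                rw.GetBondBetweenAtoms(b.a, b.b).SetIsAromatic(True)
        mol = rw.GetMol()
        mol.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(mol)

        for ts in self.tet_stereo:
            atom = mol.GetAtomWithIdx(ts.center)
            stored = [b.GetOtherAtomIdx(ts.center) for b in atom.GetBonds()]
            if len(stored) == 3:
                stored.append(H_PLACEHOLDER)
            if sorted(stored) != sorted(ts.neighbors):
                continue  # stereo reference no longer resolvable
            flips = _permutation_parity(list(ts.neighbors), stored)
            winding = ts.winding if flips % 2 == 0 else _flip(ts.winding)
            atom.SetChiralTag(
                Chem.ChiralType.CHI_TETRAHEDRAL_CCW
                if winding == "ccw"
                else Chem.ChiralType.CHI_TETRAHEDRAL_CW
            )
        for ds in self.db_stereo:
            bond = mol.GetBondBetweenAtoms(ds.a, ds.b)
            if bond is None or bond.GetBondType() != Chem.BondType.DOUBLE:
                continue
            bond.SetStereoAtoms(ds.ref_a, ds.ref_b)
            bond.SetStereo(
                Chem.BondStereo.STEREOCIS
                if ds.config == "together"
                else Chem.BondStereo.STEREOTRANS
            )
        return mol

    # -- structure permutation -------------------------------------------

    def permute(self, order: list[int]) -> "MolecularGraph":
        """Return the isomorphic graph whose new atom ``i`` is old atom
        ``order[i]``.  Stereo descriptors are index-remapped; since both
        stereo conventions are defined over *reference lists*, remapping
        indices leaves the described chemistry unchanged."""
        if sorted(order) != list(range(self.n_atoms)):
            raise ValueError("order must be a permutation of atom indices")
        new_pos = {old: new for new, old in enumerate(order)}

        def m(idx: int) -> int:
            return H_PLACEHOLDER if idx == H_PLACEHOLDER else new_pos[idx]

        atoms = [
            replace(self.atoms[old], index=new) for new, old in enumerate(order)
        ]
        bonds = [replace(b, a=m(b.a), b=m(b.b)) for b in self.bonds]
        tet = [
            TetrahedralStereo(
                center=m(t.center),
                neighbors=tuple(m(n) for n in t.neighbors),
                winding=t.winding,
            )
            for t in self.tet_stereo
        ]
        dbs = [
            DoubleBondStereo(
                a=m(d.a), b=m(d.b), ref_a=m(d.ref_a), ref_b=m(d.ref_b),
                config=d.config,
            )
            for d in self.db_stereo
        ]
        return MolecularGraph(atoms=atoms, bonds=bonds, tet_stereo=tet, db_stereo=dbs)


def _flip(winding: str) -> str:
    return "cw" if winding == "ccw" else "ccw"


def _permutation_parity(src: list, dst: list) -> int:
    """Number of transpositions taking ``src`` to ``dst`` (mod 2)."""
    src = list(src)
    count = 0
    for i in range(len(src)):
        if src[i] != dst[i]:
            j = src.index(dst[i], i + 1)
            src[i], src[j] = src[j], src[i]
            count += 1
    return count


# -- readers ---------------------------------------------------------------


def read_smiles(text: str) -> MolecularGraph:
    """Parse an OpenSMILES string into a :class:`MolecularGraph`.

    Explicit hydrogen atoms written as ``[H]``/``[2H]`` tokens are kept as
    graph atoms; in-bracket hydrogen counts (``[C@H]``) become implicit
    hydrogens.  Atom order equals token order.
    """
    params = Chem.SmilesParserParams()
    params.removeHs = False
    mol = Chem.MolFromSmiles(text, params)
    if mol is None:
        raise ParseError(f"invalid SMILES: {text!r}")
    return MolecularGraph.from_rdkit(mol)


def read_molfile(text: str) -> MolecularGraph:
    """Parse an MDL Mol (V2000) block, converting wedge/hash marks and 2D/3D
    geometry into stereo descriptors.  Atom order follows the file."""
    mol = Chem.MolFromMolBlock(text, sanitize=True, removeHs=False)
    if mol is None:
        raise ParseError("malformed Mol block")
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    return MolecularGraph.from_rdkit(mol)


def permute_atoms(g: MolecularGraph, seed: int) -> MolecularGraph:
    """Seeded pseudo-random reordering of the atoms of ``g``; the result is
    isomorphic to ``g`` (identical InChI for every seed)."""
    order = list(range(g.n_atoms))
    random.Random(seed).shuffle(order)
    return g.permute(order)


def perceive_aromaticity(g: MolecularGraph) -> MolecularGraph:
    """Re-run aromaticity perception (the backend's default model) on the
    stored Kekule structure, refreshing atom and bond aromatic flags."""
    mol = g.to_rdkit(aromatic_flags=False)
    try:
        Chem.SanitizeMol(
            mol,
            Chem.SANITIZE_SYMMRINGS
            | Chem.SANITIZE_KEKULIZE
            | Chem.SANITIZE_SETAROMATICITY
            | Chem.SANITIZE_SETCONJUGATION,
        )
    except Chem.KekulizeException as exc:
        raise KekulizationError(str(exc)) from exc
    return MolecularGraph.from_rdkit(mol)


__all__ = [
    "Atom",
    "Bond",
    "TetrahedralStereo",
    "DoubleBondStereo",
    "MolecularGraph",
    "H_PLACEHOLDER",
    "read_smiles",
    "read_molfile",
    "permute_atoms",
    "perceive_aromaticity",
]
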