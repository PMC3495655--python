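"""Adapter around the official InChI library (via RDKit's libinchi wrapper).

The InChI canonicalisation itself is never reimplemented here; this module
isolates exactly two calls so a different backend could be swapped in:

* :func:`to_inchi` -- structure -> (InChI, AuxInfo), standard or with the
  non-standard *FixedH*/*RecMet* options;
* :func:`from_inchi` -- InChI -> normalised structure in canonical atom order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import inchi as _rdinchi

from .errors import InchiGenerationError
from .molgraph import MolecularGraph


@dataclass(frozen=True)
class InchiOptions:
    """InChI generation options.

    Universal SMILES requires ``fixed_h`` and ``rec_met`` both true; the
    Inchified roundtrip uses the Standard InChI (both false).
    """

    fixed_h: bool = False
    rec_met: bool = False

    @property
    def flags(self) -> str:
        parts = []
        if self.fixed_h:
            parts.append("/FixedH")
        if self.rec_met:
            parts.append("/RecMet")
        return " ".join(parts)


UNIVERSAL_OPTIONS = InchiOptions(fixed_h=True, rec_met=True)
STANDARD_OPTIONS = InchiOptions()


@dataclass(frozen=True)
class InchiResult:
    inchi: str
    auxinfo: str
    warnings: tuple[str, ...] = ()


def to_inchi(g: MolecularGraph, opts: InchiOptions = STANDARD_OPTIONS) -> InchiResult:
    """Generate the InChI and auxiliary information for ``g``.

    The strings are those of the official InChI software for the same
    structure in the same atom order (the AuxInfo ``/N`` layer refers to the
    graph's atom indices, 1-based).
    """
    mol = g.to_rdkit()
    warnings: list[str] = []
    try:
        ich, aux = _rdinchi.MolToInchiAndAuxInfo(
            mol, options=opts.flags, treatWarningAsError=False
        )
    except Exception as exc:  # pragma: no cover - backend-specific failures
        raise InchiGenerationError(str(exc)) from exc
    if not ich or not ich.startswith("InChI="):
        raise InchiGenerationError(f"InChI generation failed (got {ich!r})")
    if not aux or not aux.startswith("AuxInfo="):
        raise InchiGenerationError(f"no auxiliary information (got {aux!r})")
    return InchiResult(inchi=ich, auxinfo=aux, warnings=tuple(warnings))


def from_inchi(text: str) -> MolecularGraph:
    """Convert an InChI back to its normalised structure.

    Atom order in the returned graph is the InChI canonical order (heavy
    atoms first, in canonical numbering; any explicit hydrogens the library
    materialises follow).  Normalisations encoded by the InChI -- nitro
    expansion to N(=O)=O, tautomer collapse, metal disconnection for the
    Standard InChI -- are reflected in the graph.
    """
    if not text.startswith("InChI="):
        raise InchiGenerationError(f"not an InChI string: {text!r}")
    mol, code, _msg, _log = _rdinchi.rdinchi.InchiToMol(text, False, False)
    if mol is None or code not in (0, 1):
        raise InchiGenerationError(f"InChI conversion failed for {text!r}: {_msg}")
    _restore_expanded_nitro(mol)
    mol = _restore_isotopic_hydrogens(mol, text)
    mol.UpdatePropertyCache(strict=False)
    Chem.SanitizeMol(
        mol,
        Chem.SANITIZE_SYMMRINGS
        | Chem.SANITIZE_SETAROMATICITY
        | Chem.SANITIZE_SETCONJUGATION,
        catchErrors=True,
    )
    return MolecularGraph.from_rdkit(mol)


def _restore_expanded_nitro(mol: Chem.Mol) -> None:
    """Undo the backend's re-separation of nitro charges.

    The InChI structure model stores nitro groups with expanded valence,
    N(=O)=O; the RDKit conversion layer unconditionally rewrites them as
    [N+](=O)[O-].  Restore the expanded form so the returned graph matches
    what the InChI library actually encodes.  Only the unambiguous textbook
    pattern (3-connected N+ with one =O and one -O(-)) is rewritten.
    """
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "N" or atom.GetFormalCharge() != 1:
            continue
        if atom.GetDegree() != 3 or atom.GetIsAromatic():
            continue
        has_double_o = any(
            b.GetBondType() == Chem.BondType.DOUBLE
            and b.GetOtherAtom(atom).GetSymbol() == "O"
            for b in atom.GetBonds()
        )
        if not has_double_o:
            continue
        for b in atom.GetBonds():
            o = b.GetOtherAtom(atom)
            if (
                b.GetBondType() == Chem.BondType.SINGLE
                and o.GetSymbol() == "O"
                and o.GetFormalCharge() == -1
                and o.GetDegree() == 1
            ):
                b.SetBondType(Chem.BondType.DOUBLE)
                o.SetFormalCharge(0)
                atom.SetFormalCharge(0)
                break


_ISO_ENTRY = re.compile(r"^(\d+)(?:[+-]\d+)?((?:[HDT]\d*)*)$")
_ISO_TOKEN = re.compile(r"([HDT])(\d*)")
_ISO_MASS = {"H": 1, "D": 2, "T": 3}


def _restore_isotopic_hydrogens(mol: Chem.Mol, inchi_text: str) -> Chem.Mol:
    """Materialise isotopic hydrogens dropped by the backend conversion.

    When one atom carries several *different* hydrogen isotopes (e.g. the
    ``/i1TD`` layer of CHDT-Cl), the backend creates only one of them.  The
    fixed isotopic layer is compared against the explicit hydrogens actually
    present and the missing ones are added; the (possibly new) molecule is
    returned.  Any unexpected layer syntax is left untouched.
    """
    m = re.search(r"/i([^/]*)", inchi_text)
    if not m or not m.group(1):
        return mol
    # local-to-global numbering: canonical components are contiguous
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() != 1]
    comp_sizes = []
    if heavy:
        frags = Chem.GetMolFrags(mol)
        comp_sizes = [
            sum(1 for i in frag if mol.GetAtomWithIdx(i).GetAtomicNum() != 1)
            for frag in frags
        ]
    offsets = [0]
    for size in comp_sizes[:-1]:
        offsets.append(offsets[-1] + size)

    rw = None
    for comp_idx, comp in enumerate(m.group(1).split(";")):
        if not comp or comp_idx >= len(offsets):
            continue
        for entry in comp.split(","):
            em = _ISO_ENTRY.match(entry)
            if not em or not em.group(2):
                continue
            atom_idx = offsets[comp_idx] + int(em.group(1)) - 1
            if atom_idx >= mol.GetNumAtoms():
                continue
            want: dict[int, int] = {}
            for sym, count in _ISO_TOKEN.findall(em.group(2)):
                want[_ISO_MASS[sym]] = int(count) if count else 1
            atom = mol.GetAtomWithIdx(atom_idx)
            have: dict[int, int] = {}
            for b in atom.GetBonds():
                o = b.GetOtherAtom(atom)
                if o.GetAtomicNum() == 1 and o.GetIsotope():
                    have[o.GetIsotope()] = have.get(o.GetIsotope(), 0) + 1
            for mass, n in want.items():
                for _ in range(n - have.get(mass, 0)):
                    if rw is None:
                        rw = Chem.RWMol(mol)
                    h = Chem.Atom(1)
                    h.SetIsotope(mass)
                    h.SetNoImplicit(True)
                    new_idx = rw.AddAtom(h)
                    rw.AddBond(atom_idx, new_idx, Chem.BondType.SINGLE)
    return rw.GetMol() if rw is not None else mol


__all__ = [
    "InchiOptions",
    "InchiResult",
    "UNIVERSAL_OPTIONS",
    "STANDARD_OPTIONS",
    "to_inchi",
    "from_inchi",
]
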