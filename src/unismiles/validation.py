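"""Order-invariance (shuffle) and duplicate tests, plus the built-in
fixture set they run on.

The shuffle test writes several anti-canonical SMILES for a structure,
re-reads each and regenerates the canonical form; a structure passes when
every regenerated string is identical.  The duplicate test groups records
whose canonical key (InChI, Universal or Inchified SMILES) is byte-equal.

Two failure classes are expected and shipped as tagged fixtures: molecules
whose graph symmetry is broken only by charge states in a delocalised
system, and molecules whose symmetry is broken only by hydrogen isotopes
(the canonical-label section associated with the InChI isotopic layer is
not used; see the package documentation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UnismilesError
from .molgraph import MolecularGraph, permute_atoms, read_smiles
from .auxinfo import identity_labeling
from .inchi_backend import STANDARD_OPTIONS, to_inchi
from .pipeline import inchified_smiles, universal_smiles
from .writer import write_smiles


@dataclass(frozen=True)
class FixtureRecord:
    """One fixture structure.

    ``expected_fail`` names the class of *Universal* shuffle failure the
    record is shipped to demonstrate; the Inchified form of the same record
    is expected to pass (a given InChI always yields the same Inchified
    SMILES, so InChI-canonicalisable structures cannot fail that mode).
    """

    record_id: str
    smiles: str
    expected_fail: str | None = None  # "delocalised_charge" | "isotope_layer"
    tags: tuple[str, ...] = ()


@dataclass
class ShuffleReport:
    record_id: str
    n_reps: int
    distinct_outputs: set[str] = field(default_factory=set)
    errors: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return len(self.distinct_outputs) == 1 and not self.errors


@dataclass
class DuplicateReport:
    key_kind: str  # "inchi" | "universal" | "inchified"
    groups: list[tuple[str, list[str]]] = field(default_factory=list)
    errors: list[tuple[str, str]] = field(default_factory=list)

    def group_for(self, record_id: str) -> list[str] | None:
        for _, members in self.groups:
            if record_id in members:
                return members
        return None


_MODE_FN = {
    "universal": universal_smiles,
    "inchified": inchified_smiles,
}


def shuffle_test(
    g: MolecularGraph,
    n_reps: int = 10,
    mode: str = "universal",
    base_seed: int = 0,
    record_id: str = "",
) -> ShuffleReport:
    """Regenerate the canonical SMILES from ``n_reps`` anti-canonical
    orderings of ``g``; pass means a single distinct output and no errors."""
    fn = _MODE_FN[mode]
    report = ShuffleReport(record_id=record_id, n_reps=n_reps)
    for i in range(1, n_reps + 1):
        try:
            gp = permute_atoms(g, base_seed + i)
            anti = write_smiles(gp, identity_labeling(gp))
            report.distinct_outputs.add(fn(read_smiles(anti)))
        except UnismilesError as exc:
            report.errors.append(f"rep {i}: {exc}")
    return report


def duplicate_test(
    records: list[FixtureRecord] | list[tuple[str, str]],
    key_kind: str = "inchi",
) -> DuplicateReport:
    """Group records whose canonical key is byte-identical."""
    report = DuplicateReport(key_kind=key_kind)
    by_key: dict[str, list[str]] = {}
    for rec in records:
        rid, smi = (
            (rec.record_id, rec.smiles)
            if isinstance(rec, FixtureRecord)
            else rec
        )
        try:
            g = read_smiles(smi)
            if key_kind == "inchi":
                key = to_inchi(g, STANDARD_OPTIONS).inchi
            else:
                key = _MODE_FN[key_kind](g)
        except UnismilesError as exc:
            report.errors.append((rid, str(exc)))
            continue
        by_key.setdefault(key, []).append(rid)
    report.groups = [
        (key, members) for key, members in by_key.items() if len(members) > 1
    ]
    return report


# --------------------------------------------------------------------------
# fixtures

# Worked examples from the canonicalisation recipe
_TABLE_EXAMPLES = [
    ("t1-ethanol", "OCC"),
    ("t1-bromoacetylchloride", "ClCC(=O)Br"),
    ("t1-methane-pair", "C.C"),
    ("t1-methane-ethane", "C.CC"),
    ("t1-ethane-expl-h", "C([H])C"),
    ("t1-methanol-d", "C([2H])O"),
    ("t2-h-oxalate-a", "C(=O)([O-])C(=O)O"),
    ("t2-h-oxalate-b", "C(=O)(O)C(=O)[O-]"),
    ("rule-d-dhalomethane", "C([2H])([3H])Cl"),
    ("rule-d-dhalomethane-rev", "C(Cl)([3H])[2H]"),
    ("rule-g-haloethene", "Cl/C=C(\\Br)/I"),
    ("rule-h-trans", "Cl/C=C/I"),
    ("rule-h-trans-rev", "I/C=C/Cl"),
    ("rule-i-ring-closure", "C/C=C\\1/NC1"),
    ("fig1-fluorovinyl-nitrobenzene", "c1cc(/C=C/F)cc(c1)[N+](=O)[O-]"),
]

# Hydrogen species and isotopes
_HYDROGEN = [
    ("dihydrogen", "[H][H]"),
    ("hydride", "[H-]"),
    ("proton", "[H+]"),
    ("hydronium-pair", "O.[H+]"),
    ("heavy-water", "[2H]O[2H]"),
    ("methane-expl", "C([H])([H])([H])[H]"),
    ("c13-methane", "[13CH4]"),
    ("acetic-d3", "OC(=O)C([2H])([2H])[2H]"),
    ("chloroform-d", "[2H]C(Cl)(Cl)Cl"),
]

# Multi-component structures and salts
_SALTS = [
    ("nacl", "[Na+].[Cl-]"),
    ("na-acetate", "CC(=O)[O-].[Na+]"),
    ("amine-hcl", "Cl.CCN"),
    ("ammonium-sulfate", "[NH4+].[NH4+].[O-]S(=O)(=O)[O-]"),
    ("three-comp", "C.CC.CCC"),
    ("pt-complex", "C(=O)O[Pt](N)(N)Cl"),
    ("cisplatin-like", "N[Pt](N)(Cl)Cl"),
]

# Rings: fused, spiro, bridged (closure-digit behaviour)
_RINGS = [
    ("cyclopropane", "C1CC1"),
    ("cyclohexane", "C1CCCCC1"),
    ("benzene", "c1ccccc1"),
    ("benzene-kekule", "C1=CC=CC=C1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("decalin", "C1CCC2CCCCC2C1"),
    ("spiro44", "C1CCC2(CC1)CCCC2"),
    ("norbornane", "C1CC2CCC1C2"),
    ("adamantane", "C1C2CC3CC1CC(C2)C3"),
    ("cubane", "C12C3C4C1C5C4C3C25"),
    ("biphenyl", "c1ccc(-c2ccccc2)cc1"),
    ("indole", "c1ccc2c(c1)cc[nH]2"),
    ("quinoline", "c1ccc2ncccc2c1"),
    ("bicyclooctane", "C1CC2CCC1CC2"),
    ("morpholine", "C1COCCN1"),
]

_AROMATICS = [
    ("pyridine", "c1ccncc1"),
    ("pyrrole", "c1cc[nH]c1"),
    ("furan", "c1ccoc1"),
    ("thiophene", "c1ccsc1"),
    ("imidazole", "c1c[nH]cn1"),
    ("pyrazole", "c1cc[nH]n1"),
    ("oxazole", "c1cnco1"),
    ("pyrimidine", "c1cncnc1"),
    ("aniline", "Nc1ccccc1"),
    ("phenol", "Oc1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("styrene", "C=Cc1ccccc1"),
    ("benzoate", "O=C([O-])c1ccccc1"),
    ("nitrobenzene", "O=[N+]([O-])c1ccccc1"),
    ("furfural", "O=Cc1ccco1"),
]

# Tetrahedral stereocentres
_TETRAHEDRAL = [
    ("l-alanine", "N[C@@H](C)C(=O)O"),
    ("l-alanine-expl-h", "N[C@@]([H])(C)C(=O)O"),
    ("d-alanine", "N[C@]([H])(C)C(=O)O"),
    ("bcfm", "F[C@H](Cl)Br"),
    ("halomethane-4sub", "[C@](F)(Cl)(Br)I"),
    ("butan-2-ol", "C[C@H](O)CC"),
    ("threitol-frag", "OC[C@H](O)[C@@H](O)CO"),
    ("tartaric", "O[C@H]([C@@H](O)C(=O)O)C(=O)O"),
    ("meso-tartaric", "O[C@H]([C@H](O)C(=O)O)C(=O)O"),
    ("sulfoxide-chiral", "C[S@](=O)CC"),
    ("menthol", "CC(C)[C@@H]1CC[C@@H](C)C[C@H]1O"),
    ("glycerald", "OC[C@@H](O)C=O"),
]

# Double-bond stereochemistry (isolated, conjugated, ring, closure)
_CISTRANS = [
    ("trans-difluoroethene", "F/C=C/F"),
    ("cis-difluoroethene", "F/C=C\\F"),
    ("cis-3-hexene", "CC/C=C\\CC"),
    ("sorbaldehyde-frag", "C/C=C/C=C/C"),
    ("conjugated-zz", "C/C=C\\C=C\\C"),
    ("trisub-ene", "C/C(F)=C/Cl"),
    ("crotonate", "C/C=C/C(=O)O"),
    ("cinnamaldehyde", "O=C/C=C/c1ccccc1"),
    ("both-stereo", "C/C=C/[C@@H](C)O"),
    ("ring-cis-large", "C1CCCCCC/C=C\\1"),
    ("trans-cyclooctene", "C1CCC/C=C/CC1"),
    ("fumarate", "OC(=O)/C=C/C(=O)O"),
]

# Charged species and normalisation probes
_CHARGED = [
    ("ammonium", "[NH4+]"),
    ("hydroxide", "[OH-]"),
    ("tma", "C[N+](C)(C)C"),
    ("acetate", "CC(=O)[O-]"),
    ("acetate-rev", "[O-]C(C)=O"),
    ("carbonate", "[O-]C([O-])=O"),
    ("nitroethane", "CC[N+](=O)[O-]"),
    ("sulfoxide-ionic", "C[S+](C)[O-]"),
    ("sulfoxide-neutral", "CS(C)=O"),
    ("pyridinium", "c1cc[nH+]cc1"),
    ("phosphate", "OP(=O)(O)O"),
    ("hydroxypyridine", "Oc1ccccn1"),
    ("pyridone", "O=c1cccc[nH]1"),
]

_MISC = [
    ("acetamide", "CC(=O)N"),
    ("acetonitrile", "CC#N"),
    ("acetylene", "C#C"),
    ("co2", "O=C=O"),
    ("allene", "C=C=C"),
    ("urea", "NC(N)=O"),
    ("guanidinium", "NC(N)=[NH2+]"),
    ("sulfonamide", "CS(=O)(=O)N"),
    ("ethyl-acetate", "CCOC(C)=O"),
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("isobutane", "CC(C)C"),
    ("neopentane", "CC(C)(C)C"),
    ("glucose-open", "OCC(O)C(O)C(O)C(O)C=O"),
    ("tnt-frag", "Cc1ccc(cc1)[N+](=O)[O-]"),
]

_EXPECTED_FAIL = [
    ("deloc-imidazolium", "C[n+]1ccn(C)c1", "delocalised_charge"),
    ("iso-propane-d", "[2H]CCC", "isotope_layer"),
    ("iso-acetone-d", "[2H]CC(=O)C", "isotope_layer"),
]


def make_fixtures(seed: int = 0) -> list[FixtureRecord]:
    """Deterministic fixture set (~200 records).

    Contains the worked examples, stereo/isotope/salt/ring cases, the
    tagged expected-fail classes, and for each base structure one extra
    record written from a seeded atom permutation (so the set carries
    duplicate pairs that differ only in input order).
    """
    base: list[FixtureRecord] = []
    for group, tag in [
        (_TABLE_EXAMPLES, "worked-example"),
        (_HYDROGEN, "hydrogen"),
        (_SALTS, "salt"),
        (_RINGS, "ring"),
        (_AROMATICS, "aromatic"),
        (_TETRAHEDRAL, "tetrahedral"),
        (_CISTRANS, "cistrans"),
        (_CHARGED, "charged"),
        (_MISC, "misc"),
    ]:
        for rid, smi in group:
            base.append(FixtureRecord(rid, smi, None, (tag,)))
    for rid, smi, cls in _EXPECTED_FAIL:
        base.append(FixtureRecord(rid, smi, cls, ("expected-fail",)))

    out = list(base)
    for i, rec in enumerate(base):
        g = read_smiles(rec.smiles)
        if g.n_atoms < 2:
            continue
        gp = permute_atoms(g, seed * 100003 + i)
        variant = write_smiles(gp, identity_labeling(gp))
        out.append(
            FixtureRecord(
                rec.record_id + "#shuffled",
                variant,
                rec.expected_fail,
                rec.tags + ("order-variant",),
            )
        )
    return out


__all__ = [
    "FixtureRecord",
    "ShuffleReport",
    "DuplicateReport",
    "shuffle_test",
    "duplicate_test",
    "make_fixtures",
]
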