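"""Exception hierarchy for unismiles."""


class UnismilesError(Exception):
    """Base class for all package errors."""


class ParseError(UnismilesError):
    """A SMILES string, Mol block, or AuxInfo string could not be parsed."""


class AuxInfoIntegrityError(UnismilesError):
    """An AuxInfo canonical-label section is not a valid permutation, or a
    hydrogen that must carry an InChI label does not."""


class InchiGenerationError(UnismilesError):
    """The InChI backend failed to produce an InChI (or to convert one back)."""


class KekulizationError(UnismilesError):
    """Aromatic input admits no valid Kekule assignment."""


class StereoConsistencyError(UnismilesError):
    """Cis/trans direction constraints around double bonds are contradictory."""
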