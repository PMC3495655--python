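"""End-to-end generation modes.

* **Universal SMILES** -- canonical labels are taken from the auxiliary
  information of a non-standard InChI (*FixedH* + *RecMet*) of the original
  structure; the original structure itself is written.
* **Inchified SMILES** -- the structure is round-tripped through the
  Standard InChI; the returned normalised structure is already in canonical
  atom order and is written with identity labels.  InChI normalisations
  (nitro expansion, tautomer collapse, metal disconnection) are inherited.
* **anti-canonical SMILES** -- seeded random labels, for stress-testing
  order invariance.
"""

from __future__ import annotations

from functools import lru_cache

from .auxinfo import (
    extract_labels,
    hydrogen_order_keys,
    identity_labeling,
    parse_auxinfo,
    random_labeling,
)
from .inchi_backend import (
    STANDARD_OPTIONS,
    UNIVERSAL_OPTIONS,
    InchiOptions,
    from_inchi,
    to_inchi,
)
from .molgraph import MolecularGraph, read_smiles
from .writer import write_smiles


def universal_smiles(
    g: MolecularGraph, opts: InchiOptions = UNIVERSAL_OPTIONS
) -> str:
    """Canonical SMILES of ``g`` using InChI canonical labels.

    ``opts`` exists to demonstrate the role of the non-standard options;
    canonical behaviour requires the default (*FixedH* + *RecMet*).
    """
    res = to_inchi(g, opts)
    lab = hydrogen_order_keys(g, extract_labels(parse_auxinfo(res.auxinfo)))
    return write_smiles(g, lab)


@lru_cache(maxsize=16384)
def _normalised_graph(inchi: str) -> MolecularGraph:
    return from_inchi(inchi)


def inchified_smiles(g: MolecularGraph) -> str:
    """Canonical SMILES of the InChI-normalised structure of ``g``."""
    res = to_inchi(g, STANDARD_OPTIONS)
    g2 = _normalised_graph(res.inchi)
    return write_smiles(g2, identity_labeling(g2))


def anticanonical_smiles(g: MolecularGraph, seed: int) -> str:
    """A SMILES of ``g`` written from seeded random canonical labels."""
    return write_smiles(g, random_labeling(g, seed))


MODES = {
    "universal": lambda g: universal_smiles(g),
    "inchified": inchified_smiles,
}


def generate(smiles: str, mode: str, seed: int = 0) -> str:
    """Convenience wrapper: parse ``smiles`` and emit the requested mode."""
    g = read_smiles(smiles)
    if mode == "anticanonical":
        return anticanonical_smiles(g, seed)
    return MODES[mode](g)


__all__ = [
    "universal_smiles",
    "inchified_smiles",
    "anticanonical_smiles",
    "generate",
    "MODES",
]
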