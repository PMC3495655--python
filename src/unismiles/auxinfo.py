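"""Parsing of InChI auxiliary-information strings and canonical-label
extraction.

The auxiliary information emitted alongside an InChI contains, per
connected component, the list of 1-based input atom numbers in canonical
order: the ``/N:`` section for the base structure, ``/F:`` for the
fixed-hydrogen variant, and a nested ``/R:`` record (with its own ``/N``
and ``/F``) for the reconnected-metal variant.  The label source preference
is: reconnected-metal fixed-H, reconnected-metal base, fixed-H, base.

Abbreviations used by the InChI software inside these sections are
expanded during parsing: ``m`` copies the corresponding component of the
preceding ``/N`` section, and a count prefix (``5m`` or ``5*m``) repeats it.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field, replace

from .errors import AuxInfoIntegrityError, ParseError
from .molgraph import MolecularGraph

_COMP_MULT = re.compile(r"^(\d+)\*?m$")


@dataclass(frozen=True)
class AuxInfoRecord:
    """One (possibly nested) auxiliary-information record.

    ``layers`` preserves every section in order for diagnostics and
    serialisation; ``n_layer``/``f_layer`` hold the expanded per-component
    atom-number lists used for ranking.  ``r_record`` is the nested
    reconnected-metal record, if present.
    """

    version: str | None
    norm_type: str
    layers: tuple[tuple[str, str], ...]
    n_layer: tuple[tuple[int, ...], ...] | None
    f_layer: tuple[tuple[int, ...], ...] | None
    r_record: "AuxInfoRecord | None" = None

    def serialize(self) -> str:
        head = f"AuxInfo={self.version}/" if self.version is not None else "/"
        body = head + self.norm_type
        for tag, value in self.layers:
            body += f"/{tag}:{value}"
        if self.r_record is not None:
            body += "/R:" + self.r_record.serialize()
        return body


@dataclass(frozen=True)
class CanonicalLabeling:
    """Per-atom canonical ranks (0-based atom index -> 1-based label).

    Only atoms the InChI labelled carry a rank; explicit hydrogens the InChI
    left unlabelled instead receive branch-ordering keys (``h_keys``) via
    :func:`hydrogen_order_keys`.
    """

    rank: dict[int, int]
    source: str  # "N" | "F" | "R_N" | "R_F" | "identity" | "random"
    h_keys: dict[int, int] = field(default_factory=dict)


def parse_auxinfo(text: str) -> AuxInfoRecord:
    """Parse an AuxInfo string as emitted by the official InChI software."""
    if not text.startswith("AuxInfo="):
        raise ParseError(f"not an AuxInfo string: {text!r}")
    rest = text[len("AuxInfo="):]
    segments = rest.split("/")
    if len(segments) < 2:
        raise ParseError(f"truncated AuxInfo string: {text!r}")
    version = segments[0]
    record = _parse_segments(segments[1:], version)
    return record


def _parse_segments(segments: list[str], version: str | None) -> AuxInfoRecord:
    norm_type = segments[0]
    layers: list[tuple[str, str]] = []
    r_record = None
    i = 1
    while i < len(segments):
        seg = segments[i]
        if ":" not in seg:
            raise ParseError(f"unrecognised AuxInfo segment {seg!r}")
        tag, value = seg.split(":", 1)
        if tag == "R":
            r_record = _parse_segments(segments[i + 1:], None)
            break
        layers.append((tag, value))
        i += 1

    n_layer = f_layer = None
    for tag, value in layers:
        if tag == "N" and n_layer is None:
            n_layer = _expand_components(value, reference=None)
        elif tag == "F" and f_layer is None:
            f_layer = _expand_components(value, reference=n_layer)
    return AuxInfoRecord(
        version=version,
        norm_type=norm_type,
        layers=tuple(layers),
        n_layer=n_layer,
        f_layer=f_layer,
        r_record=r_record,
    )


def _expand_components(
    value: str, reference: tuple[tuple[int, ...], ...] | None
) -> tuple[tuple[int, ...], ...]:
    tokens: list[str] = []
    for token in value.split(";"):
        m = _COMP_MULT.match(token)
        if m:
            tokens.extend(["m"] * int(m.group(1)))
        else:
            tokens.append(token)
    comps: list[tuple[int, ...]] = []
    for pos, token in enumerate(tokens):
        if token == "":
            comps.append(())
        elif token == "m":
            if reference is None or pos >= len(reference):
                raise ParseError(
                    f"component abbreviation 'm' at position {pos} has no "
                    f"reference /N component"
                )
            comps.append(reference[pos])
        else:
            try:
                comps.append(tuple(int(x) for x in token.split(",")))
            except ValueError as exc:
                raise ParseError(f"bad AuxInfo component {token!r}") from exc
    return tuple(comps)


def extract_labels(rec: AuxInfoRecord) -> CanonicalLabeling:
    """Build canonical ranks from ``rec`` following the source preference
    R/F > R/N > F > N.  Component label blocks are offset by the sizes of
    preceding components, making labels globally unique; a component's atoms
    therefore share a contiguous label block and components are ordered by
    their lowest label."""
    candidates = []
    if rec.r_record is not None:
        candidates.append(("R_F", rec.r_record.f_layer))
        candidates.append(("R_N", rec.r_record.n_layer))
    candidates.append(("F", rec.f_layer))
    candidates.append(("N", rec.n_layer))
    for source, layer in candidates:
        if layer is not None:
            break
    else:
        raise AuxInfoIntegrityError("AuxInfo record has no /N or /F section")

    rank: dict[int, int] = {}
    offset = 0
    for comp in layer:
        for i, atom_number in enumerate(comp):
            idx = atom_number - 1
            if idx < 0 or idx in rank:
                raise AuxInfoIntegrityError(
                    f"{source} section is not a permutation: atom "
                    f"{atom_number} repeated or invalid"
                )
            rank[idx] = offset + i + 1
        offset += len(comp)
    return CanonicalLabeling(rank=rank, source=source)


# isotope ordering for unlabelled explicit hydrogens: D, then T, then others
_H_ISO_ORDER = {2: 0, 3: 1}


def hydrogen_order_keys(
    g: MolecularGraph, lab: CanonicalLabeling
) -> CanonicalLabeling:
    """Attach branch-ordering keys for explicit hydrogens the InChI left
    unlabelled: such a hydrogen is visited before other singly-bonded
    branches of its parent, deuterium before tritium before the rest, and is
    never chosen as a traversal start atom."""
    h_keys: dict[int, int] = {}
    for atom in g.atoms:
        if not atom.is_explicit_h or atom.index in lab.rank:
            continue
        heavy_nbrs = [
            n for _, n in g.neighbors(atom.index) if not g.atoms[n].is_explicit_h
        ]
        if len(heavy_nbrs) > 1:
            raise AuxInfoIntegrityError(
                f"bridging hydrogen (atom {atom.index}) lacks an InChI label"
            )
        h_keys[atom.index] = _H_ISO_ORDER.get(atom.isotope, 2)
    missing = [
        a.index
        for a in g.atoms
        if not a.is_explicit_h and a.index not in lab.rank
    ]
    if missing:
        raise AuxInfoIntegrityError(
            f"heavy atoms without canonical labels: {missing}"
        )
    return replace(lab, h_keys=h_keys)


# -- labelings that do not come from an AuxInfo record ---------------------


def _labelled_set(g: MolecularGraph) -> list[int]:
    """Atoms that receive ranks when no AuxInfo is involved: every heavy
    atom, plus all atoms of components consisting wholly of hydrogen."""
    out = []
    for comp in g.components:
        all_h = all(g.atoms[i].is_explicit_h for i in comp)
        for i in comp:
            if all_h or not g.atoms[i].is_explicit_h:
                out.append(i)
    return sorted(out)


def identity_labeling(g: MolecularGraph) -> CanonicalLabeling:
    """Ranks in atom-index order (used after an InChI roundtrip, where the
    graph is already in canonical order)."""
    rank = {idx: i + 1 for i, idx in enumerate(_labelled_set(g))}
    return hydrogen_order_keys(g, CanonicalLabeling(rank=rank, source="identity"))


def random_labeling(g: MolecularGraph, seed: int) -> CanonicalLabeling:
    """Seeded uniformly random ranks (anti-canonical output orderings)."""
    idxs = _labelled_set(g)
    labels = list(range(1, len(idxs) + 1))
    random.Random(seed).shuffle(labels)
    rank = dict(zip(idxs, labels))
    return hydrogen_order_keys(g, CanonicalLabeling(rank=rank, source="random"))


__all__ = [
    "AuxInfoRecord",
    "CanonicalLabeling",
    "parse_auxinfo",
    "extract_labels",
    "hydrogen_order_keys",
    "identity_labeling",
    "random_labeling",
]
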