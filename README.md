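# unismiles

Canonical SMILES strings derived from the InChI canonicalisation.

SMILES is the most widely used line notation for molecules, but there is no
community standard for generating a *canonical* SMILES: every toolkit ships
its own unpublished algorithm, so the "canonical" string for one molecule
differs between programs. The InChI, by contrast, has a single reference
implementation whose canonical atom numbering is available everywhere. This
package uses those canonical labels to write SMILES strings that are
invariant to input atom order — including tetrahedral and double-bond
stereochemistry — and therefore usable as database keys by anyone with an
InChI library. It is aimed at cheminformaticians building registration
systems, deduplicating compound collections, or comparing the chemical
models of different toolkits.

## The two canonical forms

* **Universal SMILES** keeps the original structure (and tautomeric state).
  A non-standard InChI is generated with the *FixedH* (fixed-hydrogen
  layer) and *RecMet* (reconnected metals) options, and the canonical
  labels are parsed from the auxiliary information: the reconnected-metal
  `/R:` record's labels are preferred over the top-level ones, and within
  each, the fixed-hydrogen `/F:` list over the base `/N:` list. *FixedH*
  matters whenever molecular symmetry is broken only by a protonation
  state (e.g. hydrogen oxalate); *RecMet* whenever ligand–metal bonds
  would otherwise be disconnected.
* **Inchified SMILES** is the canonical SMILES of the Standard-InChI
  *normalised* structure: the molecule is converted to its Standard InChI
  and back, inheriting the InChI normalisations (nitro ion pairs expanded
  to `N(=O)=O`, sulfoxides to `S=O`, supported tautomers collapsed, metals
  disconnected). The reconstructed molecule arrives in canonical atom
  order, so identity labels suffice.

Given the labels, the writer performs a depth-first traversal and emits
OpenSMILES standard form. In brief: start each component at its
lowest-labelled atom, except that a negatively charged oxygen start is
replaced by a carbonyl oxygen on the same neighbour (the InChI may swap
such labels); at branch points take multiple bonds first, then unlabelled
explicit hydrogens (deuterium before tritium), then ascending label;
ring-closure digits take the lowest available value and are reused, with
openings before closings on an atom; every explicit substituent of a
configured double bond carries a direction symbol, the earliest symbol of
each isolated or conjugated cis/trans system is `/`, and a direction at a
ring closure appears only at the digit on the double-bond atom; the
hydrogen of a stereocentre is written inside the brackets (`[C@H]`).

The InChI algorithm itself is consumed through RDKit's embedded copy of
the official library — never reimplemented.

## Worked example

```python
>>> from unismiles import read_smiles, universal_smiles, inchified_smiles
>>> universal_smiles(read_smiles("OCC"))
'CCO'
>>> universal_smiles(read_smiles("C(=O)([O-])C(=O)O"))
'C(=O)(C(=O)[O-])O'
>>> universal_smiles(read_smiles("C(=O)(O)C(=O)[O-]"))
'C(=O)(C(=O)[O-])O'
>>> g = read_smiles("c1cc(/C=C/F)cc(c1)[N+](=O)[O-]")
>>> universal_smiles(g)
'c1cc(/C=C/F)cc(c1)[N+](=O)[O-]'
>>> inchified_smiles(g)
'c1cc(/C=C/F)cc(c1)N(=O)=O'
```

The two hydrogen-oxalate inputs differ only in atom order; the fixed-
hydrogen layer makes their labels agree, so both produce the same string.
The last pair shows the normalisation split: Universal keeps the
charge-separated nitro group of the input, Inchified inherits the InChI's
expanded-valence form.

The same operations are available from a shell:

```sh
echo "OCC ethanol" | unismiles gen --mode universal
unismiles shuffle --reps 10 --mode universal     # order-invariance test
unismiles dups --key inchified                   # duplicate detection
```

`unismiles shuffle` writes, for each record, ten "anti-canonical" SMILES
(seeded random output orderings), regenerates the canonical form from each
and reports PASS only if all ten agree. Two structure classes are known
not to canonicalise in Universal mode and ship as tagged fixtures: ring
systems whose symmetry is broken only by the position of a delocalised
charge (`C[n+]1ccn(C)c1` / `Cn1cc[n+](C)c1`), and molecules whose
symmetry is broken only by hydrogen isotopes. See `docs/methods.md`.

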