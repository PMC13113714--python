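"""Worked-example inputs: a synthetic hadrosauroid cladogram and the
hollow-crest character.

The topology returned here is a *synthetic example* assembled from published
descriptions of recent hadrosauroid strict-consensus trees; it is not a
deposited data file.  It places an early-branching crested focal taxon
(``Qianjiangsaurus``) outside Hadrosauridae, ``Nanningosaurus`` as sister to
Hadrosauridae, and a conventional (Hadrosaurinae, (Saurolophinae,
Lambeosaurinae)) arrangement inside.  It exists so that crest-character
mapping and origin counting can be demonstrated and tested without any
external download.
"""
from __future__ import annotations

import dendropy

from .characters import CharacterMatrix
from .parsimony import tree_from_newick

LAMBEOSAURINES = (
    "Parasaurolophus", "Charonosaurus", "Lambeosaurus", "Corythosaurus",
    "Hypacrosaurus", "Olorotitan",
)

SAUROLOPHINES = ("Saurolophus", "Edmontosaurus", "Prosaurolophus", "Gryposaurus")

#: Taxa coded 1 (hollow supracranial crest present): the lambeosaurine clade
#: plus the early-branching focal taxon.
HOLLOW_CRESTED = frozenset(LAMBEOSAURINES) | {"Qianjiangsaurus"}

_SAUROLOPHINAE = "(Gryposaurus,(Prosaurolophus,(Saurolophus,Edmontosaurus)))"
_LAMBEOSAURINAE = (
    "(Parasaurolophus,(Charonosaurus,(Lambeosaurus,(Corythosaurus,"
    "(Hypacrosaurus,Olorotitan)))))"
)
_HADROSAURIDAE = f"(Hadrosaurus,({_SAUROLOPHINAE},{_LAMBEOSAURINAE}))"
_CONSENSUS_NEWICK = (
    "(Iguanodon,(Gobihadros,(Gilmoreosaurus,(Bactrosaurus,"
    "((Claosaurus,Plesiohadros),((Telmatosaurus,Tethyshadros),"
    "((Zhanghenglong,Eotrachodon),(Qianjiangsaurus,(Nanningosaurus,"
    f"{_HADROSAURIDAE})))))))));"
)


def example_consensus_tree() -> dendropy.Tree:
    """Synthetic strict-consensus-style cladogram of Hadrosauroidea."""
    return tree_from_newick(_CONSENSUS_NEWICK)


def hollow_crest_matrix() -> CharacterMatrix:
    """One binary character over the example tree's taxa: hollow
    supracranial crest absent (0) / present (1)."""
    tree = example_consensus_tree()
    taxa = tuple(lf.taxon.label for lf in tree.leaf_node_iter())
    cells = tuple(
        (frozenset({"1"}) if t in HOLLOW_CRESTED else frozenset({"0"}),)
        for t in taxa
    )
    return CharacterMatrix(taxa=taxa, cells=cells)
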