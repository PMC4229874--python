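"""Fitch small-parsimony substitution counts over a species tree.

Used to characterise an alignment's evolutionary depth: the minimum number
of substitutions per column implied by the species tree, and the
alignment-wide mean.  A mean of at least ~3 substitutions per position is
the usual diversity criterion for an alignment to be informative enough
for missense grading.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .gvgd import GAP_CHARS, ProteinAlignment

__all__ = ["ParsimonyResult", "parsimony_substitutions", "fitch_count"]


@dataclass(frozen=True)
class ParsimonyResult:
    per_column: list[int]
    mean: float

    def meets_diversity_criterion(self, threshold: float = 3.0) -> bool:
        return self.mean >= threshold


def fitch_count(tree: dendropy.Tree, leaf_states: dict[str, str | None]) -> int:
    """Minimum substitution count for one character by Fitch's algorithm.

    ``leaf_states`` maps leaf taxon labels to a single residue, or ``None``
    for missing data (gaps); missing leaves carry the universal state set
    and never force a substitution.
    """
    observed = {s for s in leaf_states.values() if s is not None}
    if len(observed) <= 1:
        return 0
    count = 0
    state_sets: dict[int, frozenset[str] | None] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            state = leaf_states[label]
            state_sets[id(node)] = frozenset((state,)) if state is not None else None
        else:
            child_sets = [
                state_sets[id(c)] for c in node.child_nodes() if state_sets[id(c)] is not None
            ]
            if not child_sets:
                state_sets[id(node)] = None
                continue
            merged = child_sets[0]
            for cs in child_sets[1:]:
                inter = merged & cs
                if inter:
                    merged = inter
                else:
                    merged = merged | cs
                    count += 1
            state_sets[id(node)] = merged
    return count


def parsimony_substitutions(
    alignment: ProteinAlignment, tree: dendropy.Tree
) -> ParsimonyResult:
    """Per-column Fitch counts and their mean over the whole alignment.

    Every tree leaf must have a sequence in the alignment; gap characters
    are treated as missing data.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [l for l in leaves if l not in alignment.sequences]
    if missing:
        raise ValueError(f"tree leaves without alignment sequences: {missing}")
    counts = []
    for col in range(alignment.n_columns):
        states: dict[str, str | None] = {}
        for label in leaves:
            ch = alignment.sequences[label][col].upper()
            states[label] = None if ch in GAP_CHARS else ch
        counts.append(fitch_count(tree, states))
    mean = sum(counts) / len(counts) if counts else 0.0
    return ParsimonyResult(per_column=counts, mean=mean)
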