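"""Subset-overlap bookkeeping shared by the clone-tracing and screen calls."""

from __future__ import annotations

import itertools
from typing import Mapping, Set


def venn_counts(sets: Mapping[str, Set]) -> dict:
    """Exact Venn-region counts and multiplicity tallies for named sets.

    ``exact`` maps each non-empty label subset (sorted tuple) to the number
    of items belonging to exactly those sets; ``at_least`` to the number
    belonging to at least those sets (the plain intersection);
    ``multiplicity`` tallies items by how many sets they belong to
    (1 = single, 2 = double, ...).
    """
    labels = sorted(sets)
    membership: dict = {}
    for lab in labels:
        for item in sets[lab]:
            membership.setdefault(item, set()).add(lab)
    exact: dict[tuple, int] = {}
    for combo_size in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, combo_size):
            exact[combo] = 0
    for item, labs in membership.items():
        exact[tuple(sorted(labs))] += 1
    at_least = {
        combo: sum(c for sub, c in exact.items()
                   if set(combo) <= set(sub))
        for combo in exact
    }
    multiplicity = {m: 0 for m in range(1, len(labels) + 1)}
    for labs in membership.values():
        multiplicity[len(labs)] += 1
    return {"exact": exact, "at_least": at_least,
            "multiplicity": multiplicity}
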