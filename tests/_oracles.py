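"""Brute-force oracles, independent of the package implementation.

Closures are computed by naive fixpoint iteration over a hand-written
edge list; similarities are computed directly from those closures with
plain set arithmetic.  Nothing here imports gofa graph machinery.
"""

from itertools import combinations

# canonical fixture parent links, written down independently
CANONICAL_PARENTS = {
    "R": [],
    "A": ["R"],
    "B": ["R"],
    "C": ["A"],
    "D": ["A"],
    "E": ["B"],
}


def closure(term, parents=CANONICAL_PARENTS):
    """Ancestor closure by repeated expansion until a fixed point."""
    out = {term}
    while True:
        grown = set(out)
        for t in out:
            grown.update(parents.get(t, []))
        if grown == out:
            return frozenset(out)
        out = grown


def set_closure(terms, parents=CANONICAL_PARENTS):
    out = set()
    for t in terms:
        out |= closure(t, parents)
    return frozenset(out)


def gs2_pair(s1, s2, parents=CANONICAL_PARENTS):
    a1, a2 = set_closure(s1, parents), set_closure(s2, parents)
    overlap = len(a1 & a2)
    return 0.5 * (overlap / len(a1) + overlap / len(a2))


def gs2_multiset_pairwise(sets, parents=CANONICAL_PARENTS):
    """Per-set mean of pairwise GS2 directional scores, the quadratic
    reference for the linear-time one-pass computation.

    The per-set directional score of set i against set j is
    |Ai n Aj| / |Ai|; the per-set value averages that over the other
    sets, and the overall value averages the per-set values.
    """
    closures = [set_closure(s, parents) for s in sets]
    k = len(closures)
    per_set = []
    for i, a_i in enumerate(closures):
        vals = [
            len(a_i & a_j) / len(a_i)
            for j, a_j in enumerate(closures)
            if j != i
        ]
        per_set.append(sum(vals) / (k - 1))
    return per_set, sum(per_set) / k


def redundancy_bruteforce(terms, parents=CANONICAL_PARENTS):
    """Count terms that appear in the closure of a different set member."""
    terms = set(terms)
    redundant = sum(
        1
        for i in terms
        if any(i in closure(j, parents) for j in terms if j != i)
    )
    return redundant / len(terms)


def hierarchical_overlap(scored, against, parents=CANONICAL_PARENTS):
    """Directional hierarchical score by direct enumeration."""
    total = 0.0
    for s in scored:
        a_s = closure(s, parents)
        total += max(
            len(a_s & closure(t, parents)) / len(a_s) for t in against
        )
    return total / len(scored)


def all_subsets(items, max_size=None):
    items = sorted(items)
    top = len(items) if max_size is None else max_size
    for k in range(1, top + 1):
        yield from combinations(items, k)
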