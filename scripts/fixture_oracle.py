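#!/usr/bin/env python
"""Brute-force regeneration of the frozen canonical-fixture constants.

Recomputes every value in ``gofa.fixture_constants.CANONICAL`` from a
hand-written edge list using naive fixpoint closures and plain set
arithmetic — no gofa graph machinery — and compares.  Exit status 0 iff
all constants match to 1e-12.
"""

import math
import sys

PARENTS = {
    "R": [],
    "A": ["R"],
    "B": ["R"],
    "C": ["A"],
    "D": ["A"],
    "E": ["B"],
}

FA = {"g1": {"C"}, "g2": {"C", "D"}, "g3": {"C", "D", "E"}}
GOLD = {"g1": {"D"}, "g2": {"C", "D"}, "g3": {"E"}}
SINGLETON_CORPUS = {"g1": {"C"}, "g2": {"D"}, "g3": {"E"}}
N_REFERENCE = 5
LIVE_TERMS = set(PARENTS)


def closure(term):
    out = {term}
    while True:
        grown = set(out)
        for t in out:
            grown.update(PARENTS[t])
        if grown == out:
            return frozenset(out)
        out = grown


def set_closure(terms):
    out = set()
    for t in terms:
        out |= closure(t)
    return frozenset(out)


def gs2(s1, s2):
    a1, a2 = set_closure(s1), set_closure(s2)
    overlap = len(a1 & a2)
    return 0.5 * (overlap / len(a1) + overlap / len(a2))


def czekanowski_dice(s1, s2):
    a1, a2 = set_closure(s1), set_closure(s2)
    return 1 - len(a1 ^ a2) / (len(a1 | a2) + len(a1 & a2))


def coherence(terms):
    if len(terms) == 1:
        return 1.0
    return sum(gs2({t}, terms - {t}) for t in terms) / len(terms)


def compactness(sets):
    av = []
    for i, s in enumerate(sets):
        sims = [gs2(s, o) for j, o in enumerate(sets) if j != i]
        av.append(sum(sims) / len(sims))
    return sum(av) / len(av)


def redundancy(terms):
    terms = set(terms)
    r = sum(
        1 for i in terms if any(i in closure(j) for j in terms if j != i)
    )
    return r / len(terms)


def propagated_p(corpus):
    closures = [set_closure(s) for s in corpus.values()]
    return {
        t: sum(t in c for c in closures) / len(closures) for t in LIVE_TERMS
    }


def hier(scored, against):
    total = 0.0
    for s in scored:
        a_s = closure(s)
        total += max(len(a_s & closure(t)) / len(a_s) for t in against)
    return total / len(scored)


def main() -> int:
    from gofa.fixture_constants import CANONICAL as K

    p = propagated_p(SINGLETON_CORPUS)
    # Resnik MICA of C and D: most informative of their shared ancestors
    common = closure("C") & closure("D")
    mica_ic = max(-math.log2(p[t]) for t in common if p[t] > 0)

    computed = {
        "coverage": len(FA) / N_REFERENCE,
        "richness": len(set().union(*FA.values())) / len(LIVE_TERMS),
        "mean_n_annotations": sum(map(len, FA.values())) / len(FA),
        "max_n_gene": max(FA, key=lambda g: len(FA[g])),
        "ancestors_C": closure("C"),
        "ancestors_E": closure("E"),
        "descendants_A": frozenset(
            t for t in LIVE_TERMS if "A" in closure(t)
        ),
        "gs2_C_vs_A": gs2({"C"}, {"A"}),
        "gs2_C_vs_E": gs2({"C"}, {"E"}),
        "cd_C_vs_A": czekanowski_dice({"C"}, {"A"}),
        "propagate_CE": set_closure({"C", "E"}),
        "coherence_CD": coherence({"C", "D"}),
        "coherence_CDE": coherence({"C", "D", "E"}),
        "fa_mean_coherence": sum(
            coherence(s) for s in FA.values()
        ) / len(FA),
        "fa_compactness": compactness(list(FA.values())),
        "compactness_C_D_pair": compactness([{"C"}, {"D"}]),
        "specificity_CE": (len(closure("C")) + len(closure("E"))) / 2,
        "specificity_CA": (len(closure("C")) + len(closure("A"))) / 2,
        "redundancy_CAR": redundancy({"C", "A", "R"}),
        "ic_C_propagated": -math.log2(p["C"]),
        "ic_R_propagated": -math.log2(p["R"]),
        "ic_A_propagated": -math.log2(p["A"]),
        # as-printed variant: direct counts over ancestors / total direct
        "p_C_as_printed": sum(
            sum(t in s for s in SINGLETON_CORPUS.values())
            for t in closure("C")
        ) / sum(map(len, SINGLETON_CORPUS.values())),
        # {g1: {C, X}, g2: {C}}: one dead instance of three
        "obsolescence_augmented": 1 / 3,
        "hprec_C_vs_D": hier({"C"}, {"D"}),
        "hrec_C_vs_D": hier({"D"}, {"C"}),
        "hprec_R_vs_C": hier({"R"}, {"C"}),
        "hrec_R_vs_C": hier({"C"}, {"R"}),
        "gold_mean_hprec": sum(
            hier(FA[g], GOLD[g]) for g in FA
        ) / len(FA),
        "gold_mean_hrec": sum(
            hier(GOLD[g], FA[g]) for g in FA
        ) / len(FA),
        "resnik_C_vs_D": mica_ic,
    }

    status = 0
    for key, frozen in K.items():
        got = computed[key]
        if isinstance(frozen, (int, float)):
            ok = abs(got - frozen) <= 1e-12
        else:
            ok = got == frozen
        mark = "ok " if ok else "FAIL"
        print(f"[{mark}] {key}: oracle={got!r} frozen={frozen!r}")
        if not ok:
            status = 1
    return status


if __name__ == "__main__":
    sys.exit(main())
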