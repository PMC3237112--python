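"""Frozen hand-checked values on the canonical fixture.

Every number here was derived by hand from the canonical 6-live-term DAG
(R; A,B under R; C,D under A; E under B) and is independently recomputed
by the brute-force oracle in ``scripts/fixture_oracle.py``.  Tests
compare implementation output against these constants; the oracle script
guards the constants themselves.
"""

import math

CANONICAL = {
    # quantity
    "coverage": 3 / 5,
    "richness": 3 / 6,
    "mean_n_annotations": 2.0,
    "max_n_gene": "g3",
    # closures
    "ancestors_C": frozenset({"C", "A", "R"}),
    "ancestors_E": frozenset({"E", "B", "R"}),
    "descendants_A": frozenset({"A", "C", "D"}),
    # similarity
    "gs2_C_vs_A": 5 / 6,
    "gs2_C_vs_E": 1 / 3,
    "cd_C_vs_A": 4 / 5,
    "propagate_CE": frozenset({"C", "A", "R", "E", "B"}),
    # diversity
    "coherence_CD": 2 / 3,
    "coherence_CDE": 163 / 360,
    "fa_mean_coherence": 763 / 1080,
    "fa_compactness": 59 / 72,
    "compactness_C_D_pair": 2 / 3,
    # informativeness
    "specificity_CE": 3.0,
    "specificity_CA": 2.5,
    "redundancy_CAR": 2 / 3,
    "ic_C_propagated": math.log2(3),
    "ic_R_propagated": 0.0,
    "ic_A_propagated": math.log2(3 / 2),
    "p_C_as_printed": 1 / 3,
    "obsolescence_augmented": 1 / 3,
    # gold-standard comparison
    "hprec_C_vs_D": 2 / 3,
    "hrec_C_vs_D": 2 / 3,
    "hprec_R_vs_C": 1.0,
    "hrec_R_vs_C": 1 / 3,
    "gold_mean_hprec": 20 / 27,
    "gold_mean_hrec": 8 / 9,
    # resnik on the singleton corpus
    "resnik_C_vs_D": math.log2(3 / 2),
}
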