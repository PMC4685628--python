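"""Independent brute-force oracles used to validate the package's fast paths.

These deliberately share no code with episcreen: the HWE oracle enumerates
exact rational probabilities with ``fractions.Fraction``; the MDR oracle is a
plain-dict reimplementation of risk-grid cross-validation; the set-cover
oracle enumerates subsets exhaustively.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb
from typing import Optional


def hwe_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional HWE p-value by full enumeration with Fractions.

    P(h | n, nA) = [n! / (nAA! h! naa!)] 2^h * nA! na! / (2n)! summed over
    all heterozygote counts h of the right parity; the p-value adds up the
    probabilities of tables no more probable than the observed one.
    """
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    n_rare = min(nA, na)

    def prob(h: int) -> Fraction:
        hom_r = (n_rare - h) // 2
        hom_c = (max(nA, na) - h) // 2
        # multinomial(n; hom_r, h, hom_c) * 2^h / multinomial(2n; nA, na)
        num = Fraction(comb(n, h) * comb(n - h, hom_r) * 2**h)
        den = Fraction(comb(2 * n, n_rare))
        return num / den

    hs = list(range(n_rare % 2, n_rare + 1, 2))
    probs = {h: prob(h) for h in hs}
    assert sum(probs.values()) == 1
    obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= obs))


def naive_mdr_cvv(
    g1: list[int],
    g2: list[int],
    status: list[int],
    fold_ids: list[int],
    n_folds: int,
    policy: str = "low_risk",
    T: Optional[float] = None,
) -> float:
    """Dict-based MDR cross-validation, written independently of the package.

    Genotypes < 0 are missing.  Returns the mean held-out balanced accuracy.
    """
    n = len(status)
    bas = []
    for f in range(n_folds):
        train = [i for i in range(n) if fold_ids[i] != f]
        test = [i for i in range(n) if fold_ids[i] == f]
        counts: dict[tuple[int, int], list[int]] = {}
        for i in train:
            if g1[i] < 0 or g2[i] < 0:
                continue
            c = counts.setdefault((g1[i], g2[i]), [0, 0])
            c[0 if status[i] == 1 else 1] += 1
        tr_ca = sum(v[0] for v in counts.values())
        tr_co = sum(v[1] for v in counts.values())

        def label(cell: tuple[int, int]) -> str:
            if cell not in counts:
                return "empty"
            ca, co = counts[cell]
            if co == 0:
                return "high"
            if T is None:
                return "high" if ca * tr_co >= co * tr_ca else "low"
            return "high" if ca >= T * co else "low"

        tp = tn = 0
        n_ca = sum(1 for i in test if status[i] == 1)
        n_co = len(test) - n_ca
        for i in test:
            if g1[i] < 0 or g2[i] < 0:
                lab = "empty"
            else:
                lab = label((g1[i], g2[i]))
            if lab == "empty" and policy == "unknown_misclassified":
                continue  # counts as an error for its class
            pred_case = lab == "high"
            if status[i] == 1 and pred_case:
                tp += 1
            if status[i] == 0 and not pred_case:
                tn += 1
        if n_ca > 0 and n_co > 0:
            ba = (tp / n_ca + tn / n_co) / 2.0
        elif n_ca > 0:
            ba = tp / n_ca
        elif n_co > 0:
            ba = tn / n_co
        else:
            ba = 0.5
        bas.append(ba)
    return sum(bas) / n_folds


def brute_force_min_cover(cover_sets: list[set[int]]) -> int:
    """Size of the smallest collection of sets covering all elements.

    ``cover_sets[u]`` is the set of elements variant u covers (including u).
    Exhaustive over subsets; only feasible for ~15 elements.
    """
    m = len(cover_sets)
    universe = set(range(m))
    for k in range(1, m + 1):
        for combo in itertools.combinations(range(m), k):
            if set().union(*(cover_sets[u] for u in combo)) >= universe:
                return k
    raise AssertionError("no cover exists")
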