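"""Shared independent oracles and scoring helpers for the test suite."""

import itertools

import numpy as np

from promland.codec import mutation_indicator_index
from promland.model import LandscapeModel


def brute_force_coefficient_count(L: int, order: int) -> int:
    """Explicit feature enumeration, independent of the closed-form count."""
    feats = {()}  # intercept
    singles = [(i, m) for i in range(L) for m in range(3)]
    feats.update((s,) for s in singles)
    if order >= 2:
        feats.update(
            (a, b)
            for a, b in itertools.combinations(singles, 2)
            if a[0] != b[0]
        )
    if order >= 3:
        feats.update(
            (a, b, c)
            for a, b, c in itertools.combinations(singles, 3)
            if len({a[0], b[0], c[0]}) == 3
        )
    return len(feats)


def all_sequences(L: int) -> list[str]:
    return ["".join(p) for p in itertools.product("ACGT", repeat=L)]


def brute_force_local_maxima(model: LandscapeModel, wildtype: str) -> dict[str, float]:
    """Oracle: full 4^L table with explicit neighbor comparisons."""
    L = len(wildtype)
    seqs = all_sequences(L)
    vals = {s: model.predict([s], wildtype)[0] for s in seqs}
    maxima = {}
    for s in seqs:
        neighbors = [
            s[:i] + b + s[i + 1 :] for i in range(L) for b in "ACGT" if b != s[i]
        ]
        if all(vals[n] <= vals[s] for n in neighbors):
            maxima[s] = vals[s]
    return maxima


def reciprocal_sign_pair_model(wt: str = "AA"):
    """Two sites, every mutation harmful, but one double mutant is best.

    The landscape has exactly two maxima: the wild type and the
    reciprocal-sign double mutant (unreachable uphill from the wild type).
    """
    beta = -np.ones(6)
    a = 3 * 0 + mutation_indicator_index("A", "C")
    b = 3 * 1 + mutation_indicator_index("A", "G")
    return LandscapeModel(5.0, beta, {(a, b): 3.5}), wt


def j_recovery_scores(true_J: dict, fitted_J: dict):
    """Correlation over the union support + sign agreement on recovered truth."""
    keys = sorted(set(true_J) | set(fitted_J))
    tv = np.array([true_J.get(k, 0.0) for k in keys])
    fv = np.array([fitted_J.get(k, 0.0) for k in keys])
    corr = float(np.corrcoef(tv, fv)[0, 1]) if len(keys) > 1 else float("nan")
    signs = [
        np.sign(fitted_J[k]) == np.sign(v)
        for k, v in true_J.items()
        if fitted_J.get(k, 0.0) != 0.0
    ]
    sign_agreement = float(np.mean(signs)) if signs else float("nan")
    return corr, sign_agreement
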