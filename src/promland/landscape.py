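"""Exploration of an inferred genotype-phenotype landscape.

Tools to probe the global shape of a fitted model: the phenotype
distribution of uniformly random sequences (how functional is neutral
sequence space, and how exceptional is the wild type), uphill adaptive
walks in the weak-mutation regime (a large population fixes one beneficial
single substitution at a time and cannot escape local maxima), exhaustive
local-maximum enumeration on small site subsets, and a two-environment
Pareto analysis of whether any sequence beats the wild type in both
environments at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codec import hamming_to_wildtype, ints_to_seq, seq_to_ints
from .model import LandscapeModel, random_sequences


def random_phenotype_sample(
    model: LandscapeModel,
    wildtype: str,
    n: int = 10_000,
    seed: int = 0,
    n_hist_bins: int = 50,
) -> dict:
    """Predictions for i.i.d. uniform random sequences, with a histogram summary.

    The histogram mode marks the phenotype of typical non-functional
    sequence space (what neutral evolution would drift to); the wild-type
    prediction and its percentile among random sequences quantify how
    strongly selected the wild type is.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    preds = model.predict(random_sequences(n, len(wildtype), rng), wildtype)
    wt_value = float(model.predict([wildtype], wildtype)[0])
    counts, edges = np.histogram(preds, bins=n_hist_bins)
    k = int(np.argmax(counts))
    return {
        "predictions": preds,
        "histogram": (counts, edges),
        "mode_region": (float(edges[k]), float(edges[k + 1])),
        "wildtype_value": wt_value,
        "wildtype_percentile": float(np.mean(preds < wt_value) * 100.0),
    }


@dataclass
class WalkResult:
    endpoint: str
    steps: int
    hamming_to_wildtype: int
    value: float
    converged: bool


def _single_substitution_gains(
    model: LandscapeModel, codes: np.ndarray, wt_codes: np.ndarray, M: np.ndarray
) -> np.ndarray:
    """Gain of every (site, target base) move from the current sequence.

    Returns an (L, 4) array; the entry for the current base is -inf.
    Uses the identity that the contribution of switching one site only
    involves its own additive term plus pair terms with the *other*
    currently mutated sites (same-site pair entries are structurally 0).
    """
    L = len(codes)
    offset = (codes - wt_codes) % 4
    mutated = np.nonzero(offset)[0]
    z = np.zeros(3 * L)
    active = 3 * mutated + offset[mutated] - 1
    z[active] = 1.0
    contrib = model.beta + M @ z          # value of turning each indicator on

    cur_contrib = np.zeros(L)
    cur_contrib[mutated] = contrib[active]

    gains = np.full((L, 4), -np.inf)
    for b in range(4):
        off_b = (b - wt_codes) % 4
        new_contrib = np.where(off_b == 0, 0.0, contrib[np.arange(L) * 3 + off_b - 1])
        gains[:, b] = new_contrib - cur_contrib
    gains[np.arange(L), codes] = -np.inf
    return gains


def adaptive_walk(
    model: LandscapeModel,
    wildtype: str,
    start: str | None = None,
    seed: int = 0,
    max_steps: int = 1000,
    rule: str = "increment",
) -> WalkResult:
    """Uphill-only adaptive walk over single substitutions.

    At each step all 3L single-substitution neighbors are enumerated, the
    strictly improving ones kept, and one is fixed with probability
    proportional to its phenotype increment (``rule="increment"``; the
    transformed bins are a log-fluorescence scale, so the increment is
    already a log-scale fitness difference) or to log(1 + increment)
    (``rule="log1p"``).  The walk stops at a local maximum; running out of
    ``max_steps`` is flagged as non-converged.
    """
    if rule not in ("increment", "log1p"):
        raise ValueError(f"unknown rule {rule!r}")
    if model.T:
        raise NotImplementedError("adaptive walks support pairwise models only")
    start = start if start is not None else wildtype
    rng = np.random.default_rng(seed)
    wt_codes = seq_to_ints(wildtype)
    codes = seq_to_ints(start).copy()
    M = model.pair_matrix()
    value = float(model.predict([ints_to_seq(codes)], wildtype)[0])

    steps = 0
    converged = False
    while steps < max_steps:
        gains = _single_substitution_gains(model, codes, wt_codes, M)
        improving = np.argwhere(gains > 0.0)
        if len(improving) == 0:
            converged = True
            break
        w = gains[improving[:, 0], improving[:, 1]]
        if rule == "log1p":
            w = np.log1p(w)
        pick = improving[rng.choice(len(improving), p=w / w.sum())]
        value += float(gains[pick[0], pick[1]])
        codes[pick[0]] = pick[1]
        steps += 1
    else:
        converged = False

    endpoint = ints_to_seq(codes)
    return WalkResult(
        endpoint=endpoint,
        steps=steps,
        hamming_to_wildtype=hamming_to_wildtype(endpoint, wildtype),
        value=float(model.predict([endpoint], wildtype)[0]),
        converged=converged,
    )


def walk_census(
    model: LandscapeModel,
    wildtype: str,
    n_walks: int = 1000,
    start: str | None = None,
    seed: int = 0,
    max_steps: int = 1000,
    rule: str = "increment",
) -> pd.DataFrame:
    """Distinct adaptive-walk endpoints with visit counts and distances.

    ``start`` may be a sequence, None (start at the wild type) or
    ``"random"`` (a fresh uniform random start per walk, which explores
    basins unreachable uphill from the wild type).
    """
    if n_walks < 1:
        raise ValueError("n_walks must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(n_walks) % (2**31)
    start_rng = np.random.default_rng(seed)
    hits: dict[str, dict] = {}
    for s in seeds:
        s0 = (
            random_sequences(1, len(wildtype), start_rng)[0]
            if start == "random"
            else start
        )
        res = adaptive_walk(
            model, wildtype, start=s0, seed=int(s), max_steps=max_steps, rule=rule
        )
        h = hits.setdefault(
            res.endpoint,
            {
                "count": 0,
                "hamming_to_wildtype": res.hamming_to_wildtype,
                "value": res.value,
                "converged": res.converged,
            },
        )
        h["count"] += 1
    df = pd.DataFrame.from_dict(hits, orient="index").sort_values(
        "count", ascending=False
    )
    df.index.name = "endpoint"
    return df.reset_index()


def enumerate_local_maxima(
    model: LandscapeModel,
    wildtype: str,
    site_subset: list[int],
    background: str | None = None,
) -> pd.DataFrame:
    """Exact local maxima of the landscape restricted to a small site subset.

    Enumerates all 4^m assignments of the subset sites (the rest of the
    sequence fixed at ``background``, the wild type by default) and keeps
    those with no strictly improving single substitution inside the subset.
    """
    sub = sorted(site_subset)
    m = len(sub)
    if m > 10:
        raise ValueError("site subset too large for exhaustive 4^m enumeration")
    if model.T:
        raise NotImplementedError("enumeration supports pairwise models only")
    background = background if background is not None else wildtype
    L = len(wildtype)
    wt_codes = seq_to_ints(wildtype)
    bg_codes = seq_to_ints(background)
    M = model.pair_matrix()

    # fixed contribution of background mutations outside the subset
    outside = np.setdiff1d(np.arange(L), sub)
    off_bg = (bg_codes - wt_codes) % 4
    bg_mut = outside[off_bg[outside] > 0]
    bg_ind = 3 * bg_mut + off_bg[bg_mut] - 1
    z_bg = np.zeros(3 * L)
    z_bg[bg_ind] = 1.0
    alpha_eff = model.alpha + model.beta[bg_ind].sum()
    if len(bg_ind) >= 2:
        alpha_eff += M[np.ix_(bg_ind, bg_ind)].sum() / 2.0

    # per subset-site, per base: additive + cross-with-background contribution
    A = np.zeros((m, 4))
    cross = model.beta + M @ z_bg
    for t, s in enumerate(sub):
        for b in range(4):
            off = (b - wt_codes[s]) % 4
            if off:
                A[t, b] = cross[3 * s + off - 1]

    n_comb = 4**m
    idx = np.arange(n_comb)
    codes = (idx[:, None] // (4 ** np.arange(m - 1, -1, -1))[None, :]) % 4

    pred = np.full(n_comb, alpha_eff)
    for t in range(m):
        pred += A[t, codes[:, t]]
    for t in range(m):
        st = sub[t]
        for u in range(t + 1, m):
            su = sub[u]
            P = np.zeros((4, 4))
            for bt in range(4):
                ot = (bt - wt_codes[st]) % 4
                if not ot:
                    continue
                for bu in range(4):
                    ou = (bu - wt_codes[su]) % 4
                    if ou:
                        P[bt, bu] = M[3 * st + ot - 1, 3 * su + ou - 1]
            pred += P[codes[:, t], codes[:, u]]

    is_max = np.ones(n_comb, dtype=bool)
    radix = 4 ** np.arange(m - 1, -1, -1)
    for t in range(m):
        cur = codes[:, t]
        for b in range(4):
            nb = idx + (b - cur) * radix[t]
            better = pred[nb] > pred
            better[b == cur] = False
            is_max &= ~better

    rows = []
    full = bg_codes.copy()
    for i in np.nonzero(is_max)[0]:
        full_i = full.copy()
        full_i[sub] = codes[i]
        seq = ints_to_seq(full_i)
        rows.append({"sequence": seq, "value": float(pred[i])})
    return pd.DataFrame(rows).sort_values("value", ascending=False).reset_index(drop=True)


@dataclass
class ParetoReport:
    table: pd.DataFrame               # sequence, pred_A, pred_B, dominates_wildtype
    wildtype_pred: tuple[float, float]
    fraction_dominating: float
    random_fraction_dominating: float | None = None


def pareto_analysis(
    model_A: LandscapeModel,
    model_B: LandscapeModel,
    sequences: list[str],
    wildtype: str,
    n_random: int = 1000,
    seed: int = 0,
) -> ParetoReport:
    """Two-environment dominance analysis against the wild type.

    A sequence dominates the wild type when its prediction is strictly
    higher under model A (expression wanted high, e.g. lactose/cAMP) AND
    strictly lower under model B (expression wanted low, e.g. glucose).
    The dominating fraction is reported for the given sequences and for an
    i.i.d. uniform random sample; a near-zero fraction places the wild
    type close to the multi-objective Pareto front.
    """
    wt_a = float(model_A.predict([wildtype], wildtype)[0])
    wt_b = float(model_B.predict([wildtype], wildtype)[0])
    pa = model_A.predict(sequences, wildtype)
    pb = model_B.predict(sequences, wildtype)
    dom = (pa > wt_a) & (pb < wt_b)
    table = pd.DataFrame(
        {
            "sequence": list(sequences),
            "pred_A": pa,
            "pred_B": pb,
            "dominates_wildtype": dom,
        }
    )
    rand_frac = None
    if n_random:
        rng = np.random.default_rng(seed)
        rs = random_sequences(n_random, len(wildtype), rng)
        ra = model_A.predict(rs, wildtype)
        rb = model_B.predict(rs, wildtype)
        rand_frac = float(((ra > wt_a) & (rb < wt_b)).mean())
    return ParetoReport(
        table=table,
        wildtype_pred=(wt_a, wt_b),
        fraction_dominating=float(dom.mean()),
        random_fraction_dominating=rand_frac,
    )
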