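"""Classification of inferred interactions and binding-site block summaries.

Each nonzero pairwise coefficient J with marginal effects (beta_i, beta_j)
falls into exactly one of three exclusive classes:

* synergistic  — beta_i, beta_j and J all share one sign (the double
  mutant is more extreme than the sum of the singles);
* antagonistic — beta_i and beta_j share a sign, J opposes it
  (diminishing returns);
* sign         — beta_i and beta_j have opposite signs and J is nonzero.

Pairs with J != 0 but a zero marginal fall outside these definitions and
are flagged separately rather than forced into a class.  "Nonzero" means
structurally present in the sparse model (L1 selection produces exact
zeros); a magnitude threshold tau is available for dense fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codec import RegionMap
from .model import LandscapeModel

CLASSES = ("synergistic", "antagonistic", "sign")


def classify_interaction(beta_i: float, beta_j: float, J: float, tau: float = 0.0) -> str:
    """One of 'synergistic' / 'antagonistic' / 'sign' / 'none' / 'unclassified'."""
    if abs(J) <= tau:
        return "none"
    if abs(beta_i) <= tau or abs(beta_j) <= tau:
        return "unclassified"
    same_marginals = (beta_i > 0) == (beta_j > 0)
    if not same_marginals:
        return "sign"
    return "synergistic" if (J > 0) == (beta_i > 0) else "antagonistic"


def _iter_classified(model: LandscapeModel, tau: float = 0.0):
    for (a, b), J in model.J.items():
        yield a, b, J, classify_interaction(model.beta[a], model.beta[b], J, tau)


def census(model: LandscapeModel, tau: float = 0.0) -> dict:
    """Class counts and total |J| over all structurally nonzero interactions."""
    counts = {c: 0 for c in CLASSES}
    counts["unclassified"] = 0
    total_absJ = 0.0
    nonzero = 0
    for _, _, J, cls in _iter_classified(model, tau):
        if cls == "none":
            continue
        nonzero += 1
        total_absJ += abs(J)
        counts[cls] += 1
    return {"nonzero": nonzero, "sum_abs_J": total_absJ, **counts}


def classify_zero_beta_cases(model: LandscapeModel, tau: float = 0.0) -> list[tuple]:
    """Interactions with J != 0 but a zero marginal effect (outside the 3 classes)."""
    return [
        (a, b, J)
        for a, b, J, cls in _iter_classified(model, tau)
        if cls == "unclassified"
    ]


@dataclass
class BlockSummary:
    """Per block-pair interaction totals; always reports the map it used."""

    region_map: RegionMap
    cells: pd.DataFrame  # index (block_a, block_b); columns sum_abs_J, nonzero, classes


def block_summary(
    model: LandscapeModel, region_map: RegionMap, tau: float = 0.0
) -> BlockSummary:
    """Assign every interaction to a within- or between-block cell.

    Cells are unordered block pairs (within-block when both sites fall in
    one block); interactions touching a site outside every block aggregate
    into 'other'.  Overlapping blocks are rejected because they would make
    the assignment ambiguous.
    """
    seen: dict[int, str] = {}
    for name in region_map.blocks:
        for s in region_map.sites(name):
            if s in seen:
                raise ValueError(f"blocks {seen[s]} and {name} overlap at site {s}")
            seen[s] = name

    rows: dict[tuple[str, str], dict] = {}
    for a, b, J, cls in _iter_classified(model, tau):
        if cls == "none":
            continue
        ba = region_map.block_of(a // 3)
        bb = region_map.block_of(b // 3)
        key = ("other", "other") if ba is None or bb is None else tuple(sorted((ba, bb)))
        cell = rows.setdefault(
            key,
            {"sum_abs_J": 0.0, "nonzero": 0, **{c: 0 for c in CLASSES}, "unclassified": 0},
        )
        cell["sum_abs_J"] += abs(J)
        cell["nonzero"] += 1
        if cls != "none":
            cell[cls if cls in CLASSES else "unclassified"] += 1

    cells = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    cells.index.names = ["block_a", "block_b"]
    return BlockSummary(region_map, cells)


def grouped_block_table(
    model: LandscapeModel,
    region_map: RegionMap,
    families: dict[str, list[str]] | None = None,
    tau: float = 0.0,
) -> pd.DataFrame:
    """Census table in the conventional layout: all, each block, each
    within-family pair, and the cross-family cell (e.g. CRP x RNAP)."""
    families = families or {
        "CRP": [b for b in region_map.blocks if b.startswith("CRP")],
        "RNAP": [b for b in region_map.blocks if b.startswith("RNAP")],
    }
    fam_of = {b: f for f, bs in families.items() for b in bs}

    def new_row():
        return {"sum_abs_J": 0.0, "nonzero": 0, **{c: 0 for c in CLASSES}}

    rows: dict[str, dict] = {"all": new_row()}
    for name in region_map.blocks:
        rows[name] = new_row()
    for f, bs in families.items():
        if len(bs) == 2:
            rows[f"{bs[0]}x{bs[1]}"] = new_row()
    if len(families) == 2:
        f1, f2 = families
        rows[f"{f1}x{f2}"] = new_row()

    for a, b, J, cls in _iter_classified(model, tau):
        if cls == "none":
            continue
        targets = ["all"]
        ba = region_map.block_of(a // 3)
        bb = region_map.block_of(b // 3)
        if ba is not None and bb is not None:
            if ba == bb:
                targets.append(ba)
            elif fam_of.get(ba) == fam_of.get(bb):
                pair = sorted((ba, bb))
                targets.append(f"{pair[0]}x{pair[1]}")
            else:
                fams = sorted({fam_of.get(ba, "?"), fam_of.get(bb, "?")})
                name = f"{fams[0]}x{fams[1]}"
                if name in rows:
                    targets.append(name)
        for t in targets:
            rows[t]["sum_abs_J"] += abs(J)
            rows[t]["nonzero"] += 1
            if cls in CLASSES:
                rows[t][cls] += 1
    return pd.DataFrame.from_dict(rows, orient="index")


def sitewise_magnitude_profiles(model: LandscapeModel) -> dict:
    """Per-site additive and epistatic magnitude profiles and their correlation.

    additive[i] = sum of |beta| over the site's 3 mutations, / 3;
    epistatic[i] = sum of |J| over every pair touching the site, / 9.
    The Pearson correlation of the two profiles measures how tightly
    epistasis tracks the additively important (binding-site) positions.
    """
    L = model.length
    additive = np.abs(model.beta).reshape(L, 3).sum(axis=1) / 3.0
    epistatic = np.zeros(L)
    for (a, b), J in model.J.items():
        epistatic[a // 3] += abs(J) / 9.0
        epistatic[b // 3] += abs(J) / 9.0
    if epistatic.std() == 0.0 or additive.std() == 0.0:
        corr = None
    else:
        corr = float(np.corrcoef(additive, epistatic)[0, 1])
    return {"additive": additive, "epistatic": epistatic, "correlation": corr}


def pair_site_matrix(model: LandscapeModel) -> np.ndarray:
    """L x L symmetric matrix of sum |J| per site pair (the interaction heat map)."""
    L = model.length
    M = np.zeros((L, L))
    for (a, b), J in model.J.items():
        i, j = a // 3, b // 3
        M[i, j] += abs(J)
        M[j, i] += abs(J)
    return M
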