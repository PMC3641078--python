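"""Sparse genotype-phenotype landscape models.

A :class:`LandscapeModel` is the quadratic/cubic map

    g = alpha + sum_i beta_i x_i + sum_{i<j} J_ij x_i x_j (+ triples)

over the 3L mutation indicators x of a sequence relative to the wild type.
``beta`` is dense (length 3L); the interaction terms are sparse dicts keyed
by flat indicator indices (3 * site + mutation), reflecting the exact
sparsity that L1 selection produces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .codec import BASES, FeatureIndex, _mutation_lists

PairKey = tuple[int, int]          # flat indicator indices a < b, distinct sites
TripleKey = tuple[int, int, int]


@dataclass
class LandscapeModel:
    """Intercept + additive + sparse pairwise (and optional 3rd-order) coefficients."""

    alpha: float
    beta: np.ndarray                       # length 3L
    J: dict[PairKey, float] = field(default_factory=dict)
    T: dict[TripleKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        for a, b in self.J:
            if a // 3 == b // 3:
                raise ValueError(f"pair key ({a}, {b}) has both indicators on one site")
            if not a < b:
                raise ValueError(f"pair key ({a}, {b}) not sorted")
        for a, b, c in self.T:
            if len({a // 3, b // 3, c // 3}) != 3 or not (a < b < c):
                raise ValueError(f"invalid triple key ({a}, {b}, {c})")

    @property
    def length(self) -> int:
        return len(self.beta) // 3

    # -- evaluation ---------------------------------------------------------

    def pair_matrix(self) -> np.ndarray:
        """Dense symmetric 3L x 3L matrix with both (a,b) and (b,a) set to J_ab."""
        p = len(self.beta)
        M = np.zeros((p, p))
        for (a, b), v in self.J.items():
            M[a, b] = M[b, a] = v
        return M

    def predict_encoded(self, mut_lists: Iterable[np.ndarray]) -> np.ndarray:
        """Predictions for sequences given their flat mutation-indicator lists."""
        mut_lists = list(mut_lists)
        n = len(mut_lists)
        if n > 200 and not self.T:
            # vectorized path: indicator matrix Z, pair term = z'Mz / 2
            from scipy import sparse as sp

            indptr = np.zeros(n + 1, dtype=np.int64)
            indptr[1:] = np.cumsum([len(m) for m in mut_lists])
            indices = (
                np.concatenate(mut_lists) if indptr[-1] else np.empty(0, dtype=np.int64)
            )
            Z = sp.csr_matrix(
                (np.ones(len(indices)), indices.astype(np.int64), indptr),
                shape=(n, len(self.beta)),
            )
            out = self.alpha + Z @ self.beta
            if self.J:
                M = self.pair_matrix()
                out = out + np.asarray(Z.multiply(Z @ M).sum(axis=1)).ravel() / 2.0
            return np.asarray(out).ravel()
        M = self.pair_matrix() if self.J else None
        out = np.empty(n)
        for r, m in enumerate(mut_lists):
            v = self.alpha + self.beta[m].sum()
            if M is not None and len(m) >= 2:
                v += M[np.ix_(m, m)].sum() / 2.0
            if self.T and len(m) >= 3:
                ms = sorted(int(x) for x in m)
                for trip in combinations(ms, 3):
                    v += self.T.get(trip, 0.0)
            out[r] = v
        return out

    def predict(self, sequences: Sequence[str], wildtype: str) -> np.ndarray:
        """Evaluate the model on base-string sequences (wild type -> alpha)."""
        return self.predict_encoded(_mutation_lists(sequences, wildtype))

    # -- construction / serialization ---------------------------------------

    @classmethod
    def from_coefficients(
        cls,
        alpha: float,
        coef: np.ndarray,
        index: FeatureIndex,
        tol: float = 0.0,
    ) -> "LandscapeModel":
        """Build from a flat coefficient vector aligned with a FeatureIndex."""
        L = index.length
        beta = np.array(coef[: 3 * L], dtype=float)
        J: dict[PairKey, float] = {}
        T: dict[TripleKey, float] = {}
        for col, lab in enumerate(index.labels[3 * L :], start=3 * L):
            v = float(coef[col])
            if abs(v) <= tol:
                continue
            if lab[0] == "J":
                _, i, mi, j, mj = lab
                J[(3 * i + mi, 3 * j + mj)] = v
            else:
                _, i, mi, j, mj, k, mk = lab
                T[(3 * i + mi, 3 * j + mj, 3 * k + mk)] = v
        return cls(alpha, beta, J, T)

    def to_json_dict(self, wildtype: str | None = None) -> dict:
        L = self.length

        def site_label(a: int) -> dict:
            site, m = divmod(int(a), 3)
            d = {"site": site, "position": site - L, "mutation_index": m}
            if wildtype is not None:
                from .codec import mutant_base

                d["wt_base"] = wildtype[site]
                d["mut_base"] = mutant_base(wildtype[site], m)
            return d

        return {
            "alpha": self.alpha,
            "length": L,
            "beta": [
                {**site_label(a), "value": float(v)}
                for a, v in enumerate(self.beta)
                if v != 0.0
            ],
            "J": [
                {"a": site_label(a), "b": site_label(b), "value": float(v)}
                for (a, b), v in sorted(self.J.items())
            ],
            "T": [
                {
                    "a": site_label(a),
                    "b": site_label(b),
                    "c": site_label(c),
                    "value": float(v),
                }
                for (a, b, c), v in sorted(self.T.items())
            ],
        }

    def save_json(self, path, wildtype: str | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(wildtype), fh, indent=1)

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "LandscapeModel":
        L = int(d["length"])
        beta = np.zeros(3 * L)
        for e in d["beta"]:
            beta[3 * e["site"] + e["mutation_index"]] = e["value"]

        def flat(x: Mapping) -> int:
            return 3 * x["site"] + x["mutation_index"]

        J = {(flat(e["a"]), flat(e["b"])): float(e["value"]) for e in d.get("J", [])}
        T = {
            (flat(e["a"]), flat(e["b"]), flat(e["c"])): float(e["value"])
            for e in d.get("T", [])
        }
        return cls(float(d["alpha"]), beta, J, T)

    @classmethod
    def load_json(cls, path) -> "LandscapeModel":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def random_sequences(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """i.i.d. sequences with each site uniform over the four bases."""
    codes = rng.integers(0, 4, size=(n, length))
    return ["".join(BASES[c] for c in row) for row in codes]
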