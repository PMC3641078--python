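"""Sequence encoding, record filtering and design-matrix construction.

Sort-seq records pair a mutagenized promoter sequence (fixed length L,
alphabet A/C/G/T) with an ordinal expression bin 1..K.  Sequences are
represented relative to a wild type: each site carries three binary
indicators, one per possible substitution, so the wild type encodes to the
all-zero vector and the design space of an order-1 model has 3L columns.

The per-site code is cyclic in the base order (A, T, C, G): a substitution
that advances the wild-type base by one position in that cycle sets the
first indicator ("100"), by two the second ("010"), by three the third
("001").  Interaction features for higher-order models are products of
these indicators.

Positions are held 0-based internally; the display convention for a
promoter window upstream of the transcription start is -L..-1
(report position = index - L).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

BASES = "ATCG"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: indicator index k is set when the mutant base is (wt + k + 1) mod 4
#: in the cyclic base order A, T, C, G
_CODES = ("100", "010", "001")


class InvalidAlphabetError(ValueError):
    """A character outside {A, C, G, T} was encountered."""


def _check_bases(s: str) -> None:
    for ch in s:
        if ch not in _BASE_INDEX:
            raise InvalidAlphabetError(f"invalid base {ch!r}; expected one of ACGT")


def seq_to_ints(seq: str) -> np.ndarray:
    """Map a base string to integer codes in the cyclic order A,T,C,G."""
    _check_bases(seq)
    codes = np.frombuffer(seq.translate(_TRANS).encode(), dtype=np.uint8) - ord("0")
    return codes.astype(np.int64)


_TRANS = str.maketrans({b: str(i) for b, i in _BASE_INDEX.items()})


def ints_to_seq(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def encode_mutation(wt_base: str, mut_base: str) -> str:
    """Three-bit indicator code of a substitution relative to the wild type.

    Returns "000" iff the bases agree; otherwise one of "100", "010", "001"
    following the cyclic scheme over the base order A, T, C, G.
    """
    if wt_base not in _BASE_INDEX or mut_base not in _BASE_INDEX:
        raise InvalidAlphabetError(
            f"invalid base in ({wt_base!r}, {mut_base!r}); expected ACGT"
        )
    if wt_base == mut_base:
        return "000"
    offset = (_BASE_INDEX[mut_base] - _BASE_INDEX[wt_base]) % 4
    return _CODES[offset - 1]


def mutation_indicator_index(wt_base: str, mut_base: str) -> int:
    """Index 0..2 of the indicator set by this substitution (wt != mut)."""
    offset = (_BASE_INDEX[mut_base] - _BASE_INDEX[wt_base]) % 4
    if offset == 0:
        raise ValueError("wild-type base is not a mutation")
    return offset - 1


def mutant_base(wt_base: str, indicator: int) -> str:
    """Inverse of :func:`mutation_indicator_index`."""
    return BASES[(_BASE_INDEX[wt_base] + indicator + 1) % 4]


def encode_sequence(seq: str, wildtype: str) -> np.ndarray:
    """Length-3L binary indicator vector of mutations relative to ``wildtype``."""
    if len(seq) != len(wildtype):
        raise ValueError(f"length mismatch: {len(seq)} vs {len(wildtype)}")
    s = seq_to_ints(seq)
    w = seq_to_ints(wildtype)
    enc = np.zeros(3 * len(seq), dtype=np.int8)
    offset = (s - w) % 4
    mutated = np.nonzero(offset)[0]
    enc[3 * mutated + offset[mutated] - 1] = 1
    return enc


def decode_sequence(enc: np.ndarray, wildtype: str) -> str:
    """Inverse of :func:`encode_sequence`."""
    enc = np.asarray(enc).reshape(len(wildtype), 3)
    if (enc.sum(axis=1) > 1).any():
        raise ValueError("invalid encoding: more than one indicator set at a site")
    w = seq_to_ints(wildtype)
    offset = enc.argmax(axis=1) + 1
    offset[enc.sum(axis=1) == 0] = 0
    return ints_to_seq((w + offset) % 4)


def hamming_to_wildtype(seq: str, wildtype: str) -> int:
    """Number of sites at which ``seq`` differs from ``wildtype``."""
    if len(seq) != len(wildtype):
        raise ValueError(f"length mismatch: {len(seq)} vs {len(wildtype)}")
    return sum(a != b for a, b in zip(seq, wildtype))


# ---------------------------------------------------------------------------
# records

@dataclass(frozen=True)
class RegionMap:
    """Named binding-site intervals as 0-based half-open [start, end) indices.

    The default layout places the two CRP half-sites and the two RNA
    polymerase contact regions (-35 and -10 elements, roughly) inside a
    75-nt promoter window; it is a convention of this package, not a
    measured annotation, and every block summary echoes the map in use.
    """

    blocks: dict[str, tuple[int, int]]
    length: int = 75

    def __post_init__(self) -> None:
        for name, (s, e) in self.blocks.items():
            if not (0 <= s < e <= self.length):
                raise ValueError(f"block {name}: [{s}, {e}) outside [0, {self.length})")

    @classmethod
    def from_report_coords(
        cls, blocks: dict[str, tuple[int, int]], length: int = 75
    ) -> "RegionMap":
        """Build from -L..-1 display coordinates (half-open)."""
        return cls(
            {n: (s + length, e + length) for n, (s, e) in blocks.items()}, length
        )

    @classmethod
    def default(cls, length: int = 75) -> "RegionMap":
        return cls.from_report_coords(
            {
                "CRP1": (-75, -65),
                "CRP2": (-65, -50),
                "RNAP1": (-40, -25),
                "RNAP2": (-15, -1),
            },
            length,
        )

    def sites(self, name: str) -> range:
        s, e = self.blocks[name]
        return range(s, e)

    def all_sites(self) -> set[int]:
        out: set[int] = set()
        for name in self.blocks:
            out.update(self.sites(name))
        return out

    def block_of(self, site: int) -> str | None:
        for name, (s, e) in self.blocks.items():
            if s <= site < e:
                return name
        return None

    def to_report_coords(self) -> dict[str, tuple[int, int]]:
        L = self.length
        return {n: (s - L, e - L) for n, (s, e) in self.blocks.items()}


def make_records(
    sequences: Iterable[str],
    bins: Iterable[int],
    condition: str | Iterable[str] = "synthetic",
    counts: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Assemble a sort-seq record table (columns: sequence, bin, condition, count)."""
    df = pd.DataFrame({"sequence": list(sequences), "bin": list(bins)})
    df["condition"] = condition if isinstance(condition, str) else list(condition)
    df["count"] = 1 if counts is None else list(counts)
    return df


def read_records_tsv(path) -> pd.DataFrame:
    """Read the TSV dialect: header columns ``sequence  bin  condition`` (+ optional count)."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    missing = {"sequence", "bin"} - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    if "condition" not in df.columns:
        df["condition"] = "default"
    if "count" not in df.columns:
        df["count"] = 1
    df["bin"] = df["bin"].astype(int)
    return df


def write_records_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=["sequence", "bin", "condition", "count"])


def read_records_fasta(path, condition: str = "default") -> pd.DataFrame:
    """Read records from FASTA; the bin is parsed from a ``bin=<int>`` key in the description."""
    from Bio import SeqIO

    seqs, bins = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split() if "=" in kv
        )
        if "bin" not in fields:
            raise ValueError(f"record {rec.id}: no 'bin=' key in description")
        seqs.append(str(rec.seq).upper())
        bins.append(int(fields["bin"]))
    return make_records(seqs, bins, condition=condition)


def filter_records(
    records: pd.DataFrame,
    wildtype: str,
    max_mutations: int = 20,
    collapse_same_bin_duplicates: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Apply the data-quality filters and return (filtered records, report).

    Records further than ``max_mutations`` substitutions from the wild type
    are rejected as likely errors.  Identical sequences recorded in the same
    bin (and condition) are unlikely to be independent measurements, so when
    ``collapse_same_bin_duplicates`` is set only the first of each
    (sequence, bin, condition) group is kept; its ``count`` accumulates the
    group size so duplicate multiplicity survives for the noise estimator,
    which relies on duplicates across *different* bins.
    """
    report = {"n_input": int(len(records)), "max_mutations": int(max_mutations)}
    if len(records) == 0:
        report.update(n_removed_mutations=0, n_removed_duplicates=0, n_output=0)
        return records.copy(), report

    dist = records["sequence"].map(lambda s: hamming_to_wildtype(s, wildtype))
    keep = dist <= max_mutations
    report["n_removed_mutations"] = int((~keep).sum())
    out = records.loc[keep].copy()

    n_dup = 0
    if collapse_same_bin_duplicates and len(out):
        grouped = out.groupby(["sequence", "bin", "condition"], sort=False)
        total = grouped["count"].transform("sum")
        first = ~out.duplicated(["sequence", "bin", "condition"])
        n_dup = int(len(out) - first.sum())
        out = out.loc[first].copy()
        out["count"] = total.loc[first]
    report["n_removed_duplicates"] = n_dup
    report["n_output"] = int(len(out))
    return out.reset_index(drop=True), report


def write_filter_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


# ---------------------------------------------------------------------------
# design matrices

@dataclass(frozen=True)
class FeatureIndex:
    """Canonical column labels for a design matrix of order 1-3.

    Labels are tuples: ``("b", site, m)`` for additive indicators,
    ``("J", i, mi, j, mj)`` with i < j for pairwise products and
    ``("T", i, mi, j, mj, k, mk)`` with i < j < k for triples, where
    m are indicator indices 0..2 in code order "100", "010", "001".
    """

    length: int
    order: int
    labels: tuple = field(repr=False, default=())

    @classmethod
    def build(cls, length: int, order: int) -> "FeatureIndex":
        if order not in (1, 2, 3):
            raise ValueError(f"unknown order {order}")
        labels: list[tuple] = [
            ("b", i, m) for i in range(length) for m in range(3)
        ]
        if order >= 2:
            for i in range(length):
                for j in range(i + 1, length):
                    labels.extend(
                        ("J", i, mi, j, mj) for mi in range(3) for mj in range(3)
                    )
        if order >= 3:
            for i in range(length):
                for j in range(i + 1, length):
                    for k in range(j + 1, length):
                        labels.extend(
                            ("T", i, mi, j, mj, k, mk)
                            for mi in range(3)
                            for mj in range(3)
                            for mk in range(3)
                        )
        return cls(length, order, tuple(labels))

    def __len__(self) -> int:
        return len(self.labels)

    def position(self, label: tuple) -> int:
        # additive and pair blocks have closed-form offsets; fall back to search
        kind = label[0]
        L = self.length
        if kind == "b":
            _, i, m = label
            return 3 * i + m
        if kind == "J" and self.order >= 2:
            _, i, mi, j, mj = label
            pair_rank = i * L - i * (i + 1) // 2 + (j - i - 1)
            return 3 * L + 9 * pair_rank + 3 * mi + mj
        return self.labels.index(label)


def count_model_coefficients(L: int, order: int) -> int:
    """Total coefficient count (intercept included) of the order-1/2/3 model.

    At most one mutation per site is possible in a single genome, so the
    interaction features pair *sites*, not raw indicators: 9 mutation pairs
    per unordered site pair, 27 triples per site triple.
    """
    if order not in (1, 2, 3):
        raise ValueError(f"unknown order {order}")
    if L < order:
        raise ValueError(f"sequence length {L} shorter than model order {order}")
    n = 1 + 3 * L
    if order >= 2:
        n += 9 * comb(L, 2)
    if order >= 3:
        n += 27 * comb(L, 3)
    return n


def _mutation_lists(sequences: Sequence[str], wildtype: str) -> list[np.ndarray]:
    """Per sequence, the sorted flat indicator indices (3*site + m) that are set."""
    w = seq_to_ints(wildtype)
    out = []
    for s in sequences:
        si = seq_to_ints(s)
        if len(si) != len(w):
            raise ValueError("mixed sequence lengths in design matrix input")
        offset = (si - w) % 4
        mutated = np.nonzero(offset)[0]
        out.append(3 * mutated + offset[mutated] - 1)
    return out


def build_design_matrix(
    sequences: Sequence[str] | pd.DataFrame,
    wildtype: str,
    order: int = 1,
) -> tuple[sparse.csr_matrix, FeatureIndex]:
    """Sparse 0/1 design matrix (one row per record) for a model of order 1-3.

    Columns follow the canonical layout of :class:`FeatureIndex`: the 3L
    additive indicators site-major first, then all 9 products per site pair
    (i < j lexicographic), then all 27 per site triple.  The intercept is not
    a column; models fit it separately.
    """
    if isinstance(sequences, pd.DataFrame):
        sequences = sequences["sequence"].tolist()
    index = FeatureIndex.build(len(wildtype), order)
    L = len(wildtype)
    muts = _mutation_lists(sequences, wildtype)

    indptr = [0]
    indices: list[int] = []
    pair_base = 3 * L
    n_pair_cols = 9 * comb(L, 2)
    triple_base = pair_base + n_pair_cols
    for m in muts:
        cols = list(m)
        if order >= 2 and len(m) >= 2:
            sites = m // 3
            mi = m % 3
            for a in range(len(m)):
                for b in range(a + 1, len(m)):
                    i, j = int(sites[a]), int(sites[b])
                    pr = i * L - i * (i + 1) // 2 + (j - i - 1)
                    cols.append(pair_base + 9 * pr + 3 * int(mi[a]) + int(mi[b]))
        if order >= 3 and len(m) >= 3:
            sites = m // 3
            mi = m % 3
            n = len(m)
            for a in range(n):
                for b in range(a + 1, n):
                    for c in range(b + 1, n):
                        i, j, k = int(sites[a]), int(sites[b]), int(sites[c])
                        tr = _triple_rank(i, j, k, L)
                        cols.append(
                            triple_base
                            + 27 * tr
                            + 9 * int(mi[a])
                            + 3 * int(mi[b])
                            + int(mi[c])
                        )
        indices.extend(cols)
        indptr.append(len(indices))

    X = sparse.csr_matrix(
        (np.ones(len(indices)), np.array(indices, dtype=np.int64), np.array(indptr)),
        shape=(len(sequences), len(index)),
        dtype=np.float64,
    )
    return X, index


def _triple_rank(i: int, j: int, k: int, L: int) -> int:
    """Lexicographic rank of the site triple i<j<k among C(L,3) triples."""
    return comb(L, 3) - comb(L - i, 3) + (comb(L - i - 1, 2) - comb(L - j, 2)) + (k - j - 1)
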