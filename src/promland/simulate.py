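"""Synthetic sort-seq data with known ground truth.

Emulates the statistical structure of a sorted-cell promoter mutagenesis
experiment: a mutagenized library around a 75-nt wild type (on average ~7
substitutions per sequence), a sparse block-structured landscape whose
additive effects and pairwise interactions concentrate in transcription
factor (CRP) and RNA polymerase binding sites, and a read-out that bins a
latent log-expression phenotype into K ordered fluorescence gates with a
background floor saturating the lowest bins and Gaussian intrinsic noise
before binning.

Everything is deterministic given one top-level seed; independent stages
draw from named substreams so that any stage can be regenerated alone.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codec import BASES, RegionMap, ints_to_seq, make_records, seq_to_ints
from .model import LandscapeModel

DEFAULT_WILDTYPE_SEED = 20130501


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible child stream of the top-level seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def default_wildtype(length: int = 75, seed: int = DEFAULT_WILDTYPE_SEED) -> str:
    """A fixed random wild-type sequence (the real promoter is not bundled)."""
    rng = np.random.default_rng(seed)
    return ints_to_seq(rng.integers(0, 4, size=length))


# ---------------------------------------------------------------------------
# ground-truth landscapes

@dataclass
class GroundTruthLandscape:
    wildtype: str
    model: LandscapeModel
    region_map: RegionMap

    @property
    def length(self) -> int:
        return len(self.wildtype)


def sample_landscape(
    L: int = 75,
    region_map: RegionMap | None = None,
    additive_scale: float = 1.0,
    epistatic_scale: float = 0.4,
    epistatic_sparsity: float = 0.03,
    antagonistic_bias: float = 0.62,
    seed: int = 0,
    wildtype: str | None = None,
    third_order_scale: float = 0.0,
    third_order_sparsity: float = 0.0,
    within_family_fraction: float = 0.8,
) -> GroundTruthLandscape:
    """Draw a sparse block-structured ground-truth landscape.

    Additive effects inside binding-site blocks are strong and mostly
    deleterious (binding sites are near-optimal in the wild type, so most
    substitutions lower expression); outside the blocks they are an order
    of magnitude weaker.  Pairwise coefficients J are nonzero only for site
    pairs within or between blocks, at an overall density of
    ``epistatic_sparsity`` among all 9*C(L,2) possible entries.  Their
    geography mirrors the clustered interaction maps of real regulatory
    regions: a ``within_family_fraction`` of interactions join sites of the
    same protein's blocks (block families = name prefixes, e.g. CRP1 and
    CRP2 belong to CRP), the rest bridge families.  A fraction
    ``antagonistic_bias`` of interactions are antagonistic (J opposing the
    shared sign of the two marginal effects), the dominant mode reported
    for regulatory sequences.
    """
    if not 0.0 <= epistatic_sparsity <= 1.0:
        raise ValueError(f"epistatic_sparsity must be in [0, 1], got {epistatic_sparsity}")
    if not 0.0 <= antagonistic_bias <= 1.0:
        raise ValueError("antagonistic_bias must be in [0, 1]")
    region_map = region_map or RegionMap.default(L)
    rng = substream(seed, "landscape")
    if wildtype is None:
        wildtype = ints_to_seq(rng.integers(0, 4, size=L))

    block_sites = np.array(sorted(region_map.all_sites()))
    in_block = np.zeros(L, dtype=bool)
    in_block[block_sites] = True

    beta = 0.1 * additive_scale * rng.normal(size=3 * L)
    strong = rng.normal(loc=-1.0, scale=0.5, size=3 * L) * additive_scale
    site_of = np.arange(3 * L) // 3
    beta[in_block[site_of]] = strong[in_block[site_of]]

    # eligible indicator pairs: distinct sites, both inside blocks, split
    # into same-family (near-diagonal clusters) and cross-family pools
    family_of = {
        s: name.rstrip("0123456789")
        for name in region_map.blocks
        for s in region_map.sites(name)
    }
    within: list[tuple[int, int]] = []
    cross: list[tuple[int, int]] = []
    for ia, sa in enumerate(block_sites):
        for sb in block_sites[ia + 1 :]:
            pool = within if family_of[sa] == family_of[sb] else cross
            for ma in range(3):
                for mb in range(3):
                    pool.append((3 * sa + ma, 3 * sb + mb))
    n_total = 9 * L * (L - 1) // 2
    n_nonzero = min(int(round(epistatic_sparsity * n_total)), len(within) + len(cross))
    quota = {
        "within": int(round(within_family_fraction * n_nonzero)) if cross else n_nonzero,
    }
    quota["cross"] = n_nonzero - quota["within"]

    J: dict[tuple[int, int], float] = {}
    for pool_name, pool in (("within", within), ("cross", cross)):
        k = min(quota[pool_name], len(pool))
        n_antag = int(round(antagonistic_bias * k))
        same_sign = [p for p in pool if beta[p[0]] * beta[p[1]] > 0]
        rng.shuffle(same_sign)
        for a, b in same_sign[:n_antag]:
            J[(int(a), int(b))] = float(-np.sign(beta[a]) * abs(rng.normal()) * epistatic_scale)
        rest = [p for p in pool if p not in J]
        rng.shuffle(rest)
        for a, b in rest[: k - min(n_antag, len(same_sign))]:
            J[(int(a), int(b))] = float(rng.normal() * epistatic_scale)

    T: dict[tuple[int, int, int], float] = {}
    if third_order_sparsity > 0 and third_order_scale > 0 and len(block_sites) >= 3:
        n_trip_total = 27 * len(block_sites) * (len(block_sites) - 1) * (len(block_sites) - 2) // 6
        n_trip = max(1, int(round(third_order_sparsity * n_trip_total)))
        seen: set[tuple[int, int, int]] = set()
        while len(seen) < n_trip:
            s3 = rng.choice(block_sites, size=3, replace=False)
            s3.sort()
            m3 = rng.integers(0, 3, size=3)
            seen.add(tuple(int(3 * s + m) for s, m in zip(s3, m3)))
        for key in seen:
            T[key] = float(rng.normal() * third_order_scale)

    alpha = 0.0  # wild-type latent is the reference point
    return GroundTruthLandscape(
        wildtype, LandscapeModel(alpha, beta, J, T), region_map
    )


def knockout_blocks(
    truth: GroundTruthLandscape, block_names: list[str]
) -> GroundTruthLandscape:
    """Zero all additive and interaction coefficients touching the given blocks.

    Models a condition in which a factor does not bind (e.g. CRP without
    cAMP): its binding-site sequence no longer influences expression.
    """
    dead = set()
    for name in block_names:
        dead.update(truth.region_map.sites(name))
    beta = truth.model.beta.copy()
    for a in range(len(beta)):
        if a // 3 in dead:
            beta[a] = 0.0
    J = {
        k: v
        for k, v in truth.model.J.items()
        if k[0] // 3 not in dead and k[1] // 3 not in dead
    }
    T = {
        k: v
        for k, v in truth.model.T.items()
        if all(a // 3 not in dead for a in k)
    }
    return GroundTruthLandscape(
        truth.wildtype,
        LandscapeModel(truth.model.alpha, beta, J, T),
        truth.region_map,
    )


# ---------------------------------------------------------------------------
# mutagenesis

def mutagenize_library(
    wildtype: str,
    n_sequences: int,
    per_site_rate: float = 7 / 75,
    region_restriction: tuple[int, int] | list[tuple[int, int]] | None = None,
    seed: int = 0,
) -> list[str]:
    """i.i.d. per-site mutagenesis of the wild type.

    Each site independently substitutes to a uniformly random different
    base with probability ``per_site_rate`` (mean mutation load L * rate,
    ~7 for the defaults), optionally restricted to half-open intervals.
    """
    if not 0.0 <= per_site_rate <= 1.0:
        raise ValueError("per_site_rate must be in [0, 1]")
    L = len(wildtype)
    allowed = np.zeros(L, dtype=bool)
    if region_restriction is None:
        allowed[:] = True
    else:
        intervals = (
            [region_restriction]
            if isinstance(region_restriction, tuple)
            else list(region_restriction)
        )
        for s, e in intervals:
            if e <= s:
                raise ValueError(f"empty restriction interval [{s}, {e})")
            allowed[s:e] = True
        if not allowed.any():
            raise ValueError("region restriction covers no sites")

    rng = substream(seed, "library")
    w = seq_to_ints(wildtype)
    hit = (rng.random((n_sequences, L)) < per_site_rate) & allowed
    shift = rng.integers(1, 4, size=(n_sequences, L))
    codes = np.where(hit, (w + shift) % 4, w)
    lut = np.array(list(BASES))
    return ["".join(row) for row in lut[codes]]


def pooled_mutagenized_library(
    wildtype: str,
    n_sequences: int,
    region_map: RegionMap,
    per_seq_mutations: float = 7.0,
    seed: int = 0,
) -> list[str]:
    """Library pooled from one whole-window and two region-targeted designs.

    Emulates the combined design of the assay this package models: equal
    thirds of sequences mutagenized over the whole window, over the CRP
    binding area only, and over the RNAP binding area only — each at the
    per-site rate that yields ``per_seq_mutations`` expected substitutions.
    Targeted designs concentrate the same mutation load on fewer sites,
    which multiplies the coverage of within-block mutation pairs.
    """

    def hull(prefix: str) -> tuple[int, int]:
        spans = [v for k, v in region_map.blocks.items() if k.startswith(prefix)]
        if not spans:
            raise ValueError(f"region map has no '{prefix}*' blocks")
        return min(s for s, _ in spans), max(e for _, e in spans)

    L = len(wildtype)
    designs = [
        (None, per_seq_mutations / L),
        (hull("CRP"), None),
        (hull("RNAP"), None),
    ]
    out: list[str] = []
    per = n_sequences // 3
    for d_idx, (restriction, rate) in enumerate(designs):
        n_d = per if d_idx < 2 else n_sequences - 2 * per
        if rate is None:
            width = restriction[1] - restriction[0]
            rate = min(per_seq_mutations / width, 0.75)
        out.extend(
            mutagenize_library(
                wildtype, n_d, per_site_rate=rate,
                region_restriction=restriction, seed=seed + 7919 * d_idx,
            )
        )
    return out


# ---------------------------------------------------------------------------
# binning

@dataclass
class BinningSpec:
    """Monotone binning of the latent phenotype into K ordered gates.

    ``thresholds`` are K-1 strictly increasing latent cut points;
    ``background_floor`` is the latent value below which measurements are
    dominated by background fluorescence and become indistinguishable;
    ``noise_sd`` is the standard deviation of Gaussian intrinsic noise
    added to the (floored) latent before thresholding.
    """

    K: int
    thresholds: np.ndarray
    background_floor: float = -np.inf
    noise_sd: float = 0.0
    #: fractional reduction of noise_sd from the bottom to the top gate:
    #: strong expressors are measured more precisely than dim, background-
    #: dominated cells, so replicate wild-type controls under-estimate the
    #: average noise (sd(z) = noise_sd * (1 - noise_slope * gate position))
    noise_slope: float = 0.0

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if len(self.thresholds) != self.K - 1:
            raise ValueError(f"need {self.K - 1} thresholds for K={self.K}")
        if not np.all(np.diff(self.thresholds) > 0):
            raise ValueError("thresholds must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.noise_slope < 1.0:
            raise ValueError("noise_slope must be in [0, 1)")

    def local_noise_sd(self, z: np.ndarray) -> np.ndarray:
        """Latent-dependent noise level at (floored) latent values ``z``."""
        if self.noise_slope == 0.0:
            return np.full(np.shape(z), self.noise_sd)
        t0, t1 = self.thresholds[0], self.thresholds[-1]
        pos = np.clip((np.asarray(z) - t0) / (t1 - t0), 0.0, 1.0)
        return self.noise_sd * (1.0 - self.noise_slope * pos)

    @classmethod
    def from_latent_sample(
        cls,
        latent: np.ndarray,
        K: int = 9,
        noise_sd: float = 0.0,
        background_floor_quantile: float | None = None,
        span: tuple[float, float] = (0.02, 0.995),
    ) -> "BinningSpec":
        """Gates spanning the latent distribution of a library.

        The latent scale is log-expression, so equally spaced latent cut
        points correspond to logarithmically spaced fluorescence gates.
        ``background_floor_quantile`` (if given) saturates that lower tail
        of the library, emulating background-dominated low bins.
        """
        lo, hi = np.quantile(latent, span)
        thresholds = np.linspace(lo, hi, K - 1)
        floor = (
            float(np.quantile(latent, background_floor_quantile))
            if background_floor_quantile is not None
            else -np.inf
        )
        return cls(K, thresholds, background_floor=floor, noise_sd=noise_sd)

    @classmethod
    def default_for_latent(
        cls,
        latent: np.ndarray,
        K: int = 9,
        noise_in_gates: float = 0.6,
        floor_in_gates: float = 0.6,
        noise_slope: float = 0.5,
        span: tuple[float, float] = (0.02, 0.995),
    ) -> "BinningSpec":
        """Study-condition defaults: K log-spaced gates over the library range,
        a background floor just above the lowest gate (the bottom bins are
        background-dominated, so the transform should flatten there), and
        intrinsic noise of ``noise_in_gates`` gate widths at the dim end,
        shrinking by ``noise_slope`` towards the bright end (strong
        expressors are measured more precisely)."""
        lo, hi = np.quantile(latent, span)
        thresholds = np.linspace(lo, hi, K - 1)
        h = thresholds[1] - thresholds[0]
        return cls(
            K,
            thresholds,
            background_floor=float(thresholds[0] + floor_in_gates * h),
            noise_sd=float(noise_in_gates * h),
            noise_slope=noise_slope,
        )

    def to_json_dict(self) -> dict:
        return {
            "K": self.K,
            "thresholds": self.thresholds.tolist(),
            "background_floor": float(self.background_floor),
            "noise_sd": float(self.noise_sd),
            "noise_slope": float(self.noise_slope),
        }


def phenotype_to_bin(
    latent: np.ndarray | float,
    spec: BinningSpec,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sort latent phenotypes into bins 1..K (monotone in the latent, in expectation)."""
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "binning")
    latent = np.atleast_1d(np.asarray(latent, dtype=float))
    z = np.maximum(latent, spec.background_floor)
    if spec.noise_sd > 0:
        z = z + rng.normal(size=z.shape) * spec.local_noise_sd(z)
    # side="left" counts thresholds strictly below z
    return 1 + np.searchsorted(spec.thresholds, z, side="left").astype(int)


# ---------------------------------------------------------------------------
# dataset assembly

def generate_dataset(
    landscape: GroundTruthLandscape | dict[str, GroundTruthLandscape],
    n: int,
    spec: BinningSpec | dict[str, BinningSpec],
    duplicate_fraction: float = 0.0,
    seed: int = 0,
    per_site_rate: float = 7 / 75,
    region_restriction=None,
) -> pd.DataFrame:
    """Emit n sort-seq records for one condition or a dict of conditions.

    A ``duplicate_fraction`` of the emitted records are second measurements
    of an already-emitted sequence with an independently re-sampled bin
    (the raw material for the duplicate-based noise estimator); the record
    total stays n.  In multi-condition mode n is split evenly and each
    condition uses its own landscape (e.g. a CRP knockout for a no-cAMP
    environment) and, like the separate experiments it emulates, may use
    its own gate calibration (pass a dict of specs).
    """
    if not 0.0 <= duplicate_fraction < 1.0:
        raise ValueError("duplicate_fraction must be in [0, 1)")
    conditions = (
        landscape if isinstance(landscape, dict) else {"synthetic": landscape}
    )
    per_cond = n // len(conditions)
    frames = []
    for c_idx, (name, truth) in enumerate(conditions.items()):
        c_spec = spec[name] if isinstance(spec, dict) else spec
        n_c = per_cond + (n % len(conditions) if c_idx == len(conditions) - 1 else 0)
        n_dup = int(round(duplicate_fraction * n_c))
        seqs = mutagenize_library(
            truth.wildtype,
            n_c - n_dup,
            per_site_rate=per_site_rate,
            region_restriction=region_restriction,
            seed=seed + 104729 * c_idx,
        )
        frames.append(
            assemble_records(
                truth, seqs, c_spec, n_duplicates=n_dup,
                seed=seed + 104729 * c_idx, condition=name,
            )
        )
    return pd.concat(frames, ignore_index=True)


def assemble_records(
    truth: GroundTruthLandscape,
    sequences: list[str],
    spec: BinningSpec,
    n_duplicates: int = 0,
    seed: int = 0,
    condition: str = "synthetic",
) -> pd.DataFrame:
    """Bin a pre-built library into sort-seq records (plus re-measured duplicates)."""
    rng = substream(seed, "dataset")
    dup_idx = (
        rng.choice(len(sequences), size=n_duplicates, replace=False)
        if n_duplicates
        else []
    )
    all_seqs = list(sequences) + [sequences[i] for i in dup_idx]
    latent = truth.model.predict(all_seqs, truth.wildtype)
    bins = phenotype_to_bin(latent, spec, rng)
    return make_records(all_seqs, bins, condition=condition)


def write_ground_truth(
    truth: GroundTruthLandscape, spec: BinningSpec, seed: int, path
) -> None:
    """JSON sidecar with the full generating model for recovery scoring."""
    payload = {
        "seed": int(seed),
        "wildtype": truth.wildtype,
        "region_map": truth.region_map.to_report_coords(),
        "binning": spec.to_json_dict(),
        "model": truth.model.to_json_dict(truth.wildtype),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def intrinsic_noise_truth(
    truth: GroundTruthLandscape,
    spec: BinningSpec,
    sequences: list[str],
    n_reps: int = 30,
    seed: int = 12345,
) -> float:
    """Monte-Carlo ground truth for the intrinsic-noise fraction.

    Simulates ``n_reps`` independent re-measurements (bin draws) of each
    sequence and returns E[Var(y | sequence)] / Var(y), the share of the
    raw-bin variance that no genotype model can explain.
    """
    rng = substream(seed, "noise-truth")
    latent = truth.model.predict(sequences, truth.wildtype)
    draws = np.stack(
        [phenotype_to_bin(latent, spec, rng) for _ in range(n_reps)], axis=0
    ).astype(float)
    within = draws.var(axis=0, ddof=1).mean()
    total = draws.var(ddof=1)
    return float(within / total)
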