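"""Intrinsic-noise estimates and explainable-variance accounting.

Repeated measurements of the same genotype disagree because of
fluorescence noise, sorting errors and sequencing errors.  The share of
the response variance due to this intrinsic noise is a hard ceiling for
any genotype model: R^2 can never exceed 1 - noise_fraction.  Two
estimators bracket it:

* duplicates — identical library sequences recorded in different bins give
  a within-genotype variance; restricting to groups whose recorded values
  actually differ (groups collapsing to one bin carry no variance
  information) biases the ratio upward, so this is an upper bound;
* controls — replicate measurements of the wild type alone; strong
  expressors are measured more precisely than the bulk of the library, so
  this underestimates the average noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .additive import BinTransform, transform_response


@dataclass
class NoiseEstimate:
    duplicate_upper_bound: float | None
    control_lower_estimate: float | None
    n_duplicate_groups: int


def duplicate_noise_fraction(
    records: pd.DataFrame, g: BinTransform
) -> tuple[float | None, int]:
    """Upper bound on the intrinsic-noise fraction from duplicate sequences.

    Averages the sample variance (n-1 convention, unweighted over groups)
    of g(y) within groups of identical sequences (per condition) that span
    at least two distinct bins, divided by the total variance of g(y).
    Returns (None, 0) when no duplicate group exists at all; returns 0.0
    when duplicates exist but all agree.
    """
    gy = transform_response(records["bin"].to_numpy(), g)
    df = records[["sequence", "condition"]].copy()
    df["gy"] = gy
    groups = df.groupby(["sequence", "condition"], sort=False)["gy"]
    sizes = groups.size()
    n_groups = int((sizes >= 2).sum())
    if n_groups == 0:
        warnings.warn("no duplicate sequence groups; noise bound undefined")
        return None, 0
    stats = groups.agg(["size", "var", "nunique"])
    informative = stats[(stats["size"] >= 2) & (stats["nunique"] >= 2)]
    if len(informative) == 0:
        return 0.0, n_groups
    within = float(informative["var"].mean())
    total = float(np.var(gy, ddof=1))
    return within / total, n_groups


def control_noise_fraction(
    control_g_values: np.ndarray, data_g_variance: float
) -> float:
    """Lower estimate: replicate-control variance over the data variance."""
    control_g_values = np.asarray(control_g_values, dtype=float)
    if len(control_g_values) < 2:
        raise ValueError("need at least 2 control replicates")
    if data_g_variance <= 0:
        raise ValueError("data variance must be positive")
    return float(np.var(control_g_values, ddof=1) / data_g_variance)


def explainable_variance_share(r2: float, noise_fraction: float) -> float:
    """Share of the *explainable* variance (total minus noise) a model accounts for."""
    if not 0.0 <= noise_fraction < 1.0:
        raise ValueError("noise_fraction must be in [0, 1)")
    ceiling = 1.0 - noise_fraction
    if r2 > ceiling:
        warnings.warn(
            f"R^2 = {r2:.3f} exceeds the explainable ceiling {ceiling:.3f}; clipping"
        )
        r2 = ceiling
    return r2 / ceiling


def epistasis_variance_share(
    r2_epistatic: float, r2_additive: float, noise_fraction: float
) -> float:
    """Explainable-variance share contributed by the epistatic terms alone."""
    if not 0.0 <= noise_fraction < 1.0:
        raise ValueError("noise_fraction must be in [0, 1)")
    if r2_epistatic < r2_additive:
        warnings.warn(
            "epistatic R^2 below additive R^2; returning the signed share"
        )
    return (r2_epistatic - r2_additive) / (1.0 - noise_fraction)


def noise_report(
    records: pd.DataFrame,
    g: BinTransform,
    control_g_values: np.ndarray | None = None,
) -> dict:
    """Both estimates plus the variance decomposition, JSON-ready."""
    gy = transform_response(records["bin"].to_numpy(), g)
    data_var = float(np.var(gy, ddof=1))
    dup, n_groups = duplicate_noise_fraction(records, g)
    ctrl = (
        control_noise_fraction(control_g_values, data_var)
        if control_g_values is not None and len(control_g_values) >= 2
        else None
    )
    return {
        "duplicate_upper_bound": dup,
        "control_lower_estimate": ctrl,
        "n_duplicate_groups": n_groups,
        "variance_g_y": data_var,
        "variance_raw_bins": float(np.var(records["bin"].to_numpy(), ddof=1)),
        "n_records": int(len(records)),
    }
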