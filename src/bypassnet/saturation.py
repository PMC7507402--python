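"""Discovery-saturation analysis of suppressor isolation experiments.

To judge how close a suppressor hunt is to saturation, the experiment log
is split into artificial screens: for each query, its isolation
experiments are randomly assigned one-per-screen to ``n_screens`` screens
(queries with fewer experiments than screens are dropped; queries with
more are subsampled). Screen 1 counts the discoveries it finds; each
later screen counts only discoveries not seen before. Averaging over many
random assignments yields a rarefaction-style curve of new discoveries
per additional screen, to which a logarithmic model C(k) = a + b*ln(k) is
fitted on the cumulative counts and extrapolated. Because the logarithmic
model is unbounded, the "fraction discovered" is always reported against
an explicit horizon; a bounded exponential-saturation fit is offered as a
sensitivity alternative.

Two discovery endpoints are supported: dispensable query genes, and
(query, suppressor) pairs — the latter ignoring strains whose suppressor
gene could not be identified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DiscoveryCurve",
    "SaturationModel",
    "assign_artificial_screens",
    "average_discovery_curve",
    "fit_and_extrapolate",
]

ENDPOINTS = ("dispensable_genes", "query_suppressor_pairs")


@dataclass
class DiscoveryCurve:
    endpoint: str
    mean_new: np.ndarray  # mean new discoveries per screen index (1..K)
    se_new: np.ndarray  # permutation standard error of each mean
    n_permutations: int
    n_queries_used: int

    @property
    def n_screens(self) -> int:
        return len(self.mean_new)

    @property
    def mean_cumulative(self) -> np.ndarray:
        return np.cumsum(self.mean_new)


@dataclass
class SaturationModel:
    intercept: float  # a in C(k) = a + b ln k
    slope: float  # b
    residuals: np.ndarray
    horizon: int
    extrapolated_new: np.ndarray  # expected new discoveries per screen k > K
    discovered_fraction: float  # C(K) / C(horizon)
    bounded_fit: Optional[dict] = None  # alternative C(k) = S (1 - exp(-lam k))

    def cumulative(self, k) -> np.ndarray:
        return self.intercept + self.slope * np.log(np.asarray(k, dtype=float))


def _validate_log(log: pd.DataFrame) -> pd.DataFrame:
    required = {"query_gene", "experiment_id", "outcome"}
    if not required.issubset(log.columns):
        raise ValueError(f"experiment log needs columns {sorted(required)}")
    if log.empty:
        raise ValueError("degenerate input: empty experiment log")
    return log


def assign_artificial_screens(
    log: pd.DataFrame, n_screens: int = 4, seed: int = 0
) -> pd.DataFrame:
    """Randomly assign each query's experiments to artificial screens.

    Queries with fewer than ``n_screens`` experiments are disregarded;
    queries with more have ``n_screens`` experiments randomly selected.
    Each retained experiment lands in exactly one screen (a random
    one-to-one assignment). Returns the log restricted to retained
    experiments with an added ``screen`` column (1-based).
    """
    if n_screens < 2:
        raise ValueError("n_screens must be >= 2")
    log = _validate_log(log)
    rng = np.random.default_rng(seed)
    parts = []
    for _, sub in log.groupby("query_gene", sort=False):
        n = len(sub)
        if n < n_screens:
            continue
        take = rng.choice(n, size=n_screens, replace=False) if n > n_screens else np.arange(n)
        chosen = sub.iloc[take].copy()
        chosen["screen"] = rng.permutation(n_screens) + 1
        parts.append(chosen)
    if not parts:
        return log.iloc[0:0].assign(screen=pd.Series(dtype=int))
    return pd.concat(parts, ignore_index=True)


def _new_discoveries(assigned: pd.DataFrame, endpoint: str, n_screens: int) -> np.ndarray:
    """Count discoveries first seen in each screen for one assignment."""
    hits = assigned.loc[assigned["outcome"] == "dispensable_found"]
    if endpoint == "dispensable_genes":
        keys = hits["query_gene"]
    else:  # query_suppressor_pairs: skip strains with unidentified suppressor
        if "suppressor_gene" not in assigned.columns:
            raise ValueError(
                "pairs endpoint requires a 'suppressor_gene' column"
            )
        known = hits.loc[hits["suppressor_gene"].notna()]
        keys = known["query_gene"].astype(str) + "\t" + known["suppressor_gene"].astype(str)
        hits = known
    first = pd.DataFrame({"key": keys, "screen": hits["screen"]}).groupby("key")["screen"].min()
    counts = np.zeros(n_screens)
    vc = first.value_counts()
    for screen, n in vc.items():
        counts[int(screen) - 1] = n
    return counts


def average_discovery_curve(
    log: pd.DataFrame,
    endpoint: str = "dispensable_genes",
    n_screens: int = 4,
    n_permutations: int = 1000,
    seed: int = 0,
) -> DiscoveryCurve:
    """Average new-discovery counts per screen over random assignments.

    Repeats the artificial-screen assignment ``n_permutations`` times
    (re-drawing the subsample for queries with surplus experiments each
    time) and averages the number of discoveries first found in each
    screen.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    log = _validate_log(log)
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_permutations, n_screens))
    n_used = 0
    for i in range(n_permutations):
        assigned = assign_artificial_screens(
            log, n_screens=n_screens, seed=int(rng.integers(2**31))
        )
        if i == 0:
            n_used = assigned["query_gene"].nunique() if len(assigned) else 0
        counts[i] = _new_discoveries(assigned, endpoint, n_screens)
    return DiscoveryCurve(
        endpoint=endpoint,
        mean_new=counts.mean(axis=0),
        se_new=counts.std(axis=0, ddof=1) / math.sqrt(n_permutations),
        n_permutations=n_permutations,
        n_queries_used=n_used,
    )


def fit_and_extrapolate(
    curve: DiscoveryCurve, horizon: int = 20, bounded: bool = True
) -> SaturationModel:
    """Fit C(k) = a + b*ln(k) to the cumulative discovery curve and
    extrapolate.

    The fit uses ordinary least squares on the cumulative means at
    k = 1..K (K >= 3 required). Expected new discoveries at k > K are
    C(k) - C(k-1); the discovered fraction is C(K)/C(horizon) and is
    meaningful only relative to that explicit horizon. When ``bounded``
    is set, an exponential-saturation alternative
    C(k) = S * (1 - exp(-lambda k)) is also fitted for sensitivity.
    """
    K = curve.n_screens
    if K < 3:
        raise ValueError("need at least 3 screen points to fit")
    if horizon <= K:
        raise ValueError("horizon must exceed the number of observed screens")
    k = np.arange(1, K + 1, dtype=float)
    cum = curve.mean_cumulative
    b, a = np.polyfit(np.log(k), cum, 1)
    fitted = a + b * np.log(k)
    ks = np.arange(K + 1, horizon + 1, dtype=float)
    extrapolated = (a + b * np.log(ks)) - (a + b * np.log(ks - 1))
    c_horizon = a + b * math.log(horizon)
    fraction = float(cum[-1] / c_horizon) if c_horizon > 0 else float("nan")

    bounded_fit = None
    if bounded:
        try:
            def model(x, s, lam):
                return s * (1 - np.exp(-lam * x))

            s0 = max(cum[-1] * 1.5, 1e-6)
            (s_hat, lam_hat), _ = curve_fit(
                model, k, cum, p0=[s0, 0.5], maxfev=10000,
                bounds=([1e-9, 1e-9], [np.inf, np.inf]),
            )
            bounded_fit = {
                "pool_size": float(s_hat),
                "rate": float(lam_hat),
                "discovered_fraction": float(cum[-1] / s_hat),
            }
        except RuntimeError:  # no convergence: report the primary fit only
            bounded_fit = None
    return SaturationModel(
        intercept=float(a),
        slope=float(b),
        residuals=cum - fitted,
        horizon=horizon,
        extrapolated_new=extrapolated,
        discovered_fraction=fraction,
        bounded_fit=bounded_fit,
    )
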