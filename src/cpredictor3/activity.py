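"""Three-sigma active-protein detection from expression time courses.

A protein is "active" at a time point when its expression value reaches its
personal threshold

    Active(p) = mu(p) + beta * sigma(p) * (1 - 1 / (1 + sigma(p)^2))

where mu and sigma are the mean and standard deviation of the protein's
expression profile.  The sigma-dependent damping factor keeps thresholds close
to the mean for flat profiles (low sigma: the protein is probably always
expressed at that level) and close to mu + beta*sigma for strongly varying
ones.  beta tunes stringency: beta=0 reduces the threshold to the row mean,
larger beta shrinks the active sets monotonically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["activity_threshold", "activity_profile", "detect_active_sets"]


def _mu_sigma(values: np.ndarray, sd_mode: str) -> tuple[np.ndarray, np.ndarray]:
    if sd_mode not in ("population", "sample"):
        raise ValueError(f"sd_mode must be 'population' or 'sample', got {sd_mode!r}")
    ddof = 0 if sd_mode == "population" else 1
    mu = values.mean(axis=-1)
    if ddof == 1 and values.shape[-1] < 2:
        raise ValueError("sample standard deviation needs at least two time points")
    sigma = values.std(axis=-1, ddof=ddof)
    return mu, sigma


def activity_threshold(
    values, beta: float, sd_mode: str = "population"
) -> float:
    """Per-protein active threshold mu + beta*sigma*(1 - 1/(1+sigma^2)).

    ``values`` is the protein's expression profile over the measured time
    points; ``beta`` must be non-negative.  With sd_mode="population" (the
    default) sigma divides by n, the convention of the three-sigma activity
    literature.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("values must be a non-empty 1-D vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    mu, sigma = _mu_sigma(arr, sd_mode)
    return float(mu + beta * sigma * (1.0 - 1.0 / (1.0 + sigma**2)))


def activity_profile(
    expr: pd.DataFrame, beta: float, sd_mode: str = "population"
) -> pd.DataFrame:
    """Per-protein mean, standard deviation and active threshold.

    Returns a DataFrame indexed like ``expr`` with columns ``mu``, ``sigma``
    and ``threshold``.
    """
    if expr.empty:
        raise ValueError("expression matrix is empty")
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    values = expr.to_numpy(dtype=float)
    mu, sigma = _mu_sigma(values, sd_mode)
    threshold = mu + beta * sigma * (1.0 - 1.0 / (1.0 + sigma**2))
    return pd.DataFrame(
        {"mu": mu, "sigma": sigma, "threshold": threshold}, index=expr.index
    )


def detect_active_sets(
    expr: pd.DataFrame, beta: float, sd_mode: str = "population"
) -> list[set[str]]:
    """Active protein sets AP_1..AP_n, one per time point.

    AP_i collects every protein whose expression at time point i is no less
    than its threshold (inclusive comparison).  With beta=0 each protein is
    active at least at its maximal time point.  Proteins absent from ``expr``
    are simply never active.
    """
    profile = activity_profile(expr, beta, sd_mode)
    values = expr.to_numpy(dtype=float)
    active = values >= profile["threshold"].to_numpy()[:, None]
    proteins = np.asarray(expr.index)
    return [set(proteins[active[:, i]]) for i in range(expr.shape[1])]
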