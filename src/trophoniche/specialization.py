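"""Individual dietary specialization index Ɛ.

Ɛ is the Euclidean distance between a diet vector p (on the K-simplex) and
the ultra-generalist reference g = (1/K, …, 1/K), normalised by the distance
from g to a simplex vertex, √((K−1)/K) — the unique scaling for which an
ultra-generalist scores 0 and a single-source (ultra-specialist) diet scores
exactly 1.

Applied to a diet posterior, Ɛ is computed per MCMC draw and summarised
(mean ± SD); Ɛ of the posterior-mean diet is also reported, and is never
larger than the per-draw mean (Jensen's inequality on the norm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixing_model import DietPosterior

__all__ = [
    "SpecializationError",
    "StrategyThresholds",
    "SpecializationResult",
    "epsilon",
    "epsilon_array",
    "epsilon_posterior",
    "classify_strategy",
]


class SpecializationError(ValueError):
    """Invalid specialization-index input."""


def epsilon_array(p: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Vectorised Ɛ over compositions on the last axis."""
    p = np.asarray(p, float)
    k = p.shape[-1]
    if k < 2:
        raise SpecializationError("need at least 2 sources (K >= 2)")
    sums = p.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > tol) or np.any(p < -tol):
        raise SpecializationError("input is not on the simplex")
    g = 1.0 / k
    dist = np.sqrt(((p - g) ** 2).sum(axis=-1))
    # normaliser = distance from g to a vertex, computed through the same
    # floating-point path as the numerator so a vertex maps to exactly 1
    vertex = np.zeros(k)
    vertex[0] = 1.0
    norm = np.sqrt(((vertex - g) ** 2).sum())
    return dist / norm


def epsilon(p) -> float:
    """Specialization index Ɛ ∈ [0, 1] of one diet vector.

    0 = ultra-generalist (equal use of all K sources); 1 = ultra-specialist
    (all mass on one source).
    """
    p = np.asarray(p, float)
    if p.ndim != 1:
        raise SpecializationError("epsilon expects a single diet vector")
    return float(epsilon_array(p))


@dataclass(frozen=True)
class StrategyThresholds:
    """Ɛ class boundaries.  Boundary values go to the lower-specialization
    class (e.g. Ɛ = generalist_max is still 'generalist')."""

    generalist_max: float = 0.34
    specialist_min: float = 0.6

    def __post_init__(self) -> None:
        if not 0 <= self.generalist_max < self.specialist_min <= 1:
            raise SpecializationError(
                "require 0 <= generalist_max < specialist_min <= 1 (non-overlapping bands)"
            )


def classify_strategy(eps: float, thresholds: StrategyThresholds | None = None) -> str:
    """Label a Ɛ value: generalist / specialist-generalist / specialist."""
    t = thresholds or StrategyThresholds()
    if not 0 <= eps <= 1 + 1e-12:
        raise SpecializationError(f"Ɛ must lie in [0, 1], got {eps!r}")
    if eps <= t.generalist_max:
        return "generalist"
    if eps <= t.specialist_min:
        return "specialist-generalist"
    return "specialist"


@dataclass
class SpecializationResult:
    """Per-unit Ɛ summaries computed from a diet posterior.

    ``per_unit`` columns: unit_type, unit_id, group, eps_mean, eps_sd,
    eps_of_mean_diet, label (classification of eps_mean).  ``draws`` maps
    unit_type -> Ɛ per flattened draw per unit, for downstream summaries.
    ``k`` is the number of sources the diets are over; comparisons across
    posteriors with different K are not meaningful and should be flagged.
    """

    per_unit: pd.DataFrame
    draws: dict[str, np.ndarray]
    k: int
    thresholds: StrategyThresholds

    def summary_by(self, key: str, groups: pd.Series | None = None) -> pd.DataFrame:
        """Mean ± SD and min/max of per-unit Ɛ means, optionally per group."""
        df = self.per_unit[self.per_unit["unit_type"] == key]
        if groups is not None:
            df = df.assign(by=df["unit_id"].map(groups))
            grouped = df.groupby("by")["eps_mean"]
        else:
            grouped = df.assign(by="all").groupby("by")["eps_mean"]
        return grouped.agg(["mean", "std", "min", "max", "count"]).reset_index()


def epsilon_posterior(
    posterior: DietPosterior, thresholds: StrategyThresholds | None = None
) -> SpecializationResult:
    """Compute Ɛ per draw for every individual and group in a posterior.

    Reports both the per-draw summary (eps_mean ± eps_sd) and Ɛ of the
    posterior-mean diet — the two differ in general (the former averages the
    index, the latter indexes the average) and both are first-class outputs.
    """
    if posterior.n_draws == 0:
        raise SpecializationError("empty posterior")
    thresholds = thresholds or StrategyThresholds()
    rows = []
    draws: dict[str, np.ndarray] = {}
    for kind, names, flat, grp in (
        ("individual", posterior.individual_ids, posterior.flat_individual(), posterior.individual_group),
        ("group", posterior.group_names, posterior.flat_group(), posterior.group_names),
    ):
        eps = epsilon_array(flat, tol=1e-6)  # (draws, units)
        draws[kind] = eps
        mean_diet = flat.mean(axis=0)
        eps_of_mean = epsilon_array(mean_diet, tol=1e-6)
        for j, name in enumerate(names):
            rows.append(
                {
                    "unit_type": kind,
                    "unit_id": name,
                    "group": grp[j],
                    "eps_mean": float(eps[:, j].mean()),
                    "eps_sd": float(eps[:, j].std(ddof=1)),
                    "eps_of_mean_diet": float(eps_of_mean[j]),
                    "label": classify_strategy(float(eps[:, j].mean()), thresholds),
                }
            )
    return SpecializationResult(
        per_unit=pd.DataFrame(rows),
        draws=draws,
        k=posterior.n_sources,
        thresholds=thresholds,
    )
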