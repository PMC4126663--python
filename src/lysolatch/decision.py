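"""Lysis/lysogeny classification of simulated trajectories.

A run is classified from the transient dynamics of a single readout, the
CII concentration: if its time average over a decision window (default the
first 60 minutes after infection) exceeds a threshold K the cell commits to
lysogeny, otherwise to lysis.  An endpoint (single-time-point) criterion is
also provided, together with the Gaussian threshold-crossing approximation

    P(lysogeny) = 1/2 (1 - erf((K - mu) / (sigma sqrt(2))))

whose argument changes sign with K - mu: ensembles with larger CII noise
cross a supra-mean threshold more often and a sub-mean threshold less often,
which is the mechanism linking multiplicity of infection to the decision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .engine import Trajectory
from .model import CII_WEIGHTS

__all__ = [
    "DecisionCriterion",
    "DecisionOutcome",
    "LysogenyEstimate",
    "cii_readout",
    "decide",
    "lysogeny_rate",
    "analytic_rate",
    "pheno_rate",
    "wilson_interval",
    "write_decision_tsv",
    "write_rate_tsv",
]


@dataclass(frozen=True)
class DecisionCriterion:
    """Threshold K, decision window (t0, t1) and readout mode."""

    threshold: float = 0.0
    window: tuple = (0.0, 60.0)
    mode: str = "time_average"  # or "single_timepoint"

    def __post_init__(self) -> None:
        t0, t1 = self.window
        if not (0 <= t0 < t1):
            raise ValueError("window must satisfy 0 <= t0 < t1")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.mode not in ("time_average", "single_timepoint"):
            raise ValueError(f"unknown decision mode {self.mode!r}")

    def with_threshold(self, K: float) -> "DecisionCriterion":
        return DecisionCriterion(threshold=K, window=self.window, mode=self.mode)


@dataclass(frozen=True)
class DecisionOutcome:
    """Per-run decision statistic and its classification."""

    statistic: float
    label: str  # "lysis" or "lysogeny"


@dataclass(frozen=True)
class LysogenyEstimate:
    """Ensemble lysogeny fraction with binomial (Wald) standard error."""

    n_runs: int
    n_lysogeny: int
    rate: float
    se: float


def cii_readout(traj: Trajectory, mode: str = "total") -> np.ndarray:
    """Per-sample CII concentration: protein equivalents / current volume.

    ``total`` counts every CII-containing species weighted by its monomer
    content (monomer 1, dimer 2, promoter-bound dimer 2, tetramer 4);
    ``free_monomer`` and ``free_dimer`` restrict to the respective free pool.
    """
    if mode == "total":
        weights = CII_WEIGHTS
    elif mode == "free_monomer":
        weights = {"CII": 1}
    elif mode == "free_dimer":
        weights = {"CII2": 1}
    else:
        raise ValueError(f"unknown readout mode {mode!r}")
    present = [sp for sp in weights if sp in traj.species]
    if not present:
        raise ValueError("trajectory contains no CII-family species")
    total = np.zeros(len(traj.times))
    for sp in present:
        total = total + weights[sp] * traj.counts[:, traj.species_index(sp)]
    return total / traj.volumes


def statistic_from_series(
    times: np.ndarray, series: np.ndarray, criterion: DecisionCriterion
) -> float:
    """Decision statistic of a readout series under the given criterion."""
    t0, t1 = criterion.window
    if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9:
        raise ValueError("decision window not contained in the trajectory span")
    if criterion.mode == "single_timepoint":
        return float(series[np.argmin(np.abs(times - t1))])
    mask = (times >= t0 - 1e-9) & (times <= t1 + 1e-9)
    if not mask.any():
        raise ValueError("empty decision window")
    return float(series[mask].mean())


def decide(
    traj: Trajectory, criterion: DecisionCriterion, readout_mode: str = "total"
) -> DecisionOutcome:
    """Classify one trajectory: lysogeny iff the statistic exceeds K.

    Ties (statistic == K) classify as lysis; with integer counts on a volume
    grid exact ties are possible, and a cell that never clears the threshold
    is lytic by definition.
    """
    series = cii_readout(traj, mode=readout_mode)
    stat = statistic_from_series(traj.times, series, criterion)
    label = "lysogeny" if stat > criterion.threshold else "lysis"
    return DecisionOutcome(statistic=stat, label=label)


def lysogeny_rate(outcomes: Sequence[DecisionOutcome]) -> LysogenyEstimate:
    """Fraction of runs classified lysogenic, with binomial standard error."""
    n = len(outcomes)
    if n < 1:
        raise ValueError("need at least one outcome")
    k = sum(1 for o in outcomes if o.label == "lysogeny")
    rate = k / n
    se = math.sqrt(rate * (1.0 - rate) / n)
    return LysogenyEstimate(n_runs=n, n_lysogeny=k, rate=rate, se=se)


def analytic_rate(mu: float, sigma: float, K: float) -> float:
    """Gaussian approximation of the lysogeny probability P(X > K)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return 1.0 if mu > K else 0.0
    return 0.5 * (1.0 - math.erf((K - mu) / (sigma * math.sqrt(2.0))))


def pheno_rate(moi: int, volume: float, K_half: float = 1.0, h: float = 2.0) -> float:
    """Phenomenological unanimous-decision lysogeny probability.

    Each of the ``moi`` phage independently "votes" for lysogeny with a Hill
    probability in the viral concentration c = moi/volume; lysogeny requires
    a unanimous vote: [c^h / (c^h + K_half^h)]^moi.
    """
    if moi < 1 or volume <= 0 or K_half <= 0 or h <= 0:
        raise ValueError("all arguments must be positive")
    c = moi / volume
    single = c**h / (c**h + K_half**h)
    return single**moi


def wilson_interval(k: int, n: int, z: float = 1.96) -> tuple:
    """Wilson score interval for a binomial fraction (useful near 0 or 1)."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n, n >= 1")
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def write_decision_tsv(outcomes: Sequence[DecisionOutcome], K: float, path) -> None:
    with open(path, "w") as fh:
        fh.write("run\tstatistic\tK\tlabel\n")
        for i, o in enumerate(outcomes):
            fh.write(f"{i}\t{o.statistic:.6g}\t{K:.6g}\t{o.label}\n")


def write_rate_tsv(rows: Iterable[tuple], path) -> None:
    """Rows of (condition, LysogenyEstimate)."""
    with open(path, "w") as fh:
        fh.write("condition\tn\tn_lysogeny\trate\tse\n")
        for label, est in rows:
            fh.write(
                f"{label}\t{est.n_runs}\t{est.n_lysogeny}\t{est.rate:.6g}\t{est.se:.6g}\n"
            )
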