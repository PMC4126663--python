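"""Synthetic time-lapse cohort emulating single-cell infection movies.

Each synthetic cell is observed at two frames — first frame and the frame
of its terminal event (division for uninfected cells, the lysis/lysogeny
commitment for infected ones).  Cells elongate exponentially; the
elongation rate decreases with the number of infecting phage, a configured
fraction of infected cells does not grow at all, and measured lengths carry
multiplicative noise.  The generator is the stand-in for the original
microscopy data: it reproduces the *structure* of those measurements
(lengths, frame times, MOI counts, fates), not any image-derived artefact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .decision import pheno_rate

__all__ = [
    "CellRecord",
    "CohortConfig",
    "generate_cohort",
    "estimate_growth_rate",
    "estimate_growth_rate_linear",
    "growth_by_moi",
    "division_time_summary",
    "cohort_to_tsv",
    "cohort_from_tsv",
]


@dataclass(frozen=True)
class CellRecord:
    """One synthetic cell: two-frame lengths, times, MOI, fate."""

    moi: int
    L0: float
    Lf: float
    t0: float
    tf: float
    true_g: float
    fate: str  # "division", "lysis" or "lysogeny"

    def __post_init__(self) -> None:
        if self.L0 <= 0 or self.Lf <= 0:
            raise ValueError("lengths must be > 0")
        if self.tf <= self.t0:
            raise ValueError("tf must exceed t0")
        if self.moi < 0:
            raise ValueError("moi must be >= 0")
        if self.fate not in ("division", "lysis", "lysogeny"):
            raise ValueError(f"unknown fate {self.fate!r}")
        if self.moi == 0 and self.fate != "division":
            raise ValueError("uninfected cells can only divide")


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for a synthetic cohort.

    ``moi_mean`` parameterises a Poisson MOI distribution truncated at
    ``moi_max`` (or pass explicit ``moi_weights``).  Growth: baseline
    elongation rate ``g0`` minus ``delta_g`` per infecting phage, floored at
    zero; infected cells are additionally non-growing with probability
    ``nongrower_base + moi * nongrower_slope``.  Measured final length is
    L0 * exp(g dt) * (1 + eps) with multiplicative noise of CV
    ``noise_cv``.  Fates follow the phenomenological unanimous-vote rate in
    the viral concentration; lysogens divide ``lysogeny_delay`` minutes
    later than the baseline cycle, and cycle lengths carry multiplicative
    variability of CV ``cycle_cv`` (septation timing is not a deterministic
    function of size).
    """

    n_cells: int = 2000
    moi_mean: float = 1.0
    moi_max: int = 5
    moi_weights: Optional[tuple] = None
    g0: float = math.log(2) / 60.0
    delta_g: float = 0.0015
    noise_cv: float = 0.05
    nongrower_base: float = 0.0
    nongrower_slope: float = 0.05
    pheno_constants: tuple = (1.0, 2.0)
    decision_time: float = 60.0
    lysogeny_delay: float = 20.0
    cycle_cv: float = 0.1
    L0_mean: float = 1.6
    L0_cv: float = 0.15
    linear_elongation: bool = False

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.g0 - self.moi_max * self.delta_g < 0:
            raise ValueError("g0 - moi_max * delta_g must be >= 0")
        if self.noise_cv < 0 or self.delta_g < 0:
            raise ValueError("noise_cv and delta_g must be >= 0")


def _moi_probs(cfg: CohortConfig) -> np.ndarray:
    if cfg.moi_weights is not None:
        w = np.asarray(cfg.moi_weights, dtype=float)
        if w.size != cfg.moi_max + 1 or (w < 0).any() or w.sum() <= 0:
            raise ValueError("moi_weights must be nonnegative over 0..moi_max")
        return w / w.sum()
    k = np.arange(cfg.moi_max + 1)
    lam = cfg.moi_mean
    logp = k * math.log(lam) - lam - np.array([math.lgamma(i + 1) for i in k])
    p = np.exp(logp)
    return p / p.sum()


def generate_cohort(config: CohortConfig, seed: int) -> list:
    """Draw a seeded synthetic cohort of :class:`CellRecord`."""
    rng = np.random.default_rng(seed)
    probs = _moi_probs(config)
    if config.cycle_cv > 0:
        s2 = math.log(1.0 + config.cycle_cv**2)
        cycle_noise = lambda: rng.lognormal(-s2 / 2.0, math.sqrt(s2))
    else:
        cycle_noise = lambda: 1.0
    records = []
    for _ in range(config.n_cells):
        moi = int(rng.choice(probs.size, p=probs))
        L0 = max(config.L0_mean * (1.0 + config.L0_cv * rng.standard_normal()), 0.2)
        g = max(config.g0 - moi * config.delta_g, 0.0)
        if moi > 0:
            p_ng = min(config.nongrower_base + moi * config.nongrower_slope, 1.0)
            if rng.random() < p_ng:
                g = 0.0
        if moi == 0:
            fate = "division"
            dt = math.log(2) / config.g0 * cycle_noise()
        else:
            K_half, h = config.pheno_constants
            p_lys = pheno_rate(moi, L0 / config.L0_mean, K_half, h)
            if rng.random() < p_lys:
                fate = "lysogeny"
                dt = math.log(2) / config.g0 * cycle_noise() + config.lysogeny_delay
            else:
                fate = "lysis"
                dt = config.decision_time
        if config.linear_elongation:
            Lf_true = L0 * (1.0 + g * dt)
        else:
            Lf_true = L0 * math.exp(g * dt)
        eps = config.noise_cv * rng.standard_normal()
        Lf = max(Lf_true * (1.0 + eps), 0.05)
        records.append(
            CellRecord(moi=moi, L0=L0, Lf=Lf, t0=0.0, tf=dt, true_g=g, fate=fate)
        )
    return records


def estimate_growth_rate(L0: float, Lf: float, delta_t: float) -> float:
    """Exponential-elongation estimator: ln(Lf / L0) / delta_t."""
    if L0 <= 0 or Lf <= 0:
        raise ValueError("lengths must be > 0")
    if delta_t <= 0:
        raise ValueError("delta_t must be > 0")
    return math.log(Lf / L0) / delta_t


def estimate_growth_rate_linear(L0: float, Lf: float, delta_t: float) -> float:
    """Linear-elongation alternative: (Lf - L0) / (L0 * delta_t)."""
    if L0 <= 0 or Lf <= 0:
        raise ValueError("lengths must be > 0")
    if delta_t <= 0:
        raise ValueError("delta_t must be > 0")
    return (Lf - L0) / (L0 * delta_t)


def growth_by_moi(records: Sequence[CellRecord]) -> pd.DataFrame:
    """Per-MOI mean estimated elongation rate, non-growers removed.

    A cell is excluded as a non-grower if it is flagged as such in the
    record (``true_g == 0``, the stand-in for cells visually classified as
    non-growing) or if its estimated rate is <= 0.
    """
    rows = []
    for r in records:
        if r.true_g == 0:
            continue
        g_hat = estimate_growth_rate(r.L0, r.Lf, r.tf - r.t0)
        if g_hat > 0:
            rows.append((r.moi, g_hat))
    if not rows:
        return pd.DataFrame(columns=["moi", "n", "mean_g", "se"])
    df = pd.DataFrame(rows, columns=["moi", "g_hat"])
    out = (
        df.groupby("moi")["g_hat"]
        .agg(n="size", mean_g="mean", se=lambda x: x.std(ddof=1) / np.sqrt(len(x)))
        .reset_index()
    )
    return out


def division_time_summary(records: Sequence[CellRecord]) -> pd.DataFrame:
    """Observation spans by group: uninfected dividers vs infected lysogens."""
    groups = {"uninfected": [], "lysogeny": []}
    for r in records:
        if r.moi == 0 and r.fate == "division":
            groups["uninfected"].append(r.tf - r.t0)
        elif r.moi >= 1 and r.fate == "lysogeny":
            groups["lysogeny"].append(r.tf - r.t0)
    rows = []
    for name, vals in groups.items():
        if not vals:
            continue
        arr = np.asarray(vals)
        se = arr.std(ddof=1) / math.sqrt(arr.size) if arr.size > 1 else 0.0
        rows.append(dict(group=name, n=arr.size, mean_time=arr.mean(), se=se))
    return pd.DataFrame(rows)


def cohort_to_tsv(records: Sequence[CellRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("moi\tL0\tLf\tt0\ttf\ttrue_g\tfate\n")
        for r in records:
            fh.write(
                f"{r.moi}\t{r.L0:.6g}\t{r.Lf:.6g}\t{r.t0:g}\t{r.tf:.6g}\t"
                f"{r.true_g:.6g}\t{r.fate}\n"
            )


def cohort_from_tsv(path) -> list:
    records = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            moi, L0, Lf, t0, tf, g, fate = line.rstrip("\n").split("\t")
            records.append(
                CellRecord(
                    moi=int(moi), L0=float(L0), Lf=float(Lf), t0=float(t0),
                    tf=float(tf), true_g=float(g), fate=fate,
                )
            )
    return records
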