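"""Random-effects pooling of relative risks across comparative studies.

The pooled SUAVR-vs-CAVR relative risk for each 30-day or 1-year outcome is
estimated with the DerSimonian–Laird method-of-moments estimator and applied
multiplicatively to the baseline (CAVR) probability, clamped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import MissingInputError, ValidationError


@dataclass(frozen=True)
class StudyArmCounts:
    """2x2 event counts for one study (treated = SUAVR, control = CAVR)."""

    events_trt: int
    n_trt: int
    events_ctl: int
    n_ctl: int

    def __post_init__(self) -> None:
        for e, n, label in (
            (self.events_trt, self.n_trt, "treated"),
            (self.events_ctl, self.n_ctl, "control"),
        ):
            if n <= 0:
                raise ValidationError(f"{label} arm size must be positive")
            if not 0 <= e <= n:
                raise ValidationError(f"{label} events {e} outside [0, {n}]")


@dataclass(frozen=True)
class StudyEffect:
    log_rr: float
    se_log_rr: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.se_log_rr) and self.se_log_rr > 0):
            raise ValidationError(f"se_log_rr must be finite positive, got {self.se_log_rr}")


@dataclass(frozen=True)
class PooledRR:
    rr: float
    ci_low: float
    ci_high: float
    tau2: float
    q_stat: float
    k: int


def study_log_rr(counts: StudyArmCounts, continuity: float = 0.5) -> StudyEffect:
    """Log relative risk and its delta-method standard error for one study.

    If either event cell is zero, ``continuity`` is added to all four cells
    (events and denominators of both arms) before computation.
    """
    e_t, n_t = float(counts.events_trt), float(counts.n_trt)
    e_c, n_c = float(counts.events_ctl), float(counts.n_ctl)
    if e_t == 0.0 or e_c == 0.0:
        e_t += continuity
        e_c += continuity
        n_t += continuity
        n_c += continuity
    log_rr = math.log((e_t / n_t) / (e_c / n_c))
    se = math.sqrt(1.0 / e_t - 1.0 / n_t + 1.0 / e_c - 1.0 / n_c)
    return StudyEffect(log_rr=log_rr, se_log_rr=se)


def pool_dl(effects: Sequence[StudyEffect]) -> PooledRR:
    """DerSimonian–Laird random-effects pooling on the log-RR scale.

    Fixed-effect weights w_i = 1/se_i^2 give Cochran's Q; the between-study
    variance is tau^2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w)));
    random-effects weights 1/(se_i^2 + tau^2) give the pooled estimate and a
    normal-theory 95% CI, exponentiated back to the RR scale.
    """
    k = len(effects)
    if k == 0:
        raise MissingInputError("pool_dl requires at least one study")
    w = [1.0 / (e.se_log_rr**2) for e in effects]
    y = [e.log_rr for e in effects]
    sw = sum(w)
    y_fe = sum(wi * yi for wi, yi in zip(w, y)) / sw
    q = sum(wi * (yi - y_fe) ** 2 for wi, yi in zip(w, y))
    if k == 1:
        tau2 = 0.0
    else:
        denom = sw - sum(wi * wi for wi in w) / sw
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_re = [1.0 / (e.se_log_rr**2 + tau2) for e in effects]
    sw_re = sum(w_re)
    y_re = sum(wi * yi for wi, yi in zip(w_re, y)) / sw_re
    se_re = math.sqrt(1.0 / sw_re)
    z = 1.959963984540054  # Phi^-1(0.975)
    return PooledRR(
        rr=math.exp(y_re),
        ci_low=math.exp(y_re - z * se_re),
        ci_high=math.exp(y_re + z * se_re),
        tau2=tau2,
        q_stat=q,
        k=k,
    )


def adjust_probability(p_base: float, rr: float) -> float:
    """Apply a pooled RR to a baseline probability, clamped into [0, 1]."""
    if p_base < 0.0 or p_base > 1.0:
        raise ValidationError(f"baseline probability {p_base} outside [0, 1]")
    if rr < 0.0:
        raise ValidationError(f"relative risk must be nonnegative, got {rr}")
    return min(1.0, p_base * rr)


def read_study_table(path: Path | str) -> pd.DataFrame:
    """Read a study-level CSV {study, design, events_trt, n_trt, events_ctl, n_ctl, outcome}."""
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"study table not found: {path}")
    df = pd.read_csv(path)
    required = {"study", "events_trt", "n_trt", "events_ctl", "n_ctl", "outcome"}
    missing = required - set(df.columns)
    if missing:
        raise MissingInputError(f"study table missing columns {sorted(missing)}")
    return df


def pool_outcome(df: pd.DataFrame, outcome: str) -> PooledRR:
    """Pool every study row for one outcome label."""
    sub = df[df["outcome"] == outcome]
    if sub.empty:
        raise MissingInputError(f"no studies for outcome {outcome!r}")
    effects = [
        study_log_rr(
            StudyArmCounts(
                events_trt=int(r.events_trt),
                n_trt=int(r.n_trt),
                events_ctl=int(r.events_ctl),
                n_ctl=int(r.n_ctl),
            )
        )
        for r in sub.itertuples()
    ]
    return pool_dl(effects)
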