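"""Evaluation of a selected screening panel against wet-lab outcomes,
random-selection baselines, and grid-search tuning of the scoring
weights.

Hit rates are computed at two conversion cutoffs: a permissive 2%
cutoff ("any activity") and a demanding 50% cutoff ("competent hit").
The random baseline answers the question a bench scientist would ask —
how often would a randomly chosen sub-panel of the same size have done
as well — both analytically (hypergeometric closed form for best-hit
retrieval) and by Monte-Carlo resampling.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import ActiveSiteProfile, ScoringWeights

__all__ = [
    "ScreeningOutcome",
    "EvaluationConfig",
    "TuningGrid",
    "EvaluationReport",
    "RandomBaseline",
    "CalibrationRecord",
    "hit_rate",
    "best_hit_retrieval",
    "retrieval_probability",
    "random_baseline",
    "tune_weights",
    "evaluate_panel",
    "read_outcomes_csv",
    "write_outcomes_csv",
    "read_calibration_csv",
    "write_calibration_csv",
]


@dataclass(frozen=True)
class ScreeningOutcome:
    """Measured product conversion (%) for one screened sequence."""

    sequence_id: str
    conversion: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.conversion <= 100.0:
            raise ValueError(
                f"{self.sequence_id}: conversion must be in [0, 100]"
            )


@dataclass(frozen=True)
class EvaluationConfig:
    panel_size: int = 20
    low_cutoff: float = 2.0
    high_cutoff: float = 50.0
    n_draws: int = 10_000
    seed: int | None = None
    ci_multiplier: float = 1.96

    def __post_init__(self) -> None:
        for name in ("low_cutoff", "high_cutoff"):
            if not 0.0 <= getattr(self, name) <= 100.0:
                raise ValueError(f"{name} must be in [0, 100]")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass(frozen=True)
class TuningGrid:
    """Integer-spaced search grid for the scoring weights."""

    lo: float = -10.0
    hi: float = 10.0
    step: float = 1.0
    tuned_weights: tuple[str, ...] = (
        "w_vina", "w_acidic", "w_his", "w_basic",
    )

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("grid lo must be <= hi")
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        valid = {"w_vina", "w_acidic", "w_his", "w_basic"}
        if not set(self.tuned_weights) <= valid or not self.tuned_weights:
            raise ValueError(f"tuned_weights must be a nonempty subset of "
                             f"{sorted(valid)}")

    def values(self) -> np.ndarray:
        n = int(math.floor((self.hi - self.lo) / self.step + 1e-9)) + 1
        return self.lo + self.step * np.arange(n)


@dataclass(frozen=True)
class RandomBaseline:
    mean: float
    sem: float
    ci95: tuple[float, float]
    retrieval_frequency: float


@dataclass(frozen=True)
class EvaluationReport:
    hit_rate_low: float
    hit_rate_high: float
    best_hit_retrieved: bool
    random_mean: float
    random_sem: float
    random_ci95: tuple[float, float]
    retrieval_probability: float


@dataclass(frozen=True)
class CalibrationRecord:
    """One candidate's docking score, active-site profile and measured
    conversion — a row of the weight-tuning table."""

    sequence_id: str
    vina_score: float
    profile: ActiveSiteProfile
    conversion: float


def _conversion_map(
    outcomes: Sequence[ScreeningOutcome],
) -> dict[str, float]:
    return {o.sequence_id: o.conversion for o in outcomes}


def hit_rate(
    selected: Sequence[str],
    outcomes: Sequence[ScreeningOutcome],
    cutoff: float,
) -> float:
    """Fraction of selected sequences with conversion >= cutoff."""
    if not selected:
        raise ValueError("empty selection")
    conv = _conversion_map(outcomes)
    unknown = [s for s in selected if s not in conv]
    if unknown:
        raise ValueError(f"selected ids without outcomes: {unknown}")
    hits = sum(1 for s in selected if conv[s] >= cutoff)
    return hits / len(selected)


def best_hit_retrieval(
    selected: Sequence[str], outcomes: Sequence[ScreeningOutcome]
) -> bool:
    """True iff any sequence attaining the panel's maximum conversion is
    in the selection (ties: any tied-best counts)."""
    if not outcomes:
        raise ValueError("empty outcomes")
    best = max(o.conversion for o in outcomes)
    best_ids = {o.sequence_id for o in outcomes if o.conversion == best}
    return bool(best_ids & set(selected))


def retrieval_probability(panel_size_total: int, k: int, n_best: int) -> float:
    """Probability a uniform random k-subset of N sequences contains at
    least one of the m tied-best: 1 - C(N-m, k)/C(N, k).

    Reduces to k/N when the best hit is unique (m = 1).
    """
    N, m = panel_size_total, n_best
    if not 1 <= m <= N:
        raise ValueError("require 1 <= n_best <= panel_size_total")
    if not 0 <= k <= N:
        raise ValueError("require 0 <= k <= panel_size_total")
    if k > N - m:
        return 1.0
    return 1.0 - math.comb(N - m, k) / math.comb(N, k)


def random_baseline(
    outcomes: Sequence[ScreeningOutcome],
    cfg: EvaluationConfig,
    cutoff: float | None = None,
) -> RandomBaseline:
    """Monte-Carlo baseline: hit rate and best-hit retrieval of uniform
    random sub-panels of ``cfg.panel_size`` sequences.

    The confidence band is mean ± ci_multiplier × SEM over the draws,
    clipped to [0, 1].
    """
    if cfg.seed is None:
        raise ValueError("random_baseline requires an explicit seed")
    N, k = len(outcomes), cfg.panel_size
    if N < k:
        raise ValueError(f"panel ({N}) smaller than selection size ({k})")
    if cutoff is None:
        cutoff = cfg.low_cutoff
    conv = np.array([o.conversion for o in outcomes], dtype=float)
    is_hit = conv >= cutoff
    best = conv.max()
    is_best = conv == best
    rng = np.random.default_rng(cfg.seed)
    rates = np.empty(cfg.n_draws)
    retrieved = np.empty(cfg.n_draws, dtype=bool)
    for i in range(cfg.n_draws):
        idx = rng.choice(N, size=k, replace=False)
        rates[i] = is_hit[idx].mean()
        retrieved[i] = bool(is_best[idx].any())
    mean = float(rates.mean())
    sem = float(rates.std(ddof=1) / math.sqrt(cfg.n_draws)) if cfg.n_draws > 1 else 0.0
    lo = max(0.0, mean - cfg.ci_multiplier * sem)
    hi = min(1.0, mean + cfg.ci_multiplier * sem)
    return RandomBaseline(
        mean=mean,
        sem=sem,
        ci95=(lo, hi),
        retrieval_frequency=float(retrieved.mean()),
    )


def evaluate_panel(
    selected: Sequence[str],
    outcomes: Sequence[ScreeningOutcome],
    cfg: EvaluationConfig,
) -> EvaluationReport:
    """Hit rates at both cutoffs, best-hit retrieval, and the random
    baseline (Monte-Carlo at the low cutoff, analytic retrieval)."""
    baseline = random_baseline(outcomes, cfg, cutoff=cfg.low_cutoff)
    best = max(o.conversion for o in outcomes)
    n_best = sum(1 for o in outcomes if o.conversion == best)
    return EvaluationReport(
        hit_rate_low=hit_rate(selected, outcomes, cfg.low_cutoff),
        hit_rate_high=hit_rate(selected, outcomes, cfg.high_cutoff),
        best_hit_retrieved=best_hit_retrieval(selected, outcomes),
        random_mean=baseline.mean,
        random_sem=baseline.sem,
        random_ci95=baseline.ci95,
        retrieval_probability=retrieval_probability(
            len(outcomes), cfg.panel_size, n_best
        ),
    )


def _panel_hit_rates(
    scores: np.ndarray,
    conversions: np.ndarray,
    k: int,
    low_cutoff: float,
    high_cutoff: float,
    order_ids: np.ndarray,
) -> tuple[float, float]:
    """Hit rates of the top-k by ascending score, with the full ranking
    tie-break (score, then sequence id)."""
    order = np.lexsort((order_ids, scores))
    top = order[:k]
    return (
        float((conversions[top] >= high_cutoff).mean()),
        float((conversions[top] >= low_cutoff).mean()),
    )


def tune_weights(
    calibration: Sequence[CalibrationRecord],
    grid: TuningGrid = TuningGrid(),
    cfg: EvaluationConfig = EvaluationConfig(),
) -> ScoringWeights:
    """Exhaustive grid search for the scoring weights.

    Each grid point ranks the calibration set by its refined score and
    is judged by the hit rate at the high (50%) cutoff within the top
    ``panel_size``; ties break toward the higher low-cutoff hit rate,
    then the smallest L1 norm of the weight vector, then lexicographic
    weight order. Weights not listed in ``grid.tuned_weights`` stay at
    their defaults.
    """
    if len(calibration) <= cfg.panel_size:
        raise ValueError("calibration set must exceed the panel size")
    values = grid.values()
    if len(values) == 0:
        raise ValueError("empty tuning grid")
    defaults = ScoringWeights()
    names = ("w_vina", "w_acidic", "w_his", "w_basic")
    axes = [
        values if n in grid.tuned_weights else np.array([getattr(defaults, n)])
        for n in names
    ]
    # feature matrix: refined = X @ (w_vina, w_acidic, w_his, w_basic)
    X = np.array(
        [
            (r.vina_score, r.profile.n_acidic, -r.profile.n_his,
             r.profile.n_basic)
            for r in calibration
        ],
        dtype=float,
    )
    conversions = np.array([r.conversion for r in calibration], dtype=float)
    ids = np.array([r.sequence_id for r in calibration])
    order_ids = np.argsort(np.argsort(ids))  # lexicographic rank of each id

    best_key: tuple | None = None
    best_w: tuple[float, float, float, float] | None = None
    for w in itertools.product(*axes):
        scores = X @ np.asarray(w)
        hi_rate, lo_rate = _panel_hit_rates(
            scores, conversions, cfg.panel_size,
            cfg.low_cutoff, cfg.high_cutoff, order_ids,
        )
        key = (-hi_rate, -lo_rate, sum(abs(v) for v in w), w)
        if best_key is None or key < best_key:
            best_key, best_w = key, w
    assert best_w is not None
    return ScoringWeights(*best_w)


# ---------------------------------------------------------------------------
# Tabular I/O

def read_outcomes_csv(path: str | Path) -> list[ScreeningOutcome]:
    df = pd.read_csv(path)
    missing = {"sequence_id", "conversion"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        ScreeningOutcome(str(r.sequence_id), float(r.conversion))
        for r in df.itertuples()
    ]


def write_outcomes_csv(
    outcomes: Sequence[ScreeningOutcome], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "sequence_id": [o.sequence_id for o in outcomes],
            "conversion": [o.conversion for o in outcomes],
        }
    ).to_csv(path, index=False)


def read_calibration_csv(path: str | Path) -> list[CalibrationRecord]:
    df = pd.read_csv(path)
    required = {
        "sequence_id", "vina_score", "n_acidic", "n_basic", "n_his",
        "conversion",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        CalibrationRecord(
            sequence_id=str(r.sequence_id),
            vina_score=float(r.vina_score),
            profile=ActiveSiteProfile(
                n_acidic=int(r.n_acidic),
                n_basic=int(r.n_basic),
                n_his=int(r.n_his),
            ),
            conversion=float(r.conversion),
        )
        for r in df.itertuples()
    ]


def write_calibration_csv(
    records: Sequence[CalibrationRecord], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "sequence_id": [r.sequence_id for r in records],
            "vina_score": [r.vina_score for r in records],
            "n_acidic": [r.profile.n_acidic for r in records],
            "n_basic": [r.profile.n_basic for r in records],
            "n_his": [r.profile.n_his for r in records],
            "conversion": [r.conversion for r in records],
        }
    ).to_csv(path, index=False)
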