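"""Test–retest variability thresholds from linear quantile regression.

Short-term repeat tests (all within a 4-month window, assumed free of true
change) are turned into (baseline, follow-up) pairs per metric: the first
test in the window is the independent variable and every subsequent
in-window test forms a dependent observation.  A linear quantile line

    q_tau(followup | baseline) = intercept + slope * baseline

is then fitted by minimizing the pinball (check) loss

    rho_tau(u) = u * (tau - 1[u < 0]),   u = y - a - b x,

cast as a linear program and solved exactly with HiGHS.  ``tau`` always
names the *worsening-tail* probability: for metrics that fall with damage
the lower tau-quantile is fitted, while for PSD (which rises with damage)
the upper tail is used by fitting 1 - tau.  The ``paper_literal`` switch
forces the lower tail for every metric.

An eye is later called a statistical progressor when its follow-up value
lies strictly beyond the fitted line evaluated at its baseline value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .cohort import CohortDataset
from .metrics import Direction, get_metric

DEFAULT_WINDOW_DAYS = 120
DEFAULT_MIN_PAIRS = 20
DEFAULT_TAUS = (0.05, 0.025)


@dataclass(frozen=True)
class Pair:
    baseline: float
    followup: float
    eye_id: str
    dt_days: int


@dataclass
class PairSet:
    """All test–retest pairs of one metric within the short-term window."""

    metric: str
    pairs: list[Pair]
    window_days: int = DEFAULT_WINDOW_DAYS

    def __len__(self) -> int:
        return len(self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.array([p.baseline for p in self.pairs], dtype=float)
        y = np.array([p.followup for p in self.pairs], dtype=float)
        return x, y


@dataclass
class ThresholdModel:
    """A fitted quantile line mapping baseline value to event cutoff."""

    metric: str
    tau: float                 # worsening-tail probability
    intercept: float
    slope: float
    n_pairs: int
    intercept_only: bool = False

    def threshold_at(self, baseline_value: float) -> float:
        return self.intercept + self.slope * baseline_value


def build_pairs(
    cohort: CohortDataset,
    metric: str,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> PairSet:
    """Construct (first test, each later in-window test) pairs for one metric.

    For each eye the first non-missing test opens the window; every further
    non-missing test within ``window_days`` of it contributes one pair.
    Eyes with fewer than two in-window tests contribute nothing.
    """
    get_metric(metric)
    pairs: list[Pair] = []
    for eye in cohort:
        tests = eye.metric_tests(metric)
        if len(tests) < 2:
            continue
        d0, v0 = tests[0]
        for d, v in tests[1:]:
            dt_days = (d - d0).days
            if dt_days <= window_days:
                pairs.append(Pair(v0, v, eye.eye_id, dt_days))
    return PairSet(metric, pairs, window_days)


def _pinball_loss(x: np.ndarray, y: np.ndarray, a: float, b: float, tau: float) -> float:
    u = y - a - b * x
    return float(np.sum(u * (tau - (u < 0))))


def _fit_pinball_lp(x: np.ndarray, y: np.ndarray, tau: float) -> tuple[float, float]:
    """Exact pinball-loss minimizer via LP (variables: a±, b±, residual splits)."""
    n = len(y)
    # columns: a+, a-, b+, b-, u+ (n), u- (n)
    c = np.concatenate([[0.0, 0.0, 0.0, 0.0], np.full(n, tau), np.full(n, 1.0 - tau)])
    ones = np.ones(n)
    A = sparse.hstack(
        [
            sparse.csc_matrix(ones.reshape(-1, 1)),
            sparse.csc_matrix(-ones.reshape(-1, 1)),
            sparse.csc_matrix(x.reshape(-1, 1)),
            sparse.csc_matrix(-x.reshape(-1, 1)),
            sparse.eye(n, format="csc"),
            -sparse.eye(n, format="csc"),
        ],
        format="csc",
    )
    res = linprog(c, A_eq=A, b_eq=y, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - HiGHS is robust on these LPs
        raise RuntimeError(f"quantile LP failed: {res.message}")
    a = res.x[0] - res.x[1]
    b = res.x[2] - res.x[3]
    return float(a), float(b)


def fit_quantile_line(
    pairs: PairSet,
    tau: float,
    *,
    paper_literal: bool = False,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> ThresholdModel:
    """Fit the tau worsening-tail quantile line for one metric's pair set.

    ``tau`` must lie in (0, 0.5]; for increase-worsening metrics the line is
    fitted at probability ``1 - tau`` (upper tail) unless ``paper_literal``.
    Degenerate baselines (zero variance) fall back to an intercept-only
    empirical quantile with a warning.
    """
    if not 0.0 < tau <= 0.5:
        raise ValueError(f"tau must be in (0, 0.5], got {tau}")
    if len(pairs) < min_pairs:
        raise ValueError(
            f"{pairs.metric}: {len(pairs)} pairs < required minimum {min_pairs}"
        )
    direction = get_metric(pairs.metric).direction
    eff_tau = tau if (direction == Direction.DECREASE or paper_literal) else 1.0 - tau
    x, y = pairs.arrays()
    if np.ptp(x) < 1e-12:
        warnings.warn(
            f"{pairs.metric}: degenerate baseline values; fitting intercept-only model",
            stacklevel=2,
        )
        q = float(np.quantile(y, eff_tau, method="inverted_cdf"))
        return ThresholdModel(pairs.metric, tau, q, 0.0, len(pairs), intercept_only=True)
    a, b = _fit_pinball_lp(x, y, eff_tau)
    return ThresholdModel(pairs.metric, tau, a, b, len(pairs))


def threshold_at(model: ThresholdModel, baseline_value: float) -> float:
    """Event cutoff at a given baseline value (intercept + slope * baseline)."""
    return model.threshold_at(baseline_value)


class ThresholdBank:
    """Complete map of (metric, tau) -> fitted :class:`ThresholdModel`."""

    def __init__(self, models: dict[tuple[str, float], ThresholdModel]):
        self._models = dict(models)

    def get(self, metric: str, tau: float) -> ThresholdModel:
        key = (metric, tau)
        if key not in self._models:
            raise KeyError(f"no threshold model for metric={metric!r}, tau={tau}")
        return self._models[key]

    def __contains__(self, key: tuple[str, float]) -> bool:
        return key in self._models

    def __len__(self) -> int:
        return len(self._models)

    def items(self):
        return self._models.items()

    @classmethod
    def fit(
        cls,
        retest_cohort: CohortDataset,
        metrics: Iterable[str] | None = None,
        taus: Sequence[float] = DEFAULT_TAUS,
        *,
        window_days: int = DEFAULT_WINDOW_DAYS,
        min_pairs: int = DEFAULT_MIN_PAIRS,
        paper_literal: bool = False,
    ) -> "ThresholdBank":
        """Fit one quantile line per requested metric and tau level."""
        from .metrics import metric_names

        names = list(metrics) if metrics is not None else metric_names()
        models = {}
        for m in names:
            ps = build_pairs(retest_cohort, m, window_days)
            for tau in taus:
                models[(m, tau)] = fit_quantile_line(
                    ps, tau, paper_literal=paper_literal, min_pairs=min_pairs
                )
        return cls(models)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "metric": m.metric,
                "tau": m.tau,
                "intercept": m.intercept,
                "slope": m.slope,
                "n_pairs": m.n_pairs,
                "intercept_only": m.intercept_only,
            }
            for m in self._models.values()
        ]
        return pd.DataFrame(
            rows, columns=["metric", "tau", "intercept", "slope", "n_pairs", "intercept_only"]
        )

    def to_csv(self, dest) -> None:
        self.to_frame().to_csv(dest, index=False)

    @classmethod
    def from_csv(cls, source) -> "ThresholdBank":
        df = pd.read_csv(source)
        models = {}
        for row in df.itertuples(index=False):
            m = ThresholdModel(
                metric=str(row.metric),
                tau=float(row.tau),
                intercept=float(row.intercept),
                slope=float(row.slope),
                n_pairs=int(row.n_pairs),
                intercept_only=bool(row.intercept_only),
            )
            models[(m.metric, m.tau)] = m
        return cls(models)

    def check_crossing(self, baseline_range: tuple[float, float]) -> list[str]:
        """Warn (and report) metrics whose tau-lines cross inside a baseline range.

        With non-crossing lines, the stricter 2.5th-percentile flags are a
        subset of the 5th-percentile flags.
        """
        crossed = []
        by_metric: dict[str, list[ThresholdModel]] = {}
        for (m, _), model in self._models.items():
            by_metric.setdefault(m, []).append(model)
        lo, hi = baseline_range
        for m, models in by_metric.items():
            models = sorted(models, key=lambda t: t.tau)
            for inner, outer in zip(models, models[1:]):
                # inner tau < outer tau: inner line must stay beyond outer's.
                direction = get_metric(m).direction
                sgn = 1.0 if direction == Direction.DECREASE else -1.0
                for b in (lo, hi):
                    if sgn * (outer.threshold_at(b) - inner.threshold_at(b)) < 0:
                        crossed.append(m)
                        warnings.warn(
                            f"{m}: quantile lines tau={inner.tau}/{outer.tau} cross "
                            f"within baseline range {baseline_range}",
                            stacklevel=2,
                        )
                        break
        return crossed
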