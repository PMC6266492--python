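"""GM(1,1) grey forecasting for short, positive annual series.

The GM(1,1) model smooths a short positive series x⁽⁰⁾(1..n) through the
accumulated generating operation (AGO, the running sum x⁽¹⁾) and models the
accumulated series with the first-order grey differential equation

    dx⁽¹⁾/dt + a·x⁽¹⁾ = u

whose discretisation over unit steps uses the background value
z⁽¹⁾(k) = ½·(x⁽¹⁾(k) + x⁽¹⁾(k−1)):

    x⁽⁰⁾(k) = −a·z⁽¹⁾(k) + u ,   k = 2..n.

The development coefficient ``a`` and endogenous control coefficient ``u``
are estimated by ordinary least squares on these n−1 equations.  The time
response, anchored at the first observation, is

    x̂⁽¹⁾(t+1) = (x⁽⁰⁾(1) − u/a)·e^(−a·t) + u/a ,   t = 0, 1, ...

and original-scale values are restored by first differences (inverse AGO).
For t ≥ 1 the restored values form a geometric sequence with ratio e^(−a),
so the model suits series with a roughly exponential drift — the typical use
case being 4–10 annual observations where classical time-series models
cannot be identified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import DomainError, FitError

#: |a| below this fits the flat-series limit x̂⁽⁰⁾ ≡ u instead of the
#: exponential response (which degenerates as u/a blows up).
DEGENERACY_THRESHOLD = 1e-10

#: Grade ladder on the mean relative error, boundary inclusive.
DEFAULT_GRADE_THRESHOLDS: Tuple[Tuple[float, str], ...] = (
    (0.01, "excellent"),
    (0.03, "good"),
    (0.05, "qualified"),
)


@dataclass(frozen=True)
class GreySeries:
    """A labelled positive series, e.g. annual per-capita indicators."""

    labels: Tuple[int, ...]
    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise DomainError(
                f"labels ({len(self.labels)}) and values ({len(self.values)}) "
                "differ in length"
            )
        if len(self.values) == 0:
            raise DomainError("series is empty")

    @classmethod
    def from_arrays(cls, labels: Sequence[int], values: Sequence[float]) -> "GreySeries":
        return cls(tuple(int(x) for x in labels),
                   tuple(float(v) for v in values))

    def __len__(self) -> int:
        return len(self.values)


def ago(values: Sequence[float]) -> np.ndarray:
    """Accumulated generating operation: x⁽¹⁾(k) = Σ_{i≤k} x⁽⁰⁾(i)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DomainError("cannot accumulate an empty series")
    return np.cumsum(arr)


def iago(cumulative: Sequence[float]) -> np.ndarray:
    """Inverse AGO: first differences with the first value kept."""
    arr = np.asarray(cumulative, dtype=float)
    if arr.size == 0:
        raise DomainError("cannot difference an empty series")
    return np.diff(arr, prepend=0.0)


def background_sequence(
    cumulative: Sequence[float], weight: float = 0.5
) -> np.ndarray:
    """Background values z⁽¹⁾(k) = w·x⁽¹⁾(k) + (1−w)·x⁽¹⁾(k−1), k = 2..n."""
    if not (0.0 <= weight <= 1.0):
        raise DomainError(f"background weight must lie in [0, 1], got {weight}")
    arr = np.asarray(cumulative, dtype=float)
    if arr.size < 2:
        raise DomainError("background sequence needs at least 2 points")
    return weight * arr[1:] + (1.0 - weight) * arr[:-1]


@dataclass
class GM11Fit:
    """Fitted GM(1,1) model.

    ``restored`` are the in-sample fitted values on the original scale;
    ``restored[0]`` equals the first observation by the anchoring convention.
    """

    a: float
    u: float
    initial_value: float
    labels: Tuple[int, ...]
    observed: np.ndarray
    fitted_cumulative: np.ndarray
    restored: np.ndarray
    background_weight: float = 0.5
    degenerate: bool = False

    @property
    def asymptote(self) -> float:
        """u/a — the level the accumulated series approaches (a > 0)."""
        if self.degenerate:
            return float("nan")
        return self.u / self.a

    @property
    def amplitude(self) -> float:
        """x⁽⁰⁾(1) − u/a, the coefficient of the exponential term."""
        if self.degenerate:
            return float("nan")
        return self.initial_value - self.u / self.a

    @property
    def residuals(self) -> np.ndarray:
        return self.observed - self.restored

    @property
    def relative_errors(self) -> np.ndarray:
        """|x⁽⁰⁾(k) − x̂⁽⁰⁾(k)| / x⁽⁰⁾(k) for k = 2..n."""
        return np.abs(self.residuals[1:]) / self.observed[1:]

    @property
    def mean_relative_error(self) -> float:
        return float(np.mean(self.relative_errors))

    def to_dict(self) -> dict:
        rep = accuracy_report(self)
        return {
            "a": self.a,
            "u": self.u,
            "initial_value": self.initial_value,
            "asymptote": None if self.degenerate else self.asymptote,
            "amplitude": None if self.degenerate else self.amplitude,
            "background_weight": self.background_weight,
            "degenerate": self.degenerate,
            "years": list(self.labels),
            "observed": [float(v) for v in self.observed],
            "fitted": [float(v) for v in self.fitted_cumulative],
            "restored": [float(v) for v in self.restored],
            "mre": rep.mean_relative_error,
            "grade": rep.grade,
        }


def _time_response(
    a: float, u: float, x1: float, n_points: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Cumulative and restored model values at k = 1..n_points."""
    t = np.arange(n_points, dtype=float)  # t = k - 1
    cumulative = (x1 - u / a) * np.exp(-a * t) + u / a
    restored = np.empty(n_points)
    restored[0] = x1
    restored[1:] = np.diff(cumulative)
    return cumulative, restored


def fit_gm11(
    series: GreySeries,
    background_weight: float = 0.5,
    degeneracy_threshold: float = DEGENERACY_THRESHOLD,
) -> GM11Fit:
    """Estimate (a, u) by least squares and build the time response.

    Requires n >= 4 strictly positive observations.  When the estimated
    development coefficient is numerically zero the flat-series limit is
    returned (``degenerate=True``), with all restored values after the first
    equal to ``u``.
    """
    x0 = np.asarray(series.values, dtype=float)
    n = x0.size
    if n < 4:
        raise DomainError(f"GM(1,1) needs at least 4 observations, got {n}")
    if np.any(x0 <= 0):
        raise DomainError("GM(1,1) requires strictly positive values")

    x1 = ago(x0)
    z = background_sequence(x1, weight=background_weight)
    design = np.column_stack([-z, np.ones_like(z)])
    solution, _, rank, _ = np.linalg.lstsq(design, x0[1:], rcond=None)
    if rank < 2:
        raise FitError("singular normal equations in GM(1,1) fit")
    a, u = float(solution[0]), float(solution[1])

    if abs(a) < degeneracy_threshold:
        cumulative = x0[0] + u * np.arange(n, dtype=float)
        restored = np.full(n, u)
        restored[0] = x0[0]
        return GM11Fit(
            a=a, u=u, initial_value=float(x0[0]), labels=series.labels,
            observed=x0, fitted_cumulative=cumulative, restored=restored,
            background_weight=background_weight, degenerate=True,
        )

    cumulative, restored = _time_response(a, u, float(x0[0]), n)
    return GM11Fit(
        a=a, u=u, initial_value=float(x0[0]), labels=series.labels,
        observed=x0, fitted_cumulative=cumulative, restored=restored,
        background_weight=background_weight, degenerate=False,
    )


def forecast(fit: GM11Fit, steps: int) -> np.ndarray:
    """Restored out-of-sample values x̂⁽⁰⁾(n+1 .. n+steps).

    With n observations at years Y₁..Yₙ the first forecast step is year
    Yₙ₊₁ (time index t = n in the response function).
    """
    if steps < 1:
        raise DomainError(f"steps must be >= 1, got {steps}")
    n = fit.observed.size
    if fit.degenerate:
        return np.full(steps, fit.u)
    cumulative, restored = _time_response(
        fit.a, fit.u, fit.initial_value, n + steps
    )
    return restored[n:]


@dataclass
class AccuracyReport:
    """Per-point relative errors and the grade of a fitted model."""

    labels: Tuple[int, ...]
    relative_errors: np.ndarray
    mean_relative_error: float
    grade: str
    thresholds: Tuple[Tuple[float, str], ...] = field(
        default=DEFAULT_GRADE_THRESHOLDS
    )


def accuracy_report(
    fit: GM11Fit,
    thresholds: Tuple[Tuple[float, str], ...] = DEFAULT_GRADE_THRESHOLDS,
) -> AccuracyReport:
    """Grade the fit on its mean relative error (boundaries inclusive)."""
    mre = fit.mean_relative_error
    grade = "unqualified"
    for bound, name in sorted(thresholds):
        if mre <= bound:
            grade = name
            break
    return AccuracyReport(
        labels=fit.labels[1:],
        relative_errors=fit.relative_errors,
        mean_relative_error=mre,
        grade=grade,
        thresholds=tuple(sorted(thresholds)),
    )
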