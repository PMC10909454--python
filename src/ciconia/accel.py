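"""Accelerometry: ODBA, burst features, behavior classification, budgets.

Tri-axial acceleration is recorded in short bursts (9 s every 20 min on the
study tags).  Each burst yields two quantities: ODBA, the overall dynamic
body acceleration used as a proxy for locomotion energy expenditure, and a
behavior label from the four-class set {foraging, resting, soaring,
flapping} assigned by a supervised classifier.

ODBA is computed by removing the static (gravitational) component of each
axis with a centered running mean and summing the absolute residuals over
the three axes:

    ODBA = mean_t  sum_axis | a_axis(t) - smooth(a_axis)(t) |

The running-mean window is 4 s by default.  Aggregating with the mean over
samples (rather than the sum) makes values comparable across burst
durations and sampling rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

__all__ = [
    "BEHAVIORS",
    "AccelBurst",
    "BehaviorBudget",
    "running_mean",
    "compute_odba",
    "extract_features",
    "FEATURE_NAMES",
    "train_classifier",
    "classify_burst",
    "behavioral_budget",
]

#: Closed set of behavior labels, in canonical order.
BEHAVIORS: tuple[str, ...] = ("foraging", "resting", "soaring", "flapping")


class InputError(ValueError):
    """Raised for invalid inputs (bad shapes, NaNs, unknown labels)."""


@dataclass
class AccelBurst:
    """One tri-axial acceleration burst.

    Parameters
    ----------
    individual : str
        Identifier of the tagged bird.
    timestamp : datetime
        UTC start time of the burst.
    surge, sway, heave : ndarray
        Equal-length acceleration sample vectors in g (surge = forward,
        sway = lateral, heave = dorsoventral).
    rate : float
        Sampling rate in Hz.
    tag_type : str
        Tag family metadata, carried through outputs untouched.
    """

    individual: str
    timestamp: datetime
    surge: np.ndarray
    sway: np.ndarray
    heave: np.ndarray
    rate: float
    tag_type: str = "default"

    def __post_init__(self) -> None:
        self.surge = np.asarray(self.surge, dtype=float)
        self.sway = np.asarray(self.sway, dtype=float)
        self.heave = np.asarray(self.heave, dtype=float)
        n = len(self.surge)
        if n < 1 or len(self.sway) != n or len(self.heave) != n:
            raise InputError("burst axes must be equal-length and non-empty")
        if not self.rate > 0:
            raise InputError(f"sampling rate must be positive, got {self.rate}")

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.surge, self.sway, self.heave

    @property
    def n_samples(self) -> int:
        return len(self.surge)


@dataclass
class BehaviorBudget:
    """Proportion of bursts per behavior for one individual and period."""

    individual: str
    period: str
    proportions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if self.proportions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"budget proportions sum to {total}, expected 1")


def running_mean(series: np.ndarray, window: float, rate: float) -> np.ndarray:
    """Centered running mean over ``window`` seconds at ``rate`` Hz.

    The window width is ``round(window * rate)`` samples, centered on each
    sample and truncated at the edges (no padding), so a constant input is
    returned unchanged and a window covering the whole series returns the
    series mean everywhere.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise InputError("cannot smooth an empty series")
    width = int(round(window * rate))
    if width < 1:
        raise InputError(
            f"window of {window}s at {rate}Hz spans {window * rate:.3g} samples; need >= 1"
        )
    return (
        pd.Series(series)
        .rolling(window=width, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def compute_odba(burst: AccelBurst, window: float = 4.0) -> float:
    """Overall dynamic body acceleration of a burst, in g.

    The static component of each axis is estimated with a centered running
    mean of ``window`` seconds and subtracted; ODBA is the per-sample sum of
    absolute residuals over the three axes, averaged over the burst.  The
    result is non-negative, zero exactly for bursts with no dynamic
    component, and invariant to adding a constant to any axis.
    """
    dyn = np.zeros(burst.n_samples)
    for axis in burst.axes:
        if not np.all(np.isfinite(axis)):
            raise InputError("burst contains non-finite samples")
        dyn += np.abs(axis - running_mean(axis, window, burst.rate))
    return float(dyn.mean())


#: Fixed feature order used by :func:`extract_features`.
FEATURE_NAMES: tuple[str, ...] = (
    "mean_surge",
    "mean_sway",
    "mean_heave",
    "sd_surge",
    "sd_sway",
    "sd_heave",
    "odba",
    "range_surge",
    "range_sway",
    "range_heave",
    "corr_surge_sway",
    "corr_surge_heave",
    "corr_sway_heave",
    "dominant_heave_freq",
    "spectral_power_ratio",
)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    # correlation is 0 by convention when either axis is constant
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _heave_spectrum(heave: np.ndarray, rate: float) -> tuple[float, float]:
    """Dominant non-DC frequency of the heave axis and the fraction of
    dynamic spectral power above half the Nyquist frequency."""
    detrended = heave - heave.mean()
    power = np.abs(np.fft.rfft(detrended)) ** 2
    freqs = np.fft.rfftfreq(len(heave), d=1.0 / rate)
    power[0] = 0.0  # DC carries no dynamic information
    total = power.sum()
    if total == 0:
        return 0.0, 0.0
    dominant = float(freqs[int(np.argmax(power))])
    high = power[freqs > rate / 4.0].sum()
    return dominant, float(high / total)


def extract_features(burst: AccelBurst) -> np.ndarray:
    """Fixed-order feature vector for behavior classification.

    Per-axis mean, SD and dynamic range, ODBA, pairwise axis correlations,
    dominant heave frequency and the high-frequency spectral power ratio.
    The chosen feature set separates posture (means), activity level (SDs,
    ODBA, ranges), gait coordination (correlations) and wingbeat
    periodicity (spectral features).
    """
    if burst.n_samples < 2:
        raise InputError("need >= 2 samples to extract features")
    s, w, h = burst.axes
    dom_freq, power_ratio = _heave_spectrum(h, burst.rate)
    features = np.array(
        [
            s.mean(),
            w.mean(),
            h.mean(),
            s.std(),
            w.std(),
            h.std(),
            compute_odba(burst),
            np.ptp(s),
            np.ptp(w),
            np.ptp(h),
            _safe_corr(s, w),
            _safe_corr(s, h),
            _safe_corr(w, h),
            dom_freq,
            power_ratio,
        ]
    )
    if not np.all(np.isfinite(features)):
        raise InputError("non-finite feature encountered")
    return features


@dataclass
class TrainedClassifier:
    """A fitted behavior classifier plus its held-out evaluation report."""

    model: RandomForestClassifier
    classes: tuple[str, ...]
    holdout_accuracy: float
    per_class_accuracy: dict[str, float]
    tag_type: str = "default"


def train_classifier(
    bursts: Sequence[AccelBurst],
    labels: Sequence[str],
    seed: int = 0,
    holdout_fraction: float = 0.25,
    tag_type: str = "default",
) -> TrainedClassifier:
    """Train a random-forest behavior classifier on labeled bursts.

    A stratified held-out split (default 25%) provides the accuracy report;
    training is deterministic given ``seed``.  Separate classifier
    instances can be trained per tag family by filtering the corpus and
    passing ``tag_type``.
    """
    if len(bursts) != len(labels):
        raise InputError("bursts and labels must have equal length")
    unknown = set(labels) - set(BEHAVIORS)
    if unknown:
        raise InputError(f"unknown behavior labels: {sorted(unknown)}")
    if len(set(labels)) < 2:
        raise InputError("training set must contain >= 2 classes")

    X = np.array([extract_features(b) for b in bursts])
    y = np.asarray(labels)
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    model = RandomForestClassifier(n_estimators=200, random_state=seed)
    model.fit(X_train, y_train)
    pred = model.predict(X_test)
    per_class = {
        cls: float((pred[y_test == cls] == cls).mean())
        for cls in sorted(set(y_test))
    }
    return TrainedClassifier(
        model=model,
        classes=tuple(model.classes_),
        holdout_accuracy=float((pred == y_test).mean()),
        per_class_accuracy=per_class,
        tag_type=tag_type,
    )


def classify_burst(classifier: TrainedClassifier, burst: AccelBurst) -> str:
    """Assign one of the four behavior labels to a burst."""
    features = extract_features(burst).reshape(1, -1)
    return str(classifier.model.predict(features)[0])


def classify_bursts(classifier: TrainedClassifier, bursts: Sequence[AccelBurst]) -> list[str]:
    """Batch variant of :func:`classify_burst` (one model call)."""
    if not bursts:
        return []
    X = np.array([extract_features(b) for b in bursts])
    return [str(label) for label in classifier.model.predict(X)]


def behavioral_budget(
    labeled: Iterable[tuple[datetime, str]],
    individual: str = "",
    period: str = "all",
) -> BehaviorBudget:
    """Behavioral time budget over a period.

    ``labeled`` is an iterable of (timestamp, behavior) pairs.  Bursts are
    equally spaced in time, so the proportion of bursts is the proportion
    of time.  Proportions are computed per calendar day first and then
    averaged across days, so days with fewer bursts are not under-weighted.
    """
    rows = [(ts, lab) for ts, lab in labeled]
    if not rows:
        raise InputError(f"no labeled bursts in period {period!r}")
    df = pd.DataFrame(rows, columns=["timestamp", "behavior"])
    df["date"] = pd.to_datetime(df["timestamp"]).dt.date
    daily = (
        df.groupby("date")["behavior"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    for b in BEHAVIORS:
        if b not in daily.columns:
            daily[b] = 0.0
    mean_props = daily[list(BEHAVIORS)].mean(axis=0)
    props = (mean_props / mean_props.sum()).to_dict()
    return BehaviorBudget(individual=individual, period=period, proportions=props)
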