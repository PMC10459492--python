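"""NARX design matrices for per-trial SISO signals.

A trial is one period-aligned record of an exogenous perturbation input
``u(t)`` and the evoked response ``y(t)``. The regressor set for target
``y(t)`` is the NARX structure

    y(t) = f(y(t-1)..y(t-ny), u(t-1)..u(t-nu), engineered features of u) + e(t)

with six engineered input features, all functions of the input only:
rolling mean / standard deviation / skewness of ``u`` over a causal window
ending at ``u(t-1)``, the first difference ``u(t-1) - u(t-2)``, the cube
``u(t-1)^3``, and a signed logarithm ``sign(u) * ln(1 + |u|)`` of
``u(t-1)`` (the input crosses zero, so a plain log is undefined).

Every row for target time ``t`` references only samples at times ``<= t-1``
(no lookahead), and lags never cross trial boundaries: each trial loses its
first ``max(ny, nu, window)`` samples as burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrialSignal",
    "FeatureSpec",
    "DesignMatrix",
    "ParticipantSplit",
    "TrialTooShortError",
    "ProtocolError",
    "signed_log",
    "rolling_skewness",
    "build_design",
    "build_design_set",
    "split_sessions",
    "read_trials",
    "write_trials",
]


class TrialTooShortError(ValueError):
    """Trial has fewer samples than the burn-in requires."""


class ProtocolError(ValueError):
    """Trial collection does not match the expected per-participant layout."""


@dataclass
class TrialSignal:
    """One perturbation signal: input ``u`` and response ``y`` at rate ``fs``."""

    participant: str | int
    signal_id: int
    u: np.ndarray
    y: np.ndarray
    fs: float = 256.0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.u.shape != self.y.shape or self.u.ndim != 1:
            raise ValueError("u and y must be 1-D arrays of equal length")
        if not (np.isfinite(self.u).all() and np.isfinite(self.y).all()):
            raise ValueError("trial signals must be finite")

    def __len__(self) -> int:
        return self.u.size


@dataclass(frozen=True)
class FeatureSpec:
    """Lag depths and engineered-feature window.

    Defaults: five output lags, three input lags, a three-sample window.
    Burn-in (rows dropped at the start of each trial) is
    ``max(ny, nu, window)``.
    """

    ny: int = 5
    nu: int = 3
    window: int = 3

    def __post_init__(self) -> None:
        if self.ny < 1 or self.nu < 1 or self.window < 2:
            raise ValueError("require ny >= 1, nu >= 1, window >= 2")

    @property
    def burn_in(self) -> int:
        return max(self.ny, self.nu, self.window)

    @property
    def columns(self) -> list[str]:
        return (
            [f"y_lag{k}" for k in range(1, self.ny + 1)]
            + [f"u_lag{k}" for k in range(1, self.nu + 1)]
            + ["u_mean_w", "u_std_w", "u_skew_w", "u_diff12", "u_cube", "u_slog"]
        )


@dataclass
class DesignMatrix:
    """Named regressors ``X``, targets ``y`` and 1-based provenance per row."""

    X: pd.DataFrame
    y: np.ndarray
    provenance: pd.DataFrame  # columns: participant, signal_id, t (1-based target)
    spec: FeatureSpec = field(default_factory=FeatureSpec)

    def __len__(self) -> int:
        return len(self.X)

    @property
    def fold_labels(self) -> np.ndarray:
        """Leave-one-signal-out CV labels: the originating signal id."""
        return self.provenance["signal_id"].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        out = pd.concat([self.provenance.reset_index(drop=True),
                         self.X.reset_index(drop=True)], axis=1)
        out["target"] = self.y
        return out


def signed_log(x):
    """Odd, monotone, total surrogate for the logarithm: sign(x) ln(1+|x|)."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.log1p(np.abs(x))
    return float(out) if out.ndim == 0 else out


def rolling_skewness(values) -> float:
    """Moment skewness g1 = m3 / m2^(3/2) of one window; 0 at zero variance."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("skewness window needs at least 2 values")
    d = v - v.mean()
    m2 = np.mean(d * d)
    if m2 == 0.0:
        return 0.0
    return float(np.mean(d**3) / m2**1.5)


def _window_stats(u: np.ndarray, window: int):
    """Causal rolling mean, std (ddof=1) and g1 skewness over trailing windows.

    Entry ``j`` summarizes ``u[j-window+1 .. j]``; the first ``window-1``
    entries are NaN (consumed by burn-in).
    """
    n = u.size
    wins = np.lib.stride_tricks.sliding_window_view(u, window)
    mean = np.full(n, np.nan)
    std = np.full(n, np.nan)
    skew = np.full(n, np.nan)
    mean[window - 1:] = wins.mean(axis=1)
    std[window - 1:] = wins.std(axis=1, ddof=1)
    d = wins - wins.mean(axis=1, keepdims=True)
    m2 = np.mean(d * d, axis=1)
    m3 = np.mean(d**3, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        g1 = np.where(m2 > 0, m3 / np.where(m2 > 0, m2, 1.0) ** 1.5, 0.0)
    skew[window - 1:] = g1
    return mean, std, skew


def build_design(trial: TrialSignal, spec: FeatureSpec | None = None) -> DesignMatrix:
    """NARX design matrix for one trial.

    Row count is ``N - burn_in``; the first usable 1-based target index is
    ``burn_in + 1``. All columns are functions of samples strictly before
    the target time.
    """
    spec = spec or FeatureSpec()
    u, y = trial.u, trial.y
    N = len(trial)
    b = spec.burn_in
    if N <= b:
        raise TrialTooShortError(
            f"trial of length {N} cannot support burn-in {b}"
        )
    idx = np.arange(b, N)  # 0-based target positions
    cols: dict[str, np.ndarray] = {}
    for k in range(1, spec.ny + 1):
        cols[f"y_lag{k}"] = y[idx - k]
    for k in range(1, spec.nu + 1):
        cols[f"u_lag{k}"] = u[idx - k]
    mean, std, skew = _window_stats(u, spec.window)
    cols["u_mean_w"] = mean[idx - 1]
    cols["u_std_w"] = std[idx - 1]
    cols["u_skew_w"] = skew[idx - 1]
    cols["u_diff12"] = u[idx - 1] - u[idx - 2]
    cols["u_cube"] = u[idx - 1] ** 3
    cols["u_slog"] = signed_log(u[idx - 1])

    X = pd.DataFrame(cols, columns=spec.columns)
    prov = pd.DataFrame(
        {
            "participant": np.repeat(trial.participant, idx.size),
            "signal_id": np.repeat(trial.signal_id, idx.size),
            "t": idx + 1,  # 1-based target time
        }
    )
    return DesignMatrix(X, y[idx].copy(), prov, spec)


def build_design_set(trials, spec: FeatureSpec | None = None) -> DesignMatrix:
    """Stack per-trial design matrices; lags never cross trial boundaries."""
    spec = spec or FeatureSpec()
    parts = [build_design(t, spec) for t in trials]
    X = pd.concat([p.X for p in parts], ignore_index=True)
    y = np.concatenate([p.y for p in parts])
    prov = pd.concat([p.provenance for p in parts], ignore_index=True)
    return DesignMatrix(X, y, prov, spec)


@dataclass
class ParticipantSplit:
    participant: str | int
    train: list  # TrialSignal, one per training signal (CV fold = signal id)
    test: TrialSignal


def split_sessions(trials, n_signals: int = 7) -> list[ParticipantSplit]:
    """Per participant: the last signal is the test set, the rest train.

    Requires exactly ``n_signals`` distinct signal ids per participant.
    The leave-one-signal-out CV fold of a training row is its signal id.
    """
    by_part: dict = {}
    for t in trials:
        by_part.setdefault(t.participant, []).append(t)
    splits = []
    for part in sorted(by_part, key=str):
        group = sorted(by_part[part], key=lambda t: t.signal_id)
        ids = [t.signal_id for t in group]
        if len(set(ids)) != len(ids) or len(ids) != n_signals:
            raise ProtocolError(
                f"participant {part!r}: expected {n_signals} distinct signals, "
                f"got ids {ids}"
            )
        splits.append(ParticipantSplit(part, group[:-1], group[-1]))
    return splits


def write_trials(trials, path) -> None:
    """Delimited text with header participant,signal_id,t,u,y (t is 1-based)."""
    frames = []
    for tr in trials:
        frames.append(
            pd.DataFrame(
                {
                    "participant": tr.participant,
                    "signal_id": tr.signal_id,
                    "t": np.arange(1, len(tr) + 1),
                    "u": tr.u,
                    "y": tr.y,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trials(path, fs: float = 256.0) -> list[TrialSignal]:
    df = pd.read_csv(path)
    required = {"participant", "signal_id", "t", "u", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"trial file must have columns {sorted(required)}")
    trials = []
    for (part, sig), g in df.groupby(["participant", "signal_id"], sort=True):
        g = g.sort_values("t")
        trials.append(TrialSignal(part, int(sig), g["u"].to_numpy(), g["y"].to_numpy(), fs))
    return trials
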