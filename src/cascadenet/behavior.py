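"""Microsaccade event-table analysis and a synthetic event generator.

The analysis stage mirrors the experimental test of the behavioral
predictions: given detected microsaccade events (subject, trial, onset
time, magnitude), it forms within-trial pairs

* (M_n, (TI)_n): each event's magnitude against the interval to the next
  event, ``(TI)_n = t_{n+1} - t_n``;
* ((TI)_n, (TI)_{n+1}): consecutive intervals;

and fits an exponential to the first relation and a line to the second.
All trends hold in the statistical-average sense; fits are on the raw
pairs, with equal-count binned means reported alongside for display.

Because the original five-subject recordings are not deposited, the module
also ships a generator of synthetic event tables with exactly the
statistical structure the predictions describe — a magnitude-dependent mean
interval ``a exp(-b M) + c`` and lag-1 interval correlation via an AR(1)
process on the log interval — so the analysis stage can be validated by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .predictions import FittedRelation, fit_relation

__all__ = [
    "EVENT_COLUMNS",
    "PairedEvents",
    "RelationEstimate",
    "load_events",
    "save_events",
    "pair_events",
    "estimate_relations",
    "generate_synthetic_events",
]

EVENT_COLUMNS = ("subject", "trial", "t_ms", "magnitude")

#: Trial length of the fixation recordings being emulated, ms.
DEFAULT_TRIAL_MS = 10020.0


def load_events(path) -> pd.DataFrame:
    """Read a tab-separated event table with the standard header."""
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table is missing columns: {sorted(missing)}")
    return df


def save_events(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(EVENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"event table is missing columns: {sorted(missing)}")
    if (table["magnitude"] <= 0).any():
        raise ValueError("magnitudes must be strictly positive")
    return table


@dataclass
class PairedEvents:
    """Within-trial event pairs for the two behavioral relations.

    ``magnitude_interval`` has columns (subject, trial, M, TI);
    ``interval_interval`` has (subject, trial, TI_n, TI_next).  Trials with
    fewer than two events contribute nothing and are counted in
    ``n_skipped_trials``.
    """

    magnitude_interval: pd.DataFrame
    interval_interval: pd.DataFrame
    n_trials: int
    n_skipped_trials: int


def pair_events(table: pd.DataFrame) -> PairedEvents:
    """Form (M_n, (TI)_n) and ((TI)_n, (TI)_{n+1}) pairs, strictly per trial.

    Rows are sorted by event time within each (subject, trial) group first,
    so the pairing is invariant to the row order of the input.
    """
    table = _validate(table)
    mi_rows, ii_rows = [], []
    n_trials = n_skipped = 0
    for (subject, trial), grp in table.groupby(["subject", "trial"], sort=True):
        n_trials += 1
        grp = grp.sort_values("t_ms")
        t = grp["t_ms"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"event times must be strictly increasing within a trial "
                f"(subject={subject!r}, trial={trial!r})"
            )
        if len(t) < 2:
            n_skipped += 1
            continue
        m = grp["magnitude"].to_numpy(dtype=float)
        ti = np.diff(t)
        for k in range(len(ti)):
            mi_rows.append((subject, trial, m[k], ti[k]))
        for k in range(len(ti) - 1):
            ii_rows.append((subject, trial, ti[k], ti[k + 1]))
    return PairedEvents(
        magnitude_interval=pd.DataFrame(
            mi_rows, columns=["subject", "trial", "M", "TI"]),
        interval_interval=pd.DataFrame(
            ii_rows, columns=["subject", "trial", "TI_n", "TI_next"]),
        n_trials=n_trials, n_skipped_trials=n_skipped)


@dataclass
class RelationEstimate:
    """One estimated behavioral relation on event data.

    ``binned`` holds equal-count bin centers and mean y per bin (with
    counts), for display; ``fitted`` is the fit on the raw pairs.  All
    statements derived from this estimate hold in the statistical-average
    sense only — individual pairs scatter widely.
    """

    relation_kind: Literal["magnitude_interval", "interval_interval"]
    x: np.ndarray
    y: np.ndarray
    binned: pd.DataFrame
    fitted: FittedRelation
    n_pairs: int
    note: str = "trend holds in the sense of the statistical average"


def _equal_count_bins(x: np.ndarray, y: np.ndarray, n_bins: int) -> pd.DataFrame:
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    edges = np.linspace(0, len(xs), n_bins + 1).astype(int)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi > lo:
            rows.append((xs[lo:hi].mean(), ys[lo:hi].mean(), hi - lo))
    return pd.DataFrame(rows, columns=["x_mean", "y_mean", "count"])


def estimate_relations(pairs: PairedEvents, n_bins: int = 8,
                       min_pairs: int = 10,
                       mode: Literal["pooled", "per_subject"] = "pooled") -> dict:
    """Fit both behavioral relations from paired events.

    Magnitude -> interval uses an exponential fit, interval -> interval a
    linear fit.  In ``per_subject`` mode the pairs are first averaged into
    per-subject bins before fitting; ``pooled`` (default) fits all raw
    pairs at once.

    Returns ``{"magnitude_interval": RelationEstimate,
    "interval_interval": RelationEstimate}``.
    """
    out = {}
    specs = [
        ("magnitude_interval", pairs.magnitude_interval, "M", "TI",
         "exponential"),
        ("interval_interval", pairs.interval_interval, "TI_n", "TI_next",
         "linear"),
    ]
    for kind, df, xcol, ycol, form in specs:
        if len(df) < min_pairs:
            raise ValueError(
                f"{kind}: {len(df)} pairs is fewer than the required "
                f"{min_pairs}"
            )
        if mode == "per_subject":
            parts = [_equal_count_bins(g[xcol].to_numpy(dtype=float),
                                       g[ycol].to_numpy(dtype=float), n_bins)
                     for _, g in df.groupby("subject")]
            binned_all = pd.concat(parts, ignore_index=True)
            x = binned_all["x_mean"].to_numpy()
            y = binned_all["y_mean"].to_numpy()
        else:
            x = df[xcol].to_numpy(dtype=float)
            y = df[ycol].to_numpy(dtype=float)
        fitted = fit_relation(x, y, form, x_label=xcol, y_label=ycol)
        out[kind] = RelationEstimate(
            relation_kind=kind, x=x, y=y,
            binned=_equal_count_bins(x, y, n_bins),
            fitted=fitted, n_pairs=len(df))
    return out


def generate_synthetic_events(
    n_subjects: int = 5,
    trials_per_subject: int = 20,
    trial_ms: float = DEFAULT_TRIAL_MS,
    interval_a: float = 600.0,
    interval_b: float = 0.5,
    interval_c: float = 100.0,
    rho: float = 0.3,
    noise_sd: float = 0.3,
    magnitude_mean: float = 2.0,
    magnitude_sd: float = 0.7,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Generate a reproducible synthetic microsaccade event table.

    The generative model per trial:

    * magnitudes M_n are i.i.d. lognormal with the given mean and standard
      deviation, truncated to [0.3, 6];
    * the mean interval after an event of magnitude M is
      ``mu(M) = interval_a * exp(-interval_b * M) + interval_c`` (ms);
    * the realized interval is ``TI_n = mu(M_n) * exp(eta_n)`` where
      ``eta_n`` is a stationary AR(1) process with lag-1 correlation
      ``rho`` and stationary standard deviation ``noise_sd`` —
      i.e. multiplicative lognormal noise with a positive lag-1 coupling
      between consecutive intervals;
    * events accumulate from t = 0 until the trial length is exceeded.

    With ``rho = 0`` and ``noise_sd = 0`` the table is noiseless and the
    analysis stage recovers (a, b, c) exactly.  The same seed always yields
    the same table.
    """
    if n_subjects <= 0 or trials_per_subject <= 0 or trial_ms <= 0:
        raise ValueError("counts and trial length must be positive")
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    if noise_sd < 0 or interval_a <= 0 or interval_b < 0 or interval_c < 0:
        raise ValueError("invalid interval-model parameters")
    if magnitude_mean <= 0 or magnitude_sd <= 0:
        raise ValueError("invalid magnitude-distribution parameters")
    if rng is None:
        rng = np.random.default_rng(seed)

    # lognormal parameterized by its real-space mean/sd
    s2 = np.log(1.0 + (magnitude_sd / magnitude_mean) ** 2)
    mu_log = np.log(magnitude_mean) - s2 / 2.0
    innovation_sd = noise_sd * np.sqrt(1.0 - rho ** 2)

    rows = []
    for subject in range(1, n_subjects + 1):
        for trial in range(1, trials_per_subject + 1):
            t = 0.0
            eta = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            # first event at a magnitude-independent start time
            t += float(rng.uniform(0.0, interval_c + interval_a / 2))
            while t <= trial_ms:
                m = float(np.clip(rng.lognormal(mu_log, np.sqrt(s2)), 0.3, 6.0))
                rows.append((subject, trial, t, m))
                mu = interval_a * np.exp(-interval_b * m) + interval_c
                t += mu * float(np.exp(eta))
                if noise_sd > 0:
                    eta = rho * eta + rng.normal(0.0, innovation_sd)
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
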