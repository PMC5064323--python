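"""Parameter sweeps over (M, TI), curve fits, and behavioral predictions.

The sweeps reproduce the two model experiments: ST as a function of the
microsaccade magnitude M (at a fixed fixation-microsaccade interval) and ST
as a function of the interval TI (at a fixed magnitude), each with the
thalamocortical STD enabled and disabled.

From the sweeps two behavioral predictions are constructed.  Both rest on
the premise that, because microsaccades counteract visual fading, the
sustaining time of the microsaccade-evoked response sets the time until the
next microsaccade is needed — so the predicted interval is a positively
calibrated (monotone affine) image of ST, and all sign and shape claims are
invariant under that calibration:

* magnitude -> interval: (TI)_n versus M_n follows ST(M), fitted with an
  exponential;
* interval -> interval: (TI)_{n+1} versus (TI)_n follows ST(TI), fitted
  linearly when STD is on and exponentially when STD is off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .metrics import NoDecayError, NoPeakError, measure
from .params import ModelParams
from .simulate import run
from .stimulation import single_microsaccade_protocol

__all__ = [
    "DEFAULT_M_GRID",
    "DEFAULT_TI_GRID",
    "SweepResult",
    "FittedRelation",
    "BehavioralPrediction",
    "sweep_ST",
    "fit_relation",
    "build_predictions",
]

#: Magnitude grid for the ST(M) sweep, run at TI = 150 ms.  The range
#: brackets the reference magnitude M = 2.2 and starts near the stimulus
#: width: below M ~ sigma_O the displaced stimulus barely clears its own
#: adapted footprint and the weak evoked transient is swamped by the tail
#: of the fixation-onset response.
DEFAULT_M_GRID = (1.4, 1.8, 2.2, 2.6, 3.0)

#: Interval grid for the ST(TI) sweep, run at M = 2.2.  Intervals below
#: ~100 ms overlap the fixation-onset transient, which contaminates the
#: ST measurement; 300 ms caps the "small region" in which the interval
#: dependence is informative (the adaptation state has settled beyond it).
DEFAULT_TI_GRID = (100.0, 150.0, 200.0, 250.0, 300.0)

#: Anchor condition: the M sweep holds TI at this value.
SWEEP_FIXED_TI = 150.0
#: Anchor condition: the TI sweep holds M at this value.
SWEEP_FIXED_M = 2.2


@dataclass
class SweepResult:
    """RT/ST over both sweep axes for one STD condition.

    ``table`` has one row per simulated cell with columns
    ``sweep`` ("M" or "TI"), ``M``, ``TI``, ``std_enabled``, ``RT``, ``ST``,
    ``status`` ("ok", "NoPeak" or "NoDecay"; RT/ST are NaN when not "ok").
    """

    table: pd.DataFrame
    m_grid: tuple = DEFAULT_M_GRID
    ti_grid: tuple = DEFAULT_TI_GRID
    std_enabled: bool = True

    def axis(self, sweep: Literal["M", "TI"]) -> pd.DataFrame:
        """Rows of one sweep axis, ordered along its grid."""
        sub = self.table[self.table["sweep"] == sweep]
        return sub.sort_values(sweep).reset_index(drop=True)


def sweep_ST(M_grid: Sequence[float] = DEFAULT_M_GRID,
             TI_grid: Sequence[float] = DEFAULT_TI_GRID,
             params: Optional[ModelParams] = None,
             std_enabled: bool = True,
             fixed_TI: float = SWEEP_FIXED_TI,
             fixed_M: float = SWEEP_FIXED_M,
             post_ms: float = 2000.0) -> SweepResult:
    """Run both sweeps and tabulate RT/ST per grid point.

    The M sweep fixes TI = ``fixed_TI`` (150 ms); the TI sweep fixes
    M = ``fixed_M`` (2.2).  Cells whose measurement fails record their
    error status instead of aborting the sweep.  Deterministic.
    """
    if params is None:
        params = ModelParams()
    if len(M_grid) == 0 or len(TI_grid) == 0:
        raise ValueError("sweep grids must be nonempty")
    if any(m <= 0 for m in M_grid) or any(ti <= 0 for ti in TI_grid):
        raise ValueError("sweep grids must be strictly positive")

    rows = []
    cells = [("M", float(m), fixed_TI) for m in M_grid] + \
            [("TI", fixed_M, float(ti)) for ti in TI_grid]
    for sweep, m, ti in cells:
        protocol = single_microsaccade_protocol(M=m, TI=ti, params=params,
                                                post_ms=post_ms)
        trace = run(protocol, params, std_enabled=std_enabled)
        try:
            timing = measure(trace, 0, alpha=params.alpha)
            rows.append((sweep, m, ti, std_enabled, timing.RT, timing.ST, "ok"))
        except NoPeakError:
            rows.append((sweep, m, ti, std_enabled, np.nan, np.nan, "NoPeak"))
        except NoDecayError:
            rows.append((sweep, m, ti, std_enabled, np.nan, np.nan, "NoDecay"))
    table = pd.DataFrame(rows, columns=["sweep", "M", "TI", "std_enabled",
                                        "RT", "ST", "status"])
    return SweepResult(table=table, m_grid=tuple(M_grid),
                       ti_grid=tuple(TI_grid), std_enabled=std_enabled)


@dataclass(frozen=True)
class FittedRelation:
    """A fitted exponential ``y = a exp(-b x) + c`` or linear ``y = m x + q``.

    For the exponential form ``b > 0`` means a decreasing relation.
    ``stderr`` holds one standard error per coefficient (same order as
    ``coefficients``).
    """

    form: Literal["exponential", "linear"]
    coefficients: dict
    stderr: dict
    rss: float
    r_squared: float
    x_label: str = "x"
    y_label: str = "y"

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = self.coefficients
        if self.form == "exponential":
            return c["a"] * np.exp(-c["b"] * x) + c["c"]
        return c["m"] * x + c["q"]

    @property
    def decreasing(self) -> bool:
        """Whether the fitted curve is decreasing in x."""
        c = self.coefficients
        if self.form == "exponential":
            return (c["a"] * c["b"]) > 0
        return c["m"] < 0


def fit_relation(xs, ys, form: Literal["exponential", "linear"],
                 x_label: str = "x", y_label: str = "y") -> FittedRelation:
    """Least-squares fit of the stated form.

    The exponential fit is initialized from the data (offset ``c`` near the
    minimum of y, amplitude from the range, decay rate from a log-linear
    regression of ``y - c``) because nonlinear exponential fits are
    sensitive to their starting point.

    Raises
    ------
    ValueError
        On fewer than 4 finite points, or if the optimizer fails to
        converge (the message reports the initialization used).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    good = np.isfinite(xs) & np.isfinite(ys)
    xs, ys = xs[good], ys[good]
    if len(xs) < 4:
        raise ValueError(f"need at least 4 finite points, got {len(xs)}")

    if form == "linear":
        res = stats.linregress(xs, ys)
        resid = ys - (res.slope * xs + res.intercept)
        rss = float(resid @ resid)
        return FittedRelation(
            form="linear",
            coefficients={"m": float(res.slope), "q": float(res.intercept)},
            stderr={"m": float(res.stderr), "q": float(res.intercept_stderr)},
            rss=rss, r_squared=float(res.rvalue ** 2),
            x_label=x_label, y_label=y_label)
    if form != "exponential":
        raise ValueError(f"unknown fit form {form!r}")

    p0 = _exponential_init(xs, ys)

    def model(x, a, b, c):
        return a * np.exp(-b * x) + c

    try:
        with warnings.catch_warnings():
            # a perfect (noiseless) fit makes the covariance degenerate
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(model, xs, ys, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise ValueError(
            f"exponential fit did not converge from initialization "
            f"(a, b, c) = {tuple(round(v, 6) for v in p0)}: {err}"
        ) from None
    resid = ys - model(xs, *popt)
    rss = float(resid @ resid)
    tss = float(np.sum((ys - ys.mean()) ** 2))
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else \
        np.full(3, np.nan)
    return FittedRelation(
        form="exponential",
        coefficients={"a": float(popt[0]), "b": float(popt[1]), "c": float(popt[2])},
        stderr={"a": float(perr[0]), "b": float(perr[1]), "c": float(perr[2])},
        rss=rss, r_squared=float(1.0 - rss / tss) if tss > 0 else 1.0,
        x_label=x_label, y_label=y_label)


def _exponential_init(xs: np.ndarray, ys: np.ndarray) -> tuple:
    """Data-driven starting point for the exponential fit."""
    span = ys.max() - ys.min()
    increasing = np.polyfit(xs, ys, 1)[0] > 0
    if increasing:
        # y rises toward c: a < 0 with b > 0
        c0 = ys.max() + 0.05 * span
        a_sign = -1.0
    else:
        c0 = ys.min() - 0.05 * span
        a_sign = 1.0
    z = np.log(np.maximum(np.abs(ys - c0), 1e-12))
    slope, intercept = np.polyfit(xs, z, 1)
    b0 = -slope
    a0 = a_sign * np.exp(intercept)
    if span == 0:
        return (0.0, 1.0, float(ys[0]))
    return (float(a0), float(b0), float(c0))


@dataclass(frozen=True)
class BehavioralPrediction:
    """One predicted behavioral relation derived from a sweep.

    ``relation_kind`` is ``"magnitude_interval"`` (M_n -> (TI)_n) or
    ``"interval_interval"`` ((TI)_n -> (TI)_{n+1}); ``qualitative_sign`` is
    ``"decreasing"`` or ``"increasing"`` and always agrees with the sign of
    the fitted coefficients.
    """

    relation_kind: Literal["magnitude_interval", "interval_interval"]
    std_enabled: bool
    fitted: FittedRelation
    qualitative_sign: Literal["decreasing", "increasing"]
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)


def _check_monotone(x: np.ndarray, y: np.ndarray, label: str,
                    atol: float) -> str:
    """Direction of a strictly monotone sequence; error listing violations."""
    d = np.diff(y)
    if np.all(d < atol):
        return "decreasing"
    if np.all(d > -atol):
        return "increasing"
    bad = [f"{label}={x[i + 1]:g} (ST step {d[i]:+.3f} ms)"
           for i in range(len(d))
           if (d[i] >= atol if np.median(d) < 0 else d[i] <= -atol)]
    raise ValueError(
        f"ST along the {label} axis is not monotone beyond tolerance "
        f"{atol} ms; violating cells: {', '.join(bad)}"
    )


def build_predictions(sweep_on: SweepResult, sweep_off: SweepResult,
                      calibration: tuple = (0.0, 1.0),
                      monotone_atol: float = 0.1) -> list:
    """Construct the four behavioral predictions from an STD-on/off pair.

    ``calibration = (u, v)`` with ``v > 0`` maps a sustaining time to a
    predicted interval, ``TI_pred = u + v * ST``; the default is the
    identity.  Each sweep's ST column must be strictly monotone along its
    axis (up to ``monotone_atol``), otherwise the offending cells are
    reported and no prediction is built.

    Returns the four predictions: magnitude->interval and
    interval->interval, each for STD on and off.
    """
    u, v = calibration
    if v <= 0:
        raise ValueError("calibration scale v must be positive")
    out = []
    for sweep in (sweep_on, sweep_off):
        for kind, axis_col in (("magnitude_interval", "M"),
                               ("interval_interval", "TI")):
            sub = sweep.axis("M" if axis_col == "M" else "TI")
            bad = sub[sub["status"] != "ok"]
            if len(bad):
                raise ValueError(
                    f"sweep has unmeasurable cells on the {axis_col} axis: "
                    f"{bad[[axis_col, 'status']].to_dict('records')}"
                )
            x = sub[axis_col].to_numpy(dtype=float)
            y = u + v * sub["ST"].to_numpy(dtype=float)
            sign = _check_monotone(x, y, axis_col, atol=monotone_atol * v)
            if kind == "magnitude_interval":
                form = "exponential"
            else:
                # linear under STD (slightly positive relation), exponential
                # in its absence
                form = "linear" if sweep.std_enabled else "exponential"
            fitted = fit_relation(
                x, y, form,
                x_label="M_n" if kind == "magnitude_interval" else "TI_n",
                y_label="TI_n" if kind == "magnitude_interval" else "TI_n+1")
            out.append(BehavioralPrediction(
                relation_kind=kind, std_enabled=sweep.std_enabled,
                fitted=fitted, qualitative_sign=sign, x=x, y=y))
    return out
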