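"""From raw intensities to phosphorylation-ratio series, signal durations
and integrated fold changes.

Normalization chain (per molecule and replicate):

1. divide each channel by the negative-control intensity of the same
   time/replicate (removes global array gain);
2. divide the phospho signal by the total (unphosphorylated) signal;
3. divide by the t = 0 value, so the series starts at exactly 1.

The signal duration tau is the time at which the phosphorylation ratio
first returns to its pre-stimulation level, found as the zero crossing of
the line through two measured points (t1, dX1), (t2, dX2) of the decline:

    tau = (t2*dX1 - t1*dX2) / (dX1 - dX2)

With the ``"last_above"`` point-pair rule, t1 is the last grid time whose
excess ratio dX = r - 1 exceeds ``signal_threshold`` and t2 is its
successor. The ``"peak"`` dialect instead takes t2 = the first grid time
after the peak with dX <= threshold and t1 = its predecessor, i.e. the
first genuine decline crossing; a single noisy late point cannot then drag
tau toward the end of the grid. Both are exact on noiseless pulses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import NEGCTRL_ID, DatasetError, PhosphoArrayDataset
from .st_core import compute_str


@dataclass(frozen=True)
class RatioSeries:
    """Normalized phosphorylation ratio r(t) for one molecule/replicate;
    r(0) = 1 by construction."""

    molecule_id: str
    replicate: int
    times: np.ndarray
    ratio: np.ndarray
    condition: str = ""

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "ratio", np.asarray(self.ratio, dtype=float))
        if len(self.times) != len(self.ratio):
            raise ValueError("times and ratio must have equal length")
        if np.any(self.ratio <= 0):
            raise ValueError("ratios must be positive")

    @property
    def excess(self) -> np.ndarray:
        """dX(t) = r(t) - 1, the above-baseline signal in normalized units."""
        return self.ratio - 1.0


@dataclass(frozen=True)
class DurationEstimate:
    """Signal duration tau for one molecule/replicate.

    ``status`` is ``estimated`` (zero crossing found), ``censored_at_grid_end``
    (the signal never returned to baseline within the grid) or ``no_signal``.
    tau may exceed t2 when dX2 is still positive (extrapolation).
    """

    molecule_id: str
    replicate: int
    tau: float
    t1: float | None = None
    t2: float | None = None
    dX1: float | None = None
    dX2: float | None = None
    status: str = "estimated"


def normalize(dataset: PhosphoArrayDataset) -> list[RatioSeries]:
    """Normalize a dataset into one RatioSeries per molecule per replicate."""
    nc = dataset.negative_control()
    series: list[RatioSeries] = []
    for mol in dataset.molecules:
        if mol == NEGCTRL_ID:
            continue
        try:
            ph = dataset.channel(mol, "phospho")
            tot = dataset.channel(mol, "total")
        except DatasetError as err:
            raise DatasetError(f"molecule {mol!r}: {err}") from err
        if ph.isna().any().any() or tot.isna().any().any():
            raise DatasetError(f"molecule {mol!r}: missing time/replicate entries")
        s = (ph / nc) / (tot / nc)  # negative control cancels algebraically
        r = s / s.iloc[0]
        for rep in r.columns:
            series.append(
                RatioSeries(mol, int(rep), r.index.to_numpy(), r[rep].to_numpy(),
                            condition=dataset.condition)
            )
    return series


def negative_control_series(dataset: PhosphoArrayDataset) -> list[RatioSeries]:
    """Ratio series of the antibody-free control spot itself (r = nc/nc(0)),
    used to propagate measurement noise through the same duration/rate
    pipeline and set the noise floor."""
    nc = dataset.negative_control()
    r = nc / nc.iloc[0]
    return [
        RatioSeries(NEGCTRL_ID, int(rep), r.index.to_numpy(), r[rep].to_numpy(),
                    condition=dataset.condition)
        for rep in r.columns
    ]


def estimate_tau(
    series: RatioSeries,
    signal_threshold: float = 0.0,
    dialect: str = "last_above",
) -> DurationEstimate:
    """Estimate the signal duration of one ratio series.

    ``dialect="last_above"`` (default): t1 = last grid time with
    dX > threshold, t2 = the following grid time. ``dialect="peak"``:
    t2 = first time after the peak with dX <= threshold, t1 = its
    predecessor (robust to isolated late noise).
    """
    if signal_threshold < 0:
        raise ValueError("signal_threshold must be >= 0")
    t, dx = series.times, series.excess
    mol, rep = series.molecule_id, series.replicate
    above = dx > signal_threshold
    if not above.any():
        return DurationEstimate(mol, rep, float("nan"), status="no_signal")

    if dialect == "last_above":
        i1 = int(np.flatnonzero(above)[-1])
        i2 = i1 + 1
    elif dialect == "peak":
        ipk = int(np.argmax(dx))
        after = np.flatnonzero(~above[ipk + 1:])
        i2 = ipk + 1 + int(after[0]) if len(after) else len(t)
        i1 = i2 - 1
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if i2 >= len(t):
        return DurationEstimate(
            mol, rep, float(t[-1]), t1=float(t[i1]), dX1=float(dx[i1]),
            status="censored_at_grid_end",
        )
    dx1, dx2 = float(dx[i1]), float(dx[i2])
    if dx1 == dx2:
        raise ZeroDivisionError(
            f"{mol} rep {rep}: degenerate decline slope (dX({t[i1]}) == dX({t[i2]}))"
        )
    tau = (t[i2] * dx1 - t[i1] * dx2) / (dx1 - dx2)
    return DurationEstimate(
        mol, rep, float(tau), t1=float(t[i1]), t2=float(t[i2]),
        dX1=dx1, dX2=dx2, status="estimated",
    )


def integrate_ratio(series: RatioSeries, est: DurationEstimate) -> float:
    """Time-averaged fold change over [0, tau]:
    integral of r(t) dt / tau, by the trapezoid rule on grid points within
    [0, tau], appending the analytic endpoint (tau, 1) when tau is off-grid
    (dX(tau) = 0 defines tau)."""
    if est.status == "no_signal":
        raise ValueError("cannot integrate a series with no signal")
    tau = est.tau
    inside = series.times <= tau
    t = series.times[inside]
    r = series.ratio[inside]
    if t[-1] < tau:
        t = np.append(t, tau)
        r = np.append(r, 1.0)
    return float(np.trapezoid(r, t) / tau)


def str_estimates(
    series_list: list[RatioSeries],
    signal_threshold: float = 0.0,
    dialect: str = "last_above",
) -> pd.DataFrame:
    """Per molecule/replicate signal-transduction-rate table.

    Columns: molecule_id, replicate, status, tau_min, integral_ratio,
    beta_per_min, delta_I_nats. A series with no signal gets beta 0 (no
    information was transmitted); censored series use the grid end as tau
    and are flagged by status.
    """
    rows = []
    for s in series_list:
        est = estimate_tau(s, signal_threshold=signal_threshold, dialect=dialect)
        if est.status == "no_signal":
            rows.append((s.molecule_id, s.replicate, est.status,
                         float("nan"), float("nan"), 0.0, 0.0))
            continue
        ratio = integrate_ratio(s, est)
        beta = compute_str(ratio, est.tau)
        rows.append((s.molecule_id, s.replicate, est.status,
                     est.tau, ratio, beta, beta * est.tau))
    return pd.DataFrame(
        rows,
        columns=["molecule_id", "replicate", "status", "tau_min",
                 "integral_ratio", "beta_per_min", "delta_I_nats"],
    )
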