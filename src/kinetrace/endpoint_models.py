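"""Endpoint models fitted to a table of initial rates.

Once every kinetic trace has been reduced to an initial rate with a
standard error, the per-experiment question is answered by one of three
models:

* a substrate titration is fit to the Michaelis-Menten hyperbola
  ``v = Vmax [S] / (KM + [S])``;
* an inhibitor/activator dose series is fit to the 4-parameter logistic
  ``y = bottom + (top - bottom) / (1 + 10^(hill (midpoint - x)))``;
* a screening plate is summarised by its mean rate and wells are flagged
  when they fall more than a chosen number of standard deviations away.

All fits are weighted by the inverse variance of the initial rates, so the
uncertainty of each per-trace fit propagates into the endpoint parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "RateRow",
    "RateTable",
    "MMFit",
    "LogisticFit",
    "HTSResult",
    "fit_michaelis_menten",
    "fit_logistic4",
    "hts_flag",
    "subtract_blank_rates",
]


@dataclass(frozen=True)
class RateRow:
    """One trace's initial rate: label, titrant concentration, rate +/- stderr."""

    label: str
    concentration: float
    rate: float
    stderr: float = 0.0
    mode: str = ""
    window: tuple[float, float] = (math.nan, math.nan)

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"negative concentration for {self.label!r}")
        if not math.isfinite(self.stderr) or self.stderr < 0:
            raise ValueError(f"stderr must be finite and >= 0 for {self.label!r}")


@dataclass(frozen=True)
class RateTable:
    """Ordered collection of :class:`RateRow`, the input to every endpoint model."""

    rows: tuple[RateRow, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        if len(self.rows) < 1:
            raise ValueError("rate table must contain at least one row")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([r.concentration for r in self.rows], dtype=float)

    @property
    def rates(self) -> np.ndarray:
        return np.array([r.rate for r in self.rows], dtype=float)

    @property
    def stderrs(self) -> np.ndarray:
        return np.array([r.stderr for r in self.rows], dtype=float)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.rows)

    @classmethod
    def from_arrays(
        cls,
        labels: Sequence[str],
        concentrations: Sequence[float],
        rates: Sequence[float],
        stderrs: Sequence[float] | None = None,
        modes: Sequence[str] | None = None,
        windows: Sequence[tuple[float, float]] | None = None,
    ) -> "RateTable":
        n = len(labels)
        stderrs = [0.0] * n if stderrs is None else list(stderrs)
        modes = [""] * n if modes is None else list(modes)
        windows = [(math.nan, math.nan)] * n if windows is None else list(windows)
        rows = [
            RateRow(str(l), float(c), float(r), float(s), str(m), (float(w[0]), float(w[1])))
            for l, c, r, s, m, w in zip(labels, concentrations, rates, stderrs, modes, windows)
        ]
        return cls(tuple(rows))


@dataclass(frozen=True)
class MMFit:
    """Michaelis-Menten parameters with standard errors from the weighted fit."""

    vmax: float
    km: float
    stderr_vmax: float
    stderr_km: float

    def predict(self, s: np.ndarray | float) -> np.ndarray | float:
        s = np.asarray(s, dtype=float)
        return self.vmax * s / (self.km + s)


@dataclass(frozen=True)
class LogisticFit:
    """4-parameter logistic fit.

    ``midpoint`` is the half-maximal point on whichever x-axis was fit
    (the concentration itself for ``x_scale='linear'``, its log10 —
    i.e. a pIC50-style value — for ``x_scale='log10'``). Fixed parameters
    carry stderr 0 and are listed in ``fixed``.
    """

    bottom: float
    top: float
    hill: float
    midpoint: float
    stderr_bottom: float
    stderr_top: float
    stderr_hill: float
    stderr_midpoint: float
    fixed: tuple[str, ...] = ()
    x_scale: str = "linear"

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        return _logistic4(x, self.bottom, self.top, self.hill, self.midpoint)


@dataclass(frozen=True)
class HTSResult:
    """Plate summary: mean/SD of the rates and a flag per sample.

    Flags use strict inequalities: ``above`` iff rate > mean + k*sd,
    ``below`` iff rate < mean - k*sd, else ``none``. A zero-variance plate
    flags nothing.
    """

    mean_rate: float
    sd_rate: float
    threshold_sd: float
    flags: dict[str, str]

    @property
    def n_above(self) -> int:
        return sum(1 for f in self.flags.values() if f == "above")

    @property
    def n_below(self) -> int:
        return sum(1 for f in self.flags.values() if f == "below")


def _weights_sigma(stderrs: np.ndarray) -> np.ndarray | None:
    """Per-point sigma for inverse-variance weighting.

    Rows with stderr 0 borrow the smallest positive stderr in the table;
    if every stderr is zero the fit is unweighted (returns None).
    """
    positive = stderrs[stderrs > 0]
    if positive.size == 0:
        return None
    sigma = stderrs.copy()
    sigma[sigma == 0] = positive.min()
    return sigma


def _weighted_sse(y: np.ndarray, yhat: np.ndarray, sigma: np.ndarray | None) -> float:
    r = y - yhat
    if sigma is not None:
        r = r / sigma
    return float(r @ r)


def _mm_model(s: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * s / (km + s)


def fit_michaelis_menten(table: RateTable, *, max_nfev: int = 20000) -> MMFit:
    """Weighted nonlinear least-squares fit of v = Vmax [S] / (KM + [S]).

    Rows at concentration 0 (blank wells) carry no Michaelis-Menten
    information and are excluded. Weights are 1/stderr^2 with the zero-sigma
    fallback of :func:`_weights_sigma`; parameter standard errors come from
    the covariance at the optimum treating the stderrs as absolute. A short
    multi-start over KM (log-spaced across the concentration range) guards
    against local minima.
    """
    rows = [r for r in table.rows if r.concentration > 0]
    conc = np.array([r.concentration for r in rows], dtype=float)
    if np.unique(conc).size < 3:
        raise ValueError("need at least 3 distinct nonzero concentrations for a Michaelis-Menten fit")
    v = np.array([r.rate for r in rows], dtype=float)
    sigma = _weights_sigma(np.array([r.stderr for r in rows], dtype=float))

    km_grid = np.geomspace(conc.min() / 10.0, conc.max() * 10.0, 7)
    best = None
    for km0 in km_grid:
        vmax0 = float(np.max(np.abs(v)) * (km0 + conc.max()) / conc.max()) or 1.0
        try:
            popt, pcov = curve_fit(
                _mm_model,
                conc,
                v,
                p0=[vmax0, km0],
                sigma=sigma,
                absolute_sigma=sigma is not None,
                maxfev=max_nfev,
            )
        except RuntimeError:
            continue
        if popt[1] <= 0 or not np.all(np.isfinite(popt)):
            continue
        score = _weighted_sse(v, _mm_model(conc, *popt), sigma)
        if best is None or score < best[0]:
            best = (score, popt, pcov)
    if best is None:
        raise RuntimeError("Michaelis-Menten fit failed to converge from every KM start")
    _, popt, pcov = best
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return MMFit(vmax=float(popt[0]), km=float(popt[1]), stderr_vmax=float(perr[0]), stderr_km=float(perr[1]))


def _logistic4(x: np.ndarray, bottom: float, top: float, hill: float, midpoint: float) -> np.ndarray:
    with np.errstate(over="ignore"):  # far-from-midpoint points saturate cleanly
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (midpoint - x)))


_L4_NAMES = ("bottom", "top", "hill", "midpoint")


def fit_logistic4(
    table: RateTable,
    fixed: Mapping[str, float] | None = None,
    x_scale: str = "linear",
    *,
    max_nfev: int = 20000,
) -> LogisticFit:
    """Weighted 4-parameter logistic (dose-response) fit.

    ``x`` is the concentration itself (``x_scale='linear'``) or its log10
    (``x_scale='log10'``; zero concentrations have no finite log and are
    dropped with a warning). Any of bottom/top/hill (and midpoint) may be
    fixed via ``fixed``; fixed parameters are excluded from the optimisation
    and reported with stderr 0.
    """
    if x_scale not in ("linear", "log10"):
        raise ValueError(f"x_scale must be 'linear' or 'log10', got {x_scale!r}")
    fixed = dict(fixed or {})
    unknown = set(fixed) - set(_L4_NAMES)
    if unknown:
        raise ValueError(f"unknown fixed parameter(s): {sorted(unknown)}")
    free = [n for n in _L4_NAMES if n not in fixed]
    if not free:
        raise ValueError("all four logistic parameters fixed; nothing to fit")

    rows = list(table.rows)
    if x_scale == "log10":
        dropped = [r.label for r in rows if r.concentration <= 0]
        if dropped:
            warnings.warn(
                f"dropping {len(dropped)} zero-concentration row(s) from log10-scale logistic fit: {dropped}",
                UserWarning,
                stacklevel=2,
            )
        rows = [r for r in rows if r.concentration > 0]
    if len(rows) < 4:
        raise ValueError("need at least 4 usable rows for a 4-parameter logistic fit")

    x = np.array([r.concentration for r in rows], dtype=float)
    if x_scale == "log10":
        x = np.log10(x)
    y = np.array([r.rate for r in rows], dtype=float)
    sigma = _weights_sigma(np.array([r.stderr for r in rows], dtype=float))

    if np.ptp(y) <= 1e-12 * max(1.0, float(np.max(np.abs(y)))):
        raise RuntimeError("response is flat (top == bottom); logistic fit is unidentifiable")

    def f(xv: np.ndarray, *free_vals: float) -> np.ndarray:
        p = dict(fixed)
        p.update(zip(free, free_vals))
        return _logistic4(xv, p["bottom"], p["top"], p["hill"], p["midpoint"])

    defaults = {"bottom": float(y.min()), "top": float(y.max()), "hill": 1.0, "midpoint": float(np.median(x))}
    mid_grid = np.linspace(x.min(), x.max(), 5) if "midpoint" in free else [fixed["midpoint"]]
    hill_grid = (1.0, -1.0) if "hill" in free else (fixed["hill"],)
    best = None
    for mid0 in mid_grid:
        for hill0 in hill_grid:
            p0 = [
                {**defaults, "midpoint": float(mid0), "hill": float(hill0)}[n]
                for n in free
            ]
            try:
                popt, pcov = curve_fit(
                    f, x, y, p0=p0, sigma=sigma, absolute_sigma=sigma is not None, maxfev=max_nfev
                )
            except RuntimeError:
                continue
            if not np.all(np.isfinite(popt)):
                continue
            score = _weighted_sse(y, f(x, *popt), sigma)
            if best is None or score < best[0]:
                best = (score, popt, pcov)
    if best is None:
        raise RuntimeError("4-parameter logistic fit failed to converge from every start")
    _, popt, pcov = best
    params = dict(fixed)
    params.update(zip(free, popt))
    perr_free = dict(zip(free, np.sqrt(np.clip(np.diag(pcov), 0, None))))
    stderr = {n: float(perr_free.get(n, 0.0)) for n in _L4_NAMES}
    if params["top"] == params["bottom"]:
        raise RuntimeError("degenerate logistic fit: top == bottom")
    return LogisticFit(
        bottom=float(params["bottom"]),
        top=float(params["top"]),
        hill=float(params["hill"]),
        midpoint=float(params["midpoint"]),
        stderr_bottom=stderr["bottom"],
        stderr_top=stderr["top"],
        stderr_hill=stderr["hill"],
        stderr_midpoint=stderr["midpoint"],
        fixed=tuple(sorted(fixed)),
        x_scale=x_scale,
    )


def hts_flag(table: RateTable, threshold_sd: float) -> HTSResult:
    """Flag screening wells whose rate deviates from the plate mean.

    Uses the sample standard deviation (n-1 denominator) and strict
    inequalities; a well exactly at mean +/- k*sd is not flagged.
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    if len(table) < 2:
        raise ValueError("need at least 2 rows to compute a plate mean and SD")
    rates = table.rates
    mean = float(np.mean(rates))
    sd = float(np.std(rates, ddof=1))
    flags: dict[str, str] = {}
    for row in table.rows:
        if sd == 0.0:
            flags[row.label] = "none"
        elif row.rate > mean + threshold_sd * sd:
            flags[row.label] = "above"
        elif row.rate < mean - threshold_sd * sd:
            flags[row.label] = "below"
        else:
            flags[row.label] = "none"
    return HTSResult(mean_rate=mean, sd_rate=sd, threshold_sd=float(threshold_sd), flags=flags)


def subtract_blank_rates(table: RateTable, blank_label: str) -> RateTable:
    """Subtract the blank sample's rate from every other row.

    Standard errors combine in quadrature; the blank row is removed.
    """
    blanks = [r for r in table.rows if r.label == blank_label]
    if not blanks:
        raise KeyError(f"blank label {blank_label!r} not found in rate table")
    blank = blanks[0]
    rows = []
    for r in table.rows:
        if r.label == blank_label:
            continue
        rows.append(
            replace(r, rate=r.rate - blank.rate, stderr=math.hypot(r.stderr, blank.stderr))
        )
    if not rows:
        raise ValueError("rate table contains only the blank row")
    return RateTable(tuple(rows))
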