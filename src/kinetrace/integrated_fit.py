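"""Closed-form Michaelis-Menten progress curves and their global fit.

Schnell and Mendoza's closed-form solution of the irreversible
Michaelis-Menten rate law expresses the substrate concentration at time t
through the Lambert W function:

    S(t) = KM * W0( (S0/KM) * exp((S0 - Vmax t) / KM) )

Because the W argument overflows for large S0/KM, evaluation happens in
the log domain throughout: with u = ln(S0/KM) + (S0 - Vmax t)/KM we have
W0(e^u) = omega(u), the Wright omega function, which is well defined for
every real u.

Fitting this curve simultaneously to all traces of a titration (shared KM
and Vmax, one free S0 per trace initialised from the column header) uses
the entire progress curve instead of only its earliest points, which is
what makes the mode valuable when substrate sits below KM and no linear
segment exists. Like every quasi-steady-state treatment it is only valid
when E0 / (KM + S0) << 1; the fit computes that ratio when the enzyme
concentration is supplied and warns when it is not small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import wrightomega

from .trace_io import KineticDataset, subtract_blank_line

__all__ = [
    "SMParams",
    "SMFitResult",
    "schnell_mendoza_curve",
    "fit_schnell_mendoza_global",
    "check_qss_validity",
]

#: warn when E0/(KM+S0) reaches this value; the closed form assumes it is << 1
QSS_WARN_RATIO = 0.1


@dataclass(frozen=True)
class SMParams:
    """Shared Michaelis-Menten parameters plus one initial substrate per trace."""

    km: float
    vmax: float
    s0: tuple[float, ...]
    e0: float | None = None

    def __post_init__(self) -> None:
        if self.km <= 0 or self.vmax <= 0:
            raise ValueError("KM and Vmax must be positive")
        if any(s <= 0 for s in self.s0):
            raise ValueError("all S0 must be positive")
        if self.e0 is not None and self.e0 <= 0:
            raise ValueError("E0 must be positive when given")


@dataclass(frozen=True)
class SMFitResult:
    """Result of the global progress-curve fit."""

    params: SMParams
    stderr_km: float
    stderr_vmax: float
    rss_per_trace: tuple[float, ...]
    qss_ratio_max: float | None
    labels: tuple[str, ...]


def schnell_mendoza_curve(
    t: np.ndarray | Sequence[float] | float,
    s0: float,
    km: float,
    vmax: float,
) -> np.ndarray:
    """Substrate concentration S(t) of the closed-form Michaelis-Menten solution.

    Evaluated on the principal Lambert branch in the log domain, so large
    S0/KM ratios cannot overflow. S(0) equals S0 exactly (W(x e^x) = x) and
    S decreases monotonically to zero.
    """
    if s0 <= 0 or km <= 0 or vmax <= 0:
        raise ValueError("s0, km and vmax must all be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    u = np.log(s0 / km) + (s0 - vmax * t) / km
    s = km * np.real(wrightomega(u))
    if not np.all(np.isfinite(s)):
        raise FloatingPointError("non-finite substrate concentration; check parameters")
    return s


def check_qss_validity(e0: float, km: float, s0: float) -> float:
    """The quasi-steady-state ratio E0 / (KM + S0); the closed form needs it << 1."""
    if e0 <= 0 or km <= 0 or s0 <= 0:
        raise ValueError("e0, km and s0 must all be positive")
    return e0 / (km + s0)


def _median_slope(time: np.ndarray, signal: np.ndarray) -> float:
    return float(np.median(np.diff(signal) / np.diff(time)))


def fit_schnell_mendoza_global(
    dataset: KineticDataset,
    e0: float | None = None,
    blank_label: str | None = None,
    *,
    qss_warn_ratio: float = QSS_WARN_RATIO,
    max_nfev: int = 20000,
) -> SMFitResult:
    """Globally fit KM and Vmax to every trace of a substrate-depletion dataset.

    Signals must already be substrate concentrations decreasing over time
    (apply a transform, and the -1 inversion for product-accumulation data,
    first). If ``blank_label`` is set, a straight line fitted to that trace
    is subtracted from all others before fitting. Each trace's S0 starts at
    its parsed header concentration but is refined as a free parameter —
    nominal concentrations carry pipetting error. Standard errors come from
    the least-squares covariance at the optimum.
    """
    blank_label = blank_label or dataset.blank_label
    if blank_label is not None:
        dataset = subtract_blank_line(dataset, blank_label)
    traces = dataset.traces
    if not traces:
        raise ValueError("no traces to fit")
    if len(traces) < 2:
        warnings.warn("global fit with a single trace; KM and Vmax may be poorly constrained", UserWarning, stacklevel=2)

    med = float(np.median([_median_slope(tr.time, tr.signal) for tr in traces]))
    if med > 0:
        raise ValueError(
            "traces increase over time; substrate-depletion data required. "
            "Product-accumulation signals must be inverted (multiplied by -1) first."
        )

    tiny = 1e-12
    s0_init = np.array(
        [tr.concentration if tr.concentration > 0 else max(float(tr.signal[0]), tiny) for tr in traces]
    )
    s0_init = np.clip(s0_init, tiny, None)

    def _initial_slope(tr):
        k = max(3, len(tr) // 4)
        return _median_slope(tr.time[:k], tr.signal[:k])

    v0_est = max(max(-_initial_slope(tr) for tr in traces), tiny)

    def residuals(p: np.ndarray) -> np.ndarray:
        km, vmax = p[0], p[1]
        s0s = p[2:]
        out = []
        for tr, s0 in zip(traces, s0s):
            out.append(tr.signal - schnell_mendoza_curve(tr.time - tr.time[0], s0, km, vmax))
        return np.concatenate(out)

    km_grid = np.geomspace(0.1 * float(np.median(s0_init)), 10.0 * float(np.max(s0_init)), 5)
    best = None
    for km0 in km_grid:
        vmax0 = v0_est * (km0 + s0_init.max()) / s0_init.max()
        x0 = np.concatenate([[km0, vmax0], s0_init])
        res = least_squares(
            residuals,
            x0,
            bounds=(np.full(x0.size, tiny), np.full(x0.size, np.inf)),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=max_nfev,
        )
        if res.status > 0 and np.all(np.isfinite(res.x)):
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise RuntimeError("global progress-curve fit failed to converge from every KM start")

    km, vmax = float(best.x[0]), float(best.x[1])
    s0s = tuple(float(v) for v in best.x[2:])

    n = sum(len(tr) for tr in traces)
    p = best.x.size
    dof = max(n - p, 1)
    s2 = 2.0 * best.cost / dof
    cov = s2 * np.linalg.pinv(best.jac.T @ best.jac)
    stderr_km = float(np.sqrt(max(cov[0, 0], 0.0)))
    stderr_vmax = float(np.sqrt(max(cov[1, 1], 0.0)))

    rss = []
    for tr, s0 in zip(traces, s0s):
        r = tr.signal - schnell_mendoza_curve(tr.time - tr.time[0], s0, km, vmax)
        rss.append(float(r @ r))

    qss_ratio_max = None
    if e0 is not None:
        qss_ratio_max = max(check_qss_validity(e0, km, s0) for s0 in s0s)
        if qss_ratio_max >= qss_warn_ratio:
            warnings.warn(
                f"quasi-steady-state ratio E0/(KM+S0) reaches {qss_ratio_max:.3g} "
                f"(>= {qss_warn_ratio:g}); the closed-form solution assumes it is << 1",
                UserWarning,
                stacklevel=2,
            )

    return SMFitResult(
        params=SMParams(km=km, vmax=vmax, s0=s0s, e0=e0),
        stderr_km=stderr_km,
        stderr_vmax=stderr_vmax,
        rss_per_trace=tuple(rss),
        qss_ratio_max=qss_ratio_max,
        labels=tuple(tr.label for tr in traces),
    )
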