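"""Synthetic continuous-assay experiments with known ground truth.

Generates the same CSV dialect :mod:`kinetrace.trace_io` reads — time in
the first column, one trace per further column, the titrant concentration
in each header — from exact Michaelis-Menten progress curves (via the
closed-form solution), a signal model ``background + gain * concentration``
and i.i.d. Gaussian read noise in signal space. Three experiment builders
mirror the three analysis modes: a substrate titration (doubling series
0-320, eight traces plus a zero-concentration blank, matching the usual
demonstration design), an inhibitor dose series feeding the 4PL fit, and
a screening plate with planted outlier wells. Every builder returns the
ground truth next to the CSV so downstream tests are self-verifying.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .integrated_fit import schnell_mendoza_curve
from .trace_io import KineticTrace

__all__ = [
    "SimConfig",
    "SimulatedTrace",
    "SimulatedExperiment",
    "simulate_progress_curve",
    "simulate_mm_experiment",
    "simulate_ic50_experiment",
    "simulate_hts_plate",
]

#: default doubling substrate series of the demonstration titration (0 is the blank)
DEFAULT_S0_SERIES = (5.0, 10.0, 20.0, 40.0, 80.0, 160.0, 320.0)


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth kinetic parameters and instrument model for the generator.

    Defaults describe a typical photometric titration: KM = 100 and
    Vmax = 5 in concentration units per time unit, a doubling substrate
    series up to 320, one-minute-style reads over 0-60 time units, unit
    signal gain and 0.5 signal-units read noise.
    """

    km: float = 100.0
    vmax: float = 5.0
    s0_list: tuple[float, ...] = DEFAULT_S0_SERIES
    times: tuple[float, ...] = tuple(np.arange(0.0, 60.5, 0.5))
    noise_sd: float = 0.5
    background: float = 0.0
    delay: float = 0.0
    signal_gain: float = 1.0
    direction: str = "substrate_loss"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.km <= 0 or self.vmax <= 0:
            raise ValueError("km and vmax must be positive")
        if any(s <= 0 for s in self.s0_list):
            raise ValueError("all s0 values must be positive")
        t = np.asarray(self.times, dtype=float)
        if t.size < 3 or not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing with >= 3 points")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")
        if self.direction not in ("substrate_loss", "product_gain"):
            raise ValueError("direction must be 'substrate_loss' or 'product_gain'")

    @property
    def time_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)


class SimulatedTrace(NamedTuple):
    trace: KineticTrace
    truth: dict


class SimulatedExperiment(NamedTuple):
    csv: str
    truth: dict


def _progress_signal(config: SimConfig, s0: float, rng: np.random.Generator) -> np.ndarray:
    """Noisy instrument signal for one progress curve.

    The mixing dead-time shifts the evaluation times: acquisition starts
    ``delay`` after the reaction did, so the first recorded point already
    sits on the depleted part of the true curve.
    """
    t = config.time_array + config.delay
    s = schnell_mendoza_curve(t, s0, config.km, config.vmax)
    if config.direction == "substrate_loss":
        clean = config.background + config.signal_gain * s
    else:
        clean = config.background + config.signal_gain * (s0 - s)
    noise = rng.normal(0.0, config.noise_sd, size=clean.size) if config.noise_sd > 0 else 0.0
    return clean + noise


def simulate_progress_curve(config: SimConfig, s0: float, *, label: str | None = None) -> SimulatedTrace:
    """One simulated kinetic trace with its ground truth.

    The true initial rate recorded alongside is the Michaelis-Menten
    velocity at S0, Vmax * S0 / (KM + S0), scaled by the signal gain (and
    negated for substrate-loss signals, which fall over time).
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    rng = np.random.default_rng(config.seed)
    signal = _progress_signal(config, s0, rng)
    label = label if label is not None else _format_number(s0)
    trace = KineticTrace(label=label, concentration=s0, time=config.time_array, signal=signal)
    v0 = config.vmax * s0 / (config.km + s0)
    sign = -1.0 if config.direction == "substrate_loss" else 1.0
    truth = {
        "km": config.km,
        "vmax": config.vmax,
        "s0": s0,
        "v0_concentration": v0,
        "v0_signal": sign * config.signal_gain * v0,
        "delay": config.delay,
    }
    return SimulatedTrace(trace=trace, truth=truth)


def _format_number(x: float) -> str:
    return f"{x:.10g}"


def _to_csv(time: np.ndarray, columns: dict[str, np.ndarray]) -> str:
    df = pd.DataFrame({"time": time, **columns})
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.10g")
    return buf.getvalue()


def simulate_mm_experiment(config: SimConfig | None = None) -> SimulatedExperiment:
    """A full substrate titration in CSV form, blank column included.

    Column headers are the S0 values; the "0" column is an enzyme-free
    blank carrying only background and noise. Truth records KM, Vmax and
    the per-trace true initial velocities.
    """
    config = config if config is not None else SimConfig()
    rng = np.random.default_rng(config.seed)
    t = config.time_array
    columns: dict[str, np.ndarray] = {}
    blank = np.full(t.size, config.background, dtype=float)
    if config.noise_sd > 0:
        blank = blank + rng.normal(0.0, config.noise_sd, size=t.size)
    columns["0"] = blank
    v0 = {}
    for s0 in config.s0_list:
        columns[_format_number(s0)] = _progress_signal(config, s0, rng)
        v0[_format_number(s0)] = config.vmax * s0 / (config.km + s0)
    truth = {
        "km": config.km,
        "vmax": config.vmax,
        "s0": dict(zip((_format_number(s) for s in config.s0_list), config.s0_list)),
        "v0_concentration": v0,
        "direction": config.direction,
        "signal_gain": config.signal_gain,
        "background": config.background,
        "delay": config.delay,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
    }
    return SimulatedExperiment(csv=_to_csv(t, columns), truth=truth)


def logistic4_rate(conc: float, bottom: float, top: float, hill: float, midpoint_log10: float) -> float:
    """True 4PL rate at one inhibitor concentration (midpoint on the log10 axis)."""
    if conc <= 0:
        raise ValueError("concentration must be positive")
    x = np.log10(conc)
    return float(bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (midpoint_log10 - x))))


def simulate_ic50_experiment(
    true_params: dict,
    config: SimConfig | None = None,
    concentrations: Sequence[float] | None = None,
) -> SimulatedExperiment:
    """Dose-response experiment: one straight-line trace per inhibitor concentration.

    ``true_params`` needs bottom, top, hill and midpoint (the log10 of the
    IC50/EC50 in the concentration units used). The default design is eight
    concentrations log-spaced three decades either side of the midpoint.
    The slope of each trace is the 4PL value at its concentration.
    """
    config = config if config is not None else SimConfig()
    bottom, top = float(true_params["bottom"]), float(true_params["top"])
    hill, mid = float(true_params["hill"]), float(true_params["midpoint"])
    if concentrations is None:
        concentrations = np.logspace(mid - 3.0, mid + 3.0, 8)
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("dose-response concentrations must be positive")
    rng = np.random.default_rng(config.seed)
    t = config.time_array
    columns: dict[str, np.ndarray] = {}
    rates = {}
    for c in conc:
        rate = logistic4_rate(c, bottom, top, hill, mid)
        clean = config.background + rate * t
        noise = rng.normal(0.0, config.noise_sd, size=t.size) if config.noise_sd > 0 else 0.0
        columns[_format_number(c)] = clean + noise
        rates[_format_number(c)] = rate
    truth = {
        "bottom": bottom,
        "top": top,
        "hill": hill,
        "midpoint": mid,
        "rates": rates,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
    }
    return SimulatedExperiment(csv=_to_csv(t, columns), truth=truth)


def simulate_hts_plate(
    n_wells: int,
    outlier_spec: Sequence[tuple[int, float]] = (),
    config: SimConfig | None = None,
    *,
    baseline_rate: float = 1.0,
    well_sd: float = 0.05,
) -> SimulatedExperiment:
    """Screening plate: line traces with normally distributed baseline slopes.

    ``outlier_spec`` plants wells at ``baseline_rate + z * well_sd`` for
    each ``(well_index, z)`` pair — activators at positive z, inhibitors at
    negative z. Headers are ``well_<i>`` so the well index doubles as the
    parsed "concentration".
    """
    if n_wells < 2:
        raise ValueError("need at least 2 wells")
    config = config if config is not None else SimConfig()
    rng = np.random.default_rng(config.seed)
    slopes = rng.normal(baseline_rate, well_sd, size=n_wells)
    planted = {}
    for idx, z in outlier_spec:
        if not 0 <= idx < n_wells:
            raise ValueError(f"outlier index {idx} outside plate of {n_wells} wells")
        slopes[idx] = baseline_rate + z * well_sd
        planted[int(idx)] = float(z)
    t = config.time_array
    columns: dict[str, np.ndarray] = {}
    for i, slope in enumerate(slopes):
        clean = config.background + slope * t
        noise = rng.normal(0.0, config.noise_sd, size=t.size) if config.noise_sd > 0 else 0.0
        columns[f"well_{i}"] = clean + noise
    truth = {
        "baseline_rate": baseline_rate,
        "well_sd": well_sd,
        "slopes": {f"well_{i}": float(s) for i, s in enumerate(slopes)},
        "planted": planted,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
    }
    return SimulatedExperiment(csv=_to_csv(t, columns), truth=truth)
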