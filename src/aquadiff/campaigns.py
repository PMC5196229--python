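"""Simulation campaigns: ADC versus permeability / labelled-cell fraction.

Two campaigns mirror the pellet model studies: a sweep of the (uniform)
membrane permeability, and a sweep of the fraction of high-permeability
cells in a mixed population averaged over random label arrangements.  The
resulting monotone ADC(P) curve supports inversion of a measured ADC to a
membrane permeability.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .dwi import GradientScheme, adc_from_trajectories
from .errors import ConfigurationError, OutOfRangeError
from .lattice import (
    HIGH_PERM,
    LOW_PERM,
    CellLattice,
    assign_labels,
    build_fcc_lattice,
)
from .units import tau_us_to_ms

__all__ = [
    "SweepTable",
    "permeability_sweep",
    "fraction_sweep",
    "invert_adc_to_permeability",
    "invert_adc_with_trend_extrapolation",
]

#: b-value (s/mm^2) used to read out simulated ensembles; top of the
#: experimental 0-800 s/mm^2 range, where attenuation is well resolved.
DEFAULT_READOUT_B = 800.0
DEFAULT_DELTA_MS = 7.0

_AXES = np.eye(3)


@dataclass
class SweepTable:
    """Simulated ADC on a grid of (axis value, effective diffusion time).

    ``axis_name`` is ``"permeability"`` (um/ms) or ``"fraction"``
    (dimensionless).  ``adc`` and ``adc_se`` have shape
    (len(axis_values), len(delta_eff_values)), in um^2/s.
    """

    axis_name: str
    axis_values: np.ndarray
    delta_eff_values: np.ndarray  # ms
    adc: np.ndarray
    adc_se: np.ndarray
    n_walkers: int
    n_arrangements: int = 1
    seeds: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.axis_values = np.asarray(self.axis_values, dtype=float)
        self.delta_eff_values = np.asarray(self.delta_eff_values, dtype=float)
        self.adc = np.asarray(self.adc, dtype=float)
        self.adc_se = np.asarray(self.adc_se, dtype=float)

    def column(self, delta_eff_ms: float):
        """ADC and SE versus axis value at one diffusion time."""
        k = int(np.argmin(np.abs(self.delta_eff_values - delta_eff_ms)))
        if abs(self.delta_eff_values[k] - delta_eff_ms) > 1.0:
            raise OutOfRangeError(
                f"sweep does not cover Delta_eff={delta_eff_ms} ms "
                f"(available: {self.delta_eff_values.tolist()})"
            )
        return self.adc[:, k], self.adc_se[:, k]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, av in enumerate(self.axis_values):
            for k, t in enumerate(self.delta_eff_values):
                rows.append(
                    {
                        self.axis_name: av,
                        "delta_eff_ms": t,
                        "adc_um2_per_s": self.adc[a, k],
                        "adc_se_um2_per_s": self.adc_se[a, k],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "axis_name": self.axis_name,
                "axis_values": self.axis_values.tolist(),
                "delta_eff_values": self.delta_eff_values.tolist(),
                "adc": self.adc.tolist(),
                "adc_se": self.adc_se.tolist(),
                "n_walkers": self.n_walkers,
                "n_arrangements": self.n_arrangements,
                "seeds": self.seeds,
                "meta": self.meta,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SweepTable":
        d = json.loads(text)
        return cls(
            axis_name=d["axis_name"],
            axis_values=np.array(d["axis_values"]),
            delta_eff_values=np.array(d["delta_eff_values"]),
            adc=np.array(d["adc"]),
            adc_se=np.array(d["adc_se"]),
            n_walkers=d["n_walkers"],
            n_arrangements=d["n_arrangements"],
            seeds=d["seeds"],
            meta=d["meta"],
        )


def _steps_for_times(delta_eff_ms: np.ndarray, tau_ms: float):
    steps = np.asarray(np.round(np.asarray(delta_eff_ms) / tau_ms), dtype=np.int64)
    if np.any(steps < 1):
        raise ConfigurationError("every Delta_eff must span at least one time step")
    return steps


def _adc_at_snapshots(snapshots, record_steps, tau_ms, delta_ms, readout_b):
    """Axis-averaged attenuation ADC (and SE) at each recorded time."""
    adcs = np.empty(len(record_steps))
    ses = np.empty(len(record_steps))
    for k, s in enumerate(record_steps):
        t_eff = s * tau_ms  # actual simulated diffusion time
        disp = snapshots[int(s)]
        vals = []
        errs = []
        for ax in range(3):
            scheme = GradientScheme.for_b(
                readout_b, Delta_ms=t_eff + delta_ms / 3.0, delta_ms=delta_ms,
                axis=tuple(_AXES[ax]),
            )
            r = adc_from_trajectories(disp[:, ax], scheme)
            vals.append(r.adc)
            errs.append(r.standard_error)
        adcs[k] = float(np.mean(vals))
        ses[k] = float(np.sqrt(np.sum(np.square(errs)))) / 3.0
    return adcs, ses


def permeability_sweep(
    P_values,
    delta_eff_values_ms,
    lattice_config: dict | None = None,
    sim: engine.SimulationParams | None = None,
    readout_b_s_per_mm2: float = DEFAULT_READOUT_B,
    delta_ms: float = DEFAULT_DELTA_MS,
    seed: int = 0,
    lattice: CellLattice | None = None,
) -> SweepTable:
    """Simulate ADC(Delta_eff) for each uniform membrane permeability.

    One lattice geometry — built from the sweep seed, or passed in — is
    shared across the whole permeability grid so that the curve isolates
    the permeability effect (lattice realizations differ enough in packing
    fraction to otherwise swamp the walker-level error).  For each P a
    fresh walker ensemble is propagated to the largest requested diffusion
    time, snapshotting displacements at each requested time; ADC is the
    attenuation estimator averaged over the three gradient axes.
    """
    P_values = np.asarray(P_values, dtype=float)
    if np.any(P_values < 0):
        raise ConfigurationError("permeabilities must be >= 0")
    delta_eff_values_ms = np.asarray(delta_eff_values_ms, dtype=float)
    sim = sim or engine.SimulationParams()
    lattice_config = dict(lattice_config or {})
    tau_ms = tau_us_to_ms(sim.tau_us)
    record = _steps_for_times(delta_eff_values_ms, tau_ms)
    n_steps = int(record.max())

    ss = np.random.SeedSequence(seed)
    s_lat = ss.spawn(1)[0]
    lat_seed = int(s_lat.generate_state(1)[0] & 0x7FFFFFFF)
    lat = lattice if lattice is not None else build_fcc_lattice(
        seed=lat_seed, **lattice_config
    )
    # uniform-permeability sweep: every cell carries the same label
    lat = dataclasses.replace(lat, labels=np.full(lat.n_cells, LOW_PERM, dtype="U16"))
    adc = np.empty((len(P_values), len(delta_eff_values_ms)))
    adc_se = np.empty_like(adc)
    seeds = {"lattice": None if lattice is not None else lat_seed}
    for a, P in enumerate(P_values):
        s_walk, s_prop = ss.spawn(2)
        walk_seed = int(s_walk.generate_state(1)[0] & 0x7FFFFFFF)
        prop_seed = int(s_prop.generate_state(1)[0] & 0x7FFFFFFF)
        seeds[f"P={P}"] = [walk_seed, prop_seed]
        params = dataclasses.replace(
            sim, permeability_by_label={LOW_PERM: float(P)}, seed=prop_seed
        )
        ens = engine.init_walkers(lat, sim.n_walkers, seed=walk_seed)
        out = engine.propagate(ens, lat, params, n_steps, record_steps=record)
        adc[a], adc_se[a] = _adc_at_snapshots(
            out.snapshots, record, tau_ms, delta_ms, readout_b_s_per_mm2
        )
    return SweepTable(
        axis_name="permeability",
        axis_values=P_values,
        delta_eff_values=delta_eff_values_ms,
        adc=adc,
        adc_se=adc_se,
        n_walkers=sim.n_walkers,
        n_arrangements=1,
        seeds=seeds,
        meta={
            "tau_us": sim.tau_us,
            "d_in_um2s": sim.d_in_um2s,
            "d_ex_um2s": sim.d_ex_um2s,
            "readout_b_s_per_mm2": readout_b_s_per_mm2,
            "delta_ms": delta_ms,
            "lattice_config": lattice_config,
            "seed": seed,
        },
    )


def fraction_sweep(
    fractions,
    P_high: float = 0.14,
    P_low: float = 0.039,
    n_arrangements: int = 100,
    delta_eff_values_ms=(398.0,),
    lattice_config: dict | None = None,
    sim: engine.SimulationParams | None = None,
    readout_b_s_per_mm2: float = DEFAULT_READOUT_B,
    delta_ms: float = DEFAULT_DELTA_MS,
    seed: int = 0,
    lattice: CellLattice | None = None,
) -> SweepTable:
    """Simulate ADC versus the fraction of high-permeability cells.

    For each fraction the label assignment is redrawn ``n_arrangements``
    times on a fixed lattice geometry (fresh walker/propagation seeds each
    time); the table reports the mean ADC over arrangements and, as SE, the
    standard error of that mean (which folds in both walker noise and
    arrangement-to-arrangement variability).
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ConfigurationError("fractions must lie in [0, 1]")
    if n_arrangements < 1:
        raise ConfigurationError("n_arrangements must be >= 1")
    delta_eff_values_ms = np.asarray(delta_eff_values_ms, dtype=float)
    sim = sim or engine.SimulationParams()
    lattice_config = dict(lattice_config or {})
    tau_ms = tau_us_to_ms(sim.tau_us)
    record = _steps_for_times(delta_eff_values_ms, tau_ms)
    n_steps = int(record.max())

    ss = np.random.SeedSequence(seed)
    lat_seed = int(ss.spawn(1)[0].generate_state(1)[0] & 0x7FFFFFFF)
    base_lat = lattice if lattice is not None else build_fcc_lattice(
        seed=lat_seed, **lattice_config
    )
    perm = {LOW_PERM: float(P_low), HIGH_PERM: float(P_high)}

    adc = np.empty((len(fractions), len(delta_eff_values_ms)))
    adc_se = np.empty_like(adc)
    seeds = {"lattice": lat_seed}
    for a, f in enumerate(fractions):
        per_arr = np.empty((n_arrangements, len(delta_eff_values_ms)))
        per_arr_se = np.empty_like(per_arr)
        for m in range(n_arrangements):
            s_lab, s_walk, s_prop = ss.spawn(3)
            lab_seed = int(s_lab.generate_state(1)[0] & 0x7FFFFFFF)
            walk_seed = int(s_walk.generate_state(1)[0] & 0x7FFFFFFF)
            prop_seed = int(s_prop.generate_state(1)[0] & 0x7FFFFFFF)
            lat = assign_labels(base_lat, float(f), seed=lab_seed)
            params = dataclasses.replace(sim, permeability_by_label=perm, seed=prop_seed)
            ens = engine.init_walkers(lat, sim.n_walkers, seed=walk_seed)
            out = engine.propagate(ens, lat, params, n_steps, record_steps=record)
            per_arr[m], per_arr_se[m] = _adc_at_snapshots(
                out.snapshots, record, tau_ms, delta_ms, readout_b_s_per_mm2
            )
        adc[a] = per_arr.mean(axis=0)
        if n_arrangements > 1:
            adc_se[a] = per_arr.std(axis=0, ddof=1) / np.sqrt(n_arrangements)
        else:
            adc_se[a] = per_arr_se[0]
    return SweepTable(
        axis_name="fraction",
        axis_values=fractions,
        delta_eff_values=delta_eff_values_ms,
        adc=adc,
        adc_se=adc_se,
        n_walkers=sim.n_walkers,
        n_arrangements=n_arrangements,
        seeds=seeds,
        meta={
            "P_high": P_high,
            "P_low": P_low,
            "tau_us": sim.tau_us,
            "readout_b_s_per_mm2": readout_b_s_per_mm2,
            "lattice_config": lattice_config,
            "seed": seed,
        },
    )


def _pava_increasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: least-squares non-decreasing fit."""
    y = np.asarray(y, dtype=float)
    level = y.copy()
    weight = np.ones_like(y)
    # block representation
    vals = list(level)
    wts = list(weight)
    idx = [[i] for i in range(len(y))]
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1]:
            w = wts[i] + wts[i + 1]
            v = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / w
            vals[i : i + 2] = [v]
            wts[i : i + 2] = [w]
            idx[i : i + 2] = [idx[i] + idx[i + 1]]
            if i > 0:
                i -= 1
        else:
            i += 1
    out = np.empty_like(y)
    for v, members in zip(vals, idx):
        out[members] = v
    return out


def invert_adc_to_permeability(
    adc_measured: float, sweep: SweepTable, delta_eff_ms: float = 398.0
) -> float:
    """Invert a measured ADC through the simulated ADC(P) curve.

    The tabulated curve is made non-decreasing by a least-squares monotone
    (pool-adjacent-violators) fit — Monte Carlo noise can produce local
    inversions — then inverted by piecewise-linear interpolation.  Values
    outside the tabulated ADC range raise ``OutOfRangeError`` with the
    bracketing values; no extrapolation is performed.
    """
    if sweep.axis_name != "permeability":
        raise ConfigurationError("inversion requires a permeability sweep")
    order = np.argsort(sweep.axis_values)
    P = sweep.axis_values[order]
    adc_col, _ = sweep.column(delta_eff_ms)
    adc_col = adc_col[order]
    mono = _pava_increasing(adc_col)
    if adc_measured < mono[0] or adc_measured > mono[-1]:
        raise OutOfRangeError(
            f"ADC {adc_measured:.4g} um^2/s outside simulated range "
            f"[{mono[0]:.4g}, {mono[-1]:.4g}] for P in [{P[0]}, {P[-1]}] um/ms"
        )
    # strictly increasing support for interp: collapse ties to their P-midpoint
    uniq, inv = np.unique(mono, return_index=False, return_inverse=True)
    P_support = np.array([P[inv == k].mean() for k in range(len(uniq))])
    if len(uniq) == 1:
        return float(P_support[0])
    return float(np.interp(adc_measured, uniq, P_support))


def invert_adc_with_trend_extrapolation(
    adc_measured: float, sweep: SweepTable, delta_eff_ms: float = 398.0
) -> tuple[float, bool]:
    """Inversion with a linear-trend fallback outside the simulated range.

    Within the tabulated ADC range this is exactly
    :func:`invert_adc_to_permeability` (flag ``False``).  Outside it, the
    least-squares line through the adjacent half of the monotone curve is
    extrapolated to the measured ADC (flag ``True``).  The extrapolated
    branch exists because a measured ADC can exceed the simulated curve's
    ceiling (the membrane-transparent composite limit); such a value cannot
    be interpolated and the extrapolation makes the disagreement explicit
    and quantifiable instead of unreportable.
    """
    try:
        return invert_adc_to_permeability(adc_measured, sweep, delta_eff_ms), False
    except OutOfRangeError:
        pass
    order = np.argsort(sweep.axis_values)
    P = sweep.axis_values[order]
    adc_col, _ = sweep.column(delta_eff_ms)
    mono = _pava_increasing(adc_col[order])
    half = max(2, len(P) // 2)
    if adc_measured > mono[-1]:
        Ph, ah = P[-half:], mono[-half:]
    else:
        Ph, ah = P[:half], mono[:half]
    slope, intercept = np.polyfit(ah, Ph, 1)
    if slope <= 0:
        raise OutOfRangeError(
            "simulated trend is flat; cannot extrapolate a permeability for "
            f"ADC {adc_measured:.4g} um^2/s"
        )
    return float(slope * adc_measured + intercept), True
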