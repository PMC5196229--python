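"""Monte Carlo random walk of water molecules through a packed-cell lattice.

Walkers take Gaussian steps with a compartment-specific free diffusivity
(per-axis scale sqrt(2*D*tau)).  When a step's path crosses a cell membrane
the walker is either transmitted (with probability p = P*sqrt(pi*tau/D_in),
where P is the membrane water permeability) or specularly reflected; the
remaining path length is carried across the event, rescaled by
sqrt(D_new/D_old) on a compartment change so that step-length statistics
stay consistent with the local diffusivity.

Coordinates are unwrapped (the periodic box applies to the geometry only),
emulating an effectively infinite pellet.  Internally lengths are um and
times ms; constructors accept the conventional um^2/s, um/ms and us units.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import ConfigurationError
from .lattice import EXTRACELLULAR, HIGH_PERM, LOW_PERM, CellLattice
from .units import d_um2s_to_um2ms, tau_us_to_ms

__all__ = [
    "SimulationParams",
    "WalkerEnsemble",
    "init_walkers",
    "step_sigma",
    "transmission_probability",
    "propagate",
]


@dataclass
class SimulationParams:
    """Engine parameters.

    Defaults follow the pellet-at-bore-temperature regime: time step 50 us,
    intracellular free diffusivity 554.7 um^2/s, extracellular 1664.2 um^2/s,
    and membrane permeabilities of 0.039 um/ms (control cells) and 0.14 um/ms
    (aquaporin-expressing cells).
    """

    tau_us: float = 50.0
    d_in_um2s: float = 554.7
    d_ex_um2s: float = 1664.2
    permeability_by_label: dict = field(
        default_factory=lambda: {LOW_PERM: 0.039, HIGH_PERM: 0.14}
    )
    #: Optional direct transmission probabilities per label, bypassing the
    #: permeability formula (e.g. p=1 as an infinite-permeability surrogate).
    transmission_by_label: dict | None = None
    #: If True, the reference diffusivity in the transmission probability is
    #: that of the donor (departure-side) compartment instead of always D_in.
    donor_side_reference: bool = False
    n_walkers: int = 10_000
    seed: int = 0
    max_crossings: int = 10

    def validate(self) -> None:
        if self.tau_us <= 0:
            raise ConfigurationError("tau must be positive")
        if self.d_in_um2s <= 0 or self.d_ex_um2s <= 0:
            raise ConfigurationError("diffusivities must be positive")
        if self.n_walkers < 1:
            raise ConfigurationError("n_walkers must be >= 1")
        for label, p in self.permeability_by_label.items():
            if p < 0:
                raise ConfigurationError(f"permeability for {label!r} is negative")


@dataclass
class WalkerEnsemble:
    """Positions and compartment tags of the walker ensemble.

    ``positions`` are unwrapped; ``displacement`` is always exactly
    ``positions - start_positions``.  ``snapshots`` maps a step count to the
    (n, 3) displacement array recorded after that many steps.
    """

    start_positions: np.ndarray
    positions: np.ndarray
    compartments: np.ndarray
    seed: int | None = None
    snapshots: dict | None = None
    n_aborted_steps: int = 0

    @property
    def n_walkers(self) -> int:
        return len(self.positions)

    @property
    def displacement(self) -> np.ndarray:
        return self.positions - self.start_positions


def step_sigma(d_um2s: float, tau_us: float) -> float:
    """Per-axis Gaussian step scale sqrt(2*D*tau) in um.

    D is given in um^2/s and tau in us; e.g. D=554.7 um^2/s at tau=50 us
    gives 0.2355 um.
    """
    if d_um2s <= 0 or tau_us <= 0:
        raise ConfigurationError("D and tau must be positive")
    return math.sqrt(2.0 * d_um2s_to_um2ms(d_um2s) * tau_us_to_ms(tau_us))


def transmission_probability(
    p_um_per_ms: float, d_reference_um2s: float = 554.7, tau_us: float = 50.0
) -> float:
    """Membrane transmission probability p = P*sqrt(pi*tau/D).

    The reference diffusivity is the intracellular one by convention.  A
    result above 1 is a configuration error (reduce the time step) rather
    than a silent clamp.
    """
    if p_um_per_ms < 0:
        raise ConfigurationError("permeability must be non-negative")
    p = p_um_per_ms * math.sqrt(
        math.pi * tau_us_to_ms(tau_us) / d_um2s_to_um2ms(d_reference_um2s)
    )
    if p > 1.0:
        raise ConfigurationError(
            f"transmission probability {p:.3f} exceeds 1; use a smaller time step"
        )
    return p


def init_walkers(lattice: CellLattice, n_walkers: int, seed: int = 0) -> WalkerEnsemble:
    """Scatter walkers uniformly over the periodic box.

    Compartment occupancy is therefore proportional to volume fractions in
    expectation.  Deterministic for a fixed seed.
    """
    if n_walkers < 1:
        raise ConfigurationError("n_walkers must be >= 1")
    rng = np.random.default_rng(seed)
    start = rng.uniform(0.0, 1.0, size=(n_walkers, 3)) * lattice.box_lengths
    comp = np.asarray(lattice.locate(start), dtype=np.int64).reshape(-1)
    return WalkerEnsemble(
        start_positions=start,
        positions=start.copy(),
        compartments=comp,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# neighbour grid


def _build_grid(lattice: CellLattice, reach: float):
    """Per-voxel candidate sphere lists covering every surface within
    ``reach`` of any point of the voxel."""
    box = lattice.box_lengths
    ng = max(3, int(np.floor(box.min() / 8.0)))
    voxel = box / ng
    half_diag = 0.5 * float(np.linalg.norm(voxel))
    ii, jj, kk = np.meshgrid(range(ng), range(ng), range(ng), indexing="ij")
    vc = (np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) + 0.5) * voxel
    diff = vc[:, None, :] - lattice.centers[None, :, :]
    diff = diff - box * np.round(diff / box)
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    within = d <= lattice.radii[None, :] + half_diag + reach
    counts = within.sum(axis=1)
    maxc = max(1, int(counts.max()))
    cand = np.full((len(vc), maxc), -1, dtype=np.int64)
    for v in range(len(vc)):
        idx = np.nonzero(within[v])[0]
        cand[v, : len(idx)] = idx
    return ng, voxel, cand, counts.astype(np.int64)


# ---------------------------------------------------------------------------
# kernel

_EPS_T = 1e-10  # parametric exclusion at segment start
_NUDGE = 1e-7  # um, offset off a membrane after an event


@njit(cache=True)
def _walk_kernel(
    pos,
    start,
    comp_arr,
    centers,
    radii,
    p_from_in,
    p_from_out,
    box,
    d_in,
    d_ex,
    tau,
    n_steps,
    record_steps,
    out_disp,
    ng,
    voxel,
    grid_cand,
    grid_cnt,
    reach,
    max_crossings,
    seed,
):  # pragma: no cover - exercised via propagate()
    np.random.seed(seed)
    n_walkers = pos.shape[0]
    n_cells = centers.shape[0]
    n_rec = record_steps.shape[0]
    aborted = 0
    bx, by, bz = box[0], box[1], box[2]
    for i in range(n_walkers):
        px, py, pz = pos[i, 0], pos[i, 1], pos[i, 2]
        comp = comp_arr[i]
        safe = -1.0
        rec = 0
        for s in range(n_steps):
            if comp >= 0:
                D = d_in
            else:
                D = d_ex
            sig = math.sqrt(2.0 * D * tau)
            vx = sig * np.random.standard_normal()
            vy = sig * np.random.standard_normal()
            vz = sig * np.random.standard_normal()
            l = math.sqrt(vx * vx + vy * vy + vz * vz)
            if l < safe:
                px += vx
                py += vy
                pz += vz
                safe -= l
            else:
                # recompute clearance to the nearest membrane
                wx = px - bx * math.floor(px / bx)
                wy = py - by * math.floor(py / by)
                wz = pz - bz * math.floor(pz / bz)
                if comp >= 0:
                    dx = wx - centers[comp, 0]
                    dy = wy - centers[comp, 1]
                    dz = wz - centers[comp, 2]
                    dx -= bx * math.floor(dx / bx + 0.5)
                    dy -= by * math.floor(dy / by + 0.5)
                    dz -= bz * math.floor(dz / bz + 0.5)
                    cl = radii[comp] - math.sqrt(dx * dx + dy * dy + dz * dz)
                else:
                    cl = reach
                    vix = int(wx / voxel[0])
                    viy = int(wy / voxel[1])
                    viz = int(wz / voxel[2])
                    if vix >= ng:
                        vix = ng - 1
                    if viy >= ng:
                        viy = ng - 1
                    if viz >= ng:
                        viz = ng - 1
                    vi = (vix * ng + viy) * ng + viz
                    for q in range(grid_cnt[vi]):
                        j = grid_cand[vi, q]
                        dx = wx - centers[j, 0]
                        dy = wy - centers[j, 1]
                        dz = wz - centers[j, 2]
                        dx -= bx * math.floor(dx / bx + 0.5)
                        dy -= by * math.floor(dy / by + 0.5)
                        dz -= bz * math.floor(dz / bz + 0.5)
                        dj = math.sqrt(dx * dx + dy * dy + dz * dz) - radii[j]
                        if dj < cl:
                            cl = dj
                if l < cl:
                    px += vx
                    py += vy
                    pz += vz
                    safe = cl - l
                else:
                    # event loop: walk sub-segments across membrane events
                    safe = -1.0
                    crossings = 0
                    while True:
                        l2 = vx * vx + vy * vy + vz * vz
                        if l2 < 1e-24:
                            break
                        l = math.sqrt(l2)
                        wx = px - bx * math.floor(px / bx)
                        wy = py - by * math.floor(py / by)
                        wz = pz - bz * math.floor(pz / bz)
                        tmin = 2.0
                        jmin = -1
                        if comp >= 0:
                            j0 = comp
                            j1 = j0 + 1
                            use_grid = False
                        elif l <= reach:
                            use_grid = True
                            vix = int(wx / voxel[0])
                            viy = int(wy / voxel[1])
                            viz = int(wz / voxel[2])
                            if vix >= ng:
                                vix = ng - 1
                            if viy >= ng:
                                viy = ng - 1
                            if viz >= ng:
                                viz = ng - 1
                            vi = (vix * ng + viy) * ng + viz
                            j0 = 0
                            j1 = grid_cnt[vi]
                        else:
                            use_grid = False
                            j0 = 0
                            j1 = n_cells
                        for q in range(j0, j1):
                            if use_grid:
                                j = grid_cand[vi, q]
                            else:
                                j = q
                            rx = centers[j, 0] - wx
                            ry = centers[j, 1] - wy
                            rz = centers[j, 2] - wz
                            rx -= bx * math.floor(rx / bx + 0.5)
                            ry -= by * math.floor(ry / by + 0.5)
                            rz -= bz * math.floor(rz / bz + 0.5)
                            bq = vx * rx + vy * ry + vz * rz
                            cq = rx * rx + ry * ry + rz * rz - radii[j] * radii[j]
                            disc = bq * bq - l2 * cq
                            if disc <= 0.0:
                                continue
                            sq = math.sqrt(disc)
                            t1 = (bq - sq) / l2
                            t2 = (bq + sq) / l2
                            t = -1.0
                            if t1 > _EPS_T and t1 <= 1.0:
                                t = t1
                            elif t2 > _EPS_T and t2 <= 1.0:
                                t = t2
                            else:
                                continue
                            if t < tmin:
                                tmin = t
                                jmin = j
                        if jmin < 0:
                            px += vx
                            py += vy
                            pz += vz
                            break
                        # advance to the membrane
                        px += tmin * vx
                        py += tmin * vy
                        pz += tmin * vz
                        rem = (1.0 - tmin) * l
                        # outward unit normal at the hit point
                        wx = px - bx * math.floor(px / bx)
                        wy = py - by * math.floor(py / by)
                        wz = pz - bz * math.floor(pz / bz)
                        nx = wx - centers[jmin, 0]
                        ny = wy - centers[jmin, 1]
                        nz = wz - centers[jmin, 2]
                        nx -= bx * math.floor(nx / bx + 0.5)
                        ny -= by * math.floor(ny / by + 0.5)
                        nz -= bz * math.floor(nz / bz + 0.5)
                        nn = math.sqrt(nx * nx + ny * ny + nz * nz)
                        nx /= nn
                        ny /= nn
                        nz /= nn
                        ux = vx / l
                        uy = vy / l
                        uz = vz / l
                        transmit = False
                        if comp == jmin or comp < 0:
                            if comp >= 0:
                                pj = p_from_in[jmin]
                            else:
                                pj = p_from_out[jmin]
                            if np.random.random() < pj:
                                transmit = True
                        if transmit:
                            if comp == jmin:
                                comp = -1
                                Dn = d_ex
                            else:
                                comp = jmin
                                Dn = d_in
                            rem *= math.sqrt(Dn / D)
                            D = Dn
                            if comp >= 0:
                                px -= nx * _NUDGE
                                py -= ny * _NUDGE
                                pz -= nz * _NUDGE
                            else:
                                px += nx * _NUDGE
                                py += ny * _NUDGE
                                pz += nz * _NUDGE
                            vx = ux * rem
                            vy = uy * rem
                            vz = uz * rem
                        else:
                            dot = ux * nx + uy * ny + uz * nz
                            ux -= 2.0 * dot * nx
                            uy -= 2.0 * dot * ny
                            uz -= 2.0 * dot * nz
                            if comp == jmin:
                                px -= nx * _NUDGE
                                py -= ny * _NUDGE
                                pz -= nz * _NUDGE
                            else:
                                px += nx * _NUDGE
                                py += ny * _NUDGE
                                pz += nz * _NUDGE
                            vx = ux * rem
                            vy = uy * rem
                            vz = uz * rem
                        crossings += 1
                        if crossings >= max_crossings:
                            aborted += 1
                            break
            if rec < n_rec and s + 1 == record_steps[rec]:
                out_disp[rec, i, 0] = px - start[i, 0]
                out_disp[rec, i, 1] = py - start[i, 1]
                out_disp[rec, i, 2] = pz - start[i, 2]
                rec += 1
        pos[i, 0] = px
        pos[i, 1] = py
        pos[i, 2] = pz
        comp_arr[i] = comp
    return aborted


def _transmission_arrays(lattice: CellLattice, params: SimulationParams):
    """Per-cell transmission probabilities for crossings from inside/outside."""
    p_in = np.empty(lattice.n_cells)
    p_out = np.empty(lattice.n_cells)
    for label in np.unique(lattice.labels):
        mask = lattice.labels == label
        if params.transmission_by_label is not None and label in params.transmission_by_label:
            p = float(params.transmission_by_label[label])
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("transmission override must lie in [0, 1]")
            p_in[mask] = p
            p_out[mask] = p
            continue
        if label not in params.permeability_by_label:
            raise ConfigurationError(f"no permeability configured for label {label!r}")
        perm = params.permeability_by_label[label]
        p_in[mask] = transmission_probability(perm, params.d_in_um2s, params.tau_us)
        d_ref_out = params.d_ex_um2s if params.donor_side_reference else params.d_in_um2s
        p_out[mask] = transmission_probability(perm, d_ref_out, params.tau_us)
    return p_in, p_out


def propagate(
    ensemble: WalkerEnsemble,
    lattice: CellLattice,
    params: SimulationParams,
    n_steps: int,
    record_steps=None,
) -> WalkerEnsemble:
    """Propagate the ensemble ``n_steps`` time steps through the lattice.

    ``record_steps`` is an optional increasing sequence of step counts after
    which the displacement of every walker is snapshotted (returned in
    ``snapshots``).  The input ensemble is not modified; the returned one
    carries updated unwrapped positions and compartment tags.  Steps in
    which a walker undergoes more than ``params.max_crossings`` membrane
    interactions are aborted at the last event (the count is reported in
    ``n_aborted_steps``; a non-negligible fraction indicates the time step
    is too large).
    """
    params.validate()
    if n_steps < 0:
        raise ConfigurationError("n_steps must be non-negative")
    if record_steps is None:
        record_idx = np.empty(0, dtype=np.int64)
    else:
        record_idx = np.asarray(sorted(set(int(r) for r in record_steps)), dtype=np.int64)
        if len(record_idx) and (record_idx[0] < 1 or record_idx[-1] > n_steps):
            raise ConfigurationError("record_steps must lie in [1, n_steps]")

    pos = np.ascontiguousarray(ensemble.positions, dtype=np.float64).copy()
    start = np.ascontiguousarray(ensemble.start_positions, dtype=np.float64)
    comp = np.asarray(ensemble.compartments, dtype=np.int64).copy()
    out_disp = np.zeros((len(record_idx), len(pos), 3))

    if n_steps == 0:
        return dataclasses.replace(
            ensemble, positions=pos, compartments=comp, snapshots={}
        )

    tau_ms = tau_us_to_ms(params.tau_us)
    d_in = d_um2s_to_um2ms(params.d_in_um2s)
    d_ex = d_um2s_to_um2ms(params.d_ex_um2s)
    sigma_max = math.sqrt(2.0 * max(d_in, d_ex) * tau_ms)
    reach = 8.0 * sigma_max
    p_in, p_out = _transmission_arrays(lattice, params)
    ng, voxel, grid_cand, grid_cnt = _build_grid(lattice, reach)

    aborted = _walk_kernel(
        pos,
        start,
        comp,
        np.ascontiguousarray(lattice.centers),
        np.ascontiguousarray(lattice.radii),
        p_in,
        p_out,
        np.ascontiguousarray(lattice.box_lengths),
        d_in,
        d_ex,
        tau_ms,
        int(n_steps),
        record_idx,
        out_disp,
        ng,
        voxel,
        grid_cand,
        grid_cnt,
        reach,
        int(params.max_crossings),
        int(params.seed) & 0x7FFFFFFF,
    )

    snapshots = {int(k): out_disp[q] for q, k in enumerate(record_idx)}
    return dataclasses.replace(
        ensemble,
        positions=pos,
        compartments=comp,
        snapshots=snapshots,
        n_aborted_steps=int(aborted),
    )
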