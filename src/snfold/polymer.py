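"""Contact-constrained chromosome reconstruction by dissipative particle dynamics.

A chromosome is modeled as a bead chain (one bead per genomic bin) in
explicit solvent.  DPD is coarse-grained molecular dynamics with soft
conservative forces and a momentum-conserving pairwise thermostat:

* conservative: F_c = a_ij (1 − r/R_c) r̂ for r < R_c (soft repulsion,
  no singularity, so a large time step is stable),
* dissipative:  F_d = −γ_d w(r)² (r̂·v_ij) r̂,
* random:       F_r = σ_n w(r) θ_ij / √dt r̂,   σ_n² = 2 γ_d k_BT,
* elastic:      F_b = −k (r − l₀) r̂ for bonded pairs,

with w(r) = 1 − r/R_c, velocity-Verlet integration, and periodic
boundaries.  Repulsion a_ps > a_pp puts the chain at the theta point
(Flory χ = 0.306·(a_ps − a_pp) ≈ 0.5): a free chain is Gaussian.

Single-cell contacts enter as extra harmonic bonds between the
contacting beads (|i−j| > 1); after equilibration, overstretched
contact bonds (length > l_max) are removed one by one with
re-equilibration — backbone bonds are never removed.  Mean distance
matrices over conformations, model contact maps (distance < R_cut),
the coefficient of difference K between structures, R(s) scaling, and
chromosome-territory radial profiles complete the analysis toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .maps import SparseContactMap

__all__ = [
    "DPDParams",
    "PolymerState",
    "Trajectory",
    "build_system",
    "run_dpd",
    "prune_overstretched_bonds",
    "mean_distance_matrix",
    "model_contact_map",
    "coefficient_of_difference",
    "r_of_s",
    "fit_rs_exponents",
    "radial_profile",
    "smooth_path",
]


@dataclass(frozen=True)
class DPDParams:
    """DPD interaction and integration parameters (DPD reduced units).

    Defaults reproduce the production setting: theta-solvent repulsion
    (χ ≈ 0.5), bond length l₀ = 0.5 with stiffness 40, dt = 0.04,
    number density 3 in a 22³ box.  ``chain_box`` is the edge of the
    sub-cube in which the initial random-walk conformation is grown.
    The dissipative/random pair (γ_d = 4.5, σ_n = 3) satisfies the
    fluctuation–dissipation relation σ_n² = 2 γ_d k_BT at k_BT = 1.
    """

    a_pp: float = 25.0
    a_ss: float = 25.0
    a_ps: float = 26.63
    l0: float = 0.5
    k_bond: float = 40.0
    dt: float = 0.04
    density: float = 3.0
    box: float = 22.0
    r_cut: float = 1.0
    gamma_d: float = 4.5
    kt: float = 1.0
    chain_box: float = 10.0
    lam: float = 0.65  # velocity-prediction factor of the modified Verlet

    @property
    def sigma_n(self) -> float:
        return float(np.sqrt(2.0 * self.gamma_d * self.kt))

    @property
    def chi(self) -> float:
        return 0.306 * (self.a_ps - self.a_pp)


@dataclass
class PolymerState:
    """Particle coordinates/velocities plus the bond list.

    Positions are stored unwrapped (continuous trajectories); wrapping
    happens inside the force kernel.  ``types`` is 0 for polymer beads
    (the first ``n_polymer`` particles) and 1 for solvent.  Bonds are
    index pairs; ``removable`` is False for backbone bonds.
    """

    positions: np.ndarray
    velocities: np.ndarray
    types: np.ndarray
    bonds: np.ndarray  # (n_bonds, 2) int
    removable: np.ndarray  # (n_bonds,) bool
    n_polymer: int
    params: DPDParams

    def bond_lengths(self) -> np.ndarray:
        box = self.params.box
        d = self.positions[self.bonds[:, 0]] - self.positions[self.bonds[:, 1]]
        d -= box * np.round(d / box)
        return np.sqrt((d**2).sum(axis=1))

    def kinetic_temperature(self) -> float:
        return float((self.velocities**2).sum() / (3 * len(self.velocities)))

    def momentum(self) -> np.ndarray:
        return self.velocities.sum(axis=0)


@dataclass
class Trajectory:
    """Sampled polymer-bead frames plus thermodynamic logs."""

    frames: np.ndarray  # (n_frames, n_polymer, 3), unwrapped
    times: np.ndarray  # step index of each frame
    temperature: np.ndarray  # per frame
    final_state: "PolymerState"


def build_system(
    contact_map: SparseContactMap | np.ndarray | None,
    n_beads: int | None = None,
    params: DPDParams = DPDParams(),
    seed: int | None = None,
    with_solvent: bool = True,
) -> PolymerState:
    """Random-walk chain + solvent + contact bonds from a binary map.

    The chain (one bead per bin of the map; or ``n_beads`` for a free
    chain) is grown as a random walk of step l₀ inside a central cube
    of edge ``chain_box``; solvent particles fill the box to number
    density σ.  Every map entry with |i−j| > 1 adds a removable
    harmonic bond; backbone bonds i,i+1 are permanent.

    ``with_solvent=False`` builds the bare chain: for ideal-chain runs
    (all repulsion zero) the pairwise thermostat acts through the
    bonded neighbors, and dropping the solvent makes long relaxation
    runs cheap.
    """
    rng = np.random.default_rng(seed)
    if contact_map is None:
        if n_beads is None:
            raise ValueError("need a contact map or n_beads")
        contact_pairs = np.zeros((0, 2), dtype=np.int64)
    else:
        if isinstance(contact_map, SparseContactMap):
            ch = contact_map.chromosomes[0]
            i, j, _ = contact_map.triplets(ch)
            n_from_map = contact_map.chrom_bins[ch]
        else:
            dense = np.asarray(contact_map)
            i, j = np.nonzero(np.triu(dense, 1))
            n_from_map = dense.shape[0]
        if n_beads is None:
            n_beads = n_from_map
        elif n_beads != n_from_map:
            raise ValueError("n_beads disagrees with the contact map size")
        sel = np.abs(i - j) > 1  # adjacent beads are already bonded
        contact_pairs = np.stack([i[sel], j[sel]], axis=1).astype(np.int64)

    box = params.box
    n_total = int(round(params.density * box**3)) if with_solvent else n_beads
    if n_beads > n_total:
        raise ValueError("chain longer than the box can hold at this density")
    # random-walk conformation in the central sub-cube
    lo = (box - params.chain_box) / 2.0
    pos = np.empty((n_beads, 3))
    pos[0] = lo + rng.random(3) * params.chain_box
    for b in range(1, n_beads):
        step = rng.normal(size=3)
        step *= params.l0 / np.linalg.norm(step)
        nxt = pos[b - 1] + step
        nxt = np.clip(nxt, lo, lo + params.chain_box)
        pos[b] = nxt
    n_solvent = n_total - n_beads
    solvent = rng.random((n_solvent, 3)) * box
    positions = np.concatenate([pos, solvent], axis=0)
    velocities = rng.normal(0.0, np.sqrt(params.kt), size=(n_total, 3))
    velocities -= velocities.mean(axis=0)  # zero total momentum
    types = np.zeros(n_total, dtype=np.int64)
    types[n_beads:] = 1
    backbone = np.stack(
        [np.arange(n_beads - 1), np.arange(1, n_beads)], axis=1
    ).astype(np.int64)
    bonds = np.concatenate([backbone, contact_pairs], axis=0)
    removable = np.zeros(len(bonds), dtype=bool)
    removable[len(backbone) :] = True
    return PolymerState(
        positions=positions,
        velocities=velocities,
        types=types,
        bonds=bonds,
        removable=removable,
        n_polymer=n_beads,
        params=params,
    )


@njit(cache=True)
def _compute_forces(
    pos, vel, types, bonds, box, r_cut, a_mat, gamma_d, sigma_n, k_bond, l0, sqrt_dt
):
    n = pos.shape[0]
    f = np.zeros((n, 3))
    ncell = max(1, int(box / r_cut))
    cell_sz = box / ncell
    ncell3 = ncell * ncell * ncell
    head = np.full(ncell3, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cx = np.empty(n, dtype=np.int64)
    cy = np.empty(n, dtype=np.int64)
    cz = np.empty(n, dtype=np.int64)
    for p in range(n):
        x = pos[p, 0] % box
        y = pos[p, 1] % box
        z = pos[p, 2] % box
        ix = min(int(x / cell_sz), ncell - 1)
        iy = min(int(y / cell_sz), ncell - 1)
        iz = min(int(z / cell_sz), ncell - 1)
        cx[p], cy[p], cz[p] = ix, iy, iz
        c = (ix * ncell + iy) * ncell + iz
        nxt[p] = head[c]
        head[c] = p
    half = box / 2.0
    for p in range(n):
        for dx in range(-1, 2):
            for dy in range(-1, 2):
                for dz in range(-1, 2):
                    ix = (cx[p] + dx) % ncell
                    iy = (cy[p] + dy) % ncell
                    iz = (cz[p] + dz) % ncell
                    q = head[(ix * ncell + iy) * ncell + iz]
                    while q >= 0:
                        if q > p:
                            rx = pos[p, 0] - pos[q, 0]
                            ry = pos[p, 1] - pos[q, 1]
                            rz = pos[p, 2] - pos[q, 2]
                            rx -= box * np.round(rx / box)
                            ry -= box * np.round(ry / box)
                            rz -= box * np.round(rz / box)
                            r2 = rx * rx + ry * ry + rz * rz
                            if 1e-12 < r2 < r_cut * r_cut:
                                r = np.sqrt(r2)
                                ex, ey, ez = rx / r, ry / r, rz / r
                                w = 1.0 - r / r_cut
                                a = a_mat[types[p], types[q]]
                                fc = a * w
                                vxx = vel[p, 0] - vel[q, 0]
                                vyy = vel[p, 1] - vel[q, 1]
                                vzz = vel[p, 2] - vel[q, 2]
                                rv = ex * vxx + ey * vyy + ez * vzz
                                fd = -gamma_d * w * w * rv
                                theta = np.random.normal()
                                fr = sigma_n * w * theta / sqrt_dt
                                ft = fc + fd + fr
                                f[p, 0] += ft * ex
                                f[p, 1] += ft * ey
                                f[p, 2] += ft * ez
                                f[q, 0] -= ft * ex
                                f[q, 1] -= ft * ey
                                f[q, 2] -= ft * ez
                        q = nxt[q]
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        rx = pos[i, 0] - pos[j, 0]
        ry = pos[i, 1] - pos[j, 1]
        rz = pos[i, 2] - pos[j, 2]
        rx -= box * np.round(rx / box)
        ry -= box * np.round(ry / box)
        rz -= box * np.round(rz / box)
        r = np.sqrt(rx * rx + ry * ry + rz * rz)
        if r > 1e-12:
            fb = -k_bond * (r - l0) / r
            f[i, 0] += fb * rx
            f[i, 1] += fb * ry
            f[i, 2] += fb * rz
            f[j, 0] -= fb * rx
            f[j, 1] -= fb * ry
            f[j, 2] -= fb * rz
    return f


@njit(cache=True)
def _integrate(
    pos, vel, types, bonds, n_steps, box, r_cut, a_mat, gamma_d, sigma_n,
    k_bond, l0, dt, seed, lam,
):
    # modified velocity-Verlet for DPD: the dissipative force is
    # evaluated at the predicted velocity v + λ·dt·f (λ = 0.65 keeps
    # the kinetic temperature within ~1% of k_BT at dt = 0.04)
    np.random.seed(seed)
    sqrt_dt = np.sqrt(dt)
    f = _compute_forces(
        pos, vel, types, bonds, box, r_cut, a_mat, gamma_d, sigma_n, k_bond, l0, sqrt_dt
    )
    for _ in range(n_steps):
        pos += dt * vel + 0.5 * dt * dt * f
        v_pred = vel + lam * dt * f
        f_new = _compute_forces(
            pos, v_pred, types, bonds, box, r_cut, a_mat, gamma_d, sigma_n, k_bond, l0, sqrt_dt
        )
        vel += 0.5 * dt * (f + f_new)
        f = f_new
    return pos, vel


def run_dpd(
    state: PolymerState,
    n_steps: int,
    seed: int = 0,
    sample_every: int = 0,
) -> Trajectory:
    """Integrate the system; optionally sample polymer frames.

    ``sample_every`` = 0 records only the final frame.  The DPD
    thermostat keeps the kinetic temperature at k_BT; total momentum is
    conserved to round-off by the pairwise force antisymmetry.  Raises
    if the integration diverges (non-finite coordinates).
    """
    p = state.params
    a_mat = np.array([[p.a_pp, p.a_ps], [p.a_ps, p.a_ss]])
    pos = state.positions.copy()
    vel = state.velocities.copy()
    frames, times, temps = [], [], []
    rng_seed = int(seed) % (2**31 - 1)
    done = 0
    chunk = sample_every if sample_every else n_steps
    while done < n_steps:
        todo = min(chunk, n_steps - done)
        pos, vel = _integrate(
            pos, vel, state.types, state.bonds, todo, p.box, p.r_cut, a_mat,
            p.gamma_d, p.sigma_n, p.k_bond, p.l0, p.dt, rng_seed, p.lam,
        )
        rng_seed = (rng_seed * 1103515245 + 12345) % (2**31 - 1)
        done += todo
        if not np.isfinite(pos).all():
            raise FloatingPointError(
                f"DPD integration diverged at step {done}: non-finite coordinates "
                f"(dt={p.dt}, k_bond={p.k_bond}); reduce dt or bond stiffness"
            )
        frames.append(pos[: state.n_polymer].copy())
        times.append(done)
        temps.append(float((vel**2).sum() / (3 * len(vel))))
    final = replace_state(state, pos, vel)
    return Trajectory(
        frames=np.array(frames),
        times=np.array(times),
        temperature=np.array(temps),
        final_state=final,
    )


def replace_state(state: PolymerState, pos: np.ndarray, vel: np.ndarray) -> PolymerState:
    return PolymerState(
        positions=pos,
        velocities=vel,
        types=state.types,
        bonds=state.bonds,
        removable=state.removable,
        n_polymer=state.n_polymer,
        params=state.params,
    )


def prune_overstretched_bonds(
    state: PolymerState,
    l_max: float = 1.5,
    reequil_steps: int = 20_000,
    seed: int = 0,
    max_removals: int | None = None,
) -> tuple[PolymerState, list[tuple[int, int, float]]]:
    """Iteratively remove the longest overstretched removable bond.

    While any removable (contact) bond exceeds ``l_max``, the single
    longest one is removed and the system re-equilibrated for
    ``reequil_steps``.  Backbone bonds are never candidates.  Returns
    the final state and a removal log ``(i, j, length-at-removal)``.
    Terminates: the removable bond set is finite and only shrinks.
    """
    log: list[tuple[int, int, float]] = []
    step_seed = int(seed)
    current = state
    while True:
        lengths = current.bond_lengths()
        cand = np.flatnonzero(current.removable & (lengths > l_max))
        if len(cand) == 0:
            break
        worst = cand[np.argmax(lengths[cand])]
        i, j = (int(x) for x in current.bonds[worst])
        log.append((i, j, float(lengths[worst])))
        keep = np.ones(len(current.bonds), dtype=bool)
        keep[worst] = False
        current = PolymerState(
            positions=current.positions,
            velocities=current.velocities,
            types=current.types,
            bonds=current.bonds[keep],
            removable=current.removable[keep],
            n_polymer=current.n_polymer,
            params=current.params,
        )
        if max_removals is not None and len(log) >= max_removals:
            break
        step_seed += 1
        traj = run_dpd(current, reequil_steps, seed=step_seed)
        current = traj.final_state
    return current, log


def mean_distance_matrix(traj: Trajectory, n_conf: int = 100) -> np.ndarray:
    """Mean inter-bead distance matrix over the last ``n_conf`` frames.

    Frames are unwrapped chain coordinates, so plain Euclidean
    distances are used (no minimum image across the territory).
    """
    frames = traj.frames[-n_conf:]
    if len(frames) == 0:
        raise ValueError("trajectory holds no frames")
    n = frames.shape[1]
    acc = np.zeros((n, n))
    for fr in frames:
        d = np.sqrt(((fr[:, None, :] - fr[None, :, :]) ** 2).sum(-1))
        acc += d
    return acc / len(frames)


def model_contact_map(
    traj: Trajectory,
    r_cut: float = 0.7,
    n_conf: int | None = None,
    binsize: int = 10_000,
    chrom: str = "chr1",
) -> SparseContactMap:
    """Contacts of the model: bead pairs with D_ij < R_cut per snapshot.

    Counts the number of snapshots in which each pair (|i−j| >= 1) is
    in contact; the |i−j| = 1 backbone diagonal is excluded to match
    the single-cell map convention.
    """
    frames = traj.frames if n_conf is None else traj.frames[-n_conf:]
    if len(frames) == 0:
        raise ValueError("trajectory holds no frames")
    n = frames.shape[1]
    counts = np.zeros((n, n), dtype=np.int64)
    for fr in frames:
        d = np.sqrt(((fr[:, None, :] - fr[None, :, :]) ** 2).sum(-1))
        counts += d < r_cut
    upper = np.triu(counts, 2)  # drop self and backbone diagonals
    return SparseContactMap.from_dense(
        upper + upper.T, binsize, chrom=chrom,
        metadata={"model": "dpd", "r_cut": r_cut, "n_conf": len(frames)},
    )


def coefficient_of_difference(
    d1: np.ndarray, d2: np.ndarray, band: tuple[int, int] | None = None
) -> float:
    """K = ‖D − D′‖ / ‖D + D′‖ (Frobenius), optionally on a distance band.

    K = 0 for identical matrices and < 1 for non-negative matrices;
    ``band=(lo, hi)`` restricts the norm to entries with lo <= |i−j| < hi,
    giving the K-vs-genomic-distance curve.
    """
    a = np.asarray(d1, float)
    b = np.asarray(d2, float)
    if a.shape != b.shape:
        raise ValueError("distance matrices must have the same shape")
    if band is not None:
        n = a.shape[0]
        sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        mask = (sep >= band[0]) & (sep < band[1])
        a = a[mask]
        b = b[mask]
    denom = np.linalg.norm(a + b)
    if denom == 0:
        return 0.0
    return float(np.linalg.norm(a - b) / denom)


def r_of_s(dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean spatial distance R(s) vs backbone separation s (bins)."""
    d = np.asarray(dist)
    n = d.shape[0]
    s = np.arange(1, n)
    r = np.array([np.mean(np.diagonal(d, k)) for k in s])
    return s, r


def fit_rs_exponents(
    s: np.ndarray, r: np.ndarray, ranges: list[tuple[int, int]]
) -> list[float]:
    """Log-log slopes of R(s) on the given s-ranges (bins, half-open)."""
    out = []
    for lo, hi in ranges:
        m = (s >= lo) & (s < hi) & (r > 0)
        if m.sum() < 2:
            out.append(float("nan"))
            continue
        slope = np.polyfit(np.log(s[m]), np.log(r[m]), 1)[0]
        out.append(float(slope))
    return out


def radial_profile(
    positions: np.ndarray, labels: np.ndarray | None = None
) -> dict:
    """Distances from each bead to the chromosome-territory surface.

    The territory surface is the convex hull of the bead cloud; a
    bead's depth is its minimal distance to the hull's face planes
    (hull vertices are at depth 0).  With ``labels``, returns per-label
    distance arrays for radial-position comparisons of chromatin
    classes.
    """
    from scipy.spatial import ConvexHull, QhullError

    pts = np.asarray(positions, float)
    if len(pts) < 4:
        raise ValueError("need at least 4 points for a 3D hull")
    try:
        hull = ConvexHull(pts)
    except QhullError as err:
        raise ValueError("degenerate geometry: points are coplanar") from err
    # hull.equations: outward normals, n·x + b <= 0 inside
    dist = -(pts @ hull.equations[:, :3].T + hull.equations[:, 3])
    depth = dist.min(axis=1)
    depth = np.maximum(depth, 0.0)
    if labels is None:
        return {"depth": depth}
    labels = np.asarray(labels)
    out = {"depth": depth}
    for lab in np.unique(labels):
        out[str(lab)] = depth[labels == lab]
    return out


def smooth_path(positions: np.ndarray, window: int = 15) -> np.ndarray:
    """Centered moving average along the chain; window shrinks at the ends."""
    pts = np.asarray(positions, float)
    n = len(pts)
    half = window // 2
    out = np.empty_like(pts)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = pts[lo:hi].mean(axis=0)
    return out
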