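"""Monte-Carlo random walk of spins through a periodic substrate.

Spins take fixed-length steps ell = sqrt(6 D dt) in uniformly random
directions.  Membranes (cylinder and sphere surfaces) are impermeable: a
step that would change any spin's inside/outside state is specularly
reflected about the local surface normal, and rejected (the spin stays) if
the reflected step still crosses a membrane.  Box faces are periodic in all
three axes; positions are tracked unwrapped so displacements are true.

The PGSE signal is computed from per-spin phase integrals: during each
gradient pulse the (vector) integral of the position is accumulated, and
the per-volume phase is phi = gamma G u . (A1 - A2).  b = 0 volumes are
exactly 1 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .forward import RawSignal
from .protocol import AcquisitionProtocol
from .substrate import Substrate

_NZ_TABLE = 256  # centreline lookup resolution along z


class GeometryError(RuntimeError):
    """A spin ended up in an inconsistent compartment (geometry bug)."""


@dataclass
class WalkConfig:
    """Spin-walk settings.

    Defaults mirror the simulation regime this module emulates: 160,000
    spins, 8.62 us time step, bulk diffusivity 1 um^2/ms (ex-vivo).
    """

    n_spins: int = 160_000
    dt: float = 8.62e-3  # ms
    diffusivity: float = 1.0  # um^2/ms
    rng_seed: int = 0
    seed_in_spheres: bool = True

    @property
    def step_length(self) -> float:
        return float(np.sqrt(6.0 * self.diffusivity * self.dt))


@dataclass
class WalkResult:
    signal: RawSignal
    std_error: np.ndarray  # per-volume Monte-Carlo standard error
    displacements: np.ndarray  # (n_spins, 3), unwrapped
    phase_integrals: np.ndarray  # (n_spins, 3), um ms
    start_positions: np.ndarray  # (n_spins, 3)


# ---------------------------------------------------------------------------
# geometry helpers (compiled)

@njit(cache=True, fastmath=True, inline="always")
def _wrap(x, L):
    x = x % L
    if x < 0:
        x += L
    return x


@njit(cache=True, fastmath=True, inline="always")
def _find_cylinder(xw, yw, zw, lx, ly, lz, tab, radius2,
                   cell_start, cell_items, gx, gy):
    # branch-based minimum image: candidates come from the wrapped cell, so
    # offsets are at most one box period
    if radius2.shape[0] == 0:
        return -1
    cx = int(xw * (gx / lx))
    cy = int(yw * (gy / ly))
    if cx >= gx:
        cx = gx - 1
    if cy >= gy:
        cy = gy - 1
    cell = cx * gy + cy
    nz = tab.shape[1]
    zi = zw * (nz / lz)
    j0 = int(zi)
    if j0 >= nz:
        j0 = nz - 1
    f = zi - j0
    j1 = j0 + 1
    if j1 == nz:
        j1 = 0
    hx, hy = 0.5 * lx, 0.5 * ly
    for k in range(cell_start[cell], cell_start[cell + 1]):
        i = cell_items[k]
        clx = tab[i, j0, 0] * (1.0 - f) + tab[i, j1, 0] * f
        cly = tab[i, j0, 1] * (1.0 - f) + tab[i, j1, 1] * f
        dx = xw - clx
        if dx > hx:
            dx -= lx
        elif dx < -hx:
            dx += lx
        dy = yw - cly
        if dy > hy:
            dy -= ly
        elif dy < -hy:
            dy += ly
        if dx * dx + dy * dy < radius2[i]:
            return i
    return -1


@njit(cache=True, fastmath=True, inline="always")
def _find_sphere(xw, yw, zw, lx, ly, lz, centers, radius2,
                 cell_start, cell_items, sgx, sgy, sgz):
    if radius2.shape[0] == 0:
        return -1
    cx = int(xw * (sgx / lx))
    cy = int(yw * (sgy / ly))
    cz = int(zw * (sgz / lz))
    if cx >= sgx:
        cx = sgx - 1
    if cy >= sgy:
        cy = sgy - 1
    if cz >= sgz:
        cz = sgz - 1
    cell = (cx * sgy + cy) * sgz + cz
    hx, hy, hz = 0.5 * lx, 0.5 * ly, 0.5 * lz
    for k in range(cell_start[cell], cell_start[cell + 1]):
        i = cell_items[k]
        dx = xw - centers[i, 0]
        if dx > hx:
            dx -= lx
        elif dx < -hx:
            dx += lx
        dy = yw - centers[i, 1]
        if dy > hy:
            dy -= ly
        elif dy < -hy:
            dy += ly
        dz = zw - centers[i, 2]
        if dz > hz:
            dz -= lz
        elif dz < -hz:
            dz += lz
        if dx * dx + dy * dy + dz * dz < radius2[i]:
            return i
    return -1


@njit(cache=True, fastmath=True)
def _walk_kernel(pos, in_cyl, in_sph, n_steps, dt, ell, weights,
                 lx, ly, lz,
                 tab, cyl_r2, ccell_start, ccell_items, gx, gy,
                 sph_c, sph_r2, scell_start, scell_items, sgx, sgy, sgz,
                 free_steps, fgx, fgy, fgz, use_free,
                 dir_tab, seed):
    n = pos.shape[0]
    phase = np.zeros((n, 3))
    # splitmix64 counter RNG: cheap, high-quality high bits for table picks
    state = np.uint64(seed) | np.uint64(1)
    golden = np.uint64(0x9E3779B97F4A7C15)
    mix1 = np.uint64(0xBF58476D1CE4E5B9)
    mix2 = np.uint64(0x94D049BB133111EB)
    s30 = np.uint64(30)
    s27 = np.uint64(27)
    s31 = np.uint64(31)
    s49 = np.uint64(49)
    ntab = dir_tab.shape[0]
    inv_fx = fgx / lx
    inv_fy = fgy / ly
    inv_fz = fgz / lz
    for s in range(n):
        x, y, z = pos[s, 0], pos[s, 1], pos[s, 2]
        # wrapped coordinates maintained incrementally (steps are << box)
        xw = _wrap(x, lx)
        yw = _wrap(y, ly)
        zw = _wrap(z, lz)
        cc = in_cyl[s]
        cs = in_sph[s]
        budget = 0  # guaranteed membrane-free steps remaining
        for t in range(n_steps):
            state = state + golden
            zmix = (state ^ (state >> s30)) * mix1
            zmix = (zmix ^ (zmix >> s27)) * mix2
            zmix = zmix ^ (zmix >> s31)
            j = int(zmix >> s49)  # 15 high bits -> index into 2^15 table
            vx = ell * dir_tab[j, 0]
            vy = ell * dir_tab[j, 1]
            vz = ell * dir_tab[j, 2]
            nxw = xw + vx
            if nxw >= lx:
                nxw -= lx
            elif nxw < 0.0:
                nxw += lx
            nyw = yw + vy
            if nyw >= ly:
                nyw -= ly
            elif nyw < 0.0:
                nyw += ly
            nzw = zw + vz
            if nzw >= lz:
                nzw -= lz
            elif nzw < 0.0:
                nzw += lz
            if budget > 0:
                # the spin is provably further from every membrane than it
                # can travel in `budget` steps: accept without checks
                budget -= 1
                x += vx
                y += vy
                z += vz
                xw, yw, zw = nxw, nyw, nzw
                w = weights[t]
                if w != 0.0:
                    phase[s, 0] += w * x * dt
                    phase[s, 1] += w * y * dt
                    phase[s, 2] += w * z * dt
                continue
            ncyl = _find_cylinder(nxw, nyw, nzw, lx, ly, lz, tab, cyl_r2,
                                  ccell_start, ccell_items, gx, gy)
            nsph = _find_sphere(nxw, nyw, nzw, lx, ly, lz, sph_c, sph_r2,
                                scell_start, scell_items, sgx, sgy, sgz)
            if ncyl != cc or nsph != cs:
                # specular reflection about the violated surface
                rx, ry, rz = 0.0, 0.0, 0.0
                if ncyl != cc:
                    i = cc if cc >= 0 else ncyl
                    nzt = tab.shape[1]
                    zi = nzw * (nzt / lz)
                    j0 = int(zi)
                    if j0 >= nzt:
                        j0 = nzt - 1
                    f = zi - j0
                    j1 = j0 + 1
                    if j1 == nzt:
                        j1 = 0
                    clx = tab[i, j0, 0] * (1.0 - f) + tab[i, j1, 0] * f
                    cly = tab[i, j0, 1] * (1.0 - f) + tab[i, j1, 1] * f
                    rx = nxw - clx
                    rx -= lx * np.round(rx / lx)
                    ry = nyw - cly
                    ry -= ly * np.round(ry / ly)
                    rz = 0.0
                else:
                    i = cs if cs >= 0 else nsph
                    rx = nxw - sph_c[i, 0]
                    rx -= lx * np.round(rx / lx)
                    ry = nyw - sph_c[i, 1]
                    ry -= ly * np.round(ry / ly)
                    rz = nzw - sph_c[i, 2]
                    rz -= lz * np.round(rz / lz)
                rn = np.sqrt(rx * rx + ry * ry + rz * rz)
                ok = False
                if rn > 0.0:
                    rx, ry, rz = rx / rn, ry / rn, rz / rn
                    dot = vx * rx + vy * ry + vz * rz
                    wx = vx - 2.0 * dot * rx
                    wy = vy - 2.0 * dot * ry
                    wz = vz - 2.0 * dot * rz
                    mxw = _wrap(xw + wx, lx)
                    myw = _wrap(yw + wy, ly)
                    mzw = _wrap(zw + wz, lz)
                    ncyl = _find_cylinder(mxw, myw, mzw, lx, ly, lz, tab,
                                          cyl_r2, ccell_start, ccell_items,
                                          gx, gy)
                    nsph = _find_sphere(mxw, myw, mzw, lx, ly, lz, sph_c,
                                        sph_r2, scell_start, scell_items,
                                        sgx, sgy, sgz)
                    if ncyl == cc and nsph == cs:
                        ok = True
                        vx, vy, vz = wx, wy, wz
                        nxw, nyw, nzw = mxw, myw, mzw
                if not ok:
                    vx, vy, vz = 0.0, 0.0, 0.0  # reject: stay put
                    nxw, nyw, nzw = xw, yw, zw
            else:
                # clear of every membrane: refill the free-flight budget
                # from the precomputed per-cell clearance (only valid for
                # spins outside all obstacles)
                if use_free != 0 and cc < 0 and cs < 0:
                    fx = int(nxw * inv_fx)
                    fy = int(nyw * inv_fy)
                    fz = int(nzw * inv_fz)
                    if fx >= fgx:
                        fx = fgx - 1
                    if fy >= fgy:
                        fy = fgy - 1
                    if fz >= fgz:
                        fz = fgz - 1
                    budget = free_steps[(fx * fgy + fy) * fgz + fz]
            x += vx
            y += vy
            z += vz
            xw, yw, zw = nxw, nyw, nzw
            w = weights[t]
            if w != 0.0:
                phase[s, 0] += w * x * dt
                phase[s, 1] += w * y * dt
                phase[s, 2] += w * z * dt
        pos[s, 0], pos[s, 1], pos[s, 2] = x, y, z
    return phase


# ---------------------------------------------------------------------------
# grid construction

def _cylinder_table(sub: Substrate, nz: int = _NZ_TABLE):
    zs = np.arange(nz) * (sub.box[2] / nz)
    tab = np.zeros((sub.n_cylinders, nz, 2))
    for i in range(sub.n_cylinders):
        tab[i] = sub.centerline_xy(i, zs)
    return tab


def _rect_dist(px, py, x0, x1, y0, y1):
    dx = max(x0 - px, 0.0, px - x1)
    dy = max(y0 - py, 0.0, py - y1)
    return np.hypot(dx, dy)


def _cylinder_grid(sub: Substrate, gx: int = 16, gy: int = 16):
    lx, ly, _ = sub.box
    lists = [[] for _ in range(gx * gy)]
    for i in range(sub.n_cylinders):
        reach = sub.cyl_radius[i] + sub.max_displacement(i) + 1e-6
        ax, ay = sub.cyl_anchor[i]
        for cx in range(gx):
            for cy in range(gy):
                x0, x1 = cx * lx / gx, (cx + 1) * lx / gx
                y0, y1 = cy * ly / gy, (cy + 1) * ly / gy
                hit = False
                for ox in (-lx, 0.0, lx):
                    for oy in (-ly, 0.0, ly):
                        if _rect_dist(ax + ox, ay + oy, x0, x1, y0, y1) <= reach:
                            hit = True
                            break
                    if hit:
                        break
                if hit:
                    lists[cx * gy + cy].append(i)
    start = np.zeros(gx * gy + 1, dtype=np.int64)
    items = []
    for c, l in enumerate(lists):
        items.extend(l)
        start[c + 1] = len(items)
    return start, np.asarray(items, dtype=np.int64), gx, gy


def _sphere_grid(sub: Substrate, sgx: int = 16, sgy: int = 16, sgz: int = 2):
    lx, ly, lz = sub.box
    lists = [[] for _ in range(sgx * sgy * sgz)]
    sizes = np.array([lx / sgx, ly / sgy, lz / sgz])
    for i in range(sub.n_spheres):
        reach = sub.sph_radius[i] + 1e-6
        c = sub.sph_center[i]
        for cx in range(sgx):
            for cy in range(sgy):
                for cz in range(sgz):
                    lo = np.array([cx, cy, cz]) * sizes
                    hi = lo + sizes
                    hit = False
                    for ox in (-lx, 0.0, lx):
                        for oy in (-ly, 0.0, ly):
                            for oz in (-lz, 0.0, lz):
                                p = c + np.array([ox, oy, oz])
                                d = np.linalg.norm(
                                    np.maximum(lo - p, 0.0)
                                    + np.maximum(p - hi, 0.0)
                                )
                                if d <= reach:
                                    hit = True
                                    break
                            if hit:
                                break
                        if hit:
                            break
                    if hit:
                        lists[(cx * sgy + cy) * sgz + cz].append(i)
    start = np.zeros(sgx * sgy * sgz + 1, dtype=np.int64)
    items = []
    for c, l in enumerate(lists):
        items.extend(l)
        start[c + 1] = len(items)
    return start, np.asarray(items, dtype=np.int64), sgx, sgy, sgz


def _memberships(sub: Substrate, pos: np.ndarray, tables) -> tuple[np.ndarray, np.ndarray]:
    tab, cyl_r2, cs, ci, gx, gy, sph_c, sph_r2, ss, si, sgx, sgy, sgz = tables
    lx, ly, lz = sub.box
    cyl = np.empty(pos.shape[0], dtype=np.int64)
    sph = np.empty(pos.shape[0], dtype=np.int64)
    for k in range(pos.shape[0]):
        xw, yw, zw = pos[k, 0] % lx, pos[k, 1] % ly, pos[k, 2] % lz
        cyl[k] = _find_cylinder(xw, yw, zw, lx, ly, lz, tab, cyl_r2, cs, ci, gx, gy)
        sph[k] = _find_sphere(xw, yw, zw, lx, ly, lz, sph_c, sph_r2, ss, si,
                              sgx, sgy, sgz)
    return cyl, sph


def _prep_tables(sub: Substrate):
    cs, ci, gx, gy = _cylinder_grid(sub)
    ss, si, sgx, sgy, sgz = _sphere_grid(sub)
    tab = _cylinder_table(sub)
    return (tab, sub.cyl_radius**2, cs, ci, gx, gy,
            np.asarray(sub.sph_center, float).reshape(-1, 3),
            sub.sph_radius**2, ss, si, sgx, sgy, sgz)


def _free_grid(sub: Substrate, ell: float, fgx: int = 20, fgy: int = 20,
               fgz: int = 4):
    """Per-cell free-flight budgets: how many steps of length ``ell`` a
    spin anywhere in the cell can take before it could possibly reach a
    membrane.  Conservative (uses obstacle bounding regions)."""
    lx, ly, lz = sub.box
    sx, sy, sz = lx / fgx, ly / fgy, lz / fgz
    budgets = np.empty(fgx * fgy * fgz, dtype=np.int64)
    cap = 1 << 30
    cyl_reach = sub.cyl_radius + np.array(
        [sub.max_displacement(i) for i in range(sub.n_cylinders)]
    ) if sub.n_cylinders else np.zeros(0)
    for cx in range(fgx):
        for cy in range(fgy):
            x0, x1 = cx * sx, (cx + 1) * sx
            y0, y1 = cy * sy, (cy + 1) * sy
            d2_min = np.inf
            for i in range(sub.n_cylinders):
                ax, ay = sub.cyl_anchor[i]
                best = np.inf
                for ox in (-lx, 0.0, lx):
                    for oy in (-ly, 0.0, ly):
                        d = _rect_dist(ax + ox, ay + oy, x0, x1, y0, y1)
                        best = min(best, d)
                d2_min = min(d2_min, best - cyl_reach[i])
            for cz in range(fgz):
                z0, z1 = cz * sz, (cz + 1) * sz
                clearance = d2_min
                for i in range(sub.n_spheres):
                    c = sub.sph_center[i]
                    best = np.inf
                    for ox in (-lx, 0.0, lx):
                        for oy in (-ly, 0.0, ly):
                            for oz in (-lz, 0.0, lz):
                                p = c + np.array([ox, oy, oz])
                                dx = max(x0 - p[0], 0.0, p[0] - x1)
                                dy = max(y0 - p[1], 0.0, p[1] - y1)
                                dz = max(z0 - p[2], 0.0, p[2] - z1)
                                best = min(best, np.sqrt(dx * dx + dy * dy
                                                         + dz * dz))
                    clearance = min(clearance, best - sub.sph_radius[i])
                k = (cx * fgy + cy) * fgz + cz
                if not np.isfinite(clearance):
                    budgets[k] = cap
                else:
                    budgets[k] = max(0, int((clearance - 1e-9) / ell))
    return budgets, fgx, fgy, fgz


def _direction_table(n: int, rng: np.random.Generator,
                     n_whiten: int = 50) -> np.ndarray:
    """Antipodally symmetric table of unit step directions whose empirical
    covariance is whitened to I/3, so the walk's per-step second moments are
    exact rather than subject to table sampling noise."""
    v = rng.standard_normal((n // 2, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    for _ in range(n_whiten):
        c = (v.T @ v) / v.shape[0]
        L = np.linalg.cholesky(3.0 * c)
        v = v @ np.linalg.inv(L).T
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    return np.concatenate([v, -v])


def _pulse_weights(protocol: AcquisitionProtocol, dt: float) -> np.ndarray:
    """Signed per-step gradient on/off weights with fractional boundaries."""
    d, D = protocol.delta_small, protocol.delta_big
    n_steps = int(np.ceil((D + d) / dt))
    t0 = np.arange(n_steps) * dt
    t1 = t0 + dt

    def overlap(a, b):
        return np.clip(np.minimum(t1, b) - np.maximum(t0, a), 0.0, None) / dt

    return overlap(0.0, d) - overlap(D, D + d)


def simulate_walk(
    substrate: Substrate,
    walk: WalkConfig,
    sequence: AcquisitionProtocol,
    init_positions: np.ndarray | None = None,
) -> WalkResult:
    """Simulate the PGSE experiment for one substrate.

    Returns the per-volume signal (b=0 volumes exactly 1), its Monte-Carlo
    standard error, and per-spin displacements for diagnostics.
    """
    rng = np.random.default_rng(walk.rng_seed)
    lx, ly, lz = substrate.box
    radii = np.concatenate([substrate.cyl_radius, substrate.sph_radius])
    if radii.size and walk.step_length > radii.min() / 5.0:
        warnings.warn(
            f"step length {walk.step_length:.3f} um exceeds 1/5 of the "
            f"smallest obstacle radius {radii.min():.3f} um"
        )
    tables = _prep_tables(substrate)

    if init_positions is None:
        pos = rng.uniform([0, 0, 0], [lx, ly, lz], size=(walk.n_spins, 3))
        if not walk.seed_in_spheres and substrate.n_spheres:
            for _ in range(200):
                _, sph = _memberships(substrate, pos, tables)
                bad = sph >= 0
                if not bad.any():
                    break
                pos[bad] = rng.uniform([0, 0, 0], [lx, ly, lz],
                                       size=(int(bad.sum()), 3))
    else:
        pos = np.array(init_positions, dtype=float)
    pos0 = pos.copy()
    in_cyl, in_sph = _memberships(substrate, pos, tables)

    weights = _pulse_weights(sequence, walk.dt)
    dir_tab = _direction_table(1 << 15, rng)
    free_steps, fgx, fgy, fgz = _free_grid(substrate, walk.step_length)
    # free flight only pays off when a fair share of the box is far from
    # every membrane; otherwise the refill bookkeeping is pure overhead
    use_free = 1 if (free_steps >= 4).mean() > 0.25 else 0
    phase = _walk_kernel(
        pos, in_cyl, in_sph, len(weights), walk.dt, walk.step_length, weights,
        lx, ly, lz, *tables,
        free_steps, fgx, fgy, fgz, use_free,
        dir_tab, int(rng.integers(0, 2**31 - 1)),
    )
    end_cyl, end_sph = _memberships(substrate, pos, tables)
    if np.any(end_cyl != in_cyl) or np.any(end_sph != in_sph):
        raise GeometryError("spin crossed an impermeable membrane")

    d, D = sequence.delta_small, sequence.delta_big
    values = np.ones(sequence.n_volumes)
    errors = np.zeros(sequence.n_volumes)
    col = sequence.n_b0
    for shell in sequence.shells:
        gamma_g = np.sqrt(shell.b_value / (D - d / 3.0)) / d  # rad/(um ms)
        ph = gamma_g * (phase @ shell.directions.T)  # (n_spins, n_dirs)
        c = np.cos(ph).mean(axis=0)
        s = np.sin(ph).mean(axis=0)
        mag = np.hypot(c, s)
        proj = (np.cos(ph) * c + np.sin(ph) * s) / np.maximum(mag, 1e-300)
        se = proj.std(axis=0) / np.sqrt(ph.shape[0])
        values[col : col + shell.n_directions] = mag
        errors[col : col + shell.n_directions] = se
        col += shell.n_directions

    return WalkResult(
        signal=RawSignal(values=values, protocol=sequence),
        std_error=errors,
        displacements=pos - pos0,
        phase_integrals=phase,
        start_positions=pos0,
    )


def simulate_in_sphere(
    radius: float,
    diffusivity: float,
    sequence: AcquisitionProtocol,
    n_spins: int = 100_000,
    dt: float = 8.62e-3,
    rng_seed: int = 0,
) -> WalkResult:
    """Walk spins confined to a single impermeable sphere (GPD oracle)."""
    box = (max(6 * radius, 10.0),) * 3
    sub = Substrate(
        box=box,
        sph_center=np.array([[box[0] / 2, box[1] / 2, box[2] / 2]]),
        sph_radius=np.array([radius]),
    )
    rng = np.random.default_rng(rng_seed)
    pos = np.empty((n_spins, 3))
    filled = 0
    while filled < n_spins:
        cand = rng.uniform(-radius, radius, size=(2 * (n_spins - filled), 3))
        cand = cand[np.einsum("ij,ij->i", cand, cand) < radius**2]
        take = cand[: n_spins - filled]
        pos[filled : filled + take.shape[0]] = take + np.asarray(sub.sph_center[0])
        filled += take.shape[0]
    cfg = WalkConfig(n_spins=n_spins, dt=dt, diffusivity=diffusivity,
                     rng_seed=rng_seed)
    return simulate_walk(sub, cfg, sequence, init_positions=pos)
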