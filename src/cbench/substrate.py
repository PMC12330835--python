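"""Parametric white-matter-like substrates for Monte-Carlo simulation.

A substrate is a 3D-periodic box (default 200 x 200 x 25 um^3) containing
non-overlapping undulating cylinders (axons) and spheres (cell soma).
Cylinders are parameterised by z: each z-plane cuts a disc of fixed radius
whose centre follows

    c_xy(z) = anchor
            + A_u sin(2 pi z / lambda_u + phi_u) e_u      (undulation)
            + A_m sin(2 pi z / Lz      + phi_m) e_m       (meander)

The meander term realises a per-cylinder inclination sampled from a Watson
distribution about the box's short (z) axis while keeping the whole
substrate exactly periodic in z; a straight tilted cylinder would not be.
Because every z-plane cuts a full disc, each cylinder's volume is exactly
pi r^2 Lz regardless of undulation (a shear preserves area), so the
analytic volume fractions are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .compartments import odi_to_kappa

DEFAULT_BOX = (200.0, 200.0, 25.0)
CYLINDER_COUNTS = (4, 48, 88, 168)
SPHERE_COUNTS = (0, 9, 15, 21, 27, 33, 39, 45, 51, 57)


class PackingError(RuntimeError):
    """Could not place the requested obstacles without overlap."""


@dataclass
class Substrate:
    box: tuple[float, float, float] = DEFAULT_BOX
    # cylinders, all (nc, ...) arrays
    cyl_anchor: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    cyl_radius: np.ndarray = field(default_factory=lambda: np.zeros(0))
    cyl_und_amp: np.ndarray = field(default_factory=lambda: np.zeros(0))
    cyl_und_wavelength: np.ndarray = field(default_factory=lambda: np.zeros(0))
    cyl_und_phase: np.ndarray = field(default_factory=lambda: np.zeros(0))
    cyl_und_dir: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    cyl_meander_amp: np.ndarray = field(default_factory=lambda: np.zeros(0))
    cyl_meander_phase: np.ndarray = field(default_factory=lambda: np.zeros(0))
    cyl_meander_dir: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    # spheres
    sph_center: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    sph_radius: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_cylinders(self) -> int:
        return self.cyl_radius.shape[0]

    @property
    def n_spheres(self) -> int:
        return self.sph_radius.shape[0]

    def centerline_xy(self, i: int, z) -> np.ndarray:
        """Cylinder i's centreline at height(s) z; (len(z), 2)."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        lz = self.box[2]
        u = self.cyl_und_amp[i] * np.sin(
            2 * np.pi * z / self.cyl_und_wavelength[i] + self.cyl_und_phase[i]
        )
        m = self.cyl_meander_amp[i] * np.sin(
            2 * np.pi * z / lz + self.cyl_meander_phase[i]
        )
        return (
            self.cyl_anchor[i]
            + u[:, None] * self.cyl_und_dir[i]
            + m[:, None] * self.cyl_meander_dir[i]
        )

    def max_displacement(self, i: int) -> float:
        return float(self.cyl_und_amp[i] + self.cyl_meander_amp[i])

    def to_json(self, path=None) -> str:
        d = {
            "box": list(self.box),
            "cylinders": {
                "anchor": self.cyl_anchor.tolist(),
                "radius": self.cyl_radius.tolist(),
                "und_amp": self.cyl_und_amp.tolist(),
                "und_wavelength": self.cyl_und_wavelength.tolist(),
                "und_phase": self.cyl_und_phase.tolist(),
                "und_dir": self.cyl_und_dir.tolist(),
                "meander_amp": self.cyl_meander_amp.tolist(),
                "meander_phase": self.cyl_meander_phase.tolist(),
                "meander_dir": self.cyl_meander_dir.tolist(),
            },
            "spheres": {
                "center": self.sph_center.tolist(),
                "radius": self.sph_radius.tolist(),
            },
        }
        text = json.dumps(d)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "Substrate":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            d = json.loads(Path(source).read_text())
        else:
            d = json.loads(source)
        c, s = d["cylinders"], d["spheres"]
        return cls(
            box=tuple(d["box"]),
            cyl_anchor=np.asarray(c["anchor"], float).reshape(-1, 2),
            cyl_radius=np.asarray(c["radius"], float),
            cyl_und_amp=np.asarray(c["und_amp"], float),
            cyl_und_wavelength=np.asarray(c["und_wavelength"], float),
            cyl_und_phase=np.asarray(c["und_phase"], float),
            cyl_und_dir=np.asarray(c["und_dir"], float).reshape(-1, 2),
            cyl_meander_amp=np.asarray(c["meander_amp"], float),
            cyl_meander_phase=np.asarray(c["meander_phase"], float),
            cyl_meander_dir=np.asarray(c["meander_dir"], float).reshape(-1, 2),
            sph_center=np.asarray(s["center"], float).reshape(-1, 3),
            sph_radius=np.asarray(s["radius"], float),
        )

    def to_mesh(self, n_seg: int = 24, n_z: int = 50):
        """Triangulated surface (trimesh.Trimesh) for export/visualisation."""
        import trimesh

        meshes = []
        zs = np.linspace(0.0, self.box[2], n_z)
        ang = np.linspace(0, 2 * np.pi, n_seg, endpoint=False)
        ring = np.stack([np.cos(ang), np.sin(ang)], axis=1)
        for i in range(self.n_cylinders):
            cl = self.centerline_xy(i, zs)
            verts = np.concatenate(
                [
                    np.column_stack([cl[j, 0] + self.cyl_radius[i] * ring[:, 0],
                                     cl[j, 1] + self.cyl_radius[i] * ring[:, 1],
                                     np.full(n_seg, zs[j])])
                    for j in range(n_z)
                ]
            )
            faces = []
            for j in range(n_z - 1):
                for k in range(n_seg):
                    a = j * n_seg + k
                    b = j * n_seg + (k + 1) % n_seg
                    faces += [[a, b, a + n_seg], [b, b + n_seg, a + n_seg]]
            meshes.append(trimesh.Trimesh(vertices=verts, faces=faces, process=False))
        for i in range(self.n_spheres):
            sph = trimesh.creation.icosphere(subdivisions=2,
                                             radius=float(self.sph_radius[i]))
            sph.apply_translation(self.sph_center[i])
            meshes.append(sph)
        if not meshes:
            return trimesh.Trimesh()
        return trimesh.util.concatenate(meshes)

    def to_ply(self, path) -> None:
        self.to_mesh().export(str(path), file_type="ply", encoding="ascii")


def volume_fractions(substrate: Substrate) -> tuple[float, float]:
    """(intra-cylinder, intra-sphere) volume fractions, analytic and exact
    (per-z disc cross-sections make the cylinder volume independent of the
    undulation)."""
    lx, ly, lz = substrate.box
    v = lx * ly * lz
    v_cyl = float(np.sum(np.pi * substrate.cyl_radius**2) * lz)
    v_sph = float(np.sum(4.0 / 3.0 * np.pi * substrate.sph_radius**3))
    return v_cyl / v, v_sph / v


def _min_image(d, period):
    return d - period * np.round(d / period)


def _sample_watson_slope(kappa: float, rng: np.random.Generator,
                         max_angle: float = np.pi / 3) -> float:
    """tan(theta) with cos(theta) Watson-distributed about the z axis."""
    while True:
        t = rng.uniform(0.0, 1.0)
        if rng.uniform() < np.exp(kappa * (t * t - 1.0)):
            theta = np.arccos(t)
            if theta <= max_angle:
                return float(np.tan(theta))


def build_substrate(
    n_cylinders: int,
    n_spheres: int,
    target_odi: float = 0.1,
    rng_seed: int = 0,
    box: tuple[float, float, float] = DEFAULT_BOX,
    cyl_radius: float = 2.5,
    sph_radius: float = 5.0,
    und_amp: float = 1.0,
    und_wavelength: float = 25.0,
    max_tries: int = 20_000,
) -> Substrate:
    """Place non-overlapping undulating cylinders and spheres by rejection.

    Cylinder inclinations are Watson-sampled about z with concentration
    mapped from ``target_odi`` and realised as z-periodic meanders (module
    docstring).  Raises :class:`PackingError` when placement fails.
    """
    rng = np.random.default_rng(rng_seed)
    lx, ly, lz = box
    kappa = float(odi_to_kappa(target_odi))
    zs = np.linspace(0.0, lz, 33)

    anchors, und_dirs, und_phases = [], [], []
    m_amps, m_phases, m_dirs = [], [], []
    centrelines: list[np.ndarray] = []  # accepted centrelines, sampled at zs
    for _ in range(n_cylinders):
        slope = _sample_watson_slope(kappa, rng)
        amp_m = slope * lz / (2 * np.pi)
        ang_u, ang_m = rng.uniform(0, 2 * np.pi, size=2)
        ph_u, ph_m = rng.uniform(0, 2 * np.pi, size=2)
        e_u = np.array([np.cos(ang_u), np.sin(ang_u)])
        e_m = np.array([np.cos(ang_m), np.sin(ang_m)])
        wiggle = (
            und_amp * np.sin(2 * np.pi * zs / und_wavelength + ph_u)[:, None] * e_u
            + amp_m * np.sin(2 * np.pi * zs / lz + ph_m)[:, None] * e_m
        )
        placed = False
        for _try in range(max_tries):
            anchor = rng.uniform([0, 0], [lx, ly])
            cl_new = anchor + wiggle
            ok = True
            for cl_old in centrelines:
                d = _min_image(cl_new[:, 0] - cl_old[:, 0], lx) ** 2
                d += _min_image(cl_new[:, 1] - cl_old[:, 1], ly) ** 2
                if np.min(d) < (2 * cyl_radius) ** 2:
                    ok = False
                    break
            if ok:
                anchors.append(anchor)
                und_dirs.append(e_u)
                und_phases.append(ph_u)
                m_amps.append(amp_m)
                m_phases.append(ph_m)
                m_dirs.append(e_m)
                centrelines.append(cl_new)
                placed = True
                break
        if not placed:
            raise PackingError(
                f"failed to place cylinder {len(anchors) + 1}/{n_cylinders}"
            )

    sub = Substrate(
        box=box,
        cyl_anchor=np.asarray(anchors, float).reshape(-1, 2),
        cyl_radius=np.full(n_cylinders, cyl_radius),
        cyl_und_amp=np.full(n_cylinders, und_amp),
        cyl_und_wavelength=np.full(n_cylinders, und_wavelength),
        cyl_und_phase=np.asarray(und_phases, float),
        cyl_und_dir=np.asarray(und_dirs, float).reshape(-1, 2),
        cyl_meander_amp=np.asarray(m_amps, float),
        cyl_meander_phase=np.asarray(m_phases, float),
        cyl_meander_dir=np.asarray(m_dirs, float).reshape(-1, 2),
    )

    centers = []
    zgrid = np.linspace(-1.0, 1.0, 17)
    for _ in range(n_spheres):
        placed = False
        for _try in range(max_tries):
            c = rng.uniform([0, 0, 0], [lx, ly, lz])
            ok = True
            for prev in centers:
                d = _min_image(c - prev, np.array([lx, ly, lz]))
                if d @ d < (2 * sph_radius) ** 2:
                    ok = False
                    break
            if ok and n_cylinders:
                dz = zgrid * sph_radius
                cut = np.sqrt(np.maximum(0.0, sph_radius**2 - dz**2))
                for i in range(n_cylinders):
                    cl = sub.centerline_xy(i, c[2] + dz)
                    dx = _min_image(c[0] - cl[:, 0], lx)
                    dy = _min_image(c[1] - cl[:, 1], ly)
                    if np.any(np.hypot(dx, dy) < cyl_radius + cut):
                        ok = False
                        break
            if ok:
                centers.append(c)
                placed = True
                break
        if not placed:
            raise PackingError(f"failed to place sphere {len(centers) + 1}/{n_spheres}")

    sub.sph_center = np.asarray(centers, float).reshape(-1, 3)
    sub.sph_radius = np.full(n_spheres, sph_radius)
    return sub


def substrate_grid(
    cylinder_counts=CYLINDER_COUNTS,
    sphere_counts=SPHERE_COUNTS,
    target_odi: float = 0.1,
    rng_seed: int = 0,
    **kwargs,
) -> list[Substrate]:
    """The full simulation grid: every (cylinder count, sphere count) pair."""
    subs = []
    seeds = np.random.SeedSequence(rng_seed).spawn(
        len(cylinder_counts) * len(sphere_counts)
    )
    k = 0
    for nc in cylinder_counts:
        for ns in sphere_counts:
            subs.append(
                build_substrate(
                    nc, ns, target_odi=target_odi,
                    rng_seed=int(seeds[k].generate_state(1)[0] % (2**31)),
                    **kwargs,
                )
            )
            k += 1
    return subs
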