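"""Initial geometries and the three bundled case studies.

The scenarios bundle everything needed to rerun the model's demonstration
episodes from configuration alone:

* ``toggle_switch`` — a ball-shaped tissue of idle cells embedding a
  signal-mediated toggle switch: Wnt production is switched on in a marked
  subregion at t = 20 min, the secreted ligand diffuses across the tissue,
  and cells that receive enough of it flip the Target gene ON via the
  Tcf+/Tcf- activation/repression switch.  Cells divide sporadically.
* ``delta_notch`` — a cubic tissue whose anterior half receives a brief
  pulse of protein X; mutual Delta/Notch induction across the resulting
  Anterior/posterior boundary differentiates exactly two adjacent monolayers
  of epithelial cells (Epi posterior, Epi2 anterior).  No division.
* ``epiboly`` — a blastoderm cap of mesenchymal deep cells on a spherical
  yolk under an EVL shell; radial guidance ligand released by the EVL
  orients bipolar protrusion, driving radial intercalation, flattening of
  the deep-cell mass and descent of the margin toward the vegetal pole.

Every geometry is generated programmatically, so all tests run without any
external data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import configio
from .engine import run_simulation
from .state_core import BodyParticle, Cell, Tissue, Trajectory, cell_rng

SCENARIOS = ("toggle_switch", "delta_notch", "epiboly")


# ---------------------------------------------------------------------------
# Geometry generators
# ---------------------------------------------------------------------------


def _init_cells(points: np.ndarray, radius: float) -> list[Cell]:
    # cycle phases are left at 0 here; the engine draws initial phases from
    # the simulation seed when division is enabled
    return [Cell(id=i, position=p, radii=(radius, radius), rng_stream=i)
            for i, p in enumerate(points)]


def make_cube_tissue(n_side: int, spacing: float = 11.0, jitter: float = 0.3,
                     seed: int = 0, cell_radius: float = 6.0) -> Tissue:
    """n_side^3 idle cells on a jittered cubic lattice centred at the origin."""
    if n_side < 2:
        raise ValueError("n_side must be >= 2")
    ax = (np.arange(n_side) - (n_side - 1) / 2.0) * spacing
    pts = np.array([[x, y, z] for x in ax for y in ax for z in ax])
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7,)))
    pts = pts + jitter * rng.standard_normal(pts.shape)
    return Tissue(cells=_init_cells(pts, cell_radius))


def make_lattice_ball(n_cells: int, spacing: float = 11.0, jitter: float = 0.3,
                      seed: int = 0, cell_radius: float = 6.0) -> Tissue:
    """Roughly spherical tissue: the n_cells lattice sites nearest the origin."""
    n_side = int(np.ceil((n_cells * 6 / np.pi) ** (1 / 3))) + 2
    ax = (np.arange(n_side) - (n_side - 1) / 2.0) * spacing
    pts = np.array([[x, y, z] for x in ax for y in ax for z in ax])
    order = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")
    pts = pts[order[:n_cells]]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7,)))
    pts = pts + jitter * rng.standard_normal(pts.shape)
    return Tissue(cells=_init_cells(pts, cell_radius))


def _fibonacci_cap(n: int, radius: float, cap_angle: float) -> np.ndarray:
    """n points quasi-uniform on the spherical cap theta <= cap_angle (pole +z)."""
    k = np.arange(n) + 0.5
    cmin = np.cos(cap_angle)
    z = 1.0 - k / n * (1.0 - cmin)  # uniform in cos(theta) over the cap
    phi = np.pi * (1 + 5**0.5) * k
    s = np.sqrt(np.clip(1 - z**2, 0, None))
    return radius * np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def make_blastoderm(R_yolk: float = 60.0, n_deep: int = 330, n_evl: int = 260,
                    n_yolk_membrane: int = 560, cap_angle: float = 0.9,
                    seed: int = 0, cell_radius: float = 6.0,
                    evl_radius: float = 6.0, yolk_particle_radius: float = 6.0,
                    dome_height: float = 42.0, spacing: float = 10.0) -> Tissue:
    """Blastoderm-on-yolk geometry: a lens-shaped deep-cell dome sealed by an EVL.

    The animal-vegetal axis is +z with the animal pole at +z.  The deep-cell
    mass fills the lens between the yolk sphere (radius ``R_yolk``) and an
    outer spherical envelope chosen to pass through the dome apex
    (``R_yolk + dome_height`` on the axis) and through the margin circle at
    polar angle ``cap_angle`` on the yolk — so the blastoderm is thick at the
    animal pole and tapers to a closed wedge at the margin, as in the oblong
    stage.  EVL particles cover the outer envelope down to the margin (where
    they meet the yolk); the yolk membrane is a full sphere of body particles.
    """
    if min(n_deep, n_evl, n_yolk_membrane) <= 0:
        raise ValueError("particle counts must be > 0")
    # envelope sphere through apex (0,0,R+H) and the margin circle
    z_m = R_yolk * np.cos(cap_angle)
    rho_m = R_yolk * np.sin(cap_angle)
    z_apex = R_yolk + dome_height
    # centre (0,0,c): (z_apex-c)^2 = rho_m^2 + (z_m-c)^2
    c = (z_apex**2 - rho_m**2 - z_m**2) / (2.0 * (z_apex - z_m))
    rho = z_apex - c
    if rho <= cell_radius or dome_height <= 2 * cell_radius:
        raise ValueError("cap too thin: no room for deep cells between yolk and EVL")
    centre = np.array([0.0, 0.0, c])

    # carve a jittered cubic lattice to the lens interior
    lim = R_yolk + dome_height + spacing
    ax = np.arange(-lim, lim + spacing, spacing)
    X, Y, Z = np.meshgrid(ax, ax, ax[ax > 0.0], indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    r_yolk_d = np.linalg.norm(pts, axis=1)
    r_env_d = np.linalg.norm(pts - centre, axis=1)
    inside = (r_yolk_d > R_yolk + 0.8 * cell_radius) & \
             (r_env_d < rho - 0.8 * cell_radius)
    pts = pts[inside]
    if len(pts) < n_deep:
        raise ValueError(
            f"cap too thin: only {len(pts)} lattice sites for {n_deep} deep cells")
    theta = np.arccos(np.clip(pts[:, 2] / np.linalg.norm(pts, axis=1), -1, 1))
    order = np.argsort(theta, kind="stable")  # trim the outermost margin sites
    pts = pts[order[:n_deep]]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(8,)))
    pts = pts + 0.5 * rng.standard_normal(pts.shape)
    cells = _init_cells(pts, cell_radius)

    # EVL on the envelope sphere from apex down to the margin circle
    alpha_m = np.arccos(np.clip((z_m - c) / rho, -1, 1))
    evl_pts = centre + _fibonacci_cap(n_evl, rho, alpha_m)
    yolk_pts = _fibonacci_cap(n_yolk_membrane, R_yolk, np.pi)
    bodies = [BodyParticle(id=10_000_000 + i, position=p, body="EVL",
                           radius=evl_radius) for i, p in enumerate(evl_pts)]
    bodies += [BodyParticle(id=10_000_000 + n_evl + i, position=p,
                            body="yolk_membrane", radius=yolk_particle_radius)
               for i, p in enumerate(yolk_pts)]
    return Tissue(cells=cells, bodies=bodies)


def build_geometry(geom: dict, seed: int = None) -> Tissue:
    """Build an initial tissue; the lattice-jitter seed is the geometry's own
    (``geometry.seed``, default 0), separate from the simulation seed, so the
    initial configuration is a property of the scenario, not of the run."""
    kind = geom.get("kind", "cube")
    g = {k: v for k, v in geom.items() if k != "kind"}
    g.setdefault("seed", 0)
    if kind == "cube":
        return make_cube_tissue(**g)
    if kind == "lattice_ball":
        return make_lattice_ball(**g)
    if kind == "blastoderm":
        return make_blastoderm(**g)
    raise ValueError(f"unknown geometry kind {kind!r}")


# ---------------------------------------------------------------------------
# Scenario running
# ---------------------------------------------------------------------------


def scenario_config(name: str, overrides=None) -> dict:
    if name not in SCENARIOS and not name.endswith("_small"):
        raise KeyError(f"unknown scenario {name!r} (have {SCENARIOS})")
    d = configio.load_bundled_config(name)
    return configio.apply_overrides(d, overrides or [])


def run_config_dict(d: dict) -> Trajectory:
    geom, config, grn = configio.build_from_dict(d)
    tissue = build_geometry(geom, config.seed)
    settle = float(d.get("sim", {}).get("settle_min", 0.0))
    if settle > 0:
        # passive settling phase: relax the carved lattice (and establish any
        # clamped ligand gradients) with active behaviour and division off,
        # then restart the clock for the behavioural run proper
        import dataclasses
        pre = dataclasses.replace(
            config,
            behaviour=dataclasses.replace(config.behaviour, phi=0.0, lambda_ran=0.0),
            division=dataclasses.replace(config.division, enabled=False),
            duration=settle, snapshot_every=settle)
        tissue = run_simulation(tissue, grn, pre).snapshots[-1]
        tissue.time = 0.0
    return run_simulation(tissue, grn, config)


def run_scenario(name: str, overrides=None) -> Trajectory:
    """Run a bundled scenario (optionally a ``*_small`` test variant)."""
    return run_config_dict(scenario_config(name, overrides))


# ---------------------------------------------------------------------------
# Synthetic reference curves for epiboly fitness
# ---------------------------------------------------------------------------


def synthetic_reference_curves(t_start: float = 0.0, t_end: float = 96.0,
                               n_points: int = 25,
                               yh_eh=(0.705, 0.715), mh_eh=(0.59, 0.555),
                               md_eh=(0.66, 0.69), midpoint: float = 0.5,
                               steepness: float = 6.0) -> pd.DataFrame:
    """Smooth logistic-style stand-in for live-embryo epiboly landmark curves.

    SYNTHETIC: these curves emulate only the qualitative course of the first
    epiboly phase — normalized yolk height (yh_eh) and margin diameter
    (md_eh) rising, normalized margin height (mh_eh) falling — and are not
    measurements of any real embryo.  Each metric runs from its start to its
    end value along a logistic in normalized time.
    """
    t = np.linspace(t_start, t_end, n_points)
    x = (t - t_start) / max(t_end - t_start, 1e-9)
    sig = 1.0 / (1.0 + np.exp(-steepness * (x - midpoint)))
    sig = (sig - sig[0]) / (sig[-1] - sig[0]) if sig[-1] > sig[0] else x * 0.0

    def curve(lo_hi):
        a, b = lo_hi
        return a + (b - a) * sig

    return pd.DataFrame({"time_min": t, "yh_eh": curve(yh_eh),
                         "mh_eh": curve(mh_eh), "md_eh": curve(md_eh)})
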