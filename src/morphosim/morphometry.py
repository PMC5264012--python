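"""Epiboly landmarks, morphometric curves, fitness and the (phi, lambda_ran) sweep.

Epiboly progress is quantified from five landmarks on the extraembryonic
particles: the vegetal pole (VP, yolk-membrane particle with minimal z), the
animal pole of the embryo (APe, EVL particle with maximal z), the yolk animal
pole (APy, yolk-membrane particle with maximal z) and the margin ring (EVL
particles at the lowest EVL latitude; a full ring rather than two projected
sagittal points, which is more robust for particle models — the 2-point
variant is available via ``margin_mode='sagittal'``).  Four distances follow:
embryo height EH = z(APe) - z(VP), yolk height YH = z(APy) - z(VP), margin
height MH = mean margin z - z(VP) and margin diameter MD = twice the mean
radial distance of the margin ring from the animal-vegetal axis.  YH, MH and
MD are normalized by EH.  Fitness against a reference curve table is the mean
absolute difference per metric, and the global fitness F their average —
lower is better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .state_core import Tissue, Trajectory


@dataclass
class EpibolyMetrics:
    EH: float
    YH: float
    MH: float
    MD: float

    @property
    def yh_eh(self):
        return self.YH / self.EH

    @property
    def mh_eh(self):
        return self.MH / self.EH

    @property
    def md_eh(self):
        return self.MD / self.EH


@dataclass
class FitnessResult:
    F_YH: float
    F_MH: float
    F_MD: float

    @property
    def F(self):
        return (self.F_YH + self.F_MH + self.F_MD) / 3.0


def landmarks(snapshot: Tissue, margin_band: float = None,
              margin_mode: str = "ring") -> dict:
    """Extremal-particle landmarks; ties broken deterministically by lower id."""
    evl = [b for b in snapshot.bodies if b.body == "EVL"]
    yolk = [b for b in snapshot.bodies if b.body == "yolk_membrane"]
    if not evl:
        raise ValueError("no EVL particles in snapshot")
    if not yolk:
        raise ValueError("no yolk-membrane particles in snapshot")

    def extremal(parts, sign):
        best = None
        for p in parts:  # max of sign*z, ties -> lower id
            key = (sign * p.position[2], -p.id)
            if best is None or key > best[0]:
                best = (key, p)
        return best[1]

    vp = extremal(yolk, -1.0)
    apy = extremal(yolk, +1.0)
    ape = extremal(evl, +1.0)
    z = np.array([p.position[2] for p in evl])
    if margin_band is None:
        # one typical inter-particle spacing of the EVL shell
        pos = np.array([p.position for p in evl])
        r_shell = float(np.mean(np.linalg.norm(pos, axis=1)))
        margin_band = 2.0 * r_shell / np.sqrt(len(evl))
    ring = [p for p in evl if p.position[2] <= z.min() + margin_band]
    if margin_mode == "sagittal":
        # two extreme-|x| members of the ring, emulating projected L/R margins
        ring = sorted(ring, key=lambda p: (-abs(p.position[0]), p.id))[:2]
    return {"VP": vp, "APe": ape, "APy": apy, "margin_ring": ring}


def epiboly_metrics(snapshot: Tissue, **kw) -> EpibolyMetrics:
    lm = landmarks(snapshot, **kw)
    z_vp = lm["VP"].position[2]
    eh = lm["APe"].position[2] - z_vp
    if eh <= 0:
        raise ValueError("degenerate geometry: EH <= 0")
    yh = lm["APy"].position[2] - z_vp
    ring = np.array([p.position for p in lm["margin_ring"]])
    mh = float(np.mean(ring[:, 2]) - z_vp)
    md = float(2.0 * np.mean(np.linalg.norm(ring[:, :2], axis=1)))
    return EpibolyMetrics(EH=eh, YH=yh, MH=mh, MD=md)


def metrics_curves(trajectory: Trajectory, **kw) -> pd.DataFrame:
    """Normalized landmark metrics at every snapshot time."""
    rows = []
    for snap in trajectory.snapshots:
        m = epiboly_metrics(snap, **kw)
        rows.append({"time_min": snap.time, "yh_eh": m.yh_eh,
                     "mh_eh": m.mh_eh, "md_eh": m.md_eh})
    return pd.DataFrame(rows)


def fitness(sim_curves: pd.DataFrame, ref_curves: pd.DataFrame) -> FitnessResult:
    """Mean absolute difference per normalized metric on the reference grid.

    The simulated curves are linearly interpolated onto the reference time
    grid; the time ranges must overlap.
    """
    ts = np.asarray(sim_curves["time_min"], dtype=float)
    tr = np.asarray(ref_curves["time_min"], dtype=float)
    if tr.min() > ts.max() or tr.max() < ts.min():
        raise ValueError("simulated and reference curves do not overlap in time")
    grid = tr[(tr >= ts.min() - 1e-9) & (tr <= ts.max() + 1e-9)]
    out = {}
    for col in ("yh_eh", "mh_eh", "md_eh"):
        sim = np.interp(grid, ts, np.asarray(sim_curves[col], dtype=float))
        ref = np.interp(grid, tr, np.asarray(ref_curves[col], dtype=float))
        out[col] = float(np.mean(np.abs(sim - ref)))
    return FitnessResult(F_YH=out["yh_eh"], F_MH=out["mh_eh"], F_MD=out["md_eh"])


def sweep(phi_grid, lambda_ran_grid, scenario_dict: dict, ref_curves: pd.DataFrame,
          seeds, runner=None) -> pd.DataFrame:
    """Fitness landscape over the protrusion-intensity x polarization-noise grid.

    Runs the scenario for every (phi, lambda_ran, seed) combination and
    records the fitness components; failed runs are recorded with NaN values
    and the failure reason, and the sweep continues.  Results are independent
    of evaluation order (each run derives all randomness from its own seed).
    """
    from . import scenarios
    from .configio import apply_overrides

    if runner is None:
        runner = scenarios.run_config_dict
    rows = []
    for phi in phi_grid:
        for lran in lambda_ran_grid:
            for seed in seeds:
                over = {"behaviour.phi": float(phi),
                        "behaviour.lambda_ran": float(lran),
                        "sim.seed": int(seed)}
                row = {"phi": float(phi), "lambda_ran": float(lran),
                       "seed": int(seed), "error": ""}
                try:
                    traj = runner(apply_overrides(scenario_dict, over))
                    fr = fitness(metrics_curves(traj), ref_curves)
                    row.update({"F_YH": fr.F_YH, "F_MH": fr.F_MH,
                                "F_MD": fr.F_MD, "F": fr.F})
                except Exception as e:  # record and continue
                    row.update({"F_YH": np.nan, "F_MH": np.nan,
                                "F_MD": np.nan, "F": np.nan, "error": str(e)})
                rows.append(row)
    return pd.DataFrame(rows)


def plot_landscape(table: pd.DataFrame, path=None, metric: str = "F"):
    """Heat-map of the mean fitness landscape with isocline contours."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    piv = table.pivot_table(index="lambda_ran", columns="phi", values=metric)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(piv.columns, piv.index, piv.values, shading="nearest",
                       cmap="viridis_r")
    try:
        ax.contour(piv.columns, piv.index, piv.values, colors="w", linewidths=0.7)
    except Exception:
        pass
    ax.set_xlabel("protrusion intensity phi")
    ax.set_ylabel("polarization noise lambda_ran")
    fig.colorbar(im, ax=ax, label=metric)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
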