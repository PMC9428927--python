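"""Joint-spacing sweeps and spacing-vs-mobility trend analysis.

Joint spacing (mm) stands in for maximum articular-cartilage thickness.
Comparative thicknesses are scaled between specimens as a percentage of
femoral length; a sweep reruns the 4-DOF classification at each spacing
and records the viable-pose count and cosine-corrected alpha volume; trend
fitting regresses mobility on spacing and reports a descriptive plateau
estimate (mobility stops increasing beyond a spacing threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .rig import JointRig
from .romspace import alpha_volume, cosine_correct, default_alpha
from .sampling import PoseGrid, ROMMap, auto_offset_direction, classify_poses

__all__ = [
    "SpacingConfig",
    "SpacingScan",
    "TrendReport",
    "pct_of_femur",
    "scan_spacing",
    "fit_trends",
    "plot_scan",
]


def pct_of_femur(thickness: float, femur_length: float) -> float:
    """Thickness as a percentage of femoral length, to 3 decimals."""
    if femur_length <= 0:
        raise ValueError("femur length must be positive")
    if thickness < 0:
        raise ValueError("thickness must be non-negative")
    return round(100.0 * thickness / femur_length, 3)


@dataclass
class SpacingConfig:
    """A set of joint spacings to sweep, with provenance labels."""

    femur_length: float                 # mm
    spacings: list[float]               # mm
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.femur_length <= 0:
            raise ValueError("femur length must be positive")
        if any(s < 0 for s in self.spacings):
            raise ValueError("spacings must be non-negative")
        if not self.labels:
            self.labels = [f"spacing_{s:g}mm" for s in self.spacings]
        if len(self.labels) != len(self.spacings):
            raise ValueError("one label per spacing required")

    def as_pct_of_femur(self) -> list[float]:
        return [pct_of_femur(s, self.femur_length) for s in self.spacings]


@dataclass
class SpacingScan:
    """Per-spacing viable-pose counts and alpha volumes, ordered by spacing."""

    rows: list[tuple[float, int, float, str]]   # (mm, count, degree^3, label)
    grid_size: int
    alpha: float
    maps: list[ROMMap] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["spacing_mm", "viable_count", "volume_deg3", "label"]
        )

    def to_csv(self, path: str | Path, provenance: str = "") -> Path:
        path = Path(path)
        header = f"# osteorom spacing scan | alpha={self.alpha:g} | grid_size={self.grid_size}"
        if provenance:
            header += f" | {provenance}"
        with open(path, "w") as fh:
            fh.write(header + "\n")
            self.to_frame().to_csv(fh, index=False)
        return path


def scan_spacing(rig: JointRig, grid: PoseGrid, config: SpacingConfig,
                 alpha: float | None = None, direction=None,
                 keep_maps: bool = False, contact_tol: float = 0.0) -> SpacingScan:
    """Run the 4-DOF classification at every configured spacing.

    Each spacing becomes a static translational offset along the ACS Y axis
    (sign chosen automatically as the one that opens the joint, unless a
    *direction* unit vector is supplied). The alpha volume of each map's
    cosine-corrected cloud is recorded; maps with fewer than four viable
    poses get volume NaN.
    """
    if alpha is None:
        alpha = default_alpha(grid.step)
    if direction is None:
        direction = auto_offset_direction(rig)
    direction = np.asarray(direction, dtype=np.float64).reshape(3)
    order = np.argsort(config.spacings, kind="stable")
    rows: list[tuple[float, int, float, str]] = []
    maps: list[ROMMap] = []
    for i in order:
        spacing = float(config.spacings[i])
        rom = classify_poses(rig, grid, regime="4dof",
                             static_offset=direction * spacing,
                             contact_tol=contact_tol)
        if rom.n_viable >= 4:
            try:
                vol = alpha_volume(cosine_correct(rom), alpha).volume
            except ValueError:   # coplanar viable set
                vol = math.nan
        else:
            vol = math.nan
        rows.append((spacing, rom.n_viable, vol, config.labels[i]))
        if keep_maps:
            maps.append(rom)
    return SpacingScan(rows=rows, grid_size=grid.size, alpha=float(alpha),
                       maps=maps if keep_maps else None)


@dataclass
class TrendTerm:
    """OLS linear trend plus quadratic curvature for one response."""

    response: str
    slope: float
    intercept: float
    adj_r_squared: float
    p_value: float
    quad_coeffs: tuple[float, float, float]     # a, b, c of a x^2 + b x + c
    quad_vertex: float | None                   # stationary point, if in range


@dataclass
class TrendReport:
    terms: dict[str, TrendTerm]
    plateau_spacing: float | None   # first spacing where growth < 1% of grid

    def to_text(self) -> str:
        lines = []
        for t in self.terms.values():
            lines.append(
                f"{t.response}: slope={t.slope:.6g} adjR2={t.adj_r_squared:.3f} "
                f"p={t.p_value:.4g} quad_vertex="
                f"{'-' if t.quad_vertex is None else format(t.quad_vertex, '.4g')}"
            )
        lines.append(
            "plateau_spacing_mm="
            + ("-" if self.plateau_spacing is None else f"{self.plateau_spacing:.4g}")
        )
        return "\n".join(lines) + "\n"


def _fit_one(x: np.ndarray, y: np.ndarray, name: str) -> TrendTerm:
    model = sm.OLS(y, sm.add_constant(x)).fit()
    a, b, c = np.polyfit(x, y, 2)
    vertex = None
    if abs(a) > 1e-12:
        v = -b / (2 * a)
        if x.min() <= v <= x.max():
            vertex = float(v)
    return TrendTerm(
        response=name,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        adj_r_squared=float(model.rsquared_adj),
        p_value=float(model.pvalues[1]),
        quad_coeffs=(float(a), float(b), float(c)),
        quad_vertex=vertex,
    )


def fit_trends(scan: SpacingScan) -> TrendReport:
    """Regress viable counts and volumes on spacing; estimate the plateau.

    Linear OLS gives slope, adjusted R^2 and the two-sided p-value of the
    slope; a quadratic fit's stationary point (when inside the spacing
    range) plus the first spacing whose count increment falls below 1% of
    the grid size give two descriptive plateau indicators.
    """
    df = scan.to_frame()
    if len(df) < 3:
        raise ValueError("trend fitting needs at least 3 spacings")
    x = df["spacing_mm"].to_numpy(float)
    if np.ptp(x) < 1e-12:
        raise ValueError("spacings are constant; trends are undefined")
    terms = {"viable_count": _fit_one(x, df["viable_count"].to_numpy(float),
                                      "viable_count")}
    vols = df["volume_deg3"].to_numpy(float)
    ok = np.isfinite(vols)
    if ok.sum() >= 3 and np.ptp(x[ok]) > 1e-12:
        terms["volume_deg3"] = _fit_one(x[ok], vols[ok], "volume_deg3")
    counts = df["viable_count"].to_numpy(float)
    plateau = None
    threshold = 0.01 * scan.grid_size
    for i in range(1, len(counts)):
        if counts[i] - counts[i - 1] < threshold:
            plateau = float(x[i])
            break
    return TrendReport(terms=terms, plateau_spacing=plateau)


def plot_scan(scan: SpacingScan, path: str | Path) -> Path:
    """Counts and volumes vs spacing with linear and quadratic overlays."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = scan.to_frame()
    x = df["spacing_mm"].to_numpy(float)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6))
    for ax, col, title in zip(
        axes, ["viable_count", "volume_deg3"],
        ["Viable poses", "Volume (degree$^3$)"],
    ):
        y = df[col].to_numpy(float)
        ok = np.isfinite(y)
        ax.plot(x[ok], y[ok], "ko", ms=5)
        if ok.sum() >= 3 and np.ptp(x[ok]) > 0:
            xs = np.linspace(x[ok].min(), x[ok].max(), 100)
            lin = np.polyfit(x[ok], y[ok], 1)
            quad = np.polyfit(x[ok], y[ok], 2)
            ax.plot(xs, np.polyval(lin, xs), "-", lw=1, label="linear")
            ax.plot(xs, np.polyval(quad, xs), "--", lw=1, label="quadratic")
            ax.legend(fontsize=8)
        ax.set_xlabel("joint spacing (mm)")
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
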