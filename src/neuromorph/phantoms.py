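"""Synthetic phantoms and cohorts with analytic ground truth.

Two generator families make every metric testable without real data:

* **Voxel phantoms** — tubes swept along parametric curves (line, arc,
  helix, sinusoid) whose curvature integral is known in closed form, so
  the measured sum-of-angles tortuosity has an analytic target (line: 0;
  arc of radius r: 1/r; helix radius r, rise c per radian: r/(r^2+c^2));
  and pitted cubes whose discrete compactness decreases monotonically
  with pitting level.

* **Three-class cohorts** — per-subject multimodal feature tables (HC,
  MCI, AD) with Gaussian class-conditional features and declared
  standardized mean shifts per disease stage. Default directionality
  follows the disease: volumes, compactness, cortical thickness, MMSE and
  CSF beta-amyloid-42 decrease with stage; tortuosity and CSF tau
  increase; plasma markers carry no effect, so screening should drop the
  plasma block.

Every phantom ships with its analytic expectation; generation is
bit-reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .classify import image_feature_names
from .morphometrics import discrete_compactness, exposed_face_area
from .volumes import BinaryMask

__all__ = [
    "CurveSpec",
    "CohortSpec",
    "make_tube_phantom",
    "make_compact_phantom",
    "make_cohort",
    "voxelize_and_measure",
]


@dataclass
class CurveSpec:
    """Parametric space curve with closed-form curvature integral.

    kinds:
      line     — straight segment of ``length`` mm; curvature 0.
      arc      — circular arc, ``radius`` mm, ``length`` mm along the arc
                 (default quarter circle); curvature 1/radius.
      helix    — radius ``radius`` mm, rise ``pitch`` mm per radian,
                 ``length`` = parameter sweep in radians (default 2*pi);
                 curvature radius/(radius^2 + pitch^2).
      sinusoid — y = amplitude*sin(2*pi*x/period) over ``length`` mm of x;
                 mean curvature obtained by quadrature of the exact
                 curvature formula (no elementary closed form).
    """

    kind: str = "line"
    radius: float = 10.0
    pitch: float = 10.0
    amplitude: float = 5.0
    period: float = 40.0
    length: float = 40.0
    step: float = 0.25  # sampling step along the parameter, mm or rad

    def sample(self) -> np.ndarray:
        """Densely sampled (N, 3) polyline in mm."""
        if self.kind == "line":
            t = np.arange(0.0, self.length + self.step / 2, self.step)
            return np.column_stack([t, np.zeros_like(t), np.zeros_like(t)])
        if self.kind == "arc":
            theta_max = self.length / self.radius
            t = np.arange(0.0, theta_max + 1e-12, self.step / self.radius)
            return np.column_stack(
                [self.radius * np.sin(t), self.radius * (1 - np.cos(t)), np.zeros_like(t)]
            )
        if self.kind == "helix":
            t = np.arange(0.0, self.length + 1e-12, self.step / self.radius)
            return np.column_stack(
                [self.radius * np.cos(t), self.radius * np.sin(t), self.pitch * t]
            )
        if self.kind == "sinusoid":
            t = np.arange(0.0, self.length + self.step / 2, self.step)
            return np.column_stack(
                [t, self.amplitude * np.sin(2 * np.pi * t / self.period), np.zeros_like(t)]
            )
        raise ValueError(f"unknown curve kind {self.kind!r}")

    def expected_tortuosity(self) -> float:
        """Analytic mean curvature = (integral of curvature ds) / arc length."""
        if self.kind == "line":
            return 0.0
        if self.kind == "arc":
            return 1.0 / self.radius
        if self.kind == "helix":
            return self.radius / (self.radius**2 + self.pitch**2)
        if self.kind == "sinusoid":
            a, w = self.amplitude, 2 * np.pi / self.period
            x = np.linspace(0.0, self.length, 20001)
            yp = a * w * np.cos(w * x)
            ypp = -a * w**2 * np.sin(w * x)
            kappa = np.abs(ypp) / (1 + yp**2) ** 1.5
            ds = np.sqrt(1 + yp**2)
            return float(np.trapezoid(kappa * ds, x) / np.trapezoid(ds, x))
        raise ValueError(f"unknown curve kind {self.kind!r}")

    def arc_length(self) -> float:
        pts = self.sample()
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def make_tube_phantom(
    curve: CurveSpec, tube_radius: float = 3.0, spacing: float = 1.0
) -> tuple[BinaryMask, float, float]:
    """Voxelize a tube of radius ``tube_radius`` mm around a curve.

    Returns (mask, expected_TR, expected_volume). The mask holds voxels
    whose center is within ``tube_radius`` of the curve polyline; volume
    expectation is pi*r^2*L (end caps ignored). Phantoms are generated
    directly on the isotropic lattice, decoupling metric tests from
    resampling.
    """
    if tube_radius < 2 * spacing:
        raise ValueError(
            f"tube radius {tube_radius} below 2x spacing {spacing}; not skeletonizable"
        )
    pts = curve.sample()
    if pts.shape[0] < 2:
        raise ValueError("degenerate curve: fewer than 2 samples")
    pad = tube_radius + 3 * spacing
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    shape = tuple(int(np.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    grids = [lo[i] + spacing * np.arange(shape[i]) for i in range(3)]
    centers = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
    dist, _ = cKDTree(pts).query(centers, workers=-1)
    mask = (dist <= tube_radius).reshape(shape)
    expected_tr = curve.expected_tortuosity()
    expected_vol = float(np.pi * tube_radius**2 * curve.arc_length())
    return (
        BinaryMask(mask, np.full(3, float(spacing))),
        expected_tr,
        expected_vol,
    )


def make_compact_phantom(
    level: int, base_side: int = 10, seed: int = 0
) -> BinaryMask:
    """Solid cube with seeded surface pitting; DC strictly decreases with level.

    Level 0 is the pristine cube (DC = 1). Each level removes ``level *
    base_side`` face-centered surface voxels, chosen seeded and pairwise
    non-adjacent, which raises the exposed surface at near-constant voxel
    count. If pitting fragments the mask into dust, regeneration is
    retried with a derived seed (bounded retries).
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    if base_side < 4:
        raise ValueError("base_side must be >= 4")
    for attempt in range(8):
        rng = np.random.default_rng((seed + 7919 * attempt) % 2**31)
        cube = np.ones((base_side,) * 3, dtype=bool)
        if level > 0:
            n_pits = level * base_side
            # candidate face voxels: on exactly one boundary plane, not on edges
            idx = np.argwhere(cube)
            on_bound = np.sum(
                (idx == 0) | (idx == base_side - 1), axis=1
            )
            candidates = idx[on_bound == 1]
            rng.shuffle(candidates)
            removed: list[tuple] = []
            for v in map(tuple, candidates):
                if len(removed) >= n_pits:
                    break
                if any(max(abs(v[i] - r[i]) for i in range(3)) <= 1 for r in removed):
                    continue  # keep pits non-adjacent so each adds full surface
                removed.append(v)
            for v in removed:
                cube[v] = False
        labeled, n_comp = ndimage.label(cube, structure=np.ones((3, 3, 3), bool))
        if n_comp == 1:
            return BinaryMask(cube, np.ones(3))
    raise RuntimeError("could not generate a connected pitted cube")


# ---------------------------------------------------------------------------
# Cohorts

BIOCHEM_FEATURES = (
    "tau_csf", "abeta42_csf", "abeta40_plasma", "abeta42_plasma", "plasma_ratio",
)

# (baseline mean, within-class SD, direction of change per disease stage)
# Baselines are plausible clinical scales: volumes in mm^3-ish magnitudes,
# NV as ICV fractions, DC in (0,1), CT in mm, TR in rad/mm, CSF markers in
# pg/mL, MMSE points. Direction -1 = decreases HC -> MCI -> AD, +1 = grows.
_FEATURE_MODEL: dict[str, tuple[float, float, int]] = {
    "V": (5.0e5, 5.0e4, -1),
    "NV": (0.35, 0.035, -1),
    "DC": (0.85, 0.04, -1),
    "CT": (2.5, 0.25, -1),
    "TR": (0.08, 0.012, +1),
    "tau_csf": (250.0, 60.0, +1),
    "abeta42_csf": (800.0, 150.0, -1),
    "abeta40_plasma": (180.0, 40.0, 0),
    "abeta42_plasma": (40.0, 10.0, 0),
    "plasma_ratio": (4.5, 1.0, 0),
    "MMSE": (29.0, 1.5, -1),
}


@dataclass
class CohortSpec:
    """Design of a synthetic three-class cohort.

    ``effects`` maps a feature block to its standardized mean shift per
    disease stage (HC -> MCI -> AD), applied in the block's declared
    direction; 0.8 SD per stage for affected blocks is the default, plasma
    0 by design. ``n_train``/``n_holdout`` are per-class counts.
    """

    n_train: int = 40
    n_holdout: int = 10
    effects: dict = field(
        default_factory=lambda: {
            "V": 0.8, "NV": 0.8, "DC": 0.8, "CT": 0.8, "TR": 0.8,
            "tau_csf": 0.8, "abeta42_csf": 0.8,
            "abeta40_plasma": 0.0, "abeta42_plasma": 0.0, "plasma_ratio": 0.0,
            "MMSE": 0.8,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_holdout < 1:
            raise ValueError("per-class counts must be >= 1")
        for k, v in self.effects.items():
            if not np.isfinite(v):
                raise ValueError(f"effect size for {k!r} must be finite")
            if k not in _FEATURE_MODEL:
                raise ValueError(f"unknown feature block {k!r}")


_CLASSES = ("HC", "MCI", "AD")
_CDR_BY_CLASS = {"HC": 0.0, "MCI": 0.5, "AD": 1.0}


def _simulate_class(rng, label: str, n: int, spec: CohortSpec) -> pd.DataFrame:
    from .morphometrics import STRUCTURES

    stage = _CLASSES.index(label)
    cols: dict[str, np.ndarray] = {}
    for metric in ("V", "NV", "DC", "CT", "TR"):
        base, sd, direction = _FEATURE_MODEL[metric]
        shift = spec.effects.get(metric, 0.0) * direction * stage * sd
        for s in STRUCTURES:
            # per-structure baseline scaling keeps columns distinguishable
            scale = 1.0 + 0.1 * STRUCTURES.index(s)
            cols[f"{metric}_{s}"] = rng.normal(base * scale + shift * scale, sd * scale, n)
    for feat in BIOCHEM_FEATURES:
        base, sd, direction = _FEATURE_MODEL[feat]
        shift = spec.effects.get(feat, 0.0) * direction * stage * sd
        cols[feat] = rng.normal(base + shift, sd, n)
    base, sd, direction = _FEATURE_MODEL["MMSE"]
    shift = spec.effects.get("MMSE", 0.0) * direction * stage * sd
    cols["MMSE"] = np.clip(rng.normal(base + shift, sd, n), 0.0, 30.0)
    df = pd.DataFrame(cols)
    # NV must stay a fraction; the baseline keeps it well inside (0, 1),
    # clip only as a guard for extreme draws at large effect sizes.
    for s in STRUCTURES:
        df[f"NV_{s}"] = df[f"NV_{s}"].clip(1e-6, 1.0)
    df.insert(0, "label", label)
    df["CDR"] = _CDR_BY_CLASS[label]
    df["age"] = np.round(rng.normal(75.0, 5.0, n), 1)
    df["sex"] = rng.choice(["F", "M"], size=n)
    return df


def make_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (train, holdout, truth) tables for a three-class cohort.

    Train and holdout tables carry one row per subject: ``subject_id``,
    ``label``, the 30 image columns, 5 biochemical columns, MMSE, CDR, age
    and sex. The truth table records the declared standardized effect and
    direction per feature block — generator ground truth for recovery
    tests, never read from the code under test.
    """
    rng = np.random.default_rng(spec.seed)

    def build(n_per_class: int, prefix: str) -> pd.DataFrame:
        parts = [_simulate_class(rng, c, n_per_class, spec) for c in _CLASSES]
        df = pd.concat(parts, ignore_index=True)
        df.insert(0, "subject_id", [f"{prefix}{i:04d}" for i in range(len(df))])
        return df

    train = build(spec.n_train, "T")
    holdout = build(spec.n_holdout, "H")
    truth = pd.DataFrame(
        [
            {
                "block": k,
                "effect_sd_per_stage": spec.effects.get(k, 0.0),
                "direction": _FEATURE_MODEL[k][2],
            }
            for k in _FEATURE_MODEL
        ]
    )
    return train, holdout, truth


def voxelize_and_measure(
    curves: list[CurveSpec],
    tube_radius: float = 3.0,
    spacings: tuple[float, ...] = (1.0,),
    smoothing_window: int = 1,
) -> pd.DataFrame:
    """Discretization-bias report: measured vs analytic tortuosity.

    Voxelizes each curve at each spacing, runs the full skeleton + SOAM
    pipeline and tabulates measured TR against the analytic value with a
    relative-error column.
    """
    from .morphometrics import MetricsConfig, structure_metrics

    if len(curves) < 2:
        raise ValueError("need at least 2 curves for a comparison report")
    rows = []
    cfg = MetricsConfig(smoothing_window=smoothing_window)
    for i, curve in enumerate(curves):
        for sp in spacings:
            mask, expected_tr, expected_vol = make_tube_phantom(
                curve, tube_radius=tube_radius, spacing=sp
            )
            m = structure_metrics(mask, icv=max(mask.count, 1), config=cfg,
                                  structure=f"{curve.kind}_{i}")
            rel = (
                abs(m.TR - expected_tr) / expected_tr if expected_tr > 0 else np.nan
            )
            rows.append(
                {
                    "curve": curve.kind,
                    "index": i,
                    "spacing_mm": sp,
                    "measured_TR": m.TR,
                    "analytic_TR": expected_tr,
                    "rel_error": rel,
                    "measured_V_mm3": m.V,
                    "analytic_V_mm3": expected_vol,
                }
            )
    return pd.DataFrame(rows)
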