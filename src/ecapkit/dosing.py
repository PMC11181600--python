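"""Dosing-level analyses.

* 2-D response surfaces over stimulation-parameter grids (GP posterior
  means) with declarative off-target constraints, feasibility masks and
  constrained optima — the "space available for on-target adjustment once
  off-target effects are excluded" view of a parameter grid;
* 15-dimensional activation vectors ((A-beta, A-gamma, B) × five probe
  currents at 260 µs) per stimulation location, projected into a 2-D
  latent space by PCA with an exact reverse projection;
* per-frequency linear planes mapping (A-gamma, B) recruitment to ΔHR,
  anchored at the origin — the linearisation of heart-rate effects in
  eCAP space;
* slope-comparison ANOVA between stimulation locations, used to probe
  whether a predictor sits on the causal path (a predictor on the path
  shows no location-dependent slope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .drcmodels import GPFit, approx_f_test, fit_gp
from .errors import ConfigurationError, ValidationError

PROBE_CURRENTS_MA = (0.1, 0.25, 0.5, 1.0, 2.0)
PROBE_PULSE_WIDTH_US = 260.0
VECTOR_FIBERS = ("Abeta", "Agamma", "B")


# ---------------------------------------------------------------------------
# Response surfaces and dose maps
# ---------------------------------------------------------------------------

def response_surface(df: pd.DataFrame, value_col: str,
                     axis_cols: tuple[str, str], grid_n: int = 25,
                     kernel: str = "squared_exponential",
                     ) -> tuple[tuple[np.ndarray, np.ndarray], np.ndarray,
                                GPFit]:
    """GP posterior-mean surface of one response over two parameters.

    The grid spans exactly the tested ranges (no extrapolation). Events
    must vary along the two axis parameters only.
    """
    pts = df[list(axis_cols)].to_numpy(dtype=float)
    y = df[value_col].to_numpy(dtype=float)
    if np.unique(pts, axis=0).shape[0] < 4:
        raise ValidationError(
            "response surface needs >= 4 distinct grid points")
    gp = fit_gp(pts, y, kernel=kernel)
    g1 = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid_n)
    g2 = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid_n)
    xx, yy = np.meshgrid(g1, g2, indexing="ij")
    surf = gp.predict(np.column_stack([xx.ravel(), yy.ravel()]))
    return (g1, g2), surf.reshape(grid_n, grid_n), gp


@dataclass(frozen=True)
class Constraint:
    """Declarative off-target constraint: ``metric comparator bound``."""

    metric: str
    comparator: str  # "le" or "ge"
    bound: float

    def __post_init__(self) -> None:
        if self.comparator not in ("le", "ge"):
            raise ConfigurationError(
                f"comparator must be 'le' or 'ge', got {self.comparator!r}")

    def holds(self, values: np.ndarray) -> np.ndarray:
        if self.comparator == "le":
            return values <= self.bound
        return values >= self.bound


@dataclass
class DoseMap:
    """On-target and off-target response surfaces over a 2-D parameter grid."""

    axis_names: tuple[str, str]
    axes: tuple[np.ndarray, np.ndarray]
    on_target: np.ndarray  # ΔHR surface (GP posterior mean)
    off_target: dict[str, np.ndarray] = field(default_factory=dict)
    mask: np.ndarray | None = None  # True = feasible
    constraints: tuple[Constraint, ...] = ()

    def __post_init__(self) -> None:
        shape = (self.axes[0].size, self.axes[1].size)
        if self.on_target.shape != shape:
            raise ValidationError("on-target surface shape != grid shape")
        for name, surf in self.off_target.items():
            if surf.shape != shape:
                raise ValidationError(
                    f"off-target surface {name!r} shape != grid shape")


def build_dose_map(physio_df: pd.DataFrame, axis_cols: tuple[str, str],
                   on_target_col: str = "delta_hr_bpm",
                   off_target_cols: Sequence[str] = ("delta_br_pct",
                                                     "twitch_count",
                                                     "spasm_score"),
                   grid_n: int = 25) -> DoseMap:
    """Fit the on-target and every off-target surface on a common grid."""
    axes, on_surf, _ = response_surface(physio_df, on_target_col, axis_cols,
                                        grid_n)
    off = {}
    for col in off_target_cols:
        if col not in physio_df.columns:
            continue
        _, surf, _ = response_surface(physio_df, col, axis_cols, grid_n)
        off[col] = surf
    return DoseMap(axis_names=axis_cols, axes=axes, on_target=on_surf,
                   off_target=off)


def feasibility_mask(dose_map: DoseMap,
                     constraints: Sequence[Constraint]) -> np.ndarray:
    """Boolean grid of cells satisfying every off-target constraint.

    Tightening any constraint can only remove feasible cells (monotone).
    An unknown metric is a configuration error; an empty feasible set is
    allowed but warned about.
    """
    mask = np.ones_like(dose_map.on_target, dtype=bool)
    surfaces = dict(dose_map.off_target)
    surfaces.setdefault("on_target", dose_map.on_target)
    for con in constraints:
        if con.metric not in surfaces:
            raise ConfigurationError(
                f"unknown constraint metric {con.metric!r}; available: "
                f"{sorted(surfaces)}")
        mask &= con.holds(surfaces[con.metric])
    if not mask.any():
        warnings.warn("no feasible dose under the given constraints",
                      stacklevel=2)
    dose_map.mask = mask
    dose_map.constraints = tuple(constraints)
    return mask


def constrained_optimum(dose_map: DoseMap, objective: str = "min",
                        ) -> tuple[tuple[int, int], tuple[float, float],
                                   float]:
    """Best feasible cell of the on-target surface.

    ``objective="min"`` (bradycardia targets) or ``"max"``. Returns the
    grid indices, the parameter values of that cell and the on-target
    value; ties break lexicographically in grid order. Raises when the
    feasible mask is empty.
    """
    if objective not in ("min", "max"):
        raise ConfigurationError("objective must be 'min' or 'max'")
    mask = dose_map.mask if dose_map.mask is not None else \
        np.ones_like(dose_map.on_target, dtype=bool)
    if not mask.any():
        raise ValidationError("no feasible dose")
    surf = dose_map.on_target.copy()
    bad = np.inf if objective == "min" else -np.inf
    surf[~mask] = bad
    flat = int(np.argmin(surf) if objective == "min" else np.argmax(surf))
    i, j = np.unravel_index(flat, surf.shape)
    cell = (int(i), int(j))
    return cell, (float(dose_map.axes[0][i]), float(dose_map.axes[1][j])), \
        float(dose_map.on_target[i, j])


# ---------------------------------------------------------------------------
# Activation vectors and latent space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivationVector:
    """15-dim evoked-activation fingerprint of one stimulation location.

    Ordering is fiber-major, current-minor:
    (Abeta@0.1, Abeta@0.25, ..., Abeta@2.0, Agamma@0.1, ..., B@2.0).
    """

    location: str  # contact pair + polarity
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(VECTOR_FIBERS) * len(PROBE_CURRENTS_MA):
            raise ValidationError(
                f"activation vector must have "
                f"{len(VECTOR_FIBERS) * len(PROBE_CURRENTS_MA)} entries")


def build_activation_vectors(table: pd.DataFrame,
                             probe_currents: Sequence[float]
                             = PROBE_CURRENTS_MA,
                             pulse_width: float = PROBE_PULSE_WIDTH_US,
                             fibers: Sequence[str] = VECTOR_FIBERS,
                             channel_id: str | None = None,
                             rel_tol: float = 0.1,
                             value_col: str = "activation_norm",
                             ) -> list[ActivationVector]:
    """One activation vector per stimulation location.

    ``table`` is the long-format activation table. For each location
    (contact pair × polarity) and each (fiber, probe current) cell the
    nearest tested current within ``rel_tol`` relative tolerance is used;
    locations with any missing cell are dropped with a warning.
    """
    sel = table[table["pulse_width_us"] == pulse_width]
    if channel_id is not None:
        sel = sel[sel["channel_id"] == channel_id]
    elif sel["channel_id"].nunique() > 1:
        sel = sel[sel["channel_id"] == sorted(sel["channel_id"].unique())[0]]
    vectors = []
    for (pair, pol), grp in sel.groupby(["contact_pair", "polarity"]):
        values: list[float] = []
        complete = True
        for fiber in fibers:
            fg = grp[grp["fiber"] == fiber]
            tested = fg["current_mA"].unique()
            for probe in probe_currents:
                if tested.size == 0:
                    complete = False
                    break
                nearest = tested[np.argmin(np.abs(tested - probe))]
                if abs(nearest - probe) > rel_tol * probe * (1 + 1e-9):
                    complete = False
                    break
                values.append(float(
                    fg[fg["current_mA"] == nearest][value_col].mean()))
            if not complete:
                break
        if not complete:
            warnings.warn(f"location {pair}/{pol} dropped: missing probe "
                          "currents", stacklevel=2)
            continue
        vectors.append(ActivationVector(location=f"{pair}/{pol}",
                                        values=tuple(values)))
    return vectors


@dataclass
class LatentSpace:
    """Rank-2 PCA latent space over activation vectors (centered, unscaled)."""

    loadings: np.ndarray  # (2, 15), orthonormal rows
    projections: pd.DataFrame  # location, z1, z2
    explained_variance_ratio: np.ndarray
    centering: np.ndarray  # (15,)

    def project(self, v: np.ndarray) -> np.ndarray:
        return (np.asarray(v, dtype=float) - self.centering) @ self.loadings.T

    def reverse_project(self, z: np.ndarray) -> np.ndarray:
        return self.centering + np.asarray(z, dtype=float) @ self.loadings


def fit_latent_space(vectors: Sequence[ActivationVector]) -> LatentSpace:
    """PCA of the activation vectors, 2 components retained.

    Vectors are centered but not variance-scaled (all entries share the
    normalised-activation unit). ``reverse_project(project(v))`` is the
    rank-2 reconstruction of ``v``; ``reverse_project(0)`` is the mean
    vector.
    """
    if len(vectors) < 3:
        raise ValidationError("latent space needs >= 3 activation vectors")
    X = np.array([v.values for v in vectors], dtype=float)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < 2:
        raise ValidationError("activation vectors have rank < 2")
    pca = PCA(n_components=2)
    z = pca.fit_transform(X)
    proj = pd.DataFrame({"location": [v.location for v in vectors],
                         "z1": z[:, 0], "z2": z[:, 1]})
    return LatentSpace(loadings=pca.components_.copy(), projections=proj,
                       explained_variance_ratio=
                       pca.explained_variance_ratio_.copy(),
                       centering=pca.mean_.copy())


# ---------------------------------------------------------------------------
# eCAP-space linearisation of heart-rate effects
# ---------------------------------------------------------------------------

@dataclass
class HrActivationPlane:
    """Origin-anchored linear map (A-gamma, B) recruitment → ΔHR."""

    frequency: float
    w_agamma: float
    w_b: float
    r_squared: float
    n: int

    def predict(self, rec_agamma: np.ndarray, rec_b: np.ndarray,
                ) -> np.ndarray:
        return self.w_agamma * np.asarray(rec_agamma) \
            + self.w_b * np.asarray(rec_b)


def hr_plane_inputs(table: pd.DataFrame, physio_df: pd.DataFrame,
                    agamma_fiber: str = "Agamma", b_fiber: str = "B",
                    ) -> pd.DataFrame:
    """Assemble the per-event (rec_Aγ, rec_B, ΔHR) table for plane fits.

    Normalised activations are averaged across all recording channels,
    which halves the variance of the recruitment estimates compared to a
    single cuff.
    """
    def fiber_col(fiber: str, name: str) -> pd.DataFrame:
        sel = table[table["fiber"] == fiber]
        return sel.groupby("event_id")["activation_norm"].mean() \
            .rename(name).reset_index()

    return physio_df.merge(fiber_col(agamma_fiber, "rec_agamma"),
                           on="event_id") \
        .merge(fiber_col(b_fiber, "rec_b"), on="event_id")


def fit_hr_activation_planes(df: pd.DataFrame,
                             agamma_col: str = "rec_agamma",
                             b_col: str = "rec_b",
                             hr_col: str = "delta_hr_bpm",
                             freq_col: str = "frequency_hz",
                             ) -> list[HrActivationPlane]:
    """Per-frequency least-squares planes through the origin.

    For each frequency group (>= 3 events) the model
    ``ΔHR = w_Aγ · rec_Aγ + w_B · rec_B`` is fitted with a (0, 0) → 0
    anchor appended, so every plane passes through the origin.
    """
    planes = []
    for freq, grp in df.groupby(freq_col):
        if len(grp) < 3:
            raise ValidationError(
                f"frequency {freq}: need >= 3 events for a plane")
        X = np.column_stack([grp[agamma_col].to_numpy(dtype=float),
                             grp[b_col].to_numpy(dtype=float)])
        y = grp[hr_col].to_numpy(dtype=float)
        if not np.any(np.abs(X) > 0):
            raise ValidationError(
                f"frequency {freq}: zero activations, plane undefined")
        X_anch = np.vstack([X, [0.0, 0.0]])
        y_anch = np.concatenate([y, [0.0]])
        if np.linalg.matrix_rank(X_anch) < 2:
            raise ValidationError(
                f"frequency {freq}: collinear activations")
        coef, _, _, _ = np.linalg.lstsq(X_anch, y_anch, rcond=None)
        resid = y_anch - X_anch @ coef
        ss_tot = float(np.sum(y_anch ** 2))  # through-origin R²
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
        planes.append(HrActivationPlane(frequency=float(freq),
                                        w_agamma=float(coef[0]),
                                        w_b=float(coef[1]),
                                        r_squared=r2, n=len(grp)))
    return planes


# ---------------------------------------------------------------------------
# Slope-comparison ANOVA
# ---------------------------------------------------------------------------

@dataclass
class _OlsFit:
    rss: float
    n: int
    df_model: int


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((y - X @ coef) ** 2))


def slope_comparison(effect: np.ndarray, predictor: np.ndarray,
                     group: Sequence) -> tuple[float, float]:
    """F-test for slope differences between groups (ANOVA on interaction).

    Compares the linear model with per-group intercepts and a common slope
    against the model adding group × predictor interactions. A predictor
    on the causal path of the effect should show no significant slope
    difference across stimulation locations.
    """
    y = np.asarray(effect, dtype=float)
    x = np.asarray(predictor, dtype=float)
    groups = pd.Categorical(group)
    if len(groups.categories) < 2:
        raise ValidationError("slope comparison needs >= 2 groups")
    counts = pd.Series(groups.codes).value_counts()
    if (counts < 3).any():
        raise ValidationError("every group needs >= 3 points")
    dummies = pd.get_dummies(groups, drop_first=True).to_numpy(dtype=float)
    X_small = np.column_stack([np.ones_like(x), x, dummies])
    X_large = np.column_stack([X_small, dummies * x[:, None]])
    n = y.size
    small = _OlsFit(rss=_ols_rss(X_small, y), n=n,
                    df_model=X_small.shape[1])
    large = _OlsFit(rss=_ols_rss(X_large, y), n=n,
                    df_model=X_large.shape[1])
    return approx_f_test(small, large)


__all__ = [
    "ActivationVector", "Constraint", "DoseMap", "HrActivationPlane",
    "LatentSpace", "PROBE_CURRENTS_MA", "PROBE_PULSE_WIDTH_US",
    "VECTOR_FIBERS", "build_activation_vectors", "build_dose_map",
    "constrained_optimum", "feasibility_mask", "fit_hr_activation_planes",
    "fit_latent_space", "hr_plane_inputs", "response_surface",
    "slope_comparison",
]
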