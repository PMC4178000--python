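"""Posterior predictions over covariate grids and detection summaries.

Predictions evaluate the distribution sub-model draw by draw on a raw
covariate grid standardized with the *training* scaling, then summarize
pointwise (posterior mean and central 95% interval).  Non-focal covariates
sit at reference values: continuous covariates at their training mean,
categorical covariates at their reference level, year 2010.  Quadratic
partner columns move coherently with their base covariate through the same
standardize-square-restandardize pipeline used at training time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import OCC_COLUMNS, CAM_COLUMNS, CHEV_COLUMNS, standardize_grid
from .mcmc import PosteriorSamples, ModelSpec
from .models import inv_logit

__all__ = ["PredictionGrid", "reference_row", "predict_curve",
           "predict_surface", "detection_summary"]

_QUADRATIC_BASES = ("depth", "lat", "temp")


@dataclass
class PredictionGrid:
    """Posterior mean and 95% interval of psi (basic) or lambda (RN) over a
    covariate grid on the raw scale."""

    axes: dict[str, np.ndarray]
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    response: str                      # "psi" | "lambda"

    def to_frame(self) -> pd.DataFrame:
        names = list(self.axes)
        if len(names) == 1:
            df = pd.DataFrame({names[0]: self.axes[names[0]]})
        else:
            mesh = np.meshgrid(*self.axes.values(), indexing="ij")
            df = pd.DataFrame({n: m.ravel() for n, m in zip(names, mesh)})
        df["mean"] = self.mean.ravel()
        df["lower"] = self.lower.ravel()
        df["upper"] = self.upper.ravel()
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def reference_row(scaling: dict, square_standardized: bool = True,
                  overrides: dict | None = None) -> np.ndarray:
    """The occupancy design row at reference covariate values.

    Continuous covariates sit at their mean (0 standardized), so their
    quadratic partners take the standardized value of 0^2; dummies are 0
    (reference categories, year 2010).  ``overrides`` replaces individual
    columns by name after the reference is built.
    """
    row = np.zeros(len(OCC_COLUMNS))
    cols = list(OCC_COLUMNS)
    for base in _QUADRATIC_BASES:
        mu, _ = scaling[base]
        mu2, sd2 = scaling[base + "2"]
        sq = 0.0 if square_standardized else mu ** 2
        row[cols.index(base + "2")] = (sq - mu2) / sd2
    for name, value in (overrides or {}).items():
        row[cols.index(name)] = value
    return row


def _draw_curves(samples: PosteriorSamples, X: np.ndarray):
    eff = samples.effective_coefficients("occ")
    lp = eff[:, 0][:, None] + eff[:, 1:] @ X.T
    if samples.model_spec.family == "basic":
        return inv_logit(lp), "psi"
    return np.exp(lp), "lambda"


def _summaries(values: np.ndarray):
    mean = values.mean(axis=0)
    lower, upper = np.percentile(values, [2.5, 97.5], axis=0)
    return mean, lower, upper


def predict_curve(samples: PosteriorSamples, scaling: dict,
                  covariate_name: str, grid: np.ndarray,
                  reference_values: dict | None = None,
                  square_standardized: bool = True,
                  guard_sd: float = 5.0) -> PredictionGrid:
    """Posterior prediction of psi or lambda along one continuous covariate.

    ``grid`` is on the raw scale (metres, degrees, ...).  A grid point more
    than ``guard_sd`` training standard deviations from the training mean
    is refused as extrapolation.
    """
    if covariate_name not in _QUADRATIC_BASES:
        raise ValueError(f"predict_curve supports {_QUADRATIC_BASES}, "
                         f"got {covariate_name!r}")
    grid = np.asarray(grid, dtype=float)
    z, z2 = standardize_grid(grid, covariate_name, scaling, square_standardized)
    if np.any(np.abs(z) > guard_sd):
        raise ValueError(
            f"grid extends beyond {guard_sd} training SDs of {covariate_name!r}; "
            "widen guard_sd to extrapolate deliberately"
        )
    base_row = reference_row(scaling, square_standardized, reference_values)
    X = np.tile(base_row, (grid.size, 1))
    cols = list(OCC_COLUMNS)
    X[:, cols.index(covariate_name)] = z
    X[:, cols.index(covariate_name + "2")] = z2
    values, response = _draw_curves(samples, X)
    mean, lower, upper = _summaries(values)
    return PredictionGrid(axes={covariate_name: grid}, mean=mean,
                          lower=lower, upper=upper, response=response)


def predict_surface(samples: PosteriorSamples, scaling: dict,
                    lat_grid: np.ndarray, depth_grid: np.ndarray,
                    reference_values: dict | None = None,
                    square_standardized: bool = True,
                    guard_sd: float = 5.0) -> PredictionGrid:
    """Posterior prediction of psi or lambda over a latitude x depth grid."""
    lat_grid = np.asarray(lat_grid, dtype=float)
    depth_grid = np.asarray(depth_grid, dtype=float)
    zl, zl2 = standardize_grid(lat_grid, "lat", scaling, square_standardized)
    zd, zd2 = standardize_grid(depth_grid, "depth", scaling, square_standardized)
    for name, z in (("lat", zl), ("depth", zd)):
        if np.any(np.abs(z) > guard_sd):
            raise ValueError(f"{name} grid extends beyond {guard_sd} training SDs")
    base_row = reference_row(scaling, square_standardized, reference_values)
    n_lat, n_dep = lat_grid.size, depth_grid.size
    X = np.tile(base_row, (n_lat * n_dep, 1))
    cols = list(OCC_COLUMNS)
    L, D = np.meshgrid(np.arange(n_lat), np.arange(n_dep), indexing="ij")
    X[:, cols.index("lat")] = zl[L.ravel()]
    X[:, cols.index("lat2")] = zl2[L.ravel()]
    X[:, cols.index("depth")] = zd[D.ravel()]
    X[:, cols.index("depth2")] = zd2[D.ravel()]
    values, response = _draw_curves(samples, X)
    mean, lower, upper = _summaries(values)
    shape = (n_lat, n_dep)
    return PredictionGrid(
        axes={"lat": lat_grid, "depth": depth_grid},
        mean=mean.reshape(shape), lower=lower.reshape(shape),
        upper=upper.reshape(shape), response=response,
    )


def detection_summary(samples: PosteriorSamples,
                      model_spec: ModelSpec | None = None) -> pd.DataFrame:
    """Gear-level detection posteriors at reference covariates, plus camera
    contrasts for high turbidity and current-away conditions.

    For the basic family the rows are species detection probabilities p;
    for Royle-Nichols they are individual detection probabilities r.  Each
    contrast row is the per-draw difference p(condition) - p(reference).
    """
    model_spec = model_spec or samples.model_spec
    alpha = samples.effective_coefficients("chev")
    phi = samples.effective_coefficients("cam")
    p_chev = inv_logit(alpha[:, 0])
    p_cam = inv_logit(phi[:, 0])
    cam_cols = list(CAM_COLUMNS)
    rows = {}
    rows["chevron"] = p_chev
    rows["camera"] = p_cam
    for cov, label in (("turb.h", "camera_turb.h_contrast"),
                       ("cdir.a", "camera_cdir.a_contrast")):
        shifted = inv_logit(phi[:, 0] + phi[:, 1 + cam_cols.index(cov)])
        rows[label] = shifted - p_cam
    out = []
    for name, vals in rows.items():
        lo, hi = np.percentile(vals, [2.5, 97.5])
        out.append({"quantity": name, "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=0)),
                    "q2.5": float(lo), "q97.5": float(hi)})
    df = pd.DataFrame(out).set_index("quantity")
    df.attrs["scale"] = "p" if model_spec.family == "basic" else "r"
    return df
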