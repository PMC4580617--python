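"""Allometric body-mass estimation from dental measurements.

Body mass scales with linear skeletal and dental dimensions as a power law,
so mass is regressed on a predictor in log-log space:

    ln(mass in g) = a + b * ln(predictor in mm)

The built-in calibration is the printed table of lower-molar-row lengths
(M1-M3 length, mm) and masses for Paleogene hyaenodonts, which lies exactly
on one such line; the dental model is re-fitted from those pairs rather than
hard-coding legacy regression coefficients, so the module is self-contained
and auditable.  Regressions based on other predictors (skull length,
astragalar dimensions) whose coefficients are not printed anywhere in the
calibration data are supported as user-supplied models loaded from a TOML
config.  Estimated masses can be folded into the five-state ordinal
body-mass character used in the phylogenetic matrix
(<1, 1-11, 11-31, 31-100, >100 kg).
"""

from __future__ import annotations

import math
import statistics
import tomllib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as _stats


class AllometryError(ValueError):
    pass


#: kg thresholds between ordinal body-mass states 0..4
MASS_CATEGORY_BOUNDS_KG = (1.0, 11.0, 31.0, 100.0)


@dataclass(frozen=True)
class AllometricModel:
    """ln(mass_g) = intercept + slope * ln(predictor)."""

    intercept: float
    slope: float
    predictor_name: str = "lower molar row length (mm)"
    method: str = "dental"

    def __post_init__(self):
        if self.slope <= 0:
            raise AllometryError("a mass model must have a positive slope")


@dataclass(frozen=True)
class MassEstimate:
    method: str
    point_kg: float
    ln_mass: float  # natural log of mass in grams
    range_kg: tuple[float, float] | None = None


@dataclass(frozen=True)
class MassCategory:
    state: int
    bounds_kg: tuple[float | None, float | None]


@dataclass(frozen=True)
class FitReport:
    model: AllometricModel
    residuals: tuple[float, ...]  # in ln(mass_g) space
    r_squared: float
    stderr_slope: float


def fit_loglog(pairs, predictor_name: str = "lower molar row length (mm)",
               method: str = "dental") -> FitReport:
    """Least-squares log-log fit of (predictor, mass_kg) pairs."""
    pairs = list(pairs)
    if len(pairs) < 2:
        raise AllometryError("need at least 2 calibration pairs")
    if any(x <= 0 or m <= 0 for x, m in pairs):
        raise AllometryError("predictors and masses must be positive")
    x = np.log([p for p, _ in pairs])
    y = np.log([m * 1000.0 for _, m in pairs])
    res = _stats.linregress(x, y)
    model = AllometricModel(intercept=float(res.intercept),
                            slope=float(res.slope),
                            predictor_name=predictor_name, method=method)
    resid = y - (res.intercept + res.slope * x)
    return FitReport(model=model, residuals=tuple(float(r) for r in resid),
                     r_squared=float(res.rvalue ** 2),
                     stderr_slope=float(res.stderr))


def predict_mass(model: AllometricModel, predictor: float) -> MassEstimate:
    if predictor <= 0:
        raise AllometryError("predictor must be positive")
    ln_mass = model.intercept + model.slope * math.log(predictor)
    return MassEstimate(method=model.method, point_kg=math.exp(ln_mass) / 1000.0,
                        ln_mass=ln_mass)


def categorize_mass(mass_kg: float) -> MassCategory:
    """Ordinal body-mass state; a boundary mass belongs to the upper bin."""
    if mass_kg <= 0:
        raise AllometryError("mass must be positive")
    state = int(np.searchsorted(MASS_CATEGORY_BOUNDS_KG, mass_kg, side="right"))
    lo = MASS_CATEGORY_BOUNDS_KG[state - 1] if state > 0 else None
    hi = MASS_CATEGORY_BOUNDS_KG[state] if state < len(MASS_CATEGORY_BOUNDS_KG) else None
    return MassCategory(state=state, bounds_kg=(lo, hi))


def combine_estimates(estimates: list[MassEstimate]) -> dict:
    """Median point estimate (mean of the central pair for even counts) and
    the full min-max range across methods."""
    if not estimates:
        raise AllometryError("no estimates to combine")
    points = [e.point_kg for e in estimates]
    return {
        "median_kg": float(statistics.median(points)),
        "range_kg": (min(points), max(points)),
        "n_methods": len(estimates),
    }


# ---------------------------------------------------------------------------
# calibration table and reports
# ---------------------------------------------------------------------------

def load_calibration_table() -> pd.DataFrame:
    """The packaged tooth-measurement table (one row per species occurrence
    per biochronological level; species repeat across levels)."""
    with resources.files("parsimonia.data").joinpath("tooth_mass_table.csv").open() as fh:
        return pd.read_csv(fh)


def calibration_pairs(table: pd.DataFrame | None = None,
                      exclude_species: str | None = None) -> list[tuple[float, float]]:
    """Unique (molar row length, mass kg) pairs, optionally excluding one
    species (for leave-one-out validation)."""
    if table is None:
        table = load_calibration_table()
    t = table.drop_duplicates(subset="species")
    if exclude_species is not None:
        t = t[t["species"] != exclude_species]
    return list(zip(t["molar_row_length_mm"], t["mass_kg"]))


def mass_report(tooth_table: pd.DataFrame, model: AllometricModel) -> pd.DataFrame:
    """Per-species masses and ln-masses from a (species, group, predictor)
    table, rounded to two decimals as reported."""
    rows = []
    for _, rec in tooth_table.iterrows():
        est = predict_mass(model, rec["molar_row_length_mm"])
        rows.append({
            "species": rec["species"],
            "group": rec.get("group"),
            "molar_row_length_mm": rec["molar_row_length_mm"],
            "mass_kg": round(est.point_kg, 2),
            "ln_mass": round(est.ln_mass, 2),
        })
    return pd.DataFrame(rows, columns=["species", "group", "molar_row_length_mm",
                                       "mass_kg", "ln_mass"])


def load_models_config(path) -> list[dict]:
    """User-supplied regression models from a TOML file.

    Each ``[models.<name>]`` table needs ``intercept``, ``slope``,
    ``predictor_name`` and ``predictor_value`` (the focal specimen's
    measurement); masses from these models join the multi-method summary.
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    out = []
    for name, spec in cfg.get("models", {}).items():
        model = AllometricModel(intercept=spec["intercept"], slope=spec["slope"],
                                predictor_name=spec.get("predictor_name", name),
                                method=name)
        out.append({"model": model, "predictor_value": spec["predictor_value"],
                    "range_kg": tuple(spec["range_kg"]) if "range_kg" in spec else None})
    return out


def plot_ln_mass(report: pd.DataFrame, path=None):
    """Scatter of ln-mass by group and level (a size-through-time view)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for group, sub in report.groupby("group"):
        x = sub["mp"] if "mp" in sub else range(len(sub))
        ax.scatter(x, sub["ln_mass"], label=str(group))
    ax.set_xlabel("reference level")
    ax.set_ylabel("ln body mass (g)")
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
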