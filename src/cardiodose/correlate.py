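"""Regional dose–strain alignment, correlation, and the polynomial dose-response fit.

The myocardium is partitioned into equal-angle sectors about the LV center
(default 6, a single-slice analogue of segment models); per sector the mean
accumulated dose, mean peak strain, and abnormal-strain fraction are
tabulated.  The abnormal fraction is the default proxy for regional
functional loss; mean circumferential-strain magnitude is available as an
alternative response.

Because neighbouring sectors are spatially correlated, significance is
assessed by a seeded permutation test (region labels shuffled) rather than
parametric p-values.  A least-squares polynomial of configurable degree maps
dose to response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ImageFrame


@dataclass
class DoseResponseFit:
    """Polynomial dose→response model with fit diagnostics."""

    coefficients: np.ndarray  # ascending powers: response per Gy^k
    degree: int
    residual_rmse: float
    correlation: float  # Pearson r of response vs dose

    def predict(self, dose_gy: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(dose_gy, dtype=float), self.coefficients)


def regionalize(
    strain_map: np.ndarray,
    dose_map: np.ndarray,
    myocardium_mask: np.ndarray,
    n_sectors: int,
    lv_center: np.ndarray,
    frame: ImageFrame,
    abnormal_mask: np.ndarray | None = None,
    valid_mask: np.ndarray | None = None,
    deficit_map: np.ndarray | None = None,
) -> pd.DataFrame:
    """Partition the myocardium into equal-angle sectors and tabulate per-sector stats.

    Columns: ``region``, ``pixel_count``, ``mean_dose_Gy``, ``mean_strain``,
    ``abnormal_fraction`` and, when ``deficit_map`` is given,
    ``strain_deficit`` (mean contraction deficit, an always-defined graded
    alternative response).  Sector 0 starts at angle 0 (the +x axis) and
    sectors advance counter-clockwise; pixel counts sum exactly to the mask
    size.  ``valid_mask`` (e.g. dose-trajectory validity) restricts the
    dose/strain averages but not the partition.
    """
    if n_sectors < 1:
        raise ValueError("n_sectors must be >= 1")
    myo = np.asarray(myocardium_mask, dtype=bool)
    rel = frame.pixel_centers() - np.asarray(lv_center, dtype=float)
    theta = np.mod(np.arctan2(rel[..., 1], rel[..., 0]), 2.0 * np.pi)
    sector = np.minimum((theta / (2.0 * np.pi / n_sectors)).astype(int), n_sectors - 1)
    stat_ok = myo if valid_mask is None else (myo & np.asarray(valid_mask, dtype=bool))
    rows = []
    for s in range(n_sectors):
        in_sector = myo & (sector == s)
        in_stats = stat_ok & (sector == s)
        n_px = int(in_sector.sum())
        if in_stats.sum() > 0:
            mean_dose = float(np.asarray(dose_map)[in_stats].mean())
            mean_strain = float(np.asarray(strain_map)[in_stats].mean())
            abnormal = (
                float(np.asarray(abnormal_mask, dtype=bool)[in_stats].mean())
                if abnormal_mask is not None
                else 0.0
            )
            deficit = (
                float(np.asarray(deficit_map)[in_stats].mean()) if deficit_map is not None else np.nan
            )
        else:
            mean_dose = mean_strain = abnormal = deficit = np.nan
        row = {
            "region": s,
            "pixel_count": n_px,
            "mean_dose_Gy": mean_dose,
            "mean_strain": mean_strain,
            "abnormal_fraction": abnormal,
        }
        if deficit_map is not None:
            row["strain_deficit"] = deficit
        rows.append(row)
    return pd.DataFrame(rows)


def dose_strain_correlation(
    table: pd.DataFrame,
    method: str = "rank",
    response: str = "abnormal_fraction",
) -> float:
    """Spearman (``rank``) or Pearson (``linear``) correlation of regional dose vs response."""
    if method not in ("rank", "linear"):
        raise ValueError(f"method must be 'rank' or 'linear', got {method!r}")
    t = table.dropna(subset=["mean_dose_Gy", response])
    dose = t["mean_dose_Gy"].to_numpy()
    resp = t[response].to_numpy()
    if np.unique(dose).size < 3:
        raise ValueError("need at least 3 regions with distinct dose values")
    if np.ptp(dose) == 0 or np.ptp(resp) == 0:
        raise ValueError("zero variance in dose or response: correlation undefined")
    if method == "linear":
        r = stats.pearsonr(dose, resp).statistic
    else:
        r = stats.spearmanr(dose, resp).statistic
    return float(r)


def permutation_test(
    dose: np.ndarray,
    response: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    statistic: str = "pearson",
    alternative: str = "greater",
) -> tuple[float, float, np.ndarray]:
    """Seed-reproducible permutation test of the dose–response association.

    Region labels of the response are permuted; returns
    ``(observed, p_value, permuted_statistics)``.  ``alternative`` is
    ``greater`` (positive association) or ``two-sided``.
    """
    dose = np.asarray(dose, dtype=float)
    response = np.asarray(response, dtype=float)
    stat_fn = {
        "pearson": lambda d, r: stats.pearsonr(d, r).statistic,
        "spearman": lambda d, r: stats.spearmanr(d, r).statistic,
        "slope": lambda d, r: np.polynomial.polynomial.polyfit(d, r, 1)[1],
    }[statistic]
    observed = float(stat_fn(dose, response))
    rng = np.random.default_rng(seed)
    perm = np.empty(n_permutations)
    for i in range(n_permutations):
        perm[i] = stat_fn(dose, rng.permutation(response))
    if alternative == "greater":
        exceed = np.sum(perm >= observed)
    elif alternative == "two-sided":
        exceed = np.sum(np.abs(perm) >= abs(observed))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = float((1 + exceed) / (1 + n_permutations))
    return observed, p, perm


def fit_dose_response(
    table: pd.DataFrame,
    degree: int = 2,
    response: str = "abnormal_fraction",
) -> DoseResponseFit:
    """Least-squares polynomial (given degree) mapping regional dose → response."""
    if degree < 1:
        raise ValueError("degree must be >= 1")
    t = table.dropna(subset=["mean_dose_Gy", response])
    if len(t) <= degree + 1:
        raise ValueError(f"need more than degree+1={degree + 1} regions, have {len(t)}")
    dose = t["mean_dose_Gy"].to_numpy()
    resp = t[response].to_numpy()
    coeffs = np.polynomial.polynomial.polyfit(dose, resp, degree)
    pred = np.polynomial.polynomial.polyval(dose, coeffs)
    rmse = float(np.sqrt(np.mean((resp - pred) ** 2)))
    r = float(stats.pearsonr(dose, resp).statistic) if np.ptp(resp) > 0 else 0.0
    return DoseResponseFit(coefficients=coeffs, degree=degree, residual_rmse=rmse, correlation=r)
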