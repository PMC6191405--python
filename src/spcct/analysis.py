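"""ROI extraction and the quantification statistics of the phantom study.

Circular ROIs are seeded at the known tube positions on the conventional
image, refined by intensity centroid, and reused unchanged on every image of
the dataset.  Per-tube ROI means feed the study statistics:

* ordinary least-squares regression of measured on prepared concentration
  (slope, offset, R², residual RMSE, 95 % CI of the slope);
* Bland–Altman bias and limits of agreement;
* cross-contamination RMSE of an off-target material image against its
  expected constant (0 mg/mL, or 1000 mg/mL for water);
* contrast-to-noise ratio CNR = |mean_tube − mean_PBS| / SD_PBS and its
  per-(mg/mL) slope over the dilution series;
* two-way mixed-effects intraclass correlation between the unmixed and
  mixed measurements of one agent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phantom import PBS_TUBE_ID, PhantomSpec
from .recon import ImageGrid

__all__ = [
    "Roi",
    "RoiSet",
    "detect_rois",
    "roi_stats",
    "regress_prepared_vs_measured",
    "RegressionResult",
    "bland_altman",
    "cross_contamination_rmse",
    "cnr",
    "cnr_slope",
    "icc_two_way_mixed",
]


@dataclass(frozen=True)
class Roi:
    tube_id: int
    centre_px: tuple[float, float]  # (row, col)
    radius_px: float

    def mask(self, n: int) -> np.ndarray:
        rr, cc = np.ogrid[:n, :n]
        return (rr - self.centre_px[0]) ** 2 + (
            cc - self.centre_px[1]
        ) ** 2 <= self.radius_px**2


@dataclass(frozen=True)
class RoiSet:
    rois: tuple[Roi, ...]

    def __iter__(self):
        return iter(self.rois)

    def __len__(self):
        return len(self.rois)

    def get(self, tube_id: int) -> Roi:
        for r in self.rois:
            if r.tube_id == tube_id:
                return r
        raise KeyError(tube_id)

    @property
    def pbs(self) -> Roi:
        return self.get(PBS_TUBE_ID)


def _tube_centre_px(spec: PhantomSpec, img: ImageGrid, k: int):
    cx, cy = spec.hole_centres_cm[k]
    n = img.n_pixels
    return (n // 2 - cy / img.pixel_size_cm, n // 2 + cx / img.pixel_size_cm)


def detect_rois(
    conventional: ImageGrid,
    spec: PhantomSpec,
    radius_fraction: float = 0.6,
) -> RoiSet:
    """Automatic circular ROIs in the middle of every tube.

    ROIs are seeded at the known hole centres, refined by the intensity
    centroid within the tube footprint, and sized to ``radius_fraction`` of
    the tube radius (default 60 %, keeping clear of edge and
    partial-volume pixels).  A refinement that escapes the footprint falls
    back to the geometric centre with a warning.
    """
    n = conventional.n_pixels
    tube_r_px = spec.hole_diameter_cm / 2 / conventional.pixel_size_cm
    roi_r = radius_fraction * tube_r_px
    rois = []
    rr, cc = np.indices((n, n))
    # refinement is capped at a small displacement: it tracks sub-pixel
    # misalignment of a tube but cannot drift toward the brighter body
    # material surrounding the hole
    max_shift = 0.15 * tube_r_px
    for k in range(spec.n_holes):
        r0, c0 = _tube_centre_px(spec, conventional, k)
        centre = (r0, c0)
        # fixed-point centroid iteration: recentre the footprint on the
        # running centroid so a shifted tube is tracked fully, not half-way
        for _ in range(3):
            d2 = (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2
            foot = d2 <= tube_r_px**2
            vals = conventional.values[foot]
            # polarity-aware weighting: a tube may sit darker than the
            # surrounding body material on the conventional image, in which
            # case the centroid must weight the dark interior
            inner_mean = conventional.values[d2 <= (0.5 * tube_r_px) ** 2].mean()
            ring_mean = conventional.values[foot & (d2 >= (0.8 * tube_r_px) ** 2)].mean()
            if inner_mean >= ring_mean:
                w = vals - vals.min()
            else:
                w = vals.max() - vals
            if w.sum() <= 0:
                break
            cand = (
                float((rr[foot] * w).sum() / w.sum()),
                float((cc[foot] * w).sum() / w.sum()),
            )
            if (cand[0] - r0) ** 2 + (cand[1] - c0) ** 2 > tube_r_px**2:
                warnings.warn(
                    f"ROI refinement escaped tube {k + 1}; using geometric centre"
                )
                centre = (r0, c0)
                break
            shift = np.hypot(cand[0] - r0, cand[1] - c0)
            if shift > max_shift:
                scale = max_shift / shift
                cand = (r0 + scale * (cand[0] - r0), c0 + scale * (cand[1] - c0))
            if np.hypot(cand[0] - centre[0], cand[1] - centre[1]) < 0.05:
                centre = cand
                break
            centre = cand
        rois.append(Roi(k + 1, centre, roi_r))
    return RoiSet(tuple(rois))


def roi_stats(img: ImageGrid, roi: Roi) -> tuple[float, float]:
    """(mean, SD) of the image inside one ROI."""
    v = img.values[roi.mask(img.n_pixels)]
    return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    offset: float
    r_squared: float
    rmse: float
    ci95_slope: tuple[float, float]
    n: int

    def __post_init__(self):
        if not (self.ci95_slope[0] <= self.slope <= self.ci95_slope[1]):
            raise ValueError("confidence interval must contain the slope")

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "offset": self.offset,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "ci95_slope": list(self.ci95_slope),
            "n": self.n,
        }


def regress_prepared_vs_measured(prepared, measured) -> RegressionResult:
    """OLS fit measured = slope · prepared + offset with t-based slope CI."""
    x = np.asarray(prepared, float)
    y = np.asarray(measured, float)
    if x.size < 3:
        raise ValueError("at least three points required")
    if np.ptp(x) == 0:
        raise ValueError("prepared concentrations are degenerate")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    resid = y - model.predict(sm.add_constant(x))
    return RegressionResult(
        slope=float(model.params[1]),
        offset=float(model.params[0]),
        r_squared=float(model.rsquared),
        rmse=float(np.sqrt(np.mean(resid**2))),
        ci95_slope=(float(ci[1, 0]), float(ci[1, 1])),
        n=int(x.size),
    )


def bland_altman(prepared, measured) -> dict:
    """Bias and 95 % limits of agreement of measured − prepared."""
    x = np.asarray(prepared, float)
    y = np.asarray(measured, float)
    if x.size < 2:
        raise ValueError("at least two pairs required")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "sd": sd,
    }


def cross_contamination_rmse(roi_means, expected: float) -> float:
    """RMSE of off-target ROI means against the expected constant (mg/mL)."""
    v = np.asarray(roi_means, float)
    if v.size == 0:
        raise ValueError("empty ROI list")
    return float(np.sqrt(np.mean((v - expected) ** 2)))


def cnr(mean_tube: float, mean_pbs: float, sd_pbs: float) -> float:
    """Contrast-to-noise ratio |mean_tube − mean_PBS| / SD_PBS."""
    if sd_pbs <= 0:
        raise ValueError("PBS standard deviation must be positive")
    return abs(mean_tube - mean_pbs) / sd_pbs


def cnr_slope(concentrations, cnrs, through_origin: bool = False) -> float:
    """Per-(mg/mL) slope of CNR against prepared concentration (OLS)."""
    x = np.asarray(concentrations, float)
    y = np.asarray(cnrs, float)
    if x.size < 3:
        raise ValueError("at least three tubes required")
    if np.ptp(x) == 0:
        raise ValueError("concentrations are degenerate")
    if through_origin:
        return float((x @ y) / (x @ x))
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return float(model.params[1])


def icc_two_way_mixed(ratings: np.ndarray) -> dict:
    """Two-way mixed-effects ICC of an (n_targets × k_raters) matrix.

    Returns the consistency form for the mean of k raters (ICC3k,
    ``(MS_rows − MS_error) / MS_rows``) with its 95 % CI, and the
    absolute-agreement form (ICC2k) alongside.  Computed through
    ``pingouin.intraclass_corr``.
    """
    import pingouin as pg

    r = np.asarray(ratings, float)
    if r.ndim != 2 or r.shape[0] < 3 or r.shape[1] < 2:
        raise ValueError("ratings must be (n >= 3) x (k >= 2)")
    if not np.all(np.isfinite(r)):
        raise ValueError("missing cells are not supported")
    n, k = r.shape
    df = pd.DataFrame(
        {
            "target": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": r.ravel(),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = pg.intraclass_corr(
            df, targets="target", raters="rater", ratings="score"
        ).set_index("Type")
    ci_col = "CI95%" if "CI95%" in tab.columns else "CI95"
    out = {}
    for form, key in (("ICC(C,k)", "consistency"), ("ICC(A,k)", "absolute")):
        row = tab.loc[form]
        out[key] = {
            "icc": float(row["ICC"]),
            "ci95": [float(row[ci_col][0]), float(row[ci_col][1])],
        }
    out["icc"] = out["consistency"]["icc"]
    out["ci95"] = out["consistency"]["ci95"]
    return out
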