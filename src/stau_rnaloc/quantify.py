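"""Single-molecule copy-number calibration of mRNP intensities.

A detected mRNP may hold several mRNA molecules; its integrated
intensity is (copy number) x (single-molecule unit intensity) up to
noise. The unit intensity is estimated by fitting Gaussian mixtures to
an intensity distribution dominated by single molecules (in the source
experiments, nurse-cell spots): among the fitted components the one
carrying the largest weight is taken as the single-molecule component
and its mean as the unit. Empirically that component also has the
smallest mean; the calibration records this as a consistency flag
rather than enforcing it.

Raw intensities are then normalised by the unit and clustered into
copy-number bins [2^i, 2^(i+1)) for i in 0..8, i.e. 1, 2:3, 4:7, 8:15,
..., 256:511; normalised intensities below a sub-unit threshold
(default 0.5) are excluded as background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from stau_rnaloc.errors import InvalidParameterError

BIN_LABELS = (
    "1",
    "2:3",
    "4:7",
    "8:15",
    "16:31",
    "32:63",
    "64:127",
    "128:255",
    "256:511",
)
MAX_BIN = len(BIN_LABELS) - 1


def copy_bin_index(copies_or_normalized) -> np.ndarray:
    """Bin index i = clamp(floor(log2(max(x, 1))), 0, 8)."""
    x = np.maximum(np.asarray(copies_or_normalized, dtype=float), 1.0)
    return np.clip(np.floor(np.log2(x)).astype(int), 0, MAX_BIN)


# ---------------------------------------------------------------------------
# spot detection (simple LoG detector for rendered/raw 2-D images)
# ---------------------------------------------------------------------------


def detect_spots(
    image: np.ndarray,
    sigma_px: float,
    threshold_sd: float = 5.0,
    radius_px: float | None = None,
    channel: str = "detected",
) -> pd.DataFrame:
    """Laplacian-of-Gaussian spot detection with integrated intensities.

    Local maxima of the scale-normalised LoG response above
    ``threshold_sd`` robust standard deviations of the response
    background are kept. For each detection the background-subtracted
    intensity is integrated within ``radius_px`` (default ``3*sigma``)
    and a subpixel intensity-weighted centroid is computed. Positions
    are returned in pixel units in ``x_um``/``y_um`` columns scaled by
    1 px = 1 µm unless the caller rescales.
    """
    from scipy import ndimage
    from skimage.feature import peak_local_max

    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InvalidParameterError("detect_spots expects a 2-D image")
    if sigma_px <= 0:
        raise InvalidParameterError("sigma must be positive")
    if radius_px is None:
        radius_px = 3.0 * sigma_px
    if np.any(image >= 65535):
        warnings.warn("image contains saturated (16-bit max) pixels", stacklevel=2)

    background = float(np.median(image))
    bg_sd = 1.4826 * float(np.median(np.abs(image - background)))
    if bg_sd <= 0:
        bg_sd = float(image.std())  # e.g. noise-free renders
    # scale-normalised LoG; bright spots give positive peaks
    response = -(sigma_px**2) * ndimage.gaussian_laplace(image, sigma_px)
    # propagate the image noise sd through the LoG filter (its L2 norm)
    half = int(np.ceil(4 * sigma_px))
    delta = np.zeros((2 * half + 1, 2 * half + 1))
    delta[half, half] = 1.0
    kern = -(sigma_px**2) * ndimage.gaussian_laplace(delta, sigma_px)
    resp_noise_sd = bg_sd * float(np.sqrt((kern**2).sum()))
    thresh = max(threshold_sd * resp_noise_sd, 1e-12)

    peaks = peak_local_max(
        response,
        min_distance=max(int(round(sigma_px)), 1),
        threshold_abs=thresh,
        exclude_border=False,
    )

    records = []
    r_int = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    disk = (xx**2 + yy**2) <= radius_px**2
    ny, nx = image.shape
    for k, (r, c) in enumerate(peaks):
        r0, r1 = r - r_int, r + r_int + 1
        c0, c1 = c - r_int, c + r_int + 1
        if r0 < 0 or c0 < 0 or r1 > ny or c1 > nx:
            continue  # too close to the border to integrate
        patch = image[r0:r1, c0:c1] - background
        w = np.where(disk, np.maximum(patch, 0.0), 0.0)
        wsum = w.sum()
        if wsum <= 0:
            continue
        dy = float((w * yy).sum() / wsum)
        dx = float((w * xx).sum() / wsum)
        records.append(
            {
                "id": k,
                # pixel centre (c + 0.5, r + 0.5) plus the subpixel shift
                "x_um": c + 0.5 + dx,
                "y_um": r + 0.5 + dy,
                "channel": channel,
                "intensity": float(np.where(disk, patch, 0.0).sum()),
            }
        )
    df = pd.DataFrame(records, columns=["id", "x_um", "y_um", "channel", "intensity"])
    df["id"] = np.arange(len(df))
    return df


# ---------------------------------------------------------------------------
# Gaussian-mixture calibration
# ---------------------------------------------------------------------------


@dataclass
class MixtureFit:
    """Gaussian mixture on raw intensities, components sorted by mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    k: int
    bic_scores: dict[int, float]

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "log_likelihood": self.log_likelihood,
            "k": self.k,
            "bic_scores": {str(k): v for k, v in self.bic_scores.items()},
        }


@dataclass
class UnitCalibration:
    """Single-molecule unit intensity chosen from a mixture fit."""

    unit_intensity: float
    component: int
    portion: float
    consistent: bool  # True iff the largest-weight component has the smallest mean
    mixture: MixtureFit

    def to_dict(self) -> dict:
        return {
            "unit_intensity": self.unit_intensity,
            "component": self.component,
            "portion": self.portion,
            "consistent": self.consistent,
            "mixture": self.mixture.to_dict(),
        }


def fit_gmm(
    intensities,
    k_candidates=range(1, 6),
    n_init: int = 5,
    seed: int | None = 0,
    max_iter: int = 500,
    log_scale: bool = True,
) -> MixtureFit:
    """EM Gaussian-mixture fit with BIC selection over candidate K.

    With ``log_scale=True`` (default) the Gaussians are fitted to the
    log intensities, i.e. the components are log-normal on the raw
    scale — matching the multiplicative nature of fluorescence
    intensity noise. Because the single-molecule peak is right-skewed
    on the raw scale, raw-scale Gaussians systematically split it and
    bias the dominant component's mean low; the log-scale fit removes
    that bias. ``log_scale=False`` fits on raw intensities instead.
    Reported ``means``/``sds`` are always on the raw intensity scale
    (for log-scale fits: the component median exp(mu) and its local
    scale exp(mu)*sigma).

    Requires n >= 10*max(K). Components whose sd collapses towards zero
    are pruned with a warning (their weight is renormalised away).
    """
    x = np.asarray(intensities, dtype=float).reshape(-1, 1)
    x = x[np.isfinite(x[:, 0])]
    if log_scale:
        pos = x[:, 0] > 0
        if not pos.all():
            warnings.warn(
                f"dropped {int((~pos).sum())} non-positive intensity value(s) "
                "before log-scale mixture fitting",
                stacklevel=2,
            )
            x = x[pos]
        x = np.log(x)
    ks = sorted(int(k) for k in k_candidates)
    if not ks or ks[0] < 1:
        raise InvalidParameterError("K candidates must be positive integers")
    if len(x) < 10 * ks[-1]:
        raise InvalidParameterError(
            f"need at least {10 * ks[-1]} intensities for K up to {ks[-1]}, got {len(x)}"
        )
    scale = float(np.std(x)) or 1.0
    bic_scores: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in ks:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            max_iter=max_iter,
            reg_covar=1e-6 * scale**2,
            random_state=seed,
        ).fit(x)
        bic_scores[k] = float(gm.bic(x))
        fits[k] = gm
    best_k = min(bic_scores, key=bic_scores.get)
    gm = fits[best_k]

    weights = gm.weights_.copy()
    means = gm.means_.ravel().copy()
    sds = np.sqrt(gm.covariances_.reshape(-1))
    tiny = sds < 1e-6 * scale
    if tiny.any() and (~tiny).any():
        warnings.warn(
            f"pruned {int(tiny.sum())} degenerate mixture component(s) with sd ~ 0",
            stacklevel=2,
        )
        weights, means, sds = weights[~tiny], means[~tiny], sds[~tiny]
        weights = weights / weights.sum()
    if log_scale:
        # back-transform to the raw scale: median and local spread
        means, sds = np.exp(means), np.exp(means) * sds
    order = np.argsort(means)
    return MixtureFit(
        weights=weights[order],
        means=means[order],
        sds=sds[order],
        log_likelihood=float(gm.score(x) * len(x)),
        k=len(order),
        bic_scores=bic_scores,
    )


def calibrate_unit(fit: MixtureFit) -> UnitCalibration:
    """Unit intensity = mean of the largest-weight mixture component.

    The consistency flag records whether that component is also the
    lowest-mean one; an inconsistency is surfaced, not raised.
    """
    idx = int(np.argmax(fit.weights))
    unit = float(fit.means[idx])
    if unit <= 0:
        raise InvalidParameterError(
            f"chosen component has non-positive mean {unit}; cannot calibrate"
        )
    consistent = idx == 0  # components are sorted by mean ascending
    return UnitCalibration(
        unit_intensity=unit,
        component=idx,
        portion=float(fit.weights[idx]),
        consistent=consistent,
        mixture=fit,
    )


def assign_copy_bins(
    spots: pd.DataFrame,
    calib: UnitCalibration | float,
    min_normalized: float = 0.5,
) -> tuple[pd.DataFrame, int]:
    """Normalise intensities by the unit and assign 2^i copy bins.

    Returns the copy-number table (columns ``id, intensity, normalized,
    bin, bin_label``) and the count of excluded records (non-positive
    intensity, or normalised intensity below ``min_normalized``).
    """
    unit = calib.unit_intensity if isinstance(calib, UnitCalibration) else float(calib)
    if unit <= 0:
        raise InvalidParameterError("unit intensity must be positive")
    intensity = spots["intensity"].to_numpy(dtype=float)
    nonpos = intensity <= 0
    if nonpos.any():
        warnings.warn(
            f"excluded {int(nonpos.sum())} record(s) with non-positive intensity",
            stacklevel=2,
        )
    normalized = np.where(nonpos, np.nan, intensity / unit)
    keep = ~nonpos & (normalized >= min_normalized)
    n_excluded = int((~keep).sum())
    table = pd.DataFrame(
        {
            "id": spots["id"].to_numpy()[keep],
            "intensity": intensity[keep],
            "normalized": normalized[keep],
        }
    )
    table["bin"] = copy_bin_index(table["normalized"])
    table["bin_label"] = [BIN_LABELS[i] for i in table["bin"]]
    return table, n_excluded


class UnitIntensityCalibrator(BaseEstimator):
    """sklearn-style wrapper: fit the mixture, transform to copy bins.

    ``fit`` consumes the calibration intensities (typically a
    single-molecule-dominated distribution); ``transform`` converts any
    spot table into a copy-number table using the fitted unit.
    """

    def __init__(
        self,
        k_candidates=range(1, 6),
        n_init: int = 5,
        max_iter: int = 500,
        min_normalized: float = 0.5,
        log_scale: bool = True,
        random_state: int | None = 0,
    ):
        self.k_candidates = k_candidates
        self.n_init = n_init
        self.max_iter = max_iter
        self.min_normalized = min_normalized
        self.log_scale = log_scale
        self.random_state = random_state

    def fit(self, intensities, y=None):
        mixture = fit_gmm(
            intensities,
            k_candidates=self.k_candidates,
            n_init=self.n_init,
            seed=self.random_state,
            max_iter=self.max_iter,
            log_scale=self.log_scale,
        )
        calib = calibrate_unit(mixture)
        self.mixture_ = mixture
        self.calibration_ = calib
        self.unit_intensity_ = calib.unit_intensity
        self.portion_ = calib.portion
        self.consistent_ = calib.consistent
        return self

    def transform(self, spots: pd.DataFrame) -> pd.DataFrame:
        table, n_excluded = assign_copy_bins(
            spots, self.calibration_, min_normalized=self.min_normalized
        )
        self.n_excluded_ = n_excluded
        return table
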