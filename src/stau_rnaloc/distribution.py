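"""Anteroposterior signal-distribution matrices and group statistics.

Per-oocyte point signal is redistributed into a 100 x 100 matrix of
signal fractions: columns follow the anterior->posterior axis (column 1
anterior, column 100 posterior, each column covering 1% of the AP
extent), rows the orthogonal coordinate. From the matrix two
descriptors are extracted:

* centre of mass relative to the geometric centre, per axis in
  [-0.5, +0.5] with the AP component positive toward posterior;
* posterior fraction — the summed signal of the maximal contiguous run
  of columns ending at the posterior-most column whose column sums all
  reach a minimum fold-enrichment (default 2x) over the uniform
  expectation of 0.01 per column.

Groups of descriptor samples are compared with a tie-corrected
Kruskal-Wallis omnibus test followed by pairwise two-sided
Mann-Whitney U tests against a reference group at a Bonferroni
corrected alpha (divisor = number of pairwise tests performed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from stau_rnaloc.annotation import OocyteAnnotation
from stau_rnaloc.errors import InvalidParameterError

MATRIX_SIZE = 100


def normalize_coords(
    spots: pd.DataFrame,
    annot: OocyteAnnotation,
) -> tuple[pd.DataFrame, int]:
    """Map spot positions into the axis-aligned unit square.

    ``u`` is the scalar projection onto the anterior->posterior axis,
    affinely scaled so the outline's projection spans [0, 1]; ``v`` is
    the orthogonal coordinate scaled by the outline's extent in the
    rotated frame. Both are invariant under rigid motions of
    annotation plus points. Points outside the outline are excluded
    with a warning; the exclusion count is returned alongside.
    """
    xy = spots[["x_um", "y_um"]].to_numpy(dtype=float)
    inside = annot.contains(xy, atol=1e-9)
    n_excluded = int((~inside).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} point(s) outside the oocyte outline were excluded",
            stacklevel=2,
        )
    kept = spots.loc[inside].reset_index(drop=True)
    xy = xy[inside]

    axis = annot.posterior - annot.anterior
    u_hat = axis / np.linalg.norm(axis)
    v_hat = np.array([-u_hat[1], u_hat[0]])

    proj_u_outline = annot.outline @ u_hat
    proj_v_outline = annot.outline @ v_hat
    u0, u1 = proj_u_outline.min(), proj_u_outline.max()
    v0, v1 = proj_v_outline.min(), proj_v_outline.max()
    if u1 - u0 <= 0 or v1 - v0 <= 0:
        raise InvalidParameterError("degenerate outline: zero extent along an axis")

    u = (xy @ u_hat - u0) / (u1 - u0)
    v = (xy @ v_hat - v0) / (v1 - v0)
    out = kept.copy()
    out["u"] = u
    out["v"] = v
    return out, n_excluded


def build_matrix(
    normalized: pd.DataFrame,
    size: int = MATRIX_SIZE,
) -> np.ndarray:
    """Accumulate intensities into a ``size x size`` fraction matrix.

    Cell (row, col) = (floor(v*size), floor(u*size)); u = 1 or v = 1
    map to the last cell. The matrix is normalised to total 1.
    """
    if len(normalized) == 0:
        raise InvalidParameterError("no points to build a matrix from")
    u = normalized["u"].to_numpy(dtype=float)
    v = normalized["v"].to_numpy(dtype=float)
    w = normalized["intensity"].to_numpy(dtype=float)
    total = w.sum()
    if total <= 0:
        raise InvalidParameterError("total intensity must be positive")
    cols = np.clip(np.floor(u * size).astype(int), 0, size - 1)
    rows = np.clip(np.floor(v * size).astype(int), 0, size - 1)
    mat = np.zeros((size, size))
    np.add.at(mat, (rows, cols), w)
    return mat / total


def average_matrices(
    matrices: Sequence[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Cell-wise mean (renormalised to sum 1) and cell-wise sample sd."""
    if len(matrices) < 2:
        raise InvalidParameterError("need at least 2 matrices to average")
    mats = [np.asarray(m, dtype=float) for m in matrices]
    if not all(m.shape == mats[0].shape for m in mats):
        raise InvalidParameterError("matrix shapes differ")
    stack = np.stack(mats)
    mean = stack.mean(axis=0)
    mean = mean / mean.sum()
    sd = stack.std(axis=0, ddof=1)
    return mean, sd


def center_of_mass(matrix: np.ndarray) -> tuple[float, float]:
    """(AP, orthogonal) offset of the signal centroid from the centre.

    Components lie in [-0.5, +0.5]; the AP component is positive
    toward posterior (column 100).
    """
    matrix = np.asarray(matrix, dtype=float)
    size_r, size_c = matrix.shape
    total = matrix.sum()
    if total <= 0:
        raise InvalidParameterError("matrix total must be positive")
    m = matrix / total
    col_centers = (np.arange(size_c) + 0.5) / size_c
    row_centers = (np.arange(size_r) + 0.5) / size_r
    com_ap = float(m.sum(axis=0) @ col_centers - 0.5)
    com_orth = float(m.sum(axis=1) @ row_centers - 0.5)
    return com_ap, com_orth


def posterior_fraction(
    matrix: np.ndarray,
    enrichment: float = 2.0,
    expected: np.ndarray | None = None,
) -> float:
    """Signal share in the posterior enriched domain.

    The posterior domain is the maximal contiguous run of columns
    ending at the last (posterior-most) column whose column sums are
    all >= ``enrichment`` times the expected column sum (uniform 1/size
    by default, or a caller-supplied per-column expectation). Returns 0
    when the last column itself is not enriched.
    """
    if enrichment <= 1:
        raise InvalidParameterError("enrichment fold must be > 1")
    matrix = np.asarray(matrix, dtype=float)
    col_sums = matrix.sum(axis=0)
    size = len(col_sums)
    if expected is None:
        expected = np.full(size, 1.0 / size)
    expected = np.asarray(expected, dtype=float)
    if expected.shape != (size,):
        raise InvalidParameterError("expected must have one entry per column")
    enriched = col_sums >= enrichment * expected
    frac = 0.0
    for j in range(size - 1, -1, -1):
        if not enriched[j]:
            break
        frac += col_sums[j]
    return float(frac)


@dataclass
class GroupComparison:
    """Omnibus and pairwise-vs-reference test results on a descriptor."""

    groups: dict[str, np.ndarray]
    reference: str
    kruskal_stat: float
    kruskal_p: float
    pairwise_p: dict[str, float]
    alpha: float
    corrected_alpha: float

    def significant(self) -> dict[str, bool]:
        return {g: p < self.corrected_alpha for g, p in self.pairwise_p.items()}

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "n_per_group": {g: int(len(v)) for g, v in self.groups.items()},
            "kruskal_stat": self.kruskal_stat,
            "kruskal_p": self.kruskal_p,
            "pairwise_p_vs_reference": self.pairwise_p,
            "alpha": self.alpha,
            "corrected_alpha": self.corrected_alpha,
            "significant": self.significant(),
        }


def compare_groups(
    samples: Mapping[str, Sequence[float]],
    reference: str,
    alpha: float = 0.05,
) -> GroupComparison:
    """Kruskal-Wallis omnibus + pairwise Mann-Whitney U vs reference.

    The pairwise tests are two-sided; scipy's method="auto" uses the
    exact null for small tie-free samples and the tie/continuity
    corrected normal approximation otherwise. The corrected alpha is
    ``alpha`` divided by the number of pairwise tests performed.
    """
    if len(samples) < 2:
        raise InvalidParameterError("need at least 2 groups")
    if reference not in samples:
        raise InvalidParameterError(f"reference group {reference!r} missing")
    groups = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    for k, v in groups.items():
        if len(v) < 3:
            raise InvalidParameterError(f"group {k!r} has n < 3")
    kw = stats.kruskal(*groups.values())
    others = [g for g in groups if g != reference]
    corrected_alpha = alpha / len(others)
    pairwise = {}
    for g in others:
        res = stats.mannwhitneyu(
            groups[g], groups[reference], alternative="two-sided", method="auto"
        )
        pairwise[g] = float(res.pvalue)
    return GroupComparison(
        groups=groups,
        reference=reference,
        kruskal_stat=float(kw.statistic),
        kruskal_p=float(kw.pvalue),
        pairwise_p=pairwise,
        alpha=alpha,
        corrected_alpha=corrected_alpha,
    )


def oocyte_descriptors(
    spots: pd.DataFrame,
    annot: OocyteAnnotation,
    enrichment: float = 2.0,
) -> dict[str, float]:
    """Convenience: normalise, build the matrix and extract descriptors."""
    normalized, n_excluded = normalize_coords(spots, annot)
    mat = build_matrix(normalized)
    com_ap, com_orth = center_of_mass(mat)
    return {
        "com_ap": com_ap,
        "com_orth": com_orth,
        "posterior_fraction": posterior_fraction(mat, enrichment=enrichment),
        "n_spots": float(len(normalized)),
        "n_excluded": float(n_excluded),
    }
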