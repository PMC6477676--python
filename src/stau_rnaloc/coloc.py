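"""Nearest-neighbour colocalization with a randomization null.

For every mRNP the Euclidean nearest protein particle is found; the
pair is colocalized when the distance is at most a radius ``r`` (µm,
default 0.3 — one-way nearest neighbour, configurable). Observed
colocalized fractions per copy-number bin are compared against the
expectation under the null that particle positions are unrelated to
the RNA: protein positions are redrawn uniformly inside the oocyte
outline (counts preserved) ``n_rand`` times and the colocalized
fraction recomputed, giving a randomization mean and sd per bin and an
enrichment ratio observed/expected.

Protein-per-copy scaling is quantified per genotype by ordinary least
squares of normalised protein intensity on mRNA copy number; slopes
are compared pairwise through genotype x copy interaction contrasts in
a pooled linear model with a Bonferroni-corrected alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import cKDTree

from stau_rnaloc.annotation import OocyteAnnotation
from stau_rnaloc.errors import InvalidParameterError, UnderDeterminedError
from stau_rnaloc.quantify import copy_bin_index


def nn_pairs(
    rna: pd.DataFrame,
    protein: pd.DataFrame,
    r_um: float,
) -> pd.DataFrame:
    """One-way nearest-neighbour pairing from mRNPs to protein particles.

    Returns a table with ``rna_id, nn_id, distance_um, colocalized``.
    With an empty protein table all flags are False and distances NaN.
    """
    if r_um <= 0:
        raise InvalidParameterError("colocalization radius must be positive")
    if len(rna) == 0:
        raise InvalidParameterError("RNA spot table is empty")
    rna_ids = rna["id"].to_numpy()
    if len(protein) == 0:
        return pd.DataFrame(
            {
                "rna_id": rna_ids,
                "nn_id": np.full(len(rna), -1),
                "distance_um": np.full(len(rna), np.nan),
                "colocalized": np.zeros(len(rna), bool),
            }
        )
    tree = cKDTree(protein[["x_um", "y_um"]].to_numpy(dtype=float))
    dist, idx = tree.query(rna[["x_um", "y_um"]].to_numpy(dtype=float), k=1)
    return pd.DataFrame(
        {
            "rna_id": rna_ids,
            "nn_id": protein["id"].to_numpy()[idx],
            "distance_um": dist,
            "colocalized": dist <= r_um,
        }
    )


@dataclass
class ExpectedColoc:
    """Randomization-null colocalized fractions."""

    per_bin: pd.DataFrame  # columns: bin, expected_fraction, expected_sd
    overall_mean: float
    overall_sd: float
    n_rand: int

    def lookup(self, bins: np.ndarray) -> np.ndarray:
        m = dict(zip(self.per_bin["bin"], self.per_bin["expected_fraction"]))
        return np.array([m.get(int(b), np.nan) for b in bins])


def expected_coloc(
    rna: pd.DataFrame,
    protein: pd.DataFrame,
    annot: OocyteAnnotation,
    r_um: float,
    n_rand: int = 100,
    seed: int | None = 0,
    bins: np.ndarray | None = None,
    randomize_rna: bool = False,
) -> ExpectedColoc:
    """Colocalized fraction expected from object densities alone.

    Protein positions are redrawn uniformly inside the outline
    ``n_rand`` times (particle count preserved; optionally the RNA
    positions too) and the per-bin colocalized fraction recomputed;
    the mean and sd over randomizations are returned.
    """
    if n_rand < 20:
        raise InvalidParameterError("n_rand must be >= 20 for a usable null")
    if annot.area <= 0:
        raise InvalidParameterError("degenerate outline: zero area")
    rng = np.random.default_rng(seed)
    if bins is None:
        bins = np.zeros(len(rna), dtype=int)
    bins = np.asarray(bins, dtype=int)
    if len(bins) != len(rna):
        raise InvalidParameterError("bins must align with the RNA table")

    uniq = np.unique(bins)
    fractions = np.empty((n_rand, len(uniq)))
    overall = np.empty(n_rand)
    rna_xy = rna[["x_um", "y_um"]].to_numpy(dtype=float)
    n_protein = len(protein)
    for it in range(n_rand):
        prot_xy = annot.sample_uniform(n_protein, rng)
        xy = annot.sample_uniform(len(rna), rng) if randomize_rna else rna_xy
        if n_protein == 0:
            flags = np.zeros(len(rna), bool)
        else:
            dist, _ = cKDTree(prot_xy).query(xy, k=1)
            flags = dist <= r_um
        overall[it] = flags.mean()
        for j, b in enumerate(uniq):
            sel = bins == b
            fractions[it, j] = flags[sel].mean() if sel.any() else np.nan
    per_bin = pd.DataFrame(
        {
            "bin": uniq,
            "expected_fraction": np.nanmean(fractions, axis=0),
            "expected_sd": np.nanstd(fractions, axis=0, ddof=1),
        }
    )
    return ExpectedColoc(
        per_bin=per_bin,
        overall_mean=float(overall.mean()),
        overall_sd=float(overall.std(ddof=1)),
        n_rand=n_rand,
    )


def coloc_by_bin(
    pairing: pd.DataFrame,
    copies: pd.DataFrame,
    expected: ExpectedColoc | None = None,
    min_n: int = 5,
) -> pd.DataFrame:
    """Observed (and, when given, expected) colocalization per copy bin.

    ``copies`` is a copy-number table with ``id`` and ``bin`` columns;
    ids must match the pairing's ``rna_id``. Bins with fewer than
    ``min_n`` mRNPs are flagged low-confidence; empty fractions are
    NaN. Enrichment = observed / expected.
    """
    missing = set(pairing["rna_id"]) - set(copies["id"])
    if missing:
        raise InvalidParameterError(
            f"copy-number table is missing ids: {sorted(missing)[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    merged = pairing.merge(
        copies[["id", "bin"]], left_on="rna_id", right_on="id", how="inner"
    )
    rows = []
    for b, grp in merged.groupby("bin"):
        n = len(grp)
        obs = grp["colocalized"].mean() if n else np.nan
        rows.append(
            {
                "bin": int(b),
                "n": n,
                "observed_fraction": obs,
                "low_confidence": n < min_n,
            }
        )
    out = pd.DataFrame(rows)
    if expected is not None:
        exp = expected.lookup(out["bin"].to_numpy())
        out["expected_fraction"] = exp
        out["expected_sd"] = expected.per_bin.set_index("bin").reindex(out["bin"])[
            "expected_sd"
        ].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            out["enrichment"] = out["observed_fraction"] / exp
    return out


@dataclass
class ScalingFit:
    """Per-genotype protein-per-copy slopes and pairwise comparisons."""

    per_genotype: pd.DataFrame  # genotype, slope, intercept, r2, n, slope_se
    pairwise: pd.DataFrame  # genotype_a, genotype_b, diff, p
    alpha: float
    corrected_alpha: float

    def to_dict(self) -> dict:
        return {
            "per_genotype": self.per_genotype.to_dict(orient="records"),
            "pairwise": self.pairwise.to_dict(orient="records"),
            "alpha": self.alpha,
            "corrected_alpha": self.corrected_alpha,
        }


def scaling_fit(
    data: pd.DataFrame,
    copy_col: str = "copy_number",
    intensity_col: str = "protein_intensity",
    genotype_col: str = "genotype",
    alpha: float = 0.05,
) -> ScalingFit:
    """OLS of normalised protein intensity on mRNA copy number.

    One line per genotype (slope, intercept, R²); slope differences are
    tested through interaction contrasts of a pooled model
    ``intensity ~ genotype * copy`` (a transparent equivalent of
    comparing least-squares means trends), Bonferroni-corrected over
    the pairs tested.
    """
    genotypes = list(pd.unique(data[genotype_col]))
    rows = []
    for g in genotypes:
        sub = data[data[genotype_col] == g]
        if sub[copy_col].nunique() < 3:
            raise UnderDeterminedError(
                f"genotype {g!r} has fewer than 3 distinct copy-number values"
            )
        x = sm.add_constant(sub[copy_col].to_numpy(dtype=float))
        fit = sm.OLS(sub[intensity_col].to_numpy(dtype=float), x).fit()
        rows.append(
            {
                "genotype": g,
                "slope": float(fit.params[1]),
                "intercept": float(fit.params[0]),
                "slope_se": float(fit.bse[1]),
                "r2": float(fit.rsquared),
                "n": int(len(sub)),
            }
        )
    per_genotype = pd.DataFrame(rows)

    pairs = list(combinations(genotypes, 2))
    pairwise_rows = []
    if pairs:
        # pooled design: per-genotype intercepts and slopes (cell-means form)
        design_cols = []
        names = []
        for g in genotypes:
            ind = (data[genotype_col] == g).to_numpy(dtype=float)
            design_cols.append(ind)
            design_cols.append(ind * data[copy_col].to_numpy(dtype=float))
            names.extend([f"int_{g}", f"slope_{g}"])
        design = np.column_stack(design_cols)
        # multiplicative intensity noise makes residual variance grow with
        # copy number; HC3 keeps the contrast tests honest under that
        pooled = sm.OLS(data[intensity_col].to_numpy(dtype=float), design).fit(
            cov_type="HC3"
        )
        for ga, gb in pairs:
            contrast = np.zeros(design.shape[1])
            contrast[names.index(f"slope_{ga}")] = 1.0
            contrast[names.index(f"slope_{gb}")] = -1.0
            test = pooled.t_test(contrast)
            pairwise_rows.append(
                {
                    "genotype_a": ga,
                    "genotype_b": gb,
                    "diff": float(np.atleast_1d(test.effect)[0]),
                    "p": float(np.atleast_1d(test.pvalue).ravel()[0]),
                }
            )
    pairwise = pd.DataFrame(
        pairwise_rows, columns=["genotype_a", "genotype_b", "diff", "p"]
    )
    corrected_alpha = alpha / len(pairs) if pairs else alpha
    return ScalingFit(
        per_genotype=per_genotype,
        pairwise=pairwise,
        alpha=alpha,
        corrected_alpha=corrected_alpha,
    )


def copy_bins_from_truth(copies: np.ndarray) -> np.ndarray:
    """True copy numbers -> the 2^i bin index (testing convenience)."""
    return copy_bin_index(copies)
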