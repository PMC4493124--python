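"""Variance components by one-way ANOVA and the RR-BLUP prediction model.

The prediction model for line-mean phenotypes is

    y = μ1 + X g + e,       g_j ~ N(0, V_g / N_M),    e ~ N(0, V_e,eff I)

with X the lines × markers matrix of {0, 2} allele-count codes (kept
uncentered; the intercept absorbs the shift).  Solving the mixed-model
equations with an unpenalized intercept is equivalent to a ridge regression
on column-centered data with shrinkage λ = V_e,eff / (V_g / N_M), where
V_e,eff = V_e / n_reps is the residual variance of an n_reps-plot line mean.
When markers outnumber training lines the mathematically equivalent dual
(observation-dimension) solve is used.

Prediction accuracy is reported both as r_MP (correlation of predicted with
observed phenotype) and on the genetic scale as r_MG = r_MP / h, with h the
square root of the line-mean heritability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .io import MISSING, GenotypeMatrix, PlotPhenotypes


@dataclass(frozen=True)
class VarianceEstimates:
    """ANOVA variance components on the plot (Ve) and line (Vg) level."""

    Vg: float
    Ve: float
    h2: float  # line-mean basis: Vg / (Vg + Ve / n_reps)
    n_reps: float  # replicates per line (harmonic mean if unbalanced)

    def lambda_for(self, n_markers: int) -> float:
        """Ridge shrinkage λ = (Ve / n_reps) / (Vg / N_M)."""
        if self.Vg <= 0:
            raise ValueError("Vg must be positive to form the shrinkage ratio")
        return (self.Ve / self.n_reps) / (self.Vg / n_markers)


@dataclass
class RRBlupFit:
    """Fitted RR-BLUP model: intercept, marker breeding values, shrinkage."""

    mu: float
    g: np.ndarray  # length N_M marker effects
    lam: float
    marker_ids: tuple
    training_ids: tuple
    solver: str  # 'primal' or 'dual'

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"marker": list(self.marker_ids), "effect": self.g})


@dataclass(frozen=True)
class AccuracyResult:
    """Correlation-based prediction accuracy, optionally heritability-scaled."""

    r_MP: float
    r_MG: float
    h_used: float


def estimate_variance_anova(plots: PlotPhenotypes) -> VarianceEstimates:
    """One-way (lines) ANOVA variance components from plot phenotypes.

    Ve is the within-line mean square; Vg = (MS_between − MS_within) / r,
    truncated at zero, with r the (harmonic-mean) number of replicates.
    h² is reported on the line-mean basis.
    """
    df = plots.table
    groups = df.groupby("line")["value"]
    k = groups.ngroups
    if k < 2:
        raise ValueError("need at least 2 lines for ANOVA")
    n_i = groups.size().to_numpy(dtype=float)
    if (n_i <= 1).all():
        raise ValueError(
            "single replicate per line: Ve is unidentifiable — supply h² directly"
        )
    n_total = float(n_i.sum())
    grand = df["value"].mean()
    means = groups.mean().to_numpy()
    ss_between = float((n_i * (means - grand) ** 2).sum())
    ss_within = float(((df["value"] - groups.transform("mean")) ** 2).sum())
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n_total - k)
    r = k / float((1.0 / n_i).sum())  # harmonic mean of replicate counts
    ve = ms_within
    vg = max(0.0, (ms_between - ms_within) / r)
    denom = vg + ve / r
    h2 = 1.0 if denom == 0 else vg / denom
    return VarianceEstimates(Vg=vg, Ve=ve, h2=h2, n_reps=r)


def fit_rrblup(
    X: GenotypeMatrix | np.ndarray,
    y: np.ndarray | pd.Series,
    var: VarianceEstimates | None = None,
    lam: float | None = None,
    solver: str = "auto",
    marker_ids=None,
    training_ids=None,
) -> RRBlupFit:
    """Solve the RR-BLUP mixed-model equations for (μ, g).

    Shrinkage comes from ``var`` as λ = (Ve/n_reps)/(Vg/N_M) unless ``lam``
    is given explicitly.  ``solver`` picks the marker-dimension ('primal') or
    the equivalent observation-dimension ('dual') normal equations; 'auto'
    uses the cheaper of the two.
    """
    if isinstance(X, GenotypeMatrix):
        if marker_ids is None:
            marker_ids = tuple(X.map.marker_ids)
        if training_ids is None:
            training_ids = tuple(X.line_ids)
        X = X.codes
    X = np.asarray(X, dtype=float)
    if (X == MISSING).any():
        raise ValueError("training genotypes contain missing codes; impute first")
    y = np.asarray(pd.Series(y), dtype=float)
    n_p, n_m = X.shape
    if n_p < 2:
        raise ValueError("need at least 2 training lines")
    if len(y) != n_p:
        raise ValueError("y length does not match the number of training lines")

    if lam is None:
        if var is None:
            raise ValueError("provide either variance estimates or an explicit lambda")
        lam = var.lambda_for(n_m)
    if lam < 0 or (lam == 0 and n_m >= n_p):
        raise ValueError("shrinkage lambda must be > 0 (system singular at lambda = 0)")

    col_means = X.mean(axis=0)
    Xc = X - col_means
    ybar = float(y.mean())
    yc = y - ybar

    if solver == "auto":
        solver = "primal" if n_m <= n_p else "dual"
    if solver == "primal":
        A = Xc.T @ Xc
        A[np.diag_indices_from(A)] += lam
        g = scipy.linalg.solve(A, Xc.T @ yc, assume_a="pos")
    elif solver == "dual":
        K = Xc @ Xc.T
        K[np.diag_indices_from(K)] += lam
        g = Xc.T @ scipy.linalg.solve(K, yc, assume_a="pos")
    else:
        raise ValueError("solver must be 'auto', 'primal' or 'dual'")

    mu = ybar - float(col_means @ g)
    if marker_ids is None:
        marker_ids = tuple(range(n_m))
    if training_ids is None:
        training_ids = tuple(range(n_p))
    return RRBlupFit(mu=mu, g=g, lam=float(lam), marker_ids=tuple(marker_ids),
                     training_ids=tuple(training_ids), solver=solver)


def predict_gebv(fit: RRBlupFit, X_new: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Genomic estimated breeding values ŷ = μ + X_new g."""
    if isinstance(X_new, GenotypeMatrix):
        new_ids = tuple(X_new.map.marker_ids)
        if new_ids != fit.marker_ids:
            missing = sorted(set(fit.marker_ids) - set(new_ids))[:5]
            extra = sorted(set(new_ids) - set(fit.marker_ids))[:5]
            raise ValueError(
                f"marker set mismatch with the fit (missing {missing}, extra {extra})"
            )
        X_new = X_new.codes
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != len(fit.g):
        raise ValueError("marker count mismatch with the fitted effects")
    if (X_new == MISSING).any():
        raise ValueError("prediction genotypes contain missing codes; impute first")
    return fit.mu + X_new @ fit.g


def accuracy(predicted, observed, h2: float) -> AccuracyResult:
    """Prediction accuracy: r_MP and its heritability-scaled form r_MG.

    r_MP is the Pearson correlation between predicted and observed
    phenotypes; r_MG = r_MP / sqrt(h2), reported uncapped (values above 1
    are possible by construction).
    """
    if not 0 < h2 <= 1:
        raise ValueError("h2 must lie in (0, 1]")
    p = np.asarray(pd.Series(predicted), dtype=float)
    o = np.asarray(pd.Series(observed), dtype=float)
    if len(p) != len(o):
        raise ValueError("predicted and observed lengths differ")
    if len(p) < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(p) == 0 or np.std(o) == 0:
        warnings.warn("zero variance in predicted or observed values", stacklevel=2)
        return AccuracyResult(float("nan"), float("nan"), float(np.sqrt(h2)))
    r_mp = float(np.corrcoef(p, o)[0, 1])
    h = float(np.sqrt(h2))
    return AccuracyResult(r_MP=r_mp, r_MG=r_mp / h, h_used=h)
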