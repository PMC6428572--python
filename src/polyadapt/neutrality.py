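"""Neutrality tests for population polygenic scores.

Both tests condition on the multivariate-normal neutral null
``Z ~ MVN(mu 1, 2 VA F)``:

* the over-dispersion statistic
  ``QX = (Z - mu 1)' F^+ (Z - mu 1) / (2 VA)``, chi-square with
  ``df = rank(F)`` degrees of freedom under the null (``M - 1`` when F is
  estimated from centered standardized frequencies);
* the geographic-axis statistic
  ``(Y'Z - mu Y'1)^2 / (2 VA Y'F Y)``, chi-square with 1 df, for an axis
  ``Y`` such as population latitudes or longitudes.

Because the sample co-ancestry matrix is singular by construction, the
"inverse" of F is taken as the Moore-Penrose pseudoinverse restricted to the
non-null eigenspace; this is equivalent to dropping one population, the
established convention for this statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import CoancestryMatrix, PolygenicScoreSet
from .exceptions import DegenerateAxisError, DegenerateInputError

__all__ = ["NeutralityResult", "qx_test", "axis_test", "qx_decomposition"]


@dataclass(frozen=True)
class NeutralityResult:
    """Outcome of a chi-square neutrality test on polygenic scores."""

    statistic: float
    df: int
    p_value: float
    method: str  # "qx" | "axis"
    axis_label: str | None = None
    snp_count: int = 0

    def summary(self) -> str:
        label = f" ({self.axis_label})" if self.axis_label else ""
        return (
            f"{self.method.upper()} test{label}: statistic = {self.statistic:.4f}, "
            f"df = {self.df}, p = {self.p_value:.4g}, SNPs = {self.snp_count}"
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "axis_label": self.axis_label,
            "snp_count": self.snp_count,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def _eigen_support(F: np.ndarray, n_snps: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of F above the pseudoinverse cutoff.

    The cutoff ``max(M, L) * eps * lambda_max`` mirrors the conventional
    rcond used for rank determination of an M x M Gram matrix built from L
    observations.
    """
    eigvals, eigvecs = np.linalg.eigh(F)
    m = F.shape[0]
    cutoff = max(m, max(n_snps, 1)) * np.finfo(float).eps * max(eigvals.max(), 0.0)
    keep = eigvals > cutoff
    return eigvals[keep], eigvecs[:, keep]


def _check_scores(scores: PolygenicScoreSet, F: CoancestryMatrix) -> None:
    if scores.populations != F.populations:
        raise DegenerateInputError("scores and F refer to different population sets")
    if scores.n_pops < 2:
        raise DegenerateInputError("need at least 2 populations")
    if scores.va <= 0:
        raise DegenerateInputError("VA is zero; all effects vanish or SNPs are fixed")


def qx_test(scores: PolygenicScoreSet, F: CoancestryMatrix) -> NeutralityResult:
    """Over-dispersion test of polygenic scores against the drift null."""
    _check_scores(scores, F)
    eigvals, eigvecs = _eigen_support(F.F, F.n_snps_used)
    if eigvals.size == 0:
        raise DegenerateInputError("co-ancestry matrix has rank 0")
    dev = scores.z - scores.mu
    proj = eigvecs.T @ dev
    qx = float((proj**2 / eigvals).sum() / (2.0 * scores.va))
    df = int(eigvals.size)
    p = float(stats.chi2.sf(qx, df))
    return NeutralityResult(
        statistic=qx, df=df, p_value=max(p, np.finfo(float).tiny),
        method="qx", snp_count=scores.snp_count,
    )


def qx_decomposition(scores: PolygenicScoreSet, F: CoancestryMatrix) -> np.ndarray:
    """Per-eigenvector contributions to QX (squared standardized projections).

    The entries sum to the QX statistic; a signal concentrated on one axis of
    population structure loads a single component, whereas a diffuse signal is
    spread across all of them.
    """
    _check_scores(scores, F)
    eigvals, eigvecs = _eigen_support(F.F, F.n_snps_used)
    if eigvals.size == 0:
        raise DegenerateInputError("co-ancestry matrix has rank 0")
    dev = scores.z - scores.mu
    proj = eigvecs.T @ dev
    return proj**2 / eigvals / (2.0 * scores.va)


def axis_test(
    scores: PolygenicScoreSet,
    F: CoancestryMatrix,
    axis: np.ndarray,
    axis_label: str | None = None,
) -> NeutralityResult:
    """Test for an unexpectedly strong cline of scores along a geographic axis.

    Parameters
    ----------
    scores, F
        Polygenic scores with null moments, and the co-ancestry matrix.
    axis
        Per-population axis values ``Y`` (e.g. latitude in degrees).  The
        statistic is invariant to centering Y whenever ``F 1 = 0``, which
        holds for F estimated from centered standardized frequencies.
    axis_label
        Optional label recorded in the result (e.g. ``"latitude"``).
    """
    _check_scores(scores, F)
    y = np.asarray(axis, dtype=float)
    if y.shape != (scores.n_pops,):
        raise DegenerateInputError("axis must have one value per population")
    yfy = float(y @ F.F @ y)
    tol = 1e-12 * max(1.0, float(np.abs(F.F).max()) * float(y @ y))
    if yfy <= tol:
        raise DegenerateAxisError(
            "axis lies in the null space of F; the cline test is undefined"
        )
    num = float(y @ scores.z - scores.mu * y.sum())
    statistic = num**2 / (2.0 * scores.va * yfy)
    p = float(stats.chi2.sf(statistic, 1))
    return NeutralityResult(
        statistic=statistic, df=1, p_value=max(p, np.finfo(float).tiny),
        method="axis", axis_label=axis_label, snp_count=scores.snp_count,
    )
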