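"""Matrix correlation and matrix regression with node-permutation nulls.

Dyadic observations are not independent — every dyad shares a node with
2(N-2) others — so significance for matrix statistics comes from node
permutations: relabelling individuals (jointly permuting rows and columns)
preserves the dependence structure while breaking the association between
matrices.

* :func:`mantel_test` — Pearson (or Spearman) correlation of the
  off-diagonal entries of two aligned symmetric matrices, with a
  node-permutation null.
* :func:`mrqap_dsp` — multiple regression quadratic assignment procedure
  with Dekker's double semi-partialling: each predictor's significance
  comes from node-permuting the *residual* of that predictor on the other
  predictors, which keeps the test calibrated when predictors are mutually
  correlated.  All matrices are standardized (off-diagonal z-scores), so
  coefficients are scaled effect sizes comparable across predictors.
* :func:`fold_difference` — ratio of the roost co-occurrence effect to the
  previous-year association effect, the headline contrast between roost
  fidelity and persistent social preference.

Permutation p-values use the +1 convention,
``p = (#{extreme} + 1) / (n_perm + 1)``, and are reproducible under a
fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from coroost.association import AssociationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MantelResult",
    "MRQAPResult",
    "mantel_test",
    "align_years",
    "mrqap_dsp",
    "scale_matrix",
    "fold_difference",
    "year_gap_summary",
]

#: conventional predictor names used by the pipeline
PREV_ASSOCIATION = "prev_association"
COOCCURRENCE = "cooccurrence"


# ---------------------------------------------------------------------------
# helpers


def _as_matrix(M) -> tuple[np.ndarray, Optional[list[str]]]:
    """Extract (square ndarray, labels or None) from supported inputs."""
    if isinstance(M, AssociationMatrix):
        return np.asarray(M.sri, dtype=float), list(M.bats)
    if hasattr(M, "values") and hasattr(M, "bats"):  # CooccurrenceMatrix
        return np.asarray(M.values, dtype=float), list(M.bats)
    if isinstance(M, pd.DataFrame):
        return M.to_numpy(dtype=float), [str(c) for c in M.columns]
    arr = np.asarray(M, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("expected a square matrix")
    return arr, None


def _check_aligned(labels_a, labels_b) -> None:
    if labels_a is not None and labels_b is not None and labels_a != labels_b:
        raise ValueError("matrix indices are not aligned")


def _node_permutations(n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    perms = np.tile(np.arange(n), (n_perm, 1))
    return rng.permuted(perms, axis=1)


def _permuted_upper(values: np.ndarray, perms: np.ndarray, iu, ju) -> np.ndarray:
    """Upper-triangle vectors of node-permuted matrices, one row per
    permutation."""
    return values[perms[:, iu], perms[:, ju]]


def scale_matrix(M: np.ndarray) -> np.ndarray:
    """Z-score the off-diagonal entries of a symmetric matrix.

    Off-diagonal entries are standardized to mean 0 and (sample) sd 1;
    symmetry is preserved and the diagonal set to 0.  Affine transforms of
    the input map to the same output.  A constant off-diagonal is an error.
    """
    M, _ = _as_matrix(M)
    n = M.shape[0]
    mask = ~np.eye(n, dtype=bool)
    vals = M[mask]
    sd = vals.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("matrix has constant off-diagonal entries")
    out = np.zeros_like(M, dtype=float)
    out[mask] = (vals - vals.mean()) / sd
    return out


# ---------------------------------------------------------------------------
# Mantel


@dataclasses.dataclass
class MantelResult:
    r: float
    p_two_tailed: float
    p_one_tailed: float
    n_permutations: int
    n_shared_bats: int
    year_pair: Optional[tuple[int, int]] = None
    method: str = "pearson"

    @property
    def year_gap(self) -> Optional[int]:
        if self.year_pair is None:
            return None
        return abs(self.year_pair[1] - self.year_pair[0])


def mantel_test(
    M1,
    M2,
    n_perm: int = 999,
    rng: Optional[np.random.Generator] = None,
    *,
    method: str = "pearson",
    year_pair: Optional[tuple[int, int]] = None,
) -> MantelResult:
    """Mantel test between two aligned symmetric matrices.

    ``r`` is the Pearson (or Spearman) correlation of the upper-triangle
    off-diagonal entries; the null distribution comes from jointly
    permuting the rows and columns of ``M2`` with the same node
    permutation.  Constant matrices give NaN r and p.
    """
    rng = np.random.default_rng() if rng is None else rng
    A, la = _as_matrix(M1)
    B, lb = _as_matrix(M2)
    _check_aligned(la, lb)
    if A.shape != B.shape:
        raise ValueError("matrix shapes differ")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals")
    iu, ju = np.triu_indices(n, k=1)
    v1 = A[iu, ju]
    v2 = B[iu, ju]
    if method == "spearman":
        v1 = rankdata(v1)
        v2 = rankdata(v2)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    if v1.std() == 0 or v2.std() == 0:
        logger.warning("constant matrix in Mantel test; r undefined")
        return MantelResult(
            float("nan"), float("nan"), float("nan"), n_perm, n, year_pair, method
        )
    r_obs = float(np.corrcoef(v1, v2)[0, 1])

    perms = _node_permutations(n, n_perm, rng)
    V = _permuted_upper(B, perms, iu, ju)
    if method == "spearman":
        V = rankdata(V, axis=1)
    Vc = V - V.mean(axis=1, keepdims=True)
    v1c = v1 - v1.mean()
    denom = np.sqrt((Vc**2).sum(axis=1)) * np.sqrt((v1c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = (Vc @ v1c) / denom
    r_perm = np.nan_to_num(r_perm, nan=0.0)
    p_two = float((np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12) + 1) / (n_perm + 1))
    p_one = float((np.sum(r_perm >= r_obs - 1e-12) + 1) / (n_perm + 1))
    return MantelResult(r_obs, p_two, p_one, n_perm, n, year_pair, method)


def align_years(
    net_focal: AssociationMatrix,
    net_comp: AssociationMatrix,
    *,
    min_shared: int = 3,
) -> Optional[tuple[AssociationMatrix, AssociationMatrix, list[str]]]:
    """Restrict two yearly networks to their shared bats, identically
    ordered.  Returns None (with a warning) when fewer than ``min_shared``
    bats qualify in both years."""
    shared = sorted(set(net_focal.bats) & set(net_comp.bats))
    if len(shared) < min_shared:
        logger.warning(
            "years %s/%s share only %d bats; comparison skipped",
            net_focal.year,
            net_comp.year,
            len(shared),
        )
        return None
    return net_focal.subset(shared), net_comp.subset(shared), shared


# ---------------------------------------------------------------------------
# MRQAP


@dataclasses.dataclass
class MRQAPResult:
    """MRQAP fit: scaled effect sizes with double semi-partialling p-values."""

    predictors: list[str]
    coefficients: dict[str, float]
    p_two_tailed: dict[str, float]
    p_one_tailed: dict[str, float]
    r_squared: float
    n_bats: int
    n_permutations: int
    focal_year: Optional[int] = None
    comparison_year: Optional[int] = None

    @property
    def year_gap(self) -> Optional[int]:
        if self.focal_year is None or self.comparison_year is None:
            return None
        return abs(self.focal_year - self.comparison_year)


def mrqap_dsp(
    Y,
    X: Mapping[str, object],
    n_perm: int = 999,
    rng: Optional[np.random.Generator] = None,
    *,
    focal_year: Optional[int] = None,
    comparison_year: Optional[int] = None,
    condition_threshold: float = 1e8,
) -> MRQAPResult:
    """Multiple regression QAP with Dekker double semi-partialling.

    The dependent and every predictor matrix are standardized
    (:func:`scale_matrix`), so point estimates — ordinary least squares on
    the upper-triangle vectors — are scaled effect sizes.  For each
    predictor, significance comes from node-permuting the residual of that
    predictor's matrix on the remaining predictors, refitting, and
    comparing coefficient magnitudes (+1 convention).
    """
    rng = np.random.default_rng() if rng is None else rng
    if len(X) < 1:
        raise ValueError("need at least one predictor")
    Yv, ly = _as_matrix(Y)
    n = Yv.shape[0]
    if n < 4:
        raise ValueError("need at least 4 individuals for MRQAP")
    names = list(X)
    Xmats = []
    for name in names:
        Xi, lx = _as_matrix(X[name])
        _check_aligned(ly, lx)
        if Xi.shape != Yv.shape:
            raise ValueError(f"predictor {name!r} shape mismatch")
        Xmats.append(scale_matrix(Xi))
    Ys = scale_matrix(Yv)

    iu, ju = np.triu_indices(n, k=1)
    y = Ys[iu, ju]
    Xcols = np.column_stack([Xi[iu, ju] for Xi in Xmats])
    m, k = Xcols.shape
    design = np.column_stack([np.ones(m), Xcols])
    cond = np.linalg.cond(design)
    if cond > condition_threshold:
        corr = np.corrcoef(Xcols, rowvar=False)
        raise ValueError(
            f"collinear predictors (condition number {cond:.3g}); "
            f"predictor correlations:\n{np.round(corr, 4)}"
        )
    beta_full, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta_full
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 - ss_res / ss_tot

    coefficients = dict(zip(names, beta_full[1:].astype(float)))
    p_two: dict[str, float] = {}
    p_one: dict[str, float] = {}
    for idx, name in enumerate(names):
        xk = Xcols[:, idx]
        others = np.delete(Xcols, idx, axis=1)
        W = np.column_stack([np.ones(m), others])
        WtW_inv = np.linalg.inv(W.T @ W)
        proj = lambda v: W @ (WtW_inv @ (W.T @ v))  # noqa: E731
        e_k = xk - proj(xk)
        y_r = y - proj(y)
        beta_obs = float(e_k @ y_r / (e_k @ e_k))
        # residual back in matrix form for node permutation
        E = np.zeros((n, n))
        E[iu, ju] = e_k
        E = E + E.T
        perms = _node_permutations(n, n_perm, rng)
        Ep = _permuted_upper(E, perms, iu, ju)
        coef = (Ep @ W) @ WtW_inv  # (n_perm, k)
        Ep_r = Ep - coef @ W.T
        num = Ep_r @ y_r
        den = (Ep_r**2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            beta_perm = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        p_two[name] = float(
            (np.sum(np.abs(beta_perm) >= abs(beta_obs) - 1e-12) + 1) / (n_perm + 1)
        )
        p_one[name] = float((np.sum(beta_perm >= beta_obs - 1e-12) + 1) / (n_perm + 1))
    return MRQAPResult(
        predictors=names,
        coefficients=coefficients,
        p_two_tailed=p_two,
        p_one_tailed=p_one,
        r_squared=float(r_squared),
        n_bats=n,
        n_permutations=n_perm,
        focal_year=focal_year,
        comparison_year=comparison_year,
    )


def fold_difference(
    result: MRQAPResult,
    numerator: str = COOCCURRENCE,
    denominator: str = PREV_ASSOCIATION,
) -> Optional[float]:
    """Scaled co-occurrence effect divided by the previous-year association
    effect.  Returns None (undefined, not infinite) when the divisor is 0;
    missing predictors are an error."""
    for name in (numerator, denominator):
        if name not in result.coefficients:
            raise ValueError(f"predictor {name!r} missing from MRQAP result")
    den = result.coefficients[denominator]
    if den == 0:
        logger.warning("fold difference undefined: divisor effect is 0")
        return None
    return float(result.coefficients[numerator] / den)


def year_gap_summary(
    mantel_results: Sequence[MantelResult] = (),
    mrqap_results: Sequence[MRQAPResult] = (),
    *,
    mean_per_gap: bool = False,
) -> pd.DataFrame:
    """Long table of inter-year statistics keyed by year gap.

    Rows carry Mantel R and/or MRQAP fold-difference per year pair; with
    ``mean_per_gap`` the statistics are averaged within each gap (no other
    smoothing)."""
    rows = []
    for res in mantel_results:
        rows.append(
            {
                "year_pair": res.year_pair,
                "year_gap": res.year_gap,
                "statistic": "mantel_r",
                "value": res.r,
            }
        )
    for res in mrqap_results:
        fd = None
        if (
            COOCCURRENCE in res.coefficients
            and PREV_ASSOCIATION in res.coefficients
            and res.coefficients[PREV_ASSOCIATION] != 0
        ):
            fd = fold_difference(res)
        rows.append(
            {
                "year_pair": (res.comparison_year, res.focal_year),
                "year_gap": res.year_gap,
                "statistic": "fold_difference",
                "value": fd,
            }
        )
    df = pd.DataFrame(rows, columns=["year_pair", "year_gap", "statistic", "value"])
    if mean_per_gap and not df.empty:
        df = (
            df.dropna(subset=["value"])
            .groupby(["year_gap", "statistic"])["value"]
            .mean()
            .reset_index()
        )
    return df
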