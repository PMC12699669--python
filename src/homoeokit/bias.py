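"""Homoeolog expression-bias classification on the expression simplex.

For a 1:1:1 triad with per-tissue mean expression (tA, tB, tC) in TPM, the
triad is *expressed* in a tissue when tA + tB + tC exceeds a threshold
(default 0.5 TPM, strict inequality). Expressed triads are normalized to
proportions p = (pA, pB, pC) on the 2-simplex and assigned to the bias
category whose ideal point (centroid) lies at the shortest Euclidean
distance, computed on the raw 3-vector:

========================  =================
category                  centroid
========================  =================
balanced                  (1/3, 1/3, 1/3)
A_dominant                (1, 0, 0)
B_dominant                (0, 1, 0)
C_dominant                (0, 0, 1)
A_suppressed              (0, 1/2, 1/2)
B_suppressed              (1/2, 0, 1/2)
C_suppressed              (1/2, 1/2, 0)
========================  =================

Ties are broken by centroid order (balanced first, then dominants, then
suppressed). The classifier is exposed in scikit-learn estimator form
(:class:`NearestCentroidBiasClassifier`) so it composes with sklearn
pipelines; the module-level functions wrap it for the tabular workflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ContractError, InputError

#: Default TPM threshold above which a triad counts as expressed (strict >).
EXPRESSION_THRESHOLD: float = 0.5

#: Ideal simplex points, in tie-break order.
DEFAULT_CENTROIDS: tuple[tuple[str, tuple[float, float, float]], ...] = (
    ("balanced", (1 / 3, 1 / 3, 1 / 3)),
    ("A_dominant", (1.0, 0.0, 0.0)),
    ("B_dominant", (0.0, 1.0, 0.0)),
    ("C_dominant", (0.0, 0.0, 1.0)),
    ("A_suppressed", (0.0, 0.5, 0.5)),
    ("B_suppressed", (0.5, 0.0, 0.5)),
    ("C_suppressed", (0.5, 0.5, 0.0)),
)

CATEGORIES: tuple[str, ...] = tuple(name for name, _ in DEFAULT_CENTROIDS)

_SIMPLEX_ATOL = 1e-9


def _as_simplex_array(P, atol: float = _SIMPLEX_ATOL) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim == 1:
        P = P[None, :]
    if P.ndim != 2 or P.shape[1] != 3:
        raise ContractError(f"expected proportions of shape (n, 3), got {P.shape}")
    if np.any(P < -atol) or np.any(P > 1 + atol):
        raise ContractError("proportions must lie in [0, 1]")
    bad = np.abs(P.sum(axis=1) - 1.0) > atol
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ContractError(
            f"row {i} does not lie on the simplex (sum = {P[i].sum()!r})"
        )
    return P


class NearestCentroidBiasClassifier(BaseEstimator, ClassifierMixin):
    """Assign simplex proportions to the nearest ideal bias centroid.

    The centroids are fixed ideal points rather than learned from data, so
    :meth:`fit` only materializes them (``X``/``y`` are accepted and ignored
    for pipeline compatibility).

    Parameters
    ----------
    centroids : sequence of (name, (pA, pB, pC)), optional
        Ordered centroid set; the order defines the tie-break. Defaults to
        the seven-category set (balanced, 3 dominant, 3 suppressed).
    atol : float
        Tolerance for the on-simplex validation of inputs.

    Attributes
    ----------
    categories_ : ndarray of str, shape (k,)
        Centroid names in tie-break order.
    centroids_ : ndarray, shape (k, 3)
        Centroid coordinates.
    classes_ : ndarray of str
        Sorted unique categories (sklearn contract).
    """

    def __init__(self, centroids=None, atol: float = _SIMPLEX_ATOL):
        self.centroids = centroids
        self.atol = atol

    def fit(self, X=None, y=None):
        spec = DEFAULT_CENTROIDS if self.centroids is None else tuple(self.centroids)
        names = [name for name, _ in spec]
        if len(set(names)) != len(names):
            raise InputError(f"duplicate centroid names: {names}")
        points = np.asarray([point for _, point in spec], dtype=float)
        if points.ndim != 2 or points.shape[1] != 3:
            raise InputError("each centroid must be a 3-vector of proportions")
        if not np.allclose(points.sum(axis=1), 1.0, atol=1e-9):
            raise InputError("every centroid must sum to 1")
        self.categories_ = np.asarray(names, dtype=object)
        self.centroids_ = points
        self.classes_ = np.unique(self.categories_)
        return self

    def transform(self, X) -> np.ndarray:
        """Euclidean distances to every centroid, shape (n, k)."""
        check_is_fitted(self, "centroids_")
        P = _as_simplex_array(X, self.atol)
        diff = P[:, None, :] - self.centroids_[None, :, :]
        return np.sqrt(np.einsum("nkj,nkj->nk", diff, diff))

    def predict(self, X) -> np.ndarray:
        """Category of the nearest centroid (ties -> earliest centroid)."""
        # np.argmin returns the first minimum, which is exactly the
        # documented tie-break (centroid declaration order).
        idx = np.argmin(self.transform(X), axis=1)
        return self.categories_[idx]

    def assign(self, X) -> pd.DataFrame:
        """Predictions plus per-centroid distances as a DataFrame."""
        D = self.transform(X)
        idx = np.argmin(D, axis=1)
        out = pd.DataFrame(D, columns=[f"dist_{c}" for c in self.categories_])
        out.insert(0, "category", self.categories_[idx])
        return out


def default_centroids() -> tuple[tuple[str, tuple[float, float, float]], ...]:
    """The seven ideal bias centroids in tie-break order."""
    return DEFAULT_CENTROIDS


def assign_bias(p, centroids=None) -> tuple[str, dict[str, float]]:
    """Classify a single proportion vector; returns (category, distances)."""
    clf = NearestCentroidBiasClassifier(centroids=centroids).fit()
    D = clf.transform(np.asarray(p, dtype=float)[None, :])[0]
    category = clf.categories_[int(np.argmin(D))]
    return str(category), {str(c): float(d) for c, d in zip(clf.categories_, D)}


# ---------------------------------------------------------------------------
# tabular workflow: expression matrix -> per-triad assignments
# ---------------------------------------------------------------------------


def load_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene × sample TPM matrix (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[0] != "gene_id":
        raise InputError(f"expression matrix {path} must start with a gene_id column")
    df = df.set_index("gene_id")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = df.index[coerced.isna()][0]
                raise InputError(
                    f"non-numeric TPM at gene {row!r}, sample {col!r} in {path}"
                )
        df = df.apply(pd.to_numeric)
        values = df.to_numpy()
    if (values < 0).any():
        gi, si = np.argwhere(values < 0)[0]
        raise InputError(
            f"negative TPM at gene {df.index[gi]!r}, sample {df.columns[si]!r}"
        )
    return df


def load_design(path: str | Path) -> pd.DataFrame:
    """Read the sample design table (sample_id, tissue, replicate)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "tissue": str})
    need = {"sample_id", "tissue", "replicate"}
    if not need <= set(df.columns):
        raise InputError(f"design table {path} must have columns {sorted(need)}")
    if df.duplicated(["tissue", "replicate"]).any():
        raise InputError(f"design table {path} has duplicate (tissue, replicate) pairs")
    return df


def aggregate_replicates(
    expression: pd.DataFrame, design: pd.DataFrame, stat: str = "mean"
) -> pd.DataFrame:
    """Collapse replicate samples to one column per tissue (mean or median)."""
    missing = set(design["sample_id"]) - set(expression.columns)
    if missing:
        raise InputError(f"design samples absent from expression matrix: {sorted(missing)}")
    if stat not in ("mean", "median"):
        raise InputError(f"unsupported replicate statistic {stat!r}")
    cols = {}
    for tissue, sub in design.groupby("tissue", sort=True):
        samples = list(sub["sample_id"])
        if not samples:
            raise InputError(f"tissue {tissue!r} has no samples")
        block = expression[samples]
        cols[tissue] = block.mean(axis=1) if stat == "mean" else block.median(axis=1)
    return pd.DataFrame(cols)


def triad_tpm(triads: pd.DataFrame, tissue_expression: pd.DataFrame) -> pd.DataFrame:
    """Per-triad, per-tissue homoeolog TPM.

    Returns a long table: triad_id, tissue, tpm_A, tpm_B, tpm_C, total.
    """
    genes = pd.unique(triads[["gene_A", "gene_B", "gene_C"]].to_numpy().ravel())
    missing = [g for g in genes if g not in tissue_expression.index]
    if missing:
        bad = triads[
            triads[["gene_A", "gene_B", "gene_C"]].isin(missing).any(axis=1)
        ]["triad_id"].tolist()
        raise InputError(
            f"{len(missing)} triad genes missing from the expression matrix "
            f"(triads {bad[:5]})"
        )
    rows = []
    for tissue in tissue_expression.columns:
        col = tissue_expression[tissue]
        tA = col.loc[triads["gene_A"]].to_numpy()
        tB = col.loc[triads["gene_B"]].to_numpy()
        tC = col.loc[triads["gene_C"]].to_numpy()
        rows.append(
            pd.DataFrame(
                {
                    "triad_id": triads["triad_id"].to_numpy(),
                    "tissue": tissue,
                    "tpm_A": tA,
                    "tpm_B": tB,
                    "tpm_C": tC,
                    "total": tA + tB + tC,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def is_expressed(total, threshold: float = EXPRESSION_THRESHOLD):
    """Strict TPM filter: the triad's summed TPM must exceed the threshold."""
    return np.asarray(total, dtype=float) > threshold


def normalize_triad(tpm, threshold: float = EXPRESSION_THRESHOLD) -> np.ndarray:
    """Simplex proportions of one expressed triad's (tA, tB, tC)."""
    t = np.asarray(tpm, dtype=float)
    total = t.sum()
    if not total > threshold:
        raise ContractError(
            f"triad with total TPM {total} is not expressed (threshold {threshold})"
        )
    return t / total


def classify_triads(
    triad_expr: pd.DataFrame,
    threshold: float = EXPRESSION_THRESHOLD,
    classifier: NearestCentroidBiasClassifier | None = None,
) -> pd.DataFrame:
    """Filter, normalize and classify the output of :func:`triad_tpm`.

    Adds ``status`` (expressed / not_expressed), proportions ``p_A..p_C``,
    ``category`` and per-centroid distance columns. Non-expressed triads keep
    NaN proportions and an empty category — they are never classified.
    """
    clf = classifier if classifier is not None else NearestCentroidBiasClassifier()
    if not hasattr(clf, "centroids_"):
        clf.fit()
    out = triad_expr.copy()
    expressed = is_expressed(out["total"].to_numpy(), threshold)
    out["status"] = np.where(expressed, "expressed", "not_expressed")
    T = out.loc[expressed, ["tpm_A", "tpm_B", "tpm_C"]].to_numpy()
    P = T / T.sum(axis=1, keepdims=True)
    for j, s in enumerate(("p_A", "p_B", "p_C")):
        out[s] = np.nan
        out.loc[expressed, s] = P[:, j]
    out["category"] = ""
    for c in clf.categories_:
        out[f"dist_{c}"] = np.nan
    if expressed.any():
        assigned = clf.assign(P)
        out.loc[expressed, "category"] = assigned["category"].to_numpy()
        for c in clf.categories_:
            out.loc[expressed, f"dist_{c}"] = assigned[f"dist_{c}"].to_numpy()
    return out


@dataclass(frozen=True)
class BiasSummary:
    """Category fractions per tissue and pooled over tissue-observations.

    Pooled counts treat each expressed triad × tissue as one observation
    (a triad expressed in both leaf and root counts twice).
    """

    per_tissue: pd.DataFrame  # index tissue, columns categories, values fractions
    pooled: pd.Series  # category -> fraction
    grouped: pd.Series  # balanced / dominant / suppressed -> fraction
    n_expressed: pd.Series  # per tissue, plus "pooled"

    def to_dict(self) -> dict:
        return {
            "n_expressed": {k: int(v) for k, v in self.n_expressed.items()},
            "pooled": {k: float(v) for k, v in self.pooled.items()},
            "grouped": {k: float(v) for k, v in self.grouped.items()},
            "per_tissue": {
                t: {c: float(self.per_tissue.loc[t, c]) for c in self.per_tissue.columns}
                for t in self.per_tissue.index
            },
        }


def summarize_bias(assignments: pd.DataFrame) -> BiasSummary:
    """Category fractions from a :func:`classify_triads` table."""
    expressed = assignments[assignments["status"] == "expressed"]
    if expressed.empty:
        raise InputError("no expressed triads to summarize")
    cats = list(CATEGORIES)
    per_tissue = (
        expressed.groupby("tissue")["category"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=cats, fill_value=0.0)
    )
    pooled = (
        expressed["category"].value_counts(normalize=True).reindex(cats, fill_value=0.0)
    )
    grouped = pd.Series(
        {
            "balanced": pooled["balanced"],
            "dominant": pooled[[c for c in cats if c.endswith("dominant")]].sum(),
            "suppressed": pooled[[c for c in cats if c.endswith("suppressed")]].sum(),
        }
    )
    n_expressed = expressed.groupby("tissue").size()
    n_expressed["pooled"] = len(expressed)
    return BiasSummary(per_tissue=per_tissue, pooled=pooled, grouped=grouped, n_expressed=n_expressed)


# ---------------------------------------------------------------------------
# ternary plotting coordinates
# ---------------------------------------------------------------------------

_SQRT3_2 = math.sqrt(3.0) / 2.0


def ternary_xy(p) -> np.ndarray:
    """Planar coordinates for simplex points: x = pB + pC/2, y = (√3/2)·pC.

    The A, B, C vertices map to (0,0), (1,0) and (0.5, √3/2).
    """
    P = _as_simplex_array(p)
    xy = np.column_stack([P[:, 1] + P[:, 2] / 2.0, _SQRT3_2 * P[:, 2]])
    return xy[0] if np.asarray(p).ndim == 1 else xy


def xy_to_simplex(xy) -> np.ndarray:
    """Inverse of :func:`ternary_xy`."""
    XY = np.asarray(xy, dtype=float)
    single = XY.ndim == 1
    if single:
        XY = XY[None, :]
    pC = XY[:, 1] / _SQRT3_2
    pB = XY[:, 0] - pC / 2.0
    pA = 1.0 - pB - pC
    P = np.column_stack([pA, pB, pC])
    return P[0] if single else P
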