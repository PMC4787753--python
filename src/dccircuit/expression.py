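"""Differential expression and stage-specific clustering.

Differential expression between two cell states uses a moderated two-sample
t-test: gene-wise variances are shrunk toward the median gene variance with
a fixed prior weight of ``d0`` pseudo-degrees of freedom, a simplified
empirical-Bayes scheme in the spirit of limma. A gene is called
differentially expressed when its fold change exceeds ``fc_threshold``
(default 2, i.e. |log2FC| > 1) and its raw p-value falls below ``alpha``;
Benjamini-Hochberg adjusted p-values are reported alongside and can be used
as the gate instead (``gate="adjusted"``).

Clustering of differentially expressed genes into the six developmental
clusters (MPP/CDP, MPP, CDP, pan-DC, cDC, pDC) uses fuzzy c-means on
row-standardized state-mean profiles, exposed as the sklearn-style
:class:`FuzzyCMeans` estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils import check_random_state
from statsmodels.stats.multitest import multipletests

CLUSTER_NAMES = ("MPP/CDP", "MPP", "CDP", "pan-DC", "cDC", "pDC")


class ExpressionMatrix:
    """genes x samples log2 expression with replicate-group labels."""

    def __init__(
        self,
        values: pd.DataFrame,
        group_map: Mapping[str, str],
    ):
        if values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        unknown = set(values.columns) - set(group_map)
        if unknown:
            raise ValueError(f"samples without group label: {sorted(unknown)}")
        self.values = values.astype(float)
        self.group_map = dict(group_map)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def states(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.group_map[s]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_of(self, state: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_map[s] == state]

    def state_means(self, states: Sequence[str] | None = None) -> pd.DataFrame:
        """genes x states matrix of replicate-group means."""
        states = list(states) if states is not None else self.states
        return pd.DataFrame(
            {st: self.values[self.samples_of(st)].mean(axis=1) for st in states}
        )

    def write_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(
        cls, path: str | Path, group_map: Mapping[str, str] | None = None
    ) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if group_map is None:
            # sample columns named <state>_rep<k>
            group_map = {c: c.rsplit("_", 1)[0] for c in df.columns}
        return cls(df, group_map)


@dataclass
class DEResult:
    gene_id: str
    log2_fold_change: float
    t_statistic: float
    p_value: float
    adjusted_p: float
    is_de: bool


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    matrix: ExpressionMatrix,
    state_a: str,
    state_b: str,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    method: str = "moderated",
    d0: float = 4.0,
    gate: str = "raw",
) -> list[DEResult]:
    """Per-gene differential expression of ``state_a`` versus ``state_b``.

    log2FC = mean(a) - mean(b). ``method`` is "moderated" (variance
    shrinkage toward the median gene variance, prior weight ``d0``) or
    "welch". ``gate`` selects whether the DE call uses the raw or the
    BH-adjusted p-value.
    """
    from scipy import stats

    for st in (state_a, state_b):
        if st not in matrix.states:
            raise ValueError(f"state {st!r} absent from expression matrix")
        if len(matrix.samples_of(st)) < 2:
            raise ValueError(f"state {st!r} has <2 replicates; DE test impossible")
    if gate not in ("raw", "adjusted"):
        raise ValueError(f"unknown gate {gate!r}")

    a = matrix.values[matrix.samples_of(state_a)].to_numpy()
    b = matrix.values[matrix.samples_of(state_b)].to_numpy()
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    lfc = mean_a - mean_b

    if method == "welch":
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        t = np.nan_to_num(t)
        p = np.where(np.isnan(p), 1.0, p)
    elif method == "moderated":
        var_a = a.var(axis=1, ddof=1)
        var_b = b.var(axis=1, ddof=1)
        df = na + nb - 2
        pooled = ((na - 1) * var_a + (nb - 1) * var_b) / df
        prior = float(np.median(pooled))
        var_mod = (d0 * prior + df * pooled) / (d0 + df)
        # variance floor: exactly-constant genes inherit the prior variance
        var_mod = np.maximum(var_mod, np.finfo(float).tiny)
        se = np.sqrt(var_mod * (1.0 / na + 1.0 / nb))
        t = lfc / se
        p = 2.0 * stats.t.sf(np.abs(t), df + d0)
    else:
        raise ValueError(f"unknown method {method!r}")

    adj = bh_adjust(p)
    gate_p = p if gate == "raw" else adj
    log2_fc_cut = np.log2(fc_threshold)
    de = (np.abs(lfc) > log2_fc_cut) & (gate_p < alpha)
    return [
        DEResult(g, float(lfc[i]), float(t[i]), float(p[i]), float(adj[i]), bool(de[i]))
        for i, g in enumerate(matrix.gene_ids)
    ]


def de_table(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "log2_fold_change": [r.log2_fold_change for r in results],
            "t_statistic": [r.t_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "is_de": [r.is_de for r in results],
        }
    ).set_index("gene_id")


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Bezdek fuzzy c-means clustering.

    Alternates membership and centroid updates for the standard FCM
    objective sum_ik u_ik^m ||x_i - c_k||^2 until the maximum centroid
    shift drops below ``tol``. Centroids are initialized from randomly
    chosen distinct data rows.

    Attributes
    ----------
    cluster_centers_ : (c, p) centroid matrix
    membership_ : (n, c) membership matrix, rows sum to 1
    labels_ : hard labels, argmax membership (ties -> lowest index)
    n_iter_ : iterations run
    converged_ : whether the tolerance was reached within ``max_iter``
    objective_ : trajectory of the FCM objective, one value per iteration
    """

    def __init__(
        self,
        n_clusters: int = 6,
        fuzzifier: float = 2.0,
        tol: float = 1e-6,
        max_iter: int = 500,
        random_state: int | None = 0,
    ):
        self.n_clusters = n_clusters
        self.fuzzifier = fuzzifier
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _memberships(self, X: np.ndarray, centers: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        any_zero = zero.any(axis=1)
        with np.errstate(divide="ignore"):
            inv = d2 ** (-1.0 / (self.fuzzifier - 1.0))
        u = np.empty_like(d2)
        ok = ~any_zero
        u[ok] = inv[ok] / inv[ok].sum(axis=1, keepdims=True)
        # a point sitting exactly on >=1 centroids splits among those
        u[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
        return u

    def fit(self, X, y=None) -> "FuzzyCMeans":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, _ = X.shape
        c = self.n_clusters
        if c > n:
            raise ValueError(f"n_clusters={c} exceeds n_samples={n}")
        if self.fuzzifier <= 1.0:
            raise ValueError("fuzzifier must be > 1")
        rng = check_random_state(self.random_state)
        # distinct starting rows where possible
        uniq = np.unique(X, axis=0)
        if len(uniq) >= c:
            centers = uniq[rng.choice(len(uniq), size=c, replace=False)].copy()
        else:
            centers = X[rng.choice(n, size=c, replace=False)].copy()

        objective: list[float] = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            u = self._memberships(X, centers)
            um = u**self.fuzzifier
            new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
            d2 = ((X[:, None, :] - new_centers[None, :, :]) ** 2).sum(axis=2)
            objective.append(float((um * d2).sum()))
            shift = float(np.abs(new_centers - centers).max())
            centers = new_centers
            if shift < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"fuzzy c-means did not converge in {self.max_iter} iterations",
                RuntimeWarning,
                stacklevel=2,
            )
        self.cluster_centers_ = centers
        self.membership_ = self._memberships(X, centers)
        self.labels_ = np.argmax(self.membership_, axis=1)
        self.n_iter_ = it
        self.converged_ = converged
        self.objective_ = np.asarray(objective)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


@dataclass
class ClusterAssignment:
    gene_id: str
    membership: np.ndarray
    hard_label: str


def standardize_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Row z-score; constant rows map to all-zero profiles."""
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0).replace(0.0, 1.0)
    return df.sub(mu, axis=0).div(sd, axis=0)


def fuzzy_cmeans(
    de_matrix: pd.DataFrame,
    c: int = 6,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = 0,
    cluster_names: Sequence[str] | None = None,
    standardize: bool = True,
) -> list[ClusterAssignment]:
    """Cluster gene state-mean profiles into ``c`` fuzzy clusters.

    Rows are z-scored first so clustering follows profile shape rather
    than expression magnitude. ``cluster_names``, when given, labels the
    fitted clusters by index; by default labels are the cluster index as a
    string (fitted cluster order is arbitrary, so biological names such as
    :data:`CLUSTER_NAMES` should only be attached after inspecting the
    centroids).
    """
    X = standardize_rows(de_matrix) if standardize else de_matrix
    est = FuzzyCMeans(
        n_clusters=c, fuzzifier=fuzzifier, tol=tol, max_iter=max_iter, random_state=seed
    ).fit(X.to_numpy())
    names = list(cluster_names) if cluster_names is not None else [
        str(k) for k in range(c)
    ]
    if len(names) != c:
        raise ValueError("cluster_names length must equal c")
    return [
        ClusterAssignment(g, est.membership_[i].copy(), names[int(est.labels_[i])])
        for i, g in enumerate(de_matrix.index)
    ]


def cluster_signal_summary(
    assignment: Sequence[ClusterAssignment],
    signal_matrices: Mapping[str, pd.DataFrame],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Geometric-mean signal per (cluster, mark, state).

    For each cluster and each mark's genes x states signal matrix, the
    summary is exp(mean(log(signal + pseudocount))) - pseudocount over the
    cluster's member genes. Empty clusters yield NaN, not zero.
    """
    labels = sorted({a.hard_label for a in assignment})
    members: dict[str, list[str]] = {lab: [] for lab in labels}
    for a in assignment:
        members[a.hard_label].append(a.gene_id)
    rows = []
    for lab in labels:
        genes = members[lab]
        for mark, sig in signal_matrices.items():
            missing = set(genes) - set(sig.index)
            if missing:
                raise KeyError(
                    f"genes absent from {mark} signal matrix: {sorted(missing)[:5]}"
                )
            for state in sig.columns:
                vals = sig.loc[genes, state].to_numpy(dtype=float)
                if len(vals) == 0:
                    gm = np.nan
                else:
                    gm = float(np.exp(np.mean(np.log(vals + pseudocount))) - pseudocount)
                rows.append(
                    {"cluster": lab, "mark": mark, "state": state, "geometric_mean": gm}
                )
    return pd.DataFrame(rows)
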