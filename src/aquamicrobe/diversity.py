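"""Alpha/beta diversity: rarefaction, Shannon index, ordination, PERMANOVA.

Rarefaction subsamples each sample without replacement to a common depth
(default 9000 reads) so diversity comparisons are not confounded by library
size. Beta diversity uses Bray-Curtis dissimilarity on rarefied counts by
default (configurable), ordinated by classical principal-coordinates
analysis. Variance in the distance matrix is partitioned across design
factors by a sequential (Type I) multi-term PERMANOVA with free permutation
of sample labels, supporting interaction terms — the decomposition used to
attribute beta-diversity to compartment, inoculum and their interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "rarefy",
    "rarefy_table",
    "shannon",
    "rarefaction_curve",
    "bray_curtis",
    "pcoa",
    "permanova",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarities with a zero diagonal."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape does not match ids")
        if np.abs(d - d.T).max() > 1e-12:
            raise ValueError("distance matrix not symmetric")
        if np.abs(np.diag(d)).max() > 1e-12:
            raise ValueError("distance matrix diagonal not zero")
        if d.min() < 0:
            raise ValueError("negative distance")
        self.data = d

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class PermanovaResult:
    """Sequential variance partition of a distance matrix.

    ``table`` has one row per term plus 'Residual', with columns
    df, sum_sq, r_squared, pseudo_f, p_value (NaN for the residual).
    """

    table: pd.DataFrame
    n_permutations: int

    def r_squared(self, term: str) -> float:
        return float(self.table.loc[term, "r_squared"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p_value"])


def rarefy(
    counts_row: pd.Series | np.ndarray,
    depth: int,
    seed: int | np.random.Generator = 0,
    sample_id: str | None = None,
) -> pd.Series | np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement."""
    values = np.asarray(counts_row, dtype=np.int64)
    total = int(values.sum())
    if depth > total:
        name = sample_id or getattr(counts_row, "name", None) or "<sample>"
        raise ValueError(f"rarefaction depth {depth} exceeds library size {total} of {name}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = rng.multivariate_hypergeometric(values, depth)
    if isinstance(counts_row, pd.Series):
        return pd.Series(out, index=counts_row.index, name=counts_row.name)
    return out


def rarefy_table(counts: pd.DataFrame, depth: int, seed: int = 0) -> pd.DataFrame:
    """Rarefy every sample (row) of a count table to a common depth."""
    rng = np.random.default_rng(seed)
    rows = [rarefy(counts.loc[s], depth, rng, sample_id=str(s)) for s in counts.index]
    return pd.DataFrame(rows, index=counts.index, columns=counts.columns)


def shannon(counts_row: pd.Series | np.ndarray) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats), over positive taxa."""
    values = np.asarray(counts_row, dtype=float)
    total = values.sum()
    if total <= 0:
        raise ValueError("Shannon index of an all-zero sample")
    p = values[values > 0] / total
    return float(-(p * np.log(p)).sum())


def rarefaction_curve(
    counts_row: pd.Series | np.ndarray,
    depths: list[int],
    n_reps: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Mean Shannon index after subsampling to each depth (n_reps each)."""
    rng = np.random.default_rng(seed)
    means = []
    for depth in depths:
        means.append(
            float(np.mean([shannon(rarefy(counts_row, depth, rng)) for _ in range(n_reps)]))
        )
    return pd.Series(means, index=pd.Index(depths, name="depth"), name="shannon")


def bray_curtis(counts: pd.DataFrame, metric: str = "braycurtis") -> DistanceMatrix:
    """Pairwise Bray-Curtis (or jaccard/euclidean) distances between samples."""
    x = counts.to_numpy(dtype=float)
    if (x.sum(axis=1) == 0).any():
        bad = counts.index[x.sum(axis=1) == 0].tolist()
        raise ValueError(f"all-zero samples in count table: {bad}")
    if metric == "jaccard":
        d = pdist(x > 0, metric="jaccard")
    else:
        d = pdist(x, metric=metric)
    return DistanceMatrix(list(map(str, counts.index)), squareform(d))


def _gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G = -1/2 J D^2 J."""
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(distance: DistanceMatrix) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Classical scaling of a distance matrix.

    Returns (coordinates, eigenvalues, proportions). Coordinates span the
    axes with positive eigenvalues, ordered by eigenvalue; negative
    eigenvalues are reported in the eigenvalue series but excluded from the
    coordinates and from the per-axis variance proportions (each positive
    eigenvalue over the positive sum).
    """
    n = len(distance)
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    g = _gower_center(distance.data)
    evals, evecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(evals.max(), 1.0)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    coord_df = pd.DataFrame(coords, index=distance.ids, columns=axes)
    eig = pd.Series(evals, index=[f"PC{i + 1}" for i in range(n)], name="eigenvalue")
    proportions = pd.Series(
        evals[pos] / evals[pos].sum(), index=axes, name="proportion_explained"
    )
    return coord_df, eig, proportions


def _term_design(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Centered dummy design for one term; 'a:b' builds an interaction."""
    parts = term.split(":")
    mats = []
    for col in parts:
        if col not in metadata.columns:
            raise KeyError(f"term {term!r}: column {col!r} not in metadata")
        series = metadata[col]
        if series.dtype.kind in "biufc" and series.nunique() > 2:
            mats.append(series.to_numpy(dtype=float)[:, None])
        else:
            levels = pd.unique(series)
            if len(levels) < 2:
                raise ValueError(f"term {col!r} has a single level")
            dummies = pd.get_dummies(series.astype(str), drop_first=True)
            mats.append(dummies.to_numpy(dtype=float))
    x = mats[0]
    for m in mats[1:]:
        x = np.einsum("ij,ik->ijk", x, m).reshape(len(metadata), -1)
    return x - x.mean(axis=0)


def _hat(x: np.ndarray) -> np.ndarray:
    """Projection matrix onto the column space of [1, x]."""
    n = x.shape[0]
    design = np.column_stack([np.ones(n), x])
    q, r = np.linalg.qr(design)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def permanova(
    distance: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential (Type I) multi-term PERMANOVA with free label permutation.

    Terms enter in the given order; an interaction is written 'a:b'. For
    each term, SS is the increment in tr(H G) over the previous model, the
    pseudo-F uses the full-model residual, and the p-value is
    (1 + #{F_perm >= F_obs}) / (1 + n_perm). Term R-squared values plus the
    residual sum to 1.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    meta = metadata.copy()
    meta.index = meta.index.map(str)
    meta = meta.loc[distance.ids]
    n = len(distance)
    g = _gower_center(distance.data)
    total_ss = float(np.trace(g))

    designs = [_term_design(meta, t) for t in terms]
    dfs = [np.linalg.matrix_rank(d) for d in designs]
    hats = []
    cum = None
    for d in designs:
        cum = d if cum is None else np.column_stack([cum, d])
        hats.append(_hat(cum))

    def term_ss(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        traces = np.array([float(np.sum(h * gmat)) for h in hats])
        ss = np.diff(np.concatenate(([0.0], traces)))
        resid = float(np.trace(gmat)) - traces[-1]
        return ss, resid

    ss_obs, resid_obs = term_ss(g)
    df_resid = n - 1 - sum(dfs)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    f_obs = (ss_obs / np.array(dfs)) / (resid_obs / df_resid)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        p = rng.permutation(n)
        gp = g[np.ix_(p, p)]
        ss_p, resid_p = term_ss(gp)
        f_p = (ss_p / np.array(dfs)) / (resid_p / df_resid)
        exceed += f_p >= f_obs - 1e-12
    p_vals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for t, df, ss, f, p in zip(terms, dfs, ss_obs, f_obs, p_vals):
        rows.append({"term": t, "df": df, "sum_sq": ss, "r_squared": ss / total_ss,
                     "pseudo_f": f, "p_value": p})
    rows.append({"term": "Residual", "df": df_resid, "sum_sq": resid_obs,
                 "r_squared": resid_obs / total_ss, "pseudo_f": np.nan, "p_value": np.nan})
    table = pd.DataFrame(rows).set_index("term")
    if abs(table["r_squared"].sum() - 1.0) > 1e-9:
        raise AssertionError("PERMANOVA R-squared values do not sum to 1")
    return PermanovaResult(table, n_perm)
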