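"""Expectation-maximization resolution of multi-mapped long reads.

Error-prone full-length 16S reads map ambiguously, often to dozens of
near-identical references. Reference abundances theta are estimated by EM on
a sparse read x reference compatibility matrix (per-read weights proportional
to alignment identity, or to an alignment score when one is available):

    E-step:  gamma[i, r] = theta[r] * w[i, r] / sum_r' theta[r'] * w[i, r']
    M-step:  theta[r]    = sum_i gamma[i, r] / n

No gene-length correction is applied — the 16S amplicon has a fixed length.
A naive baseline assigns each read wholly to its best-scoring reference.
Low-abundance references (expected counts below a read-count cutoff,
default 300) are treated as spurious mappings and dropped, and abundances
are collapsed onto a taxonomic rank (default genus) for downstream analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .io_formats import AlignmentRecord, TaxonomyEntry

__all__ = [
    "QuantParams",
    "CompatibilityMatrix",
    "AbundanceEstimate",
    "build_compatibility",
    "naive_count",
    "em_quantify",
    "apply_cutoff",
    "collapse_taxonomy",
    "quantify_sample",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantParams:
    max_alignments: int = 100
    tolerance: float = 1e-6  # on max |delta theta|
    max_iterations: int = 1000
    count_cutoff: float = 300.0
    cutoff_inclusive: bool = True
    uniform_weights: bool = False  # ignore scores, weight all alignments equally

    def __post_init__(self) -> None:
        if min(self.max_alignments, self.tolerance, self.max_iterations) <= 0:
            raise ValueError("QuantParams values must be positive")


@dataclass
class CompatibilityMatrix:
    """Sparse per-read weights over candidate references (rows sum to 1)."""

    weights: sparse.csr_matrix  # n_reads x n_refs
    read_ids: list[str]
    ref_ids: list[str]
    raw_scores: sparse.csr_matrix  # pre-normalization scores, same pattern
    n_unaligned: int = 0

    @property
    def n_reads(self) -> int:
        return self.weights.shape[0]

    @property
    def n_refs(self) -> int:
        return self.weights.shape[1]


@dataclass
class AbundanceEstimate:
    """EM output: relative abundances and expected read counts per reference."""

    theta: pd.Series  # ref_id -> relative abundance
    n_reads: int
    log_likelihood: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = True

    @property
    def expected_counts(self) -> pd.Series:
        return self.theta * self.n_reads


def _alignment_score(a: AlignmentRecord, uniform: bool) -> float:
    if uniform:
        return 1.0
    if a.align_score is not None:
        return max(float(a.align_score), 0.0)
    return a.identity


def build_compatibility(
    alignments: list[AlignmentRecord],
    params: QuantParams = QuantParams(),
    ref_ids: list[str] | None = None,
) -> CompatibilityMatrix:
    """Build the per-read weight matrix from alignments.

    Per read, duplicate (read, ref) pairs keep their best score, the top
    ``max_alignments`` by score are retained, and weights are normalized to
    sum to one. When ``ref_ids`` is given (e.g. from a bound taxonomy), an
    alignment to an unknown reference is an error.
    """
    known = set(ref_ids) if ref_ids is not None else None
    per_read: dict[str, dict[str, float]] = {}
    for a in alignments:
        if known is not None and a.ref_id not in known:
            raise ValueError(f"alignment references unknown reference {a.ref_id!r}")
        s = _alignment_score(a, params.uniform_weights)
        best = per_read.setdefault(a.read_id, {})
        if s > best.get(a.ref_id, -1.0):
            best[a.ref_id] = s

    if ref_ids is None:
        ref_ids = sorted({r for hits in per_read.values() for r in hits})
    ref_index = {r: j for j, r in enumerate(ref_ids)}

    read_ids, rows, cols, w_data, s_data = [], [], [], [], []
    n_dropped = 0
    for i, (read_id, hits) in enumerate(per_read.items()):
        items = sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))[: params.max_alignments]
        total = sum(s for _, s in items)
        if total <= 0:
            n_dropped += 1
            continue
        row = len(read_ids)
        read_ids.append(read_id)
        for r, s in items:
            rows.append(row)
            cols.append(ref_index[r])
            w_data.append(s / total)
            s_data.append(s)
    shape = (len(read_ids), len(ref_ids))
    weights = sparse.csr_matrix((w_data, (rows, cols)), shape=shape)
    raw = sparse.csr_matrix((s_data, (rows, cols)), shape=shape)
    return CompatibilityMatrix(weights, read_ids, list(ref_ids), raw, n_unaligned=n_dropped)


def naive_count(matrix: CompatibilityMatrix) -> pd.Series:
    """Highest-scoring-match counting: each read contributes 1 to its best
    reference; exact ties break to the lexicographically smallest ref_id."""
    counts = np.zeros(matrix.n_refs, dtype=np.int64)
    scores = matrix.raw_scores
    for i in range(matrix.n_reads):
        start, end = scores.indptr[i], scores.indptr[i + 1]
        idx = scores.indices[start:end]
        vals = scores.data[start:end]
        tied = idx[vals == vals.max()]
        if tied.size == 1:
            counts[tied[0]] += 1
        else:
            names = [matrix.ref_ids[j] for j in tied]
            counts[tied[int(np.argmin(np.array(names, dtype=object)))]] += 1
    return pd.Series(counts, index=matrix.ref_ids)


def em_quantify(
    matrix: CompatibilityMatrix, params: QuantParams = QuantParams()
) -> AbundanceEstimate:
    """Run EM to a fixed point of the multi-mapping assignment problem.

    theta starts uniform over references with at least one positive weight;
    iteration stops when max |delta theta| < tolerance or at the iteration
    cap (returned with ``converged=False`` and a warning). The log-likelihood
    sum_i log sum_r theta[r] w[i, r] is recorded every iteration and is
    non-decreasing.
    """
    if matrix.n_reads == 0:
        raise ValueError("empty compatibility matrix")
    W = matrix.weights
    n = matrix.n_reads
    active = np.asarray((W > 0).sum(axis=0)).ravel() > 0
    theta = np.where(active, 1.0 / active.sum(), 0.0)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, params.max_iterations + 1):
        denom = W @ theta  # (n,)
        trace.append(float(np.log(denom).sum()))
        new_theta = theta * (W.T @ (1.0 / denom)) / n
        new_theta = np.where(active, new_theta, 0.0)
        new_theta /= new_theta.sum()
        delta = np.abs(new_theta - theta).max()
        theta = new_theta
        if delta < params.tolerance:
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge in %d iterations", params.max_iterations)
    # final log-likelihood at the returned theta
    trace.append(float(np.log(W @ theta).sum()))
    if any(b < a - 1e-9 for a, b in zip(trace, trace[1:])):
        raise AssertionError("EM log-likelihood decreased")
    return AbundanceEstimate(
        theta=pd.Series(theta, index=matrix.ref_ids),
        n_reads=n,
        log_likelihood=trace,
        n_iterations=it,
        converged=converged,
    )


def apply_cutoff(
    estimate: AbundanceEstimate, count_cutoff: float = 300.0, inclusive: bool = True
) -> AbundanceEstimate:
    """Drop references whose expected read counts fall below the cutoff.

    Expected counts are rounded half-up before thresholding (read-count
    units); surviving counts are left unchanged — no renormalization, they
    feed downstream as-is. ``inclusive`` keeps counts exactly at the cutoff.
    """
    counts = np.floor(estimate.expected_counts + 0.5)
    keep = counts >= count_cutoff if inclusive else counts > count_cutoff
    if not keep.any():
        logger.warning("abundance cutoff %.0f removed every reference", count_cutoff)
    return AbundanceEstimate(
        theta=estimate.theta[keep],
        n_reads=estimate.n_reads,
        log_likelihood=estimate.log_likelihood,
        n_iterations=estimate.n_iterations,
        converged=estimate.converged,
    )


def collapse_taxonomy(
    counts: pd.Series | AbundanceEstimate,
    taxonomy: dict[str, TaxonomyEntry],
    rank: str = "genus",
) -> pd.Series:
    """Sum per-reference counts within each taxon at ``rank``.

    References unassigned at the rank pool into an explicit "unclassified"
    bin; a reference without any taxonomy entry is an error.
    """
    if isinstance(counts, AbundanceEstimate):
        counts = counts.expected_counts
    labels = []
    for ref_id in counts.index:
        if ref_id not in taxonomy:
            raise KeyError(f"no taxonomy entry for reference {ref_id!r}")
        labels.append(taxonomy[ref_id].rank(rank) or "unclassified")
    out = counts.groupby(pd.Index(labels, name=rank)).sum()
    return out.sort_index()


def quantify_sample(
    alignments: list[AlignmentRecord],
    taxonomy: dict[str, TaxonomyEntry],
    params: QuantParams = QuantParams(),
    rank: str = "genus",
    method: str = "em",
    cutoff: float | None = None,
) -> pd.Series:
    """One-call quantification: compatibility -> EM/naive -> cutoff -> collapse."""
    matrix = build_compatibility(alignments, params, ref_ids=sorted(taxonomy))
    if method == "em":
        est = em_quantify(matrix, params)
        est = apply_cutoff(
            est,
            params.count_cutoff if cutoff is None else cutoff,
            inclusive=params.cutoff_inclusive,
        )
        ref_counts = np.floor(est.expected_counts + 0.5)
    elif method == "naive":
        ref_counts = naive_count(matrix).astype(float)
        thr = params.count_cutoff if cutoff is None else cutoff
        ref_counts = ref_counts[
            ref_counts >= thr if params.cutoff_inclusive else ref_counts > thr
        ]
    else:
        raise ValueError(f"unknown method {method!r}; use 'em' or 'naive'")
    return collapse_taxonomy(ref_counts, taxonomy, rank)
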