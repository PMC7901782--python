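"""Cross-technology validation of long-read abundance estimates.

Compares an estimated abundance table against a ground-truth table from an
independent platform: rank-wise log-log regression and Spearman concordance
on taxa observed by both technologies, quantification of spurious mappings
(taxa present only in the estimate), and the fraction of spurious taxa a
read-count abundance cutoff removes. A watch-list detector reports
presence/absence of taxa of interest (default: the canonical nitrifiers
Nitrosomonas, Nitrobacter and Nitrospira) before and after the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcordanceResult",
    "SpuriousReport",
    "NITRIFIER_WATCH_LIST",
    "compare_platforms",
    "spurious_fraction_removed",
    "detect_taxa",
]

NITRIFIER_WATCH_LIST = ("Nitrosomonas", "Nitrobacter", "Nitrospira")


@dataclass
class ConcordanceResult:
    rank: str
    n_shared_taxa: int
    n_spurious: int
    slope: float
    intercept: float
    r_squared: float
    spearman_rho: float
    p_value: float

    @property
    def defined(self) -> bool:
        return not np.isnan(self.r_squared)


@dataclass
class SpuriousReport:
    rank: str
    cutoff: float
    spurious: pd.Series  # taxon -> abundance in the estimate
    fraction_removed: float
    vacuous: bool = False  # no spurious taxa existed


def _positive(series: pd.Series) -> pd.Series:
    s = series[series > 0]
    return s[~s.index.isna()] if s.index.hasnans else s


def compare_platforms(
    estimate: pd.Series, truth: pd.Series, rank: str = "genus", relative: bool = False
) -> ConcordanceResult:
    """Rank-wise concordance between an estimate and a ground-truth table.

    Both inputs are taxon-indexed abundances already collapsed to ``rank``.
    The regression (log10 abundance vs log10 abundance) and Spearman rho use
    only taxa observed (abundance > 0) on both platforms; zeros never enter
    the log. Spurious = taxa positive in the estimate but absent from the
    truth. With fewer than 3 shared taxa the regression fields are NaN.
    ``relative=True`` compares proportions instead of raw counts.
    """
    est = _positive(estimate.astype(float))
    tru = _positive(truth.astype(float))
    if relative:
        est = est / est.sum()
        tru = tru / tru.sum()
    shared = est.index.intersection(tru.index)
    spurious = est.index.difference(tru.index)
    if len(shared) < 3:
        return ConcordanceResult(
            rank, len(shared), len(spurious),
            np.nan, np.nan, np.nan, np.nan, np.nan,
        )
    x = np.log10(tru.loc[shared].to_numpy())
    y = np.log10(est.loc[shared].to_numpy())
    fit = stats.linregress(x, y)
    rho = stats.spearmanr(x, y).statistic
    return ConcordanceResult(
        rank=rank,
        n_shared_taxa=len(shared),
        n_spurious=len(spurious),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        spearman_rho=float(rho),
        p_value=float(fit.pvalue),
    )


def spurious_fraction_removed(
    estimate: pd.Series, truth: pd.Series, rank: str = "genus", cutoff: float = 300.0
) -> SpuriousReport:
    """Fraction of spurious taxa an abundance cutoff removes.

    Spurious taxa are those positive in the estimate but absent from the
    truth at this rank; the cutoff removes those with abundance strictly
    below it (retention at the cutoff is inclusive, matching the
    quantification stage). With no spurious taxa the fraction is defined as
    1 and flagged vacuous.
    """
    est = _positive(estimate.astype(float))
    tru = _positive(truth.astype(float))
    spurious = est.loc[est.index.difference(tru.index)].sort_index()
    if spurious.empty:
        return SpuriousReport(rank, cutoff, spurious, 1.0, vacuous=True)
    removed = (spurious < cutoff).sum()
    return SpuriousReport(rank, cutoff, spurious, float(removed / len(spurious)))


def detect_taxa(
    table: pd.DataFrame | pd.Series,
    watch_list: tuple[str, ...] = NITRIFIER_WATCH_LIST,
    cutoff: float = 300.0,
) -> pd.DataFrame:
    """Presence/abundance of watched taxa, before and after the cutoff.

    ``table`` is a samples x taxa count frame (or a single taxon-indexed
    Series treated as one sample). Returns one row per (sample, taxon) with
    found flags pre- and post-cutoff.
    """
    if not watch_list:
        raise ValueError("watch_list must be non-empty")
    if isinstance(table, pd.Series):
        table = table.to_frame().T
        table.index = ["sample"]
    rows = []
    for sample, counts in table.iterrows():
        for taxon in watch_list:
            abundance = float(counts.get(taxon, 0.0))
            rows.append(
                {
                    "sample_id": sample,
                    "taxon": taxon,
                    "abundance": abundance,
                    "found": abundance > 0,
                    "found_after_cutoff": abundance >= cutoff,
                }
            )
    return pd.DataFrame(rows)
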