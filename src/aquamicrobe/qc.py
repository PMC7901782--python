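"""Read trimming and filtering for long 16S amplicon reads.

Rules: the first 10 bases of the 5' end are trimmed, reads are capped at
1.5 kbp (truncation, not removal), and a read is discarded if it has more
than 200 expected errors under the Illumina quality model or more than two
ambiguous (N) base calls. Threshold comparisons are strict, so boundary
reads pass. Expected errors are computed on the post-trim qualities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import ReadRecord

__all__ = ["QCParams", "QCReport", "expected_errors", "trim_read", "filter_reads", "run_qc"]


@dataclass(frozen=True)
class QCParams:
    trim5: int = 10
    max_len: int = 1500
    max_expected_errors: float = 200.0
    max_n: int = 2

    def __post_init__(self) -> None:
        if min(self.trim5, self.max_len, self.max_expected_errors, self.max_n) < 0:
            raise ValueError("QC parameters must be non-negative")


@dataclass
class QCReport:
    """Per-batch filter tally. A read failing both rules counts once, under
    the first-failing-rule order: expected errors, then N count."""

    n_input: int = 0
    n_dropped_short: int = 0
    n_fail_ee: int = 0
    n_fail_n: int = 0
    n_pass: int = 0

    @property
    def pass_fraction(self) -> float:
        return self.n_pass / self.n_input if self.n_input else float("nan")

    def check(self) -> None:
        total = self.n_pass + self.n_fail_ee + self.n_fail_n + self.n_dropped_short
        if total != self.n_input:
            raise AssertionError(f"QC tally {total} != n_input {self.n_input}")


def expected_errors(qualities: Sequence[int] | np.ndarray) -> float:
    """Sum of per-base error probabilities, sum_i 10^(-Q_i / 10)."""
    q = np.asarray(qualities, dtype=float)
    if q.size == 0:
        raise ValueError("expected_errors of empty quality vector")
    if q.min() < 0:
        raise ValueError("negative Phred score")
    return float(np.sum(10.0 ** (-q / 10.0)))


def trim_read(read: ReadRecord, params: QCParams = QCParams()) -> ReadRecord | None:
    """Trim the 5' end, then truncate to the maximum length.

    Returns None (read dropped) when the read is not longer than the 5'
    trim; qualities stay in register with the sequence.
    """
    if len(read) <= params.trim5:
        return None
    end = params.trim5 + params.max_len
    return ReadRecord(
        read.read_id,
        read.sequence[params.trim5:end],
        read.qualities[params.trim5:end],
    )


def filter_reads(
    reads: Iterable[ReadRecord], params: QCParams = QCParams()
) -> tuple[list[ReadRecord], QCReport]:
    """Apply the expected-error and ambiguous-base filters to trimmed reads.

    A read passes iff expected_errors <= max_expected_errors and
    count('N') <= max_n (both comparisons strict on failure).
    """
    report = QCReport()
    passed: list[ReadRecord] = []
    for read in reads:
        report.n_input += 1
        if expected_errors(read.qualities) > params.max_expected_errors:
            report.n_fail_ee += 1
        elif read.sequence.count("N") > params.max_n:
            report.n_fail_n += 1
        else:
            report.n_pass += 1
            passed.append(read)
    report.check()
    return passed, report


def run_qc(
    reads: Iterable[ReadRecord], params: QCParams = QCParams()
) -> tuple[list[ReadRecord], QCReport]:
    """Trim then filter a batch, tallying short-read drops in the report."""
    trimmed: list[ReadRecord] = []
    n_short = 0
    n_input = 0
    for read in reads:
        n_input += 1
        t = trim_read(read, params)
        if t is None:
            n_short += 1
        else:
            trimmed.append(t)
    passed, report = filter_reads(trimmed, params)
    report.n_input = n_input
    report.n_dropped_short = n_short
    report.check()
    return passed, report
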