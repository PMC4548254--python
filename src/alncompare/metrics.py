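"""Specificity/accuracy metrics and the paired percentile bootstrap.

Per aligner, with TP/FP/TN counted over the classified reads (false
negatives are deliberately not part of the design):

    specificity = TN / (TN + FP)          (true-negative rate)
    accuracy    = (TP + TN) / (TP + FP + TN)

The between-aligner differences (A - B) are assessed with a paired
percentile bootstrap: reads — i.e. their (label_a, label_b) outcome
pairs — are resampled with replacement, keeping the pairing, and both
metrics are recomputed per replicate. The confidence interval is the
empirical percentile interval of the replicate differences; a
difference is significant when its interval excludes zero. Defaults are
10,000 replicates at the 95% level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .errors import UndefinedMetricError
from .scenarios import ComparisonTally, Label

logger = logging.getLogger(__name__)

DEFAULT_N_BOOT = 10_000
DEFAULT_LEVEL = 0.95
#: Default bootstrap seed; fixed so repeated runs of the same comparison
#: reproduce the same intervals unless the user chooses otherwise.
DEFAULT_SEED = 20_150_101

#: Integer codes for vectorised resampling.
_CODE = {Label.TP: 0, Label.FP: 1, Label.TN: 2, Label.NONE: 3}

#: Replicates per chunk when resampling; bounds peak memory at roughly
#: chunk * n_reads * 8 bytes without affecting results.
_CHUNK = 256


def specificity(tp: int, fp: int, tn: int) -> float:
    """True-negative rate TN / (TN + FP); TP does not enter."""
    if tn + fp == 0:
        raise UndefinedMetricError("specificity undefined: TN + FP == 0")
    return tn / (tn + fp)


def accuracy(tp: int, fp: int, tn: int) -> float:
    """(TP + TN) / (TP + FP + TN), with false negatives excluded."""
    if tp + fp + tn == 0:
        raise UndefinedMetricError("accuracy undefined: all counts are 0")
    return (tp + tn) / (tp + fp + tn)


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimates, difference CIs and significance flags."""

    spec_a: float
    spec_b: float
    acc_a: float
    acc_b: float
    diff_spec: float
    diff_acc: float
    ci_spec: Tuple[float, float]
    ci_acc: Tuple[float, float]
    n_boot: int
    level: float
    seed: int
    significant_spec: bool
    significant_acc: bool
    n_dropped_spec: int = 0
    n_dropped_acc: int = 0

    @property
    def verdict(self) -> str:
        """Joint decision: a side is selected only when BOTH metrics
        differ significantly in its favour; one-sided significance is
        'mixed'; otherwise no significant difference."""
        if self.significant_spec and self.significant_acc:
            same_dir = (self.ci_spec[0] > 0) == (self.ci_acc[0] > 0)
            if same_dir:
                return "A" if self.ci_spec[0] > 0 else "B"
            return "mixed"
        if self.significant_spec or self.significant_acc:
            return "mixed"
        return "no significant difference"


def _encode(outcomes: Sequence[Tuple[Label, Label]]) -> Tuple[np.ndarray, np.ndarray]:
    a = np.fromiter((_CODE[la] for la, _ in outcomes), dtype=np.int8,
                    count=len(outcomes))
    b = np.fromiter((_CODE[lb] for _, lb in outcomes), dtype=np.int8,
                    count=len(outcomes))
    return a, b


def _tally_codes(codes: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row TP/FP/TN counts for a (replicates, reads) code matrix."""
    tp = (codes == 0).sum(axis=1)
    fp = (codes == 1).sum(axis=1)
    tn = (codes == 2).sum(axis=1)
    return tp, fp, tn


def bootstrap_difference(
    per_read_outcomes: Sequence[Tuple[Label, Label]],
    n_boot: int = DEFAULT_N_BOOT,
    level: float = DEFAULT_LEVEL,
    seed: int = DEFAULT_SEED,
) -> BootstrapResult:
    """Paired bootstrap CIs for the specificity and accuracy differences.

    Point estimates come from the unresampled outcomes; the intervals
    from ``n_boot`` with-replacement resamples of reads. Reads carrying
    a ``NONE`` label on one side (unique-vs-unmapped and
    multi-vs-unmapped scenarios) enter the resampling like any read and
    contribute to the other side's counts only. Replicates where a
    metric's denominator is zero are dropped from that metric's
    percentile computation (the dropped count is reported and logged).

    Deterministic given (outcomes, n_boot, level, seed).
    """
    if not per_read_outcomes:
        raise UndefinedMetricError("no classified reads to resample")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")

    codes_a, codes_b = _encode(per_read_outcomes)
    n = codes_a.size

    def point(codes: np.ndarray) -> Tuple[float, float]:
        tp = int((codes == 0).sum())
        fp = int((codes == 1).sum())
        tn = int((codes == 2).sum())
        return specificity(tp, fp, tn), accuracy(tp, fp, tn)

    spec_a, acc_a = point(codes_a)
    spec_b, acc_b = point(codes_b)

    rng = np.random.default_rng(seed)
    diffs_spec = np.empty(n_boot)
    diffs_acc = np.empty(n_boot)
    for start in range(0, n_boot, _CHUNK):
        m = min(_CHUNK, n_boot - start)
        idx = rng.integers(0, n, size=(m, n))
        ra, rb = codes_a[idx], codes_b[idx]
        tp_a, fp_a, tn_a = _tally_codes(ra)
        tp_b, fp_b, tn_b = _tally_codes(rb)
        with np.errstate(divide="ignore", invalid="ignore"):
            sp_a = tn_a / (tn_a + fp_a)
            sp_b = tn_b / (tn_b + fp_b)
            ac_a = (tp_a + tn_a) / (tp_a + fp_a + tn_a)
            ac_b = (tp_b + tn_b) / (tp_b + fp_b + tn_b)
        diffs_spec[start : start + m] = sp_a - sp_b
        diffs_acc[start : start + m] = ac_a - ac_b

    alpha = 1.0 - level

    def ci(diffs: np.ndarray) -> Tuple[Tuple[float, float], int]:
        valid = diffs[np.isfinite(diffs)]
        n_dropped = diffs.size - valid.size
        if valid.size == 0:
            return (float("nan"), float("nan")), n_dropped
        lo, hi = np.quantile(valid, [alpha / 2, 1 - alpha / 2])
        return (float(lo), float(hi)), n_dropped

    ci_spec, dropped_spec = ci(diffs_spec)
    ci_acc, dropped_acc = ci(diffs_acc)
    if dropped_spec or dropped_acc:
        logger.info(
            "dropped degenerate replicates: %d (specificity), %d (accuracy)",
            dropped_spec,
            dropped_acc,
        )

    def excludes_zero(bounds: Tuple[float, float]) -> bool:
        lo, hi = bounds
        return np.isfinite(lo) and np.isfinite(hi) and (lo > 0 or hi < 0)

    return BootstrapResult(
        spec_a=spec_a,
        spec_b=spec_b,
        acc_a=acc_a,
        acc_b=acc_b,
        diff_spec=spec_a - spec_b,
        diff_acc=acc_a - acc_b,
        ci_spec=ci_spec,
        ci_acc=ci_acc,
        n_boot=n_boot,
        level=level,
        seed=seed,
        significant_spec=excludes_zero(ci_spec),
        significant_acc=excludes_zero(ci_acc),
        n_dropped_spec=dropped_spec,
        n_dropped_acc=dropped_acc,
    )


def bootstrap_from_tally(
    tally: ComparisonTally,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = DEFAULT_LEVEL,
    seed: int = DEFAULT_SEED,
) -> BootstrapResult:
    """Convenience wrapper running the bootstrap on a comparison tally."""
    return bootstrap_difference(
        tally.per_read_outcomes, n_boot=n_boot, level=level, seed=seed
    )
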