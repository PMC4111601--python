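"""Relative quantification (2^-ddCt) and qPCR quality-control calls.

C_T is the cycle at which fluorescence crosses threshold; one extra cycle
means half the template.  Fold changes are computed against a reference
(housekeeping) assay and a calibrator condition.  An "Undetermined" C_T (the
run ended without crossing) is a sentinel: quantification rejects it, while
presence calls map it to the run length (40 cycles).
"""

from __future__ import annotations

import itertools
import math
import statistics
from dataclasses import dataclass

import numpy as np

from .data import UNDETERMINED, QpcrRecord
from .trend import TTestResult, two_sample_t_summary

__all__ = [
    "ddct_fold_change",
    "FoldChange",
    "presence_call",
    "presence_call_summary",
    "PresenceCall",
    "housekeeping_stability",
]


def _require_numeric(values, what: str) -> list[float]:
    vals = list(np.atleast_1d(values))
    out = []
    for v in vals:
        if v == UNDETERMINED:
            raise ValueError(
                f"{what} contains an Undetermined C_T; run presence_call first "
                "and exclude absent assays from quantification"
            )
        out.append(float(v))
    return out


@dataclass(frozen=True)
class FoldChange:
    fold: float
    ddct: float
    sd: float | None  # SD of replicate fold changes, if replicates given


def ddct_fold_change(
    ct_target_sample,
    ct_ref_sample,
    ct_target_calibrator,
    ct_ref_calibrator,
) -> FoldChange:
    """2^-ddCt relative quantification.

    dCt = Ct_target - Ct_reference within each condition; ddCt subtracts the
    calibrator's dCt; the fold change is 2^-ddCt.  Replicate C_T values are
    averaged; the SD is propagated from the replicate sample dCt spread
    (calibrator dCt taken at its mean).
    """
    ts = _require_numeric(ct_target_sample, "target/sample")
    rs = _require_numeric(ct_ref_sample, "reference/sample")
    tc = _require_numeric(ct_target_calibrator, "target/calibrator")
    rc = _require_numeric(ct_ref_calibrator, "reference/calibrator")
    dct_cal = statistics.fmean(tc) - statistics.fmean(rc)
    if len(ts) == len(rs) and len(ts) > 1:
        dcts = [t - r for t, r in zip(ts, rs)]
    else:
        dcts = [statistics.fmean(ts) - statistics.fmean(rs)]
    ddcts = [d - dct_cal for d in dcts]
    ddct = statistics.fmean(ddcts)
    folds = [2.0 ** (-d) for d in ddcts]
    sd = statistics.stdev(folds) if len(folds) > 1 else None
    return FoldChange(fold=2.0 ** (-ddct), ddct=ddct, sd=sd)


@dataclass(frozen=True)
class PresenceCall:
    present: bool
    mean_ct: float
    ttest: TTestResult | None  # vs NTC; None when absent on the C_T cut alone


def presence_call(
    sample: QpcrRecord,
    ntc: QpcrRecord,
    ct_absent_cut: float = 35.0,
    max_cycles: float = 40.0,
    alpha: float = 0.01,
) -> PresenceCall:
    """Absent if mean C_T exceeds the cut; otherwise present iff the C_T
    values differ from the no-template control at p < ``alpha``.

    Undetermined replicates are mapped to ``max_cycles`` for this comparison
    only.
    """
    if not ntc.is_ntc:
        raise ValueError("ntc record must be flagged is_ntc")
    if not ntc.ct:
        raise ValueError("no NTC replicates")

    def as_numbers(rec: QpcrRecord) -> list[float]:
        return [max_cycles if v == UNDETERMINED else float(v) for v in rec.ct]

    obs = as_numbers(sample)
    ref = as_numbers(ntc)
    mean_ct = statistics.fmean(obs)
    if mean_ct > ct_absent_cut:
        return PresenceCall(present=False, mean_ct=mean_ct, ttest=None)
    res = two_sample_t_summary(
        statistics.fmean(ref), statistics.stdev(ref) if len(ref) > 1 else 0.0, max(len(ref), 2),
        mean_ct, statistics.stdev(obs) if len(obs) > 1 else 0.0, max(len(obs), 2),
    )
    return PresenceCall(present=res.p < alpha, mean_ct=mean_ct, ttest=res)


def presence_call_summary(
    mean_ct: float,
    sd_ct: float,
    n: int,
    ntc_mean: float,
    ntc_sd: float,
    n_ntc: int,
    ct_absent_cut: float = 35.0,
    alpha: float = 0.01,
) -> PresenceCall:
    """Presence call from published mean C_T +/- SD summaries (see
    :func:`presence_call` for the rule)."""
    if mean_ct > ct_absent_cut:
        return PresenceCall(present=False, mean_ct=mean_ct, ttest=None)
    res = two_sample_t_summary(ntc_mean, ntc_sd, n_ntc, mean_ct, sd_ct, n)
    return PresenceCall(present=res.p < alpha, mean_ct=mean_ct, ttest=res)


def housekeeping_stability(
    ct_by_condition: dict[str, dict[str, list[float]]],
    alpha: float = 0.05,
) -> tuple[list[tuple[str, bool, float]], str]:
    """Rank candidate reference genes by cross-condition C_T stability.

    ``ct_by_condition[candidate][condition]`` holds replicate C_T values.  A
    candidate is stable iff no pairwise two-sample t across conditions is
    significant at ``alpha``.  Returns (candidate, stable, max |t|) sorted
    with the chosen candidate first: stable ones ranked by smallest max |t|;
    if none is stable the least-unstable candidate is returned with a
    warning-level log entry.
    """
    import logging

    ranked = []
    for cand, conditions in ct_by_condition.items():
        if len(conditions) < 2:
            raise ValueError(f"candidate {cand!r} needs >=2 conditions")
        max_t = 0.0
        stable = True
        for c1, c2 in itertools.combinations(sorted(conditions), 2):
            a, b = conditions[c1], conditions[c2]
            if len(a) < 2 or len(b) < 2:
                raise ValueError(f"candidate {cand!r} needs >=2 replicates per condition")
            res = two_sample_t_summary(
                statistics.fmean(a), statistics.stdev(a), len(a),
                statistics.fmean(b), statistics.stdev(b), len(b),
            )
            max_t = max(max_t, abs(res.t)) if math.isfinite(res.t) else math.inf
            if res.p < alpha:
                stable = False
        ranked.append((cand, stable, max_t))
    ranked.sort(key=lambda r: (not r[1], r[2], r[0]))
    chosen = ranked[0][0]
    if not ranked[0][1]:
        logging.getLogger(__name__).warning(
            "no stable housekeeping candidate; returning least-unstable %r", chosen
        )
    return ranked, chosen
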