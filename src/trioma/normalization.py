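"""Two-stage normalization: quantile equalization, then baseline-anchored SLR.

mRNA/lncRNA chips are quantile normalized; miRNA chips instead use a
detection floor on background-subtracted intensity followed by scaling to a
set of endogenous control probes.  The second stage divides every sample by
the baseline sample (Day 2 for maturation, 0 hr for OGD) and takes log2,
giving the Signal Log Ratio (SLR).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import Channel, ExpressionMatrix, SampleDesign, SLRMatrix

logger = logging.getLogger(__name__)

__all__ = ["quantile_normalize", "mirna_preprocess", "compute_slr"]


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (row-mean of sorted columns) distribution.

    Ties within a column receive the mean of the reference values over their
    rank span, so the operation is idempotent and permutation-equivariant.
    """
    X = m.values
    n_probes, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X, dtype=float)
    for j in range(n_samples):
        col = X[:, j]
        # each value takes the mean of the reference over its tie rank span
        csum = np.concatenate(([0.0], np.cumsum(reference)))
        lo = rankdata(col, method="min").astype(int) - 1
        hi = rankdata(col, method="max").astype(int)
        out[:, j] = (csum[hi] - csum[lo]) / (hi - lo)
    df = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(channel=m.channel, data=df)


def mirna_preprocess(
    m: ExpressionMatrix,
    control_probe_ids: list[str],
    floor: float = 300.0,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Detection-flag and control-normalize a background-subtracted miRNA matrix.

    A probe is flagged detected iff its mean intensity across samples is at
    least ``floor``.  Each sample is then divided by the geometric mean of
    that sample's endogenous-control probe intensities.  Flags are computed
    before scaling, so they are invariant to the control normalization.

    Returns the scaled matrix and a boolean detection Series (all probes
    retained; undetected ones are simply flagged ``False``).
    """
    if m.channel != Channel.MIRNA:
        raise ValueError("mirna_preprocess expects the miRNA channel")
    missing = [p for p in control_probe_ids if p not in m.data.index]
    if missing:
        raise ValueError(f"control probe(s) missing from matrix: {missing}")
    controls = m.data.loc[control_probe_ids]
    if (controls.to_numpy() <= 0).any():
        raise ValueError("control probes must be positive in every sample")
    detected = m.data.mean(axis=1) >= floor
    detected.name = "detected"
    scale = np.exp(np.log(controls.to_numpy(dtype=float)).mean(axis=0))
    df = m.data / scale
    return ExpressionMatrix(channel=m.channel, data=df), detected


def compute_slr(m: ExpressionMatrix, design: SampleDesign) -> SLRMatrix:
    """log2 ratio of every sample to the design's baseline sample.

    Probes with a non-positive intensity in any design sample cannot enter
    log space and are dropped (logged at INFO).
    """
    missing = [s for s in design.sample_ids if s not in m.data.columns]
    if missing:
        raise ValueError(f"design sample(s) missing from matrix: {missing}")
    sub = m.data[design.sample_ids]
    ok = (sub > 0).all(axis=1)
    dropped = sub.index[~ok].tolist()
    if dropped:
        logger.info("dropping %d probe(s) with non-positive intensity: %s",
                    len(dropped), dropped[:10])
    sub = sub.loc[ok]
    slr = np.log2(sub.div(sub[design.baseline], axis=0))
    slr[design.baseline] = 0.0  # exact zero, not just log2(1)
    return SLRMatrix(data=slr, design=design)
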