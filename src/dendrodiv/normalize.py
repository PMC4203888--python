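"""Probe-set summarization and per-array centering/scaling.

Probe-level log intensities are summarized to one probe-set value per array
with the upper-decile statistic (the 90th percentile of the member probes),
then every array is median-centered and scaled by its 10th–90th percentile
range so that arrays from different platforms share a common scale.
Percentiles use linear interpolation between order statistics throughout.
Input is assumed to be on the log scale already; ``log2`` is available for
raw intensities.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd


def upper_decile_summarize(
    probe_values: pd.DataFrame, probe_to_set: Mapping[str, str]
) -> pd.DataFrame:
    """Summarize probe rows to probe-set rows as the per-array 90th percentile.

    ``probe_values`` is indexed by probe id; ``probe_to_set`` assigns each
    probe row to its probe set. Probe sets must be non-empty.
    """
    unknown = [p for p in probe_values.index if p not in probe_to_set]
    if unknown:
        raise KeyError(f"probes without a probe set: {unknown[:5]}")
    groups = probe_values.groupby(
        probe_values.index.map(probe_to_set.__getitem__), sort=True
    )
    out = groups.quantile(0.9, interpolation="linear")
    out.index.name = probe_values.index.name
    return out


def log2_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount) for raw (non-log) intensity matrices."""
    if (matrix.to_numpy() + pseudocount <= 0).any():
        raise ValueError("log2 undefined: values <= -pseudocount present")
    return np.log2(matrix + pseudocount)


def median_center_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Median-center each array and scale by its interdecile (q90 - q10) range.

    After normalization every column has median 0 and q90 - q10 = 1. Raises
    on a degenerate array whose 10th and 90th percentiles coincide.
    """
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in expression matrix")
    med = np.median(values, axis=0)
    q10, q90 = np.percentile(values, [10, 90], axis=0)
    scale = q90 - q10
    degenerate = np.flatnonzero(scale <= 0)
    if degenerate.size:
        names = [str(matrix.columns[i]) for i in degenerate]
        raise ValueError(f"degenerate array(s) with q90 == q10: {names}")
    out = (values - med) / scale
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
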