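"""Relative expression by the Livak 2^-ddCt method.

A qPCR run reports a threshold cycle (Ct) per well.  For each sample the
target gene is normalized to a reference gene (dCt = mean Ct_target -
mean Ct_reference, replicates averaged on the Ct scale), then to a
calibrator sample (ddCt = dCt_sample - dCt_calibrator); the fold change
is 2^-ddCt, with amplification efficiency fixed at 2 as the method's name
implies.  The calibrator's fold change is exactly 1 by construction.
Replicate spread is propagated as sd(dCt) = sqrt(sd_target^2 +
sd_reference^2) and reported as the fold-change band
2^-(ddCt +- sd).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["relative_expression", "fold_difference"]


def relative_expression(table: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Per-sample fold changes relative to a calibrator sample.

    ``table`` needs columns sample, gene ('target'/'reference'), ct (a
    replicate column is conventional but not required).  Returns one row
    per sample: delta_ct, sd_delta_ct, ddct, fold, fold_lo, fold_hi.
    """
    required = {"sample", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    if np.any(table["ct"] <= 0):
        raise ValueError("Ct values must be positive")
    samples = list(dict.fromkeys(table["sample"]))
    if calibrator not in samples:
        raise ValueError(f"calibrator sample {calibrator!r} not in table")

    genes_per_sample = table.groupby("sample")["gene"].agg(set)
    incomplete = [s for s in samples if not {"target", "reference"} <= genes_per_sample[s]]
    if incomplete:
        raise ValueError(f"sample(s) {incomplete} lack Ct values for target or reference gene")

    stats = (
        table.groupby(["sample", "gene"])["ct"].agg(["mean", "std", "count"]).unstack("gene")
    )

    delta_ct = stats["mean"]["target"] - stats["mean"]["reference"]
    sd = np.sqrt(
        stats["std"]["target"].fillna(0.0) ** 2 + stats["std"]["reference"].fillna(0.0) ** 2
    )
    ddct = delta_ct - delta_ct.loc[calibrator]
    fold = 2.0 ** (-ddct)
    out = pd.DataFrame(
        {
            "sample": delta_ct.index,
            "delta_ct": delta_ct.to_numpy(),
            "sd_delta_ct": sd.to_numpy(),
            "ddct": ddct.to_numpy(),
            "fold": fold.to_numpy(),
            "fold_lo": (2.0 ** (-(ddct + sd))).to_numpy(),
            "fold_hi": (2.0 ** (-(ddct - sd))).to_numpy(),
        }
    )
    # preserve input sample order
    out = out.set_index("sample").loc[samples].reset_index()
    return out


def fold_difference(expr_a: float, expr_b: float) -> float:
    """Ratio of two fold changes (e.g. parent A over parent B).

    >>> round(fold_difference(2.99, 0.84), 2)
    3.56
    """
    if expr_b <= 0:
        raise ValueError("denominator expression must be positive")
    return expr_a / expr_b
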