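"""Two-condition expression comparison.

With one library per condition there is no dispersion estimate, so this is a
descriptive outlier screen, not a calibrated differential-expression test:
per-gene log-ratios are standardized over the gene set and flagged beyond a
standard-deviation threshold (primary criterion) and beyond an absolute
fold-change threshold (secondary).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import TxscapeError
from .quantify import ExpressionTable, classify_tiers


def _aligned(table_a: ExpressionTable, table_b: ExpressionTable) -> pd.DataFrame:
    a = table_a.df.set_index("feature_id")
    b = table_b.df.set_index("feature_id")
    if set(a.index) != set(b.index):
        raise TxscapeError("feature sets differ between conditions")
    b = b.loc[a.index]
    return a, b


def compare_conditions(
    table_a: ExpressionTable,
    table_b: ExpressionTable,
    pseudocount: float = 0.1,
    z_threshold: float = 2.5,
    log2fc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log-ratio, z-score and flags between two conditions.

    delta   = log10((tpm_b + c) / (tpm_a + c))
    z       = (delta - mean delta) / SD(delta)        (SD over the table)
    log2fc  = log2((tpm_b + c) / (tpm_a + c))
    is_sd_outlier iff |z| > z_threshold; is_fc_flagged iff |log2fc| >
    log2fc_threshold.
    """
    a, b = _aligned(table_a, table_b)
    if len(a) < 3:
        raise TxscapeError("need at least 3 genes for an SD-based screen")
    tpm_a = a["tpm"].to_numpy()
    tpm_b = b["tpm"].to_numpy()
    ratio = (tpm_b + pseudocount) / (tpm_a + pseudocount)
    delta = np.log10(ratio)
    sd = delta.std()  # population SD: z then has SD exactly 1
    if sd == 0:
        z = np.zeros_like(delta)
    else:
        z = (delta - delta.mean()) / sd
    log2fc = np.log2(ratio)
    return pd.DataFrame(
        {
            "feature_id": a.index,
            "tpm_a": tpm_a,
            "tpm_b": tpm_b,
            "delta": delta,
            "z": z,
            "log2fc": log2fc,
            "is_sd_outlier": np.abs(z) > z_threshold,
            "is_fc_flagged": np.abs(log2fc) > log2fc_threshold,
        }
    ).reset_index(drop=True)


def average_conditions(
    table_a: ExpressionTable, table_b: ExpressionTable
) -> ExpressionTable:
    """Average two conditions gene-wise: mean TPM, summed counts.

    TPM is linear in the per-gene rates, so the averaged table still sums to
    one million.  Tiers are re-derived from the averaged values.
    """
    a, b = _aligned(table_a, table_b)
    df = pd.DataFrame(
        {
            "feature_id": a.index,
            "length": a["length"].to_numpy(),
            "count": a["count"].to_numpy() + b["count"].to_numpy(),
            "tpm": (a["tpm"].to_numpy() + b["tpm"].to_numpy()) / 2.0,
            "is_cds": a["is_cds"].to_numpy(),
        }
    ).reset_index(drop=True)
    fracs = None
    if table_a.category_fractions and table_b.category_fractions:
        keys = set(table_a.category_fractions) | set(table_b.category_fractions)
        fracs = {
            k: (
                table_a.category_fractions.get(k, 0.0)
                + table_b.category_fractions.get(k, 0.0)
            )
            / 2.0
            for k in sorted(keys)
        }
    out = ExpressionTable(
        df,
        condition=f"mean({table_a.condition},{table_b.condition})",
        category_fractions=fracs,
    )
    return classify_tiers(out)


def write_comparison_tsv(comparison: pd.DataFrame, path: str | Path) -> None:
    out = comparison.copy()
    for col in ("tpm_a", "tpm_b", "delta", "z", "log2fc"):
        out[col] = out[col].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)


__all__ = ["compare_conditions", "average_conditions", "write_comparison_tsv"]
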