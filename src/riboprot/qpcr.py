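"""Relative expression from qRT-PCR Ct values (Livak 2^-ΔΔCt method).

Per replicate, ΔCt = Ct(target) − Ct(reference gene); per group,
ΔΔCt = ΔCt − mean ΔCt of the calibrator group, and relative expression
R = 2^−ΔΔCt. The group-level R is computed from the group-mean ΔΔCt, so the
calibrator group's R is exactly 1 by construction; the per-replicate spread
is reported as mean ± SD of the replicate-wise R values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ddct", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("gene", "group", "ct_target", "ct_reference")


def ddct(table: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Relative expression per gene × group from a tidy Ct table.

    ``table`` needs one row per replicate with columns ``gene``, ``group``,
    ``ct_target`` and ``ct_reference`` (the reference-gene Ct measured in
    the same sample; the field convention for tilapia gonads is eef1a1a).
    ``calibrator`` names the group against which all others are expressed.

    Returns a DataFrame indexed by (gene, group) with columns ``ddct``
    (group-mean ΔΔCt), ``r`` (2^−ΔΔCt of the group mean; 1.0 for the
    calibrator), ``r_mean`` and ``r_sd`` (over replicate-wise R values) and
    ``n`` replicates. Adding a constant to every Ct value leaves R
    unchanged, and log2(r) == −ddct exactly.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing column(s): {missing}")
    bad_ref = table["ct_reference"].isna()
    if bad_ref.any():
        rows = table.index[bad_ref].tolist()
        raise ValueError(f"missing reference-gene Ct in row(s) {rows}")
    if (table[["ct_target", "ct_reference"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")

    df = table.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]

    out = []
    for gene, sub in df.groupby("gene", sort=False):
        if calibrator not in set(sub["group"]):
            raise ValueError(f"gene {gene!r}: calibrator group {calibrator!r} absent")
        cal_mean = sub.loc[sub["group"] == calibrator, "dct"].mean()
        for group, g in sub.groupby("group", sort=False):
            ddct_rep = g["dct"] - cal_mean
            r_rep = np.exp2(-ddct_rep)
            out.append(
                {
                    "gene": gene,
                    "group": group,
                    "ddct": float(ddct_rep.mean()),
                    "r": float(np.exp2(-ddct_rep.mean())),
                    "r_mean": float(r_rep.mean()),
                    "r_sd": float(r_rep.std(ddof=1)) if len(r_rep) > 1 else 0.0,
                    "n": len(g),
                }
            )
    return pd.DataFrame(out).set_index(["gene", "group"])
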