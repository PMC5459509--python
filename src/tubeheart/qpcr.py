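"""Relative-expression math for qPCR cycle-threshold tables.

Two modes: per-sample normalization against a housekeeping reference gene
(delta-Ct, default reference MCM2, as used on nanofluidic arrays) and the
two-step delta-delta-Ct used for RT-qPCR (default reference actin), with
the conventional 2^-ddCt fold change emitted alongside the raw values.
Lower dCt means higher relative expression; the output tables carry that
annotation explicitly.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .core import DataError

__all__ = ["read_ct_table", "delta_ct", "delta_delta_ct"]

REQUIRED_COLUMNS = {"sample", "gene", "ct"}


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = REQUIRED_COLUMNS - set(df.columns)
    if missing:
        raise DataError(f"Ct table missing columns: {sorted(missing)}")
    return df


def _validate(df: pd.DataFrame, reference: str) -> None:
    missing = REQUIRED_COLUMNS - set(df.columns)
    if missing:
        raise DataError(f"Ct table missing columns: {sorted(missing)}")
    cts = df["ct"].to_numpy(float)
    if not np.all(np.isfinite(cts)) or np.any(cts <= 0):
        raise DataError("Ct values must be finite and positive")
    for sample, grp in df.groupby("sample"):
        if reference not in set(grp["gene"]):
            raise DataError(f"sample {sample!r} lacks reference gene {reference!r}")


def delta_ct(df: pd.DataFrame, reference: str = "MCM2") -> pd.DataFrame:
    """Per-sample dCt = Ct(gene) - Ct(reference).

    Technical replicates of the reference within a sample are averaged.
    The ``note`` column records the sign convention (lower dCt = higher
    relative expression).
    """
    _validate(df, reference)
    ref = df[df["gene"] == reference].groupby("sample")["ct"].mean()
    out = df[df["gene"] != reference].copy()
    out["dct"] = out["ct"] - out["sample"].map(ref)
    out["note"] = "lower dCt = higher relative expression"
    return out.reset_index(drop=True)


def delta_delta_ct(df: pd.DataFrame, reference: str = "actin",
                   control_group: str = "control") -> pd.DataFrame:
    """Two-step relative quantification per gene.

    dCt is computed per sample against ``reference``; ddCt subtracts the
    control-group mean dCt of the same gene; fold = 2^-ddCt (a reporting
    convention, emitted alongside the raw ddCt).  Genes present in only one
    group are skipped with a warning.  Returns per-group mean +/- SEM and
    per-sample values.
    """
    if "group" not in df.columns:
        raise DataError("delta_delta_ct requires a 'group' column")
    dct = delta_ct(df, reference=reference)
    rows = []
    for gene, grp in dct.groupby("gene"):
        groups = set(grp["group"])
        if control_group not in groups or len(groups) < 2:
            warnings.warn(f"gene {gene!r}: need control and experimental "
                          "groups; skipped", stacklevel=2)
            continue
        ctrl_mean = float(grp.loc[grp["group"] == control_group, "dct"].mean())
        for _, r in grp.iterrows():
            ddct = float(r["dct"]) - ctrl_mean
            rows.append({
                "sample": r["sample"], "group": r["group"], "gene": gene,
                "dct": float(r["dct"]), "ddct": ddct,
                "fold_change": 2.0 ** (-ddct),
            })
    if not rows:
        raise DataError("no genes with both groups present")
    out = pd.DataFrame(rows)
    summary = (
        out.groupby(["gene", "group"])["ddct"]
        .agg(mean_ddct="mean",
             sem_ddct=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan)
        .reset_index()
    )
    summary["mean_fold_change"] = 2.0 ** (-summary["mean_ddct"])
    out.attrs["summary"] = summary
    return out
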