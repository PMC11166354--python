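"""Relative quantification of qPCR signal by the 2^-ddCt method.

Used both for qRT-PCR expression (target transcript normalised to a
reference gene) and MNase-qPCR chromatin accessibility (nucleosome-bound
DNA at tiled amplicons normalised to a reference locus).  Technical
replicates are averaged on the Ct scale; dCt = Ct_target - Ct_reference
per sample; ddCt subtracts the calibrator-group mean dCt; fold = 2^-ddCt.
Amplification efficiency is fixed at 2.0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ["sample", "group", "amplicon", "replicate", "ct"]


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return table


@dataclass
class FoldChangeResult:
    amplicon: str
    reference_amplicon: str
    calibrator_group: str
    per_sample: pd.DataFrame  # columns: sample, group, dct, ddct, fold
    group_means: dict[str, float] = field(default_factory=dict)  # mean fold
    group_sem: dict[str, float] = field(default_factory=dict)
    t: float = math.nan
    p: float = math.nan
    p_dct: float = math.nan  # same test on dCt values
    test: str = "welch"

    def fold(self, group: str) -> float:
        return self.group_means[group]


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    calibrator_group: str,
    test: str = "welch",
) -> FoldChangeResult:
    """2^-ddCt fold change of ``target`` relative to ``reference``,
    calibrated to the mean dCt of ``calibrator_group``.

    Samples lacking a reference Ct are dropped with a warning.  The
    two-sided two-sample t-test compares per-sample folds between the two
    groups (p on dCt values is also reported).
    """
    if test not in {"welch", "pooled"}:
        raise ValueError(f"unknown test variant {test!r}")
    table = validate_ct_table(table)
    sub = table[table["amplicon"].isin([target, reference])]
    # technical replicates -> one Ct per (sample, amplicon)
    ct = sub.groupby(["sample", "group", "amplicon"])["ct"].mean().unstack("amplicon")
    if reference not in ct.columns:
        raise ValueError(f"reference amplicon {reference!r} not measured")
    if target not in ct.columns:
        raise ValueError(f"target amplicon {target!r} not measured")
    incomplete = ct[reference].isna() | ct[target].isna()
    if incomplete.any():
        dropped = [s for s, _ in ct.index[incomplete]]
        warnings.warn(f"samples dropped for missing Ct: {dropped}")
        ct = ct[~incomplete]
    ct = ct.reset_index()
    if calibrator_group not in set(ct["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} absent")
    ct["dct"] = ct[target] - ct[reference]
    calib_mean = ct.loc[ct["group"] == calibrator_group, "dct"].mean()
    ct["ddct"] = ct["dct"] - calib_mean
    ct["fold"] = 2.0 ** -ct["ddct"]
    per_sample = ct[["sample", "group", "dct", "ddct", "fold"]]
    means = per_sample.groupby("group")["fold"].mean().to_dict()
    sems = {
        g: stats.sem(v) if len(v) > 1 else math.nan
        for g, v in per_sample.groupby("group")["fold"]
    }
    groups = sorted(means)
    t = p = p_dct = math.nan
    if len(groups) == 2:
        a = per_sample.loc[per_sample["group"] == groups[0], "fold"]
        b = per_sample.loc[per_sample["group"] == groups[1], "fold"]
        if min(len(a), len(b)) > 1:
            t, p = stats.ttest_ind(a, b, equal_var=(test == "pooled"))
            da = per_sample.loc[per_sample["group"] == groups[0], "dct"]
            db = per_sample.loc[per_sample["group"] == groups[1], "dct"]
            _, p_dct = stats.ttest_ind(da, db, equal_var=(test == "pooled"))
    return FoldChangeResult(
        target, reference, calibrator_group, per_sample,
        means, sems, float(t), float(p), float(p_dct), test,
    )


def mnase_enrichment(
    table: pd.DataFrame,
    amplicons: list[str],
    reference: str,
    calibrator_group: str,
    test: str = "welch",
) -> dict[str, FoldChangeResult]:
    """Per-amplicon 2^-ddCt quantification across a tiled amplicon panel
    (identical arithmetic to :func:`delta_delta_ct`, applied per amplicon)."""
    return {
        amp: delta_delta_ct(table, amp, reference, calibrator_group, test)
        for amp in amplicons
    }
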