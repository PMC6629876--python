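"""RT-qPCR relative expression with two reference genes.

Each row of a Ct table is one biological replicate of one gene under one
condition (``control`` or ``treated``), carrying the target Ct and the Cts
of the two housekeeping reference genes measured in the same run. Analysis
per gene:

1. ΔCt = Ct_target − mean(Ct_ref1, Ct_ref2) per replicate (averaging the
   two reference Cts is the log-scale equivalent of geometric-mean
   normalization of linear quantities, the standard two-reference method).
2. Each treated replicate is compared to the mean control ΔCt (replicates
   are independent cultures, so there is no natural run pairing):
   log2FC_i = −(ΔCt_treated,i − mean(ΔCt_control)).
3. The reported log2 fold change is the mean of the replicate log2FCs; the
   P-value is a two-sided one-sample t-test of the replicate log2FCs
   against 0.
4. Significance rule: |log2FC| > 1 (i.e. more than twofold change) AND
   P < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["gene", "condition", "replicate", "ct_target", "ct_ref1", "ct_ref2"]
CONDITIONS = ("control", "treated")

LOG2FC_CUTOFF = 1.0
P_CUTOFF = 0.05


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    log2_fold_change: float
    p_value: float
    significant: bool
    replicate_log2fcs: tuple[float, ...]

    @property
    def fold_change(self) -> float:
        """Linear fold change, 2**log2FC."""
        return float(2.0 ** self.log2_fold_change)


def validate_ct_table(table: pd.DataFrame) -> None:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing column(s): {', '.join(missing)}")
    bad_cond = set(table["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown condition label(s): {sorted(bad_cond)}")
    for col in ("ct_target", "ct_ref1", "ct_ref2"):
        vals = table[col]
        if vals.isna().any():
            raise ValueError(f"missing {col} value(s) in Ct table")
        if ((vals <= 0) | (vals >= 45)).any():
            raise ValueError(f"{col} values must lie in (0, 45)")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    validate_ct_table(table)
    return table


def write_ct_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def _one_sample_p(values: np.ndarray) -> float:
    """Two-sided one-sample t-test against 0; degenerate zero-variance
    replicate sets get p=0 for a nonzero mean and p=1 otherwise."""
    if np.std(values, ddof=1) == 0.0:
        return 0.0 if values.mean() != 0.0 else 1.0
    t = stats.ttest_1samp(values, popmean=0.0)
    return float(t.pvalue)


def relative_expression(table: pd.DataFrame, gene: str) -> ExpressionResult:
    """Relative expression of one gene: treated vs control, see module docs."""
    validate_ct_table(table)
    sub = table[table["gene"] == gene]
    if sub.empty:
        raise ValueError(f"gene {gene!r} absent from Ct table")
    parts = {}
    for cond in CONDITIONS:
        rows = sub[sub["condition"] == cond]
        if rows.empty:
            raise ValueError(f"gene {gene!r} has no {cond} replicates")
        parts[cond] = rows
    if len(parts["treated"]) < 2:
        raise ValueError(
            f"gene {gene!r}: need >= 2 treated replicates for the t-test"
        )

    def delta_ct(rows: pd.DataFrame) -> np.ndarray:
        ref = (rows["ct_target"] - (rows["ct_ref1"] + rows["ct_ref2"]) / 2.0)
        return ref.to_numpy(dtype=float)

    control_mean = delta_ct(parts["control"]).mean()
    log2fcs = -(delta_ct(parts["treated"]) - control_mean)
    mean_fc = float(log2fcs.mean())
    p = _one_sample_p(log2fcs)
    significant = (abs(mean_fc) > LOG2FC_CUTOFF) and (p < P_CUTOFF)
    return ExpressionResult(
        gene=gene,
        log2_fold_change=mean_fc,
        p_value=p,
        significant=significant,
        replicate_log2fcs=tuple(float(x) for x in log2fcs),
    )


def batch_expression(
    table: pd.DataFrame, correction: str | None = None
) -> list[ExpressionResult]:
    """One :class:`ExpressionResult` per gene, in table order.

    No multiple-testing correction by default; ``correction="bh"`` applies
    Benjamini–Hochberg to the P-values and re-evaluates significance on the
    adjusted values.
    """
    validate_ct_table(table)
    genes = list(dict.fromkeys(table["gene"]))
    results = [relative_expression(table, g) for g in genes]
    if correction is None:
        return results
    if correction != "bh":
        raise ValueError(f"unknown correction {correction!r} (only 'bh')")
    adjusted = stats.false_discovery_control([r.p_value for r in results])
    return [
        ExpressionResult(
            gene=r.gene,
            log2_fold_change=r.log2_fold_change,
            p_value=float(p_adj),
            significant=(abs(r.log2_fold_change) > LOG2FC_CUTOFF) and (p_adj < P_CUTOFF),
            replicate_log2fcs=r.replicate_log2fcs,
        )
        for r, p_adj in zip(results, adjusted)
    ]


def write_expression_results(
    results: Sequence[ExpressionResult], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            (r.gene, r.log2_fold_change, r.p_value, r.significant)
            for r in results
        ],
        columns=["gene", "log2_fold_change", "p_value", "significant"],
    )
    df.to_csv(path, sep="\t", index=False)
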