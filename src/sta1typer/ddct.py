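"""Relative expression by the delta-delta-Ct method.

Expression of a target gene is quantified from qPCR cycle-threshold (Ct)
values, normalised to one or more reference ("house-keeping") genes and
expressed relative to a calibrator sample:

    dCt   = Ct_target - mean(Ct_references)          (per biological replicate)
    ddCt  = dCt_sample - mean(dCt_calibrator)
    RQ    = 2 ** (-ddCt)                             (100% efficiency)

Averaging the reference Cts on the cycle scale equals geometric-mean
normalisation of their linear quantities, the standard multi-reference
practice.  Per-gene amplification efficiencies E may replace the base 2
by (1 + E).  Technical replicates are averaged to one Ct before any
difference is taken; biological replicates propagate to a standard
deviation on the log2 scale, and sample means are geometric (so the
calibrator's mean relative quantity is exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CT_RANGE = (0.0, 45.0)


@dataclass
class ExpressionResult:
    per_replicate: pd.DataFrame   # sample, bio_rep, log2_rq, rel_quantity
    summary: pd.DataFrame         # sample, mean_rq, sd_log2, n_bio
    target: str
    refs: tuple[str, ...]
    calibrator: str

    def fold_change(self, sample: str, other: str) -> float:
        means = self.summary.set_index("sample")["mean_rq"]
        return float(means[sample] / means[other])


def _validate(table: pd.DataFrame, target: str, refs, calibrator: str) -> None:
    required = {"sample", "bio_rep", "gene", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if not refs:
        raise ValueError("at least one reference gene required")
    if calibrator not in set(table["sample"]):
        raise ValueError(f"calibrator sample {calibrator!r} not in table")
    bad = table[(table["ct"] <= CT_RANGE[0]) | (table["ct"] > CT_RANGE[1])]
    if len(bad):
        raise ValueError(f"Ct values outside {CT_RANGE}: "
                         f"{bad[['sample', 'gene', 'ct']].to_dict('records')[:3]}")
    genes = {target, *refs}
    per_unit = table.groupby(["sample", "bio_rep"])["gene"].agg(set)
    missing = per_unit[~per_unit.map(genes.issubset)]
    if len(missing):
        raise ValueError(f"missing gene measurements for {list(missing.index)[:3]}")


def relative_expression(table: pd.DataFrame, target: str,
                        refs: list[str] | tuple[str, ...],
                        calibrator: str,
                        efficiencies: dict[str, float] | None = None
                        ) -> ExpressionResult:
    """Normalised relative quantities for every (sample, biological replicate).

    ``table`` is tidy with columns (sample, bio_rep, gene, ct); multiple
    rows per (sample, bio_rep, gene) are technical replicates.  With
    ``efficiencies`` (gene -> E in [0, 1]), gene quantities use base
    (1 + E) instead of 2.
    """
    refs = tuple(refs)
    _validate(table, target, refs, calibrator)
    eff = efficiencies or {}

    ct = (table.groupby(["sample", "bio_rep", "gene"])["ct"]
          .mean().reset_index())   # technical replicates -> one Ct

    # Per-gene log2 quantity relative to an arbitrary per-gene origin;
    # bases other than 2 rescale the gene's cycle axis onto log2.
    def log2_quantity(row):
        base = 1.0 + eff.get(row["gene"], 1.0)
        return -row["ct"] * np.log2(base)

    ct["log2_q"] = ct.apply(log2_quantity, axis=1)
    wide = ct.pivot_table(index=["sample", "bio_rep"], columns="gene",
                          values="log2_q")
    norm = wide[target] - wide[list(refs)].mean(axis=1)   # -dCt on log2 scale

    cal_mean = norm.loc[calibrator].mean()
    log2_rq = (norm - cal_mean).rename("log2_rq").reset_index()
    log2_rq["rel_quantity"] = 2.0 ** log2_rq["log2_rq"]

    summary = (log2_rq.groupby("sample")["log2_rq"]
               .agg(mean_log2="mean", sd_log2="std", n_bio="count")
               .reset_index())
    summary["mean_rq"] = 2.0 ** summary.pop("mean_log2")
    summary = summary[["sample", "mean_rq", "sd_log2", "n_bio"]]
    return ExpressionResult(log2_rq, summary, target, refs, calibrator)


def read_ct_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
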