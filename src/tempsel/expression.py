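"""Per-million read-count normalisation and the between-site ratio of change.

Candidate-gene expression is measured per individual as the number of
RNA-seq reads mapped to the gene's contig; because library sizes differ by
an order of magnitude between sequencing campaigns, counts are standardised
to reads per million filtered reads.  The statistic of interest is the
ratio of mean normalised expression at the affected site over the control
site, computed separately per epoch, so a before/after drop in the ratio
indicates a site-specific expression change across the intervention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class ExpressionError(ValueError):
    pass


def normalize_per_million(mapped_reads: int, total_reads: int) -> float:
    """Mapped reads per million total filtered reads."""
    if total_reads <= 0:
        raise ExpressionError("total_reads must be positive")
    if mapped_reads < 0 or mapped_reads > total_reads:
        raise ExpressionError(
            f"mapped_reads {mapped_reads} outside [0, total_reads={total_reads}]"
        )
    return mapped_reads / total_reads * 1e6


def add_normalized(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of *table* with a ``normalized`` column added."""
    required = {"site", "epoch", "mapped_reads", "total_reads"}
    missing = required - set(table.columns)
    if missing:
        raise ExpressionError(f"expression table missing columns {sorted(missing)}")
    out = table.copy()
    out["normalized"] = [
        normalize_per_million(m, t)
        for m, t in zip(out["mapped_reads"], out["total_reads"])
    ]
    return out


def ratio_of_change(
    table: pd.DataFrame, affected_site: str, control_site: str, epoch: str
) -> float:
    """Mean normalised expression at the affected site over the control site.

    Group means (not means of per-pair ratios) are used, so unequal group
    sizes pose no pairing problem.
    """
    norm = add_normalized(table)
    sub = norm[norm["epoch"] == epoch]
    means = {}
    for site in (affected_site, control_site):
        vals = sub.loc[sub["site"] == site, "normalized"]
        if vals.empty:
            raise ExpressionError(f"no individuals for site {site!r} in epoch {epoch!r}")
        means[site] = float(np.mean(vals))
    if means[control_site] == 0.0:
        raise ExpressionError(f"control site {control_site!r} has zero mean expression")
    return means[affected_site] / means[control_site]


def ratio_report(
    table: pd.DataFrame, affected_site: str, control_site: str
) -> pd.DataFrame:
    """Per-epoch ratio of change (the before/after pair of ratios)."""
    norm = add_normalized(table)
    rows = []
    for epoch in sorted(norm["epoch"].unique()):
        rows.append(
            {
                "epoch": epoch,
                "ratio_affected_over_control": ratio_of_change(
                    norm, affected_site, control_site, epoch
                ),
                "n_affected": int(
                    ((norm["epoch"] == epoch) & (norm["site"] == affected_site)).sum()
                ),
                "n_control": int(
                    ((norm["epoch"] == epoch) & (norm["site"] == control_site)).sum()
                ),
            }
        )
    return pd.DataFrame(rows)
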