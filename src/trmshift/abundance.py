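"""Per-subset 2x2 contingency tables, odds ratios and Wald intervals.

For a focal subset, cells are cross-classified as focal ("yes") versus all
other cells in the same stratum ("no"), separately for the WT and TG groups.
With per-group focal proportions p_WT and p_TG the odds ratio is

    OR = (p_TG / (1 - p_TG)) / (p_WT / (1 - p_WT))

and the standard error of log(OR) is the usual Woolf form

    SE = sqrt(1/n_WT_yes + 1/n_WT_no + 1/n_TG_yes + 1/n_TG_no),

with the 95% interval exp(log(OR) +/- 1.96 * SE).  If any of the four cells
is zero, the Haldane-Anscombe correction adds 0.5 to all four before any
quantity is computed, keeping the SE finite; the result is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log, sqrt

import pandas as pd

from .errors import ValidationError
from .simulate import GROUPS, UNASSIGNED

#: normal quantile used for the 95% Wald interval
CI_Z = 1.96


@dataclass(frozen=True)
class ContingencyTable:
    """Focal-subset vs rest counts for the two groups."""

    n_wt_yes: float
    n_wt_no: float
    n_tg_yes: float
    n_tg_no: float

    def __post_init__(self) -> None:
        counts = (self.n_wt_yes, self.n_wt_no, self.n_tg_yes, self.n_tg_no)
        if any(c < 0 for c in counts):
            raise ValidationError(f"negative count in contingency table {counts}")
        if self.n_wt_yes + self.n_wt_no <= 0:
            raise ValidationError("WT group has zero total cells")
        if self.n_tg_yes + self.n_tg_no <= 0:
            raise ValidationError("TG group has zero total cells")


@dataclass(frozen=True)
class ORResult:
    """Odds ratio with log-scale standard error and 95% Wald CI."""

    p_wt: float
    p_tg: float
    odds_ratio: float
    log_or: float
    se_log_or: float
    ci_low: float
    ci_high: float
    corrected: bool


def build_tables(
    cells: pd.DataFrame,
    compartment: str = "all",
    include_unassigned: bool = False,
) -> dict[str, ContingencyTable]:
    """One focal-vs-rest table per subset observed in the stratum.

    ``compartment`` selects "brain", "meninges" or "all" (both pooled).
    Unassigned cells are dropped unless ``include_unassigned`` is set, in
    which case they form their own subset and count in every denominator.
    """
    sub = cells if compartment == "all" else cells[cells["compartment"] == compartment]
    if not include_unassigned:
        sub = sub[sub["subset"] != UNASSIGNED]
    if sub.empty:
        raise ValidationError(f"no cells in compartment {compartment!r}")
    totals = sub["group"].value_counts()
    for group in GROUPS:
        if totals.get(group, 0) == 0:
            raise ValidationError(
                f"group {group!r} absent from compartment {compartment!r}"
            )
    n_wt, n_tg = int(totals["WT"]), int(totals["TG"])
    yes = (
        sub.groupby(["subset", "group"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(GROUPS), fill_value=0)
    )
    return {
        subset: ContingencyTable(
            n_wt_yes=int(row["WT"]),
            n_wt_no=n_wt - int(row["WT"]),
            n_tg_yes=int(row["TG"]),
            n_tg_no=n_tg - int(row["TG"]),
        )
        for subset, row in yes.sort_index().iterrows()
    }


def odds_ratio_from_counts(t: ContingencyTable) -> ORResult:
    """Odds ratio, SE of log(OR) and 95% CI from a 2x2 table."""
    a, b, c, d = t.n_wt_yes, t.n_wt_no, t.n_tg_yes, t.n_tg_no
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    p_wt = a / (a + b)
    p_tg = c / (c + d)
    log_or = log(c) - log(d) - log(a) + log(b)
    se = sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ORResult(
        p_wt=p_wt,
        p_tg=p_tg,
        odds_ratio=exp(log_or),
        log_or=log_or,
        se_log_or=se,
        ci_low=exp(log_or - CI_Z * se),
        ci_high=exp(log_or + CI_Z * se),
        corrected=corrected,
    )


def odds_ratio_from_proportions(p_wt: float, p_tg: float) -> float:
    """TG-vs-WT odds ratio from the two group proportions.

    No SE is available in this form (it needs the counts).  Both
    proportions must lie strictly inside (0, 1).
    """
    for name, p in (("p_wt", p_wt), ("p_tg", p_tg)):
        if not 0.0 < p < 1.0:
            raise ValidationError(f"{name}={p} must be strictly inside (0, 1)")
    return (p_tg / (1.0 - p_tg)) / (p_wt / (1.0 - p_wt))
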