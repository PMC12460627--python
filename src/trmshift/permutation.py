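"""Permutation calibration of per-subset odds ratios with FDR control.

The null distribution is built by reshuffling the genotype labels over the
stratum's cells while keeping both group totals fixed; every subset's odds
ratio is recomputed from the same shuffle, preserving the cross-subset
dependence of the composition.  The empirical p-value of a subset is the
raw fraction of permuted odds ratios deviating from 1 at least as much as
the observed one, with deviation measured as |log OR| so that enrichment
and depletion are treated symmetrically on the ratio scale; a p-value of
exactly 0 is attainable because the observed statistic is not added to the
null sample.  Benjamini-Hochberg adjustment is applied across the subsets
of each compartment analysis (brain, meninges and pooled are corrected
separately by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .abundance import build_tables, odds_ratio_from_counts
from .errors import ValidationError
from .simulate import COMPARTMENTS, UNASSIGNED

_EXHAUSTIVE_CAP = 500_000  # largest C(n, n_tg) enumerated exhaustively


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the permutation test."""

    n_perm: int = 10_000
    seed: int = 0
    scope: str = "per_compartment"  # or "pooled": pooled analysis only
    fdr_family: str = "per_compartment"  # or "global": one BH family
    include_unassigned: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValidationError(f"n_perm must be >= 1, got {self.n_perm}")
        if self.scope not in ("per_compartment", "pooled"):
            raise ValidationError(f"unknown scope {self.scope!r}")
        if self.fdr_family not in ("per_compartment", "global"):
            raise ValidationError(f"unknown fdr_family {self.fdr_family!r}")


@dataclass
class AbundanceReport:
    """Per-subset abundance statistics plus the permutation-null summary."""

    table: pd.DataFrame  # one row per (compartment, subset)
    null_summary: pd.DataFrame  # permuted-OR percentiles per row
    seed: int
    n_perm: int


def _stratum_frame(
    cells: pd.DataFrame, compartment: str, include_unassigned: bool
) -> pd.DataFrame:
    sub = cells if compartment == "all" else cells[cells["compartment"] == compartment]
    if not include_unassigned:
        sub = sub[sub["subset"] != UNASSIGNED]
    if sub.empty:
        raise ValidationError(f"no cells in compartment {compartment!r}")
    return sub


def _null_log_ors(
    codes: np.ndarray,
    is_tg: np.ndarray,
    n_subsets: int,
    n_perm: int,
    rng: np.random.Generator,
    exhaustive: bool,
) -> np.ndarray:
    """Matrix (n_draws, n_subsets) of permuted log odds ratios.

    Each draw reassigns the TG labels to a subset of cells of the original
    TG size and recomputes every subset's focal-vs-rest table from that one
    shuffle (Haldane-Anscombe +0.5 wherever a table cell is zero, keeping
    the null finite).
    """
    n = codes.size
    n_tg = int(is_tg.sum())
    n_wt = n - n_tg
    if n_wt == 0 or n_tg == 0:
        raise ValidationError("both groups must be present in the stratum")
    totals = np.bincount(codes, minlength=n_subsets)

    if exhaustive:
        if comb(n, n_tg) > _EXHAUSTIVE_CAP:
            raise ValidationError(
                f"exhaustive enumeration infeasible: C({n}, {n_tg}) relabelings"
            )
        draws = np.array(
            [
                np.bincount(codes[list(tg_cells)], minlength=n_subsets)
                for tg_cells in combinations(range(n), n_tg)
            ]
        )
    else:
        draws = np.empty((n_perm, n_subsets), dtype=np.int64)
        for i in range(n_perm):
            tg_cells = rng.permutation(n)[:n_tg]
            draws[i] = np.bincount(codes[tg_cells], minlength=n_subsets)

    c = draws.astype(float)  # TG yes
    d = n_tg - c
    a = totals[None, :] - c  # WT yes
    b = n_wt - a
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    for arr in (a, b, c, d):
        arr += 0.5 * zero
    return np.log(c) - np.log(d) - np.log(a) + np.log(b)


def permute_null(
    cells: pd.DataFrame,
    compartment: str,
    config: PermutationConfig,
    *,
    exhaustive: bool = False,
) -> dict[str, np.ndarray]:
    """Per-subset arrays of permuted log odds ratios for one stratum.

    With ``exhaustive=True`` every distinct reassignment of group labels
    (at fixed group totals) is enumerated instead of sampling ``n_perm``
    shuffles — feasible only for small strata, and the reference behaviour
    the sampled null converges to.
    """
    sub = _stratum_frame(cells, compartment, config.include_unassigned)
    subsets = np.sort(sub["subset"].unique())
    codes = pd.Categorical(sub["subset"], categories=subsets).codes.astype(np.int64)
    is_tg = (sub["group"] == "TG").to_numpy()
    rng = np.random.default_rng(config.seed)
    null = _null_log_ors(codes, is_tg, subsets.size, config.n_perm, rng, exhaustive)
    return {name: null[:, i] for i, name in enumerate(subsets)}


def empirical_p(obs_log_or: float, null_log_ors: np.ndarray) -> float:
    """Fraction of permuted ORs deviating from 1 at least as much as observed.

    Deviation is |log OR|; the raw fraction is returned (no add-one
    smoothing), so 0 is a possible value.
    """
    null_log_ors = np.asarray(null_log_ors, dtype=float)
    if null_log_ors.size == 0:
        raise ValidationError("empty null sample")
    if not np.all(np.isfinite(null_log_ors)):
        raise ValidationError("non-finite permuted log odds ratios")
    if not np.isfinite(obs_log_or):
        raise ValidationError("observed log odds ratio is not finite")
    return float(np.mean(np.abs(null_log_ors) >= abs(obs_log_or)))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("pvals must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_abundance_test(
    cells: pd.DataFrame, config: PermutationConfig
) -> AbundanceReport:
    """Full per-subset abundance analysis over the requested strata.

    For each analysed compartment (brain, meninges and both pooled under
    ``scope="per_compartment"``; pooled only under ``scope="pooled"``):
    contingency tables, odds ratios with 95% CIs, a shared permutation
    null, empirical p-values and BH-FDR q-values.  Rows are sorted by
    compartment then subset; the seed and ``n_perm`` are recorded both in
    the rows and on the report.
    """
    if config.scope == "pooled":
        compartments = ["all"]
    else:
        present = [c for c in COMPARTMENTS if (cells["compartment"] == c).any()]
        compartments = present + ["all"] if len(present) > 1 else present
    rows: list[dict] = []
    null_rows: list[dict] = []
    for k, compartment in enumerate(compartments):
        sub = _stratum_frame(cells, compartment, config.include_unassigned)
        subsets = np.sort(sub["subset"].unique())
        if subsets.size < 2:
            raise ValidationError(
                f"compartment {compartment!r}: at least 2 subsets required, "
                f"found {subsets.size}"
            )
        try:
            tables = build_tables(cells, compartment, config.include_unassigned)
            # one independent, reproducible substream per compartment
            comp_cfg = PermutationConfig(
                n_perm=config.n_perm,
                seed=int(
                    np.random.SeedSequence([config.seed, k]).generate_state(1)[0]
                    % 2**31
                ),
                scope=config.scope,
                fdr_family=config.fdr_family,
                include_unassigned=config.include_unassigned,
            )
            null = permute_null(cells, compartment, comp_cfg)
            for subset in subsets:
                t = tables[subset]
                res = odds_ratio_from_counts(t)
                rows.append(
                    {
                        "compartment": compartment,
                        "subset": subset,
                        "n_wt_yes": t.n_wt_yes,
                        "n_wt_no": t.n_wt_no,
                        "n_tg_yes": t.n_tg_yes,
                        "n_tg_no": t.n_tg_no,
                        "p_wt": res.p_wt,
                        "p_tg": res.p_tg,
                        "odds_ratio": res.odds_ratio,
                        "log_or": res.log_or,
                        "se_log_or": res.se_log_or,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "corrected": res.corrected,
                        "p_emp": empirical_p(res.log_or, null[subset]),
                        "n_perm": config.n_perm,
                        "seed": config.seed,
                    }
                )
                lo, med, hi = np.percentile(np.exp(null[subset]), [2.5, 50, 97.5])
                null_rows.append(
                    {
                        "compartment": compartment,
                        "subset": subset,
                        "or_null_p2.5": lo,
                        "or_null_p50": med,
                        "or_null_p97.5": hi,
                    }
                )
        except ValidationError as exc:
            raise ValidationError(f"compartment {compartment!r}: {exc}") from exc

    table = pd.DataFrame(rows).sort_values(["compartment", "subset"], kind="stable")
    table = table.reset_index(drop=True)
    if config.fdr_family == "global":
        table["q_fdr"] = bh_fdr(table["p_emp"].to_numpy())
    else:
        table["q_fdr"] = np.nan
        for compartment in table["compartment"].unique():
            mask = table["compartment"] == compartment
            table.loc[mask, "q_fdr"] = bh_fdr(table.loc[mask, "p_emp"].to_numpy())
    null_summary = (
        pd.DataFrame(null_rows)
        .sort_values(["compartment", "subset"], kind="stable")
        .reset_index(drop=True)
    )
    return AbundanceReport(
        table=table,
        null_summary=null_summary,
        seed=config.seed,
        n_perm=config.n_perm,
    )
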