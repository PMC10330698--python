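"""Paired fold-change differential statistics and the cross-therapy contrast.

Two rules drive the comparative analysis:

* within one therapy, a gene is a responder-associated DEG when the mean
  paired log2 fold change of responders exceeds that of non-responders by at
  least ``fc_threshold`` (default 1, i.e. a two-fold difference of the
  arithmetic averages) AND the BH-adjusted t-test p value is below
  ``q_threshold``;
* across therapies, the second difference
  ``ddfc = delta_fc_A - delta_fc_B`` selects genes whose responder-specific
  induction is at least two-fold stronger under therapy A than therapy B,
  conditional on a within-therapy effect ``delta_fc_A >= within_threshold``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import FoldChangeTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DeltaFCResult:
    """Per-gene responder-vs-non-responder contrast for one therapy."""

    therapy: str
    table: pd.DataFrame  # columns: mean_fc_R, mean_fc_NR, delta_fc, t, p, q, n_R, n_NR, direction
    up_genes: list[str]
    down_genes: list[str]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


@dataclass
class CrossTherapyResult:
    """Second-difference contrast between two therapies' responder effects."""

    therapy_a: str
    therapy_b: str
    table: pd.DataFrame  # columns: delta_fc_A, delta_fc_B, ddfc, selected_for

    def selected(self, therapy: str) -> list[str]:
        return self.table.index[self.table["selected_for"] == therapy].tolist()


@dataclass
class DEGClassification:
    a_specific: set[str]
    b_specific: set[str]
    shared: set[str]

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(g, "A_specific") for g in sorted(self.a_specific)]
            + [(g, "shared") for g in sorted(self.shared)]
            + [(g, "B_specific") for g in sorted(self.b_specific)]
        )
        return pd.DataFrame(rows, columns=["gene", "class"])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (q values).

    ``q_(i) = min_{j >= i} (m * p_(j) / j)``, capped at 1, returned in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def delta_fc_test(
    fc: FoldChangeTable,
    therapy: str,
    fc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    equal_var: bool = False,
) -> DeltaFCResult:
    """Responder-vs-non-responder contrast of paired fold changes in one therapy.

    Per gene, a two-sided two-sample t test (Welch by default) compares the
    responder pairs' fold changes with the non-responder pairs'; p values are
    BH-adjusted across all tested genes.  Up-DEGs satisfy
    ``delta_fc >= fc_threshold`` and ``q < q_threshold``; down-DEGs obey the
    mirrored rule.  Genes with zero variance in both groups get p = 1.
    """
    mask = fc.pairs["therapy"] == therapy
    r_cols = fc.pairs.index[mask & (fc.pairs["response"] == "R")].tolist()
    nr_cols = fc.pairs.index[mask & (fc.pairs["response"] == "NR")].tolist()
    if len(r_cols) < 2 or len(nr_cols) < 2:
        raise ValidationError(
            f"therapy {therapy!r} needs >= 2 pairs per response group "
            f"(got {len(r_cols)} R, {len(nr_cols)} NR)"
        )
    r_vals = fc.log2fc[r_cols].to_numpy()
    nr_vals = fc.log2fc[nr_cols].to_numpy()
    # drop genes without at least 2 finite fold changes per group
    finite_ok = (np.isfinite(r_vals).sum(axis=1) >= 2) & (np.isfinite(nr_vals).sum(axis=1) >= 2)
    genes = fc.log2fc.index[finite_ok]
    r_vals = r_vals[finite_ok.to_numpy() if hasattr(finite_ok, "to_numpy") else finite_ok]
    nr_vals = nr_vals[finite_ok.to_numpy() if hasattr(finite_ok, "to_numpy") else finite_ok]
    mean_r = np.nanmean(r_vals, axis=1)
    mean_nr = np.nanmean(nr_vals, axis=1)
    delta = mean_r - mean_nr
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p = stats.ttest_ind(r_vals, nr_vals, axis=1, equal_var=equal_var,
                                    nan_policy="omit")
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.info("%d genes with zero variance in both groups: p set to 1",
                    int(degenerate.sum()))
        p = np.where(degenerate, 1.0, p)
        t_stat = np.where(np.isfinite(t_stat), t_stat, 0.0)
    q = bh_adjust(p)
    direction = np.where(
        (delta >= fc_threshold) & (q < q_threshold),
        "up",
        np.where((delta <= -fc_threshold) & (q < q_threshold), "down", "ns"),
    )
    table = pd.DataFrame(
        {
            "mean_fc_R": mean_r,
            "mean_fc_NR": mean_nr,
            "delta_fc": delta,
            "t": t_stat,
            "p": p,
            "q": q,
            "n_R": len(r_cols),
            "n_NR": len(nr_cols),
            "direction": direction,
        },
        index=genes,
    )
    return DeltaFCResult(
        therapy=therapy,
        table=table,
        up_genes=table.index[table["direction"] == "up"].tolist(),
        down_genes=table.index[table["direction"] == "down"].tolist(),
    )


def cross_therapy_contrast(
    result_a: DeltaFCResult,
    result_b: DeltaFCResult,
    ddfc_threshold: float = 1.0,
    within_threshold: float = 1.0,
) -> CrossTherapyResult:
    """Second-difference contrast: which therapy's responders drive each gene.

    On the shared gene universe, a gene is selected for therapy A when
    ``delta_fc_A - delta_fc_B >= ddfc_threshold`` and
    ``delta_fc_A >= within_threshold``; symmetrically for B; otherwise
    neither.
    """
    shared = result_a.table.index.intersection(result_b.table.index)
    if len(shared) == 0:
        raise ValidationError("the two results share no genes")
    da = result_a.table.loc[shared, "delta_fc"].to_numpy()
    db = result_b.table.loc[shared, "delta_fc"].to_numpy()
    ddfc = da - db
    sel = np.where(
        (ddfc >= ddfc_threshold) & (da >= within_threshold),
        result_a.therapy,
        np.where((-ddfc >= ddfc_threshold) & (db >= within_threshold),
                 result_b.therapy, "neither"),
    )
    table = pd.DataFrame(
        {"delta_fc_A": da, "delta_fc_B": db, "ddfc": ddfc, "selected_for": sel},
        index=shared,
    )
    return CrossTherapyResult(therapy_a=result_a.therapy, therapy_b=result_b.therapy, table=table)


def classify_degs(degs_a, degs_b) -> DEGClassification:
    """Partition two DEG lists into A-specific, B-specific and shared sets."""
    a, b = set(degs_a), set(degs_b)
    return DEGClassification(a_specific=a - b, b_specific=b - a, shared=a & b)


def group_compare(values, groups) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) comparison of two groups.

    Exact enumeration when both groups have fewer than 8 observations and no
    ties cross groups; otherwise the normal approximation with tie
    correction.  Returns ``(U statistic, two-sided p)``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValidationError(f"group_compare needs exactly 2 groups, got {list(labels)}")
    x = values[groups == labels[0]]
    y = values[groups == labels[1]]
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size < 8 and y.size < 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
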