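"""Gene expression tables and the three-way response classification.

Genes are classed by how they respond to global demethylation:

* ``de_repressed`` — silent in the parental condition, active after
  demethylation: log2 parental expression < 1.5 and log2 demethylated
  expression > 2.5 (strict), on mean log2(normalized + 1) values;
* ``up`` / ``down`` — differentially expressed at P < 0.05 and linear fold
  change > 1.2 (de-repressed genes are removed first);
* ``unchanged`` — expressed but neither of the above;
* ``not_expressed`` — zero mean normalized expression in both conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import ValidationError

CLASSES = ("de_repressed", "up", "down", "unchanged", "not_expressed")


class ExpressionTable:
    """Normalized linear expression, genes x (condition, replicate)."""

    def __init__(self, values: pd.DataFrame, condition_a: str, condition_b: str):
        """``values``: index gene_id, columns ``<condition>_rep<k>``."""
        self.condition_a = condition_a
        self.condition_b = condition_b
        self.rep_cols = {
            condition_a: [c for c in values.columns if c.startswith(condition_a + "_rep")],
            condition_b: [c for c in values.columns if c.startswith(condition_b + "_rep")],
        }
        for cond, cols in self.rep_cols.items():
            if not cols:
                raise ValidationError(f"no replicate columns for condition {cond!r}")
        use = self.rep_cols[condition_a] + self.rep_cols[condition_b]
        values = values[use].astype(float)
        if values.isna().any().any():
            missing = values[values.isna().any(axis=1)].index[0]
            raise ValidationError(f"gene {missing!r} missing a replicate value")
        if (values < 0).any().any():
            bad = values[(values < 0).any(axis=1)].index[0]
            raise ValidationError(f"negative expression for gene {bad!r}")
        self.values = values

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def __len__(self) -> int:
        return len(self.values)

    def replicate_values(self, gene_id: str, condition: str) -> np.ndarray:
        return self.values.loc[gene_id, self.rep_cols[condition]].to_numpy(float)

    def mean_linear(self, condition: str) -> pd.Series:
        return self.values[self.rep_cols[condition]].mean(axis=1)

    def mean_log2(self, condition: str) -> pd.Series:
        """Per-condition mean of log2(x + 1) across replicates."""
        return np.log2(self.values[self.rep_cols[condition]] + 1.0).mean(axis=1)

    @classmethod
    def read(cls, path, condition_a: str, condition_b: str) -> "ExpressionTable":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame, condition_a, condition_b)

    def write(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


def classify_derepressed(
    expr: ExpressionTable, low_cut: float = 1.5, high_cut: float = 2.5
) -> set[str]:
    """Genes silent in A and active in B: mean log2(A) < low_cut AND mean
    log2(B) > high_cut, both strict."""
    if not low_cut < high_cut:
        raise ValueError("low_cut must be below high_cut")
    la = expr.mean_log2(expr.condition_a)
    lb = expr.mean_log2(expr.condition_b)
    mask = (la < low_cut) & (lb > high_cut)
    return set(la.index[mask])


def builtin_de_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Welch (unequal-variance) t-test on log2(x + 1) values.

    A pragmatic built-in stand-in for a dedicated differential-expression
    model; callers reproducing published gene lists should supply external
    p-values instead. Degenerate zero-variance groups are handled explicitly:
    identical data give p = 1, two distinct constants give p = 0.
    """
    a = np.log2(np.asarray(values_a, dtype=float) + 1.0)
    b = np.log2(np.asarray(values_b, dtype=float) + 1.0)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("builtin_de_test needs >= 2 replicates per condition")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def classify_differential(
    expr: ExpressionTable,
    p_values: Mapping[str, float] | None = None,
    p_cut: float = 0.05,
    fc_cut: float = 1.2,
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Label genes up / down / unchanged by P-value and linear fold change.

    up: p < p_cut and mean(B)/mean(A) > fc_cut; down: p < p_cut and
    mean(A)/mean(B) > fc_cut; otherwise unchanged (including the
    undefined-fold-change case where both means are zero). Genes in
    ``exclude`` (typically the de-repressed set) are dropped first. Without
    supplied p-values the built-in Welch test is used, which requires >= 2
    replicates per condition.

    Returns a DataFrame indexed by gene_id with columns ``label``,
    ``fold_change`` (B over A; inf/NaN possible) and ``p_value``.
    """
    exclude = set(exclude)
    genes = [g for g in expr.gene_ids if g not in exclude]
    ma = expr.mean_linear(expr.condition_a)
    mb = expr.mean_linear(expr.condition_b)
    labels, fcs, ps = [], [], []
    for g in genes:
        if p_values is not None:
            p = float(p_values[g])
        else:
            p = builtin_de_test(
                expr.replicate_values(g, expr.condition_a),
                expr.replicate_values(g, expr.condition_b),
            )
        a, b = float(ma[g]), float(mb[g])
        if a == 0.0 and b == 0.0:
            fc = np.nan
            label = "unchanged"
        else:
            fc = np.inf if a == 0.0 else b / a
            if p < p_cut and fc > fc_cut:
                label = "up"
            elif p < p_cut and a > 0 and (np.inf if b == 0.0 else a / b) > fc_cut:
                label = "down"
            else:
                label = "unchanged"
        labels.append(label)
        fcs.append(fc)
        ps.append(p)
    return pd.DataFrame(
        {"label": labels, "fold_change": fcs, "p_value": ps}, index=pd.Index(genes, name="gene_id")
    )


def build_gene_class_table(
    expr: ExpressionTable,
    p_values: Mapping[str, float] | None = None,
    low_cut: float = 1.5,
    high_cut: float = 2.5,
    p_cut: float = 0.05,
    fc_cut: float = 1.2,
) -> pd.DataFrame:
    """Full mutually exclusive classification of every gene.

    Precedence: not_expressed (zero in both conditions), then de_repressed,
    then up/down/unchanged from the differential test.
    """
    la = expr.mean_log2(expr.condition_a)
    lb = expr.mean_log2(expr.condition_b)
    ma = expr.mean_linear(expr.condition_a)
    mb = expr.mean_linear(expr.condition_b)
    not_expressed = set(ma.index[(ma == 0) & (mb == 0)])
    derepressed = classify_derepressed(expr, low_cut, high_cut) - not_expressed
    diff = classify_differential(
        expr, p_values, p_cut, fc_cut, exclude=not_expressed | derepressed
    )
    rows = []
    for g in expr.gene_ids:
        if g in not_expressed:
            cls, fc, p = "not_expressed", np.nan, np.nan
        elif g in derepressed:
            cls = "de_repressed"
            fc = np.inf if ma[g] == 0 else mb[g] / ma[g]
            p = np.nan
        else:
            cls = diff.loc[g, "label"]
            fc = diff.loc[g, "fold_change"]
            p = diff.loc[g, "p_value"]
        rows.append((g, cls, float(la[g]), float(lb[g]), fc, p))
    out = pd.DataFrame(
        rows, columns=["gene_id", "class", "log2_a", "log2_b", "fold_change", "p_value"]
    ).set_index("gene_id")
    return out


def read_tsg_list(path) -> list[str]:
    """1-column TSV of tumor-suppressor gene names."""
    names = []
    with open(path) as fh:
        for line in fh:
            name = line.strip().split("\t")[0]
            if name and not name.startswith("#"):
                names.append(name)
    return names


def annotate_tsg(genes: Iterable[str], tsg_list: Sequence[str]) -> set[str]:
    """Case-insensitive intersection of a gene set with a tumor-suppressor
    list. An empty list yields an empty result (with a warning)."""
    import warnings

    if not tsg_list:
        warnings.warn("empty tumor-suppressor list; no genes annotated")
        return set()
    tsg_lower = {t.lower() for t in tsg_list}
    return {g for g in genes if g.lower() in tsg_lower}
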