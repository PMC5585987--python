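"""qRT-PCR relative expression: 2^-ddCt, one-way ANOVA, Tukey compact letters.

Ct values are normalized to a reference (housekeeping) gene per
sample/replicate (dCt), then to a calibrator sample (ddCt); fold change is
2^-ddCt. ANOVA and Tukey comparisons run on dCt values, which are better
behaved than folds; letters summarize the pairwise tests (groups sharing a
letter are not significantly different).
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["gene", "sample", "replicate", "ct"]


class ExpressionError(ValueError):
    pass


@dataclass
class CtTable:
    """Long-format Ct measurements plus reference gene and calibrator sample."""
    data: pd.DataFrame
    reference_gene: str = "EF1a"
    calibrator_sample: str | None = None

    def __post_init__(self):
        missing = [c for c in CT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ExpressionError(f"Ct table missing columns {missing}")
        self.data = self.data[CT_COLUMNS].copy()
        if not np.isfinite(self.data["ct"]).all():
            raise ExpressionError("non-finite Ct value")
        if self.reference_gene not in set(self.data["gene"]):
            raise ExpressionError(f"reference gene {self.reference_gene!r} absent")
        if self.calibrator_sample is None:
            self.calibrator_sample = str(self.data["sample"].iloc[0])

    @classmethod
    def from_tsv(cls, path, reference_gene: str = "EF1a",
                 calibrator_sample: str | None = None) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"), reference_gene, calibrator_sample)

    @property
    def target_genes(self) -> list[str]:
        return [g for g in self.data["gene"].unique() if g != self.reference_gene]


def delta_delta_ct(table: CtTable) -> pd.DataFrame:
    """Per (gene, sample, replicate): dCt, ddCt and fold change 2^-ddCt.

    dCt = Ct(target) - Ct(reference) in the same sample/replicate; ddCt
    subtracts the calibrator sample's mean dCt of the same gene, so the
    calibrator's mean fold change is exactly 1.
    """
    ref = table.data[table.data["gene"] == table.reference_gene]
    ref_ct = {(r.sample, r.replicate): r.ct for r in ref.itertuples(index=False)}
    rows = []
    for r in table.data[table.data["gene"] != table.reference_gene].itertuples(index=False):
        key = (r.sample, r.replicate)
        if key not in ref_ct:
            raise ExpressionError(
                f"no reference Ct for sample {r.sample!r} replicate {r.replicate!r}")
        rows.append({"gene": r.gene, "sample": r.sample, "replicate": r.replicate,
                     "delta_ct": r.ct - ref_ct[key]})
    long = pd.DataFrame(rows)
    if table.calibrator_sample not in set(long["sample"]):
        raise ExpressionError(f"calibrator sample {table.calibrator_sample!r} absent")
    cal = (long[long["sample"] == table.calibrator_sample]
           .groupby("gene")["delta_ct"].mean())
    long["delta_delta_ct"] = long["delta_ct"] - long["gene"].map(cal)
    long["fold_change"] = 2.0 ** (-long["delta_delta_ct"])
    return long


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    mse: float
    group_means: dict = field(default_factory=dict)
    group_n: dict = field(default_factory=dict)


def anova_oneway(groups: dict[str, np.ndarray] | list) -> AnovaResult:
    """Standard between/within one-way ANOVA decomposition."""
    if not isinstance(groups, dict):
        groups = {str(i): g for i, g in enumerate(groups)}
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ExpressionError("ANOVA needs at least 2 groups")
    for k, v in arrays.items():
        if v.size < 2:
            raise ExpressionError(f"group {k!r} has fewer than 2 replicates")
    all_values = np.concatenate(list(arrays.values()))
    grand = all_values.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in arrays.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    df_b = len(arrays) - 1
    df_w = all_values.size - len(arrays)
    msb = ss_between / df_b
    mse = ss_within / df_w
    if ss_between <= 1e-30:
        f, p = 0.0, 1.0
    elif mse == 0.0:
        f, p = math.inf, 0.0
    else:
        f = msb / mse
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(F=float(f), p=p, df_between=df_b, df_within=df_w, mse=float(mse),
                       group_means={k: float(v.mean()) for k, v in arrays.items()},
                       group_n={k: int(v.size) for k, v in arrays.items()})


def tukey_cld(group_means: dict[str, float], mse: float, n_per_group,
              df_within: int, alpha: float = 0.05) -> tuple[pd.DataFrame, dict[str, str]]:
    """Tukey pairwise comparisons via the studentized range, plus letter labels.

    ``n_per_group`` may be a single int (balanced) or a dict; unbalanced
    designs use the harmonic mean n. Two groups share a letter iff they are
    not significantly different at ``alpha``.
    """
    if mse <= 0:
        raise ExpressionError("mean squared error must be positive")
    names = list(group_means)
    k = len(names)
    if isinstance(n_per_group, dict):
        ns = np.array([n_per_group[g] for g in names], dtype=float)
        n_h = k / np.sum(1.0 / ns)
    else:
        n_h = float(n_per_group)
    q_crit = float(stats.studentized_range.ppf(1.0 - alpha, k, df_within))
    hsd = q_crit * math.sqrt(mse / n_h)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(group_means[names[i]] - group_means[names[j]])
            rows.append({"group_a": names[i], "group_b": names[j],
                         "abs_diff": diff, "critical_range": hsd,
                         "significant": bool(diff > hsd)})
    pairwise = pd.DataFrame(rows)
    letters = _compact_letter_display(group_means, hsd)
    return pairwise, letters


def _compact_letter_display(group_means: dict[str, float], hsd: float) -> dict[str, str]:
    # insert-and-absorb on the mean-sorted groups; with a single critical range
    # the non-significant sets are intervals, so maximal windows suffice
    order = sorted(group_means, key=lambda g: (-group_means[g], g))
    means = [group_means[g] for g in order]
    k = len(order)
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and abs(means[i] - means[j + 1]) <= hsd:
            j += 1
        intervals.append((i, j))
    maximal = [iv for iv in intervals
               if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in intervals)]
    seen = []
    for iv in maximal:
        if iv not in seen:
            seen.append(iv)
    letters = {g: "" for g in order}
    alphabet = string.ascii_lowercase
    for idx, (lo, hi) in enumerate(seen):
        letter = alphabet[idx % 26] * (idx // 26 + 1)
        for g in order[lo:hi + 1]:
            letters[g] += letter
    return letters


@dataclass
class GeneExpressionSummary:
    gene_id: str
    table: pd.DataFrame                  # sample, mean_fold, sd_fold, letters
    anova: AnovaResult | None
    preferential_sample: str


def expression_profile_report(table: CtTable, alpha: float = 0.05) -> dict[str, GeneExpressionSummary]:
    """Per-gene summary: mean fold +/- SD per sample, ANOVA on dCt, Tukey letters.

    The preferential sample is the one with the highest mean fold change.
    Single-sample tables get a summary without ANOVA/letters.
    """
    long = delta_delta_ct(table)
    out = {}
    for gene, sub in long.groupby("gene", sort=False):
        agg = sub.groupby("sample", sort=False).agg(
            mean_fold=("fold_change", "mean"),
            sd_fold=("fold_change", "std"),
            mean_ddct=("delta_delta_ct", "mean"),
        ).reset_index()
        agg["sd_fold"] = agg["sd_fold"].fillna(0.0)
        anova = None
        letters = {s: "" for s in agg["sample"]}
        groups = {s: g["delta_ct"].to_numpy() for s, g in sub.groupby("sample", sort=False)}
        if len(groups) >= 2 and min(len(v) for v in groups.values()) >= 2:
            anova = anova_oneway(groups)
            if anova.mse > 0:
                _, letters = tukey_cld(anova.group_means, anova.mse,
                                       anova.group_n, anova.df_within, alpha)
            else:
                shared = "a"
                letters = {s: shared for s in groups}
        agg["letters"] = agg["sample"].map(letters)
        pref = agg.loc[agg["mean_fold"].idxmax(), "sample"]
        out[gene] = GeneExpressionSummary(gene_id=gene, table=agg, anova=anova,
                                          preferential_sample=str(pref))
    return out


def wide_fold_matrix(report: dict[str, GeneExpressionSummary]) -> pd.DataFrame:
    """Genes x samples matrix of 'mean+/-sd letters' strings plus numeric means."""
    rows = {}
    for gene, summ in report.items():
        rows[gene] = {r.sample: r.mean_fold for r in summ.table.itertuples(index=False)}
    return pd.DataFrame(rows).T
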