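"""Validation statistics: qPCR preferential expression and transactivation.

Relative expression follows the comparative-Ct convention with two reference
genes: RE = 2^(-dCt) with dCt = Ct_target - mean(Ct_ref1, Ct_ref2), assuming
100% amplification efficiency (one PCR cycle doubles the template). Averaging
the two reference Ct values is equivalent to normalizing by the geometric
mean of the reference expression levels on the linear scale.

A gene is called preferentially expressed in a target tissue when that
tissue has the highest mean relative expression AND the Tukey HSD adjusted
p-value against every other tissue is below alpha, following a one-way
ANOVA across tissues. Transactivation strength is the mean firefly/renilla
luciferase ratio of an effector divided by that of the negative-control
effector, compared by a two-sided Student's t test (a Welch switch is
available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ("gene", "tissue", "replicate", "ct")
LUC_COLUMNS = ("effector", "replicate", "fluc", "rluc")


@dataclass
class PreferentialCall:
    gene: str
    verdict: bool
    target_tissue: str
    f_statistic: float
    anova_p: float
    tukey: pd.DataFrame  # pairwise tissue table with adjusted p-values
    group_means: dict[str, float]


def validate_ct_table(ct: pd.DataFrame, reference_genes: Sequence[str]) -> None:
    missing = set(CT_COLUMNS) - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    if len(reference_genes) != 2:
        raise ValueError("exactly two reference genes are required")
    refs = ct[ct["gene"].isin(reference_genes)]
    for (tissue, rep), group in ct.groupby(["tissue", "replicate"]):
        have = set(refs[(refs["tissue"] == tissue) & (refs["replicate"] == rep)]["gene"])
        if have != set(reference_genes):
            raise ValueError(
                f"({tissue}, replicate {rep}) lacks reference Ct for "
                f"{sorted(set(reference_genes) - have)}"
            )


def relative_expression(
    ct: pd.DataFrame, reference_genes: Sequence[str] = ("CUL", "EF1A")
) -> pd.DataFrame:
    """Per (gene, tissue, replicate) relative expression, RE = 2^(-dCt).

    dCt is the target Ct minus the arithmetic mean of the two reference-gene
    Ct values of the same tissue and replicate.
    """
    validate_ct_table(ct, reference_genes)
    refs = (
        ct[ct["gene"].isin(reference_genes)]
        .groupby(["tissue", "replicate"])["ct"]
        .mean()
        .rename("ref_ct")
    )
    targets = ct[~ct["gene"].isin(reference_genes)].copy()
    targets = targets.join(refs, on=["tissue", "replicate"])
    targets["delta_ct"] = targets["ct"] - targets["ref_ct"]
    targets["rel_expr"] = 2.0 ** (-targets["delta_ct"])
    return targets[["gene", "tissue", "replicate", "rel_expr"]].reset_index(drop=True)


def preferential_call(
    re_table: pd.DataFrame,
    target_tissue: str,
    alpha: float = 0.05,
) -> list[PreferentialCall]:
    """One-way ANOVA + Tukey HSD preferential-expression verdict per gene.

    Verdict is True iff the target tissue has the highest group mean and the
    Tukey-adjusted p-value of target-vs-other is below alpha for every other
    tissue. Identical groups give F = 0 and a False verdict.
    """
    required = {"gene", "tissue", "replicate", "rel_expr"}
    if not required <= set(re_table.columns):
        raise ValueError(f"relative-expression table needs columns {sorted(required)}")
    calls: list[PreferentialCall] = []
    for gene, sub in re_table.groupby("gene", sort=True):
        tissues = sorted(sub["tissue"].unique())
        if target_tissue not in tissues:
            raise ValueError(f"{gene}: target tissue {target_tissue!r} absent")
        if len(tissues) < 2:
            raise ValueError(f"{gene}: need at least two tissues")
        groups = [sub.loc[sub["tissue"] == t, "rel_expr"].to_numpy(float) for t in tissues]
        if any(len(g) < 2 for g in groups):
            bad = [t for t, g in zip(tissues, groups) if len(g) < 2]
            raise ValueError(f"{gene}: tissues with a single replicate: {bad}")
        means = {t: float(np.mean(g)) for t, g in zip(tissues, groups)}
        if np.ptp(np.concatenate(groups)) == 0:
            f_stat, p_anova = 0.0, 1.0
            pairs = pd.DataFrame(
                [
                    {"tissue_a": a, "tissue_b": b, "p_adj": 1.0}
                    for i, a in enumerate(tissues)
                    for b in tissues[i + 1 :]
                ]
            )
            verdict = False
        else:
            f_stat, p_anova = stats.f_oneway(*groups)
            hsd = stats.tukey_hsd(*groups)
            rows = []
            for i, a in enumerate(tissues):
                for j in range(i + 1, len(tissues)):
                    rows.append(
                        {
                            "tissue_a": a,
                            "tissue_b": tissues[j],
                            "p_adj": float(hsd.pvalue[i, j]),
                        }
                    )
            pairs = pd.DataFrame(rows)
            target_is_max = means[target_tissue] == max(means.values()) and (
                sum(np.isclose(means[target_tissue], m) for m in means.values()) == 1
            )
            target_pairs = pairs[
                (pairs["tissue_a"] == target_tissue) | (pairs["tissue_b"] == target_tissue)
            ]
            verdict = bool(target_is_max and (target_pairs["p_adj"] < alpha).all())
        calls.append(
            PreferentialCall(
                gene=gene,
                verdict=verdict,
                target_tissue=target_tissue,
                f_statistic=float(f_stat),
                anova_p=float(p_anova),
                tukey=pairs,
                group_means=means,
            )
        )
    return calls


def validate_luciferase_table(luc: pd.DataFrame, control: str) -> None:
    missing = set(LUC_COLUMNS) - set(luc.columns)
    if missing:
        raise ValueError(f"luciferase table lacks columns: {sorted(missing)}")
    if (luc["rluc"] <= 0).any():
        raise ValueError("rLUC must be positive in every replicate")
    if control not in set(luc["effector"]):
        raise ValueError(f"control effector {control!r} absent from table")
    counts = luc.groupby("effector")["replicate"].count()
    low = counts[counts < 2]
    if not low.empty:
        raise ValueError(f"effectors with fewer than 2 replicates: {list(low.index)}")


def transactivation_fold(
    luc: pd.DataFrame,
    control: str = "GUS",
    welch: bool = False,
    fold_flag_threshold: float = 20.0,
) -> pd.DataFrame:
    """Normalized transactivation fold change per effector, with a t test.

    Each replicate's activity is fLUC/rLUC; the fold change is the effector's
    mean ratio over the control's mean ratio. The p-value is a two-sided
    Student's t test of effector ratios against control ratios (Welch's
    correction optional). The control row has fold 1 and p 1 by definition.
    ``strong`` flags effectors whose fold exceeds ``fold_flag_threshold``.
    """
    validate_luciferase_table(luc, control)
    work = luc.copy()
    work["ratio"] = work["fluc"] / work["rluc"]
    control_ratios = work.loc[work["effector"] == control, "ratio"].to_numpy(float)
    rows = []
    for effector, sub in work.groupby("effector", sort=True):
        ratios = sub["ratio"].to_numpy(float)
        fold = float(ratios.mean() / control_ratios.mean())
        if effector == control:
            p = 1.0
        else:
            _, p = stats.ttest_ind(ratios, control_ratios, equal_var=not welch)
        rows.append(
            {
                "effector": effector,
                "n": len(ratios),
                "fold": fold,
                "sd_ratio": float(ratios.std(ddof=1)),
                "p_value": float(p),
                "strong": fold > fold_flag_threshold,
            }
        )
    return pd.DataFrame(rows)
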