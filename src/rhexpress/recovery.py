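"""Treatment-response recovery scoring.

For a cohort with non-lesional (NL), lesional-baseline and
lesional-week-2 skin samples, each candidate gene g gets

* a baseline dysregulation  d_g = mean(LS baseline) - mean(NL)  (log2),
* a treatment effect        t_g = mean over patients of (week2 - baseline),
* an improvement            -t_g / d_g * 100  (percent of the baseline
  dysregulation recovered; positive = toward NL, >100 = overshoot,
  <0 = worsening — reported, never clipped).

Genes with |d_g| below a floor are excluded (a near-zero denominator
makes the ratio meaningless), a gene is "improved" when its improvement
reaches a threshold (inclusive, default 75%), and the complement is the
residual-disease profile.  Each arm is summarized by the proportion of
eligible genes improved and the mean log2 movement toward NL,
mean(-sign(d_g) * t_g), also expressed as a linear fold change.

The dysregulation may instead be supplied as a precomputed LS-vs-NL
effect table (the role a meta-analysis transcriptome plays), which
overrides the matrix-derived estimate gene by gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .exceptions import (
    DataError,
    DegenerateDataError,
    DesignError,
    InvalidParameterError,
)

__all__ = [
    "dysregulation",
    "treatment_effect",
    "improvement",
    "classify_and_summarize",
    "RecoveryModel",
    "RecoveryResults",
]


def _require_genes(matrix: ExpressionMatrix, genes) -> list[str]:
    genes = list(genes)
    missing = [g for g in genes if g not in matrix.probe_ids]
    if missing:
        raise DataError(f"genes absent from cohort matrix: {sorted(missing)[:10]}")
    return genes


def dysregulation(
    cohort: ExpressionMatrix, genes, effects: pd.Series | None = None
) -> pd.Series:
    """Baseline dysregulation d_g = mean(LS baseline) - mean(NL), log2.

    ``effects`` (gene -> log2 effect) overrides the matrix estimate for
    the genes it covers; a gene found in neither source is an error.
    """
    genes = list(genes)
    nl = cohort.samples_where(condition="NL")
    ls = cohort.samples_where(condition="LS", timepoint="baseline")
    if not nl or not ls:
        raise DesignError("need at least one NL and one LS-baseline sample")
    from_table = set() if effects is None else set(effects.index) & set(genes)
    from_matrix = [g for g in genes if g not in from_table]
    missing = [g for g in from_matrix if g not in cohort.probe_ids]
    if missing:
        raise DataError(
            f"genes absent from both matrix and effect table: {sorted(missing)[:10]}"
        )
    d = pd.Series(np.nan, index=pd.Index(genes, name="gene_id"), dtype=float)
    if from_matrix:
        vals = cohort.values.loc[from_matrix]
        d.loc[from_matrix] = vals[ls].mean(axis=1) - vals[nl].mean(axis=1)
    for g in from_table:
        d.loc[g] = float(effects.loc[g])
    return d


def treatment_effect(cohort: ExpressionMatrix, arm: str, genes) -> pd.Series:
    """Mean within-patient (week2 - baseline) log2 change for an arm.

    The change is formed per patient first, then averaged across the
    arm's patients.
    """
    if arm not in set(cohort.samples["arm"]):
        raise InvalidParameterError(f"unknown arm {arm!r}")
    genes = _require_genes(cohort, genes)
    base = cohort.samples_where(condition="LS", timepoint="baseline", arm=arm)
    week2 = cohort.samples_where(condition="LS", timepoint="week2", arm=arm)
    base_by_subj = {cohort.samples.at[s, "subject_id"]: s for s in base}
    deltas = []
    for s in week2:
        subj = cohort.samples.at[s, "subject_id"]
        if subj not in base_by_subj:
            raise DesignError(f"week-2 sample {s!r} has no baseline for {subj!r}")
        deltas.append(
            cohort.values.loc[genes, s] - cohort.values.loc[genes, base_by_subj[subj]]
        )
    if not deltas:
        raise DesignError(f"arm {arm!r} has no complete baseline/week-2 pair")
    return pd.concat(deltas, axis=1).mean(axis=1).rename("t")


def improvement(
    d: pd.Series, t: pd.Series, floor: float = 0.1
) -> pd.DataFrame:
    """Per-gene improvement percentage and exclusion flag.

    improvement_pct = -t_g / d_g * 100; genes with |d_g| < floor are
    flagged ``excluded`` (their percentage is NaN) rather than divided.
    """
    if floor < 0:
        raise InvalidParameterError("floor must be >= 0")
    genes = d.index.intersection(t.index)
    d, t = d.loc[genes], t.loc[genes]
    excluded = d.abs() < floor
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = -t / d * 100.0
    pct = pct.where(~excluded, np.nan)
    return pd.DataFrame({"d": d, "t": t, "improvement_pct": pct, "excluded": excluded})


def classify_and_summarize(
    imp: pd.DataFrame, threshold: float = 75.0
) -> tuple[pd.DataFrame, dict]:
    """Flag improved genes (inclusive threshold) and summarize the arm.

    Returns the per-gene table (with ``improved``) and a summary dict:
    ``n_genes`` eligible, ``prop_improved``, ``mean_log2_recovery``
    (mean of -sign(d) * t over eligible genes) and its linear form
    ``fch_recovery`` = 2^mean_log2_recovery.  Non-improved genes form
    the residual-disease profile (``residual_genes``).
    """
    eligible = imp[~imp["excluded"]]
    if eligible.empty:
        raise DegenerateDataError("no eligible gene (all below dysregulation floor)")
    out = imp.copy()
    out["improved"] = (~out["excluded"]) & (out["improvement_pct"] >= threshold)
    improved = out.loc[eligible.index, "improved"]
    mean_log2 = float((-np.sign(eligible["d"]) * eligible["t"]).mean())
    summary = {
        "n_genes": int(len(eligible)),
        "n_excluded": int(imp["excluded"].sum()),
        "prop_improved": float(improved.mean()),
        "mean_log2_recovery": mean_log2,
        "fch_recovery": float(2.0**mean_log2),
        "residual_genes": tuple(sorted(eligible.index[~improved])),
    }
    return out, summary


class RecoveryModel:
    """Per-arm recovery scoring of a gene list on a cohort matrix.

    Parameters
    ----------
    cohort
        :class:`ExpressionMatrix` whose sample sheet distinguishes NL,
        LS-baseline and LS-week2 samples and assigns arms (rows are
        genes here, not probes).
    genes
        The genes to score (e.g. cytokine-response DEGs restricted to
        the cohort's platform and intersected with a disease signature).
    effects
        Optional precomputed LS-vs-NL log2 effects overriding the
        matrix-derived dysregulation.
    """

    def __init__(
        self,
        cohort: ExpressionMatrix,
        genes,
        effects: pd.Series | None = None,
    ):
        self.cohort = cohort
        self.genes = list(genes)
        if not self.genes:
            raise DataError("empty gene list")
        self.effects = effects
        self.arms = [a for a in dict.fromkeys(cohort.samples["arm"]) if a]
        if not self.arms:
            raise DesignError("cohort sample sheet assigns no arms")

    def fit(self, threshold: float = 75.0, floor: float = 0.1) -> "RecoveryResults":
        d = dysregulation(self.cohort, self.genes, self.effects)
        per_arm_tables: dict[str, pd.DataFrame] = {}
        summaries = []
        for arm in self.arms:
            t = treatment_effect(self.cohort, arm, self.genes)
            table, summary = classify_and_summarize(
                improvement(d, t, floor=floor), threshold=threshold
            )
            per_arm_tables[arm] = table
            summaries.append({"arm": arm, **summary})
        summary_df = pd.DataFrame(summaries).set_index("arm")
        return RecoveryResults(
            per_gene=per_arm_tables,
            summary_table=summary_df.drop(columns=["residual_genes"]),
            residual_genes={
                row["arm"]: row["residual_genes"] for row in summaries
            },
            threshold=threshold,
            floor=floor,
        )


@dataclass
class RecoveryResults:
    """Per-gene recovery tables (one per arm) and the per-arm summary."""

    per_gene: dict[str, pd.DataFrame]
    summary_table: pd.DataFrame
    residual_genes: dict[str, tuple]
    threshold: float
    floor: float

    def to_tsv(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for arm, table in self.per_gene.items():
            out = table.copy()
            out.index.name = "gene_id"
            out.to_csv(outdir / f"recovery_{arm}.tsv", sep="\t", float_format="%.6g")
        st = self.summary_table.copy()
        st.index.name = "arm"
        st.to_csv(outdir / "recovery_summary.tsv", sep="\t", float_format="%.6g")
        for arm, genes in self.residual_genes.items():
            (outdir / f"residual_profile_{arm}.txt").write_text(
                "\n".join(genes) + ("\n" if genes else "")
            )

    def summary(self) -> str:
        lines = [
            f"Treatment-recovery scoring (improved = improvement >= {self.threshold:g}%,"
            f" |d| floor {self.floor:g} log2)",
            "=" * 72,
            self.summary_table.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)
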