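"""Expression filtering and the empirical-Bayes moderated paired t-test.

The differential-expression stage for a paired treated/control design:

1. ``filter_probes`` drops probes that are never expressed (max over
   samples <= ``min_expr`` on the log2 scale) or flat (SD <= ``min_sd``).
   Both inequalities are strict.
2. ``paired_diffs`` forms per-pair log2 differences (treated - control).
3. ``estimate_prior`` fits the variance prior by moments on the
   log-variances: residual variances are modelled as draws from a scaled
   inverse chi-square distribution with ``d0`` prior degrees of freedom
   and prior variance ``s0_sq``.
4. ``moderated_t`` shrinks each probe's variance toward the prior,

       s_tilde^2 = (d0 * s0^2 + df * s^2) / (d0 + df),

   and refers t = mean_diff / sqrt(s_tilde^2 / n) to a Student t with
   ``df + d0`` degrees of freedom (standard normal when d0 is infinite).
5. ``bh_adjust`` applies Benjamini-Hochberg step-up FDR control.
6. ``call_degs`` applies the DEG thresholds |FCH| > 1.5 and FDR < 0.1
   (both strict), with FCH the signed linear fold change
   sign(mean_diff) * 2^|mean_diff|.

``ModeratedPairedTTest`` bundles steps 2-5 into a model object whose
``fit`` returns a :class:`DEResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, PlatformAnnotation, as_float_array
from .exceptions import (
    DataError,
    DegenerateDataError,
    DesignError,
    InvalidParameterError,
)

__all__ = [
    "EBayesPrior",
    "filter_probes",
    "paired_diffs",
    "estimate_prior",
    "moderated_t",
    "bh_adjust",
    "call_degs",
    "signed_fold_change",
    "ModeratedPairedTTest",
    "DEResults",
]


@dataclass(frozen=True)
class EBayesPrior:
    """Variance-shrinkage prior: ``d0`` prior df (0 = no shrinkage,
    ``inf`` = full shrinkage to ``s0_sq``) and prior variance ``s0_sq``
    in (log2 units)^2."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or np.isnan(self.d0):
            raise InvalidParameterError(f"d0 must be >= 0 or inf, got {self.d0}")
        if not self.s0_sq > 0:
            raise InvalidParameterError(f"s0_sq must be > 0, got {self.s0_sq}")


# ---------------------------------------------------------------------------
# filtering and pairing
# ---------------------------------------------------------------------------

def filter_probes(
    matrix: ExpressionMatrix, min_expr: float = 3.0, min_sd: float = 0.1
) -> ExpressionMatrix:
    """Keep probes expressed in at least one sample and with variation.

    A probe survives iff max over samples > ``min_expr`` AND the sample
    standard deviation (denominator n-1) > ``min_sd``; both strict.
    """
    if matrix.n_probes == 0 or matrix.n_samples == 0:
        raise DataError("cannot filter an empty expression matrix")
    vals = matrix.values
    keep = (vals.max(axis=1) > min_expr) & (vals.std(axis=1, ddof=1) > min_sd)
    return matrix.subset_probes(vals.index[keep])


def paired_diffs(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-pair treated-minus-control log2 differences (probes x pairs).

    Every sample must carry a ``pair_id`` and a ``condition`` of
    ``control`` or ``treated``; each pair id must appear exactly once per
    condition.
    """
    meta = matrix.samples
    unpaired = meta.index[meta["pair_id"] == ""].tolist()
    if unpaired:
        raise DesignError(f"samples without a pair id: {unpaired}")
    bad_cond = meta.index[~meta["condition"].isin(["control", "treated"])].tolist()
    if bad_cond:
        raise DesignError(
            f"samples with condition outside control/treated: {bad_cond}"
        )
    pair_order = list(dict.fromkeys(meta["pair_id"]))
    cols = {}
    for pair in pair_order:
        members = meta.index[meta["pair_id"] == pair]
        conds = meta.loc[members, "condition"]
        ctrl = members[conds == "control"]
        trt = members[conds == "treated"]
        if len(ctrl) != 1 or len(trt) != 1:
            raise DesignError(
                f"pair {pair!r} is not a (control, treated) couple: "
                f"{sorted(members.tolist())}"
            )
        cols[pair] = matrix.values[trt[0]] - matrix.values[ctrl[0]]
    return pd.DataFrame(cols, index=matrix.probe_ids)


# ---------------------------------------------------------------------------
# the variance prior
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    # Newton iteration on x -> trigamma(x); monotone decreasing, so the
    # multiplicative update below converges from x0 = 0.5 + 1/y.
    if y <= 0:
        raise InvalidParameterError("trigamma inverse needs y > 0")
    if y > 1e7:  # trigamma(x) ~ 1/x^2 for small x
        return 1.0 / np.sqrt(y)
    if y < 1e-6:  # trigamma(x) ~ 1/x for large x
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s_sq, df_resid: float) -> EBayesPrior:
    """Moment estimator of (d0, s0^2) from per-probe sample variances.

    Works on e_g = log(s_g^2) - digamma(df/2) + log(df/2), whose mean and
    excess dispersion over trigamma(df/2) identify the prior:
    ``trigamma(d0/2)`` equals the excess dispersion, solved by monotone
    root finding; zero or negative excess means no spread beyond the
    sampling noise of a common variance, i.e. d0 = infinity.
    """
    s_sq = as_float_array(s_sq, "variances")
    if df_resid < 1:
        raise InvalidParameterError(f"df_resid must be >= 1, got {df_resid}")
    pos = s_sq[s_sq > 0]
    if pos.size == 0:
        raise DegenerateDataError("all variances are zero")
    if pos.size < 2:
        raise DegenerateDataError("need >= 2 positive variances to fit the prior")
    half_df = df_resid / 2.0
    e = np.log(pos) - special.digamma(half_df) + np.log(half_df)
    ebar = e.mean()
    n = e.size
    var_e = np.mean((e - ebar) ** 2) * n / (n - 1)
    excess = var_e - special.polygamma(1, half_df)
    if excess <= 0:
        # log-variances no more dispersed than chi-square sampling noise:
        # a common variance explains the data; back out the correction so
        # identical inputs return exactly their (geometric mean) value
        s0_sq = float(np.exp(ebar + special.digamma(half_df) - np.log(half_df)))
        return EBayesPrior(d0=np.inf, s0_sq=s0_sq)
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# the moderated t-statistic
# ---------------------------------------------------------------------------

def moderated_t(mean_diff, s_sq, df_resid: float, prior: EBayesPrior, n_pairs: int):
    """Shrunken variances, moderated t, total df and two-sided p-values.

    Returns four arrays aligned with the input: ``s_tilde_sq``, ``t_mod``,
    ``df_total`` and ``p``.  Probes with a zero posterior variance get
    t = +/-inf and p = 0 when the mean difference is nonzero, t = 0 and
    p = 1 when it is zero.
    """
    mean_diff = as_float_array(mean_diff, "mean_diff")
    s_sq = as_float_array(s_sq, "s_sq")
    if mean_diff.shape != s_sq.shape:
        raise InvalidParameterError("mean_diff and s_sq must be aligned")
    if n_pairs < 2:
        raise InvalidParameterError(f"need >= 2 pairs, got {n_pairs}")
    d0, s0 = prior.d0, prior.s0_sq
    if np.isinf(d0):
        s_tilde = np.full_like(s_sq, s0)
        df_total = np.full_like(s_sq, np.inf)
    elif d0 == 0:
        s_tilde = s_sq.copy()
        df_total = np.full_like(s_sq, float(df_resid))
    else:
        s_tilde = (d0 * s0 + df_resid * s_sq) / (d0 + df_resid)
        df_total = np.full_like(s_sq, float(df_resid + d0))

    se = np.sqrt(s_tilde / n_pairs)
    zero_se = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_se, 0.0, mean_diff / np.where(zero_se, 1.0, se))
        t = np.where(zero_se & (mean_diff != 0), np.sign(mean_diff) * np.inf, t)

    p = np.empty_like(t)
    inf_df = np.isinf(df_total)
    p[inf_df] = 2.0 * stats.norm.sf(np.abs(t[inf_df]))
    p[~inf_df] = 2.0 * stats.t.sf(np.abs(t[~inf_df]), df=df_total[~inf_df])
    p = np.where(zero_se & (mean_diff != 0), 0.0, p)
    p = np.where(zero_se & (mean_diff == 0), 1.0, p)
    return s_tilde, t, df_total, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * G / j, capped at 1.  Exact zeros are
    floored at the smallest positive float first.
    """
    p = as_float_array(p, "p-values")
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise InvalidParameterError("p-values must lie in [0, 1]")
    p = np.maximum(p, np.nextafter(0.0, 1.0))
    return multipletests(p, method="fdr_bh")[1]


def signed_fold_change(mean_log2_diff) -> np.ndarray:
    """Signed linear fold change: sign(d) * 2^|d| (1.0 at d = 0)."""
    d = as_float_array(mean_log2_diff, "mean_log2_diff")
    out = np.sign(d) * np.exp2(np.abs(d))
    return np.where(d == 0, 1.0, out)


def call_degs(
    de_table: pd.DataFrame, fch_threshold: float = 1.5, fdr_threshold: float = 0.1
) -> pd.DataFrame:
    """Flag DEGs (|FCH| > fch_threshold AND FDR < fdr_threshold, strict)
    and sort by |FCH| descending, ties broken by probe id."""
    if de_table.empty:
        raise DataError("differential-expression table is empty")
    out = de_table.copy()
    out["is_deg"] = (np.abs(out["fch"]) > fch_threshold) & (
        out["fdr"] < fdr_threshold
    )
    out["direction"] = np.where(out["mean_log2_diff"] >= 0, "up", "down")
    out = out.iloc[
        np.lexsort((out.index.to_numpy(), -np.abs(out["fch"].to_numpy())))
    ]
    return out


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class ModeratedPairedTTest:
    """Moderated paired t-test on an expression matrix.

    Parameters
    ----------
    matrix
        Filtered :class:`ExpressionMatrix` with paired control/treated
        samples (see :func:`paired_diffs` for the metadata contract).
    annotation
        Optional :class:`PlatformAnnotation`; when given, results carry a
        ``gene_id`` column.

    Examples
    --------
    >>> model = ModeratedPairedTTest(matrix)
    >>> res = model.fit()
    >>> degs = res.call_degs(fch_threshold=1.5, fdr_threshold=0.1)
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        annotation: PlatformAnnotation | None = None,
    ):
        self.matrix = matrix
        self.annotation = annotation
        self.diffs = paired_diffs(matrix)
        self.n_pairs = self.diffs.shape[1]
        if self.n_pairs < 2:
            raise DesignError(f"need >= 2 pairs, got {self.n_pairs}")
        self.df_resid = self.n_pairs - 1

    def fit(self, prior: EBayesPrior | None = None) -> "DEResults":
        """Estimate the variance prior (unless supplied) and test every probe."""
        mean_diff = self.diffs.mean(axis=1).to_numpy()
        s_sq = self.diffs.var(axis=1, ddof=1).to_numpy()
        if prior is None:
            prior = estimate_prior(s_sq, self.df_resid)
        s_tilde, t, df_total, p = moderated_t(
            mean_diff, s_sq, self.df_resid, prior, self.n_pairs
        )
        table = pd.DataFrame(
            {
                "mean_log2_diff": mean_diff,
                "fch": signed_fold_change(mean_diff),
                "s_sq": s_sq,
                "s_tilde_sq": s_tilde,
                "t_mod": t,
                "df_total": df_total,
                "p": p,
                "fdr": bh_adjust(p),
            },
            index=self.diffs.index,
        )
        if self.annotation is not None:
            table.insert(
                0, "gene_id", self.annotation.table["gene_id"].reindex(table.index)
            )
        return DEResults(table=table, prior=prior, n_pairs=self.n_pairs)


@dataclass
class DEResults:
    """Per-probe differential-expression results plus the fitted prior.

    ``table`` is indexed by probe id with columns ``mean_log2_diff``,
    ``fch``, ``s_sq``, ``s_tilde_sq``, ``t_mod``, ``df_total``, ``p``,
    ``fdr`` (and ``gene_id`` when an annotation was attached).
    """

    table: pd.DataFrame
    prior: EBayesPrior
    n_pairs: int

    def call_degs(
        self, fch_threshold: float = 1.5, fdr_threshold: float = 0.1
    ) -> pd.DataFrame:
        return call_degs(self.table, fch_threshold, fdr_threshold)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t", float_format="%.6g")

    def summary(
        self, fch_threshold: float = 1.5, fdr_threshold: float = 0.1, top: int = 10
    ) -> str:
        degs = self.call_degs(fch_threshold, fdr_threshold)
        n_up = int((degs["is_deg"] & (degs["direction"] == "up")).sum())
        n_down = int((degs["is_deg"] & (degs["direction"] == "down")).sum())
        lines = [
            "Moderated paired t-test",
            "=" * 55,
            f"probes tested        {len(self.table):>10d}",
            f"pairs                {self.n_pairs:>10d}",
            f"prior df (d0)        {self.prior.d0:>10.4g}",
            f"prior variance s0^2  {self.prior.s0_sq:>10.4g}",
            f"DEGs (|FCH|>{fch_threshold}, FDR<{fdr_threshold})"
            f"  up: {n_up}  down: {n_down}",
            "",
            f"top {min(top, len(degs))} probes by |FCH|:",
            degs.head(top)[["fch", "t_mod", "p", "fdr", "is_deg"]].to_string(
                float_format=lambda v: f"{v:.4g}"
            ),
        ]
        return "\n".join(lines)
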