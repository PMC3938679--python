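"""Synthetic microarray data with the structure the analysis assumes.

Two generators, both on the log2 scale with Gaussian noise (emulating
GCRMA-style normalized output):

* a paired treated/control epidermis experiment — per-probe baseline
  means, a scaled inverse chi-square variance prior (``d0``, ``s0_sq``),
  an additive per-pair subject effect, and planted log2 fold changes on a
  fraction ``pi_de`` of probes;
* a three-arm psoriasis cohort — non-lesional (NL), lesional-baseline and
  lesional-week-2 samples per patient, with per-gene dysregulation
  effects and per-gene recovery fractions ``r`` drawn from an arm-level
  Beta distribution (week2 = baseline - r * dysregulation + noise).

Every generator records its ground truth in a :class:`SimTruth` so that
downstream stages can be scored for sensitivity, false discovery and
parameter recovery.  Identical config + seed gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    PlatformAnnotation,
)
from .exceptions import InvalidParameterError

#: default per-arm recovery Beta parameters; None means the degenerate
#: r = 0 arm (a placebo that leaves dysregulation untouched)
DEFAULT_ARMS: dict[str, Optional[tuple[float, float]]] = {
    "il17_blockade": (8.5, 2.0),  # P(r >= 0.75) ~ 0.73: strong responder arm
    "tnf_blockade": (1.0, 0.85),  # P(r >= 0.75) ~ 0.31: partial responder arm
    "placebo": None,              # r = 0: dysregulation untouched
}


@dataclass
class CohortConfig:
    """Psoriasis-cohort generator settings.

    ``arms`` maps each arm label to Beta(alpha, beta) parameters for the
    per-gene recovered fraction r in [0, 1], to a constant in [0, 1]
    (degenerate arm, e.g. 0 for a placebo that leaves dysregulation
    untouched or 1 for full recovery), or to None (alias for 0).  Each
    patient contributes an NL, an LS-baseline and an LS-week-2 sample.
    """

    n_patients_per_arm: int = 10
    arms: dict[str, Optional[tuple[float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_ARMS)
    )
    n_genes: int = 2000
    n_dysreg_genes: int = 300
    dysreg_loc: float = 2.2
    dysreg_scale: float = 0.5
    frac_dysreg_up: float = 2.0 / 3.0
    baseline_loc: float = 7.0
    baseline_scale: float = 1.0
    noise_sd: float = 0.05

    def validate(self) -> None:
        if self.n_patients_per_arm < 1:
            raise InvalidParameterError("n_patients_per_arm must be >= 1")
        if not self.arms:
            raise InvalidParameterError("cohort needs at least one arm")
        for arm, params in self.arms.items():
            if params is None:
                continue
            if isinstance(params, (int, float)):
                if not 0 <= params <= 1:
                    raise InvalidParameterError(
                        f"arm {arm!r}: constant recovery must lie in [0, 1]"
                    )
            else:
                a, b = params
                if not (a > 0 and b > 0):
                    raise InvalidParameterError(
                        f"arm {arm!r}: Beta parameters must be > 0, got {params}"
                    )
        if self.n_dysreg_genes > self.n_genes:
            raise InvalidParameterError(
                "n_dysreg_genes exceeds the gene universe size"
            )
        for name in ("dysreg_scale", "baseline_scale", "noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not 0 <= self.frac_dysreg_up <= 1:
            raise InvalidParameterError("frac_dysreg_up must lie in [0, 1]")


@dataclass
class SimConfig:
    """Paired-experiment generator settings (all expression in log2 units)."""

    seed: int = 0
    n_probes_shared: int = 10_000
    n_probes_plus_only: int = 2_000
    n_pairs: int = 4
    baseline_mean_loc: float = 7.0
    baseline_mean_scale: float = 2.0
    d0: float = 4.0
    s0_sq: float = 0.05
    pi_de: float = 0.1
    lfc_loc: float = 1.5
    lfc_scale: float = 0.25
    frac_up: float = 0.66
    subject_sd: float = 0.3
    max_probes_per_gene: int = 3
    var_floor: float = 1e-8
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def validate(self) -> None:
        for name in ("n_probes_shared", "n_probes_plus_only", "n_pairs"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        for name in ("baseline_mean_scale", "lfc_scale", "subject_sd", "var_floor"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        for name in ("pi_de", "frac_up"):
            if not 0 <= getattr(self, name) <= 1:
                raise InvalidParameterError(f"{name} must lie in [0, 1]")
        if not self.d0 > 0:
            raise InvalidParameterError("d0 must be > 0 (use inf for no spread)")
        if self.s0_sq < 0:
            raise InvalidParameterError("s0_sq must be >= 0")
        if self.max_probes_per_gene < 1:
            raise InvalidParameterError("max_probes_per_gene must be >= 1")
        self.cohort.validate()

    @property
    def n_probes(self) -> int:
        return self.n_probes_shared + self.n_probes_plus_only


@dataclass
class SimTruth:
    """Ground truth emitted by the generators.

    The paired-experiment fields (``responsive_probes``, ``true_lfc``,
    ``true_sigma_sq``, ``d0``, ``s0_sq``) and the cohort fields
    (``dysreg_genes``, ``true_dysreg``, ``true_recovery_frac``) are
    populated by their respective generators; the other group is empty.
    """

    responsive_probes: frozenset = frozenset()
    true_lfc: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    d0: float = np.nan
    s0_sq: float = np.nan
    true_sigma_sq: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    dysreg_genes: frozenset = frozenset()
    true_dysreg: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    true_recovery_frac: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# primitive generators
# ---------------------------------------------------------------------------

def generate_variances(
    n: int, d0: float, s0_sq: float, seed, var_floor: float = 1e-8
) -> np.ndarray:
    """Draw per-probe residual variances from the scaled inverse
    chi-square prior: d0 * s0_sq / sigma_g^2 ~ chi-square(d0).

    With ``d0 = inf`` every variance equals ``s0_sq`` exactly.  Variances
    are truncated below at ``var_floor`` to avoid degenerate division.
    """
    if n < 0:
        raise InvalidParameterError(f"n must be >= 0, got {n}")
    if not s0_sq > 0:
        raise InvalidParameterError(f"s0_sq must be > 0, got {s0_sq}")
    if not d0 > 0:
        raise InvalidParameterError(f"d0 must be > 0 or inf, got {d0}")
    if n == 0:
        return np.empty(0)
    if np.isinf(d0):
        return np.full(n, float(s0_sq))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sigma_sq = d0 * s0_sq / rng.chisquare(d0, size=n)
    return np.maximum(sigma_sq, var_floor)


def generate_annotation(
    n_shared: int,
    n_plus_only: int,
    max_probes_per_gene: int = 3,
    seed=0,
) -> PlatformAnnotation:
    """Random probe -> gene annotation over two nested platform universes.

    Shared probes carry both platform tags ("A2" and "APlus2"); the
    remaining ``n_plus_only`` probes exist only on the larger platform.
    Each gene owns 1..max_probes_per_gene probes, and probes never cross
    the shared / plus-only boundary, so exactly ``n_plus_only`` probes
    carry the single tag.
    """
    if n_shared < 0 or n_plus_only < 0:
        raise InvalidParameterError("probe counts must be >= 0")
    if max_probes_per_gene < 1:
        raise InvalidParameterError("max_probes_per_gene must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    rows = []
    gene_counter = 10_001  # ENTREZ-style numeric ids

    def assign(probe_ids: list[str], platforms: str) -> None:
        nonlocal gene_counter
        i = 0
        while i < len(probe_ids):
            k = int(rng.integers(1, max_probes_per_gene + 1))
            gene = str(gene_counter)
            for probe in probe_ids[i : i + k]:
                rows.append((probe, gene, f"SYN{gene}", platforms))
            gene_counter += 1
            i += k

    assign([f"{100000 + i}_at" for i in range(n_shared)], "A2,APlus2")
    assign([f"{200000 + i}_at" for i in range(n_plus_only)], "APlus2")
    table = pd.DataFrame(
        rows, columns=["probe_id", "gene_id", "symbol", "platforms"]
    ).set_index("probe_id")
    return PlatformAnnotation(table)


# ---------------------------------------------------------------------------
# the paired treated/control experiment
# ---------------------------------------------------------------------------

def generate_paired_experiment(
    config: SimConfig, annotation: PlatformAnnotation | None = None
) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate a paired cytokine-treatment experiment.

    value(probe g, sample in pair i) =
        mu_g + subject_i + [delta_g if treated and g responsive] + eps,
    eps ~ Normal(0, sigma_g^2) with sigma_g^2 from the variance prior.
    ``config.s0_sq = 0`` is the exact noiseless limit (all eps = 0).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_ann, rng_mu, rng_var, rng_de, rng_subj, rng_eps = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )
    if annotation is None:
        annotation = generate_annotation(
            config.n_probes_shared,
            config.n_probes_plus_only,
            config.max_probes_per_gene,
            seed=rng_ann,
        )
    probes = annotation.probe_ids
    n = len(probes)

    mu = rng_mu.normal(config.baseline_mean_loc, config.baseline_mean_scale, n)
    if config.s0_sq == 0:
        sigma_sq = np.zeros(n)
    else:
        sigma_sq = generate_variances(
            n, config.d0, config.s0_sq, rng_var, config.var_floor
        )

    responsive = rng_de.random(n) < config.pi_de
    magnitude = np.maximum(
        np.abs(rng_de.normal(config.lfc_loc, config.lfc_scale, n)), 1e-3
    )
    sign = np.where(rng_de.random(n) < config.frac_up, 1.0, -1.0)
    delta = np.where(responsive, sign * magnitude, 0.0)

    subject = rng_subj.normal(0.0, config.subject_sd, config.n_pairs)
    cols, meta_rows = {}, []
    for i in range(config.n_pairs):
        base = mu + subject[i]
        for cond, shift in (("control", 0.0), ("treated", 1.0)):
            eps = (
                rng_eps.normal(0.0, np.sqrt(sigma_sq))
                if config.s0_sq > 0
                else np.zeros(n)
            )
            sid = f"RHE_{cond[:4]}_{i + 1}"
            cols[sid] = base + shift * delta + eps
            meta_rows.append(
                (sid, cond, f"pair{i + 1}", f"donor{i + 1}", "", "")
            )
    values = pd.DataFrame(cols, index=probes)
    samples = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "condition", "pair_id", "subject_id", "timepoint", "arm"],
    ).set_index("sample_id")
    matrix = ExpressionMatrix(values, samples, platform="APlus2")
    truth = SimTruth(
        responsive_probes=frozenset(probes[responsive]),
        true_lfc=pd.Series(delta, index=probes),
        d0=config.d0,
        s0_sq=config.s0_sq,
        true_sigma_sq=pd.Series(sigma_sq, index=probes),
    )
    return matrix, truth


def simulate_rhe_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, PlatformAnnotation, SimTruth]:
    """Convenience wrapper: generate the annotation and the paired
    experiment over it in one call."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_ann = np.random.default_rng(ss.spawn(6)[0])
    annotation = generate_annotation(
        config.n_probes_shared,
        config.n_probes_plus_only,
        config.max_probes_per_gene,
        seed=rng_ann,
    )
    matrix, truth = generate_paired_experiment(config, annotation=annotation)
    return matrix, annotation, truth


# ---------------------------------------------------------------------------
# the psoriasis cohort
# ---------------------------------------------------------------------------

def generate_cohort(
    config: CohortConfig, seed, genes=None, dysreg_genes=None
) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate a three-group psoriasis cohort with arm-specific recovery.

    Per dysregulated gene g: LS baseline mean = NL mean + d_g; week-2
    mean = LS baseline mean - r_{g,arm} * d_g, with r drawn from the
    arm's Beta distribution (or 0 for a placebo-style arm).  Gaussian
    noise of SD ``noise_sd`` is added to every measurement.

    ``genes`` optionally fixes the gene universe (overriding
    ``config.n_genes``) so the cohort can share identifiers with an
    array annotation; ``dysreg_genes`` forces which genes are
    dysregulated (a subset of the universe, overriding
    ``config.n_dysreg_genes``) — disease genes in real cohorts are not
    random, they include the cytokine-responsive ones.
    """
    config.validate()
    ss = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    rng_base, rng_dys, rng_rec, rng_eps = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    if genes is None:
        genes = pd.Index(
            [f"{50_001 + i}" for i in range(config.n_genes)], name="gene_id"
        )
    else:
        genes = pd.Index([str(g) for g in genes], name="gene_id")
        if genes.has_duplicates:
            raise InvalidParameterError("gene universe contains duplicates")
    n_genes = len(genes)
    baseline = rng_base.normal(config.baseline_loc, config.baseline_scale, n_genes)

    if dysreg_genes is None:
        if config.n_dysreg_genes > n_genes:
            raise InvalidParameterError("n_dysreg_genes exceeds the gene universe")
        dys_idx = np.sort(
            rng_dys.choice(n_genes, size=config.n_dysreg_genes, replace=False)
        )
    else:
        dysreg_genes = [str(g) for g in dysreg_genes]
        unknown = set(dysreg_genes) - set(genes)
        if unknown:
            raise InvalidParameterError(
                f"dysreg genes outside the universe: {sorted(unknown)[:5]}"
            )
        dys_idx = np.sort(genes.get_indexer(list(dict.fromkeys(dysreg_genes))))
    n_dysreg = len(dys_idx)
    magnitude = np.maximum(
        np.abs(rng_dys.normal(config.dysreg_loc, config.dysreg_scale, n_dysreg)),
        1e-3,
    )
    sign = np.where(rng_dys.random(n_dysreg) < config.frac_dysreg_up, 1.0, -1.0)
    d = np.zeros(n_genes)
    d[dys_idx] = sign * magnitude

    recovery = {}
    for arm, params in config.arms.items():
        r = np.zeros(n_genes)
        if isinstance(params, (int, float)) and params is not None:
            r[dys_idx] = float(params)
        elif params is not None:
            a, b = params
            r[dys_idx] = rng_rec.beta(a, b, size=n_dysreg)
        recovery[arm] = r
    recovery_df = pd.DataFrame(recovery, index=genes).iloc[dys_idx]

    cols, meta_rows = {}, []

    def emit(sid, mean, condition, timepoint, subject, arm):
        noise = (
            rng_eps.normal(0.0, config.noise_sd, n_genes)
            if config.noise_sd > 0
            else 0.0
        )
        cols[sid] = mean + noise
        meta_rows.append((sid, condition, "", subject, timepoint, arm))

    for arm in config.arms:
        r = recovery[arm]
        for p in range(1, config.n_patients_per_arm + 1):
            subject = f"{arm}_P{p:02d}"
            emit(f"{subject}_NL", baseline, "NL", "baseline", subject, arm)
            emit(f"{subject}_LS0", baseline + d, "LS", "baseline", subject, arm)
            emit(f"{subject}_LS2", baseline + (1.0 - r) * d, "LS", "week2", subject, arm)

    values = pd.DataFrame(cols, index=genes)
    samples = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "condition", "pair_id", "subject_id", "timepoint", "arm"],
    ).set_index("sample_id")
    matrix = ExpressionMatrix(values, samples, platform="A2")
    truth = SimTruth(
        dysreg_genes=frozenset(genes[dys_idx]),
        true_dysreg=pd.Series(d, index=genes).iloc[dys_idx],
        true_recovery_frac=recovery_df,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def truth_gene_sets(
    truth: SimTruth, annotation: PlatformAnnotation
) -> GeneSetCollection:
    """Gene sets derived from the planted truth: responsive genes,
    split by direction — the synthetic analogue of a curated
    cytokine-response signature."""
    lfc = truth.true_lfc
    gene_ids = annotation.table["gene_id"]
    up = sorted(set(gene_ids.loc[lfc.index[lfc > 0]]))
    down = sorted(set(gene_ids.loc[lfc.index[lfc < 0]]))
    coll = GeneSetCollection()
    if up:
        coll.add(GeneSet("RESPONSIVE_UP", "genes with planted positive effect", tuple(up)))
    if down:
        coll.add(GeneSet("RESPONSIVE_DOWN", "genes with planted negative effect", tuple(down)))
    return coll


def random_gene_sets(
    genes, n_sets: int, size: int, seed
) -> GeneSetCollection:
    """Random gene sets drawn uniformly from a gene universe (null sets)."""
    genes = list(genes)
    if size > len(genes):
        raise InvalidParameterError("set size exceeds the gene universe")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    coll = GeneSetCollection()
    for i in range(n_sets):
        members = rng.choice(genes, size=size, replace=False)
        coll.add(GeneSet(f"RANDOM_{i + 1:03d}", "uniform random set", tuple(sorted(members))))
    return coll
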