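"""Analysis suites tying features and expression tables together.

Each suite is a pure function of (inputs, config, seed) returning a tidy
table with one row per tested association: suite, dataset, outcome,
predictor, method, controlled covariates, coefficient, analytic P,
permutation P, and the number of genes used (listwise deletion over the
exact variable set involved, so n varies per row).

Suites:

* primary associations — inhibitory-pair content (fraction and presence)
  vs each outcome, marginal and partial (each covariate individually and
  all simultaneously);
* frame-shift controls — the same hexamers scanned in the +1/+2 frames,
  with frame-0 rows alongside for comparison;
* UTR controls — presence of the hexamers in 3'UTRs, marginal only;
* codon-optimality suite — tAI vs outcomes, marginal, partial
  (controlling pair content), and marginal on the zero-pair gene subset;
* position effect — pair position within single-pair genes vs decay;
* all-pairs scan — marginal correlations for every one of the 3721
  sense-codon pairs, with a rank-sum comparison of the 17 inhibitory
  pairs against the 3704 others.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_stats import (
    AssociationResult,
    PermutationConfig,
    associate,
    wilcoxon_rank_sum,
)
from .features import (
    CodonPairSet,
    SENSE_CODONS,
    _sense_codes,
    codon_code,
)
from .io_formats import EXPRESSION_COLUMNS, GeneRecord

logger = logging.getLogger("codonpairs")

RESULT_COLUMNS = (
    "suite", "dataset", "outcome", "predictor", "method", "covariates",
    "coefficient", "analytic_p", "permutation_p", "n",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Covariates, predictor modes, methods and permutation settings."""

    covariates: tuple[str, ...] = ("gc", "tai", "dipeptide_fraction", "coding_length")
    predictors: tuple[str, ...] = ("pair_fraction", "pair_presence")
    methods: tuple[str, ...] = ("spearman", "kendall")
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    alpha: float = 0.05


def prepare_table(features: pd.DataFrame, expression: pd.DataFrame) -> pd.DataFrame:
    """Join features and expression on gene_id; add derived columns.

    ``coding_length`` aliases the sense-codon count and frame presence
    flags are derived from the frame counts.
    """
    df = features.merge(expression, on="gene_id", how="inner", validate="1:1")
    df["coding_length"] = df["n_codons"]
    for f in (1, 2):
        df[f"frame{f}_presence"] = (df[f"frame{f}_count"] >= 1).astype(int)
    return df


def _check_covariates(df: pd.DataFrame, config: AnalysisConfig) -> None:
    missing = [c for c in config.covariates if c not in df.columns]
    if missing:
        raise ValueError(f"covariate column(s) {missing} absent from feature table")


def _outcomes_present(df: pd.DataFrame, outcomes: Sequence[str] | None) -> list[str]:
    wanted = outcomes if outcomes is not None else EXPRESSION_COLUMNS
    present = [o for o in wanted if o in df.columns and df[o].notna().any()]
    for o in set(wanted) - set(present):
        logger.info("outcome %s absent or empty; skipped", o)
    return present


def _row(suite: str, dataset: str, res: AssociationResult) -> dict:
    return {
        "suite": suite,
        "dataset": dataset,
        "outcome": res.outcome,
        "predictor": res.predictor,
        "method": res.method,
        "covariates": "+".join(res.covariates),
        "coefficient": res.coefficient,
        "analytic_p": res.analytic_p,
        "permutation_p": res.permutation_p,
        "n": res.n,
    }


def _as_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_primary_associations(
    features: pd.DataFrame,
    expression: pd.DataFrame,
    config: AnalysisConfig | None = None,
    dataset: str = "",
    outcomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pair-content vs outcome associations, marginal and partial."""
    config = config or AnalysisConfig()
    df = prepare_table(features, expression)
    _check_covariates(df, config)
    covariate_sets: list[tuple[str, ...]] = [()]
    covariate_sets += [(c,) for c in config.covariates]
    if len(config.covariates) > 1:
        covariate_sets.append(tuple(config.covariates))
    rows = []
    for outcome in _outcomes_present(df, outcomes):
        for predictor, method, covs in itertools.product(
            config.predictors, config.methods, covariate_sets
        ):
            res = associate(df, predictor, outcome, covs, method, config.permutation)
            rows.append(_row("primary", dataset, res))
    return _as_frame(rows)


def run_frameshift_controls(
    features: pd.DataFrame,
    expression: pd.DataFrame,
    config: AnalysisConfig | None = None,
    dataset: str = "",
    outcomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Shifted-frame hexamer content vs outcomes, frame 0 alongside.

    Partial rows control the frame-0 covariate set (GC, tAI, the
    dipeptide content encoded by the in-frame pairs, coding length).
    """
    config = config or AnalysisConfig()
    df = prepare_table(features, expression)
    _check_covariates(df, config)
    frame_predictors = {
        0: {"fraction": "pair_fraction", "presence": "pair_presence"},
        1: {"fraction": "frame1_fraction", "presence": "frame1_presence"},
        2: {"fraction": "frame2_fraction", "presence": "frame2_presence"},
    }
    rows = []
    for outcome in _outcomes_present(df, outcomes):
        for frame, mapping in frame_predictors.items():
            for mode, method in itertools.product(config.predictors, config.methods):
                key = "fraction" if mode.endswith("fraction") else "presence"
                predictor = mapping[key]
                sub = df[[predictor]].dropna()
                if len(sub) == 0 or (frame > 0 and (sub[predictor] == 0).all()):
                    logger.info(
                        "frame %d %s: no out-of-frame occurrences; row skipped",
                        frame, key,
                    )
                    continue
                for covs in ((), tuple(config.covariates)):
                    res = associate(df, predictor, outcome, covs, method, config.permutation)
                    rows.append(_row(f"frameshift_frame{frame}", dataset, res))
    return _as_frame(rows)


def run_utr_controls(
    features: pd.DataFrame,
    expression: pd.DataFrame,
    config: AnalysisConfig | None = None,
    dataset: str = "",
    outcomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """3'UTR hexamer presence vs outcomes — marginal correlations only.

    Genes without a UTR annotation are excluded by listwise deletion; if
    no gene has one, the suite is skipped with a log entry.
    """
    config = config or AnalysisConfig()
    df = prepare_table(features, expression)
    if "utr_presence" not in df.columns or df["utr_presence"].isna().all():
        logger.warning("no UTR annotations available; UTR suite skipped")
        return _as_frame([])
    rows = []
    for outcome in _outcomes_present(df, outcomes):
        for method in config.methods:
            res = associate(df, "utr_presence", outcome, (), method, config.permutation)
            rows.append(_row("utr", dataset, res))
    return _as_frame(rows)


def run_optimality_suite(
    features: pd.DataFrame,
    expression: pd.DataFrame,
    config: AnalysisConfig | None = None,
    dataset: str = "",
    outcomes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """tAI vs outcomes: marginal, pair-controlled partial, zero-pair subset.

    Returns (table, subset_table); the subset table holds marginal
    associations recomputed on genes with zero inhibitory pairs.
    """
    config = config or AnalysisConfig()
    df = prepare_table(features, expression)
    _check_covariates(df, config)
    rows = []
    for outcome in _outcomes_present(df, outcomes):
        for method in config.methods:
            res = associate(df, "tai", outcome, (), method, config.permutation)
            rows.append(_row("optimality_marginal", dataset, res))
            for mode in config.predictors:
                covs = ("gc", mode, "dipeptide_fraction", "coding_length")
                res = associate(df, "tai", outcome, covs, method, config.permutation)
                rows.append(_row("optimality_partial", dataset, res))
    subset = df[df["pair_count"] == 0]
    sub_rows = []
    if len(subset) == 0:
        logger.warning("zero-pair gene subset is empty; subset table empty")
    else:
        for outcome in _outcomes_present(subset, outcomes):
            for method in config.methods:
                res = associate(subset, "tai", outcome, (), method, config.permutation)
                sub_rows.append(_row("optimality_zero_pair", dataset, res))
    return _as_frame(rows), _as_frame(sub_rows)


def run_position_effect(
    features: pd.DataFrame,
    expression: pd.DataFrame,
    config: AnalysisConfig | None = None,
    dataset: str = "",
    outcomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pair position vs decay for genes with exactly one inhibitory pair."""
    config = config or AnalysisConfig()
    df = prepare_table(features, expression)
    df = df[df["single_pair_position"].notna()]
    if outcomes is None:
        outcomes = [o for o in ("decay_rate", "protein_decay_rate") if o in df.columns]
    rows = []
    for outcome in _outcomes_present(df, outcomes):
        usable = df[[outcome, "single_pair_position"]].dropna()
        if len(usable) < 3:
            logger.warning("position-effect suite: <3 usable genes for %s; skipped", outcome)
            continue
        for method in config.methods:
            res = associate(df, "single_pair_position", outcome, (), method, config.permutation)
            rows.append(_row("position", dataset, res))
    return _as_frame(rows)


# --- all-pairs scan ------------------------------------------------------

def all_codon_pairs() -> tuple[str, ...]:
    """The full universe of sense-codon pairs (61 x 61 = 3721 hexamers)."""
    return tuple(a + b for a in SENSE_CODONS for b in SENSE_CODONS)


@dataclass
class PairScanResult:
    """Per-pair correlation table and the inhibitory-vs-other comparison."""

    per_pair: pd.DataFrame
    group_comparison: pd.DataFrame

    @property
    def n_pairs(self) -> int:
        return len(self.per_pair)

    @property
    def n_inhibitory(self) -> int:
        return int(self.per_pair["inhibitory"].sum())


def _pair_fraction_matrix(
    records: Sequence[GeneRecord], universe: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-gene fraction of each universe pair: (fractions, counts, gene_ids)."""
    code_to_col = np.full(64 * 64, -1, dtype=np.int64)
    for col, hexamer in enumerate(universe):
        code_to_col[codon_code(hexamer[:3]) * 64 + codon_code(hexamer[3:])] = col
    n_pairs = len(universe)
    counts = np.zeros((len(records), n_pairs), dtype=np.int32)
    denom = np.empty(len(records))
    gene_ids = []
    for g, rec in enumerate(records):
        codes = _sense_codes(rec.cds)
        gene_ids.append(rec.gene_id)
        L = len(codes)
        denom[g] = max(L - 1, 1)
        if L < 2:
            continue
        cols = code_to_col[codes[:-1] * 64 + codes[1:]]
        cols = cols[cols >= 0]
        counts[g] = np.bincount(cols, minlength=n_pairs)
    fractions = counts / denom[:, None]
    return fractions, counts, gene_ids


def _columnwise_spearman(F: np.ndarray, y: np.ndarray) -> np.ndarray:
    Rf = stats.rankdata(F, axis=0)
    ry = stats.rankdata(y)
    Rf = Rf - Rf.mean(axis=0)
    ry = ry - ry.mean()
    num = Rf.T @ ry
    den = np.sqrt((Rf ** 2).sum(axis=0) * (ry ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = num / den
    return rho


def _columnwise_kendall(F: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sign-covariance Kendall of each column of F against y."""
    Sy = np.sign(y[:, None] - y[None, :]).astype(np.int8)
    cyy = float(np.sum(Sy.astype(np.int64) ** 2))
    taus = np.empty(F.shape[1])
    for col in range(F.shape[1]):
        x = F[:, col]
        Sx = np.sign(x[:, None] - x[None, :]).astype(np.int8)
        cxx = float(np.sum(Sx.astype(np.int64) ** 2))
        if cxx == 0 or cyy == 0:
            taus[col] = np.nan
            continue
        cxy = float(np.sum(Sx * Sy, dtype=np.int64))
        taus[col] = cxy / np.sqrt(cxx * cyy)
    return taus


def run_all_pairs_scan(
    records: Sequence[GeneRecord],
    expression: pd.DataFrame,
    config: AnalysisConfig | None = None,
    dataset: str = "",
    outcomes: Sequence[str] | None = None,
    pairs: CodonPairSet | None = None,
) -> PairScanResult:
    """Marginal correlation of every sense-codon pair with each outcome.

    Pairs present in very few genes are retained (their per-outcome gene
    count is reported so users can filter downstream).  The group
    comparison is a one-sided rank-sum test of whether the inhibitory
    pairs' coefficients exceed those of the 3704 other pairs.
    """
    config = config or AnalysisConfig()
    pairs = pairs or CodonPairSet()
    universe = all_codon_pairs()
    inhibitory = np.array([p in set(pairs.pairs) for p in universe])
    F, counts, gene_ids = _pair_fraction_matrix(records, universe)
    expr = expression.set_index("gene_id").reindex(gene_ids)
    if outcomes is None:
        outcomes = [o for o in ("decay_rate",) if o in expr.columns]
    per_pair = pd.DataFrame({
        "hexamer": universe,
        "inhibitory": inhibitory,
        "n_genes_with_pair": (counts > 0).sum(axis=0),
    })
    comparisons = []
    for outcome in outcomes:
        y = expr[outcome].to_numpy(dtype=float)
        valid = np.isfinite(y)
        if valid.sum() < 3:
            logger.warning("scan: outcome %s has <3 measured genes; skipped", outcome)
            continue
        Fv, yv = F[valid], y[valid]
        per_pair[f"n_genes_{outcome}"] = (counts[valid] > 0).sum(axis=0)
        for method in config.methods:
            if method == "spearman":
                coef = _columnwise_spearman(Fv, yv)
            else:
                coef = _columnwise_kendall(Fv, yv)
            col = f"{method}_{outcome}"
            per_pair[col] = coef
            a = coef[inhibitory]
            b = coef[~inhibitory]
            p = wilcoxon_rank_sum(a[np.isfinite(a)], b[np.isfinite(b)], "greater")
            comparisons.append({
                "dataset": dataset, "outcome": outcome, "method": method,
                "rank_sum_p": p,
                "n_inhibitory": int(np.isfinite(a).sum()),
                "n_other": int(np.isfinite(b).sum()),
            })
    return PairScanResult(
        per_pair=per_pair,
        group_comparison=pd.DataFrame(
            comparisons,
            columns=["dataset", "outcome", "method", "rank_sum_p",
                     "n_inhibitory", "n_other"],
        ),
    )


def render_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy suite table into a method-by-outcome wide layout."""
    if table.empty:
        return table
    wide = table.pivot_table(
        index=["suite", "dataset", "outcome", "predictor", "covariates"],
        columns="method",
        values=["coefficient", "analytic_p", "permutation_p"],
        aggfunc="first",
        sort=False,
    )
    wide.columns = [f"{m}_{v}" for v, m in wide.columns]
    return wide.reset_index()
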