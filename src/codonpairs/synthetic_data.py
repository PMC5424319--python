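"""Synthetic coding sequences, 3'UTRs and expression tables.

The generator emulates the statistical structure of the genome-scale
inputs the analyses consume, with planted, user-controlled effects:

* per-gene coding sequences whose codons are drawn from a two-component
  optimal/nonoptimal mixture (a per-gene mixture weight induces a smooth
  tAI distribution across genes);
* inhibitory codon pairs inserted at a per-gene Poisson rate, optionally
  coupled to the nonoptimal mixture weight so that pair content and
  codon optimality are confounded, as they are in the real genome;
* expression variables generated on the log scale as a linear function
  of the true sequence features plus Gaussian noise, exponentiated so
  all rates are positive, with per-outcome missingness emulating the
  partial coverage of real kinetic datasets.

Ground-truth features are recomputed from the emitted sequences (not
read back from the insertion log), so spontaneous pair occurrences
arising from background codon sampling are counted as real.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    CodonPairSet,
    SENSE_CODONS,
    _ALL_CODONS,
    codon_code,
    compute_gene_features,
)
from .io_formats import (
    CodonWeightTable,
    GeneRecord,
    write_codon_weights,
    write_fasta,
)

logger = logging.getLogger("codonpairs")


def default_weight_table(pairs: CodonPairSet | None = None) -> CodonWeightTable:
    """A deterministic synthetic codon-weight table.

    The constituent codons of the inhibitory pairs are always classified
    nonoptimal (as they are in S. cerevisiae); the remaining sense codons
    are split into 26 optimal codons with high relative adaptiveness and
    the rest nonoptimal with low adaptiveness.  Weights are spaced
    deterministically so the table is identical across runs.
    """
    pairs = pairs or CodonPairSet()
    constituent = pairs.codons
    others = [c for c in sorted(SENSE_CODONS) if c not in constituent]
    optimal = others[::2][:26]
    nonoptimal = [c for c in sorted(SENSE_CODONS) if c not in optimal]
    weights: dict[str, float] = {}
    for rank, c in enumerate(sorted(optimal)):
        weights[c] = round(0.62 + 0.38 * rank / max(len(optimal) - 1, 1), 4)
    for rank, c in enumerate(sorted(nonoptimal)):
        weights[c] = round(0.08 + 0.38 * rank / max(len(nonoptimal) - 1, 1), 4)
    return CodonWeightTable(weights=weights, optimal_set=frozenset(optimal))


@dataclass(frozen=True)
class OutcomeEffect:
    """Log-scale linear effect of the true features on one outcome.

    log(value) = beta0 + beta_pair*pair_fraction + beta_tai*(1 - tai)
               + beta_gc*gc + beta_len*log(L) + beta_utr*utr_presence
               + Normal(0, sigma^2)

    pair_fraction is of order 1e-3, so beta_pair magnitudes around 100
    produce partial correlations of the order seen genome-wide (~0.1).
    """

    beta0: float = 0.0
    beta_pair: float = 0.0
    beta_tai: float = 0.0
    beta_gc: float = 0.0
    beta_len: float = 0.0
    beta_utr: float = 0.0
    sigma: float = 0.8
    missing_rate: float = 0.15


def default_effects() -> dict[str, OutcomeEffect]:
    """Effects reproducing the qualitative genome-scale sign pattern.

    Decay is faster for pair-rich and nonoptimal genes; synthesis and
    protein decay depend on codon optimality only (so their marginal
    association with pair content is purely the usage confound); both
    translation-efficiency proxies carry genuine negative pair effects
    on top of a positive optimality effect.
    """
    return {
        "synthesis_rate": OutcomeEffect(beta0=0.5, beta_tai=-4.0),
        "decay_rate": OutcomeEffect(beta0=-3.0, beta_pair=60.0, beta_tai=3.0),
        "protein_per_mrna": OutcomeEffect(beta0=6.0, beta_pair=-50.0, beta_tai=-3.0),
        "ribosome_occupancy": OutcomeEffect(beta0=0.0, beta_pair=-50.0, beta_tai=-2.5),
        "protein_decay_rate": OutcomeEffect(beta0=-4.0, beta_tai=1.5),
    }


def null_effects(missing_rate: float = 0.0) -> dict[str, OutcomeEffect]:
    """All betas zero: outcomes independent of every feature."""
    return {
        name: OutcomeEffect(missing_rate=missing_rate)
        for name in default_effects()
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped defaults for the synthetic genome.

    4879 genes matches the verified nuclear ORF set the real analysis
    uses; lengths are lognormal with a 400-codon median (typical of the
    yeast proteome); planted pairs arrive at a per-gene Poisson rate of
    0.3 on top of spontaneous occurrences from background codon
    sampling, giving roughly one pair per gene overall.  With
    ``couple_pairs_to_usage`` the pair rate scales with the nonoptimal
    mixture weight, reproducing the real confounding between pair
    content and codon optimality.
    """

    n_genes: int = 4879
    length_median: float = 400.0
    length_sigma: float = 0.45
    min_length: int = 10
    mix_alpha: float = 6.0
    mix_beta: float = 3.0
    pair_lambda: float = 0.3
    couple_pairs_to_usage: bool = True
    background_excludes_pair_codons: bool = False
    utr_prob: float = 0.8
    utr_length: int = 120
    utr_gc: float = 0.35
    utr_hexamer_prob: float = 0.0
    effects: dict[str, OutcomeEffect] = field(default_factory=default_effects)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pair_lambda < 0:
            raise ValueError("pair_lambda must be >= 0")
        if self.min_length < 10:
            raise ValueError("min_length must be >= 10 codons")
        for name, eff in self.effects.items():
            if eff.sigma <= 0:
                raise ValueError(f"sigma for {name} must be > 0")


def _sample_pair_positions(L: int, k: int, rng: np.random.Generator) -> np.ndarray | None:
    """k 0-based 5'-codon positions in 0..L-2, separated by >= 3 codons.

    The one-codon gap between inserted pairs prevents the 3' codon of one
    insertion abutting the 5' codon of the next, which could itself form
    a member pair and break the planted count.
    """
    if k * 3 - 1 > L:
        return None
    for _ in range(200):
        pos = np.sort(rng.choice(L - 1, size=k, replace=False))
        if k == 1 or np.all(np.diff(pos) >= 3):
            return pos
    return None


def generate_genes(
    config: GeneratorConfig,
    seed: int | None = None,
    pairs: CodonPairSet | None = None,
    weights: CodonWeightTable | None = None,
) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Generate gene records and the ground-truth feature table.

    Returns (records, truth) where ``truth`` is the full feature table
    recomputed from the emitted sequences with the standard feature
    extractor, so it is exact by construction.
    """
    pairs = pairs or CodonPairSet()
    weights = weights or default_weight_table(pairs)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_genes

    lengths = np.maximum(
        np.rint(config.length_median * np.exp(config.length_sigma * rng.standard_normal(n))),
        config.min_length,
    ).astype(int)
    w_opt = rng.beta(config.mix_alpha, config.mix_beta, size=n)

    constituent_codes = {codon_code(c) for c in pairs.codons}
    opt_codes = np.array(sorted(codon_code(c) for c in weights.optimal_set))
    non_codes_all = sorted(
        codon_code(c) for c in SENSE_CODONS if c not in weights.optimal_set
    )
    if config.background_excludes_pair_codons:
        non_codes = np.array([c for c in non_codes_all if c not in constituent_codes])
        opt_codes = np.array([c for c in opt_codes if c not in constituent_codes])
    else:
        non_codes = np.array(non_codes_all)

    total = int(lengths.sum())
    w_rep = np.repeat(w_opt, lengths)
    is_opt = rng.random(total) < w_rep
    codes = np.where(
        is_opt,
        opt_codes[rng.integers(0, len(opt_codes), total)],
        non_codes[rng.integers(0, len(non_codes), total)],
    )
    per_gene = np.split(codes, np.cumsum(lengths)[:-1])

    mean_wopt = config.mix_alpha / (config.mix_alpha + config.mix_beta)
    if config.couple_pairs_to_usage:
        lam = config.pair_lambda * (1.0 - w_opt) / (1.0 - mean_wopt)
    else:
        lam = np.full(n, config.pair_lambda)
    n_insert = rng.poisson(lam)

    member5 = np.array([codon_code(p[:3]) for p in pairs.pairs])
    member3 = np.array([codon_code(p[3:]) for p in pairs.pairs])
    codon_strs = np.array(_ALL_CODONS)

    records: list[GeneRecord] = []
    planted = np.zeros(n, dtype=int)
    for g in range(n):
        gene_codes = per_gene[g]
        k = int(n_insert[g])
        while k > 0:
            pos = _sample_pair_positions(lengths[g], k, rng)
            if pos is not None:
                which = rng.integers(0, len(pairs.pairs), k)
                gene_codes[pos] = member5[which]
                gene_codes[pos + 1] = member3[which]
                break
            logger.info("gene g%04d too short for %d insertions; resampling", g, k)
            k = int(rng.poisson(lam[g]))
        planted[g] = k
        cds = "".join(codon_strs[gene_codes].tolist()) + "TAA"
        utr = None
        if rng.random() < config.utr_prob:
            utr = _make_utr(config, rng, pairs)
        records.append(GeneRecord(gene_id=f"g{g:04d}", cds=cds, utr3=utr, status="Verified"))

    truth = compute_gene_features(records, weights, pairs)
    # generator-side ground truth: emitted features are recomputed above,
    # these two columns record the latent per-gene generating quantities
    truth["planted_pairs"] = planted
    truth["mix_weight"] = w_opt
    return records, truth


def _make_utr(config: GeneratorConfig, rng: np.random.Generator, pairs: CodonPairSet) -> str:
    p_gc = config.utr_gc / 2.0
    p_at = (1.0 - config.utr_gc) / 2.0
    bases = rng.choice(list("ACGT"), size=config.utr_length, p=[p_at, p_gc, p_gc, p_at])
    utr = "".join(bases)
    if rng.random() < config.utr_hexamer_prob:
        hexamer = pairs.pairs[rng.integers(0, len(pairs.pairs))]
        start = int(rng.integers(0, config.utr_length - 6))
        utr = utr[:start] + hexamer + utr[start + 6:]
    return utr


def generate_expression(
    truth: pd.DataFrame,
    config: GeneratorConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate the per-gene expression table from true features.

    Outcomes follow the log-linear effect model of ``config.effects``;
    values are exponentiated so all rates are positive, then masked at
    each outcome's missing rate to emulate partial dataset coverage.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 1])
    )
    n = len(truth)
    pf = truth["pair_fraction"].to_numpy(dtype=float)
    tai = truth["tai"].to_numpy(dtype=float)
    gc = truth["gc"].to_numpy(dtype=float)
    logL = np.log(truth["n_codons"].to_numpy(dtype=float))
    utr = truth["utr_presence"].astype(float).fillna(0.0).to_numpy()
    out = pd.DataFrame({"gene_id": truth["gene_id"]})
    for name, eff in config.effects.items():
        log_v = (
            eff.beta0
            + eff.beta_pair * pf
            + eff.beta_tai * (1.0 - tai)
            + eff.beta_gc * gc
            + eff.beta_len * logL
            + eff.beta_utr * utr
            + eff.sigma * rng.standard_normal(n)
        )
        v = np.exp(log_v)
        if eff.missing_rate > 0:
            v[rng.random(n) < eff.missing_rate] = np.nan
        out[name] = v
    return out


# --- reporter constructs ------------------------------------------------

def make_reporter(
    n_codons: int,
    n_optimal: int,
    n_pairs: int,
    weights: CodonWeightTable | None = None,
    pairs: CodonPairSet | None = None,
) -> str:
    """Build a synthetic reporter CDS with exact composition.

    Exactly ``n_pairs`` member pairs (placed non-adjacently so no
    spurious pair forms), exactly ``n_optimal`` optimal sense codons, and
    ``n_codons`` sense codons total, plus a terminal stop.  Requires
    n_optimal <= n_codons - 2*n_pairs since pair codons are nonoptimal.
    """
    pairs = pairs or CodonPairSet()
    weights = weights or default_weight_table(pairs)
    if n_optimal > n_codons - 2 * n_pairs:
        raise ValueError("not enough non-pair positions for requested optimal codons")
    constituent = pairs.codons
    optimal_fill = sorted(weights.optimal_set)
    nonopt_fill = sorted(
        c for c in SENSE_CODONS
        if c not in weights.optimal_set and c not in constituent
    )
    codons: list[str | None] = [None] * n_codons
    for k in range(n_pairs):
        p = pairs.pairs[k % len(pairs.pairs)]
        i = 3 * k  # pair at codons 3k, 3k+1; a filler codon separates pairs
        codons[i], codons[i + 1] = p[:3], p[3:]
    free = [i for i, c in enumerate(codons) if c is None]
    for rank, i in enumerate(free):
        if rank < n_optimal:
            codons[i] = optimal_fill[rank % len(optimal_fill)]
        else:
            codons[i] = nonopt_fill[rank % len(nonopt_fill)]
    return "".join(codons) + "TAA"


# --- bundled fixture ----------------------------------------------------

FIXTURE_DATASETS = ("sim_a", "sim_b", "sim_c", "sim_d")


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a deterministic 200-gene mini-genome and expression tables.

    Emits a genome FASTA, 3'UTR FASTA, annotation and codon-weight TSVs,
    and four expression TSVs emulating kinetic datasets with differing
    noise and coverage.  Byte-identical for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = CodonPairSet()
    weights = default_weight_table(pairs)
    config = replace(GeneratorConfig(), n_genes=200, length_median=200.0, seed=seed)
    records, truth = generate_genes(config, pairs=pairs, weights=weights)

    paths: dict[str, Path] = {}
    paths["genome"] = out_dir / "genome.fasta"
    write_fasta(records, paths["genome"])
    paths["utrs"] = out_dir / "utrs.fasta"
    with open(paths["utrs"], "w") as fh:
        for rec in records:
            if rec.utr3:
                fh.write(f">{rec.gene_id}\n{rec.utr3}\n")
    paths["annotation"] = out_dir / "annotation.tsv"
    pd.DataFrame(
        {"gene_id": [r.gene_id for r in records], "status": "Verified"}
    ).to_csv(paths["annotation"], sep="\t", index=False)
    paths["weights"] = out_dir / "weights.tsv"
    write_codon_weights(weights, paths["weights"])

    for d, name in enumerate(FIXTURE_DATASETS):
        effects = {
            k: replace(v, sigma=v.sigma * (1.0 + 0.2 * d), missing_rate=0.1 + 0.05 * d)
            for k, v in config.effects.items()
        }
        expr = generate_expression(truth, replace(config, effects=effects), seed=seed + 1000 + d)
        p = out_dir / f"expression_{name}.tsv"
        expr.to_csv(p, sep="\t", index=False, na_rep="NA", float_format="%.6g")
        paths[name] = p
    return paths
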