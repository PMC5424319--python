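"""Per-gene sequence features used by the association analyses.

The central predictor is the content of 17 adjacent codon pairs that
strongly inhibit translation elongation in S. cerevisiae reporter assays
(DEFAULT_INHIBITORY_PAIRS).  For each gene this module computes, from the
coding sequence alone:

* in-frame pair count and fraction (count / (L-1) adjacent sense-codon
  positions, stop codon excluded) plus a presence flag;
* hexamer occurrences of the same sequences in the +1/+2 shifted frames
  (negative controls separating codon-pair effects from hexanucleotide
  effects), and presence in the 3'UTR (frameless, untranslated);
* the covariates used in partial correlations: gene-level tAI (geometric
  mean of per-codon relative adaptiveness), GC content, the fraction of
  encoded residue pairs matching the dipeptides of the inhibitory pairs,
  and coding length in sense codons;
* the codon position of the pair for genes carrying exactly one
  (position-effect analysis) and per-reporter summaries.

Counting is overlap-inclusive: CGA CGA CGA holds two CGACGA pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io_formats import CodonWeightTable, GeneRecord, STOP_CODONS

logger = logging.getLogger("codonpairs")

#: The 17 inhibitory adjacent codon pairs (5' codon + 3' codon hexamers).
DEFAULT_INHIBITORY_PAIRS = (
    "AGGCGA", "AGGCGG", "ATACGA", "ATACGG", "CGAATA", "CGACCG",
    "CGACGA", "CGACGG", "CGACTG", "CGAGCG", "CTCCCG", "CTGATA",
    "CTGCCG", "CTGCGA", "GTACCG", "GTACGA", "GTGCGA",
)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

# --- nucleotide/codon integer codecs -----------------------------------
_NT_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _nt in enumerate("ACGT"):
    _NT_CODE[ord(_nt)] = _i

_ALL_CODONS = ["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"]
SENSE_CODONS = tuple(c for c in _ALL_CODONS if c not in STOP_CODONS)
_STOP_CODES = frozenset(_ALL_CODONS.index(c) for c in STOP_CODONS)

# codon code -> one-letter amino acid ('*' for stop)
_AA_BY_CODE = np.array(
    [_STANDARD_TABLE.forward_table.get(c, "*") for c in _ALL_CODONS]
)


def _nt_codes(seq: str) -> np.ndarray:
    codes = _NT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) > 3:
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def _codon_codes(cds: str) -> np.ndarray:
    """Encode a CDS as an array of codon codes 0..63 (A=0,C=1,G=2,T=3)."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    nt = _nt_codes(cds).reshape(-1, 3).astype(np.int64)
    return nt[:, 0] * 16 + nt[:, 1] * 4 + nt[:, 2]


def _sense_codes(cds: str) -> np.ndarray:
    """Codon codes with a terminal stop codon, if present, removed."""
    codes = _codon_codes(cds)
    if len(codes) and codes[-1] in _STOP_CODES:
        codes = codes[:-1]
    return codes


def codon_code(codon: str) -> int:
    return int(_codon_codes(codon)[0])


@dataclass(frozen=True)
class CodonPairSet:
    """An ordered set of codon-pair hexamers and their encoded dipeptides.

    Neither half of a member may be a stop codon.  ``dipeptides`` holds
    one two-letter residue string per distinct translation of a member.
    """

    pairs: tuple[str, ...] = DEFAULT_INHIBITORY_PAIRS
    dipeptides: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        seen = set()
        dipeps = set()
        for p in self.pairs:
            if len(p) != 6 or set(p) - set("ACGT"):
                raise ValueError(f"invalid codon pair {p!r}")
            if p[:3] in STOP_CODONS or p[3:] in STOP_CODONS:
                raise ValueError(f"codon pair {p!r} contains a stop codon")
            if p in seen:
                raise ValueError(f"duplicate codon pair {p!r}")
            seen.add(p)
            dipeps.add(
                _STANDARD_TABLE.forward_table[p[:3]]
                + _STANDARD_TABLE.forward_table[p[3:]]
            )
        object.__setattr__(self, "dipeptides", frozenset(dipeps))

    @cached_property
    def pair_codes(self) -> np.ndarray:
        """Members encoded as 12-bit integers (64 * code5' + code3')."""
        return np.array(
            [codon_code(p[:3]) * 64 + codon_code(p[3:]) for p in self.pairs],
            dtype=np.int64,
        )

    @cached_property
    def hexamer_codes(self) -> np.ndarray:
        """Members encoded base-4 over all six nucleotides."""
        weights = 4 ** np.arange(5, -1, -1)
        return np.array([int(_nt_codes(p) @ weights) for p in self.pairs])

    @property
    def codons(self) -> frozenset[str]:
        """The distinct constituent codons of the member pairs."""
        return frozenset(c for p in self.pairs for c in (p[:3], p[3:]))


def count_inframe_pairs(cds: str, pairs: CodonPairSet) -> tuple[int, int]:
    """Count in-frame member pairs among sense codons; return (count, L).

    L is the number of sense codons (terminal stop excluded).  Adjacent
    positions i, i+1 for 1 <= i <= L-1 are tested; overlapping
    occurrences each count.
    """
    codes = _sense_codes(cds)
    L = len(codes)
    if L < 2:
        logger.warning("count_inframe_pairs: CDS with %d sense codon(s)", L)
        return 0, L
    pair_codes = codes[:-1] * 64 + codes[1:]
    count = int(np.isin(pair_codes, pairs.pair_codes).sum())
    return count, L


def pair_fraction(count: int, L: int) -> float | None:
    """Pair count divided by the L-1 adjacent sense-codon positions."""
    if L < 2:
        return None
    return count / (L - 1)


def shifted_frame_counts(
    cds: str, pairs: CodonPairSet, frame: int
) -> tuple[int, float | None]:
    """Hexamer occurrences at nucleotide offsets congruent to ``frame``.

    Scans the raw nucleotide string at offsets p with p mod 3 == frame,
    0 <= p <= len(cds)-6; the fraction divides by the number of scanned
    offsets.  Frame 0 here is a plain hexamer scan and so may exceed the
    codon-pair count when a member hexamer overlaps the stop codon.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    if len(cds) < 6:
        return 0, None
    nt = _nt_codes(cds).astype(np.int64)
    n_offsets = len(cds) - 5
    hexcodes = np.zeros(n_offsets, dtype=np.int64)
    for i in range(6):
        hexcodes = hexcodes * 4 + nt[i : i + n_offsets]
    member_hex = pairs.hexamer_codes
    offsets = np.arange(n_offsets)
    sel = offsets % 3 == frame
    if not sel.any():
        return 0, None
    count = int(np.isin(hexcodes[sel], member_hex).sum())
    return count, count / int(sel.sum())


def utr_pair_presence(utr3: str | None, pairs: CodonPairSet) -> int | None:
    """1 if any member hexamer occurs anywhere in the 3'UTR, else 0.

    The search is frameless (UTRs are untranslated).  A missing or empty
    UTR yields None so the gene drops out of the UTR analysis.
    """
    if not utr3:
        return None
    utr3 = utr3.upper()
    return int(any(p in utr3 for p in pairs.pairs))


def _weight_array(weights: CodonWeightTable) -> np.ndarray:
    """Codon-code-indexed weight lookup (NaN for absent codons), cached."""
    arr = getattr(weights, "_weight_array", None)
    if arr is None:
        arr = np.full(64, np.nan)
        for codon, w in weights.weights.items():
            arr[codon_code(codon)] = w
        weights._weight_array = arr
    return arr


def gene_tai(cds: str, weights: CodonWeightTable) -> float | None:
    """Gene-level tAI: geometric mean of relative adaptiveness over sense codons."""
    codes = _sense_codes(cds)
    if len(codes) == 0:
        return None
    w = _weight_array(weights)[codes]
    if np.isnan(w).any():
        missing = {_ALL_CODONS[c] for c in codes if _ALL_CODONS[c] not in weights.weights}
        logger.warning("gene_tai: missing weight(s) for %s", sorted(missing))
        return None
    return float(np.exp(np.mean(np.log(w))))


def gc_content(cds: str) -> float:
    """Fraction of G+C over the full CDS, stop codon included."""
    if not cds:
        raise ValueError("empty sequence")
    return (cds.count("G") + cds.count("C")) / len(cds)


def dipeptide_fraction(cds: str, pairs: CodonPairSet) -> float | None:
    """Fraction of adjacent residue pairs matching the member dipeptides.

    Sense codons are translated with the standard nuclear code; an
    internal stop codon flags the gene and yields a missing value.
    """
    codes = _sense_codes(cds)
    L = len(codes)
    if L < 2:
        return None
    aa = _AA_BY_CODE[codes]
    if (aa == "*").any():
        logger.warning("dipeptide_fraction: internal stop codon; feature missing")
        return None
    dipeps = np.char.add(aa[:-1], aa[1:])
    members = np.array(sorted(pairs.dipeptides))
    return float(np.isin(dipeps, members).sum() / (L - 1))


def single_pair_position(cds: str, pairs: CodonPairSet) -> int | None:
    """1-based codon index of the 5' codon of the unique in-frame pair.

    Defined only for genes carrying exactly one member pair; genes with
    zero or two or more (including overlapping) occurrences yield None.
    """
    codes = _sense_codes(cds)
    if len(codes) < 2:
        return None
    pair_codes = codes[:-1] * 64 + codes[1:]
    hits = np.flatnonzero(np.isin(pair_codes, pairs.pair_codes))
    if len(hits) != 1:
        return None
    return int(hits[0]) + 1


@dataclass(frozen=True)
class ReporterSummary:
    n_optimal: int
    optimal_fraction: float
    pair_count: int
    pair_fraction: float


def reporter_summary(
    cds: str, weights: CodonWeightTable, pairs: CodonPairSet
) -> ReporterSummary:
    """Optimal-codon and inhibitory-pair content of a reporter construct.

    The optimal fraction divides by L sense codons; the pair fraction by
    the L-1 adjacent positions.
    """
    codes = _sense_codes(cds)
    L = len(codes)
    optimal_codes = {codon_code(c) for c in weights.optimal_set}
    n_optimal = int(sum(int(c) in optimal_codes for c in codes))
    count, _ = count_inframe_pairs(cds, pairs)
    return ReporterSummary(
        n_optimal=n_optimal,
        optimal_fraction=n_optimal / L,
        pair_count=count,
        pair_fraction=count / (L - 1) if L >= 2 else float("nan"),
    )


FEATURE_COLUMNS = (
    "gene_id", "n_codons", "pair_count", "pair_fraction", "pair_presence",
    "frame1_count", "frame1_fraction", "frame2_count", "frame2_fraction",
    "utr_presence", "tai", "gc", "dipeptide_fraction", "single_pair_position",
)


def compute_gene_features(
    records: Sequence[GeneRecord],
    weights: CodonWeightTable,
    pairs: CodonPairSet | None = None,
) -> pd.DataFrame:
    """Assemble the full per-gene feature table (one row per record)."""
    pairs = pairs or CodonPairSet()
    rows = []
    for rec in records:
        count, L = count_inframe_pairs(rec.cds, pairs)
        f1c, f1f = shifted_frame_counts(rec.cds, pairs, 1)
        f2c, f2f = shifted_frame_counts(rec.cds, pairs, 2)
        rows.append(
            {
                "gene_id": rec.gene_id,
                "n_codons": L,
                "pair_count": count,
                "pair_fraction": pair_fraction(count, L),
                "pair_presence": int(count >= 1),
                "frame1_count": f1c,
                "frame1_fraction": f1f,
                "frame2_count": f2c,
                "frame2_fraction": f2f,
                "utr_presence": utr_pair_presence(rec.utr3, pairs),
                "tai": gene_tai(rec.cds, weights),
                "gc": gc_content(rec.cds),
                "dipeptide_fraction": dipeptide_fraction(rec.cds, pairs),
                "single_pair_position": single_pair_position(rec.cds, pairs),
            }
        )
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return df


def write_features_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_features_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
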