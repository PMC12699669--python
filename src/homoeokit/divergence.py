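"""Pairwise coding-sequence divergence: 4DTv and NG86 Ka/Ks.

Both statistics operate on codon-aligned nucleotide pairs (equal length,
multiple of 3, alphabet ACGT-N). A codon column is *skipped* when either
codon contains a gap or N, or encodes a stop.

4DTv
    The proportion of transversion differences at fourfold-degenerate third
    codon positions. A third position is counted only when the first two
    codon positions are identical between the sequences and that shared
    prefix belongs to one of the eight fourfold codon families (Ala GCN,
    Gly GGN, Val GTN, Pro CCN, Arg CGN, Leu CTN, Ser TCN, Thr ACN). Low 4DTv
    indicates recent divergence; paralog-wide distributions of 4DTv (or Ks)
    are used to date whole-genome duplications.

NG86
    Nei & Gojobori (1986) counting. Synonymous site counts per codon take,
    at each position, the fraction of the three possible single-nucleotide
    changes that preserve the amino acid; changes that would create a stop
    codon count toward the nonsynonymous fraction, so S + N is always 3 per
    counted codon. Site totals are averaged over the two sequences. Codons
    differing at several positions are resolved by averaging synonymous /
    nonsynonymous step counts over all minimal substitution pathways,
    excluding pathways that pass through a stop codon (if every pathway is
    blocked, all pathways are used). Proportions ps = Sd/S and pn = Nd/N are
    corrected for multiple hits with the Jukes–Cantor formula
    d = -(3/4)·ln(1 - (4/3)p); p >= 3/4 is flagged saturated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

from .errors import InputError

_NT = "ACGT"
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

#: Two-base prefixes whose third position is fourfold degenerate.
FOURFOLD_PREFIXES = frozenset({"GC", "GG", "GT", "CC", "CG", "CT", "TC", "AC"})

_CODON_TO_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_CODON_TO_AA))


def is_transversion(a: str, b: str) -> bool:
    """True when a <-> b exchanges a purine and a pyrimidine."""
    return (a in _PURINES) != (b in _PURINES) and a != b


@dataclass(frozen=True)
class CodonPair:
    """A codon-aligned sequence pair over {A, C, G, T, -, N}.

    Sequences are upper-cased and U is mapped to T on construction.
    """

    pair_id: str
    seq1: str
    seq2: str

    def __post_init__(self) -> None:
        for attr in ("seq1", "seq2"):
            seq = getattr(self, attr).upper().replace("U", "T")
            object.__setattr__(self, attr, seq)
            bad = set(seq) - set("ACGT-N")
            if bad:
                raise InputError(
                    f"pair {self.pair_id!r}: invalid characters {sorted(bad)} in {attr}"
                )
        if len(self.seq1) != len(self.seq2):
            raise InputError(
                f"pair {self.pair_id!r}: aligned lengths differ "
                f"({len(self.seq1)} vs {len(self.seq2)})"
            )
        if len(self.seq1) % 3 != 0:
            raise InputError(
                f"pair {self.pair_id!r}: alignment length {len(self.seq1)} "
                "is not a multiple of 3"
            )

    @property
    def n_codons(self) -> int:
        return len(self.seq1) // 3

    def codons(self) -> Iterable[tuple[int, str, str]]:
        """Yield (codon_index, codon1, codon2)."""
        for k in range(self.n_codons):
            yield k, self.seq1[3 * k : 3 * k + 3], self.seq2[3 * k : 3 * k + 3]


def codon_skippable(c1: str, c2: str) -> bool:
    """A codon column is skipped for gaps, Ns, or stop codons."""
    pair = c1 + c2
    if "-" in pair or "N" in pair:
        return True
    return c1 in STOP_CODONS or c2 in STOP_CODONS


@lru_cache(maxsize=None)
def _site_syn_fractions(codon: str) -> tuple[float, float, float]:
    """Per-position fraction of the 3 possible changes that are synonymous.

    Changes to stop codons are not synonymous, so the nonsynonymous fraction
    is the complement and sites sum to 3 per codon.
    """
    aa = _CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        syn = 0
        for nt in _NT:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt not in STOP_CODONS and _CODON_TO_AA[alt] == aa:
                syn += 1
        out.append(syn / 3.0)
    return tuple(out)  # type: ignore[return-value]


def codon_syn_sites(codon: str) -> float:
    """NG86 synonymous site count of one sense codon (0..3)."""
    return sum(_site_syn_fractions(codon))


def _aa_or_stop(codon: str) -> str:
    return _CODON_TO_AA.get(codon, "*")


def _pathways(c1: str, c2: str, allow_stops: bool) -> list[tuple[int, int]]:
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    paths: list[tuple[int, int]] = []
    for order in itertools.permutations(diffs):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[: pos] + c2[pos] + cur[pos + 1 :]
            if not allow_stops and nxt in STOP_CODONS:
                ok = False
                break
            if _aa_or_stop(cur) == _aa_or_stop(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    return paths


@lru_cache(maxsize=None)
def codon_difference_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences per codon pair.

    Minimal substitution pathways through stop codons are excluded; when all
    pathways are blocked the average falls back to the full pathway set.
    """
    if c1 == c2:
        return (0.0, 0.0)
    paths = _pathways(c1, c2, allow_stops=False)
    if not paths:
        paths = _pathways(c1, c2, allow_stops=True)
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return (sd, nd)


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


@dataclass(frozen=True)
class DivergenceEstimate:
    """Per-pair 4DTv and NG86 quantities; NaN marks undefined values."""

    pair_id: str
    n_codons: int
    fourfold_sites: int
    transversions: int
    four_dtv: float
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float
    Ka: float
    flags: tuple[str, ...]


def fourfold_sites(pair: CodonPair) -> list[int]:
    """Alignment indices (0-based) of counted fourfold third positions.

    A third position is counted iff the codon column is not skipped, the
    first two positions are identical between the sequences, and the shared
    prefix is fourfold degenerate.
    """
    sites = []
    for k, c1, c2 in pair.codons():
        if codon_skippable(c1, c2):
            continue
        if c1[:2] == c2[:2] and c1[:2] in FOURFOLD_PREFIXES:
            sites.append(3 * k + 2)
    return sites


def four_dtv(pair: CodonPair) -> tuple[int, int, float]:
    """(fourfold_sites, transversions, ratio); ratio is NaN when no sites."""
    n_sites = 0
    n_tv = 0
    for _, c1, c2 in pair.codons():
        if codon_skippable(c1, c2):
            continue
        if c1[:2] == c2[:2] and c1[:2] in FOURFOLD_PREFIXES:
            n_sites += 1
            if is_transversion(c1[2], c2[2]):
                n_tv += 1
    ratio = n_tv / n_sites if n_sites else float("nan")
    return n_sites, n_tv, ratio


def ng86(pair: CodonPair) -> dict:
    """NG86 site/difference counts and JC-corrected Ka, Ks for one pair."""
    S1 = S2 = Sd = Nd = 0.0
    counted = 0
    for _, c1, c2 in pair.codons():
        if codon_skippable(c1, c2):
            continue
        counted += 1
        S1 += codon_syn_sites(c1)
        S2 += codon_syn_sites(c2)
        sd, nd = codon_difference_counts(c1, c2)
        Sd += sd
        Nd += nd
    flags: list[str] = []
    if counted == 0:
        flags.append("no_codons")
        nan = float("nan")
        return dict(n_codons=0, S=nan, N=nan, Sd=nan, Nd=nan, ps=nan, pn=nan,
                    Ks=nan, Ka=nan, flags=tuple(flags))
    S = (S1 + S2) / 2.0
    N = 3.0 * counted - S
    ps = Sd / S if S > 0 else float("nan")
    pn = Nd / N if N > 0 else float("nan")
    Ks = Ka = float("nan")
    if math.isfinite(ps):
        d = jukes_cantor(ps)
        if d is None:
            flags.append("ks_saturated")
        else:
            Ks = d
    if math.isfinite(pn):
        d = jukes_cantor(pn)
        if d is None:
            flags.append("ka_saturated")
        else:
            Ka = d
    return dict(n_codons=counted, S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn,
                Ks=Ks, Ka=Ka, flags=tuple(flags))


def estimate_divergence(pair: CodonPair) -> DivergenceEstimate:
    """All divergence statistics for one codon pair."""
    n_sites, n_tv, ratio = four_dtv(pair)
    ng = ng86(pair)
    flags = list(ng.pop("flags"))
    if n_sites == 0:
        flags.append("no_fourfold_sites")
    return DivergenceEstimate(
        pair_id=pair.pair_id,
        fourfold_sites=n_sites,
        transversions=n_tv,
        four_dtv=ratio,
        flags=tuple(flags),
        **ng,
    )


def batch_divergence(pairs: Sequence[CodonPair]) -> pd.DataFrame:
    """One row of divergence statistics per pair, in input order."""
    rows = []
    for pair in pairs:
        est = estimate_divergence(pair)
        row = est.__dict__.copy()
        row["flags"] = ";".join(est.flags)
        rows.append(row)
    columns = [
        "pair_id", "n_codons", "fourfold_sites", "transversions", "four_dtv",
        "S", "N", "Sd", "Nd", "ps", "pn", "Ks", "Ka", "flags",
    ]
    return pd.DataFrame(rows, columns=columns)


def read_pairs(cds_path: str | Path, pairs_path: str | Path) -> list[CodonPair]:
    """Load aligned CDS pairs from a FASTA plus an anchor-pair TSV.

    The TSV needs columns gene1 and gene2 (optional pair_id, defaulting to
    "gene1|gene2"). Sequences must be pre-aligned: equal lengths, multiples
    of 3.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(cds_path), "fasta"):
        if rec.id in seqs:
            raise InputError(f"duplicate FASTA id {rec.id!r} in {cds_path}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise InputError(f"no FASTA records found in {cds_path}")
    table = pd.read_csv(pairs_path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if not {"gene1", "gene2"} <= set(table.columns):
        raise InputError(f"pair table {pairs_path} must have columns gene1, gene2")
    pairs = []
    for _, row in table.iterrows():
        g1, g2 = row["gene1"], row["gene2"]
        for g in (g1, g2):
            if g not in seqs:
                raise InputError(f"pair table references unknown sequence id {g!r}")
        pid = row["pair_id"] if "pair_id" in table.columns and row["pair_id"] else f"{g1}|{g2}"
        pairs.append(CodonPair(pid, seqs[g1], seqs[g2]))
    return pairs
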