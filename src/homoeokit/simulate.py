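"""Synthetic datasets with ground truth for every analysis stage.

The generators emit exactly the file dialects the analysis modules read
(gene catalog TSV, expression + design TSVs, codon-pair FASTA + anchor TSV,
gene-order TSVs) together with ``truth_*`` tables holding the generating
labels, so recovery can be scored without touching generator internals.
All randomness flows from the single ``seed`` in :class:`SimulationConfig`;
equal configs produce byte-identical files.

Models
------
* Retention: group classes drawn i.i.d. from a mixture; copy vectors are
  sampled uniformly within each class's admissible patterns.
* Expression: per triad × tissue, a bias category is drawn from a mixture;
  true proportions come from a Dirichlet centered on the category centroid
  (zero components clipped to 1e-3 and renormalized — the Dirichlet is
  undefined at zero); the triad total is log-normal; replicate TPMs are the
  expected homoeolog TPM times multiplicative log-normal noise with a given
  coefficient of variation. A configurable fraction of triads is simulated
  below the expression threshold.
* Codon pairs: ancestral codons are drawn uniformly from the 32 codons of
  the eight fourfold-degenerate families; the two lineages then evolve
  independently under Kimura's two-parameter model (K80) with
  transition/transversion rate ratio kappa. The branch length is inverted
  in closed form so the expected transversion proportion at fourfold sites
  (or, via a one-dimensional root solve on the exact expected NG86 estimate,
  the expected Ks) hits each mode's target. Stop codons are rejected by
  per-lineage resampling.
* Gene orders: collinear blocks of configurable size, gap pattern and
  orientation are planted into two single-chromosome gene orders.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import divergence as dv
from .bias import CATEGORIES, DEFAULT_CENTROIDS, EXPRESSION_THRESHOLD
from .errors import InputError
from .retention import SUBGENOMES, GeneCatalog, write_gene_catalog

_NT = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(_NT)}

#: The 32 sense codons with a fourfold-degenerate third position.
FOURFOLD_CODONS: tuple[str, ...] = tuple(
    sorted(p + n for p in dv.FOURFOLD_PREFIXES for n in _NT)
)

_DEFAULT_BIAS_WEIGHTS = {
    # leaf+root headline fractions typical of hexaploid bamboo triads:
    # balanced ~37%, dominance ~23% (B rarest), suppression ~40%
    "balanced": 36.8,
    "A_dominant": 8.05,
    "B_dominant": 7.3,
    "C_dominant": 8.05,
    "A_suppressed": 12.7,
    "B_suppressed": 14.5,
    "C_suppressed": 12.7,
}

_DEFAULT_RETENTION_MIXTURE = {
    "triad": 0.15,
    "duplet": 0.33,
    "singleton": 0.04,
    "other_multicopy": 0.48,
}


def _normalized(weights: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(weights.values()))
    if total <= 0:
        raise InputError("mixture weights must have a positive sum")
    return {k: v / total for k, v in weights.items()}


@dataclass(frozen=True)
class DivergenceMode:
    """One mode of the simulated divergence distribution."""

    target: float  # expected statistic (4DTv or Ks) for the mode
    weight: float
    kappa: float = 2.0


@dataclass
class SimulationConfig:
    """All knobs of the synthetic generators; ``seed`` is mandatory."""

    seed: int
    # retention
    n_groups: int = 1000
    retention_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RETENTION_MIXTURE)
    )
    # expression
    n_triads: int = 500
    bias_mixture: Mapping[str, float] = field(
        default_factory=lambda: _normalized(_DEFAULT_BIAS_WEIGHTS)
    )
    dirichlet_concentration: float | None = 200.0  # None -> noise-free limit
    total_tpm_lognormal: tuple[float, float] = (2.0, 1.0)  # (mu, sigma) of ln TPM
    replicate_cv: float = 0.10
    tissues: tuple[str, ...] = ("leaf", "root")
    replicates_per_tissue: int = 3
    not_expressed_fraction: float = 0.05
    expression_threshold: float = EXPRESSION_THRESHOLD
    # codon pairs
    n_pairs: int = 500
    codons_per_pair: int = 300
    divergence_statistic: str = "4dtv"  # or "ks"
    divergence_modes: tuple[DivergenceMode, ...] = (
        DivergenceMode(0.056, 0.5, 2.0),
        DivergenceMode(0.208, 0.5, 2.0),
    )
    # gene orders
    synteny_genes_per_chrom: int = 300
    planted_blocks: tuple[tuple[int, int, str], ...] = ((12, 2, "same"), (15, 1, "inverted"))
    synteny_noise_pairs: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise InputError("a seed is mandatory for reproducibility")
        for name, mixture, keys in (
            ("retention_mixture", self.retention_mixture, set(_DEFAULT_RETENTION_MIXTURE)),
            ("bias_mixture", self.bias_mixture, set(CATEGORIES)),
        ):
            if set(mixture) != keys:
                raise InputError(f"{name} must have exactly the keys {sorted(keys)}")
            if any(v < 0 for v in mixture.values()):
                raise InputError(f"{name} has negative weights")
            if abs(sum(mixture.values()) - 1.0) > 1e-6:
                raise InputError(f"{name} must sum to 1")
        for n in (self.n_groups, self.n_triads, self.n_pairs, self.codons_per_pair,
                  self.replicates_per_tissue):
            if n <= 0:
                raise InputError("all counts must be positive")
        if self.dirichlet_concentration is not None:
            if not np.isfinite(self.dirichlet_concentration):
                object.__setattr__(self, "dirichlet_concentration", None)
            elif self.dirichlet_concentration <= 0:
                raise InputError("dirichlet_concentration must be positive")
        if self.replicate_cv < 0:
            raise InputError("replicate_cv must be non-negative")
        if not 0 <= self.not_expressed_fraction < 1:
            raise InputError("not_expressed_fraction must be in [0, 1)")
        if self.divergence_statistic not in ("4dtv", "ks"):
            raise InputError("divergence_statistic must be '4dtv' or 'ks'")
        if not self.divergence_modes:
            raise InputError("divergence_modes must be non-empty")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        return np.random.default_rng([int(self.seed), stage])


# ---------------------------------------------------------------------------
# K80 machinery
# ---------------------------------------------------------------------------


def k80_site_probabilities(d: float, kappa: float) -> tuple[float, float, float]:
    """(P_same, P_transition, P_each_transversion) at sequence distance d.

    The process is normalized to one expected substitution per site per unit
    of d; kappa is the transition/transversion *rate* ratio alpha/beta.
    """
    if d < 0 or kappa <= 0:
        raise InputError("need d >= 0 and kappa > 0")
    beta = 1.0 / (kappa + 2.0)
    e1 = np.exp(-4.0 * beta * d)
    e2 = np.exp(-2.0 * (kappa + 1.0) * beta * d)
    p_tv_total = 0.5 * (1.0 - e1)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_same = 1.0 - p_ts - p_tv_total
    return float(p_same), float(p_ts), float(p_tv_total / 2.0)


def k80_transition_matrix(d: float, kappa: float) -> np.ndarray:
    """4x4 nucleotide substitution matrix over ACGT at distance d."""
    p_same, p_ts, p_tv = k80_site_probabilities(d, kappa)
    P = np.full((4, 4), p_tv)
    for i in range(4):
        P[i, i] = p_same
    # transitions: A<->G (0, 2), C<->T (1, 3)
    for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):
        P[i, j] = p_ts
    return P


def k80_rate_matrix(kappa: float) -> np.ndarray:
    """The normalized K80 generator (rows sum to 0, 1 substitution/unit d)."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    Q = np.full((4, 4), beta)
    for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):
        Q[i, j] = alpha
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def branch_length_for_4dtv(target: float, kappa: float) -> float:
    """Pairwise distance d with expected transversion proportion = target.

    Closed-form inversion of P_tv(d) = (1 - exp(-4 d / (kappa+2))) / 2;
    targets >= 0.5 are unattainable under K80.
    """
    if not 0 <= target < 0.5:
        raise InputError(
            f"4DTv target {target} unattainable: the K80 transversion "
            "proportion saturates below 0.5"
        )
    beta = 1.0 / (kappa + 2.0)
    return float(-np.log(1.0 - 2.0 * target) / (4.0 * beta))


def _codon_index_array(codons: Sequence[str]) -> np.ndarray:
    return np.array([[_NT_INDEX[c] for c in codon] for codon in codons], dtype=np.intp)


def _codon_transition_matrix(d_branch: float, kappa: float) -> np.ndarray:
    """Sense-codon transition matrix for one lineage of length d_branch.

    Rows are renormalized over sense codons, matching the per-lineage
    stop-rejection used by the simulator.
    """
    P4 = k80_transition_matrix(d_branch, kappa)
    idx = _codon_index_array(dv.SENSE_CODONS)
    M = (
        P4[idx[:, None, 0], idx[None, :, 0]]
        * P4[idx[:, None, 1], idx[None, :, 1]]
        * P4[idx[:, None, 2], idx[None, :, 2]]
    )
    return M / M.sum(axis=1, keepdims=True)


def expected_ng86_ks(d: float, kappa: float) -> float:
    """Expected NG86 Ks for fourfold-family ancestors at pair distance d.

    Uses the exact per-codon transition probabilities (each lineage evolves
    d/2, conditioned on remaining a sense codon) and the NG86 site /
    pathway-difference tables to form E[Sd]/E[S], then applies the
    Jukes-Cantor correction.
    """
    sense = dv.SENSE_CODONS
    M = _codon_transition_matrix(d / 2.0, kappa)
    anc = [sense.index(c) for c in FOURFOLD_CODONS]
    S_vec = np.array([dv.codon_syn_sites(c) for c in sense])
    Sd_tab = np.array(
        [[dv.codon_difference_counts(c1, c2)[0] for c2 in sense] for c1 in sense]
    )
    Ma = M[anc]  # ancestors x sense
    exp_S = float((Ma @ S_vec).mean())  # per-lineage expectation == pair average
    exp_Sd = float(np.einsum("ab,bc,ac->a", Ma, Sd_tab, Ma).mean())
    ps = exp_Sd / exp_S
    d_corr = dv.jukes_cantor(ps)
    if d_corr is None:
        raise InputError(f"expected synonymous proportion saturated at d={d}")
    return d_corr


def branch_length_for_ks(target: float, kappa: float) -> float:
    """Pairwise distance d whose expected NG86 Ks equals the target."""
    if target < 0:
        raise InputError("Ks target must be non-negative")
    if target == 0:
        return 0.0
    lo, hi = 1e-9, 0.05
    while expected_ng86_ks(hi, kappa) < target:
        hi *= 2.0
        if hi > 50:
            raise InputError(f"Ks target {target} unattainable")
    return float(brentq(lambda d: expected_ng86_ks(d, kappa) - target, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# retention
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedRetention:
    catalog: GeneCatalog
    truth: pd.DataFrame  # group_id, truth_class, n_A, n_B, n_C

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "catalog": outdir / "gene_catalog.tsv",
            "truth": outdir / "retention_truth.tsv",
        }
        write_gene_catalog(self.catalog, paths["catalog"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
        return paths


_DUPLET_PATTERNS = [p for p in itertools.product((0, 1), repeat=3) if sum(p) == 2]
_SINGLETON_PATTERNS = [p for p in itertools.product((0, 1), repeat=3) if sum(p) == 1]
_MULTI_PATTERNS = [
    p for p in itertools.product(range(4), repeat=3) if max(p) > 1
]


def simulate_retention(config: SimulationConfig) -> SimulatedRetention:
    """Draw homoeolog groups from the retention-class mixture."""
    rng = config.rng(1)
    classes = list(config.retention_mixture)
    probs = [config.retention_mixture[c] for c in classes]
    drawn = rng.choice(len(classes), size=config.n_groups, p=probs)
    counters = {s: 0 for s in SUBGENOMES}
    cat_rows: list[dict] = []
    truth_rows: list[dict] = []
    for g in range(config.n_groups):
        cls = classes[int(drawn[g])]
        if cls == "triad":
            cv = (1, 1, 1)
        elif cls == "duplet":
            cv = _DUPLET_PATTERNS[int(rng.integers(len(_DUPLET_PATTERNS)))]
        elif cls == "singleton":
            cv = _SINGLETON_PATTERNS[int(rng.integers(len(_SINGLETON_PATTERNS)))]
        else:
            cv = _MULTI_PATTERNS[int(rng.integers(len(_MULTI_PATTERNS)))]
        gid = f"og{g:06d}"
        for s, n in zip(SUBGENOMES, cv):
            for _ in range(n):
                counters[s] += 1
                cat_rows.append(
                    {"gene_id": f"{s}_g{counters[s]:06d}", "subgenome": s, "group_id": gid}
                )
        truth_rows.append(
            {"group_id": gid, "truth_class": cls,
             "n_A": cv[0], "n_B": cv[1], "n_C": cv[2]}
        )
    catalog = GeneCatalog(pd.DataFrame(cat_rows, columns=["gene_id", "subgenome", "group_id"]))
    truth = pd.DataFrame(truth_rows, columns=["group_id", "truth_class", "n_A", "n_B", "n_C"])
    return SimulatedRetention(catalog=catalog, truth=truth)


# ---------------------------------------------------------------------------
# triad expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedExpression:
    expression: pd.DataFrame  # gene x sample TPM
    design: pd.DataFrame
    triads: pd.DataFrame
    truth: pd.DataFrame  # triad_id, tissue, truth_status, truth_category, ...

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / "expression_tpm.tsv",
            "design": outdir / "sample_design.tsv",
            "triads": outdir / "triads.tsv",
            "truth": outdir / "expression_truth.tsv",
        }
        self.expression.reset_index().rename(columns={"index": "gene_id"}).to_csv(
            paths["expression"], sep="\t", index=False, float_format="%.6g",
            lineterminator="\n",
        )
        self.design.to_csv(paths["design"], sep="\t", index=False, lineterminator="\n")
        self.triads.to_csv(paths["triads"], sep="\t", index=False, lineterminator="\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6g",
                          lineterminator="\n")
        return paths


def _clipped_centroid(point: Sequence[float], floor: float = 1e-3) -> np.ndarray:
    p = np.maximum(np.asarray(point, dtype=float), floor)
    return p / p.sum()


def simulate_triads_expression(config: SimulationConfig) -> SimulatedExpression:
    """Simulate replicate TPM matrices for triads with known bias categories."""
    rng = config.rng(2)
    centroid_map = dict(DEFAULT_CENTROIDS)
    cats = list(config.bias_mixture)
    probs = [config.bias_mixture[c] for c in cats]
    mu, sigma = config.total_tpm_lognormal
    noise_sigma = float(np.sqrt(np.log1p(config.replicate_cv**2)))
    triad_ids = [f"tri{i:05d}" for i in range(config.n_triads)]
    genes = {s: [f"{t}_{s}" for t in triad_ids] for s in SUBGENOMES}
    samples = [
        (f"{tissue}_r{r}", tissue, r)
        for tissue in config.tissues
        for r in range(1, config.replicates_per_tissue + 1)
    ]
    design = pd.DataFrame(samples, columns=["sample_id", "tissue", "replicate"])
    expressed = rng.random(config.n_triads) >= config.not_expressed_fraction
    matrix = np.zeros((3 * config.n_triads, len(samples)))
    truth_rows: list[dict] = []
    gene_index = [g for s in SUBGENOMES for g in genes[s]]
    col = 0
    sample_cols = {}
    for sid, tissue, r in samples:
        sample_cols[sid] = col
        col += 1
    for tissue in config.tissues:
        cat_draw = rng.choice(len(cats), size=config.n_triads, p=probs)
        totals = rng.lognormal(mu, sigma, size=config.n_triads)
        totals = np.maximum(totals, 2.0 * config.expression_threshold)
        totals = np.where(expressed, totals, 0.2 * config.expression_threshold)
        for i, tid in enumerate(triad_ids):
            category = cats[int(cat_draw[i])]
            centroid = np.asarray(centroid_map[category], dtype=float)
            if config.dirichlet_concentration is None:
                p = centroid.copy()
            else:
                alpha = config.dirichlet_concentration * _clipped_centroid(centroid)
                p = rng.dirichlet(alpha)
            expected = totals[i] * p
            for r in range(1, config.replicates_per_tissue + 1):
                noise = (
                    np.ones(3)
                    if config.replicate_cv == 0
                    else rng.lognormal(-noise_sigma**2 / 2.0, noise_sigma, size=3)
                )
                values = expected * noise
                c = sample_cols[f"{tissue}_r{r}"]
                for j in range(3):
                    matrix[j * config.n_triads + i, c] = values[j]
            truth_rows.append(
                {
                    "triad_id": tid,
                    "tissue": tissue,
                    "truth_status": "expressed" if expressed[i] else "not_expressed",
                    "truth_category": category if expressed[i] else "",
                    "truth_p_A": p[0],
                    "truth_p_B": p[1],
                    "truth_p_C": p[2],
                    "truth_total": totals[i],
                }
            )
    expression = pd.DataFrame(matrix, index=pd.Index(gene_index, name="gene_id"),
                              columns=[s[0] for s in samples])
    triads = pd.DataFrame(
        {
            "triad_id": triad_ids,
            "gene_A": genes["A"],
            "gene_B": genes["B"],
            "gene_C": genes["C"],
        }
    )
    truth = pd.DataFrame(truth_rows)
    return SimulatedExpression(expression=expression, design=design, triads=triads, truth=truth)


# ---------------------------------------------------------------------------
# codon pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedCodonPairs:
    sequences: dict[str, str]  # fasta id -> sequence
    pairs: pd.DataFrame  # pair_id, gene1, gene2
    truth: pd.DataFrame  # pair_id, truth_mode, truth_target, ...

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "cds_pairs.fasta",
            "pairs": outdir / "anchor_pairs.tsv",
            "truth": outdir / "divergence_truth.tsv",
        }
        with open(paths["fasta"], "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for k in range(0, len(seq), 60):
                    fh.write(seq[k : k + 60] + "\n")
        self.pairs.to_csv(paths["pairs"], sep="\t", index=False, lineterminator="\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6g",
                          lineterminator="\n")
        return paths


_STOP_CODON_INDICES = frozenset(
    16 * _NT_INDEX[c[0]] + 4 * _NT_INDEX[c[1]] + _NT_INDEX[c[2]] for c in dv.STOP_CODONS
)


def _evolve_lineage(anc: np.ndarray, P4: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Evolve codon nt-index array (n_codons, 3); stops resampled per codon."""
    cum = P4.cumsum(axis=1)
    def draw(src: np.ndarray) -> np.ndarray:
        u = rng.random(src.shape)
        return (u[..., None] > cum[src]).sum(axis=-1).astype(np.intp)

    desc = draw(anc)
    while True:
        codes = 16 * desc[:, 0] + 4 * desc[:, 1] + desc[:, 2]
        stop = np.isin(codes, list(_STOP_CODON_INDICES))
        if not stop.any():
            return desc
        desc[stop] = draw(anc[stop])


def simulate_codon_pairs(config: SimulationConfig) -> SimulatedCodonPairs:
    """Evolve codon pairs under K80 so each mode hits its target statistic."""
    rng = config.rng(3)
    modes = config.divergence_modes
    weights = np.array([m.weight for m in modes], dtype=float)
    if weights.sum() <= 0:
        raise InputError("divergence mode weights must have a positive sum")
    weights = weights / weights.sum()
    distances = []
    for m in modes:
        if config.divergence_statistic == "4dtv":
            distances.append(branch_length_for_4dtv(m.target, m.kappa))
        else:
            distances.append(branch_length_for_ks(m.target, m.kappa))
    mode_of_pair = rng.choice(len(modes), size=config.n_pairs, p=weights)
    anc_codon_idx = _codon_index_array(FOURFOLD_CODONS)
    letters = np.array(list(_NT))
    sequences: dict[str, str] = {}
    pair_rows = []
    truth_rows = []
    for i in range(config.n_pairs):
        m = int(mode_of_pair[i])
        P4 = k80_transition_matrix(distances[m] / 2.0, modes[m].kappa)
        anc = anc_codon_idx[rng.integers(len(FOURFOLD_CODONS), size=config.codons_per_pair)]
        s1 = _evolve_lineage(anc, P4, rng)
        s2 = _evolve_lineage(anc, P4, rng)
        id1, id2 = f"p{i:05d}_1", f"p{i:05d}_2"
        sequences[id1] = "".join(letters[s1.ravel()])
        sequences[id2] = "".join(letters[s2.ravel()])
        pair_rows.append({"pair_id": f"p{i:05d}", "gene1": id1, "gene2": id2})
        truth_rows.append(
            {
                "pair_id": f"p{i:05d}",
                "truth_mode": m,
                "truth_statistic": config.divergence_statistic,
                "truth_target": modes[m].target,
                "truth_kappa": modes[m].kappa,
                "truth_distance": distances[m],
            }
        )
    return SimulatedCodonPairs(
        sequences=sequences,
        pairs=pd.DataFrame(pair_rows, columns=["pair_id", "gene1", "gene2"]),
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# gene orders
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedGeneOrders:
    orders1: pd.DataFrame
    orders2: pd.DataFrame
    pairs: pd.DataFrame  # gene1, gene2
    truth: pd.DataFrame  # gene1, gene2, truth_block (-1 for noise pairs)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "orders1": outdir / "gene_order_genome1.tsv",
            "orders2": outdir / "gene_order_genome2.tsv",
            "pairs": outdir / "homolog_pairs.tsv",
            "truth": outdir / "synteny_truth.tsv",
        }
        self.orders1.to_csv(paths["orders1"], sep="\t", index=False, lineterminator="\n")
        self.orders2.to_csv(paths["orders2"], sep="\t", index=False, lineterminator="\n")
        self.pairs.to_csv(paths["pairs"], sep="\t", index=False, lineterminator="\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
        return paths


_BLOCK_SPACER = 12  # background genes between planted regions; > any max_gap used


def simulate_gene_orders(config: SimulationConfig) -> SimulatedGeneOrders:
    """Plant collinear blocks into two single-chromosome gene orders."""
    rng = config.rng(4)
    n = config.synteny_genes_per_chrom
    anchors: list[tuple[int, int]] = []  # (rank1, rank2)
    block_of: list[int] = []
    cursor1 = cursor2 = _BLOCK_SPACER
    for b, (size, gap_max, orientation) in enumerate(config.planted_blocks):
        if orientation not in ("same", "inverted"):
            raise InputError(f"unknown block orientation {orientation!r}")
        gaps1 = rng.integers(0, gap_max + 1, size=size - 1) if size > 1 else []
        gaps2 = rng.integers(0, gap_max + 1, size=size - 1) if size > 1 else []
        r1 = cursor1 + np.concatenate([[0], np.cumsum(np.asarray(gaps1) + 1)]).astype(int)
        r2 = cursor2 + np.concatenate([[0], np.cumsum(np.asarray(gaps2) + 1)]).astype(int)
        if orientation == "inverted":
            r2 = r2[::-1]
        for a, c in zip(r1, r2):
            anchors.append((int(a), int(c)))
            block_of.append(b)
        cursor1 = int(r1.max()) + _BLOCK_SPACER
        cursor2 = int(max(r2)) + _BLOCK_SPACER
    if cursor1 > n or cursor2 > n:
        raise InputError(
            f"planted blocks need more than {n} genes per chromosome; "
            "increase synteny_genes_per_chrom"
        )
    orders1 = pd.DataFrame(
        {"gene_id": [f"G1_{r:05d}" for r in range(n)], "chromosome": "chr1", "rank": range(n)}
    )
    orders2 = pd.DataFrame(
        {"gene_id": [f"G2_{r:05d}" for r in range(n)], "chromosome": "chr1", "rank": range(n)}
    )
    pair_rows = [
        {"gene1": f"G1_{r1:05d}", "gene2": f"G2_{r2:05d}"} for r1, r2 in anchors
    ]
    truth_rows = [
        {"gene1": p["gene1"], "gene2": p["gene2"], "truth_block": b}
        for p, b in zip(pair_rows, block_of)
    ]
    anchor_r1 = {r1 for r1, _ in anchors}
    anchor_r2 = {r2 for _, r2 in anchors}
    free1 = [r for r in range(n) if r not in anchor_r1]
    free2 = [r for r in range(n) if r not in anchor_r2]
    for _ in range(config.synteny_noise_pairs):
        r1 = free1[int(rng.integers(len(free1)))]
        r2 = free2[int(rng.integers(len(free2)))]
        pair_rows.append({"gene1": f"G1_{r1:05d}", "gene2": f"G2_{r2:05d}"})
        truth_rows.append({"gene1": f"G1_{r1:05d}", "gene2": f"G2_{r2:05d}", "truth_block": -1})
    return SimulatedGeneOrders(
        orders1=orders1,
        orders2=orders2,
        pairs=pd.DataFrame(pair_rows, columns=["gene1", "gene2"]),
        truth=pd.DataFrame(truth_rows, columns=["gene1", "gene2", "truth_block"]),
    )
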