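"""Collinear (syntenic) block calling on gene-rank coordinates.

A collinear block is a chain of homologous gene pairs (anchors) whose ranks
increase monotonically along both genomes (or increase on genome 1 while
decreasing on genome 2 for an inverted block), with at most ``max_gap``
intervening non-anchor genes between consecutive anchors on *each* genome.
Chains shorter than ``min_pairs`` anchors are discarded. Defaults follow the
common practice for intragenomic homoeology screens: at least 10 anchor
pairs with at most 6 intervening genes.

Chains are found per chromosome pair by dynamic programming maximizing
chain length (ties: smaller rank span, then lexicographically smallest
first anchor), and extracted greedily by descending score so that each
anchor pair belongs to at most one block.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import InputError


@dataclass(frozen=True)
class CollinearBlock:
    block_id: str
    chrom1: str
    chrom2: str
    orientation: str  # "same" or "inverted"
    anchors: tuple[tuple[str, str], ...]  # (gene1, gene2) in chain order

    @property
    def size(self) -> int:
        return len(self.anchors)


def load_gene_orders(path: str | Path) -> pd.DataFrame:
    """Read a gene-order TSV (gene_id, chromosome, rank) and validate it.

    Ranks must be consecutive integers from 0 within each chromosome and
    gene ids unique within the genome.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "chromosome": str})
    need = {"gene_id", "chromosome", "rank"}
    if not need <= set(df.columns):
        raise InputError(f"gene-order table {path} must have columns {sorted(need)}")
    return validate_gene_orders(df, name=str(path))


def validate_gene_orders(df: pd.DataFrame, name: str = "gene orders") -> pd.DataFrame:
    if df["gene_id"].duplicated().any():
        raise InputError(f"{name}: duplicate gene ids")
    for chrom, sub in df.groupby("chromosome"):
        ranks = sorted(int(r) for r in sub["rank"])
        if ranks != list(range(len(ranks))):
            raise InputError(
                f"{name}: ranks on chromosome {chrom!r} are not consecutive from 0"
            )
    return df.reset_index(drop=True)


def gene_orders_from_gff(path: str | Path) -> pd.DataFrame:
    """Derive 0-based gene ranks from a GFF3 file (genes ordered by start).

    Only ``gene`` features are used; the gene id is taken from the ID
    attribute.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type("gene"):
        rows.append({"gene_id": feat.id, "chromosome": feat.seqid, "start": feat.start})
    if not rows:
        raise InputError(f"no gene features found in {path}")
    df = pd.DataFrame(rows).sort_values(["chromosome", "start"], kind="stable")
    df["rank"] = df.groupby("chromosome").cumcount()
    return df[["gene_id", "chromosome", "rank"]].reset_index(drop=True)


def load_homolog_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if not {"gene1", "gene2"} <= set(df.columns):
        raise InputError(f"homolog-pair table {path} must have columns gene1, gene2")
    return df


def _best_chain(anchors: list[tuple[int, int, str, str]], orientation: str, max_gap: int):
    """Best chain over one chromosome pair and orientation.

    ``anchors`` holds (rank1, rank2, gene1, gene2). Returns
    (length, span, first(r1, r2), end(r1, r2), chain-as-index-list) or None.
    Score order: longer first, then smaller rank span (sum over both
    genomes), then lexicographically smaller first anchor, then end anchor.
    """
    if not anchors:
        return None
    sign = 1 if orientation == "same" else -1
    # t2 makes both orientations "strictly increasing" chains
    items = sorted(
        range(len(anchors)),
        key=lambda i: (anchors[i][0], sign * anchors[i][1]),
    )
    r1 = [anchors[i][0] for i in items]
    t2 = [sign * anchors[i][1] for i in items]
    r2 = [anchors[i][1] for i in items]
    n = len(items)
    length = [1] * n
    # first-anchor bookkeeping: span = (r1_i - f.r1) + (t2_i - f.t2), so for a
    # fixed end the span is minimized by maximizing f.r1 + f.t2.
    first_score = [r1[i] + t2[i] for i in range(n)]
    first_anchor = [(r1[i], r2[i]) for i in range(n)]
    first_t2 = list(t2)
    first_r1 = list(r1)
    parent = [-1] * n
    for i in range(n):
        best = None
        for j in range(i):
            if r1[j] >= r1[i] or t2[j] >= t2[i]:
                continue
            if r1[i] - r1[j] - 1 > max_gap or t2[i] - t2[j] - 1 > max_gap:
                continue
            key = (length[j], first_score[j], tuple(-x for x in first_anchor[j]),
                   (-r1[j], -r2[j]))
            if best is None or key > best[0]:
                best = (key, j)
        if best is not None:
            j = best[1]
            length[i] = length[j] + 1
            first_score[i] = first_score[j]
            first_anchor[i] = first_anchor[j]
            first_r1[i] = first_r1[j]
            first_t2[i] = first_t2[j]
            parent[i] = j
    best_end = None
    for i in range(n):
        span = (r1[i] - first_r1[i]) + (t2[i] - first_t2[i])
        key = (-length[i], span, first_anchor[i], (r1[i], r2[i]))
        if best_end is None or key < best_end[0]:
            best_end = (key, i)
    i = best_end[1]
    chain = []
    while i != -1:
        chain.append(items[i])
        i = parent[i]
    chain.reverse()
    _, span, first, end = best_end[0][0], best_end[0][1], best_end[0][2], best_end[0][3]
    return (length[best_end[1]], span, first, end, chain)


def call_collinear_blocks(
    orders1: pd.DataFrame,
    orders2: pd.DataFrame,
    pairs: pd.DataFrame,
    min_pairs: int = 10,
    max_gap: int = 6,
) -> list[CollinearBlock]:
    """Call collinear blocks from two gene orders and a homolog-pair table.

    Every pair must reference placed genes; both orientations are attempted
    per chromosome pair. Each anchor pair ends up in at most one block.
    """
    orders1 = validate_gene_orders(orders1, "genome 1")
    orders2 = validate_gene_orders(orders2, "genome 2")
    pos1 = {g: (c, int(r)) for g, c, r in orders1[["gene_id", "chromosome", "rank"]].itertuples(index=False)}
    pos2 = {g: (c, int(r)) for g, c, r in orders2[["gene_id", "chromosome", "rank"]].itertuples(index=False)}
    pools: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for g1, g2 in pairs[["gene1", "gene2"]].itertuples(index=False):
        if g1 not in pos1:
            raise InputError(f"pair gene {g1!r} is not placed in genome 1")
        if g2 not in pos2:
            raise InputError(f"pair gene {g2!r} is not placed in genome 2")
        c1, r1 = pos1[g1]
        c2, r2 = pos2[g2]
        pools.setdefault((c1, c2), []).append((r1, r2, g1, g2))
    blocks: list[CollinearBlock] = []
    orient_rank = {"same": 0, "inverted": 1}
    while True:
        best = None
        for (c1, c2), anchors in pools.items():
            for orientation in ("same", "inverted"):
                res = _best_chain(anchors, orientation, max_gap)
                if res is None or res[0] < min_pairs:
                    continue
                length, span, first, _end, chain = res
                key = (-length, span, c1, c2, orient_rank[orientation], first)
                if best is None or key < best[0]:
                    best = (key, (c1, c2), orientation, chain)
        if best is None:
            break
        _, (c1, c2), orientation, chain = best
        anchors = pools[(c1, c2)]
        chosen = [anchors[i] for i in chain]
        blocks.append(
            CollinearBlock(
                block_id=f"block_{len(blocks) + 1:04d}",
                chrom1=c1,
                chrom2=c2,
                orientation=orientation,
                anchors=tuple((a[2], a[3]) for a in chosen),
            )
        )
        keep = set(chain)
        pools[(c1, c2)] = [a for i, a in enumerate(anchors) if i not in keep]
    return blocks


def blocks_to_frame(blocks: list[CollinearBlock]) -> pd.DataFrame:
    rows = [
        {
            "block_id": b.block_id,
            "chrom1": b.chrom1,
            "chrom2": b.chrom2,
            "orientation": b.orientation,
            "size": b.size,
            "anchors": ";".join(f"{g1},{g2}" for g1, g2 in b.anchors),
        }
        for b in blocks
    ]
    return pd.DataFrame(
        rows, columns=["block_id", "chrom1", "chrom2", "orientation", "size", "anchors"]
    )


def validate_block(
    block: CollinearBlock,
    orders1: pd.DataFrame,
    orders2: pd.DataFrame,
    min_pairs: int,
    max_gap: int,
) -> bool:
    """Post-hoc check of the monotonicity / gap / size contract of a block."""
    pos1 = dict(zip(orders1["gene_id"], orders1["rank"].astype(int)))
    pos2 = dict(zip(orders2["gene_id"], orders2["rank"].astype(int)))
    r1 = [pos1[g1] for g1, _ in block.anchors]
    r2 = [pos2[g2] for _, g2 in block.anchors]
    if block.size < min_pairs:
        return False
    sign = 1 if block.orientation == "same" else -1
    for a, b in zip(range(block.size - 1), range(1, block.size)):
        d1 = r1[b] - r1[a]
        d2 = sign * (r2[b] - r2[a])
        if d1 <= 0 or d2 <= 0:
            return False
        if d1 - 1 > max_gap or d2 - 1 > max_gap:
            return False
    return True
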