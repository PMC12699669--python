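"""Gene-retention classes for homoeolog groups in a hexaploid genome.

An allohexaploid carries three subgenomes (A, B, C). After polyploidization,
duplicated genes are progressively lost (fractionation), so a homoeologous
gene group may retain copies in all three subgenomes or only in some. The
retention classes used here partition every group by its copy vector
``(nA, nB, nC)``:

* ``triad`` — exactly one copy in each subgenome, (1, 1, 1);
* ``duplet`` — single copies in exactly two subgenomes, e.g. (1, 0, 1);
* ``singleton`` — a single copy in exactly one subgenome;
* ``other_multicopy`` — every remaining configuration, i.e. any group in
  which some present subgenome contributes more than one copy (the
  copy-number-variant class).

Per-subgenome summaries report, for each subgenome, how many (and what
percentage of) its genes fall into each class, plus the "absence-bearing"
fraction (duplet% + singleton%), which measures gene loss pressure on that
subgenome.

Genes that belong to no homoeolog group are counted as singletons by default
so that per-class percentages partition the full per-subgenome gene totals;
pass ``ungrouped_as_singleton=False`` to restrict summaries to grouped genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ContractError, InputError

SUBGENOMES: tuple[str, ...] = ("A", "B", "C")
RETENTION_CLASSES: tuple[str, ...] = ("triad", "duplet", "singleton", "other_multicopy")

_CATALOG_COLUMNS = ("gene_id", "subgenome", "group_id")


def _round2(x: float) -> float:
    """Round to 2 decimals, half to even (banker's rounding)."""
    return float(np.round(x, 2))


@dataclass(frozen=True)
class HomoeologGroup:
    """One homoeologous gene group with its per-subgenome members."""

    group_id: str
    members: Mapping[str, tuple[str, ...]]

    @property
    def copy_vector(self) -> tuple[int, int, int]:
        return tuple(len(self.members.get(s, ())) for s in SUBGENOMES)  # type: ignore[return-value]

    def gene_ids(self) -> list[str]:
        return [g for s in SUBGENOMES for g in self.members.get(s, ())]


@dataclass(frozen=True)
class GeneCatalog:
    """All annotated genes with their subgenome and (optional) group id.

    ``frame`` has columns gene_id, subgenome, group_id; group_id is the empty
    string for ungrouped genes. gene_id is unique.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _CATALOG_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"gene catalog is missing columns: {missing}")
        bad = ~df["subgenome"].isin(SUBGENOMES)
        if bad.any():
            row = df.index[bad][0]
            raise InputError(
                f"unknown subgenome label {df.loc[row, 'subgenome']!r} for gene "
                f"{df.loc[row, 'gene_id']!r} (row {row}); expected one of {SUBGENOMES}"
            )
        dup = df["gene_id"].duplicated()
        if dup.any():
            dupes = sorted(df.loc[dup, "gene_id"].unique()[:5])
            raise InputError(f"duplicate gene_id(s) in catalog: {dupes}")

    @property
    def totals(self) -> dict[str, int]:
        """Gene count per subgenome."""
        counts = self.frame["subgenome"].value_counts()
        return {s: int(counts.get(s, 0)) for s in SUBGENOMES}

    def __len__(self) -> int:
        return len(self.frame)


def load_gene_catalog(path: str | Path) -> GeneCatalog:
    """Read a gene catalog TSV (gene_id, subgenome, group_id; '#' comments).

    Subgenome labels are upper-cased before validation; group_id may be empty.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise InputError(f"cannot parse gene catalog {path}: {exc}") from exc
    if not set(_CATALOG_COLUMNS) <= set(df.columns):
        raise InputError(
            f"gene catalog {path} must have header columns {_CATALOG_COLUMNS}, "
            f"found {list(df.columns)}"
        )
    df = df.loc[:, list(_CATALOG_COLUMNS)].copy()
    df["subgenome"] = df["subgenome"].str.upper()
    return GeneCatalog(df.reset_index(drop=True))


def write_gene_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    catalog.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def groups_from_catalog(catalog: GeneCatalog) -> list[HomoeologGroup]:
    """Assemble homoeolog groups from the catalog's group_id column.

    Rows with an empty group_id are ungrouped and contribute no group.
    Groups are returned sorted by group_id; member lists keep catalog order.
    """
    df = catalog.frame
    grouped = df[df["group_id"] != ""]
    out: list[HomoeologGroup] = []
    for gid, sub in grouped.groupby("group_id", sort=True):
        members = {
            s: tuple(sub.loc[sub["subgenome"] == s, "gene_id"]) for s in SUBGENOMES
        }
        out.append(HomoeologGroup(str(gid), {s: m for s, m in members.items() if m}))
    return out


def classify_copy_vector(copy_vector: Iterable[int]) -> str:
    """Map a (nA, nB, nC) copy vector to its retention class.

    Raises :class:`InputError` for negative components or the all-zero vector.
    """
    cv = tuple(int(n) for n in copy_vector)
    if len(cv) != len(SUBGENOMES):
        raise InputError(f"copy vector must have {len(SUBGENOMES)} components, got {cv}")
    if any(n < 0 for n in cv):
        raise InputError(f"negative copy number in {cv}")
    if all(n == 0 for n in cv):
        raise InputError("copy vector (0, 0, 0) describes no group")
    if max(cv) > 1:
        return "other_multicopy"
    present = sum(cv)
    if present == 3:
        return "triad"
    if present == 2:
        return "duplet"
    return "singleton"


def classify_group(group: HomoeologGroup) -> str:
    return classify_copy_vector(group.copy_vector)


def classify_all(
    groups: Iterable[HomoeologGroup],
    catalog: GeneCatalog,
    *,
    ungrouped_as_singleton: bool = True,
) -> pd.Series:
    """Assign a retention class to every gene in the catalog.

    Each gene inherits the class of its group. Genes that appear in no group
    are counted as ``singleton`` when ``ungrouped_as_singleton`` (they have a
    single copy visible in one subgenome), otherwise they are dropped.

    Returns a Series of class names indexed by gene_id.
    """
    known = set(catalog.frame["gene_id"])
    assigned: dict[str, str] = {}
    for group in groups:
        cls = classify_group(group)
        genes = group.gene_ids()
        missing = [g for g in genes if g not in known]
        if missing:
            raise InputError(
                f"group {group.group_id!r} references genes absent from the "
                f"catalog: {missing[:5]}"
            )
        for g in genes:
            assigned[g] = cls
    if ungrouped_as_singleton:
        for g in catalog.frame["gene_id"]:
            if g not in assigned:
                assigned[g] = "singleton"
    series = pd.Series(assigned, name="retention_class")
    series.index.name = "gene_id"
    return series


@dataclass(frozen=True)
class RetentionSummary:
    """Per-subgenome retention accounting.

    ``counts``/``percent`` are subgenome × class DataFrames (percent rounded
    to 2 decimals, half-even); ``fractions`` keeps the unrounded values.
    ``absence_bearing_percent`` is duplet% + singleton% per subgenome,
    summed before rounding.
    """

    counts: pd.DataFrame
    percent: pd.DataFrame
    fractions: pd.DataFrame
    absence_bearing_percent: pd.Series
    totals: pd.Series

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per subgenome × class."""
        rows = []
        for s in self.counts.index:
            for c in self.counts.columns:
                rows.append(
                    {
                        "subgenome": s,
                        "retention_class": c,
                        "n_genes": int(self.counts.loc[s, c]),
                        "percent": self.percent.loc[s, c],
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            s: {
                "total_genes": int(self.totals[s]),
                "class_counts": {c: int(self.counts.loc[s, c]) for c in self.counts.columns},
                "class_percent": {c: float(self.percent.loc[s, c]) for c in self.percent.columns},
                "absence_bearing_percent": float(self.absence_bearing_percent[s]),
            }
            for s in self.counts.index
        }

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False, lineterminator="\n")
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def summarize_retention(assignments: pd.Series, catalog: GeneCatalog) -> RetentionSummary:
    """Tally retention classes per subgenome over the full catalog.

    Denominators are the catalog's per-subgenome gene totals; every catalog
    gene must carry an assignment. Subgenomes with zero genes are rejected
    (their percentages are undefined).
    """
    df = catalog.frame
    unassigned = set(df["gene_id"]) - set(assignments.index)
    if unassigned:
        raise ContractError(
            f"{len(unassigned)} catalog genes have no retention assignment "
            f"(e.g. {sorted(unassigned)[:3]})"
        )
    totals = pd.Series(catalog.totals)
    empty = totals[totals == 0]
    if not empty.empty:
        raise InputError(
            f"subgenome(s) {list(empty.index)} contain no genes; per-class "
            "percentages are undefined"
        )
    merged = df.assign(retention_class=df["gene_id"].map(assignments))
    counts = (
        merged.groupby(["subgenome", "retention_class"], sort=False)
        .size()
        .unstack(fill_value=0)
        .reindex(index=list(SUBGENOMES), columns=list(RETENTION_CLASSES), fill_value=0)
    )
    fractions = counts.div(totals, axis=0) * 100.0
    percent = fractions.map(_round2)
    absence_raw = fractions["duplet"] + fractions["singleton"]
    absence = absence_raw.map(_round2)
    return RetentionSummary(
        counts=counts,
        percent=percent,
        fractions=fractions,
        absence_bearing_percent=absence,
        totals=totals,
    )


def extract_triads(groups: Iterable[HomoeologGroup]) -> pd.DataFrame:
    """Table of 1:1:1 triads: columns triad_id, gene_A, gene_B, gene_C.

    One row per group whose copy vector is (1, 1, 1), sorted by group id.
    """
    rows = []
    for group in groups:
        if classify_group(group) == "triad":
            rows.append(
                {
                    "triad_id": group.group_id,
                    "gene_A": group.members["A"][0],
                    "gene_B": group.members["B"][0],
                    "gene_C": group.members["C"][0],
                }
            )
    out = pd.DataFrame(rows, columns=["triad_id", "gene_A", "gene_B", "gene_C"])
    return out.sort_values("triad_id", kind="stable").reset_index(drop=True)


def build_catalog_from_counts(
    n_triads: int,
    duplet_pairs: Mapping[tuple[str, str], int],
    singletons: Mapping[str, int],
    multicopy_genes: Mapping[str, int],
) -> GeneCatalog:
    """Construct a catalog realizing exact per-class gene counts.

    Useful for benchmarking the retention summary against published
    per-subgenome tallies. ``duplet_pairs`` maps subgenome pairs, e.g.
    ("A", "B"), to numbers of duplet *groups* (each contributes one gene to
    both subgenomes); ``singletons`` maps subgenomes to singleton-group
    counts; ``multicopy_genes`` maps subgenomes to a gene count realized as
    a single multi-copy group per subgenome (must be 0 or >= 2 so the group
    classifies as other_multicopy).
    """
    rows: list[dict] = []
    counters = {s: 0 for s in SUBGENOMES}
    group_no = 0

    def add_gene(sub: str, gid: str) -> None:
        counters[sub] += 1
        rows.append(
            {"gene_id": f"{sub}_g{counters[sub]:06d}", "subgenome": sub, "group_id": gid}
        )

    for _ in range(n_triads):
        group_no += 1
        gid = f"og{group_no:06d}"
        for s in SUBGENOMES:
            add_gene(s, gid)
    for (s1, s2), n in sorted(duplet_pairs.items()):
        for _ in range(n):
            group_no += 1
            gid = f"og{group_no:06d}"
            add_gene(s1, gid)
            add_gene(s2, gid)
    for s, n in sorted(singletons.items()):
        for _ in range(n):
            group_no += 1
            add_gene(s, f"og{group_no:06d}")
    for s, n in sorted(multicopy_genes.items()):
        if n == 1:
            raise InputError(
                "a single-gene multicopy group is impossible; counts must be 0 or >= 2"
            )
        if n:
            group_no += 1
            gid = f"og{group_no:06d}"
            for _ in range(n):
                add_gene(s, gid)
    return GeneCatalog(pd.DataFrame(rows, columns=list(_CATALOG_COLUMNS)))


def load_triads(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    need = {"triad_id", "gene_A", "gene_B", "gene_C"}
    if not need <= set(df.columns):
        raise InputError(f"triad table {path} must have columns {sorted(need)}")
    return df
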