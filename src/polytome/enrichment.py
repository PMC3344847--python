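"""Gene-set enrichment: single-selection Fisher tests and ranked-list scans.

Two complementary modes over user-supplied GMT collections:

* ``fisher_term_enrichment`` — classic 2x2 over-representation of each set
  among a selected gene list versus a background, Fisher exact p with
  Benjamini–Hochberg adjustment across sets.
* ``ranked_partition_scan`` — threshold-free scanning of a ranked gene
  list: partition k of ``n_partitions`` selects the top
  ``ceil(k*n/(n_partitions+1))`` genes and runs the same Fisher machinery,
  with BH adjustment across all (set, partition) tests and the best
  partition reported per set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (id, description, members)."""

    sets: dict = field(default_factory=dict)
    descriptions: dict = field(default_factory=dict)

    @classmethod
    def from_gmt(cls, source) -> "GeneSetCollection":
        """Parse a GMT file: one set per line, tab-separated
        ``name<TAB>description<TAB>member...``."""
        sets: dict[str, frozenset] = {}
        descriptions: dict[str, str] = {}
        close = False
        if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
            handle = open(source)
            close = True
        else:
            handle = source
        try:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ConfigurationError(
                        f"GMT line {lineno}: expected name, description and members"
                    )
                name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
                if name in sets:
                    raise ConfigurationError(f"GMT line {lineno}: duplicate set id {name!r}")
                if not members:
                    raise ConfigurationError(f"GMT line {lineno}: set {name!r} has no members")
                sets[name] = frozenset(members)
                descriptions[name] = desc
        finally:
            if close:
                handle.close()
        return cls(sets=sets, descriptions=descriptions)

    def to_gmt(self, path) -> None:
        with open(path, "w") as out:
            for name in self.sets:
                members = "\t".join(sorted(self.sets[name]))
                out.write(f"{name}\t{self.descriptions.get(name, '')}\t{members}\n")

    def __len__(self) -> int:
        return len(self.sets)


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def fisher_term_enrichment(
    selected,
    background,
    collection: GeneSetCollection,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Fisher exact over-representation of each gene set.

    ``selected`` must be a subset of ``background``.  Each set is first
    intersected with the background; sets vanishing there are skipped with
    a log entry.  Counts follow the 2x2 layout (in-set & selected, in-set &
    unselected, out-set & selected, out-set & unselected).  ``p_adj`` is
    Benjamini–Hochberg across the tested sets.
    """
    selected = set(selected)
    background = set(background)
    stray = selected - background
    if stray:
        preview = ", ".join(sorted(stray)[:10])
        raise ConfigurationError(
            f"{len(stray)} selected id(s) missing from background: {preview}"
        )
    if not background:
        raise ConfigurationError("background is empty")
    n_bg = len(background)
    n_sel = len(selected)
    rows = []
    for name, members in collection.sets.items():
        in_bg = members & background
        if not in_bg:
            log.info("set %s has no members in background; skipped", name)
            continue
        a = len(in_bg & selected)
        b = len(in_bg) - a
        c = n_sel - a
        d = n_bg - n_sel - b
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative).pvalue)
        rows.append(
            {
                "set_id": name,
                "n_set_background": len(in_bg),
                "in_set_selected": a,
                "in_set_unselected": b,
                "out_set_selected": c,
                "out_set_unselected": d,
                "odds_ratio": _odds_ratio(a, b, c, d),
                "p_value": p,
            }
        )
    results = pd.DataFrame(rows)
    if not results.empty:
        results["p_adj"] = multipletests(results["p_value"], method="fdr_bh")[1]
    return results


def partition_sizes(n: int, n_partitions: int) -> list[int]:
    """Top-list size of each partition: ceil(k*n/(n_partitions+1)), k=1.."""
    return [math.ceil(k * n / (n_partitions + 1)) for k in range(1, n_partitions + 1)]


def ranked_partition_scan(
    ranked_ids,
    collection: GeneSetCollection,
    n_partitions: int = 30,
    alternative: str = "two-sided",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan a ranked gene list against a collection at many cut points.

    Returns ``(results, best)``: all (set, partition) Fisher tests with BH
    adjustment across the whole family, and per set the minimal adjusted p
    with the partition attaining it.

    Raises
    ------
    ConfigurationError
        On duplicate ranked ids or an out-of-range ``n_partitions``.
    """
    ranked = list(ranked_ids)
    if len(set(ranked)) != len(ranked):
        raise ConfigurationError("ranked id list contains duplicates")
    n = len(ranked)
    if not (1 <= n_partitions < n):
        raise ConfigurationError(
            f"n_partitions must be in [1, {n - 1}] for a list of {n}, got {n_partitions}"
        )
    background = set(ranked)
    frames = []
    for k, size in enumerate(partition_sizes(n, n_partitions), start=1):
        res = fisher_term_enrichment(
            ranked[:size], background, collection, alternative=alternative
        )
        if res.empty:
            continue
        res = res.drop(columns=["p_adj"])
        res.insert(1, "partition", k)
        res.insert(2, "top_size", size)
        frames.append(res)
    if not frames:
        return pd.DataFrame(), pd.DataFrame()
    results = pd.concat(frames, ignore_index=True)
    results["p_adj"] = multipletests(results["p_value"], method="fdr_bh")[1]
    best = (
        results.loc[results.groupby("set_id")["p_adj"].idxmin()]
        .sort_values("p_adj")
        .reset_index(drop=True)
    )
    return results, best


def read_ranking(source, sep: str = "\t") -> list[str]:
    """Read a two-column (gene_id, score) table; ids ordered by falling score."""
    df = pd.read_csv(source, sep=sep, dtype={0: str})
    df.columns = ["gene_id", "score"][: len(df.columns)]
    df = df.sort_values("score", ascending=False, kind="mergesort")
    return df["gene_id"].tolist()
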