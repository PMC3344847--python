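"""Cross-species comparison of translation efficiencies via ortholog pairs.

Given per-gene expression tables for two species and a two-column ortholog
table, build the paired TE table and measure agreement (Pearson r, R^2)
within abundance strata.  Requiring ``min(A_a, A_b) >= cutoff`` is the
conservative reading of an abundance threshold applied across species.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def read_ortholog_pairs(source, sep: str = "\t") -> pd.DataFrame:
    """Read a two-column ortholog table (id_a, id_b); extra columns ignored."""
    pairs = pd.read_csv(source, sep=sep, dtype=str)
    pairs = pairs.iloc[:, :2]
    pairs.columns = ["id_a", "id_b"]
    return pairs


def pair_translatomes(
    pairs: pd.DataFrame, expr_a: pd.DataFrame, expr_b: pd.DataFrame
) -> pd.DataFrame:
    """Join two expression tables through an ortholog pair table.

    Duplicate pairs are dropped before joining; one-to-many orthology is
    expanded to all combinations (logged).  Only pairs with both genes
    measured are retained.
    """
    pairs = pairs.drop_duplicates(subset=["id_a", "id_b"]).copy()
    a = expr_a.rename(columns={"gene_id": "id_a", "M": "te_a", "A": "a_a"})
    b = expr_b.rename(columns={"gene_id": "id_b", "M": "te_b", "A": "a_b"})
    paired = pairs.merge(a[["id_a", "te_a", "a_a"]], on="id_a", how="inner")
    paired = paired.merge(b[["id_b", "te_b", "a_b"]], on="id_b", how="inner")
    n_multi = int(
        (paired["id_a"].duplicated(keep=False) | paired["id_b"].duplicated(keep=False)).sum()
    )
    if n_multi:
        log.info("%d paired row(s) arise from one-to-many ortholog mappings", n_multi)
    log.info("retained %d of %d ortholog pairs with both genes measured", len(paired), len(pairs))
    return paired.reset_index(drop=True)


def stratified_correlation(paired: pd.DataFrame, a_cutoffs) -> pd.DataFrame:
    """Pearson r and R^2 of (te_a, te_b) per abundance stratum.

    Stratum ``c`` keeps pairs with ``min(a_a, a_b) >= c``.  Strata with
    fewer than 3 pairs (or zero variance) report ``r = NaN``.
    """
    a_min = np.minimum(paired["a_a"].to_numpy(float), paired["a_b"].to_numpy(float))
    te_a = paired["te_a"].to_numpy(float)
    te_b = paired["te_b"].to_numpy(float)
    rows = []
    for cutoff in sorted(a_cutoffs):
        mask = a_min >= cutoff
        n = int(mask.sum())
        if n >= 3 and np.std(te_a[mask]) > 0 and np.std(te_b[mask]) > 0:
            r = float(np.corrcoef(te_a[mask], te_b[mask])[0, 1])
        else:
            r = float("nan")
        rows.append({"a_cutoff": float(cutoff), "n": n, "r": r, "r2": r * r})
    return pd.DataFrame(rows)
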