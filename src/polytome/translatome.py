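"""Stress-induced translation changes and S/R/I translation classes.

Comparing translation efficiencies (M = log2 P/FM) between control and
stressed cells partitions mRNAs into three behavioural classes:

* **S** (stress-sensitive): translation fell by at least 0.8 log2 units.
* **R** (arrest-resistant): M >= 0.8 in *both* conditions — the mRNA keeps
  translating at moderate-to-high rates through the initiation blockade.
* **I** (inducible): poorly translated under control conditions
  (M <= 0) but gaining >= 1 log2 unit under stress (the ATF4-like pattern
  driven by upstream ORFs and eIF2alpha phosphorylation).
* **U**: none of the above.

Rules are evaluated with precedence I -> R -> S, so an mRNA whose TE drops
from 3.0 to 1.0 counts as resistant (it still translates well), not
sensitive.  The same module quantifies translatome–transcriptome
coordination (Venn overlap of translation vs abundance changes) and places
calibration-marker genes on the TE distribution by midrank percentile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ConfigurationError, PolytomeError

log = logging.getLogger(__name__)

CLASS_LABELS = ("S", "R", "I", "U")


@dataclass(frozen=True)
class ClassThresholds:
    """Cutoffs defining the translation classes and "changed" calls.

    Attributes
    ----------
    s_delta
        Maximum translation change (log2) for a sensitive call; must be < 0.
    r_level
        Minimum M in both conditions for a resistant call; must be > 0.
    i_control_max
        Maximum control M for an inducible call.
    i_delta
        Minimum translation gain (log2) for an inducible call; must be > 0.
    venn_translation_delta
        |delta M| at or above which translation counts as "changed" in the
        coordination analysis (kept separate from ``s_delta``: the class
        definition uses 0.8, the Venn analysis uses 1).
    abundance_delta
        |delta A| at or above which abundance counts as "changed".
    """

    s_delta: float = -0.8
    r_level: float = 0.8
    i_control_max: float = 0.0
    i_delta: float = 1.0
    venn_translation_delta: float = 1.0
    abundance_delta: float = 1.0

    def __post_init__(self):
        values = [
            self.s_delta, self.r_level, self.i_control_max,
            self.i_delta, self.venn_translation_delta, self.abundance_delta,
        ]
        if not all(math.isfinite(v) for v in values):
            raise ConfigurationError("all class thresholds must be finite")
        if self.s_delta >= 0:
            raise ConfigurationError("s_delta must be negative")
        if self.r_level <= 0:
            raise ConfigurationError("r_level must be positive")
        if self.i_delta <= 0:
            raise ConfigurationError("i_delta must be positive")
        if self.i_control_max >= self.r_level:
            raise ConfigurationError(
                "i_control_max must be below r_level so that I and R are disjoint"
            )


ENTRY_COLUMNS = (
    "gene_id", "te_control", "te_stress", "delta_te",
    "a_control", "a_stress", "delta_a", "class_label",
)


def compute_translation_change(
    control: pd.DataFrame, stress: pd.DataFrame
) -> pd.DataFrame:
    """Pair the two conditions gene-wise and compute delta M / delta A.

    Both inputs are expression tables (``gene_id``, ``M``, ``A``).  Genes
    present in only one condition are dropped with a logged count.  The
    returned entries carry ``class_label = 'U'``; call
    :func:`assign_classes` to classify.
    """
    merged = control.merge(
        stress, on="gene_id", how="inner", suffixes=("_control", "_stress")
    )
    dropped = (len(control) - len(merged)) + (len(stress) - len(merged))
    if dropped:
        log.info(
            "dropped %d gene(s) present in only one condition (%d shared)",
            dropped, len(merged),
        )
    if merged.empty:
        log.warning("no genes shared between conditions")
    entries = pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "te_control": merged["M_control"],
            "te_stress": merged["M_stress"],
            "delta_te": merged["M_stress"] - merged["M_control"],
            "a_control": merged["A_control"],
            "a_stress": merged["A_stress"],
            "delta_a": merged["A_stress"] - merged["A_control"],
            "class_label": "U",
        }
    )
    return entries


def classify_translation(
    te_control: float, te_stress: float, thresholds: ClassThresholds | None = None
) -> str:
    """Class label for a single (control, stress) TE pair.

    Precedence: inducible, then resistant, then sensitive, else U.
    """
    thr = thresholds or ClassThresholds()
    delta = te_stress - te_control
    if te_control <= thr.i_control_max and delta >= thr.i_delta:
        return "I"
    if te_control >= thr.r_level and te_stress >= thr.r_level:
        return "R"
    if delta <= thr.s_delta:
        return "S"
    return "U"


def assign_classes(
    entries: pd.DataFrame, thresholds: ClassThresholds | None = None
) -> pd.DataFrame:
    """Vectorised class assignment; returns a copy with ``class_label`` set."""
    thr = thresholds or ClassThresholds()
    tc = entries["te_control"].to_numpy(float)
    ts = entries["te_stress"].to_numpy(float)
    delta = ts - tc
    label = np.select(
        [
            (tc <= thr.i_control_max) & (delta >= thr.i_delta),
            (tc >= thr.r_level) & (ts >= thr.r_level),
            delta <= thr.s_delta,
        ],
        ["I", "R", "S"],
        default="U",
    )
    out = entries.copy()
    out["class_label"] = label
    return out


def percentile_placement(
    te_values: pd.Series, markers
) -> dict[str, float | None]:
    """Midrank percentile of each marker gene within a TE distribution.

    ``te_values`` is indexed by gene id.  Ties share their midrank, so the
    percentile of a value v is ``(midrank(v) - 0.5) / n * 100``; an absent
    marker maps to ``None`` (logged, not raised).
    """
    values = te_values.to_numpy(float)
    ranks = rankdata(values, method="average")
    pct = (ranks - 0.5) / len(values) * 100.0
    by_gene = pd.Series(pct, index=te_values.index)
    placements: dict[str, float | None] = {}
    for marker in markers:
        if marker in by_gene.index:
            placements[marker] = float(by_gene[marker])
        else:
            log.warning("marker %s absent from distribution", marker)
            placements[marker] = None
    return placements


def _pct(k: int, n: int) -> float:
    return 100.0 * k / n if n else 0.0


def coordination_analysis(
    entries: pd.DataFrame, thresholds: ClassThresholds | None = None
) -> dict:
    """Quantify coordination between translation and abundance changes.

    Returns a JSON-ready dict with

    * ``venn`` — counts of genes whose translation only, abundance only, or
      both changed (|delta M| >= ``venn_translation_delta``,
      |delta A| >= ``abundance_delta``);
    * ``classes`` — per S/R/I class, the count and percentage whose
      abundance went up (delta A >= cutoff) or down (<= -cutoff);
    * ``abundance_up`` — among genes whose abundance increased, the
      percentage translationally induced (delta M >= ``i_delta``) and
      repressed (delta M <= ``s_delta``).
    """
    thr = thresholds or ClassThresholds()
    classified = assign_classes(entries, thr)
    d_te = classified["delta_te"].to_numpy(float)
    d_a = classified["delta_a"].to_numpy(float)
    t_changed = np.abs(d_te) >= thr.venn_translation_delta
    a_changed = np.abs(d_a) >= thr.abundance_delta

    report: dict = {
        "venn": {
            "translation_only": int((t_changed & ~a_changed).sum()),
            "abundance_only": int((a_changed & ~t_changed).sum()),
            "both": int((t_changed & a_changed).sum()),
        },
        "classes": {},
    }
    labels = classified["class_label"].to_numpy()
    for cls in ("S", "R", "I"):
        mask = labels == cls
        n = int(mask.sum())
        up = int((mask & (d_a >= thr.abundance_delta)).sum())
        down = int((mask & (d_a <= -thr.abundance_delta)).sum())
        report["classes"][cls] = {
            "n": n,
            "abundance_up": up,
            "pct_abundance_up": _pct(up, n),
            "abundance_down": down,
            "pct_abundance_down": _pct(down, n),
        }
    a_up = d_a >= thr.abundance_delta
    n_up = int(a_up.sum())
    report["abundance_up"] = {
        "n": n_up,
        "pct_translation_up": _pct(int((a_up & (d_te >= thr.i_delta)).sum()), n_up),
        "pct_translation_down": _pct(int((a_up & (d_te <= thr.s_delta)).sum()), n_up),
    }
    report["metadata"] = {
        "class_precedence": "I,R,S",
        "thresholds": {
            "s_delta": thr.s_delta,
            "r_level": thr.r_level,
            "i_control_max": thr.i_control_max,
            "i_delta": thr.i_delta,
            "venn_translation_delta": thr.venn_translation_delta,
            "abundance_delta": thr.abundance_delta,
        },
    }
    return report


def subset_summary(entries: pd.DataFrame, gene_ids) -> dict:
    """Mean +/- sample SD of control and stress TE over a gene subset.

    Raises
    ------
    PolytomeError
        If the id list does not intersect the entries.
    """
    ids = list(gene_ids)
    subset = entries[entries["gene_id"].isin(ids)]
    if subset.empty:
        raise PolytomeError(
            f"subset of {len(ids)} id(s) has no overlap with the translatome entries"
        )
    def _stats(col):
        v = subset[col].to_numpy(float)
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        return {"mean": float(np.mean(v)), "sd": sd}
    return {
        "n": int(len(subset)),
        "n_requested": len(ids),
        "te_control": _stats("te_control"),
        "te_stress": _stats("te_stress"),
    }


def write_translatome_table(entries: pd.DataFrame, path) -> None:
    """Write the per-gene translatome table as TSV."""
    entries.to_csv(path, sep="\t", index=False, float_format="%.10g")
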