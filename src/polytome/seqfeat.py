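"""Transcript anatomy features and their association with translation classes.

Each transcript is partitioned by its CDS coordinates (0-based, half-open,
inclusive of start and stop codons) into 5'UTR / CDS / 3'UTR.  The feature
set mirrors the classic initiation-control determinants: region lengths and
G+C content, the number of upstream AUG triplets in the 5'UTR (uAUG — the
ATF4-style repressive elements), and whether the initiator AUG sits in a
favourable context (purine at position -3, the Kozak R of RnnAUG).

``class_feature_report`` compares these features across translation groups
(Total / High / Low / R / I) after the standard selection filter
(A >= 5.5, both UTRs >= 10 nt): Welch t-tests for continuous features and
Fisher exact tests for proportions, each group against its complement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

log = logging.getLogger(__name__)

_VALID = set("ACGTN")


@dataclass(frozen=True)
class TranscriptAnnotation:
    """A sense-strand transcript sequence with CDS coordinates.

    ``sequence`` is stored uppercase with U normalised to T;
    ``cds_start``/``cds_end`` delimit the CDS as a 0-based half-open
    interval including both the initiator ATG and the stop codon.
    """

    transcript_id: str
    sequence: str
    cds_start: int
    cds_end: int

    @property
    def utr5(self) -> str:
        return self.sequence[: self.cds_start]

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    @property
    def utr3(self) -> str:
        return self.sequence[self.cds_end :]


@dataclass(frozen=True)
class FeatureVector:
    """Derived anatomy features of one transcript."""

    cds_len: int
    cds_gc: float
    utr5_len: int
    utr5_gc: float
    utr3_len: int
    utr3_gc: float
    n_uaug: int
    start_context_purine: bool | None


def normalize_sequence(seq: str) -> str:
    """Uppercase and map U to T; raises ValueError on foreign characters."""
    s = str(seq).upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"invalid nucleotide character(s): {sorted(bad)}")
    return s


def parse_annotation(
    fasta_source,
    cds_table: pd.DataFrame | str,
    validate_frame: bool = True,
) -> list[TranscriptAnnotation]:
    """Build annotations from a FASTA file and a CDS coordinate table.

    ``cds_table`` is a DataFrame or TSV path with columns
    ``transcript_id``, ``cds_start``, ``cds_end``.  Rows referencing a
    missing FASTA record, out-of-range coordinates, frame violations (when
    ``validate_frame``) or foreign characters are skipped with a logged
    reason; valid transcripts are returned.
    """
    if not isinstance(cds_table, pd.DataFrame):
        cds_table = pd.read_csv(cds_table, sep="\t", dtype={"transcript_id": str})
    sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_source, "fasta")}
    annotations: list[TranscriptAnnotation] = []
    for row in cds_table.itertuples(index=False):
        tid = str(row.transcript_id)
        if tid not in sequences:
            log.warning("transcript %s: no FASTA record; row skipped", tid)
            continue
        try:
            seq = normalize_sequence(sequences[tid])
        except ValueError as exc:
            log.warning("transcript %s rejected: %s", tid, exc)
            continue
        start, end = int(row.cds_start), int(row.cds_end)
        if not (0 <= start < end <= len(seq)):
            log.warning(
                "transcript %s rejected: CDS [%d, %d) outside sequence of length %d",
                tid, start, end, len(seq),
            )
            continue
        if validate_frame and (end - start) % 3 != 0:
            log.warning(
                "transcript %s rejected: CDS length %d not divisible by 3",
                tid, end - start,
            )
            continue
        annotations.append(TranscriptAnnotation(tid, seq, start, end))
    return annotations


def gc_percent(region: str) -> float:
    """G+C percentage over A/C/G/T (Ns excluded); NaN for an empty region."""
    acgt = sum(region.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return 100.0 * (region.count("G") + region.count("C")) / acgt


def count_uaug(utr5: str) -> int:
    """Number of ATG triplets lying entirely within the 5'UTR.

    All positions are scanned, so overlapping occurrences each count.
    """
    count, pos = 0, utr5.find("ATG")
    while pos != -1:
        count += 1
        pos = utr5.find("ATG", pos + 1)
    return count


def extract_features(annotation: TranscriptAnnotation) -> FeatureVector:
    """Compute the feature vector of one transcript (pure function)."""
    utr5, cds, utr3 = annotation.utr5, annotation.cds, annotation.utr3
    if len(utr5) < 3:
        context: bool | None = None
    else:
        base = utr5[-3]
        context = None if base == "N" else base in ("A", "G")
    return FeatureVector(
        cds_len=len(cds),
        cds_gc=gc_percent(cds),
        utr5_len=len(utr5),
        utr5_gc=gc_percent(utr5),
        utr3_len=len(utr3),
        utr3_gc=gc_percent(utr3),
        n_uaug=count_uaug(utr5),
        start_context_purine=context,
    )


def features_table(annotations) -> pd.DataFrame:
    """Feature vectors for a collection of annotations, one row each."""
    rows = []
    for ann in annotations:
        fv = extract_features(ann)
        rows.append({"transcript_id": ann.transcript_id, **fv.__dict__})
    return pd.DataFrame(rows)


#: continuous features reported as group medians and tested by Welch t
_CONTINUOUS = ("cds_len", "cds_gc", "utr5_len", "utr5_gc", "utr3_len", "utr3_gc")
MAX_UAUG_CLASS = 5


@dataclass
class FeatureReport:
    """Table-style feature report across translation groups.

    ``values`` holds the displayed statistic per (feature row, group):
    medians for lengths, means for GC%, frequencies/percentages for
    proportion rows.  ``pvalues`` holds the group-vs-complement p per cell
    (NaN for Total and for groups with n < 2).  ``metadata`` records test
    choices and filter settings.
    """

    values: pd.DataFrame
    pvalues: pd.DataFrame
    group_sizes: dict
    n_selected: int
    n_dropped: int
    metadata: dict

    def significant(self, alpha: float = 0.005) -> pd.DataFrame:
        return self.pvalues < alpha


def _welch_p(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or len(y) < 2:
        return float("nan")
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def _fisher_p(k_in: int, n_in: int, k_out: int, n_out: int) -> float:
    if n_in < 2 or n_out < 2:
        return float("nan")
    table = [[k_in, n_in - k_in], [k_out, n_out - k_out]]
    return float(stats.fisher_exact(table).pvalue)


def class_feature_report(
    features: pd.DataFrame,
    *,
    a_min: float = 5.5,
    utr5_min: int = 10,
    utr3_min: int = 10,
    high_cutoff: float = 2.0,
    low_cutoff: float = -1.5,
) -> FeatureReport:
    """Compare features across translation groups, Table-style.

    ``features`` must carry the feature columns plus ``A`` (abundance) and
    ``m`` (control translation efficiency); an optional ``class_label``
    column adds the R and I groups.  Groups: Total (all selected), High
    (m >= ``high_cutoff``), Low (m <= ``low_cutoff``), and R / I from
    ``class_label``.  Each group is tested against its complement within the
    selected set.
    """
    selected = features[
        (features["A"] >= a_min)
        & (features["utr5_len"] >= utr5_min)
        & (features["utr3_len"] >= utr3_min)
    ].reset_index(drop=True)
    n_dropped = len(features) - len(selected)
    log.info("feature-report filter kept %d of %d transcripts", len(selected), len(features))

    masks: dict[str, np.ndarray] = {
        "Total": np.ones(len(selected), dtype=bool),
        "High": selected["m"].to_numpy(float) >= high_cutoff,
        "Low": selected["m"].to_numpy(float) <= low_cutoff,
    }
    if "class_label" in selected.columns:
        labels = selected["class_label"].to_numpy()
        masks["R"] = labels == "R"
        masks["I"] = labels == "I"

    row_names = (
        ["n"]
        + list(_CONTINUOUS)
        + ["rnn_aug_freq"]
        + [f"uaug_ge_{k}_pct" for k in range(1, MAX_UAUG_CLASS + 1)]
    )
    values = pd.DataFrame(index=row_names, columns=list(masks), dtype=float)
    pvalues = pd.DataFrame(index=row_names, columns=list(masks), dtype=float)

    n_uaug = selected["n_uaug"].to_numpy(int) if len(selected) else np.array([], dtype=int)
    purine = selected["start_context_purine"] if len(selected) else pd.Series(dtype=object)
    for name, mask in masks.items():
        comp = ~mask if name != "Total" else np.zeros(len(selected), dtype=bool)
        n_g, n_c = int(mask.sum()), int(comp.sum())
        values.loc["n", name] = n_g
        for feat in _CONTINUOUS:
            col = selected[feat].to_numpy(float) if len(selected) else np.array([])
            g = col[mask]
            if n_g == 0:
                values.loc[feat, name] = float("nan")
            elif feat.endswith("_gc"):
                values.loc[feat, name] = float(np.nanmean(g))
            else:
                values.loc[feat, name] = float(np.nanmedian(g))
            if name != "Total":
                pvalues.loc[feat, name] = _welch_p(
                    col[mask][~np.isnan(col[mask])], col[comp][~np.isnan(col[comp])]
                )
        known = purine.notna().to_numpy() if len(selected) else np.array([], dtype=bool)
        k_in = int((purine[mask & known] == True).sum()) if n_g else 0  # noqa: E712
        m_in = int((mask & known).sum())
        values.loc["rnn_aug_freq", name] = k_in / m_in if m_in else float("nan")
        if name != "Total":
            k_out = int((purine[comp & known] == True).sum())  # noqa: E712
            pvalues.loc["rnn_aug_freq", name] = _fisher_p(
                k_in, m_in, k_out, int((comp & known).sum())
            )
        for k in range(1, MAX_UAUG_CLASS + 1):
            row = f"uaug_ge_{k}_pct"
            hits_in = int((n_uaug[mask] >= k).sum()) if n_g else 0
            values.loc[row, name] = 100.0 * hits_in / n_g if n_g else float("nan")
            if name != "Total":
                hits_out = int((n_uaug[comp] >= k).sum()) if n_c else 0
                pvalues.loc[row, name] = _fisher_p(hits_in, n_g, hits_out, n_c)

    return FeatureReport(
        values=values,
        pvalues=pvalues,
        group_sizes={name: int(mask.sum()) for name, mask in masks.items()},
        n_selected=len(selected),
        n_dropped=n_dropped,
        metadata={
            "filter": {"a_min": a_min, "utr5_min": utr5_min, "utr3_min": utr3_min},
            "group_cutoffs": {"high": high_cutoff, "low": low_cutoff},
            "continuous_test": "welch_t_two_sided",
            "proportion_test": "fisher_exact_two_sided",
            "note": (
                "proportion rows tested by Fisher exact rather than t-test; "
                "comparison is group vs complement of the selected set"
            ),
        },
    )


def write_feature_report(report: FeatureReport, path) -> None:
    """Write the report values with a parallel p-value column per group."""
    out = report.values.copy()
    for name in report.pvalues.columns:
        if name != "Total":
            out[f"p_{name}"] = report.pvalues[name]
    out.to_csv(path, sep="\t", index_label="feature", float_format="%.6g")
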