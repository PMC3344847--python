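"""Equilibrium base-pair probabilities and positional structure profiles.

The partition function over all pseudoknot-free secondary structures of a
sequence is computed by McCaskill's dynamic programme under a simplified
energy model: each allowed pair type (AU/UA, GC/CG, GU/UG) contributes a
configurable Boltzmann weight, there are no stacking or loop terms, and
hairpin loops must span at least ``min_loop`` unpaired bases.  A structure's
weight is the product of its pair weights; the empty structure has weight 1,
so Z >= 1 always.

Pair probabilities come from the inside–outside decomposition of the
(unambiguous) grammar

    S -> a S | P S | eps          P -> a S b   (a, b an allowed pair)

which yields the standard O(N^3) recursions.  ``positional_bpp_profile``
anchors per-base pairing probabilities (the marginal sum over partners) at
the start or stop codon, averages them per transcript group, and tests the
two groups position-by-position (Welch t).  Offset +1 is the A of the
initiator AUG, or the first base of the stop codon; there is no offset 0.

External base-pair probability matrices (e.g. from a full thermodynamic
folder) can be loaded with :func:`read_bpp_matrix` for parity runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

#: default Boltzmann weight per pair type (relative stability ordering)
DEFAULT_PAIR_WEIGHTS = {"GC": 3.0, "AU": 1.5, "GU": 0.8}

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


@dataclass(frozen=True)
class PairModel:
    """Pair-weight model: Boltzmann weight per allowed pair type.

    Weight keys are two-letter pair names; each key applies to both
    orientations (``"GC"`` covers GC and CG).  ``min_loop`` is the minimum
    number of unpaired bases enclosed by a hairpin (default 3, the
    steric minimum).
    """

    weights: dict = field(default_factory=lambda: dict(DEFAULT_PAIR_WEIGHTS))
    min_loop: int = 3

    def weight_of(self, a: str, b: str) -> float:
        for key, w in self.weights.items():
            if {a, b} == set(key) and a != b:
                return float(w)
            if a == b and key == a + b:
                return float(w)
        return 0.0


def _encode(sequence: str) -> str:
    seq = str(sequence).upper().replace("T", "U")
    bad = [i for i, c in enumerate(seq) if c not in "ACGU"]
    if bad:
        raise ValueError(f"invalid characters at position(s) {bad[:10]}")
    return seq


def _weight_matrix(seq: str, model: PairModel) -> np.ndarray:
    """W[i, j] = Boltzmann weight of pair (i, j), zero if disallowed."""
    n = len(seq)
    base_w = np.zeros((4, 4))
    idx = {b: k for k, b in enumerate("ACGU")}
    for a in "ACGU":
        for b in "ACGU":
            base_w[idx[a], idx[b]] = model.weight_of(a, b)
    codes = np.array([idx[c] for c in seq])
    W = base_w[np.ix_(codes, codes)]
    # enforce the minimum hairpin-loop span: pair (i, j) needs j - i > min_loop
    ii, jj = np.indices((n, n))
    W[jj - ii <= model.min_loop] = 0.0
    return np.triu(W)


def partition_function(sequence: str, model: PairModel | None = None) -> float:
    """Total Boltzmann-weighted count of nested structures (>= 1)."""
    model = model or PairModel()
    seq = _encode(sequence)
    Zh, _ = _inside(seq, model)
    return float(Zh[0, len(seq)])


def _inside(seq: str, model: PairModel):
    """Inside recursion over half-open intervals.

    ``Zh[i, j]`` is the partition function of subsequence ``[i, j)``;
    empty intervals have Zh = 1.
    """
    n = len(seq)
    W = _weight_matrix(seq, model)
    Zh = np.zeros((n + 1, n + 1))
    for i in range(n + 1):
        Zh[i, i] = 1.0
    for length in range(1, n + 1):
        for i in range(0, n - length + 1):
            j = i + length
            total = Zh[i + 1, j]  # base i unpaired
            ms = np.arange(i + model.min_loop + 1, j)  # partners of base i
            if ms.size:
                total += float(np.sum(W[i, ms] * Zh[i + 1, ms] * Zh[ms + 1, j]))
            Zh[i, j] = total
    return Zh, W


def pair_probabilities(
    sequence: str, model: PairModel | None = None
) -> np.ndarray:
    """Symmetric matrix of equilibrium pair probabilities p(i, j).

    Sequences shorter than ``min_loop + 2`` cannot pair; an all-zero matrix
    is returned with a warning.
    """
    model = model or PairModel()
    seq = _encode(sequence)
    n = len(seq)
    P = np.zeros((n, n))
    if n < model.min_loop + 2:
        log.warning("sequence of length %d too short to pair; zero matrix", n)
        return P
    Zh, W = _inside(seq, model)
    Z = Zh[0, n]
    ml = model.min_loop

    # alpha_P[i, j]: inside weight of pair (i, j-1) enclosing [i+1, j-1)
    AP = np.zeros((n + 1, n + 1))
    for i in range(n):
        js = np.arange(i + ml + 2, n + 1)
        if js.size:
            AP[i, js] = W[i, js - 1] * Zh[i + 1, js - 1]

    bS = np.zeros((n + 1, n + 1))  # outside of S over [i, j)
    bP = np.zeros((n + 1, n + 1))  # outside of a pair spanning [i, j)
    for length in range(n, -1, -1):
        for i in range(0, n - length + 1):
            j = i + length
            v = 1.0 if (i == 0 and j == n) else 0.0
            if i >= 1:
                v += bS[i - 1, j]  # S(i-1, j) -> unpaired . S(i, j)
                # S(p, j) -> P(p, i) S(i, j)
                pmax = i - ml - 2
                if pmax >= 0:
                    v += float(bS[: pmax + 1, j] @ AP[: pmax + 1, i])
                # P(i-1, j+1) -> base . S(i, j) . base
                if j <= n - 1 and W[i - 1, j] > 0:
                    v += W[i - 1, j] * bP[i - 1, j + 1]
            bS[i, j] = v
            if length >= ml + 2 and W[i, j - 1] > 0:
                bP[i, j] = float(bS[i, j : n + 1] @ Zh[j, j : n + 1])

    for i in range(n):
        js = np.arange(i + ml + 2, n + 1)
        if js.size:
            P[i, js - 1] = AP[i, js] * bP[i, js] / Z
    P = P + P.T
    return P


def pairing_profile(p_matrix: np.ndarray) -> np.ndarray:
    """Per-base probability of being paired: the marginal sum over partners."""
    return p_matrix.sum(axis=1)


def _anchor_index(cds_start: int, cds_end: int, anchor: str) -> int:
    if anchor == "start":
        return cds_start
    if anchor == "stop":
        return cds_end - 3
    raise ValueError(f"anchor must be 'start' or 'stop', got {anchor!r}")


def offsets_to_indices(
    cds_start: int, cds_end: int, anchor: str, offsets: np.ndarray
) -> np.ndarray:
    """Map codon-anchored offsets (no 0; +1 = first anchor base) to indices."""
    base = _anchor_index(cds_start, cds_end, anchor)
    return base + np.where(offsets > 0, offsets - 1, offsets)


def window_offsets(lo: int, hi: int) -> np.ndarray:
    """All offsets from lo to hi inclusive, skipping the nonexistent 0."""
    offs = np.arange(lo, hi + 1)
    return offs[offs != 0]


def transcript_window_profile(
    annotation,
    anchor: str,
    offsets: np.ndarray,
    flank: int = 50,
    model: PairModel | None = None,
) -> np.ndarray | None:
    """Pairing probability at each window offset of one transcript.

    The transcript is folded over the window extended by ``flank`` bases on
    each side (clipped to the sequence); ``None`` when the window itself
    falls outside the sequence.
    """
    idx = offsets_to_indices(annotation.cds_start, annotation.cds_end, anchor, offsets)
    n = len(annotation.sequence)
    if idx.min() < 0 or idx.max() >= n:
        return None
    lo = max(0, int(idx.min()) - flank)
    hi = min(n, int(idx.max()) + 1 + flank)
    sub = annotation.sequence[lo:hi]
    p = pair_probabilities(sub, model)
    return pairing_profile(p)[idx - lo]


def positional_bpp_profile(
    annotations,
    groups: dict,
    anchor: str = "start",
    window: tuple[int, int] = (-20, 40),
    flank: int = 50,
    model: PairModel | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mean positional pairing-probability profile per group, with tests.

    ``groups`` maps exactly two group names to iterables of transcript ids.
    Transcripts whose window is not fully inside the sequence are excluded
    (logged).  Per position the two groups are compared by a two-sided
    Welch t-test; raw and Benjamini–Hochberg-adjusted p-values are
    reported, with ``significant`` flagging raw p < ``alpha``.
    """
    if len(groups) != 2:
        raise ValueError("positional_bpp_profile expects exactly two groups")
    offsets = window_offsets(*window)
    by_id = {ann.transcript_id: ann for ann in annotations}
    profiles: dict[str, np.ndarray] = {}
    for name, ids in groups.items():
        rows, skipped = [], 0
        for tid in ids:
            ann = by_id.get(tid)
            prof = (
                transcript_window_profile(ann, anchor, offsets, flank, model)
                if ann is not None
                else None
            )
            if prof is None:
                skipped += 1
                continue
            rows.append(prof)
        if skipped:
            log.info("group %s: excluded %d transcript(s) with insufficient window", name, skipped)
        profiles[name] = np.array(rows) if rows else np.empty((0, len(offsets)))

    (name_a, mat_a), (name_b, mat_b) = profiles.items()
    out = pd.DataFrame({"offset": offsets})
    out[f"mean_{name_a}"] = mat_a.mean(axis=0) if len(mat_a) else np.nan
    out[f"mean_{name_b}"] = mat_b.mean(axis=0) if len(mat_b) else np.nan
    out[f"n_{name_a}"] = len(mat_a)
    out[f"n_{name_b}"] = len(mat_b)
    if len(mat_a) >= 2 and len(mat_b) >= 2:
        p = stats.ttest_ind(mat_a, mat_b, axis=0, equal_var=False).pvalue
    else:
        p = np.full(len(offsets), np.nan)
    out["p_value"] = p
    finite = np.isfinite(p)
    adj = np.full(len(offsets), np.nan)
    if finite.any():
        adj[finite] = multipletests(p[finite], method="fdr_bh")[1]
    out["p_bh"] = adj
    out["significant"] = out["p_value"] < alpha
    return out


def read_bpp_matrix(source, n: int, sep: str = "\t") -> np.ndarray:
    """Load a sparse (i, j, p) table (1-based indices) as a dense matrix."""
    df = pd.read_csv(source, sep=sep, names=["i", "j", "p"], comment="#")
    P = np.zeros((n, n))
    ii = df["i"].to_numpy(int) - 1
    jj = df["j"].to_numpy(int) - 1
    P[ii, jj] = df["p"].to_numpy(float)
    P[jj, ii] = df["p"].to_numpy(float)
    return P


def write_bpp_matrix(p_matrix: np.ndarray, path, threshold: float = 1e-6) -> None:
    """Write pair probabilities above ``threshold`` as sparse (i, j, p), 1-based."""
    ii, jj = np.where(np.triu(p_matrix) > threshold)
    pd.DataFrame({"i": ii + 1, "j": jj + 1, "p": p_matrix[ii, jj]}).to_csv(
        path, sep="\t", index=False, header=False, float_format="%.8g"
    )
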