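"""Two-colour polysome-array ingestion and preprocessing.

A polysome-profiling array hybridises the polysome (P) RNA pool labelled in
the green channel (Cy3) against the free+monosome (FM) pool labelled in the
red channel (Cy5).  For every probe the scanner reports a foreground and a
local background intensity per channel.  This module turns such probe tables
into per-gene expression records:

* ``M`` — the translation efficiency, ``log2(green/red) = log2(P/FM)``.
  Positive M means the transcript is enriched on polysomes (translating).
* ``A`` — the abundance proxy, ``0.5 * log2(green * red)``, the mean of the
  log2 channel intensities.

Processing order follows standard two-colour practice: background-correct
each channel, compute per-probe M/A, average replicate probes of the same
gene on the M/A scale, then filter low-abundance genes by A.
"""

from __future__ import annotations

import io
import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import log_ndtr
from scipy.stats import norm

from .exceptions import ConfigurationError, ContractError, ParseError

log = logging.getLogger(__name__)

#: canonical probe-record fields, in column order
PROBE_FIELDS = ("probe_id", "gene_id", "green_fg", "green_bg", "red_fg", "red_bg")

#: recognised background-correction methods
BACKGROUND_METHODS = ("none", "half", "normexp")

_INTENSITY_FIELDS = ("green_fg", "green_bg", "red_fg", "red_bg")


def read_probe_table(
    source,
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a delimited probe table into the canonical probe layout.

    Parameters
    ----------
    source
        Path or text stream of a delimited file with a header row.
    column_map
        Maps each canonical field in :data:`PROBE_FIELDS` to the column name
        used in the file.  ``None`` means the file already uses canonical
        names.  An optional ``"condition"`` entry is carried through.
    sep
        Field delimiter (default tab).

    Returns
    -------
    pandas.DataFrame
        One row per probe with columns :data:`PROBE_FIELDS` (plus
        ``condition`` when mapped), input row order preserved.  Rows with any
        negative intensity are dropped with a logged count.

    Raises
    ------
    ConfigurationError
        If a required column is missing from the header.
    ParseError
        If an intensity field is not numeric; the message carries the
        1-based line number of the offending data row.
    """
    column_map = dict(column_map) if column_map else {f: f for f in PROBE_FIELDS}
    for field in PROBE_FIELDS:
        column_map.setdefault(field, field)

    raw = pd.read_csv(source, sep=sep, dtype=str, skipinitialspace=True)
    missing = [column_map[f] for f in PROBE_FIELDS if column_map[f] not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"probe table is missing required column(s): {', '.join(missing)}"
        )

    out = pd.DataFrame(
        {field: raw[column_map[field]] for field in PROBE_FIELDS},
        index=raw.index,
    )
    if "condition" in column_map and column_map["condition"] in raw.columns:
        out["condition"] = raw[column_map["condition"]]

    for field in _INTENSITY_FIELDS:
        values = pd.to_numeric(out[field], errors="coerce")
        bad = values.isna() & out[field].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"non-numeric value {out[field][row]!r} in column "
                f"{column_map[field]!r}",
                line=row + 2,  # header is line 1
            )
        out[field] = values.astype(float)

    negative = (out[list(_INTENSITY_FIELDS)] < 0).any(axis=1)
    if negative.any():
        log.warning("dropping %d probe row(s) with negative intensities", int(negative.sum()))
        out = out[~negative]
    if out["probe_id"].isna().any() or (out["probe_id"] == "").any():
        raise ParseError("empty probe_id encountered")
    return out.reset_index(drop=True)


def _normexp_fit(x: np.ndarray) -> tuple[float, float, float]:
    """Moment (skewness) estimators for the Normal+Exponential convolution.

    Observed ``X = B + S`` with background ``B ~ N(mu, sigma^2)`` and signal
    ``S ~ Exp(mean alpha)``.  Then ``E X = mu + alpha``,
    ``Var X = sigma^2 + alpha^2`` and the third central moment is
    ``2 alpha^3``, which identifies all three parameters.

    Raises ``ValueError`` when the sample skewness or implied variance is
    non-positive (degenerate fit).
    """
    m = float(np.mean(x))
    v = float(np.var(x, ddof=1))
    m3 = float(np.mean((x - m) ** 3))
    if m3 <= 0:
        raise ValueError("non-positive sample skewness")
    alpha = (m3 / 2.0) ** (1.0 / 3.0)
    sigma2 = v - alpha**2
    if sigma2 <= 0:
        raise ValueError("moment estimate of background variance <= 0")
    return m - alpha, float(np.sqrt(sigma2)), alpha


def _normexp_expected_signal(
    x: np.ndarray, mu: float, sigma: float, alpha: float
) -> np.ndarray:
    """Conditional mean ``E[S | X = x]`` under the Normal+Exponential model.

    Uses the closed normal cdf/pdf form; evaluated through ``log_ndtr`` so
    the Mills-ratio term stays finite far into the left tail.
    """
    mu_sx = x - mu - sigma**2 / alpha
    z = mu_sx / sigma
    mills = np.exp(norm.logpdf(z) - log_ndtr(z))
    signal = mu_sx + sigma * mills
    # mathematically positive; guard the extreme-tail cancellation only
    return np.maximum(signal, 1e-10)


def background_correct(
    probes: pd.DataFrame,
    method: str = "half",
    half_floor: float = 0.5,
) -> pd.DataFrame:
    """Background-correct both channels, adding ``green``/``red`` columns.

    Methods
    -------
    ``none``
        Foreground intensities passed through unchanged.
    ``half``
        ``max(fg - bg, half_floor)``; the conventional positive floor keeps
        downstream log-ratios finite.
    ``normexp``
        Conditional expected signal under the normal(background) +
        exponential(signal) convolution, parameters estimated per channel by
        moments on ``fg - bg``.  Falls back to ``half`` with a logged warning
        when the moment fit is degenerate.

    Raises
    ------
    ConfigurationError
        Unknown method, or fewer than 50 probes for ``normexp``.
    """
    if method not in BACKGROUND_METHODS:
        raise ConfigurationError(
            f"unknown background method {method!r}; expected one of {BACKGROUND_METHODS}"
        )
    out = probes.copy()
    if method == "none":
        out["green"] = out["green_fg"].to_numpy(float)
        out["red"] = out["red_fg"].to_numpy(float)
        return out
    if method == "normexp" and len(out) < 50:
        raise ConfigurationError(
            f"normexp needs at least 50 probes per channel, got {len(out)}"
        )
    for channel in ("green", "red"):
        fg = out[f"{channel}_fg"].to_numpy(float)
        bg = out[f"{channel}_bg"].to_numpy(float)
        if method == "half":
            out[channel] = np.maximum(fg - bg, half_floor)
        else:
            x = fg - bg
            try:
                mu, sigma, alpha = _normexp_fit(x)
                out[channel] = _normexp_expected_signal(x, mu, sigma, alpha)
            except ValueError as exc:
                log.warning(
                    "normexp moment fit degenerate for %s channel (%s); "
                    "falling back to half",
                    channel,
                    exc,
                )
                out[channel] = np.maximum(x, half_floor)
    return out


def summarize_expression(corrected: pd.DataFrame) -> pd.DataFrame:
    """Per-gene M/A values from background-corrected probes.

    Per probe, ``M = log2(green/red)`` and ``A = 0.5*log2(green*red)``;
    replicate probes of a gene are then averaged on the M/A scale and the
    probe count recorded.

    Raises
    ------
    ContractError
        If any corrected intensity is non-positive (background correction
        must run first).
    """
    for col in ("green", "red"):
        if col not in corrected.columns:
            raise ContractError("run background_correct before summarize_expression")
    green = corrected["green"].to_numpy(float)
    red = corrected["red"].to_numpy(float)
    if np.any(green <= 0) or np.any(red <= 0):
        raise ContractError(
            "non-positive corrected intensity; background correction must "
            "produce strictly positive values"
        )
    per_probe = pd.DataFrame(
        {
            "gene_id": corrected["gene_id"].to_numpy(),
            "M": np.log2(green / red),
            "A": 0.5 * np.log2(green * red),
        }
    )
    expr = (
        per_probe.groupby("gene_id", sort=True)
        .agg(M=("M", "mean"), A=("A", "mean"), n_probes=("M", "size"))
        .reset_index()
    )
    return expr


def filter_by_abundance(expression: pd.DataFrame, a_min: float) -> pd.DataFrame:
    """Keep genes with ``A`` strictly greater than ``a_min``.

    The strict inequality reads the "A values above x" convention literally;
    the number of discarded genes is logged.
    """
    if not np.isfinite(a_min) and not a_min == -np.inf:
        raise ConfigurationError(f"a_min must be finite or -inf, got {a_min!r}")
    keep = expression["A"] > a_min
    dropped = int((~keep).sum())
    if dropped:
        log.info("abundance filter (A > %g) discarded %d of %d genes", a_min, dropped, len(expression))
    return expression[keep].reset_index(drop=True)


def write_expression_table(expression: pd.DataFrame, path) -> None:
    """Write a per-condition expression table (TSV: gene_id, M, A, n_probes)."""
    expression.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_expression_table(path) -> pd.DataFrame:
    """Read a table written by :func:`write_expression_table`."""
    expr = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "M", "A"):
        if col not in expr.columns:
            raise ConfigurationError(f"expression table {path} lacks column {col!r}")
    return expr
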