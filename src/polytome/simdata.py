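"""Synthetic polysome-profiling datasets with known ground truth.

The generator inverts the analysis statistic: a transcript with translation
efficiency ``te`` (log2 P/FM) has polysome-engagement fraction
``phi = 2**te / (1 + 2**te)``, and its expected two-channel intensities are

    green (Cy3, polysome)       ~ gain_p  * abundance * phi
    red   (Cy5, free+monosome)  ~ gain_fm * abundance * (1 - phi)

so that, with equal gains and no noise, the analysis pipeline recovers the
true TE exactly.  Stress shifts each transcript's TE by a class-dependent
delta drawn so that the ground-truth class is consistent with the S/R/I
calling rules (including the I -> R -> S precedence).  Probe replicates get
multiplicative log-normal noise and additive normal background; an optional
global P:FM mass-ratio constraint rescales the polysome-channel gain the
way proportional labeling does.

Sequence features are coupled to the translation classes in the direction
seen on real arrays: inducible transcripts carry more upstream AUGs, longer
CDS and slightly lower G+C; highly translated transcripts are compact and
nearly uAUG-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .seqfeat import TranscriptAnnotation, count_uaug

log = logging.getLogger(__name__)

CLASSES = ("S", "R", "I", "U")
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement-noise settings for the simulated scanner."""

    intensity_sd: float = 0.25  # sigma of multiplicative log-normal noise
    background_mean: float = 40.0  # additive background, intensity units
    background_sd: float = 8.0

    def noiseless(self) -> "NoiseConfig":
        return NoiseConfig(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SequenceConfig:
    """Transcript-anatomy targets; lengths are log-normal medians (nt)."""

    utr5_len_median: float = 140.0
    utr5_len_sigma: float = 0.5
    cds_len_median: float = 1200.0
    cds_len_sigma: float = 0.45
    utr3_len_median: float = 700.0
    utr3_len_sigma: float = 0.6
    utr5_gc: float = 0.65
    cds_gc: float = 0.53
    utr3_gc: float = 0.43
    gc_sd: float = 0.05
    #: mean upstream-AUG count per class (Poisson); high-TE transcripts
    #: override to ``uaug_rate_high_te``
    uaug_rate: dict = field(
        default_factory=lambda: {"S": 0.9, "R": 0.7, "I": 1.6, "U": 0.8}
    )
    uaug_rate_high_te: float = 0.25
    high_te_cutoff: float = 2.0
    start_purine_freq: float = 0.86


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``class_proportions`` gives the S/R/I mixture (remainder U);
    ``mass_ratio_control``/``_stress`` optionally constrain the global
    P:FM RNA mass ratio, reproducing the labeling-protocol confounding of
    channel gains.  ``seed`` is mandatory: every draw derives from it.
    """

    seed: int
    n_genes: int = 2000
    class_proportions: dict = field(
        default_factory=lambda: {"S": 0.45, "R": 0.04, "I": 0.08}
    )
    probes_per_gene: int = 3
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seq: SequenceConfig = field(default_factory=SequenceConfig)
    gain_p: float = 1.0
    gain_fm: float = 1.0
    mass_ratio_control: float | None = None
    mass_ratio_stress: float | None = None
    log2_abundance_mean: float = 9.0
    log2_abundance_sd: float = 1.5

    def __post_init__(self):
        total = sum(self.class_proportions.values())
        if total > 1 + 1e-12 or any(v < 0 for v in self.class_proportions.values()):
            raise ConfigurationError("class proportions must be >= 0 and sum to <= 1")
        if self.n_genes < 1 or self.probes_per_gene < 1:
            raise ConfigurationError("n_genes and probes_per_gene must be positive")


def jurkat_like(seed: int, **overrides) -> SimConfig:
    """Human-leukemia-like preset: large R class, P:FM 2:1 control, 1:3 stress."""
    base = dict(
        seed=seed,
        class_proportions={"S": 0.50, "R": 0.13, "I": 0.015},
        mass_ratio_control=2.0,
        mass_ratio_stress=1.0 / 3.0,
    )
    base.update(overrides)
    return SimConfig(**base)


def nih3t3_like(seed: int, **overrides) -> SimConfig:
    """Fibroblast-like preset: large I class, P:FM 1.5:1 control, 1:3 stress."""
    base = dict(
        seed=seed,
        class_proportions={"S": 0.45, "R": 0.035, "I": 0.08},
        mass_ratio_control=1.5,
        mass_ratio_stress=1.0 / 3.0,
    )
    base.update(overrides)
    return SimConfig(**base)


def _rng(config: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), tag])


def _draw_classes(rng, config: SimConfig) -> np.ndarray:
    props = config.class_proportions
    p = [props.get("S", 0.0), props.get("R", 0.0), props.get("I", 0.0)]
    p.append(max(0.0, 1.0 - sum(p)))
    return rng.choice(np.array(CLASSES), size=config.n_genes, p=np.array(p) / sum(p))


def _draw_te(rng, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class-consistent control TE and stress shift.

    Construction guarantees the truth satisfies the calling rules under the
    I -> R -> S precedence: sensitive transcripts always end below the
    resistant level after stress, inducible ones start at or below 0.
    """
    n = len(labels)
    tc = np.empty(n)
    delta = np.empty(n)

    # S: well-translated in control (population median ~1), strongly
    # repressed by the initiation blockade (mean drop ~2 log2)
    m = labels == "S"
    k = int(m.sum())
    tc[m] = rng.normal(1.2, 0.7, k)
    ts = np.minimum(tc[m], 1.6) - 1.2 - rng.exponential(1.2, k)
    delta[m] = ts - tc[m]

    # R: BiP-like, high engagement in both conditions with clear margin
    # above the resistant level
    m = labels == "R"
    k = int(m.sum())
    tc[m] = 1.2 + rng.exponential(0.8, k)
    delta[m] = (1.2 + rng.exponential(0.8, k)) - tc[m]

    # I: ATF4-like, repressed in control (mean -1.5) and strongly relieved
    # under stress (mean gain ~2.2 log2)
    m = labels == "I"
    k = int(m.sum())
    tc[m] = -0.5 - rng.exponential(1.0, k)
    delta[m] = 1.5 + rng.exponential(0.7, k)

    # U: moderate engagement, sub-threshold drift in either direction;
    # stress TE capped below the resistant level
    m = labels == "U"
    k = int(m.sum())
    tc[m] = rng.uniform(0.1, 0.7, k)
    ts = rng.uniform(tc[m] - 0.55, np.minimum(tc[m] + 0.85, 0.7))
    delta[m] = ts - tc[m]
    return tc, delta


def _random_region(rng, length: int, gc: float) -> np.ndarray:
    gc = min(max(gc, 0.05), 0.95)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _strip_atg(region: np.ndarray) -> None:
    """Destroy every ATG in place (G -> C; cannot create a new ATG)."""
    s = "".join(region)
    pos = s.find("ATG")
    while pos != -1:
        region[pos + 2] = "C"
        s = s[: pos + 2] + "C" + s[pos + 3 :]
        pos = s.find("ATG", pos)


def _build_utr5(rng, length: int, gc: float, n_uaug: int, purine_context: bool) -> np.ndarray:
    region = _random_region(rng, length, gc)
    _strip_atg(region)
    if length >= 3:
        region[length - 3] = (
            rng.choice(np.array(list("AG"))) if purine_context else rng.choice(np.array(list("CT")))
        )
        _strip_atg(region)  # the context base may have completed an ATG
    # plant the requested upstream AUGs at non-overlapping positions
    if n_uaug > 0 and length >= 3:
        placed: list[int] = []
        for pos in rng.permutation(length - 2):
            if len(placed) == n_uaug:
                break
            if all(abs(pos - q) >= 3 for q in placed):
                placed.append(int(pos))
        for pos in placed:
            region[pos : pos + 3] = list("ATG")
    return region


_STOPS = ("TAA", "TAG", "TGA")


def _build_cds(rng, length: int, gc: float) -> np.ndarray:
    n_codons = length // 3
    body = _random_region(rng, 3 * (n_codons - 2), gc)
    # avoid premature stops so the CDS reads as a plausible ORF
    for i in range(0, len(body) - 2, 3):
        while body[i] == "T" and "".join(body[i : i + 3]) in _STOPS:
            body[i + 1] = _BASES[rng.integers(0, 4)]
    stop = np.array(list(_STOPS[rng.integers(0, 3)]))
    return np.concatenate([np.array(list("ATG")), body, stop])


def simulate_transcriptome(
    config: SimConfig, sequences: bool = True
) -> tuple[list[TranscriptAnnotation], pd.DataFrame]:
    """Draw ground-truth translation states and (optionally) sequences.

    Returns ``(annotations, truth)``.  The truth table stores *realized*
    feature values (re-measured from the generated sequences), so recovery
    tests compare against exactly what is in the FASTA.  With
    ``sequences=False`` the annotation list is empty and feature columns
    hold the drawn targets; array simulation only needs the truth.
    """
    rng = _rng(config, 0)
    sq = config.seq
    n = config.n_genes
    labels = _draw_classes(rng, config)
    tc, delta = _draw_te(rng, labels)
    log2_ab = np.clip(
        rng.normal(config.log2_abundance_mean, config.log2_abundance_sd, n), 6.0, 14.0
    )

    scale_cls = {"S": 1.0, "R": 1.2, "I": 1.8, "U": 1.0}
    cds_scale = np.array([scale_cls[c] for c in labels]) * np.where(tc >= sq.high_te_cutoff, 0.7, 1.0)
    cds_len = np.maximum(
        30, (sq.cds_len_median * cds_scale * np.exp(rng.normal(0, sq.cds_len_sigma, n))).astype(int)
    )
    cds_len = (cds_len // 3) * 3

    utr_scale = np.where(np.isin(labels, ["R", "I"]), 1.4, 1.0) * np.where(
        tc >= sq.high_te_cutoff, 0.75, 1.0
    )
    utr5_len = np.maximum(
        6, (sq.utr5_len_median * utr_scale * np.exp(rng.normal(0, sq.utr5_len_sigma, n))).astype(int)
    )
    utr3_scale = np.where(labels == "I", 1.7, 1.0) * np.where(tc >= sq.high_te_cutoff, 0.6, 1.0)
    utr3_len = np.maximum(
        20, (sq.utr3_len_median * utr3_scale * np.exp(rng.normal(0, sq.utr3_len_sigma, n))).astype(int)
    )

    lam = np.array([sq.uaug_rate[c] for c in labels])
    lam = np.where(tc >= sq.high_te_cutoff, sq.uaug_rate_high_te, lam)
    n_uaug = np.minimum(rng.poisson(lam), utr5_len // 3)

    gc_shift = np.where(labels == "I", -0.04, 0.0)
    utr5_gc = np.clip(rng.normal(sq.utr5_gc + gc_shift, sq.gc_sd), 0.2, 0.9)
    cds_gc = np.clip(rng.normal(sq.cds_gc + gc_shift, sq.gc_sd * 0.8), 0.2, 0.9)
    utr3_gc = np.clip(rng.normal(sq.utr3_gc + gc_shift, sq.gc_sd), 0.2, 0.9)
    purine = rng.random(n) < sq.start_purine_freq

    ids = np.array([f"TX{i:05d}" for i in range(n)])
    annotations: list[TranscriptAnnotation] = []
    if sequences:
        real_uaug = np.empty(n, dtype=int)
        for i in range(n):
            utr5 = _build_utr5(rng, int(utr5_len[i]), utr5_gc[i], int(n_uaug[i]), bool(purine[i]))
            cds = _build_cds(rng, int(cds_len[i]), cds_gc[i])
            utr3 = _random_region(rng, int(utr3_len[i]), utr3_gc[i])
            seq = "".join(np.concatenate([utr5, cds, utr3]))
            ann = TranscriptAnnotation(
                ids[i], seq, int(utr5_len[i]), int(utr5_len[i] + len(cds))
            )
            annotations.append(ann)
            real_uaug[i] = count_uaug(ann.utr5)
        n_uaug = real_uaug

    truth = pd.DataFrame(
        {
            "transcript_id": ids,
            "true_class": labels,
            "log2_abundance": log2_ab,
            "abundance": 2.0**log2_ab,
            "te_control": tc,
            "delta_te": delta,
            "te_stress": tc + delta,
            "utr5_len": utr5_len,
            "cds_len": cds_len,
            "utr3_len": utr3_len,
            "n_uaug": n_uaug,
            "utr5_gc": 100.0 * utr5_gc,
            "cds_gc": 100.0 * cds_gc,
            "utr3_gc": 100.0 * utr3_gc,
            "start_context_purine": purine,
        }
    )
    return annotations, truth


def _phi(te: np.ndarray) -> np.ndarray:
    return 2.0**te / (1.0 + 2.0**te)


def simulate_arrays(
    truth: pd.DataFrame,
    config: SimConfig,
    condition: str = "control",
    seed: int | None = None,
) -> pd.DataFrame:
    """Two-channel probe intensities for one hybridisation.

    ``condition`` is ``"control"`` or any stress label (e.g. ``"stress_3h"``);
    stress conditions use ``te_control + delta_te``.  Replicate probes share
    the gene's expectation and differ by the noise draws.
    """
    is_stress = condition != "control"
    te = truth["te_control"].to_numpy(float)
    if is_stress:
        te = te + truth["delta_te"].to_numpy(float)
    ab = truth["abundance"].to_numpy(float)
    phi = _phi(te)

    gain_p, gain_fm = config.gain_p, config.gain_fm
    target = config.mass_ratio_stress if is_stress else config.mass_ratio_control
    if target is not None:
        realized = float(np.sum(ab * phi) / np.sum(ab * (1 - phi)))
        gain_p = gain_p * target / realized

    expected_g = gain_p * ab * phi
    expected_r = gain_fm * ab * (1 - phi)

    reps = config.probes_per_gene
    rng = np.random.default_rng(
        [int(seed)] if seed is not None else [int(config.seed), 1 + int(is_stress)]
    )
    noise = config.noise
    n = len(truth)

    def channel(expected: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        e = np.repeat(expected, reps)
        if noise.intensity_sd > 0:
            e = e * np.exp(rng.normal(0.0, noise.intensity_sd, n * reps))
        if noise.background_mean > 0 or noise.background_sd > 0:
            bg = np.clip(rng.normal(noise.background_mean, noise.background_sd, n * reps), 0.0, None)
        else:
            bg = np.zeros(n * reps)
        return e + bg, bg

    g_fg, g_bg = channel(expected_g)
    r_fg, r_bg = channel(expected_r)
    gene_ids = np.repeat(truth["transcript_id"].to_numpy(), reps)
    probe_ids = np.array([f"{g}_p{k}" for g in truth["transcript_id"] for k in range(1, reps + 1)])
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_id": gene_ids,
            "green_fg": g_fg,
            "green_bg": g_bg,
            "red_fg": r_fg,
            "red_bg": r_bg,
            "condition": condition,
        }
    )


def class_gene_sets(
    truth: pd.DataFrame,
    rng: np.random.Generator,
    n_random_sets: int = 8,
    random_set_size: int = 50,
):
    """A synthetic GMT-style collection coupled to the ground-truth classes.

    One set per class holds a 60% sample of that class plus a sprinkling of
    other genes; the random sets are uniform draws, serving as nulls.
    """
    from .enrichment import GeneSetCollection

    ids = truth["transcript_id"].to_numpy()
    labels = truth["true_class"].to_numpy()
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    for cls in ("S", "R", "I"):
        members = ids[labels == cls]
        if len(members) < 5:
            continue
        core = rng.choice(members, size=max(3, int(0.6 * len(members))), replace=False)
        extra = rng.choice(ids, size=max(1, len(core) // 20), replace=False)
        sets[f"TRUTH_{cls}_PROGRAM"] = frozenset(core) | frozenset(extra)
        descriptions[f"TRUTH_{cls}_PROGRAM"] = f"synthetic program enriched in class {cls}"
    for k in range(n_random_sets):
        sets[f"RANDOM_{k:02d}"] = frozenset(
            rng.choice(ids, size=min(random_set_size, len(ids)), replace=False)
        )
        descriptions[f"RANDOM_{k:02d}"] = "uniformly drawn null set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_dataset(outdir, config: SimConfig, stress_label: str = "stress_3h") -> dict:
    """Generate and write a complete synthetic dataset.

    Produces probe TSVs for control and stress, the truth table, the
    transcript FASTA + CDS table, and a class-coupled GMT — all consumable
    by the analysis modules unchanged.  Returns the path map.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    annotations, truth = simulate_transcriptome(config)
    paths = {
        "control_probes": os.path.join(outdir, "probes_control.tsv"),
        "stress_probes": os.path.join(outdir, f"probes_{stress_label}.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "fasta": os.path.join(outdir, "transcripts.fasta"),
        "cds": os.path.join(outdir, "cds.tsv"),
        "gmt": os.path.join(outdir, "sets.gmt"),
    }
    simulate_arrays(truth, config, "control").to_csv(
        paths["control_probes"], sep="\t", index=False, float_format="%.10g"
    )
    simulate_arrays(truth, config, stress_label).to_csv(
        paths["stress_probes"], sep="\t", index=False, float_format="%.10g"
    )
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    with open(paths["fasta"], "w") as fa:
        for ann in annotations:
            fa.write(f">{ann.transcript_id}\n")
            for i in range(0, len(ann.sequence), 70):
                fa.write(ann.sequence[i : i + 70] + "\n")
    pd.DataFrame(
        {
            "transcript_id": [a.transcript_id for a in annotations],
            "cds_start": [a.cds_start for a in annotations],
            "cds_end": [a.cds_end for a in annotations],
        }
    ).to_csv(paths["cds"], sep="\t", index=False)
    class_gene_sets(truth, _rng(config, 3)).to_gmt(paths["gmt"])
    return paths
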