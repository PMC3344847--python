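"""End-to-end orchestration: config file -> report bundle.

``run_full_pipeline`` executes, as enabled, preprocess (per condition) ->
classify/coordination -> orthologs / features / base-pair-probability
profiles / enrichment, writes every module's table under the output
directory, and finishes with a JSON run summary carrying versions, seed,
thresholds and the gene counts at each filter boundary.  Identical config
and inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import __version__, arrayio, enrichment, orthologs, rnastruct, seqfeat, translatome
from .exceptions import ConfigurationError, PipelineError

log = logging.getLogger(__name__)

ALL_STAGES = (
    "preprocess", "classify", "coordination", "orthologs",
    "features", "bpp", "enrichment",
)


@dataclass
class RunConfig:
    """Validated run configuration (typically loaded from YAML)."""

    control_probes: str
    stress_probes: str
    output_dir: str
    seed: int = 0
    background_method: str = "normexp"
    a_min: float = 4.0
    half_floor: float = 0.5
    column_map: dict | None = None
    thresholds: translatome.ClassThresholds = field(default_factory=translatome.ClassThresholds)
    stages: tuple = ALL_STAGES
    stress_label: str = "stress"
    # optional stage inputs
    fasta: str | None = None
    cds_table: str | None = None
    ortholog_pairs: str | None = None
    partner_expression: str | None = None
    gmt: str | None = None
    # stage parameters
    feature_a_min: float = 5.5
    bpp_anchor: str = "start"
    bpp_window: tuple = (-20, 40)
    bpp_flank: int = 50
    high_cutoff: float = 2.0
    low_cutoff: float = -1.5
    n_partitions: int = 30
    ortholog_a_cutoffs: tuple = (4.0, 6.0, 8.0, 10.0)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = translatome.ClassThresholds(**raw["thresholds"])
        for key in ("stages", "bpp_window", "ortholog_a_cutoffs"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        known = {f for f in cls.__dataclass_fields__}
        stray = set(raw) - known
        if stray:
            raise ConfigurationError(f"unknown config field(s): {sorted(stray)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc

    def validate(self) -> None:
        """Check stage/input consistency and path resolvability up front."""
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
        required = {"control_probes": self.control_probes, "stress_probes": self.stress_probes}
        if "features" in self.stages or "bpp" in self.stages:
            for fld in ("fasta", "cds_table"):
                if getattr(self, fld) is None:
                    raise ConfigurationError(
                        f"config field '{fld}' is required when features/bpp stages are enabled"
                    )
                required[fld] = getattr(self, fld)
        if "enrichment" in self.stages:
            if self.gmt is None:
                raise ConfigurationError(
                    "config field 'gmt' is required when the enrichment stage is enabled"
                )
            required["gmt"] = self.gmt
        if "orthologs" in self.stages and self.ortholog_pairs is not None:
            required["ortholog_pairs"] = self.ortholog_pairs
            if self.partner_expression is None:
                raise ConfigurationError(
                    "config field 'partner_expression' is required with ortholog_pairs"
                )
            required["partner_expression"] = self.partner_expression
        for name, path in required.items():
            if not os.path.exists(path):
                raise ConfigurationError(f"config field '{name}': path not found: {path}")


def _preprocess(config: RunConfig, probe_path: str, counts: dict, label: str) -> pd.DataFrame:
    probes = arrayio.read_probe_table(probe_path, column_map=config.column_map)
    counts[f"{label}_probes"] = int(len(probes))
    corrected = arrayio.background_correct(
        probes, method=config.background_method, half_floor=config.half_floor
    )
    expr = arrayio.summarize_expression(corrected)
    counts[f"{label}_genes"] = int(len(expr))
    expr = arrayio.filter_by_abundance(expr, config.a_min)
    counts[f"{label}_genes_after_a_filter"] = int(len(expr))
    counts[f"{label}_genes_dropped_by_a_filter"] = (
        counts[f"{label}_genes"] - counts[f"{label}_genes_after_a_filter"]
    )
    return expr


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the run summary dict.

    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs of previously completed stages persist on disk.
    """
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    out = lambda name: os.path.join(config.output_dir, name)  # noqa: E731
    counts: dict = {}
    summary: dict = {
        "versions": {
            "polytome": __version__,
            "numpy": __import__("numpy").__version__,
            "scipy": __import__("scipy").__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "thresholds": asdict(config.thresholds),
        "stages": list(config.stages),
        "counts": counts,
    }

    stage = "preprocess"
    try:
        control = _preprocess(config, config.control_probes, counts, "control")
        stress = _preprocess(config, config.stress_probes, counts, "stress")
        arrayio.write_expression_table(control, out("expression_control.tsv"))
        arrayio.write_expression_table(stress, out(f"expression_{config.stress_label}.tsv"))

        stage = "classify"
        entries = translatome.compute_translation_change(control, stress)
        counts["genes_in_both_conditions"] = int(len(entries))
        entries = translatome.assign_classes(entries, config.thresholds)
        translatome.write_translatome_table(entries, out("translatome.tsv"))
        class_counts = entries["class_label"].value_counts().to_dict()
        counts["classes"] = {c: int(class_counts.get(c, 0)) for c in translatome.CLASS_LABELS}

        if "coordination" in config.stages:
            stage = "coordination"
            report = translatome.coordination_analysis(entries, config.thresholds)
            with open(out("coordination.json"), "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)

        if "orthologs" in config.stages and config.ortholog_pairs is not None:
            stage = "orthologs"
            pairs = orthologs.read_ortholog_pairs(config.ortholog_pairs)
            partner = arrayio.read_expression_table(config.partner_expression)
            paired = orthologs.pair_translatomes(pairs, control, partner)
            counts["ortholog_pairs_resolved"] = int(len(paired))
            paired.to_csv(out("ortholog_pairs.tsv"), sep="\t", index=False, float_format="%.10g")
            strata = orthologs.stratified_correlation(paired, config.ortholog_a_cutoffs)
            strata.to_csv(out("ortholog_strata.tsv"), sep="\t", index=False, float_format="%.10g")

        annotations = None
        if "features" in config.stages or "bpp" in config.stages:
            stage = "annotations"
            annotations = seqfeat.parse_annotation(config.fasta, config.cds_table)
            counts["annotations"] = int(len(annotations))

        if "features" in config.stages:
            stage = "features"
            feats = seqfeat.features_table(annotations)
            merged = feats.merge(
                control.rename(columns={"gene_id": "transcript_id", "M": "m"}),
                on="transcript_id", how="inner",
            ).merge(
                entries[["gene_id", "class_label"]].rename(columns={"gene_id": "transcript_id"}),
                on="transcript_id", how="left",
            )
            merged["class_label"] = merged["class_label"].fillna("U")
            counts["features_with_expression"] = int(len(merged))
            report = seqfeat.class_feature_report(
                merged, a_min=config.feature_a_min,
                high_cutoff=config.high_cutoff, low_cutoff=config.low_cutoff,
            )
            seqfeat.write_feature_report(report, out("feature_report.tsv"))

        if "bpp" in config.stages:
            stage = "bpp"
            m_by_id = control.set_index("gene_id")["M"]
            present = [a.transcript_id for a in annotations if a.transcript_id in m_by_id.index]
            groups = {
                "high": [t for t in present if m_by_id[t] >= config.high_cutoff],
                "low": [t for t in present if m_by_id[t] <= config.low_cutoff],
            }
            counts["bpp_groups"] = {k: len(v) for k, v in groups.items()}
            profile = rnastruct.positional_bpp_profile(
                annotations, groups, anchor=config.bpp_anchor,
                window=tuple(config.bpp_window), flank=config.bpp_flank,
            )
            profile.to_csv(
                out(f"bpp_profile_{config.bpp_anchor}.tsv"),
                sep="\t", index=False, float_format="%.8g",
            )

        if "enrichment" in config.stages:
            stage = "enrichment"
            collection = enrichment.GeneSetCollection.from_gmt(config.gmt)
            background = entries["gene_id"].tolist()
            frames = []
            for cls in ("S", "R", "I"):
                sel = entries.loc[entries["class_label"] == cls, "gene_id"].tolist()
                if not sel:
                    continue
                res = enrichment.fisher_term_enrichment(sel, background, collection)
                res.insert(0, "class", cls)
                frames.append(res)
            if frames:
                pd.concat(frames, ignore_index=True).to_csv(
                    out("enrichment_classes.tsv"), sep="\t", index=False, float_format="%.8g"
                )
            ranking = entries.sort_values(
                "te_control", ascending=False, kind="mergesort"
            )["gene_id"].tolist()
            _, best = enrichment.ranked_partition_scan(
                ranking, collection, n_partitions=min(config.n_partitions, len(ranking) - 1)
            )
            best.to_csv(out("enrichment_scan.tsv"), sep="\t", index=False, float_format="%.8g")
    except (ConfigurationError, PipelineError):
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise PipelineError(stage, str(exc)) from exc

    with open(out("run_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
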