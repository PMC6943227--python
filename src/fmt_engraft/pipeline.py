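"""Pipeline orchestration: one config in, one consolidated report out.

Stages run in dependency order: load-or-simulate inputs, diversity and
community comparison, species-source partitioning, strain tracking,
per-taxon prediction, delta correlation.  A stage whose inputs are absent
(e.g. no SNV table) is skipped with a logged reason and its report section
marked absent; only hard errors abort the run.  Given a fixed seed the
whole report is byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .clinical_correlation import correlate_cohort
from .community_metrics import (
    TransformSpec,
    bray_curtis,
    cosine_similarity,
    euclidean_shift,
    kruskal_wallis,
    shannon_index,
)
from .engraftment_prediction import predict_cohort
from .errors import ConfigError
from .io_formats import (
    export_network,
    read_abundance_table,
    read_clinical,
    read_manifest,
    read_snv_table,
    write_edges_tsv,
    write_report,
)
from .species_engraftment import donor_gain_summary, partition_cohort, partitions_long_table
from .strain_tracking import (
    PresenceThresholds,
    classification_summary,
    cohort_retention_summary,
    new_snv_rate,
    track_cohort,
)
from .synthetic_data import (
    DEFAULT_CLINICAL_INDEXES,
    CohortSimSpec,
    StrainSimSpec,
    simulate_clinical,
    simulate_snv_cohort,
    simulate_species_cohort,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration; exactly one of inputs/simulate is set."""

    seed: int = 0
    out_dir: str | None = None
    inputs: dict = field(default_factory=dict)  # abundance/manifest/snv/clinical paths
    simulate: dict | None = None  # species/snv/clinical sub-specs
    detection_threshold: float = 0.001
    transform: dict = field(default_factory=dict)
    strain: dict = field(default_factory=dict)
    prediction: dict = field(default_factory=dict)
    correlation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if bool(self.inputs) == bool(self.simulate):
            raise ConfigError("provide exactly one of 'inputs' and 'simulate'")
        if self.inputs and not {"abundance", "manifest"} <= set(self.inputs):
            raise ConfigError("'inputs' needs at least 'abundance' and 'manifest' paths")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def canonical(self) -> str:
        payload = {
            k: getattr(self, k)
            for k in sorted(self.__dataclass_fields__)
            if k != "out_dir"
        }
        return json.dumps(payload, sort_keys=True, default=str)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _round_trip(obj):
    """Make a report fragment plain-JSON (floats, ints, str keys)."""
    return json.loads(json.dumps(obj, sort_keys=True, default=_default))


def _default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim = config.simulate
        sp = dict(sim.get("species", {}))
        sp.setdefault("seed", config.seed % 2**31)
        species_spec = CohortSimSpec(**sp)
        abundance, manifest, truth = simulate_species_cohort(species_spec)
        snv = None
        if sim.get("snv") is not None:
            sv = dict(sim["snv"])
            sv.setdefault("seed", (config.seed + 1) % 2**31)
            snv, _ = simulate_snv_cohort(StrainSimSpec(**sv), manifest)
        clinical = None
        if sim.get("clinical") is not None:
            cl = dict(sim["clinical"])
            effects = {
                tuple(k.split("~", 1)) if isinstance(k, str) else tuple(k): v
                for k, v in (cl.get("effects") or {}).items()
            }
            clinical = simulate_clinical(
                manifest,
                effects,
                abundance,
                index_names=tuple(cl.get("index_names", ())) or DEFAULT_CLINICAL_INDEXES,
                seed=(config.seed + 2) % 2**31,
            )
        return abundance, manifest, snv, clinical
    paths = config.inputs
    abundance = read_abundance_table(paths["abundance"])
    manifest = read_manifest(paths["manifest"])
    snv = read_snv_table(paths["snv"]) if paths.get("snv") else None
    clinical = read_clinical(paths["clinical"]) if paths.get("clinical") else None
    return abundance, manifest, snv, clinical


def _community_section(abundance, manifest, transform: TransformSpec) -> dict:
    shannon = {s: shannon_index(abundance.data[s]) for s in abundance.sample_ids}
    groups: dict[str, list[float]] = {}
    for _, row in manifest.records.iterrows():
        if row["sample_id"] not in shannon:
            continue
        if row["role"] == "donor":
            key = "donor"
        else:
            key = f"{row['subtype']}_day{int(row['day'])}"
        groups.setdefault(key, []).append(shannon[row["sample_id"]])
    kw = None
    multi = [v for v in groups.values() if v]
    if len(multi) >= 2:
        h, p = kruskal_wallis(multi)
        kw = {"H": h, "p": p, "groups": sorted(groups)}

    per_pair = []
    for pair in manifest.pairs():
        if pair.donor_sample is None or pair.baseline_sample is None:
            continue
        donor = abundance.data[pair.donor_sample].to_numpy()
        pre = abundance.data[pair.baseline_sample].to_numpy()
        for day, sample_id in pair.post_samples.items():
            post = abundance.data[sample_id].to_numpy()
            shift = euclidean_shift(pre, post, donor, transform)
            per_pair.append(
                {
                    "recipient": pair.recipient,
                    "subtype": pair.subtype,
                    "day": day,
                    "bray_curtis_pre_post": bray_curtis(pre, post, transform),
                    "cosine_post_pre": cosine_similarity(post, pre),
                    "cosine_post_donor": cosine_similarity(post, donor),
                    "d_pre_post": shift.d_pre_post,
                    "d_post_donor": shift.d_post_donor,
                    "d_pre_donor": shift.d_pre_donor,
                }
            )
    return {"shannon": shannon, "kruskal_wallis": kw, "pairwise": per_pair}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every runnable stage and return the consolidated report."""
    abundance, manifest, snv, clinical = _load_inputs(config)
    transform = TransformSpec(**config.transform) if config.transform else TransformSpec()
    threshold = config.detection_threshold

    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_sha256": config.digest(),
        }
    }

    report["community"] = _community_section(abundance, manifest, transform)

    parts = partition_cohort(abundance, manifest, threshold)
    summary = donor_gain_summary(((st, p) for st, _, p in parts), kind="abundance")
    summary_count = donor_gain_summary(((st, p) for st, _, p in parts), kind="count")
    report["species"] = {
        "per_sample": [
            {
                "sample_id": p.sample_id,
                "subtype": st,
                "day": day,
                "n_detected": p.n_detected,
                "count_fractions": dict(p.count_fractions),
                "abundance_fractions": dict(p.abundance_fractions),
            }
            for st, day, p in parts
        ],
        "donor_gain_abundance": summary.to_dict(orient="records"),
        "donor_gain_count": summary_count.to_dict(orient="records"),
    }

    if snv is not None:
        thr_cfg = dict(config.strain)
        min_positions = int(thr_cfg.pop("min_positions", 20))
        hi = float(thr_cfg.pop("hi", 0.8))
        lo = float(thr_cfg.pop("lo", 0.2))
        thresholds = PresenceThresholds(**thr_cfg) if thr_cfg else PresenceThresholds()
        series = track_cohort(snv, manifest, thresholds, min_positions, hi, lo)
        new_rates = []
        for pair in manifest.pairs():
            if pair.baseline_sample not in (snv.sample_ids or []):
                continue
            for day, sample_id in pair.post_samples.items():
                if sample_id not in snv.sample_ids:
                    continue
                pooled, _ = new_snv_rate(snv, pair.baseline_sample, sample_id, thresholds)
                new_rates.append(
                    {
                        "recipient": pair.recipient,
                        "subtype": pair.subtype,
                        "day": day,
                        "new_snv_rate": pooled,
                    }
                )
        report["strain"] = {
            "series": series.to_dict(orient="records"),
            "retention_summary": cohort_retention_summary(series).to_dict(orient="records"),
            "classification_summary": classification_summary(series).to_dict(orient="records"),
            "new_snv_rates": new_rates,
        }
    else:
        logger.info("no SNV table; strain stage skipped")
        report["strain"] = None

    pred_cfg = dict(config.prediction)
    if pred_cfg.pop("enabled", True):
        pred = predict_cohort(
            abundance,
            manifest,
            clinical,
            threshold=threshold,
            seed=(config.seed + 3) % 2**31,
            **pred_cfg,
        )
        report["prediction"] = {
            "n_recipients": pred["n_recipients"],
            "small_sample": pred["small_sample"],
            "n_presence_models": pred["n_presence_models"],
            "mean_auc": pred["mean_auc"],
            "pooled_rho": pred["pooled_rho"],
            "pooled_p": pred["pooled_p"],
            "per_taxon": [
                {
                    "taxon_id": r.taxon_id,
                    "task": r.task,
                    "auc": r.auc,
                    "oob_error": r.oob_error,
                    "mtry": r.chosen_mtry,
                    "n_positive": r.n_positive,
                }
                for r in pred["results"]
            ],
            "skipped": [list(s) for s in pred["skipped"]],
            "importance": pred["importance"].to_dict(orient="records"),
        }
    else:
        report["prediction"] = None

    if clinical is not None:
        corr_cfg = dict(config.correlation)
        corr = correlate_cohort(abundance, clinical, manifest, **corr_cfg)
        report["correlation"] = {
            "n_tested": corr["n_tested"],
            "n_significant": corr["n_significant"],
            "edges": corr["edges"].drop(columns=["skip_reason"]).to_dict(orient="records"),
        }
        if config.out_dir:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            export_network(corr["graph"], out / "correlation_network.graphml", "graphml")
            write_edges_tsv(corr["edges"], out / "correlation_edges.tsv")
    else:
        logger.info("no clinical table; correlation stage skipped")
        report["correlation"] = None

    report = _round_trip(report)
    if config.out_dir:
        out = Path(config.out_dir)
        write_report(report, out)
        parts_table = partitions_long_table(parts)
        parts_table.to_csv(out / "species_partitions.tsv", sep="\t", index=False)
    return report
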