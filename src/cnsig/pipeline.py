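"""End-to-end orchestration: filters -> CN features -> categories -> matrices
-> SV annotation -> complex-event classification -> signature extraction ->
chromothripsis prediction, with reproducibility metadata.

Every stage's outputs are written under the run directory; matrices carry
the configuration hash as a comment line, and run_metadata.json records the
seed, stage parameters and diagnostics.  Re-running the same configuration
reproduces the matrices byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .categories import CategoryScheme, build_cn_matrix, fit_category_scheme
from .events import EventConfig, calls_to_frame, classify_components, sample_has_chromothripsis
from .features import extract_features
from .io import GenomeAssets, apply_filters, read_segments, read_sv_bedpe, write_matrix
from .predict import call_cn_pred, crossval_predict
from .signatures import HdpConfig, extract_hdp, extract_nmf
from .simulate import SimulationConfig, simulate_cohort
from .svfeatures import annotate_pairs, build_sv_matrix

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_end_to_end"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``simulate`` (a SimulationConfig) or ``segments_path`` (+
    optional ``bedpe_paths`` and ``labels_path``) provides the inputs.
    """

    output_dir: str | Path = "cnsig_run"
    seed: int = 0
    simulate: SimulationConfig | None = None
    segments_path: str | Path | None = None
    bedpe_paths: list[str | Path] = field(default_factory=list)
    labels_path: str | Path | None = None
    min_seg_bp: int = 50_000
    max_components: int = 10
    mixture_restarts: int = 20
    backend: str = "nmf"  # "nmf" | "hdp"
    nmf_k_range: tuple[int, int] = (2, 8)
    cv_folds: int = 10
    cn_pred_threshold: float = 0.6
    event_config: EventConfig = field(default_factory=EventConfig)
    hdp_config: HdpConfig = field(default_factory=HdpConfig)
    force: bool = False

    def config_hash(self) -> str:
        payload = {
            k: str(v)
            for k, v in sorted(self.__dict__.items())
            if k not in ("output_dir", "force")
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimulationConfig(**raw["simulate"])
        if "event_config" in raw:
            raw["event_config"] = EventConfig(**raw["event_config"])
        if "hdp_config" in raw:
            raw["hdp_config"] = HdpConfig(**raw["hdp_config"])
        return cls(**raw)


def _load_inputs(config: RunConfig, assets: GenomeAssets):
    if config.simulate is not None:
        cohort = simulate_cohort(config.simulate, assets)
        labels = cohort.truth["chromothripsis"]
        return cohort.profiles, cohort.catalogs, labels
    if config.segments_path is None:
        raise ValueError("config needs either a simulate block or segments_path")
    profiles = read_segments(config.segments_path)
    catalogs = []
    for p in config.bedpe_paths:
        catalogs.extend(read_sv_bedpe(p))
    labels = None
    if config.labels_path is not None:
        lab = pd.read_csv(config.labels_path, sep="\t", index_col=0)
        labels = lab.iloc[:, 0]
        labels.index = labels.index.astype(str)
    return profiles, catalogs, labels


def run_end_to_end(config: RunConfig, assets: GenomeAssets | None = None) -> Path:
    """Execute every stage in order and return the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not config.force:
        raise FileExistsError(f"{out} is not empty (use force)")
    assets = assets or GenomeAssets.grch37()
    chash = config.config_hash()
    meta: dict = {"config_hash": chash, "seed": config.seed, "version": __version__, "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        meta["stages"][name] = "done"

    try:
        stage("load")
        profiles, catalogs, labels = _load_inputs(config, assets)
        cat_by_sample = {c.sample_id: c for c in catalogs}

        stage("filters")
        filtered, fcatalogs = [], []
        for prof in profiles:
            cat = cat_by_sample.get(prof.sample_id)
            fp, fc = apply_filters(prof, cat, assets, min_seg_bp=config.min_seg_bp)
            filtered.append(fp)
            if fc is not None:
                fcatalogs.append(fc)

        stage("cn_features")
        feats = [extract_features(p, assets) for p in filtered]

        stage("categories")
        scheme = fit_category_scheme(
            feats, max_components=config.max_components, seed=config.seed,
            n_restarts=config.mixture_restarts,
        )
        scheme.to_yaml(out / "scheme.yaml")

        stage("cn_matrix")
        cn_matrix = build_cn_matrix(feats, scheme)
        write_matrix(cn_matrix, out / "cn_matrix.tsv", comment=f"cnsig-config:{chash}")

        sv_matrix = None
        if fcatalogs:
            stage("sv_annotation")
            ann = pd.concat([annotate_pairs(c) for c in fcatalogs], ignore_index=True)
            ann.to_csv(out / "sv_annotations.tsv", sep="\t", index=False)
            stage("sv_matrix")
            sv_matrix = build_sv_matrix(fcatalogs)
            write_matrix(sv_matrix, out / "sv_matrix.tsv", comment=f"cnsig-config:{chash}")

            stage("complex_events")
            prof_by_sample = {p.sample_id: p for p in filtered}
            all_calls = []
            call_labels = {}
            for c in fcatalogs:
                calls = classify_components(c, prof_by_sample[c.sample_id], config.event_config)
                all_calls.extend(calls)
                call_labels[c.sample_id] = int(sample_has_chromothripsis(calls))
            calls_to_frame(all_calls).to_csv(out / "event_calls.tsv", sep="\t", index=False)
            pd.Series(call_labels, name="chromothripsis").rename_axis("sample").to_csv(
                out / "called_labels.tsv", sep="\t"
            )

        stage("signature_extraction")
        extract = {
            "nmf": lambda m, prefix: extract_nmf(
                m, k_range=range(*config.nmf_k_range), seed=config.seed, name_prefix=prefix
            ),
            "hdp": lambda m, prefix: extract_hdp(
                m, config=config.hdp_config, seed=config.seed, name_prefix=prefix
            ),
        }[config.backend]
        cn_sigs, cn_expo = extract(cn_matrix, "CN-SIG")
        write_matrix(cn_sigs.to_frame(), out / "cn_signatures.tsv", comment=f"cnsig-config:{chash}")
        write_matrix(cn_expo.to_frame(), out / "cn_exposures.tsv", comment=f"cnsig-config:{chash}")
        meta["n_cn_categories"] = scheme.total_categories
        meta["n_cn_signatures"] = cn_sigs.k
        sv_expo = None
        if sv_matrix is not None and sv_matrix.to_numpy().sum() > 0:
            sv_sigs, sv_expo = extract(sv_matrix, "SV-SIG")
            write_matrix(sv_sigs.to_frame(), out / "sv_signatures.tsv", comment=f"cnsig-config:{chash}")
            write_matrix(sv_expo.to_frame(), out / "sv_exposures.tsv", comment=f"cnsig-config:{chash}")
            meta["n_sv_signatures"] = sv_sigs.k

        if labels is not None:
            stage("prediction")
            y = pd.Series(labels).reindex(cn_expo.to_frame().index).astype(int)
            k = min(config.cv_folds, int(np.bincount(y, minlength=2).min()))
            if k >= 2 and y.nunique() == 2:
                result = crossval_predict(cn_expo.to_frame(), y.to_numpy(), k=k, seed=config.seed)
                calls = call_cn_pred(result, labels=y.to_numpy(), threshold=config.cn_pred_threshold)
                calls["fold"] = result.folds
                calls.to_csv(out / "predictions.tsv", sep="\t")
                meta["cn_cv_mean_auc"] = result.mean_auc
                meta["cn_pred_sensitivity"] = calls.attrs.get("sensitivity")
                meta["cn_pred_specificity"] = calls.attrs.get("specificity")
                if sv_expo is not None:
                    combined = pd.concat(
                        [cn_expo.to_frame(), sv_expo.to_frame()], axis=1
                    ).fillna(0.0)
                    res2 = crossval_predict(combined, y.to_numpy(), k=k, seed=config.seed)
                    meta["cnsv_cv_mean_auc"] = res2.mean_auc
            else:
                logger.warning("labels too unbalanced for %d-fold CV; prediction skipped", config.cv_folds)
                meta["stages"]["prediction"] = "skipped"
        else:
            logger.info("no labels provided; prediction stage skipped")
            meta["stages"]["prediction"] = "skipped"
    except Exception as exc:
        failed = [s for s, v in meta["stages"].items() if v == "done"]
        raise RuntimeError(
            f"pipeline failed after stages {failed}: {exc}"
        ) from exc

    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=float))
    return out
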