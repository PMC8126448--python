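"""End-to-end orchestration: load -> differential expression -> multivariate
-> per-condition networks -> topology -> DNM, with a JSON run report."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, dataio, diffexpr, dnm, multivariate, netinfer, topology
from .exceptions import ConfigurationError

log = logging.getLogger("metabodnm")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    intensity_path: str
    sample_sheet_path: str
    out_dir: str
    annotation_path: str | None = None
    alpha: float = 0.05
    median_scale: bool = False
    mi_estimator: str = "gaussian_spearman"
    dpi_eps: float = 0.0
    weight_floor: float = 0.0
    weighted: bool = True
    binarize: bool = False
    hosvd_center: bool = True
    loading_quantiles: tuple[float, float] = (0.05, 0.95)
    volcano_quantiles: tuple[float, float] = (0.025, 0.975)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["loading_quantiles"] = list(self.loading_quantiles)
        data["volcano_quantiles"] = list(self.volcano_quantiles)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def validate(self) -> None:
        for name in ("intensity_path", "sample_sheet_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigurationError(f"{name} does not exist: {p}")
        if self.annotation_path is not None and not Path(self.annotation_path).exists():
            raise ConfigurationError(f"annotation_path does not exist: {self.annotation_path}")
        if self.mi_estimator not in netinfer.ESTIMATORS:
            raise ConfigurationError(f"unknown MI estimator {self.mi_estimator!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class NetworkAnalysis:
    """Per-condition networks, partitions, centralities, CV and the DNM report."""

    networks: dict  # {"post"|"fasted": MiNetwork}
    partitions: dict  # {"post"|"fasted": ModulePartition}
    centrality: pd.DataFrame  # c_post, c_fasted, delta_c
    cv: pd.DataFrame  # cv_post, cv_fasted
    dnm_report: "dnm.DnmReport"

    def selected_dnm_members(self) -> set:
        return self.dnm_report.selected_members(self.partitions["fasted"])


def network_dnm_analysis(
    tensor,
    mi_estimator: str = "gaussian_spearman",
    dpi_eps: float = 0.0,
    weight_floor: float = 0.0,
    weighted: bool = True,
    binarize: bool = False,
    alpha: float = 0.05,
) -> NetworkAnalysis:
    """Network, topology and DNM stages on one tensor (no files written)."""
    logv = tensor.log2_values()
    nets, parts, cents = {}, {}, {}
    for ci, slab in enumerate(("post", "fasted")):
        logslice = pd.DataFrame(
            logv[:, :, ci], index=tensor.metabolite_ids, columns=tensor.individual_ids
        )
        mi = netinfer.pairwise_mi(logslice, estimator=mi_estimator)
        net = netinfer.dpi_prune(
            mi, eps=dpi_eps, weight_floor=weight_floor, condition=tensor.conditions[ci]
        )
        if binarize:
            for _, _, d in net.graph.edges(data=True):
                d["weight"] = 1.0
        nets[slab] = net
        parts[slab] = topology.leading_eigenvector_partition(net, weighted=weighted)
        cents[slab] = topology.eigenvector_centrality(net, weighted=weighted)
    cent_tab = topology.centrality_table(cents["post"], cents["fasted"])
    cv = dnm.between_individual_cv(tensor)
    report = dnm.rank_dnm_candidates(parts["fasted"], parts["post"], cent_tab, cv, alpha=alpha)
    return NetworkAnalysis(nets, parts, cent_tab, cv, report)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in fixed order and write all outputs.

    Returns the run report (also written as ``run_report.json``), listing
    every output file with its checksum plus warnings raised along the way.
    Reruns with the same config and inputs are byte-identical apart from no
    timestamps being recorded at all.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    captured: list[str] = []
    stage = "load"
    try:
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")

            tensor = dataio.load_dataset(
                config.intensity_path, config.sample_sheet_path, config.annotation_path
            )
            if config.median_scale:
                tensor = dataio.median_scale(tensor)
            catalogue = dataio.summarize_catalogue(tensor)
            log.info("loaded %d metabolites x %d individuals", tensor.n_metabolites,
                     tensor.n_individuals)

            stage = "diffexpr"
            de = diffexpr.run_diffexpr(tensor, alpha=config.alpha)
            outputs["diffexpr"] = out / "diffexpr.tsv"
            de.to_csv(outputs["diffexpr"], sep="\t")
            volcano = diffexpr.volcano_table(de, *config.volcano_quantiles)
            outputs["volcano"] = out / "volcano.tsv"
            volcano.to_csv(outputs["volcano"], sep="\t")
            de_summary = diffexpr.classify_and_summarize(de, tensor.annotations, config.alpha)
            outputs["diffexpr_summary"] = out / "diffexpr_summary.tsv"
            de_summary.to_csv(outputs["diffexpr_summary"], sep="\t")

            stage = "multivariate"
            X, cond = multivariate.multilevel_center(tensor)
            pls = multivariate.plsda_fit(X, cond)
            outputs["plsda_scores"] = out / "plsda_scores.tsv"
            pls.scores.join(cond).to_csv(outputs["plsda_scores"], sep="\t")
            outputs["plsda_loadings"] = out / "plsda_loadings.tsv"
            pls.loadings.to_csv(outputs["plsda_loadings"], sep="\t")
            selected = multivariate.select_top_loadings(pls, *config.loading_quantiles)
            outputs["plsda_selected"] = out / "plsda_selected_loadings.tsv"
            pd.DataFrame(
                [(c, m) for c, ms in selected.items() for m in ms],
                columns=["component", "metabolite_id"],
            ).to_csv(outputs["plsda_selected"], sep="\t", index=False)
            hos = multivariate.hosvd(tensor, center=config.hosvd_center)
            outputs["hosvd_contributions"] = out / "hosvd_contributions.tsv"
            hos.contributions.to_csv(outputs["hosvd_contributions"], sep="\t")

            stage = "networks+topology+dnm"
            analysis = network_dnm_analysis(
                tensor,
                mi_estimator=config.mi_estimator,
                dpi_eps=config.dpi_eps,
                weight_floor=config.weight_floor,
                weighted=config.weighted,
                binarize=config.binarize,
                alpha=config.alpha,
            )
            parts = analysis.partitions
            for slab, net in analysis.networks.items():
                outputs[f"network_{slab}_graphml"] = out / f"network_{slab}.graphml"
                outputs[f"network_{slab}_edges"] = out / f"network_{slab}_edges.tsv"
                netinfer.write_network(
                    net, outputs[f"network_{slab}_graphml"], outputs[f"network_{slab}_edges"]
                )
                outputs[f"partition_{slab}"] = out / f"partition_{slab}.tsv"
                part_df = parts[slab].assignment.to_frame()
                part_df["q_contrib"] = parts[slab].assignment.map(parts[slab].q_contrib)
                part_df.to_csv(outputs[f"partition_{slab}"], sep="\t")
            match = topology.match_modules(parts["post"], parts["fasted"])
            outputs["centrality"] = out / "centrality.tsv"
            analysis.centrality.join(match.membership_changed).to_csv(
                outputs["centrality"], sep="\t"
            )
            outputs["cv"] = out / "cv.tsv"
            analysis.cv.to_csv(outputs["cv"], sep="\t")
            report = analysis.dnm_report
            outputs["dnm_report"] = out / "dnm_report.json"
            report.write_json(outputs["dnm_report"])
            if not report.module_summary.empty:
                outputs["dnm_module_summary"] = out / "dnm_module_summary.tsv"
                report.module_summary.to_csv(outputs["dnm_module_summary"], sep="\t")
            for name, res in report.glms.items():
                outputs[f"glm_{name}_groups"] = out / f"glm_{name}_groups.tsv"
                res.group_table.to_csv(outputs[f"glm_{name}_groups"], sep="\t", index=False)

            captured = [str(w.message) for w in wrec]
    except Exception as exc:
        marker = out / "FAILED"
        marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        log.error("pipeline failed at stage %s: %s", stage, exc)
        raise

    report_dict = {
        "version": __version__,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "catalogue": catalogue,
        "significant_metabolites": int((de["p_adj"] < config.alpha).sum()),
        "plsda_explained_variance": [float(v) for v in pls.explained_variance],
        "modularity": {slab: parts[slab].Q for slab in parts},
        "n_modules": {slab: len(parts[slab].labels) for slab in parts},
        "selected_dnm_module": report.selected_module,
        "dnm_detected": report.dnm_detected,
        "flags": report.flags,
        "warnings": captured,
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in outputs.items()},
    }
    (out / "run_report.json").write_text(json.dumps(report_dict, indent=2) + "\n")
    return report_dict
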