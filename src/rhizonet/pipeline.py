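"""End-to-end pipeline orchestration.

Runs simulate -> normalize -> diversity -> dissimilarity/PERMANOVA ->
membership -> co-occurrence networks -> topology -> phenotype networks ->
prioritization, writing every intermediate artifact plus a JSON manifest
with seeds, thresholds, and file hashes. A single global seed is expanded
into per-stage substreams through a counter-based spawn scheme recorded in
the manifest, so any stage can be rerun in isolation and reproduce.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, diversity, membership, network, phona, synthetic

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "normalize",
    "diversity",
    "betadiv",
    "membership",
    "network",
    "topology",
    "phona",
    "prioritize",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    simulation: synthetic.SimulationConfig = field(
        default_factory=synthetic.SimulationConfig
    )
    rho_threshold: float = 0.6
    q_threshold: float = 0.05
    hub_threshold: float = 0.2
    walk_steps: int = 4
    core_threshold: float = 0.5
    min_prevalence: float = 0.2
    top_k: int = 20
    css_quantile: float = 0.5
    n_perm: int = 999
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    outdir: str = "rhizonet_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", {})
        sim.setdefault("seed", raw.get("seed", 0))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        sim["planted_pairs"] = [tuple(p) for p in sim.get("planted_pairs", [])]
        sim["planted_effects"] = [tuple(e) for e in sim.get("planted_effects", [])]
        return cls(simulation=synthetic.SimulationConfig(**sim), **raw)


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed, kept below 2**31."""
    return int(
        np.random.SeedSequence([seed, STAGES.index(stage)]).generate_state(1)[0]
        % (2**31)
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages and return the output manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "stage_seeds": {s: _stage_seed(cfg.seed, s) for s in cfg.stages},
        "thresholds": {
            "rho": cfg.rho_threshold,
            "q": cfg.q_threshold,
            "hub": cfg.hub_threshold,
            "core": cfg.core_threshold,
            "min_prevalence": cfg.min_prevalence,
        },
        "outputs": {},
    }

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    state: dict = {}
    for stage in cfg.stages:
        try:
            _run_stage(stage, cfg, state, outdir, emit)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(stage, exc) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return manifest


def _run_stage(stage, cfg: PipelineConfig, state: dict, outdir: Path, emit) -> None:
    if stage == "simulate":
        sim = synthetic.SimulationConfig(**{**asdict(cfg.simulation), "seed": cfg.seed})
        sim.planted_pairs = [tuple(p) for p in sim.planted_pairs]
        sim.planted_effects = [tuple(e) for e in sim.planted_effects]
        ct, md, ann, truth = synthetic.generate_community(sim)
        ph, _ = synthetic.generate_phenotypes(ct, sim, md)
        ct = ct.drop_empty_samples()
        state.update(ct=ct, md=md, ann=ann, ph=ph, sim=sim)
        io.write_count_table(ct, outdir / "counts.tsv")
        io.write_metadata(md, outdir / "metadata.tsv")
        ann.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        if not ph.empty and ph.shape[1] > 1:
            io.write_phenotypes(ph, outdir / "phenotypes.tsv")
            emit("phenotypes", outdir / "phenotypes.tsv")
        truth.to_json(outdir / "truth.json")
        for name in ("counts", "metadata", "annotations"):
            emit(name, outdir / f"{name}.tsv")
        emit("truth", outdir / "truth.json")
    elif stage == "normalize":
        state["nt"] = diversity.css_normalize(state["ct"], cfg.css_quantile)
        path = outdir / "css_normalized.tsv"
        state["nt"].to_dataframe().to_csv(path, sep="\t", float_format="%.12g")
        emit("css_normalized", path)
    elif stage == "diversity":
        alpha = diversity.alpha_diversity(state["ct"])
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t", float_format="%.12g")
        emit("alpha_diversity", outdir / "alpha_diversity.tsv")
    elif stage == "betadiv":
        dm = diversity.dissimilarity(state["nt"], "bray_curtis")
        dm.to_dataframe().to_csv(outdir / "bray_curtis.tsv", sep="\t",
                                 float_format="%.12g")
        emit("bray_curtis", outdir / "bray_curtis.tsv")
        md = state["md"].set_index("sample_id").loc[dm.sample_ids]
        results = {}
        for factor in ("treatment", "cultivar", "growth_stage"):
            res = diversity.permanova(
                dm, md[factor], strata=md["field_block"], n_perm=cfg.n_perm,
                seed=_stage_seed(cfg.seed, "betadiv"),
            )
            results[factor] = asdict(res)
        path = outdir / "permanova.json"
        path.write_text(json.dumps(results, indent=2))
        emit("permanova", path)
    elif stage == "membership":
        prev = membership.prevalence(state["ct"])
        core = membership.core_taxa(diversity.relative_abundance(state["ct"]),
                                    cfg.core_threshold)
        report = {
            "core_taxa": core,
            "prevalence": {t: float(p) for t, p in prev.items()},
            "unique_taxa": {
                factor: membership.unique_taxa(state["ct"], state["md"], factor)
                for factor in ("treatment", "cultivar", "growth_stage")
            },
        }
        state["prevalence"] = prev
        path = outdir / "membership.json"
        path.write_text(json.dumps(report, indent=2))
        emit("membership", path)
    elif stage == "network":
        assoc = network.pairwise_associations(state["nt"], "spearman")
        net = network.build_network(assoc, cfg.rho_threshold, cfg.q_threshold)
        state["net"] = net
        assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False,
                     float_format="%.12g")
        emit("associations", outdir / "associations.tsv")
        edge_path, graphml_path = io.write_network(net, outdir / "cooccurrence")
        emit("network_edges", edge_path)
        emit("network_graphml", graphml_path)
    elif stage == "topology":
        summary = network.summarize_topology(
            state["net"], cfg.hub_threshold, cfg.walk_steps
        )
        path = outdir / "topology.tsv"
        summary.to_series().to_frame("value").to_csv(path, sep="\t",
                                                     float_format="%.12g")
        emit("topology", path)
    elif stage == "phona":
        ph = state.get("ph")
        state["scores"] = {}
        if ph is None or ph.shape[1] <= 1:
            logger.warning("no phenotypes; skipping phenotype-network stage")
            return
        nt = state["nt"]
        X = pd.DataFrame(nt.values.T, index=nt.sample_ids, columns=nt.taxon_ids)
        seed = _stage_seed(cfg.seed, "phona")
        for name in ph.columns.drop("sample_id"):
            y = ph.set_index("sample_id").loc[nt.sample_ids, name].to_numpy()
            selected = phona.lasso_select(X, y, seed=seed)
            if selected.empty:
                glm = pd.DataFrame(columns=["taxon_id", "coefficient", "sign", "p"])
            else:
                glm = phona.fit_glm(
                    X[selected["taxon_id"]], y,
                    selected.set_index("taxon_id")["coefficient"],
                )
            pt = phona.assemble_phona(state["net"], glm, name,
                                      state.get("prevalence"))
            state["scores"][name] = phona.score_network(pt, cfg.walk_steps)
            edge_path, graphml_path = io.write_network(
                io.Network(pt.graph), outdir / f"phona_{name}"
            )
            emit(f"phona_{name}_edges", edge_path)
            emit(f"phona_{name}_graphml", graphml_path)
    elif stage == "prioritize":
        scores = state.get("scores") or {}
        if not scores:
            logger.warning("no scored phenotype networks; skipping prioritization")
            return
        report = phona.prioritize(
            scores, state["prevalence"], cfg.min_prevalence, cfg.top_k
        )
        path = outdir / "prioritization.tsv"
        report.to_csv(path, sep="\t", index=False, float_format="%.12g")
        emit("prioritization", path)
        path_json = outdir / "prioritization.json"
        path_json.write_text(report.to_json(orient="records", indent=2))
        emit("prioritization_json", path_json)
    else:
        raise ValueError(f"unknown stage {stage!r}")
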