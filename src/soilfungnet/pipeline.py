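"""End-to-end analysis pipeline with fixed data routing.

The routing is deliberate and runtime-asserted:

* merged, low-count-filtered, control-cleaned counts are **rarefied**
  before richness, habitat-preference and all distance-based analyses;
* co-occurrence networks are inferred from the **unrarefied** merged
  counts (prevalence-filtered per depth), because equalising totals by
  rarefaction can introduce artifacts into compositional correlation
  estimates.  Networks are restricted by default to the three shallowest
  depth classes, where enough positions retain adequate sequencing depth.

Every stochastic stage receives a child seed spawned deterministically
from one master seed, recorded in the run manifest; a rerun with the same
manifest reproduces all outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .community import (
    depth_trend_test,
    mantel_correlogram,
    permanova,
    permdisp,
    raup_crick,
    richness_per_sample,
)
from .cooccur import estimate_mb, estimate_sparcc, threshold_to_graph
from .habitat import habitat_preference
from .io import (
    CommunityMatrix,
    read_community_table,
    read_sample_metadata,
    write_community_table,
    write_edge_table,
    write_sample_metadata,
)
from .modules import extract_modules, summarize_modules
from .preprocess import (
    filter_low_count_otus,
    merge_replicates,
    prevalence_filter,
    rarefy,
    remove_control_otus,
)
from .synthetic import SyntheticConfig, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All parameters of one pipeline run.

    Either ``synthetic`` is set (the input is generated) or both
    ``matrix_path`` and ``metadata_path`` point at existing files.
    """

    output_dir: str | Path = "soilfungnet_run"
    synthetic: SyntheticConfig | None = None
    matrix_path: str | Path | None = None
    metadata_path: str | Path | None = None

    min_total_reads: int = 10
    rarefy_depth: int = 1000
    prevalence_fraction: Fraction = Fraction(1, 3)
    network_cutoff: float = 0.4
    n_perm: int = 10000
    raup_crick_n_null: int = 999
    #: depth classes for network inference; None = the three shallowest
    network_depths: list[str] | None = None
    n_network_depths: int = 3
    depth_coding: str = "numeric"
    sparcc_resamples: int = 20
    mb_stability_reps: int = 50
    mb_lambda_points: int = 30
    mb_stars_threshold: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.synthetic is None and (self.matrix_path is None or self.metadata_path is None):
            raise ValueError("either a synthetic config or matrix+metadata paths are required")
        if self.rarefy_depth <= 0:
            raise ValueError("rarefy_depth must be positive")
        if self.min_total_reads < 0:
            raise ValueError("min_total_reads must be non-negative")
        if not 0 < float(self.prevalence_fraction) <= 1:
            raise ValueError("prevalence_fraction must be in (0, 1]")
        if not 0 < self.network_cutoff < 1:
            raise ValueError("network_cutoff must be in (0, 1)")
        if self.n_perm < 1 or self.raup_crick_n_null < 1:
            raise ValueError("permutation counts must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = (
            json.loads(path.read_text())
            if path.suffix == ".json"
            else yaml.safe_load(path.read_text())
        )
        if "synthetic" in raw and raw["synthetic"] is not None:
            synth = dict(raw["synthetic"])
            if "association_pairs" in synth:
                synth["association_pairs"] = tuple(
                    (str(a), str(b), float(r)) for a, b, r in synth["association_pairs"]
                )
            if "preference_effects" in synth and isinstance(synth["preference_effects"], dict):
                synth["preference_effects"] = {
                    tuple(str(k).split("|", 1)): float(v)
                    for k, v in synth["preference_effects"].items()
                }
            raw["synthetic"] = SyntheticConfig(**synth)
        if "prevalence_fraction" in raw:
            raw["prevalence_fraction"] = Fraction(str(raw["prevalence_fraction"]))
        return cls(**raw)

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        out["output_dir"] = str(self.output_dir)
        out["prevalence_fraction"] = str(self.prevalence_fraction)
        if self.synthetic is not None:
            s = dataclasses.asdict(self.synthetic)
            s["preference_effects"] = {
                f"{o}|{d}": v for (o, d), v in self.synthetic.preference_effects.items()
            }
            s["association_pairs"] = [list(p) for p in self.synthetic.association_pairs]
            out["synthetic"] = s
        for key in ("matrix_path", "metadata_path"):
            if out[key] is not None:
                out[key] = str(out[key])
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _result_dict(res) -> dict:
    return {
        "statistic": res.statistic,
        "p_value": res.p_value,
        "n_permutations": res.n_permutations,
        "permutation_seed": res.permutation_seed,
        "extra": {k: (list(v) if isinstance(v, tuple) else v) for k, v in res.extra.items()},
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    config.validate()
    t0 = time.monotonic()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # one child seed per stochastic stage, spawned from the master seed
    ss = np.random.SeedSequence(config.seed)
    stage_names = ["rarefy", "raup_crick", "permanova", "permdisp", "mantel", "hp",
                   "sparcc", "mb"]
    children = ss.spawn(len(stage_names))
    stage_seed = {
        name: int(child.generate_state(1)[0] % (2**31)) for name, child in zip(stage_names, children)
    }

    manifest: dict = {
        "tool": "soilfungnet",
        "version": __version__,
        "config": config.to_jsonable(),
        "stage_seeds": stage_seed,
        "stages": [],
        "warnings": [],
    }

    # ---- input ----------------------------------------------------------
    if config.synthetic is not None:
        logger.info("stage synth: generating synthetic dataset")
        matrix, metas, truth = generate_dataset(config.synthetic)
        write_community_table(matrix, out / "raw_counts.tsv")
        write_sample_metadata(metas, out / "sample_metadata.tsv")
        truth.basis.round(6).to_csv(out / "truth_basis.tsv", sep="\t", lineterminator="\n")
        _write_json(
            {
                "preference_effects": {
                    f"{o}|{d}": v for (o, d), v in truth.preference_effects.items()
                },
                "association_pairs": [list(p) for p in truth.association_pairs],
            },
            out / "truth.json",
        )
    else:
        matrix = read_community_table(config.matrix_path)
        metas = read_sample_metadata(config.metadata_path)
        matrix = matrix.with_metadata(metas)
        manifest["input_checksums"] = {
            "matrix": _sha256(Path(config.matrix_path)),
            "metadata": _sha256(Path(config.metadata_path)),
        }

    def record(step, report=None, **info):
        entry = {"stage": step}
        if report is not None:
            entry["report"] = report.to_dict()
            manifest["warnings"].extend(report.notes)
        entry.update(info)
        manifest["stages"].append(entry)
        logger.info("stage %s done", step)

    # ---- shared preprocessing -------------------------------------------
    merged, rep = merge_replicates(matrix)
    record("merge_replicates", rep)
    filtered, rep = filter_low_count_otus(merged, config.min_total_reads)
    record("filter_low_count_otus", rep)
    cleaned, rep = remove_control_otus(filtered)
    record("remove_control_otus", rep)

    # ---- branch A: rarefied matrix -> diversity / HP / distance tests ---
    rarefied, rep = rarefy(cleaned, config.rarefy_depth, seed=stage_seed["rarefy"])
    record("rarefy", rep)
    assert (rarefied.counts.sum(axis=1) == config.rarefy_depth).all(), \
        "rarefied rows must sum to the rarefaction depth"
    write_community_table(rarefied, out / "rarefied_counts.tsv")

    richness = richness_per_sample(rarefied)
    richness.to_csv(out / "richness.tsv", sep="\t", lineterminator="\n")
    depth_of = pd.Series(
        {s.sample_id: s.depth_value_cm for s in rarefied.samples}, name="depth_value_cm"
    )
    trend = depth_trend_test(richness, depth_of)
    record("depth_trend", None, result=_result_dict(trend))

    dist = raup_crick(rarefied, n_null=config.raup_crick_n_null, seed=stage_seed["raup_crick"])
    dist.to_frame().round(6).to_csv(out / "raup_crick.tsv", sep="\t", lineterminator="\n")

    perma = permanova(
        dist, depth_of.reindex(dist.ids).to_numpy(), n_perm=config.n_perm,
        seed=stage_seed["permanova"], coding=config.depth_coding,
    )
    record("permanova", None, result=_result_dict(perma))
    depth_class_of = np.array([s.depth_class for s in rarefied.samples])
    disp = permdisp(dist, depth_class_of, n_perm=config.n_perm, seed=stage_seed["permdisp"])
    record("permdisp", None, result=_result_dict(disp))
    positions = np.array([s.horizontal_position_m for s in rarefied.samples])
    correlogram = mantel_correlogram(
        dist, positions, n_perm=config.n_perm, seed=stage_seed["mantel"]
    )
    pd.DataFrame(
        [
            {
                "class_index": r.extra["class_index"],
                "lower_m": r.extra["lower"],
                "upper_m": r.extra["upper"],
                "n_pairs": r.extra["n_pairs"],
                "mantel_r": r.statistic,
                "p": r.p_value,
                "p_corrected": r.extra["p_corrected"],
            }
            for r in correlogram
        ]
    ).to_csv(out / "mantel_correlogram.tsv", sep="\t", index=False, lineterminator="\n")
    record("mantel_correlogram", None, n_classes=len(correlogram))

    hp = habitat_preference(rarefied, n_perm=config.n_perm, seed=stage_seed["hp"])
    hp.to_table().to_csv(out / "habitat_preference.tsv", sep="\t", index=False,
                         lineterminator="\n", float_format="%.6g")
    record("habitat_preference", None, n_tests=int(hp.p_value.size))

    # ---- branch B: unrarefied counts -> per-depth networks --------------
    # routing guard: networks must never see the rarefied object
    assert cleaned is not rarefied, "network branch must consume unrarefied counts"
    depth_order = cleaned.depth_classes()
    net_depths = config.network_depths or depth_order[: config.n_network_depths]
    module_summaries = []
    for depth_class in net_depths:
        sub = prevalence_filter(cleaned, depth_class, config.prevalence_fraction)
        safe = depth_class.replace("+", "p").replace("-", "m")
        if sub.n_otus < 4:
            msg = f"depth {depth_class}: only {sub.n_otus} OTUs pass prevalence; skipped"
            logger.warning(msg)
            manifest["warnings"].append(msg)
            continue
        est = estimate_sparcc(
            sub, n_resamples=config.sparcc_resamples, seed=stage_seed["sparcc"]
        )
        est.rho.round(6).to_csv(out / f"sparcc_rho_{safe}.tsv", sep="\t", lineterminator="\n")
        graph = threshold_to_graph(est, cutoff=config.network_cutoff, depth_class=depth_class)
        for sign, tag in (("+", "positive"), ("-", "negative")):
            sg = graph.filter_sign(sign)
            write_edge_table(sg, out / f"sparcc_{tag}_{safe}.tsv", format="tsv")
            write_edge_table(sg, out / f"sparcc_{tag}_{safe}.graphml", format="graphml")
        mb_graph = estimate_mb(
            sub,
            lambda_grid=np.logspace(-3, 0, config.mb_lambda_points),
            stability_reps=config.mb_stability_reps,
            stars_threshold=config.mb_stars_threshold,
            seed=stage_seed["mb"],
            depth_class=depth_class,
        )
        for sign, tag in (("+", "positive"), ("-", "negative")):
            sg = mb_graph.filter_sign(sign)
            write_edge_table(sg, out / f"mb_{tag}_{safe}.tsv", format="tsv")
            write_edge_table(sg, out / f"mb_{tag}_{safe}.graphml", format="graphml")
        mods = extract_modules(graph.filter_sign("+"))
        summary = summarize_modules(mods)
        summary.insert(0, "depth_class", depth_class)
        module_summaries.append(summary)
        membership = pd.DataFrame(
            [
                {"depth_class": depth_class, "module_id": m.module_id, "otu_id": o}
                for m in mods.modules
                for o in sorted(m.members)
            ],
            columns=["depth_class", "module_id", "otu_id"],
        )
        membership.to_csv(out / f"modules_{safe}.tsv", sep="\t", index=False,
                          lineterminator="\n")
        record(
            f"network_{depth_class}",
            None,
            n_otus=sub.n_otus,
            sparcc_edges=graph.n_edges,
            sparcc_positive_edges=graph.filter_sign("+").n_edges,
            mb_edges=mb_graph.n_edges,
            n_modules=len(mods.modules),
        )
    if module_summaries:
        pd.concat(module_summaries, ignore_index=True).to_csv(
            out / "module_summary.tsv", sep="\t", index=False, lineterminator="\n"
        )

    manifest["elapsed_stages"] = len(manifest["stages"])
    _write_json(manifest, out / "manifest.json")
    logger.info("pipeline finished in %.1f s", time.monotonic() - t0)
    return manifest
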