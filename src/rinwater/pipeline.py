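"""End-to-end orchestration: structure → RIN variants → centralities →
differential report → serialized artifacts."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import exporters
from .centrality import CENTRAL_Z_THRESHOLD, bca, rca
from .differential import ExclusionPolicy, compare, interface_report, water_removal_experiment
from .rin import RIN, ContactThresholds, build_rin
from .structure_io import Structure, parse_pdb, select_chains

log = logging.getLogger("rinwater")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is stage-tagged."""


@dataclass
class RunConfig:
    """Configuration for a full analysis run.

    ``chain_groups`` is a pair of chain-id groups defining the interface
    (e.g. (["A"], ["B"])); when None and the structure has exactly two
    chains, they are used. ``variants`` must include both "wet" and "dry"
    for a differential report to be produced.
    """

    input_path: str | Path | None = None
    structure: Structure | None = None
    chains: list[str] | None = None
    water_policy: str = "all"
    chain_groups: tuple[list[str], list[str]] | None = None
    thresholds: ContactThresholds = field(default_factory=ContactThresholds)
    variants: tuple[str, ...] = ("dry", "wet", "interface_waters")
    methods: tuple[str, ...] = ("RCA", "BCA")
    z_threshold: float = CENTRAL_Z_THRESHOLD
    excluded_labels: dict[str, str] = field(default_factory=dict)
    water_removal_selectors: tuple = ()  # e.g. ("max_degree", ("degree_ge", 5))
    output_dir: str | Path = "rinwater-out"

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")


def _load_structure(cfg: RunConfig) -> Structure:
    if cfg.structure is not None:
        s = cfg.structure
    elif cfg.input_path is not None:
        s = parse_pdb(cfg.input_path)
    else:
        raise PipelineError("[load] neither input_path nor structure given")
    if cfg.chains:
        s = select_chains(s, cfg.chains, keep_waters=cfg.water_policy)
    return s


def _chain_groups(cfg: RunConfig, s: Structure) -> tuple[list[str], list[str]] | None:
    if cfg.chain_groups is not None:
        return cfg.chain_groups
    chains = s.chains
    if len(chains) == 2:
        return ([chains[0]], [chains[1]])
    return None


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured analysis and write all artifacts to
    ``cfg.output_dir``. Returns an in-memory summary with the built RINs,
    centrality results and the differential report (if computed)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        s = _load_structure(cfg)
    except Exception as e:  # stage-tagged abort
        raise PipelineError(f"[load] {e}") from e
    groups = _chain_groups(cfg, s)

    fns = {"RCA": rca, "BCA": bca}
    rins: dict[str, RIN] = {}
    results: dict[tuple[str, str], object] = {}
    for variant in cfg.variants:
        try:
            rin = build_rin(s, variant=variant, thresholds=cfg.thresholds, chain_groups=groups)
        except Exception as e:
            raise PipelineError(f"[build_rin:{variant}] {e}") from e
        rins[variant] = rin
        log.info(
            "variant=%s nodes=%d (waters=%d) edges=%d",
            variant,
            rin.graph.number_of_nodes(),
            len(rin.water_nodes),
            rin.graph.number_of_edges(),
        )
        exporters.write_sif(rin, out / f"rin_{variant}.sif")
        exporters.write_node_table(rin, out / f"rin_{variant}_nodes.tsv")
        for method in cfg.methods:
            try:
                res = fns[method](rin)
            except Exception as e:
                raise PipelineError(f"[centrality:{variant}:{method}] {e}") from e
            results[(variant, method)] = res
            log.info(
                "centrality variant=%s method=%s population=%d",
                variant,
                method,
                res.rin_metadata.get("z_population_size"),
            )
            exporters.write_centrality_tsv(res, out / f"centrality_{variant}_{method.lower()}.tsv", cfg.z_threshold)

    summary: dict = {"structure": s, "rins": rins, "results": results, "output_dir": out}

    if "wet" in cfg.variants and "dry" in cfg.variants:
        wet = {m: results[("wet", m)] for m in cfg.methods}
        dry = {m: results[("dry", m)] for m in cfg.methods}
        try:
            report = compare(
                wet,
                dry,
                threshold=cfg.z_threshold,
                exclusions=ExclusionPolicy(dict(cfg.excluded_labels)) if cfg.excluded_labels else None,
                structure_id=s.id,
            )
        except Exception as e:
            raise PipelineError(f"[differential] {e}") from e
        if groups is not None:
            from .rin import annotate_interface

            iface = annotate_interface(s, groups, cfg.thresholds.d_int)
            report = interface_report(report, iface)
        exporters.write_differential_json(report, out / "differential.json")
        exporters.write_added_table_tsv(report, out / "added_central_nodes.tsv")
        exporters.export_z_table(
            {(c, m): results[(c, m)] for c in ("dry", "wet") for m in cfg.methods},
            sorted(report.union_added - set(rins["wet"].water_nodes)),
            out / "z_table_added.tsv",
        )
        summary["report"] = report

        removals = []
        for sel in cfg.water_removal_selectors:
            if isinstance(sel, tuple) and sel[0] == "degree_ge":
                exp = water_removal_experiment(
                    rins["wet"], selector="degree_ge", k=sel[1], methods=cfg.methods, threshold=cfg.z_threshold
                )
            elif isinstance(sel, (list, tuple)) and sel and sel[0] == "explicit":
                exp = water_removal_experiment(
                    rins["wet"], selector=list(sel[1]), methods=cfg.methods, threshold=cfg.z_threshold
                )
            else:
                exp = water_removal_experiment(
                    rins["wet"], selector=sel, methods=cfg.methods, threshold=cfg.z_threshold
                )
            removals.append(exp)
        if removals:
            import json

            (out / "water_removal.json").write_text(json.dumps(removals, indent=2, sort_keys=True) + "\n")
            summary["water_removal"] = removals
    elif cfg.methods:
        log.warning("wet+dry variants not both requested; no differential report")

    exporters.write_run_metadata(
        out / "run_metadata.json",
        structure_id=s.id,
        chains=cfg.chains,
        water_policy=cfg.water_policy,
        chain_groups=groups,
        thresholds={
            "d_rr": cfg.thresholds.d_rr,
            "d_w": cfg.thresholds.d_w,
            "d_int": cfg.thresholds.d_int,
        },
        variants=list(cfg.variants),
        methods=list(cfg.methods),
        z_threshold=cfg.z_threshold,
        excluded_labels=cfg.excluded_labels,
        rin_sizes={
            v: {"nodes": r.graph.number_of_nodes(), "edges": r.graph.number_of_edges()}
            for v, r in rins.items()
        },
    )
    return summary
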