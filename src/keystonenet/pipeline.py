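"""End-to-end orchestration: files in, report bundle out."""

from __future__ import annotations

import csv
import dataclasses
import importlib.metadata
import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ingest, network, preference, summaries

logger = logging.getLogger(__name__)


def default_growth_forms() -> dict[str, str]:
    """Woody/herbaceous lookup shipped with the package (common North-China
    urban-forest genera); users supply their own CSV for other floras."""
    ref = importlib.resources.files("keystonenet.data") / "growth_forms.csv"
    return _parse_growth_forms(ref.read_text().splitlines())


def load_growth_forms(path: str | Path) -> dict[str, str]:
    with Path(path).open(newline="") as fh:
        return _parse_growth_forms(fh)


def _parse_growth_forms(lines) -> dict[str, str]:
    reader = csv.DictReader(lines)
    return {row["taxon"].strip(): row["growth_form"].strip() for row in reader}


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run.

    Defaults reproduce the standard thresholds: OTUs kept above 100 total
    reads, diet edges kept above 100 reads, nest edges unfiltered, literal
    wMD, pooled usage fractions for the preference indices, calendar-thirds
    temporal grouping and a 0.1% composition-partition threshold.
    """

    coi_path: str | None = None
    rbcl_path: str | None = None
    samples_path: str | None = None
    nests_path: str | None = None
    community_path: str | None = None
    growth_forms_path: str | None = None
    outdir: str = "results"
    min_otu_reads: int = 100
    edge_min_diet: int = 100
    edge_min_nest: int = 0
    wmd_variant: str = "literal"
    usage_level: str = "per_pool"
    composition_level: str = "per_sample_mean"
    temporal_scheme: str = "calendar_thirds"
    partition_threshold: float = 0.001
    remove_host_reads: bool = True
    exclude_families: tuple[str, ...] = ("Hominidae",)
    preference_cutoff: float | None = None
    top_k: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "exclude_families" in raw:
            raw["exclude_families"] = tuple(raw["exclude_families"])
        return cls(**raw)


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Emits, per network kind, GraphML + edge-list + node-importance files,
    plus FP/NP tables, a composition table, overlap counts, temporal bins, a
    nest summary and a manifest echoing every setting used. Returns a dict
    with artifact paths and an ``empty`` flag set when every network came out
    empty (degenerate thresholds or inputs).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logging.getLogger("keystonenet").addHandler(collector)
    artifacts: dict[str, str] = {}
    try:
        result = _run(cfg, outdir, artifacts)
    finally:
        logging.getLogger("keystonenet").removeHandler(collector)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "version": _version(),
        "warnings": collector.messages,
        "artifacts": artifacts,
        "empty": result["empty"],
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    result["manifest"] = manifest_path
    result["artifacts"] = artifacts
    return result


def _version() -> str:
    try:
        return importlib.metadata.version("keystonenet")
    except importlib.metadata.PackageNotFoundError:
        return "unknown"


def _run(cfg: RunConfig, outdir: Path, artifacts: dict[str, str]) -> dict:
    stage = "ingest"
    try:
        coi = ingest.read_otu_table(cfg.coi_path, "COI") if cfg.coi_path else None
        rbcl = ingest.read_otu_table(cfg.rbcl_path, "rbcL") if cfg.rbcl_path else None
        meta = ingest.read_sample_meta(cfg.samples_path) if cfg.samples_path else []
        nests = ingest.read_nest_records(cfg.nests_path) if cfg.nests_path else []
        community = (
            ingest.read_community_table(cfg.community_path) if cfg.community_path else None
        )
        growth_forms = (
            load_growth_forms(cfg.growth_forms_path)
            if cfg.growth_forms_path
            else default_growth_forms()
        )

        stage = "filter"
        if coi is not None:
            coi = ingest.filter_otus(coi, cfg.min_otu_reads)
        if rbcl is not None:
            rbcl = ingest.filter_otus(rbcl, cfg.min_otu_reads)

        stage = "host assignment"
        samples = ingest.assign_hosts(coi, meta) if coi is not None else list(meta)
        if coi is not None and cfg.remove_host_reads:
            coi = ingest.remove_host_reads(coi, samples)

        stage = "networks"
        nets: dict[str, network.BipartiteNetwork] = {}
        if coi is not None:
            nets["diet_animal"] = network.build_network(
                "diet_animal", samples=samples, otu=coi,
                edge_min=cfg.edge_min_diet, exclude_families=cfg.exclude_families,
            )
        if rbcl is not None:
            nets["diet_plant"] = network.build_network(
                "diet_plant", samples=samples, otu=rbcl, edge_min=cfg.edge_min_diet
            )
        if nests:
            nets["nest_plant"] = network.build_network(
                "nest_plant", nests=nests, edge_min=cfg.edge_min_nest
            )
        for kind, net in nets.items():
            network.export_graph(net, outdir / f"network_{kind}.graphml", "graphml")
            network.export_graph(net, outdir / f"network_{kind}.tsv", "edge_tsv")
            artifacts[f"network_{kind}_graphml"] = f"network_{kind}.graphml"
            artifacts[f"network_{kind}_tsv"] = f"network_{kind}.tsv"
            with (outdir / f"importance_{kind}.csv").open("w", newline="") as fh:
                writer = csv.writer(fh, lineterminator="\n")
                writer.writerow(["node", "degree", "wmd"])
                if net.resource_nodes:
                    for s in network.rank_keystones(net, by="wmd", variant=cfg.wmd_variant):
                        writer.writerow([s.node, s.degree, f"{s.wmd:.10g}"])
            artifacts[f"importance_{kind}"] = f"importance_{kind}.csv"

        stage = "preference indices"
        if rbcl is not None and community is not None:
            try:
                usage = preference.diet_relative_abundance(rbcl, samples, level=cfg.usage_level)
                fp = preference.preference_index(usage, community, kind="FP")
                if cfg.preference_cutoff is not None:
                    fp = [r for r in fp if r.flag or r.index >= cfg.preference_cutoff]
            except ValueError as exc:
                logger.warning("food-preference table is empty: %s", exc)
                fp = []
            preference.preference_to_csv(fp, outdir / "preference_fp.csv")
            artifacts["preference_fp"] = "preference_fp.csv"
        if nests and community is not None:
            try:
                np_usage = preference.nest_relative_abundance(nests)
                np_res = preference.preference_index(np_usage, community, kind="NP")
                if cfg.preference_cutoff is not None:
                    np_res = [r for r in np_res if r.flag or r.index >= cfg.preference_cutoff]
            except ValueError as exc:
                logger.warning("nesting-preference table is empty: %s", exc)
                np_res = []
            preference.preference_to_csv(np_res, outdir / "preference_np.csv")
            artifacts["preference_np"] = "preference_np.csv"

        stage = "summaries"
        if rbcl is not None:
            try:
                comp = summaries.composition(
                    rbcl, samples, growth_forms=growth_forms,
                    partition_threshold=cfg.partition_threshold, level=cfg.composition_level,
                )
                table = comp.table
            except ValueError as exc:
                logger.warning("composition table is empty: %s", exc)
                table = pd.DataFrame(
                    columns=["taxon", "mean_relative_abundance", "cumulative_share", "growth_form"]
                )
            table.to_csv(outdir / "composition.csv", index=False)
            artifacts["composition"] = "composition.csv"
            if "diet_plant" in nets:
                overlap = summaries.overlap_counts(summaries.presence_sets(nets["diet_plant"]))
                summaries.overlap_to_tsv(overlap, outdir / "overlap.tsv")
                artifacts["overlap"] = "overlap.tsv"
            bins = summaries.temporal_bins(samples, scheme=cfg.temporal_scheme, otu=rbcl)
            if bins.abundance is not None:
                bins.abundance.to_csv(outdir / "temporal_bins.csv")
                artifacts["temporal_bins"] = "temporal_bins.csv"
        if nests:
            shares = summaries.nest_shares(nests)
            with (outdir / "nest_shares.csv").open("w", newline="") as fh:
                writer = csv.writer(fh, lineterminator="\n")
                writer.writerow(["category", "value"])
                writer.writerow(["n_total", shares.n_total])
                writer.writerow(["n_identified", shares.n_identified])
                writer.writerow(["n_artificial", shares.n_artificial])
                writer.writerow(["n_vegetation", shares.n_vegetation])
                for gf, frac in shares.growth_form_fractions.items():
                    writer.writerow([f"share_{gf}", f"{frac:.10g}"])
            artifacts["nest_shares"] = "nest_shares.csv"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    empty_kinds = [kind for kind, n in nets.items() if n.n_edges == 0]
    if empty_kinds:
        logger.warning(
            "network(s) with no edges: %s; check thresholds and inputs",
            ", ".join(empty_kinds),
        )
    return {"networks": nets, "empty": bool(empty_kinds), "outdir": outdir}
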