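"""End-to-end orchestration: config, run_screen, and fixture bundles.

``run_screen`` executes the full in-silico screen from one validated
config: per study it collapses probes to genes, selects DEGs with the
moderated t, maps symbols to human orthologs, computes the Characteristic
Direction signature on the DEG genes, and scores the drug library by
cosine distance; the per-study ranked lists are Borda-merged into a
consensus; the merged DEG union feeds PPI centrality and gene-set
over-representation.  Every stage writes its TSV into the output
directory and contributes counts to a JSON manifest, so a run is a fully
auditable funnel (probes in, genes after collapse, DEGs per study, union
size, drugs scored/skipped).

``write_bundle`` emits a complete synthetic input bundle (expression,
annotations, groups, ortholog map, library, edges, gene sets, ground
truth) that ``run_screen`` can consume directly — the offline stand-in
for the GEO + LINCS + STRING downloads.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import cdscreen
from cdscreen import dge, io_formats, network, preprocess, screening, signature
from cdscreen import synthetic

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    name: str
    expression: str
    groups: str
    annotation: str
    format: str = "tsv"
    ortholog_map: str | None = None
    alpha: float = dge.DEFAULT_ALPHA
    min_abs_log_fc: float = 0.0


@dataclass
class ScreenConfig:
    """Validated configuration of a full screen run."""

    studies: list[StudyConfig]
    library: str
    edges: str
    gene_sets: str
    output_dir: str
    gamma: float = signature.DEFAULT_GAMMA
    gene_cap: int = signature.DEFAULT_GENE_CAP
    mode: str = "reverse"
    top_n: int = screening.DEFAULT_TOP_N
    min_overlap: int = screening.DEFAULT_MIN_OVERLAP
    base_score: int = screening.DEFAULT_BASE_SCORE
    score_min: int = 800
    seed: int = 0

    def validate_paths(self) -> None:
        missing = []
        for s in self.studies:
            for p in (s.expression, s.groups, s.annotation, s.ortholog_map):
                if p is not None and not Path(p).exists():
                    missing.append(p)
        for p in (self.library, self.edges, self.gene_sets):
            if not Path(p).exists():
                missing.append(p)
        if missing:
            raise FileNotFoundError(f"config references missing path(s): {missing}")
        if not self.studies:
            raise ValueError("config lists no studies")


def load_config(path: str | Path) -> ScreenConfig:
    """Load a YAML screen config; relative paths resolve against the file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    base = path.parent

    def resolve(p):
        return str((base / p)) if p is not None and not Path(p).is_absolute() else p

    studies = [
        StudyConfig(
            name=s["name"],
            expression=resolve(s["expression"]),
            groups=resolve(s["groups"]),
            annotation=resolve(s["annotation"]),
            format=s.get("format", "tsv"),
            ortholog_map=resolve(s.get("ortholog_map")),
            alpha=float(s.get("alpha", dge.DEFAULT_ALPHA)),
            min_abs_log_fc=float(s.get("min_abs_log_fc", 0.0)),
        )
        for s in raw["studies"]
    ]
    return ScreenConfig(
        studies=studies,
        library=resolve(raw["library"]),
        edges=resolve(raw["edges"]),
        gene_sets=resolve(raw["gene_sets"]),
        output_dir=resolve(raw["output_dir"]),
        gamma=float(raw.get("gamma", signature.DEFAULT_GAMMA)),
        gene_cap=int(raw.get("gene_cap", signature.DEFAULT_GENE_CAP)),
        mode=raw.get("mode", "reverse"),
        top_n=int(raw.get("top_n", screening.DEFAULT_TOP_N)),
        min_overlap=int(raw.get("min_overlap", screening.DEFAULT_MIN_OVERLAP)),
        base_score=int(raw.get("base_score", screening.DEFAULT_BASE_SCORE)),
        score_min=int(raw.get("score_min", 800)),
        seed=int(raw.get("seed", 0)),
    )


def _signature_study(
    gene_study: io_formats.ExpressionStudy,
    degs: dict[str, str],
    omap: io_formats.OrthologMap | None,
) -> io_formats.ExpressionStudy:
    """Restrict a gene-level study to its unambiguous DEGs, in target symbols.

    Rows are renamed through the ortholog map (identity when absent);
    when two source symbols map to one target, the lexicographically
    first source is kept — deterministic and rare in practice.
    """
    directional = preprocess.directional(degs)
    sources = sorted(g for g in gene_study.values.index if str(g) in directional)
    rename: dict[str, str] = {}
    seen_targets: set[str] = set()
    for src in sources:
        tgt = omap.mapping.get(src, None) if omap is not None else src
        if omap is None:
            tgt = src
        if tgt is None or tgt in seen_targets:
            continue
        rename[src] = tgt
        seen_targets.add(tgt)
    if not rename:
        raise ValueError("no DEG maps into the target gene space")
    sub = gene_study.values.loc[list(rename)].rename(index=rename)
    return io_formats.ExpressionStudy(values=sub, groups=gene_study.groups)


def run_screen(config: ScreenConfig) -> dict:
    """Run the full screen; returns the manifest dict (also written to disk)."""
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    lib = io_formats.read_signature_library(config.library)
    edges = io_formats.read_edges(config.edges, score_min=config.score_min)
    gene_sets = io_formats.read_gmt(config.gene_sets)

    manifest: dict = {
        "tool": "cdscreen",
        "version": cdscreen.__version__,
        "seed": config.seed,
        "parameters": {
            "gamma": config.gamma,
            "gene_cap": config.gene_cap,
            "mode": config.mode,
            "top_n": config.top_n,
            "min_overlap": config.min_overlap,
            "base_score": config.base_score,
            "score_min": config.score_min,
        },
        "studies": {},
    }

    ranked_lists: list[pd.DataFrame] = []
    deg_sets: list[dict[str, str]] = []
    universe: set[str] = set()

    for sc in config.studies:
        stage = f"study {sc.name}"
        try:
            study = io_formats.read_expression(sc.expression, format=sc.format)
            groups = io_formats.read_sample_groups(sc.groups)
            study = io_formats.attach_groups(study, groups)
            ann = io_formats.read_probe_annotation(sc.annotation)
            omap = (
                io_formats.read_ortholog_map(sc.ortholog_map)
                if sc.ortholog_map
                else None
            )

            gene_study, provenance = preprocess.collapse_probes(study, ann)
            table = dge.moderated_t(gene_study, alpha=sc.alpha)
            degs_src = dge.select_degs(
                table, alpha=sc.alpha, min_abs_log_fc=sc.min_abs_log_fc
            )
            degs = (
                preprocess.map_orthologs(degs_src, omap)
                if omap is not None
                else dict(degs_src)
            )

            gene_symbols = set(gene_study.values.index.astype(str))
            if omap is not None:
                universe |= {
                    omap.mapping[g] for g in gene_symbols if g in omap.mapping
                }
            else:
                universe |= gene_symbols

            sig_study = _signature_study(gene_study, degs_src, omap)
            sig = signature.characteristic_direction(
                sig_study, gamma=config.gamma, gene_cap=config.gene_cap
            )
            ranked = screening.score_library(
                sig,
                lib,
                mode=config.mode,
                top_n=config.top_n,
                min_overlap=config.min_overlap,
            )
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

        io_formats.write_table(table, out / f"{sc.name}_dge.tsv", index_label="gene")
        signature.write_signature(sig, out / f"{sc.name}_signature.tsv")
        io_formats.write_ranked_list(ranked, out / f"{sc.name}_ranked.tsv")

        ranked_lists.append(ranked)
        deg_sets.append(degs)
        manifest["studies"][sc.name] = {
            "probes_in": len(study.values),
            "genes_after_collapse": len(gene_study.values),
            "degs": len(degs_src),
            "degs_after_ortholog_map": len(degs),
            "drugs_scored": len(ranked),
            "drugs_skipped": ranked.attrs.get("skipped", 0),
        }

    try:
        consensus = screening.borda_merge(ranked_lists, base_score=config.base_score)
        io_formats.write_table(consensus, out / "consensus.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'borda merge' failed: {exc}") from exc

    try:
        union = preprocess.merge_deg_sets(deg_sets)
        graph = network.build_graph(set(union), edges)
        cent = network.centrality(graph)
        io_formats.write_table(cent, out / "centrality.tsv", index_label="gene")
        query = set(union) & universe
        enrich = network.overrepresentation(query, gene_sets, universe)
        io_formats.write_table(enrich, out / "enrichment.tsv", index_label="set")
    except Exception as exc:
        raise RuntimeError(f"stage 'network analysis' failed: {exc}") from exc

    manifest["deg_union_size"] = len(union)
    manifest["deg_union_ambiguous"] = sum(
        1 for s in union.values() if s == dge.AMBIGUOUS
    )
    manifest["consensus_size"] = len(consensus)
    manifest["top_drug"] = str(consensus["drug_id"].iloc[0]) if len(consensus) else None
    manifest["network_nodes"] = graph.number_of_nodes()
    manifest["network_edges"] = graph.number_of_edges()

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


# ---------------------------------------------------------------------------
# synthetic input bundles
# ---------------------------------------------------------------------------


@dataclass
class BundleSpec:
    """Shape of a complete synthetic input bundle.

    Five studies share one planted DEG pattern (so one true disease
    direction exists) but differ in noise realisations, mirroring
    independent expression studies of the same condition.  The library
    plants one reverser of that direction; the PPI graph plants hubs on
    DEG genes; one gene set is enriched in the DEG genes.
    """

    n_studies: int = 5
    study: synthetic.StudySpec = field(default_factory=synthetic.StudySpec)
    library: synthetic.LibrarySpec = field(default_factory=synthetic.LibrarySpec)
    ppi_edge_prob: float = 0.02
    ppi_n_hubs: int = 2
    ppi_hub_boost: int = 20
    n_gene_sets: int = 20
    gene_set_size: int = 25
    seed: int = 0


def write_bundle(spec: BundleSpec, out_dir: str | Path) -> dict:
    """Write the full synthetic fixture bundle and a ground-truth manifest.

    Per-stage seeds fan out deterministically from ``spec.seed`` so the
    bundle is bit-reproducible and stages stay independently debuggable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base_seed = int(spec.seed)

    study_names = []
    truth = None
    for i in range(spec.n_studies):
        sspec = synthetic.StudySpec(
            **{
                **spec.study.__dict__,
                "seed": (base_seed * 1000 + i) % (2**31),
            }
        )
        study, ann, truth = synthetic.simulate_study(sspec)
        name = f"study{i + 1}"
        io_formats.write_expression(study, out / f"{name}_expression.tsv")
        io_formats.write_sample_groups(study.groups, out / f"{name}_groups.tsv")
        io_formats.write_probe_annotation(ann, out / f"{name}_annotation.tsv")
        study_names.append(name)

    direction = synthetic.planted_direction(spec.study)
    lspec = synthetic.LibrarySpec(
        **{**spec.library.__dict__, "seed": (base_seed * 1000 + 500) % (2**31)}
    )
    lib, lib_truth = synthetic.simulate_library(lspec, direction)
    io_formats.write_signature_library(lib, out / "library.tsv")

    genes = synthetic.gene_names(spec.study.n_genes)
    edges, ppi_truth = synthetic.simulate_ppi(
        n_nodes=spec.study.n_genes,
        edge_prob=spec.ppi_edge_prob,
        n_hubs=spec.ppi_n_hubs,
        hub_degree_boost=spec.ppi_hub_boost,
        seed=(base_seed * 1000 + 600) % (2**31),
        node_names=genes,
    )
    io_formats.write_edges(edges, out / "edges.tsv")

    deg_genes = sorted(truth.deg_signs)
    overlap = min(spec.gene_set_size, max(1, len(deg_genes) // 2))
    sets, set_truth = synthetic.simulate_gene_sets(
        universe=genes,
        n_sets=spec.n_gene_sets,
        set_size=spec.gene_set_size,
        planted_query_overlap=overlap,
        seed=(base_seed * 1000 + 700) % (2**31),
        query=deg_genes,
    )
    io_formats.write_gmt(sets, out / "gene_sets.gmt")

    # identity ortholog map over the gene universe (single-species bundle)
    io_formats.write_ortholog_map(
        io_formats.OrthologMap(mapping={g: g for g in genes}),
        out / "orthologs.tsv",
    )

    ground_truth = {
        "deg_signs": truth.deg_signs,
        "reversers": lib_truth.reversers,
        "mimickers": lib_truth.mimickers,
        "hubs": ppi_truth.hubs,
        "enriched_sets": set_truth.enriched_sets,
    }
    (out / "ground_truth.json").write_text(
        json.dumps(ground_truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    config = {
        "studies": [
            {
                "name": name,
                "expression": f"{name}_expression.tsv",
                "groups": f"{name}_groups.tsv",
                "annotation": f"{name}_annotation.tsv",
            }
            for name in study_names
        ],
        "library": "library.tsv",
        "edges": "edges.tsv",
        "gene_sets": "gene_sets.gmt",
        "output_dir": "results",
        "seed": base_seed,
    }
    (out / "config.yaml").write_text(
        yaml.safe_dump(config, sort_keys=True), encoding="utf-8"
    )
    return ground_truth
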