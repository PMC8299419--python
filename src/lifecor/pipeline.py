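"""End-to-end orchestration: simulate/ingest -> select -> score -> collapse
-> overlap/rank -> enrich, from a single YAML/JSON config.

Output layout mirrors the per-tissue/global split of the analysis::

    <out_dir>/
      <dataset_id>/   selection.tsv, scores.tsv, gene_scores.tsv,
                      top_features.tsv, enrichment.tsv (if gene sets given)
      global/         overlap_XX.tsv, shared_gene_ranking.tsv,
                      presence_histogram.tsv, sign_patterns.tsv, report.json
      figures/        tidy per-figure tables
      truth/          planted ground truth (synthetic runs only)

All randomness flows from the single config seed; rerunning the same
config and seed reproduces every TSV byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as lio
from .cross_dataset import (
    overlap_matrix,
    presence_histogram,
    shared_gene_ranking,
    sign_pattern_matrix,
)
from .enrich import DEFAULT_MAX_SET_SIZE, DEFAULT_MIN_SET_SIZE, run_enrichment
from .scoring import (
    DEFAULT_MIN_OBS,
    threshold_tag,
    collapse_features_to_genes,
    pass_column,
    score_dataset,
    top_k_features,
)
from .selection import match_strains, select_extremes
from .simulate import SyntheticConfig, generate_panel, identity_gene_map

logger = logging.getLogger(__name__)


@dataclass
class DatasetSpec:
    """Descriptor of one input expression matrix."""

    path: str
    dataset_id: str
    tissue: str = ""
    sex: str = "combined"
    omics_type: str = "transcript"
    normalization: str = "zscore"
    selection_mode: str = "tails"
    tail_size: int | None = None
    transpose: bool = False


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    Either ``synthetic`` (a SyntheticConfig) or ``datasets`` + a lifespan
    table path must be given.  ``thresholds`` are the vetting cutoffs;
    the first (lowest) one drives the shared-gene ranking and enrichment.
    """

    out_dir: str
    seed: int = 0
    thresholds: tuple = (0.4, 0.7)
    tail_size: int = 4
    min_obs: int = DEFAULT_MIN_OBS
    sex_policy: str = "match_sex"
    synthetic: SyntheticConfig | None = None
    datasets: list = field(default_factory=list)
    lifespan_table: str | None = None
    gene_map: str | None = None
    gene_sets: str | None = None
    selection_mode_overrides: dict = field(default_factory=dict)
    min_set_size: int = DEFAULT_MIN_SET_SIZE
    max_set_size: int = DEFAULT_MAX_SET_SIZE
    top_n_shared: int = 10
    top_k_per_dataset: int = 6
    log_level: str = "info"

    def __post_init__(self):
        self.thresholds = tuple(sorted(float(t) for t in self.thresholds))
        if not self.thresholds:
            raise ValueError("at least one threshold required")
        for t in self.thresholds:
            if not 0.0 < t <= 1.0:
                raise ValueError(f"threshold {t} outside (0, 1]")
        if self.synthetic is None and not self.datasets:
            raise ValueError("config needs either synthetic: or datasets:")
        if self.datasets and self.lifespan_table is None:
            raise ValueError("file-based datasets require lifespan_table")

    @property
    def ranking_threshold(self) -> float:
        return self.thresholds[0]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        synth = d.pop("synthetic", None)
        if synth is not None:
            synth.setdefault("seed", d.get("seed", 0))
            synth = SyntheticConfig.from_dict(synth)
        datasets = [DatasetSpec(**spec) for spec in d.pop("datasets", [])]
        if "thresholds" in d:
            d["thresholds"] = tuple(d["thresholds"])
        return cls(synthetic=synth, datasets=datasets, **d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset covers JSON
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)


def _setup_logging(out_dir: Path, level: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    root = logging.getLogger("lifecor")
    for h in list(root.handlers):  # avoid piling up handlers across runs
        if isinstance(h, logging.FileHandler):
            root.removeHandler(h)
            h.close()
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root.setLevel(getattr(logging, level.upper(), logging.INFO))
    root.addHandler(handler)
    logging.basicConfig(level=logging.WARNING)  # stderr echo for warnings


def _load_inputs(config: RunConfig):
    """Return (datasets, lifespans, gene_map, truth)."""
    if config.synthetic is not None:
        datasets, lifespans, truth = generate_panel(config.synthetic)
        gene_map = identity_gene_map(datasets)
        return datasets, lifespans, gene_map, truth
    lifespans = lio.read_lifespan_table(config.lifespan_table)
    datasets = []
    for spec in config.datasets:
        datasets.append(
            lio.read_expression_matrix(
                spec.path,
                dataset_id=spec.dataset_id,
                tissue=spec.tissue,
                sex=spec.sex,
                omics_type=spec.omics_type,
                normalization=spec.normalization,
                transpose=spec.transpose,
            )
        )
    gene_map = (
        lio.read_feature_gene_map(config.gene_map) if config.gene_map else None
    )
    return datasets, lifespans, gene_map, None


def _selection_mode_for(config: RunConfig, dataset_id: str) -> tuple:
    """(mode, tail_size) for a dataset, honouring per-dataset overrides."""
    mode = config.selection_mode_overrides.get(dataset_id)
    tail_size = config.tail_size
    for spec in config.datasets:
        if spec.dataset_id == dataset_id:
            if mode is None:
                mode = spec.selection_mode
            if spec.tail_size is not None:
                tail_size = spec.tail_size
    return mode or "tails", tail_size


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the machine-readable run report."""
    out_dir = Path(config.out_dir)
    _setup_logging(out_dir, config.log_level)
    logger.info("lifecor %s starting run (seed=%d)", __version__, config.seed)

    try:
        datasets, lifespans, gene_map, truth = _load_inputs(config)
    except Exception as exc:
        raise RuntimeError(f"input stage failed: {exc}") from exc

    collection = lio.read_gmt(config.gene_sets) if config.gene_sets else None

    report_datasets = {}
    plans = {}
    feature_tables = {}
    gene_tables = []
    for dataset in datasets:
        ds_dir = out_dir / dataset.dataset_id
        ds_dir.mkdir(parents=True, exist_ok=True)
        mode, tail_size = _selection_mode_for(config, dataset.dataset_id)
        try:
            matched = match_strains(dataset, lifespans, config.sex_policy)
            plan = select_extremes(matched, mode=mode, tail_size=tail_size)
            scores = score_dataset(
                dataset, plan, thresholds=config.thresholds,
                min_obs=config.min_obs,
            )
        except Exception as exc:
            raise RuntimeError(
                f"selection/scoring stage failed for {dataset.dataset_id}: {exc}"
            ) from exc
        plans[dataset.dataset_id] = plan
        feature_tables[dataset.dataset_id] = scores
        plan.to_frame().to_csv(ds_dir / "selection.tsv", sep="\t", index=False)
        lio.write_score_table(scores, ds_dir / "scores.tsv")
        top = top_k_features(scores, config.top_k_per_dataset)
        top_out = top.copy()
        top_out.index.name = f"{scores.key}_id"
        top_out.to_csv(ds_dir / "top_features.tsv", sep="\t", na_rep="")

        if gene_map is not None:
            gtable = collapse_features_to_genes(scores, gene_map)
        else:
            gtable = scores  # features already gene-keyed
        gene_tables.append(gtable)
        lio.write_score_table(gtable, ds_dir / "gene_scores.tsv")

        report_datasets[dataset.dataset_id] = {
            "tissue": dataset.tissue,
            "sex": dataset.sex,
            "omics_type": dataset.omics_type,
            "selection_mode": plan.mode,
            "n_strains_in_matrix": len(dataset.strain_ids),
            "n_matched": int(len(matched)),
            "n_selected": int(len(plan.selected_strains)),
            "n_features": len(dataset.feature_ids),
            "n_scored_defined": int(scores.scores["r"].notna().sum()),
            "n_undefined": scores.n_undefined(),
            "hits": {
                str(t): int(len(scores.hits(t))) for t in config.thresholds
            },
            "n_genes": int(len(gtable.scores)),
        }

    global_dir = out_dir / "global"
    global_dir.mkdir(parents=True, exist_ok=True)

    overlaps = {}
    if len(gene_tables) >= 2:
        for t in config.thresholds:
            om = overlap_matrix(gene_tables, t)
            overlaps[t] = om
            om.to_long_frame().to_csv(
                global_dir / f"overlap_{threshold_tag(t)}.tsv",
                sep="\t", index=False, na_rep="",
            )
    else:
        logger.info("single dataset: overlap stage skipped")

    ranking = shared_gene_ranking(gene_tables, config.ranking_threshold)
    ranking.to_csv(
        global_dir / "shared_gene_ranking.tsv", sep="\t", na_rep=""
    )
    hist = presence_histogram(ranking, n_datasets=len(gene_tables))
    hist.to_frame().to_csv(global_dir / "presence_histogram.tsv", sep="\t")
    patterns = sign_pattern_matrix(ranking, config.top_n_shared)
    patterns.to_csv(global_dir / "sign_patterns.tsv", sep="\t", na_rep="")

    enrichment_summary = {}
    if collection is not None:
        for gtable in gene_tables:
            hits = gtable.hits(config.ranking_threshold)
            universe = gtable.measured() or collection.all_members()
            result = run_enrichment(
                hits, universe, collection,
                min_set_size=config.min_set_size,
                max_set_size=config.max_set_size,
            )
            result.to_csv(
                out_dir / gtable.dataset_id / "enrichment.tsv",
                sep="\t", index=False,
            )
            enrichment_summary[gtable.dataset_id] = {
                "n_sets_tested": int(len(result)),
                "n_fdr_below_0.05": int((result["fdr"] < 0.05).sum())
                if len(result) else 0,
            }

    if truth is not None:
        truth_dir = out_dir / "truth"
        truth_dir.mkdir(parents=True, exist_ok=True)
        truth.planted.to_csv(truth_dir / "planted.tsv", sep="\t", index=False)
        lio.write_lifespan_table(truth.lifespans, truth_dir / "lifespans.tsv")

    report = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": list(config.thresholds),
        "ranking_threshold": config.ranking_threshold,
        "overlap_definition": "jaccard_over_shared_measured_universe",
        "datasets": report_datasets,
        "global": {
            "n_datasets": len(gene_tables),
            "n_genes_ranked": int(len(ranking)),
            "presence_histogram": {
                str(k): int(v) for k, v in hist.items()
            },
            "top_shared_genes": list(ranking.head(config.top_n_shared).index),
            "overlap_computed": bool(overlaps),
            "enrichment": enrichment_summary,
        },
    }
    if truth is not None:
        report["truth"] = {
            "universal_genes": truth.universal_genes(len(gene_tables)),
            "n_planted_entries": int(len(truth.planted)),
        }

    make_figure_tables(
        out_dir, datasets, plans, feature_tables, overlaps, ranking,
        config,
    )

    with open(global_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %s", out_dir)
    return report


def make_figure_tables(
    out_dir, datasets, plans, feature_tables, overlaps, ranking, config
) -> None:
    """Write one tidy TSV per figure analogue.

    * ranked strain lifespans with tail flags (lifespan-ranking panels)
    * top-k features per dataset (top-genes panels)
    * pairwise overlap fractions (overlap diagrams)
    * signed correlation pattern of the top shared genes (heatmap layer)
    * expression-vs-lifespan points for the top shared genes (scatter layer)
    """
    fig_dir = Path(out_dir) / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)

    frames = []
    for ds_id, plan in plans.items():
        f = plan.to_frame()
        f.insert(0, "dataset_id", ds_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(
        fig_dir / "figure1_lifespan_ranking.tsv", sep="\t", index=False
    )

    tops = []
    for ds_id, table in feature_tables.items():
        top = top_k_features(table, config.top_k_per_dataset).copy()
        top.insert(0, "dataset_id", ds_id)
        top.insert(1, "feature_id", top.index)
        top.insert(2, "figure_rank", range(1, len(top) + 1))
        tops.append(top.reset_index(drop=True))
    pd.concat(tops, ignore_index=True).to_csv(
        fig_dir / "figure2_top_features.tsv", sep="\t", index=False, na_rep=""
    )

    if overlaps:
        longs = []
        for t, om in overlaps.items():
            lf = om.to_long_frame()
            lf.insert(0, "threshold", t)
            longs.append(lf)
        pd.concat(longs, ignore_index=True).to_csv(
            fig_dir / "figure4_overlap.tsv", sep="\t", index=False, na_rep=""
        )

    sign_pattern_matrix(ranking, config.top_n_shared).to_csv(
        fig_dir / "figure5_sign_patterns.tsv", sep="\t", na_rep=""
    )

    # expression vs lifespan for the top shared genes, selected strains only
    top_genes = list(ranking.head(2).index)
    points = []
    by_id = {d.dataset_id: d for d in datasets}
    for ds_id, table in feature_tables.items():
        dataset = by_id[ds_id].to_zscore()
        plan = plans[ds_id]
        life = plan.lifespans
        for gene in top_genes:
            if gene not in dataset.values.index:
                continue
            expr = dataset.values.loc[gene, plan.selected_strains]
            for strain in plan.selected_strains:
                points.append(
                    {
                        "gene_id": gene,
                        "dataset_id": ds_id,
                        "strain_id": strain,
                        "expression_z": expr[strain],
                        "median_lifespan_days": life[strain],
                    }
                )
    pd.DataFrame(
        points,
        columns=["gene_id", "dataset_id", "strain_id",
                 "expression_z", "median_lifespan_days"],
    ).to_csv(fig_dir / "figure6_top_gene_points.tsv", sep="\t",
             index=False, na_rep="")
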