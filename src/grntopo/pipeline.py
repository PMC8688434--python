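"""End-to-end orchestration: network → features → bins → sets → trees → report.

:func:`run_pipeline` wires the stages in the order the analysis prescribes:
parse (or generate) the network, compute the 13 topological attributes, check
scale-freeness, σ-discretize per network, expand gene roles into instances,
hold out a balanced 10% test set, undersample the training targets into
balanced sets, select attributes (CFS best-first, supported by an
information-gain ranking, on the whole instance matrix), induce one
gain-ratio tree per balanced set with cross-validation, average them into the
consensus model, classify the held-out set, repeat with label-shuffled sets
as the random control, compare the two score lists (Shapiro–Wilk, then
Mann–Whitney), and extract the majority-rule consensus tree with per-leaf
gene assignments.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import dataset_builder, discretize, feature_selection, grn_io, topology, tree_learning
from .synthetic_data import SyntheticGRNConfig, generate_synthetic_grn

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; all randomness flows from explicit seeds."""

    input_path: str | None = None  # edge-list TSV; None → synthetic
    synthetic: SyntheticGRNConfig = field(default_factory=SyntheticGRNConfig)
    evidence_filter: list[str] | None = None
    split_fraction: float = 0.10
    seed: int = 0
    min_leaf: int = 20
    cv_folds: int = 10
    consensus_majority: float = 0.5
    max_stale: int = 5
    pagerank_damping: float = 0.85
    sd_ddof: int = 1
    select_on: str = "all"  # "all" = training+test matrix; "train" = training only
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = SyntheticGRNConfig(**d["synthetic"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class PipelineResult:
    config: PipelineConfig
    network: grn_io.GeneNetwork
    features: pd.DataFrame
    power_law: topology.PowerLawFit
    schemes: dict
    instances: pd.DataFrame
    split: dataset_builder.SplitResult
    balanced_sets: dataset_builder.BalancedSetCollection
    ig_ranking: list
    cfs: feature_selection.SubsetSelection
    selected_attributes: list[str]
    trees: list
    cv_reports: list
    consensus: tree_learning.ConsensusModel
    test_report: tree_learning.PerformanceReport
    random_test_report: tree_learning.PerformanceReport
    normal_tree_ccis: list[float]
    random_tree_ccis: list[float]
    comparison: dict
    consensus_tree: tree_learning.ConsensusTree | None
    leaf_assignments: list
    manifest: dict


def _load_network(config: PipelineConfig) -> grn_io.GeneNetwork:
    if config.input_path is not None:
        return grn_io.load_network(
            config.input_path, filter_spec=config.evidence_filter
        )
    return generate_synthetic_grn(config.synthetic)


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    config = config or PipelineConfig()
    seed = config.seed

    network = _load_network(config)
    logger.info("network: %s", network.summary())

    features = topology.compute_node_features(
        network, pagerank_damping=config.pagerank_damping
    )
    power_law = topology.fit_power_law(network)

    schemes = discretize.fit_bin_schemes(
        features, topology.FEATURE_COLUMNS, ddof=config.sd_ddof
    )
    usable = features[[c for c in topology.FEATURE_COLUMNS if c in schemes] + ["role"]]
    binned = discretize.discretize_table(usable, schemes)
    instances = dataset_builder.make_instances(binned)

    split = dataset_builder.split_train_test(
        instances, fraction=config.split_fraction, seed=seed + 1
    )

    selection_matrix = instances if config.select_on == "all" else split.training
    ig_ranking = feature_selection.rank_information_gain(selection_matrix)
    cfs = feature_selection.select_cfs_subset(selection_matrix, max_stale=config.max_stale)
    selected = sorted(cfs.selected)
    if not selected:
        selected = [s.attribute for s in ig_ranking[:3]]
    logger.info("selected attributes: %s", selected)

    cols = selected + [dataset_builder.CLASS_COLUMN]
    training = split.training[cols]
    test = split.test[cols]

    balanced = dataset_builder.make_balanced_sets(training, seed=seed + 2)

    trees, cv_reports = [], []
    for i, s in enumerate(balanced):
        tree = tree_learning.induce_tree(s, min_leaf=config.min_leaf)
        trees.append(tree)
        min_class = min(s[dataset_builder.CLASS_COLUMN].value_counts())
        folds = min(config.cv_folds, int(min_class))
        if folds >= 2:
            cv_reports.append(
                tree_learning.cross_validate(
                    s, folds=folds, seed=seed + 4, min_leaf=config.min_leaf
                )
            )
        else:
            cv_reports.append(None)

    consensus = tree_learning.build_consensus(trees)
    _, test_report = tree_learning.classify_instances(consensus, test)

    random_trees, random_cv_reports = [], []
    for i, s in enumerate(balanced):
        shuffled = dataset_builder.randomize_labels(s, seed=seed + 100 + i)
        random_trees.append(tree_learning.induce_tree(shuffled, min_leaf=config.min_leaf))
        min_class = min(shuffled[dataset_builder.CLASS_COLUMN].value_counts())
        folds = min(config.cv_folds, int(min_class))
        random_cv_reports.append(
            tree_learning.cross_validate(
                shuffled, folds=folds, seed=seed + 4, min_leaf=config.min_leaf
            )
            if folds >= 2
            else None
        )
    random_consensus = tree_learning.build_consensus(random_trees)
    _, random_test_report = tree_learning.classify_instances(random_consensus, test)

    normal_ccis = [
        tree_learning.classify_instances(t, test)[1].cci for t in trees
    ]
    random_ccis = [
        tree_learning.classify_instances(t, test)[1].cci for t in random_trees
    ]
    # normal-vs-random comparison on per-set cross-validated CCI (the training
    # performances), which has far more resolution than the small test set
    normal_cv_ccis = [r.cci for r in cv_reports if r is not None]
    random_cv_ccis = [r.cci for r in random_cv_reports if r is not None]
    comparison = tree_learning.compare_performance(normal_cv_ccis, random_cv_ccis)

    consensus_tree = None
    leaf_assignments = []
    if len(trees) >= 2:
        try:
            consensus_tree = tree_learning.extract_consensus_tree(
                trees, majority=config.consensus_majority
            )
            leaf_assignments = tree_learning.assign_to_leaves(
                consensus_tree, instances[cols]
            )
        except tree_learning.ConsensusError as exc:
            logger.warning("consensus tree not extracted: %s", exc)

    manifest = {
        "config": config.to_dict(),
        "network": network.summary(),
        "power_law": {
            "gamma": power_law.gamma,
            "r_squared": power_law.r_squared,
            "n_degree_classes": power_law.n_degree_classes,
        },
        "n_instances": len(instances),
        "n_training": len(split.training),
        "n_test": len(split.test),
        "balanced_set_sizes": balanced.manifest["set_sizes"],
        "selected_attributes": selected,
        "info_gain_ranking": [
            {"attribute": s.attribute, "info_gain": s.info_gain, "rank": s.rank}
            for s in ig_ranking
        ],
        "cfs_merit": cfs.merit,
        "tree_leaf_counts": [t.n_leaves for t in trees],
        "cv_mean_cci": [r.cci if r else None for r in cv_reports],
        "test_report": test_report.to_dict(),
        "random_test_report": random_test_report.to_dict(),
        "normal_tree_test_cci": normal_ccis,
        "random_tree_test_cci": random_ccis,
        "comparison": comparison,
        "consensus_tree_leaves": consensus_tree.n_leaves if consensus_tree else None,
    }

    result = PipelineResult(
        config=config,
        network=network,
        features=features,
        power_law=power_law,
        schemes=schemes,
        instances=instances,
        split=split,
        balanced_sets=balanced,
        ig_ranking=ig_ranking,
        cfs=cfs,
        selected_attributes=selected,
        trees=trees,
        cv_reports=cv_reports,
        consensus=consensus,
        test_report=test_report,
        random_test_report=random_test_report,
        normal_tree_ccis=normal_ccis,
        random_tree_ccis=random_ccis,
        comparison=comparison,
        consensus_tree=consensus_tree,
        leaf_assignments=leaf_assignments,
        manifest=manifest,
    )
    if config.output_dir:
        _write_outputs(result, Path(config.output_dir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    grn_io.write_edge_list(result.network, outdir / "edges.tsv")
    grn_io.write_roles(result.network, outdir / "roles.tsv")
    topology.write_feature_table(result.features, outdir / "features.csv")
    discretize.write_schemes_json(result.schemes, outdir / "bin_schemes.json")
    result.instances.to_csv(outdir / "instances.csv", na_rep="")
    for i, s in enumerate(result.balanced_sets):
        s.to_csv(outdir / f"balanced_set_{i:02d}.csv", na_rep="")
    tree_learning.save_model_json(result.consensus, outdir / "consensus_model.json")
    if result.consensus_tree is not None:
        tree_learning.save_model_json(
            result.consensus_tree, outdir / "consensus_tree.json"
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
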