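"""End-to-end orchestration: classification -> enrichment -> profiles.

``run_pipeline`` wires the analysis stages together on a result directory,
writing a manifest (config, seeds, package version, input hashes) next to
every stage's outputs so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .copsets import (
    OrthoClusterCollection,
    SpeciesTree,
    classify_collection,
    representation_summary,
    set_members,
    write_summary_tsv,
)
from .errors import BstkError
from .fixtures import (
    EnrichmentFixtureSpec,
    ExpressionFixtureSpec,
    make_enrichment_fixture,
    make_expression_fixture,
    make_reference_cluster_fixture,
)
from .msgea import run_msgea, write_results_tsv
from .profiles import characteristic_profiles, normalize_expression, pooled_profiles


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the synthetic end-to-end analysis into *out_dir*.

    Stages: generate (or load) the cluster collection, classify it and
    summarise representation; run the pooled enrichment test on a planted
    study set; normalize a planted expression matrix and extract
    characteristic profile clusters.  Every stage failure aborts with the
    stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": [],
        "inputs": {},
    }

    # -- stage: cluster classification ------------------------------------
    try:
        if "groups" in config.paths:
            from .copsets import parse_groups

            collection = parse_groups(config.paths["groups"])
            tree = SpeciesTree(
                newick=config.newick, clades=config.clades, exempt=config.exempt_species
            )
            manifest["inputs"]["groups"] = _sha256(Path(config.paths["groups"]))
        else:
            collection, tree = make_reference_cluster_fixture(seed=config.seed)
        membership = classify_collection(
            collection, tree, model_species=config.model_species
        )
        for set_name in ("C", "M", "L", "A", "Lprime"):
            table, mean_rep = representation_summary(
                collection, membership, set_name, exempt=config.exempt_species
            )
            write_summary_tsv(table, mean_rep, out / f"summary_{set_name}.tsv")
        sizes = {
            s: len(set_members(membership, s)) for s in ("C", "M", "L", "A", "Lprime")
        }
        (out / "set_sizes.json").write_text(json.dumps(sizes, indent=1))
        manifest["stages"].append("classify")
    except BstkError as exc:
        raise BstkError(f"stage 'classify' failed: {exc}") from exc

    # -- stage: enrichment --------------------------------------------------
    try:
        annotations, study_sets, graph = make_enrichment_fixture(
            EnrichmentFixtureSpec(), seed=config.seed
        )
        table, crosstab = run_msgea(
            study_sets,
            annotations,
            graph=graph,
            alpha=config.alpha,
            method="enumerate",
            seed=config.seed,
        )
        write_results_tsv(table, out / "msgea.tsv")
        (out / "msgea_crosstab.json").write_text(json.dumps(crosstab, indent=1))
        manifest["stages"].append("msgea")
    except BstkError as exc:
        raise BstkError(f"stage 'msgea' failed: {exc}") from exc

    # -- stage: expression profiles ----------------------------------------
    try:
        matrix, meta, key = make_expression_fixture(
            ExpressionFixtureSpec(), seed=config.seed
        )
        norm = normalize_expression(matrix)
        norm.to_csv(out / "normalized_expression.tsv", sep="\t")
        target = [g for genes in key.values() for g in genes]
        clusters = characteristic_profiles(
            target,
            norm,
            alpha=config.alpha,
            thresholds=config.correlation_thresholds,
            cut_height=config.cluster_cut_height,
        )
        pd.Series(clusters.assignments, name="cluster").to_csv(
            out / "profile_clusters.tsv", sep="\t", index_label="gene"
        )
        clusters.mean_profiles.to_csv(out / "profile_cluster_means.tsv", sep="\t")
        pooled = pooled_profiles({"planted": target}, norm)
        pooled.to_csv(out / "pooled_profiles.tsv", sep="\t")
        manifest["stages"].append("profiles")
    except BstkError as exc:
        raise BstkError(f"stage 'profiles' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
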