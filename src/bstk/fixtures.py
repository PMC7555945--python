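"""Seedable synthetic-data generators for every analysis stage.

Three generators cover the toolkit's inputs:

* :func:`make_reference_cluster_fixture` — an ortholog-cluster collection of
  125 single-loss ("set L") clusters whose per-species presence counts
  equal the published reference marginals of the bilaterian COP analysis,
  with the C. elegans-missing (31) and D. melanogaster-missing (9) clusters
  disjoint, so that the L ∩ M intersection contains exactly 85 clusters.
  The marginals force the structure: six clusters lose the
  (A. gambiae, D. melanogaster) cherry as a single loss event, three lose
  D. melanogaster alone, and the remaining absences are single-leaf losses.
* :func:`make_enrichment_fixture` — per-species genome annotations with one
  GO term per gene and study sets drawn with a configurable
  over-representation fold for a planted term (fold 1 = exact null, since a
  uniform draw makes the per-term study count hypergeometric).
* :func:`make_expression_fixture` — a log-normal expression matrix with
  exchangeable background profiles and planted profile shapes (rising,
  falling, peaked) plus Gaussian noise on the log10 scale.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .copsets import (
    DEFAULT_CLADES,
    DEFAULT_NEWICK,
    OrthoClusterCollection,
    SpeciesTree,
)
from .errors import ValidationError
from .ontology import AnnotationSet, OntologyGraph
from .profiles import ExpressionMatrix, StageMetadata

import networkx as nx

# ---------------------------------------------------------------------------
# Published reference marginals of the COP set classification (printed
# summary tables of the original bilaterian analysis), used as generator
# constraints and as worked-example inputs.  Keys: set name -> (number of
# clusters, per-species number of clusters containing the species).
# ---------------------------------------------------------------------------
REFERENCE_SET_MARGINALS: dict[str, tuple[int, dict[str, int]]] = {
    "C": (
        506,
        {
            "drerio": 415,
            "spurpuratus": 254,
            "mmusculus": 349,
            "agambiae": 300,
            "dmelanogaster": 379,
            "celegans": 278,
            "cteleta": 376,
            "hrobusta": 325,
            "lgigantea": 337,
            "acalifornica": 7,
        },
    ),
    "M": (
        160,
        {
            "drerio": 160,
            "spurpuratus": 89,
            "mmusculus": 134,
            "agambiae": 120,
            "dmelanogaster": 160,
            "celegans": 160,
            "cteleta": 116,
            "hrobusta": 109,
            "lgigantea": 117,
            "acalifornica": 4,
        },
    ),
    "L": (
        125,
        {
            "drerio": 125,
            "spurpuratus": 103,
            "mmusculus": 121,
            "agambiae": 112,
            "dmelanogaster": 116,
            "celegans": 94,
            "cteleta": 119,
            "hrobusta": 115,
            "lgigantea": 121,
            "acalifornica": 2,
        },
    ),
    "Lprime": (
        85,
        {
            "drerio": 85,
            "spurpuratus": 63,
            "mmusculus": 81,
            "agambiae": 78,
            "dmelanogaster": 85,
            "celegans": 85,
            "cteleta": 79,
            "hrobusta": 75,
            "lgigantea": 81,
            "acalifornica": 2,
        },
    ),
    "A": (
        34,
        {
            "drerio": 34,
            "spurpuratus": 34,
            "mmusculus": 34,
            "agambiae": 34,
            "dmelanogaster": 34,
            "celegans": 34,
            "cteleta": 34,
            "hrobusta": 34,
            "lgigantea": 34,
            "acalifornica": 1,
        },
    ),
}

#: per-species (number of proteins, number of clusters containing the
#: species) over the union of the C and M sets (519 clusters) — the inputs
#: of the average-paralog (proteins per COP) arithmetic.
REFERENCE_PARALOG_COUNTS: dict[str, tuple[int, int]] = {
    "drerio": (1190, 428),
    "spurpuratus": (652, 260),
    "mmusculus": (867, 357),
    "agambiae": (380, 307),
    "dmelanogaster": (989, 392),
    "celegans": (602, 291),
    "acalifornica": (15, 7),
    "cteleta": (642, 376),
    "hrobusta": (420, 325),
    "lgigantea": (492, 337),
}


# -- cluster-collection fixture ---------------------------------------------

# Set-L absence structure forced by the reference marginals: single-leaf
# losses, one cherry loss shared by A. gambiae + D. melanogaster, and
# complete clusters.
_SINGLE_LOSSES: dict[str, int] = {
    "spurpuratus": 22,
    "mmusculus": 4,
    "agambiae": 7,
    "dmelanogaster": 3,
    "celegans": 31,
    "cteleta": 6,
    "hrobusta": 10,
    "lgigantea": 4,
}
_CHERRY_LOSSES = 6  # clusters missing both agambiae and dmelanogaster
_N_CLUSTERS = 125
_N_ACAL = 2  # clusters containing the exempt A. californica


def make_reference_cluster_fixture(
    seed: int = 0,
) -> tuple[OrthoClusterCollection, SpeciesTree]:
    """Cluster collection reproducing the published set-L presence marginals.

    Classifying the output yields 125 set-L clusters, 85 in L ∩ M, and the
    per-species cluster counts of the reference tables; the seed only
    shuffles which cluster ids receive which absence pattern.
    """
    rng = np.random.default_rng(seed)
    nonexempt = [sp for sp in DEFAULT_CLADES if sp != "acalifornica"]
    patterns: list[set[str]] = []
    for sp, count in _SINGLE_LOSSES.items():
        for _ in range(count):
            patterns.append(set(nonexempt) - {sp})
    for _ in range(_CHERRY_LOSSES):
        patterns.append(set(nonexempt) - {"agambiae", "dmelanogaster"})
    n_complete = _N_CLUSTERS - len(patterns)
    complete_idx: list[int] = []
    for _ in range(n_complete):
        complete_idx.append(len(patterns))
        patterns.append(set(nonexempt))
    # the exempt species joins complete clusters so that its presence count
    # survives every set filter
    for i in complete_idx[:_N_ACAL]:
        patterns[i] = patterns[i] | {"acalifornica"}
    order = rng.permutation(len(patterns))
    clusters: dict[str, dict[str, list[str]]] = {}
    for rank, idx in enumerate(order, start=1):
        cid = f"c{rank:03d}"
        clusters[cid] = {sp: [f"{sp}_p{rank:03d}"] for sp in sorted(patterns[idx])}
    tree = SpeciesTree(newick=DEFAULT_NEWICK, clades=DEFAULT_CLADES)
    return OrthoClusterCollection(clusters), tree


# -- enrichment fixture ------------------------------------------------------


@dataclass
class EnrichmentFixtureSpec:
    """Conditions of the planted-enrichment experiment.

    ``fold`` multiplies the sampling odds of planted-term genes when study
    sets are drawn; fold 1 reproduces the exact null.
    """

    species: Sequence[str] = ("drerio", "dmelanogaster", "celegans")
    genome_size: int = 1000
    n_terms: int = 40
    study_size: int = 50
    planted_term: str = "GO:T001"
    fold: float = 1.0
    fold_by_species: Mapping[str, float] | None = None

    def species_fold(self, sp: str) -> float:
        if self.fold_by_species is not None and sp in self.fold_by_species:
            return float(self.fold_by_species[sp])
        return float(self.fold)


def _term_ids(n_terms: int) -> list[str]:
    return [f"GO:T{i + 1:03d}" for i in range(n_terms)]


def make_enrichment_fixture(
    spec: EnrichmentFixtureSpec, seed: int = 0
) -> tuple[dict[str, AnnotationSet], dict[str, list[str]], OntologyGraph]:
    """Genome annotations, study sets and a flat ontology with planted signal.

    Every genome gene carries exactly one term (terms equally frequent), so
    under fold 1 each per-term study count is hypergeometric with the
    genome margins — the pooled test's null holds exactly.  With fold > 1
    the study set is drawn with sampling odds multiplied by the fold for
    planted-term genes (a noncentral-hypergeometric alternative).
    """
    if spec.fold <= 0:
        raise ValidationError("fold must be positive")
    terms = _term_ids(spec.n_terms)
    if spec.planted_term not in terms:
        raise ValidationError(f"planted term {spec.planted_term} not among terms")
    rng = np.random.default_rng(seed)
    annotations: dict[str, AnnotationSet] = {}
    study_sets: dict[str, list[str]] = {}
    for sp in spec.species:
        genes = [f"{sp}_g{i + 1:05d}" for i in range(spec.genome_size)]
        gene_terms = {
            gene: {terms[i % spec.n_terms]} for i, gene in enumerate(genes)
        }
        annotations[sp] = AnnotationSet(species=sp, annotations=gene_terms)
        fold = spec.species_fold(sp)
        n_planted_expected = (
            spec.study_size
            * fold
            * sum(1 for g in genes if spec.planted_term in gene_terms[g])
            / spec.genome_size
        )
        if n_planted_expected > spec.study_size:
            raise ValidationError(
                f"infeasible fold for {sp}: expected planted count "
                f"{n_planted_expected:.1f} exceeds study size {spec.study_size}"
            )
        if spec.study_size == 0:
            study_sets[sp] = []
            continue
        weights = np.array(
            [fold if spec.planted_term in gene_terms[g] else 1.0 for g in genes]
        )
        weights = weights / weights.sum()
        chosen = rng.choice(
            genes, size=spec.study_size, replace=False, p=weights
        )
        study_sets[sp] = sorted(chosen)
    graph = _flat_ontology(terms)
    return annotations, study_sets, graph


def _flat_ontology(terms: Sequence[str]) -> OntologyGraph:
    g = nx.DiGraph()
    root = "GO:T000"
    g.add_node(root, name="root", namespace="default")
    for t in terms:
        g.add_node(t, name=t.lower(), namespace="default")
        g.add_edge(t, root, relation="is_a")
    return OntologyGraph(g)


# -- expression fixture ------------------------------------------------------

_SHAPES = ("rising", "falling", "peaked")


@dataclass
class ExpressionFixtureSpec:
    """Conditions of the planted-profile expression experiment.

    Background genes have exchangeable standard-normal log10 profiles;
    planted genes follow a shape template of unit amplitude plus Gaussian
    log10 noise of ``noise_sd``.
    """

    n_background: int = 200
    n_stages: int = 10
    planted: Mapping[str, int] = field(
        default_factory=lambda: {"rising": 10, "falling": 10}
    )
    noise_sd: float = 0.25
    species: str = "drerio"

    def __post_init__(self):
        unknown = set(self.planted) - set(_SHAPES)
        if unknown:
            raise ValidationError(f"unknown planted shapes: {sorted(unknown)}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.n_stages < 2:
            raise ValidationError("need at least 2 stages")


def _shape_template(shape: str, n_stages: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n_stages)
    if shape == "rising":
        return 2.0 * t - 1.0
    if shape == "falling":
        return 1.0 - 2.0 * t
    if shape == "peaked":
        # mid-development peak, the hallmark of the phylotypic period
        return np.exp(-(((t - 0.5) / 0.18) ** 2)) * 2.0 - 1.0
    raise ValidationError(f"unknown shape {shape!r}")


def make_expression_fixture(
    spec: ExpressionFixtureSpec, seed: int = 0
) -> tuple[ExpressionMatrix, StageMetadata, dict[str, list[str]]]:
    """Expression matrix with planted profile shapes and a planted-set key."""
    rng = np.random.default_rng(seed)
    stages = [f"s{i + 1:02d}" for i in range(spec.n_stages)]
    rows: dict[str, np.ndarray] = {}
    key: dict[str, list[str]] = {}
    for shape in sorted(spec.planted):
        count = spec.planted[shape]
        template = _shape_template(shape, spec.n_stages)
        genes = []
        for i in range(count):
            gene = f"{spec.species}_{shape}{i + 1:03d}"
            rows[gene] = template + rng.normal(0.0, spec.noise_sd, spec.n_stages)
            genes.append(gene)
        key[shape] = genes
    for i in range(spec.n_background):
        gene = f"{spec.species}_bg{i + 1:05d}"
        rows[gene] = rng.normal(0.0, 1.0, spec.n_stages)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=stages)
    matrix = ExpressionMatrix(np.power(10.0, values))
    # phases split evenly across the stage axis
    n = spec.n_stages
    bounds = [0, max(1, n // 4), max(2, n // 2), max(3, 3 * n // 4), n]
    phases = []
    from .profiles import PHASES

    for i in range(4):
        phases.extend([PHASES[i]] * (bounds[i + 1] - bounds[i]))
    meta = StageMetadata(
        pd.DataFrame(
            {
                "stage": stages,
                "order": range(1, n + 1),
                "phase": phases[:n],
                "landmark": [""] * n,
                "excluded": [False] * n,
            }
        )
    )
    return matrix, meta, key
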