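"""Ortholog-cluster set classification and homology pre-filtering.

Clusters of orthologous proteins (COPs) are classified into four nested sets
by how widely they are shared across the bilaterian species sample:

* **C** — at least one representative from each of the three major clades
  (Deuterostomia, Ecdysozoa, Lophotrochozoa);
* **M** — representatives from all model organisms
  (D. rerio, D. melanogaster, C. elegans);
* **L** — clade coverage as in C, and the presence/absence pattern across
  species is explained by at most one loss event on the species tree
  (Dollo parsimony: a single gain at the root, losses pruning whole
  subtrees);
* **A** — all species present (no loss), except possibly species in the
  exempt set (by default A. californica, whose annotation quality does not
  support requiring its presence);
* **L'** = L ∩ M, the working set for the functional analyses.

The module also implements the two homology-search post-processing rules:
discarding queries with a significant hit (E-value below threshold) to any
non-bilaterian subject, and keeping the k best hits per taxon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .errors import ParseError, ValidationError

#: canonical short tags for the nine non-exempt bilaterian species plus the
#: exempt A. californica, and their clades
DEFAULT_CLADES = {
    "drerio": "Deuterostomia",
    "spurpuratus": "Deuterostomia",
    "mmusculus": "Deuterostomia",
    "agambiae": "Ecdysozoa",
    "dmelanogaster": "Ecdysozoa",
    "celegans": "Ecdysozoa",
    "cteleta": "Lophotrochozoa",
    "hrobusta": "Lophotrochozoa",
    "lgigantea": "Lophotrochozoa",
    "acalifornica": "Lophotrochozoa",
}

DEFAULT_MODELS = frozenset({"drerio", "dmelanogaster", "celegans"})
DEFAULT_EXEMPT = frozenset({"acalifornica"})

#: default species-tree topology used by the synthetic fixtures
DEFAULT_NEWICK = (
    "((((drerio,mmusculus),spurpuratus),"
    "((agambiae,dmelanogaster),celegans)),"
    "((cteleta,hrobusta),(lgigantea,acalifornica)));"
)

BLAST_COLUMNS = [
    "query",
    "subject",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


# -- cluster collection -----------------------------------------------------


class OrthoClusterCollection:
    """Mapping cluster id -> species -> member protein ids."""

    def __init__(self, clusters: Mapping[str, Mapping[str, Sequence[str]]]):
        self.clusters: dict[str, dict[str, list[str]]] = {}
        for cid, by_species in clusters.items():
            entry: dict[str, list[str]] = {}
            for sp, prots in by_species.items():
                prots = list(prots)
                if not prots:
                    raise ValidationError(
                        f"cluster {cid}: species {sp} listed with no proteins"
                    )
                entry[sp] = prots
            self.clusters[cid] = entry

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def __getitem__(self, cid: str) -> dict[str, list[str]]:
        return self.clusters[cid]

    def species_universe(self) -> set[str]:
        out: set[str] = set()
        for by_species in self.clusters.values():
            out |= set(by_species)
        return out

    def present_species(self, cid: str) -> set[str]:
        return set(self.clusters[cid])


def parse_groups(
    path: str | Path, species: Iterable[str] | None = None
) -> OrthoClusterCollection:
    """Parse an OrthoMCL-style groups file: ``cluster_id: sp|prot sp|prot ...``.

    Duplicate protein ids within a cluster are dropped with a warning.  If
    *species* is given, an unknown species tag raises a parse error naming it.
    """
    known = set(species) if species is not None else None
    clusters: dict[str, dict[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ParseError(f"{path}:{lineno}: missing 'cluster_id:' prefix")
            cid, _, members = line.partition(":")
            cid = cid.strip()
            entry: dict[str, list[str]] = {}
            seen: set[tuple[str, str]] = set()
            for token in members.split():
                if "|" not in token:
                    raise ParseError(
                        f"{path}:{lineno}: member {token!r} lacks a 'species|' tag"
                    )
                sp, _, prot = token.partition("|")
                if known is not None and sp not in known:
                    raise ParseError(
                        f"{path}:{lineno}: unknown species tag {sp!r}"
                    )
                if (sp, prot) in seen:
                    warnings.warn(
                        f"{path}:{lineno}: duplicate member {token!r} dropped",
                        stacklevel=2,
                    )
                    continue
                seen.add((sp, prot))
                entry.setdefault(sp, []).append(prot)
            clusters[cid] = entry
    return OrthoClusterCollection(clusters)


def write_groups(collection: OrthoClusterCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(collection.clusters):
            members = [
                f"{sp}|{prot}"
                for sp in sorted(collection.clusters[cid])
                for prot in collection.clusters[cid][sp]
            ]
            fh.write(f"{cid}: {' '.join(members)}\n")


# -- species tree -----------------------------------------------------------


class SpeciesTree:
    """Rooted species tree with clade labels and an exempt-species set."""

    def __init__(
        self,
        newick: str = DEFAULT_NEWICK,
        clades: Mapping[str, str] | None = None,
        exempt: Iterable[str] = DEFAULT_EXEMPT,
    ):
        self.tree = dendropy.Tree.get(data=newick, schema="newick")
        self.clades = dict(clades if clades is not None else DEFAULT_CLADES)
        self.exempt = frozenset(exempt)
        self._leaves = frozenset(
            leaf.taxon.label.replace(" ", "_")
            for leaf in self.tree.leaf_node_iter()
        )

    @property
    def leaves(self) -> frozenset[str]:
        return self._leaves

    @property
    def nonexempt_leaves(self) -> frozenset[str]:
        return self._leaves - self.exempt

    def clade_of(self, species: str) -> str:
        try:
            return self.clades[species]
        except KeyError:
            raise ValidationError(f"species {species!r} has no clade label") from None

    @classmethod
    def from_files(
        cls,
        newick_path: str | Path,
        clades_path: str | Path | None = None,
        exempt: Iterable[str] = DEFAULT_EXEMPT,
    ) -> "SpeciesTree":
        newick = Path(newick_path).read_text()
        clades = None
        if clades_path is not None:
            clades = {}
            with open(clades_path) as fh:
                for lineno, line in enumerate(fh, start=1):
                    line = line.strip()
                    if not line or line.startswith("#"):
                        continue
                    parts = line.split("\t")
                    if len(parts) < 2:
                        raise ParseError(
                            f"{clades_path}:{lineno}: expected species<TAB>clade"
                        )
                    clades[parts[0]] = parts[1]
        return cls(newick=newick, clades=clades, exempt=exempt)


def min_loss_events(present_species: Iterable[str], tree: SpeciesTree) -> int:
    """Dollo minimum number of losses explaining a presence pattern.

    Assumes a single gain at the root; a loss event removes one whole
    subtree.  Exempt species are pruned before counting, so their absence is
    never charged as a loss.  The minimum equals the number of maximal
    subtrees whose (non-exempt) leaves are all absent.
    """
    present = set(present_species) - tree.exempt
    leaves = tree.nonexempt_leaves
    unknown = present - leaves
    if unknown:
        raise ValidationError(f"species not in tree: {sorted(unknown)}")
    if not present:
        raise ValidationError("presence pattern empty after removing exempt species")
    absent = leaves - present

    losses = 0
    # two-pass: cache subtree states, then count maximal absent subtrees
    _absent_cache: dict[int, bool] = {}
    _exempt_only_cache: dict[int, bool] = {}

    def count(node, parent_absent: bool) -> None:
        nonlocal losses
        node_absent = _absent_cache[id(node)]
        if node_absent and not parent_absent and not _exempt_only_cache[id(node)]:
            losses += 1
        for c in node.child_nodes():
            count(c, node_absent)

    def fill(node) -> tuple[bool, bool]:
        """Return (all leaves absent-or-exempt, all leaves exempt)."""
        if node.is_leaf():
            label = node.taxon.label.replace(" ", "_")
            is_exempt = label in tree.exempt
            state = is_exempt or label in absent
            _absent_cache[id(node)] = state
            _exempt_only_cache[id(node)] = is_exempt
            return state, is_exempt
        states = [fill(c) for c in node.child_nodes()]
        state = all(s for s, _ in states)
        exempt_only = all(e for _, e in states)
        _absent_cache[id(node)] = state
        _exempt_only_cache[id(node)] = exempt_only
        return state, exempt_only

    fill(tree.tree.seed_node)
    count(tree.tree.seed_node, False)
    return losses


# -- classification ---------------------------------------------------------


@dataclass
class SetMembership:
    """Set flags for one cluster; A ⊆ L ⊆ C and L' = L ∩ M by construction."""

    in_C: bool
    in_M: bool
    in_L: bool
    in_A: bool
    min_losses: int
    in_Lprime: bool = field(init=False)

    def __post_init__(self):
        self.in_Lprime = self.in_L and self.in_M


def classify_cluster(
    present_species: Iterable[str],
    tree: SpeciesTree,
    model_species: Iterable[str] = DEFAULT_MODELS,
) -> SetMembership:
    """Classify one cluster's species-presence pattern into the A/L/M/C sets."""
    present = set(present_species)
    models = set(model_species)
    clades_present = {tree.clade_of(sp) for sp in present if sp in tree.clades}
    in_C = {"Deuterostomia", "Ecdysozoa", "Lophotrochozoa"} <= clades_present
    in_M = models <= present
    nonexempt_present = present & tree.nonexempt_leaves
    if nonexempt_present:
        losses = min_loss_events(present, tree)
    else:
        losses = len(tree.nonexempt_leaves)  # degenerate: everything lost
    in_L = in_C and losses <= 1
    in_A = nonexempt_present == tree.nonexempt_leaves
    return SetMembership(in_C=in_C, in_M=in_M, in_L=in_L, in_A=in_A, min_losses=losses)


def classify_collection(
    collection: OrthoClusterCollection,
    tree: SpeciesTree,
    model_species: Iterable[str] = DEFAULT_MODELS,
) -> dict[str, SetMembership]:
    return {
        cid: classify_cluster(collection.present_species(cid), tree, model_species)
        for cid in collection
    }


SET_FLAGS = {"C": "in_C", "M": "in_M", "L": "in_L", "A": "in_A", "Lprime": "in_Lprime"}


def set_members(membership: Mapping[str, SetMembership], set_name: str) -> list[str]:
    flag = SET_FLAGS[set_name]
    return sorted(cid for cid, m in membership.items() if getattr(m, flag))


# -- summaries --------------------------------------------------------------


def representation_from_counts(
    cluster_counts: Mapping[str, int],
    set_size: int,
    exempt: Iterable[str] = DEFAULT_EXEMPT,
) -> tuple[pd.Series, float]:
    """Per-species representation ratios and their non-exempt mean.

    ``cluster_counts`` maps species -> #C, the number of clusters of the set
    containing at least one protein of that species.  The ratio is
    ``100 * #C / set_size`` to one decimal; the mean representation is the
    mean of the non-exempt species' (unrounded) ratios, to one decimal.
    """
    if set_size <= 0:
        return pd.Series(dtype=float), float("nan")
    exempt = set(exempt)
    raw = pd.Series(
        {sp: 100.0 * c / set_size for sp, c in cluster_counts.items()}
    ).sort_index()
    mean = float(raw[[sp for sp in raw.index if sp not in exempt]].mean())
    return raw.round(1), round(mean, 1)


def representation_summary(
    collection: OrthoClusterCollection,
    membership: Mapping[str, SetMembership],
    set_name: str,
    exempt: Iterable[str] = DEFAULT_EXEMPT,
) -> tuple[pd.DataFrame, float]:
    """Per-species (#P, #C, ratio, proteins-per-COP) table for one set.

    #P counts proteins of the species in the set's clusters, #C counts
    clusters containing the species; ratio is the percentage of the set's
    clusters containing the species.  Returns the table and the mean
    representation across non-exempt species.
    """
    members = set_members(membership, set_name)
    size = len(members)
    species = sorted(collection.species_universe())
    n_prot = {sp: 0 for sp in species}
    n_clust = {sp: 0 for sp in species}
    for cid in members:
        for sp, prots in collection[cid].items():
            n_prot[sp] += len(prots)
            n_clust[sp] += 1
    ratios, mean = representation_from_counts(n_clust, size, exempt)
    rows = []
    for sp in species:
        ratio = float(ratios.get(sp, float("nan"))) if size else float("nan")
        ppc = round(n_prot[sp] / n_clust[sp], 2) if n_clust[sp] else float("nan")
        rows.append(
            {
                "species": sp,
                "n_proteins": n_prot[sp],
                "n_clusters": n_clust[sp],
                "ratio": ratio,
                "proteins_per_cop": ppc,
            }
        )
    table = pd.DataFrame(rows).set_index("species")
    return table, mean


def proteins_per_cop(n_proteins: int, n_clusters: int) -> float:
    """Average paralog count: proteins divided by clusters, two decimals."""
    if n_clusters <= 0:
        raise ValidationError("cluster count must be positive")
    return round(n_proteins / n_clusters, 2)


# -- BLAST-table operations --------------------------------------------------


def read_blast_table(source: str | Path | StringIO) -> pd.DataFrame:
    """Read a 12-column tabular homology-hit table (BLAST outfmt 6)."""
    df = pd.read_csv(
        source, sep="\t", names=BLAST_COLUMNS, comment="#", header=None
    )
    if df["evalue"].isna().any():
        bad = df.index[df["evalue"].isna()][0]
        raise ParseError(f"unparseable E-value in hit-table row {bad}")
    return df


def blast_filter(
    hits: pd.DataFrame,
    nonbilaterian_subjects: Iterable[str],
    evalue_threshold: float = 1e-5,
) -> list[str]:
    """Retain queries with no significant hit to a non-bilaterian subject.

    A query is discarded iff it has at least one hit to a subject in
    ``nonbilaterian_subjects`` with E-value strictly below the threshold.
    Returns the retained query ids, sorted (the result is independent of
    row order and idempotent).
    """
    subjects = set(nonbilaterian_subjects)
    sig = hits["subject"].isin(subjects) & (hits["evalue"] < evalue_threshold)
    discarded = set(hits.loc[sig, "query"])
    return sorted(set(hits["query"]) - discarded)


def select_top_hits(
    hits: pd.DataFrame, per_taxon_k: int = 10, taxon_col: str = "taxon"
) -> pd.DataFrame:
    """Keep the k best hits per (query, taxon).

    Ranking is by ascending E-value, then descending bit-score, then
    lexicographic subject id, making the output deterministic under ties.
    """
    if taxon_col not in hits.columns:
        raise ValidationError(f"hit table lacks a {taxon_col!r} column")
    ranked = hits.sort_values(
        by=["evalue", "bitscore", "subject"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return (
        ranked.groupby(["query", taxon_col], sort=True, group_keys=False)
        .head(per_taxon_k)
        .reset_index(drop=True)
    )


def write_summary_tsv(table: pd.DataFrame, mean_representation: float, path) -> None:
    with open(path, "w") as fh:
        table.to_csv(fh, sep="\t")
        fh.write(f"# mean_representation\t{mean_representation}\n")
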