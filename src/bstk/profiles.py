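"""Developmental expression profiles: normalization, profile enrichment,
characteristic-profile extraction and pooled set profiles.

Expression values (genes x ordered developmental stages) are normalized per
stage by dividing by the genome-wide mean on the raw scale, applied as
``log10(x) - log10(mean_genes(x))``, so a value of 0 means "at the stage
average" and 1 means tenfold above it.

A profile of a target-set gene is *characteristic* when similar profiles are
significantly more abundant among the target set than in the rest of the
genome.  Two test families quantify this per gene, both on Pearson
correlations between normalized profiles:

(i)  a one-sided Mann–Whitney test comparing the gene's correlations with
     the other target-set genes against its correlations with the genomic
     background;
(ii) one-sided Fisher exact tests on the 2x2 table (highly correlated
     yes/no x target-set yes/no) at correlation thresholds 0.5, 0.7 and 0.9.

Each family is Benjamini–Hochberg adjusted separately.  Significant profiles
are clustered by complete linkage on the distance 1 - r and the dendrogram is
cut at height 0.75, which guarantees a maximum within-cluster distance of
0.75.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .msgea import bh_adjust

DEFAULT_THRESHOLDS = (0.5, 0.7, 0.9)
DEFAULT_CUT_HEIGHT = 0.75

PHASES = ("Blastoderm", "Gastrulation and Organogenesis", "Hatching to Larva", "Adult")


@dataclass
class StageMetadata:
    """Ordered developmental stages with phase labels and landmarks.

    ``excluded`` flags stages to drop before analysis (e.g. adult stages of
    a species whose adult data are not used).
    """

    table: pd.DataFrame  # columns: stage, order, phase, landmark, excluded

    def __post_init__(self):
        required = {"stage", "order", "phase"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"stage metadata lacks columns: {sorted(missing)}")
        if "landmark" not in self.table.columns:
            self.table["landmark"] = ""
        if "excluded" not in self.table.columns:
            self.table["excluded"] = False
        self.table = self.table.sort_values("order").reset_index(drop=True)

    @property
    def stages(self) -> list[str]:
        return list(self.table.loc[~self.table["excluded"].astype(bool), "stage"])

    @classmethod
    def read_tsv(cls, path: str | Path) -> "StageMetadata":
        df = pd.read_csv(path, sep="\t")
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


class ExpressionMatrix:
    """Raw non-negative expression, genes x ordered stages."""

    def __init__(self, values: pd.DataFrame, stages: StageMetadata | None = None):
        if values.shape[1] < 2:
            raise ValidationError("expression matrix needs at least 2 stages")
        if (values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")
        if stages is not None:
            keep = [s for s in stages.stages if s in values.columns]
            values = values[keep]
        self.values = values
        self.stages = stages

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @classmethod
    def read_tsv(
        cls, path: str | Path, stages: StageMetadata | None = None
    ) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, stages)

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")


def normalize_expression(
    matrix: ExpressionMatrix | pd.DataFrame, pseudocount: float | None = None
) -> pd.DataFrame:
    """Per-stage log-mean normalization: log10(x+pc) - log10(mean(x+pc)).

    With ``pseudocount=None`` a pseudocount is applied only if zeros are
    present, defaulting to the smallest positive value in the matrix.  With
    an explicit ``pseudocount=0`` a zero raises, since log10(0) is undefined.
    """
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    x = df.to_numpy(dtype=float)
    if pseudocount is None:
        pseudocount = float(x[x > 0].min()) if (x == 0).any() else 0.0
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    if pseudocount == 0 and (x == 0).any():
        raise ValidationError(
            "zero expression with pseudocount=0; set a positive pseudocount"
        )
    shifted = x + pseudocount
    norm = np.log10(shifted) - np.log10(shifted.mean(axis=0, keepdims=True))
    return pd.DataFrame(norm, index=df.index, columns=df.columns)


# -- profile enrichment ------------------------------------------------------


@dataclass
class ProfileTestResult:
    gene: str
    mw_p: float
    fisher_p: dict[float, float]
    mw_q: float = np.nan
    fisher_q: dict[float, float] = field(default_factory=dict)
    characteristic: bool = False


def _correlation_matrix(norm: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Gene-gene Pearson correlations; constant-profile genes are dropped."""
    sd = norm.std(axis=1, ddof=0)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(
            f"{len(constant)} constant profile(s) excluded from correlation tests",
            stacklevel=3,
        )
    kept = norm.drop(index=constant)
    corr = pd.DataFrame(
        np.corrcoef(kept.to_numpy()), index=kept.index, columns=kept.index
    )
    return corr, constant


def profile_tests(
    target_set: Iterable[str],
    norm: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    alpha: float = 0.05,
    exclude_target_from_background: bool = True,
) -> pd.DataFrame:
    """Per-gene profile-enrichment tests for every gene of the target set.

    For each target gene the Mann–Whitney test (alternative: greater)
    compares its correlations with the other target genes to its
    correlations with the background genes; the Fisher tests ask, at each
    threshold, whether highly correlated profiles are enriched among target
    genes.  BH adjustment is applied per family; a gene is flagged
    ``characteristic`` when any family is significant at *alpha*.
    """
    target = [g for g in target_set if g in norm.index]
    if len(target) < 3:
        raise ValidationError("target set must contain at least 3 genes with profiles")
    corr, constant = _correlation_matrix(norm)
    target = [g for g in target if g in corr.index]
    background = [g for g in corr.index if g not in set(target)]
    if not background:
        raise ValidationError("no background genes left after removing the target set")

    rows = []
    for gene in target:
        r_target = corr.loc[gene, [g for g in target if g != gene]].to_numpy()
        if exclude_target_from_background:
            r_bg = corr.loc[gene, background].to_numpy()
        else:
            r_bg = corr.loc[gene, [g for g in corr.index if g != gene]].to_numpy()
        mw_p = float(
            stats.mannwhitneyu(r_target, r_bg, alternative="greater").pvalue
        )
        fisher = {}
        for thr in thresholds:
            a = int((r_target > thr).sum())
            b = len(r_target) - a
            c = int((r_bg > thr).sum())
            d = len(r_bg) - c
            fisher[thr] = float(
                stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            )
        rows.append({"gene": gene, "mw_p": mw_p, **{f"fisher_p_{t}": p for t, p in fisher.items()}})
    table = pd.DataFrame(rows).set_index("gene")
    table["mw_q"] = bh_adjust(table["mw_p"].to_numpy())
    sig = table["mw_q"] < alpha
    for thr in thresholds:
        table[f"fisher_q_{thr}"] = bh_adjust(table[f"fisher_p_{thr}"].to_numpy())
        sig = sig | (table[f"fisher_q_{thr}"] < alpha)
    table["characteristic"] = sig
    return table


@dataclass
class ProfileClusterSet:
    """Characteristic-profile clusters from a complete-linkage cut."""

    assignments: dict[str, int]
    mean_profiles: pd.DataFrame  # clusters x stages
    cut_height: float

    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))


def characteristic_profiles(
    target_set: Iterable[str],
    norm: pd.DataFrame,
    alpha: float = 0.05,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    cut_height: float = DEFAULT_CUT_HEIGHT,
) -> ProfileClusterSet:
    """Cluster the significant (characteristic) profiles of the target set.

    Complete-linkage clustering on distance 1 - r, cut at *cut_height*.
    Cluster mean profiles are computed after centring each member profile by
    its own mean across stages (removing overall expression level), then
    averaging stage-wise across members.
    """
    tests = profile_tests(target_set, norm, thresholds=thresholds, alpha=alpha)
    sig_genes = list(tests.index[tests["characteristic"]])
    if not sig_genes:
        return ProfileClusterSet({}, pd.DataFrame(columns=norm.columns), cut_height)
    profiles = norm.loc[sig_genes]
    if len(sig_genes) == 1:
        labels = np.array([1])
    else:
        dist = 1.0 - np.corrcoef(profiles.to_numpy())
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize round-off
        Z = linkage(squareform(dist, checks=False), method="complete")
        labels = fcluster(Z, t=cut_height, criterion="distance")
    assignments = dict(zip(sig_genes, (int(x) for x in labels)))
    centred = profiles.sub(profiles.mean(axis=1), axis=0)
    mean_profiles = centred.groupby(pd.Series(labels, index=profiles.index)).mean()
    mean_profiles.index.name = "cluster"
    return ProfileClusterSet(assignments, mean_profiles, cut_height)


def pooled_profiles(
    gene_sets: Mapping[str, Iterable[str]], norm: pd.DataFrame
) -> pd.DataFrame:
    """Per-stage mean and median normalized expression for each gene set.

    Returns a table indexed by (set, statistic) with one column per stage;
    typical sets are "AO" (all orthologs and paralogs) and "MCO" (most
    conserved orthologs only).
    """
    rows = {}
    for name, genes in gene_sets.items():
        genes = [g for g in genes if g in norm.index]
        if not genes:
            raise ValidationError(f"gene set {name!r} has no genes with profiles")
        block = norm.loc[genes]
        rows[(name, "mean")] = block.mean(axis=0)
        rows[(name, "median")] = block.median(axis=0)
    out = pd.DataFrame(rows).T
    out.index.names = ["set", "statistic"]
    return out
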