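"""Background gene-set sampling for expression comparisons.

Three background constructions are provided:

* **random** — replicate sets of the target's size drawn uniformly from the
  genome, recording the per-stage mean normalized expression of each
  replicate (the null distribution of stage means for "a set this large");
* **matched-function** — replicate sets matched to the target's GO-term
  frequency spectrum: for each term occurrence in the target set a random
  carrier of that term is drawn, the draws are pooled, and the final set of
  target size is drawn from the pool;
* **age stratification** — the genome split into "older" genes (phylostrata
  1–6, predating Bilateria) and "younger" genes (phylostrata >= 8) with the
  clade-specific candidate genes removed from both, so that target profiles
  can be compared against age-restricted backgrounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

DEFAULT_N_REPS = 100
DEFAULT_YOUNG_MIN = 8
OLD_MAX = 6


@dataclass
class BackgroundDistribution:
    """Per-stage distributions of replicate mean normalized expressions."""

    stage_means: pd.DataFrame  # replicates x stages
    replicate_sets: list[list[str]]
    mode: str
    seed: int | None

    @property
    def n_reps(self) -> int:
        return len(self.stage_means)

    def write_tsv(self, path: str | Path) -> None:
        self.stage_means.to_csv(path, sep="\t", index_label="replicate")


def _stage_means(genes: Sequence[str], norm: pd.DataFrame) -> pd.Series:
    return norm.loc[list(genes)].mean(axis=0)


def random_background(
    genome_genes: Sequence[str],
    set_size: int,
    norm: pd.DataFrame,
    n_reps: int = DEFAULT_N_REPS,
    seed: int | None = None,
) -> BackgroundDistribution:
    """Uniform random replicate sets (without replacement within a set)."""
    genome = list(genome_genes)
    if set_size > len(genome):
        raise ValidationError("set_size exceeds genome size")
    rng = np.random.default_rng(seed)
    reps: list[list[str]] = []
    means = []
    for _ in range(n_reps):
        chosen = list(rng.choice(genome, size=set_size, replace=False))
        reps.append(chosen)
        means.append(_stage_means(chosen, norm))
    return BackgroundDistribution(
        stage_means=pd.DataFrame(means).reset_index(drop=True),
        replicate_sets=reps,
        mode="random",
        seed=seed,
    )


def _term_occurrences(
    target_genes: Iterable[str], annotations: Mapping[str, set[str]]
) -> dict[str, int]:
    occ: dict[str, int] = {}
    for gene in target_genes:
        for term in annotations.get(gene, ()):  # unannotated genes contribute nothing
            occ[term] = occ.get(term, 0) + 1
    return occ


def matched_function_background(
    target_genes: Sequence[str],
    genome_annotations: Mapping[str, set[str]],
    norm: pd.DataFrame,
    n_reps: int = DEFAULT_N_REPS,
    seed: int | None = None,
    target_size: int | None = None,
    target_annotations: Mapping[str, set[str]] | None = None,
) -> BackgroundDistribution:
    """Replicate sets matched to the target's GO-frequency spectrum.

    Three steps per replicate: (1) for each term occurrence in the target
    set, draw as many random carriers of the term from the genome (without
    replacement within a term's carrier list); (2) pool the per-term draws
    (a gene may appear several times via different terms); (3) draw the
    final set of ``target_size`` distinct genes from the pool.  Terms with
    no genome carriers are dropped with a warning; if the pool runs out of
    distinct genes the set is topped up from the genome at random.
    """
    target = list(target_genes)
    if target_size is None:
        target_size = len(target)
    carriers: dict[str, list[str]] = {}
    for gene, terms in genome_annotations.items():
        for term in terms:
            carriers.setdefault(term, []).append(gene)
    for term in carriers:
        carriers[term].sort()
    if target_annotations is None:
        target_annotations = genome_annotations
    occurrences = _term_occurrences(target, target_annotations)
    usable: dict[str, int] = {}
    for term, count in sorted(occurrences.items()):
        pool = carriers.get(term)
        if not pool:
            warnings.warn(f"term {term} has no genome carriers; dropped", stacklevel=2)
            continue
        usable[term] = count
    if not usable:
        raise ValidationError("no target term has genome carriers")
    genome = sorted(genome_annotations)
    rng = np.random.default_rng(seed)
    reps: list[list[str]] = []
    means = []
    for _ in range(n_reps):
        pooled: list[str] = []
        for term, count in usable.items():
            pool = carriers[term]
            k = min(count, len(pool))
            pooled.extend(rng.choice(pool, size=k, replace=False))
        # draw distinct genes from the pooled list, respecting multiplicity
        order = rng.permutation(len(pooled))
        chosen: list[str] = []
        seen: set[str] = set()
        for idx in order:
            gene = pooled[idx]
            if gene not in seen:
                seen.add(gene)
                chosen.append(gene)
            if len(chosen) == target_size:
                break
        if len(chosen) < target_size:
            remaining = [g for g in genome if g not in seen]
            extra = rng.choice(remaining, size=target_size - len(chosen), replace=False)
            chosen.extend(extra)
        reps.append(chosen)
        means.append(_stage_means([g for g in chosen if g in norm.index], norm))
    return BackgroundDistribution(
        stage_means=pd.DataFrame(means).reset_index(drop=True),
        replicate_sets=reps,
        mode="matched_function",
        seed=seed,
    )


# -- age stratification ------------------------------------------------------


@dataclass
class PhylostratumMap:
    """Gene -> phylostratum (1 = oldest origin) for one species."""

    species: str
    strata: dict[str, int]

    def __post_init__(self):
        bad = {g: s for g, s in self.strata.items() if s < 1}
        if bad:
            raise ValidationError(f"phylostrata must be >= 1; offending: {bad}")

    @classmethod
    def read_tsv(cls, path: str | Path, species: str) -> "PhylostratumMap":
        strata: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ParseError(f"{path}:{lineno}: expected gene<TAB>stratum")
                try:
                    strata[parts[0]] = int(parts[1])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad stratum: {exc}") from exc
        return cls(species=species, strata=strata)


def age_stratify(
    strata: PhylostratumMap,
    cop_genes: Iterable[str],
    young_min: int = DEFAULT_YOUNG_MIN,
    old_max: int = OLD_MAX,
) -> tuple[set[str], set[str]]:
    """Split genes into older (strata 1..old_max) and younger (>= young_min).

    Clade-specific candidate genes (``cop_genes``) are excluded from both
    groups regardless of their stratum; genes between ``old_max`` and
    ``young_min`` (the focal clade's own stratum) fall in neither group.
    """
    cops = set(cop_genes)
    older = {
        g for g, s in strata.strata.items() if s <= old_max and g not in cops
    }
    younger = {
        g for g, s in strata.strata.items() if s >= young_min and g not in cops
    }
    return older, younger
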