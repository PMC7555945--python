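"""Most-Conserved-Ortholog (MCO) selection from per-site conservation scores.

Within each ortholog cluster and species, genes are ranked by their fraction
of strongly conserved sites — sites whose conservation score (e.g. PhastCons
posterior) strictly exceeds a cutoff, 0.99 by default.  The top-ranking gene
per species is kept as the Most Conserved Ortholog; less conserved paralogs
are discarded.  This reduces protein counts without changing cluster counts.

The fraction-of-strong-sites measure targets conservation of function (a few
highly constrained sites) rather than average sequence conservation, but the
two are highly correlated genome-wide; ``conservation_correlation`` computes
that correlation as a QC statistic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ParseError, ValidationError

DEFAULT_CUTOFF = 0.99


def fraction_conserved(scores: Sequence[float], cutoff: float = DEFAULT_CUTOFF) -> float:
    """Fraction of sites with score strictly greater than *cutoff*."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty score array")
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValidationError("conservation scores must lie in [0, 1]")
    return float((arr > cutoff).sum() / arr.size)


@dataclass
class ConservationProfile:
    """Per-site conservation scores of one gene."""

    gene: str
    species: str
    scores: np.ndarray
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        # validates range / non-emptiness
        self.fraction_strong = fraction_conserved(self.scores, self.cutoff)
        self.mean_score = float(self.scores.mean())


def select_mco(
    cluster: Mapping[str, Sequence[str]],
    profiles: Mapping[str, ConservationProfile],
) -> dict[str, str]:
    """Pick the most conserved member per species of one cluster.

    Ranking is by fraction of strongly conserved sites; ties break by higher
    mean score, then by lexicographic gene id, so the choice is independent
    of member order.  Members without a profile are excluded with a warning;
    a species with no scored member is omitted from the result.
    """
    out: dict[str, str] = {}
    for sp in sorted(cluster):
        scored = []
        for gene in cluster[sp]:
            prof = profiles.get(gene)
            if prof is None:
                warnings.warn(
                    f"no conservation profile for {gene} ({sp}); excluded",
                    stacklevel=2,
                )
                continue
            scored.append(prof)
        if not scored:
            warnings.warn(f"species {sp}: no scored members; omitted", stacklevel=2)
            continue
        best = min(scored, key=lambda p: (-p.fraction_strong, -p.mean_score, p.gene))
        out[sp] = best.gene
    return out


def conservation_correlation(
    profiles: Sequence[ConservationProfile],
) -> float:
    """Pearson r between fraction-of-strong-sites and mean score across genes.

    Returns NaN with a warning when fewer than 3 profiles are given or
    either measure has zero variance.
    """
    if len(profiles) < 3:
        warnings.warn("fewer than 3 profiles; correlation undefined", stacklevel=2)
        return float("nan")
    frac = np.array([p.fraction_strong for p in profiles])
    mean = np.array([p.mean_score for p in profiles])
    if np.ptp(frac) == 0 or np.ptp(mean) == 0:
        warnings.warn("zero variance in a conservation measure", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(frac, mean).statistic)


# -- IO ---------------------------------------------------------------------


def read_scores_tsv(
    path: str | Path, cutoff: float = DEFAULT_CUTOFF
) -> dict[str, ConservationProfile]:
    """Read ``gene_id<TAB>species<TAB>comma-separated scores`` rows."""
    out: dict[str, ConservationProfile] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated columns")
            gene, species, scores = parts
            try:
                arr = np.array([float(x) for x in scores.split(",")])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad score value: {exc}") from exc
            out[gene] = ConservationProfile(gene, species, arr, cutoff)
    return out


def read_scores_json(
    path: str | Path, cutoff: float = DEFAULT_CUTOFF
) -> dict[str, ConservationProfile]:
    """Read a JSON object ``{gene: {"species": ..., "scores": [...]}}``."""
    with open(path) as fh:
        raw = json.load(fh)
    return {
        gene: ConservationProfile(gene, rec["species"], np.asarray(rec["scores"]), cutoff)
        for gene, rec in raw.items()
    }


def write_mco_tsv(
    mco_by_cluster: Mapping[str, Mapping[str, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("cluster\tspecies\tgene\n")
        for cid in sorted(mco_by_cluster):
            for sp in sorted(mco_by_cluster[cid]):
                fh.write(f"{cid}\t{sp}\t{mco_by_cluster[cid][sp]}\n")
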