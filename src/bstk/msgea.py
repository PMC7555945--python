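"""Multi-species gene-set enrichment: the MSGEA pooled exact test.

Single-species GO enrichment (one-tailed Fisher's exact test) cannot detect a
term that is moderately, but jointly, over-represented across several
species.  MSGEA pools species: for a term *go* with study-set count
``n_go_s`` and genome count ``N_go_s`` in species *s* (with totals
``n_s = sum_go n_go_s`` and ``N_s = sum_go N_go_s``), the score is the sum of
per-species standardised enrichments

    X_go = sum_s (n_go_s - N_go_s * n_s / N_s) / sqrt(N_go_s * n_s / N_s),

where a Poisson approximation supplies the standard deviation.  Under the
null hypothesis — species evolving independently after a starlike divergence,
with no ancestral over-representation — the ``n_go_s`` are independent
hypergeometric variables with parameters ``(N_s, N_go_s, n_s)``, and the
exact p-value is the probability that the summed score reaches the observed
one:

    p_go = Prob(x >= X_go | N_go_s, n_s, N_s).

For a single species the test reduces exactly to the one-tailed Fisher exact
test, because the score is strictly increasing in the single count.  Only
over-representation (upper tail) is tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .ontology import AnnotationSet, OntologyGraph

#: score comparisons use this absolute tolerance so that joint outcomes tied
#: with the observed score are counted in the tail (preserving the Fisher
#: identity for a single species)
SCORE_TOL = 1e-12

#: default ceiling on the joint-support size for full enumeration
DEFAULT_ENUM_CEILING = 10_000_000


class CountTable:
    """Per-term, per-species study and genome counts.

    Stored as two aligned DataFrames (terms x species): ``n`` for the study
    set and ``N`` for the genome.  Column totals give ``n_s`` and ``N_s``.
    """

    def __init__(self, n: pd.DataFrame, N: pd.DataFrame):
        if not n.index.equals(N.index) or not n.columns.equals(N.columns):
            raise ValidationError("study and genome count tables must be aligned")
        if (n.to_numpy() < 0).any() or (N.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        if (n.to_numpy() > N.to_numpy()).any():
            raise ValidationError("study count exceeds genome count for some term")
        self.n = n.astype(np.int64)
        self.N = N.astype(np.int64)

    @property
    def species(self) -> list[str]:
        return list(self.n.columns)

    @property
    def terms(self) -> list[str]:
        return list(self.n.index)

    @property
    def n_totals(self) -> pd.Series:
        """n_s: total study gene–term pairs per species."""
        return self.n.sum(axis=0)

    @property
    def N_totals(self) -> pd.Series:
        """N_s: total genome gene–term pairs per species."""
        return self.N.sum(axis=0)

    def term_counts(self, term: str) -> "TermCounts":
        return TermCounts(
            species=self.species,
            n_go=self.n.loc[term].to_numpy(),
            N_go=self.N.loc[term].to_numpy(),
            n_tot=self.n_totals.to_numpy(),
            N_tot=self.N_totals.to_numpy(),
        )


@dataclass
class TermCounts:
    """Counts for one term across species (the unit the test consumes)."""

    species: Sequence[str]
    n_go: np.ndarray
    N_go: np.ndarray
    n_tot: np.ndarray
    N_tot: np.ndarray

    def informative(self) -> np.ndarray:
        """Mask of species that carry information for this term.

        A species whose genome lacks the term (``N_go_s == 0``) or whose
        study set is empty contributes nothing to score or null.
        """
        return (self.N_go > 0) & (self.n_tot > 0)


@dataclass
class EnrichmentResult:
    """Result row of the pooled test for one term."""

    term: str
    score: float
    z_by_species: dict[str, float]
    p_exact: float
    q: float = np.nan
    fisher_p: dict[str, float] = field(default_factory=dict)
    fisher_q: dict[str, float] = field(default_factory=dict)
    n_descendants: int | None = None
    level: int | None = None
    method: str = "exact"


def build_counts(
    study_sets: Mapping[str, Iterable[str]],
    annotations: Mapping[str, AnnotationSet],
    missing_gene: str = "warn",
) -> CountTable:
    """Assemble the per-term per-species count table.

    Counting is over gene–term annotation pairs: a gene with three terms
    contributes three to ``n_s``.  Terms present in a genome but absent from
    its study set are retained with a zero study count.

    ``missing_gene`` controls what happens when a study gene has no
    annotation entry: ``"warn"`` drops it with a warning, ``"error"`` raises.
    """
    if set(study_sets) - set(annotations):
        raise ValidationError(
            f"study sets name species without annotations: "
            f"{sorted(set(study_sets) - set(annotations))}"
        )
    from collections import Counter

    species = sorted(annotations)
    genome_counts: dict[str, Counter] = {}
    study_counts: dict[str, Counter] = {}
    for sp in species:
        ann = annotations[sp].annotations
        gc: Counter = Counter()
        for terms in ann.values():
            gc.update(terms)
        sc: Counter = Counter()
        for gene in study_sets.get(sp, []):
            if gene not in ann:
                if missing_gene == "error":
                    raise ValidationError(
                        f"study gene {gene} missing from {sp} annotations"
                    )
                warnings.warn(
                    f"study gene {gene} missing from {sp} annotations; dropped",
                    stacklevel=2,
                )
                continue
            sc.update(ann[gene])
        genome_counts[sp] = gc
        study_counts[sp] = sc
    index = sorted(set().union(*(genome_counts[sp] for sp in species)))
    n = pd.DataFrame(
        {sp: [study_counts[sp].get(t, 0) for t in index] for sp in species},
        index=index,
        dtype=np.int64,
    )
    N = pd.DataFrame(
        {sp: [genome_counts[sp].get(t, 0) for t in index] for sp in species},
        index=index,
        dtype=np.int64,
    )
    return CountTable(n, N)


# -- score ------------------------------------------------------------------


def _z_scores(m: np.ndarray, N_go: float, n_tot: float, N_tot: float) -> np.ndarray:
    """Standardised enrichment of count(s) *m* under the Poisson-SD scaling."""
    expect = N_go * n_tot / N_tot
    return (m - expect) / np.sqrt(expect)


def msgea_score(counts: TermCounts) -> tuple[float, dict[str, float]]:
    """Pooled enrichment score X_go and the per-species z contributions.

    Species with ``N_go_s == 0`` (term absent from that genome) contribute 0.
    Raises if no species is informative.
    """
    mask = counts.informative()
    if not mask.any():
        raise ValidationError(
            "score undefined: term absent from every species' genome/study totals"
        )
    z: dict[str, float] = {}
    total = 0.0
    for i, sp in enumerate(counts.species):
        if mask[i]:
            zi = float(
                _z_scores(
                    np.asarray([counts.n_go[i]], dtype=float),
                    counts.N_go[i],
                    counts.n_tot[i],
                    counts.N_tot[i],
                )[0]
            )
        else:
            zi = 0.0
        z[sp] = zi
        total += zi
    return total, z


# -- exact / Monte Carlo null ------------------------------------------------


def _support_and_pmf(
    N_go: int, n_tot: int, N_tot: int
) -> tuple[np.ndarray, np.ndarray]:
    """Support values and hypergeometric PMF for one species' null count."""
    lo = max(0, n_tot + N_go - N_tot)
    hi = min(n_tot, N_go)
    m = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(m, N_tot, N_go, n_tot)
    return m, pmf


def exact_null_pvalue(
    counts: TermCounts,
    observed: float | None = None,
    method: str = "enumerate",
    mc_draws: int = 100_000,
    seed: int | None = None,
    enum_ceiling: int = DEFAULT_ENUM_CEILING,
) -> float:
    """Exact (or Monte Carlo) upper-tail p-value of the pooled score.

    Enumerates the joint support of the independent per-species
    hypergeometric counts, weighting each outcome by the product of exact
    PMFs, and sums the probability of outcomes whose summed z-score reaches
    the observed score (within ``SCORE_TOL``).  Falls back is not automatic:
    ``method="montecarlo"`` must be requested when the joint support exceeds
    ``enum_ceiling``.
    """
    if observed is None:
        observed, _ = msgea_score(counts)
    mask = counts.informative()
    if not mask.any():
        raise ValidationError("p-value undefined: no informative species")
    supports: list[np.ndarray] = []
    pmfs: list[np.ndarray] = []
    zvals: list[np.ndarray] = []
    for i in np.flatnonzero(mask):
        m, pmf = _support_and_pmf(
            int(counts.N_go[i]), int(counts.n_tot[i]), int(counts.N_tot[i])
        )
        supports.append(m)
        pmfs.append(pmf)
        zvals.append(
            _z_scores(
                m.astype(float), counts.N_go[i], counts.n_tot[i], counts.N_tot[i]
            )
        )
    if method == "enumerate":
        size = int(np.prod([len(s) for s in supports], dtype=np.int64))
        if size > enum_ceiling:
            raise ValidationError(
                f"joint support size {size} exceeds enumeration ceiling "
                f"{enum_ceiling}; use method='montecarlo'"
            )
        score = np.zeros(1)
        prob = np.ones(1)
        for z, pmf in zip(zvals, pmfs):
            score = (score[:, None] + z[None, :]).ravel()
            prob = (prob[:, None] * pmf[None, :]).ravel()
        p = float(prob[score >= observed - SCORE_TOL].sum())
        # guard against round-off outside [0, 1]
        return min(max(p, 0.0), 1.0)
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        total = np.zeros(mc_draws)
        for i in np.flatnonzero(mask):
            N_go = int(counts.N_go[i])
            draws = rng.hypergeometric(
                ngood=N_go,
                nbad=int(counts.N_tot[i]) - N_go,
                nsample=int(counts.n_tot[i]),
                size=mc_draws,
            )
            total += _z_scores(
                draws.astype(float), counts.N_go[i], counts.n_tot[i], counts.N_tot[i]
            )
        hits = int((total >= observed - SCORE_TOL).sum())
        return (hits + 1) / (mc_draws + 1)
    raise ValueError(f"unknown method {method!r}")


def fisher_single_species(counts: TermCounts, species: str) -> float:
    """One-tailed (over-representation) Fisher exact p for one species.

    Equivalent to the hypergeometric upper tail
    ``P(m >= n_go_s)`` with parameters ``(N_s, N_go_s, n_s)``.
    """
    i = list(counts.species).index(species)
    n_go, N_go = int(counts.n_go[i]), int(counts.N_go[i])
    n_tot, N_tot = int(counts.n_tot[i]), int(counts.N_tot[i])
    if n_tot == 0 or N_go == 0:
        warnings.warn(
            f"degenerate margins for {species} (n_s={n_tot}, N_go_s={N_go}); p=1",
            stacklevel=2,
        )
        return 1.0
    return float(stats.hypergeom.sf(n_go - 1, N_tot, N_go, n_tot))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- driver -----------------------------------------------------------------


def run_msgea(
    study_sets: Mapping[str, Iterable[str]],
    annotations: Mapping[str, AnnotationSet],
    graph: OntologyGraph | None = None,
    alpha: float = 0.05,
    method: str = "enumerate",
    mc_draws: int = 100_000,
    seed: int | None = None,
    enum_ceiling: int = DEFAULT_ENUM_CEILING,
    use_adjusted_for_crosstab: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the pooled test over every term occurring in any species' study set.

    Returns a result table (one row per tested term) and a cross-tabulation
    of terms significant at ``alpha`` in the pooled test only
    (``multi_only``), in at least one per-species Fisher test only
    (``single_only``), or in both (``both``).

    The pooled p-values form one BH family; each species' Fisher column is
    adjusted separately.
    """
    counts = build_counts(study_sets, annotations)
    species = counts.species
    tested = [t for t in counts.terms if counts.n.loc[t].sum() > 0]
    if not tested:
        empty = pd.DataFrame(
            columns=["term", "score", "p_exact", "q", "method"]
        ).set_index("term")
        return empty, {"multi_only": 0, "single_only": 0, "both": 0}

    rows = []
    for term in tested:
        tc = counts.term_counts(term)
        score, z = msgea_score(tc)
        p = exact_null_pvalue(
            tc,
            observed=score,
            method=method,
            mc_draws=mc_draws,
            seed=seed,
            enum_ceiling=enum_ceiling,
        )
        row: dict[str, object] = {"term": term, "score": score, "p_exact": p}
        for sp in species:
            row[f"z_{sp}"] = z[sp]
            row[f"n_{sp}"] = int(counts.n.loc[term, sp])
            row[f"N_{sp}"] = int(counts.N.loc[term, sp])
            row[f"fisher_p_{sp}"] = fisher_single_species(tc, sp)
        if graph is not None and term in graph:
            row["name"] = graph.name(term)
            row["level"] = graph.term_level(term)
            row["n_descendants"] = graph.count_descendants(term)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("term")
    table["q"] = bh_adjust(table["p_exact"].to_numpy())
    for sp in species:
        table[f"fisher_q_{sp}"] = bh_adjust(table[f"fisher_p_{sp}"].to_numpy())
    table["method"] = method

    pool_col = "q" if use_adjusted_for_crosstab else "p_exact"
    fish_cols = [
        (f"fisher_q_{sp}" if use_adjusted_for_crosstab else f"fisher_p_{sp}")
        for sp in species
    ]
    multi_sig = table[pool_col] < alpha
    single_sig = (table[fish_cols] < alpha).any(axis=1)
    crosstab = {
        "multi_only": int((multi_sig & ~single_sig).sum()),
        "single_only": int((~multi_sig & single_sig).sum()),
        "both": int((multi_sig & single_sig).sum()),
    }
    return table, crosstab


def write_results_tsv(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV with a deterministic column order."""
    table.sort_index().to_csv(path, sep="\t", index=True, index_label="term")
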