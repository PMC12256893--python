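"""Gene-set overlap and enrichment statistics.

The workhorse is :func:`fisher_exact`, which wraps the conditional
(hypergeometric) two-sided exact test and adds the odds-ratio conventions
used throughout the package: the sample OR ``ad/bc``, a Haldane–Anscombe
+0.5 continuity correction applied to every cell when any cell is zero
(flagged), and a Woolf logit 95% confidence interval.  Multiple-testing
adjustment within a panel is Bonferroni unless stated otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class EnrichmentResult:
    """A 2x2 enrichment test: counts, odds ratio, CI, exact p, adjusted p."""

    table: np.ndarray
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    p_adjusted: float = float("nan")
    family: str = ""
    family_size: int = 1
    zero_cell: bool = False
    undefined: bool = False
    label: str = ""

    def as_dict(self) -> dict:
        a, b = self.table[0]
        c, d = self.table[1]
        return {
            "label": self.label,
            "a": int(a), "b": int(b), "c": int(c), "d": int(d),
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
            "family": self.family,
            "family_size": self.family_size,
            "zero_cell": self.zero_cell,
            "undefined": self.undefined,
        }


def fisher_exact(
    table: Sequence[Sequence[int]] | np.ndarray,
    family: str = "",
    family_size: int = 1,
    label: str = "",
) -> EnrichmentResult:
    """Two-sided Fisher exact test with sample OR and Woolf logit 95% CI.

    The two-sided p-value is the conditional hypergeometric one: the sum of
    probabilities of all tables (with the observed margins) no more probable
    than the observed table.  The reported OR is the sample cross-product
    ``ad/bc``; when any cell is zero, 0.5 is added to all four cells before
    computing the OR and CI and ``zero_cell`` is flagged.  Tables with an
    all-zero row or column get ``undefined=True`` (the OR is not estimable
    even after correction in any meaningful sense).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t_int = t.astype(np.int64)
        if np.any(t_int != t) or np.any(t < 0):
            raise ValueError("table cells must be non-negative integers")
        t = t_int
    if t.sum() == 0:
        raise ValueError("all-zero table")

    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    p = min(p, 1.0)

    undefined = bool(np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0))
    zero_cell = bool(np.any(t == 0))
    cells = t.astype(float) + (0.5 if zero_cell else 0.0)
    a, b = cells[0]
    c, d = cells[1]
    odds_ratio = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_or = math.log(odds_ratio)
    ci_low = math.exp(log_or - Z_95 * se)
    ci_high = math.exp(log_or + Z_95 * se)
    return EnrichmentResult(
        table=t,
        odds_ratio=odds_ratio,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        p_adjusted=min(1.0, p * family_size),
        family=family,
        family_size=family_size,
        zero_cell=zero_cell,
        undefined=undefined,
        label=label,
    )


def bonferroni_family(results: Iterable[EnrichmentResult], family: str = "") -> list[EnrichmentResult]:
    """Assign a shared Bonferroni family to a panel of results (in place)."""
    results = list(results)
    m = len(results)
    for r in results:
        r.family = family or r.family
        r.family_size = m
        r.p_adjusted = min(1.0, r.p_value * m)
    return results


def results_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


def rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test -> (statistic, p).

    Exact enumeration when both samples have at most 50 observations and
    there are no ties; the tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        return float("nan"), float("nan")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 50 and len(y) <= 50 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# gene-set layer


def overlap_summary(gene_sets: Mapping[str, set]) -> dict:
    """Disjoint Venn regions and derived fractions for up to three gene sets.

    Returns region counts keyed by membership pattern (e.g. ``"A&B"`` for
    elements in A and B but not C), total union size, and the pairwise
    fraction ``frac_<X>_in_<Y>`` = |X ∩ Y| / |Y| for every ordered pair.
    """
    names = list(gene_sets)
    if not 1 <= len(names) <= 3:
        raise ValueError("overlap_summary supports 1-3 sets")
    sets = {n: set(gene_sets[n]) for n in names}
    universe = set().union(*sets.values())
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo), set())
            regions["&".join(combo)] = len(inside - outside)
    out = {"regions": regions, "union_size": len(universe)}
    for a, b in itertools.permutations(names, 2):
        denom = len(sets[b])
        out[f"frac_{a}_in_{b}"] = (len(sets[a] & sets[b]) / denom) if denom else float("nan")
    for a, b in itertools.combinations(names, 2):
        out[f"n_{a}&{b}"] = len(sets[a] & sets[b])
    if len(names) == 3:
        out["n_triple"] = len(set.intersection(*sets.values()))
    return out


def set_enrichment(
    target_set: set,
    attribute_set: set,
    universe: set,
    family: str = "",
    family_size: int = 1,
    label: str = "",
) -> EnrichmentResult:
    """Enrichment of an attribute in a target gene set over a stated universe.

    2x2 {in target vs not} x {has attribute vs not}.  The universe is an
    explicit input and is never inferred from the sets.
    """
    target_set, attribute_set, universe = set(target_set), set(attribute_set), set(universe)
    if not target_set <= universe:
        raise ValueError("target set is not a subset of the universe")
    if not attribute_set <= universe:
        raise ValueError("attribute set is not a subset of the universe")
    a = len(target_set & attribute_set)
    b = len(target_set - attribute_set)
    c = len(attribute_set - target_set)
    d = len(universe) - a - b - c
    return fisher_exact([[a, b], [c, d]], family=family, family_size=family_size, label=label)


def phenotype_level_distribution(
    annotations: pd.DataFrame,
    gene_set: set,
    bins: Sequence[int] = (1, 2, 3, 4),
    reference_size: int | None = None,
) -> dict:
    """Fractions of a gene set per phenotype-count level.

    Genes are binned into five levels (default 1, 2, 3, 4, >=5) on
    ``omim_phenotype_count``.  Fractions are computed against
    ``reference_size`` if given (a stated reference universe), else against
    the gene-set size.
    """
    sub = annotations[annotations["gene_id"].isin(gene_set)]
    counts = sub["omim_phenotype_count"].to_numpy()
    denom = reference_size if reference_size else max(len(sub), 1)
    levels = {}
    for b in bins:
        levels[str(b)] = int(np.sum(counts == b))
    levels[f">={bins[-1] + 1}"] = int(np.sum(counts >= bins[-1] + 1))
    fractions = {k: v / denom for k, v in levels.items()}
    return {
        "levels": levels,
        "fractions": fractions,
        "mean_count": float(counts.mean()) if len(counts) else float("nan"),
        "n": len(sub),
    }


def compare_phenotype_counts(
    annotations: pd.DataFrame, set_a: set, set_b: set
) -> dict:
    """Rank-sum comparison of per-gene phenotype counts between two sets."""
    xa = annotations.loc[annotations["gene_id"].isin(set_a), "omim_phenotype_count"]
    xb = annotations.loc[annotations["gene_id"].isin(set_b), "omim_phenotype_count"]
    stat, p = rank_sum(xa, xb)
    return {"mean_a": float(xa.mean()), "mean_b": float(xb.mean()), "statistic": stat, "p_value": p}


def composition_comparison(
    proteins: Iterable,
    set_a: set,
    set_b: set,
    alphabet: str | None = None,
) -> pd.DataFrame:
    """Per-amino-acid composition comparison between two protein sets.

    Length correction is explicit: each protein contributes its composition
    fraction count/length, and a two-sided rank-sum test compares fractions
    between the sets per amino acid.  Bonferroni adjustment across features.
    """
    from .sequence_io import AMINO_ACIDS

    alphabet = alphabet or AMINO_ACIDS
    fracs: dict[str, dict[str, float]] = {}
    groups: dict[str, str] = {}
    for rec in proteins:
        if rec.accession in set_a:
            groups[rec.accession] = "a"
        elif rec.accession in set_b:
            groups[rec.accession] = "b"
        else:
            continue
        n = rec.length
        fracs[rec.accession] = {aa: rec.sequence.count(aa) / n for aa in alphabet}
    df = pd.DataFrame.from_dict(fracs, orient="index")
    grp = pd.Series(groups)
    rows = []
    for aa in alphabet:
        va = df.loc[grp[grp == "a"].index, aa]
        vb = df.loc[grp[grp == "b"].index, aa]
        stat, p = rank_sum(va, vb)
        rows.append({
            "feature": aa,
            "mean_a": float(va.mean()),
            "mean_b": float(vb.mean()),
            "direction": "depleted_in_a" if va.mean() < vb.mean() else "enriched_in_a",
            "p_value": p,
        })
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.minimum(1.0, out["p_value"] * len(out))
    return out


def ppi_comparison(annotations: pd.DataFrame, set_a: set, set_b: set) -> dict:
    """Two-sided rank-sum on protein-protein interaction counts per set."""
    xa = annotations.loc[annotations["gene_id"].isin(set_a), "ppi_count"].dropna()
    xb = annotations.loc[annotations["gene_id"].isin(set_b), "ppi_count"].dropna()
    stat, p = rank_sum(xa, xb)
    return {
        "median_a": float(xa.median()) if len(xa) else float("nan"),
        "median_b": float(xb.median()) if len(xb) else float("nan"),
        "statistic": stat,
        "p_value": p,
    }


def containment_proportion(flags: Sequence[bool]) -> float:
    """Fraction of environments/windows containing at least one variant."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return float("nan")
    return float(flags.mean())
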