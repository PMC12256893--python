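"""Missense-variant curation: mutually exclusive classes, substitution
spectrum, codon-exchange enrichment, and per-codon CADD deleteriousness.

Variant classes follow the clinical-assertion-over-frequency precedence:
pathogenic (ClinVar pathogenic / likely pathogenic) > benign_common (ClinVar
benign / likely benign) > vus > frequency bins.  The "background"
(non-pathogenic) comparator set used in the enrichment analyses is the union
of benign_common and unlabeled common variants (allele frequency > 0.05).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .enrichment import fisher_exact
from .sequence_io import AMINO_ACIDS, enumerate_codon_snvs, translate_codon

#: default allele-frequency bins for unlabeled rare variants
RARE_AF = 1e-3
RAREST_AF = 1e-5
COMMON_AF = 0.05

PATHOGENIC_LABELS = ("pathogenic", "likely_pathogenic")
BENIGN_LABELS = ("benign", "likely_benign")

CLASSES = ("pathogenic", "benign_common", "background", "vus", "rare", "rarest")


def classify_variants(
    rows: pd.DataFrame,
    rare_af: float = RARE_AF,
    rarest_af: float = RAREST_AF,
    common_af: float = COMMON_AF,
    pool_likely: bool = True,
    clinvar_predicate=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign mutually exclusive variant classes.

    Input rows carry ``clinical_label`` (pathogenic | likely_pathogenic |
    benign | likely_benign | vus | none) and ``allele_frequency`` (NaN =
    unobserved).  One row per (accession, position, alt_aa); duplicated
    alleles carrying both a pathogenic and a benign assertion are conflicts,
    reported separately and excluded.

    Returns ``(variants, conflicts)``.  ``variants`` gains ``variant_class``
    and ``in_background_set`` (benign_common or unlabeled common) columns.
    ``clinvar_predicate`` optionally filters which clinically labeled rows
    are accepted (default: accept all).
    """
    df = rows.copy()
    if clinvar_predicate is not None:
        labeled = df["clinical_label"].isin(PATHOGENIC_LABELS + BENIGN_LABELS + ("vus",))
        keep = ~labeled | df.apply(clinvar_predicate, axis=1)
        df = df[keep]

    path_labels = PATHOGENIC_LABELS if pool_likely else ("pathogenic",)
    benign_labels = BENIGN_LABELS if pool_likely else ("benign",)

    key = ["accession", "position", "alt_aa"]
    lab = df["clinical_label"].fillna("none")
    is_path = lab.isin(path_labels)
    is_benign = lab.isin(benign_labels)
    per_allele = df.assign(_p=is_path, _b=is_benign).groupby(key)[["_p", "_b"]].any()
    conflict_keys = per_allele[per_allele["_p"] & per_allele["_b"]].index
    conflict_mask = df.set_index(key).index.isin(conflict_keys)
    conflicts = df[conflict_mask].reset_index(drop=True)
    df = df[~conflict_mask].copy()

    lab = df["clinical_label"].fillna("none")
    af = pd.to_numeric(df["allele_frequency"], errors="coerce")

    cls = pd.Series("none", index=df.index, dtype=object)
    cls[af > common_af] = "background"
    unlabeled_rare = (cls == "none") & af.notna()
    cls[unlabeled_rare & (af < rare_af)] = "rare"
    cls[unlabeled_rare & (af < rarest_af)] = "rarest"
    cls[lab == "vus"] = "vus"
    cls[lab.isin(benign_labels)] = "benign_common"
    cls[lab.isin(path_labels)] = "pathogenic"

    df["variant_class"] = cls
    df["in_background_set"] = cls.isin(["benign_common", "background"])
    # collapse duplicate rows per allele (clinical assertion wins by precedence)
    order = pd.CategoricalDtype(
        ["pathogenic", "benign_common", "vus", "background", "rare", "rarest", "none"],
        ordered=True,
    )
    df["_rank"] = df["variant_class"].astype(order)
    df = df.sort_values(key + ["_rank"]).drop_duplicates(key, keep="first")
    df = df.drop(columns="_rank").reset_index(drop=True)
    return df, conflicts


def class_counts(variants: pd.DataFrame) -> dict[str, int]:
    """Variant counts per mutually exclusive class."""
    vc = variants["variant_class"].value_counts()
    return {c: int(vc.get(c, 0)) for c in CLASSES + ("none",)}


def filter_analysis_genes(
    variants: pd.DataFrame,
    cpdaa: pd.DataFrame,
    omim_genes: set,
    accession_to_gene: dict | None = None,
) -> set:
    """Genes eligible for the residue-level analyses.

    A gene qualifies if it is in the monogenic-disease (OMIM) set, carries at
    least one CpDAA, and has at least one pathogenic and one common/benign
    (background-set) missense variant.
    """
    to_gene = accession_to_gene or {}
    def genes_of(accessions: Iterable[str]) -> set:
        return {to_gene.get(a, a) for a in accessions}

    cpd_genes = genes_of(cpdaa["accession"].unique())
    path_genes = genes_of(
        variants.loc[variants["variant_class"] == "pathogenic", "accession"].unique()
    )
    bg_genes = genes_of(variants.loc[variants["in_background_set"], "accession"].unique())
    return set(omim_genes) & cpd_genes & path_genes & bg_genes


def substitution_spectrum(
    variants: pd.DataFrame,
    class_a: str = "pathogenic",
    class_b: str = "background",
) -> pd.DataFrame:
    """Amino-acid substitution spectrum between two variant classes.

    For every ordered amino-acid pair (ref -> alt, diagonal undefined):
    counts in each class, class-normalized frequencies, and their
    difference.  Class b defaults to the background set (benign_common plus
    unlabeled common).
    """
    def sel(c):
        if c == "background":
            return variants[variants["in_background_set"]]
        return variants[variants["variant_class"] == c]

    va, vb = sel(class_a), sel(class_b)
    na, nb = len(va), len(vb)
    ca = va.groupby(["ref_aa", "alt_aa"]).size()
    cb = vb.groupby(["ref_aa", "alt_aa"]).size()
    rows = []
    for ref in AMINO_ACIDS:
        for alt in AMINO_ACIDS:
            if ref == alt:
                continue
            a = int(ca.get((ref, alt), 0))
            b = int(cb.get((ref, alt), 0))
            fa = a / na if na else 0.0
            fb = b / nb if nb else 0.0
            rows.append({
                "ref_aa": ref, "alt_aa": alt,
                "count_a": a, "count_b": b,
                "freq_a": fa, "freq_b": fb,
                "freq_diff": fa - fb,
            })
    return pd.DataFrame(rows)


def spectrum_marginals(spectrum: pd.DataFrame) -> pd.DataFrame:
    """Per-amino-acid loss (row) and gain (column) totals of a spectrum."""
    loss = spectrum.groupby("ref_aa")[["count_a", "count_b"]].sum().add_prefix("loss_")
    gain = spectrum.groupby("alt_aa")[["count_a", "count_b"]].sum().add_prefix("gain_")
    return loss.join(gain, how="outer").fillna(0).astype(int).reset_index(names="aa")


def codon_exchange_enrichment(variants: pd.DataFrame) -> pd.DataFrame:
    """Pathogenic-vs-background enrichment per single-nucleotide codon exchange.

    For each observed (ref_codon, alt_codon) pair differing at one base, a
    Fisher exact test on {this exchange vs all other exchanges} x
    {pathogenic vs background}.  Exchanges with zero total count in both
    classes get an undefined-OR flag.  Rows carry ref/alt amino acids so the
    table partitions into loss-of and gain-of panels per amino acid.
    """
    path = variants[variants["variant_class"] == "pathogenic"]
    bg = variants[variants["in_background_set"]]
    n_path, n_bg = len(path), len(bg)
    cp = path.groupby(["ref_codon", "alt_codon"]).size()
    cb = bg.groupby(["ref_codon", "alt_codon"]).size()
    exchanges = sorted(set(cp.index) | set(cb.index))
    rows = []
    for ref_c, alt_c in exchanges:
        if sum(a != b for a, b in zip(ref_c, alt_c)) != 1:
            continue
        a = int(cp.get((ref_c, alt_c), 0))
        b = int(cb.get((ref_c, alt_c), 0))
        res = fisher_exact([[a, b], [n_path - a, n_bg - b]])
        rows.append({
            "ref_codon": ref_c, "alt_codon": alt_c,
            "ref_aa": translate_codon(ref_c), "alt_aa": translate_codon(alt_c),
            "n_pathogenic": a, "n_background": b,
            "odds_ratio": res.odds_ratio,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "p_value": res.p_value,
            "undefined": a + b == 0,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = np.minimum(1.0, out["p_value"] * len(out))
    return out


def loss_gain_panels(exchange_table: pd.DataFrame, aa: str) -> dict[str, pd.DataFrame]:
    """Split a codon-exchange table into loss-of and gain-of panels for one amino acid."""
    return {
        "loss": exchange_table[exchange_table["ref_aa"] == aa].reset_index(drop=True),
        "gain": exchange_table[exchange_table["alt_aa"] == aa].reset_index(drop=True),
    }


def mean_cadd_per_codon(
    cadd: pd.DataFrame,
    deleterious_threshold: float = 25.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean CADD phred over all missense SNVs of each residue's codon.

    ``cadd`` has one row per scored substitution: accession, position,
    ref_codon, alt_codon, phred.  A residue requires a complete score set —
    one phred per missense single-nucleotide substitution of its codon —
    else it is excluded with reason ``incomplete``.  ``deleterious`` is
    strict: mean phred > 25.

    Returns ``(scores, excluded)``.
    """
    rows, excluded = [], []
    for (acc, pos, ref_c), grp in cadd.groupby(["accession", "position", "ref_codon"]):
        missense_alts = {
            s.alt_codon for s in enumerate_codon_snvs(ref_c) if s.kind == "missense"
        }
        scored = grp[grp["alt_codon"].isin(missense_alts)]
        scored = scored.drop_duplicates("alt_codon")
        if set(scored["alt_codon"]) != missense_alts:
            excluded.append({
                "accession": acc, "position": pos, "ref_codon": ref_c,
                "reason": "incomplete",
                "n_scored": len(scored), "n_required": len(missense_alts),
            })
            continue
        mean_phred = float(scored["phred"].mean())
        rows.append({
            "accession": acc, "position": int(pos), "codon": ref_c,
            "mean_phred": mean_phred,
            "n_substitutions": len(missense_alts),
            "deleterious": mean_phred > deleterious_threshold,
        })
    scores = pd.DataFrame(rows, columns=[
        "accession", "position", "codon", "mean_phred", "n_substitutions", "deleterious",
    ])
    return scores, pd.DataFrame(excluded)
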