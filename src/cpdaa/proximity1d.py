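"""Linear-sequence proximity between CysLysTyr residues and missense variants.

Distances are the absolute number of amino acids separating a missense
variant position from a reference residue position.  Direct overlaps
(distance 0) are excluded from window counts and nearest-distance
statistics; windows at protein termini are truncated, not discarded.  The
uniqueness unit for burden counts is distinct (position, alt_aa) alleles
per variant class.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, bonferroni_family, fisher_exact, rank_sum
from .sequence_io import ProteinRecord

RESIDUE_TYPES = ("C", "K", "Y")
DEFAULT_HALF_WIDTH = 6
SUPPORTED_HALF_WIDTHS = (3, 6, 15)


def enumerate_sites(
    proteins: Iterable[ProteinRecord],
    cpdaa: pd.DataFrame,
) -> pd.DataFrame:
    """Every C, K and Y position of each protein, flagged detected/undetected.

    A site is detected iff it appears in the CpDAA table.  CpDAA entries were
    already sequence-verified upstream, so a detected site at a non-CKY
    position is an internal error (asserted).
    """
    detected = set(zip(cpdaa["accession"], cpdaa["position"]))
    rows = []
    for prot in proteins:
        for i, aa in enumerate(prot.sequence, start=1):
            if aa in RESIDUE_TYPES:
                rows.append((prot.accession, i, aa, (prot.accession, i) in detected))
    sites = pd.DataFrame(rows, columns=["accession", "position", "residue_type", "detected"])
    site_keys = set(zip(sites["accession"], sites["position"]))
    stray = detected - site_keys
    known = {p.accession for p in proteins}
    stray = {(a, p) for a, p in stray if a in known}
    assert not stray, f"CpDAA at non-CysLysTyr position: {sorted(stray)[:5]}"
    return sites


def detected_fractions(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-residue-type detected/undetected counts and detected fraction."""
    g = sites.groupby("residue_type")["detected"].agg(["sum", "size"])
    g.columns = ["n_detected", "n_total"]
    g["n_detected"] = g["n_detected"].astype(int)
    g["fraction_detected"] = g["n_detected"] / g["n_total"]
    return g.reset_index()


def linear_distances(sites: pd.DataFrame, variants: pd.DataFrame) -> pd.DataFrame:
    """All (variant, site) 1D distance pairs within each protein.

    One row per pair: |variant position - site position|, with an overlap
    flag at distance 0.  Pairs never cross proteins.
    """
    merged = variants.merge(
        sites, on="accession", suffixes=("_variant", "_site")
    )
    merged["distance"] = (merged["position_variant"] - merged["position_site"]).abs()
    merged["overlap"] = merged["distance"] == 0
    cols = ["accession", "position_variant", "alt_aa", "variant_class",
            "position_site", "residue_type", "detected", "distance", "overlap"]
    return merged[[c for c in cols if c in merged.columns]]


def nearest_distance(
    anchors: pd.DataFrame,
    targets: pd.DataFrame,
    exclude_overlap: bool = True,
    anchor_col: str = "position",
    target_col: str = "position",
) -> pd.DataFrame:
    """Per-anchor minimum 1D distance to any target in the same protein.

    With ``exclude_overlap`` the anchor's own position is ineligible
    (distance 0 excluded); anchors with no eligible target are skipped.
    """
    out = []
    tgt_by_acc = {acc: np.sort(sub[target_col].unique()) for acc, sub in targets.groupby("accession")}
    for acc, sub in anchors.groupby("accession"):
        pos_t = tgt_by_acc.get(acc)
        if pos_t is None or len(pos_t) == 0:
            continue
        for _, row in sub.iterrows():
            p = row[anchor_col]
            d = np.abs(pos_t - p)
            if exclude_overlap:
                d = d[d > 0]
            if d.size == 0:
                continue
            rec = row.to_dict()
            rec["nearest_distance"] = int(d.min())
            out.append(rec)
    return pd.DataFrame(out)


def window_burden(
    sites: pd.DataFrame,
    variants: pd.DataFrame,
    half_width: int = DEFAULT_HALF_WIDTH,
    classes: Sequence[str] = ("pathogenic", "background", "vus"),
) -> pd.DataFrame:
    """Unique missense-variant counts in ±half_width windows around sites.

    Counts distinct (position, alt_aa) alleles per class at distances
    1 <= d <= half_width (direct overlaps excluded); windows are truncated
    at protein termini.  Adds boolean ``contains_<class>`` flags.
    """
    def class_mask(v: pd.DataFrame, cls: str) -> pd.Series:
        if cls == "background":
            return v["in_background_set"]
        return v["variant_class"] == cls

    burdens = sites.copy()
    for cls in classes:
        burdens[f"count_{cls}"] = 0
    by_acc = dict(tuple(variants.groupby("accession")))
    counts = {cls: np.zeros(len(sites), dtype=int) for cls in classes}
    site_acc = sites["accession"].to_numpy()
    site_pos = sites["position"].to_numpy()
    for cls in classes:
        pos_by_acc = {}
        for acc, v in by_acc.items():
            alleles = v[class_mask(v, cls)].drop_duplicates(["position", "alt_aa"])
            pos_by_acc[acc] = np.sort(alleles["position"].to_numpy())
        arr = counts[cls]
        for i in range(len(sites)):
            pv = pos_by_acc.get(site_acc[i])
            if pv is None or pv.size == 0:
                continue
            p = site_pos[i]
            lo = np.searchsorted(pv, p - half_width, side="left")
            hi = np.searchsorted(pv, p + half_width, side="right")
            n = hi - lo
            # exclude direct overlaps (d = 0)
            o_lo = np.searchsorted(pv, p, side="left")
            o_hi = np.searchsorted(pv, p, side="right")
            arr[i] = n - (o_hi - o_lo)
    for cls in classes:
        burdens[f"count_{cls}"] = counts[cls]
        burdens[f"contains_{cls}"] = counts[cls] > 0
    burdens["half_width"] = half_width
    return burdens


def _contains_table(burdens: pd.DataFrame, cls: str) -> np.ndarray:
    det = burdens["detected"].to_numpy(dtype=bool)
    has = burdens[f"contains_{cls}"].to_numpy(dtype=bool)
    return np.array([
        [int(np.sum(det & has)), int(np.sum(det & ~has))],
        [int(np.sum(~det & has)), int(np.sum(~det & ~has))],
    ])


def window_enrichment(
    burdens: pd.DataFrame,
    cls: str = "pathogenic",
    by_type: bool = True,
    family: str = "window",
) -> list[EnrichmentResult]:
    """Containment odds of a variant class in detected vs undetected windows.

    2x2 {detected vs undetected window} x {contains >=1 variant of the class
    vs not}, per residue type and pooled, Bonferroni within the panel.
    """
    results = []
    groups = [("pooled", burdens)]
    if by_type:
        groups += [(t, burdens[burdens["residue_type"] == t]) for t in RESIDUE_TYPES
                   if (burdens["residue_type"] == t).any()]
    for name, sub in groups:
        res = fisher_exact(_contains_table(sub, cls), label=f"{name}:{cls}")
        results.append(res)
    return bonferroni_family(results, family=family)


def variant_level_enrichment(
    sites: pd.DataFrame,
    variants: pd.DataFrame,
    cls: str = "pathogenic",
    baseline_cls: str = "background",
    half_width: int = DEFAULT_HALF_WIDTH,
) -> EnrichmentResult:
    """Variant-level window odds ratio (the alternative counting unit).

    2x2 {variant of ``cls`` vs variant of ``baseline_cls``} x {position
    within 1..half_width of a detected site vs not}.  This is the unit under
    which a placement odds multiplier in the synthetic generator is the true
    OR by construction.
    """
    det = sites[sites["detected"]]
    det_by_acc = {acc: np.sort(sub["position"].to_numpy())
                  for acc, sub in det.groupby("accession")}

    def near_flags(v: pd.DataFrame) -> np.ndarray:
        flags = np.zeros(len(v), dtype=bool)
        accs = v["accession"].to_numpy()
        poss = v["position"].to_numpy()
        for i in range(len(v)):
            pv = det_by_acc.get(accs[i])
            if pv is None or pv.size == 0:
                continue
            p = poss[i]
            lo = np.searchsorted(pv, p - half_width, side="left")
            hi = np.searchsorted(pv, p + half_width, side="right")
            n = hi - lo
            n -= np.searchsorted(pv, p, side="right") - np.searchsorted(pv, p, side="left")
            flags[i] = n > 0
        return flags

    def sel(c):
        if c == "background":
            return variants[variants["in_background_set"]]
        return variants[variants["variant_class"] == c]

    va = sel(cls).drop_duplicates(["accession", "position", "alt_aa"])
    vb = sel(baseline_cls).drop_duplicates(["accession", "position", "alt_aa"])
    fa, fb = near_flags(va), near_flags(vb)
    table = [[int(fa.sum()), int((~fa).sum())],
             [int(fb.sum()), int((~fb).sum())]]
    return fisher_exact(table, label=f"variant-level:{cls} vs {baseline_cls}")


def direct_overlap_enrichment(
    sites: pd.DataFrame,
    variants: pd.DataFrame,
    cls: str = "pathogenic",
    by_type: bool = True,
    family: str = "overlap",
) -> list[EnrichmentResult]:
    """Odds of a variant class overlapping detected vs undetected sites.

    2x2 {detected vs undetected site} x {>=1 variant of the class at that
    exact position vs none}.
    """
    if cls == "background":
        v = variants[variants["in_background_set"]]
    else:
        v = variants[variants["variant_class"] == cls]
    hit = set(zip(v["accession"], v["position"]))
    s = sites.copy()
    s[f"contains_{cls}"] = [
        (a, p) in hit for a, p in zip(s["accession"], s["position"])
    ]
    results = []
    groups = [("pooled", s)]
    if by_type:
        groups += [(t, s[s["residue_type"] == t]) for t in RESIDUE_TYPES
                   if (s["residue_type"] == t).any()]
    for name, sub in groups:
        results.append(fisher_exact(_contains_table(sub, cls), label=f"{name}:{cls}"))
    return bonferroni_family(results, family=family)


def distance_comparison(
    sites: pd.DataFrame,
    variants: pd.DataFrame,
    cls: str = "pathogenic",
    anchor: str = "site",
) -> pd.DataFrame:
    """Rank-sum comparison of nearest distances, detected vs undetected.

    ``anchor="site"`` compares each site's nearest variant distance;
    ``anchor="variant"`` compares each variant's nearest detected-site vs
    nearest undetected-site distance.  Direct overlaps excluded.  Per
    residue type and pooled, with Benjamini-Hochberg FDR adjustment.
    """
    from statsmodels.stats.multitest import multipletests

    if cls == "background":
        v = variants[variants["in_background_set"]]
    else:
        v = variants[variants["variant_class"] == cls]
    rows = []
    type_groups = [("pooled", None)] + [(t, t) for t in RESIDUE_TYPES]
    for name, t in type_groups:
        s = sites if t is None else sites[sites["residue_type"] == t]
        if anchor == "site":
            nd = nearest_distance(s, v, exclude_overlap=True)
            if nd.empty or nd["detected"].nunique() < 2:
                continue
            da = nd.loc[nd["detected"], "nearest_distance"]
            db = nd.loc[~nd["detected"], "nearest_distance"]
        else:
            da = nearest_distance(v, s[s["detected"]], exclude_overlap=True)
            db = nearest_distance(v, s[~s["detected"]], exclude_overlap=True)
            da = da["nearest_distance"] if not da.empty else pd.Series(dtype=float)
            db = db["nearest_distance"] if not db.empty else pd.Series(dtype=float)
            if da.empty or db.empty:
                continue
        stat, p = rank_sum(da, db)
        rows.append({
            "group": name, "class": cls, "anchor": anchor,
            "n_detected": len(da), "n_undetected": len(db),
            "median_detected": float(np.median(da)),
            "median_undetected": float(np.median(db)),
            "statistic": stat, "p_value": p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
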