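"""Reference summary counts of the merged public chemoproteomics/clinical
corpus, and the worked-example statistics derived from them.

These integers are pre-extracted inputs (the corpus itself — ClinVar,
gnomAD, OMIM, the PDB and the merged chemoproteomics inventories — is far
too large to ship); the derived fractions and totals are recomputed through
the package's own operations so the arithmetic is exercised, not assumed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chemoproteomics import ingest, protein_type_summary
from .enrichment import containment_proportion, overlap_summary
from .proximity1d import detected_fractions
from .sequence_io import ProteinRecord
from .variants import class_counts, classify_variants

#: detected vs total CysLysTyr positions in the monogenic-disease (OMIM) &
#: chemoproteomic-detected (CpD) analysis gene set
DETECTED_SITE_COUNTS = {
    "C": (1907, 13503),
    "K": (2092, 49364),
    "Y": (548, 20606),
}

#: CpD proteins carrying two or more reactive residue types, of all CpD proteins
MULTI_TYPE_PROTEINS = (1988, 4535)

#: OMIM monogenic genes that are also CpD, of all OMIM monogenic genes
OMIM_CPD_GENES = (1243, 3974)

#: missense-constrained genes with at least one CpDAA, of all such genes
CONSTRAINED_CPD_GENES = (95, 114)

#: CpDAA environments (8 Å) containing >=1 pathogenic variant, per residue type
ENV_PATHOGENIC_COUNTS = {
    "C": (266, 696),
    "Y": (127, 351),
    "K": (359, 1551),
}

#: fumarate hydratase (FH) case study: variant class composition,
#: chemoproteomic-detected residues, and the Cys333 8 Å sphere
FH_CLASS_COUNTS = {
    "pathogenic": 52, "benign_common": 3, "rare": 12, "rarest": 85, "vus": 258,
}
FH_CPDAA_TYPES = {"C": 2, "K": 13, "Y": 1}
FH_CYS333_SPHERE = (34, 44)  # residues carrying pathogenic/LP/VUS, of all within 8 Å


def detected_fraction_pct(residue_type: str) -> float:
    """Detected fraction (%) for one residue type, via site enumeration."""
    n_det, n_tot = DETECTED_SITE_COUNTS[residue_type]
    sites = pd.DataFrame({
        "accession": "corpus",
        "position": np.arange(1, n_tot + 1),
        "residue_type": residue_type,
        "detected": np.arange(n_tot) < n_det,
    })
    fr = detected_fractions(sites).set_index("residue_type")
    return 100.0 * float(fr.loc[residue_type, "fraction_detected"])


def multi_type_pct() -> float:
    """Percent of CpD proteins with >=2 reactive residue types."""
    n_multi, n_total = MULTI_TYPE_PROTEINS
    rows = []
    for i in range(n_total):
        rows.append({"accession": f"p{i}", "position": 1, "residue_type": "C"})
        if i < n_multi:
            rows.append({"accession": f"p{i}", "position": 2, "residue_type": "K"})
    _, agg = protein_type_summary(pd.DataFrame(rows))
    return 100.0 * agg["frac_ge2_types"]


def omim_cpd_pct() -> float:
    """Percent of OMIM monogenic genes that are chemoproteomically detected."""
    n_overlap, n_omim = OMIM_CPD_GENES
    omim = {f"g{i}" for i in range(n_omim)}
    cpd = {f"g{i}" for i in range(n_overlap)} | {f"x{i}" for i in range(3292)}
    s = overlap_summary({"cpd": cpd, "omim": omim})
    return 100.0 * s["frac_cpd_in_omim"]


def constrained_cpd_pct() -> float:
    """Percent of missense-constrained genes carrying at least one CpDAA."""
    n_overlap, n_constrained = CONSTRAINED_CPD_GENES
    constrained = {f"g{i}" for i in range(n_constrained)}
    cpd = {f"g{i}" for i in range(n_overlap)}
    s = overlap_summary({"cpd": cpd, "constrained": constrained})
    return 100.0 * s["frac_cpd_in_constrained"]


def env_pathogenic_pct(residue_type: str) -> float:
    """Percent of CpDAA 8 Å environments with a proximal pathogenic variant."""
    n_with, n_total = ENV_PATHOGENIC_COUNTS[residue_type]
    flags = np.arange(n_total) < n_with
    return 100.0 * containment_proportion(flags)


def _fh_variant_rows() -> pd.DataFrame:
    """FH variant table reconstructed from its printed class composition."""
    label_of = {"pathogenic": ("pathogenic", float("nan")),
                "benign_common": ("benign", 0.2),
                "rare": ("none", 1e-4),
                "rarest": ("none", 1e-6),
                "vus": ("vus", float("nan"))}
    rows = []
    pos = 1
    for cls, n in FH_CLASS_COUNTS.items():
        label, af = label_of[cls]
        for _ in range(n):
            rows.append({
                "accession": "FH", "position": pos, "ref_aa": "G", "alt_aa": "R",
                "ref_codon": "GGA", "alt_codon": "AGA",
                "clinical_label": label, "allele_frequency": af,
            })
            pos += 1
    return pd.DataFrame(rows)


def fh_total_missense() -> int:
    """Total FH missense single-nucleotide variants across all classes."""
    variants, conflicts = classify_variants(_fh_variant_rows())
    assert conflicts.empty
    counts = class_counts(variants)
    return sum(counts[c] for c in FH_CLASS_COUNTS)


def fh_cpdaa_count() -> int:
    """FH chemoproteomic-detected residues, recovered through full ingest."""
    seq = list("A" * 510)
    positions: list[tuple[int, str]] = []
    pos = 300
    for rtype, n in sorted(FH_CPDAA_TYPES.items()):
        for _ in range(n):
            seq[pos - 1] = rtype
            positions.append((pos, rtype))
            pos += 10
    protein = ProteinRecord("FH", "FH", "".join(seq))
    rows = []
    for p, rtype in positions:
        for exp in ("exp1", "exp2"):
            pep = protein.sequence[p - 6 : p] + "*" + protein.sequence[p : p + 4]
            rows.append({
                "accession": "FH", "peptide": pep, "position": p,
                "residue_type": rtype, "probe_id": "probe",
                "experiment_id": exp, "r10_1": 3.0,
            })
    res = ingest(pd.DataFrame(rows), [protein])
    return len(res["cpdaa"])


def fh_cys333_sphere_pct() -> float:
    """Percent of residues in the FH Cys333 8 Å sphere carrying
    pathogenic/likely-pathogenic/VUS variants."""
    n_flagged, n_total = FH_CYS333_SPHERE
    flags = np.arange(n_total) < n_flagged
    return 100.0 * containment_proportion(flags)


def worked_examples() -> dict[str, float]:
    """All worked-example statistics, computed at call time."""
    return {
        "cys_detected_pct": detected_fraction_pct("C"),
        "lys_detected_pct": detected_fraction_pct("K"),
        "tyr_detected_pct": detected_fraction_pct("Y"),
        "multi_type_protein_pct": multi_type_pct(),
        "omim_cpd_pct": omim_cpd_pct(),
        "constrained_cpd_pct": constrained_cpd_pct(),
        "cys_env_pathogenic_pct": env_pathogenic_pct("C"),
        "tyr_env_pathogenic_pct": env_pathogenic_pct("Y"),
        "lys_env_pathogenic_pct": env_pathogenic_pct("K"),
        "fh_total_missense_snvs": float(fh_total_missense()),
        "fh_n_cpdaa": float(fh_cpdaa_count()),
        "fh_cys333_sphere_pct": fh_cys333_sphere_pct(),
    }
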