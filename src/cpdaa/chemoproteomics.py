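"""Chemoproteomics ingest: peptide QC, replication, reactivity aggregation.

Peptide-level records (one row per detected peptide occurrence) are filtered
to singly-modified peptides of 6-45 residues, required to replicate at least
twice across experiments, averaged to a per-residue reactivity ratio
(R10:1), and verified against the canonical protein sequence before they
become chemoproteomic-detected amino acids (CpDAAs).

The modification-mark dialect is an asterisk immediately after the modified
residue letter (e.g. ``MAC*ALRY``); the parser is pluggable for other
dialects via ``mark_parser``.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .sequence_io import ProteinRecord, verify_residue

PEPTIDE_MIN_LEN = 6
PEPTIDE_MAX_LEN = 45

#: R10:1 category thresholds: high <= HIGH_MAX < medium <= MEDIUM_MAX < low
HIGH_MAX = 2.0
MEDIUM_MAX = 5.0

REJECT_REASONS = ("multi_modified", "too_short", "too_long", "unmapped",
                  "singleton", "mismatch")


def parse_asterisk_marks(peptide: str) -> tuple[str, list[int]]:
    """Split a marked peptide into (clean sequence, 0-based mark offsets).

    A mark is an asterisk immediately following the modified residue letter.
    """
    clean = []
    offsets = []
    for ch in peptide:
        if ch == "*":
            if not clean:
                raise ValueError(f"dangling modification mark in {peptide!r}")
            offsets.append(len(clean) - 1)
        else:
            clean.append(ch)
    return "".join(clean), offsets


def filter_peptides(
    records: pd.DataFrame,
    mark_parser: Callable[[str], tuple[str, list[int]]] = parse_asterisk_marks,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply peptide-level QC filters.

    Kept records carry exactly one modification mark and a clean peptide
    length within [6, 45].  Returns ``(kept, rejected)``; rejected rows get a
    ``reason`` column in {multi_modified, too_short, too_long}.  Rejection is
    data, not failure: kept + rejected partitions the input.
    """
    parsed = records["peptide"].map(mark_parser)
    clean_len = parsed.map(lambda t: len(t[0]))
    n_marks = parsed.map(lambda t: len(t[1]))

    reason = pd.Series("", index=records.index, dtype=object)
    reason[n_marks != 1] = "multi_modified"
    ok = reason == ""
    reason[ok & (clean_len < PEPTIDE_MIN_LEN)] = "too_short"
    ok = reason == ""
    reason[ok & (clean_len > PEPTIDE_MAX_LEN)] = "too_long"

    kept = records[reason == ""].copy()
    rejected = records[reason != ""].copy()
    rejected["reason"] = reason[reason != ""]
    return kept.reset_index(drop=True), rejected.reset_index(drop=True)


def require_replication(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep residues observed at least twice across experimental replicates.

    The counting unit is one record per (experiment_id, peptide) occurrence.
    Groups (accession, position) with a single observation are dropped with
    reason ``singleton``.
    """
    n_obs = records.groupby(["accession", "position"])["experiment_id"].transform("size")
    kept = records[n_obs >= 2].copy()
    kept["n_observations"] = n_obs[n_obs >= 2]
    dropped = records[n_obs < 2].copy()
    dropped["reason"] = "singleton"
    return kept.reset_index(drop=True), dropped.reset_index(drop=True)


def aggregate_reactivity(values: Iterable[float]) -> float:
    """Arithmetic mean of the non-missing R10:1 values of a residue group.

    Returns NaN when no value is present (category becomes undetermined).
    """
    vals = np.asarray([v for v in values if v is not None and not np.isnan(v)], dtype=float)
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def categorize_reactivity(mean_r10_1: float) -> str:
    """R10:1 reactivity category: high (<=2), medium (2, 5], low (>5)."""
    if np.isnan(mean_r10_1):
        return "undetermined"
    if mean_r10_1 <= 0:
        raise ValueError("R10:1 ratios are strictly positive")
    if mean_r10_1 <= HIGH_MAX:
        return "high"
    if mean_r10_1 <= MEDIUM_MAX:
        return "medium"
    return "low"


def build_cpdaa_table(
    records: pd.DataFrame,
    proteins: Iterable[ProteinRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate replicated peptide records into the verified CpDAA table.

    Every (accession, position) is verified against the canonical sequence
    (residue letter must equal ``residue_type``); mismatching or unmappable
    records are dropped with a reason code.  Returns
    ``(cpdaa, dropped)`` where ``cpdaa`` has one row per residue with
    mean R10:1 (pooled, plus per-probe means in ``probe_means``),
    reactivity category and observation count.
    """
    seqs = {p.accession: p for p in proteins}
    rows = []
    dropped = []
    for (acc, pos), grp in records.groupby(["accession", "position"], sort=True):
        rtype = grp["residue_type"].iloc[0]
        prot = seqs.get(acc)
        if prot is None:
            d = grp.copy()
            d["reason"] = "unmapped"
            dropped.append(d)
            continue
        if not verify_residue(prot, int(pos), rtype):
            d = grp.copy()
            d["reason"] = "mismatch"
            dropped.append(d)
            continue
        mean = aggregate_reactivity(grp["r10_1"])
        probe_means = {
            probe: aggregate_reactivity(sub["r10_1"])
            for probe, sub in grp.groupby("probe_id")
        }
        rows.append({
            "accession": acc,
            "position": int(pos),
            "residue_type": rtype,
            "mean_r10_1": mean,
            "reactivity_category": categorize_reactivity(mean),
            "n_observations": int(len(grp)),
            "probe_means": ";".join(f"{k}={v:.4g}" for k, v in sorted(probe_means.items())),
        })
    cpdaa = pd.DataFrame(rows, columns=[
        "accession", "position", "residue_type", "mean_r10_1",
        "reactivity_category", "n_observations", "probe_means",
    ])
    dropped_df = (
        pd.concat(dropped, ignore_index=True) if dropped
        else records.iloc[0:0].assign(reason=pd.Series(dtype=object))
    )
    return cpdaa, dropped_df


def protein_type_summary(cpdaa: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-protein residue-type summary and aggregate multi-type fractions.

    Returns a per-protein frame (counts of detected C/K/Y sites, whether the
    protein carries >=2 and all 3 residue types) plus an aggregate dict with
    the fractions of proteins with multiple reactive residue types.
    """
    per = (
        cpdaa.groupby("accession")
        .agg(
            n_sites=("position", "size"),
            n_types=("residue_type", "nunique"),
            n_c=("residue_type", lambda s: int((s == "C").sum())),
            n_k=("residue_type", lambda s: int((s == "K").sum())),
            n_y=("residue_type", lambda s: int((s == "Y").sum())),
        )
        .reset_index()
    )
    per["ge2_types"] = per["n_types"] >= 2
    per["all3_types"] = per["n_types"] == 3
    n = len(per)
    agg = {
        "n_proteins": n,
        "n_sites": int(len(cpdaa)),
        "n_ge2_types": int(per["ge2_types"].sum()),
        "n_all3_types": int(per["all3_types"].sum()),
        "frac_ge2_types": float(per["ge2_types"].mean()) if n else float("nan"),
        "frac_all3_types": float(per["all3_types"].mean()) if n else float("nan"),
    }
    return per, agg


def ingest(
    peptides: pd.DataFrame,
    proteins: Iterable[ProteinRecord],
) -> dict:
    """Full ingest chain: filter -> replication -> aggregate/verify.

    Returns a dict with the CpDAA table, all rejected/dropped rows with
    reasons, and the per-protein summary.
    """
    kept, rejected = filter_peptides(peptides)
    kept, singletons = require_replication(kept)
    cpdaa, mismatched = build_cpdaa_table(kept, proteins)
    per_protein, summary = protein_type_summary(cpdaa)
    return {
        "cpdaa": cpdaa,
        "rejected": rejected,
        "singletons": singletons,
        "mismatched": mismatched,
        "per_protein": per_protein,
        "summary": summary,
    }
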