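"""End-to-end pipeline over a fixture bundle directory.

Reads the bundle files written by :mod:`cpdaa.simulate` (or real data in the
same shapes), runs ingest -> variant classification -> 1D proximity -> 3D
environments -> prioritization, and writes deterministic result tables.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import chemoproteomics, proximity1d, proximity3d, variants as variants_mod
from .enrichment import results_frame
from .sequence_io import read_fasta, read_tsv, write_tsv


def load_bundle(bundle_dir: str | Path) -> dict:
    """Load every table of a fixture bundle."""
    d = Path(bundle_dir)
    out = {
        "proteins": read_fasta(d / "proteome.fa"),
        "peptides": read_tsv(d / "peptides.tsv"),
        "variants_raw": read_tsv(d / "variants.tsv"),
        "genes": read_tsv(d / "genes.tsv"),
        "cadd": read_tsv(d / "cadd.tsv"),
        "smap": read_tsv(d / "map.tsv"),
    }
    out["models"] = [
        proximity3d.parse_structure(p)
        for p in sorted((d / "structures").glob("*.pdb"))
    ]
    truth_path = d / "truth.json"
    out["truth"] = json.loads(truth_path.read_text()) if truth_path.exists() else None
    return out


def run_pipeline(bundle_dir: str | Path, outdir: str | Path | None = None,
                 half_width: int = 6, cutoff: float = 8.0) -> dict:
    """Run the full analysis chain on a bundle; optionally write result TSVs."""
    b = load_bundle(bundle_dir)
    proteins = b["proteins"]

    ing = chemoproteomics.ingest(b["peptides"], proteins)
    cpdaa = ing["cpdaa"]

    variants, conflicts = variants_mod.classify_variants(b["variants_raw"])

    sites = proximity1d.enumerate_sites(proteins, cpdaa)
    fractions = proximity1d.detected_fractions(sites)
    burdens = proximity1d.window_burden(sites, variants, half_width=half_width)
    window_res = proximity1d.window_enrichment(burdens, "pathogenic")
    variant_level = proximity1d.variant_level_enrichment(
        sites, variants, half_width=half_width)
    overlap_res = proximity1d.direct_overlap_enrichment(sites, variants, "pathogenic")
    dist_cmp = proximity1d.distance_comparison(sites, variants, "pathogenic")

    environments = proximity3d.compute_environments(b["models"], b["smap"], cpdaa)
    env_burden = proximity3d.environment_burden(environments, variants, cutoff=cutoff)
    cadd_scores, cadd_excluded = variants_mod.mean_cadd_per_codon(b["cadd"])
    if len(env_burden) and env_burden["residue_type"].nunique() >= 2:
        type3d = proximity3d.type_enrichment_3d(env_burden, "pathogenic")
    else:
        type3d = []
    ranked, frac_deleterious = proximity3d.rank_by_vus(env_burden, cadd_scores)

    structured_accessions = set(b["smap"]["accession"].unique())
    candidates = proximity3d.candidate_filter(
        proteins, variants, structured_accessions, cpdaa, env_burden)

    results = {
        "cpdaa": cpdaa,
        "ingest_summary": ing["summary"],
        "variants": variants,
        "conflicts": conflicts,
        "sites": sites,
        "detected_fractions": fractions,
        "window_burdens": burdens,
        "window_enrichment": window_res,
        "variant_level_enrichment": variant_level,
        "overlap_enrichment": overlap_res,
        "distance_comparison": dist_cmp,
        "environments": environments,
        "env_burden": env_burden,
        "cadd_scores": cadd_scores,
        "type_enrichment_3d": type3d,
        "ranked_vus": ranked,
        "frac_top_deleterious": frac_deleterious,
        "candidates": candidates,
        "truth": b["truth"],
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tsv(cpdaa.sort_values(["accession", "position"]), outdir / "cpdaa.tsv")
        write_tsv(variants.sort_values(["accession", "position", "alt_aa"]),
                  outdir / "variants_classified.tsv")
        write_tsv(fractions, outdir / "detected_fractions.tsv")
        write_tsv(
            burdens.sort_values(["accession", "position"]),
            outdir / "windows.tsv")
        write_tsv(results_frame(window_res), outdir / "window_enrichment.tsv")
        write_tsv(results_frame(overlap_res), outdir / "overlap_enrichment.tsv")
        write_tsv(results_frame([variant_level]), outdir / "variant_level_enrichment.tsv")
        if len(dist_cmp):
            write_tsv(dist_cmp, outdir / "distance_comparison.tsv")
        write_tsv(
            environments.sort_values(
                ["accession", "cpdaa_position", "structure_id", "neighbor_position", "chain"]
            ).reset_index(drop=True),
            outdir / "environments.tsv")
        write_tsv(env_burden.sort_values(["accession", "cpdaa_position"]),
                  outdir / "env_burden.tsv")
        if type3d:
            write_tsv(results_frame(type3d), outdir / "enrichment3d.tsv")
        write_tsv(ranked, outdir / "ranked_vus.tsv")
        write_tsv(candidates, outdir / "candidates.tsv")
    return results
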