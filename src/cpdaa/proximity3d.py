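"""Structure-based residue environments around CpDAAs.

Distances are measured from the residue-type-specific terminal side-chain
atom of a CpDAA (Cys SG, Lys NZ, Tyr OH) to all atoms of neighboring
residues, up to a 10 Å boundary; environments are then sliceable to 6 and
8 Å cutoffs.  Residues from other chains of the biological assembly are
included (interface neighbors matter); hydrogens, waters and hetero groups
are excluded.  Across multiple structures of the same protein, neighbor
sets are unioned keeping each position's minimum distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .enrichment import EnrichmentResult, bonferroni_family, fisher_exact

TERMINAL_ATOMS = {"C": "SG", "K": "NZ", "Y": "OH"}
CUTOFFS = (6.0, 8.0, 10.0)
MAX_RADIUS = 10.0

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class StructureResidue:
    chain: str
    number: int
    name: str
    atom_names: list[str]
    coords: np.ndarray  # (n_atoms, 3), Å


@dataclass
class StructureModel:
    structure_id: str
    residues: list[StructureResidue]

    def atom_array(self) -> tuple[np.ndarray, np.ndarray]:
        """All coordinates stacked with a residue index per atom."""
        coords = np.concatenate([r.coords for r in self.residues])
        idx = np.concatenate([
            np.full(len(r.coords), i) for i, r in enumerate(self.residues)
        ])
        return coords, idx


def terminal_atom_name(residue_type: str) -> str:
    """Terminal side-chain atom anchoring 3D distances: C->SG, K->NZ, Y->OH."""
    try:
        return TERMINAL_ATOMS[residue_type]
    except KeyError:
        raise ValueError(f"unsupported residue type {residue_type!r}") from None


def parse_structure(path: str | Path) -> StructureModel:
    """Parse a PDB-format file into a lightweight structure model.

    Model 1 of multi-model files is used; the first alternate location of
    each atom is kept; waters, hetero groups and hydrogens are excluded.
    """
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    st.remove_alternative_conformations()
    st.remove_waters()
    st.remove_hydrogens()
    model = st[0]
    residues: list[StructureResidue] = []
    for chain in model:
        for res in chain:
            if res.name not in THREE_TO_ONE:
                continue  # hetero / nonstandard residues excluded from neighbors
            names, xyz = [], []
            for atom in res:
                names.append(atom.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
            if not xyz:
                continue
            residues.append(StructureResidue(
                chain=chain.name,
                number=res.seqid.num,
                name=res.name,
                atom_names=names,
                coords=np.asarray(xyz, dtype=float),
            ))
    return StructureModel(structure_id=Path(path).stem, residues=residues)


def validate_structure_map(smap: pd.DataFrame) -> pd.DataFrame:
    """Drop structure-map rows whose sequence/structure residues disagree.

    Rows with ``aa_match`` false (engineered or mutated constructs) are
    removed; the dropped rows are logged via the returned frame's attrs.
    """
    ok = smap["aa_match"].astype(bool)
    out = smap[ok].reset_index(drop=True)
    out.attrs["n_dropped_mismatch"] = int((~ok).sum())
    return out


def residue_environment(
    model: StructureModel,
    smap: pd.DataFrame,
    cpdaa_row: Mapping,
    max_radius: float = MAX_RADIUS,
) -> pd.DataFrame | None:
    """Neighbor residues of one CpDAA within ``max_radius`` of its terminal atom.

    ``smap`` maps sequence positions to structure residues for this
    structure (columns: accession, position, chain, structure_residue_number,
    aa_match).  Returns one row per neighboring mapped residue with the
    minimum over its atoms of the Euclidean distance to the terminal atom
    (Å, 3 decimals), or None when the CpDAA does not map or its terminal
    atom is absent (skip reasons ``missing_map`` / ``missing_atom`` in attrs).
    """
    acc = cpdaa_row["accession"]
    pos = int(cpdaa_row["position"])
    rtype = cpdaa_row["residue_type"]
    m = smap[(smap["accession"] == acc) & (smap["position"] == pos)
             & smap["aa_match"].astype(bool)]
    if m.empty:
        return None
    chain = m.iloc[0]["chain"]
    resnum = int(m.iloc[0]["structure_residue_number"])
    by_key = {(r.chain, r.number): i for i, r in enumerate(model.residues)}
    idx = by_key.get((chain, resnum))
    if idx is None:
        return None
    anchor_res = model.residues[idx]
    atom = terminal_atom_name(rtype)
    if atom not in anchor_res.atom_names:
        return None
    anchor = anchor_res.coords[anchor_res.atom_names.index(atom)]

    # map structure residues back to sequence positions (all chains)
    mm = smap[(smap["accession"] == acc) & smap["aa_match"].astype(bool)]
    seq_pos = {(c, int(n)): int(p) for c, n, p in
               zip(mm["chain"], mm["structure_residue_number"], mm["position"])}

    rows = []
    for i, res in enumerate(model.residues):
        key = (res.chain, res.number)
        if key not in seq_pos:
            continue
        if seq_pos[key] == pos:
            continue  # the CpDAA's own residue (any chain copy of it keeps its position)
        d = float(np.min(np.linalg.norm(res.coords - anchor, axis=1)))
        if d <= max_radius:
            rows.append({
                "accession": acc,
                "cpdaa_position": pos,
                "residue_type": rtype,
                "structure_id": model.structure_id,
                "neighbor_position": seq_pos[key],
                "chain": res.chain,
                "min_distance": round(d, 3),
            })
    return pd.DataFrame(rows, columns=[
        "accession", "cpdaa_position", "residue_type", "structure_id",
        "neighbor_position", "chain", "min_distance",
    ])


def compute_environments(
    models: Iterable[StructureModel],
    smap: pd.DataFrame,
    cpdaa: pd.DataFrame,
    structure_index: pd.DataFrame | None = None,
    max_radius: float = MAX_RADIUS,
) -> pd.DataFrame:
    """Environments for every CpDAA across every applicable structure.

    ``structure_index`` optionally restricts which (accession, structure_id)
    pairs are attempted; by default every structure whose map covers the
    protein is used.
    """
    smap = validate_structure_map(smap)
    frames = []
    for model in models:
        sub = smap[smap["structure_id"] == model.structure_id] if "structure_id" in smap else smap
        for acc in sub["accession"].unique():
            for _, row in cpdaa[cpdaa["accession"] == acc].iterrows():
                env = residue_environment(model, sub, row, max_radius=max_radius)
                if env is not None and len(env):
                    frames.append(env)
    if not frames:
        return pd.DataFrame(columns=[
            "accession", "cpdaa_position", "residue_type", "structure_id",
            "neighbor_position", "chain", "min_distance",
        ])
    return pd.concat(frames, ignore_index=True)


def union_environments(environments: pd.DataFrame) -> pd.DataFrame:
    """Union neighbor sets across structures, keeping minimum distances."""
    if environments.empty:
        return environments
    return (
        environments
        .groupby(["accession", "cpdaa_position", "residue_type", "neighbor_position"],
                 as_index=False)["min_distance"].min()
    )


def environment_burden(
    environments: pd.DataFrame,
    variants: pd.DataFrame,
    cutoff: float = 8.0,
    classes: Sequence[str] = ("pathogenic", "background", "vus"),
) -> pd.DataFrame:
    """Per-CpDAA unique-allele burden within a distance cutoff.

    Neighbors are the cross-structure union (minimum distance per position);
    burden per class counts distinct (position, alt_aa) alleles among
    neighbor positions; ``contains_<class>`` flags derive from counts.
    """
    uni = union_environments(environments)
    uni = uni[uni["min_distance"] <= cutoff]

    def sel(c):
        if c == "background":
            return variants[variants["in_background_set"]]
        return variants[variants["variant_class"] == c]

    # one row per CpDAA with a computed environment, even when no neighbor
    # survives this cutoff (information-carrying absence)
    keys = environments[["accession", "cpdaa_position", "residue_type"]].drop_duplicates()
    out = keys.reset_index(drop=True).copy()
    if out.empty:
        for cls in classes:
            out[f"count_{cls}"] = pd.Series(dtype=int)
            out[f"contains_{cls}"] = pd.Series(dtype=bool)
        out["cutoff"] = pd.Series(dtype=float)
        return out
    out["cutoff"] = cutoff
    for cls in classes:
        v = sel(cls).drop_duplicates(["accession", "position", "alt_aa"])
        merged = uni.merge(
            v[["accession", "position", "alt_aa"]],
            left_on=["accession", "neighbor_position"],
            right_on=["accession", "position"],
        )
        counts = (
            merged.groupby(["accession", "cpdaa_position"])
            .size().rename(f"count_{cls}").reset_index()
        )
        out = out.merge(counts, on=["accession", "cpdaa_position"], how="left")
        out[f"count_{cls}"] = out[f"count_{cls}"].fillna(0).astype(int)
        out[f"contains_{cls}"] = out[f"count_{cls}"] > 0
    return out


def position_level_burden(environments: pd.DataFrame, variants: pd.DataFrame,
                          cutoff: float = 8.0,
                          classes: Sequence[str] = ("pathogenic", "background", "vus"),
                          ) -> pd.DataFrame:
    """Burden counting unique variant *positions* rather than alleles.

    Emitted alongside the allele-level statistic because per-allele vs
    per-position counting is ambiguous when one position carries several
    variants.
    """
    v = variants.drop_duplicates(["accession", "position", "variant_class"])
    return environment_burden(environments, v.drop_duplicates(["accession", "position", "alt_aa"]),
                              cutoff=cutoff, classes=classes)


def type_enrichment_3d(
    burdens: pd.DataFrame,
    cls: str = "pathogenic",
    family: str = "3d-type",
) -> list[EnrichmentResult]:
    """Containment odds for each CpDAA type versus all other types.

    2x2 {CpDAA of type t vs other types} x {contains >=1 proximal variant of
    the class vs not}, over deduplicated CpDAAs, Bonferroni within the panel.
    """
    if burdens["residue_type"].nunique() < 2:
        raise ValueError("type enrichment requires >=2 residue types")
    has = burdens[f"contains_{cls}"].to_numpy(dtype=bool)
    results = []
    for t in sorted(burdens["residue_type"].unique()):
        is_t = (burdens["residue_type"] == t).to_numpy()
        table = [[int(np.sum(is_t & has)), int(np.sum(is_t & ~has))],
                 [int(np.sum(~is_t & has)), int(np.sum(~is_t & ~has))]]
        results.append(fisher_exact(table, label=f"{t}:{cls}"))
    return bonferroni_family(results, family=family)


def rank_by_vus(
    burdens: pd.DataFrame,
    cadd_scores: pd.DataFrame,
    k: int = 50,
    deleterious_threshold: float = 25.0,
) -> tuple[pd.DataFrame, float]:
    """Top-k CpDAAs by local VUS burden, annotated with mean CADD phred.

    Ties broken by (accession, position) ascending for determinism.  Returns
    the ranked table and the fraction of the top k with mean CADD above the
    deleterious threshold (rows without a score count as not deleterious).
    """
    ranked = burdens.sort_values(
        ["count_vus", "accession", "cpdaa_position"],
        ascending=[False, True, True],
    ).head(k).reset_index(drop=True)
    ranked = ranked.merge(
        cadd_scores[["accession", "position", "mean_phred", "deleterious"]],
        left_on=["accession", "cpdaa_position"],
        right_on=["accession", "position"],
        how="left",
    ).drop(columns=["position"])
    ranked["deleterious"] = ranked["deleterious"].map(lambda v: bool(v) if v == v else False)
    frac = float(ranked["deleterious"].mean()) if len(ranked) else float("nan")
    return ranked, frac


def cluster_burden(
    burden_matrix: pd.DataFrame,
    count_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Split CpDAAs into high/low local missense burden groups.

    Rows are centered (row mean subtracted; no unit-variance scaling), then
    hierarchically clustered (Euclidean, average linkage) and cut at two
    groups; the group with the larger mean total burden is labeled "high".
    Identical rows make the cut degenerate (flagged).
    """
    if len(burden_matrix) < 2:
        raise ValueError("clustering needs at least 2 rows")
    count_columns = count_columns or [c for c in burden_matrix.columns
                                      if c.startswith("count_")]
    X = burden_matrix[list(count_columns)].to_numpy(dtype=float)
    totals = X.sum(axis=1)
    centered = X - X.mean(axis=1, keepdims=True)
    degenerate = bool(np.allclose(centered, centered[0]))
    Z = linkage(centered, method="average", metric="euclidean")
    labels = fcluster(Z, t=2, criterion="maxclust")
    means = {g: totals[labels == g].mean() for g in np.unique(labels)}
    high = max(means, key=means.get)
    out = burden_matrix.copy()
    out["total_missense"] = totals.astype(int)
    out["burden_group"] = np.where(labels == high, "high", "low")
    out.attrs["degenerate"] = degenerate
    return out


def candidate_filter(
    proteins,
    variants: pd.DataFrame,
    structured_accessions: set,
    cpdaa: pd.DataFrame,
    burdens: pd.DataFrame,
    max_length: int = 1000,
) -> pd.DataFrame:
    """Five-criterion candidate-protein filter.

    Per protein: (1) has both pathogenic and common/benign missense
    variants, (2) has a structure, (3) is shorter than ``max_length``
    residues, (4) has a variant inside a CpDAA 3D environment, and (5) is
    chemoproteomically detected.  ``passes`` is the conjunction.
    """
    lengths = {p.accession: p.length for p in proteins}
    path = set(variants.loc[variants["variant_class"] == "pathogenic", "accession"])
    benign = set(variants.loc[variants["in_background_set"], "accession"])
    detected = set(cpdaa["accession"])
    contains_cols = [c for c in burdens.columns if c.startswith("contains_")]
    env_hit = set(
        burdens.loc[burdens[contains_cols].any(axis=1), "accession"]
    ) if len(burdens) else set()
    rows = []
    for acc, length in sorted(lengths.items()):
        flags = {
            "accession": acc,
            "has_path_and_benign": acc in path and acc in benign,
            "has_structure": acc in structured_accessions,
            "length_lt_1000": length < max_length,
            "variant_in_cpdaa_env": acc in env_hit,
            "is_cky_detected": acc in detected,
        }
        flags["passes"] = all(v for k, v in flags.items() if k != "accession")
        rows.append(flags)
    return pd.DataFrame(rows)
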