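"""Seeded synthetic fixture bundles with planted, known enrichment.

The generator emulates every input shape the pipeline consumes — proteome
FASTA with coding sequences, peptide-level chemoproteomics records, variant
tables, gene annotations, CADD scores, ideal-helix PDB structures with a
sequence<->structure map — and records the ground truth needed to verify
every planted quantity exactly.

Planted effects
---------------
* window enrichment: pathogenic variants are placed by rejection sampling
  with an odds multiplier ``planted_window_or`` for positions within ±6
  residues (1 <= d <= 6) of a detected site, so the variant-level placement
  odds ratio equals the multiplier exactly by construction;
* direct overlap: each CysLysTyr site independently receives an overlapping
  pathogenic variant with per-site Bernoulli odds multiplied by
  ``planted_overlap_or`` at detected sites (positional placements avoid
  CysLysTyr positions so overlaps come only from this mechanism);
* 3D burden: ``n_burden_targets`` detected residues receive
  ``vus_per_target`` extra VUS alleles at sequence positions within 8 Å of
  their terminal atom on the ideal helix, making those residues the
  top-ranked by local VUS burden (and, with >20 alleles, the high-burden
  cluster).

Structures are ideal α-helices (rise 1.5 Å/residue, twist 100°/residue) so
that inter-residue distances have closed forms usable as oracles.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import (AMINO_ACIDS, CODON_TABLE, ProteinRecord, STOP,
                          enumerate_codon_snvs, write_fasta, write_tsv)

# mean human proteome amino-acid frequencies (normalized at use)
DEFAULT_AA_FREQUENCIES = {
    "A": 7.0, "R": 5.6, "N": 3.6, "D": 4.7, "C": 2.3, "Q": 4.8, "E": 7.1,
    "G": 6.6, "H": 2.6, "I": 4.3, "L": 10.0, "K": 5.7, "M": 2.1, "F": 3.7,
    "P": 6.3, "S": 8.3, "T": 5.3, "W": 1.2, "Y": 2.7, "V": 6.0,
}

#: detection probability per residue type (matches reported detected fractions)
DEFAULT_CPDAA_RATES = {"C": 0.14, "K": 0.042, "Y": 0.027}

#: R10:1 category mix among reactivity-profiled residues
DEFAULT_REACTIVITY_MIX = {"high": 0.10, "medium": 0.30, "low": 0.60}

_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(CODON_TABLE.items()):
    if aa != STOP:
        _CODONS_BY_AA.setdefault(aa, []).append(codon)


@dataclass
class HelixGeometry:
    rise: float = 1.5        # Å per residue along the axis
    twist: float = 100.0     # degrees per residue
    radius: float = 2.3      # Å, CA radius
    side_offset: float = 1.8  # Å, extra radius of side-chain pseudo-atoms


@dataclass
class SimConfig:
    """Study conditions for one synthetic bundle (pure function of seed)."""

    n_proteins: int = 40
    length_range: tuple[int, int] = (200, 600)
    aa_frequencies: dict = field(default_factory=lambda: dict(DEFAULT_AA_FREQUENCIES))
    cpdaa_rates: dict = field(default_factory=lambda: dict(DEFAULT_CPDAA_RATES))
    reactivity_mix: dict = field(default_factory=lambda: dict(DEFAULT_REACTIVITY_MIX))
    planted_window_or: float = 2.0
    planted_overlap_or: float = 2.0
    planted_env_or: float = 1.0
    overlap_base_rate: float = 0.02
    n_pathogenic: int = 600
    n_background: int = 600
    n_vus: int = 300
    n_benign_common: int = 60
    n_rare: int = 100
    n_rarest: int = 100
    n_env_pathogenic: int = 0
    half_width: int = 6
    decoy_fraction: float = 0.1
    n_structures: int = 8
    two_chain_fraction: float = 0.5
    chain_offset: float = 7.0   # Å translation of the second chain
    n_burden_targets: int = 1
    vus_per_target: int = 25
    cadd_incomplete_fraction: float = 0.05
    omim_fraction: float = 0.5
    fda_fraction: float = 0.1
    helix: HelixGeometry = field(default_factory=HelixGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_range[0] < 10:
            raise ValueError("minimum protein length too small")
        if self.planted_window_or <= 0 or self.planted_overlap_or <= 0:
            raise ValueError("planted odds multipliers must be positive")
        for v in self.cpdaa_rates.values():
            if not 0 <= v <= 1:
                raise ValueError("cpdaa rates are probabilities")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# proteome


def simulate_proteome(cfg: SimConfig, rng: np.random.Generator | None = None
                      ) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Draw protein sequences from the configured amino-acid frequencies.

    Coding sequences are back-translated with uniform codon choice.  Returns
    ``(proteins, cds_by_accession)``.
    """
    rng = rng or cfg.rng()
    letters = np.array(list(AMINO_ACIDS))
    freqs = np.array([cfg.aa_frequencies[a] for a in AMINO_ACIDS], dtype=float)
    if freqs.sum() <= 0:
        raise ValueError("degenerate amino-acid frequencies")
    freqs = freqs / freqs.sum()
    proteins: list[ProteinRecord] = []
    cds: dict[str, str] = {}
    lo, hi = cfg.length_range
    width = max(len(str(cfg.n_proteins)), 4)
    for i in range(cfg.n_proteins):
        n = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=n, p=freqs))
        acc = f"P{i + 1:0{width}d}"
        proteins.append(ProteinRecord(acc, f"G{i + 1:0{width}d}", seq))
        n_choices = np.array([len(_CODONS_BY_AA[aa]) for aa in seq])
        picks = rng.integers(0, n_choices)
        cds[acc] = "".join(_CODONS_BY_AA[aa][k] for aa, k in zip(seq, picks))
    return proteins, cds


# ---------------------------------------------------------------------------
# chemoproteomics records


def _peptide_for_site(seq: str, pos: int, rng: np.random.Generator,
                      length: int | None = None) -> tuple[str, int]:
    """A marked tryptic-like peptide covering a 1-based site position."""
    n = len(seq)
    L = length or int(rng.integers(6, min(45, n) + 1))
    start_lo = max(1, pos - L + 1)
    start_hi = min(pos, n - L + 1)
    start = int(rng.integers(start_lo, start_hi + 1))
    clean = seq[start - 1 : start - 1 + L]
    off = pos - start  # 0-based offset of the site within the peptide
    marked = clean[: off + 1] + "*" + clean[off + 1 :]
    return marked, start


def draw_detected_sites(proteins: list[ProteinRecord], cfg: SimConfig,
                        rng: np.random.Generator) -> list[dict]:
    """Bernoulli detection of CysLysTyr sites with a planted R10:1 value each."""
    cats = sorted(cfg.reactivity_mix)
    cat_p = np.array([cfg.reactivity_mix[c] for c in cats], dtype=float)
    cat_p = cat_p / cat_p.sum()
    ranges = {"high": (0.5, 2.0), "medium": (2.05, 5.0), "low": (5.05, 15.0)}
    truth_sites = []
    for prot in proteins:
        for pos0, aa in enumerate(prot.sequence):
            if aa not in cfg.cpdaa_rates:
                continue
            if rng.random() >= cfg.cpdaa_rates[aa]:
                continue
            cat = cats[int(rng.choice(len(cats), p=cat_p))]
            lo, hi = ranges[cat]
            truth_sites.append({
                "accession": prot.accession, "position": pos0 + 1,
                "residue_type": aa,
                "r10_1": round(float(rng.uniform(lo, hi)), 4),
                "category": cat,
            })
    return truth_sites


def simulate_cpdaa(proteins: list[ProteinRecord], cfg: SimConfig,
                   rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    """Peptide-level records for planted detected sites, plus decoys.

    Each detected site is emitted as >=2 replicate records sharing its
    planted R10:1 value, so the ingest mean and category recover the plant
    exactly.  A ``decoy_fraction`` of extra records deliberately violates
    each QC filter (multi-mark, too short, too long, singleton).
    """
    probe_of = {"C": "IA-alkyne", "K": "STP-alkyne", "Y": "HHS-465"}
    truth_sites = draw_detected_sites(proteins, cfg, rng)
    rows = []
    by_acc = {p.accession: p for p in proteins}
    for site in truth_sites:
        prot = by_acc[site["accession"]]
        pos, aa, r10 = site["position"], site["residue_type"], site["r10_1"]
        n_rep = int(rng.integers(2, 4))
        for rep in range(n_rep):
            pep, _ = _peptide_for_site(prot.sequence, pos, rng)
            rows.append({
                "accession": prot.accession,
                "peptide": pep,
                "position": pos,
                "residue_type": aa,
                "probe_id": probe_of[aa],
                "experiment_id": f"exp{rep + 1}",
                "r10_1": r10,
            })

    n_decoys = int(round(cfg.decoy_fraction * len(truth_sites)))
    decoys = []
    flavors = ["multi_modified", "too_short", "too_long", "singleton"]
    for j in range(n_decoys):
        prot = proteins[int(rng.integers(0, len(proteins)))]
        cky = [i + 1 for i, a in enumerate(prot.sequence) if a in "CKY"]
        if not cky:
            continue
        pos = int(cky[int(rng.integers(0, len(cky)))])
        aa = prot.sequence[pos - 1]
        flavor = flavors[j % len(flavors)]
        base = {
            "accession": prot.accession, "position": pos, "residue_type": aa,
            "probe_id": probe_of[aa], "experiment_id": "exp_decoy",
            "r10_1": round(float(rng.uniform(0.5, 10.0)), 4),
        }
        if flavor == "multi_modified":
            pep, _ = _peptide_for_site(prot.sequence, pos, rng, length=10)
            pep = pep[0] + "*" + pep[1:] if not pep.startswith("*") else pep
            decoys.append({**base, "peptide": pep})
        elif flavor == "too_short":
            L = 5
            if pos >= L:
                clean = prot.sequence[pos - L : pos]
                decoys.append({**base, "peptide": clean[:-1] + clean[-1] + "*"})
        elif flavor == "too_long":
            if prot.length >= 50:
                start = max(1, pos - 25)
                clean = prot.sequence[start - 1 : start - 1 + 50]
                if len(clean) == 50 and start <= pos < start + 50:
                    off = pos - start
                    decoys.append({**base,
                                   "peptide": clean[: off + 1] + "*" + clean[off + 1 :]})
        else:  # singleton: one valid record only, at a position kept unique
            pep, _ = _peptide_for_site(prot.sequence, pos, rng)
            decoys.append({**base, "peptide": pep, "experiment_id": "exp_single"})
    # singletons must stay single: drop any that coincide with a planted
    # (replicated) site or with another singleton decoy
    planted = {(t["accession"], t["position"]) for t in truth_sites}
    filtered = []
    singleton_used: set = set()
    for d in decoys:
        if d["experiment_id"] == "exp_single":
            key = (d["accession"], d["position"])
            if key in planted or key in singleton_used:
                continue
            singleton_used.add(key)
        filtered.append(d)
    decoys = filtered

    peptides = pd.DataFrame(rows + decoys)
    truth = {
        "detected_sites": truth_sites,
        "n_decoys": len(decoys),
    }
    return peptides, truth


# ---------------------------------------------------------------------------
# variants


def _near_zone(proteins, detected, half_width: int) -> dict[str, np.ndarray]:
    """Boolean mask per protein: position within 1..half_width of a detected site."""
    det_by_acc: dict[str, list[int]] = {}
    for acc, pos in detected:
        det_by_acc.setdefault(acc, []).append(pos)
    zones = {}
    for prot in proteins:
        mask = np.zeros(prot.length + 1, dtype=bool)  # index 1..length
        for p in det_by_acc.get(prot.accession, []):
            lo = max(1, p - half_width)
            hi = min(prot.length, p + half_width)
            mask[lo : hi + 1] = True
            mask[p] = False if not mask[p] else mask[p]
            # d = 0 is not "near": clear the site's own position unless another
            # detected site covers it
        for p in det_by_acc.get(prot.accession, []):
            others = [q for q in det_by_acc[prot.accession] if q != p]
            if not any(1 <= abs(q - p) <= half_width for q in others):
                mask[p] = False
        zones[prot.accession] = mask
    return zones


def _random_missense(cds: str, pos: int, rng: np.random.Generator):
    ref_codon = cds[(pos - 1) * 3 : pos * 3]
    subs = [s for s in enumerate_codon_snvs(ref_codon) if s.kind == "missense"]
    s = subs[int(rng.integers(0, len(subs)))]
    return s


def simulate_variants(proteins: list[ProteinRecord], cds: dict[str, str],
                      detected: set, cfg: SimConfig,
                      rng: np.random.Generator,
                      helix_neighbors: dict | None = None) -> tuple[pd.DataFrame, dict]:
    """Variant table with planted window, overlap and 3D-burden effects.

    Positional placements (pathogenic, background, VUS, rare bins) avoid
    CysLysTyr positions so that direct overlaps arise only from the
    dedicated per-site overlap mechanism; pathogenic positions are rejection
    sampled with odds multiplier ``planted_window_or`` inside the ±6 zone
    of detected sites.
    """
    zones = _near_zone(proteins, detected, cfg.half_width)
    # eligible positions: all non-CysLysTyr residues
    pools = {}
    for prot in proteins:
        pos = np.array([i + 1 for i, a in enumerate(prot.sequence) if a not in "CKY"])
        pools[prot.accession] = pos
    accs = [p.accession for p in proteins]
    sizes = np.array([len(pools[a]) for a in accs], dtype=float)
    acc_p = sizes / sizes.sum()

    used: set[tuple[str, int, str]] = set()
    rows = []
    truth_rows = []

    def place(accession: str, position: int, label: str, cls_hint: str,
              af: float, mechanism: str) -> bool:
        sub = _random_missense(cds[accession], position, rng)
        key = (accession, position, sub.alt_aa)
        if key in used:
            return False
        used.add(key)
        rows.append({
            "accession": accession, "position": position,
            "ref_aa": sub.ref_aa, "alt_aa": sub.alt_aa,
            "ref_codon": sub.ref_codon, "alt_codon": sub.alt_codon,
            "clinical_label": label, "allele_frequency": af,
        })
        truth_rows.append({
            "accession": accession, "position": position, "alt_aa": sub.alt_aa,
            "class": cls_hint, "mechanism": mechanism,
            "near_window": bool(zones[accession][position]),
        })
        return True

    def uniform_place(n: int, label: str, cls_hint: str, af_sampler, mechanism: str):
        placed = 0
        attempts = 0
        while placed < n and attempts < 50 * n + 100:
            attempts += 1
            acc = accs[int(rng.choice(len(accs), p=acc_p))]
            pool = pools[acc]
            pos = int(pool[int(rng.integers(0, len(pool)))])
            if place(acc, pos, label, cls_hint, af_sampler(), mechanism):
                placed += 1
        return placed

    def weighted_place(n: int, or_mult: float, label: str, cls_hint: str,
                       af_sampler, mechanism: str):
        """Rejection sampling: weight or_mult inside the near zone, 1 outside."""
        wmax = max(or_mult, 1.0)
        placed = 0
        attempts = 0
        while placed < n and attempts < 500 * n + 1000:
            attempts += 1
            acc = accs[int(rng.choice(len(accs), p=acc_p))]
            pool = pools[acc]
            pos = int(pool[int(rng.integers(0, len(pool)))])
            w = or_mult if zones[acc][pos] else 1.0
            if rng.random() >= w / wmax:
                continue
            if place(acc, pos, label, cls_hint, af_sampler(), mechanism):
                placed += 1
        return placed

    if cfg.n_pathogenic and not detected:
        raise ValueError("cannot plant window enrichment without detected sites")

    nan = lambda: float("nan")
    common_af = lambda: round(float(rng.uniform(0.051, 0.5)), 6)
    rare_af = lambda: float(10 ** rng.uniform(-5, -3.05))
    rarest_af = lambda: float(10 ** rng.uniform(-8, -5.05))

    weighted_place(cfg.n_pathogenic, cfg.planted_window_or,
                   "pathogenic", "pathogenic", nan, "window_plant")
    uniform_place(cfg.n_background, "none", "background", common_af, "uniform")
    uniform_place(cfg.n_vus, "vus", "vus", nan, "uniform")
    uniform_place(cfg.n_benign_common, "benign", "benign_common", common_af, "uniform")
    uniform_place(cfg.n_rare, "none", "rare", rare_af, "uniform")
    uniform_place(cfg.n_rarest, "none", "rarest", rarest_af, "uniform")

    # direct-overlap plant: per-site Bernoulli with planted odds ratio
    p_u = cfg.overlap_base_rate
    odds_u = p_u / (1 - p_u)
    odds_d = odds_u * cfg.planted_overlap_or
    p_d = odds_d / (1 + odds_d)
    for prot in proteins:
        for i, aa in enumerate(prot.sequence):
            if aa not in "CKY":
                continue
            pos = i + 1
            is_det = (prot.accession, pos) in detected
            if rng.random() < (p_d if is_det else p_u):
                place(prot.accession, pos, "pathogenic", "pathogenic",
                      float("nan"), "overlap_plant")

    # 3D environment plant: extra VUS at positions 3D-proximal to targets
    burden_targets = []
    if helix_neighbors:
        target_keys = sorted(helix_neighbors)[: cfg.n_burden_targets]
        for acc, pos in target_keys:
            neighbors = helix_neighbors[(acc, pos)]
            placed = 0
            k = 0
            while placed < cfg.vus_per_target and k < 50 * cfg.vus_per_target:
                k += 1
                npos = int(neighbors[int(rng.integers(0, len(neighbors)))])
                if place(acc, npos, "vus", "vus", float("nan"), "env_plant"):
                    placed += 1
            burden_targets.append({"accession": acc, "position": pos,
                                   "n_planted_vus": placed})

    variants = pd.DataFrame(rows)
    truth = {
        "planted_window_or": cfg.planted_window_or,
        "planted_overlap_or": cfg.planted_overlap_or,
        "overlap_base_rate": cfg.overlap_base_rate,
        "variants": truth_rows,
        "burden_targets": burden_targets,
    }
    return variants, truth


def window_recovery_trial(planted_or: float, seed: int,
                          n_proteins: int = 100,
                          length_range: tuple[int, int] = (400, 540),
                          n_pathogenic: int = 600,
                          n_background: int = 600):
    """One seeded parameter-recovery run for the planted window odds ratio.

    Generates a proteome with roughly 5,000 CysLysTyr sites, plants
    pathogenic placement at ``planted_or`` odds within ±6 of detected
    sites, and estimates the variant-level window OR.  Returns the
    :class:`~cpdaa.enrichment.EnrichmentResult` whose CI should cover the
    plant.  The per-site overlap mechanism is disabled so window placement
    is the only planted effect.
    """
    from .proximity1d import variant_level_enrichment
    from .variants import classify_variants

    cfg = SimConfig(
        n_proteins=n_proteins, length_range=length_range,
        planted_window_or=planted_or, overlap_base_rate=1e-12,
        n_pathogenic=n_pathogenic, n_background=n_background,
        n_vus=0, n_benign_common=0, n_rare=0, n_rarest=0,
        n_burden_targets=0, seed=seed,
    )
    rng = cfg.rng()
    proteins, cds = simulate_proteome(cfg, rng)
    truth_sites = draw_detected_sites(proteins, cfg, rng)
    detected = {(t["accession"], t["position"]) for t in truth_sites}
    raw, _ = simulate_variants(proteins, cds, detected, cfg, rng)
    variants, _ = classify_variants(raw)
    rows = []
    for prot in proteins:
        for i, aa in enumerate(prot.sequence):
            if aa in "CKY":
                rows.append((prot.accession, i + 1, aa,
                             (prot.accession, i + 1) in detected))
    sites = pd.DataFrame(rows, columns=["accession", "position",
                                        "residue_type", "detected"])
    return variant_level_enrichment(sites, variants, half_width=cfg.half_width)


# ---------------------------------------------------------------------------
# structures


def helix_coords(index0: int, geom: HelixGeometry, radius: float | None = None
                 ) -> np.ndarray:
    """Ideal-helix coordinates for 0-based residue index."""
    theta = math.radians(geom.twist) * index0
    r = geom.radius if radius is None else radius
    return np.array([r * math.cos(theta), r * math.sin(theta),
                     geom.rise * index0])


def helix_ca_chord(delta: int, geom: HelixGeometry) -> float:
    """Closed-form CA-CA distance between residues ``delta`` apart."""
    dtheta = math.radians(geom.twist) * delta
    r = geom.radius
    return math.sqrt(2 * r * r * (1 - math.cos(dtheta)) + (geom.rise * delta) ** 2)


_ELEMENT = {"CA": "C", "CB": "C", "SG": "S", "NZ": "N", "OH": "O"}
_AA3 = {v: k for k, v in {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}.items()}


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resnum: int, xyz: np.ndarray) -> str:
    name_f = f" {name:<3}" if len(name) < 4 else name
    return (f"ATOM  {serial:5d} {name_f} {resname} {chain}{resnum:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          "
            f"{_ELEMENT.get(name, name[0]):>2}")


def structure_atoms(protein: ProteinRecord, geom: HelixGeometry,
                    two_chains: bool = False, chain_offset: float = 7.0):
    """Atom list [(chain, resnum, resname, atom_name, xyz)] for the ideal helix.

    Every residue gets CA and CB pseudo-atoms; Cys/Lys/Tyr additionally get
    their terminal atom (SG/NZ/OH) at a larger radial offset.  A second
    chain, when requested, is the same helix translated along x.
    """
    atoms = []
    shifts = [("A", np.zeros(3))]
    if two_chains:
        shifts.append(("B", np.array([chain_offset, 0.0, 0.0])))
    for chain, shift in shifts:
        for i, aa in enumerate(protein.sequence):
            resname = _AA3[aa]
            resnum = i + 1
            atoms.append((chain, resnum, resname, "CA",
                          helix_coords(i, geom) + shift))
            atoms.append((chain, resnum, resname, "CB",
                          helix_coords(i, geom, geom.radius + 1.0) + shift))
            terminal = {"C": "SG", "K": "NZ", "Y": "OH"}
            if aa in terminal:
                atoms.append((chain, resnum, resname, terminal[aa],
                              helix_coords(i, geom, geom.radius + geom.side_offset) + shift))
    return atoms


def write_structure_pdb(protein: ProteinRecord, path: str | Path,
                        geom: HelixGeometry, two_chains: bool = False,
                        chain_offset: float = 7.0) -> None:
    """Write the ideal-helix structure as a PDB-format file."""
    lines = []
    serial = 0
    last_chain = None
    for chain, resnum, resname, name, xyz in structure_atoms(
            protein, geom, two_chains, chain_offset):
        if last_chain is not None and chain != last_chain:
            lines.append("TER")
        last_chain = chain
        serial += 1
        lines.append(_pdb_atom_line(serial, name, resname, chain, resnum, xyz))
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def structure_map_rows(protein: ProteinRecord, structure_id: str,
                       two_chains: bool = False) -> pd.DataFrame:
    chains = ["A", "B"] if two_chains else ["A"]
    rows = []
    for chain in chains:
        for i, aa in enumerate(protein.sequence):
            rows.append({
                "accession": protein.accession, "position": i + 1,
                "structure_id": structure_id, "chain": chain,
                "structure_residue_number": i + 1,
                "structure_aa": aa, "aa_match": True,
            })
    return pd.DataFrame(rows)


def helix_env_neighbors(protein: ProteinRecord, pos: int,
                        geom: HelixGeometry, cutoff: float = 8.0) -> list[int]:
    """Sequence positions whose nearest pseudo-atom lies within ``cutoff``
    of the terminal atom of residue ``pos`` on the single-chain helix.

    Closed-form generator-side oracle used to plant 3D burden.
    """
    aa = protein.sequence[pos - 1]
    r_t = geom.radius + (geom.side_offset if aa in "CKY" else 1.0)
    anchor = helix_coords(pos - 1, geom, r_t)
    out = []
    for j in range(protein.length):
        if j == pos - 1:
            continue
        radii = [geom.radius, geom.radius + 1.0]
        if protein.sequence[j] in "CKY":
            radii.append(geom.radius + geom.side_offset)
        d = min(np.linalg.norm(helix_coords(j, geom, r) - anchor) for r in radii)
        if d <= cutoff:
            out.append(j + 1)
    return out


# ---------------------------------------------------------------------------
# annotations and CADD


def simulate_annotations(proteins: list[ProteinRecord], cpd_accessions: set,
                         cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Gene-level annotation table with planted CpD effects.

    CpD genes receive a higher protein-protein interaction rate; OMIM
    membership and FDA-target flags are independent Bernoulli draws.
    """
    rows = []
    for prot in proteins:
        is_cpd = prot.accession in cpd_accessions
        is_omim = rng.random() < cfg.omim_fraction
        rows.append({
            "gene_id": prot.gene_id,
            "accession": prot.accession,
            "omim_phenotype_count": int(rng.poisson(1.3) + 1) if is_omim else 0,
            "is_fda_target": bool(rng.random() < cfg.fda_fraction),
            "is_cpd": is_cpd,
            "constraint_metric": round(float(rng.uniform(0.2, 0.8) if is_cpd
                                             else rng.uniform(0.4, 1.2)), 4),
            "is_lof_tolerant": bool(rng.random() < 0.05),
            "ppi_count": int(rng.poisson(20 if is_cpd else 10)),
            "protein_length": prot.length,
        })
    return pd.DataFrame(rows)


def simulate_cadd(cpdaa_truth: list[dict], cds: dict[str, str],
                  burden_targets: list[dict], cfg: SimConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Per-substitution CADD phred scores for every detected residue codon.

    High-burden target residues get phreds ~N(32, 2) (deleterious); others
    ~N(15, 5) clipped at 0.  A fraction of residues is left with an
    incomplete score set to exercise the completeness requirement.
    """
    targets = {(t["accession"], t["position"]) for t in burden_targets}
    rows = []
    for site in cpdaa_truth:
        acc, pos = site["accession"], site["position"]
        ref_codon = cds[acc][(pos - 1) * 3 : pos * 3]
        subs = [s for s in enumerate_codon_snvs(ref_codon) if s.kind == "missense"]
        incomplete = rng.random() < cfg.cadd_incomplete_fraction and (acc, pos) not in targets
        drop_idx = int(rng.integers(0, len(subs))) if incomplete else -1
        for j, s in enumerate(subs):
            if j == drop_idx:
                continue
            mu, sd = (32.0, 2.0) if (acc, pos) in targets else (15.0, 5.0)
            rows.append({
                "accession": acc, "position": pos,
                "ref_codon": s.ref_codon, "alt_codon": s.alt_codon,
                "phred": round(max(0.0, float(rng.normal(mu, sd))), 3),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(cfg: SimConfig, outdir: str | Path) -> dict:
    """Generate and write a complete fixture bundle; returns the manifest.

    The bundle is a pure function of the config (and its seed): regenerating
    with the same config reproduces every checksum.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "structures").mkdir(exist_ok=True)
    rng = cfg.rng()

    proteins, cds = simulate_proteome(cfg, rng)
    peptides, cpd_truth = simulate_cpdaa(proteins, cfg, rng)
    detected = {(t["accession"], t["position"]) for t in cpd_truth["detected_sites"]}

    # structures for the first n_structures proteins that carry detected sites
    structured = []
    det_accs = sorted({a for a, _ in detected})
    by_acc = {p.accession: p for p in proteins}
    for acc in det_accs[: cfg.n_structures]:
        structured.append(by_acc[acc])

    helix_neighbors = {}
    for prot in structured:
        for acc, pos in sorted(detected):
            if acc != prot.accession:
                continue
            nb = helix_env_neighbors(prot, pos, cfg.helix, cutoff=8.0)
            nb = [p for p in nb if prot.sequence[p - 1] not in "CKY"]
            if nb:
                helix_neighbors[(acc, pos)] = nb

    variants, var_truth = simulate_variants(
        proteins, cds, detected, cfg, rng, helix_neighbors=helix_neighbors)

    map_frames = []
    structure_files = {}
    for k, prot in enumerate(structured):
        two = (k / max(len(structured), 1)) < cfg.two_chain_fraction
        sid = f"S{k + 1:04d}"
        path = outdir / "structures" / f"{sid}.pdb"
        write_structure_pdb(prot, path, cfg.helix, two_chains=two,
                            chain_offset=cfg.chain_offset)
        map_frames.append(structure_map_rows(prot, sid, two_chains=two))
        structure_files[sid] = prot.accession
    smap = (pd.concat(map_frames, ignore_index=True) if map_frames
            else pd.DataFrame(columns=["accession", "position", "structure_id",
                                       "chain", "structure_residue_number",
                                       "structure_aa", "aa_match"]))

    cpd_accessions = {a for a, _ in detected}
    genes = simulate_annotations(proteins, cpd_accessions, cfg, rng)
    cadd = simulate_cadd(cpd_truth["detected_sites"], cds,
                         var_truth["burden_targets"], cfg, rng)

    write_fasta(proteins, outdir / "proteome.fa")
    with open(outdir / "cds.fa", "w") as fh:
        for prot in proteins:
            fh.write(f">{prot.accession}\n{cds[prot.accession]}\n")
    write_tsv(peptides, outdir / "peptides.tsv")
    write_tsv(variants, outdir / "variants.tsv")
    write_tsv(genes, outdir / "genes.tsv")
    write_tsv(cadd, outdir / "cadd.tsv")
    write_tsv(smap, outdir / "map.tsv")

    truth = {
        "config": {**{k: v for k, v in asdict(cfg).items() if k != "helix"},
                   "helix": asdict(cfg.helix)},
        "detected_sites": cpd_truth["detected_sites"],
        "n_decoys": cpd_truth["n_decoys"],
        "planted_window_or": var_truth["planted_window_or"],
        "planted_overlap_or": var_truth["planted_overlap_or"],
        "burden_targets": var_truth["burden_targets"],
        "variant_mechanisms": var_truth["variants"],
        "structures": structure_files,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))

    files = ["proteome.fa", "cds.fa", "peptides.tsv", "variants.tsv",
             "genes.tsv", "cadd.tsv", "map.tsv", "truth.json"]
    files += [f"structures/{sid}.pdb" for sid in sorted(structure_files)]
    manifest = {f: _sha256(outdir / f) for f in files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
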