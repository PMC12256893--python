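"""Sequence readers, residue verification, and codon/genetic-code utilities.

All protein positions throughout the package are 1-based and inclusive,
matching the residue naming convention of the field (e.g. Cys333).  The
standard genetic code is assumed (nuclear human genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

#: canonical 20-letter amino-acid alphabet
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
STOP = "*"

_standard = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid (stops map to "*")
CODON_TABLE: dict[str, str] = dict(_standard.forward_table)
CODON_TABLE.update({c: STOP for c in _standard.stop_codons})

NUCLEOTIDES = "ACGT"


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed or violates dataset invariants."""


@dataclass(frozen=True)
class ProteinRecord:
    """A canonical protein sequence.

    Parameters
    ----------
    accession : str
        Canonical protein identifier, unique within a dataset.
    gene_id : str
        Gene symbol or identifier.
    sequence : str
        Uppercase amino-acid sequence over the 20-letter alphabet
        (``X`` is tolerated but flagged with a warning).
    """

    accession: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence
        bad = set(seq) - _AA_SET - {"X"}
        if bad:
            raise ValueError(
                f"{self.accession}: unsupported residue letters {sorted(bad)} "
                "(selenocysteine and ambiguity codes are rejected at ingest)"
            )
        if "X" in seq:
            logger.warning("%s: sequence contains X (unknown residue)", self.accession)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue letter at a 1-based position."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside 1..{self.length}")
        return self.sequence[position - 1]


@dataclass(frozen=True)
class CodonSubstitution:
    """A single-nucleotide codon exchange and its protein-level consequence."""

    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    kind: str  # synonymous | missense | nonsense

    def __post_init__(self) -> None:
        diffs = sum(a != b for a, b in zip(self.ref_codon, self.alt_codon))
        if diffs != 1:
            raise ValueError("ref and alt codon must differ at exactly one base")


def translate_codon(codon: str) -> str:
    """Translate a DNA codon under the standard genetic code ("*" = stop)."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in NUCLEOTIDES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    return CODON_TABLE[codon]


def translate_cds(cds: str) -> str:
    """Translate a coding sequence codon-by-codon (no stop allowed internally)."""
    if len(cds) % 3:
        raise ValueError("coding sequence length not a multiple of 3")
    aas = [translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3)]
    if STOP in aas[:-1]:
        raise ValueError("internal stop codon in coding sequence")
    if aas and aas[-1] == STOP:
        aas = aas[:-1]
    return "".join(aas)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The first whitespace-separated token of the header is the accession.  A
    ``GN=<symbol>`` tag, if present, supplies the gene id; otherwise the gene
    id defaults to the accession.  Duplicate accessions are rejected.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        if accession in seen:
            raise FastaParseError(f"duplicate accession {accession!r}")
        seen.add(accession)
        gene_id = accession
        for token in rec.description.split():
            if token.startswith("GN="):
                gene_id = token[3:]
        records.append(ProteinRecord(accession, gene_id, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records as FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession} GN={rec.gene_id}\n")
            for i in range(0, rec.length, 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def verify_residue(protein: ProteinRecord, position: int, expected_aa: str) -> bool:
    """True iff ``position`` is within the sequence and holds ``expected_aa``.

    This is the hard gate applied before any residue-level join across tables;
    out-of-range positions return False rather than raising.
    """
    if position < 1:
        raise ValueError("positions are 1-based; got %d" % position)
    if position > protein.length:
        return False
    return protein.sequence[position - 1] == expected_aa


def classify_substitution(ref_aa: str, alt_aa: str) -> str:
    if alt_aa == STOP:
        return "nonsense" if ref_aa != STOP else "synonymous"
    return "synonymous" if ref_aa == alt_aa else "missense"


def enumerate_codon_snvs(ref_codon: str) -> list[CodonSubstitution]:
    """All 9 single-nucleotide substitutions of a codon, each classified.

    The reference codon must not itself be a stop codon.
    """
    ref_codon = ref_codon.upper()
    ref_aa = translate_codon(ref_codon)
    if ref_aa == STOP:
        raise ValueError(f"{ref_codon} is a stop codon")
    out: list[CodonSubstitution] = []
    for i in range(3):
        for base in NUCLEOTIDES:
            if base == ref_codon[i]:
                continue
            alt = ref_codon[:i] + base + ref_codon[i + 1 :]
            alt_aa = translate_codon(alt)
            out.append(
                CodonSubstitution(ref_codon, alt, ref_aa, alt_aa,
                                  classify_substitution(ref_aa, alt_aa))
            )
    return out


def missense_snv_count(ref_codon: str) -> int:
    """Number of the codon's 9 single-nucleotide substitutions that are missense."""
    return sum(s.kind == "missense" for s in enumerate_codon_snvs(ref_codon))


def normalize_gene_ids(
    table: pd.DataFrame,
    synonym_map: Mapping[str, str] | pd.DataFrame,
    column: str = "gene_id",
) -> pd.DataFrame:
    """Replace gene symbols by approved symbols and collapse exact duplicates.

    ``synonym_map`` is either a mapping or a two-column DataFrame
    (symbol, approved).  A symbol mapped to conflicting targets is a
    validation error; unmapped symbols are retained and logged.
    """
    if isinstance(synonym_map, pd.DataFrame):
        if synonym_map.shape[1] < 2:
            raise ValueError("synonym map needs two columns (symbol, approved)")
        sym, appr = synonym_map.columns[:2]
        grouped = synonym_map.groupby(sym)[appr].nunique()
        conflicts = grouped[grouped > 1]
        if len(conflicts):
            raise ValueError(
                f"conflicting synonym targets for: {sorted(conflicts.index)}"
            )
        mapping = dict(zip(synonym_map[sym], synonym_map[appr]))
    else:
        mapping = dict(synonym_map)
    out = table.copy()
    unmapped = sorted(set(out[column]) - set(mapping))
    if unmapped and mapping:
        logger.info("normalize_gene_ids: %d unmapped symbols retained", len(unmapped))
    out[column] = out[column].map(lambda s: mapping.get(s, s))
    return out.drop_duplicates().reset_index(drop=True)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a tab-separated table with header row (the package-wide dialect)."""
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tab-separated table, header row, no index, no quoting."""
    df.to_csv(path, sep="\t", index=False)
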