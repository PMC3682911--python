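"""Readers and writers for the formats the pipeline touches.

FASTA (per gene), Newick with internal-node support labels (PhyML/RAxML
dialect, 0-100 scale), NEXUS DATA + SETS blocks, RAxML-style partition files
and the taxonomy TSV.  Round trips are bit-stable at a fixed decimal
precision (default 6 for branch lengths).
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import dendropy

from .trees import Node, Tree, TreeError, _quote

PathLike = Union[str, Path]

NUCLEOTIDES = "ACGT"
#: canonical residue alphabet for nucleotide data in this package
NT_ALPHABET = set("ACGT-N?")
#: integer codes used in matrices: A C G T gap N ?
STATE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5, "?": 6}
CODE_CHARS = "ACGT-N?"
#: codes treated as fully missing in likelihood and completeness accounting
MISSING_CODES = (4, 5, 6)

# IUPAC ambiguity codes are collapsed to N on input (the matrix alphabet is
# the supermatrix one: present base or missing)
_IUPAC_TO_N = set("RYSWKMBDHVU")


class FormatError(ValueError):
    pass


@dataclass
class SequenceRecord:
    """One sequence for one species in one gene pool."""

    taxon_label: str
    gene: str
    residues: str

    def __post_init__(self):
        if not self.taxon_label:
            raise FormatError("empty taxon label")
        bad = set(self.residues) - NT_ALPHABET
        if bad:
            raise FormatError(
                f"residues outside alphabet for {self.taxon_label}: {sorted(bad)}"
            )

    @property
    def length_bp(self) -> int:
        """Count of non-gap, non-missing residues."""
        return sum(1 for c in self.residues if c in NUCLEOTIDES)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PartitionDef:
    """A named 1-based inclusive column range, optionally codon-structured."""

    name: str
    start: int
    end: int
    codon_position: Optional[int] = None  # None, or 1/2/3

    def __post_init__(self):
        if self.start < 1 or self.start > self.end:
            raise FormatError(f"bad partition range {self.name}: {self.start}-{self.end}")

    @property
    def length(self) -> int:
        if self.codon_position is None:
            return self.end - self.start + 1
        full = self.end - self.start + 1
        return (full - self.codon_position) // 3 + 1

    def columns0(self) -> range | list[int]:
        """0-based column indices belonging to this partition."""
        if self.codon_position is None:
            return range(self.start - 1, self.end)
        return list(range(self.start - 1 + self.codon_position - 1, self.end, 3))

    def raxml_line(self) -> str:
        rng = f"{self.start}-{self.end}"
        if self.codon_position is not None:
            rng = f"{self.start + self.codon_position - 1}-{self.end}\\3"
        return f"DNA, {self.name} = {rng}"


def check_partitions_disjoint(parts: Iterable[PartitionDef]) -> None:
    seen: set[int] = set()
    for p in parts:
        cols = set(p.columns0())
        if cols & seen:
            raise FormatError(f"partition {p.name} overlaps a previous partition")
        seen |= cols


# ---------------------------------------------------------------------- FASTA

def read_fasta(path: PathLike, gene: str) -> list[SequenceRecord]:
    """Read one gene pool from FASTA.  Order preserved, residues upper-cased,
    '-'/'?'/'N' kept as given; other IUPAC ambiguity codes collapse to N.
    Duplicate taxon labels within the file are an error."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    label, chunks = None, []

    def flush():
        if label is None:
            return
        if label in seen:
            raise FormatError(f"duplicate taxon label in {path}: {label!r}")
        seen.add(label)
        seq = "".join(chunks).upper()
        seq = "".join("N" if c in _IUPAC_TO_N else c for c in seq)
        records.append(SequenceRecord(label, gene, seq))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                label = re.sub(r"\s+", " ", line[1:].strip())
                chunks = []
            else:
                if label is None:
                    raise FormatError(f"{path}: sequence data before first '>' header")
                chunks.append(line)
        flush()
    if not records:
        warnings.warn(f"empty FASTA file: {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.taxon_label}\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i : i + width] + "\n")


# --------------------------------------------------------------------- Newick

def read_newick(source: PathLike, support_scale: str = "percent") -> Tree:
    """Parse Newick into a :class:`Tree`.  Numeric internal node labels are
    interpreted as branch supports (``support_scale='unit'`` rescales 0-1
    values to 0-100)."""
    path = Path(source)
    text = path.read_text() if path.exists() else str(source)
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"Newick parse error in {source}: {exc}") from exc

    def conv(dn) -> Node:
        if dn.is_leaf():
            label = dn.taxon.label if dn.taxon else (dn.label or "")
            n = Node(label, dn.edge.length or 0.0)
        else:
            n = Node(None, dn.edge.length or 0.0)
            lab = dn.label
            if lab is not None:
                try:
                    s = float(lab)
                    if support_scale == "unit":
                        s *= 100.0
                    if not 0.0 <= s <= 100.0:
                        raise FormatError(f"support {s} outside [0,100]")
                    n.support = s
                except ValueError:
                    n.label = lab
            for dc in dn.child_nodes():
                n.add(conv(dc))
        return n

    tree = Tree(conv(dt.seed_node))
    labels = tree.leaf_labels()
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"duplicate leaf labels: {dupes}")
    # supports only make sense on internal edges; drop any on root
    tree.root.support = None
    return tree


def write_newick(tree: Tree, path: PathLike, decimals: int = 6,
                 support_decimals: int = 0) -> None:
    Path(path).write_text(
        tree.newick(decimals=decimals, support_decimals=support_decimals) + "\n"
    )


# ---------------------------------------------------------------------- NEXUS

def write_nexus_matrix(matrix, partitions: list[PartitionDef], path: PathLike) -> None:
    """Write a supermatrix as a NEXUS DATA block plus a SETS block with one
    charset per partition.  ``matrix`` is an :class:`~sparsephylo.assembly.Supermatrix`."""
    if matrix.n_taxa == 0 or matrix.n_columns == 0:
        raise FormatError("refusing to write an empty matrix")
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_columns};\n")
        fh.write('  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n')
        width = max(len(_quote(t)) for t in matrix.taxa) + 2
        for i, taxon in enumerate(matrix.taxa):
            row = matrix.row_string(i)
            fh.write(f"  {_quote(taxon):<{width}}{row}\n")
        fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
        for p in partitions:
            rng = f"{p.start}-{p.end}"
            if p.codon_position is not None:
                rng = f"{p.start + p.codon_position - 1}-{p.end}\\3"
            fh.write(f"  CHARSET {p.name} = {rng};\n")
        fh.write("END;\n")


def read_nexus_matrix(path: PathLike):
    """Read back a NEXUS matrix written by :func:`write_nexus_matrix`
    (delegates parsing to dendropy; returns a Supermatrix)."""
    from .assembly import Supermatrix

    ds = dendropy.DnaCharacterMatrix.get(path=str(path), schema="nexus")
    taxa = [t.label for t in ds.taxon_namespace]
    rows = ["".join(str(ch) for ch in ds[t]).upper() for t in ds.taxon_namespace]
    partitions = _read_nexus_charsets(path)
    return Supermatrix.from_strings(taxa, rows, partitions)


def _read_nexus_charsets(path: PathLike) -> list[PartitionDef]:
    parts = []
    text = Path(path).read_text()
    for m in re.finditer(r"CHARSET\s+(\S+)\s*=\s*(\d+)-(\d+)(\\3)?\s*;", text, re.I):
        # codon-stride charsets ("\3") come back as plain ranges: the stride
        # start already encodes the position and the gene start is unknown
        parts.append(PartitionDef(m.group(1), int(m.group(2)), int(m.group(3))))
    return parts


def write_partition_file(partitions: list[PartitionDef], path: PathLike) -> None:
    Path(path).write_text("\n".join(p.raxml_line() for p in partitions) + "\n")


# ------------------------------------------------------------------- taxonomy

@dataclass
class TaxonomyTable:
    """species -> (genus, subfamily, family, higher_taxon, incertae_sedis)."""

    rows: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        for sp, row in self.rows.items():
            if not row.get("incertae_sedis") and not row.get("family"):
                raise FormatError(f"species {sp!r} lacks a family and is not incertae sedis")

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def rank_members(self, rank: str) -> dict[str, set]:
        """Map each named taxon at `rank` (genus/subfamily/family) to its
        species set; unnamed (empty) entries are skipped."""
        out: dict[str, set] = {}
        for sp, row in self.rows.items():
            name = row.get(rank) or ""
            if name:
                out.setdefault(name, set()).add(sp)
        return out

    def __len__(self) -> int:
        return len(self.rows)


def read_taxonomy(path: PathLike) -> TaxonomyTable:
    """Read a taxonomy TSV with header species/genus/subfamily/family
    (optional higher_taxon, incertae_sedis columns)."""
    rows: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        need = {"species", "genus", "family"}
        if not need <= set(header):
            raise FormatError(f"taxonomy header must include {sorted(need)}; got {header}")
        idx = {h: i for i, h in enumerate(header)}
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            sp = f[idx["species"]].strip()
            if sp in rows:
                raise FormatError(f"duplicate species {sp!r} (line {ln})")
            row = {
                "genus": f[idx["genus"]].strip(),
                "subfamily": f[idx["subfamily"]].strip() if "subfamily" in idx and idx["subfamily"] < len(f) else "",
                "family": f[idx["family"]].strip(),
                "higher_taxon": f[idx["higher_taxon"]].strip() if "higher_taxon" in idx and idx["higher_taxon"] < len(f) else "",
                "incertae_sedis": bool(int(f[idx["incertae_sedis"]])) if "incertae_sedis" in idx and idx["incertae_sedis"] < len(f) and f[idx["incertae_sedis"]].strip() else False,
            }
            if not row["incertae_sedis"] and not row["family"]:
                raise FormatError(f"species {sp!r} lacks a family (line {ln})")
            rows[sp] = row
    return TaxonomyTable(rows)


def write_taxonomy(table: TaxonomyTable, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("species\tgenus\tsubfamily\tfamily\thigher_taxon\tincertae_sedis\n")
        for sp, r in table.rows.items():
            fh.write(
                f"{sp}\t{r['genus']}\t{r.get('subfamily','')}\t{r['family']}\t"
                f"{r.get('higher_taxon','')}\t{int(r.get('incertae_sedis', False))}\n"
            )


def load_reference_classification() -> "pandas.DataFrame":  # noqa: F821
    """The packaged genus-level squamate classification (families,
    subfamilies, higher taxa), shipped as a test/audit fixture."""
    import pandas as pd

    with resources.files("sparsephylo.data").joinpath(
        "squamate_classification.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"incertae_sedis": bool})
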