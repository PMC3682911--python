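"""Sparse supermatrix assembly.

Per-gene sequence pools are reduced to one sequence per species (longest
wins), concatenated into a single character matrix in which a species absent
from a gene receives missing states for that gene's columns, then filtered:
species with fewer than 250 bp of data in total are dropped, and species
whose rows are identical across all genes are collapsed to the
alphabetically first label.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .formats import (
    CODE_CHARS,
    MISSING_CODES,
    PartitionDef,
    SequenceRecord,
    STATE_CODES,
    check_partitions_disjoint,
)

_DECODE = np.array(list(CODE_CHARS))
_MISSING_MASK = np.zeros(len(CODE_CHARS), dtype=bool)
_MISSING_MASK[list(MISSING_CODES)] = True


_ENC_TABLE = np.full(256, 255, dtype=np.uint8)
for _c, _v in STATE_CODES.items():
    _ENC_TABLE[ord(_c)] = _v


def encode(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = _ENC_TABLE[raw]
    if (out == 255).any():
        bad = sorted({seq[i] for i in np.nonzero(out == 255)[0]})
        raise AssemblyError(f"characters outside matrix alphabet: {bad}")
    return out


def decode(row: np.ndarray) -> str:
    return "".join(_DECODE[row])


class AssemblyError(ValueError):
    pass


@dataclass
class Supermatrix:
    """Concatenated character matrix with a partition map.

    `data` holds integer state codes (see formats.STATE_CODES); '?', 'N' and
    '-' all count as missing for completeness and likelihood purposes.
    """

    taxa: list[str]
    data: np.ndarray  # (n_taxa, n_columns) uint8
    partitions: list[PartitionDef]
    removal_log: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.taxa) != self.data.shape[0]:
            raise AssemblyError("taxa/data shape mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise AssemblyError("duplicate taxa in matrix")
        check_partitions_disjoint(self.partitions)
        total = sum(p.length for p in self.partitions)
        if self.partitions and total != self.data.shape[1]:
            raise AssemblyError(
                f"partition lengths sum to {total}, matrix has {self.data.shape[1]} columns"
            )

    # ------------------------------------------------------------- properties
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return int(self.data.shape[1])

    @property
    def present(self) -> np.ndarray:
        """Boolean mask of non-missing cells."""
        return ~_MISSING_MASK[self.data]

    @property
    def per_taxon_present_bp(self) -> np.ndarray:
        return self.present.sum(axis=1)

    def per_gene_coverage(self) -> dict[str, int]:
        """Number of taxa with at least one non-missing site per partition."""
        pres = self.present
        out = {}
        for p in self.partitions:
            cols = np.asarray(p.columns0())
            out[p.name] = int((pres[:, cols].any(axis=1)).sum())
        return out

    def genes_per_taxon(self) -> np.ndarray:
        pres = self.present
        counts = np.zeros(self.n_taxa, dtype=int)
        for p in self.partitions:
            cols = np.asarray(p.columns0())
            counts += pres[:, cols].any(axis=1)
        return counts

    def row_string(self, i: int) -> str:
        return decode(self.data[i])

    def taxon_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.taxa)}

    # ----------------------------------------------------------- constructors
    @classmethod
    def from_strings(cls, taxa: Sequence[str], rows: Sequence[str],
                     partitions: Optional[list[PartitionDef]] = None) -> "Supermatrix":
        if not taxa:
            raise AssemblyError("empty matrix")
        ncol = len(rows[0])
        if any(len(r) != ncol for r in rows):
            raise AssemblyError("ragged rows")
        data = np.stack([encode(r.upper()) for r in rows])
        if partitions is None:
            partitions = [PartitionDef("all", 1, ncol)]
        return cls(list(taxa), data, partitions)

    def subset(self, keep: Sequence[int], log: Iterable[str] = ()) -> "Supermatrix":
        return Supermatrix(
            [self.taxa[i] for i in keep],
            self.data[list(keep)].copy(),
            list(self.partitions),
            self.removal_log + list(log),
        )


# ----------------------------------------------------------------- operations

def select_longest_per_species(pool: list[SequenceRecord]) -> list[SequenceRecord]:
    """Keep, per species, the record maximizing non-missing length; ties go to
    the earliest record in input order."""
    genes = {r.gene for r in pool}
    if len(genes) > 1:
        raise AssemblyError(f"pool mixes genes: {sorted(genes)}")
    best: dict[str, SequenceRecord] = {}
    for r in pool:
        cur = best.get(r.taxon_label)
        if cur is None or r.length_bp > cur.length_bp:
            best[r.taxon_label] = r
    # preserve first-encounter species order
    seen, out = set(), []
    for r in pool:
        if r.taxon_label not in seen:
            seen.add(r.taxon_label)
            out.append(best[r.taxon_label])
    return out


def _normalize_label(label: str) -> str:
    return " ".join(label.split())


def concatenate(per_gene_alignments: Mapping[str, list[SequenceRecord]],
                gene_order: Optional[Sequence[str]] = None) -> Supermatrix:
    """Concatenate aligned per-gene pools into a supermatrix.

    Species labels are matched exactly across genes (after whitespace
    normalization); a species absent from a gene gets '?' for that gene's
    columns.  Merging genes sequenced in different studies under one species
    label is what produces composite ('chimeric') terminals.
    """
    if gene_order is None:
        gene_order = list(per_gene_alignments)
    partitions: list[PartitionDef] = []
    offset = 0
    lengths: dict[str, int] = {}
    for gene in gene_order:
        recs = per_gene_alignments[gene]
        if not recs:
            raise AssemblyError(f"gene {gene!r} has no records")
        L = len(recs[0].residues)
        if any(len(r.residues) != L for r in recs):
            raise AssemblyError(f"gene {gene!r} alignment is not rectangular")
        seen: set[str] = set()
        for r in recs:
            lab = _normalize_label(r.taxon_label)
            if lab in seen:
                raise AssemblyError(
                    f"two records for species {lab!r} in gene {gene!r}; "
                    "run select_longest_per_species first"
                )
            seen.add(lab)
        lengths[gene] = L
        partitions.append(PartitionDef(gene, offset + 1, offset + L))
        offset += L

    species: list[str] = []
    seen_sp: set[str] = set()
    for gene in gene_order:
        for r in per_gene_alignments[gene]:
            lab = _normalize_label(r.taxon_label)
            if lab not in seen_sp:
                seen_sp.add(lab)
                species.append(lab)
    species.sort()

    data = np.full((len(species), offset), STATE_CODES["?"], dtype=np.uint8)
    index = {s: i for i, s in enumerate(species)}
    for gene, part in zip(gene_order, partitions):
        s0 = part.start - 1
        for r in per_gene_alignments[gene]:
            data[index[_normalize_label(r.taxon_label)], s0 : part.end] = encode(r.residues)
    return Supermatrix(species, data, partitions)


def filter_min_total(m: Supermatrix, threshold_bp: int = 250,
                     per_gene: bool = False) -> Supermatrix:
    """Drop taxa whose total non-missing length is below `threshold_bp`
    (strict "less than").  With ``per_gene=True`` the rule instead drops
    individual gene fragments shorter than the threshold."""
    if threshold_bp < 0:
        raise AssemblyError("threshold must be non-negative")
    if per_gene:
        m2 = Supermatrix(list(m.taxa), m.data.copy(), list(m.partitions), list(m.removal_log))
        pres = m2.present
        for p in m2.partitions:
            cols = np.asarray(p.columns0())
            short = pres[:, cols].sum(axis=1) < threshold_bp
            for i in np.nonzero(short)[0]:
                m2.data[i, cols] = STATE_CODES["?"]
        return filter_min_total(m2, threshold_bp, per_gene=False)
    bp = m.per_taxon_present_bp
    keep = [i for i in range(m.n_taxa) if bp[i] >= threshold_bp]
    log = [
        f"filter_min_total: removed {m.taxa[i]} ({bp[i]} bp < {threshold_bp})"
        for i in range(m.n_taxa)
        if bp[i] < threshold_bp
    ]
    return m.subset(keep, log)


def deduplicate_identical(m: Supermatrix) -> Supermatrix:
    """Collapse groups of taxa with identical rows (same present cells *and*
    the same missingness footprint) to the case-insensitively first label."""
    groups: dict[bytes, list[int]] = {}
    canon = np.where(_MISSING_MASK[m.data], np.uint8(6), m.data)  # ? == N == -
    for i in range(m.n_taxa):
        groups.setdefault(canon[i].tobytes(), []).append(i)
    keep, log = [], []
    for idxs in groups.values():
        idxs = sorted(idxs, key=lambda i: m.taxa[i].casefold())
        keep.append(idxs[0])
        for j in idxs[1:]:
            log.append(
                f"deduplicate_identical: removed {m.taxa[j]} (identical to {m.taxa[idxs[0]]})"
            )
    keep.sort()
    return m.subset(keep, log)


def split_by_partition(m: Supermatrix) -> dict[str, list[SequenceRecord]]:
    """Inverse of concatenate: recover per-gene aligned records (dropping
    all-missing rows per gene)."""
    out: dict[str, list[SequenceRecord]] = {}
    pres = m.present
    for p in m.partitions:
        cols = np.asarray(p.columns0())
        recs = []
        for i, t in enumerate(m.taxa):
            if pres[i, cols].any():
                recs.append(SequenceRecord(t, p.name, decode(m.data[i, cols])))
        out[p.name] = recs
    return out


# ----------------------------------------------------------------- statistics

@dataclass
class MatrixStats:
    total_bp: int
    n_taxa: int
    mean_present_bp: float
    mean_genes_per_taxon: float
    percent_missing: float
    percent_present: float
    per_gene: dict[str, tuple[int, float, int]]  # gene -> (count, percent, length)
    completeness_range: tuple[int, int]

    def rounded(self) -> dict:
        """Integer-rounded percentages, the reporting convention used for
        published matrix summaries."""
        return {
            "percent_missing": round(self.percent_missing),
            "percent_present": round(self.percent_present),
            "per_gene_percent": {g: round(p) for g, (c, p, L) in self.per_gene.items()},
        }

    def report(self) -> str:
        lines = [
            f"matrix: {self.n_taxa} taxa x {self.total_bp} bp",
            f"mean present: {self.mean_present_bp:.1f} bp/taxon from "
            f"{self.mean_genes_per_taxon:.2f} genes "
            f"({self.percent_present:.1f}% present, {self.percent_missing:.1f}% missing)",
            f"completeness range: {self.completeness_range[0]}-{self.completeness_range[1]} bp",
        ]
        for g, (c, p, L) in self.per_gene.items():
            lines.append(f"  {g}: {c} taxa ({p:.1f}%), {L} bp")
        return "\n".join(lines)


def matrix_statistics(m: Supermatrix) -> MatrixStats:
    if m.n_taxa == 0:
        raise AssemblyError("empty matrix")
    bp = m.per_taxon_present_bp
    cov = m.per_gene_coverage()
    per_gene = {
        p.name: (cov[p.name], 100.0 * cov[p.name] / m.n_taxa, p.length)
        for p in m.partitions
    }
    mean_bp = float(bp.mean())
    return MatrixStats(
        total_bp=m.n_columns,
        n_taxa=m.n_taxa,
        mean_present_bp=mean_bp,
        mean_genes_per_taxon=float(m.genes_per_taxon().mean()),
        percent_missing=100.0 * (1.0 - mean_bp / m.n_columns),
        percent_present=100.0 * mean_bp / m.n_columns,
        per_gene=per_gene,
        completeness_range=(int(bp.min()), int(bp.max())),
    )
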