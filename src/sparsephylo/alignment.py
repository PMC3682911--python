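"""Alignment layer: affine-gap global alignment, translation-guided
alignment for protein-coding genes, and group-then-merge profile alignment
for ribosomal RNA, plus end trimming.

The pairwise core is Gotoh's three-state dynamic program maximizing score
under the convention that a gap of length L costs open + L * extend (the
first gap residue pays both).  Traceback ties break diagonal > up > left,
so results are deterministic.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .formats import SequenceRecord

NEG_INF = float("-inf")

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
NT_ALPHABET = "ACGT"


class AlignmentError(ValueError):
    pass


def blosum62() -> dict[tuple[str, str], float]:
    m = substitution_matrices.load("BLOSUM62")
    return {(a, b): float(m[a, b]) for a in m.alphabet for b in m.alphabet}


def nucleotide_matrix(match: float = 5.0, mismatch: float = -4.0
                      ) -> dict[tuple[str, str], float]:
    return {(a, b): (match if a == b else mismatch)
            for a in NT_ALPHABET for b in NT_ALPHABET}


@dataclass
class ScoringScheme:
    """Substitution scores plus affine gap costs (both positive costs)."""

    matrix: dict[tuple[str, str], float] = field(default_factory=blosum62)
    gap_open: float = 12.0
    gap_extend: float = 3.0

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise AlignmentError("gap costs must be positive")
        for (a, b), s in self.matrix.items():
            if abs(self.matrix.get((b, a), s) - s) > 1e-9:
                raise AlignmentError("substitution matrix must be symmetric")

    @property
    def alphabet(self) -> set[str]:
        return {a for a, _ in self.matrix}

    def score(self, a: str, b: str) -> float:
        try:
            return self.matrix[(a, b)]
        except KeyError:
            raise AlignmentError(f"symbol pair ({a!r},{b!r}) outside alphabet")

    @classmethod
    def nucleotide(cls, match: float = 5.0, mismatch: float = -4.0,
                   gap_open: float = 12.0, gap_extend: float = 3.0) -> "ScoringScheme":
        return cls(nucleotide_matrix(match, mismatch), gap_open, gap_extend)


# ------------------------------------------------------------------- pairwise

def pairwise_affine_align(a: str, b: str, scheme: Optional[ScoringScheme] = None
                          ) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences under affine gaps.

    Returns (aligned_a, aligned_b, score).  Ties in the traceback prefer
    diagonal over up (gap in b) over left (gap in a).
    """
    scheme = scheme or ScoringScheme()
    if not a or not b:
        if not a and not b:
            return "", "", 0.0
        L = max(len(a), len(b))
        cost = scheme.gap_open + L * scheme.gap_extend
        return (a or "-" * len(b), b or "-" * len(a), -cost)
    cols_a = [{ch: 1.0} for ch in a]
    cols_b = [{ch: 1.0} for ch in b]
    aligned, score = _profile_dp(cols_a, cols_b, scheme)
    out_a, out_b = [], []
    for ia, ib in aligned:
        out_a.append(a[ia] if ia is not None else "-")
        out_b.append(b[ib] if ib is not None else "-")
    return "".join(out_a), "".join(out_b), score


def _col_score(ca: dict, cb: dict, scheme: ScoringScheme) -> float:
    s = 0.0
    for x, fx in ca.items():
        for y, fy in cb.items():
            s += fx * fy * scheme.score(x, y)
    return s


def _profile_dp(cols_a: list[dict], cols_b: list[dict], scheme: ScoringScheme
                ) -> tuple[list[tuple], float]:
    """Gotoh DP over two column-profiles; returns the aligned column-index
    pairs and the optimal score.  Singleton profiles reduce exactly to
    sequence alignment."""
    n, m = len(cols_a), len(cols_b)
    go, ge = scheme.gap_open, scheme.gap_extend
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # consumes a column of A (gap in B)
    Y = np.full((n + 1, m + 1), NEG_INF)  # consumes a column of B (gap in A)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(go + i * ge)
    for j in range(1, m + 1):
        Y[0, j] = -(go + j * ge)
    sub = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            sub[i, j] = _col_score(cols_a[i], cols_b[j], scheme)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + sub[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] - (go + ge), X[i - 1, j] - ge,
                          Y[i - 1, j] - (go + ge))
            Y[i, j] = max(M[i, j - 1] - (go + ge), Y[i, j - 1] - ge,
                          X[i, j - 1] - (go + ge))
    ends = (M[n, m], X[n, m], Y[n, m])
    score = max(ends)
    # deterministic traceback: diagonal > up > left
    state = "M" if ends[0] == score else ("X" if ends[1] == score else "Y")
    i, j = n, m
    pairs: list[tuple] = []
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            pairs.append((i - 1, j - 1))
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            target = M[i, j] - sub[i - 1, j - 1]
            state = "M" if _close(prev[0], target) else (
                "X" if _close(prev[1], target) else "Y")
            i, j = i - 1, j - 1
        elif state == "X" and i > 0:
            pairs.append((i - 1, None))
            if _close(M[i - 1, j] - (go + ge), X[i, j]):
                state = "M"
            elif _close(X[i - 1, j] - ge, X[i, j]):
                state = "X"
            else:
                state = "Y"
            i -= 1
        elif state == "Y" and j > 0:
            pairs.append((None, j - 1))
            if _close(M[i, j - 1] - (go + ge), Y[i, j]):
                state = "M"
            elif _close(X[i, j - 1] - (go + ge), Y[i, j]):
                state = "X"
            else:
                state = "Y"
            j -= 1
        else:  # boundary rows/columns
            if i > 0:
                pairs.append((i - 1, None))
                i -= 1
            else:
                pairs.append((None, j - 1))
                j -= 1
    pairs.reverse()
    return pairs, float(score)


def _close(a: float, b: float) -> bool:
    return a == b or abs(a - b) < 1e-9


# ------------------------------------------------------------------- profiles

@dataclass
class AlignmentProfile:
    """A set of mutually aligned records plus per-column frequencies."""

    member_records: list[SequenceRecord]

    def __post_init__(self):
        if not self.member_records:
            raise AlignmentError("empty profile")
        L = len(self.member_records[0].residues)
        if any(len(r.residues) != L for r in self.member_records):
            raise AlignmentError("profile members differ in length")

    @property
    def width(self) -> int:
        return len(self.member_records[0].residues)

    @property
    def depth(self) -> int:
        return len(self.member_records)

    def columns(self, include_gaps: bool = True) -> list[dict]:
        """Per-column symbol-frequency dicts (frequencies sum to 1)."""
        cols = []
        k = self.depth
        for j in range(self.width):
            freq: dict[str, float] = {}
            for r in self.member_records:
                c = r.residues[j]
                freq[c] = freq.get(c, 0.0) + 1.0 / k
            if not include_gaps:
                freq.pop("-", None)
                tot = sum(freq.values())
                if tot > 0:
                    freq = {c: f / tot for c, f in freq.items()}
            cols.append(freq)
        return cols

    def occupancy(self) -> np.ndarray:
        occ = np.zeros(self.width)
        for r in self.member_records:
            occ += np.array([c not in "-?" for c in r.residues], dtype=float)
        return occ / self.depth

    @classmethod
    def from_sequences(cls, records: Sequence[SequenceRecord],
                       scheme: Optional[ScoringScheme] = None,
                       kmer: int = 6) -> "AlignmentProfile":
        """Progressive alignment of unaligned records along a UPGMA guide
        tree built on k-mer distances."""
        records = list(records)
        if not records:
            raise AlignmentError("no records to align")
        if len(records) == 1:
            return cls(list(records))
        scheme = scheme or ScoringScheme.nucleotide()
        order = _upgma_merge_order([r.residues for r in records], kmer)
        profiles: dict[int, AlignmentProfile] = {
            i: cls([r]) for i, r in enumerate(records)}
        nxt = len(records)
        for a, b in order:
            profiles[nxt] = profile_merge(profiles.pop(a), profiles.pop(b), scheme)
            nxt += 1
        (result,) = profiles.values()
        return result


def _kmer_distance(a: str, b: str, k: int) -> float:
    ka = {a[i:i + k] for i in range(max(len(a) - k + 1, 0))}
    kb = {b[i:i + k] for i in range(max(len(b) - k + 1, 0))}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _upgma_merge_order(seqs: list[str], k: int) -> list[tuple[int, int]]:
    """UPGMA join order over k-mer distances; deterministic tie-breaks by
    lowest cluster index."""
    n = len(seqs)
    D = {(i, j): _kmer_distance(seqs[i], seqs[j], k)
         for i in range(n) for j in range(i + 1, n)}
    active = {i: [i] for i in range(n)}  # cluster id -> member leaf ids
    dist = dict(D)
    order = []
    nxt = n
    while len(active) > 1:
        best = min(
            ((dist[key], key) for key in dist if key[0] in active and key[1] in active),
            key=lambda z: (z[0], z[1]),
        )
        _, (a, b) = best
        members = active[a] + active[b]
        # UPGMA average distance to every other active cluster
        for c in list(active):
            if c in (a, b):
                continue
            pairs = [D[tuple(sorted((x, y)))] for x in members for y in active[c]]
            dist[tuple(sorted((nxt, c)))] = sum(pairs) / len(pairs)
        del active[a], active[b]
        active[nxt] = members
        order.append((a, b))
        nxt += 1
    return order


def profile_merge(p1: AlignmentProfile, p2: AlignmentProfile,
                  scheme: Optional[ScoringScheme] = None) -> AlignmentProfile:
    """Profile-profile global alignment; existing columns are only ever
    split by gap insertion, never reordered, so within-profile alignments
    are preserved."""
    scheme = scheme or ScoringScheme.nucleotide()
    cols1 = p1.columns(include_gaps=False)
    cols2 = p2.columns(include_gaps=False)
    occ1, occ2 = p1.occupancy(), p2.occupancy()
    # expected-score columns weighted by occupancy
    w1 = [{c: f * occ1[j] for c, f in col.items()} for j, col in enumerate(cols1)]
    w2 = [{c: f * occ2[j] for c, f in col.items()} for j, col in enumerate(cols2)]
    pairs, _ = _profile_dp(w1, w2, scheme)
    out: list[SequenceRecord] = []
    for rec in p1.member_records:
        s = "".join(rec.residues[ia] if ia is not None else "-" for ia, _ in pairs)
        out.append(type(rec)(rec.taxon_label, rec.gene, s))
    for rec in p2.member_records:
        s = "".join(rec.residues[ib] if ib is not None else "-" for _, ib in pairs)
        out.append(type(rec)(rec.taxon_label, rec.gene, s))
    return AlignmentProfile(out)


# ------------------------------------------------------------- translation

STANDARD_STOPS = {"TAA", "TAG", "TGA"}


def _frame_without_stops(nt: str) -> Optional[int]:
    """Reading-frame offset (0/1/2) with no internal stop codon; ties go to
    the earliest frame."""
    for off in (0, 1, 2):
        coding = nt[off:]
        coding = coding[: len(coding) - len(coding) % 3]
        codons = [coding[i:i + 3] for i in range(0, len(coding) - 3, 3)]  # internal only
        if all(c not in STANDARD_STOPS for c in codons):
            return off
    return None


def translation_align(nt_records: Sequence[SequenceRecord],
                      scheme: Optional[ScoringScheme] = None,
                      kmer: int = 6,
                      ) -> tuple[list[SequenceRecord], list[tuple[str, str]]]:
    """Align coding nucleotide sequences via their amino-acid translation.

    Each record is read in the first frame without internal stop codons,
    translated, progressively aligned under the amino-acid scheme (Blosum62
    by default), and the gaps are expanded 3:1 back onto the nucleotides.
    Degapping the output recovers each input exactly.  Records with stops in
    every frame are rejected; returns (aligned_records, rejected) where
    rejected holds (taxon_label, reason).
    """
    scheme = scheme or ScoringScheme()
    usable, rejected = [], []
    meta = {}
    for r in nt_records:
        off = _frame_without_stops(r.residues)
        if off is None:
            rejected.append((r.taxon_label, "internal stop codon in all frames"))
            continue
        coding = r.residues[off:]
        tail_len = len(coding) % 3
        coding = coding[: len(coding) - tail_len] if tail_len else coding
        tail = r.residues[off + len(coding):]
        aa = str(Seq(coding.replace("?", "N")).translate()).replace("*", "X")
        meta[r.taxon_label] = (r, off, coding, tail, aa)
        usable.append(_AARecord(r.taxon_label, r.gene, aa if aa else "X"))
    if not usable:
        return [], rejected
    aa_profile = AlignmentProfile.from_sequences(usable, scheme=scheme,
                                                 kmer=min(kmer, 3))
    max_head = max(meta[r.taxon_label][1] for r in usable)
    max_tail = max(len(meta[r.taxon_label][3]) for r in usable)
    out = []
    for arec in aa_profile.member_records:
        r, off, coding, tail, aa = meta[arec.taxon_label]
        nt_aln, pos = [], 0
        for ch in arec.residues:
            if ch == "-":
                nt_aln.append("---")
            else:
                nt_aln.append(coding[pos:pos + 3])
                pos += 3
        head = r.residues[:off].rjust(max_head, "-")
        tailp = tail.ljust(max_tail, "-")
        out.append(SequenceRecord(r.taxon_label, r.gene,
                                  head + "".join(nt_aln) + tailp))
    return out, rejected


class _AARecord(SequenceRecord):
    """Amino-acid record: bypasses the nucleotide alphabet check."""

    def __post_init__(self):  # alphabet handled by the scoring scheme
        if not self.taxon_label:
            raise AlignmentError("empty taxon label")


# ----------------------------------------------------------------- trimming

def trim_ends(profile: AlignmentProfile, min_occupancy: float = 0.5
              ) -> AlignmentProfile:
    """Remove leading and trailing columns whose non-gap occupancy is below
    `min_occupancy`; internal columns are untouched."""
    occ = profile.occupancy()
    lo, hi = 0, profile.width
    while lo < hi and occ[lo] < min_occupancy:
        lo += 1
    while hi > lo and occ[hi - 1] < min_occupancy:
        hi -= 1
    if lo == hi:
        raise AlignmentError("trimming would remove every column")
    out = [SequenceRecord(r.taxon_label, r.gene, r.residues[lo:hi])
           for r in profile.member_records]
    return AlignmentProfile(out)


def low_occupancy_columns(profile: AlignmentProfile,
                          threshold: float = 0.25) -> list[int]:
    """Columns flagged for manual review (0-based indices)."""
    occ = profile.occupancy()
    return [int(i) for i in np.nonzero(occ < threshold)[0]]
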