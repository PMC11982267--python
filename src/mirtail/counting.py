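"""Dual-reference read counting: canonical vs mono-adenylated (+A) miRNA assignment.

Builds a paired reference (each mature sequence and the same sequence with one
extra 3' ``A``), trims 3' adapters, and classifies each read by full-length
exact-length Hamming comparison against both references.  The default is zero
mismatches, which makes the assignment a dictionary lookup and keeps the
counting exactly reproducible by a brute-force matcher.
"""

from __future__ import annotations

import gzip
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "MiRNARecord",
    "Collision",
    "ReferenceSet",
    "ReadAssignment",
    "CountTable",
    "build_references",
    "trim_adapter",
    "assign_read",
    "count_reads",
    "hamming",
]

_DNA = frozenset("ACGT")

ADENYLATED_SUFFIX = "+A"


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class MiRNARecord:
    """One mature miRNA: identifier plus DNA-space sequence."""

    mirna_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.mirna_id}: empty sequence")
        bad = set(self.sequence) - _DNA
        if bad:
            raise ValueError(
                f"{self.mirna_id}: non-ACGT characters {sorted(bad)!r} "
                "(use convert_u=True for RNA-space input)"
            )


@dataclass(frozen=True)
class Collision:
    """A pair of reference entries that cannot be distinguished by a read.

    kind is ``duplicate`` (two canonical sequences identical) or
    ``canonical-equals-adenylated`` (one canonical sequence equals another
    canonical sequence plus a terminal A).
    """

    id_a: str
    id_b: str
    kind: str


@dataclass
class ReferenceSet:
    """Paired canonical and +A references with collision annotations."""

    canonical: list[MiRNARecord]
    adenylated: list[MiRNARecord]
    collisions: list[Collision] = field(default_factory=list)
    _lookup: dict[str, list[tuple[str, str]]] | None = field(
        default=None, repr=False, compare=False
    )

    @classmethod
    def from_records(cls, records: Iterable[MiRNARecord]) -> "ReferenceSet":
        canonical = list(records)
        ids = [r.mirna_id for r in canonical]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate miRNA ids: {dup}")
        if not canonical:
            raise ValueError("empty reference")
        adenylated = [
            MiRNARecord(r.mirna_id + ADENYLATED_SUFFIX, r.sequence + "A")
            for r in canonical
        ]
        return cls(canonical, adenylated, collisions=_find_collisions(canonical))

    @property
    def mirna_ids(self) -> list[str]:
        return [r.mirna_id for r in self.canonical]

    def lookup(self) -> dict[str, list[tuple[str, str]]]:
        """Map sequence -> [(mirna_id, status)] over both references."""
        if self._lookup is None:
            table: dict[str, list[tuple[str, str]]] = {}
            for rec in self.canonical:
                table.setdefault(rec.sequence, []).append((rec.mirna_id, "canonical"))
            for can, ade in zip(self.canonical, self.adenylated):
                table.setdefault(ade.sequence, []).append((can.mirna_id, "adenylated"))
            self._lookup = table
        return self._lookup

    def collision_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.id_a, c.id_b, c.kind) for c in self.collisions],
            columns=["id_a", "id_b", "kind"],
        )


def _find_collisions(records: list[MiRNARecord]) -> list[Collision]:
    collisions: list[Collision] = []
    by_seq: dict[str, list[str]] = {}
    for r in records:
        by_seq.setdefault(r.sequence, []).append(r.mirna_id)
    for seq, ids in by_seq.items():
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                collisions.append(Collision(ids[i], ids[j], "duplicate"))
    # canonical(Y) == canonical(X) + "A": a read equal to Y is also X's +A form
    for r in records:
        stem = r.sequence[:-1]
        if r.sequence.endswith("A") and stem in by_seq:
            for other in by_seq[stem]:
                if other != r.mirna_id:
                    collisions.append(
                        Collision(other, r.mirna_id, "canonical-equals-adenylated")
                    )
    return collisions


def build_references(mature_fasta: str | Path, convert_u: bool = True) -> ReferenceSet:
    """Parse a mature-miRNA FASTA and build the canonical / +A reference pair.

    Parameters
    ----------
    mature_fasta:
        FASTA of mature sequences (DNA- or RNA-space).
    convert_u:
        Convert U to T on input (mature miRNA releases are RNA-space).
    """
    records = []
    with _open_text(mature_fasta) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if convert_u:
                seq = seq.replace("U", "T")
            records.append(MiRNARecord(rec.id, seq))
    if not records:
        raise ValueError(f"{mature_fasta}: no FASTA records found")
    return ReferenceSet.from_records(records)


def trim_adapter(
    read: str,
    adapter: str,
    max_mismatch: int = 0,
    min_overlap: int = 3,
) -> tuple[str, bool]:
    """Remove a 3' adapter from a read.

    Scans 5'->3' for the leftmost position where a prefix of the adapter (of
    length >= ``min_overlap``, or the full remaining read) matches within
    ``max_mismatch`` substitutions; that position and everything after it is
    removed.  Returns ``(trimmed_read, found)``; reads without a hit come back
    unchanged with ``found=False``.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty when trimming is enabled")
    n = len(read)
    for i in range(n):
        k = min(len(adapter), n - i)
        if k < min_overlap:
            break
        if hamming(read[i : i + k], adapter[:k]) <= max_mismatch:
            return read[:i], True
    return read, False


@dataclass(frozen=True)
class ReadAssignment:
    """Outcome of matching one read against the paired reference."""

    read_id: str
    status: str  # canonical | adenylated | ambiguous | unassigned
    mirna_id: str | None = None
    mismatches: int = 0

    def __post_init__(self) -> None:
        assigned = self.status in ("canonical", "adenylated")
        if assigned != (self.mirna_id is not None):
            raise ValueError("mirna_id must be present iff the read is assigned")


def assign_read(
    read: str,
    refset: ReferenceSet,
    max_mismatch: int = 0,
    policy: str = "ambiguous",
    read_id: str = "",
) -> ReadAssignment:
    """Classify one (already trimmed) read as canonical/adenylated/ambiguous/unassigned.

    Comparison is full-length and length-exact (Hamming distance, default 0).
    A read hitting both references or several miRNAs is ambiguous under the
    default policy; ``policy="canonical"`` lets a unique canonical hit win
    over adenylated hits.
    """
    if policy not in ("ambiguous", "canonical"):
        raise ValueError(f"unknown overlap policy {policy!r}")
    if max_mismatch == 0:
        hits = [(m, s, 0) for m, s in refset.lookup().get(read, [])]
    else:
        hits = []
        n = len(read)
        for rec in refset.canonical:
            if len(rec.sequence) == n:
                d = hamming(read, rec.sequence)
                if d <= max_mismatch:
                    hits.append((rec.mirna_id, "canonical", d))
        for can, ade in zip(refset.canonical, refset.adenylated):
            if len(ade.sequence) == n:
                d = hamming(read, ade.sequence)
                if d <= max_mismatch:
                    hits.append((can.mirna_id, "adenylated", d))
    if not hits:
        return ReadAssignment(read_id, "unassigned")
    distinct = sorted({(m, s) for m, s, _ in hits})
    if len(distinct) == 1:
        mirna, status = distinct[0]
        mm = min(d for _, _, d in hits)
        return ReadAssignment(read_id, status, mirna, mm)
    if policy == "canonical":
        canon = sorted({m for m, s in distinct if s == "canonical"})
        if len(canon) == 1:
            mm = min(d for m, s, d in hits if s == "canonical")
            return ReadAssignment(read_id, "canonical", canon[0], mm)
    return ReadAssignment(read_id, "ambiguous")


@dataclass
class CountTable:
    """Per-miRNA, per-sample canonical and adenylated read counts."""

    canonical: pd.DataFrame  # rows = miRNA ids, columns = samples
    adenylated: pd.DataFrame
    totals: pd.DataFrame  # rows = samples; assigned/ambiguous/unassigned/total

    def __post_init__(self) -> None:
        if not self.canonical.index.equals(self.adenylated.index):
            raise ValueError("canonical/adenylated row indices differ")
        if not self.canonical.columns.equals(self.adenylated.columns):
            raise ValueError("canonical/adenylated column sets differ")
        if (self.canonical.values < 0).any() or (self.adenylated.values < 0).any():
            raise ValueError("negative counts")

    @property
    def samples(self) -> list[str]:
        return list(self.canonical.columns)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.canonical.index)

    def check_conservation(self) -> None:
        """assigned + ambiguous + unassigned must equal total reads per sample."""
        t = self.totals
        lhs = t["assigned"] + t["ambiguous"] + t["unassigned"]
        if not (lhs == t["total"]).all():
            raise AssertionError("read-count conservation violated")

    def to_tsv(self, path: str | Path) -> None:
        """Write paired columns ``<sample>.canonical`` / ``<sample>.adenylated``."""
        out = {}
        for s in self.samples:
            out[f"{s}.canonical"] = self.canonical[s]
            out[f"{s}.adenylated"] = self.adenylated[s]
        frame = pd.DataFrame(out, index=self.canonical.index)
        frame.index.name = "mirna_id"
        frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        samples: list[str] = []
        for col in frame.columns:
            if col.endswith(".canonical"):
                samples.append(col[: -len(".canonical")])
        canonical = pd.DataFrame(
            {s: frame[f"{s}.canonical"] for s in samples}, index=frame.index
        )
        adenylated = pd.DataFrame(
            {s: frame[f"{s}.adenylated"] for s in samples}, index=frame.index
        )
        totals = pd.DataFrame(
            {
                "assigned": canonical.sum() + adenylated.sum(),
                "ambiguous": 0,
                "unassigned": 0,
            }
        )
        totals["total"] = totals.sum(axis=1)
        return cls(canonical, adenylated, totals)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path: str | Path):
    """Yield (read_id, sequence) from a FASTQ(.gz); errors name file and record."""
    index = 0
    try:
        with _open_text(path) as handle:
            for title, seq, _qual in FastqGeneralIterator(handle):
                index += 1
                yield title.split(None, 1)[0], seq.upper()
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FASTQ at record {index + 1}: {exc}") from exc


def count_reads(
    sample_fastqs: Mapping[str, str | Path],
    refset: ReferenceSet,
    max_mismatch: int = 0,
    adapter: str = "",
    adapter_max_mismatch: int = 1,
    min_overlap: int = 3,
    policy: str = "ambiguous",
) -> CountTable:
    """Tally canonical/adenylated assignments per sample over FASTQ libraries.

    ``sample_fastqs`` maps sample id -> FASTQ path.  When ``adapter`` is given
    each read is 3'-trimmed before assignment.  Conservation (assigned +
    ambiguous + unassigned == total) holds by construction and is re-checked.
    """
    ids = refset.mirna_ids
    canon_cols: dict[str, dict[str, int]] = {}
    aden_cols: dict[str, dict[str, int]] = {}
    totals_rows = []
    for sample, path in sample_fastqs.items():
        canon: dict[str, int] = {}
        aden: dict[str, int] = {}
        n_total = n_assigned = n_ambiguous = n_unassigned = 0
        for read_id, seq in iter_fastq(path):
            if adapter:
                seq, _ = trim_adapter(seq, adapter, adapter_max_mismatch, min_overlap)
            a = assign_read(seq, refset, max_mismatch, policy, read_id)
            n_total += 1
            if a.status == "canonical":
                canon[a.mirna_id] = canon.get(a.mirna_id, 0) + 1
                n_assigned += 1
            elif a.status == "adenylated":
                aden[a.mirna_id] = aden.get(a.mirna_id, 0) + 1
                n_assigned += 1
            elif a.status == "ambiguous":
                n_ambiguous += 1
            else:
                n_unassigned += 1
        canon_cols[sample] = canon
        aden_cols[sample] = aden
        totals_rows.append((n_assigned, n_ambiguous, n_unassigned, n_total))
    canonical = pd.DataFrame(
        {s: [canon_cols[s].get(m, 0) for m in ids] for s in sample_fastqs},
        index=ids,
        dtype=int,
    )
    adenylated = pd.DataFrame(
        {s: [aden_cols[s].get(m, 0) for m in ids] for s in sample_fastqs},
        index=ids,
        dtype=int,
    )
    totals = pd.DataFrame(
        totals_rows,
        index=list(sample_fastqs),
        columns=["assigned", "ambiguous", "unassigned", "total"],
        dtype=int,
    )
    table = CountTable(canonical, adenylated, totals)
    table.check_conservation()
    return table
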