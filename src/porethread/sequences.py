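"""Substrate isoform sequences and overlapping peptide windows.

The threading analysis operates on every overlapping k-mer of a set of
substrate isoform sequences.  For the bovine casein substrate used
throughout, the four precursor isoforms (alpha-S1, alpha-S2, beta, kappa;
signal peptide *included*) give exactly 802 distinct 13-residue windows,
each of which is threaded once per AAA+ ring.

Residue coordinates are 1-based and inclusive.  Precursor numbering is
used for the bundled casein records: the reported optimal peptides
(kappa 8-18 = VVTILALTLPF, beta 5-15 = ILACLVALALA) index into the
signal-peptide-included sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical one-letter amino-acid codes.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

_CANONICAL_SET = frozenset(CANONICAL_AA)


class SequenceError(ValueError):
    """Raised for malformed sequence input (bad letters, bad regions)."""


@dataclass(frozen=True)
class IsoformRecord:
    """One substrate isoform: identifier, amino-acid sequence, description."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class IsoformSet:
    """An ordered set of substrate isoform records with unique ids."""

    records: list[IsoformRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise SequenceError(f"duplicate isoform ids: {ids}")
        for rec in self.records:
            _validate_sequence(rec.id, rec.sequence)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, isoform_id: str) -> IsoformRecord:
        for rec in self.records:
            if rec.id == isoform_id:
                return rec
        raise KeyError(f"unknown isoform id {isoform_id!r}")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass(frozen=True)
class PeptideWindow:
    """A k-mer cut from a source isoform.

    ``start`` is the 1-based index of the window's first residue in the
    source sequence.  ``ring_tag`` is assigned at threading time (e.g.
    NBD1 / NBD2) and is ``None`` until then.
    """

    source_id: str
    start: int
    sequence: str
    ring_tag: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        """1-based inclusive index of the last residue in the source."""
        return self.start + len(self.sequence) - 1

    def with_ring(self, ring_tag: str) -> "PeptideWindow":
        return replace(self, ring_tag=ring_tag)


def _validate_sequence(rec_id: str, seq: str) -> None:
    for pos, letter in enumerate(seq, start=1):
        if letter not in _CANONICAL_SET:
            raise SequenceError(
                f"record {rec_id!r}: illegal residue letter {letter!r} "
                f"at position {pos}"
            )


def read_fasta(
    path: str | Path,
    noncanonical: str | Mapping[str, str] = "reject",
) -> IsoformSet:
    """Read substrate isoforms from a FASTA file.

    Parameters
    ----------
    path:
        FASTA file with one entry per isoform.
    noncanonical:
        ``"reject"`` (default) raises on any letter outside the 20
        canonical codes; alternatively a mapping (e.g. ``{"X": "A"}``)
        substitutes non-canonical letters before validation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if isinstance(noncanonical, Mapping):
            seq = "".join(noncanonical.get(c, c) for c in seq)
        _validate_sequence(entry.id, seq)
        records.append(
            IsoformRecord(id=entry.id, sequence=seq, description=entry.description)
        )
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return IsoformSet(records=records)


def load_casein_precursors() -> IsoformSet:
    """Load the bundled bovine casein precursor isoforms.

    Returns the four precursor sequences (alpha-S1, alpha-S2, beta,
    kappa; UniProt P02662 / P02663 / P02666 / P02668) with signal
    peptides included, the substrate set used by the threading study.
    """
    ref = resources.files("porethread.data") / "casein_precursors.fasta"
    with resources.as_file(ref) as path:
        return read_fasta(path)


def generate_windows(isoforms: IsoformSet, k: int) -> list[PeptideWindow]:
    """Enumerate all overlapping k-mers over every isoform.

    For a sequence of length ``L >= k`` this yields exactly ``L - k + 1``
    windows with step 1, ordered by record then start position.
    Sequences shorter than ``k`` are skipped with a warning.
    """
    if k < 3:
        raise ValueError(f"window length k must be >= 3, got {k}")
    if len(isoforms) == 0:
        raise SequenceError("cannot generate windows from an empty isoform set")
    windows: list[PeptideWindow] = []
    for rec in isoforms:
        if len(rec) < k:
            logger.warning(
                "isoform %r (length %d) shorter than window length %d; skipped",
                rec.id, len(rec), k,
            )
            continue
        for start in range(1, len(rec) - k + 2):
            windows.append(
                PeptideWindow(
                    source_id=rec.id,
                    start=start,
                    sequence=rec.sequence[start - 1 : start - 1 + k],
                )
            )
    if not windows:
        raise SequenceError(f"all sequences are shorter than window length {k}")
    return windows


def window_at(
    isoforms: IsoformSet, isoform_id: str, start: int, end: int
) -> PeptideWindow:
    """Cut the window spanning 1-based inclusive residues [start, end]."""
    rec = isoforms.get(isoform_id)
    if start < 1 or end > len(rec) or end < start:
        raise SequenceError(
            f"region {start}-{end} out of range for isoform {isoform_id!r} "
            f"(length {len(rec)})"
        )
    return PeptideWindow(
        source_id=isoform_id,
        start=start,
        sequence=rec.sequence[start - 1 : end],
    )


def windows_to_tsv(windows: Iterable[PeptideWindow], path: str | Path) -> None:
    """Write windows as a TSV table (source_id, start, sequence)."""
    df = pd.DataFrame(
        [(w.source_id, w.start, w.sequence) for w in windows],
        columns=["source_id", "start", "sequence"],
    )
    df.to_csv(path, sep="\t", index=False)


def windows_from_tsv(path: str | Path) -> list[PeptideWindow]:
    """Read windows previously written by :func:`windows_to_tsv`."""
    df = pd.read_csv(path, sep="\t")
    return [
        PeptideWindow(source_id=str(r.source_id), start=int(r.start),
                      sequence=str(r.sequence))
        for r in df.itertuples()
    ]
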