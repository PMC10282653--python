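"""FASTQ parsing, clean-read filtering and tag extraction from reads.

A 2bRAD library puts exactly one enzyme-excised fragment in each read, so
classification needs only (i) the standard short-read quality filters and
(ii) recovery of the iso-length tag anchored at the recognition motif.

Clean-read rules (checked in this fixed order, first failure reported):

1. ``too_many_N``  — fraction of unknown bases strictly above 8%;
2. ``low_quality`` — fraction of bases below Q30 strictly above 20%;
3. ``no_site``     — no recognition motif on either strand.

Boundary reads (exactly 8% N, exactly 20% sub-Q30) are kept.  Qualities
are Phred+33.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .digest import DigestScheme, canonical, _site_window

__all__ = [
    "SequencingRead",
    "QCPolicy",
    "QCSummary",
    "qc_filter",
    "extract_read_tag",
    "parse_fastq",
    "clean_tags_from_fastq",
]

PHRED_OFFSET = 33

REASON_PASS = "pass"
REASON_NO_SITE = "no_site"
REASON_TOO_MANY_N = "too_many_N"
REASON_LOW_QUALITY = "low_quality"
REASONS = (REASON_PASS, REASON_NO_SITE, REASON_TOO_MANY_N, REASON_LOW_QUALITY)


@dataclass(frozen=True)
class SequencingRead:
    read_id: str
    bases: str
    quals: str

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id}: base/quality length mismatch "
                f"({len(self.bases)} vs {len(self.quals)})"
            )

    def phred(self) -> np.ndarray:
        """Per-base Phred scores as an integer array."""
        return (
            np.frombuffer(self.quals.encode("ascii"), dtype=np.uint8).astype(np.int32)
            - PHRED_OFFSET
        )


@dataclass(frozen=True)
class QCPolicy:
    max_unknown_frac: float = 0.08
    q_threshold: int = 30
    max_lowq_frac: float = 0.20
    require_site: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.max_unknown_frac <= 1 and 0 <= self.max_lowq_frac <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.q_threshold < 0:
            raise ValueError("q_threshold must be non-negative")


def qc_filter(
    read: SequencingRead,
    policy: QCPolicy | None = None,
    scheme: DigestScheme | None = None,
) -> tuple[bool, str]:
    """Apply the clean-read filters; return ``(keep, reason)``."""
    policy = policy or QCPolicy()
    scheme = scheme or DigestScheme()
    n = len(read.bases)
    if n == 0:
        return False, REASON_NO_SITE
    bases = read.bases.upper()
    if bases.count("N") / n > policy.max_unknown_frac:
        return False, REASON_TOO_MANY_N
    if (read.phred() < policy.q_threshold).sum() / n > policy.max_lowq_frac:
        return False, REASON_LOW_QUALITY
    if policy.require_site:
        if scheme.plus_regex.search(bases) is None and (
            scheme.is_palindromic() or scheme.minus_regex.search(bases) is None
        ):
            return False, REASON_NO_SITE
    return True, REASON_PASS


def extract_read_tag(
    read: SequencingRead | str, scheme: DigestScheme | None = None
) -> str | None:
    """Recover the canonical tag from a read, or None.

    The leftmost plus-strand motif wins, then the leftmost minus-strand
    one; the window must be fully contained in the read and free of N.
    One tag per read — the library geometry yields one fragment per read.
    """
    scheme = scheme or DigestScheme()
    bases = (read if isinstance(read, str) else read.bases).upper()
    searches = [("+", scheme.plus_regex)]
    if not scheme.is_palindromic():
        searches.append(("-", scheme.minus_regex))
    for strand, regex in searches:
        for m in regex.finditer(bases):
            start, end = _site_window(m.start(), strand, scheme)
            if start < 0 or end > len(bases):
                continue
            window = bases[start:end]
            if "N" in window:
                continue
            return canonical(window)
    return None


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def parse_fastq(path: str | Path) -> Iterator[SequencingRead]:
    """Iterate over reads in a (optionally gzipped) FASTQ file."""
    with _open_text(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield SequencingRead(title.split()[0], seq, qual)


@dataclass
class QCSummary:
    """Per-reason read tallies for one sample; conserves the total."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_pass(self) -> int:
        return self.counts.get(REASON_PASS, 0)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"total": self.total, **self.counts}, fh, indent=2)


def clean_tags_from_fastq(
    path: str | Path,
    policy: QCPolicy | None = None,
    scheme: DigestScheme | None = None,
) -> tuple[list[tuple[str, str]], QCSummary]:
    """QC a FASTQ file and extract one canonical tag per clean read.

    Returns ``(read_id, tag)`` pairs for clean tag-bearing reads plus the
    QC summary.  A clean read whose motif window is truncated or
    N-containing yields no tag but still counts as passing QC.
    """
    policy = policy or QCPolicy()
    scheme = scheme or DigestScheme()
    counts = {r: 0 for r in REASONS}
    tags: list[tuple[str, str]] = []
    for read in parse_fastq(path):
        keep, reason = qc_filter(read, policy, scheme)
        counts[reason] += 1
        if keep:
            tag = extract_read_tag(read, scheme)
            if tag is not None:
                tags.append((read.read_id, tag))
    return tags, QCSummary(counts)


def write_tags_tsv(tags: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\ttag\n")
        for read_id, tag in tags:
            fh.write(f"{read_id}\t{tag}\n")


def read_tags_tsv(path: str | Path) -> list[tuple[str, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            read_id, tag = line.rstrip("\n").split("\t")
            out.append((read_id, tag))
    return out
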