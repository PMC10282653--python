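"""In-silico type IIB restriction digest and species-unique tag database.

Type IIB restriction endonucleases (the default here is BcgI, recognition
site CGA-N6-TGC) cleave both strands on both sides of a bipartite
recognition site, excising an iso-length fragment centred on the site.
Digesting a reference genome in silico therefore yields a reproducible set
of fixed-length "tags", one per recognition site.  Tags observed in exactly
one species of a reference collection form a species-unique marker
database against which sequencing reads can be classified by exact match.

Coordinates are 0-based, half-open.  Tags are stored in *canonical*
orientation: the lexicographic minimum of the window and its reverse
complement, which makes genome-derived and read-derived tags comparable
regardless of strand.
"""

from __future__ import annotations

import functools
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "DigestScheme",
    "ReferenceGenome",
    "UniqueTagDB",
    "revcomp",
    "canonical",
    "scan_recognition_sites",
    "extract_tags",
    "build_unique_tag_db",
    "read_reference_fasta",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Canonical orientation: lexicographic min of ``seq`` and its reverse
    complement.  Idempotent and strand-symmetric."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


@functools.lru_cache(maxsize=64)
def _compiled_motif(motif: str) -> re.Pattern[str]:
    # lookahead so overlapping sites are all reported; degenerate N matches
    # a real base, never an ambiguous N in the data
    return re.compile("(?=(" + motif.replace("N", "[ACGT]") + "))")


@dataclass(frozen=True)
class DigestScheme:
    """Geometry of a type IIB digest.

    Parameters
    ----------
    recognition:
        Recognition motif with ``N`` marking degenerate positions.
        Default is the BcgI site CGA(N6)TGC, 12 bp.
    arm5, arm3:
        Number of flanking bases kept upstream / downstream of the motif
        (in motif orientation).  The enzyme cuts a fixed distance outside
        the site on both sides, so the excised fragment is iso-length:
        ``tag_length = arm5 + len(recognition) + arm3``.
    """

    recognition: str = "CGANNNNNNTGC"
    arm5: int = 10
    arm3: int = 10

    def __post_init__(self) -> None:
        if self.arm5 < 0 or self.arm3 < 0:
            raise ValueError("arm lengths must be non-negative")
        if not re.fullmatch("[ACGTN]+", self.recognition):
            raise ValueError(f"bad recognition motif: {self.recognition!r}")

    @property
    def motif_length(self) -> int:
        return len(self.recognition)

    @property
    def tag_length(self) -> int:
        return self.arm5 + self.motif_length + self.arm3

    @property
    def plus_regex(self) -> re.Pattern[str]:
        return _compiled_motif(self.recognition)

    @property
    def minus_regex(self) -> re.Pattern[str]:
        return _compiled_motif(revcomp(self.recognition))

    def is_palindromic(self) -> bool:
        return self.recognition == revcomp(self.recognition)

    def to_dict(self) -> dict:
        return {
            "recognition": self.recognition,
            "arm5": self.arm5,
            "arm3": self.arm3,
            "tag_length": self.tag_length,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DigestScheme":
        scheme = cls(
            recognition=d["recognition"], arm5=int(d["arm5"]), arm3=int(d["arm3"])
        )
        if "tag_length" in d and int(d["tag_length"]) != scheme.tag_length:
            raise ValueError("inconsistent tag_length in serialized scheme")
        return scheme


@dataclass
class ReferenceGenome:
    """A reference genome: a species label plus one or more contigs."""

    species_id: str
    contigs: Sequence[str]

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")
        if not self.contigs:
            raise ValueError(f"{self.species_id}: no contigs")


def scan_recognition_sites(
    sequence: str, scheme: DigestScheme | None = None
) -> list[tuple[int, str]]:
    """Locate every recognition site on either strand.

    Returns ``(offset, strand)`` pairs where *offset* is the 0-based
    plus-strand position of the motif's first base.  Overlapping sites are
    all reported; the list is sorted by offset (plus strand first on ties).
    """
    scheme = scheme or DigestScheme()
    sequence = sequence.upper()
    hits = [(m.start(), "+") for m in scheme.plus_regex.finditer(sequence)]
    if not scheme.is_palindromic():
        hits += [(m.start(), "-") for m in scheme.minus_regex.finditer(sequence)]
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _site_window(offset: int, strand: str, scheme: DigestScheme) -> tuple[int, int]:
    """Plus-strand [start, end) of the iso-length window around a site."""
    if strand == "+":
        return offset - scheme.arm5, offset + scheme.motif_length + scheme.arm3
    return offset - scheme.arm3, offset + scheme.motif_length + scheme.arm5


def extract_tags(
    genome: ReferenceGenome, scheme: DigestScheme | None = None
) -> Counter:
    """Digest a genome in silico: canonical tag multiset over all contigs.

    Sites whose window would run off a contig end are discarded, as are
    windows containing ambiguous bases (an N can never be matched exactly
    by a read).
    """
    scheme = scheme or DigestScheme()
    tags: Counter = Counter()
    for contig in genome.contigs:
        contig = contig.upper()
        for offset, strand in scan_recognition_sites(contig, scheme):
            start, end = _site_window(offset, strand, scheme)
            if start < 0 or end > len(contig):
                continue
            window = contig[start:end]
            if "N" in window:
                continue
            tags[canonical(window)] += 1
    return tags


@dataclass
class UniqueTagDB:
    """Species-unique tag database.

    ``tag_to_species`` holds only tags found in exactly one species;
    ``T`` gives, per species, the number of distinct unique tags — the
    theoretical marker count used to normalise read counts into coverage.
    """

    scheme: DigestScheme
    tag_to_species: dict[str, str]
    T: dict[str, int]
    build_report: dict = field(default_factory=dict)

    SCHEMA_VERSION = 1

    def __post_init__(self) -> None:
        counts = Counter(self.tag_to_species.values())
        for sp, n in self.T.items():
            if counts.get(sp, 0) != n:
                raise ValueError(f"T[{sp}]={n} inconsistent with tag table")
        for tag in self.tag_to_species:
            if len(tag) != self.scheme.tag_length:
                raise ValueError(f"tag of wrong length in DB: {tag}")

    @property
    def species(self) -> list[str]:
        return sorted(self.T)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "tags.tsv", "w") as fh:
            fh.write("#tag\tspecies_id\n")
            for tag in sorted(self.tag_to_species):
                fh.write(f"{tag}\t{self.tag_to_species[tag]}\n")
        sidecar = {
            "schema_version": self.SCHEMA_VERSION,
            "scheme": self.scheme.to_dict(),
            "T": dict(sorted(self.T.items())),
            "build_report": self.build_report,
        }
        with open(outdir / "db.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, dbdir: str | Path) -> "UniqueTagDB":
        dbdir = Path(dbdir)
        with open(dbdir / "db.json") as fh:
            sidecar = json.load(fh)
        if sidecar.get("schema_version") != cls.SCHEMA_VERSION:
            raise ValueError("unsupported tag-DB schema version")
        tag_to_species: dict[str, str] = {}
        with open(dbdir / "tags.tsv") as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                tag, sp = line.rstrip("\n").split("\t")
                tag_to_species[tag] = sp
        return cls(
            scheme=DigestScheme.from_dict(sidecar["scheme"]),
            tag_to_species=tag_to_species,
            T={k: int(v) for k, v in sidecar["T"].items()},
            build_report=sidecar.get("build_report", {}),
        )


def build_unique_tag_db(
    genomes: Iterable[ReferenceGenome], scheme: DigestScheme | None = None
) -> UniqueTagDB:
    """Build the species-unique tag database from a reference set.

    Tags shared by two or more species are excluded entirely (exact-match
    classification cannot disambiguate them); tags repeated within one
    species count once towards that species' theoretical marker count T.
    Species left with zero unique tags are retained with T = 0 and flagged
    in the build report.
    """
    scheme = scheme or DigestScheme()
    per_species_tags: dict[str, set[str]] = {}
    for genome in genomes:
        if genome.species_id in per_species_tags:
            raise ValueError(f"duplicate species_id: {genome.species_id}")
        per_species_tags[genome.species_id] = set(extract_tags(genome, scheme))
    if not per_species_tags:
        raise ValueError("no genomes supplied")

    occupancy: Counter = Counter()
    for tags in per_species_tags.values():
        occupancy.update(tags)

    tag_to_species = {
        tag: sp
        for sp, tags in per_species_tags.items()
        for tag in tags
        if occupancy[tag] == 1
    }
    T = {sp: 0 for sp in per_species_tags}
    for sp in tag_to_species.values():
        T[sp] += 1
    shared = sum(1 for n in occupancy.values() if n > 1)
    report = {
        "n_species": len(per_species_tags),
        "n_unique_tags": len(tag_to_species),
        "n_shared_tags_excluded": shared,
        "species_without_unique_tags": sorted(sp for sp, n in T.items() if n == 0),
    }
    return UniqueTagDB(
        scheme=scheme, tag_to_species=tag_to_species, T=T, build_report=report
    )


def read_reference_fasta(
    path: str | Path, manifest: Mapping[str, str] | None = None
) -> list[ReferenceGenome]:
    """Read reference genomes from a multi-record FASTA.

    Record IDs are parsed as ``<species_id>|<contig_id>``; alternatively a
    *manifest* maps record IDs to species labels.  Contigs sharing a
    species label are grouped into one genome.
    """
    contigs: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if manifest is not None:
            if rec.id not in manifest:
                raise ValueError(f"record {rec.id} missing from manifest")
            sp = manifest[rec.id]
        else:
            sp = rec.id.split("|", 1)[0]
        contigs.setdefault(sp, []).append(str(rec.seq).upper())
    return [ReferenceGenome(sp, seqs) for sp, seqs in contigs.items()]
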