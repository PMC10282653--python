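"""Synthetic mock communities with ground truth.

Generates everything the pipeline consumes — reference genomes with a
controlled number of planted BcgI recognition sites, two-group community
compositions with planted differentially abundant species, and tag-bearing
short reads with configurable error, unknown-base and quality models —
together with a truth set (true compositions and per-read provenance) so
recovery can be verified exactly.

Genomes are rejection-checked: random background sequence is scrubbed of
spurious recognition sites before the requested sites are planted at
well-spaced positions, and the final genome is re-scanned to confirm the
site count.  Reads are 100 bp, one tag per read inside random non-motif
padding, mimicking the gel-selected ~100 bp 2bRAD library geometry.
Errors are substitution-only: tag classification is exact-match, so an
indel and a substitution are equally fatal to a tag and equally harmless
to padding.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .digest import (
    DigestScheme,
    ReferenceGenome,
    canonical,
    revcomp,
    scan_recognition_sites,
)
from .readqc import PHRED_OFFSET, extract_read_tag

__all__ = ["SynthConfig", "TruthSet", "StudyData", "generate_reference_set",
           "generate_composition", "simulate_sample_reads", "generate_study",
           "write_fastq"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DECOY_ID = "decoy_offdb"


@dataclass(frozen=True)
class SynthConfig:
    """Study-shape parameters for the synthetic generator.

    Group sizes default to 15 and 7 to mirror a typical imbalanced
    two-arm tumour cohort (MIBC vs NMIBC); reads per sample default to a
    desk-scale 100k.  Error/quality defaults approximate a well-behaved
    Illumina run: 0.1% substitutions, 0.1% ambiguous bases, 5% of bases
    drawn from a low-quality state.
    """

    n_species: int = 12
    genome_length: int = 20_000
    sites_per_genome: int = 50
    group_names: tuple[str, str] = ("MIBC", "NMIBC")
    n_samples_per_group: tuple[int, int] = (15, 7)
    reads_per_sample: int = 100_000
    read_length: int = 100
    base_error_rate: float = 0.001
    n_rate: float = 0.001
    quality_high: int = 38
    quality_low: int = 12
    low_quality_prob: float = 0.05
    # (species index, log2 fold-change, group name) triples
    planted_differentials: tuple[tuple[int, float, str], ...] = ()
    composition_mu: float = 0.0
    composition_sigma: float = 1.0
    contaminant_rate: float = 0.0
    plant_shared_tag: bool = False
    seed: int = 0
    scheme: DigestScheme = field(default_factory=DigestScheme)

    def __post_init__(self) -> None:
        for rate in (self.base_error_rate, self.n_rate, self.low_quality_prob,
                     self.contaminant_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.sites_per_genome < 1:
            raise ValueError("sites_per_genome must be >= 1")
        if self.read_length < self.scheme.tag_length:
            raise ValueError("read_length shorter than tag length")
        for sp, _, grp in self.planted_differentials:
            if not 0 <= sp < self.n_species:
                raise ValueError(f"differential species index {sp} out of range")
            if grp not in self.group_names:
                raise ValueError(f"unknown group {grp!r} in planted differential")

    def species_ids(self) -> list[str]:
        return [f"Synthospira_sp{i:06d}" for i in range(self.n_species)]

    def sample_ids(self) -> list[str]:
        out = []
        for g, n in zip(self.group_names, self.n_samples_per_group):
            out += [f"{g}_{k + 1:02d}" for k in range(n)]
        return out

    def groups(self) -> pd.Series:
        labels = []
        for g, n in zip(self.group_names, self.n_samples_per_group):
            labels += [g] * n
        return pd.Series(labels, index=self.sample_ids(), name="group")


@dataclass
class TruthSet:
    """Ground truth: true compositions, planted effects, read provenance."""

    composition: pd.DataFrame  # samples x species, rows sum to 1
    planted_differentials: tuple[tuple[int, float, str], ...]
    provenance: dict[str, pd.DataFrame] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _scrub_motifs(seq: np.ndarray, scheme: DigestScheme,
                  rng: np.random.Generator) -> np.ndarray:
    """Randomise bases at every recognition site until none remain."""
    for _ in range(100):
        hits = scan_recognition_sites(seq.tobytes().decode(), scheme)
        if not hits:
            return seq
        for offset, _ in hits:
            seq[offset:offset + scheme.motif_length] = _random_seq(
                rng, scheme.motif_length
            )
    raise RuntimeError("failed to scrub spurious recognition sites")


def _spaced_positions(rng: np.random.Generator, n_sites: int, low: int, high: int,
                      min_gap: int) -> np.ndarray:
    """n_sites sorted positions in [low, high) with pairwise gaps >= min_gap."""
    span = high - low - (n_sites - 1) * min_gap
    if span <= 0:
        raise ValueError("genome too small for the requested number of sites")
    raw = np.sort(rng.integers(0, span, size=n_sites))
    return low + raw + np.arange(n_sites) * min_gap


def _plant_genome(rng: np.random.Generator, config: SynthConfig) -> str:
    """One genome with exactly ``sites_per_genome`` recognition sites."""
    scheme = config.scheme
    mlen = scheme.motif_length
    fixed = np.frombuffer(scheme.recognition.encode(), dtype=np.uint8)
    wild = fixed == ord("N")
    margin = max(scheme.arm5, scheme.arm3)
    for _ in range(50):
        seq = _scrub_motifs(_random_seq(rng, config.genome_length), scheme, rng)
        positions = _spaced_positions(
            rng, config.sites_per_genome, margin,
            config.genome_length - mlen - margin, scheme.tag_length,
        )
        for pos in positions:
            motif = fixed.copy()
            motif[wild] = _random_seq(rng, int(wild.sum()))
            seq[pos:pos + mlen] = motif
        genome = seq.tobytes().decode()
        if len(scan_recognition_sites(genome, scheme)) == config.sites_per_genome:
            return genome
    raise RuntimeError("could not build a genome with the requested site count")


def generate_reference_set(
    config: SynthConfig,
) -> tuple[list[ReferenceGenome], pd.DataFrame, ReferenceGenome]:
    """Reference genomes, a taxonomy map and an off-database decoy genome.

    With ``plant_shared_tag`` the first tag window of species 0 is copied
    into species 1 (replacing one of its sites), so the two species share
    one canonical tag and each loses exactly one unique marker.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    species = config.species_ids()
    genomes = [
        ReferenceGenome(sp, [_plant_genome(rng, config)]) for sp in species
    ]
    if config.plant_shared_tag and config.n_species >= 2:
        genomes[1] = ReferenceGenome(
            species[1],
            [_transplant_first_window(genomes[0].contigs[0],
                                      genomes[1].contigs[0], config.scheme)],
        )
    decoy = ReferenceGenome(DECOY_ID, [_plant_genome(rng, config)])
    taxonomy = pd.DataFrame(
        {
            "genus": [f"Synthogenus{i // 2:03d}" for i in range(len(species))],
            "phylum": [f"Synthophyta{i // 6:02d}" for i in range(len(species))],
        },
        index=pd.Index(species, name="species_id"),
    )
    return genomes, taxonomy, decoy


def _transplant_first_window(src: str, dst: str, scheme: DigestScheme) -> str:
    """Copy the first tag window of ``src`` over the first site of ``dst``."""
    s_off, s_strand = scan_recognition_sites(src, scheme)[0]
    d_off, _ = scan_recognition_sites(dst, scheme)[0]
    start = s_off - (scheme.arm5 if s_strand == "+" else scheme.arm3)
    window = src[start:start + scheme.tag_length]
    d_start = d_off - scheme.arm5
    out = dst[:d_start] + window + dst[d_start + scheme.tag_length:]
    return out


def generate_composition(config: SynthConfig) -> TruthSet:
    """Two-group community compositions with planted fold-changes.

    Per-sample species loadings are log-normal(mu, sigma); each planted
    differential multiplies one species' loading by 2^lfc in its
    designated group; rows are normalised to sum to 1.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    groups = config.groups()
    n = len(groups)
    load = rng.lognormal(config.composition_mu, config.composition_sigma,
                         size=(n, config.n_species))
    for sp_idx, lfc, grp in config.planted_differentials:
        load[(groups == grp).to_numpy(), sp_idx] *= 2.0 ** lfc
    comp = load / load.sum(axis=1, keepdims=True)
    frame = pd.DataFrame(comp, index=groups.index, columns=config.species_ids())
    return TruthSet(composition=frame,
                    planted_differentials=config.planted_differentials)


def _species_tag_windows(
    genomes: Sequence[ReferenceGenome], scheme: DigestScheme
) -> list[list[str]]:
    """Per-genome plus-strand tag windows, in genome order."""
    out = []
    for genome in genomes:
        windows = []
        for contig in genome.contigs:
            for offset, strand in scan_recognition_sites(contig, scheme):
                start = offset - (scheme.arm5 if strand == "+" else scheme.arm3)
                windows.append(contig[start:start + scheme.tag_length])
        out.append(windows)
    return out


def _motif_counts(arr: np.ndarray, scheme: DigestScheme) -> np.ndarray:
    """Recognition-site count per row of a uint8 base matrix (both strands)."""
    n, L = arr.shape
    motifs = [scheme.recognition]
    if not scheme.is_palindromic():
        motifs.append(revcomp(scheme.recognition))
    counts = np.zeros(n, dtype=np.int64)
    for motif in motifs:
        m = np.frombuffer(motif.encode(), dtype=np.uint8)
        width = L - len(m) + 1
        if width <= 0:
            continue
        hit = np.ones((n, width), dtype=bool)
        for j in np.flatnonzero(m != ord("N")):
            hit &= arr[:, j:j + width] == m[j]
        counts += hit.sum(axis=1)
    return counts


def simulate_sample_reads(
    genomes: Sequence[ReferenceGenome],
    comp_row: np.ndarray,
    config: SynthConfig,
    rng: np.random.Generator,
    sample_id: str,
    decoy: ReferenceGenome | None = None,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate one sample's reads.

    Returns ``(reads, provenance)`` where reads are (id, bases, quals)
    triples and provenance records each read's source species, source tag
    and substitution/N positions.  Reads are drawn species-proportional to
    composition x marker count, each read carrying one randomly oriented
    tag inside random padding that is rejection-checked to introduce no
    spurious recognition site.
    """
    scheme = config.scheme
    tag_windows = _species_tag_windows(genomes, scheme)
    decoy_windows = _species_tag_windows([decoy], scheme)[0] if decoy else []
    names = [g.species_id for g in genomes]

    weights = np.asarray(comp_row, dtype=float) * np.array(
        [len(w) for w in tag_windows], dtype=float
    )
    weights = weights / weights.sum()
    n = config.reads_per_sample
    contaminant = (
        rng.random(n) < config.contaminant_rate if decoy is not None
        else np.zeros(n, dtype=bool)
    )
    source = rng.choice(len(genomes), size=n, p=weights)
    flip = rng.random(n) < 0.5
    pad_total = config.read_length - scheme.tag_length
    left_len = rng.integers(0, pad_total + 1, size=n)
    n_tags = np.array([len(w) for w in tag_windows])
    tag_idx = rng.integers(0, n_tags[source])
    decoy_idx = (
        rng.integers(0, len(decoy_windows), size=n) if decoy_windows else None
    )
    pads = rng.integers(0, 4, size=(n, pad_total))

    fwd = [[w for w in ws] for ws in tag_windows + [decoy_windows]]
    rev = [[revcomp(w) for w in ws] for ws in fwd]
    canon = [[canonical(w) for w in ws] for ws in fwd]

    inserts: list[str] = []
    prov_rows = []
    for i in range(n):
        if contaminant[i]:
            sp, ti, sp_name = len(fwd) - 1, decoy_idx[i], DECOY_ID
        else:
            sp, ti, sp_name = source[i], tag_idx[i], names[source[i]]
        inserts.append(rev[sp][ti] if flip[i] else fwd[sp][ti])
        prov_rows.append((f"{sample_id}:{i}", sp_name, canon[sp][ti]))

    # assemble reads as one uint8 matrix: pad | tag | pad, grouped by the
    # (random) left-pad length so the splice is vectorised
    tl = scheme.tag_length
    insert_arr = np.frombuffer("".join(inserts).encode(), dtype=np.uint8)
    insert_arr = insert_arr.reshape(n, tl)
    base_arr = np.empty((n, config.read_length), dtype=np.uint8)
    pad_arr = _BASES[pads]
    for k in range(pad_total + 1):
        rows = np.flatnonzero(left_len == k)
        if len(rows) == 0:
            continue
        base_arr[rows, :k] = pad_arr[rows, :k]
        base_arr[rows, k:k + tl] = insert_arr[rows]
        base_arr[rows, k + tl:] = pad_arr[rows, k:]

    # rejection check: padding must not introduce a recognition site, so
    # the planted tag is the one a motif-anchored extraction recovers
    bad = np.flatnonzero(_motif_counts(base_arr, scheme) != 1)
    for i in bad:
        k = int(left_len[i])
        read = base_arr[i].tobytes().decode()
        while extract_read_tag(read, scheme) != prov_rows[i][2]:
            pad = _random_seq(rng, pad_total).tobytes().decode()
            read = pad[:k] + inserts[i] + pad[k:]
        base_arr[i] = np.frombuffer(read.encode(), dtype=np.uint8)

    err_mask = rng.random(base_arr.shape) < config.base_error_rate
    if err_mask.any():
        shift = rng.integers(1, 4, size=int(err_mask.sum()))
        lut = np.zeros(256, dtype=np.int64)
        lut[_BASES] = np.arange(4)
        base_arr[err_mask] = _BASES[(lut[base_arr[err_mask]] + shift) % 4]
    n_mask = rng.random(base_arr.shape) < config.n_rate
    base_arr[n_mask] = ord("N")

    low = rng.random(base_arr.shape) < config.low_quality_prob
    quals = np.where(
        low,
        rng.normal(config.quality_low, 3, size=base_arr.shape),
        rng.normal(config.quality_high, 2, size=base_arr.shape),
    )
    quals = np.clip(np.rint(quals), 2, 41).astype(np.uint8) + PHRED_OFFSET

    out_reads = []
    provenance = []
    any_err = (err_mask | n_mask).any(axis=1)
    for i in range(n):
        rid, sp_name, tag = prov_rows[i]
        out_reads.append((rid, base_arr[i].tobytes().decode(),
                          quals[i].tobytes().decode()))
        errs = (
            ",".join(map(str, np.flatnonzero(err_mask[i] | n_mask[i])))
            if any_err[i] else ""
        )
        provenance.append(
            {"read_id": rid, "species": sp_name, "tag": tag,
             "error_positions": errs}
        )
    return out_reads, pd.DataFrame(provenance)


def write_fastq(reads: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, bases, qual in reads:
            fh.write(f"@{rid}\n{bases}\n+\n{qual}\n")


@dataclass
class StudyData:
    """A fully materialised synthetic study."""

    config: SynthConfig
    genomes: list[ReferenceGenome]
    taxonomy: pd.DataFrame
    decoy: ReferenceGenome
    truth: TruthSet
    fastq_paths: dict[str, Path] = field(default_factory=dict)
    reads: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)


def generate_study(
    config: SynthConfig,
    outdir: str | Path | None = None,
    keep_provenance: bool = False,
) -> StudyData:
    """Generate a complete two-group study.

    With ``outdir`` set, per-sample FASTQ files (gzipped), the reference
    FASTA, taxonomy and metadata TSVs and the truth tables are written to
    disk; otherwise reads are kept in memory on the returned object.
    Byte-identical outputs for identical config (seed included).
    """
    genomes, taxonomy, decoy = generate_reference_set(config)
    truth = generate_composition(config)
    study = StudyData(config=config, genomes=genomes, taxonomy=taxonomy,
                      decoy=decoy, truth=truth)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        _write_reference_fasta(genomes + [decoy], outdir / "references.fasta")
        taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t")
        meta = config.groups().rename("group").to_frame()
        meta.index.name = "sample_id"
        meta.to_csv(outdir / "metadata.tsv", sep="\t")
        truth.composition.to_csv(outdir / "truth_composition.tsv", sep="\t")

    sample_ids = config.sample_ids()
    for k, sample_id in enumerate(sample_ids):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3, k]))
        reads, prov = simulate_sample_reads(
            genomes, truth.composition.loc[sample_id].to_numpy(), config, rng,
            sample_id, decoy if config.contaminant_rate > 0 else None,
        )
        if keep_provenance:
            study.truth.provenance[sample_id] = prov
        if outdir is not None:
            path = outdir / f"{sample_id}.fastq.gz"
            write_fastq(reads, path)
            study.fastq_paths[sample_id] = path
        else:
            study.reads[sample_id] = reads
    return study


def _write_reference_fasta(genomes: Sequence[ReferenceGenome],
                           path: Path) -> None:
    with open(path, "w") as fh:
        for genome in genomes:
            for ci, contig in enumerate(genome.contigs):
                fh.write(f">{genome.species_id}|contig{ci}\n")
                for i in range(0, len(contig), 80):
                    fh.write(contig[i:i + 80] + "\n")
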