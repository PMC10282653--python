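"""Tag classification, G-score false-positive control and abundance estimation.

For each species *i* in a sample, three numbers summarise the evidence:

* ``s`` — reads assigned (by exact match) to unique tags of species *i*;
* ``t`` — distinct unique tags of *i* observed at least once;
* ``T`` — theoretical number of distinct unique tags of *i* in the database.

The G score, ``G = sqrt(s * t)``, is the geometric mean of read support and
tag breadth: spurious assignments typically pile reads on one or two tags
(high s, tiny t) or scatter single reads thinly, and both patterns give a
small G.  Species with G below a threshold (default 5) are discarded as
false positives.  Surviving species are quantified by marker coverage
``s / T`` — the average read depth per theoretical marker, which corrects
for genome-size and marker-count differences — normalised to relative
abundances::

    abundance_i = (s_i / T_i) / sum_j (s_j / T_j)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .digest import UniqueTagDB
from .readqc import QCPolicy, QCSummary, clean_tags_from_fastq

__all__ = [
    "SampleProfile",
    "assign_tags",
    "g_score",
    "apply_g_filter",
    "relative_abundance",
    "profile_sample",
    "merge_profiles",
    "DEFAULT_G_THRESHOLD",
]

DEFAULT_G_THRESHOLD = 5.0

PROFILE_COLUMNS = ["s", "t", "T", "g_score", "coverage", "rel_abundance"]


@dataclass
class SampleProfile:
    """Per-species evidence table for one sample.

    ``table`` is indexed by species_id with columns s, t, T, g_score,
    coverage and rel_abundance; only species surviving the G filter carry
    coverage/rel_abundance (others hold NaN after filtering, or the table
    is pre-filter and holds raw s/t/T/G only).
    """

    sample_id: str
    table: pd.DataFrame
    unassigned: int = 0
    qc: QCSummary | None = None
    extra: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "#species_id"
        out.to_csv(path, sep="\t", float_format="%.6g")

    @property
    def abundances(self) -> pd.Series:
        return self.table["rel_abundance"].dropna()


def assign_tags(
    tags: Iterable[str], db: UniqueTagDB
) -> tuple[dict[str, int], dict[str, set[str]], int]:
    """Exact-match tag classification.

    Returns per-species read counts ``s``, per-species sets of observed
    distinct tags, and the count of tags absent from the database.
    A tag whose length differs from the scheme's is a hard error — it
    indicates the reads were extracted under a different digest scheme.
    """
    want = db.scheme.tag_length
    lookup = db.tag_to_species
    s: dict[str, int] = {}
    seen: dict[str, set[str]] = {}
    unassigned = 0
    for tag in tags:
        if len(tag) != want:
            raise ValueError(
                f"tag length {len(tag)} != scheme tag length {want}; "
                "tags and database were built under different schemes"
            )
        sp = lookup.get(tag)
        if sp is None:
            unassigned += 1
            continue
        s[sp] = s.get(sp, 0) + 1
        seen.setdefault(sp, set()).add(tag)
    return s, seen, unassigned


def g_score(s: int, t: int) -> float:
    """Geometric mean sqrt(s*t) of read support and distinct-tag breadth."""
    if s < 0 or t < 0:
        raise ValueError("counts must be non-negative")
    if t > s:
        raise ValueError("t (distinct tags observed) cannot exceed s (reads)")
    return math.sqrt(s * t)


def _raw_profile(
    s: Mapping[str, int], seen: Mapping[str, set[str]], db: UniqueTagDB
) -> pd.DataFrame:
    species = sorted(s)
    rows = {
        "s": [s[sp] for sp in species],
        "t": [len(seen[sp]) for sp in species],
        "T": [db.T[sp] for sp in species],
    }
    table = pd.DataFrame(rows, index=pd.Index(species, name="species_id"))
    table["g_score"] = [g_score(a, b) for a, b in zip(table["s"], table["t"])]
    return table


def apply_g_filter(
    table: pd.DataFrame, threshold: float = DEFAULT_G_THRESHOLD
) -> pd.DataFrame:
    """Drop species with G score below the threshold (retain G >= threshold)."""
    return table.loc[table["g_score"] >= threshold].copy()


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Attach marker coverage s/T and normalised relative abundances."""
    table = table.copy()
    if (table["T"] <= 0).any():
        bad = table.index[table["T"] <= 0].tolist()
        raise ValueError(f"species with T=0 survived filtering (DB inconsistency): {bad}")
    table["coverage"] = table["s"] / table["T"]
    total = table["coverage"].sum()
    table["rel_abundance"] = table["coverage"] / total if total > 0 else 0.0
    return table


def profile_sample(
    fastq: str | Path,
    db: UniqueTagDB,
    policy: QCPolicy | None = None,
    g_threshold: float = DEFAULT_G_THRESHOLD,
    sample_id: str | None = None,
) -> SampleProfile:
    """Full per-sample pipeline: QC -> tag extraction -> classification ->
    G filter -> relative abundance."""
    sample_id = sample_id or Path(fastq).name.split(".")[0]
    pairs, qc = clean_tags_from_fastq(fastq, policy, db.scheme)
    return profile_tags(
        (tag for _, tag in pairs), db, g_threshold, sample_id=sample_id, qc=qc
    )


def profile_tags(
    tags: Iterable[str],
    db: UniqueTagDB,
    g_threshold: float = DEFAULT_G_THRESHOLD,
    sample_id: str = "sample",
    qc: QCSummary | None = None,
) -> SampleProfile:
    """Profile an already-extracted stream of canonical tags."""
    s, seen, unassigned = assign_tags(tags, db)
    raw = _raw_profile(s, seen, db)
    filtered = relative_abundance(apply_g_filter(raw, g_threshold))
    return SampleProfile(
        sample_id=sample_id,
        table=filtered,
        unassigned=unassigned,
        qc=qc,
        extra={"n_species_prefilter": len(raw), "g_threshold": g_threshold},
    )


def merge_profiles(
    profiles: Iterable[SampleProfile],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge per-sample profiles into study-level tables.

    Returns ``(abundances, counts)``: samples x species relative-abundance
    and read-count matrices.  Species detected in some sample but absent
    (or G-filtered) in another get 0 there, not a missing value.
    """
    profiles = list(profiles)
    species = sorted({sp for p in profiles for sp in p.table.index})
    samples = [p.sample_id for p in profiles]
    abund = pd.DataFrame(0.0, index=samples, columns=species)
    counts = pd.DataFrame(0, index=samples, columns=species)
    for p in profiles:
        abund.loc[p.sample_id, p.table.index] = p.table["rel_abundance"].to_numpy()
        counts.loc[p.sample_id, p.table.index] = p.table["s"].to_numpy()
    abund.index.name = counts.index.name = "sample_id"
    return abund, counts
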