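"""Post-bioinformatics MOTU filtering down to a binary detection matrix.

The filter chain is fixed and applied in this order:

1. :func:`remove_control_motus` — drop every MOTU seen in a negative control,
2. :func:`filter_similarity` — drop MOTUs below the reference-match
   similarity threshold (default 96%), unless whitelisted,
3. :func:`assign_reporting_level` — resolve candidate taxa to species /
   genus / subfamily rank,
4. :func:`filter_tag_jumps` — zero per-sample counts whose within-library,
   within-taxon read fraction falls below a frequency threshold
   (default 0.001), guarding against tag-jump artifacts,
5. :func:`to_detection_matrix` — binarize to 1/0 per taxon per sample.

The tag-jump denominator is the taxon's total read count within the
sequencing library, computed once on the input (not iteratively as cells
are zeroed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from streamdna.io_schemas import DetectionMatrix, SchemaError, Taxon, WaterSample

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Candidate:
    """One reference-database taxon matched by a MOTU."""

    species: str  # binomial, e.g. "Alces alces"
    genus: str
    subfamily: str


@dataclass(frozen=True)
class Motu:
    motu_id: str
    candidates: tuple[Candidate, ...] = ()
    best_similarity: float = 1.0
    in_negative_control: bool = False
    whitelist: bool = False
    # filled by assign_reporting_level
    assigned_name: str | None = None
    assigned_rank: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.best_similarity <= 1.0:
            raise SchemaError(
                f"MOTU {self.motu_id!r}: best_similarity must be in [0, 1]"
            )


@dataclass
class MotuTable:
    """MOTU x sample read counts with per-sample sequencing-library ids."""

    motus: list[Motu]
    counts: pd.DataFrame  # index = motu_id, columns = sample ids, ints >= 0
    library_of_sample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [m.motu_id for m in self.motus]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate motu_id")
        if list(self.counts.index) != ids:
            self.counts = self.counts.reindex(ids)
        if self.counts.isna().any().any() or (self.counts < 0).any().any():
            raise SchemaError("counts must be non-negative integers")
        missing = set(self.counts.columns) - set(self.library_of_sample)
        if missing:
            raise SchemaError(f"samples without library id: {sorted(missing)}")

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def _subset(self, keep: Sequence[bool]) -> "MotuTable":
        keep = list(keep)
        motus = [m for m, k in zip(self.motus, keep) if k]
        return MotuTable(
            motus=motus,
            counts=self.counts.loc[[m.motu_id for m in motus]].copy(),
            library_of_sample=dict(self.library_of_sample),
        )


def remove_control_motus(t: MotuTable) -> MotuTable:
    """Delete every MOTU flagged as present in a negative control."""
    keep = [not m.in_negative_control for m in t.motus]
    out = t._subset(keep)
    if not out.motus:
        logger.warning("all MOTUs were flagged in negative controls; table is empty")
    return out


def filter_similarity(t: MotuTable, threshold: float = 0.96) -> MotuTable:
    """Remove MOTUs with best reference match strictly below ``threshold``.

    Whitelisted MOTUs survive regardless (covers curated inclusions of taxa
    whose only reference sequence is a congeneric relative).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    keep = [m.whitelist or m.best_similarity >= threshold for m in t.motus]
    return t._subset(keep)


def assign_reporting_level(t: MotuTable) -> MotuTable:
    """Resolve each MOTU's candidate taxa to a reporting rank.

    A unique candidate gives a species-level assignment; multiple congeneric
    candidates collapse to the genus; candidates spanning genera within one
    subfamily collapse to the subfamily. Candidates spanning more than one
    subfamily cannot be assigned and the MOTU is excluded with a warning.
    """
    assigned: list[Motu] = []
    keep: list[bool] = []
    for m in t.motus:
        if not m.candidates:
            logger.warning("MOTU %s has no candidate taxa; excluded", m.motu_id)
            keep.append(False)
            continue
        species = {c.species for c in m.candidates}
        genera = {c.genus for c in m.candidates}
        subfamilies = {c.subfamily for c in m.candidates}
        if len(species) == 1:
            name, rank = next(iter(species)), "species"
        elif len(genera) == 1:
            name, rank = next(iter(genera)), "genus"
        elif len(subfamilies) == 1:
            name, rank = next(iter(subfamilies)), "subfamily"
        else:
            logger.warning(
                "MOTU %s: candidates span subfamilies %s; excluded",
                m.motu_id, sorted(subfamilies),
            )
            keep.append(False)
            continue
        keep.append(True)
        assigned.append(replace(m, assigned_name=name, assigned_rank=rank))
    out = t._subset(keep)
    out.motus = assigned
    return out


def filter_tag_jumps(t: MotuTable, freq: float = 0.001) -> MotuTable:
    """Zero counts whose per-taxon, per-library read fraction is below ``freq``.

    For each assigned taxon and each sequencing library, the denominator is
    the taxon's total reads across all its MOTUs and all samples of that
    library, computed on the input table. A cell is zeroed when
    ``count / total < freq``. Taxa with zero reads in a library are a no-op.
    """
    if any(m.assigned_name is None for m in t.motus):
        raise SchemaError("filter_tag_jumps requires assigned taxa")
    counts = t.counts.copy()
    taxon_of = {m.motu_id: m.assigned_name for m in t.motus}
    taxon_rows: dict[str, list[str]] = {}
    for mid, taxon in taxon_of.items():
        taxon_rows.setdefault(taxon, []).append(mid)
    lib_cols: dict[str, list[str]] = {}
    for sample, lib in t.library_of_sample.items():
        if sample in counts.columns:
            lib_cols.setdefault(lib, []).append(sample)

    for rows in taxon_rows.values():
        for cols in lib_cols.values():
            block = t.counts.loc[rows, cols]
            total = block.to_numpy().sum()
            if total == 0:
                continue
            mask = (block / total) < freq
            counts.loc[rows, cols] = block.where(~mask, 0)
    return MotuTable(motus=list(t.motus), counts=counts,
                     library_of_sample=dict(t.library_of_sample))


def to_detection_matrix(
    t: MotuTable,
    samples: Sequence[WaterSample],
    taxa_meta: dict[str, Taxon] | None = None,
) -> DetectionMatrix:
    """Binarize filtered counts to a taxon x sample detection matrix.

    Counts of MOTUs assigned to the same taxon are summed before
    binarization; effort is the sample volume in litres. Every sample column
    must appear in ``samples``.
    """
    if any(m.assigned_name is None for m in t.motus):
        raise SchemaError("to_detection_matrix requires assigned taxa")
    meta = {s.sample_id: s for s in samples}
    missing = set(t.counts.columns) - set(meta)
    if missing:
        raise SchemaError(f"samples missing from metadata: {sorted(missing)}")

    by_taxon = t.counts.groupby(
        [m.assigned_name for m in t.motus]
    ).sum()
    taxon_names = sorted(by_taxon.index)
    units = sorted(t.counts.columns)
    y = (by_taxon.loc[taxon_names, units].to_numpy() > 0).astype(np.int8)
    effort = np.array([meta[u].volume for u in units])
    rank_of = {m.assigned_name: m.assigned_rank for m in t.motus}
    taxa = [
        (taxa_meta[n] if taxa_meta and n in taxa_meta
         else Taxon(name=n, rank=rank_of.get(n, "species")))
        for n in taxon_names
    ]
    return DetectionMatrix(taxa=taxa, units=units, effort=effort, y=y)


def apply_filter_chain(
    t: MotuTable,
    samples: Sequence[WaterSample],
    similarity_threshold: float = 0.96,
    tag_jump_freq: float = 0.001,
    taxa_meta: dict[str, Taxon] | None = None,
) -> DetectionMatrix:
    """Run the full fixed-order filter chain and binarize."""
    t = remove_control_motus(t)
    t = filter_similarity(t, similarity_threshold)
    t = assign_reporting_level(t)
    t = filter_tag_jumps(t, tag_jump_freq)
    return to_detection_matrix(t, samples, taxa_meta=taxa_meta)


def percent_retained(raw_reads: int, retained_reads: int) -> float:
    """Percentage of raw sequencing reads surviving the filter chain,
    rounded to one decimal."""
    if raw_reads <= 0:
        raise ValueError("raw_reads must be > 0")
    return round(100.0 * retained_reads / raw_reads, 1)


# ---------------------------------------------------------------------------
# TSV IO
# ---------------------------------------------------------------------------

def read_motu_table(path: str | Path) -> MotuTable:
    """Read a MOTU table from TSV.

    Expected columns: ``motu_id``, ``candidates`` (semicolon-separated
    ``species|genus|subfamily`` triplets), ``best_similarity``,
    ``in_negative_control``, ``whitelist``, then one ``count:<sample>``
    column per sample and one header row mapping handled via a companion
    ``library:<sample>`` encoding in a ``#library`` comment line is NOT
    used — libraries come from a ``libraries`` column-pair file or the
    ``library_of_sample`` argument of :class:`MotuTable`. For simplicity the
    writer/reader pair here stores libraries in a second TSV next to the
    table (``<stem>.libraries.tsv``).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    count_cols = [c for c in df.columns if c.startswith("count:")]
    motus = []
    for r in df.itertuples(index=False):
        cands = []
        if isinstance(r.candidates, str) and r.candidates:
            for item in r.candidates.split(";"):
                sp, ge, sf = item.split("|")
                cands.append(Candidate(species=sp, genus=ge, subfamily=sf))
        motus.append(
            Motu(motu_id=str(r.motu_id), candidates=tuple(cands),
                 best_similarity=float(r.best_similarity),
                 in_negative_control=bool(r.in_negative_control),
                 whitelist=bool(r.whitelist))
        )
    counts = df[count_cols].copy()
    counts.columns = [c.removeprefix("count:") for c in count_cols]
    counts.index = [m.motu_id for m in motus]
    counts = counts.astype(int)
    lib_path = path.with_suffix("").with_suffix(".libraries.tsv")
    libs = pd.read_csv(lib_path, sep="\t")
    library_of_sample = dict(zip(libs["sample"].astype(str), libs["library"].astype(str)))
    return MotuTable(motus=motus, counts=counts, library_of_sample=library_of_sample)


def write_motu_table(t: MotuTable, path: str | Path) -> None:
    path = Path(path)
    records = []
    for m in t.motus:
        records.append(
            {"motu_id": m.motu_id,
             "candidates": ";".join(f"{c.species}|{c.genus}|{c.subfamily}"
                                    for c in m.candidates),
             "best_similarity": m.best_similarity,
             "in_negative_control": m.in_negative_control,
             "whitelist": m.whitelist,
             **{f"count:{s}": int(t.counts.loc[m.motu_id, s])
                for s in t.counts.columns}}
        )
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)
    lib_path = path.with_suffix("").with_suffix(".libraries.tsv")
    pd.DataFrame(
        {"sample": list(t.library_of_sample),
         "library": list(t.library_of_sample.values())}
    ).to_csv(lib_path, sep="\t", index=False)
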