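"""Readers, validators and host assignment for diet-metabarcoding inputs.

The module consumes already-classified OTU read-count tables (one per
marker: COI for the animal diet fraction, rbcL for the plant fraction),
sample metadata, nest-survey records and a vegetation-community table.
Upstream steps (read QC, OTU clustering, taxonomy assignment) are the
product of published tools and are out of scope; this module starts from
their tabular output.
"""

from __future__ import annotations

import csv
import datetime
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel host value for samples without any avian reads.
UNASSIGNED = "UNASSIGNED"
#: Sentinel for nests whose owner could not be identified in the field.
UNIDENTIFIED = "UNIDENTIFIED"
#: Sentinel substrate for nests on man-made structures or bare rock.
ARTIFICIAL = "ARTIFICIAL"

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

GROWTH_FORMS = ("deciduous_tree", "coniferous_tree", "shrub", "non_plant")


class Lineage(tuple):
    """Ranked taxonomy kingdom -> species; unclassified ranks are empty strings."""

    __slots__ = ()

    def __new__(cls, labels: Iterable[str] = ()):
        labels = tuple(labels)
        if len(labels) > len(RANKS):
            raise ValueError(f"lineage has more than {len(RANKS)} ranks: {labels!r}")
        labels = labels + ("",) * (len(RANKS) - len(labels))
        return super().__new__(cls, labels)

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        """Parse a rank-prefixed lineage string ``k__...;p__...;...;s__...``."""
        labels = []
        for i, part in enumerate(text.strip().strip(";").split(";")):
            part = part.strip()
            if i >= len(RANKS):
                raise ValueError(f"lineage has more than {len(RANKS)} ranks: {text!r}")
            if part[:3] in _PREFIXES:
                if part[:3] != _PREFIXES[i]:
                    raise ValueError(
                        f"rank prefix {part[:3]!r} out of order at position {i} in {text!r}"
                    )
                part = part[3:]
            labels.append(part)
        return cls(labels)

    def to_string(self) -> str:
        return ";".join(p + l for p, l in zip(_PREFIXES, self))

    def at(self, rank: str) -> str:
        return self[RANKS.index(rank)]

    def label_at(self, rank: str) -> str:
        """Deepest non-empty label at or above ``rank``.

        Unclassified levels aggregate to the nearest classified ancestor, so a
        genus-less OTU in family Rosaceae contributes to a "Rosaceae" bucket
        rather than an empty one.
        """
        idx = RANKS.index(rank)
        for label in reversed(self[: idx + 1]):
            if label:
                return label
        return ""

    @property
    def kingdom(self) -> str:
        return self[0]

    @property
    def species(self) -> str:
        return self[6]

    @property
    def genus(self) -> str:
        return self[5]


@dataclass
class OtuTable:
    """Marker-tagged OTU x sample read-count matrix with per-OTU lineages.

    ``counts`` has unique OTU ids as index, unique sample ids as columns and
    non-negative integer cells; ``lineages`` maps each OTU id to its ranked
    taxonomy (at least a kingdom-level label).
    """

    marker: str
    counts: pd.DataFrame
    lineages: dict[str, Lineage]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.marker not in ("COI", "rbcL"):
            raise ValueError(f"unknown marker {self.marker!r}")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate otu_id(s): {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample id(s): {dups}")
        if len(self.counts) and (self.counts.values < 0).any():
            raise ValueError("negative read counts")
        missing = set(self.counts.index) - set(self.lineages)
        if missing:
            raise ValueError(f"OTUs without lineage: {sorted(missing)}")
        for otu_id in self.counts.index:
            if not self.lineages[otu_id].kingdom:
                raise ValueError(f"OTU {otu_id!r} lacks a kingdom-level classification")

    @property
    def n_otus(self) -> int:
        return len(self.counts)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def otu_totals(self) -> pd.Series:
        """Absolute abundance per OTU: reads summed across all samples."""
        return self.counts.sum(axis=1)

    def subset_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        keep = [o for o in self.counts.index if o in set(otu_ids)]
        return OtuTable(
            marker=self.marker,
            counts=self.counts.loc[keep].copy(),
            lineages={o: self.lineages[o] for o in keep},
        )

    def aggregate(self, rank: str) -> pd.DataFrame:
        """Sum reads into taxon x sample at ``rank`` (nearest-classified label)."""
        labels = [self.lineages[o].label_at(rank) for o in self.counts.index]
        out = self.counts.groupby(pd.Index(labels, name=rank)).sum()
        return out.loc[[l for l in out.index if l]]


@dataclass
class SampleMeta:
    """One fecal sample: id, collection date, and (after host calling) its host."""

    sample_id: str
    collection_date: datetime.date
    host_species: str = UNASSIGNED
    host_reads: int = 0
    low_confidence: bool = False


@dataclass(frozen=True)
class NestRecord:
    """One surveyed nest."""

    nest_id: str
    bird_species: str
    substrate: str
    growth_form: str

    def __post_init__(self) -> None:
        if self.growth_form not in GROWTH_FORMS:
            raise ValueError(
                f"nest {self.nest_id!r}: unknown growth_form {self.growth_form!r} "
                f"(expected one of {GROWTH_FORMS})"
            )
        if (self.growth_form == "non_plant") != (self.substrate == ARTIFICIAL):
            raise ValueError(
                f"nest {self.nest_id!r}: growth_form must be non_plant iff "
                f"substrate is {ARTIFICIAL} (got {self.substrate!r}/{self.growth_form!r})"
            )


@dataclass
class CommunityTable:
    """Relative abundance of plant taxa in the study-area vegetation community."""

    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.fractions:
            return
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("negative community abundance")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"community fractions sum to {total}, expected 1")

    @classmethod
    def from_raw(cls, raw: Mapping[str, float]) -> "CommunityTable":
        """Normalize raw stem counts / cover values to fractions."""
        total = float(sum(raw.values()))
        if total <= 0:
            raise ValueError("community table has no positive abundance")
        return cls({k: v / total for k, v in raw.items()})

    def at_genus(self) -> dict[str, float]:
        """Sum species-level entries to genus (first whitespace token), case-folded."""
        out: dict[str, float] = {}
        for taxon, frac in self.fractions.items():
            genus = taxon.split()[0].strip().lower()
            out[genus] = out.get(genus, 0.0) + frac
        return out


# ---------------------------------------------------------------------------
# readers / writers


def read_otu_table(path: str | Path, marker: str) -> OtuTable:
    """Read a TSV OTU table: columns ``otu_id``, ``taxonomy``, then one per sample.

    Malformed rows are reported with their 1-based line number.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if header[:2] != ["otu_id", "taxonomy"]:
            raise ValueError(
                f"{path}: expected header to start with otu_id<TAB>taxonomy, got {header[:2]}"
            )
        sample_ids = header[2:]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError(f"{path}: duplicate sample ids in header")
        rows: dict[str, list[int]] = {}
        lineages: dict[str, Lineage] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            otu_id = row[0].strip()
            if otu_id in rows:
                raise ValueError(f"{path}:{lineno}: duplicate otu_id {otu_id!r}")
            try:
                counts = [int(c) for c in row[2:]]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer read count") from None
            if any(c < 0 for c in counts):
                raise ValueError(f"{path}:{lineno}: negative read count")
            try:
                lineages[otu_id] = Lineage.from_string(row[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            rows[otu_id] = counts
    counts_df = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids, dtype="int64")
    counts_df.index.name = "otu_id"
    if counts_df.empty:
        counts_df = pd.DataFrame(index=pd.Index([], name="otu_id"), columns=sample_ids, dtype="int64")
    return OtuTable(marker=marker, counts=counts_df, lineages=lineages)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["otu_id", "taxonomy", *table.samples])
        for otu_id in table.counts.index:
            writer.writerow(
                [otu_id, table.lineages[otu_id].to_string(), *table.counts.loc[otu_id].tolist()]
            )


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata CSV with header ``sample_id,collection_date`` (ISO dates)."""
    path = Path(path)
    out: list[SampleMeta] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"sample_id", "collection_date"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected header sample_id,collection_date")
        for lineno, row in enumerate(reader, start=2):
            sid = row["sample_id"].strip()
            if sid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate sample_id {sid!r}")
            seen.add(sid)
            try:
                date = datetime.date.fromisoformat(row["collection_date"].strip())
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: invalid ISO date {row['collection_date']!r}"
                ) from None
            out.append(SampleMeta(sample_id=sid, collection_date=date))
    return out


def write_sample_meta(samples: Sequence[SampleMeta], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["sample_id", "collection_date"])
        for s in samples:
            writer.writerow([s.sample_id, s.collection_date.isoformat()])


def read_nest_records(path: str | Path) -> list[NestRecord]:
    """Read nest-survey CSV: ``nest_id,bird_species,substrate,growth_form``."""
    path = Path(path)
    out: list[NestRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"nest_id", "bird_species", "substrate", "growth_form"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected header {','.join(sorted(required))}")
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    NestRecord(
                        nest_id=row["nest_id"].strip(),
                        bird_species=row["bird_species"].strip() or UNIDENTIFIED,
                        substrate=row["substrate"].strip(),
                        growth_form=row["growth_form"].strip(),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return out


def write_nest_records(nests: Sequence[NestRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["nest_id", "bird_species", "substrate", "growth_form"])
        for n in nests:
            writer.writerow([n.nest_id, n.bird_species, n.substrate, n.growth_form])


def read_community_table(path: str | Path) -> CommunityTable:
    """Read a community CSV ``taxon,abundance``; raw counts are renormalized."""
    path = Path(path)
    raw: dict[str, float] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"taxon", "abundance"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected header taxon,abundance")
        for lineno, row in enumerate(reader, start=2):
            taxon = row["taxon"].strip()
            if taxon in raw:
                raise ValueError(f"{path}:{lineno}: duplicate taxon {taxon!r}")
            try:
                value = float(row["abundance"])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric abundance") from None
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative abundance")
            raw[taxon] = value
    total = sum(raw.values())
    if abs(total - 1.0) > 1e-9:
        logger.info("community table sums to %g; renormalizing to fractions", total)
        return CommunityTable.from_raw(raw)
    return CommunityTable(raw)


def write_community_table(table: CommunityTable, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["taxon", "abundance"])
        for taxon, frac in table.fractions.items():
            writer.writerow([taxon, repr(frac)])


# ---------------------------------------------------------------------------
# filtering and host assignment


def filter_otus(table: OtuTable, min_reads: int = 100, scope: str = "total") -> OtuTable:
    """Drop low-abundance OTUs.

    With ``scope="total"`` (default) an OTU is retained iff its absolute
    abundance — reads summed over all samples — is strictly greater than
    ``min_reads``; an OTU with exactly ``min_reads`` total reads is removed.
    With ``scope="per_sample"`` cells with at most ``min_reads`` reads are
    zeroed and OTUs left with no reads are dropped.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    if scope == "total":
        totals = table.otu_totals()
        keep = totals.index[totals > min_reads]
        return table.subset_otus(list(keep))
    if scope == "per_sample":
        counts = table.counts.where(table.counts > min_reads, 0)
        keep = counts.index[counts.sum(axis=1) > 0]
        return OtuTable(
            marker=table.marker,
            counts=counts.loc[keep],
            lineages={o: table.lineages[o] for o in keep},
        )
    raise ValueError(f"unknown scope {scope!r}")


def assign_hosts(
    coi: OtuTable,
    meta: Sequence[SampleMeta],
    avian_class_label: str = "Aves",
) -> list[SampleMeta]:
    """Assign the host bird species of each sample from its COI profile.

    The host is the avian species-level taxon with the greatest summed reads
    in the sample. Samples without avian reads stay UNASSIGNED. Ties are
    broken lexicographically and logged; samples whose top avian taxon holds
    less than half of the sample's avian reads are flagged low-confidence.
    """
    avian_otus = [
        o for o in coi.counts.index if coi.lineages[o].at("class") == avian_class_label
    ]
    labels = pd.Index(
        [coi.lineages[o].label_at("species") for o in avian_otus], name="taxon"
    )
    by_taxon = (
        coi.counts.loc[avian_otus].groupby(labels).sum()
        if avian_otus
        else pd.DataFrame(columns=coi.samples)
    )
    out: list[SampleMeta] = []
    for s in meta:
        rec = replace(s)
        if s.sample_id not in coi.counts.columns or by_taxon.empty:
            rec.host_species, rec.host_reads = UNASSIGNED, 0
            out.append(rec)
            continue
        col = by_taxon[s.sample_id]
        col = col[col > 0]
        if col.empty:
            rec.host_species, rec.host_reads = UNASSIGNED, 0
            out.append(rec)
            continue
        top = int(col.max())
        winners = sorted(col.index[col == top])
        if len(winners) > 1:
            logger.warning(
                "sample %s: tie between avian taxa %s at %d reads; "
                "assigning %s (lexicographic)",
                s.sample_id, winners, top, winners[0],
            )
        rec.host_species = winners[0]
        rec.host_reads = top
        rec.low_confidence = top < 0.5 * col.sum()
        if rec.low_confidence:
            logger.warning(
                "sample %s: top avian taxon %s holds %d of %d avian reads (<50%%)",
                s.sample_id, rec.host_species, top, int(col.sum()),
            )
        out.append(rec)
    return out


def remove_host_reads(table: OtuTable, samples: Sequence[SampleMeta]) -> OtuTable:
    """Zero each sample's reads for OTUs classified to its own host species.

    Host-derived DNA in a fecal sample is not diet; removing it before
    composition and network steps prevents the host from appearing as its own
    dominant prey. Other avian taxa are kept — birds do occur as prey.
    """
    counts = table.counts.copy()
    host_of = {s.sample_id: s.host_species for s in samples}
    species_of = {o: table.lineages[o].label_at("species") for o in counts.index}
    for sid, host in host_of.items():
        if host == UNASSIGNED or sid not in counts.columns:
            continue
        hit = [o for o, sp in species_of.items() if sp == host]
        if hit:
            counts.loc[hit, sid] = 0
    keep = counts.index[counts.sum(axis=1) > 0]
    return OtuTable(
        marker=table.marker,
        counts=counts.loc[keep],
        lineages={o: table.lineages[o] for o in keep},
    )


def family_read_report(table: OtuTable, family: str = "Hominidae") -> pd.Series:
    """Per-sample read totals for a taxonomic family (e.g. human contamination)."""
    otus = [o for o in table.counts.index if table.lineages[o].at("family") == family]
    if not otus:
        return pd.Series(0, index=table.samples, dtype="int64")
    return table.counts.loc[otus].sum(axis=0)
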