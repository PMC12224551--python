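"""Readers and writers for every external representation the pipeline touches.

The pipeline consumes three kinds of input: a Roary-style gene
presence/absence matrix (CSV, one row per gene family, one column per
genome, cells holding locus tags), antiSMASH-style BGC region files
(GenBank, one region per file), and a genome metadata table (TSV mapping
genome_id to genus).  It emits tabular reports as TSV or JSON.  Two small
literature-derived presence/absence tables ship as packaged fixtures so the
report tabulators can be exercised without any external data.

Coordinates are 1-based inclusive throughout (GenBank convention); any
half-open arithmetic is internal to this module.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("bgcpan")

__all__ = [
    "GenomeMetadata",
    "CdsFeature",
    "BgcRegion",
    "PresenceAbsenceMatrix",
    "TableFixture",
    "FormatError",
    "read_roary_csv",
    "write_roary_csv",
    "read_region_genbank",
    "write_region_genbank",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "load_fixture",
    "write_report",
    "read_report",
]


class FormatError(ValueError):
    """A file did not conform to the expected external format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeMetadata:
    """One analyzed genome: its identifier and genus assignment."""

    genome_id: str
    genus: str
    species_label: str | None = None
    accession: str | None = None

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        if not self.genus:
            raise ValueError("genus must be non-empty")


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding gene inside a BGC region (1-based inclusive coords)."""

    locus_tag: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    translation: str = ""
    nt_seq: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.translation and not re.fullmatch(
            r"[ACDEFGHIKLMNPQRSTVWYXBZJUO]*\*?", self.translation
        ):
            raise ValueError(f"invalid translation for {self.locus_tag}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class BgcRegion:
    """One annotated cluster region with its ordered CDS features.

    Hybrid regions (several detected product classes) carry more than one
    entry in ``product_classes``.
    """

    region_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    product_classes: list[str]
    cds: list[CdsFeature]
    known_cluster: tuple[str, float] | None = None
    nt_seq: str | None = None

    def __post_init__(self) -> None:
        if not self.product_classes:
            raise ValueError("product_classes must be non-empty")
        self.cds = sorted(self.cds, key=lambda c: (c.start, c.locus_tag))
        for c in self.cds:
            if c.start < self.start or c.end > self.end:
                raise ValueError(
                    f"CDS {c.locus_tag} ({c.start}..{c.end}) outside region "
                    f"span {self.start}..{self.end}"
                )

    @property
    def gene_order(self) -> list[str]:
        """Locus tags in genomic order."""
        return [c.locus_tag for c in self.cds]


@dataclass
class PresenceAbsenceMatrix:
    """Gene families x genomes, each cell a (possibly empty) list of locus tags.

    This is the pan-genome substrate: one row per gene family, one column per
    genome.  A family is *present* in a genome when its cell is non-empty;
    paralogous copies (several tags in one cell) still count as one presence.
    """

    family_ids: list[str]
    genome_ids: list[str]
    cells: dict[tuple[str, str], list[str]]
    annotation: dict[str, str] = field(default_factory=dict)

    def tags(self, family_id: str, genome_id: str) -> list[str]:
        return self.cells.get((family_id, genome_id), [])

    def presence_count(self, family_id: str) -> int:
        return sum(1 for g in self.genome_ids if self.tags(family_id, g))

    def genomes_with(self, family_id: str) -> list[str]:
        return [g for g in self.genome_ids if self.tags(family_id, g)]

    def tag_index(self, genome_id: str) -> dict[str, str]:
        """Map locus_tag -> family_id for one genome."""
        idx: dict[str, str] = {}
        for f in self.family_ids:
            for t in self.tags(f, genome_id):
                if t in idx:
                    raise ValueError(
                        f"locus tag {t} of genome {genome_id} appears in "
                        f"families {idx[t]} and {f}"
                    )
                idx[t] = f
        return idx


@dataclass
class TableFixture:
    """A rectangular presence/absence table transcribed from the literature."""

    row_labels: list[str]
    col_labels: list[str]
    values: list[list[bool]]  # True = present

    def __post_init__(self) -> None:
        if len(self.values) != len(self.row_labels):
            raise ValueError("row count mismatch")
        for row in self.values:
            if len(row) != len(self.col_labels):
                raise ValueError("column count mismatch")

    def present(self, row_label: str, col_label: str) -> bool:
        return self.values[self.row_labels.index(row_label)][
            self.col_labels.index(col_label)
        ]


# ---------------------------------------------------------------------------
# Roary-style presence/absence CSV
# ---------------------------------------------------------------------------

# Leading metadata columns of Roary's gene_presence_absence.csv, recognized
# by name (dialects differ in how many are present).
ROARY_METADATA_COLUMNS = (
    "Gene",
    "Non-unique Gene name",
    "Annotation",
    "No. isolates",
    "No. sequences",
    "Avg sequences per isolate",
    "Genome Fragment",
    "Order within Fragment",
    "Accessory Fragment",
    "Accessory Order with Fragment",
    "QC",
    "Min group size nuc",
    "Max group size nuc",
    "Avg group size nuc",
)

_CELL_SEPARATORS = {"tab": "\t", "semicolon": ";", "space": " "}


def _split_cell(cell: str, sep: str | None) -> list[str]:
    if not cell or not cell.strip():
        return []
    if sep is None:
        return [cell.strip()]
    return [t for t in re.split(rf"{re.escape(sep)}+", cell.strip()) if t]


def _detect_cell_separator(cells: Iterable[str]) -> str | None:
    """Pick the intra-cell tag separator used by this Roary dialect."""
    for name, sep in _CELL_SEPARATORS.items():
        if any(sep in c.strip() for c in cells):
            log.debug("Roary cell separator detected: %s", name)
            return sep
    return None


def read_roary_csv(
    path: str | Path, genome_ids: Sequence[str] | None = None
) -> PresenceAbsenceMatrix:
    """Read a Roary-style gene_presence_absence.csv.

    Columns named like Roary's fixed metadata block are treated as metadata;
    every other column is a genome.  When ``genome_ids`` is given, unknown
    non-metadata columns are ignored (with a log line) instead of being taken
    for genomes.  Cells are split into locus tags on tab, semicolon or
    whitespace.  If a "No. isolates" column is present it is checked against
    the recomputed presence counts; on disagreement the cell content wins and
    the discrepancy is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, quoting=csv.QUOTE_MINIMAL)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse Roary CSV {path}: {exc}") from exc

    meta_cols = [c for c in df.columns if c in ROARY_METADATA_COLUMNS]
    other_cols = [c for c in df.columns if c not in ROARY_METADATA_COLUMNS]
    if genome_ids is not None:
        wanted = list(genome_ids)
        missing = [g for g in wanted if g not in other_cols]
        if missing:
            raise FormatError(f"{path}: missing genome columns: {missing}")
        ignored = [c for c in other_cols if c not in set(wanted)]
        if ignored:
            log.info("%s: ignoring unrecognized columns: %s", path.name, ignored)
        genome_cols = wanted
    else:
        genome_cols = other_cols
    if not genome_cols:
        raise FormatError(f"{path}: no genome columns found")
    if "Gene" not in df.columns:
        raise FormatError(f"{path}: missing 'Gene' column")

    fam_ids = df["Gene"].tolist()
    seen: set[str] = set()
    for f in fam_ids:
        if f in seen:
            raise FormatError(f"{path}: duplicate family id {f!r}")
        seen.add(f)

    sep = _detect_cell_separator(
        c for col in genome_cols for c in df[col].tolist()
    )

    cells: dict[tuple[str, str], list[str]] = {}
    for _, row in df.iterrows():
        fam = row["Gene"]
        for g in genome_cols:
            tags = _split_cell(row[g], sep)
            if tags:
                cells[(fam, g)] = tags

    annotation = (
        dict(zip(fam_ids, df["Annotation"].tolist()))
        if "Annotation" in df.columns
        else {}
    )
    matrix = PresenceAbsenceMatrix(fam_ids, list(genome_cols), cells, annotation)

    if "No. isolates" in df.columns:
        for fam, declared in zip(fam_ids, df["No. isolates"].tolist()):
            try:
                declared_n = int(declared)
            except (TypeError, ValueError):
                continue
            actual = matrix.presence_count(fam)
            if actual != declared_n:
                log.warning(
                    "%s: family %s declares %d isolates but cells show %d; "
                    "using cell content",
                    path.name,
                    fam,
                    declared_n,
                    actual,
                )
    _ = meta_cols
    return matrix


def write_roary_csv(matrix: PresenceAbsenceMatrix, path: str | Path) -> None:
    """Write a matrix back out in Roary's CSV layout (tab-separated cells)."""
    path = Path(path)
    rows = []
    for fam in matrix.family_ids:
        row: dict[str, object] = {
            "Gene": fam,
            "Non-unique Gene name": "",
            "Annotation": matrix.annotation.get(fam, ""),
            "No. isolates": matrix.presence_count(fam),
        }
        for g in matrix.genome_ids:
            row[g] = "\t".join(matrix.tags(fam, g))
        rows.append(row)
    cols = ["Gene", "Non-unique Gene name", "Annotation", "No. isolates"] + list(
        matrix.genome_ids
    )
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False, quoting=csv.QUOTE_ALL, lineterminator="\n")


# ---------------------------------------------------------------------------
# antiSMASH-style region GenBank files
# ---------------------------------------------------------------------------


def read_region_genbank(path: str | Path, genome_id: str | None = None) -> BgcRegion:
    """Read one antiSMASH-style region GenBank file into a BgcRegion.

    Region boundaries come from the "region" feature when present, else the
    full record span.  Product classes come from the region feature's
    "product" qualifiers (``["unknown"]`` when absent).  CDS features without
    a locus_tag get a synthetic ``<record_id>_cds<ordinal>`` tag and a logged
    warning.
    """
    path = Path(path)
    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except (StopIteration, ValueError) as exc:
        raise FormatError(f"cannot parse GenBank file {path}: {exc}") from exc

    region_feat = next((f for f in record.features if f.type == "region"), None)
    if region_feat is not None:
        start = int(region_feat.location.start) + 1
        end = int(region_feat.location.end)
        product_classes = list(region_feat.qualifiers.get("product", [])) or ["unknown"]
    else:
        start, end = 1, len(record.seq)
        product_classes = ["unknown"]

    gid = genome_id
    if gid is None:
        gid = record.annotations.get("source") or record.id
    contig_id = record.id

    cds_list: list[CdsFeature] = []
    ordinal = 0
    for feat in record.features:
        if feat.type != "CDS":
            continue
        ordinal += 1
        tags = feat.qualifiers.get("locus_tag", [])
        if tags:
            tag = tags[0]
        else:
            tag = f"{record.id}_cds{ordinal}"
            log.warning("%s: CDS #%d lacks locus_tag, assigned %s", path.name, ordinal, tag)
        translation = feat.qualifiers.get("translation", [""])[0]
        product = feat.qualifiers.get("product", [""])[0]
        fstart = int(feat.location.start) + 1
        fend = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        nt = None
        if len(record.seq):
            try:
                nt = str(feat.extract(record.seq))
            except Exception:
                nt = None
        cds_list.append(
            CdsFeature(
                locus_tag=tag,
                contig_id=contig_id,
                start=fstart,
                end=fend,
                strand=strand,
                product=product,
                translation=translation.rstrip("*"),
                nt_seq=nt,
            )
        )
    if not cds_list:
        raise FormatError(f"{path}: no CDS features")

    known = None
    kc = record.annotations.get("structured_comment", {})
    if isinstance(kc, dict):
        block = kc.get("antiSMASH-Data", {})
        if "knowncluster" in block and "similarity" in block:
            try:
                known = (block["knowncluster"], float(block["similarity"]))
            except (TypeError, ValueError):
                known = None

    region_id = f"{gid}|{contig_id}|{start}-{end}"
    return BgcRegion(
        region_id=region_id,
        genome_id=gid,
        contig_id=contig_id,
        start=start,
        end=end,
        product_classes=product_classes,
        cds=cds_list,
        known_cluster=known,
        nt_seq=str(record.seq) if len(record.seq) else None,
    )


def write_region_genbank(region: BgcRegion, path: str | Path) -> None:
    """Write a BgcRegion as an antiSMASH-style region GenBank file."""
    seq = region.nt_seq
    if seq is None:
        seq = "N" * (region.end - region.start + 1)
    record = SeqRecord(
        Seq(seq),
        id=region.contig_id,
        name=region.contig_id[:16],
        description=f"{region.genome_id} BGC region",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["source"] = region.genome_id
    record.annotations["date"] = "01-JAN-1980"  # fixed for reproducible output
    record.features.append(
        SeqFeature(
            SimpleLocation(region.start - 1, region.end, 1),
            type="region",
            qualifiers={"product": list(region.product_classes)},
        )
    )
    for c in region.cds:
        record.features.append(
            SeqFeature(
                SimpleLocation(c.start - 1, c.end, 1 if c.strand == "+" else -1),
                type="CDS",
                qualifiers={
                    "locus_tag": [c.locus_tag],
                    "product": [c.product] if c.product else [],
                    "translation": [c.translation] if c.translation else [],
                },
            )
        )
    with open(path, "w") as fh:
        SeqIO.write(record, fh, "genbank")


# ---------------------------------------------------------------------------
# Genome metadata TSV
# ---------------------------------------------------------------------------


def read_metadata_tsv(path: str | Path) -> list[GenomeMetadata]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "genome_id" not in df.columns or "genus" not in df.columns:
        raise FormatError(f"{path}: metadata TSV needs 'genome_id' and 'genus' columns")
    out = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        if row["genome_id"] in seen:
            raise FormatError(f"{path}: duplicate genome_id {row['genome_id']!r}")
        seen.add(row["genome_id"])
        out.append(
            GenomeMetadata(
                genome_id=row["genome_id"],
                genus=row["genus"],
                species_label=row.get("species_label") or None,
                accession=row.get("accession") or None,
            )
        )
    return out


def write_metadata_tsv(metadata: Sequence[GenomeMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"genome_id": m.genome_id, "genus": m.genus} for m in metadata],
        columns=["genome_id", "genus"],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_coordinates_tsv(path: str | Path) -> dict[tuple[str, str], tuple[str, int, int]]:
    """Read a coordinate sidecar: genome_id, locus_tag, contig, start, end.

    Used by the coordinate-overlap mapping fallback when the annotation run
    behind the region files does not share locus tags with the pan-genome
    matrix.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    needed = {"genome_id", "locus_tag", "contig", "start", "end"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: coordinate TSV needs columns {sorted(needed)}")
    out: dict[tuple[str, str], tuple[str, int, int]] = {}
    for _, row in df.iterrows():
        out[(row["genome_id"], row["locus_tag"])] = (
            row["contig"], int(row["start"]), int(row["end"])
        )
    return out


# ---------------------------------------------------------------------------
# Packaged literature fixtures
# ---------------------------------------------------------------------------

# Genus-level presence/absence of the five phylum-conserved BGCs across the
# eleven genera with enough sequenced genomes for pan-genome analysis.
_TABLE2_GENERA = [
    "Anaeromyxobacter",
    "Archangium",
    "Corallococcus",
    "Cystobacter",
    "Melittangium",
    "Myxococcus",
    "Nannocystis",
    "Polyangium",
    "Pyxidicoccus",
    "Sorangium",
    "Stigmatella",
]

_TABLE2_WITH: dict[str, list[str]] = {
    "geosmin": [
        "Archangium", "Corallococcus", "Cystobacter", "Melittangium",
        "Myxococcus", "Nannocystis", "Polyangium", "Pyxidicoccus",
        "Sorangium", "Stigmatella",
    ],
    "carotenoid": [
        "Archangium", "Corallococcus", "Cystobacter", "Melittangium",
        "Myxococcus", "Polyangium", "Pyxidicoccus", "Sorangium", "Stigmatella",
    ],
    "VEPE/AEPE/TG-1": [
        "Anaeromyxobacter", "Archangium", "Corallococcus", "Cystobacter",
        "Melittangium", "Myxococcus", "Pyxidicoccus", "Stigmatella",
    ],
    "alkylpyrone": [
        "Archangium", "Corallococcus", "Cystobacter", "Melittangium",
        "Myxococcus", "Pyxidicoccus", "Stigmatella",
    ],
    "myxochelin": [
        "Archangium", "Corallococcus", "Cystobacter", "Melittangium",
        "Myxococcus", "Pyxidicoccus", "Polyangium", "Stigmatella",
    ],
}

# Presence/absence of the five conserved BGCs in validation strains from
# genera too sparsely sequenced for pan-genome analysis.  Totals are never
# stored; the tabulator recomputes them.
_TABLE3_BGCS = ["geosmin", "carotenoid", "VEPE/AEPE/TG-1", "alkylpyrone", "myxochelin"]

_TABLE3_ROWS: list[tuple[str, str]] = [
    ("Citreicoccus inhibens", "+++++"),
    ("Hyalangium versicolor", "+++++"),
    ("Vitiosangium sp. GDMCC 1.1324", "+++++"),
    ("Chondromyces crocatus", "++++-"),
    ("Haliangium ochraceum", "+++-+"),
    ("Aggregicoccus sp. 17bor-14", "-+++-"),
    ("Enhygromyxa salina", "++-+-"),
    ("Sandaracinus amylolyticus", "-+-++"),
    ("Labilithrix luteola", "--++-"),
    ("Pseudenhygromyxa sp. WMMC2535", "++---"),
    ("Vulgatibacter incompetus", "--++-"),
]


def load_fixture(name: str) -> TableFixture:
    """Load one of the packaged literature tables.

    ``table2``: five conserved BGCs (rows) x eleven genera (columns).
    ``table3``: eleven validation strains (rows) x five BGCs (columns).
    """
    if name == "table2":
        values = [
            [g in _TABLE2_WITH[bgc] for g in _TABLE2_GENERA]
            for bgc in _TABLE3_BGCS
        ]
        return TableFixture(list(_TABLE3_BGCS), list(_TABLE2_GENERA), values)
    if name == "table3":
        values = [[c == "+" for c in cells] for _, cells in _TABLE3_ROWS]
        return TableFixture(
            [s for s, _ in _TABLE3_ROWS], list(_TABLE3_BGCS), values
        )
    raise KeyError(f"unknown fixture {name!r}; choose 'table2' or 'table3'")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_report(
    records: Sequence[Mapping[str, object]] | pd.DataFrame,
    path: str | Path,
    format: str = "tsv",
    columns: Sequence[str] | None = None,
) -> None:
    """Write a tabular report deterministically as TSV or JSON.

    Column order is the order of ``columns`` when given, else the key order
    of the first record.  Two calls with the same records produce
    byte-identical files.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if columns is not None:
            df = df[list(columns)]
    else:
        if columns is None:
            columns = list(records[0].keys()) if records else []
        df = pd.DataFrame(list(records), columns=list(columns))
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    elif format == "json":
        payload = df.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=False)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if format == "json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    raise ValueError(f"unknown report format {format!r}")
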