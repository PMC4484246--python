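"""Domain types and tab-separated readers/writers for every pipeline artifact.

All tabular files are TSV with a mandatory header row; the token ``NA``
denotes a missing value. Identifiers are preserved verbatim (no case folding,
no trimming beyond the field delimiter), so ``read(write(x)) == x`` holds
exactly for tokens and integers and to within 1e-12 for reals.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

from degnet.errors import DataError, FormatError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from degnet.metaweb import MetaNetwork

logger = logging.getLogger(__name__)

NA = "NA"

#: classes a catabolic family may belong to
CLASS_TAGS = frozenset(
    {
        "alkane",
        "monoaromatic",
        "polyaromatic",
        "ring_cleavage_extradiol",
        "ring_cleavage_intradiol",
        "other",
    }
)

HIT_SOURCES = frozenset({"dna", "imputed"})
EVIDENCE_STATUS = frozenset({"degraded", "not_degraded"})
EVIDENCE_KINDS = frozenset({"substrate_depleted", "intermediate_detected"})

#: DOT edge pen-width per percentage point of relative abundance
DOT_PENWIDTH_PER_PERCENT = 40.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CatabolicFamily:
    family_id: str
    class_tag: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.class_tag not in CLASS_TAGS:
            raise ValidationError(
                f"family {self.family_id!r}: unknown class_tag {self.class_tag!r}"
            )


@dataclass(frozen=True)
class Reaction:
    """A family-labelled substrate -> product edge template.

    Chemical codes are opaque 3-character tokens; the names are decoration.
    """

    family_id: str
    substrate_code: str
    product_code: str
    substrate_name: str = ""
    product_name: str = ""

    def __post_init__(self) -> None:
        if self.substrate_code == self.product_code:
            raise ValidationError(
                f"reaction {self.family_id!r}: substrate_code equals product_code "
                f"({self.substrate_code!r})"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.family_id, self.substrate_code, self.product_code)


@dataclass(frozen=True)
class GeneHit:
    """One annotation match of a gene to a catabolic family.

    ``count`` carries the multiplicity of taxonomy-imputed gene-equivalents;
    direct DNA hits always have count 1.
    """

    sample_id: str
    gene_id: str
    family_id: str
    bit_score: float
    e_value: float
    source: str = "dna"
    count: int = 1

    def __post_init__(self) -> None:
        if self.source not in HIT_SOURCES:
            raise ValidationError(f"hit {self.gene_id!r}: unknown source {self.source!r}")
        if self.e_value < 0:
            raise DataError(f"hit {self.gene_id!r}: negative e-value {self.e_value}")
        if self.count < 1:
            raise ValidationError(f"hit {self.gene_id!r}: count must be >= 1")


@dataclass
class SampleAnnotation:
    """All gene hits of one sample plus the denominator for relative abundance."""

    sample_id: str
    total_gene_count: int
    hits: list[GeneHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_gene_count < 0:
            raise ValidationError(f"sample {self.sample_id!r}: negative total_gene_count")
        n_dna = sum(h.count for h in self.hits if h.source == "dna")
        if self.total_gene_count < n_dna:
            raise ValidationError(
                f"sample {self.sample_id!r}: total_gene_count {self.total_gene_count} "
                f"< number of dna hits {n_dna}"
            )

    @property
    def n_hits(self) -> int:
        return sum(h.count for h in self.hits)


@dataclass
class OTUTable:
    """Counts of OTUs (rows) per sample (columns)."""

    otu_ids: list[str]
    sample_ids: list[str]
    counts: list[list[int]]  # row-major: counts[i][j] = OTU i in sample j

    def __post_init__(self) -> None:
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValidationError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        for i, row in enumerate(self.counts):
            if len(row) != len(self.sample_ids):
                raise ValidationError(f"row {i}: wrong number of columns")
            if any(c < 0 for c in row):
                raise ValidationError(f"OTU {self.otu_ids[i]!r}: negative count")

    def column(self, sample_id: str) -> list[int]:
        j = self.sample_ids.index(sample_id)
        return [row[j] for row in self.counts]


@dataclass
class GenomeAnnotation:
    genome_id: str
    total_genes: int
    family_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_genes <= 0:
            raise ValidationError(f"genome {self.genome_id!r}: total_genes must be > 0")
        if any(c < 0 for c in self.family_counts.values()):
            raise ValidationError(f"genome {self.genome_id!r}: negative family count")
        if sum(self.family_counts.values()) > self.total_genes:
            raise ValidationError(
                f"genome {self.genome_id!r}: family counts exceed total_genes"
            )


@dataclass
class OTUGenomeMap:
    """otu_id -> (genome_id, 16S identity percent); at most one genome per OTU."""

    entries: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for otu, (genome, ident) in self.entries.items():
            if not 0.0 <= ident <= 100.0:
                raise ValidationError(
                    f"OTU {otu!r} -> {genome!r}: identity {ident} outside [0, 100]"
                )


@dataclass
class SampleMetadata:
    sample_id: str
    temperature: float
    tph: float | None = None
    o2: float | None = None
    latitude: float | None = None
    longitude: float | None = None
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature):
            raise ValidationError(f"sample {self.sample_id!r}: non-finite temperature")
        if self.tph is not None and self.tph < 0:
            raise ValidationError(f"sample {self.sample_id!r}: negative TPH")


@dataclass(frozen=True)
class MetaboliteEvidence:
    sample_id: str
    chemical_code: str
    status: str
    evidence_kind: str

    def __post_init__(self) -> None:
        if self.status not in EVIDENCE_STATUS:
            raise ValidationError(f"unknown evidence status {self.status!r}")
        if self.evidence_kind not in EVIDENCE_KINDS:
            raise ValidationError(f"unknown evidence kind {self.evidence_kind!r}")


# ---------------------------------------------------------------------------
# low-level TSV helpers
# ---------------------------------------------------------------------------


def _read_rows(path, required: list[str]) -> tuple[list[str], list[tuple[int, dict[str, str]]]]:
    """Read a TSV with header; returns (header, [(line_number, row_dict), ...])."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row") from None
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
        rows = []
        for lineno, raw in enumerate(reader, start=2):
            if not raw or all(f == "" for f in raw):
                continue
            if len(raw) != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} fields, got {len(raw)}")
            rows.append((lineno, dict(zip(header, raw))))
    return header, rows


def _parse_float(value: str, path, lineno: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-numeric {column} {value!r}") from None


def _parse_int(value: str, path, lineno: int, column: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-integer {column} {value!r}") from None


def _opt_float(value: str, path, lineno: int, column: str) -> float | None:
    if value == NA or value == "":
        return None
    return _parse_float(value, path, lineno, column)


def _fmt(x: float) -> str:
    return repr(float(x))


def _write_rows(path, header: list[str], rows: Iterable[Iterable[str]]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


# ---------------------------------------------------------------------------
# gene hit tables
# ---------------------------------------------------------------------------

HIT_COLUMNS = ["sample_id", "gene_id", "family_id", "bit_score", "e_value"]


def read_hit_table(path, totals_path, source_label: str = "dna") -> dict[str, SampleAnnotation]:
    """Read a gene-hit TSV plus its companion per-sample totals table.

    Returns one :class:`SampleAnnotation` per distinct sample_id, keyed by
    sample id. Every hit carries ``source_label``. An optional ``count``
    column carries imputed multiplicities (defaults to 1).
    """
    if source_label not in HIT_SOURCES:
        raise ValidationError(f"unknown source label {source_label!r}")
    totals = read_totals_table(totals_path)
    header, rows = _read_rows(path, HIT_COLUMNS)
    has_count = "count" in header

    hits_by_sample: dict[str, list[GeneHit]] = {}
    for lineno, row in rows:
        score = _parse_float(row["bit_score"], path, lineno, "bit_score")
        evalue = _parse_float(row["e_value"], path, lineno, "e_value")
        count = _parse_int(row["count"], path, lineno, "count") if has_count else 1
        hit = GeneHit(
            sample_id=row["sample_id"],
            gene_id=row["gene_id"],
            family_id=row["family_id"],
            bit_score=score,
            e_value=evalue,
            source=source_label,
            count=count,
        )
        hits_by_sample.setdefault(hit.sample_id, []).append(hit)

    if not hits_by_sample:
        logger.warning("%s: hit table contains no data rows", path)

    annotations = {}
    for sample_id, hits in hits_by_sample.items():
        if sample_id not in totals:
            raise ValidationError(
                f"{path}: sample {sample_id!r} has hits but no entry in totals table"
            )
        annotations[sample_id] = SampleAnnotation(
            sample_id=sample_id, total_gene_count=totals[sample_id], hits=hits
        )
    # samples with a denominator but zero hits are still real samples
    for sample_id, total in totals.items():
        if sample_id not in annotations:
            annotations[sample_id] = SampleAnnotation(sample_id, total, [])
    return annotations


def read_totals_table(path) -> dict[str, int]:
    _, rows = _read_rows(path, ["sample_id", "total_gene_count"])
    totals: dict[str, int] = {}
    for lineno, row in rows:
        sample = row["sample_id"]
        if sample in totals:
            raise ValidationError(f"{path}:{lineno}: duplicate sample_id {sample!r}")
        totals[sample] = _parse_int(row["total_gene_count"], path, lineno, "total_gene_count")
    return totals


def write_hit_table(annotations: Iterable[SampleAnnotation], path, totals_path) -> None:
    rows = []
    totals = []
    for ann in annotations:
        totals.append((ann.sample_id, str(ann.total_gene_count)))
        for h in ann.hits:
            rows.append(
                (h.sample_id, h.gene_id, h.family_id, _fmt(h.bit_score), _fmt(h.e_value), str(h.count))
            )
    _write_rows(path, HIT_COLUMNS + ["count"], rows)
    _write_rows(totals_path, ["sample_id", "total_gene_count"], totals)


# ---------------------------------------------------------------------------
# family/reaction catalog
# ---------------------------------------------------------------------------

CATALOG_COLUMNS = [
    "family_id",
    "class_tag",
    "substrate_code",
    "substrate_name",
    "product_code",
    "product_name",
]


def read_catalog(path) -> tuple[list[CatabolicFamily], list[Reaction]]:
    """Read the reaction catalog: one row per reaction, families deduplicated.

    An optional ``description`` column decorates the family. Rows whose
    reaction fields are all ``NA`` declare a family with no reaction.
    """
    header, rows = _read_rows(path, CATALOG_COLUMNS)
    has_desc = "description" in header

    families: dict[str, CatabolicFamily] = {}
    reactions: dict[tuple[str, str, str], Reaction] = {}
    for lineno, row in rows:
        fam = CatabolicFamily(
            family_id=row["family_id"],
            class_tag=row["class_tag"],
            description=row.get("description", "") if has_desc else "",
        )
        prev = families.get(fam.family_id)
        if prev is not None and prev != fam:
            raise ValidationError(
                f"{path}:{lineno}: family {fam.family_id!r} redefined inconsistently"
            )
        families[fam.family_id] = fam
        if row["substrate_code"] == NA and row["product_code"] == NA:
            continue
        rxn = Reaction(
            family_id=row["family_id"],
            substrate_code=row["substrate_code"],
            product_code=row["product_code"],
            substrate_name=row["substrate_name"],
            product_name=row["product_name"],
        )
        if rxn.key in reactions:
            raise ValidationError(
                f"{path}:{lineno}: duplicate reaction {rxn.key}"
            )
        reactions[rxn.key] = rxn

    for rxn in reactions.values():
        if rxn.family_id not in families:
            raise ValidationError(f"reaction references unknown family {rxn.family_id!r}")
    return sorted(families.values(), key=lambda f: f.family_id), [
        reactions[k] for k in sorted(reactions)
    ]


def write_catalog(families: Iterable[CatabolicFamily], reactions: Iterable[Reaction], path) -> None:
    fams = {f.family_id: f for f in families}
    rows = []
    seen = set()
    for r in reactions:
        fam = fams[r.family_id]
        seen.add(r.family_id)
        rows.append(
            (r.family_id, fam.class_tag, r.substrate_code, r.substrate_name,
             r.product_code, r.product_name, fam.description)
        )
    for fid, fam in fams.items():
        if fid not in seen:
            rows.append((fid, fam.class_tag, NA, NA, NA, NA, fam.description))
    _write_rows(path, CATALOG_COLUMNS + ["description"], rows)


# ---------------------------------------------------------------------------
# OTU table / genome annotations / OTU->genome map
# ---------------------------------------------------------------------------


def read_otu_table(path) -> OTUTable:
    header, rows = _read_rows(path, ["otu_id"])
    sample_ids = header[1:]
    otu_ids = []
    counts = []
    for lineno, row in rows:
        otu_ids.append(row["otu_id"])
        counts.append([_parse_int(row[s], path, lineno, s) for s in sample_ids])
    return OTUTable(otu_ids=otu_ids, sample_ids=sample_ids, counts=counts)


def write_otu_table(table: OTUTable, path) -> None:
    rows = (
        [otu] + [str(c) for c in row]
        for otu, row in zip(table.otu_ids, table.counts)
    )
    _write_rows(path, ["otu_id"] + list(table.sample_ids), rows)


GENOME_COLUMNS = ["genome_id", "total_genes", "family_id", "count"]


def read_genome_annotations(path) -> dict[str, GenomeAnnotation]:
    """Long-format genome catabolic summaries: one row per (genome, family).

    A row with family_id ``NA`` declares a genome without catabolic families.
    """
    _, rows = _read_rows(path, GENOME_COLUMNS)
    totals: dict[str, int] = {}
    fam_counts: dict[str, dict[str, int]] = {}
    for lineno, row in rows:
        gid = row["genome_id"]
        total = _parse_int(row["total_genes"], path, lineno, "total_genes")
        if gid in totals and totals[gid] != total:
            raise ValidationError(f"{path}:{lineno}: genome {gid!r} total_genes mismatch")
        totals[gid] = total
        fam_counts.setdefault(gid, {})
        if row["family_id"] != NA:
            fam_counts[gid][row["family_id"]] = _parse_int(row["count"], path, lineno, "count")
    return {
        gid: GenomeAnnotation(genome_id=gid, total_genes=totals[gid], family_counts=fam_counts[gid])
        for gid in totals
    }


def write_genome_annotations(genomes: Mapping[str, GenomeAnnotation], path) -> None:
    rows = []
    for gid in genomes:
        g = genomes[gid]
        if not g.family_counts:
            rows.append((gid, str(g.total_genes), NA, "0"))
        for fam in g.family_counts:
            rows.append((gid, str(g.total_genes), fam, str(g.family_counts[fam])))
    _write_rows(path, GENOME_COLUMNS, rows)


def read_otu_genome_map(path) -> OTUGenomeMap:
    _, rows = _read_rows(path, ["otu_id", "genome_id", "identity_percent"])
    entries: dict[str, tuple[str, float]] = {}
    for lineno, row in rows:
        otu = row["otu_id"]
        if otu in entries:
            raise ValidationError(f"{path}:{lineno}: OTU {otu!r} mapped more than once")
        entries[otu] = (row["genome_id"], _parse_float(row["identity_percent"], path, lineno, "identity_percent"))
    return OTUGenomeMap(entries=entries)


def write_otu_genome_map(omap: OTUGenomeMap, path) -> None:
    rows = ((otu, genome, _fmt(ident)) for otu, (genome, ident) in omap.entries.items())
    _write_rows(path, ["otu_id", "genome_id", "identity_percent"], rows)


# ---------------------------------------------------------------------------
# sample metadata / metabolite evidence
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ["sample_id", "temperature", "tph", "o2", "latitude", "longitude"]


def read_metadata(path) -> dict[str, SampleMetadata]:
    header, rows = _read_rows(path, ["sample_id", "temperature"])
    extra_cols = [c for c in header if c not in METADATA_COLUMNS]
    out: dict[str, SampleMetadata] = {}
    for lineno, row in rows:
        sid = row["sample_id"]
        if sid in out:
            raise ValidationError(f"{path}:{lineno}: duplicate sample {sid!r}")
        out[sid] = SampleMetadata(
            sample_id=sid,
            temperature=_parse_float(row["temperature"], path, lineno, "temperature"),
            tph=_opt_float(row.get("tph", NA), path, lineno, "tph"),
            o2=_opt_float(row.get("o2", NA), path, lineno, "o2"),
            latitude=_opt_float(row.get("latitude", NA), path, lineno, "latitude"),
            longitude=_opt_float(row.get("longitude", NA), path, lineno, "longitude"),
            extra={c: row[c] for c in extra_cols},
        )
    return out


def write_metadata(metadata: Mapping[str, SampleMetadata], path) -> None:
    extra_cols = sorted({k for m in metadata.values() for k in m.extra})

    def opt(x):
        return NA if x is None else _fmt(x)

    rows = (
        (m.sample_id, _fmt(m.temperature), opt(m.tph), opt(m.o2), opt(m.latitude),
         opt(m.longitude), *(m.extra.get(c, NA) for c in extra_cols))
        for m in metadata.values()
    )
    _write_rows(path, METADATA_COLUMNS + extra_cols, rows)


EVIDENCE_COLUMNS = ["sample_id", "chemical_code", "status", "evidence_kind"]


def read_evidence(path) -> list[MetaboliteEvidence]:
    _, rows = _read_rows(path, EVIDENCE_COLUMNS)
    return [
        MetaboliteEvidence(
            sample_id=row["sample_id"],
            chemical_code=row["chemical_code"],
            status=row["status"],
            evidence_kind=row["evidence_kind"],
        )
        for _, row in rows
    ]


def write_evidence(evidence: Iterable[MetaboliteEvidence], path) -> None:
    rows = ((e.sample_id, e.chemical_code, e.status, e.evidence_kind) for e in evidence)
    _write_rows(path, EVIDENCE_COLUMNS, rows)


GENE_COUNT_COLUMNS = ["sample_id", "chemical_code", "gene_count"]


def read_gene_counts(path) -> dict[tuple[str, str], int]:
    _, rows = _read_rows(path, GENE_COUNT_COLUMNS)
    out: dict[tuple[str, str], int] = {}
    for lineno, row in rows:
        key = (row["sample_id"], row["chemical_code"])
        if key in out:
            raise ValidationError(f"{path}:{lineno}: duplicate (sample, chemical) {key}")
        out[key] = _parse_int(row["gene_count"], path, lineno, "gene_count")
    return out


def write_gene_counts(counts: Mapping[tuple[str, str], int], path) -> None:
    rows = ((s, c, str(k)) for (s, c), k in counts.items())
    _write_rows(path, GENE_COUNT_COLUMNS, rows)


# ---------------------------------------------------------------------------
# LC-MS feature matrices
# ---------------------------------------------------------------------------


def read_feature_matrix(path) -> tuple[list[str], list[str], list[list[float]]]:
    """Feature (rows) x replicate (columns) abundance matrix."""
    header, rows = _read_rows(path, ["feature_id"])
    replicate_ids = header[1:]
    feature_ids, values = [], []
    for lineno, row in rows:
        feature_ids.append(row["feature_id"])
        values.append([_parse_float(row[r], path, lineno, r) for r in replicate_ids])
    return feature_ids, replicate_ids, values


def write_feature_matrix(feature_ids, replicate_ids, values, path) -> None:
    rows = ([fid] + [_fmt(v) for v in row] for fid, row in zip(feature_ids, values))
    _write_rows(path, ["feature_id"] + list(replicate_ids), rows)


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

EXPORT_FORMATS = ("graphml", "dot", "edge_tsv")


def export_network(net: "MetaNetwork", path, format: str = "edge_tsv") -> None:
    """Write a meta-network to ``path`` in one of the supported formats.

    * ``edge_tsv`` — round-trippable edge list, one weight column per sample.
    * ``graphml`` — per-sample weights as edge attributes ``weight_<sample>``.
    * ``dot`` — pen-width linear in the mean weight across samples
      (:data:`DOT_PENWIDTH_PER_PERCENT` points of width per percent).
    """
    if format not in EXPORT_FORMATS:
        raise ValidationError(
            f"unknown export format {format!r}; expected one of {', '.join(EXPORT_FORMATS)}"
        )
    if format == "edge_tsv":
        _export_edge_tsv(net, path)
    elif format == "graphml":
        _export_graphml(net, path)
    else:
        _export_dot(net, path)


def _export_edge_tsv(net: "MetaNetwork", path) -> None:
    header = ["substrate_code", "product_code", "family_id"] + [
        f"weight_{s}" for s in net.samples
    ]
    rows = []
    for key in sorted(net.edges):
        sub, prod, fam = key
        weights = net.edges[key]
        rows.append([sub, prod, fam] + [_fmt(weights.get(s, 0.0)) for s in net.samples])
    _write_rows(path, header, rows)


def read_edge_tsv(path) -> "MetaNetwork":
    from degnet.metaweb import MetaNetwork

    header, rows = _read_rows(path, ["substrate_code", "product_code", "family_id"])
    samples = [c[len("weight_"):] for c in header if c.startswith("weight_")]
    edges: dict[tuple[str, str, str], dict[str, float]] = {}
    for lineno, row in rows:
        key = (row["substrate_code"], row["product_code"], row["family_id"])
        edges[key] = {
            s: _parse_float(row[f"weight_{s}"], path, lineno, f"weight_{s}") for s in samples
        }
    return MetaNetwork(samples=samples, edges=edges)


def _export_graphml(net: "MetaNetwork", path) -> None:
    import networkx as nx

    g = nx.MultiDiGraph()
    g.add_nodes_from(sorted(net.nodes))
    for key in sorted(net.edges):
        sub, prod, fam = key
        attrs = {"family_id": fam}
        for s in net.samples:
            attrs[f"weight_{s}"] = float(net.edges[key].get(s, 0.0))
        g.add_edge(sub, prod, key=fam, **attrs)
    nx.write_graphml(g, path)


def _export_dot(net: "MetaNetwork", path) -> None:
    lines = ["digraph metaweb {"]
    for node in sorted(net.nodes):
        lines.append(f'  "{node}";')
    for key in sorted(net.edges):
        sub, prod, fam = key
        weights = net.edges[key]
        mean_w = sum(weights.get(s, 0.0) for s in net.samples) / max(len(net.samples), 1)
        penwidth = mean_w * DOT_PENWIDTH_PER_PERCENT
        lines.append(
            f'  "{sub}" -> "{prod}" [label="{fam}", penwidth={penwidth:.6g}];'
        )
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
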