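"""Screening of gene hits, relative-abundance profiles, taxonomy-based
imputation and pooling of DNA with imputed evidence.

The central quantity is the per-sample percentage of all predicted
protein-coding genes that belong to each catabolic family, and their sum
(``degp_total``). All percentages are relative to the sample's total gene
count so that samples of different sequencing depth are comparable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from degnet.errors import DataError, ValidationError
from degnet.io_catalog import (
    GeneHit,
    GenomeAnnotation,
    OTUGenomeMap,
    OTUTable,
    SampleAnnotation,
)

logger = logging.getLogger(__name__)

#: default screening thresholds: bit score strictly above, e-value strictly below
DEFAULT_MIN_SCORE = 45.0
DEFAULT_MAX_EVALUE = 1e-3

#: sentinel score/e-value attached to imputed gene-equivalents; always pass screening
IMPUTED_BIT_SCORE = 1e9
IMPUTED_E_VALUE = 0.0


@dataclass
class CatabolicProfile:
    """Per-sample family-level relative abundances in percent of total genes.

    ``family_counts`` holds gene-equivalent counts (floats, since imputed
    evidence scales genome counts by OTU counts); percentages are derived.
    ``denominators`` records the (dna, imputed) gene totals so profiles can
    be pooled exactly.
    """

    sample_id: str
    family_counts: dict[str, float]
    denominators: tuple[float, float]  # (dna_total_genes, imputed_total_genes)
    source_mix: str  # one of {dna, imputed, combined}

    def __post_init__(self) -> None:
        if self.source_mix not in {"dna", "imputed", "combined"}:
            raise ValidationError(f"unknown source_mix {self.source_mix!r}")
        if any(c < 0 for c in self.family_counts.values()):
            raise ValidationError(f"sample {self.sample_id!r}: negative family count")

    @property
    def total_genes(self) -> float:
        return self.denominators[0] + self.denominators[1]

    @property
    def family_percent(self) -> dict[str, float]:
        denom = self.total_genes
        if denom == 0:
            return {f: 0.0 for f in self.family_counts}
        return {f: 100.0 * c / denom for f, c in self.family_counts.items()}

    @property
    def degp_total(self) -> float:
        denom = self.total_genes
        if denom == 0:
            return 0.0
        return 100.0 * sum(self.family_counts.values()) / denom


def screen_hits(
    ann: SampleAnnotation,
    min_score: float = DEFAULT_MIN_SCORE,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> SampleAnnotation:
    """Keep hits with bit score strictly above ``min_score`` and e-value
    strictly below ``max_evalue``; the denominator is unchanged."""
    if not (math.isfinite(min_score) and math.isfinite(max_evalue)):
        raise ValidationError("screening thresholds must be finite")
    for h in ann.hits:
        if h.e_value < 0:
            raise DataError(f"gene {h.gene_id!r}: negative e-value {h.e_value}")
    kept = [h for h in ann.hits if h.bit_score > min_score and h.e_value < max_evalue]
    return SampleAnnotation(
        sample_id=ann.sample_id, total_gene_count=ann.total_gene_count, hits=kept
    )


def profile(ann: SampleAnnotation, source_mix: str = "dna") -> CatabolicProfile:
    """Relative abundance of each family as percent of the sample's genes.

    The annotation is assumed to be already screened; every hit it carries
    counts toward its family.
    """
    if ann.total_gene_count == 0:
        raise DataError(f"sample {ann.sample_id!r}: total_gene_count is 0, undefined denominator")
    counts: dict[str, float] = {}
    for h in ann.hits:
        counts[h.family_id] = counts.get(h.family_id, 0.0) + h.count
    denominators = (
        (float(ann.total_gene_count), 0.0)
        if source_mix == "dna"
        else (0.0, float(ann.total_gene_count))
    )
    return CatabolicProfile(
        sample_id=ann.sample_id,
        family_counts=counts,
        denominators=denominators,
        source_mix=source_mix,
    )


def impute_from_taxonomy(
    otus: OTUTable,
    omap: OTUGenomeMap,
    genomes: dict[str, GenomeAnnotation],
    sample_id: str,
) -> SampleAnnotation:
    """Impute catabolic gene content for one sample from its OTU counts.

    Each OTU with count ``c`` mapped to genome ``g`` contributes
    ``c * family_counts_g[f]`` gene-equivalents per family ``f`` and
    ``c * total_genes_g`` to the imputed denominator. Multiplicity is
    materialised on the hit's ``count`` field, not as replicated rows.
    Unmapped OTUs contribute nothing and are reported in a logged warning.
    """
    for otu, (genome_id, _) in omap.entries.items():
        if genome_id not in genomes:
            raise ValidationError(f"OTU map references missing genome {genome_id!r}")
    column = otus.column(sample_id)
    hits: list[GeneHit] = []
    imputed_total = 0
    n_unmapped = 0
    for otu, count in zip(otus.otu_ids, column):
        if count == 0:
            continue
        if otu not in omap.entries:
            n_unmapped += 1
            continue
        genome_id, _ = omap.entries[otu]
        g = genomes[genome_id]
        imputed_total += count * g.total_genes
        for fam, n in g.family_counts.items():
            if n == 0:
                continue
            hits.append(
                GeneHit(
                    sample_id=sample_id,
                    gene_id=f"imp|{otu}|{fam}",
                    family_id=fam,
                    bit_score=IMPUTED_BIT_SCORE,
                    e_value=IMPUTED_E_VALUE,
                    source="imputed",
                    count=count * n,
                )
            )
    if n_unmapped:
        logger.warning(
            "sample %s: %d OTU(s) with reads had no genome mapping and were skipped",
            sample_id,
            n_unmapped,
        )
    return SampleAnnotation(sample_id=sample_id, total_gene_count=imputed_total, hits=hits)


def merge_sources(
    dna: CatabolicProfile, imputed: CatabolicProfile, mode: str = "pooled"
) -> CatabolicProfile:
    """Combine a DNA-based profile with a taxonomy-imputed one.

    ``pooled`` (default) adds gene-equivalent counts and denominators, i.e.
    combined percent = 100 * (dna_count + imputed_count) / (dna_total +
    imputed_total). ``averaged`` instead takes the unweighted mean of the two
    percentages per family (kept for sensitivity comparison).
    """
    if dna.sample_id != imputed.sample_id:
        raise ValidationError(
            f"cannot merge profiles of different samples: {dna.sample_id!r} vs {imputed.sample_id!r}"
        )
    if mode not in {"pooled", "averaged"}:
        raise ValidationError(f"unknown merge mode {mode!r}")
    families = set(dna.family_counts) | set(imputed.family_counts)
    dna_total = dna.total_genes
    imp_total = imputed.total_genes
    if mode == "pooled":
        counts = {
            f: dna.family_counts.get(f, 0.0) + imputed.family_counts.get(f, 0.0)
            for f in families
        }
    else:
        dna_pct = dna.family_percent
        imp_pct = imputed.family_percent
        combined_total = dna_total + imp_total
        counts = {
            f: (dna_pct.get(f, 0.0) + imp_pct.get(f, 0.0)) / 2.0 * combined_total / 100.0
            for f in families
        }
    return CatabolicProfile(
        sample_id=dna.sample_id,
        family_counts=counts,
        denominators=(dna_total, imp_total),
        source_mix="combined",
    )


# ---------------------------------------------------------------------------
# profile table I/O (sample x family percent matrix + degp_total)
# ---------------------------------------------------------------------------


def write_profiles(profiles: list[CatabolicProfile], path) -> None:
    from degnet.io_catalog import _fmt, _write_rows

    families = sorted({f for p in profiles for f in p.family_counts})
    header = ["sample_id", "source_mix", "dna_total_genes", "imputed_total_genes", "degp_total"] + families
    rows = []
    for p in profiles:
        pct = p.family_percent
        rows.append(
            [p.sample_id, p.source_mix, _fmt(p.denominators[0]), _fmt(p.denominators[1]),
             _fmt(p.degp_total)] + [_fmt(pct.get(f, 0.0)) for f in families]
        )
    _write_rows(path, header, rows)


def read_profiles(path) -> list[CatabolicProfile]:
    from degnet.io_catalog import _parse_float, _read_rows

    header, rows = _read_rows(
        path, ["sample_id", "source_mix", "dna_total_genes", "imputed_total_genes", "degp_total"]
    )
    families = header[5:]
    out = []
    for lineno, row in rows:
        d_tot = _parse_float(row["dna_total_genes"], path, lineno, "dna_total_genes")
        i_tot = _parse_float(row["imputed_total_genes"], path, lineno, "imputed_total_genes")
        total = d_tot + i_tot
        counts = {}
        for f in families:
            pct = _parse_float(row[f], path, lineno, f)
            if pct > 0.0:
                counts[f] = pct * total / 100.0
        out.append(
            CatabolicProfile(
                sample_id=row["sample_id"],
                family_counts=counts,
                denominators=(d_tot, i_tot),
                source_mix=row["source_mix"],
            )
        )
    return out
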