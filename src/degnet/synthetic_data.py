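"""Synthetic studies with planted, recoverable structure.

One :func:`generate_study` call produces every artifact the pipeline
consumes — gene annotations, an OTU table, reference-genome summaries, an
OTU->genome map, sample metadata, metabolite evidence — together with the
ground truth that produced them:

* a linear temperature -> catabolic-gene-fraction relationship with
  Gaussian noise,
* OTU richness decreasing in temperature (log-normal rank abundances,
  richness controlled by truncation),
* two community clusters separated by ``cluster_gap`` on the log-abundance
  scale, aligned with the warm/cold halves of the temperature gradient,
* metabolite-evidence outcomes drawn from a known gene-count ->
  degradation-probability curve.

All randomness flows from a single seed through one named generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from degnet.errors import ValidationError
from degnet.io_catalog import (
    CatabolicFamily,
    GeneHit,
    GenomeAnnotation,
    MetaboliteEvidence,
    OTUGenomeMap,
    OTUTable,
    Reaction,
    SampleAnnotation,
    SampleMetadata,
)

#: default planted line: 1.8% at 13.0 degC rising to 4.21% at 26.5 degC
DEFAULT_SLOPE = (4.21 - 1.8) / (26.5 - 13.0)
DEFAULT_INTERCEPT = 1.8 - DEFAULT_SLOPE * 13.0

#: noise on the planted line calibrated by Monte Carlo so that the
#: DEGgp-vs-temperature regression averages r^2 ~ 0.8 at the default design
DEFAULT_NOISE_SD = 0.46

#: cluster separations at or above this value are recovered with ARI 1.0 by
#: Bray-Curtis PCoA + best contiguous MDS1 split (verified by simulation)
CLUSTER_GAP_THRESHOLD = 2.0

DEFAULT_CONFIDENCE_CURVE = {0: 0.05, 1: 0.50, 2: 0.80, 3: 0.92, 4: 0.97, 5: 0.99}


def default_catalog() -> tuple[list[CatabolicFamily], list[Reaction]]:
    """A compact catabolic catalog spanning alkane oxidation, peripheral
    aromatic funnels and both ring-cleavage modes."""
    spec = [
        # family, class, substrate code/name, product code/name
        ("AlkB", "alkane", "ALK", "alkanes", "ALO", "alkanols"),
        ("P450", "alkane", "ALK", "alkanes", "ALO", "alkanols"),
        ("FaHy", "other", "FAT", "fatty acids", "FAO", "hydroxy fatty acids"),
        ("XylM", "monoaromatic", "TOL", "toluene", "BZA", "benzoate"),
        ("BenA", "monoaromatic", "BZA", "benzoate", "CAT", "catechol"),
        ("DmpN", "monoaromatic", "PHE", "phenol", "CAT", "catechol"),
        ("XylE", "ring_cleavage_extradiol", "CAT", "catechol", "124", "HOHD"),
        ("CatA", "ring_cleavage_intradiol", "CAT", "catechol", "MUC", "cis,cis-muconate"),
        ("CatB", "other", "MUC", "cis,cis-muconate", "OXA", "muconolactone"),
        ("XylF", "other", "124", "HOHD", "OXA", "2-oxopent-4-enoate"),
        ("NahAc", "polyaromatic", "NAP", "naphthalene", "SAL", "salicylate"),
        ("PhdA", "polyaromatic", "PHD", "phenanthrene", "NAP", "naphthalene"),
        ("Dfd", "polyaromatic", "DBF", "dibenzofuran", "SAL", "salicylate"),
        ("NahG", "monoaromatic", "SAL", "salicylate", "CAT", "catechol"),
        ("NagG", "monoaromatic", "SAL", "salicylate", "GEN", "gentisate"),
        ("NagI", "other", "GEN", "gentisate", "MAL", "maleylpyruvate"),
        ("PobA", "monoaromatic", "4HB", "4-hydroxybenzoate", "104", "protocatechuate"),
        ("PcaHG", "ring_cleavage_intradiol", "104", "protocatechuate", "CHM", "carboxymuconate"),
        ("LigAB", "ring_cleavage_extradiol", "104", "protocatechuate", "CHS", "CHMS"),
        ("BphA", "polyaromatic", "BPH", "biphenyl", "BZA", "benzoate"),
        ("TphA", "monoaromatic", "TER", "terephthalate", "104", "protocatechuate"),
        ("OphA", "monoaromatic", "PHT", "phthalate", "104", "protocatechuate"),
    ]
    families = [CatabolicFamily(f, tag) for f, tag, *_ in spec]
    reactions = [
        Reaction(f, sub, prod, substrate_name=sn, product_name=pn)
        for f, _, sub, sn, prod, pn in spec
    ]
    return families, reactions


def curve_value(curve: Mapping[int, float], k: int) -> float:
    """Step-function lookup: the value at the largest key <= k."""
    keys = sorted(curve)
    best = keys[0]
    for key in keys:
        if key <= k:
            best = key
        else:
            break
    return float(curve[best])


@dataclass
class StudyDesign:
    n_samples: int = 8
    temperature_range: tuple[float, float] = (13.0, 26.5)
    degp_slope: float = DEFAULT_SLOPE  # percent per degC
    degp_intercept: float = DEFAULT_INTERCEPT  # percent
    degp_noise_sd: float = DEFAULT_NOISE_SD  # percent
    richness_slope: float = -6.0  # OTUs per degC (negative)
    richness_base: int = 180  # richness at t_min
    cluster_gap: float = 3.0  # log-abundance separation between centroids
    genes_per_sample: int = 40_000
    n_otus: int = 240
    otu_depth: int = 20_000
    n_genomes: int = 12
    mapped_fraction: float = 0.7
    decoy_fraction: float = 0.15  # extra hits planted to fail screening
    confidence_curve: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFIDENCE_CURVE)
    )
    evidence_replicates: int = 1
    seed: int = 0

    def validate(self) -> None:
        t_min, t_max = self.temperature_range
        if not t_min < t_max:
            raise ValidationError("temperature_range must satisfy t_min < t_max")
        if self.n_samples < 4:
            raise ValidationError("need at least 4 samples")
        for t in (t_min, t_max):
            degp = self.degp_intercept + self.degp_slope * t
            if not 0.0 < degp < 100.0:
                raise ValidationError(
                    f"design implies DEGgp {degp:.3g}% at {t} degC, outside (0, 100)"
                )
        probs = [self.confidence_curve[k] for k in sorted(self.confidence_curve)]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("confidence_curve probabilities must lie in [0, 1]")
        if any(b < a for a, b in zip(probs, probs[1:])):
            raise ValidationError("confidence_curve must be non-decreasing in k")
        if self.richness_slope > 0:
            raise ValidationError("richness_slope must be <= 0")


@dataclass
class PlantedTruth:
    temperatures: dict[str, float]
    degp: dict[str, float]  # realized planted DEGgp % (after count quantization)
    degp_line: dict[str, float]  # intercept + slope * T, before noise
    cluster: dict[str, int]  # 1 = cold, 2 = warm
    otu_proportions: dict[str, list[float]]
    gene_counts: dict[tuple[str, str], int]  # (sample, chemical) -> k
    degradation_prob: dict[tuple[str, str], float]  # planted curve at k
    degraded: dict[tuple[str, str], bool]  # first evidence draw

    def to_dict(self) -> dict:
        return {
            "temperatures": self.temperatures,
            "degp": self.degp,
            "degp_line": self.degp_line,
            "cluster": self.cluster,
            "otu_proportions": self.otu_proportions,
            "gene_counts": {f"{s}\t{c}": k for (s, c), k in self.gene_counts.items()},
            "degradation_prob": {
                f"{s}\t{c}": p for (s, c), p in self.degradation_prob.items()
            },
            "degraded": {f"{s}\t{c}": bool(v) for (s, c), v in self.degraded.items()},
        }


@dataclass
class SyntheticStudy:
    design: StudyDesign
    families: list[CatabolicFamily]
    reactions: list[Reaction]
    annotations: dict[str, SampleAnnotation]
    otu_table: OTUTable
    genomes: dict[str, GenomeAnnotation]
    otu_map: OTUGenomeMap
    metadata: dict[str, SampleMetadata]
    evidence: list[MetaboliteEvidence]
    truth: PlantedTruth


def generate_study(
    design: StudyDesign,
    catalog: tuple[list[CatabolicFamily], list[Reaction]] | None = None,
) -> SyntheticStudy:
    """Generate a complete synthetic study; byte-identical for a fixed seed."""
    design.validate()
    families, reactions = catalog if catalog is not None else default_catalog()
    family_ids = [f.family_id for f in families]
    rng = np.random.default_rng(design.seed)

    n = design.n_samples
    t_min, t_max = design.temperature_range
    temps = np.linspace(t_min, t_max, n)
    sample_ids = [f"S{i + 1:02d}" for i in range(n)]

    # study-level family composition of the catabolic gene pool
    family_weights = rng.dirichlet(np.ones(len(family_ids)))

    annotations: dict[str, SampleAnnotation] = {}
    truth_degp: dict[str, float] = {}
    truth_line: dict[str, float] = {}
    retained_family_counts: dict[str, dict[str, int]] = {}
    for sid, t in zip(sample_ids, temps):
        line = design.degp_intercept + design.degp_slope * t
        target = line + rng.normal(0.0, design.degp_noise_sd) if design.degp_noise_sd > 0 else line
        while not 0.0 < target < 100.0:
            target = line + rng.normal(0.0, design.degp_noise_sd)
        k = int(round(target / 100.0 * design.genes_per_sample))
        k = max(k, 1)
        truth_line[sid] = float(line)
        truth_degp[sid] = 100.0 * k / design.genes_per_sample

        per_family = rng.multinomial(k, family_weights)
        hits: list[GeneHit] = []
        g = 0
        for fam, m in zip(family_ids, per_family):
            for _ in range(int(m)):
                hits.append(
                    GeneHit(
                        sample_id=sid,
                        gene_id=f"{sid}_g{g}",
                        family_id=fam,
                        bit_score=float(rng.uniform(60.0, 300.0)),
                        e_value=float(10.0 ** rng.uniform(-50.0, -5.0)),
                        source="dna",
                    )
                )
                g += 1
        retained_family_counts[sid] = {
            fam: int(m) for fam, m in zip(family_ids, per_family) if m > 0
        }
        # decoys are planted to fail both screening thresholds
        n_decoy = int(round(design.decoy_fraction * k))
        decoy_fams = rng.choice(family_ids, size=n_decoy)
        for fam in decoy_fams:
            hits.append(
                GeneHit(
                    sample_id=sid,
                    gene_id=f"{sid}_g{g}",
                    family_id=str(fam),
                    bit_score=float(rng.uniform(5.0, 44.0)),
                    e_value=float(10.0 ** rng.uniform(-2.5, -0.5)),
                    source="dna",
                )
            )
            g += 1
        annotations[sid] = SampleAnnotation(
            sample_id=sid, total_gene_count=design.genes_per_sample, hits=hits
        )

    # --- community: two clusters along the temperature gradient -----------
    cluster = {sid: (1 if i < n // 2 else 2) for i, sid in enumerate(sample_ids)}
    base_mu = rng.normal(0.0, 1.2, design.n_otus)
    direction = rng.choice([-1.0, 1.0], design.n_otus)
    otu_ids = [f"OTU{i + 1:04d}" for i in range(design.n_otus)]
    columns: dict[str, np.ndarray] = {}
    truth_props: dict[str, list[float]] = {}
    for sid, t in zip(sample_ids, temps):
        sign = -1.0 if cluster[sid] == 1 else 1.0
        mu = base_mu + sign * (design.cluster_gap / 2.0) * direction
        log_ab = mu + rng.normal(0.0, 0.4, design.n_otus)
        richness = int(round(design.richness_base + design.richness_slope * (t - t_min)))
        richness = int(np.clip(richness, 5, design.n_otus))
        keep = np.argsort(log_ab)[::-1][:richness]
        props = np.zeros(design.n_otus)
        props[keep] = np.exp(log_ab[keep])
        props /= props.sum()
        columns[sid] = rng.multinomial(design.otu_depth, props)
        truth_props[sid] = [float(p) for p in props]
    counts = [
        [int(columns[sid][i]) for sid in sample_ids] for i in range(design.n_otus)
    ]
    otu_table = OTUTable(otu_ids=otu_ids, sample_ids=sample_ids, counts=counts)

    # --- reference genomes and the OTU -> genome affiliation --------------
    genomes: dict[str, GenomeAnnotation] = {}
    for gi in range(design.n_genomes):
        gid = f"G{gi + 1:03d}"
        total = int(rng.integers(2000, 6000))
        fam_counts = {
            fam: int(rng.integers(1, 6))
            for fam in family_ids
            if rng.random() < 0.4
        }
        genomes[gid] = GenomeAnnotation(genome_id=gid, total_genes=total, family_counts=fam_counts)
    n_mapped = int(round(design.mapped_fraction * design.n_otus))
    mapped = rng.choice(design.n_otus, size=n_mapped, replace=False)
    entries = {
        otu_ids[i]: (
            f"G{int(rng.integers(design.n_genomes)) + 1:03d}",
            float(rng.uniform(90.0, 100.0)),
        )
        for i in sorted(mapped)
    }
    otu_map = OTUGenomeMap(entries=entries)

    # --- metadata ----------------------------------------------------------
    metadata = {}
    for sid, t in zip(sample_ids, temps):
        metadata[sid] = SampleMetadata(
            sample_id=sid,
            temperature=float(t),
            tph=float(round(10.0 ** rng.uniform(2.06, 5.4), 1)),
            o2=None if rng.random() < 0.2 else float(round(rng.uniform(0.0, 22.0), 2)),
            latitude=float(round(rng.uniform(27.0, 43.0), 4)),
            longitude=float(round(rng.uniform(-6.0, 35.0), 4)),
        )

    # --- metabolite evidence from the planted confidence curve -------------
    fams_for_chem: dict[str, set[str]] = {}
    for r in reactions:
        fams_for_chem.setdefault(r.substrate_code, set()).add(r.family_id)
    gene_counts: dict[tuple[str, str], int] = {}
    prob: dict[tuple[str, str], float] = {}
    degraded: dict[tuple[str, str], bool] = {}
    evidence: list[MetaboliteEvidence] = []
    for sid in sample_ids:
        for chem in sorted(fams_for_chem):
            k = sum(
                retained_family_counts[sid].get(f, 0) for f in fams_for_chem[chem]
            )
            gene_counts[(sid, chem)] = k
            p = curve_value(design.confidence_curve, k)
            prob[(sid, chem)] = p
            for rep in range(design.evidence_replicates):
                is_deg = bool(rng.random() < p)
                if rep == 0:
                    degraded[(sid, chem)] = is_deg
                kind = (
                    ("substrate_depleted", "intermediate_detected")[int(rng.integers(2))]
                    if is_deg
                    else "substrate_depleted"
                )
                evidence.append(
                    MetaboliteEvidence(
                        sample_id=sid,
                        chemical_code=chem,
                        status="degraded" if is_deg else "not_degraded",
                        evidence_kind=kind,
                    )
                )

    truth = PlantedTruth(
        temperatures={s: float(t) for s, t in zip(sample_ids, temps)},
        degp=truth_degp,
        degp_line=truth_line,
        cluster=cluster,
        otu_proportions=truth_props,
        gene_counts=gene_counts,
        degradation_prob=prob,
        degraded=degraded,
    )
    return SyntheticStudy(
        design=design,
        families=families,
        reactions=reactions,
        annotations=annotations,
        otu_table=otu_table,
        genomes=genomes,
        otu_map=otu_map,
        metadata=metadata,
        evidence=evidence,
        truth=truth,
    )


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write every artifact in the pipeline's TSV formats plus truth.json."""
    import os

    from degnet import io_catalog as io

    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(outdir, name)
    io.write_hit_table(study.annotations.values(), p("hits_dna.tsv"), p("totals_dna.tsv"))
    io.write_catalog(study.families, study.reactions, p("catalog.tsv"))
    io.write_otu_table(study.otu_table, p("otu_table.tsv"))
    io.write_genome_annotations(study.genomes, p("genomes.tsv"))
    io.write_otu_genome_map(study.otu_map, p("otu_map.tsv"))
    io.write_metadata(study.metadata, p("metadata.tsv"))
    io.write_evidence(study.evidence, p("evidence.tsv"))
    io.write_gene_counts(study.truth.gene_counts, p("gene_counts.tsv"))
    with open(p("truth.json"), "w") as fh:
        json.dump(study.truth.to_dict(), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# focused generators for calibration experiments
# ---------------------------------------------------------------------------


def generate_confidence_evidence(
    curve: Mapping[int, float], n: int, seed: int = 0
) -> tuple[list[MetaboliteEvidence], dict[tuple[str, str], int], np.ndarray, np.ndarray]:
    """Draw n evidence rows with gene counts uniform over the curve's domain
    and outcomes Bernoulli(curve(k)). Returns (evidence, gene_counts, ks, ys)."""
    rng = np.random.default_rng(seed)
    k_max = max(curve)
    ks = rng.integers(0, k_max + 1, size=n)
    probs = np.array([curve_value(curve, int(k)) for k in ks])
    ys = (rng.random(n) < probs).astype(int)
    evidence = []
    gene_counts = {}
    for i, (k, y) in enumerate(zip(ks, ys)):
        sid = f"e{i}"
        evidence.append(
            MetaboliteEvidence(
                sample_id=sid,
                chemical_code="GLB",
                status="degraded" if y else "not_degraded",
                evidence_kind="intermediate_detected" if y else "substrate_depleted",
            )
        )
        gene_counts[(sid, "GLB")] = int(k)
    return evidence, gene_counts, ks, ys


def tail_conditional(curve: Mapping[int, float], ks: Sequence[int]) -> np.ndarray:
    """The planted tail-conditional P(degraded | gene count >= k) induced by
    a per-count curve and an observed gene-count sample, for k = 0..max(ks).

    This is the population quantity that :func:`degnet.metaweb.fit_confidence`
    estimates; recovery tests compare against it.
    """
    ks = np.asarray(ks)
    probs = np.array([curve_value(curve, int(k)) for k in ks])
    out = np.empty(int(ks.max()) + 1)
    for k in range(len(out)):
        mask = ks >= k
        out[k] = probs[mask].mean()
    return out


def generate_mass_features(
    n_features: int,
    groups: Sequence[str],
    n_signal: int,
    effect_sd: float = 5.0,
    dropout: float = 0.1,
    seed: int = 0,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """LC-MS-like feature x replicate matrix with planted group shifts.

    ``n_signal`` features get a between-group mean shift of ``effect_sd``
    within-group standard deviations and full within-group presence; the
    remaining features are null with random dropout (zeros). Returns
    (feature_ids, matrix, is_signal).
    """
    if n_signal > n_features:
        raise ValidationError("n_signal must be <= n_features")
    groups = list(groups)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValidationError("exactly two groups are required")
    for g in labels:
        if groups.count(g) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 replicates")
    rng = np.random.default_rng(seed)
    n_reps = len(groups)
    is_signal = np.zeros(n_features, dtype=bool)
    is_signal[rng.permutation(n_features)[:n_signal]] = True
    mu = rng.uniform(8.0, 12.0, size=n_features)
    matrix = mu[:, None] + rng.normal(0.0, 1.0, size=(n_features, n_reps))
    shift_cols = np.array([g == labels[1] for g in groups])
    matrix[np.ix_(is_signal, shift_cols)] += effect_sd
    matrix = np.clip(matrix, 0.1, None)  # detected everywhere before dropout
    null_rows = ~is_signal
    drop = rng.random(size=(n_features, n_reps)) < dropout
    drop[is_signal, :] = False
    matrix[drop] = 0.0
    assert null_rows.sum() + is_signal.sum() == n_features
    feature_ids = [f"m{i + 1:05d}" for i in range(n_features)]
    return feature_ids, matrix, is_signal
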