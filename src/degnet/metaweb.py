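"""Weighted substrate->product degradation networks and the calibrated
confidence that a chemical is actually degraded.

A :class:`MetaNetwork` has one directed edge per catalog reaction whose gene
family is present in at least one sample; the edge carries, per sample, the
family's relative abundance (percent of total genes). The
:class:`ConfidenceModel` maps the number of supporting catabolic genes to a
probability of degradation, anchored to metabolite-evidence outcomes: for
each chemical the empirical frequency of "degraded" among evidence rows with
gene count >= k is Laplace-smoothed and then made non-decreasing in k by
pool-adjacent-violators. Chemicals without evidence inherit a model pooled
over all chemicals.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

from degnet.abundance import CatabolicProfile
from degnet.errors import ValidationError
from degnet.io_catalog import MetaboliteEvidence, Reaction

DEFAULT_THRESHOLD = 0.90

EdgeKey = tuple[str, str, str]  # (substrate_code, product_code, family_id)


@dataclass
class MetaNetwork:
    samples: list[str]
    edges: dict[EdgeKey, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, weights in self.edges.items():
            if any(w < 0 for w in weights.values()):
                raise ValidationError(f"edge {key}: negative weight")

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for sub, prod, _ in self.edges:
            out.add(sub)
            out.add(prod)
        return out

    def weight(self, key: EdgeKey, sample_id: str) -> float:
        return self.edges.get(key, {}).get(sample_id, 0.0)

    def sample_edges(self, sample_id: str) -> list[EdgeKey]:
        """Edges with strictly positive weight in one sample."""
        return [k for k, w in self.edges.items() if w.get(sample_id, 0.0) > 0.0]

    def substrates(self, sample_id: str | None = None) -> set[str]:
        """Chemicals with at least one positively weighted outgoing edge."""
        if sample_id is None:
            return {
                sub for (sub, _, _), w in self.edges.items() if any(v > 0 for v in w.values())
            }
        return {sub for (sub, _, _) in self.sample_edges(sample_id)}


def build_network(
    profiles: Sequence[CatabolicProfile],
    reactions: Sequence[Reaction],
    families: Iterable[str] | None = None,
) -> MetaNetwork:
    """Connect substrates to products for every reaction whose family was
    detected (family percent > 0) in at least one sample.

    Each edge's per-sample weight is the family's full relative abundance in
    that sample; a family feeding several reactions contributes its full
    percentage to each of its edges (one line per reaction, scaled by gene
    abundance).
    """
    if families is not None:
        known = set(families)
        for p in profiles:
            for fam in p.family_counts:
                if fam not in known:
                    raise ValidationError(
                        f"profile {p.sample_id!r} references family {fam!r} absent from the catalog"
                    )
    samples = [p.sample_id for p in profiles]
    if len(set(samples)) != len(samples):
        raise ValidationError("duplicate sample ids among profiles")
    percents = {p.sample_id: p.family_percent for p in profiles}
    edges: dict[EdgeKey, dict[str, float]] = {}
    for rxn in reactions:
        weights = {
            s: percents[s].get(rxn.family_id, 0.0) for s in samples
        }
        if any(w > 0.0 for w in weights.values()):
            edges[(rxn.substrate_code, rxn.product_code, rxn.family_id)] = weights
    return MetaNetwork(samples=samples, edges=edges)


# ---------------------------------------------------------------------------
# confidence model
# ---------------------------------------------------------------------------


@dataclass
class ConfidenceCurve:
    """Non-decreasing step function conf(k) over gene counts k = 0, 1, ...

    ``raw`` keeps the pre-monotonization smoothed frequencies so that the
    construction is auditable and an alternative formula can be swapped in.
    """

    conf: np.ndarray  # conf[k] for k = 0..K; conf(k > K) = conf[K]
    raw: np.ndarray
    support: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.conf) < -1e-12):
            raise ValidationError("confidence curve must be non-decreasing")
        if np.any((self.conf < 0) | (self.conf > 1)):
            raise ValidationError("confidence values must lie in [0, 1]")

    def __call__(self, k: int) -> float:
        if k < 0:
            raise ValidationError("gene count must be >= 0")
        return float(self.conf[min(k, len(self.conf) - 1)])


@dataclass
class ConfidenceModel:
    curves: dict[str, ConfidenceCurve]
    global_curve: ConfidenceCurve
    threshold: float = DEFAULT_THRESHOLD

    def curve_for(self, chemical_code: str) -> ConfidenceCurve:
        return self.curves.get(chemical_code, self.global_curve)

    def confidence(self, chemical_code: str, k: int) -> float:
        return self.curve_for(chemical_code)(k)


def _fit_curve(ks: np.ndarray, ys: np.ndarray) -> ConfidenceCurve:
    max_k = int(ks.max())
    raw = np.empty(max_k + 1)
    for k in range(max_k + 1):
        mask = ks >= k
        n = int(mask.sum())
        raw[k] = (ys[mask].sum() + 1.0) / (n + 2.0)  # add-one smoothing
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
    conf = iso.fit_transform(np.arange(max_k + 1), raw)
    return ConfidenceCurve(conf=np.asarray(conf, dtype=float), raw=raw, support=len(ks))


def fit_confidence(
    evidence: Sequence[MetaboliteEvidence],
    gene_counts: Mapping[tuple[str, str], int],
    catalog_codes: Iterable[str] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> ConfidenceModel:
    """Calibrate per-chemical degradation confidence on metabolite evidence.

    Every evidence row must have a gene count under ``(sample_id,
    chemical_code)`` in ``gene_counts``.
    """
    if not evidence:
        raise ValidationError("cannot fit a confidence model on empty evidence")
    if catalog_codes is not None:
        known = set(catalog_codes)
        for e in evidence:
            if e.chemical_code not in known:
                raise ValidationError(
                    f"evidence chemical {e.chemical_code!r} absent from catalog"
                )
    rows_by_chem: dict[str, list[tuple[int, int]]] = {}
    all_rows: list[tuple[int, int]] = []
    for e in evidence:
        key = (e.sample_id, e.chemical_code)
        if key not in gene_counts:
            raise ValidationError(f"no gene count for evidence row {key}")
        pair = (gene_counts[key], 1 if e.status == "degraded" else 0)
        rows_by_chem.setdefault(e.chemical_code, []).append(pair)
        all_rows.append(pair)

    def fit(rows: list[tuple[int, int]]) -> ConfidenceCurve:
        ks = np.array([r[0] for r in rows])
        ys = np.array([r[1] for r in rows], dtype=float)
        return _fit_curve(ks, ys)

    curves = {chem: fit(rows) for chem, rows in rows_by_chem.items()}
    return ConfidenceModel(curves=curves, global_curve=fit(all_rows), threshold=threshold)


# ---------------------------------------------------------------------------
# degradable chemicals
# ---------------------------------------------------------------------------


@dataclass
class DegradableSet:
    per_sample: dict[str, set[str]]
    threshold: float

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for s in self.per_sample.values():
            out |= s
        return out


def degradable(
    net: MetaNetwork,
    model: ConfidenceModel,
    gene_counts: Mapping[tuple[str, str], int],
    threshold: float = DEFAULT_THRESHOLD,
) -> DegradableSet:
    """Chemicals possibly degraded per sample at the given confidence level.

    A chemical qualifies in a sample iff it has at least one outgoing edge
    with positive weight there (the substrate is consumed) and its
    confidence at the sample's gene count meets the threshold (inclusive,
    "at least").
    """
    if not (0.0 < threshold <= 1.0):
        raise ValidationError("threshold must lie in (0, 1]")
    per_sample: dict[str, set[str]] = {}
    for s in net.samples:
        chems = set()
        for c in net.substrates(s):
            k = gene_counts.get((s, c), 0)
            if model.confidence(c, k) >= threshold:
                chems.add(c)
        per_sample[s] = chems
    return DegradableSet(per_sample=per_sample, threshold=threshold)


def reachable_products(
    net: MetaNetwork, sample_id: str, sources: Iterable[str]
) -> set[str]:
    """Chemicals reachable by directed traversal over edges with positive
    weight in the sample; a source is included only if it is itself reached
    through at least one edge."""
    nodes = net.nodes
    sources = set(sources)
    unknown = sources - nodes
    if unknown:
        raise ValidationError(f"unknown source code(s): {', '.join(sorted(unknown))}")
    adjacency: dict[str, set[str]] = {}
    for sub, prod, _ in net.sample_edges(sample_id):
        adjacency.setdefault(sub, set()).add(prod)
    reached: set[str] = set()
    queue = deque(sources)
    while queue:
        node = queue.popleft()
        for nxt in adjacency.get(node, ()):
            if nxt not in reached:
                reached.add(nxt)
                queue.append(nxt)
    return reached


# ---------------------------------------------------------------------------
# network comparison
# ---------------------------------------------------------------------------


@dataclass
class NetworkComparison:
    shared_edges: set[EdgeKey]
    only_in_a: set[EdgeKey]
    only_in_b: set[EdgeKey]
    families_only_in_a: set[str]
    families_only_in_b: set[str]
    family_weight_ratio: dict[str, float]  # mean weight in a / mean weight in b
    n_substrates_a: int
    n_substrates_b: int


def _family_mean_weight(net: MetaNetwork, family: str) -> float:
    weights = [
        w
        for (sub, prod, fam), per_sample in net.edges.items()
        if fam == family
        for w in per_sample.values()
    ]
    return float(np.mean(weights)) if weights else 0.0


def compare_networks(a: MetaNetwork, b: MetaNetwork) -> NetworkComparison:
    edges_a, edges_b = set(a.edges), set(b.edges)
    fams_a = {fam for _, _, fam in edges_a}
    fams_b = {fam for _, _, fam in edges_b}
    ratio = {}
    for fam in fams_a & fams_b:
        denom = _family_mean_weight(b, fam)
        num = _family_mean_weight(a, fam)
        ratio[fam] = num / denom if denom > 0 else float("inf")
    return NetworkComparison(
        shared_edges=edges_a & edges_b,
        only_in_a=edges_a - edges_b,
        only_in_b=edges_b - edges_a,
        families_only_in_a=fams_a - fams_b,
        families_only_in_b=fams_b - fams_a,
        family_weight_ratio=ratio,
        n_substrates_a=len(a.substrates()),
        n_substrates_b=len(b.substrates()),
    )


def gene_counts_by_chemical(
    annotations: Mapping[str, "SampleAnnotation"],
    reactions: Sequence[Reaction],
) -> dict[tuple[str, str], int]:
    """Count, per (sample, substrate chemical), the screened catabolic genes
    belonging to families that take the chemical as substrate."""
    fams_for_chem: dict[str, set[str]] = {}
    for r in reactions:
        fams_for_chem.setdefault(r.substrate_code, set()).add(r.family_id)
    out: dict[tuple[str, str], int] = {}
    for sample_id, ann in annotations.items():
        per_family: dict[str, int] = {}
        for h in ann.hits:
            per_family[h.family_id] = per_family.get(h.family_id, 0) + h.count
        for chem, fams in fams_for_chem.items():
            out[(sample_id, chem)] = sum(per_family.get(f, 0) for f in fams)
    return out
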