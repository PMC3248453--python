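"""End-to-end orchestration: genome -> detected elements -> domain hits ->
classification -> families -> most successful element -> census row ->
concatenated pol tree."""

from __future__ import annotations

from dataclasses import dataclass, field

from . import seedbank
from .census import CensusRow, genome_summary
from .detect import DetectorParams, ElementRecord, find_ltr_pairs, merge_predictions
from .domains import (DomainHit, ElementClassification, default_profiles,
                      scan_element, six_frame_translate, classify_element)
from .families import Family, MostSuccessfulElement, greedy_cluster, select_most_successful
from .phylo import MSA, Tree, concatenate, distance_matrix, nj_tree, \
    progressive_align, root_with_outgroup, trim_columns

__all__ = [
    "AnnotatedElement",
    "annotate_genome",
    "genome_census",
    "extract_domain_proteins",
    "build_pol_tree",
    "domain_coinheritance_experiment",
    "superfamily_component_experiment",
    "POL_TREE_DOMAIN_ORDER",
]

POL_TREE_DOMAIN_ORDER = ("RT", "INT", "RH", "AP")


@dataclass
class AnnotatedElement:
    record: ElementRecord
    sequence: str
    hits: list[DomainHit] = field(default_factory=list)
    classification: ElementClassification | None = None

    @property
    def element_id(self) -> str:
        return self.record.element_id


def annotate_genome(genome: dict[str, str],
                    detector_params: DetectorParams = DetectorParams(),
                    profiles: dict | None = None,
                    extra_candidate_sets: list[list] | None = None,
                    ) -> list[AnnotatedElement]:
    """Detect, merge, scan and classify every element of one genome."""
    if profiles is None:
        profiles = default_profiles()
    candidates = find_ltr_pairs(genome, detector_params)
    sets: list[list] = [candidates]
    if extra_candidate_sets:
        sets.extend(extra_candidate_sets)
    merged = merge_predictions(sets, detector_params.dedup_overlap_threshold)
    out: list[AnnotatedElement] = []
    for rec in merged:
        seq = genome[rec.contig][rec.start:rec.end]
        hits = scan_element(seq, profiles, element_id=rec.element_id)
        out.append(AnnotatedElement(
            record=rec, sequence=seq, hits=hits,
            classification=classify_element(hits)))
    return out


def genome_census(elements: list[AnnotatedElement],
                  genome_id: str,
                  family_threshold: float = 0.8,
                  phylum: str = "",
                  order: str = "",
                  ) -> tuple[CensusRow, list[Family], MostSuccessfulElement | None]:
    """Families, most-successful element and census row for one annotated
    genome."""
    seqs = {e.element_id: e.sequence for e in elements}
    families = greedy_cluster(seqs, threshold=family_threshold,
                              genome_id=genome_id)
    annotations = {e.element_id: {"classification": e.classification,
                                  "hits": e.hits}
                   for e in elements}
    lengths = {e.element_id: len(e.sequence) for e in elements}
    mse = select_most_successful(families, annotations, lengths)
    mse_sf = None
    if mse is not None:
        mse_sf = annotations[mse.element_id]["classification"].superfamily
    row = genome_summary(
        {e.element_id: e.classification for e in elements},
        families, genome_id, phylum=phylum, order=order,
        mse_superfamily=mse_sf)
    return row, families, mse


def extract_domain_proteins(element: AnnotatedElement) -> dict[str, str]:
    """Best-scoring protein sequence per pol-region base domain (RT, INT,
    RH, AP), sliced out of the hit's frame translation."""
    frames = {fr.frame: fr for fr in six_frame_translate(element.sequence)}
    best: dict[str, DomainHit] = {}
    for h in element.hits:
        base = h.domain.split("_")[0]
        if base not in POL_TREE_DOMAIN_ORDER:
            continue
        if base not in best or h.score > best[base].score:
            best[base] = h
    return {base: frames[h.frame].protein[h.aa_start:h.aa_end]
            for base, h in best.items()}


def build_pol_tree(domain_proteins: dict[str, dict[str, str]],
                   outgroup: dict[str, dict[str, str]] | None = None,
                   trim_gap_fraction: float = 0.5,
                   ) -> tuple[Tree, MSA]:
    """Concatenated-domain tree over most-successful elements.

    ``domain_proteins`` maps taxon -> {domain base name -> protein}. When
    ``outgroup`` is None the packaged Bel/Pao-like stand-ins are added and
    used for rooting. Returns (rooted tree, concatenated trimmed MSA).
    """
    if outgroup is None:
        outgroup = seedbank.outgroup_domains()
    taxa = dict(domain_proteins)
    taxa.update(outgroup)
    blocks: list[MSA] = []
    for base in POL_TREE_DOMAIN_ORDER:
        seqs = {t: doms[base] for t, doms in taxa.items() if base in doms}
        if len(seqs) < 2:
            continue
        blocks.append(trim_columns(progressive_align(seqs), trim_gap_fraction))
    if not blocks:
        raise ValueError("no domain block has two or more sequences")
    concat = concatenate(blocks)
    dm = distance_matrix(concat, model="poisson")
    tree = nj_tree(dm)
    out_labels = [t for t in outgroup if t in concat.taxa]
    if out_labels and len(out_labels) < len(concat.taxa):
        tree = root_with_outgroup(tree, out_labels)
    return tree, concat


def superfamily_component_experiment(
    seed: int = 1,
    copies_per_superfamily: int = 6,
    divergence: float = 0.02,
    threshold_fraction: float = 0.78,
) -> dict[str, list[list[str]]]:
    """Similarity-graph components of RT and RH domain sets drawn from one
    Copia and one Gypsy population.

    Edge threshold is ``threshold_fraction`` of the median self-alignment
    score, i.e. a normalised-score cutoff, which keeps the operating point
    stable across template draws. With intra-population divergence of a few
    percent both domain sets split into exactly two components, one per
    superfamily.
    """
    import numpy as np

    from .detect import ElementRecord
    from .domains import scan_element
    from .phylo import pairwise_score, similarity_components
    from .simulate import DegradationParams, default_templates, degrade_element

    templates = default_templates(seed)
    rng = np.random.default_rng(seed + 1000)
    sets: dict[str, dict[str, str]] = {"RT": {}, "RH": {}}
    params = DegradationParams(point_rate=divergence)
    for t in templates:
        for i in range(copies_per_superfamily):
            label = f"{t.superfamily}_{i}"
            seq, _ = degrade_element(t, params, rng)
            elem = AnnotatedElement(
                record=ElementRecord("c", 0, len(seq), element_id=label),
                sequence=seq,
                hits=scan_element(seq, element_id=label))
            doms = extract_domain_proteins(elem)
            for d in sets:
                if d in doms:
                    sets[d][label] = doms[d]
    out = {}
    for d, seqs in sets.items():
        self_scores = [pairwise_score(s, s) for s in seqs.values()]
        thr = threshold_fraction * float(np.median(self_scores))
        out[d] = similarity_components(seqs, thr)
    return out


def domain_coinheritance_experiment(
    seed: int = 11,
    n_copies: int = 18,
    base_rate: float = 0.10,
    ap_multiplier: float = 25.0,
    template_seed: int = 7,
    min_age: float = 0.3,
    model: str = "poisson",
) -> dict[str, float]:
    """Contrast the co-inherited RT/RH pair against the fast-evolving
    protease.

    A population of copies of one Gypsy template is aged (per-copy age in
    U(min_age, 1) scales the substitution rate) while the aspartic
    protease mutates at a rate high enough to saturate every copy.
    Pairwise protein distance matrices are built for RT, RH and AP; the
    Mantel correlation between the RT and RH matrices measures the shared
    age signal those two domains retain, and the RT-AP correlation
    measures how much of it survives in the protease. The saturating
    condition matters: at mild rate elevation the protease keeps the age
    signal and all three matrices stay equally correlated; only when every
    copy's protease is mutated to saturation does its distance matrix
    decouple from the age structure, which is the testable form of the
    observation that RT and RH cluster almost identically while the
    protease does not.
    """
    from Bio.Seq import Seq as _Seq

    import numpy as np

    from .phylo import mantel_r
    from .simulate import DegradationParams, build_element_template, degrade_element

    template = build_element_template("Gypsy", True, 300, rng_seed=template_seed)
    params = DegradationParams(point_rate=base_rate,
                               domain_rate_multipliers={"AP": ap_multiplier})
    rng = np.random.default_rng(seed)
    taxa: list[str] = []
    rows: dict[str, list[str]] = {"RT": [], "RH": [], "AP": []}
    for i in range(n_copies):
        age = min_age + (1.0 - min_age) * rng.random()
        seq, _ = degrade_element(template, params, rng, rate_scale=age)
        taxa.append(f"copy{i}")
        for domain, s, e in template.layout_in_element_coords():
            if domain in rows:
                rows[domain].append(
                    str(_Seq(seq[s:e]).translate()).replace("*", "X"))
    dms = {d: distance_matrix(MSA(list(taxa), r), model=model)
           for d, r in rows.items()}
    return {"mantel_rt_rh": mantel_r(dms["RT"], dms["RH"]),
            "mantel_rt_ap": mantel_r(dms["RT"], dms["AP"])}
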